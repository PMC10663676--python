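"""Capsid protein stoichiometry and the 60-subunit assembly/mass model.

Molar amounts of the viral-protein (VP) isoforms are obtained from
214-nm peak areas divided by sequence-derived molar extinction
coefficients; the icosahedral particle is modelled as 60 subunits drawn
independently from the molar fractions (multinomial incorporation, no
cooperativity), which yields closed-form mass moments and an exhaustive
composition search for a target particle mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

__all__ = [
    "PEPTIDE_BOND_E214",
    "SIDE_CHAIN_E214",
    "PROLINE_NTERMINAL_E214",
    "VPSpecies",
    "StoichiometryResult",
    "CapsidEnsembleSpec",
    "CompositionCandidate",
    "AssemblyMoments",
    "molar_extinction_214",
    "average_sequence_mass",
    "stoichiometry_from_areas",
    "expected_counts_60",
    "theoretical_particle_mass",
    "assembly_mass_moments",
    "sample_assembly",
    "sample_assembly_arrays",
    "compositions_for_mass",
    "mass_ppm_error",
    "round_half_away",
    "read_vp_fasta",
    "stoichiometry_to_csv",
    "candidates_to_csv",
]

N_SUBUNITS = 60

# 214-nm molar absorptivities, 1/(M cm): uniform peptide-bond term plus
# side-chain contributions (Kuipers & Gruppen, J Agric Food Chem 2007,
# 55:5445).  Proline engaged in a peptide bond carries its own bond
# coefficient; an N-terminal proline contributes only its residue value.
# N-terminal acetylation is treated as zero additional absorbance.
PEPTIDE_BOND_E214 = 923.0
PROLINE_NTERMINAL_E214 = 30.0
SIDE_CHAIN_E214 = {
    "A": 0.0,
    "C": 225.0,
    "D": 0.0,
    "E": 0.0,
    "F": 5200.0,
    "G": 0.0,
    "H": 5125.0,
    "I": 0.0,
    "K": 0.0,
    "L": 0.0,
    "M": 980.0,
    "N": 136.0,
    "P": 2675.0,
    "Q": 142.0,
    "R": 102.0,
    "S": 0.0,
    "T": 0.0,
    "V": 0.0,
    "W": 29050.0,
    "Y": 5375.0,
}

_VP3_LIKE_PREFIX = "VP3"


def molar_extinction_214(sequence: str) -> float:
    """Molar extinction coefficient at 214 nm from a one-letter sequence.

    epsilon = (L - 1) * peptide-bond coefficient + per-residue side-chain
    contributions.  An empty sequence has no residues and no bonds and
    returns 0.

    Raises
    ------
    ValueError
        If the sequence contains a character outside the 20 standard
        one-letter codes (the message names the offending character and
        its 1-based position).
    """
    if not sequence:
        return 0.0
    eps = PEPTIDE_BOND_E214 * (len(sequence) - 1)
    for i, aa in enumerate(sequence):
        try:
            side = SIDE_CHAIN_E214[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at position {i + 1}"
            ) from None
        if aa == "P" and i == 0:
            side = PROLINE_NTERMINAL_E214
        eps += side
    return eps


def average_sequence_mass(sequence: str) -> float:
    """Average (isotope-abundance-weighted) mass of a protein chain in Da."""
    return float(molecular_weight(sequence, seq_type="protein"))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.315 -> 0.32 at two decimals)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def mass_ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * abs(observed - theoretical) / theoretical


@dataclass(frozen=True)
class VPSpecies:
    """One capsid-protein isoform.

    ``monomer_mass`` may come from the sequence or be overridden with a
    deconvoluted experimental mass; when a sequence is present the two
    are compared (not forced) via :meth:`mass_matches_sequence`.
    """

    name: str
    monomer_mass: float
    epsilon214: float
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise ValueError(f"{self.name}: monomer_mass must be positive")
        if self.sequence is not None and len(self.sequence) >= 2:
            if self.epsilon214 <= 0:
                raise ValueError(f"{self.name}: epsilon214 must be positive")

    @classmethod
    def from_sequence(
        cls, name: str, sequence: str, monomer_mass: float | None = None
    ) -> "VPSpecies":
        if monomer_mass is None:
            monomer_mass = average_sequence_mass(sequence)
        return cls(
            name=name,
            monomer_mass=monomer_mass,
            epsilon214=molar_extinction_214(sequence),
            sequence=sequence,
        )

    def mass_matches_sequence(self, tol_ppm: float = 25.0) -> bool:
        """Whether monomer_mass agrees with the sequence mass within tol_ppm."""
        if self.sequence is None:
            return True
        seq_mass = average_sequence_mass(self.sequence)
        return mass_ppm_error(self.monomer_mass, seq_mass) <= tol_ppm


@dataclass(frozen=True)
class StoichiometryResult:
    """Per-species molar stoichiometry derived from peak areas."""

    names: tuple[str, ...]
    ratios: np.ndarray  # molar amounts normalized to VP1 = 1
    fractions: np.ndarray  # molar fractions, sum 1
    expected_counts_60: np.ndarray  # 60 * fractions
    vp12_over_vp3total: float

    def vp12_over_vp3total_rounded(self, ndigits: int = 2) -> float:
        return round_half_away(self.vp12_over_vp3total, ndigits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.names,
                "ratio_vs_vp1": self.ratios,
                "molar_fraction": self.fractions,
                "expected_count_60mer": self.expected_counts_60,
            }
        )


def _vp3_mask(names: Sequence[str]) -> np.ndarray:
    return np.array([n.upper().startswith(_VP3_LIKE_PREFIX) for n in names])


def stoichiometry_from_areas(
    areas: Sequence[float],
    epsilons: Sequence[float],
    names: Sequence[str] = ("VP1", "VP2", "VP3", "VP3clip"),
) -> StoichiometryResult:
    """Convert 214-nm peak areas into molar stoichiometry.

    Molar amount n_i is proportional to area_i / epsilon_i.  Ratios are
    normalized to VP1 = 1; (VP1+VP2)/VP3_total uses every species whose
    name starts with "VP3" in the denominator and the rest in the
    numerator.
    """
    areas = np.asarray(areas, dtype=float)
    eps = np.asarray(epsilons, dtype=float)
    if areas.shape != eps.shape or areas.ndim != 1:
        raise ValueError("areas and epsilons must be 1-D and equal length")
    if len(names) != areas.size:
        raise ValueError("names must match areas length")
    if np.any(areas < 0):
        raise ValueError("peak areas must be non-negative")
    if np.any(eps <= 0):
        raise ValueError("extinction coefficients must be positive")

    amounts = areas / eps
    names = tuple(names)
    try:
        i_vp1 = names.index("VP1")
    except ValueError:
        i_vp1 = 0
    if amounts[i_vp1] <= 0:
        raise ValueError("VP1 molar amount is zero; cannot normalize ratios")

    ratios = amounts / amounts[i_vp1]
    fractions = amounts / amounts.sum()
    vp3 = _vp3_mask(names)
    denom = amounts[vp3].sum()
    if denom <= 0:
        raise ValueError("VP3_total is zero; (VP1+VP2)/VP3_total undefined")
    vp12 = amounts[~vp3].sum()
    return StoichiometryResult(
        names=names,
        ratios=ratios,
        fractions=fractions,
        expected_counts_60=N_SUBUNITS * fractions,
        vp12_over_vp3total=float(vp12 / denom),
    )


def expected_counts_60(fractions: Sequence[float]) -> np.ndarray:
    """Expected per-species copies in a 60-mer: 60 * fraction."""
    p = np.asarray(fractions, dtype=float)
    if np.any(p < 0):
        raise ValueError("fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    return N_SUBUNITS * p


@dataclass(frozen=True)
class CapsidEnsembleSpec:
    """Molar fractions of VP species plus genome mass for a 60-mer ensemble."""

    species: tuple[VPSpecies, ...]
    fractions: np.ndarray
    genome_mass: float = 0.0
    n_subunits: int = N_SUBUNITS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fractions", np.asarray(self.fractions, dtype=float)
        )
        if len(self.species) != self.fractions.size:
            raise ValueError("species and fractions length mismatch")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.genome_mass < 0:
            raise ValueError("genome_mass must be non-negative")
        if self.n_subunits != N_SUBUNITS:
            raise ValueError("the assembly model is fixed at 60 subunits")

    @classmethod
    def from_ratios(
        cls,
        species: Iterable[VPSpecies],
        ratios: Sequence[float],
        genome_mass: float = 0.0,
    ) -> "CapsidEnsembleSpec":
        r = np.asarray(ratios, dtype=float)
        return cls(tuple(species), r / r.sum(), genome_mass)

    @property
    def monomer_masses(self) -> np.ndarray:
        return np.array([s.monomer_mass for s in self.species])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)


@dataclass(frozen=True)
class CompositionCandidate:
    """An integer 60-mer composition with its particle mass."""

    counts: tuple[int, ...]
    mass: float
    deviation: float

    def __post_init__(self) -> None:
        if sum(self.counts) != N_SUBUNITS:
            raise ValueError("counts must sum to 60")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class AssemblyMoments:
    mean: float
    sd: float
    fwhm: float


def theoretical_particle_mass(spec: CapsidEnsembleSpec) -> float:
    """Mean particle mass: 60 * sum(p_i * m_i) + genome mass (Da)."""
    return float(
        spec.n_subunits * np.dot(spec.fractions, spec.monomer_masses)
        + spec.genome_mass
    )


_FWHM_PER_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))


def assembly_mass_moments(spec: CapsidEnsembleSpec) -> AssemblyMoments:
    """Closed-form mass moments of the multinomial 60-mer ensemble.

    The per-draw mass variance is E[m^2] - E[m]^2 over the molar
    fractions; 60 independent draws multiply it by 60.  The FWHM is the
    Gaussian-equivalent 2*sqrt(2 ln 2)*sd.
    """
    m = spec.monomer_masses
    p = spec.fractions
    mean_m = float(np.dot(p, m))
    var_single = float(np.dot(p, m**2) - mean_m**2)
    var_single = max(var_single, 0.0)  # guard rounding on degenerate specs
    sd = math.sqrt(spec.n_subunits * var_single)
    return AssemblyMoments(
        mean=theoretical_particle_mass(spec),
        sd=sd,
        fwhm=_FWHM_PER_SD * sd,
    )


def sample_assembly_arrays(
    spec: CapsidEnsembleSpec,
    n_particles: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial samples as arrays: (counts [n x k], masses [n])."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = rng.multinomial(spec.n_subunits, spec.fractions, size=n_particles)
    masses = counts @ spec.monomer_masses + spec.genome_mass
    return counts, masses


def sample_assembly(
    spec: CapsidEnsembleSpec,
    n_particles: int,
    seed: int | np.random.Generator = 0,
) -> list[CompositionCandidate]:
    """Monte-Carlo particles from the multinomial incorporation model.

    ``deviation`` is reported relative to the ensemble mean mass.
    """
    counts, masses = sample_assembly_arrays(spec, n_particles, seed)
    mean = theoretical_particle_mass(spec)
    return [
        CompositionCandidate(tuple(int(x) for x in c), float(m), float(m - mean))
        for c, m in zip(counts, masses)
    ]


def _weak_compositions(total: int, parts: int):
    """All non-negative integer tuples of length `parts` summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _weak_compositions(total - head, parts - 1):
            yield (head,) + rest


def compositions_for_mass(
    target_mass: float,
    tolerance: float,
    spec: CapsidEnsembleSpec,
) -> list[CompositionCandidate]:
    """All integer 60-mer compositions whose mass is within ``tolerance``.

    Exhaustive enumeration over the weak compositions of 60 into
    len(species) parts (<= 39,711 tuples for four species), sorted by
    absolute deviation then lexicographic counts.  An empty list is a
    valid result.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    m = spec.monomer_masses
    out: list[CompositionCandidate] = []
    for counts in _weak_compositions(spec.n_subunits, len(m)):
        mass = float(np.dot(counts, m) + spec.genome_mass)
        dev = mass - target_mass
        if abs(dev) <= tolerance:
            out.append(CompositionCandidate(counts, mass, dev))
    # round the sort key so float summation order cannot scramble exact ties
    out.sort(key=lambda c: (round(abs(c.deviation), 6), c.counts))
    return out


def read_vp_fasta(path) -> list[VPSpecies]:
    """Read VP species from FASTA; the first word of the header is the name."""
    species = []
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id.split("|")[0]
        species.append(VPSpecies.from_sequence(name, str(record.seq).upper()))
    if not species:
        raise ValueError(f"no sequences found in {path}")
    return species


def stoichiometry_to_csv(result: StoichiometryResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def candidates_to_csv(candidates: list[CompositionCandidate], names, path) -> None:
    rows = [
        {
            **{f"n_{name}": c for name, c in zip(names, cand.counts)},
            "mass_da": cand.mass,
            "deviation_da": cand.deviation,
        }
        for cand in candidates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
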