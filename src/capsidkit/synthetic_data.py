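"""Seeded generators for every input the analysis pipeline consumes.

Five default scenarios cover a two-cycle fractionation design: a bulk
preparation that
is a 50:50 mixture of two full-particle ensembles differing only in VP
stoichiometry (low-density/high-density pair), plus two homogeneous
single-residue variants.  Each generator draws from the statistical
model the downstream analysis assumes (multinomial 60-mer incorporation,
Gaussian detector noise, surface-area charge scaling) and every writer
emits a ground-truth sidecar so recovery tests are self-contained.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import capsid_model as cm
from .capsid_model import CapsidEnsembleSpec, VPSpecies
from .cdms_proc import PROTON_MASS
from .cge_quant import Electropherogram

__all__ = [
    "SSDNA_RESIDUE_MASS",
    "DEFAULT_GENOME_LENGTH",
    "DEFAULT_MOIS",
    "DEFAULT_MIGRATION",
    "default_windows",
    "ScenarioSpec",
    "CdmsSimulation",
    "default_vp_species",
    "default_scenarios",
    "make_cge_trace",
    "make_cdms_events",
    "make_density_readouts",
    "make_potency_table",
    "make_thermal_scan",
    "write_scenario",
    "write_potency_table",
]

# average ssDNA nucleotide residue mass (Da); genome mass = length * this
SSDNA_RESIDUE_MASS = 308.97
DEFAULT_GENOME_LENGTH = 2520  # nt, stand-in for the unpublished transgene cassette

DEFAULT_MOIS = (1.0e2, 5.0e2, 1.0e3, 2.5e3, 5.0e3)

# apex migration times (min); absolute times are instrument-specific, the
# order (VP3clip, VP3, VP2, VP1) is what matters downstream
DEFAULT_MIGRATION = {"VP3clip": 23.8, "VP3": 24.5, "VP2": 27.0, "VP1": 29.0}
CGE_PEAK_SIGMA = 0.08  # min

GDH_MASS = 336_000.0  # Da, hexameric calibrant
GDH_CHARGES = np.arange(38, 49)

_FWHM_PER_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))

# residue alphabet with typical globular-protein frequencies, used to
# synthesize stand-in VP sequences (real sequences are not bundled)
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [8.3, 1.4, 5.4, 6.2, 3.9, 7.3, 2.3, 5.3, 5.8, 9.0,
     2.4, 4.3, 5.1, 4.0, 5.1, 6.9, 5.6, 6.6, 1.4, 3.2]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_VP1_LENGTH = 735
_VP2_OFFSET = 137
_VP3_OFFSET = 202
_VP3CLIP_OFFSET = 210  # eight residues shorter than VP3

_SPECIES_SEED = 20231024  # fixed: species are stable package constants


def default_windows(half_width: float = 0.3) -> dict[str, tuple[float, float]]:
    """Species-assignment migration windows around the default apexes."""
    return {
        name: (pos - half_width, pos + half_width)
        for name, pos in DEFAULT_MIGRATION.items()
    }


def default_vp_species() -> tuple[VPSpecies, ...]:
    """Deterministic stand-in VP1/VP2/VP3/VP3clip species.

    One synthetic VP1-length chain is drawn once from a fixed internal
    seed; VP2, VP3 and VP3clip are its N-terminal truncations, mirroring
    the shared C-terminal region of the real isoforms.
    """
    rng = np.random.default_rng(_SPECIES_SEED)
    vp1_seq = "".join(rng.choice(_AA, size=_VP1_LENGTH, p=_AA_FREQ))
    return (
        VPSpecies.from_sequence("VP1", vp1_seq),
        VPSpecies.from_sequence("VP2", vp1_seq[_VP2_OFFSET:]),
        VPSpecies.from_sequence("VP3", vp1_seq[_VP3_OFFSET:]),
        VPSpecies.from_sequence("VP3clip", vp1_seq[_VP3CLIP_OFFSET:]),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth for one simulated preparation.

    ``components`` with ``weights`` describe a particle-level mixture
    (the bulk preparation mixes the low- and high-density ensembles);
    homogeneous scenarios have a single component.
    """

    name: str
    components: tuple[CapsidEnsembleSpec, ...]
    weights: tuple[float, ...]
    buoyant_densities: tuple[float, ...]  # g/cm^3, one per component
    potency_effect: dict[float, float]  # MOI -> multiplier vs bulk
    tm: float  # deg C
    cdms_fwhm_target: float  # Da, total mass-histogram FWHM to emulate
    cge_noise_sd: float = 0.001  # fraction of tallest peak
    density_sd: float = 0.001  # g/cm^3
    potency_sd: float = 0.004  # absolute, per well
    bcm_noise_sd: float = 0.03  # nm
    charge_coeff: float = 5.5e-3  # charge = coeff * mass^exponent
    charge_exponent: float = 2.0 / 3.0  # surface-area scaling
    charge_sd: float = 0.04  # relative
    low_charge_fraction: float = 0.05
    low_charge_scale: float = 0.6
    cal_distortion: float = 1.0  # multiplicative m/z distortion

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights) or len(self.components) != len(
            self.buoyant_densities
        ):
            raise ValueError("components, weights and densities must align")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")

    @property
    def ensemble(self) -> CapsidEnsembleSpec:
        """Weight-averaged molar fractions as a single ensemble spec."""
        fractions = sum(
            w * c.fractions for w, c in zip(self.weights, self.components)
        )
        first = self.components[0]
        return CapsidEnsembleSpec(first.species, fractions, first.genome_mass)

    def mixture_mass_moments(self) -> tuple[float, float]:
        """(mean, sd) of particle mass over the component mixture."""
        means, variances = [], []
        for comp in self.components:
            mom = cm.assembly_mass_moments(comp)
            means.append(mom.mean)
            variances.append(mom.sd**2)
        w = np.asarray(self.weights)
        means = np.asarray(means)
        variances = np.asarray(variances)
        mean = float(np.dot(w, means))
        var = float(np.dot(w, variances + means**2) - mean**2)
        return mean, math.sqrt(max(var, 0.0))

    def cdms_measurement_sd(self) -> float:
        """Measurement noise needed to land at the target total FWHM."""
        _, sd_comp = self.mixture_mass_moments()
        sd_target = self.cdms_fwhm_target / _FWHM_PER_SD
        return math.sqrt(max(sd_target**2 - sd_comp**2, 0.0))

    def effect_at(self, moi: float) -> float:
        """Potency multiplier vs bulk, log-MOI interpolated between points."""
        if not self.potency_effect:
            return 1.0
        mois = np.array(sorted(self.potency_effect))
        vals = np.array([self.potency_effect[m] for m in mois])
        return float(np.interp(math.log10(moi), np.log10(mois), vals))

    def truth(self) -> dict:
        fractions = self.ensemble.fractions
        names = self.ensemble.names
        vp3 = np.array([n.startswith("VP3") for n in names])
        mean, sd_comp = self.mixture_mass_moments()
        return {
            "name": self.name,
            "species": list(names),
            "molar_fractions": fractions.tolist(),
            "vp12_over_vp3total": float(
                fractions[~vp3].sum() / fractions[vp3].sum()
            ),
            "genome_mass_da": self.components[0].genome_mass,
            "theoretical_mass_da": mean,
            "compositional_sd_da": sd_comp,
            "cdms_fwhm_target_da": self.cdms_fwhm_target,
            "buoyant_densities": list(self.buoyant_densities),
            "tm_c": self.tm,
            "potency_effect": {str(k): v for k, v in self.potency_effect.items()},
            "low_charge_fraction": self.low_charge_fraction,
            "cal_distortion": self.cal_distortion,
        }


def _ensemble(species, ratios, genome_mass) -> CapsidEnsembleSpec:
    return CapsidEnsembleSpec.from_ratios(species, ratios, genome_mass)


def default_scenarios(
    genome_length: int = DEFAULT_GENOME_LENGTH,
) -> dict[str, ScenarioSpec]:
    """The five default preparations keyed by name.

    Molar ratios for the fractionated pair are the measured
    1.0:1.3:6.9:0.4 and 1.0:1.4:8.6:0.4; the variant ratios are chosen
    to reproduce the published (VP1+VP2)/VP3_total summary values (0.35
    and 0.32) with the VP3-clip shifts each mutation induces.  Densities
    (1.352/1.361/1.359), Tm values (67.1/68.2/67.7), FWHM targets
    (0.18/0.13/0.16 MDa) and potency endpoints (+8.9%, -17.8%, +24.7%,
    +11.9%) are the published per-sample values; potency between quoted
    MOI endpoints is interpolated in log-MOI.
    """
    species = default_vp_species()
    genome_mass = genome_length * SSDNA_RESIDUE_MASS
    f11 = _ensemble(species, (1.0, 1.3, 6.9, 0.4), genome_mass)
    f22 = _ensemble(species, (1.0, 1.4, 8.6, 0.4), genome_mass)
    m203v = _ensemble(species, (1.0, 1.8, 3.0, 5.0), genome_mass)
    m211v = _ensemble(species, (1.0, 1.05, 6.4, 0.0), genome_mass)

    scenarios = {
        "bulk_wt": ScenarioSpec(
            name="bulk_wt",
            components=(f11, f22),
            weights=(0.5, 0.5),
            buoyant_densities=(1.352, 1.361),
            potency_effect={moi: 1.0 for moi in DEFAULT_MOIS},
            tm=67.1,
            cdms_fwhm_target=0.18e6,
        ),
        "f1_1": ScenarioSpec(
            name="f1_1",
            components=(f11,),
            weights=(1.0,),
            buoyant_densities=(1.352,),
            potency_effect={
                1.0e2: 1.060, 5.0e2: 1.089, 1.0e3: 1.070,
                2.5e3: 1.050, 5.0e3: 1.040,
            },
            tm=67.1,
            cdms_fwhm_target=0.17e6,
        ),
        "f2_2": ScenarioSpec(
            name="f2_2",
            components=(f22,),
            weights=(1.0,),
            buoyant_densities=(1.361,),
            potency_effect={
                1.0e2: 0.850, 5.0e2: 0.870, 1.0e3: 0.822,
                2.5e3: 0.850, 5.0e3: 0.880,
            },
            tm=67.1,
            cdms_fwhm_target=0.17e6,
        ),
        "m203v": ScenarioSpec(
            name="m203v",
            components=(m203v,),
            weights=(1.0,),
            buoyant_densities=(1.359,),
            potency_effect={
                1.0e2: 1.247, 5.0e2: 1.219, 1.0e3: 1.200,
                2.5e3: 1.180, 5.0e3: 1.170,
            },
            tm=68.2,
            cdms_fwhm_target=0.13e6,
        ),
        "m211v": ScenarioSpec(
            name="m211v",
            components=(m211v,),
            weights=(1.0,),
            buoyant_densities=(1.359,),
            potency_effect={
                1.0e2: 1.100, 5.0e2: 1.105, 1.0e3: 1.119,
                2.5e3: 1.082, 5.0e3: 1.060,
            },
            tm=67.7,
            cdms_fwhm_target=0.16e6,
        ),
    }
    return scenarios


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _gaussian_peak(axis, apex, sigma, area):
    return area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
        -0.5 * ((axis - apex) / sigma) ** 2
    )


def make_cge_trace(
    spec: ScenarioSpec,
    channel: str = "protein",
    seed: int = 0,
    noise_sd: float | None = None,
    genome_length: int | None = None,
) -> tuple[Electropherogram, dict]:
    """Synthetic electropherogram plus its injected ground truth.

    Protein channel: one Gaussian per species at the default migration
    position with area proportional to n_i * epsilon214_i, on a drifting
    baseline with additive Gaussian noise.  ssDNA channel: a single
    genome peak whose apex encodes the genome length.
    """
    rng = np.random.default_rng(seed)
    ens = spec.ensemble
    if channel == "protein":
        axis = np.arange(20.0, 32.0, 0.004)
        eps = np.array([s.epsilon214 for s in ens.species])
        raw_areas = ens.fractions * eps
        heights = raw_areas / (CGE_PEAK_SIGMA * math.sqrt(2.0 * math.pi))
        scale = 1.0 / heights.max()
        areas = raw_areas * scale
        sig = np.zeros_like(axis)
        for name, area in zip(ens.names, areas):
            if area > 0:
                sig += _gaussian_peak(axis, DEFAULT_MIGRATION[name], CGE_PEAK_SIGMA, area)
        truth = {
            "channel": "protein",
            "areas": dict(zip(ens.names, areas.tolist())),
            "epsilons": dict(zip(ens.names, eps.tolist())),
            "molar_fractions": dict(zip(ens.names, ens.fractions.tolist())),
        }
    elif channel == "ssdna":
        if genome_length is None:
            genome_length = int(round(ens.genome_mass / SSDNA_RESIDUE_MASS))
        axis = np.arange(15.0, 25.0, 0.004)
        apex = 10.0 + 0.004 * genome_length
        sig = _gaussian_peak(axis, apex, 0.15, 0.15 * math.sqrt(2 * math.pi))
        truth = {"channel": "ssdna", "apex_min": apex, "genome_length": genome_length}
    else:
        raise ValueError(f"unknown channel {channel!r}")

    baseline = 0.05 + 0.01 * (axis - axis[0]) / (axis[-1] - axis[0])
    if noise_sd is None:
        noise_sd = spec.cge_noise_sd
    noise = rng.normal(0.0, noise_sd * max(sig.max(), 1e-12), size=axis.size)
    return Electropherogram(axis, sig + baseline + noise, channel), truth


@dataclass(frozen=True)
class CdmsSimulation:
    events: pd.DataFrame  # columns: mz, charge
    gdh_observed: np.ndarray
    gdh_theoretical: np.ndarray
    truth: dict


def make_cdms_events(
    spec: ScenarioSpec, n_ions: int = 3600, seed: int = 0
) -> CdmsSimulation:
    """Simulated ion events plus distorted calibrant peaks.

    Per-ion composition is multinomial over the (possibly mixed)
    ensemble; measurement noise is sized so the total mass-histogram
    FWHM lands at the scenario target; charge follows a surface-area
    (mass^(2/3)) law with an optional compact low-charge subpopulation;
    observed m/z is multiplied by the scenario's calibration distortion.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(spec.weights)
    comp_idx = rng.choice(len(spec.components), size=n_ions, p=weights)
    masses = np.empty(n_ions)
    for k, comp in enumerate(spec.components):
        sel = comp_idx == k
        n_k = int(sel.sum())
        if n_k == 0:
            continue
        counts = rng.multinomial(comp.n_subunits, comp.fractions, size=n_k)
        masses[sel] = counts @ comp.monomer_masses + comp.genome_mass

    sd_meas = spec.cdms_measurement_sd()
    masses_obs = masses + rng.normal(0.0, sd_meas, size=n_ions)

    charge = spec.charge_coeff * masses_obs**spec.charge_exponent
    charge = charge * (1.0 + rng.normal(0.0, spec.charge_sd, size=n_ions))
    low = rng.random(n_ions) < spec.low_charge_fraction
    charge[low] *= spec.low_charge_scale
    charge = np.clip(charge, 1.0, None)

    mz_true = masses_obs / charge + PROTON_MASS
    mz_obs = spec.cal_distortion * mz_true

    gdh_theoretical = (GDH_MASS + GDH_CHARGES * PROTON_MASS) / GDH_CHARGES
    gdh_observed = spec.cal_distortion * gdh_theoretical * (
        1.0 + rng.normal(0.0, 1e-4, size=GDH_CHARGES.size)
    )

    mean, sd_comp = spec.mixture_mass_moments()
    truth = {
        "mean_mass_da": mean,
        "compositional_sd_da": sd_comp,
        "measurement_sd_da": sd_meas,
        "total_fwhm_da": _FWHM_PER_SD * math.hypot(sd_comp, sd_meas),
        "low_charge_fraction": spec.low_charge_fraction,
        "cal_distortion": spec.cal_distortion,
        "median_charge": float(np.median(charge)),
    }
    events = pd.DataFrame({"mz": mz_obs, "charge": charge})
    return CdmsSimulation(events, gdh_observed, gdh_theoretical, truth)


def make_density_readouts(
    spec: ScenarioSpec,
    n_replicates: int = 3,
    seed: int = 0,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Noisy buoyant-density estimates, one row per component per replicate.

    Mixture scenarios (the bulk preparation) emit one density per
    component band.
    """
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = spec.density_sd
    rows = []
    for k, density in enumerate(spec.buoyant_densities):
        for rep in range(n_replicates):
            rows.append(
                {
                    "sample": spec.name,
                    "component": k,
                    "replicate": rep,
                    "buoyant_density": density + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


def bulk_dose_response(moi, pmax: float = 0.85, k_half: float = 600.0):
    """Saturating bulk dose-response: fraction GFP+ = pmax * MOI/(MOI + K)."""
    moi = np.asarray(moi, dtype=float)
    out = pmax * moi / (moi + k_half)
    return float(out) if out.ndim == 0 else out


def make_potency_table(
    specs: dict[str, ScenarioSpec] | list[ScenarioSpec],
    mois=DEFAULT_MOIS,
    n_wells: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-well flow-cytometry table across scenarios and MOI levels.

    Each sample's expected fraction is the bulk dose-response times its
    per-MOI potency multiplier, with per-well Gaussian noise, clipped to
    [0, 1].
    """
    if isinstance(specs, dict):
        specs = list(specs.values())
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        for moi in mois:
            expected = bulk_dose_response(moi) * spec.effect_at(moi)
            for well in range(n_wells):
                value = expected + rng.normal(0.0, spec.potency_sd)
                rows.append(
                    {
                        "sample": spec.name,
                        "moi": moi,
                        "replicate": well,
                        "gfp_positive": float(np.clip(value, 0.0, 1.0)),
                    }
                )
    return pd.DataFrame(rows)


def make_thermal_scan(
    spec: ScenarioSpec,
    seed: int = 0,
    t_start: float = 30.0,
    t_stop: float = 90.0,
    step: float = 0.25,
    bcm_low: float = 330.0,
    bcm_high: float = 345.0,
    slope: float = 1.2,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Logistic BCM redshift centered at the scenario Tm, with noise."""
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = spec.bcm_noise_sd
    t = np.arange(t_start, t_stop + step / 2, step)
    bcm = bcm_low + (bcm_high - bcm_low) / (1.0 + np.exp(-(t - spec.tm) / slope))
    bcm = bcm + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame({"temperature_c": t, "bcm_nm": bcm})


# ---------------------------------------------------------------------------
# file emission (CSV/FASTA/JSON only; ground truth sidecar always written)
# ---------------------------------------------------------------------------


def _write_trace(trace: Electropherogram, path) -> None:
    pd.DataFrame({"minutes": trace.axis, "signal": trace.signal}).to_csv(
        path, index=False, float_format="%.8g"
    )


def write_scenario(spec: ScenarioSpec, outdir, seed: int = 0) -> dict:
    """Write every per-scenario input file plus a truth sidecar.

    Files: vp_sequences.fasta, cge_protein.csv, cge_ssdna.csv,
    cdms_events.csv, gdh_calibration.csv, densities.csv, thermal.csv,
    truth.json.  Deterministic for a fixed (spec, seed).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "vp_sequences.fasta", "w") as fh:
        for sp in spec.ensemble.species:
            fh.write(f">{sp.name}\n{sp.sequence}\n")

    protein, cge_truth = make_cge_trace(spec, "protein", seed=seed)
    _write_trace(protein, outdir / "cge_protein.csv")
    ssdna, ssdna_truth = make_cge_trace(spec, "ssdna", seed=seed + 1)
    _write_trace(ssdna, outdir / "cge_ssdna.csv")

    sim = make_cdms_events(spec, seed=seed + 2)
    sim.events.to_csv(outdir / "cdms_events.csv", index=False, float_format="%.8g")
    pd.DataFrame(
        {"observed_mz": sim.gdh_observed, "theoretical_mz": sim.gdh_theoretical}
    ).to_csv(outdir / "gdh_calibration.csv", index=False, float_format="%.10g")

    make_density_readouts(spec, seed=seed + 3).to_csv(
        outdir / "densities.csv", index=False, float_format="%.8g"
    )
    make_thermal_scan(spec, seed=seed + 4).to_csv(
        outdir / "thermal.csv", index=False, float_format="%.8g"
    )

    truth = spec.truth()
    truth["cge"] = cge_truth
    truth["ssdna"] = ssdna_truth
    truth["cdms"] = sim.truth
    truth["seed"] = seed
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def write_potency_table(
    specs: dict[str, ScenarioSpec], outdir, seed: int = 0
) -> pd.DataFrame:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = make_potency_table(specs, seed=seed)
    table.to_csv(outdir / "potency.csv", index=False, float_format="%.8g")
    truth = {
        name: {str(moi): spec.effect_at(moi) for moi in DEFAULT_MOIS}
        for name, spec in specs.items()
    }
    with open(outdir / "potency_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return table
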