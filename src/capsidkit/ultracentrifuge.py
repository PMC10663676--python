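"""Isopycnic CsCl density-gradient physics and sedimentation consistency checks.

Covers partial-specific-volume (vbar) conversions, composition-based
theoretical vbar, the equilibrium CsCl gradient of a spinning column
with band position/width/separation (the physics behind running a
second, slower isopycnic cycle), and a smooth-sphere Svedberg model
relating sedimentation coefficient to molar mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_weights
from scipy.optimize import brentq

from .capsid_model import CapsidEnsembleSpec

__all__ = [
    "R_GAS_CGS",
    "N_AVOGADRO",
    "DEFAULT_BETA0",
    "DEFAULT_DNA_VBAR",
    "RESIDUE_VBAR",
    "DensityMeasurement",
    "GradientModel",
    "DensityProfile",
    "BandPrediction",
    "SedimentationRecord",
    "vbar_from_density",
    "protein_vbar_from_sequence",
    "composition_vbar",
    "particle_vbar",
    "equilibrium_gradient",
    "band_position",
    "band_radius",
    "band_width",
    "band_separation",
    "svedberg_sphere_mass",
]

R_GAS_CGS = 8.31446e7  # erg / (mol K)
N_AVOGADRO = 6.02214076e23  # 1/mol
WATER_MASS = 18.01528  # Da

# CsCl density-gradient proportionality constant beta0, cm^5/(g s^2):
# single representative literature value near the working density
# (Ifft, Voet & Vinograd, J Phys Chem 1961, 65:1138); configurable.
DEFAULT_BETA0 = 1.19e9

# Amino-acid residue partial specific volumes at 25 C, cm^3/g
# (Cohn & Edsall, Proteins, Amino Acids and Peptides, 1943).
RESIDUE_VBAR = {
    "A": 0.74,
    "R": 0.70,
    "N": 0.62,
    "D": 0.60,
    "C": 0.63,
    "Q": 0.67,
    "E": 0.66,
    "G": 0.64,
    "H": 0.67,
    "I": 0.90,
    "L": 0.90,
    "K": 0.82,
    "M": 0.75,
    "F": 0.77,
    "P": 0.76,
    "S": 0.63,
    "T": 0.70,
    "W": 0.74,
    "Y": 0.71,
    "V": 0.86,
}

DEFAULT_DNA_VBAR = 0.55  # cm^3/g, sodium-salt ssDNA; configurable

# residue (in-chain) average masses: free amino acid minus one water
_RESIDUE_MASS = {aa: w - WATER_MASS for aa, w in protein_weights.items()}


def vbar_from_density(rho: float) -> float:
    """vbar at the isopycnic point: reciprocal of the banding density."""
    if rho <= 0:
        raise ValueError("density must be positive")
    return 1.0 / rho


@dataclass(frozen=True)
class DensityMeasurement:
    sample: str
    buoyant_density: float  # g/cm^3

    def __post_init__(self) -> None:
        if not 1.0 < self.buoyant_density < 2.0:
            raise ValueError(
                "buoyant density outside the CsCl working range (1, 2) g/cm^3"
            )

    @property
    def vbar(self) -> float:
        return vbar_from_density(self.buoyant_density)


def protein_vbar_from_sequence(
    sequence: str, residue_vbar: dict[str, float] | None = None
) -> float:
    """Mass-weighted residue partial-specific-volume average for one chain."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    table = RESIDUE_VBAR if residue_vbar is None else residue_vbar
    total_mass = 0.0
    weighted = 0.0
    for i, aa in enumerate(sequence):
        try:
            m = _RESIDUE_MASS[aa]
            v = table[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}") from None
        total_mass += m
        weighted += m * v
    return weighted / total_mass


def particle_vbar(
    protein_mass: float, protein_vbar_value: float, dna_mass: float, dna_vbar: float
) -> float:
    """Mass-weighted particle vbar of the protein shell plus packaged DNA."""
    total = protein_mass + dna_mass
    if total <= 0:
        raise ValueError("total mass must be positive")
    return (protein_mass * protein_vbar_value + dna_mass * dna_vbar) / total


def composition_vbar(
    spec: CapsidEnsembleSpec,
    residue_vbar: dict[str, float] | None = None,
    dna_vbar: float = DEFAULT_DNA_VBAR,
) -> float:
    """Theoretical particle vbar in water from VP stoichiometry and genome.

    Per-species protein vbar is the mass-weighted residue average; the
    ensemble protein vbar weights species by their molar-fraction mass
    contribution; the particle value mixes protein and DNA by mass.
    """
    vbars = []
    for sp in spec.species:
        if sp.sequence is None:
            raise ValueError(f"species {sp.name} has no sequence for vbar")
        vbars.append(protein_vbar_from_sequence(sp.sequence, residue_vbar))
    m = spec.monomer_masses
    p = spec.fractions
    protein_mass = spec.n_subunits * float(np.dot(p, m))
    protein_v = float(np.dot(p * m, vbars) / np.dot(p, m))
    return particle_vbar(protein_mass, protein_v, spec.genome_mass, dna_vbar)


@dataclass(frozen=True)
class GradientModel:
    """Rotor/geometry/CsCl parameters for an equilibrium density gradient."""

    rpm: float
    r_top: float = 6.7  # cm, nominal SW41 meniscus
    r_bottom: float = 15.3  # cm, nominal SW41 tube bottom
    loading_density: float = 1.37  # g/cm^3
    temperature: float = 293.15  # K
    beta0: float = DEFAULT_BETA0  # cm^5/(g s^2)

    def __post_init__(self) -> None:
        if self.rpm < 0:
            raise ValueError("rpm must be non-negative")
        if self.r_top >= self.r_bottom:
            raise ValueError("r_top must be below r_bottom")
        if not 1.0 <= self.loading_density <= 1.9:
            raise ValueError("loading density outside CsCl solubility range")
        if self.temperature <= 0 or self.beta0 <= 0:
            raise ValueError("temperature and beta0 must be positive")

    @property
    def omega(self) -> float:
        """Angular velocity, rad/s."""
        return 2.0 * math.pi * self.rpm / 60.0

    @property
    def r_iso(self) -> float:
        """Isoconcentration radius of a sector-shaped (weight ~ r) column."""
        return math.sqrt((self.r_top**2 + self.r_bottom**2) / 2.0)

    def density_at(self, r) -> np.ndarray | float:
        """Equilibrium density: rho0 + (omega^2/beta0) (r^2 - r_iso^2) / 2."""
        r = np.asarray(r, dtype=float)
        rho = (
            self.loading_density
            + (self.omega**2 / self.beta0) * (r**2 - self.r_iso**2) / 2.0
        )
        return float(rho) if rho.ndim == 0 else rho

    def slope_at(self, r: float) -> float:
        """d(rho)/dr at radius r: omega^2 r / beta0."""
        return self.omega**2 * r / self.beta0


@dataclass(frozen=True)
class DensityProfile:
    r: np.ndarray
    rho: np.ndarray
    model: GradientModel | None = None
    below_unity: bool = False  # any rho < 1.0 in the column

    def density_at(self, radius: float) -> float:
        if self.model is not None:
            return float(self.model.density_at(radius))
        return float(np.interp(radius, self.r, self.rho))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_cm": self.r, "rho_g_per_cm3": self.rho})


@dataclass(frozen=True)
class BandPrediction:
    r_band: float
    sigma_r: float
    in_column: bool


def equilibrium_gradient(model: GradientModel, n_points: int = 501) -> DensityProfile:
    """Equilibrium CsCl density profile conserving total salt.

    The isoconcentration radius is fixed by requiring the volume-
    weighted (sector-shaped, weight ~ r) mean density to equal the
    loading density, so the profile conserves salt by construction.
    """
    r = np.linspace(model.r_top, model.r_bottom, n_points)
    rho = np.asarray(model.density_at(r))
    return DensityProfile(
        r=r, rho=rho, model=model, below_unity=bool(np.any(rho < 1.0))
    )


def band_radius(model: GradientModel, particle_density: float) -> float:
    """Closed-form banding radius (may fall outside the physical column)."""
    if model.omega == 0:
        raise ValueError("no banding at zero rotor speed")
    r_sq = model.r_iso**2 + 2.0 * (particle_density - model.loading_density) * (
        model.beta0 / model.omega**2
    )
    if r_sq <= 0:
        raise ValueError("particle density too low: no real banding radius")
    return math.sqrt(r_sq)


def band_position(profile: DensityProfile, particle_density: float) -> BandPrediction:
    """Radius where the gradient density equals the particle density.

    Root-finding on the profile (analytic when the profile carries its
    model, interpolated otherwise); out-of-column particles are flagged
    rather than erroring.
    """
    rho = profile.rho
    if np.any(np.diff(rho) < 0):
        raise ValueError("density profile must be monotone non-decreasing")
    if particle_density < rho[0] or particle_density > rho[-1]:
        return BandPrediction(r_band=math.nan, sigma_r=math.nan, in_column=False)
    if rho[0] == rho[-1]:  # uniform profile (omega = 0): no unique band
        return BandPrediction(r_band=math.nan, sigma_r=math.nan, in_column=False)
    r_band = brentq(
        lambda r: profile.density_at(r) - particle_density,
        float(profile.r[0]),
        float(profile.r[-1]),
        xtol=1e-12,
    )
    return BandPrediction(r_band=float(r_band), sigma_r=math.nan, in_column=True)


def band_width(
    model: GradientModel,
    r_band: float,
    particle_mass: float,
    vbar: float,
    slope: float | None = None,
) -> float:
    """Equilibrium band standard deviation (cm) for a banded particle.

    sigma_r = sqrt(R T / (M vbar (drho/dr) omega^2 r_band)) with M the
    molar mass (g/mol = Da), cgs units throughout.
    """
    if model.omega == 0:
        raise ValueError("no banding (zero gradient slope) at omega = 0")
    if particle_mass <= 0 or vbar <= 0 or r_band <= 0:
        raise ValueError("mass, vbar and r_band must be positive")
    if slope is None:
        slope = model.slope_at(r_band)
    if slope <= 0:
        raise ValueError("gradient slope must be positive for banding")
    return math.sqrt(
        R_GAS_CGS
        * model.temperature
        / (particle_mass * vbar * slope * model.omega**2 * r_band)
    )


def band_separation(
    model: GradientModel,
    density_a: float,
    density_b: float,
    linearized: bool = True,
) -> float:
    """Radial separation between the bands of two particle densities (cm).

    By default the first-order (Meselson-style) separation at the
    isoconcentration point, |drho| / (drho/dr at r_iso), which scales
    exactly as omega^-2 and is the standard resolution metric; pass
    ``linearized=False`` for the exact difference of banding radii.
    """
    if linearized:
        if model.omega == 0:
            raise ValueError("no banding at zero rotor speed")
        return abs(density_b - density_a) / model.slope_at(model.r_iso)
    return abs(band_radius(model, density_b) - band_radius(model, density_a))


@dataclass(frozen=True)
class SedimentationRecord:
    s_value: float  # Svedberg (1e-13 s)
    solvent_density: float  # g/cm^3
    solvent_viscosity: float  # poise
    vbar: float  # cm^3/g


def svedberg_sphere_mass(rec: SedimentationRecord) -> float:
    """Molar mass (Da) of an anhydrous smooth sphere with sedimentation s.

    Solves s = M (1 - vbar rho) / (N_A 6 pi eta R_s) with
    R_s = (3 M vbar / (4 pi N_A))^(1/3); closed form gives M ~ s^(3/2).
    A consistency-check tool (frictional ratio 1, hydration ignored),
    not a mass determination.
    """
    buoyancy = 1.0 - rec.vbar * rec.solvent_density
    if buoyancy <= 0:
        raise ValueError("buoyancy term <= 0: particle floats, no sedimentation")
    if rec.s_value <= 0 or rec.solvent_viscosity <= 0 or rec.vbar <= 0:
        raise ValueError("s, viscosity and vbar must be positive")
    s_seconds = rec.s_value * 1e-13
    radius_coeff = (3.0 * rec.vbar / (4.0 * math.pi * N_AVOGADRO)) ** (1.0 / 3.0)
    return (
        s_seconds
        * N_AVOGADRO
        * 6.0
        * math.pi
        * rec.solvent_viscosity
        * radius_coeff
        / buoyancy
    ) ** 1.5
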