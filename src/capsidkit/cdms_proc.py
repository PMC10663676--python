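"""Charge-detection mass-spectrometry processing.

Multiplicative m/z calibration against a calibrant's theoretical charge
states, per-ion mass computation, acquisition-order mass-window
filtering, histogramming with a locally fitted mode and interpolated
FWHM, and low-charge subpopulation reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PROTON_MASS",
    "IonEvent",
    "CalibrationResult",
    "MassHistogram",
    "calibration_factor",
    "ion_mass",
    "filter_mass_window",
    "mass_histogram",
    "low_charge_fraction",
    "read_events_csv",
]

PROTON_MASS = 1.00728  # Da


@dataclass(frozen=True)
class IonEvent:
    mz: float  # Th
    charge: float  # elementary charges, real-valued as measured

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.charge <= 0:
            raise ValueError("charge must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    """Dimensionless multiplicative m/z correction: corrected = factor * observed."""

    factor: float = 1.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("calibration factor must be positive")


def calibration_factor(observed_mz, theoretical_mz) -> CalibrationResult:
    """Least-squares slope through the origin of theoretical vs observed m/z.

    factor = sum(t*o) / sum(o^2), so that factor*observed best matches
    theoretical in the least-squares sense.
    """
    o = np.asarray(observed_mz, dtype=float)
    t = np.asarray(theoretical_mz, dtype=float)
    if o.size == 0 or t.size == 0:
        raise ValueError("calibration requires at least one peak pair")
    if o.shape != t.shape:
        raise ValueError("observed and theoretical lists must pair up")
    if np.any(o <= 0) or np.any(t <= 0):
        raise ValueError("m/z values must be positive")
    return CalibrationResult(float(np.dot(t, o) / np.dot(o, o)))


def ion_mass(mz, charge, cal: CalibrationResult | None = None):
    """Ion mass in Da: charge * (factor * m/z - proton mass).

    Accepts scalars or arrays; the proton-mass term is negligible at the
    MDa scale but kept for correctness.
    """
    factor = 1.0 if cal is None else cal.factor
    mz = np.asarray(mz, dtype=float)
    charge = np.asarray(charge, dtype=float)
    out = charge * (factor * mz - PROTON_MASS)
    return float(out) if out.ndim == 0 else out


def filter_mass_window(masses, low: float, high: float, cap: int) -> np.ndarray:
    """First ``cap`` masses (acquisition order) inside the closed [low, high]."""
    if low >= high:
        raise ValueError("window low bound must be below high bound")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    masses = np.asarray(masses, dtype=float)
    selected = masses[(masses >= low) & (masses <= high)]
    return selected[:cap]


@dataclass(frozen=True)
class MassHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_mass: float
    fwhm: float
    n_ions: int

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.bin_edges[0] <= self.mode_mass <= self.bin_edges[-1]:
            raise ValueError("mode mass must lie within the binned range")
        if self.fwhm < 0:
            raise ValueError("fwhm must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "count": self.counts})

    def summary(self) -> dict:
        return {
            "mode_mass_da": float(self.mode_mass),
            "fwhm_da": float(self.fwhm),
            "n_ions": int(self.n_ions),
        }

    def write(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_mode(
    centers: np.ndarray, counts: np.ndarray, i_max: int, bw: float
) -> tuple[float, float]:
    """Gaussian fit around the tallest bin: (mode, peak amplitude).

    Falls back to the tallest bin itself when the fit fails or wanders
    outside its neighborhood.
    """
    fallback = (float(centers[i_max]), float(counts[i_max]))
    lo = max(0, i_max - 5)
    hi = min(counts.size, i_max + 6)
    x, y = centers[lo:hi], counts[lo:hi].astype(float)
    if np.count_nonzero(y) < 3:
        return fallback
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=(float(counts[i_max]), float(centers[i_max]), 2.0 * bw),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return fallback
    amp, mu = float(popt[0]), float(popt[1])
    if not x[0] <= mu <= x[-1] or amp <= 0:
        return fallback
    return mu, amp


def _half_crossing(centers, counts, half, i_max, direction, bw) -> float:
    """Half-maximum crossing flanking the mode, by linear interpolation."""
    i = i_max
    while 0 <= i + direction < counts.size and counts[i + direction] >= half:
        i += direction
    j = i + direction
    if j < 0 or j >= counts.size:
        # histogram never drops below half on this side: use the data edge
        return float(centers[i] + direction * bw / 2.0)
    c_i, c_j = float(counts[i]), float(counts[j])
    if c_i == c_j:
        return float(centers[j])
    frac = (c_i - half) / (c_i - c_j)
    return float(centers[i] + direction * frac * bw)


def _half_crossing_regression(
    centers, counts, half, peak, i_max, direction, bw
) -> float:
    """Half-maximum crossing from a local linear fit of the flank.

    The flank bins between 20% and 80% of the peak level are fitted with
    a straight line and the half level is interpolated on it, averaging
    the per-bin Poisson noise that a two-bin interpolation would inherit
    wholesale.  Falls back to plain two-bin interpolation on degenerate
    flanks.
    """
    fallback = _half_crossing(centers, counts, half, i_max, direction, bw)
    idx = []
    j = i_max
    while 0 <= j + direction < counts.size and counts[j] >= 0.2 * peak:
        j += direction
        if counts[j] <= 0.8 * peak:
            idx.append(j)
        if counts[j] < 0.2 * peak:
            break
    if len(idx) < 3:
        return fallback
    x = centers[idx]
    y = counts[idx].astype(float)
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0 or np.sign(slope) == direction:  # flank must descend outward
        return fallback
    crossing = (half - intercept) / slope
    lo, hi = sorted((x[0], x[-1]))
    if not lo - 2 * bw <= crossing <= hi + 2 * bw:
        return fallback
    return float(crossing)


def mass_histogram(masses, bin_width: float = 1.0e4) -> MassHistogram:
    """Uniform-bin mass histogram with fitted mode and interpolated FWHM.

    The mode is the center of a Gaussian fitted to the +/-5-bin
    neighborhood of the tallest bin; the FWHM interpolates the half-
    maximum crossings flanking the mode (inner crossings when the
    binned counts are multimodal).  Degenerate single-bin data report
    fwhm = bin_width.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size < 10:
        raise ValueError("mass histogram requires at least 10 ions")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(masses.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((masses.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(masses, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    i_max = int(np.argmax(counts))
    mode, amplitude = _fit_mode(centers, counts, i_max, bin_width)
    mode = float(np.clip(mode, edges[0], edges[-1]))

    # half level from the fitted amplitude (the raw tallest-bin count is a
    # Poisson draw; halving it directly makes the FWHM needlessly noisy)
    peak = min(amplitude, float(counts[i_max]))
    half = peak / 2.0
    left = _half_crossing_regression(centers, counts, half, peak, i_max, -1, bin_width)
    right = _half_crossing_regression(centers, counts, half, peak, i_max, +1, bin_width)
    return MassHistogram(
        bin_edges=edges,
        counts=counts,
        mode_mass=mode,
        fwhm=max(right - left, 0.0),
        n_ions=int(masses.size),
    )


def low_charge_fraction(
    mz,
    charge,
    cal: CalibrationResult | None = None,
    charge_threshold: float = 100.0,
    mass_low: float | None = None,
    mass_high: float | None = None,
) -> float:
    """Fraction of (optionally mass-windowed) ions with charge below threshold."""
    if charge_threshold <= 0:
        raise ValueError("charge threshold must be positive")
    charge = np.asarray(charge, dtype=float)
    masses = ion_mass(mz, charge, cal)
    keep = np.ones(charge.shape, dtype=bool)
    if mass_low is not None:
        keep &= masses >= mass_low
    if mass_high is not None:
        keep &= masses <= mass_high
    if not np.any(keep):
        raise ValueError("no ions in the selected mass window")
    return float(np.mean(charge[keep] < charge_threshold))


def read_events_csv(path, mass_column: bool = False) -> pd.DataFrame:
    """Read ion events: columns (mz, charge), or (mass, charge) if flagged."""
    df = pd.read_csv(path)
    expected = {"mass", "charge"} if mass_column else {"mz", "charge"}
    if not expected.issubset(df.columns):
        raise ValueError(f"events CSV must have columns {sorted(expected)}")
    return df
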