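"""Assay readout processing: transduction-potency normalization,
stoichiometry-potency correlation, and thermal-melt Tm extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PotencyRecord",
    "relative_potency",
    "stoichiometry_metrics",
    "stoich_potency_correlation",
    "tm_from_bcm",
]

POTENCY_COLUMNS = ["sample", "moi", "replicate", "gfp_positive"]


@dataclass(frozen=True)
class PotencyRecord:
    """One flow-cytometry transduction measurement."""

    sample: str
    moi: float  # viral genomes per cell
    gfp_positive: float  # fraction of viable cells
    replicate: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.gfp_positive <= 1.0:
            raise ValueError("gfp_positive must be in [0, 1]")
        if self.moi <= 0:
            raise ValueError("MOI must be positive")


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(POTENCY_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"potency table missing columns {sorted(missing)}")
        return records
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "moi": r.moi,
                "replicate": r.replicate,
                "gfp_positive": r.gfp_positive,
            }
            for r in records
        ]
    )


def relative_potency(records, bulk_label: str) -> pd.DataFrame:
    """Per sample x MOI potency relative to the bulk sample.

    value = replicate mean / bulk replicate mean at the same MOI; the
    ratio SD is propagated to first order from the replicate SDs.  The
    bulk sample itself is therefore 1 at every MOI.
    """
    df = _records_frame(records)
    if bulk_label not in set(df["sample"]):
        raise ValueError(f"bulk sample {bulk_label!r} not present")
    agg = (
        df.groupby(["sample", "moi"])["gfp_positive"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    agg["std"] = agg["std"].fillna(0.0)
    bulk = agg[agg["sample"] == bulk_label].set_index("moi")
    missing = sorted(set(agg["moi"]) - set(bulk.index))
    if missing:
        raise ValueError(f"bulk sample missing at MOI(s): {missing}")

    rows = []
    for _, row in agg.iterrows():
        b_mean = bulk.loc[row["moi"], "mean"]
        b_std = bulk.loc[row["moi"], "std"]
        if b_mean <= 0:
            raise ValueError(f"bulk mean is zero at MOI {row['moi']}")
        value = row["mean"] / b_mean
        # first-order SD of a ratio of means
        rel_var = 0.0
        if row["mean"] > 0:
            rel_var += (row["std"] / row["mean"]) ** 2
        rel_var += (b_std / b_mean) ** 2
        rows.append(
            {
                "sample": row["sample"],
                "moi": row["moi"],
                "value": value,
                "sd": value * np.sqrt(rel_var),
            }
        )
    return pd.DataFrame(rows)


def stoichiometry_metrics(ratios, names=("VP1", "VP2", "VP3", "VP3clip")) -> dict:
    """The three correlation metrics from a molar-ratio vector.

    VP1-only = VP1/(VP2 + VP3_total), VP2-only = VP2/(VP1 + VP3_total),
    combined = (VP1 + VP2)/VP3_total, with VP3_total summing every
    species whose name starts with VP3.
    """
    n = dict(zip(names, np.asarray(ratios, dtype=float)))
    vp3_total = sum(v for k, v in n.items() if k.upper().startswith("VP3"))
    if vp3_total <= 0:
        raise ValueError("VP3_total must be positive")
    return {
        "vp1_only": n["VP1"] / (n["VP2"] + vp3_total),
        "vp2_only": n["VP2"] / (n["VP1"] + vp3_total),
        "vp12_over_vp3total": (n["VP1"] + n["VP2"]) / vp3_total,
    }


def stoich_potency_correlation(
    metrics: pd.DataFrame, potencies: pd.Series
) -> pd.DataFrame:
    """Pearson r and least-squares line per stoichiometry metric.

    ``metrics`` is indexed by sample with one column per metric;
    ``potencies`` maps the same samples to relative potency at a single
    MOI.  Metrics with zero variance are flagged degenerate (r = NaN).
    """
    samples = metrics.index.intersection(potencies.index)
    if len(samples) < 3:
        raise ValueError("correlation requires at least 3 samples")
    y = potencies.loc[samples].to_numpy(dtype=float)
    rows = []
    for metric in metrics.columns:
        x = metrics.loc[samples, metric].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            rows.append(
                {
                    "metric": metric,
                    "r": np.nan,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "degenerate": True,
                }
            )
            continue
        r, _ = stats.pearsonr(x, y)
        slope, intercept = np.polyfit(x, y, 1)
        rows.append(
            {
                "metric": metric,
                "r": float(r),
                "slope": float(slope),
                "intercept": float(intercept),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def tm_from_bcm(temperature, bcm) -> float:
    """Melting temperature from a barycentric-mean-wavelength thermal scan.

    Tm is the temperature at the maximum of the first derivative of the
    (3-point-smoothed) BCM with respect to temperature, i.e. the
    midpoint of the unfolding redshift, refined by parabolic
    interpolation of the derivative around its peak.
    """
    t = np.asarray(temperature, dtype=float)
    b = np.asarray(bcm, dtype=float)
    if t.size < 20:
        raise ValueError("thermal scan requires at least 20 points")
    if t.shape != b.shape:
        raise ValueError("temperature and bcm must be equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature must be strictly increasing")

    smooth = b.copy()
    smooth[1:-1] = (b[:-2] + b[1:-1] + b[2:]) / 3.0
    deriv = np.gradient(smooth, t)

    scale = max(abs(deriv).max(), 1e-30)
    if np.ptp(deriv) < 1e-6 * scale or deriv.max() <= 0:
        raise ValueError("no unfolding transition: derivative has no peak")
    i = int(np.argmax(deriv))
    if i == 0 or i == deriv.size - 1:
        raise ValueError("derivative peaks at the scan boundary: no transition")

    # parabolic sub-grid refinement of the derivative maximum
    y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    offset = 0.5 * (y0 - y2) / denom
    offset = float(np.clip(offset, -1.0, 1.0))
    # local spacing (scan may be non-uniform)
    dt = (t[i + 1] - t[i - 1]) / 2.0
    return float(t[i] + offset * dt)
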