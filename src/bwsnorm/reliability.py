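"""Split-batch reliability of utility scales.

The design's batches are parallel measurements of the same items (six
observations per item each), so agreement across batch scales measures the
internal consistency of the norms.  Two summaries are reported: the pairwise
Pearson correlation matrix between batch scales, and standardized Cronbach's
alpha from its mean off-diagonal correlation,

    alpha = k * rbar / (1 + (k - 1) * rbar).

With three batches correlating at .57 this gives alpha = .80.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityReport",
    "batch_scale_matrix",
    "interbatch_correlations",
    "cronbach_alpha_standardized",
    "cronbach_alpha_raw",
    "granularity_report",
    "reliability_report",
]


@dataclass
class ReliabilityReport:
    correlation_matrix: pd.DataFrame
    mean_offdiagonal: float
    alpha: float
    n_items: int
    spearman_matrix: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "correlation_matrix": self.correlation_matrix.round(6).values.tolist(),
            "batches": list(self.correlation_matrix.columns),
            "mean_offdiagonal": round(self.mean_offdiagonal, 6),
            "alpha": round(self.alpha, 6),
            "n_items": self.n_items,
        }


def batch_scale_matrix(scored: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long score table (item_id, score, batch) to items x batches.

    The pooled run is dropped; items missing a score in any batch are
    removed listwise.
    """
    batches = scored[scored["batch"] != "pooled"]
    wide = batches.pivot_table(index="item_id", columns="batch", values="score")
    return wide.dropna(axis=0, how="any")


def interbatch_correlations(
    batch_scales: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations between batch scales (items x batches input)."""
    if batch_scales.shape[1] < 2:
        raise ValueError("need at least two batch scales")
    if len(batch_scales) < 3:
        raise ValueError(f"only {len(batch_scales)} shared items; need >= 3")
    return batch_scales.corr(method=method)


def _mean_offdiag(corr: np.ndarray) -> float:
    k = corr.shape[0]
    return float((corr.sum() - np.trace(corr)) / (k * (k - 1)))


def cronbach_alpha_standardized(correlation_matrix: pd.DataFrame | np.ndarray) -> float:
    """Standardized Cronbach's alpha from a batch correlation matrix."""
    corr = np.asarray(correlation_matrix, dtype=float)
    k = corr.shape[0]
    if k < 2 or corr.shape[1] != k:
        raise ValueError("need a square correlation matrix of size >= 2")
    rbar = _mean_offdiag(corr)
    if rbar <= -1.0 / (k - 1):
        raise ValueError(f"alpha undefined: mean correlation {rbar:.4f} <= -1/(k-1)")
    return k * rbar / (1.0 + (k - 1) * rbar)


def cronbach_alpha_raw(batch_scales: pd.DataFrame, standardize: bool = True) -> float:
    """Alpha via the variance-decomposition route on raw batch scores.

    alpha = k/(k-1) * (1 - sum(var_j) / var(total)).  With ``standardize``
    the columns are z-scored first, making this exactly the standardized
    closed form — the two routes are an equivalence check on each other.
    """
    X = batch_scales.to_numpy(dtype=float)
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def granularity_report(scale: pd.Series | np.ndarray, bins: int = 50) -> dict:
    """Distinct-value count, histogram over [0, 1], and shape summary.

    Low granularity (few distinct values) is the signature of scales built
    from few observations per item.
    """
    vals = pd.Series(scale).dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty scale")
    hist, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    degenerate = np.unique(vals).size < 2
    return {
        "n_distinct": int(np.unique(vals).size),
        "n_items": int(vals.size),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "skew": float(stats.skew(vals)) if vals.size > 2 and not degenerate else 0.0,
        "kurtosis": float(stats.kurtosis(vals)) if vals.size > 3 and not degenerate else 0.0,
    }


def reliability_report(scored: pd.DataFrame) -> ReliabilityReport:
    """Full report from a long per-batch score table."""
    wide = batch_scale_matrix(scored)
    pear = interbatch_correlations(wide, "pearson")
    spear = interbatch_correlations(wide, "spearman")
    rbar = _mean_offdiag(pear.to_numpy())
    return ReliabilityReport(
        correlation_matrix=pear,
        mean_offdiagonal=rbar,
        alpha=cronbach_alpha_standardized(pear),
        n_items=len(wide),
        spearman_matrix=spear,
    )
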