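"""Relating utility norms to lexical covariates.

Once per-item utility scores exist they are analysed like any other lexical
norm: a correlation matrix against covariates (word frequency, length,
age of acquisition, prevalence, concreteness, ...) ordered by hierarchical
clustering; an OLS multiple regression of utility on the covariates; and
tables of the items with the most extreme regression residuals — words that
are more (or less) useful than their lexical profile predicts.

Because the real mega-study covariate databases are external downloads, a
synthetic predictor-table generator with a configurable correlation
structure and a planted linear utility stands in for them; every analysis
here runs identically on real tables with the same columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.special import ndtr

__all__ = [
    "RegressionReport",
    "clustered_correlation_matrix",
    "fit_utility_regression",
    "residual_extremes",
    "synthesize_predictor_table",
    "permutation_importance",
    "DEFAULT_COVARIATE_SPEC",
]


@dataclass
class RegressionReport:
    coefficients: pd.DataFrame  # term, coef, se, t, p
    r_squared: float
    n: int
    residuals: pd.Series  # indexed by item_id
    fitted: pd.Series
    observed: pd.Series
    model: object = field(repr=False, default=None)


def clustered_correlation_matrix(
    table: pd.DataFrame, method: str = "average"
) -> dict:
    """Pearson and Spearman correlation matrices in clustered variable order.

    Variables are ordered by hierarchical clustering (``method`` linkage,
    default average) on the correlation distance 1 - r (Pearson).  Constant
    columns are dropped with a warning entry in the result.
    """
    num = table.select_dtypes(include=[np.number])
    dropped = [c for c in num.columns if num[c].nunique(dropna=True) <= 1]
    num = num.drop(columns=dropped)
    if num.shape[1] < 2:
        raise ValueError("need at least two non-constant numeric columns")
    num = num.dropna(axis=0, how="any")
    if len(num) < 3:
        raise ValueError("need at least three complete rows")
    pear = num.corr(method="pearson")
    spear = num.corr(method="spearman")
    dist = 1.0 - pear.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if method != "average":
        from scipy.cluster.hierarchy import linkage

        Z = linkage(squareform(dist, checks=False), method=method)
    else:
        Z = average(squareform(dist, checks=False))
    order = [pear.columns[i] for i in leaves_list(Z)]
    return {
        "pearson": pear.loc[order, order],
        "spearman": spear.loc[order, order],
        "order": order,
        "dropped_constant": dropped,
        "linkage": Z,
    }


def _design_matrix(predictors: pd.DataFrame) -> pd.DataFrame:
    """Numeric columns as-is; categorical part_of_speech as treatment
    contrasts with the most frequent category as reference."""
    num = predictors.select_dtypes(include=[np.number])
    X = num.copy()
    if "part_of_speech" in predictors.columns:
        pos = predictors["part_of_speech"].astype("category")
        ref = pos.value_counts().idxmax()
        dummies = pd.get_dummies(pos, prefix="pos", dtype=float)
        X = pd.concat([X, dummies.drop(columns=f"pos_{ref}")], axis=1)
    return X


def fit_utility_regression(
    scores: pd.DataFrame | pd.Series,
    predictors: pd.DataFrame,
) -> RegressionReport:
    """OLS regression of utility scores on item covariates.

    ``scores``: Series indexed by item_id, or a DataFrame with ``item_id``
    and ``score`` columns.  ``predictors``: DataFrame with ``item_id`` plus
    numeric covariates and optional categorical ``part_of_speech``.
    Complete cases only (listwise deletion).  Raises on rank deficiency,
    naming the collinear columns.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores.set_index("item_id")["score"]
    preds = predictors.set_index("item_id") if "item_id" in predictors.columns else predictors
    X = _design_matrix(preds)
    merged = X.join(scores.rename("_utility"), how="inner").dropna(axis=0, how="any")
    if merged.shape[1] - 1 < 2:
        raise ValueError("need at least two predictors")
    y = merged.pop("_utility")
    Xc = sm.add_constant(merged, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy(dtype=float))
    if rank < Xc.shape[1]:
        corr = merged.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {Xc.shape[1]}); "
            f"most collinear pair: {corr.columns[i]!r}, {corr.columns[j]!r}"
        )
    fit = sm.OLS(y, Xc.astype(float)).fit()
    coef = pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return RegressionReport(
        coefficients=coef,
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        residuals=pd.Series(fit.resid, index=merged.index, name="residual"),
        fitted=pd.Series(fit.fittedvalues, index=merged.index, name="predicted"),
        observed=y,
        model=fit,
    )


def residual_extremes(
    report: RegressionReport,
    items: pd.DataFrame | None = None,
    top_n: int = 20,
    degenerate_tol: float = 1e-10,
) -> dict:
    """Items with the largest positive and negative regression residuals.

    Returns ``positive`` and ``negative`` DataFrames shaped like the study's
    residual tables: columns ``Word``, ``Utility``, ``Predicted Utility``
    (plus ``residual``), up to ``top_n`` rows each.  An (essentially) exact
    fit is flagged degenerate rather than ranked on numerical noise.
    """
    res = report.residuals
    degenerate = bool(np.abs(res).max() < degenerate_tol)
    if top_n > len(res):
        import warnings

        warnings.warn(f"top_n={top_n} > {len(res)} items; truncating")
        top_n = len(res)
    names = None
    if items is not None:
        key = "item_id" if "item_id" in items.columns else None
        names = items.set_index(key)["item"] if key else items["item"]

    def table(idx) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "Word": (names.reindex(idx) if names is not None else pd.Series(idx, index=idx).astype(str)),
                "Utility": report.observed.reindex(idx).round(2),
                "Predicted Utility": report.fitted.reindex(idx).round(2),
                "residual": res.reindex(idx),
            }
        )
        return out.reset_index(names="item_id")

    pos_idx = res.sort_values(ascending=False).head(top_n).index
    neg_idx = res.sort_values(ascending=True).head(top_n).index
    return {
        "positive": table(pos_idx),
        "negative": table(neg_idx),
        "degenerate": degenerate,
    }


# ---------------------------------------------------------------------------
# synthetic covariates

# Correlation structure loosely emulating lexical norms: a familiarity /
# prevalence / frequency cluster, an AoA axis opposing it, and a weakly
# related concreteness / valence / arousal block.
DEFAULT_COVARIATE_SPEC = {
    "columns": [
        "frequency_zipf",
        "familiarity",
        "prevalence_probit",
        "length",
        "aoa",
        "concreteness",
        "valence",
        "arousal",
        "centrality",
    ],
    "correlation": [
        [1.00, 0.65, 0.60, -0.30, -0.50, 0.05, 0.10, 0.00, 0.45],
        [0.65, 1.00, 0.70, -0.25, -0.55, 0.10, 0.15, 0.00, 0.40],
        [0.60, 0.70, 1.00, -0.20, -0.50, 0.10, 0.10, 0.00, 0.35],
        [-0.30, -0.25, -0.20, 1.00, 0.30, -0.15, 0.00, 0.05, -0.15],
        [-0.50, -0.55, -0.50, 0.30, 1.00, -0.20, -0.10, 0.05, -0.30],
        [0.05, 0.10, 0.10, -0.15, -0.20, 1.00, 0.05, -0.10, 0.10],
        [0.10, 0.15, 0.10, 0.00, -0.10, 0.05, 1.00, -0.20, 0.10],
        [0.00, 0.00, 0.00, 0.05, 0.05, -0.10, -0.20, 1.00, 0.00],
        [0.45, 0.40, 0.35, -0.15, -0.30, 0.10, 0.10, 0.00, 1.00],
    ],
    # planted standardized effects on utility; frequency positive,
    # concreteness negative, AoA negative — the sign pattern lexical
    # utility analyses recover
    "coefficients": {
        "frequency_zipf": 0.35,
        "familiarity": 0.25,
        "prevalence_probit": 0.20,
        "length": -0.05,
        "aoa": -0.20,
        "concreteness": -0.15,
        "valence": 0.05,
        "arousal": 0.02,
        "centrality": 0.10,
    },
    "noise_sd": 0.5,
}


def synthesize_predictor_table(
    n_items: int,
    covariance_spec: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a synthetic item table with covariates and planted utility.

    Covariates are multivariate Gaussian with the spec's correlation matrix
    (must be positive semidefinite); true utility is the planted linear
    combination plus Gaussian noise.  Also derives ``prevalence`` in (0, 1)
    from the probit column, a familiarity rating on 1-7, and item text.

    Returns (predictor table, true-utility Series indexed by item_id).
    """
    spec = covariance_spec or DEFAULT_COVARIATE_SPEC
    cols = spec["columns"]
    R = np.asarray(spec["correlation"], dtype=float)
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError(f"correlation spec not positive semidefinite (min eig {eig.min():.3g})")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(cols)))
    Z = rng.standard_normal((n_items, len(cols))) @ L.T
    df = pd.DataFrame(Z, columns=cols)
    df.insert(0, "item_id", np.arange(1, n_items + 1))
    df.insert(1, "item", [f"w{idx:06d}" for idx in range(1, n_items + 1)])
    df["is_mwe"] = (rng.random(n_items) < 0.5).astype(int)

    beta = spec["coefficients"]
    util = sum(beta[c] * df[c] for c in cols) + rng.normal(
        0.0, spec.get("noise_sd", 0.5), n_items
    )
    util = pd.Series(util.to_numpy(), index=pd.Index(df["item_id"], name="item_id"),
                     name="true_utility")

    if "prevalence_probit" in df.columns:
        # a familiarity-pruned pool: almost every item is known to ~90%+ of
        # raters, with a thin tail of less-known entries
        df["prevalence"] = ndtr(0.5 * df["prevalence_probit"] + 2.5)
    if "familiarity" in df.columns:
        z = df["familiarity"]
        df["familiarity"] = np.clip(4.5 + 1.2 * z, 1.0, 7.0)
    return df, util


def permutation_importance(
    report: RegressionReport,
    predictors: pd.DataFrame,
    scores: pd.Series,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Generic permutation importance over the fitted OLS.

    Importance of a column = mean drop in R^2 when that column is permuted.
    A model-agnostic screen, not a replication of random-forest variable
    importances.
    """
    preds = predictors.set_index("item_id") if "item_id" in predictors.columns else predictors
    X = _design_matrix(preds)
    merged = X.join(scores.rename("_utility"), how="inner").dropna()
    y = merged.pop("_utility").to_numpy()
    base = report.r_squared
    rng = np.random.default_rng(seed)
    rows = []
    for col in merged.columns:
        drops = []
        for _ in range(n_repeats):
            Xp = merged.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            fit = sm.OLS(y, sm.add_constant(Xp.astype(float), has_constant="add")).fit()
            drops.append(base - fit.rsquared)
        rows.append((col, float(np.mean(drops)), float(np.std(drops))))
    out = pd.DataFrame(rows, columns=["term", "importance", "sd"])
    return out.sort_values("importance", ascending=False).reset_index(drop=True)
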