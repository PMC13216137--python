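"""Utility-score estimation from best-worst responses.

A best-worst judgment over m alternatives implies 2m - 3 pairwise
preferences: the chosen best beats the other m - 1 items and each of the
m - 2 middle items beats the chosen worst (middle-vs-middle pairs carry no
information and are not extracted).

Three estimators operate on that preference stream:

* ``value_learning`` -- the primary scorer: a sequential (reinforcement-style)
  update in which each preference moves the winner's value up and the
  loser's down by ``lr * (1 - P(win))``, with P(win) the logistic of the
  value difference.  Scores are min-max mapped to [0, 1].
* ``best_worst_rate`` -- the counting baseline (#best - #worst)/appearances.
* ``bradley_terry_mle`` -- maximum-likelihood fit of the Bradley-Terry
  paired-comparison model via Hunter's MM algorithm, used as an independent
  cross-check of Value-Learning rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.special import expit

__all__ = [
    "LearnerConfig",
    "extract_pairwise",
    "value_learning",
    "best_worst_rate",
    "bradley_terry_mle",
    "score_batches",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters of the Value-Learning scorer.

    ``learning_rate`` is the initial step alpha_0 in (0, 1]; per-epoch steps
    decay harmonically (alpha_e = alpha_0 / (1 + e)).  Each epoch replays the
    full preference stream in a fresh seeded shuffle.
    """

    learning_rate: float = 0.1
    epochs: int = 50
    shuffle_seed: int = 0
    decay: str = "harmonic"  # or "constant"

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.decay not in ("harmonic", "constant"):
            raise ValueError(f"unknown decay '{self.decay}'")

    def rate(self, epoch: int) -> float:
        if self.decay == "constant":
            return self.learning_rate
        return self.learning_rate / (1.0 + epoch)


def extract_pairwise(responses: pd.DataFrame) -> pd.DataFrame:
    """Expand responses into the implied pairwise preferences.

    Returns a DataFrame with columns ``winner``, ``loser``,
    ``participant_id``, ``trial_index`` — (m - 1) + (m - 2) rows per
    response: best beats everything else, middles beat worst.
    """
    pos_cols = [c for c in responses.columns if c.startswith("pos")]
    m = len(pos_cols)
    if m < 2:
        raise ValueError("responses must carry at least two position columns")
    shown = responses[pos_cols].to_numpy(dtype=np.int64)
    best = responses["best_id"].to_numpy(dtype=np.int64)
    worst = responses["worst_id"].to_numpy(dtype=np.int64)
    if (best == worst).any():
        raise ValueError("malformed response: best == worst")
    in_set = (shown == best[:, None]).any(axis=1) & (shown == worst[:, None]).any(axis=1)
    if not in_set.all():
        bad = responses.index[~in_set].tolist()[:5]
        raise ValueError(f"malformed response rows (choice not shown): {bad}")

    pid = responses["participant_id"].to_numpy()
    tix = responses["trial_index"].to_numpy()

    # best beats the other m-1
    others = shown[shown != best[:, None]].reshape(len(shown), m - 1)
    w1 = np.repeat(best, m - 1)
    l1 = others.ravel()
    # middles (not best, not worst) beat worst
    mid_mask = (shown != best[:, None]) & (shown != worst[:, None])
    mids = shown[mid_mask].reshape(len(shown), m - 2)
    w2 = mids.ravel()
    l2 = np.repeat(worst, m - 2)

    rep1 = np.repeat(np.arange(len(shown)), m - 1)
    rep2 = np.repeat(np.arange(len(shown)), m - 2)
    return pd.DataFrame(
        {
            "winner": np.concatenate([w1, w2]),
            "loser": np.concatenate([l1, l2]),
            "participant_id": np.concatenate([pid[rep1], pid[rep2]]),
            "trial_index": np.concatenate([tix[rep1], tix[rep2]]),
        }
    )


def _minmax_01(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-300:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def value_learning(
    preferences: pd.DataFrame,
    n_items: int | None = None,
    config: LearnerConfig = LearnerConfig(),
) -> pd.DataFrame:
    """Estimate item utilities from a pairwise-preference stream.

    Sequential update over the seeded-shuffled stream, repeated for
    ``config.epochs`` epochs: for a preference (w, l) with values v_w, v_l,

        p = logistic(v_w - v_l); v_w += a * (1 - p); v_l -= a * (1 - p)

    with per-epoch step a.  Final values are min-max rescaled to [0, 1].
    Deterministic given the shuffle seed.  Items that never appear in the
    stream get a missing (NaN) score, never a fabricated one.

    Returns a DataFrame ``item_id``, ``score``, ``n_obs``, ``algorithm``.
    """
    winners = preferences["winner"].to_numpy(dtype=np.int64)
    losers = preferences["loser"].to_numpy(dtype=np.int64)
    if winners.size == 0:
        raise ValueError("empty preference stream")
    top = int(max(winners.max(), losers.max()))
    n_items = n_items or top
    if top > n_items:
        raise ValueError(f"preference references item {top} > n_items {n_items}")

    from math import exp

    vals = [0.5] * (n_items + 1)  # index 0 unused; ids are 1-based
    rng = np.random.default_rng(config.shuffle_seed)
    n = winners.size
    for epoch in range(config.epochs):
        a = config.rate(epoch)
        order = rng.permutation(n)
        ws = winners[order].tolist()
        ls = losers[order].tolist()
        for w, l in zip(ws, ls):
            d = a / (1.0 + exp(vals[w] - vals[l]))  # a * (1 - p)
            vals[w] += d
            vals[l] -= d
    values = np.asarray(vals)

    counts = np.bincount(
        np.concatenate([winners, losers]), minlength=n_items + 1
    )
    seen = counts[1:] > 0
    scores = np.full(n_items, np.nan)
    raw = values[1:][seen]
    # value differences below the final step size are sequential-update
    # residue, not signal; a spread under that resolution is a tie
    resolution = 10.0 * config.rate(config.epochs - 1)
    if raw.max() - raw.min() < resolution:
        scores[seen] = 0.5
    else:
        scores[seen] = _minmax_01(raw)
    return pd.DataFrame(
        {
            "item_id": np.arange(1, n_items + 1),
            "score": scores,
            "n_obs": counts[1:],
            "algorithm": "value_learning",
        }
    )


def best_worst_rate(responses: pd.DataFrame, n_items: int | None = None) -> pd.DataFrame:
    """Counting baseline: (#chosen best - #chosen worst) / #appearances.

    Raw rates are min-max rescaled to [0, 1]; an all-equal profile maps to
    0.5 everywhere.  Items never shown get NaN.
    """
    if responses.empty:
        raise ValueError("no responses")
    pos_cols = [c for c in responses.columns if c.startswith("pos")]
    shown = responses[pos_cols].to_numpy(dtype=np.int64).ravel()
    top = int(shown.max())
    n_items = n_items or top
    appear = np.bincount(shown, minlength=n_items + 1)[1:]
    nb = np.bincount(responses["best_id"].to_numpy(np.int64), minlength=n_items + 1)[1:]
    nw = np.bincount(responses["worst_id"].to_numpy(np.int64), minlength=n_items + 1)[1:]
    scores = np.full(n_items, np.nan)
    seen = appear > 0
    raw = (nb[seen] - nw[seen]) / appear[seen]
    scores[seen] = _minmax_01(raw)
    return pd.DataFrame(
        {
            "item_id": np.arange(1, n_items + 1),
            "score": scores,
            "n_obs": appear,
            "algorithm": "bwrate",
        }
    )


def bradley_terry_mle(
    preferences: pd.DataFrame,
    n_items: int | None = None,
    regularization: float = 0.1,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Bradley-Terry strengths by the MM algorithm (Hunter, 2004).

    P(i beats j) = s_i / (s_i + s_j); ``regularization`` adds that many
    pseudo-wins in each direction of every pair that was ever compared,
    keeping the comparison graph connected and the MLE finite.  Returned
    ``score`` is log-strength min-max rescaled to [0, 1] (rank-equivalent to
    the strengths; the scale is only used for correlation checks).
    """
    winners = preferences["winner"].to_numpy(np.int64)
    losers = preferences["loser"].to_numpy(np.int64)
    top = int(max(winners.max(), losers.max()))
    n_items = n_items or top
    ids = np.unique(np.concatenate([winners, losers]))
    k = ids.size
    remap = {int(i): j for j, i in enumerate(ids)}
    wi = np.array([remap[int(x)] for x in winners])
    li = np.array([remap[int(x)] for x in losers])

    W = np.zeros((k, k))
    np.add.at(W, (wi, li), 1.0)
    compared = (W + W.T) > 0
    W[compared] += regularization

    s = np.ones(k)
    wins = W.sum(axis=1)
    step = np.inf
    for _ in range(max_iter):
        denom_pair = s[:, None] + s[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(compared, (W + W.T) / denom_pair, 0.0)
        new = wins / frac.sum(axis=1)
        new = new / new.sum() * k
        step = float(np.max(np.abs(new - s)))
        s = new
        if step < tol:
            break
    if step >= tol:
        import warnings

        warnings.warn(f"Bradley-Terry MM did not converge; last step {step:.2e}")

    scores = np.full(n_items, np.nan)
    strengths = np.full(n_items, np.nan)
    scores[ids - 1] = _minmax_01(np.log(s))
    strengths[ids - 1] = s
    counts = np.bincount(np.concatenate([winners, losers]), minlength=n_items + 1)[1:]
    return pd.DataFrame(
        {
            "item_id": np.arange(1, n_items + 1),
            "score": scores,
            "strength": strengths,
            "n_obs": counts,
            "algorithm": "bradley_terry",
        }
    )


_ALGOS = {
    "value_learning": lambda resp, n, cfg: value_learning(
        extract_pairwise(resp), n, cfg
    ),
    "bwrate": lambda resp, n, cfg: best_worst_rate(resp, n),
    "bradley_terry": lambda resp, n, cfg: bradley_terry_mle(extract_pairwise(resp), n),
}


def score_batches(
    responses: pd.DataFrame,
    lists: pd.DataFrame,
    n_items: int,
    config: LearnerConfig = LearnerConfig(),
    algorithm: str = "value_learning",
) -> pd.DataFrame:
    """Score each batch independently, then the pooled data.

    Batch labels come from the design table's ``batch`` column (catch trials,
    batch 0, are ignored here — they should already be filtered).  Returns a
    single long DataFrame with a ``batch`` column holding "1", "2", ...,
    and "pooled", plus a ``n_distinct`` granularity statistic per run.
    """
    if algorithm not in _ALGOS:
        raise ValueError(f"unknown algorithm '{algorithm}'")
    run = _ALGOS[algorithm]
    batch_of_list = (
        lists.loc[lists["is_catch"] == 0, ["list_id", "batch"]]
        .drop_duplicates()
        .set_index("list_id")["batch"]
    )
    resp = responses.copy()
    resp["batch"] = resp["list_id"].map(batch_of_list)
    out = []
    for b, grp in resp.groupby("batch", sort=True):
        scale = run(grp, n_items, config)
        scale["batch"] = str(int(b))
        scale["n_distinct"] = scale["score"].nunique()
        out.append(scale)
    pooled = run(resp, n_items, config)
    pooled["batch"] = "pooled"
    pooled["n_distinct"] = pooled["score"].nunique()
    out.append(pooled)
    return pd.concat(out, ignore_index=True)
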