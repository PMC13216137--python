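"""Synthetic raters for best-worst scaling studies.

Implements a Thurstonian (random-utility) choice model: each rater perceives
item utilities corrupted by i.i.d. Gumbel noise, picks the maximum as "best"
and the minimum as "worst" from one shared draw per trial.  Two departures
from the ideal rater are modeled because the study's quality control targets
them: limited word knowledge (an unknown item is pushed to the bottom of the
perceived ranking, following the task instruction to mark unknown words least
useful) and a careless subpopulation that answers uniformly at random.

With Gumbel noise the two-alternative margin has the logistic closed form
P(i best) = 1 / (1 + exp(-(u_i - u_j) / tau)), which the test suite uses as
an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "RaterModel",
    "sample_true_scale",
    "simulate_trial",
    "simulate_study",
    "prevalence_knowledge_rule",
]


def prevalence_knowledge_rule(prevalence: np.ndarray) -> np.ndarray:
    """Probability a rater knows an item = its population prevalence."""
    return np.clip(np.asarray(prevalence, dtype=float), 0.0, 1.0)


@dataclass
class RaterModel:
    """One simulated participant.

    Parameters
    ----------
    noise_scale : float
        Gumbel scale tau of the perceived-utility noise (> 0).
    p_know : mapping item_id -> probability, optional
        Probability the rater knows each item; items absent from the mapping
        are always known.  None means omniscient.
    careless : bool
        Careless raters answer best and worst uniformly at random.
    """

    noise_scale: float = 1.0
    p_know: dict[int, float] | None = None
    careless: bool = False

    def __post_init__(self) -> None:
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if self.p_know is not None:
            bad = [i for i, p in self.p_know.items() if not 0.0 <= p <= 1.0]
            if bad:
                raise ValueError(f"knowledge probabilities outside [0,1]: {bad[:5]}")


def sample_true_scale(
    n_items: int,
    distribution: str = "normal",
    seed: int | np.random.Generator = 0,
    **params,
) -> pd.Series:
    """Draw latent true utilities for ``n_items`` items (ids 1..n).

    ``distribution`` is one of ``normal`` (default, loc/scale), ``uniform``
    (low/high) or ``lognormal``.  The true scale is simulation ground truth:
    scoring never sees it.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if distribution == "normal":
        vals = rng.normal(params.get("loc", 0.0), params.get("scale", 1.0), n_items)
    elif distribution == "uniform":
        vals = rng.uniform(params.get("low", 0.0), params.get("high", 1.0), n_items)
    elif distribution == "lognormal":
        vals = rng.lognormal(params.get("mean", 0.0), params.get("sigma", 1.0), n_items)
    else:
        raise ValueError(f"unknown distribution '{distribution}'")
    return pd.Series(vals, index=pd.RangeIndex(1, n_items + 1, name="item_id"), name="true_utility")


def simulate_trial(
    item_ids: np.ndarray,
    utilities: np.ndarray,
    rater: RaterModel,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Simulate one best-worst judgment; returns (best_id, worst_id).

    Perceived value = true utility + Gumbel(0, tau), one shared draw for the
    trial.  Items the rater fails a knowledge draw for are forced below every
    known item (ties among unknowns broken uniformly).  Careless raters pick
    both answers uniformly without replacement.
    """
    item_ids = np.asarray(item_ids)
    m = item_ids.size
    if m < 2 or np.unique(item_ids).size != m:
        raise ValueError("trial needs >= 2 distinct items")
    if rater.careless:
        b, w = rng.choice(m, size=2, replace=False)
        return int(item_ids[b]), int(item_ids[w])
    perceived = np.asarray(utilities, dtype=float) + rng.gumbel(
        0.0, rater.noise_scale, m
    )
    if rater.p_know is not None:
        p = np.array([rater.p_know.get(int(i), 1.0) for i in item_ids])
        unknown = rng.random(m) >= p
        if unknown.all():
            # nothing known: the whole trial is a uniform guess
            b, w = rng.choice(m, size=2, replace=False)
            return int(item_ids[b]), int(item_ids[w])
        if unknown.any():
            floor = perceived[~unknown].min()
            # uniform tie-break among unknowns via a random subordering
            perceived = perceived.copy()
            perceived[unknown] = floor - 1.0 - rng.permutation(unknown.sum())
    best = int(np.argmax(perceived))
    worst = int(np.argmin(perceived))
    return int(item_ids[best]), int(item_ids[worst])


def simulate_study(
    lists: pd.DataFrame,
    true_scale: pd.Series,
    tau: float = 1.0,
    careless_fraction: float = 0.0,
    knowledge: pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full study: one rater per participant list.

    Parameters
    ----------
    lists : DataFrame
        Long-format design table from :func:`bwsnorm.design.assemble_lists`.
    true_scale : Series
        item_id -> latent true utility.  Items missing from the scale
        (e.g. catch fillers in a toy setup) default to utility 0.
    tau : float
        Gumbel noise scale shared by all attentive raters.
    careless_fraction : float
        Probability each rater is careless, drawn independently per rater.
    knowledge : Series, optional
        item_id -> probability a rater knows the item (e.g. word prevalence).
        None means every rater knows every item.
    seed : int
        Master seed; per-participant streams are spawned from it so the
        table is reproducible regardless of execution order.

    Returns
    -------
    DataFrame
        Long-format responses: ``participant_id``, ``list_id``,
        ``trial_index``, ``pos1..posM``, ``best_id``, ``worst_id``.
    """
    util = true_scale.to_dict()
    know = knowledge.to_dict() if knowledge is not None else None
    m = int(lists["position"].max())

    wide = (
        lists.pivot_table(
            index=["list_id", "trial_index"],
            columns="position",
            values="item_id",
            aggfunc="first",
        )
        .sort_index()
        .to_numpy(dtype=np.int64)
    )
    trial_index = (
        lists[["list_id", "trial_index"]].drop_duplicates().sort_values(
            ["list_id", "trial_index"]
        )
    )
    list_ids = trial_index["list_id"].to_numpy()
    uniq_lists = np.unique(list_ids)

    master = np.random.SeedSequence(seed)
    children = master.spawn(len(uniq_lists))
    rows = []
    for pid, (lid, child) in enumerate(zip(uniq_lists, children), start=1):
        rng = np.random.default_rng(child)
        rater = RaterModel(
            noise_scale=tau,
            p_know=know,
            careless=bool(rng.random() < careless_fraction),
        )
        mask = list_ids == lid
        for trials_row, tidx in zip(wide[mask], trial_index.loc[mask, "trial_index"]):
            utils = np.array([util.get(int(i), 0.0) for i in trials_row])
            best, worst = simulate_trial(trials_row, utils, rater, rng)
            rows.append((pid, int(lid), int(tidx), *trials_row.tolist(), best, worst))
    cols = ["participant_id", "list_id", "trial_index"]
    cols += [f"pos{i}" for i in range(1, m + 1)]
    cols += ["best_id", "worst_id"]
    return pd.DataFrame(rows, columns=cols)
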