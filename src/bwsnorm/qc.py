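"""Catch-trial quality control.

Each participant list embeds a handful of catch trials with an obvious
designated best and designated worst alternative.  A participant collects a
penalty of 3 for a full inversion in a slot (picking the designated worst as
best, or the designated best as worst) and a penalty of 1 for picking any of
the middle alternatives in either slot; correct picks cost 0.  Penalties are
summed over the catch trials and participants whose total strictly exceeds
the threshold are excluded as careless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "QCResult",
    "score_catch_trial",
    "evaluate_participants",
    "filter_responses",
    "catch_keys_from_lists",
]


@dataclass(frozen=True)
class QCConfig:
    penalty_inversion: int = 3
    penalty_other: int = 1
    exclusion_threshold: int = 5  # strict: excluded iff total > threshold

    def __post_init__(self) -> None:
        if self.penalty_inversion <= 0 or self.penalty_other <= 0:
            raise ValueError("penalties must be positive")
        if self.exclusion_threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class QCResult:
    participant_id: int
    total_penalty: int
    per_trial_penalties: list[int] = field(default_factory=list)
    excluded: bool = False
    unscorable: bool = False


def score_catch_trial(
    best_id: int,
    worst_id: int,
    catch_key: tuple[int, int],
    config: QCConfig = QCConfig(),
    shown: tuple[int, ...] | None = None,
) -> int:
    """Penalty for one catch-trial response.

    ``catch_key`` is (designated best, designated worst).  The best slot
    scores ``penalty_inversion`` if the designated worst was chosen,
    ``penalty_other`` for any middle alternative, 0 for the designated best;
    the worst slot is symmetric.  The trial penalty is the sum of both slots.
    """
    key_best, key_worst = catch_key
    if shown is not None and (best_id not in shown or worst_id not in shown):
        raise ValueError(
            f"chosen item not among shown alternatives: best={best_id} "
            f"worst={worst_id} shown={shown}"
        )
    if best_id == worst_id:
        raise ValueError("best and worst choices must differ")

    def slot(chosen: int, correct: int, inverted: int) -> int:
        if chosen == correct:
            return 0
        if chosen == inverted:
            return config.penalty_inversion
        return config.penalty_other

    return slot(best_id, key_best, key_worst) + slot(worst_id, key_worst, key_best)


def catch_keys_from_lists(lists: pd.DataFrame) -> pd.DataFrame:
    """Extract per-(list_id, trial_index) catch keys from a design table."""
    catch = lists[lists["is_catch"] == 1]
    best = catch[catch["catch_best"] == 1].set_index(["list_id", "trial_index"])[
        "item_id"
    ]
    worst = catch[catch["catch_worst"] == 1].set_index(["list_id", "trial_index"])[
        "item_id"
    ]
    out = pd.DataFrame({"key_best": best, "key_worst": worst}).reset_index()
    return out


def evaluate_participants(
    responses: pd.DataFrame,
    catch_keys: pd.DataFrame,
    config: QCConfig = QCConfig(),
    n_catch_expected: int | None = None,
) -> list[QCResult]:
    """Score every participant's catch trials and set exclusion verdicts.

    ``catch_keys`` carries ``list_id``, ``trial_index``, ``key_best``,
    ``key_worst`` (see :func:`catch_keys_from_lists`).  A participant with a
    missing catch trial is marked unscorable rather than silently passed.
    """
    merged = responses.merge(catch_keys, on=["list_id", "trial_index"], how="inner")
    if n_catch_expected is None:
        n_catch_expected = catch_keys.groupby("list_id").size().max()
        n_catch_expected = int(n_catch_expected) if pd.notna(n_catch_expected) else 0
    results = []
    for pid, grp in merged.groupby("participant_id", sort=True):
        pens = [
            score_catch_trial(
                int(r.best_id), int(r.worst_id), (int(r.key_best), int(r.key_worst)), config
            )
            for r in grp.itertuples()
        ]
        res = QCResult(
            participant_id=int(pid),
            total_penalty=int(sum(pens)),
            per_trial_penalties=pens,
        )
        if len(pens) != n_catch_expected:
            res.unscorable = True
            res.excluded = True
        else:
            res.excluded = res.total_penalty > config.exclusion_threshold
        results.append(res)
    # participants with zero catch trials never hit the merge
    seen = {r.participant_id for r in results}
    for pid in responses["participant_id"].unique():
        if int(pid) not in seen and n_catch_expected > 0:
            results.append(
                QCResult(int(pid), 0, [], excluded=True, unscorable=True)
            )
    results.sort(key=lambda r: r.participant_id)
    return results


def qc_table(results: list[QCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "total_penalty": [r.total_penalty for r in results],
            "excluded": [int(r.excluded) for r in results],
            "unscorable": [int(r.unscorable) for r in results],
        }
    )


def filter_responses(
    responses: pd.DataFrame,
    qc_results: list[QCResult],
    lists: pd.DataFrame | None = None,
    include_catch: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Drop excluded participants (and, by default, all catch trials).

    Returns the retained response table and a report dict with counts and
    the excluded fraction.  ``include_catch=True`` keeps catch-trial
    responses of retained participants, mirroring a scoring run over the
    full pool.
    """
    excluded_ids = {r.participant_id for r in qc_results if r.excluded}
    keep = ~responses["participant_id"].isin(excluded_ids)
    out = responses[keep].copy()
    if not include_catch and lists is not None:
        catch = lists.loc[lists["is_catch"] == 1, ["list_id", "trial_index"]].drop_duplicates()
        mark = out.merge(catch, on=["list_id", "trial_index"], how="left", indicator=True)
        out = out[(mark["_merge"] == "left_only").to_numpy()]
    n_total = responses["participant_id"].nunique()
    report = {
        "n_participants": int(n_total),
        "n_excluded": len(excluded_ids),
        "excluded_fraction": len(excluded_ids) / n_total if n_total else float("nan"),
        "n_retained_rows": int(len(out)),
    }
    if out.empty:
        report["warning"] = "all participants excluded; retained table is empty"
    return out.reset_index(drop=True), report
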