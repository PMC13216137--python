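"""Best-worst scaling experimental design.

Constructs the tuple design of a large-scale lexical norming study: items are
arranged into sets of ``m`` alternatives such that every item appears exactly
``k`` times, no unordered pair of items ever co-occurs twice, and the sets are
partitioned into batches of equal per-item replication.  Pair avoidance
maximizes the number of distinct comparators per item — ``k * (m - 1)`` of
them — which is what makes best-worst judgments efficient at scale.

Lists of trials (45 real sets plus 5 fixed catch trials by default) are the
unit given to a single participant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "ItemSet",
    "Design",
    "DesignError",
    "InfeasibleDesignError",
    "prepare_item_pool",
    "generate_tuple_design",
    "co_occurrence_stats",
    "build_catch_sets",
    "assemble_lists",
]


class DesignError(ValueError):
    """A design request that cannot be satisfied."""


class InfeasibleDesignError(DesignError):
    """The requested (N, k, m) admits no pair-avoiding design."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a best-worst tuple design.

    Parameters
    ----------
    n_items : int
        Number of items N in the (pruned) pool.
    reps_per_item : int
        Total appearances k of each item across the whole design (default 18).
    set_size : int
        Alternatives m shown per trial (default 6).
    sets_per_list : int
        Real (non-catch) trials per participant list (default 45).
    catch_trials_per_list : int
        Fixed quality-control trials inserted into every list (default 5).
    n_batches : int
        Independent replication blocks (default 3); each contributes
        ``reps_per_item / n_batches`` appearances per item.
    familiarity_cutoff : float
        Items with a familiarity rating strictly below this are pruned
        from the pool before design generation (default 3.5 on a 1-7 scale).
    rng_seed : int
        Seed for the design construction.
    """

    n_items: int
    reps_per_item: int = 18
    set_size: int = 6
    sets_per_list: int = 45
    catch_trials_per_list: int = 5
    n_batches: int = 3
    familiarity_cutoff: float = 3.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size < 2:
            raise DesignError("set_size must be at least 2")
        if self.n_items < self.set_size:
            raise DesignError("need at least set_size items")
        if self.reps_per_item % self.n_batches:
            raise DesignError(
                f"reps_per_item={self.reps_per_item} not divisible by "
                f"n_batches={self.n_batches}"
            )
        if (self.n_items * self.reps_per_item) % self.set_size:
            raise DesignError(
                f"N*k = {self.n_items * self.reps_per_item} not divisible by "
                f"m = {self.set_size}; choose N, k so sets come out whole"
            )

    @property
    def reps_per_batch(self) -> int:
        return self.reps_per_item // self.n_batches

    @property
    def n_sets(self) -> int:
        """Total number of item sets, N*k/m."""
        return self.n_items * self.reps_per_item // self.set_size

    @property
    def n_sets_per_batch(self) -> int:
        return self.n_items * self.reps_per_batch // self.set_size

    @property
    def trials_per_list(self) -> int:
        return self.sets_per_list + self.catch_trials_per_list

    def check_feasible(self) -> None:
        """Pair avoidance needs N - 1 >= k*(m - 1) distinct comparators."""
        need = self.reps_per_item * (self.set_size - 1)
        if self.n_items - 1 < need:
            raise InfeasibleDesignError(
                f"pair-avoiding design infeasible: each item needs "
                f"k*(m-1) = {need} distinct comparators but only "
                f"N-1 = {self.n_items - 1} other items exist"
            )


@dataclass(frozen=True)
class ItemSet:
    """One trial's worth of alternatives."""

    set_id: int
    item_ids: tuple[int, ...]
    batch: int = 0
    is_catch: bool = False
    catch_key: tuple[int, int] | None = None  # (designated best, designated worst)

    def __post_init__(self) -> None:
        if len(set(self.item_ids)) != len(self.item_ids):
            raise DesignError(f"set {self.set_id}: duplicate items")
        if self.is_catch:
            if self.catch_key is None:
                raise DesignError(f"catch set {self.set_id} lacks a key")
            b, w = self.catch_key
            if b not in self.item_ids or w not in self.item_ids or b == w:
                raise DesignError(f"catch set {self.set_id}: bad key ({b}, {w})")


@dataclass
class Design:
    """A materialized tuple design.

    ``sets`` is an (n_sets, m) array of item ids (1-based, dense), ``batch``
    the 1-based batch label per set.
    """

    sets: np.ndarray
    batch: np.ndarray
    spec: DesignSpec

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    def item_sets(self) -> list[ItemSet]:
        return [
            ItemSet(set_id=i + 1, item_ids=tuple(int(x) for x in row), batch=int(b))
            for i, (row, b) in enumerate(zip(self.sets, self.batch))
        ]


# ---------------------------------------------------------------------------
# item pool


def prepare_item_pool(raw_items: pd.DataFrame, cutoff: float = 3.5) -> pd.DataFrame:
    """Prune unfamiliar items and assign dense 1-based ids.

    Items whose ``familiarity`` rating is strictly below ``cutoff`` are
    removed (a rating of exactly ``cutoff`` is retained); items without a
    familiarity rating are retained.  Raises if nothing survives.

    Parameters
    ----------
    raw_items : DataFrame
        Must carry an ``item`` (or ``text``) column; optional ``is_mwe``,
        ``familiarity`` and arbitrary numeric covariate columns pass through.
    """
    df = raw_items.copy()
    if "item" not in df.columns:
        if "text" in df.columns:
            df = df.rename(columns={"text": "item"})
        else:
            raise DesignError("item pool needs an 'item' (or 'text') column")
    if df["item"].isna().any() or (df["item"].astype(str).str.len() == 0).any():
        raise DesignError("item pool contains empty item text")

    n_before = len(df)
    if "familiarity" in df.columns:
        fam = pd.to_numeric(df["familiarity"], errors="coerce")
        keep = fam.isna() | (fam >= cutoff)
        df = df[keep]
    if df.empty:
        raise DesignError(
            f"no items remain after familiarity pruning at cutoff {cutoff} "
            f"({n_before} in, 0 out)"
        )
    df = df.reset_index(drop=True)
    df.insert(0, "item_id", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# tuple design construction


def _build_batch(
    n_items: int,
    set_size: int,
    reps: int,
    used_pairs: set[int],
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Construct one batch of a pair-avoiding design.

    Two phases.  Greedy seeding: sets are filled item-by-item preferring
    items with the most remaining appearance quota (random tie-break),
    skipping candidates that would repeat a pair used in this or an earlier
    batch; when no conflict-free candidate remains the best conflicting one
    is taken anyway.  Min-conflicts repair: tokens are swapped between sets
    (preserving per-item appearance counts exactly) until no pair occurs
    twice, with occasional uphill moves to escape plateaus.  Returns None if
    repair stalls (caller restarts from a fresh substream).
    """
    m = set_size
    n_sets = n_items * reps // m
    quota = np.full(n_items, reps, dtype=np.int64)
    sets_arr = np.empty((n_sets, m), dtype=np.int64)

    # --- phase 1: greedy seeding -----------------------------------------
    for s in range(n_sets):
        pool = np.flatnonzero(quota > 0)
        order = pool[np.lexsort((rng.random(pool.size), -quota[pool]))]
        chosen: list[int] = []
        for cand in order:
            ok = True
            for c in chosen:
                a, b = (c, cand) if c < cand else (cand, c)
                if a * n_items + b in used_pairs:
                    ok = False
                    break
            if ok:
                chosen.append(int(cand))
                if len(chosen) == m:
                    break
        if len(chosen) < m:  # forced conflicting picks (repair fixes later)
            for cand in order:
                if cand not in chosen:
                    chosen.append(int(cand))
                    if len(chosen) == m:
                        break
        while len(chosen) < m:  # quota exhausted on distinct items
            chosen.append(int(order[0]))
        sets_arr[s] = chosen
        for c in chosen:
            quota[c] -= 1

    # --- phase 2: min-conflicts swap repair ------------------------------
    def key_of(a: int, b: int) -> int:
        return a * n_items + b if a <= b else b * n_items + a

    count: dict[int, int] = {}
    pair_sets: dict[int, list[int]] = {}
    bad: set[int] = set()

    def cost(key: int, c: int) -> int:
        if c <= 0:
            return 0
        a, b = divmod(key, n_items)
        if a == b:  # duplicate item inside a set: always a conflict
            return c
        return (c - 1) + (c if key in used_pairs else 0)

    def inc(key: int, s: int) -> int:
        c = count.get(key, 0)
        count[key] = c + 1
        pair_sets.setdefault(key, []).append(s)
        d = cost(key, c + 1) - cost(key, c)
        if cost(key, c + 1) > 0:
            bad.add(key)
        return d

    def dec(key: int, s: int) -> int:
        c = count[key]
        count[key] = c - 1
        pair_sets[key].remove(s)
        d = cost(key, c - 1) - cost(key, c)
        if cost(key, c - 1) <= 0:
            bad.discard(key)
        return d

    for s in range(n_sets):
        row = sets_arr[s]
        for i in range(m):
            for j in range(i + 1, m):
                inc(key_of(int(row[i]), int(row[j])), s)

    def swap_delta(s1: int, i1: int, s2: int, i2: int) -> int:
        """Apply the token swap and return the energy delta."""
        a, b = int(sets_arr[s1, i1]), int(sets_arr[s2, i2])
        d = 0
        for i in range(m):
            if i != i1:
                d += dec(key_of(a, int(sets_arr[s1, i])), s1)
        for i in range(m):
            if i != i2:
                d += dec(key_of(b, int(sets_arr[s2, i])), s2)
        sets_arr[s1, i1], sets_arr[s2, i2] = b, a
        for i in range(m):
            if i != i1:
                d += inc(key_of(b, int(sets_arr[s1, i])), s1)
        for i in range(m):
            if i != i2:
                d += inc(key_of(a, int(sets_arr[s2, i])), s2)
        return d

    max_moves = 2000 * n_sets
    stall_window = 2000 + 50 * n_sets
    energy = sum(cost(k, c) for k, c in count.items())
    best_energy, best_at = energy, 0
    moves = 0
    n_cand = 8
    while bad and moves < max_moves:
        moves += 1
        if moves - best_at > stall_window:
            return None  # stagnated: let the caller reseed
        key = next(iter(bad)) if len(bad) == 1 else rng.choice(tuple(bad))
        s1 = int(rng.choice(pair_sets[key]))
        a, b = divmod(int(key), n_items)
        victim = a if (a == b or rng.random() < 0.5) else b
        i1 = int(np.flatnonzero(sets_arr[s1] == victim)[0])
        # sample a few swap partners, keep the best
        best_d, best_move = None, None
        for s2 in rng.integers(0, n_sets, n_cand):
            s2 = int(s2)
            if s2 == s1:
                continue
            i2 = int(rng.integers(m))
            other = int(sets_arr[s2, i2])
            if other == victim or other in sets_arr[s1] or victim in sets_arr[s2]:
                continue
            d = swap_delta(s1, i1, s2, i2)
            swap_delta(s1, i1, s2, i2)  # revert: dry-run evaluation
            if best_d is None or d < best_d:
                best_d, best_move = d, (s2, i2)
        if best_move is None:
            continue
        if best_d <= 0 or rng.random() < 0.02:
            s2, i2 = best_move
            energy += swap_delta(s1, i1, s2, i2)
            if energy < best_energy:
                best_energy, best_at = energy, moves

    if bad:
        return None
    for k, c in count.items():
        if c > 0:
            used_pairs.add(k)
    return sets_arr


def generate_tuple_design(
    items: pd.DataFrame | int,
    spec: DesignSpec,
    max_restarts: int = 100,
) -> Design:
    """Construct the pair-avoiding tuple design described by ``spec``.

    Produces exactly ``N*k/m`` sets in which every item appears exactly ``k``
    times, no unordered item pair occurs in more than one set (globally,
    across batches), and each of the ``n_batches`` batches holds exactly
    ``reps_per_batch`` appearances of every item.

    Construction is seeded greedy sampling followed by min-conflicts repair
    (see :func:`_build_batch`); a batch whose repair stalls is rebuilt from a
    fresh substream, escalating to a full rebuild of all batches, up to
    ``max_restarts`` stalls in total.  Byte-identical output for identical
    spec + seed.
    """
    n = int(items) if isinstance(items, int) else len(items)
    if n != spec.n_items:
        raise DesignError(f"pool size {n} != spec.n_items {spec.n_items}")
    spec.check_feasible()

    ss = np.random.SeedSequence(spec.rng_seed)
    restarts = 0
    batch_fail_limit = 5
    while True:
        used_pairs: set[int] = set()
        batch_blocks: list[np.ndarray] = []
        for b in range(spec.n_batches):
            block = None
            for _ in range(batch_fail_limit):
                rng = np.random.default_rng(ss.spawn(1)[0])
                block = _build_batch(
                    n, spec.set_size, spec.reps_per_batch, used_pairs, rng
                )
                if block is not None:
                    break
                restarts += 1
                if restarts > max_restarts:
                    raise DesignError(
                        f"construction dead-ended after {restarts} restarts "
                        f"(cap {max_restarts}); the spec may be too dense for "
                        f"a pair-avoiding design"
                    )
            if block is None:
                break  # rebuild earlier batches too: global restart
            batch_blocks.append(block)
        if len(batch_blocks) == spec.n_batches:
            break

    sets = np.vstack(batch_blocks) + 1  # 1-based ids
    batch = np.repeat(
        np.arange(1, spec.n_batches + 1), [len(blk) for blk in batch_blocks]
    )
    return Design(sets=sets, batch=batch, spec=spec)


def co_occurrence_stats(design: Design) -> dict:
    """Distinct-comparator counts per item.

    For a pair-avoiding design every item co-occurs with exactly
    ``k * (m - 1)`` distinct other items.

    Returns a dict with ``counts`` (pandas Series indexed by item_id),
    ``min``, ``max``, and ``n_repeated_pairs`` (0 when pair avoidance holds).
    """
    n = design.spec.n_items
    sets = design.sets
    m = sets.shape[1]
    i_idx, j_idx = np.triu_indices(m, k=1)
    a = sets[:, i_idx].ravel()
    b = sets[:, j_idx].ravel()
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    keys = (lo - 1) * n + (hi - 1)
    uniq, cnt = np.unique(keys, return_counts=True)
    n_repeated = int((cnt > 1).sum())
    lo_u, hi_u = uniq // n + 1, uniq % n + 1
    counts = (
        pd.Series(np.concatenate([lo_u, hi_u]))
        .value_counts()
        .reindex(np.arange(1, n + 1), fill_value=0)
        .sort_index()
    )
    counts.index.name = "item_id"
    return {
        "counts": counts,
        "min": int(counts.min()),
        "max": int(counts.max()),
        "n_repeated_pairs": n_repeated,
    }


# ---------------------------------------------------------------------------
# catch trials and lists


def build_catch_sets(
    pool: pd.DataFrame,
    n_catch: int,
    spec: DesignSpec,
    seed: int = 0,
    worst_max_prevalence: float = 0.01,
    explicit: list[ItemSet] | None = None,
) -> list[ItemSet]:
    """Build the fixed catch trials reused across every participant list.

    Each catch set pairs a designated best (drawn from the highest-prevalence
    items) with a designated worst whose prevalence is below
    ``worst_max_prevalence`` (i.e. known by fewer than 1% of people), plus
    ``m - 2`` filler items.  Supplying ``explicit`` bypasses construction.
    """
    if explicit is not None:
        return list(explicit)
    if n_catch == 0:
        return []
    if "prevalence" not in pool.columns:
        raise DesignError("pool lacks a 'prevalence' column needed for catch trials")
    prev = pd.to_numeric(pool["prevalence"], errors="coerce")
    worst_pool = pool.loc[prev < worst_max_prevalence, "item_id"].to_numpy()
    if worst_pool.size < n_catch:
        raise DesignError(
            f"only {worst_pool.size} items have prevalence < "
            f"{worst_max_prevalence}; need {n_catch} designated-worst items"
        )
    best_pool = (
        pool.loc[prev.notna()]
        .sort_values("prevalence", ascending=False)["item_id"]
        .head(max(n_catch * 4, n_catch))
        .to_numpy()
    )
    rng = np.random.default_rng(seed)
    worsts = rng.choice(worst_pool, size=n_catch, replace=False)
    bests = rng.choice(best_pool[: n_catch * 4], size=n_catch, replace=False)
    middles_pool = pool.loc[
        ~pool["item_id"].isin(np.concatenate([worsts, bests])), "item_id"
    ].to_numpy()
    out = []
    for c in range(n_catch):
        mids = rng.choice(middles_pool, size=spec.set_size - 2, replace=False)
        middles_pool = middles_pool[~np.isin(middles_pool, mids)]
        ids = tuple(int(x) for x in rng.permutation(np.r_[bests[c], worsts[c], mids]))
        out.append(
            ItemSet(
                set_id=-(c + 1),
                item_ids=ids,
                batch=0,
                is_catch=True,
                catch_key=(int(bests[c]), int(worsts[c])),
            )
        )
    return out


def assemble_lists(
    design: Design,
    catch_sets: list[ItemSet],
    spec: DesignSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Partition real sets into participant lists and splice in catch trials.

    Every real set is assigned to exactly one list; each list draws its
    ``sets_per_list`` real sets from a single batch and receives all catch
    sets at seeded-random trial positions.  Within-trial display order is a
    seeded shuffle.

    Returns the long-format design table, one row per (trial, position):
    columns ``set_id``, ``batch``, ``list_id``, ``trial_index``, ``position``
    (1..m), ``item_id``, ``is_catch``, ``catch_best``, ``catch_worst``.
    """
    spec = spec or design.spec
    if len(catch_sets) != spec.catch_trials_per_list:
        raise DesignError(
            f"{len(catch_sets)} catch sets supplied but spec asks for "
            f"{spec.catch_trials_per_list} per list"
        )
    per_batch = spec.n_sets_per_batch
    if per_batch % spec.sets_per_list:
        lo = per_batch // (per_batch // spec.sets_per_list + 1)
        raise DesignError(
            f"{per_batch} real sets per batch not divisible by "
            f"sets_per_list={spec.sets_per_list}; nearest feasible values "
            f"divide {per_batch} evenly (e.g. {lo})"
        )
    rng = np.random.default_rng(seed)
    m = spec.set_size
    rows: list[tuple] = []
    list_id = 0
    for b in range(1, spec.n_batches + 1):
        idx = np.flatnonzero(design.batch == b)
        idx = rng.permutation(idx)
        for chunk in idx.reshape(-1, spec.sets_per_list):
            list_id += 1
            n_trials = spec.sets_per_list + len(catch_sets)
            catch_pos = set(
                rng.choice(n_trials, size=len(catch_sets), replace=False).tolist()
            )
            real_iter = iter(chunk)
            catch_iter = iter(catch_sets)
            for t in range(n_trials):
                if t in catch_pos:
                    cs = next(catch_iter)
                    ids = rng.permutation(cs.item_ids)
                    for pos, iid in enumerate(ids, start=1):
                        rows.append(
                            (
                                cs.set_id,
                                b,
                                list_id,
                                t + 1,
                                pos,
                                int(iid),
                                1,
                                int(iid == cs.catch_key[0]),
                                int(iid == cs.catch_key[1]),
                            )
                        )
                else:
                    s = next(real_iter)
                    ids = rng.permutation(design.sets[s])
                    for pos, iid in enumerate(ids, start=1):
                        rows.append((int(s + 1), b, list_id, t + 1, pos, int(iid), 0, 0, 0))
    return pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "batch",
            "list_id",
            "trial_index",
            "position",
            "item_id",
            "is_catch",
            "catch_best",
            "catch_worst",
        ],
    )
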