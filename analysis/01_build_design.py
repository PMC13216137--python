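#!/usr/bin/env python
"""Build the best-worst experimental design for a reduced simulated study.

Pool of 1,800 synthetic items (the full study normed 82,880), 18
presentations per item in sets of 6 across three batches, 45 real sets plus
the 5 fixed catch trials per participant list.  Writes the pool, the truth
table and the long-format design under results/design/.
"""

from pathlib import Path

import numpy as np

from bwsnorm import design as dz
from bwsnorm import norms_analysis as na

N_CANDIDATES = 2400  # synthesized entries before familiarity pruning
N_ITEMS = 1800       # normed pool (must divide into 45-set lists per batch)
SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "design"


def main() -> None:
    raw, true_utility = na.synthesize_predictor_table(N_CANDIDATES, seed=SEED)
    pool = dz.prepare_item_pool(raw.rename(columns={"item_id": "candidate_id"}), cutoff=3.5)
    print(f"pool: {N_CANDIDATES} synthesized, {len(pool)} after familiarity pruning (cutoff 3.5)")
    if len(pool) < N_ITEMS:
        raise SystemExit(f"only {len(pool)} items survive pruning; need {N_ITEMS}")
    pool = pool.head(N_ITEMS).copy()
    true_utility = true_utility.loc[pool["candidate_id"]]
    pool = pool.drop(columns=["candidate_id"])
    print(f"normed pool: first {N_ITEMS} surviving items")

    spec = dz.DesignSpec(
        n_items=len(pool), reps_per_item=18, set_size=6, sets_per_list=45,
        catch_trials_per_list=5, n_batches=3, rng_seed=SEED,
    )
    design = dz.generate_tuple_design(pool, spec)
    stats = dz.co_occurrence_stats(design)
    print(
        f"design: {design.n_sets} sets; repeated pairs {stats['n_repeated_pairs']}; "
        f"distinct comparators per item {stats['min']}..{stats['max']} "
        f"(expected {spec.reps_per_item * (spec.set_size - 1)})"
    )

    # obscure probe words for the catch trials (known by <1% of people)
    rare = pool["prevalence"].nsmallest(5).index
    pool.loc[rare, "prevalence"] = 0.003
    catch = dz.build_catch_sets(pool, 5, spec, seed=SEED)
    lists = dz.assemble_lists(design, catch, spec, seed=SEED)
    n_lists = lists["list_id"].nunique()
    print(f"lists: {n_lists} participant lists of 50 trials (45 real + 5 catch)")

    # clear catch-trial answers: lift the designated bests, sink the worsts
    truth = true_utility.copy()
    truth.index = pool["item_id"]
    for cs in catch:
        truth[cs.catch_key[0]] = truth.max() + 2.0
        truth[cs.catch_key[1]] = truth.min() - 2.0

    OUT.mkdir(parents=True, exist_ok=True)
    pool.to_csv(OUT / "pool.tsv", sep="\t", index=False)
    truth.rename("true_utility").reset_index().to_csv(OUT / "truth.tsv", sep="\t", index=False)
    lists.to_csv(OUT / "design.tsv", sep="\t", index=False)
    print(f"wrote {OUT}/pool.tsv, truth.tsv, design.tsv")


if __name__ == "__main__":
    main()
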