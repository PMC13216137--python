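#!/usr/bin/env python
"""Estimate expected-utility scores per batch and pooled.

Each response implies nine pairwise preferences (best beats five, four
middles beat worst); the Value-Learning scorer turns the preference stream
into scores on [0, 1].  Scores are computed per batch (6 observations per
item) and pooled (18), and cross-checked against the Bradley-Terry MLE and
the best-worst counting rate.  Writes results/scores.tsv.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from bwsnorm import scoring as sc

SEED = 7
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    retained = pd.read_csv(ROOT / "retained.tsv", sep="\t")
    lists = pd.read_csv(ROOT / "design" / "design.tsv", sep="\t")
    pool = pd.read_csv(ROOT / "design" / "pool.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "design" / "truth.tsv", sep="\t").set_index("item_id")[
        "true_utility"
    ]

    cfg = sc.LearnerConfig(shuffle_seed=SEED)
    scores = sc.score_batches(retained, lists, n_items=len(pool), config=cfg)
    pooled = scores[scores["batch"] == "pooled"].set_index("item_id")["score"]

    rho_truth = spearmanr(truth, pooled.reindex(truth.index), nan_policy="omit").statistic
    print(f"pooled Value-Learning scores: Spearman vs planted truth = {rho_truth:.3f}")

    prefs = sc.extract_pairwise(retained)
    bt = sc.bradley_terry_mle(prefs, len(pool))
    bw = sc.best_worst_rate(retained, len(pool))
    rho_bt = spearmanr(pooled, bt["score"], nan_policy="omit").statistic
    rho_bw = spearmanr(pooled, bw["score"], nan_policy="omit").statistic
    print(f"rank agreement: vs Bradley-Terry {rho_bt:.4f}, vs best-worst rate {rho_bw:.4f}")

    by = scores.groupby("batch")["n_distinct"].first()
    print("granularity (distinct score values):", by.to_dict())

    out = scores.merge(pool[["item_id", "item"]], on="item_id", how="left")
    cols = ["item", "item_id", "score", "n_obs", "algorithm", "batch", "n_distinct"]
    out[cols].to_csv(ROOT / "scores.tsv", sep="\t", index=False)
    print(f"wrote {ROOT}/scores.tsv")


if __name__ == "__main__":
    main()
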