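#!/usr/bin/env python
"""Simulate raters over every participant list.

One Thurstonian rater per list: perceived utility = true utility + Gumbel
noise (tau = 1), unknown items (knowledge probability = word prevalence)
marked least useful, and a 10.7% careless subpopulation answering at
random — the share of participants the quality control is built to catch.
Writes results/responses.tsv.
"""

from pathlib import Path

import pandas as pd

from bwsnorm import simulate as sim

SEED = 7
TAU = 1.0
CARELESS = 0.107
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    lists = pd.read_csv(ROOT / "design" / "design.tsv", sep="\t")
    pool = pd.read_csv(ROOT / "design" / "pool.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "design" / "truth.tsv", sep="\t").set_index("item_id")[
        "true_utility"
    ]
    knowledge = pool.set_index("item_id")["prevalence"].clip(0, 1)

    responses = sim.simulate_study(
        lists, truth, tau=TAU, careless_fraction=CARELESS,
        knowledge=knowledge, seed=SEED,
    )
    n_p = responses["participant_id"].nunique()
    print(
        f"simulated {n_p} raters x 50 trials = {len(responses)} responses "
        f"(tau={TAU}, careless={CARELESS:.1%}, knowledge=prevalence)"
    )
    responses.to_csv(ROOT / "responses.tsv", sep="\t", index=False)
    print(f"wrote {ROOT}/responses.tsv")


if __name__ == "__main__":
    main()
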