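#!/usr/bin/env python
"""Score catch trials and exclude careless participants.

Penalties: 3 per inverted slot (designated worst chosen as best or vice
versa), 1 for a middle alternative in either slot; totals above 5 over the
five catch trials exclude the participant.  Writes results/qc.tsv and the
retained (catch-free) response table results/retained.tsv.
"""

from pathlib import Path

import pandas as pd

from bwsnorm import qc

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    responses = pd.read_csv(ROOT / "responses.tsv", sep="\t")
    lists = pd.read_csv(ROOT / "design" / "design.tsv", sep="\t")

    results = qc.evaluate_participants(responses, qc.catch_keys_from_lists(lists))
    retained, report = qc.filter_responses(responses, results, lists=lists)

    qc.qc_table(results).to_csv(ROOT / "qc.tsv", sep="\t", index=False)
    retained.to_csv(ROOT / "retained.tsv", sep="\t", index=False)

    print(
        f"{report['n_participants']} participants; {report['n_excluded']} excluded "
        f"({report['excluded_fraction']:.1%}) — configured careless share was 10.7%"
    )
    totals = pd.Series([r.total_penalty for r in results])
    print(f"penalty totals: median {totals.median():.0f}, max {totals.max()}")
    print(f"retained {report['n_retained_rows']} real-trial responses -> {ROOT}/retained.tsv")


if __name__ == "__main__":
    main()
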