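"""End-to-end simulated norming studies.

Glue that runs the full chain — synthetic pool, pair-avoiding design, catch
trials, Thurstonian raters, catch-trial QC, Value-Learning scoring, and the
reliability report — with one master seed.  Both the analysis drivers and
the recovery evaluations build on this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bwsnorm import design as dz
from bwsnorm import norms_analysis as na
from bwsnorm import qc as qcm
from bwsnorm import reliability as rel
from bwsnorm import scoring as sc
from bwsnorm import simulate as sim

__all__ = ["StudyResult", "run_simulated_study", "pick_sets_per_list"]


@dataclass
class StudyResult:
    pool: pd.DataFrame
    lists: pd.DataFrame
    truth: pd.Series
    responses: pd.DataFrame
    qc_results: list = field(repr=False, default=None)
    qc_report: dict = None
    retained: pd.DataFrame = None
    scores: pd.DataFrame = None
    reliability: rel.ReliabilityReport = None

    @property
    def pooled_scores(self) -> pd.DataFrame:
        return self.scores[self.scores["batch"] == "pooled"]


def pick_sets_per_list(sets_per_batch: int, target: int = 45) -> int:
    """Largest-priority divisor of the per-batch set count nearest ``target``."""
    divisors = [d for d in range(2, min(sets_per_batch, 4 * target) + 1)
                if sets_per_batch % d == 0]
    if not divisors:
        raise dz.DesignError(f"{sets_per_batch} sets per batch has no usable divisor")
    return min(divisors, key=lambda d: (abs(d - target), -d))


def run_simulated_study(
    n_items: int,
    seed: int = 0,
    tau: float = 1.0,
    careless_fraction: float = 0.0,
    reps_per_item: int = 18,
    set_size: int = 6,
    sets_per_list: int | None = None,
    catch_per_list: int = 5,
    n_batches: int = 3,
    use_knowledge: bool = True,
    learner: sc.LearnerConfig | None = None,
    include_catch: bool = False,
) -> StudyResult:
    """Simulate a complete best-worst norming study and score it.

    The item pool comes from the synthetic covariate generator; latent true
    utilities are standard normal.  Catch trials get deliberately extreme
    probe items, mirroring how real catch trials pair an obviously useful
    expression with an obscure word: the designated worsts get prevalence
    well below 1% (so raters rarely know them) and the designated bests'
    true utilities are lifted clear of the pool.

    All randomness derives from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(6) % (2**31)
    spec_kwargs = dict(
        n_items=n_items,
        reps_per_item=reps_per_item,
        set_size=set_size,
        catch_trials_per_list=catch_per_list,
        n_batches=n_batches,
        rng_seed=int(seeds[0]),
    )
    probe = dz.DesignSpec(sets_per_list=2, **spec_kwargs)
    if sets_per_list is None:
        sets_per_list = pick_sets_per_list(probe.n_sets_per_batch)
    spec = dz.DesignSpec(sets_per_list=sets_per_list, **spec_kwargs)

    # the synthetic pool emulates the post-pruning item list, so the
    # familiarity filter has nothing to remove here
    raw, _ = na.synthesize_predictor_table(n_items, seed=int(seeds[1]))
    pool = dz.prepare_item_pool(
        raw.drop(columns=["item_id", "familiarity"]), spec.familiarity_cutoff
    )
    truth = sim.sample_true_scale(len(pool), seed=int(seeds[2]))

    catch_sets: list[dz.ItemSet] = []
    if catch_per_list > 0:
        # plant obscure probes (the study's obviously-unknown catch worsts)
        rare = pool["prevalence"].nsmallest(catch_per_list).index
        pool.loc[rare, "prevalence"] = 0.003
        catch_sets = dz.build_catch_sets(pool, catch_per_list, spec, seed=int(seeds[3]))
        for cs in catch_sets:
            truth[cs.catch_key[0]] = truth.max() + 2.0  # clearly best
            truth[cs.catch_key[1]] = truth.min() - 2.0  # clearly worst

    design = dz.generate_tuple_design(pool, spec)
    lists = dz.assemble_lists(design, catch_sets, spec, seed=int(seeds[3]))

    knowledge = None
    if use_knowledge:
        knowledge = pool.set_index("item_id")["prevalence"].clip(0.0, 1.0)
    responses = sim.simulate_study(
        lists, truth, tau=tau, careless_fraction=careless_fraction,
        knowledge=knowledge, seed=int(seeds[4]),
    )

    qc_results = qcm.evaluate_participants(
        responses, qcm.catch_keys_from_lists(lists)
    ) if catch_per_list > 0 else []
    retained, qc_report = qcm.filter_responses(
        responses, qc_results, lists=lists, include_catch=include_catch
    )

    learner = learner or sc.LearnerConfig(shuffle_seed=int(seeds[5]))
    scores = sc.score_batches(retained, lists, n_items=len(pool), config=learner)
    reliability = rel.reliability_report(scores)

    return StudyResult(
        pool=pool,
        lists=lists,
        truth=truth,
        responses=responses,
        qc_results=qc_results,
        qc_report=qc_report,
        retained=retained,
        scores=scores,
        reliability=reliability,
    )
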