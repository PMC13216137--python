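import numpy as np
import pandas as pd
import pytest

from bwsnorm import design as dz
from bwsnorm import norms_analysis as na


@pytest.fixture(scope="session")
def small_pool() -> pd.DataFrame:
    """270-item synthetic pool with covariates (divides into 45-set lists)."""
    df, util = na.synthesize_predictor_table(270, seed=11)
    df = df.copy()
    df["true_utility"] = util.to_numpy()
    # plant deliberately obscure probe words (catch-trial worsts): known by
    # <1% of people and of low latent utility
    rare = df.index[-5:]
    df.loc[rare, "prevalence"] = 0.003
    df.loc[rare, "true_utility"] = df["true_utility"].min() - 1.0
    return df


@pytest.fixture(scope="session")
def small_spec() -> dz.DesignSpec:
    return dz.DesignSpec(
        n_items=270, reps_per_item=18, set_size=6, sets_per_list=45,
        catch_trials_per_list=5, n_batches=3, rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_design(small_spec) -> dz.Design:
    return dz.generate_tuple_design(270, small_spec)


@pytest.fixture(scope="session")
def small_lists(small_pool, small_design, small_spec) -> pd.DataFrame:
    catch = dz.build_catch_sets(small_pool, 5, small_spec, seed=7)
    return dz.assemble_lists(small_design, catch, small_spec, seed=7)


@pytest.fixture(scope="session")
def small_catch(small_pool, small_spec):
    return dz.build_catch_sets(small_pool, 5, small_spec, seed=7)


def exhaustive_pair_counts(sets: np.ndarray) -> dict:
    """Brute-force oracle: count every unordered within-set pair."""
    from collections import Counter
    from itertools import combinations

    c: Counter = Counter()
    for row in sets:
        for a, b in combinations(sorted(int(x) for x in row), 2):
            c[(a, b)] += 1
    return dict(c)
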