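"""Scoring: pairwise extraction, Value Learning, baselines, batch scales."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from bwsnorm import design as dz
from bwsnorm import scoring as sc
from bwsnorm import simulate as sim

POS = [f"pos{i}" for i in range(1, 7)]


def make_response(shown, best, worst, pid=1, trial=1):
    row = [pid, pid, trial, *shown, best, worst]
    cols = ["participant_id", "list_id", "trial_index", *POS[: len(shown)], "best_id", "worst_id"]
    return pd.DataFrame([row], columns=cols)


class TestExtractPairwise:
    def test_nine_preferences_exact_multiset(self):
        # best A(=1), worst F(=6), middles B..E -> {A>B..A>F, B>F..E>F}
        resp = make_response([1, 2, 3, 4, 5, 6], best=1, worst=6)
        prefs = sc.extract_pairwise(resp)
        got = set(zip(prefs["winner"], prefs["loser"]))
        expected = {(1, 2), (1, 3), (1, 4), (1, 5), (1, 6), (2, 6), (3, 6), (4, 6), (5, 6)}
        assert len(prefs) == 9 and got == expected

    def test_pair_variant_single_preference(self):
        resp = make_response([7, 8], best=8, worst=7)
        prefs = sc.extract_pairwise(resp)
        assert len(prefs) == 1
        assert (prefs.iloc[0]["winner"], prefs.iloc[0]["loser"]) == (8, 7)

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="best == worst"):
            sc.extract_pairwise(make_response([1, 2, 3, 4, 5, 6], best=2, worst=2))
        with pytest.raises(ValueError, match="not shown"):
            sc.extract_pairwise(make_response([1, 2, 3, 4, 5, 6], best=9, worst=2))

    def test_no_middle_vs_middle_pairs(self):
        resp = make_response([1, 2, 3, 4, 5, 6], best=3, worst=5)
        prefs = sc.extract_pairwise(resp)
        middles = {1, 2, 4, 6}
        mid_pairs = [
            (w, l)
            for w, l in zip(prefs["winner"], prefs["loser"])
            if w in middles and l in middles
        ]
        assert mid_pairs == []


def _pref_frame(pairs):
    return pd.DataFrame(
        {
            "winner": [w for w, _ in pairs],
            "loser": [l for _, l in pairs],
            "participant_id": 1,
            "trial_index": np.arange(len(pairs)),
        }
    )


class TestValueLearning:
    def test_dominance_monotone(self):
        scale = sc.value_learning(_pref_frame([(1, 2)] * 10), 2)
        assert scale.loc[0, "score"] > scale.loc[1, "score"]
        assert scale["score"].between(0, 1).all()

    def test_symmetric_round_robin_all_equal(self):
        pairs = []
        for i in range(1, 5):
            for j in range(1, 5):
                if i != j:
                    pairs.append((i, j))  # every ordered pair once: symmetric
        scale = sc.value_learning(_pref_frame(pairs), 4)
        assert scale["score"].nunique() == 1

    def test_noiseless_recovery_perfect_ranks(self):
        # 10 items, equally spaced utilities, noiseless judgments over a
        # schedule of sliding 6-item windows: every adjacent pair of ranks
        # is separated by some window, so ranks are fully identified
        rng = np.random.default_rng(5)
        truth = np.linspace(0, 1, 10)
        rows = []
        t = 0
        for rep in range(6):
            for w in range(5):  # items w+1 .. w+6
                shown = rng.permutation(np.arange(w + 1, w + 7))
                u = truth[shown - 1]
                rows.append([1, 1, t, *shown, shown[np.argmax(u)], shown[np.argmin(u)]])
                t += 1
        resp = pd.DataFrame(
            rows, columns=["participant_id", "list_id", "trial_index", *POS, "best_id", "worst_id"]
        )
        scale = sc.value_learning(sc.extract_pairwise(resp), 10)
        rho = spearmanr(truth, scale["score"]).statistic
        assert rho == pytest.approx(1.0)

    def test_unseen_item_missing_not_fabricated(self):
        scale = sc.value_learning(_pref_frame([(1, 2)] * 3), n_items=3)
        assert np.isnan(scale.loc[2, "score"])
        assert scale.loc[2, "n_obs"] == 0

    def test_relabeling_symmetry(self):
        # permuting item labels permutes scores identically
        pairs = [(1, 2), (3, 1), (2, 3), (3, 2), (1, 3), (1, 2)]
        perm = {1: 2, 2: 3, 3: 1}
        scale_a = sc.value_learning(_pref_frame(pairs), 3)
        scale_b = sc.value_learning(
            _pref_frame([(perm[w], perm[l]) for w, l in pairs]), 3
        )
        for i in (1, 2, 3):
            assert scale_a.loc[i - 1, "score"] == pytest.approx(
                scale_b.loc[perm[i] - 1, "score"], abs=1e-12
            )

    def test_determinism(self):
        pairs = [(1, 2), (2, 3), (1, 3)] * 5
        a = sc.value_learning(_pref_frame(pairs), 3)
        b = sc.value_learning(_pref_frame(pairs), 3)
        pd.testing.assert_frame_equal(a, b)


class TestBestWorstRate:
    def test_hand_arithmetic_ordering(self):
        # A best 4/4 appearances, B worst 4/4, C never chosen: A > C > B
        rows = []
        for t in range(4):
            rows.append([1, 1, t, 1, 2, 3, 1, 2])
        resp = pd.DataFrame(
            rows,
            columns=["participant_id", "list_id", "trial_index", "pos1", "pos2", "pos3", "best_id", "worst_id"],
        )
        scale = sc.best_worst_rate(resp)
        s = scale.set_index("item_id")["score"]
        assert s[1] == 1.0 and s[2] == 0.0
        assert s[1] > s[3] > s[2]
        assert s[3] == pytest.approx(0.5)  # never best, never worst

    def test_all_equal_maps_to_half(self):
        resp = pd.DataFrame(
            [[1, 1, 0, 1, 2, 1, 2], [1, 1, 1, 1, 2, 2, 1]],
            columns=["participant_id", "list_id", "trial_index", "pos1", "pos2", "best_id", "worst_id"],
        )
        scale = sc.best_worst_rate(resp)
        assert (scale["score"] == 0.5).all()


class TestBradleyTerry:
    def test_two_item_closed_form(self):
        # A beats B 3 of 4 -> MLE strength ratio 3 (p-hat = 3/4)
        prefs = _pref_frame([(1, 2)] * 3 + [(2, 1)])
        fit = sc.bradley_terry_mle(prefs, regularization=0.0)
        ratio = fit.loc[0, "strength"] / fit.loc[1, "strength"]
        assert ratio == pytest.approx(3.0, rel=1e-6)

    def test_symmetric_equal_strengths(self):
        pairs = [(i, j) for i in range(1, 4) for j in range(1, 4) if i != j]
        fit = sc.bradley_terry_mle(_pref_frame(pairs))
        assert fit["strength"].std() == pytest.approx(0.0, abs=1e-8)

    def test_tournament_ranking_agrees_with_value_learning(self):
        rng = np.random.default_rng(8)
        truth = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        pairs = []
        for _ in range(600):
            i, j = rng.choice(5, size=2, replace=False)
            p = 1 / (1 + np.exp(-(truth[i] - truth[j])))
            w, l = (i, j) if rng.random() < p else (j, i)
            pairs.append((w + 1, l + 1))
        prefs = _pref_frame(pairs)
        vl = sc.value_learning(prefs, 5)
        bt = sc.bradley_terry_mle(prefs, 5)
        rho = spearmanr(vl["score"], bt["score"]).statistic
        assert rho >= 0.99


@pytest.fixture(scope="module")
def scored(small_pool, small_lists):
    truth = small_pool.set_index("item_id")["true_utility"]
    resp = sim.simulate_study(small_lists, truth, tau=1.0, seed=13)
    # keep only real trials, as the qc stage would
    catch = small_lists[small_lists["is_catch"] == 1][["list_id", "trial_index"]].drop_duplicates()
    mark = resp.merge(catch, on=["list_id", "trial_index"], how="left", indicator=True)
    resp = resp[(mark["_merge"] == "left_only").to_numpy()]
    return sc.score_batches(resp, small_lists, n_items=len(small_pool)), resp


class TestScoreBatches:
    def test_three_batches_four_scales(self, scored):
        scales, _ = scored
        assert set(scales["batch"].unique()) == {"1", "2", "3", "pooled"}

    def test_pooled_granularity_not_below_batches(self, scored):
        scales, _ = scored
        by = scales.groupby("batch")["n_distinct"].first()
        assert by["pooled"] >= by[["1", "2", "3"]].max()

    def test_pooled_invariant_to_batch_labels(self, scored, small_pool, small_lists):
        scales, resp = scored
        shuffled = small_lists.copy()
        relabel = {1: 2, 2: 3, 3: 1}
        shuffled["batch"] = shuffled["batch"].map(relabel)
        again = sc.score_batches(resp, shuffled, n_items=len(small_pool))
        a = scales[scales["batch"] == "pooled"]["score"].to_numpy()
        b = again[again["batch"] == "pooled"]["score"].to_numpy()
        np.testing.assert_allclose(a, b, equal_nan=True)

    def test_scores_in_unit_interval(self, scored):
        scales, _ = scored
        ok = scales["score"].dropna()
        assert ok.between(0, 1).all()

    def test_six_observations_per_item_per_batch(self, scored):
        scales, _ = scored
        batch1 = scales[scales["batch"] == "1"]
        # every item appears 6 times per batch; each appearance contributes
        # at least one pairwise observation
        assert (batch1["n_obs"] >= 6).all()
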