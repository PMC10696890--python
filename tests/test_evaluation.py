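import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdendmf.dmf import BurdenMap, DMFParameters, GainParameters, calibrate_fic
from burdendmf.connectome import log_normalize
from burdendmf.evaluation import (
    DEFAULT_COHORT_TABLE,
    CohortTable,
    atn_classify,
    compare_models,
    min_detectable_effect,
    rate_vs_scaling,
    shuffle_null,
)
from burdendmf.fitting import EmpiricalTarget, SimulationSettings, gain_objective
from burdendmf.synthetic import gen_connectome, gen_target_bold


def _bh_oracle(p_raw):
    """[DERIVED] Benjamini-Hochberg step-up, straight from the definition."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        k = m - rank_from_top  # 1-based rank of p[i] from the bottom
        running_min = min(running_min, p[i] * m / k)
        adj[i] = running_min
    return adj


def _exact_ranksum_p(x, y):
    """[DERIVED] exhaustive two-sided rank-sum permutation p (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        count += abs(w - mu) >= abs(w_obs - mu) - 1e-9
        total += 1
    return count / total


class TestCohortTable:
    def test_weighted_means(self):
        assert np.isclose(DEFAULT_COHORT_TABLE.weighted_mean("tau"),
                          (17 * 1.53 + 9 * 1.80 + 10 * 2.46) / 36)

    def test_validation(self):
        with pytest.raises(ValueError, match="length"):
            CohortTable(("a",), (1, 2), (1.0,), (1.0,))
        with pytest.raises(ValueError, match="positive"):
            CohortTable(("a",), (0,), (1.0,), (1.0,))


class TestCompareModels:
    def test_pairwise_count_and_bh_oracle(self):
        rng = np.random.default_rng(0)
        groups = {
            "a": rng.standard_normal(12),
            "b": rng.standard_normal(12) + 1.2,
            "c": rng.standard_normal(12) + 0.2,
        }
        df = compare_models(groups)
        assert len(df) == 3
        for _, row in df.iterrows():
            p = stats.mannwhitneyu(groups[row.group_a], groups[row.group_b],
                                   alternative="two-sided").pvalue
            assert np.isclose(row.p_raw, p)
        assert np.allclose(df["p_adjusted"], _bh_oracle(df["p_raw"]))

    def test_bh_oracle_hand_example(self):
        # classic: (0.01, 0.02, 0.03, 0.04) -> all adjusted to 0.04
        assert np.allclose(_bh_oracle([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_annotation_stars(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.standard_normal(30),
                  "b": rng.standard_normal(30) + 3.0}
        df = compare_models(groups)
        assert df["annotation"].iloc[0] == "****"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            compare_models({"a": np.ones(2), "b": np.ones(5)})
        with pytest.raises(ValueError, match="two groups"):
            compare_models({"a": np.ones(5)})

    def test_ranksum_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(4):
            x = rng.standard_normal(5)
            y = rng.standard_normal(4) + rng.normal()
            p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact").pvalue
            assert np.isclose(p_scipy, _exact_ranksum_p(x, y), atol=1e-12)


class TestAtnClassify:
    def test_tau_threshold_matches_printed_value(self):
        subjects = pd.DataFrame({"subject_id": ["s1"], "mean_abeta": [1.0],
                                 "mean_tau": [1.0]})
        _, thr = atn_classify(subjects)
        assert round(thr["tau"], 2) == 1.67

    def test_labels(self):
        subjects = pd.DataFrame({
            "subject_id": ["low", "high"],
            "mean_abeta": [1.0, 2.5],
            "mean_tau": [1.0, 2.5],
        })
        out, thr = atn_classify(subjects)
        assert list(out["atn_group"]) == ["A-T-", "A+T+"]
        assert np.isclose(thr["abeta"],
                          0.9 * DEFAULT_COHORT_TABLE.weighted_mean("abeta"))

    def test_threshold_is_inclusive(self):
        subjects = pd.DataFrame({"subject_id": ["edge"], "mean_abeta": [1.0],
                                 "mean_tau": [1.0]})
        _, thr = atn_classify(subjects)
        edge = pd.DataFrame({"subject_id": ["e"],
                             "mean_abeta": [thr["abeta"]],
                             "mean_tau": [thr["tau"]]})
        out, _ = atn_classify(edge)
        assert out["atn_group"].iloc[0] == "A+T+"

    def test_input_validation(self):
        with pytest.raises(ValueError, match="columns"):
            atn_classify(pd.DataFrame({"subject_id": ["a"]}))
        bad = pd.DataFrame({"subject_id": ["a"], "mean_abeta": [-1.0],
                            "mean_tau": [1.0]})
        with pytest.raises(ValueError, match="positive"):
            atn_classify(bad)


class TestMinDetectableEffect:
    def test_null_calibration(self):
        _, _, table = min_detectable_effect(n_sims=4000, seed=0,
                                            d_grid=[0.0])
        assert abs(table["power"].iloc[0] - 0.05) < 0.015

    def test_power_increases_with_effect(self):
        _, _, table = min_detectable_effect(n_sims=2000, seed=1,
                                            d_grid=[0.0, 0.8, 1.6])
        assert table["power"].is_monotonic_increasing

    def test_default_study_size_mdd(self):
        # exact-test power (verified against scipy's exact method) crosses
        # 0.8 near d = 1.2 for n1=17, n2=10, so d_min lands on the 1.2-1.25
        # grid points depending on Monte-Carlo seed
        d_min, mdd, _ = min_detectable_effect(n_sims=4000, seed=2)
        assert 1.1 <= d_min <= 1.35
        assert np.isclose(mdd, d_min * 0.05)

    def test_decisions_match_exact_test(self):
        # the normal approximation with continuity correction reproduces
        # scipy's exact Mann-Whitney accept/reject decision at alpha=0.05
        rng = np.random.default_rng(7)
        n1, n2 = 17, 10
        mu_u = n1 * n2 / 2.0
        sd_u = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        for _ in range(50):
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + rng.uniform(0.0, 1.5)
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            z = (abs(res.statistic - mu_u) - 0.5) / sd_u
            p_approx = 2.0 * stats.norm.sf(z)
            assert (p_approx < 0.05) == (res.pvalue < 0.05)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            min_detectable_effect(n1=1)


@pytest.fixture(scope="module")
def tiny_system():
    """A 6-node system with a short target, for simulation-backed tests."""
    sc = log_normalize(gen_connectome(6, seed=11))
    ab = BurdenMap(np.full(6, 1.5), "abeta")
    ta = BurdenMap(np.full(6, 1.5), "tau")
    settings = SimulationSettings(trial_duration_s=100.0)
    ts = gen_target_bold(sc, ab, ta, GainParameters(), G=1.0,
                         duration_s=130.0, seed=11)
    target = EmpiricalTarget.from_bold(ts, settings)
    p = DMFParameters(G=1.0)
    fic = calibrate_fic(sc, None, p, seed=11)
    return sc, ab, ta, target, settings, fic


class TestShuffleNull:
    def test_constant_maps_equal_unshuffled_objectives(self, tiny_system):
        """Permutation of a constant map is the identity, so each map's
        objectives must equal a plain evaluation with the same seeds."""
        sc, ab, ta, target, settings, fic = tiny_system
        gp = GainParameters(s_I_abeta=-0.1)
        null = shuffle_null(gp, sc, ab, ta, target, 1.0, n_maps=2,
                            trials_per_map=3, seed=5, settings=settings,
                            fic=fic)
        direct = np.concatenate([
            gain_objective(gp, sc, ab, ta, target, 1.0, n_trials=3, seed=5,
                           fic=fic, settings=settings, eval_index=m + 1,
                           return_per_trial=True)[1]
            for m in range(2)
        ])
        assert np.array_equal(null, direct)

    def test_output_size(self, tiny_system):
        sc, ab, ta, target, settings, fic = tiny_system
        null = shuffle_null(GainParameters(), sc, ab, ta, target, 1.0,
                            n_maps=2, trials_per_map=2, seed=1,
                            settings=settings, fic=fic)
        assert null.shape == (4,)
        assert np.all((null >= 0) & (null <= 1))


class TestRateVsScaling:
    def test_zero_scaling_stays_near_fic_target(self, tiny_system):
        sc, ab, ta, _, _, fic = tiny_system
        table = rate_vs_scaling(sc, ab, ta, GainParameters(),
                                [0.0, -0.2], 1.0, seed=3, fic=fic,
                                burn_ms=1000.0, window_ms=4000.0)
        assert list(table.columns) == ["s_I_abeta", "mean_r_E", "mean_r_I"]
        assert abs(table["mean_r_E"].iloc[0] - 3.0) < 0.5
        assert table["mean_r_E"].iloc[1] > table["mean_r_E"].iloc[0]
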