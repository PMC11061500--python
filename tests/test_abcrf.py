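"""Random-forest ABC on constructed reference tables."""

import numpy as np
import pandas as pd
import pytest

from hybridabc import abcrf
from hybridabc.abcrf import ModelChoiceResult, ReferenceTable, ReplicateSummary
from hybridabc.coalsim import SampleConfig
from hybridabc.scenarios import PriorSpec


def _gaussian_table(rng, centers, n_per=200, scale=0.2, stat_names=("s1", "s2", "s3")):
    """Reference table whose scenarios are Gaussian blobs in statistic space."""
    rows = []
    for sid, center in centers.items():
        x = rng.normal(center, scale, size=(n_per, len(stat_names)))
        for row in x:
            rows.append({"scenario_id": sid, "r1": rng.uniform(0.01, 0.99),
                         **dict(zip(stat_names, row))})
    df = pd.DataFrame(rows)
    return ReferenceTable(df, list(stat_names), ["r1"], {"seed": 0})


class TestModelChoice:
    def test_separable_scenarios(self, rng):
        table = _gaussian_table(rng, {1: [0, 0, 0], 2: [5, 5, 5]})
        fit = abcrf.fit_model_choice(table, n_trees=200, seed=0)
        assert fit.prior_error_rate < 0.01
        obs = pd.Series([0.1, -0.1, 0.0], index=table.stat_cols)
        res = abcrf.classify(fit, obs)
        assert res.votes[1] > 0.95
        assert res.selected == 1
        assert res.posterior_prob > 0.95
        assert sum(res.votes.values()) == pytest.approx(1.0, abs=1e-12)

    def test_shuffled_labels_hit_chance_level(self, rng):
        table = _gaussian_table(rng, {k: [0, 0, 0] for k in (1, 2, 3, 4)}, n_per=150)
        fit = abcrf.fit_model_choice(table, n_trees=200, seed=1)
        assert abs(fit.prior_error_rate - 0.75) < 0.06  # 1 - 1/K for K = 4

    def test_centroid_of_identical_scenarios_splits_votes(self, rng):
        # any one forest can lean either way on indistinguishable scenarios;
        # by symmetry the vote averaged over independent tables is 1/2
        shares = []
        for k in range(5):
            table = _gaussian_table(rng, {1: [0, 0, 0], 2: [0, 0, 0]}, n_per=200)
            fit = abcrf.fit_model_choice(table, n_trees=200, add_lda=False, seed=k)
            res = abcrf.classify(fit, pd.Series([0.0, 0.0, 0.0], index=table.stat_cols))
            shares.append(res.votes[1])
        assert abs(np.mean(shares) - 0.5) < 0.15
        assert fit.prior_error_rate > 0.4  # chance level for two identical classes

    def test_header_mismatch_is_hard_error(self, rng):
        table = _gaussian_table(rng, {1: [0, 0, 0], 2: [3, 3, 3]}, n_per=50)
        fit = abcrf.fit_model_choice(table, n_trees=50, seed=0)
        with pytest.raises(ValueError, match="header"):
            abcrf.classify(fit, pd.Series([0.0, 0.0], index=["s1", "s2"]))

    def test_fixed_seed_reproduces_votes(self, rng):
        table = _gaussian_table(rng, {1: [0, 0, 0], 2: [1, 1, 1]}, n_per=100)
        obs = pd.Series([0.4, 0.6, 0.5], index=table.stat_cols)
        r1 = abcrf.classify(abcrf.fit_model_choice(table, n_trees=100, seed=7), obs)
        r2 = abcrf.classify(abcrf.fit_model_choice(table, n_trees=100, seed=7), obs)
        assert r1.votes == r2.votes and r1.posterior_prob == r2.posterior_prob

    def test_lda_augmentation_toggle(self, rng):
        table = _gaussian_table(rng, {1: [0, 0, 0], 2: [2, 2, 2]}, n_per=100)
        for add_lda in (True, False):
            fit = abcrf.fit_model_choice(table, n_trees=50, add_lda=add_lda, seed=0)
            n_features = fit.features(table.stats_matrix()).shape[1]
            assert n_features == (4 if add_lda else 3)

    def test_vote_sum_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ModelChoiceResult({1: 0.6, 2: 0.6}, 1, 0.5, 0.1)


class TestParameterEstimation:
    def test_recovers_planted_functional_relationship(self, rng):
        n = 600
        s1 = rng.uniform(0, 1, n)
        noise = rng.normal(0, 1, (n, 2))
        df = pd.DataFrame({
            "scenario_id": 1, "r1": 3.0 * s1,
            "s1": s1, "s2": noise[:, 0], "s3": noise[:, 1],
        })
        table = ReferenceTable(df, ["s1", "s2", "s3"], ["r1"])
        obs = pd.Series([0.5, 0.0, 0.0], index=table.stat_cols)
        post = abcrf.estimate_parameters(table, 1, obs, ["r1"], n_trees=200, seed=0)[0]
        assert post.median == pytest.approx(1.5, abs=0.15)
        assert post.q95 - post.q05 < 0.6

    def test_uninformative_parameter_returns_prior_quantiles(self, rng):
        n = 800
        df = pd.DataFrame({
            "scenario_id": 1, "r1": rng.uniform(0, 1, n),
            "s1": rng.normal(0, 1, n), "s2": rng.normal(0, 1, n),
        })
        table = ReferenceTable(df, ["s1", "s2"], ["r1"])
        obs = pd.Series([0.0, 0.0], index=table.stat_cols)
        post = abcrf.estimate_parameters(
            table, 1, obs, ["r1"], n_trees=200, seed=1, min_samples_leaf=50)[0]
        assert post.median == pytest.approx(0.5, abs=0.12)
        assert post.q05 == pytest.approx(0.05, abs=0.12)
        assert post.q95 == pytest.approx(0.95, abs=0.12)

    def test_quantiles_ordered(self, rng):
        table = _gaussian_table(rng, {1: [0, 0, 0]}, n_per=100)
        obs = pd.Series([0.0, 0.0, 0.0], index=table.stat_cols)
        for seed in range(3):
            p = abcrf.estimate_parameters(table, 1, obs, ["r1"], n_trees=60, seed=seed)[0]
            assert p.q05 <= p.median <= p.q95

    def test_missing_scenario_rejected(self, rng):
        table = _gaussian_table(rng, {1: [0, 0, 0]}, n_per=30)
        obs = pd.Series([0.0, 0.0, 0.0], index=table.stat_cols)
        with pytest.raises(ValueError, match="no rows"):
            abcrf.estimate_parameters(table, 9, obs, ["r1"])


class TestReferenceTableBuild:
    def test_balanced_rows_and_determinism(self):
        config = SampleConfig({"A_deme": 4, "B_deme": 4, "HIM": 1})
        # reuse canonical demes so scenarios build: use the study design instead
        from hybridabc.synthetic_data import study_design

        design = study_design("population", n_loci=8)
        t1 = abcrf.build_reference_table(
            [1, 4], PriorSpec(), design.sample_config, 8, 0.05, 5, seed=3)
        t2 = abcrf.build_reference_table(
            [1, 4], PriorSpec(), design.sample_config, 8, 0.05, 5, seed=3)
        assert len(t1.table) == 10
        assert (t1.table["scenario_id"].value_counts() == 5).all()
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_t5_prior_bound_respected(self):
        from hybridabc.synthetic_data import study_design

        design = study_design("population", n_loci=5)
        prior = PriorSpec().with_t5_upper(750_000)
        t = abcrf.build_reference_table([1], prior, design.sample_config, 5, 0.05, 8, seed=5)
        assert t.table["t5"].max() <= 750_000
        # unused parameters stay NaN
        assert t.table["t3"].isna().all()

    def test_save_load_round_trip(self, rng, tmp_path):
        table = _gaussian_table(rng, {1: [0, 0, 0], 2: [1, 1, 1]}, n_per=20)
        table.save(tmp_path / "ref.csv")
        back = ReferenceTable.load(tmp_path / "ref.csv")
        assert back.stat_cols == table.stat_cols
        pd.testing.assert_frame_equal(back.table, table.table)


class TestReplicateSummary:
    def _stub(self, votes):
        return ModelChoiceResult(votes, max(votes, key=votes.get), 0.8, 0.2)

    def test_subset_vote_mass(self):
        reps = [self._stub({1: 0.5, 2: 0.3, 3: 0.2}), self._stub({1: 0.6, 2: 0.2, 3: 0.2})]
        summary = ReplicateSummary({1: 0.55, 2: 0.25, 3: 0.2}, {}, 0.8, 0.0, 0.2, 1, reps)
        mean, sd = summary.subset_vote_share({1, 3})
        assert mean == pytest.approx(0.75)
        assert sd == pytest.approx(np.std([0.7, 0.8], ddof=1))

    def test_single_replicate_has_nan_sd(self, caplog):
        from hybridabc.synthetic_data import study_design
        from hybridabc.sumstats import compute_summaries
        from hybridabc.synthetic_data import make_pod

        design = study_design("population", n_loci=6)
        pod, _ = make_pod(1, design, 5)
        with caplog.at_level("WARNING"):
            summary = abcrf.replicate_analysis(
                compute_summaries(pod), [1, 4], PriorSpec(), design.sample_config,
                6, 0.05, 4, n_trees=25, n_replicates=1, seed=2,
            )
        assert np.isnan(summary.posterior_sd)
        assert "single replicate" in caplog.text
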