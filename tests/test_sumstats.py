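"""Summary-statistic estimators against hand-worked and constructed oracles."""

import math

import numpy as np
import pytest

from hybridabc import coalsim, sumstats as ss
from hybridabc.coalsim import SampleConfig
from hybridabc.scenarios import single_deme_scenario

from conftest import make_dataset


class TestAlleleFreq:
    @pytest.mark.parametrize(
        "column, expected",
        [([0, 1, 2], 0.5), ([2, 2, None], 1.0), ([0, 1, None], 0.25)],
    )
    def test_examples(self, column, expected):
        ds = make_dataset([[v] for v in column])
        assert ss.allele_freq(ds, "G")[0] == pytest.approx(expected)

    def test_all_missing_is_nan(self):
        ds = make_dataset([[None], [None]])
        assert np.isnan(ss.allele_freq(ds, "G")[0])


class TestHeterozygosity:
    def test_unbiased_estimator_at_half(self):
        # p = 0.5 from n = 40 copies: 2*0.5*0.5*40/39
        ds = make_dataset([[1]] * 20)
        mean, var = ss.expected_heterozygosity(ds, "G")
        assert mean == pytest.approx(0.5 * 40 / 39)
        assert var == 0.0

    def test_fixed_locus_is_zero(self):
        ds = make_dataset([[0, 2], [0, 2]])
        mean, _ = ss.expected_heterozygosity(ds, "G")
        assert mean == 0.0


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        groups = ["A"] * 4 + ["B"] * 4
        ds = make_dataset([[2, 2]] * 4 + [[0, 0]] * 4, groups=groups)
        assert ss.hudson_fst(ds, "A", "B") == pytest.approx(1.0)

    def test_equal_frequencies_near_zero(self):
        groups = ["A"] * 20 + ["B"] * 20
        col = [0] * 10 + [2] * 10
        ds = make_dataset([[c] for c in col + col], groups=groups)
        assert abs(ss.hudson_fst(ds, "A", "B")) < 0.05

    def test_three_locus_hand_calculation(self):
        # group A: 2 diploids, group B: 2 diploids; explicit arithmetic oracle
        groups = ["A", "A", "B", "B"]
        dos = [[2, 1, 0], [1, 1, 0], [0, 1, 2], [0, 0, 1]]
        ds = make_dataset(dos, groups=groups)
        pa = [3 / 4, 2 / 4, 0.0]
        pb = [0.0, 1 / 4, 3 / 4]
        n = 4
        hw = [
            0.5 * (2 * p * (1 - p) * n / (n - 1) + 2 * q * (1 - q) * n / (n - 1))
            for p, q in zip(pa, pb)
        ]
        hb = [p * (1 - q) + q * (1 - p) for p, q in zip(pa, pb)]
        expected = 1 - (sum(hw) / 3) / (sum(hb) / 3)
        assert ss.hudson_fst(ds, "A", "B") == pytest.approx(expected)

    def test_panmictic_split_centred_on_zero(self):
        scn = single_deme_scenario(1000)
        ds = coalsim.simulate_snp_dataset(scn, SampleConfig({"A": 20}), 2000, 0.0, 42)
        labels = ["X"] * 10 + ["Y"] * 10
        ds = ds.with_groups(dict(zip(ds.individuals["individual_id"], labels)))
        per_locus = ss.hudson_fst_per_locus(ds, "X", "Y")
        se = per_locus.std(ddof=1) / np.sqrt(per_locus.size)
        assert abs(per_locus.mean()) < 3 * se


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        ds = make_dataset([[0, 1], [1, 2], [0, 1], [1, 2]],
                          groups=["A", "A", "B", "B"])
        assert ss.nei_distance(ds, "A", "B") == pytest.approx(0.0)

    def test_opposite_fixation_capped(self):
        ds = make_dataset([[2], [2], [0], [0]], groups=["A", "A", "B", "B"])
        assert ss.nei_distance(ds, "A", "B") == ss.NEI_CAP

    def test_two_locus_hand_value(self):
        groups = ["A", "A", "B", "B"]
        dos = [[2, 1], [1, 1], [0, 1], [0, 2]]
        ds = make_dataset(dos, groups=groups)
        pa, pb = [0.75, 0.5], [0.0, 0.75]
        jxy = sum(p * q + (1 - p) * (1 - q) for p, q in zip(pa, pb))
        jx = sum(p**2 + (1 - p) ** 2 for p in pa)
        jy = sum(q**2 + (1 - q) ** 2 for q in pb)
        assert ss.nei_distance(ds, "A", "B") == pytest.approx(-math.log(jxy / math.sqrt(jx * jy)))


class TestF3F4:
    def _three_groups(self, pa=0.8, pb=0.2, n=50):
        # one locus with exact group frequencies via homozygote counts;
        # the target sits at the midpoint of the two sources
        def col(p):
            n_alt = int(round(2 * n * p))
            return [2] * (n_alt // 2) + [1] * (n_alt % 2) + [0] * (n - n_alt // 2 - n_alt % 2)

        groups = ["T"] * n + ["A"] * n + ["B"] * n
        dos = [[v] for v in col(0.5) + col(pa) + col(pb)]
        return make_dataset(dos, groups=groups)

    def test_midpoint_target_is_negative(self):
        ds = self._three_groups()
        assert ss.f3(ds, "T", "A", "B") < 0

    def test_uncorrected_zero_when_target_equals_source(self):
        ds = self._three_groups()
        assert ss.f3(ds, "A", "A", "B", corrected=False) == pytest.approx(0.0)

    def test_corrected_subtracts_target_sampling_noise(self):
        ds = self._three_groups()
        raw = ss.f3(ds, "T", "A", "B", corrected=False)
        corr = ss.f3(ds, "T", "A", "B", corrected=True)
        assert corr < raw

    def test_identical_groups_near_zero(self):
        ds = make_dataset([[1, 0, 1, 0, 1, 0]] * 3, groups=["T", "A", "B"])
        val = ss.f3(ds, "T", "A", "B", corrected=False)
        assert val == pytest.approx(0.0)

    def test_f4_sign_tracks_shared_drift(self):
        groups = ["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5
        dos = [[2, 0] for _ in range(5)] + [[0, 0] for _ in range(5)] \
            + [[2, 0] for _ in range(5)] + [[0, 2] for _ in range(5)]
        ds = make_dataset(dos, groups=groups)
        # locus 1: (pA-pB)(pC-pD) = (1)(1) = 1; locus 2: (0)(-1) = 0
        assert ss.f4(ds, "A", "B", "C", "D") == pytest.approx(0.5)


class TestSummaryVector:
    def _canonical_ds(self, rng):
        from hybridabc.scenarios import PriorSpec, build_scenario, draw_parameters
        from hybridabc.synthetic_data import study_design

        design = study_design("population", n_loci=30)
        theta = draw_parameters(PriorSpec(), 1, rng)
        scn = build_scenario(1, theta)
        return coalsim.simulate_snp_dataset(scn, design.sample_config, 30, 0.05, rng)

    def test_locus_order_invariance(self, rng):
        ds = self._canonical_ds(rng)
        perm = rng.permutation(ds.n_loci)
        shuffled = ds.take_loci(perm)
        a = ss.compute_summaries(ds)
        b = ss.compute_summaries(shuffled)
        assert list(a.index) == list(b.index)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_purity_and_bit_identical_reruns(self, rng):
        ds = self._canonical_ds(rng)
        before = ds.dosages.copy()
        a = ss.compute_summaries(ds)
        b = ss.compute_summaries(ds)
        np.testing.assert_array_equal(ds.dosages, before)
        assert (a == b).all()

    def test_maf_conditioned_data_fully_polymorphic_pooled(self, rng):
        ds = self._canonical_ds(rng)
        p = ds.alt_allele_frequency()
        assert ((p > 0) & (p < 1)).all()

    def test_duplicating_individuals_barely_moves_fst(self, rng):
        import pandas as pd

        ds = self._canonical_ds(rng)
        rep = np.repeat(np.arange(ds.n_individuals), 2)
        ind = pd.DataFrame({
            "individual_id": [f"d{i}" for i in range(rep.size)],
            "group_label": ds.individuals["group_label"].to_numpy()[rep],
        })
        doubled = type(ds)(ind, ds.loci.copy(), ds.dosages[rep])
        f1 = ss.hudson_fst(ds, "PAM_N", "PAM_S")
        f2 = ss.hudson_fst(doubled, "PAM_N", "PAM_S")
        assert abs(f1 - f2) < 0.1  # only sample-size correction terms shift

    def test_names_are_versioned_and_ordered(self):
        names = ss.summary_names(["PAM_N", "PAM_S", "HYB_N", "HYB_S", "HIM"])
        assert names[-3:] == ["f3_HYB_N", "f3_HYB_S", "f4_PAM_HYB_HIM"]
        assert len(names) == 5 * 3 + 10 * 2 + 3
        assert ss.STAT_REGISTRY_VERSION == "v1"
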