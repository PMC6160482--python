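import numpy as np
import pytest

from emfspeech.dfs import (
    DFSThresholds,
    apply_c1,
    dfs_select,
    fisher_discriminant_scores,
    mahalanobis_ratio,
    max_class_probability,
)
from emfspeech.emf import EMFDataset
from conftest import random_emf_dataset
from oracles import dfs_cascade_oracle, fds_oracle, mahalanobis_ratio_oracle, max_probability_oracle


def make_dataset(class0_rows, class1_rows):
    d = np.vstack([class0_rows, class1_rows]).astype(float)
    n0 = len(class0_rows)
    labels = np.array([0] * n0 + [1] * len(class1_rows))
    return EMFDataset(
        D=d,
        Y=labels,
        L=labels,  # code 1 = PDD-NOS, irrelevant here
        subject_ids=tuple(f"s{i}" for i in range(len(labels))),
        column_names=tuple(f"b{k}" for k in range(d.shape[1])),
    )


class TestFisherScores:
    def test_identical_class_distributions_score_zero(self):
        ds = make_dataset([[0.0], [1.0]], [[1.0], [0.0]])
        assert fisher_discriminant_scores(ds)[0] == 0.0

    def test_hand_computed_value(self):
        # class0 {0,1}, class1 {2,3}: SB = 2, SW = 0.5 -> FDS = 4
        ds = make_dataset([[0.0], [1.0]], [[2.0], [3.0]])
        assert fisher_discriminant_scores(ds)[0] == pytest.approx(4.0)

    def test_separated_constants_give_infinity(self):
        ds = make_dataset([[5.0], [5.0]], [[9.0], [9.0]])
        assert np.isinf(fisher_discriminant_scores(ds)[0])

    def test_single_class_rejected(self):
        d = np.zeros((3, 1))
        ds = EMFDataset(D=d, Y=np.zeros(3, int), L=np.zeros(3, int),
                        subject_ids=("a", "b", "c"), column_names=("b0",))
        with pytest.raises(ValueError):
            fisher_discriminant_scores(ds)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            ds = random_emf_dataset(rng, n0=int(rng.integers(3, 10)),
                                    n1=int(rng.integers(3, 10)), n_features=5)
            got = fisher_discriminant_scores(ds)
            d0, d1 = ds.D[ds.Y == 0], ds.D[ds.Y == 1]
            for k in range(5):
                assert got[k] == pytest.approx(fds_oracle(d0, d1, k), abs=1e-10)


class TestC1:
    def test_threshold_semantics(self):
        fds = np.array([4.0, 0.0])
        np.testing.assert_array_equal(apply_c1(fds, 1.0), [True, False])
        np.testing.assert_array_equal(apply_c1(fds, 0.0), [True, False])
        np.testing.assert_array_equal(apply_c1(fds, np.inf), [False, False])

    def test_percentile_spec_resolves_against_training(self):
        fds = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(apply_c1(fds, "p50"), [False, False, True, True])


class TestMahalanobisRatio:
    def test_on_class_mean_is_zero(self):
        ds = make_dataset([[0.0], [2.0]], [[10.0], [12.0]])
        assert mahalanobis_ratio(1.0, ds, 0) == 0.0

    def test_hand_computed_value(self):
        # class distances with unbiased variances (both 2): M1=0.5, M2=40.5
        # -> near-anchored ratio 0.5*0.5/40.5
        ds = make_dataset([[0.0], [2.0]], [[10.0], [12.0]])
        assert mahalanobis_ratio(2.0, ds, 0) == pytest.approx(0.25 / 40.5, abs=1e-12)

    def test_equidistant_equal_variance_reduces_to_distance(self):
        ds = make_dataset([[0.0], [2.0]], [[4.0], [6.0]])
        # s=3 sits 2 units from both means, variances equal -> MR = M1
        m1 = (3.0 - 1.0) ** 2 / 2.0
        assert mahalanobis_ratio(3.0, ds, 0) == pytest.approx(m1)

    def test_zero_variance_conventions(self):
        ds = make_dataset([[5.0], [5.0]], [[9.0], [11.0]])
        assert mahalanobis_ratio(5.0, ds, 0) == 0.0  # on the constant: keep
        # off the constant but at finite distance from the other class:
        # infinitely far from one class only -> kept (ratio 0)
        assert mahalanobis_ratio(6.0, ds, 0) == 0.0
        ds2 = make_dataset([[5.0], [5.0]], [[9.0], [9.0]])
        assert np.isinf(mahalanobis_ratio(6.0, ds2, 0))  # off both constants

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            ds = random_emf_dataset(rng, n0=int(rng.integers(2, 8)),
                                    n1=int(rng.integers(2, 8)), n_features=3)
            s = rng.standard_normal(3)
            d0, d1 = ds.D[ds.Y == 0], ds.D[ds.Y == 1]
            for k in range(3):
                got = mahalanobis_ratio(float(s[k]), ds, k)
                want = mahalanobis_ratio_oracle(float(s[k]), d0[:, k], d1[:, k])
                assert got == pytest.approx(want, abs=1e-10)


class TestMaxClassProbability:
    def test_density_at_class_mean(self):
        ds = make_dataset([[-1.0], [1.0]], [[9.0], [11.0]])
        # class sd = sqrt(2); density at mean = 1/(sqrt(2 pi) sd)
        want = 1.0 / (np.sqrt(2 * np.pi) * np.sqrt(2.0))
        assert max_class_probability(0.0, ds, 0) == pytest.approx(want, abs=1e-12)

    def test_density_can_exceed_one(self):
        ds = make_dataset([[-0.1], [0.1]], [[9.0], [11.0]])
        assert max_class_probability(0.0, ds, 0) > 1.0

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            ds = random_emf_dataset(rng, n0=int(rng.integers(2, 8)),
                                    n1=int(rng.integers(2, 8)), n_features=3)
            s = rng.standard_normal(3)
            d0, d1 = ds.D[ds.Y == 0], ds.D[ds.Y == 1]
            for k in range(3):
                got = max_class_probability(float(s[k]), ds, k)
                want = max_probability_oracle(float(s[k]), d0[:, k], d1[:, k])
                assert got == pytest.approx(want, abs=1e-10)


class TestCascade:
    def test_vacuous_gates_keep_everything(self):
        rng = np.random.default_rng(7)
        ds = random_emf_dataset(rng)
        mask, trace = dfs_select(
            ds, rng.standard_normal(ds.D.shape[1]),
            DFSThresholds(th_fds=0.0, th_mr=np.inf, th_p=0.0, p_mode="density"),
        )
        assert mask.all()
        assert trace.fallback == "none"

    def test_each_gate_uniquely_fails_one_feature(self):
        # feature 0: FDS below threshold (identical class distributions);
        # feature 1: passes C1 but the test element is an outlier to both
        #            classes -> MR above threshold;
        # feature 2: passes C1+C2 but test element is far from both class
        #            means in z units -> fails C3;
        # feature 3: passes all three.
        c0 = np.array(
            [[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0], [0.5, 0.5, 0.5, 0.5]]
        )
        c1 = np.array(
            [[0.0, 4.0, 4.0, 4.0], [1.0, 5.0, 5.0, 5.0], [0.5, 4.5, 4.5, 4.5]]
        )
        ds = make_dataset(c0, c1)
        s = np.array([0.5, 40.0, 1.8, 4.5])
        th = DFSThresholds(th_fds=1.0, th_mr=6.0, th_p=2.5, p_mode="z")
        mask, trace = dfs_select(ds, s, th)
        np.testing.assert_array_equal(trace.mask_after_c1, [False, True, True, True])
        np.testing.assert_array_equal(trace.mask_after_c2, [False, False, True, True])
        np.testing.assert_array_equal(mask, [False, False, False, True])
        assert trace.fallback == "none"

    def test_masks_nested_and_final_non_empty(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            ds = random_emf_dataset(rng)
            s = rng.standard_normal(ds.D.shape[1]) * 5
            mask, trace = dfs_select(ds, s)
            assert np.all(trace.mask_after_c2 <= trace.mask_after_c1)
            assert np.all(trace.mask_after_c3 <= trace.mask_after_c2)
            assert mask.any()

    def test_statelessness_across_test_samples(self):
        rng = np.random.default_rng(9)
        ds = random_emf_dataset(rng)
        s1 = rng.standard_normal(ds.D.shape[1])
        s2 = rng.standard_normal(ds.D.shape[1])
        m1a, _ = dfs_select(ds, s1)
        m2a, _ = dfs_select(ds, s2)
        m2b, _ = dfs_select(ds, s2)
        m1b, _ = dfs_select(ds, s1)
        np.testing.assert_array_equal(m1a, m1b)
        np.testing.assert_array_equal(m2a, m2b)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            ds = random_emf_dataset(rng, n0=15, n1=15, n_features=12)
            s = rng.standard_normal(12) * 2
            th_fds = float(rng.uniform(0, 2))
            th_mr = float(rng.uniform(0.2, 5))
            th_p = float(rng.uniform(0.0, 0.4))
            mask, trace = dfs_select(
                ds, s, DFSThresholds(th_fds=th_fds, th_mr=th_mr, th_p=th_p, p_mode="density")
            )
            want = dfs_cascade_oracle(ds.D, ds.Y, s, th_fds, th_mr, th_p)
            if not want.any():  # oracle has no fallback rule
                assert trace.fallback != "none"
            else:
                np.testing.assert_array_equal(trace.mask_after_c3, want)
                np.testing.assert_array_equal(mask, want)

    def test_cascade_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        ds = random_emf_dataset(rng)
        s = rng.standard_normal(ds.D.shape[1])
        base = DFSThresholds(th_fds=0.5, th_mr=2.0, th_p=1.5, p_mode="z")
        _, t0 = dfs_select(ds, s, base)
        for _ in range(100):
            harder = DFSThresholds(
                th_fds=0.5 + float(rng.uniform(0, 2)),
                th_mr=2.0 / float(rng.uniform(1, 5)),
                th_p=1.5 / float(rng.uniform(1, 4)),
                p_mode="z",
            )
            _, t1 = dfs_select(ds, s, harder)
            assert np.all(t1.mask_after_c3 <= t0.mask_after_c3)

    def test_scale_equivariance_of_gates(self):
        # multiplying one feature column (train and test) by c > 0 leaves
        # FDS, MR and the z-mode C3 decision unchanged
        rng = np.random.default_rng(12)
        ds = random_emf_dataset(rng)
        s = rng.standard_normal(ds.D.shape[1])
        _, t0 = dfs_select(ds, s)
        c = 37.5
        d_scaled = ds.D.copy()
        d_scaled[:, 3] *= c
        ds2 = EMFDataset(D=d_scaled, Y=ds.Y, L=ds.L, subject_ids=ds.subject_ids,
                         column_names=ds.column_names)
        s2 = s.copy()
        s2[3] *= c
        _, t1 = dfs_select(ds2, s2)
        np.testing.assert_allclose(t1.fds, t0.fds, rtol=1e-9)
        np.testing.assert_allclose(t1.mr, t0.mr, rtol=1e-9)
        np.testing.assert_allclose(t1.nearest_z, t0.nearest_z, rtol=1e-9)
        np.testing.assert_array_equal(t1.final_mask, t0.final_mask)
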