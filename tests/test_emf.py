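import numpy as np
import pytest

from emfspeech import SyntheticConfig, generate_cohort
from emfspeech.data import DegenerateDataError, make_table
from emfspeech.emf import (
    VALENCE_TARGETS,
    MomentMatrix,
    build_emf_dataset,
    estimate_emf,
    per_valence_moments,
)
from emfspeech.selection import select_features, union_selected_features
from oracles import minimum_norm_lsq_oracle, moments_oracle


def _single_feature_table(neg, neu, pos):
    vals = list(neg) + list(neu) + list(pos)
    e = [-1] * len(neg) + [0] * len(neu) + [1] * len(pos)
    return make_table(["s1"] * len(vals), e, {"f1": vals})


def _f1_set():
    return union_selected_features([{0}], ["f1"])


class TestPerValenceMoments:
    def test_symmetric_three_values(self):
        # (1,2,3): m2=2/3, m3=0, m4=2/3 -> mean 2, skew 0, kurt 1.5
        t = _single_feature_table([1, 2, 3], [1, 2, 3], [1, 2, 3])
        mm = per_valence_moments(t, "s1", _f1_set())
        for row in range(3):
            assert mm.block("mean")[row, 0] == pytest.approx(2.0)
            assert mm.block("skew")[row, 0] == pytest.approx(0.0)
            assert mm.block("kurt")[row, 0] == pytest.approx(1.5)

    def test_asymmetric_four_values(self):
        # (1,2,3,6): m2=3.5, m3=4.5, m4=24.5 -> skew 4.5/3.5^1.5, kurt 2.0
        t = _single_feature_table([1, 2, 3, 6], [1, 2, 3], [1, 2, 3])
        mm = per_valence_moments(t, "s1", _f1_set())
        assert mm.block("mean")[0, 0] == pytest.approx(3.0)
        assert mm.block("skew")[0, 0] == pytest.approx(4.5 / 3.5**1.5, abs=1e-12)
        assert mm.block("kurt")[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_constant_class_degenerate_convention(self):
        t = _single_feature_table([5, 5, 5], [1, 2, 3], [1, 2, 3])
        mm = per_valence_moments(t, "s1", _f1_set())
        assert mm.block("mean")[0, 0] == 5.0
        assert mm.block("skew")[0, 0] == 0.0
        assert mm.block("kurt")[0, 0] == 0.0
        assert mm.degenerate[0, 0]

    def test_empty_class_raises(self):
        t = _single_feature_table([1, 2], [], [3, 4])
        with pytest.raises(DegenerateDataError, match="valence class 0"):
            per_valence_moments(t, "s1", _f1_set())

    def test_matches_scipy_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            vals = rng.standard_normal(int(rng.integers(3, 12)))
            t = _single_feature_table(vals, [1, 2, 3], [1, 2, 3])
            mm = per_valence_moments(t, "s1", _f1_set())
            mean, sk, ku = moments_oracle(vals)
            assert mm.block("mean")[0, 0] == pytest.approx(mean, abs=1e-10)
            assert mm.block("skew")[0, 0] == pytest.approx(sk, abs=1e-10)
            assert mm.block("kurt")[0, 0] == pytest.approx(ku, abs=1e-10)

    def test_block_layout_is_skew_mean_kurt(self, small_cohort):
        table, _, _ = small_cohort
        sel = select_features(table, 0.7)
        mm = per_valence_moments(table, table.subjects[0], sel)
        n = sel.n_opt
        assert mm.matrix.shape == (3, 3 * n)
        np.testing.assert_array_equal(mm.block("skew"), mm.matrix[:, :n])
        np.testing.assert_array_equal(mm.block("mean"), mm.matrix[:, n : 2 * n])
        assert mm.column_names[0].startswith("skew:")


class TestEstimateEMF:
    def _mm(self, matrix, n_feat):
        return MomentMatrix(
            subject_id="s1",
            matrix=matrix,
            feature_names=tuple(f"f{j}" for j in range(n_feat)),
            degenerate=np.zeros((3, n_feat), bool),
        )

    def test_all_zero_matrix_gives_zero_vector(self):
        emf = estimate_emf(self._mm(np.zeros((3, 6)), 2))
        np.testing.assert_array_equal(emf.coefficients, np.zeros(6))
        assert emf.residual_norm == pytest.approx(np.sqrt(2.0))
        assert emf.rank == 0

    def test_exact_sparse_solution(self):
        m = np.zeros((3, 6))
        m[:, 4] = [-1, 0, 1]
        emf = estimate_emf(self._mm(m, 2))
        expected = np.zeros(6)
        expected[4] = 1.0
        np.testing.assert_allclose(emf.coefficients, expected, atol=1e-12)
        assert emf.residual_norm < 1e-12

    def test_matches_pseudoinverse_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_feat = int(rng.integers(1, 7))
            m = rng.standard_normal((3, 3 * n_feat))
            emf = estimate_emf(self._mm(m, n_feat))
            expected = minimum_norm_lsq_oracle(m, VALENCE_TARGETS)
            np.testing.assert_allclose(emf.coefficients, expected, atol=1e-8)
            if np.linalg.matrix_rank(m) == 3:
                np.testing.assert_allclose(m @ emf.coefficients, VALENCE_TARGETS, atol=1e-10)

    def test_minimum_norm_among_least_squares_solutions(self):
        # any other least-squares solution (coefficients plus a null-space
        # component) must have strictly larger Euclidean norm
        rng = np.random.default_rng(2)
        for _ in range(50):
            n_feat = int(rng.integers(2, 6))
            m = rng.standard_normal((3, 3 * n_feat))
            emf = estimate_emf(self._mm(m, n_feat))
            z = rng.standard_normal(3 * n_feat)
            null_component = z - np.linalg.pinv(m) @ (m @ z)
            if np.linalg.norm(null_component) < 1e-10:
                continue
            other = emf.coefficients + null_component
            # residual unchanged, norm strictly larger
            assert np.linalg.norm(m @ other - VALENCE_TARGETS) == pytest.approx(
                emf.residual_norm, abs=1e-8
            )
            assert np.linalg.norm(other) > np.linalg.norm(emf.coefficients) + 1e-8

    def test_non_finite_moments_rejected(self):
        with pytest.raises(ValueError):
            self._mm(np.full((3, 3), np.nan), 1)


class TestBuildEMFDataset:
    def test_shape_and_labels(self, small_cohort):
        table, manifest, _ = small_cohort
        sel = select_features(table, 0.7)
        ds = build_emf_dataset(table, manifest, sel)
        assert ds.D.shape == (19, 3 * sel.n_opt)
        assert ds.Y.sum() == 9
        assert set(ds.L.tolist()) == {0, 1, 2, 3}
        np.testing.assert_array_equal(ds.Y, (ds.L > 0).astype(int))

    def test_all_td_cohort_gives_zero_labels(self):
        cfg = SyntheticConfig(n_td=4, n_nos=0, n_sli=0, n_ad=0, seed=2,
                              n_signal=2, n_nuisance=1)
        table, manifest, _ = generate_cohort(cfg)
        sel = select_features(table, 0.7)
        ds = build_emf_dataset(table, manifest, sel)
        assert ds.Y.sum() == 0

    def test_noiseless_subject_interpolates_targets_exactly(self):
        cfg = SyntheticConfig(
            n_td=4, n_nos=1, n_sli=1, n_ad=1, noise_sd=0.0, within_group_sd=0.0,
            n_signal=3, n_nuisance=0, seed=13,
        )
        table, manifest, truth = generate_cohort(cfg)
        sel = select_features(table, 0.7)
        for sid in table.subjects:
            mm = per_valence_moments(table, sid, sel)
            # noiseless linear model: mean block row for valence v is a*v+b
            a = truth.slopes[sid]
            b = truth.offsets[sid]
            for row, v in enumerate((-1, 0, 1)):
                np.testing.assert_allclose(mm.block("mean")[row], a * v + b, atol=1e-12)
            emf = estimate_emf(mm)
            if emf.rank == 3:
                np.testing.assert_allclose(
                    mm.matrix @ emf.coefficients, VALENCE_TARGETS, atol=1e-10
                )

    def test_feature_permutation_equivariance(self, small_cohort):
        table, manifest, _ = small_cohort
        sel = select_features(table, 0.7)
        assert sel.n_opt >= 2
        ds = build_emf_dataset(table, manifest, sel)
        # permute selected feature order by reversing; coefficients must
        # permute identically inside each moment block
        rev = union_selected_features([set(sel.indices)], table.feature_names)
        from emfspeech.selection import SelectedFeatureSet

        rev = SelectedFeatureSet(names=sel.names[::-1], indices=sel.indices[::-1])
        ds_rev = build_emf_dataset(table, manifest, rev)
        n = sel.n_opt
        perm = np.arange(n)[::-1]
        for blk in range(3):
            np.testing.assert_allclose(
                ds_rev.D[:, blk * n : (blk + 1) * n],
                ds.D[:, blk * n : (blk + 1) * n][:, perm],
                atol=1e-8,
            )
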