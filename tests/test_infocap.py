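"""Binning, entropies, Blahut-Arimoto and capacity estimation."""

import numpy as np
import pytest

from glycocap import infocap, synthetic
from glycocap.exceptions import DomainError, SampleSizeError
from conftest import make_dataset


def grid_search_capacity(q: np.ndarray, step: float = 0.01) -> float:
    """Independent oracle: exhaustive search over the input simplex.

    Enumerates input distributions on a grid with the given step and returns
    the maximal mutual information in bits.  Only practical for 3 inputs.
    """
    assert q.shape[0] == 3
    k = round(1.0 / step)
    pts = []
    for a in range(k + 1):
        for b in range(k + 1 - a):
            pts.append((a / k, b / k, (k - a - b) / k))
    r = np.array(pts)
    qy = r @ q  # (n_pts, n_out)
    logq = np.where(q > 0, np.log2(np.where(q > 0, q, 1.0)), 0.0)
    row_neg_h = (q * logq).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logqy = np.where(qy > 0, np.log2(np.where(qy > 0, qy, 1.0)), 0.0)
    # I(r) = sum_i r_i * [ sum_j q_ij log q_ij - sum_j q_ij log qy_j ]
    kl = row_neg_h[:, None] - q @ logqy.T  # (n_in, n_pts)
    mi = (r * kl.T).sum(axis=1)
    return float(mi.max())


class TestBinOutput:
    def test_equal_frequency_splits_counts(self):
        ds = make_dataset([np.arange(1.0, 11.0)])
        binned = infocap.bin_output(ds, 2, "equal_frequency")
        assert binned.counts.tolist() == [[5, 5]]

    def test_equal_width_separates_disjoint_supports(self):
        a = np.linspace(0.0, 0.9, 30)
        b = np.linspace(1.1, 2.0, 30)
        ds = make_dataset([a, b])
        binned = infocap.bin_output(ds, 2, "equal_width")
        assert binned.counts.tolist() == [[30, 0], [0, 30]]

    def test_identical_outputs_collapse_to_one_bin(self):
        ds = make_dataset([np.full(10, 3.0)])
        binned = infocap.bin_output(ds, 4, "equal_frequency")
        assert binned.n_bins_effective == 1
        assert binned.counts.sum() == 10

    def test_row_sums_equal_cell_counts(self):
        rng = np.random.default_rng(0)
        ds = make_dataset([rng.normal(size=n) for n in (60, 80, 100)])
        binned = infocap.bin_output(ds, 7)
        np.testing.assert_array_equal(binned.counts.sum(axis=1), [60, 80, 100])

    def test_fewer_than_two_bins_rejected(self):
        ds = make_dataset([np.arange(5.0)])
        with pytest.raises(DomainError):
            infocap.bin_output(ds, 1)


class TestEstimateJoint:
    @pytest.mark.parametrize(
        "counts,weights,expected",
        [
            ([[5, 5]], [1.0], [[0.5, 0.5]]),
            ([[10, 0], [0, 10]], [0.5, 0.5], [[0.5, 0.0], [0.0, 0.5]]),
            ([[1, 3]], [1.0], [[0.25, 0.75]]),
        ],
    )
    def test_joint_probabilities(self, counts, weights, expected):
        joint = infocap.estimate_joint(counts, weights)
        np.testing.assert_allclose(joint.joint_p, expected)
        assert joint.joint_p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_cell_row_with_weight_rejected(self):
        with pytest.raises(DomainError):
            infocap.estimate_joint([[0, 0], [5, 5]], [0.5, 0.5])


class TestInfoSummary:
    def test_perfectly_correlated(self):
        joint = infocap.estimate_joint([[10, 0], [0, 10]], [0.5, 0.5])
        s = infocap.info_summary(joint)
        assert s == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_independent_uniform(self):
        joint = infocap.estimate_joint([[5, 5], [5, 5]], [0.5, 0.5])
        s = infocap.info_summary(joint)
        assert s.H_xy == pytest.approx(2.0)
        assert s.I_xy == pytest.approx(0.0, abs=1e-12)

    def test_four_term_example(self):
        # direct summation oracle for joint [[0.25, 0.25], [0, 0.5]]
        joint = infocap.estimate_joint([[1, 1], [0, 2]], [0.5, 0.5])
        s = infocap.info_summary(joint)
        p = np.array([0.25, 0.25, 0.5])
        h_xy = -(p * np.log2(p)).sum()
        h_y = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert s.I_xy == pytest.approx(1.0 + h_y - h_xy, abs=1e-9)
        assert s.I_xy == pytest.approx(0.311278, abs=1e-4)

    def test_identity_holds_and_bounds(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            counts = rng.integers(0, 50, size=(4, 6)) + 1
            w = rng.dirichlet(np.ones(4))
            s = infocap.info_summary(infocap.estimate_joint(counts, w))
            assert s.I_xy == pytest.approx(s.H_x + s.H_y - s.H_xy, abs=1e-9)
            assert -1e-9 <= s.I_xy <= min(s.H_x, s.H_y) + 1e-9

    def test_invariant_to_output_label_permutation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 40, size=(3, 5))
        w = np.full(3, 1 / 3)
        base = infocap.info_summary(infocap.estimate_joint(counts, w)).I_xy
        for _ in range(5):
            perm = rng.permutation(5)
            s = infocap.info_summary(infocap.estimate_joint(counts[:, perm], w))
            assert s.I_xy == pytest.approx(base, abs=1e-12)

    def test_merging_adjacent_bins_never_increases_mi(self):
        # data-processing inequality under output coarsening
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, 8)) + 1
            w = rng.dirichlet(np.ones(4))
            full = infocap.info_summary(infocap.estimate_joint(counts, w)).I_xy
            j = rng.integers(0, 7)
            merged = np.delete(counts, j, axis=1)
            merged[:, j if j < 7 else j - 1] += counts[:, j]
            coarse = infocap.info_summary(infocap.estimate_joint(merged, w)).I_xy
            assert coarse <= full + 1e-9


class TestBlahutArimoto:
    def test_identity_four_inputs(self):
        res = infocap.blahut_arimoto(np.eye(4))
        assert res.bits == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(res.optimal_input, 0.25, atol=1e-6)

    def test_binary_symmetric_channel(self):
        eps = 0.11
        q = np.array([[1 - eps, eps], [eps, 1 - eps]])
        res = infocap.blahut_arimoto(q, tol=1e-10)
        h2 = -eps * np.log2(eps) - (1 - eps) * np.log2(1 - eps)
        assert res.bits == pytest.approx(1 - h2, abs=1e-9)
        np.testing.assert_allclose(res.optimal_input, 0.5, atol=1e-5)

    def test_identical_rows_zero_capacity(self):
        q = np.array([[0.4, 0.6], [0.4, 0.6]])
        assert infocap.blahut_arimoto(q).bits == pytest.approx(0.0, abs=1e-9)

    def test_non_stochastic_rejected(self):
        with pytest.raises(DomainError):
            infocap.blahut_arimoto(np.array([[0.7, 0.7], [0.5, 0.5]]))

    def test_capacity_at_least_uniform_mi(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            q = rng.dirichlet(np.ones(4), size=3)
            res = infocap.blahut_arimoto(q, tol=1e-9)
            uniform_joint = infocap.estimate_joint(q * 100, np.full(3, 1 / 3))
            mi_uniform = infocap.info_summary(uniform_joint).I_xy
            assert res.bits >= mi_uniform - 1e-9

    def test_matches_exhaustive_grid_search(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            q = rng.dirichlet(np.ones(3), size=3)
            ba = infocap.blahut_arimoto(q, tol=1e-9).bits
            grid = grid_search_capacity(q, step=0.01)
            assert ba == pytest.approx(grid, abs=0.002)
            assert ba >= grid - 1e-9  # grid is a restriction of the maximization


class TestEstimateCapacity:
    def test_separable_four_input_channel(self):
        cfg = synthetic.KnownChannelConfig(
            conditional=np.eye(4), n_cells_per_dose=2000,
            output_centers=[0.0, 1.0, 2.0, 3.0], output_jitter_sd=0.05, seed=0)
        ds = synthetic.simulate_known_channel(cfg)
        est = infocap.estimate_capacity(ds, n_bins=16, n_bootstrap=0, seed=1)
        assert est.bits == pytest.approx(2.0, abs=0.05)
        np.testing.assert_allclose(est.optimal_input, 0.25, atol=0.02)

    def test_capacity_bounded_by_log_doses(self):
        cfg = synthetic.MixtureReporterConfig(n_cells_per_dose=300, seed=8)
        ds = synthetic.simulate_mixture_reporter(cfg)
        est = infocap.estimate_capacity(ds, n_bins=15, n_bootstrap=0, seed=2)
        assert est.bits <= np.log2(ds.n_doses) + 1e-9

    def test_minimum_cells_enforced(self):
        ds = make_dataset([np.arange(10.0), np.arange(10.0) + 5])
        with pytest.raises(SampleSizeError, match="50"):
            infocap.estimate_capacity(ds, n_bins=4)

    def test_bias_correction_reduces_capacity_on_independence_data(self):
        rng = np.random.default_rng(17)
        over = 0
        for seed in range(6):
            ds = make_dataset(
                [rng.normal(size=400) for _ in range(8)])
            est = infocap.estimate_capacity(
                ds, n_bins=15, bias_correction=True, n_bootstrap=0, seed=seed)
            if est.uncorrected_bits > est.bits:
                over += 1
        assert over >= 5  # plug-in bias is positive in essentially every run

    @pytest.mark.parametrize("nested", [False, True])
    def test_bootstrap_ci_brackets_estimate(self, nested):
        cfg = synthetic.KnownChannelConfig(
            conditional=np.eye(2), n_cells_per_dose=500,
            output_centers=[0.0, 1.0], output_jitter_sd=0.05, seed=3)
        ds = synthetic.simulate_known_channel(cfg)
        est = infocap.estimate_capacity(
            ds, n_bins=8, bias_correction=True, n_bootstrap=30, seed=4,
            nested_bootstrap=nested)
        assert est.ci_low <= est.bits <= est.ci_high
        assert not est.ci_flag

    def test_deterministic_given_seed(self):
        cfg = synthetic.MixtureReporterConfig(n_cells_per_dose=200, seed=12)
        ds = synthetic.simulate_mixture_reporter(cfg)
        a = infocap.estimate_capacity(ds, n_bins=10, n_bootstrap=10, seed=5)
        b = infocap.estimate_capacity(ds, n_bins=10, n_bootstrap=10, seed=5)
        assert a.bits == b.bits and a.ci_low == b.ci_low


class TestCapacityVsMaxDose:
    def test_two_dose_dataset_gives_single_point(self):
        rng = np.random.default_rng(0)
        ds = make_dataset([rng.normal(0, 1, 200), rng.normal(3, 1, 200)],
                          doses=[0.0, 1.0])
        curve = infocap.capacity_vs_max_dose(ds, n_bins=8, n_bootstrap=0, seed=1)
        assert len(curve) == 1
        assert curve[0][0] == 1.0

    def test_true_capacity_non_decreasing_in_prefix(self):
        q = np.array([
            [0.9, 0.1, 0.0, 0.0],
            [0.1, 0.8, 0.1, 0.0],
            [0.0, 0.1, 0.8, 0.1],
            [0.0, 0.0, 0.1, 0.9],
        ])
        caps = [synthetic.true_capacity(q[:k, :]) for k in range(2, 5)]
        assert all(b >= a - 1e-12 for a, b in zip(caps, caps[1:]))

    def test_step_channel_capacity_appears_with_top_dose(self):
        # first three inputs indistinguishable; the top input separates
        q = np.array([
            [0.5, 0.5],
            [0.5, 0.5],
            [0.5, 0.5],
            [0.0, 1.0],
        ])
        truths = [synthetic.true_capacity(q[:k, :]) for k in range(2, 5)]
        assert truths[0] == pytest.approx(0.0, abs=1e-9)
        assert truths[-1] > 0.3
        cfg = synthetic.KnownChannelConfig(
            conditional=q, n_cells_per_dose=2000,
            output_centers=[0.0, 1.0], output_jitter_sd=0.0, seed=6)
        ds = synthetic.simulate_known_channel(cfg)
        curve = infocap.capacity_vs_max_dose(ds, n_bins=4, n_bootstrap=0, seed=7)
        bits = [est.bits for _, est in curve]
        assert bits[0] < 0.05 and bits[1] < 0.05
        assert bits[2] == pytest.approx(truths[-1], abs=0.05)


class TestSelectBinCount:
    def test_separable_channel_plateau_returns_smallest(self):
        cfg = synthetic.KnownChannelConfig(
            conditional=np.eye(4), n_cells_per_dose=1500,
            output_centers=[0.0, 1.0, 2.0, 3.0], output_jitter_sd=0.05, seed=2)
        ds = synthetic.simulate_known_channel(cfg)
        choice = infocap.select_bin_count(ds, candidates=(8, 16, 32), seed=3)
        assert choice == 8

    def test_independence_data_returns_smallest(self):
        rng = np.random.default_rng(9)
        ds = make_dataset([rng.normal(size=300) for _ in range(5)])
        choice = infocap.select_bin_count(ds, candidates=(10, 20, 30), seed=4)
        assert choice == 10

    def test_single_candidate_rejected(self):
        rng = np.random.default_rng(9)
        ds = make_dataset([rng.normal(size=300) for _ in range(3)])
        with pytest.raises(DomainError):
            infocap.select_bin_count(ds, candidates=(10,))
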