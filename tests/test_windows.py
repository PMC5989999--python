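"""Sliding-window plans, correlation/power series, dynamics matrices."""

import numpy as np
import pytest

from eegdyn import (BANDS, DynamicsMatrix, Segment, band_power_series,
                    bandpass_filter_segment, cdm_pdm_difference,
                    correlation_vector_series, dynamics_matrix, plan_windows)

from conftest import make_segment


def _segment(data, fs=256.0):
    return Segment("t", np.asarray(data, float), fs)


# ---------------------------------------------------------------------------
# window plans
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fs,expected_k", [(512.0, 4097), (256.0, 2049)])
def test_unit_step_window_count(fs, expected_k):
    seg = _segment(np.zeros((2, int(10 * fs))), fs)
    plan = plan_windows(seg, window_len=2.0, step=1)
    assert plan.k == expected_k
    assert plan.starts[0] == 0
    assert plan.starts[-1] == int(8 * fs)


def test_window_equal_to_segment_gives_single_window():
    seg = _segment(np.zeros((2, 512)), 256.0)
    plan = plan_windows(seg, window_len=2.0, step=1)
    assert plan.k == 1


def test_window_longer_than_segment_rejected():
    seg = _segment(np.zeros((2, 256)), 256.0)
    with pytest.raises(ValueError, match="longer than segment"):
        plan_windows(seg, window_len=2.0, step=1)


# ---------------------------------------------------------------------------
# correlation vector series
# ---------------------------------------------------------------------------

def test_correlation_vector_width_is_upper_triangle_count(rng):
    seg = _segment(rng.normal(0, 1, (19, 1024)))
    plan = plan_windows(seg, 2.0, step=64)
    series = correlation_vector_series(seg, plan)
    assert series.values.shape == (plan.k, 19 * 18 // 2)
    assert np.all(series.values >= -1) and np.all(series.values <= 1)


def test_duplicated_channel_correlates_at_one(rng):
    x = rng.normal(0, 1, 1024)
    seg = _segment(np.vstack([x, x, rng.normal(0, 1, 1024)]))
    plan = plan_windows(seg, 1.0, step=128)
    series = correlation_vector_series(seg, plan)
    # pair (0, 1) is the first upper-triangle entry in row-major order
    assert np.allclose(series.values[:, 0], 1.0)


def test_correlation_series_matches_brute_force(rng):
    seg = _segment(rng.normal(0, 5, (4, 2560)))
    plan = plan_windows(seg, 2.0, step=64)          # k = 33
    series = correlation_vector_series(seg, plan)
    for t, start in enumerate(plan.starts):
        win = seg.data[:, start:start + plan.window_samples]
        expected = np.corrcoef(win)[np.triu_indices(4, k=1)]
        assert np.max(np.abs(series.values[t] - expected)) < 1e-10


def test_constant_channel_maps_to_zero_correlation(rng):
    data = rng.normal(0, 1, (3, 512))
    data[1] = 4.2
    seg = _segment(data)
    plan = plan_windows(seg, 1.0, step=256)
    series = correlation_vector_series(seg, plan)
    assert series.n_degenerate > 0
    assert np.allclose(series.values[:, 0], 0.0)    # pair (0, constant)


# ---------------------------------------------------------------------------
# band power series
# ---------------------------------------------------------------------------

def test_sinusoid_window_power_is_half_amplitude_squared():
    fs = 256.0
    t = np.arange(int(4 * fs)) / fs
    seg = _segment(np.vstack([np.sin(2 * np.pi * 10 * t),
                              np.zeros_like(t)]), fs)
    plan = plan_windows(seg, 2.0, step=128)
    power = band_power_series(seg, plan)
    assert np.allclose(power.values[:, 0], 0.5, rtol=0.02)
    assert np.allclose(power.values[:, 1], 0.0)


def test_white_noise_window_power_near_variance():
    sigma = 7.0
    local = np.random.default_rng(2024)
    seg = _segment(local.normal(0, sigma, (1, 2560)))
    plan = plan_windows(seg, 2.0, step=256)
    power = band_power_series(seg, plan)
    rel = power.values / sigma ** 2 - 1
    # per-window mean-square of 512 white samples has ~6% relative sd
    assert abs(rel.mean()) < 0.05
    assert np.abs(rel).max() < 0.20


# ---------------------------------------------------------------------------
# dynamics matrices
# ---------------------------------------------------------------------------

def test_identical_rows_give_all_ones():
    from eegdyn import CorrelationVectorSeries
    rows = CorrelationVectorSeries(np.tile([0.2, -0.5, 0.9, 0.1], (6, 1)))
    M = dynamics_matrix(rows, "CDM")
    assert np.allclose(M.values, 1.0)


def test_alternating_orthogonal_rows_give_checkerboard():
    from eegdyn import CorrelationVectorSeries
    a = np.array([1.0, -1.0, 1.0, -1.0])
    rows = CorrelationVectorSeries(np.vstack([a, -a, a, -a]))
    M = dynamics_matrix(rows, "CDM")
    expected = np.array([[1, -1, 1, -1],
                         [-1, 1, -1, 1],
                         [1, -1, 1, -1],
                         [-1, 1, -1, 1]], dtype=float)
    assert np.allclose(M.values, expected)


def test_dynamics_matrix_matches_brute_force(rng):
    from eegdyn import CorrelationVectorSeries
    rows = CorrelationVectorSeries(rng.normal(0, 1, (20, 6)))
    M = dynamics_matrix(rows, "PDM").values
    for s in range(20):
        for t in range(20):
            expected = 1.0 if s == t else np.corrcoef(rows.values[s],
                                                      rows.values[t])[0, 1]
            assert abs(M[s, t] - expected) < 1e-10


def test_dynamics_matrix_symmetry_unit_diagonal_bounds(rng):
    seg = _segment(rng.normal(0, 10, (5, 2560)))
    plan = plan_windows(seg, 2.0, step=128)
    for maker, kind in ((correlation_vector_series, "CDM"),
                        (band_power_series, "PDM")):
        M = dynamics_matrix(maker(seg, plan), kind).values
        assert np.array_equal(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert M.min() >= -1.0 and M.max() <= 1.0


def test_constant_window_vector_zeroed_and_counted():
    from eegdyn import PowerSeries
    rows = PowerSeries(np.vstack([[1.0, 1.0, 1.0],
                                  [0.5, 1.0, 2.0],
                                  [2.0, 1.0, 0.5]]))
    M = dynamics_matrix(rows, "PDM")
    assert M.n_degenerate == 1
    assert np.allclose(M.values[0, 1:], 0.0)
    assert M.values[0, 0] == 1.0


def test_invalid_kind_rejected():
    with pytest.raises(ValueError, match="CDM or PDM"):
        DynamicsMatrix(np.eye(3), kind="XYZ")


# ---------------------------------------------------------------------------
# CDM - PDM difference
# ---------------------------------------------------------------------------

def test_difference_of_equal_matrices_is_zero():
    M = DynamicsMatrix(np.eye(4), "CDM")
    P = DynamicsMatrix(np.eye(4), "PDM")
    assert cdm_pdm_difference(M, P) == 0.0


def test_difference_ones_vs_identity():
    M = DynamicsMatrix(np.ones((4, 4)), "CDM")
    P = DynamicsMatrix(np.eye(4), "PDM")
    assert cdm_pdm_difference(M, P) == pytest.approx(0.75)


def test_difference_ignores_zero_mean_perturbation(rng):
    base = rng.uniform(-1, 1, (6, 6))
    pert = rng.normal(0, 0.1, (6, 6))
    pert = pert - pert.mean()
    d1 = cdm_pdm_difference(DynamicsMatrix(base, "CDM"),
                            DynamicsMatrix(base * 0.5, "PDM"))
    d2 = cdm_pdm_difference(DynamicsMatrix(base, "CDM"),
                            DynamicsMatrix(base * 0.5 + pert, "PDM"))
    assert d1 == pytest.approx(d2, abs=1e-12)


def test_difference_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shapes differ"):
        cdm_pdm_difference(DynamicsMatrix(np.eye(3), "CDM"),
                           DynamicsMatrix(np.eye(4), "PDM"))


# ---------------------------------------------------------------------------
# structural invariants on synthetic controls
# ---------------------------------------------------------------------------

def test_stationary_control_cdm_is_diagonal_dominant():
    """Window overlap decays with lag; far-off-diagonal stays weak.

    For strictly stationary recordings high CDM values concentrate near the
    leading diagonal: adjacent windows (sharing almost all samples)
    correlate more than windows one window-length apart, and entries beyond
    twice the window length average below 0.3.
    """
    far_means, near, one_len = [], [], []
    for seed in range(10):
        seg = make_segment("stationary_control", 100 + seed, fs=128.0)
        bb = bandpass_filter_segment(seg, BANDS["broadband"])
        plan = plan_windows(bb, 2.0, step=1)
        C = dynamics_matrix(correlation_vector_series(bb, plan), "CDM").values
        k = plan.k
        i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        lag = np.abs(i - j)
        fs = int(seg.fs)
        near.append(C[lag == 1].mean())
        one_len.append(C[lag == fs].mean())
        far_means.append(C[lag > 2 * plan.window_samples].mean())
    assert all(a >= b for a, b in zip(near, one_len))
    assert np.mean(far_means) < 0.3
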