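"""Inverse-remodelling core: NNLS optimization, magnitudes, CoV metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from jointload.errors import (
    InvalidArgumentError,
    UndefinedMetricError,
)
from jointload.fe import LoadCase
from jointload.inverse import (
    EQUILIBRIUM_STIMULUS_MPA,
    LoadingHistory,
    StimulusMatrix,
    cov_stimulus,
    magnitudes,
    mean_load_vector,
    optimize_history,
    quality_report,
    stimulus_field,
)


def grid_search_nnls(A, b, lo=0.0, hi=5.0, final_step=0.01):
    """Independent brute-force oracle: multiscale grid minimization of
    ``‖b - A·s‖²`` over the box ``[lo, hi]^n``.

    The objective is convex, so zooming the grid around the incumbent
    converges to the global box-constrained minimum; the first level scans
    the whole box exhaustively.
    """
    n = A.shape[1]
    G = A.T @ A
    h = A.T @ b
    center = np.full(n, (lo + hi) / 2)
    half = (hi - lo) / 2
    step = half / 5
    while True:
        axes = [np.clip(center[i] + np.arange(-5, 6) * step, lo, hi)
                for i in range(n)]
        S = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n)
        q = np.einsum("ij,jk,ik->i", S, G, S) - 2.0 * S @ h
        center = S[np.argmin(q)]
        if step <= final_step:
            return center
        step = max(step * 0.4, final_step)


def _unit_cases(angles):
    cases = []
    for i, a in enumerate(angles):
        th = np.deg2rad(a)
        d = -np.array([np.cos(th), np.sin(th), 0.0])
        cases.append(LoadCase(index=i + 1, angle_deg=a, resultant_N=100.0 * d,
                              node_ids=np.array([0]), nodal_force_N=100.0 * d))
    return cases


ANGLES = (-75.0, -45.0, -15.0, 15.0, 45.0, 75.0)


class TestOptimizeHistory:
    def test_separable_exact_solution(self):
        # two orthogonal columns of value 0.01: each element matched exactly
        # when 0.01 * s = 0.02
        A = np.array([[0.01, 0.0], [0.0, 0.01]])
        s = optimize_history(A, u_tilde=0.02)
        assert np.allclose(s, [2.0, 2.0], atol=1e-12)
        assert np.allclose(stimulus_field(A, s), 0.02)

    def test_beats_uniform_scaling(self, rng):
        A = rng.uniform(0.0, 0.01, size=(40, 6))
        s = optimize_history(A)
        b = np.full(40, EQUILIBRIUM_STIMULUS_MPA)
        uniform = np.full(6, EQUILIBRIUM_STIMULUS_MPA / (A @ np.ones(6)).mean())
        assert np.sum((b - A @ s) ** 2) <= np.sum((b - A @ uniform) ** 2) + 1e-15

    @pytest.mark.parametrize("seed", [7, 21, 99])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.0, 0.01, size=(30, 6))
        b = np.full(30, EQUILIBRIUM_STIMULUS_MPA)
        s = optimize_history(A)
        s_grid = grid_search_nnls(A, b)
        assert s.max() < 4.9  # optimum interior to the oracle's box
        assert np.max(np.abs(s - s_grid)) <= 0.011

    def test_nonnegativity_and_determinism(self, rng):
        A = rng.uniform(0, 1e-2, size=(50, 6))
        s1 = optimize_history(A)
        s2 = optimize_history(A.copy())
        assert (s1 >= 0).all()
        assert np.array_equal(s1, s2)

    def test_probe_optimality(self, rng):
        A = rng.uniform(0, 1e-2, size=(50, 6))
        s = optimize_history(A)
        b = np.full(50, EQUILIBRIUM_STIMULUS_MPA)
        best = np.sum((b - A @ s) ** 2)
        probes = rng.uniform(0, 2, size=(1000, 6))
        vals = np.sum((b[None, :] - probes @ A.T) ** 2, axis=1)
        assert (vals >= best - 1e-14).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(InvalidArgumentError):
            optimize_history(np.zeros((10, 6)))

    def test_scale_behaviour(self, rng):
        # scaling all SED columns by c divides s by c; A·s is invariant
        A = rng.uniform(0, 1e-2, size=(30, 6))
        s = optimize_history(A)
        s_scaled = optimize_history(3.0 * A)
        assert np.allclose(3.0 * s_scaled, s, rtol=1e-8, atol=1e-12)
        assert np.allclose(stimulus_field(A, s),
                           stimulus_field(3.0 * A, s_scaled), rtol=1e-8)


class TestMagnitudes:
    def test_algebra(self):
        assert np.allclose(magnitudes(np.full(6, 1 / 6)), 1.0)
        assert magnitudes(np.array([0.0, 1.0]))[0] == 0.0

    def test_round_trip(self, rng):
        s = rng.uniform(0, 2, size=6)
        alpha = magnitudes(s)
        assert np.allclose(alpha**2 / 6, s)

    def test_negative_rejected(self):
        with pytest.raises(InvalidArgumentError):
            magnitudes(np.array([-0.1, 1.0]))


class TestMeanLoadVector:
    def test_zero_history(self):
        cases = _unit_cases(ANGLES)
        assert np.allclose(mean_load_vector(np.zeros(6), cases), 0.0)

    def test_single_case(self):
        cases = _unit_cases(ANGLES)
        alpha = np.zeros(6)
        alpha[3] = 1.0  # +15 degrees
        fbar = mean_load_vector(alpha, cases)
        assert np.allclose(fbar, cases[3].resultant_N / 6)

    def test_symmetric_history_bisects(self):
        cases = _unit_cases(ANGLES)
        alpha = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
        fbar = mean_load_vector(alpha, cases)
        # symmetric about 0 deg: no palmar/dorsal component
        assert abs(fbar[1]) < 1e-12
        assert fbar[0] < 0  # compressive resultant points proximally


class TestCov:
    def test_constant_field_is_zero(self):
        assert cov_stimulus(np.full(100, 0.02)) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_value(self):
        assert cov_stimulus(np.array([1.0, 3.0])) == pytest.approx(50.0)

    def test_sample_sd_option(self):
        U = np.array([1.0, 3.0])
        assert cov_stimulus(U, ddof=1) == pytest.approx(100 * np.sqrt(2) / 2)

    def test_scale_invariance(self, rng):
        U = rng.uniform(0.5, 2.0, size=200)
        assert cov_stimulus(U) == pytest.approx(cov_stimulus(7.3 * U))

    def test_zero_mean_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cov_stimulus(np.zeros(5))


class TestQualityReport:
    def test_separable_case_perfect(self):
        # unbalanced columns: uniform scaling leaves an inhomogeneous field,
        # the optimum equalizes it exactly
        A = np.array([[0.01, 0.0], [0.0, 0.04]])
        s = optimize_history(A)
        cov_init, cov_opt = quality_report(A, s)
        assert cov_opt == pytest.approx(0.0, abs=1e-9)
        assert cov_init > 0

    def test_cov_init_scale_free(self, rng):
        A = rng.uniform(0, 1e-2, size=(30, 6))
        s = optimize_history(A)
        c1, _ = quality_report(A, s)
        c2, _ = quality_report(A * 5.0, optimize_history(A * 5.0))
        assert c1 == pytest.approx(c2)

    def test_optimization_never_hurts(self, rng):
        for _ in range(5):
            A = rng.uniform(0, 1e-2, size=(40, 6))
            cov_init, cov_opt = quality_report(A, optimize_history(A))
            assert cov_opt <= cov_init + 1e-9


class TestProperties:
    """Algebraic invariants over arbitrary admissible inputs."""

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(arrays(float, 6, elements=st.floats(0.0, 10.0)))
    def test_magnitudes_round_trip(self, s):
        alpha = magnitudes(s)
        assert (alpha >= 0).all()
        assert np.allclose(alpha**2 / len(s), s, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(arrays(float, (12, 4), elements=st.floats(1e-6, 1e-1)),
           st.floats(0.1, 10.0))
    def test_cov_scale_invariant_and_nonneg(self, A, c):
        U = A @ np.ones(4)
        assert cov_stimulus(U) >= 0
        assert cov_stimulus(c * U) == pytest.approx(cov_stimulus(U), rel=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(float, (15, 3), elements=st.floats(0.0, 0.05)))
    def test_nnls_solution_nonnegative_and_no_worse_than_zero(self, A):
        if not A.any():
            return
        s = optimize_history(A)
        assert (s >= 0).all()
        b = np.full(15, EQUILIBRIUM_STIMULUS_MPA)
        assert np.sum((b - A @ s) ** 2) <= np.sum(b**2) + 1e-12


class TestLoadingHistory:
    def test_alpha_s_consistency_enforced(self):
        with pytest.raises(InvalidArgumentError):
            LoadingHistory(s=np.full(6, 1 / 6), alpha=np.full(6, 2.0),
                           mean_vector_N=np.zeros(3),
                           cov_init_pct=1.0, cov_opt_pct=1.0)

    def test_json_round_trip(self, tmp_path):
        s = np.array([0.1, 0.0, 0.2, 0.3, 0.0, 0.05])
        h = LoadingHistory(s=s, alpha=np.sqrt(6 * s),
                           mean_vector_N=np.array([-10.0, 2.0, 0.0]),
                           cov_init_pct=120.0, cov_opt_pct=100.0,
                           angles_deg=np.array(ANGLES))
        path = tmp_path / "h.json"
        h.to_json(path)
        import json
        h2 = LoadingHistory.from_dict(json.loads(path.read_text()))
        assert np.allclose(h2.s, h.s)
        assert np.allclose(h2.mean_vector_N, h.mean_vector_N)
        assert h2.dominant_index == h.dominant_index


class TestStimulusMatrix:
    def test_negative_entries_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StimulusMatrix(A=np.array([[-1.0]]), elem_idx=np.zeros((1, 3), int),
                           angles_deg=np.array([0.0]))

    def test_zero_column_preserved(self, rng):
        A = rng.uniform(0, 1e-2, size=(20, 6))
        A[:, 2] = 0.0
        sm = StimulusMatrix(A=A, elem_idx=np.zeros((20, 3), int),
                            angles_deg=np.array(ANGLES))
        assert not sm.A[:, 2].any()
        assert sm.n_load_cases == 6
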