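"""Steady states, stability, separatrices, basins and bifurcation detection."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.ndimage import binary_dilation, label as cc_label

from togglescape import (assign_basin, compute_portrait, compute_separatrix,
                         detect_bifurcations, find_steady_states,
                         label_regime, vector_field)
from togglescape.scenarios import BASELINE


def brute_force_root_count(p, n=400):
    """Independent oracle: count connected clusters of grid cells in which
    both components of the flow change sign."""
    xmax, ymax = p.trapping_box()
    xs = np.linspace(0.0, xmax, n)
    ys = np.linspace(0.0, ymax, n)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    f, g = vector_field(np.stack([xx, yy]), p)

    def straddles_zero(A):
        corners = np.stack([A[:-1, :-1], A[1:, :-1], A[:-1, 1:], A[1:, 1:]])
        return (corners.min(axis=0) <= 0) & (corners.max(axis=0) >= 0)

    cand = straddles_zero(f) & straddles_zero(g)
    # a single root's candidate cells can straddle a one-cell gap; distinct
    # roots of this model are dozens of cells apart at n=400, so a one-cell
    # dilation merges fragments without ever merging distinct roots
    cand = binary_dilation(cand, structure=np.ones((3, 3)))
    _, n_comp = cc_label(cand, structure=np.ones((3, 3)))
    return n_comp


class TestSteadyStates:
    def test_bistable_census(self, bistable_portrait):
        assert len(bistable_portrait.attractors) == 2
        assert len(bistable_portrait.saddles) == 1

    def test_tristable_census(self, tristable_portrait):
        assert len(tristable_portrait.attractors) == 3
        assert len(tristable_portrait.saddles) == 2

    def test_monostable_census(self, monostable_portrait):
        assert len(monostable_portrait.attractors) == 1
        assert len(monostable_portrait.saddles) == 0

    def test_residuals_below_tolerance(self, tristable_portrait):
        for s in tristable_portrait.steady_states:
            r = np.max(np.abs(vector_field(s.position, tristable_portrait.params)))
            assert r < 1e-9

    def test_attractor_and_saddle_eigenvalue_signs(self, bistable_portrait):
        for s in bistable_portrait.attractors:
            assert np.all(np.real(s.eigenvalues) < 0)
        for s in bistable_portrait.saddles:
            re = np.sort(np.real(s.eigenvalues))
            assert re[0] < 0 < re[1]

    def test_duplicate_starts_are_merged(self, bistable_params):
        # 49 starts but only 3 distinct roots reported
        states = find_steady_states(bistable_params, grid_n=7)
        assert len(states) == 3
        pos = np.array([s.position for s in states])
        dists = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        assert np.min(dists[dists > 0]) > 1e-3

    def test_symmetric_parameters_give_mirror_symmetric_states(
            self, sweep_portraits):
        for pp in sweep_portraits:
            pos = np.array([s.position for s in pp.steady_states])
            for q in pos:
                assert np.min(np.linalg.norm(pos - q[::-1], axis=1)) < 1e-6

    @pytest.mark.parametrize("regime,band", [
        ("bistable", (0.32, 0.58)),
        ("tristable", (0.66, 0.73)),
        ("monostable", (0.80, 1.10)),
    ])
    def test_count_agrees_with_brute_force_grid_oracle(self, regime, band):
        rng = np.random.default_rng(20140404)
        checked = 0
        for _ in range(10):
            a = float(rng.uniform(*band))
            alpha = float(0.3 * rng.uniform(0.97, 1.03))
            bd = float(0.5 * rng.uniform(0.97, 1.03))
            p = BASELINE.replace(a=a, c=a, alpha_x=alpha, alpha_y=alpha,
                                 b=bd, d=bd)
            states = find_steady_states(p)
            assert len(states) == brute_force_root_count(p)
            checked += 1
        assert checked == 10


class TestRegimeLabel:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 0), "monostable"),
        ((2, 1), "bistable"),
        ((3, 2), "tristable"),
        ((2, 2), "other"),
        ((0, 1), "other"),
    ])
    def test_census_mapping(self, counts, expected):
        assert label_regime(*counts) == expected

    def test_sweep_regimes_consistent_with_counts(self, sweep_portraits):
        for pp in sweep_portraits:
            expected = label_regime(len(pp.attractors), len(pp.saddles))
            assert pp.regime == expected
            assert pp.regime in ("bistable", "tristable", "monostable")


class TestSeparatrix:
    def test_symmetric_bistable_separatrix_is_the_diagonal(
            self, bistable_portrait):
        assert len(bistable_portrait.separatrices) == 1
        poly = bistable_portrait.separatrices[0]
        assert np.max(np.abs(poly[:, 0] - poly[:, 1])) < 1e-6

    def test_saddle_lies_on_its_separatrix(self, tristable_portrait):
        for saddle, poly in zip(tristable_portrait.saddles,
                                tristable_portrait.separatrices):
            d = np.min(np.linalg.norm(poly - saddle.position[None, :], axis=1))
            assert d < 1e-12

    def test_points_flow_back_to_the_saddle(self, bistable_portrait):
        # forward-integration oracle: states on the stable manifold approach
        # the saddle before any numerical drift expels them
        p = bistable_portrait.params
        saddle = bistable_portrait.saddles[0]
        poly = bistable_portrait.separatrices[0]
        for idx in (50, 150, len(poly) - 50):
            s0 = poly[idx]
            sol = solve_ivp(lambda t, s: vector_field(s, p), (0, 50), s0,
                            dense_output=True, rtol=1e-10, atol=1e-12)
            ts = np.linspace(0, sol.t[-1], 400)
            d = np.linalg.norm(sol.sol(ts).T - saddle.position[None, :], axis=1)
            assert np.min(d) < 5e-2

    def test_non_saddle_input_rejected(self, bistable_portrait):
        with pytest.raises(ValueError):
            compute_separatrix(bistable_portrait.attractors[0],
                               bistable_portrait.params)


class TestBasins:
    def test_attractor_position_maps_to_itself(self, bistable_portrait):
        for i, s in enumerate(bistable_portrait.steady_states):
            if s.kind != "attractor":
                continue
            assert assign_basin(s.position, bistable_portrait) == i

    def test_off_diagonal_point_goes_to_the_near_attractor(
            self, bistable_portrait):
        idx = assign_basin((1.0, 0.2), bistable_portrait)
        att = bistable_portrait.steady_states[idx]
        assert att.x > att.y  # the high-x attractor

    def test_diagonal_point_is_unresolved(self, bistable_portrait):
        assert assign_basin((0.8, 0.8), bistable_portrait) is None

    def test_negative_state_rejected(self, bistable_portrait):
        with pytest.raises(ValueError):
            assign_basin((-0.1, 0.2), bistable_portrait)


class TestBifurcations:
    def test_identical_portraits_give_no_events(self, bistable_portrait):
        assert detect_bifurcations(bistable_portrait, bistable_portrait,
                                   t=0.0) == []

    def test_pitchfork_at_the_bistable_tristable_boundary(self, pitchfork_values):
        a0, a1 = pitchfork_values - 0.01, pitchfork_values + 0.01
        prev = compute_portrait(BASELINE.replace(a=a0, c=a0),
                                with_separatrices=False)
        curr = compute_portrait(BASELINE.replace(a=a1, c=a1),
                                with_separatrices=False)
        events = detect_bifurcations(prev, curr, t=1.0)
        assert [e.kind for e in events] == ["subcritical_pitchfork"]

    def test_double_saddle_node_at_the_tristable_monostable_boundary(
            self, saddle_node_value):
        a0, a1 = saddle_node_value - 0.005, saddle_node_value + 0.005
        prev = compute_portrait(BASELINE.replace(a=a0, c=a0),
                                with_separatrices=False)
        curr = compute_portrait(BASELINE.replace(a=a1, c=a1),
                                with_separatrices=False)
        events = detect_bifurcations(prev, curr, t=1.0)
        assert sorted(e.kind for e in events) == ["saddle_node", "saddle_node"]

    def test_sweep_bifurcation_sequence(self, sweep_portraits, sweep_values):
        seq = []
        for k in range(1, len(sweep_portraits)):
            for e in detect_bifurcations(sweep_portraits[k - 1],
                                         sweep_portraits[k],
                                         t=float(sweep_values[k])):
                seq.append(e.kind)
        assert seq == ["subcritical_pitchfork", "saddle_node", "saddle_node"]
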