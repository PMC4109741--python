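"""Quasi-potential accumulation, normalisation and surface construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from togglescape import (ParamSchedule, Ramp, accumulate,
                         accumulate_trajectory, build_surface, delta_vq,
                         integrate, integrate_autonomous, vector_field)
from togglescape.scenarios import BASELINE


@pytest.fixture(scope="module")
def bistable_surface(bistable_params, bistable_portrait):
    return build_surface(bistable_params, seed_grid_n=10, grid_out=60,
                         portrait=bistable_portrait)


class TestDeltaVq:
    def test_zero_flow_gives_zero_increment(self):
        assert delta_vq((0.0, 0.0), 0.5) == 0.0

    def test_direct_formula(self):
        assert delta_vq((1.0, 1.0), 0.1) == pytest.approx(-0.2)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(fx=st.floats(-5, 5), fy=st.floats(-5, 5),
           dt=st.floats(1e-4, 1.0))
    def test_nonzero_flow_gives_strictly_negative_increment(self, fx, fy, dt):
        dv = delta_vq((fx, fy), dt)
        if max(abs(fx), abs(fy)) < 1e-100:  # squaring underflows to zero
            assert dv == 0
        else:
            assert dv < 0

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            delta_vq((1, 1), 0.0)
        with pytest.raises(ValueError):
            delta_vq((1, 1), -0.1)


class TestAccumulate:
    def test_trajectory_at_attractor_stays_at_zero(self, bistable_portrait):
        s0 = bistable_portrait.attractors[0].position
        t, states = integrate_autonomous(BASELINE, s0, 10.0, 100)
        vq = accumulate(t, states, BASELINE)
        assert np.max(np.abs(vq)) < 1e-8

    def test_sequence_is_non_increasing(self):
        t, states = integrate_autonomous(BASELINE, (1.3, 1.2), 30.0, 300)
        vq = accumulate(t, states, BASELINE)
        assert np.all(np.diff(vq) <= 0)

    def test_strict_decrease_away_from_steady_states(self, bistable_portrait):
        t, states = integrate_autonomous(BASELINE, (1.3, 1.2), 5.0, 100)
        vq = accumulate(t, states, BASELINE)
        speed = np.linalg.norm(
            vector_field(states.T, BASELINE).T, axis=1)
        moving = np.minimum(speed[:-1], speed[1:]) > 1e-3
        assert np.all(np.diff(vq)[moving] < 0)

    def test_refinement_changes_terminal_value_little(self):
        coarse_t, coarse_s = integrate_autonomous(BASELINE, (1.3, 1.2), 20.0, 200)
        fine_t, fine_s = integrate_autonomous(BASELINE, (1.3, 1.2), 20.0, 400)
        v_c = accumulate(coarse_t, coarse_s, BASELINE)[-1]
        v_f = accumulate(fine_t, fine_s, BASELINE)[-1]
        # the midpoint rule converges quadratically; at these sampling
        # densities the terminal level is stable to well under 1%
        assert abs(v_c - v_f) < 5e-3 * abs(v_f)

    def test_non_constant_schedule_rejected(self):
        sch = ParamSchedule(BASELINE, (Ramp("a_c", 0, 5, 0.3, 0.5),),
                            dt_step=0.5, t_final=5)
        res = integrate(sch, (1.0, 0.3))
        with pytest.raises(ValueError, match="constant"):
            accumulate_trajectory(res.trajectory)

    def test_constant_schedule_accepted(self, bistable_portrait):
        sch = ParamSchedule(BASELINE, (), dt_step=0.5, t_final=5)
        res = integrate(sch, (1.0, 0.3), portraits=[bistable_portrait] * 10)
        vq = accumulate_trajectory(res.trajectory)
        assert len(vq) == len(res.trajectory.times)
        assert np.all(np.diff(vq) <= 0)


class TestNormalisation:
    def test_same_basin_trajectories_share_final_level(self, bistable_surface,
                                                       bistable_portrait):
        # after normalisation every attractor sits at its basin offset,
        # so the surface value at both symmetric attractors must agree
        gx, gy, V = (bistable_surface.grid_x, bistable_surface.grid_y,
                     bistable_surface.V)
        vals = []
        for s in bistable_portrait.attractors:
            i = np.argmin(np.abs(gx - s.x))
            j = np.argmin(np.abs(gy - s.y))
            vals.append(V[i, j])
        assert vals[0] == pytest.approx(vals[1], abs=1e-6)

    def test_single_basin_offset_is_pure_shift(self, monostable_params,
                                               monostable_portrait):
        surf = build_surface(monostable_params, seed_grid_n=8, grid_out=40,
                             portrait=monostable_portrait)
        assert len(surf.basin_offsets) == 1


class TestSurface:
    def test_bistable_minima_coincide_with_attractors(self, bistable_surface,
                                                      bistable_portrait):
        mins = np.array(bistable_surface.local_minima())
        att = np.array([s.position for s in bistable_portrait.attractors])
        assert len(mins) == 2
        cell = np.hypot(*bistable_surface.grid_cell)
        for a in att:
            assert np.min(np.linalg.norm(mins - a[None, :], axis=1)) <= cell

    def test_monostable_surface_has_one_minimum(self, monostable_params,
                                                monostable_portrait):
        surf = build_surface(monostable_params, seed_grid_n=8, grid_out=40,
                             portrait=monostable_portrait)
        assert len(surf.local_minima()) == 1

    def test_tristable_surface_has_three_minima(self, tristable_params,
                                                tristable_portrait):
        surf = build_surface(tristable_params, seed_grid_n=10, grid_out=60,
                             portrait=tristable_portrait)
        mins = np.array(surf.local_minima())
        att = np.array([s.position for s in tristable_portrait.attractors])
        assert len(mins) == 3
        cell = np.hypot(*surf.grid_cell)
        for a in att:
            assert np.min(np.linalg.norm(mins - a[None, :], axis=1)) <= cell

    def test_saddle_sits_on_the_ridge(self, bistable_surface,
                                      bistable_portrait):
        gx, gy, V = (bistable_surface.grid_x, bistable_surface.grid_y,
                     bistable_surface.V)
        sad = bistable_portrait.saddles[0].position
        i = np.argmin(np.abs(gx - sad[0]))
        j = np.argmin(np.abs(gy - sad[1]))
        v_saddle = V[i, j]
        for s in bistable_portrait.attractors:
            ia = np.argmin(np.abs(gx - s.x))
            ja = np.argmin(np.abs(gy - s.y))
            assert v_saddle >= V[ia, ja]

    def test_symmetric_parameters_give_mirror_symmetric_surface(
            self, bistable_surface):
        V = bistable_surface.V
        m = np.isfinite(V) & np.isfinite(V.T)
        assert np.max(np.abs(V[m] - V.T[m])) < 1e-9

    def test_steepness_tracks_flow_magnitude(self, bistable_surface,
                                             bistable_params):
        gx, gy, V = (bistable_surface.grid_x, bistable_surface.grid_y,
                     bistable_surface.V)
        dVx, dVy = np.gradient(V, gx, gy, edge_order=1)
        steep = np.hypot(dVx, dVy)
        xx, yy = np.meshgrid(gx, gy, indexing="ij")
        speed = np.hypot(*vector_field(np.stack([xx, yy]), bistable_params))
        m = np.isfinite(steep)
        rho = spearmanr(steep[m], speed[m]).statistic
        assert rho > 0.5

    def test_refinement_stability(self, bistable_params, bistable_portrait):
        a = build_surface(bistable_params, seed_grid_n=8, grid_out=40,
                          portrait=bistable_portrait)
        b = build_surface(bistable_params, seed_grid_n=16, grid_out=40,
                          portrait=bistable_portrait)
        xx, yy = np.meshgrid(a.grid_x, a.grid_y, indexing="ij")
        # compare away from the separatrix (the diagonal), where the
        # interpolant is discontinuity-free
        mask = (np.abs(xx - yy) > 0.15) & np.isfinite(a.V) & np.isfinite(b.V)
        diff = np.abs(a.V - b.V)[mask]
        assert np.median(diff) < 0.02
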