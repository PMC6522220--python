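"""Unit and closed-form oracle tests of the agent dynamics."""
import numpy as np
import pytest

from wormswarm import ModelParams
from wormswarm.model import (
    SimulationState,
    advance_body,
    initialize_state,
    knn_density_periodic,
    reversal_probability,
    reversal_update,
    run_simulation,
    speed_state_update,
    switching_rates,
    taxis_drive,
    update_heading,
)
from conftest import chain_lengths


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

class TestInitializeState:
    def test_geometry(self):
        p = ModelParams(N=40, M=18, L=1.0)
        st = initialize_state(p)
        assert st.pos.shape == (40, 18, 2)
        seg = np.hypot(*np.moveaxis(np.diff(st.pos, axis=1), -1, 0))
        assert np.allclose(seg.sum(axis=1), 1.0, atol=1e-9)

    def test_seeded_determinism(self):
        p = ModelParams(seed=7)
        a, b = initialize_state(p), initialize_state(p)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.headings, b.headings)
        assert np.array_equal(a.fast, b.fast)

    def test_arena_too_small(self):
        with pytest.raises(ValueError):
            ModelParams(arena_side=0.9, L=1.0)


# ---------------------------------------------------------------------------
# taxis
# ---------------------------------------------------------------------------

class TestTaxisDrive:
    def test_hand_computed_two_neighbours(self):
        out = taxis_drive([0, 0], [[0.5, 0], [0, 0.25]], f_t=1.0, cutoff=1.0)
        assert np.allclose(out, [2.0, 4.0])

    def test_beyond_cutoff_no_contribution(self):
        out = taxis_drive([0, 0], [[1.5, 0]], f_t=1.0, cutoff=1.0)
        assert np.allclose(out, [0.0, 0.0])

    def test_zero_weight(self):
        out = taxis_drive([0, 0], [[0.3, 0.1], [0.2, 0.2]], f_t=0.0, cutoff=1.0)
        assert np.allclose(out, [0.0, 0.0])

    def test_periodic_minimum_image(self):
        # neighbour across the boundary is effectively 0.5 mm away
        out = taxis_drive([0.1, 0], [[7.6, 0]], f_t=1.0, cutoff=1.0, side=8.0)
        assert np.allclose(out, [-2.0, 0.0])

    def test_coincident_neighbour_skipped(self):
        with pytest.warns(UserWarning, match="coincident"):
            out = taxis_drive([0, 0], [[0, 0]], f_t=1.0, cutoff=1.0)
        assert np.allclose(out, [0.0, 0.0])


class TestUpdateHeading:
    def test_no_forces_no_change(self):
        p = ModelParams(D_theta=0.0)
        assert update_heading(0.7, np.zeros(2), p) == pytest.approx(0.7)

    def test_strong_taxis_aligns_in_one_step(self):
        p = ModelParams(D_theta=0.0)
        # drive far above 1/dt turns the heading fully within one step
        out = update_heading(0.0, np.array([0.0, 1e6]), p)
        assert out == pytest.approx(np.pi / 2, abs=1e-3)

    def test_rotational_diffusion_variance(self, rng):
        """Var of heading increments matches 2*D*dt (closed form, +-5%)."""
        p = ModelParams(D_theta=0.2, dt=0.05)
        n = 40_000
        th = np.zeros(n)
        new = update_heading(th, np.zeros((n, 2)), p, rng=rng)
        var = np.var(np.asarray(new) - th)
        assert var == pytest.approx(2 * p.D_theta * p.dt, rel=0.05)


# ---------------------------------------------------------------------------
# body mechanics
# ---------------------------------------------------------------------------

def straight_worm(p, heading=0.0):
    nodes = np.zeros((p.M, 2))
    nodes[:, 0] = -np.arange(p.M) * p.rest_spacing
    from wormswarm.model import WormState

    return WormState(nodes=nodes, heading=heading, motility_fast=True,
                     reversing=False, reversal_time_left=0.0)


class TestAdvanceBody:
    def test_zero_speed_unchanged(self, small_params):
        w = straight_worm(small_params)
        before = w.nodes.copy()
        advance_body(w, 0.0, small_params)
        assert np.allclose(w.nodes, before)

    def test_straight_advance_conserves_length(self, small_params):
        p = small_params
        w = straight_worm(p)
        head0 = w.nodes[0].copy()
        advance_body(w, 0.35, p)
        assert np.allclose(w.nodes[0], head0 + [0.35 * p.dt, 0.0])
        seg = np.hypot(*np.diff(w.nodes, axis=0).T)
        assert seg.sum() == pytest.approx(p.L, rel=0.05)

    def test_stretched_segment_relaxes(self, small_params):
        p = small_params
        w = straight_worm(p)
        w.nodes[1:, 0] -= p.rest_spacing  # first segment stretched to 2x rest
        advance_body(w, 0.0, p)
        seg = np.hypot(*np.diff(w.nodes, axis=0).T)
        assert abs(seg[0] - p.rest_spacing) < p.rest_spacing  # strictly closer


# ---------------------------------------------------------------------------
# stochastic behaviour: Monte-Carlo vs closed forms
# ---------------------------------------------------------------------------

def _many_worm_state(p, n, rng):
    pp = p.replace(N=n)
    return initialize_state(pp, rng=rng), pp


class TestReversals:
    def test_zero_slope_never_reverses(self, rng):
        p = ModelParams(N=200, M=6, r_prime=0.0, arena_side=12.0)
        st = initialize_state(p, rng=rng)
        contacts = np.zeros((200, 2), dtype=bool)
        contacts[:, 0] = True  # head contact everywhere
        reversal_update(st, rho=np.full(200, 5.0), params=p, contacts=contacts)
        assert not st.reversing.any()

    def test_both_end_contact_no_reversal(self, rng):
        p = ModelParams(N=200, M=6, r_prime=10.0, arena_side=12.0)
        st = initialize_state(p, rng=rng)
        contacts = np.ones((200, 2), dtype=bool)  # inside a cluster
        reversal_update(st, rho=np.full(200, 5.0), params=p, contacts=contacts)
        assert not st.reversing.any()

    def test_initiation_frequency_matches_poisson(self, rng):
        """Head-only contact at r'*rho*dt = 0.2 starts reversals at 1-e^-0.2."""
        n = 100_000
        p = ModelParams(N=n, M=3, r_prime=0.2, dt=1.0, arena_side=400.0, knn_k=6)
        st = initialize_state(p, rng=rng)
        contacts = np.zeros((n, 2), dtype=bool)
        contacts[:, 0] = True
        rho = np.ones(n)  # r' * rho * dt = 0.2
        reversal_update(st, rho=rho, params=p, contacts=contacts)
        freq = st.reversing.mean()
        assert freq == pytest.approx(-np.expm1(-0.2), abs=0.005)

    def test_reversal_probability_closed_form(self):
        assert reversal_probability(2.0, 0.5, 0.1) == pytest.approx(1 - np.exp(-0.1))
        assert reversal_probability(0.0, 0.5, 0.1) == 0.0


class TestSpeedSwitching:
    def test_zero_density_rates_exact(self):
        p = ModelParams(k_s_prime=0.3, k_f_prime=0.7)
        k_slow, k_fast = switching_rates(0.0, True, p)
        assert float(k_slow) == pytest.approx(p.k_s0)
        assert float(k_fast) == pytest.approx(p.k_f0)

    def test_exponential_decay_of_speeding_rate(self):
        p = ModelParams(k_f0=1.0, k_f_prime=np.log(2.0))
        _, k_fast = switching_rates(1.0, True, p)
        assert float(k_fast) == pytest.approx(0.5)

    def test_no_food_suppresses_slowing_only(self):
        p = ModelParams(k_s_prime=1.0, k_f_prime=0.5)
        k_slow, k_fast = switching_rates(3.0, False, p)
        assert float(k_slow) == 0.0
        assert float(k_fast) == pytest.approx(p.k_f0 * np.exp(-1.5))

    def test_switch_frequency_matches_poisson(self, rng):
        n = 100_000
        p = ModelParams(N=n, M=3, k_s0=0.2, k_s_prime=0.0, dt=1.0,
                        arena_side=400.0)
        st = initialize_state(p, rng=rng)
        st.fast[:] = True
        speed_state_update(st, rho=np.zeros(n), food_present=True, params=p)
        frac_switched = 1.0 - st.fast.mean()
        assert frac_switched == pytest.approx(-np.expm1(-0.2), abs=0.005)

    def test_two_state_occupancy_matches_markov_closed_form(self, rng):
        """Zero-interaction worms spend k_f0/(k_f0+k_s0) of time fast (+-3%)."""
        n_worms, n_steps = 2000, 1200  # 1.2e5 worm-seconds at dt = 0.05 * 1200
        p = ModelParams(N=n_worms, M=3, dt=0.1, arena_side=200.0,
                        k_s0=1 / 240, k_f0=1 / 60)
        st = initialize_state(p, rng=rng)
        rho = np.zeros(n_worms)
        frac = []
        for _ in range(n_steps):
            speed_state_update(st, rho=rho, food_present=True, params=p)
            frac.append(st.fast.mean())
        expected = p.k_f0 / (p.k_f0 + p.k_s0)
        assert np.mean(frac) == pytest.approx(expected, abs=0.03)


# ---------------------------------------------------------------------------
# density sensing
# ---------------------------------------------------------------------------

def test_knn_density_periodic_matches_construction():
    # 6 neighbours on a unit circle plus far-away points -> d_6 = 1
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    pts = np.vstack([[5.0, 5.0], np.column_stack([5 + np.cos(ang), 5 + np.sin(ang)]),
                     [[1.0, 1.0], [9.0, 9.0]]])
    rho = knn_density_periodic(pts, k=6, side=20.0)
    assert rho[0] == pytest.approx(6 / np.pi)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

class TestRunSimulation:
    def test_determinism_and_wrapping(self):
        p = ModelParams(N=10, M=6, seed=5, r_prime=0.1, f_t=0.05, k_s_prime=0.01)
        a = run_simulation(p, duration=60, record_every=10)
        b = run_simulation(p, duration=60, record_every=10)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.centroids.min() >= 0.0 and a.centroids.max() < p.arena_side
        assert a.n_worms == p.N

    def test_chain_length_conserved_in_long_run(self, npr1):
        ds = run_simulation(npr1.replace(N=12), duration=120, record_every=30,
                            record_skeletons=True, seed=4)
        lengths = chain_lengths(ds.skeletons, npr1.arena_side)
        assert np.all(lengths > 0.95) and np.all(lengths < 1.05)

    def test_worm_crosses_boundary_and_reappears(self):
        p = ModelParams(N=2, M=4, D_theta=0.0, v_slow=0.35, knn_k=1, seed=0)
        ds = run_simulation(p, duration=60, record_every=5)
        # deterministic straight crawl must stay wrapped at all times
        assert np.all(ds.centroids >= 0) and np.all(ds.centroids < p.arena_side)
        assert np.all(np.isfinite(ds.centroids))

    def test_invalid_recording(self):
        with pytest.raises(ValueError):
            run_simulation(ModelParams(), duration=1.0, record_every=10.0)
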