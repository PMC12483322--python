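"""Trafficking model: event mechanics, conservation ledgers, rate recovery."""

import numpy as np
import pandas as pd
import pytest

from septorg.sim import (
    NAIVE,
    PHOS,
    UBIQ,
    SimConfig,
    SimState,
    default_exo_profile,
    direction_weights,
    do_endocytosis,
    do_exocytosis,
    endo_event_histogram,
    init_state,
    make_exo_profile,
    normalize_to_max,
    run_condition_sweep,
    run_simulation,
    step_diffusion,
    step_modification,
)


def small_state(n_bins=10, bins=(), states=(), pits=(), ages=()):
    bins = np.array(bins, dtype=np.int64)
    return SimState(
        n_bins=n_bins,
        cargo_bin=bins,
        cargo_state=np.array(states, dtype=np.int8),
        cargo_trapped=np.zeros(bins.size, dtype=bool),
        pit_bins=np.array(pits, dtype=np.int64),
        pit_ages=np.array(ages, dtype=np.int64),
    )


class TestExoProfile:
    def test_uniform_inputs_give_uniform_profile(self):
        _, p = make_exo_profile(np.ones(10), np.ones(10))
        np.testing.assert_allclose(p, 0.1)

    def test_point_mass_bem1_gives_point_mass(self):
        bem1 = np.zeros(8)
        bem1[3] = 2.0
        _, p = make_exo_profile(bem1, np.ones(8))
        assert p[3] == 1.0 and p.sum() == 1.0

    def test_squared_weighting_arithmetic(self):
        _, p = make_exo_profile(np.array([1.0, 2.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(p, [1 / 5, 4 / 5])

    def test_all_zero_product_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            make_exo_profile(np.array([1.0, 0.0]), np.array([0.0, 1.0]))


class TestModification:
    def test_zero_phos_probability_freezes_states(self):
        cfg = SimConfig(p_phos=0.0, p_ubiq=0.0)
        st = small_state(bins=[1, 2, 3], states=[NAIVE, NAIVE, NAIVE])
        rng = np.random.default_rng(0)
        for _ in range(100):
            step_modification(st, cfg, rng)
        assert (st.cargo_state == NAIVE).all()

    def test_certain_ubiquitination_is_immediate(self):
        cfg = SimConfig(p_ubiq=1.0)
        st = small_state(bins=[0, 1], states=[PHOS, PHOS])
        step_modification(st, cfg, np.random.default_rng(0))
        assert (st.cargo_state == UBIQ).all()

    def test_transition_count_matches_binomial_expectation(self):
        """10,000 naive cargo, one step at 1x: ~Binomial(10000, 5e-5)."""
        cfg = SimConfig()
        counts = []
        rng = np.random.default_rng(1)
        for _ in range(200):
            st = small_state(bins=np.zeros(10_000), states=np.zeros(10_000))
            c = {"naive_exposure": 0, "phos_exposure": 0, "phos_events": 0, "ubiq_events": 0}
            step_modification(st, cfg, rng, c)
            counts.append(c["phos_events"])
        mean = np.mean(counts)
        se = np.sqrt(0.5 / 200)  # var of Binomial(1e4, 5e-5) ~= 0.5
        assert abs(mean - 0.5) < 4 * se

    def test_no_backward_transitions(self):
        cfg = SimConfig(p_phos=1.0, phos_multiplier=1.0, p_ubiq=1.0)
        st = small_state(bins=[0, 1, 2], states=[NAIVE, PHOS, UBIQ])
        rng = np.random.default_rng(2)
        prev = st.cargo_state.copy()
        for _ in range(10):
            step_modification(st, cfg, rng)
            assert (st.cargo_state >= prev).all()
            prev = st.cargo_state.copy()


class TestDiffusion:
    def test_zero_move_probability(self):
        cfg = SimConfig(p_move=0.0)
        st = small_state(bins=[5], states=[NAIVE])
        step_diffusion(st, cfg, np.random.default_rng(0))
        assert st.cargo_bin[0] == 5

    def test_direction_weight_formula(self):
        """Neighbor counts 0 vs 9 give P(left|move) = 10/11."""
        pl, pr = direction_weights(0, 9)
        assert pl == pytest.approx(10 / 11)
        assert pr == pytest.approx(1 / 11)

    def test_empirical_direction_bias_follows_occupancy(self):
        cfg = SimConfig(p_move=1.0)
        rng = np.random.default_rng(3)
        went_left = 0
        trials = 2000
        for _ in range(trials):
            # mover at bin 5; 9 parked cargo at bin 6, none at bin 4
            st = small_state(bins=[5] + [6] * 9, states=[NAIVE] * 10)
            st.cargo_trapped[1:] = True  # park the crowd
            step_diffusion(st, cfg, rng)
            went_left += st.cargo_bin[0] == 4
        frac = went_left / trials
        se = np.sqrt((10 / 11) * (1 / 11) / trials)
        assert abs(frac - 10 / 11) < 4 * se

    def test_end_bin_reflects_inward(self):
        cfg = SimConfig(p_move=1.0)
        st = small_state(bins=[0], states=[NAIVE])
        step_diffusion(st, cfg, np.random.default_rng(4))
        assert st.cargo_bin[0] == 1

    def test_ubiquitinated_cargo_trapped_in_pit_stops_moving(self):
        st = small_state(bins=[4], states=[UBIQ], pits=[4], ages=[0])
        step_diffusion(st, SimConfig(p_move=0.0), np.random.default_rng(6))
        assert st.cargo_trapped[0]
        for _ in range(20):
            step_diffusion(st, SimConfig(p_move=1.0), np.random.default_rng(7))
            assert st.cargo_bin[0] == 4

    def test_naive_cargo_in_pit_is_not_trapped(self):
        st = small_state(bins=[4], states=[NAIVE], pits=[4], ages=[0])
        step_diffusion(st, SimConfig(p_move=0.0), np.random.default_rng(6))
        assert not st.cargo_trapped[0]


class TestExocytosis:
    def test_two_bins_added_and_indices_shift(self):
        cfg = SimConfig(cargo_per_exo=4)
        st = small_state(n_bins=100, bins=[10, 50, 90], states=[0, 0, 0], pits=[20, 80], ages=[1, 2])
        grid = np.array([-0.05, 0.05])
        probs = np.array([0.0, 1.0])  # force insertion right of center
        events = []
        rng = np.random.default_rng(0)
        do_exocytosis(st, cfg, grid, probs, rng, step=7, events=events)
        assert st.n_bins == 102
        kind, step, dist = events[0]
        assert kind == "exo" and step == 7
        # cargo left of the insertion stays, cargo right shifts by 2
        assert st.cargo_bin[0] == 10 and st.cargo_bin[1] in (50, 52)
        assert st.cargo_bin[2] == 92
        assert st.pit_bins[0] == 20 and st.pit_bins[1] == 82
        # delivered naive cargo landed in the new bins
        assert st.n_cargo == 7
        assert (st.cargo_state[-4:] == NAIVE).all()

    def test_point_mass_center_profile_straddles_midpoint(self):
        cfg = SimConfig(cargo_per_exo=1)
        st = small_state(n_bins=100, bins=[], states=[], pits=[0, 99], ages=[0, 0])
        grid, probs = np.array([0.0]), np.array([1.0])
        events = []
        do_exocytosis(st, cfg, grid, probs, np.random.default_rng(1), 0, events)
        assert abs(events[0][2]) <= 0.1  # at the midpoint, within one bin


class TestEndocytosis:
    def test_one_bin_removed(self):
        st = small_state(n_bins=100, bins=[10], states=[NAIVE], pits=[30, 60], ages=[5, 9])
        events = []
        do_endocytosis(st, SimConfig(), np.random.default_rng(0), 3, events)
        assert st.n_bins == 99
        assert events[0][0] == "endo"

    def test_most_mature_pit_consumed(self):
        st = small_state(
            n_bins=100,
            bins=[30, 60],
            states=[UBIQ, UBIQ],
            pits=[30, 60],
            ages=[5, 9],
        )
        st.cargo_trapped[:] = True
        events = []
        do_endocytosis(st, SimConfig(), np.random.default_rng(0), 0, events)
        # pit at 60 (age 9) went; its cargo was internalized
        assert st.internalized == 1
        assert 30 in st.cargo_bin
        assert events[0][2] == pytest.approx((60 - 49.5) * 0.1)

    def test_new_pit_forms_at_highest_ubiquitinated_bin(self):
        st = small_state(
            n_bins=10,
            bins=[2, 4, 4, 4, 6],
            states=[UBIQ, UBIQ, UBIQ, UBIQ, NAIVE],
            pits=[0, 8],
            ages=[9, 1],
        )
        events = []
        do_endocytosis(st, SimConfig(), np.random.default_rng(0), 0, events)
        # pit 0 consumed (age 9); bins shift left of nothing (bin 0 removed ->
        # all cargo bins decrement); new pit at former bin 4 (now 3)
        assert st.n_bins == 9
        assert sorted(st.pit_bins.tolist()) == [3, 7]
        assert st.pit_ages[st.pit_bins.tolist().index(3)] == 0

    def test_minimum_length_skips_with_warning(self):
        st = small_state(n_bins=2, bins=[0], states=[NAIVE], pits=[0, 1], ages=[1, 2])
        events = []
        with pytest.warns(UserWarning, match="minimum length"):
            do_endocytosis(st, SimConfig(), np.random.default_rng(0), 0, events)
        assert st.n_bins == 2 and not events


class TestRunSimulation:
    def test_no_trafficking_means_constant_bin_count(self):
        cfg = SimConfig(exo_rate_per_min=0.0, n_steps=500, init_cargo_per_bin=2)
        res = run_simulation(cfg)
        assert res.final_state.n_bins == cfg.n_bins_init
        assert len(res.events) == 0

    def test_duration_is_2000_seconds(self):
        assert SimConfig().duration_s == pytest.approx(2000.0)
        assert SimConfig().duration_s / 60 >= 30

    def test_determinism_identical_event_logs(self):
        cfg = SimConfig(n_steps=3000, seed=77)
        r1, r2 = run_simulation(cfg), run_simulation(cfg)
        pd.testing.assert_frame_equal(r1.events, r2.events)
        np.testing.assert_array_equal(r1.kymo_total, r2.kymo_total)

    def test_conservation_ledgers_exact(self):
        """Bin count and cargo count follow the event ledgers exactly."""
        cfg = SimConfig(n_steps=20_000, seed=5)
        res = run_simulation(cfg)
        st = res.final_state
        assert st.n_bins == cfg.n_bins_init + 2 * res.n_exo - res.n_endo
        assert st.n_cargo == (
            cfg.n_bins_init * cfg.init_cargo_per_bin + st.delivered - st.internalized
        )
        assert st.delivered == cfg.cargo_per_exo * res.n_exo

    def test_pit_count_constant(self):
        cfg = SimConfig(n_steps=5000, seed=8)
        res = run_simulation(cfg)
        assert res.final_state.pit_bins.size == cfg.n_pits
        assert np.unique(res.final_state.pit_bins).size == cfg.n_pits

    def test_event_distances_within_membrane_half_length(self):
        cfg = SimConfig(n_steps=20_000, seed=9)
        res = run_simulation(cfg)
        # membrane never exceeded init + 2*total exo events bins
        max_half = (cfg.n_bins_init + 2 * res.n_exo) * cfg.bin_width_um / 2
        assert (res.events["distance_um"].abs() <= max_half).all()


class TestHistograms:
    def test_single_location_single_bin(self):
        cfg = SimConfig(n_steps=10)
        res = run_simulation(cfg, rng=np.random.default_rng(0))
        res.events = pd.DataFrame(
            {"kind": ["endo"] * 3, "step": [1, 2, 3], "distance_um": [1.0, 1.0, 1.0]}
        )
        centers, counts = endo_event_histogram(res, np.arange(-5, 5.5, 0.5))
        assert counts.sum() == 3
        assert (counts > 0).sum() == 1

    def test_normalize_to_max(self):
        out = normalize_to_max(np.array([1.0, 4.0, 2.0]))
        assert out.max() == 1.0
        np.testing.assert_allclose(out, [0.25, 1.0, 0.5])
        with pytest.raises(ValueError):
            normalize_to_max(np.zeros(3))

    def test_empty_event_set_warns_zero_histogram(self):
        cfg = SimConfig(exo_rate_per_min=0.0, n_steps=10)
        res = run_simulation(cfg)
        with pytest.warns(UserWarning, match="no endocytic events"):
            _, counts = endo_event_histogram(res, np.arange(-5, 5.5, 0.5))
        assert (counts == 0).all()


class TestSweep:
    def test_single_rep_sweep_matches_single_run(self):
        cfg = SimConfig(n_steps=2000)
        sweep = run_condition_sweep(cfg, multipliers=(1.0,), n_reps=1, seed=33)
        from dataclasses import replace

        single = run_simulation(replace(cfg, phos_multiplier=1.0, seed=33))
        pd.testing.assert_frame_equal(sweep[1.0]["results"][0].events, single.events)

    def test_event_counts_match_rate_expectation(self):
        """Pooled endo events ~= rate x duration x reps (Poisson-binomial)."""
        cfg = SimConfig(n_steps=30_000)
        n_reps = 3
        sweep = run_condition_sweep(cfg, multipliers=(1.0,), n_reps=n_reps, seed=2)
        expected = cfg.p_endo_per_step * cfg.n_steps * n_reps
        got = sweep[1.0]["n_events"]
        sd = np.sqrt(expected)
        assert abs(got - expected) < 4 * sd
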