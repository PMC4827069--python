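"""Exact SSA: rates, channels, event application, trajectories.

Monte-Carlo checks are seeded and compared against closed-form oracles
(multinomial channel proportions, the harmonic-sum extinction time of a pure
death process, the (d/b)^n0 extinction probability of a linear birth-death
process).
"""

import numpy as np
import pytest

from actsim import (PopulationState, build_channels, apply_event, draw_event,
                    effective_cancer_rates, simulate, switch_rate, total_rate)
from actsim.gillespie import EventChannel

from conftest import state_of


# ---------------------------------------------------------------------------
# per-individual rates
# ---------------------------------------------------------------------------


class TestEffectiveCancerRates:
    def test_birth_floor_inactive(self, full_params):
        # u has c_b(u,x) = 4; with 50 x-cells at K=200, S_b = 1 < b_u
        state = state_of(full_params, u=1, x=50)
        B, Dbrc, Dcomp, Dther = effective_cancer_rates(state, full_params, "u")
        assert B == pytest.approx(2.5 - 4.0 * 50 / 200)
        assert Dbrc == 0.0

    def test_birth_floor_active_excess_becomes_death(self, full_params):
        # 175 x-cells: S_b = 3.5 > b_u = 2.5, excess 1.0 acts as death
        state = state_of(full_params, u=1, x=175)
        B, Dbrc, _, _ = effective_cancer_rates(state, full_params, "u")
        assert B == 0.0
        assert Dbrc == pytest.approx(1.0)
        # the floor and the excess are mutually exclusive
        assert B * Dbrc == 0.0

    def test_lone_cell_has_no_interactions(self, full_params):
        state = state_of(full_params, x=1)
        B, Dbrc, Dcomp, Dther = effective_cancer_rates(state, full_params, "x")
        assert B == pytest.approx(3.0)   # self excluded from competition
        assert (Dbrc, Dcomp, Dther) == (0.0, 0.0, 0.0)

    def test_self_exclusion_convention(self, full_params):
        # two x-cells: the focal one sees only the other (1/K), not itself
        state = state_of(full_params, x=2)
        _, _, Dcomp, _ = effective_cancer_rates(state, full_params, "x")
        assert Dcomp == pytest.approx(1.0 * 1 / 200)


class TestSwitchRate:
    def test_natural_only_without_cytokines(self, full_params):
        state = state_of(full_params, x=1)
        assert switch_rate(state, full_params, "x", "y") == pytest.approx(0.1)

    def test_induced_term_scales_with_cytokine_density(self, full_params):
        state = state_of(full_params, x=1, w=200)  # nu(w) = 1
        assert switch_rate(state, full_params, "x", "y") == pytest.approx(0.1 + 2.0)

    def test_zero_switch_configuration_blocks_dedifferentiation(self, full_params):
        full_params.cancer.s_nat = {}
        full_params.cancer.s_cyt = {}
        state = state_of(full_params, x=5)
        assert switch_rate(state, full_params, "x", "y") == 0.0

    def test_cross_genotype_request_rejected(self, full_params):
        with pytest.raises(ValueError):
            switch_rate(state_of(full_params, x=1), full_params, "x", "u")


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------


class TestBuildChannels:
    def test_empty_population_is_absorbing(self, full_params):
        channels = build_channels(state_of(full_params), full_params)
        assert channels == [] and total_rate(channels) == 0.0

    def test_single_cell_two_channels(self, single_type):
        params = single_type(b=2.0, d=1.0)
        channels = build_channels(state_of(params, p=1), params)
        assert [(c.kind, c.rate) for c in channels] == [
            ("cancer_birth", 2.0), ("cancer_death_natural", 1.0)]

    def test_predator_grows_in_presence_of_prey(self, full_params):
        state = state_of(full_params, x=100, z=4)
        tbirth = [c for c in build_channels(state, full_params)
                  if c.kind == "tcell_birth"]
        # n_z * (b_T + t_prod * nu(x))
        assert tbirth[0].rate == pytest.approx(4 * (1.0 + 8.0 * 100 / 200))


class TestDrawEvent:
    def test_single_channel_mean_waiting_time(self, rng):
        ch = [EventChannel("cancer_birth", "p", 5.0)]
        draws = [draw_event(ch, rng) for _ in range(20000)]
        assert all(c is ch[0] for _, c in draws)
        assert np.mean([dt for dt, _ in draws]) == pytest.approx(0.2, rel=0.05)

    def test_channel_choice_proportional_to_rate(self, rng):
        chs = [EventChannel("cancer_birth", "a", 1.0),
               EventChannel("cancer_birth", "b", 3.0)]
        n = 100_000
        hits = sum(draw_event(chs, rng)[1].actor == "b" for _ in range(n))
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se

    def test_fixed_seed_reproduces_sequence(self):
        chs = [EventChannel("cancer_birth", "a", 1.0),
               EventChannel("cancer_death_natural", "a", 2.5)]
        seqs = []
        for _ in range(2):
            r = np.random.default_rng(7)
            seqs.append([draw_event(chs, r) for _ in range(50)])
        assert seqs[0] == seqs[1]

    def test_absorbing_state_raises(self, rng):
        with pytest.raises(ValueError):
            draw_event([], rng)


class TestApplyEvent:
    def test_therapy_kill_releases_cytokine_burst(self, full_params, rng):
        state = state_of(full_params, x=10, z=3)
        ch = EventChannel("cancer_death_therapy", "x", 1.0, target="z")
        new = apply_event(state, ch, full_params, rng)
        assert new.counts["x"] == 9
        assert new.counts["w"] == 2          # kill_burst(x, z, w) = 2
        assert new.counts["z"] == 3

    def test_clonal_birth_without_mutation(self, single_type, rng):
        params = single_type()
        new = apply_event(state_of(params, p=5),
                          EventChannel("cancer_birth", "p", 1.0), params, rng)
        assert new.counts["p"] == 6

    def test_switch_preserves_genotype_and_total(self, full_params, rng):
        state = state_of(full_params, x=4, y=1)
        new = apply_event(state, EventChannel("cancer_switch", "x", 1.0, target="y"),
                          full_params, rng)
        assert (new.counts["x"], new.counts["y"]) == (3, 2)
        assert sum(new.counts.values()) == sum(state.counts.values())

    def test_mutant_birth_lands_on_law_target(self, full_params):
        full_params.cancer.mu = {"g": 1.0}       # every birth mutates
        rng = np.random.default_rng(0)
        new = apply_event(state_of(full_params, x=5),
                          EventChannel("cancer_birth", "x", 1.0), full_params, rng)
        assert new.counts["x"] == 5
        assert new.counts.get("u", 0) == 1       # m_law sends g-births to (h, u)

    def test_zero_actor_count_rejected(self, full_params, rng):
        with pytest.raises(ValueError):
            apply_event(state_of(full_params, x=0),
                        EventChannel("cancer_death_natural", "x", 1.0),
                        full_params, rng)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


class TestSimulate:
    def test_empty_initial_state_stops_immediately(self, full_params):
        traj = simulate(state_of(full_params), full_params, t_max=10.0, seed=0)
        assert traj.stop_reason == "all_extinct"
        assert (traj.states == 0).all()

    def test_pure_death_extinction_time_oracle(self, single_type):
        # max of n0 unit exponentials: mean = H_100 = sum 1/i
        params = single_type(b=0.0, d=1.0)
        times = [simulate(state_of(params, p=100), params, t_max=100.0,
                          seed=s, record_times=[100.0]).t_end
                 for s in range(300)]
        h100 = sum(1.0 / i for i in range(1, 101))
        se = np.sqrt(np.pi ** 2 / 6 / 300)
        assert abs(np.mean(times) - h100) < 3 * se

    def test_engines_agree_in_distribution(self, single_type):
        # extinction probability (d/b)^3 = 1/8 for b=2, d=1, n0=3
        params = single_type(b=2.0, d=1.0)
        freqs = {}
        for engine, n in (("numba", 2000), ("reference", 300)):
            ext = sum(
                simulate(state_of(params, p=3), params, t_max=40.0, seed=s,
                         record_times=[40.0], max_events=1500,
                         engine=engine).states[-1, 0] == 0
                for s in range(n))
            freqs[engine] = ext / n
        for engine, n in (("numba", 2000), ("reference", 300)):
            se = np.sqrt(0.125 * 0.875 / n)
            assert abs(freqs[engine] - 0.125) < 3 * se

    def test_no_mutation_means_no_new_genotypes(self, full_params):
        full_params.cancer.mu = {}
        traj = simulate(state_of(full_params, x=50, y=10), full_params,
                        t_max=5.0, seed=3, record_dt=0.1)
        assert (traj.column("u") == 0).all()
        assert traj.cum_mutations[-1] == 0

    def test_extinction_is_absorbing(self, single_type):
        params = single_type(b=0.5, d=1.0)
        traj = simulate(state_of(params, p=5), params, t_max=500.0, seed=1,
                        record_dt=1.0)
        assert traj.stop_reason == "all_extinct"
        dead = np.flatnonzero(traj.states[:, 0] == 0)
        assert (traj.states[dead[0]:, 0] == 0).all()

    def test_determinism_per_engine(self, full_params):
        runs = [simulate(state_of(full_params, x=100, z=5), full_params,
                         t_max=3.0, seed=42, record_dt=0.1) for _ in range(2)]
        assert np.array_equal(runs[0].states, runs[1].states)
        assert runs[0].t_end == runs[1].t_end

    def test_injections_are_applied_at_schedule_times(self, full_params):
        traj = simulate(state_of(full_params, x=100), full_params, t_max=4.0,
                        seed=0, record_dt=0.5,
                        injections=[(2.0, "z", 50)])
        before = traj.states[traj.times < 2.0]
        z_col = traj.labels.index("z")
        assert (before[:, z_col] == 0).all()
        at_end = traj.states[traj.times >= 2.5]
        assert (at_end[:, z_col] > 0).any()

    def test_event_log_reference_engine(self, single_type):
        params = single_type(b=1.0, d=0.5)
        traj = simulate(state_of(params, p=3), params, t_max=2.0, seed=9,
                        engine="reference", log_events=True)
        assert traj.events is not None
        kinds = {k for _, k, _, _ in traj.events}
        assert kinds <= {"cancer_birth_clonal", "cancer_birth_mutant",
                         "cancer_death_natural"}
        # event count matches the state increments
        assert len(traj.events) > 0


def test_trajectory_tsv_round_trip(tmp_path, single_type):
    params = single_type()
    traj = simulate(PopulationState(0.0, {"p": 10}), params, t_max=1.0,
                    seed=5, record_dt=0.25)
    out = tmp_path / "traj.tsv"
    traj.write_tsv(out)
    lines = out.read_text().strip().split("\n")
    assert lines[0].split("\t") == ["time", "p", "cum_mutations"]
    assert len(lines) == len(traj.times) + 1
    assert (tmp_path / "traj.tsv.json").exists()
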