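"""Outcome classification, ensembles, diameter read-out, built-in fixtures."""

import numpy as np
import pytest

from actsim import (DiameterCalibration, Scenario, Thresholds, classify_outcome,
                    diameter_from_count, run_ensemble, validate_parameters)
from actsim.gillespie import Trajectory
from actsim.therapy import (OUTCOME_LABELS, builtin_scenarios,
                            one_tcell_qualitative)


def make_traj(times, cols, labels=("x", "y", "z_x", "w"), nc=2, nz=1, nw=1,
              K=100):
    states = np.column_stack([np.asarray(c, dtype=np.int64) for c in cols])
    return Trajectory(labels=list(labels), nc=nc, nz=nz, nw=nw, K=K,
                      times=np.asarray(times, dtype=float), states=states,
                      cum_mutations=np.zeros(len(times), dtype=np.int64),
                      stop_reason="t_max", t_end=float(times[-1]))


THR = Thresholds(relapse_frac=0.9, remission_frac=0.01, differentiated=("x",))


class TestClassifyOutcome:
    def test_cure_when_tumour_hits_zero(self):
        # tumour dies, then T-cells and cytokines decay to zero
        traj = make_traj(
            [0, 1, 2, 3, 4],
            [[1000, 200, 0, 0, 0], [0, 0, 0, 0, 0],
             [50, 60, 40, 10, 0], [500, 400, 100, 20, 0]])
        rec = classify_outcome(traj, THR, n_pre=1000)
        assert rec.label == "cure"

    def test_flat_zero_trajectory_is_degenerate_cure(self):
        traj = make_traj([0, 1], [[0, 0], [0, 0], [0, 0], [0, 0]])
        assert classify_outcome(traj, THR, n_pre=100).label == "cure"

    def test_differentiated_relapse_after_tcell_loss(self):
        # x crashes below 1%, z dies, x regrows past 90% with x >> y
        times = np.arange(8.0)
        x = [1000, 5, 3, 4, 100, 500, 950, 980]
        y = [0, 2, 3, 4, 5, 6, 8, 10]
        z = [80, 120, 0, 0, 0, 0, 0, 0]
        w = [0, 40, 5, 0, 0, 0, 0, 0]
        rec = classify_outcome(make_traj(times, [x, y, z, w]), THR, n_pre=1000,
                               scheduled_tcells=("z_x",))
        assert rec.label == "relapse_differentiated"
        assert rec.relapse_time == 6.0
        assert rec.tcell_extinction_times["z_x"] == 2.0
        assert rec.remission_start == 1.0

    def test_dedifferentiated_relapse_by_majority_phenotype(self):
        times = np.arange(6.0)
        x = [1000, 5, 2, 10, 30, 40]
        y = [0, 3, 20, 200, 700, 950]
        z = [50, 90, 70, 60, 50, 45]
        w = [0, 30, 10, 8, 6, 5]
        rec = classify_outcome(make_traj(times, [x, y, z, w]), THR, n_pre=1000,
                               scheduled_tcells=("z_x",))
        assert rec.label == "relapse_dedifferentiated"
        assert rec.composition_at_relapse["y"] > 0.5

    def test_coexistence_all_populations_alive_no_relapse(self):
        times = np.arange(5.0)
        cols = [[1000, 20, 25, 22, 24], [0, 30, 28, 35, 33],
                [50, 60, 55, 58, 60], [0, 10, 9, 11, 10]]
        rec = classify_outcome(make_traj(times, cols), THR, n_pre=1000,
                               scheduled_tcells=("z_x",))
        assert rec.label == "coexistence"

    def test_tcell_extinction_without_regrowth(self):
        times = np.arange(5.0)
        cols = [[1000, 5, 4, 6, 20], [0, 1, 2, 2, 3],
                [50, 60, 0, 0, 0], [0, 10, 1, 0, 0]]
        rec = classify_outcome(make_traj(times, cols), THR, n_pre=1000,
                               scheduled_tcells=("z_x",))
        assert rec.label == "tcell_x_extinct"

    def test_remission_duration_measured_between_crossings(self):
        times = np.arange(7.0)
        cols = [[1000, 5, 4, 6, 20, 400, 500], [0] * 7,
                [50, 60, 30, 20, 0, 0, 0], [0] * 7]
        rec = classify_outcome(make_traj(times, cols), THR, n_pre=1000)
        assert rec.remission_start == 1.0
        assert rec.remission_duration == pytest.approx(3.0)  # exits at t=4

    def test_invariant_under_time_thinning(self):
        times = np.arange(0.0, 40.0, 0.5)
        n = len(times)
        x = np.concatenate([[1000], np.full(20, 4),
                            np.geomspace(5, 1100, 24),
                            np.full(n - 45, 1100)])
        y = np.linspace(0, 10, n)
        z = np.concatenate([np.full(10, 50), np.zeros(n - 10)])
        w = np.zeros(n)
        full = make_traj(times, [x.astype(int), y.astype(int), z.astype(int), w])
        thin = make_traj(times[::4], [x.astype(int)[::4], y.astype(int)[::4],
                                      z.astype(int)[::4], w[::4]])
        a = classify_outcome(full, THR, n_pre=1000, scheduled_tcells=("z_x",))
        b = classify_outcome(thin, THR, n_pre=1000, scheduled_tcells=("z_x",))
        assert a.label == b.label
        assert abs(a.relapse_time - b.relapse_time) <= 2.0  # one coarse interval

    def test_no_tumour_traits_rejected(self):
        traj = Trajectory(labels=["z"], nc=0, nz=1, nw=0, K=10,
                          times=np.array([0.0]), states=np.array([[3]]),
                          cum_mutations=np.array([0]), stop_reason="t_max")
        with pytest.raises(ValueError):
            classify_outcome(traj, THR, n_pre=10)


class TestRunEnsemble:
    def test_zero_replicates_empty_table(self):
        table = run_ensemble(one_tcell_qualitative(), replicates=0)
        assert len(table.per_replicate) == 0
        assert table.aggregate == {}

    def test_deterministic_given_base_seed(self):
        sc = one_tcell_qualitative()
        sc.t_max = 5.0
        t1 = run_ensemble(sc, replicates=5)
        t2 = run_ensemble(sc, replicates=5)
        assert t1.per_replicate["label"].tolist() == t2.per_replicate["label"].tolist()

    def test_frequencies_sum_to_one_with_wilson_intervals(self):
        sc = one_tcell_qualitative()
        sc.t_max = 10.0
        table = run_ensemble(sc, replicates=20)
        total = sum(f for f, _ in table.aggregate.values())
        assert total == pytest.approx(1.0)
        for f, (lo, hi) in table.aggregate.values():
            assert 0.0 <= lo <= f <= hi <= 1.0

    def test_higher_dose_increases_tcell_extinction(self):
        """Raising the initial T-cell dose deepens the tumour crash and the
        subsequent T-cell famine, making T-cell extinction more likely."""
        freqs = {}
        for factor in (1, 10):
            sc = one_tcell_qualitative()
            t, lab, n = sc.therapy_schedule[0]
            sc.therapy_schedule = [(t, lab, n * factor)]
            sc.t_max = 25.0
            table = run_ensemble(sc, replicates=60)
            df = table.per_replicate
            freqs[factor] = np.mean([
                ext["z_x"] is not None for ext in df["tcell_extinctions"]])
        assert freqs[10] > freqs[1]


class TestDiameter:
    def test_zero_cells_zero_diameter(self):
        assert diameter_from_count(0) == 0.0

    def test_cube_root_scaling(self):
        d1 = diameter_from_count(1000)
        d8 = diameter_from_count(8000)
        assert d8 == pytest.approx(2 * d1)

    def test_calibration_round_trip(self):
        calib = DiameterCalibration.from_reference(count=15000, diameter_mm=4.0)
        assert diameter_from_count(15000, calib) == pytest.approx(4.0)
        # regrowth to the original count maps back to the original diameter
        assert diameter_from_count(2 * 15000, calib) == pytest.approx(
            4.0 * 2 ** (1 / 3))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            diameter_from_count(-1)


class TestBuiltinScenarios:
    def test_all_fixtures_validate(self):
        scens = builtin_scenarios()
        assert {"one_tcell_qualitative", "two_tcell_qualitative",
                "fig4_calibrated", "mutant_invasion_fig6",
                "brc_mutation_fig7"} <= set(scens)
        for sc in scens.values():
            assert validate_parameters(sc.params) == []

    def test_fig4_carrying_capacity(self):
        assert builtin_scenarios()["fig4_calibrated"].params.K == 100000

    def test_brc_fixture_is_pure_birth_reducing(self):
        from actsim import brc_mutation_curve
        sc = builtin_scenarios()["brc_mutation_fig7"]
        arrays = sc.params.compile()
        assert np.all(arrays.c == 0)
        curve = brc_mutation_curve(b=arrays.b[0], d=arrays.d[0],
                                   c=0.0, c_b=arrays.cb[0, 0],
                                   mu=sc.params.effective_mu("g"), K=arrays.K)
        assert curve.submaximal_at_equilibrium

    def test_rescaling_preserves_densities(self):
        sc = one_tcell_qualitative()
        sc2 = sc.rescaled(1000)
        assert sc2.params.K == 1000
        for lab, n in sc.initial_counts.items():
            assert sc2.initial_counts[lab] == pytest.approx(
                n * 1000 / sc.params.K)

    def test_injection_schedule_validation(self):
        sc = one_tcell_qualitative()
        with pytest.raises(ValueError):
            Scenario(name="bad", params=sc.params, initial_counts={},
                     therapy_schedule=[(1.0, "x", 5)], t_max=1.0)

    def test_dose_response_deterministic(self):
        """Larger initial T-cell dose: the differentiated tumour reaches a
        lower minimum and the T-cells pass through a lower, broader minimum."""
        from actsim import integrate
        sc = one_tcell_qualitative()
        arrays = sc.params.compile()
        grid = np.linspace(0, 30, 601)
        mins = {}
        for factor in (1, 10):
            x0 = np.array([sc.initial_counts.get(lab, 0) / arrays.K
                           for lab in arrays.labels])
            x0[arrays.labels.index("z_x")] = 0.05 * factor
            traj, _ = integrate(x0, sc.params, grid)
            mins[factor] = (traj[:, 0].min(), traj[:, 2].min(), traj[:, 2])
        assert mins[10][0] < mins[1][0]       # lower differentiated minimum
        assert mins[10][1] < mins[1][1]       # lower T-cell minimum
        level = 2.0 * mins[1][1]
        breadth = {f: np.sum(mins[f][2] < level) for f in (1, 10)}
        assert breadth[10] > breadth[1]       # broader T-cell minimum
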