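"""Therapy scenarios: ACT with one or two T-cell specificities.

A Scenario bundles a parameter set, a tumour-initiation state, a T-cell
injection schedule and ensemble settings.  Stochastic outcomes are classified
into a closed label set: cure, differentiated or dedifferentiated relapse,
coexistence, and T-cell-extinction labels; an ensemble aggregates label
frequencies with Wilson confidence intervals.

Tumour size is read out as the diameter of a sphere at a fixed cell density,
matching how tumour burden is measured in the motivating mouse experiments
(millimetres versus days).

All built-in fixture parameter sets are synthetic: they are designed from the
qualitative structure of the modelled system (fixed-point inventory, low
T-cell minima during remission, 90/190-day relapse timings, 50-60 day
remission at carrying capacity 10^5) rather than measured rates, and should
be treated as illustrative regimes, not biological estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .gillespie import Trajectory, simulate
from .traits import (CancerParams, CytokineParams, ModelParams, PopulationState,
                     TCellParams, TraitSpace)

__all__ = [
    "Scenario",
    "Thresholds",
    "OutcomeRecord",
    "OutcomeTable",
    "DiameterCalibration",
    "classify_outcome",
    "run_ensemble",
    "diameter_from_count",
    "builtin_scenarios",
    "OUTCOME_LABELS",
]

OUTCOME_LABELS = (
    "cure",
    "relapse_differentiated",
    "relapse_dedifferentiated",
    "coexistence",
    "tcell_x_extinct",
    "tcell_y_extinct",
    "both_tcells_extinct",
)


@dataclass
class Thresholds:
    """State-based outcome thresholds, as fractions of the pre-treatment count.

    A tumour is microscopic (in remission) below ``remission_frac`` of its
    pre-treatment total; a relapse is called when it regains at least
    ``relapse_frac`` of that count after having been microscopic.  The relapse
    subtype is the majority phenotype (> 50%) at the crossing time, with the
    phenotypes in ``differentiated`` counted as the differentiated class.
    """

    relapse_frac: float = 0.9
    remission_frac: float = 0.01
    differentiated: tuple = ("x",)


@dataclass
class Scenario:
    """One therapy experiment: parameters, initiation state, injection schedule."""

    name: str
    params: ModelParams
    initial_counts: dict
    therapy_schedule: list          # (time_days, tcell_label, added_count)
    t_max: float
    replicates: int = 50
    base_seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    record_dt: float = 0.25
    t_start: float = 0.0

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.therapy_schedule]
        if any(t < 0 for t in times) or times != sorted(times):
            raise ValueError("injection times must be >= 0 and sorted")
        z_types = set(self.params.space.tcell_types)
        for _, lab, _ in self.therapy_schedule:
            if lab not in z_types:
                raise ValueError(f"injected trait {lab!r} is not a T-cell type")

    @property
    def therapy_time(self) -> float:
        return self.therapy_schedule[0][0] if self.therapy_schedule else self.t_start

    def rescaled(self, K: int) -> "Scenario":
        """Same scenario at a different carrying capacity: initial counts and
        doses scale proportionally (densities are preserved)."""
        ratio = K / self.params.K
        params = replace(self.params, K=int(K))
        return replace(
            self,
            params=params,
            initial_counts={lab: int(round(n * ratio))
                            for lab, n in self.initial_counts.items()},
            therapy_schedule=[(t, lab, int(round(n * ratio)))
                              for t, lab, n in self.therapy_schedule],
        )

    def initial_state(self) -> PopulationState:
        return PopulationState(time=self.t_start, counts=dict(self.initial_counts))

    def run(self, seed: int, **kwargs) -> Trajectory:
        defaults = dict(t_max=self.t_max, record_dt=self.record_dt,
                        injections=self.therapy_schedule)
        defaults.update(kwargs)
        return simulate(self.initial_state(), self.params, seed=seed, **defaults)


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------


@dataclass
class OutcomeRecord:
    label: str
    relapse_time: float | None = None
    remission_start: float | None = None
    remission_duration: float | None = None
    composition_at_relapse: dict | None = None
    tcell_extinction_times: dict = field(default_factory=dict)
    seed: int | None = None


def _extinction_time(times: np.ndarray, col: np.ndarray, after: float):
    """First record time (>= after) from which the count is zero to the end."""
    if col[-1] != 0:
        return None
    positive = np.flatnonzero(col > 0)
    idx = 0 if positive.size == 0 else positive[-1] + 1
    t = float(times[min(idx, len(times) - 1)])
    return max(t, after)


def classify_outcome(traj: Trajectory, thresholds: Thresholds, *,
                     n_pre: int, therapy_time: float = 0.0,
                     scheduled_tcells: tuple = ()) -> OutcomeRecord:
    """Classify one therapy trajectory into the closed outcome-label set.

    ``n_pre`` is the pre-treatment total tumour count defining the microscopic
    (remission) and relapse thresholds.  Cure means the tumour hit zero.
    Relapses are tumour regrowth past the relapse threshold after a period
    below the microscopic threshold, subtyped by the majority phenotype at the
    crossing time.  T-cell extinction times are recorded regardless of the
    final label, since trajectories may pass between scenarios.
    """
    if traj.nc == 0:
        raise ValueError("trajectory has no tumour traits")
    times = traj.times
    tumour = traj.cancer_total()
    micro = thresholds.remission_frac * n_pre
    relapse_level = thresholds.relapse_frac * n_pre

    after = times >= therapy_time
    rec = OutcomeRecord(label="coexistence")

    # remission entry/exit
    below = np.flatnonzero(after & (tumour < micro))
    if below.size:
        i0 = below[0]
        rec.remission_start = float(times[i0])
        above_again = np.flatnonzero((times > times[i0]) & (tumour >= micro))
        exit_t = float(times[above_again[0]]) if above_again.size else float(times[-1])
        rec.remission_duration = exit_t - rec.remission_start
        # relapse crossing
        cross = np.flatnonzero((times > times[i0]) & (tumour >= relapse_level))
        if cross.size:
            j = cross[0]
            rec.relapse_time = float(times[j])
            comp = traj.states[j, : traj.nc].astype(float)
            total = comp.sum()
            labels_c = traj.labels[: traj.nc]
            rec.composition_at_relapse = {
                lab: float(v / total) for lab, v in zip(labels_c, comp)}

    # T-cell extinction events
    for lab in scheduled_tcells or traj.labels[traj.nc: traj.nc + traj.nz]:
        col = traj.column(lab)
        rec.tcell_extinction_times[lab] = _extinction_time(times, col, therapy_time)

    # final label, in precedence order
    scheduled = list(scheduled_tcells or traj.labels[traj.nc: traj.nc + traj.nz])
    if tumour[-1] == 0:
        rec.label = "cure"
    elif rec.relapse_time is not None:
        diff_frac = sum(v for lab, v in rec.composition_at_relapse.items()
                        if lab in thresholds.differentiated)
        rec.label = ("relapse_differentiated" if diff_frac > 0.5
                     else "relapse_dedifferentiated")
    else:
        extinct = [lab for lab in scheduled
                   if rec.tcell_extinction_times.get(lab) is not None]
        if scheduled and len(extinct) == len(scheduled) and len(scheduled) > 1:
            rec.label = "both_tcells_extinct"
        elif extinct:
            rec.label = ("tcell_x_extinct" if extinct[0] == scheduled[0]
                         else "tcell_y_extinct")
        else:
            rec.label = "coexistence"
    return rec


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


@dataclass
class OutcomeTable:
    """Per-replicate outcome records plus aggregate label frequencies."""

    per_replicate: pd.DataFrame
    aggregate: dict                # label -> (frequency, (ci_low, ci_high))
    scenario_name: str = ""

    def frequency(self, label: str) -> float:
        return self.aggregate.get(label, (0.0, (0.0, 0.0)))[0]

    def write(self, tsv_path, json_path=None) -> None:
        self.per_replicate.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            import json as _json
            payload = {lab: {"frequency": f, "ci95": list(ci)}
                       for lab, (f, ci) in self.aggregate.items()}
            with open(json_path, "w") as fh:
                _json.dump({"scenario": self.scenario_name, "labels": payload},
                           fh, indent=1, sort_keys=True)


def run_ensemble(scenario: Scenario, *, replicates: int | None = None,
                 engine: str = "numba") -> OutcomeTable:
    """Run replicated SSA therapy experiments and classify each outcome.

    Replicate i uses seed ``base_seed + i``; results are deterministic given
    the base seed.  Aggregate frequencies carry 95% Wilson intervals.
    """
    reps = scenario.replicates if replicates is None else replicates
    n_pre = _pretreatment_count(scenario)
    scheduled = tuple(dict.fromkeys(lab for _, lab, _ in scenario.therapy_schedule))
    rows = []
    for i in range(reps):
        seed = (scenario.base_seed + i) % (2 ** 31 - 1)
        traj = scenario.run(seed=seed, engine=engine)
        rec = classify_outcome(traj, scenario.thresholds, n_pre=n_pre,
                               therapy_time=scenario.therapy_time,
                               scheduled_tcells=scheduled)
        rec.seed = seed
        rows.append({
            "seed": seed,
            "label": rec.label,
            "relapse_time": rec.relapse_time,
            "remission_start": rec.remission_start,
            "remission_duration": rec.remission_duration,
            "composition_at_relapse": rec.composition_at_relapse,
            "tcell_extinctions": rec.tcell_extinction_times,
        })
    df = pd.DataFrame(rows, columns=["seed", "label", "relapse_time",
                                     "remission_start", "remission_duration",
                                     "composition_at_relapse", "tcell_extinctions"])
    aggregate = {}
    if reps:
        for label, count in df["label"].value_counts().items():
            ci = proportion_confint(count, reps, alpha=0.05, method="wilson")
            aggregate[label] = (count / reps, (float(ci[0]), float(ci[1])))
    return OutcomeTable(per_replicate=df, aggregate=aggregate,
                        scenario_name=scenario.name)


def _pretreatment_count(scenario: Scenario) -> int:
    """Total tumour count at therapy start (deterministic reference).

    Uses the mean-field flow from the initiation state up to the first
    injection; if therapy starts immediately, it is the initial tumour count.
    """
    init_tumour = sum(
        n for lab, n in scenario.initial_counts.items()
        if lab in {p for _, p in scenario.params.space.cancer_pairs})
    t_inj = scenario.therapy_time
    if t_inj <= scenario.t_start:
        return int(init_tumour)
    from .meanfield import integrate  # local import to avoid cycle
    arrays = scenario.params.compile()
    x0 = np.array([scenario.initial_counts.get(lab, 0) / arrays.K
                   for lab in arrays.labels])
    traj, _ = integrate(x0, scenario.params, [scenario.t_start, t_inj])
    return int(round(traj[-1][: arrays.nc].sum() * arrays.K))


# ---------------------------------------------------------------------------
# diameter read-out
# ---------------------------------------------------------------------------


@dataclass
class DiameterCalibration:
    """Sphere-at-fixed-cell-density mapping from cell count to diameter (mm)."""

    cells_per_mm3: float = 1.0e6

    @classmethod
    def from_reference(cls, count: float, diameter_mm: float) -> "DiameterCalibration":
        """Calibrate the density so that ``count`` cells map to ``diameter_mm``."""
        if count <= 0 or diameter_mm <= 0:
            raise ValueError("reference count and diameter must be positive")
        volume = 4.0 / 3.0 * math.pi * (diameter_mm / 2.0) ** 3
        return cls(cells_per_mm3=count / volume)


def diameter_from_count(n_cells, calib: DiameterCalibration | None = None):
    """Diameter (mm) of a sphere of ``n_cells`` at the calibration density."""
    calib = calib or DiameterCalibration()
    n = np.asarray(n_cells, dtype=float)
    if np.any(n < 0):
        raise ValueError("cell count must be non-negative")
    return 2.0 * np.cbrt(3.0 * n / (4.0 * math.pi * calib.cells_per_mm3))


# ---------------------------------------------------------------------------
# built-in fixtures (synthetic parameter sets)
# ---------------------------------------------------------------------------


def _one_tcell_space() -> TraitSpace:
    return TraitSpace(genotypes=("g",), phenotypes_of={"g": ("x", "y")},
                      tcell_types=("z_x",), cytokine_types=("w",))


def _two_tcell_space() -> TraitSpace:
    return TraitSpace(genotypes=("g",), phenotypes_of={"g": ("x", "y")},
                      tcell_types=("z_x", "z_y"), cytokine_types=("w",))


def one_tcell_qualitative(K: int = 200) -> Scenario:
    """Qualitative one-specificity regime (synthetic parameters).

    Designed so the deterministic system has three fixed points — the origin,
    a tumour-only point with both melanoma phenotypes high, and an interior
    point (the only fully stable one) with a low differentiated-tumour level —
    and so the stochastic T-cell population passes through a low minimum
    during remission, making both T-cell survival and extinction-then-relapse
    reachable across seeds.
    """
    space = _one_tcell_space()
    cancer = CancerParams(
        b={"x": 3.0, "y": 3.0},
        d={"x": 1.0, "y": 1.0},
        c={("x", "x"): 1.0, ("x", "y"): 0.5, ("y", "x"): 0.5, ("y", "y"): 1.0},
        t_kill={("x", "z_x"): 4.0},
        kill_burst={("x", "z_x", "w"): 2},
        s_nat={("x", "y"): 0.01, ("y", "x"): 0.01},
        s_cyt={("w", "x", "y"): 2.0},
    )
    tcells = TCellParams(
        b_T={"z_x": 1.0},
        d_T={"z_x": 3.0},
        t_prod={("z_x", "x"): 8.0},
        rep_burst={("z_x", "w"): 1},
    )
    cyt = CytokineParams(d_W={"w": 10.0})
    params = ModelParams(space=space, cancer=cancer, tcells=tcells,
                         cytokines=cyt, K=int(K))
    return Scenario(
        name="one_tcell_qualitative",
        params=params,
        initial_counts={"x": int(round(1.0 * K)), "y": int(round(0.05 * K))},
        therapy_schedule=[(0.0, "z_x", max(1, int(round(0.05 * K))))],
        t_max=50.0,
        replicates=200,
        base_seed=1000,
        record_dt=0.1,
    )


def two_tcell_qualitative(K: int = 200) -> Scenario:
    """Qualitative two-specificity regime: adds T-cells attacking the
    dedifferentiated phenotype (same rates as the first type, other target),
    which opens the cure scenario and the additional fixed points."""
    base = one_tcell_qualitative(K)
    space = _two_tcell_space()
    cancer = base.params.cancer  # fresh object owned by this call
    cancer.t_kill = dict(cancer.t_kill)
    cancer.t_kill[("y", "z_y")] = 4.0
    cancer.kill_burst = dict(cancer.kill_burst)
    cancer.kill_burst[("y", "z_y", "w")] = 2
    tcells = TCellParams(
        b_T={"z_x": 1.0, "z_y": 1.0},
        d_T={"z_x": 3.0, "z_y": 3.0},
        t_prod={("z_x", "x"): 8.0, ("z_y", "y"): 8.0},
        rep_burst={("z_x", "w"): 1, ("z_y", "w"): 1},
    )
    params = ModelParams(space=space, cancer=cancer, tcells=tcells,
                         cytokines=base.params.cytokines, K=int(K))
    return Scenario(
        name="two_tcell_qualitative",
        params=params,
        initial_counts=dict(base.initial_counts),
        therapy_schedule=[(0.0, "z_x", max(1, int(round(0.05 * K)))),
                          (0.0, "z_y", max(1, int(round(0.10 * K))))],
        t_max=50.0,
        replicates=200,
        base_seed=2000,
        record_dt=0.1,
    )


def fig4_calibrated(K: int = 100000) -> Scenario:
    """Quantitative one-specificity regime (synthetic calibration).

    Calibrated so that tumour initiation at day 0 grows to treatment size by
    day ~30, therapy pushes the tumour to a microscopic level for roughly 50
    days, runs in which the T-cells die out early relapse with differentiated
    cells at ~90 days, and runs in which they persist relapse with
    dedifferentiated cells at ~190 days.

    The injected T-cells are modelled as a fixed-size bolus of effector cells
    with balanced division and (exhaustion-dominated) death, so the bolus
    size is an absolute cell count and its stochastic extinction time — the
    clock separating the two relapse types — does not scale with K.  The
    kill and cytokine-induced-switch kernels carry the matching 1/K pair-rate
    normalization, which keeps the metastable timing structure invariant
    under changes of carrying capacity.  The differentiated clone is
    re-founded from the dedifferentiated reservoir through the natural
    (reversible) switch once the T-cells are gone.
    """
    space = _one_tcell_space()
    K = int(K)
    cancer = CancerParams(
        b={"x": 0.75, "y": 0.08},
        d={"x": 0.20, "y": 0.004},
        c={("x", "x"): 0.0407, ("x", "y"): 0.010,
           ("y", "x"): 0.0013, ("y", "y"): 0.00483},
        # fixed per-cell-pair kill rate 1.42e-2 / day
        t_kill={("x", "z_x"): 14.2e-3 * K},
        kill_burst={("x", "z_x", "w"): 1},
        s_nat={("y", "x"): 0.01},
        # fixed per-molecule induced-switch rate 7.3e-5 / day at the
        # calibration scale K = 10^3
        s_cyt={("w", "x", "y"): 0.073 / K},
    )
    tcells = TCellParams(
        b_T={"z_x": 2.65},
        d_T={"z_x": 2.65},
        t_prod={},
        rep_burst={},
    )
    cyt = CytokineParams(d_W={"w": 2.0})
    params = ModelParams(space=space, cancer=cancer, tcells=tcells,
                         cytokines=cyt, K=K)
    return Scenario(
        name="fig4_calibrated",
        params=params,
        initial_counts={"x": max(1, int(round(0.15 * K)))},
        therapy_schedule=[(30.0, "z_x", 95)],   # absolute bolus, 95 cells
        t_max=260.0,
        replicates=50,
        base_seed=4000,
        record_dt=0.5,
    )


def fig4_two_tcell(K: int = 100000) -> Scenario:
    """Two-specificity prediction on the quantitative calibration: a second
    effector bolus carrying the same rates with the dedifferentiated target,
    so the switch-seeded reservoir is attacked as soon as it appears."""
    base = fig4_calibrated(K)
    space = _two_tcell_space()
    cancer = base.params.cancer  # fresh object owned by this call
    cancer.t_kill = dict(cancer.t_kill)
    cancer.t_kill[("y", "z_y")] = 14.2e-3 * int(K)
    cancer.kill_burst = dict(cancer.kill_burst)
    cancer.kill_burst[("y", "z_y", "w")] = 1
    tcells = TCellParams(
        b_T={"z_x": 2.65, "z_y": 2.65},
        d_T={"z_x": 2.65, "z_y": 2.65},
        t_prod={},
        rep_burst={},
    )
    params = ModelParams(space=space, cancer=cancer, tcells=tcells,
                         cytokines=base.params.cytokines, K=int(K))
    return Scenario(
        name="fig4_two_tcell",
        params=params,
        initial_counts=dict(base.initial_counts),
        therapy_schedule=[(30.0, "z_x", 95), (30.0, "z_y", 95)],
        t_max=260.0,
        replicates=50,
        base_seed=4500,
        record_dt=0.5,
    )


def mutant_invasion_fig6(K: int = 10000) -> Scenario:
    """Mutant-invasion regime: a single-phenotype resident at equilibrium and
    a two-phenotype mutant genotype whose phenotypes each have a negative net
    growth rate (diagonal of the mean matrix) while the genotype's invasion
    fitness λ₁ is positive — an outgoing switch loses a particle for the
    phenotype, not for the genotype."""
    space = TraitSpace(genotypes=("g", "g2"),
                       phenotypes_of={"g": ("p",), "g2": ("p1", "p2")})
    cancer = CancerParams(
        b={"p": 3.0, "p1": 3.0, "p2": 3.0},
        d={"p": 1.0, "p1": 0.9, "p2": 0.7},
        c={(a, bb): 1.0 for a in ("p", "p1", "p2") for bb in ("p", "p1", "p2")},
        s_nat={("p1", "p2"): 0.3, ("p2", "p1"): 0.7},
        mu={"g": 1e-4},
        m_law={("g", "p"): {("g2", "p1"): 0.5, ("g2", "p2"): 0.5}},
    )
    params = ModelParams(space=space, cancer=cancer, K=int(K))
    return Scenario(
        name="mutant_invasion_fig6",
        params=params,
        initial_counts={"p": 2 * int(K)},
        therapy_schedule=[],
        t_max=100.0,
        replicates=20,
        base_seed=6000,
        record_dt=0.5,
    )


def brc_mutation_fig7(K: int = 1000) -> Scenario:
    """Pure birth-reducing competition with a rare mutation to a fitter
    genotype.  With d < b/2 the equilibrium population sits past the peak of
    the quadratic total-mutation-rate curve, so a population regrowing after
    therapy mutates faster than one resting at equilibrium."""
    space = TraitSpace(genotypes=("g", "g2"),
                       phenotypes_of={"g": ("p",), "g2": ("q",)})
    cancer = CancerParams(
        b={"p": 2.0, "q": 2.0},
        d={"p": 0.5, "q": 0.25},
        c_b={("p", "p"): 1.0, ("p", "q"): 1.0, ("q", "p"): 1.0, ("q", "q"): 1.0},
        mu={"g": 0.005},
        m_law={("g", "p"): {("g2", "q"): 1.0}},
    )
    params = ModelParams(space=space, cancer=cancer, K=int(K))
    return Scenario(
        name="brc_mutation_fig7",
        params=params,
        initial_counts={"p": int(0.3 * K)},
        therapy_schedule=[],
        t_max=10.0,
        replicates=200,
        base_seed=7000,
        record_dt=0.1,
    )


def builtin_scenarios() -> dict:
    """Named fixture scenarios for the regimes studied in the motivating work."""
    return {
        "one_tcell_qualitative": one_tcell_qualitative(),
        "two_tcell_qualitative": two_tcell_qualitative(),
        "fig4_calibrated": fig4_calibrated(),
        "fig4_two_tcell": fig4_two_tcell(),
        "mutant_invasion_fig6": mutant_invasion_fig6(),
        "brc_mutation_fig7": brc_mutation_fig7(),
    }
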