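"""Exact stochastic simulation (Gillespie / SSA) of the tumour–immune process.

The population is a continuous-time Markov jump process on integer counts per
trait.  Event channels are rebuilt after every event; waiting times are
exponential in the total rate and the channel is drawn proportionally to its
rate, scanning in canonical trait order (a fixed tie-break).

Two engines implement the same law:

* ``engine="reference"`` — a pure-Python loop built from the public
  operations :func:`build_channels`, :func:`draw_event`, :func:`apply_event`;
  slow, but transparent and able to log every event.
* ``engine="numba"`` (default) — a jitted kernel for ensemble-scale work.

The engines consume independent RNG streams, so they agree in distribution,
not sample-by-sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _kernel
from ._kernel import STOP_REASONS
from .traits import ModelParams, ParamArrays, PopulationState

__all__ = [
    "EventChannel",
    "Trajectory",
    "effective_cancer_rates",
    "switch_rate",
    "build_channels",
    "total_rate",
    "draw_event",
    "apply_event",
    "simulate",
]


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventChannel:
    """One aggregated event channel.

    ``kind`` is one of: cancer_birth (clonal vs mutant resolved at application
    time), cancer_death_natural, cancer_death_competition,
    cancer_death_excess_brc, cancer_death_therapy (target = killing T-cell
    type), cancer_switch (target = destination phenotype), tcell_birth,
    tcell_death, cytokine_decay.  ``rate`` is the total per-population rate
    (per day) of the channel.
    """

    kind: str
    actor: str
    rate: float
    target: str | None = None


def _state_vector(state: PopulationState, arrays: ParamArrays) -> np.ndarray:
    vec = np.zeros(arrays.n, dtype=np.int64)
    for i, lab in enumerate(arrays.labels):
        vec[i] = int(state.counts.get(lab, 0))
    return vec


def _resolve_cancer_index(params: ModelParams, trait) -> int:
    """Accept a (genotype, phenotype) pair or a bare phenotype label."""
    pairs = params.space.cancer_pairs
    if isinstance(trait, tuple):
        if trait not in pairs:
            raise KeyError(f"cancer trait {trait!r} not in trait space")
        return pairs.index(trait)
    phenos = [p for _, p in pairs]
    if trait not in phenos:
        raise KeyError(f"cancer trait {trait!r} not in trait space")
    return phenos.index(trait)


def effective_cancer_rates(state: PopulationState, params: ModelParams, trait,
                           K: int | None = None,
                           arrays: ParamArrays | None = None):
    """Per-individual rate components for a focal cancer cell of the given trait.

    Returns ``(B_eff, D_extra_brc, D_comp, D_therapy)``.  The birth-reducing
    competition load S_b lowers the birth rate to ``max(0, b - S_b)``; any
    excess beyond the birth rate acts as additional death.  Competition sums
    exclude the focal individual's own 1/K contribution.
    """
    arrays = arrays if arrays is not None else params.compile(K=K)
    i = _resolve_cancer_index(params, trait)
    vec = _state_vector(state, arrays)
    nc = arrays.nc
    own = np.zeros(nc)
    own[i] = 1.0
    nu_c = (vec[:nc] - own) / arrays.K
    S_b = float(arrays.cb[i] @ nu_c)
    S_d = float(arrays.c[i] @ nu_c)
    B_eff = max(0.0, arrays.b[i] - S_b)
    D_extra_brc = max(0.0, S_b - arrays.b[i])
    D_therapy = float(arrays.tkill[i] @ vec[nc:nc + arrays.nz]) / arrays.K
    return B_eff, D_extra_brc, S_d, D_therapy


def switch_rate(state: PopulationState, params: ModelParams, trait, dest: str,
                K: int | None = None,
                arrays: ParamArrays | None = None) -> float:
    """Per-individual switch rate from a cancer trait to phenotype ``dest``.

    Natural rate plus the cytokine-induced rate weighted by scaled cytokine
    densities.  Destination must be a phenotype of the same genotype.
    """
    arrays = arrays if arrays is not None else params.compile(K=K)
    i = _resolve_cancer_index(params, trait)
    j = _resolve_cancer_index(params, dest if not isinstance(dest, tuple) else dest)
    if arrays.genotype_id[i] != arrays.genotype_id[j]:
        raise ValueError(f"switch {trait!r} -> {dest!r} crosses genotypes")
    if i == j:
        raise ValueError("switch destination equals source phenotype")
    vec = _state_vector(state, arrays)
    nu_w = vec[arrays.nc + arrays.nz:] / arrays.K
    return float(arrays.snat[i, j] + np.tensordot(nu_w, arrays.scyt[:, i, j], axes=1))


def build_channels(state: PopulationState, params: ModelParams,
                   K: int | None = None,
                   arrays: ParamArrays | None = None) -> list[EventChannel]:
    """Enumerate all event channels with positive actor counts, canonical order.

    The total rate is the sum of channel rates; it is zero iff no event is
    possible (absorbing state).
    """
    arrays = arrays if arrays is not None else params.compile(K=K)
    vec = _state_vector(state, arrays)
    nc, nz, nw = arrays.nc, arrays.nz, arrays.nw
    Kv = arrays.K
    labels = arrays.labels
    channels: list[EventChannel] = []
    for i in range(nc):
        ni = int(vec[i])
        if ni == 0:
            continue
        lab = labels[i]
        B_eff, D_brc, D_comp, D_ther = effective_cancer_rates(
            state, params, lab, K=Kv, arrays=arrays)
        if B_eff > 0:
            channels.append(EventChannel("cancer_birth", lab, ni * B_eff))
        if arrays.d[i] > 0:
            channels.append(EventChannel("cancer_death_natural", lab, ni * arrays.d[i]))
        if D_comp > 0:
            channels.append(EventChannel("cancer_death_competition", lab, ni * D_comp))
        if D_brc > 0:
            channels.append(EventChannel("cancer_death_excess_brc", lab, ni * D_brc))
        for z in range(nz):
            r = arrays.tkill[i, z] * vec[nc + z] / Kv
            if r > 0:
                channels.append(EventChannel(
                    "cancer_death_therapy", lab, ni * r, target=labels[nc + z]))
        for j in range(nc):
            if j == i:
                continue
            s = arrays.snat[i, j] + float(
                np.tensordot(vec[nc + nz:] / Kv, arrays.scyt[:, i, j], axes=1))
            if s > 0:
                channels.append(EventChannel("cancer_switch", lab, ni * s,
                                             target=labels[j]))
    for z in range(nz):
        nzp = int(vec[nc + z])
        if nzp == 0:
            continue
        lab = labels[nc + z]
        rb = arrays.bT[z] + float(arrays.tprod[z] @ vec[:nc]) / Kv
        if rb > 0:
            channels.append(EventChannel("tcell_birth", lab, nzp * rb))
        if arrays.dT[z] > 0:
            channels.append(EventChannel("tcell_death", lab, nzp * arrays.dT[z]))
    for w in range(nw):
        nwp = int(vec[nc + nz + w])
        if nwp > 0 and arrays.dW[w] > 0:
            channels.append(EventChannel("cytokine_decay", labels[nc + nz + w],
                                         nwp * arrays.dW[w]))
    return channels


def total_rate(channels: Iterable[EventChannel]) -> float:
    return float(sum(ch.rate for ch in channels))


def draw_event(channels: Sequence[EventChannel], rng: np.random.Generator):
    """Draw (waiting time, channel): dt ~ Exp(R), channel with prob rate/R.

    Channel choice scans the cumulative sum in list (canonical) order; raises
    if the total rate is zero (absorbing state — the caller must stop).
    """
    R = total_rate(channels)
    if R <= 0:
        raise ValueError("total rate is zero: absorbing state, no event to draw")
    dt = rng.exponential(1.0 / R)
    target = rng.random() * R
    acc = 0.0
    for ch in channels:
        acc += ch.rate
        if target < acc:
            return dt, ch
    return dt, channels[-1]


def apply_event(state: PopulationState, channel: EventChannel,
                params: ModelParams, rng: np.random.Generator,
                arrays: ParamArrays | None = None) -> PopulationState:
    """Apply one event and return the new state (time unchanged; caller advances it).

    Cancer births resolve the mutation draw here: with probability mu[g] the
    newborn's trait is drawn from the mutation law, otherwise it is a clonal
    copy.  Therapy kills and T-cell reproductions add their deterministic
    cytokine bursts.
    """
    arrays = arrays if arrays is not None else params.compile()
    counts = dict(state.counts)
    lab = channel.actor
    labels = arrays.labels
    nc, nz = arrays.nc, arrays.nz
    if counts.get(lab, 0) <= 0 and channel.kind != "noop":
        raise ValueError(f"channel actor {lab!r} has zero count")
    kind = channel.kind
    if kind == "cancer_birth":
        i = labels.index(lab)
        if arrays.mu[i] > 0 and rng.random() < arrays.mu[i]:
            row_total = arrays.m_cum[i, nc - 1]
            rmu = rng.random() * row_total
            j = int(np.searchsorted(arrays.m_cum[i], rmu, side="right"))
            j = min(j, nc - 1)
            dst = labels[j]
            counts[dst] = counts.get(dst, 0) + 1
        else:
            counts[lab] += 1
    elif kind in ("cancer_death_natural", "cancer_death_competition",
                  "cancer_death_excess_brc"):
        counts[lab] -= 1
    elif kind == "cancer_death_therapy":
        counts[lab] -= 1
        i = labels.index(lab)
        z = labels.index(channel.target) - nc
        for w in range(arrays.nw):
            burst = int(arrays.kburst[i, z, w])
            if burst:
                wl = labels[nc + nz + w]
                counts[wl] = counts.get(wl, 0) + burst
    elif kind == "cancer_switch":
        counts[lab] -= 1
        counts[channel.target] = counts.get(channel.target, 0) + 1
    elif kind == "tcell_birth":
        counts[lab] += 1
        z = labels.index(lab) - nc
        for w in range(arrays.nw):
            burst = int(arrays.rburst[z, w])
            if burst:
                wl = labels[nc + nz + w]
                counts[wl] = counts.get(wl, 0) + burst
    elif kind in ("tcell_death", "cytokine_decay"):
        counts[lab] -= 1
    else:
        raise ValueError(f"unknown channel kind {kind!r}")
    if any(v < 0 for v in counts.values()):
        raise RuntimeError("negative count after event application")
    return PopulationState(time=state.time, counts=counts)


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Recorded time series of one stochastic (or deterministic) run.

    ``states`` holds raw integer counts, one row per record, columns in
    canonical trait order; ``cum_mutations`` counts mutation events up to each
    record time.
    """

    labels: list
    nc: int
    nz: int
    nw: int
    K: int
    times: np.ndarray
    states: np.ndarray
    cum_mutations: np.ndarray
    stop_reason: str
    t_end: float | None = None
    seed: int | None = None
    params_hash: str = ""
    events: list | None = None

    def column(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def cancer_total(self) -> np.ndarray:
        return self.states[:, : self.nc].sum(axis=1)

    def tcell_total(self) -> np.ndarray:
        return self.states[:, self.nc: self.nc + self.nz].sum(axis=1)

    def scaled(self) -> np.ndarray:
        return self.states / float(self.K)

    def final_state(self) -> PopulationState:
        return PopulationState(
            time=float(self.times[-1]),
            counts={lab: int(v) for lab, v in zip(self.labels, self.states[-1])})

    # -- serialization --------------------------------------------------------

    def write_tsv(self, path, event_log_path=None) -> None:
        """Tab-separated table (time + one raw-count column per trait) with a
        JSON sidecar (params hash, seed, stop reason)."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("time\t" + "\t".join(self.labels) + "\tcum_mutations\n")
            for t, row, cm in zip(self.times, self.states, self.cum_mutations):
                cols = "\t".join(str(int(v)) for v in row)
                fh.write(f"{t:.12g}\t{cols}\t{int(cm)}\n")
        sidecar = {
            "params_hash": self.params_hash,
            "seed": self.seed,
            "stop_reason": self.stop_reason,
            "K": self.K,
            "n_records": int(len(self.times)),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
        if event_log_path is not None and self.events is not None:
            with open(event_log_path, "w") as fh:
                fh.write("time\tkind\tactor\ttarget\n")
                for t, kind, actor, target in self.events:
                    fh.write(f"{t:.12g}\t{kind}\t{actor}\t{target or ''}\n")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def _record_grid(t0: float, t_max: float, record_dt: float | None,
                 record_times) -> np.ndarray:
    if record_times is not None:
        grid = np.asarray(record_times, dtype=float)
    else:
        dt = record_dt if record_dt is not None else max((t_max - t0) / 400.0, 1e-9)
        grid = np.arange(t0, t_max + dt * 0.5, dt)
        if grid[-1] < t_max:
            grid = np.append(grid, t_max)
    if grid.size == 0 or grid[0] > t0:
        grid = np.insert(grid, 0, t0)
    return grid


def simulate(initial: PopulationState, params: ModelParams, *,
             t_max: float, seed: int, K: int | None = None,
             record_dt: float | None = None, record_times=None,
             stop_on_tumour_extinct: bool = False,
             max_events: int = 10 ** 10,
             injections: Sequence[tuple] | None = None,
             engine: str = "numba", log_events: bool = False) -> Trajectory:
    """Simulate the jump process from ``initial`` until a stop rule fires.

    Stop rules: ``t_max`` (always), global extinction (total rate zero),
    optional tumour extinction, and an event-count cap.  Records are thinned
    to a time grid (``record_dt`` spacing or explicit ``record_times``); the
    first record is the initial state.  ``injections`` is an optional sorted
    list of (time, trait_label, added_count) therapy injections.

    With a fixed ``seed`` the trajectory is reproducible within an engine.
    """
    arrays = params.compile(K=K)
    if engine == "reference":
        return _simulate_reference(initial, params, arrays, t_max=t_max, seed=seed,
                                   record_dt=record_dt, record_times=record_times,
                                   stop_on_tumour_extinct=stop_on_tumour_extinct,
                                   max_events=max_events, injections=injections,
                                   log_events=log_events)
    if engine != "numba":
        raise ValueError(f"unknown engine {engine!r}")

    t0 = float(initial.time)
    grid = _record_grid(t0, t_max, record_dt, record_times)
    vec = initial.as_vector(params.space)
    if np.any(vec < 0):
        raise ValueError("initial counts must be non-negative")
    m = grid.shape[0]
    rec_states = np.zeros((m, arrays.n), dtype=np.int64)
    rec_mut = np.zeros(m, dtype=np.int64)

    inj = sorted(injections or [], key=lambda x: x[0])
    boundaries = [t for t, _, _ in inj if t0 < t <= t_max] + [t_max]
    gi = 0
    n_mut = 0
    stop_code = _kernel.STOP_T_MAX
    events_left = max_events
    t = t0
    seed_arg = int(seed) % (2 ** 31 - 1)
    inj_i = 0
    # skip injections at or before t0 by applying them immediately
    for ti, lab, cnt in inj:
        if ti <= t0:
            vec[arrays.labels.index(lab)] += int(cnt)
            inj_i += 1
    for seg_end in sorted(set(boundaries)):
        gi, t, stop_code, n_ev, n_mut = _kernel.ssa_run(
            vec, t, seg_end, arrays.K,
            arrays.b, arrays.d, arrays.c, arrays.cb, arrays.tkill, arrays.kburst,
            arrays.snat, arrays.scyt, arrays.mu, arrays.m_cum,
            arrays.bT, arrays.dT, arrays.tprod, arrays.rburst, arrays.dW,
            grid, gi, rec_states, rec_mut,
            stop_on_tumour_extinct, events_left, n_mut, seed_arg)
        seed_arg = -1  # continue the stream across segments
        events_left -= n_ev
        if stop_code in (_kernel.STOP_TUMOUR_EXTINCT, _kernel.STOP_MAX_EVENTS):
            break
        if stop_code == _kernel.STOP_ALL_EXTINCT and inj_i >= len(inj):
            break
        # apply injections scheduled at this boundary
        while inj_i < len(inj) and inj[inj_i][0] <= seg_end:
            ti, lab, cnt = inj[inj_i]
            vec[arrays.labels.index(lab)] += int(cnt)
            inj_i += 1
        if stop_code == _kernel.STOP_ALL_EXTINCT:
            # the kernel filled the grid to the end with the frozen state;
            # entries past the injection time must be re-simulated
            while gi > 0 and grid[gi - 1] > seg_end:
                gi -= 1
            t = seg_end
    # truncate to what was recorded, append final state if past last record
    times = grid[:gi]
    states = rec_states[:gi]
    muts = rec_mut[:gi]
    if gi == 0 or times[-1] < t:
        times = np.append(times, t)
        states = np.vstack([states, vec[None, :]]) if gi else vec[None, :].copy()
        muts = np.append(muts, n_mut)
    return Trajectory(labels=list(arrays.labels), nc=arrays.nc, nz=arrays.nz,
                      nw=arrays.nw, K=arrays.K, times=times, states=states,
                      cum_mutations=muts, stop_reason=STOP_REASONS[stop_code],
                      t_end=float(t), seed=seed, params_hash=params.fingerprint())


def _simulate_reference(initial, params, arrays, *, t_max, seed, record_dt,
                        record_times, stop_on_tumour_extinct, max_events,
                        injections, log_events):
    rng = np.random.default_rng(seed)
    t0 = float(initial.time)
    grid = _record_grid(t0, t_max, record_dt, record_times)
    inj = sorted(injections or [], key=lambda x: x[0])
    state = PopulationState(time=t0, counts=dict(initial.counts))
    for ti, lab, cnt in [x for x in inj if x[0] <= t0]:
        state.counts[lab] = state.counts.get(lab, 0) + int(cnt)
    inj = [x for x in inj if t0 < x[0] <= t_max]

    times, rows, muts = [], [], []
    events = [] if log_events else None
    gi = 0
    n_mut = 0
    n_events = 0
    stop_reason = "t_max"
    t = t0

    def record_until(t_next):
        nonlocal gi
        while gi < len(grid) and grid[gi] < t_next:
            times.append(grid[gi])
            rows.append(state.as_vector(params.space))
            muts.append(n_mut)
            gi += 1

    while True:
        channels = build_channels(state, params, K=arrays.K, arrays=arrays)
        R = total_rate(channels)
        next_inj = inj[0][0] if inj else math.inf
        if R <= 0:
            if not inj:
                record_until(math.inf)
                stop_reason = "all_extinct"
                break
            # frozen until the next injection revives the process
            record_until(next_inj)
            t = next_inj
            while inj and inj[0][0] <= t:
                _, lab, cnt = inj.pop(0)
                state.counts[lab] = state.counts.get(lab, 0) + int(cnt)
            state.time = t
            continue
        dt, ch = draw_event(channels, rng)
        t_next = t + dt
        if t_next >= next_inj:
            # the exponential clock is memoryless: discard the event beyond
            # the injection time and restart from the injected state
            record_until(next_inj)
            t = next_inj
            while inj and inj[0][0] <= t:
                _, lab, cnt = inj.pop(0)
                state.counts[lab] = state.counts.get(lab, 0) + int(cnt)
            state.time = t
            continue
        record_until(t_next)
        if t_next > t_max:
            t = t_max
            stop_reason = "t_max"
            break
        t = t_next
        n_events += 1
        prev = state
        state = apply_event(state, ch, params, rng, arrays=arrays)
        state.time = t
        if events is not None:
            kind = ch.kind
            target = ch.target
            if ch.kind == "cancer_birth":
                delta = {k: state.counts.get(k, 0) - prev.counts.get(k, 0)
                         for k in set(state.counts) | set(prev.counts)}
                born = [k for k, v in delta.items() if v > 0]
                if born and born[0] != ch.actor:
                    kind = "cancer_birth_mutant"
                    target = born[0]
                else:
                    kind = "cancer_birth_clonal"
            events.append((t, kind, ch.actor, target))
        if ch.kind == "cancer_birth":
            tumour_now = sum(state.counts.get(l, 0) for l in arrays.labels[:arrays.nc])
            prev_tumour = sum(prev.counts.get(l, 0) for l in arrays.labels[:arrays.nc])
            # mutation bookkeeping: a birth that changed a non-actor cancer trait
            if tumour_now == prev_tumour + 1:
                if state.counts.get(ch.actor, 0) == prev.counts.get(ch.actor, 0):
                    n_mut += 1
        if stop_on_tumour_extinct and sum(
                state.counts.get(l, 0) for l in arrays.labels[:arrays.nc]) == 0:
            stop_reason = "tumour_extinct"
            break
        if n_events >= max_events:
            stop_reason = "max_events"
            break

    if not times or times[-1] < t:
        times.append(t)
        rows.append(state.as_vector(params.space))
        muts.append(n_mut)
    return Trajectory(labels=list(arrays.labels), nc=arrays.nc, nz=arrays.nz,
                      nw=arrays.nw, K=arrays.K, times=np.array(times),
                      states=np.array(rows, dtype=np.int64),
                      cum_mutations=np.array(muts, dtype=np.int64),
                      stop_reason=stop_reason, t_end=float(t), seed=seed,
                      params_hash=params.fingerprint(), events=events)
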