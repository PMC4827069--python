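"""Deterministic large-population (K → ∞) limit of the individual-based model.

The scaled process converges to a system of quadratic ODEs combining a
logistic part (birth, death, competition with the birth-reducing floor), a
predator–prey part between T-cells and cancer cells, a phenotype-switch part
(natural plus cytokine-induced) and, optionally, a mutation part.  Rare
mutations (mu_K → 0) are invisible in this limit, so fixed-point work is done
with mutation off.

Fixed points are located per support pattern — every subset of traits forced
to zero, mirroring the model's invariant subspaces — and classified by the
spectrum of a numerical Jacobian, optionally restricted to the support's
invariant subspace.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .traits import ModelParams, ParamArrays

__all__ = [
    "DeterministicState",
    "FixedPoint",
    "vector_field",
    "integrate",
    "find_fixed_points",
    "classify_stability",
    "write_fixed_point_report",
]

RESIDUAL_TOL = 1e-9
DEDUP_TOL = 1e-6
STABILITY_TOL = 1e-8


@dataclass
class DeterministicState:
    """Scaled densities (units of K) per trait, canonical order."""

    x: dict

    def as_vector(self, arrays: ParamArrays) -> np.ndarray:
        return np.array([float(self.x.get(lab, 0.0)) for lab in arrays.labels])


@dataclass
class FixedPoint:
    """A located equilibrium of the deterministic flow.

    ``support`` is the set of traits with positive density; ``name`` encodes
    the support as one character per trait (the label when present, 0 when
    absent), following the P_xy00-style subscript convention.
    """

    x: np.ndarray
    labels: list
    residual: float
    eigenvalues: np.ndarray | None = None
    classification: str = "unclassified"
    support: tuple = ()
    restricted_eigenvalues: np.ndarray | None = None
    restricted_classification: str | None = None

    @property
    def name(self) -> str:
        return "P_" + "".join(
            lab if lab in self.support else "0" for lab in self.labels)

    def density(self, label: str) -> float:
        return float(self.x[self.labels.index(label)])


# ---------------------------------------------------------------------------
# vector field
# ---------------------------------------------------------------------------


def _field(arrays: ParamArrays, x: np.ndarray, mutation_on: bool) -> np.ndarray:
    nc, nz, nw = arrays.nc, arrays.nz, arrays.nw
    xc = x[:nc]
    xz = x[nc:nc + nz]
    xw = x[nc + nz:]
    Sb = arrays.cb @ xc
    Sd = arrays.c @ xc
    beff = np.maximum(0.0, arrays.b - Sb)
    brc_excess = np.maximum(0.0, Sb - arrays.b)
    kill = arrays.tkill @ xz if nz else np.zeros(nc)
    # switch rate matrix at current cytokine densities: source row, dest column
    sw = arrays.snat + (np.tensordot(xw, arrays.scyt, axes=(0, 0)) if nw else 0.0)
    out_sw = sw.sum(axis=1)
    in_sw = sw.T @ xc
    mu = arrays.mu if mutation_on else np.zeros(nc)
    growth = (1.0 - mu) * beff - arrays.d - Sd - kill - brc_excess - out_sw
    dxc = xc * growth + in_sw
    if mutation_on:
        m = np.diff(np.concatenate([np.zeros((nc, 1)), arrays.m_cum], axis=1), axis=1)
        dxc = dxc + m.T @ (mu * beff * xc)
    dxz = xz * (arrays.bT - arrays.dT + arrays.tprod @ xc) if nz else np.zeros(0)
    if nw:
        kills_by_pair = arrays.tkill * np.outer(xc, xz)          # (nc, nz)
        dxw = (-arrays.dW * xw
               + np.einsum("izw,iz->w", arrays.kburst.astype(float), kills_by_pair)
               + arrays.rburst.astype(float).T @ (xz * (arrays.tprod @ xc)))
    else:
        dxw = np.zeros(0)
    return np.concatenate([dxc, dxz, dxw])


def vector_field(x, params: ModelParams, mutation_on: bool = False,
                 arrays: ParamArrays | None = None) -> np.ndarray:
    """Right-hand side of the limiting ODE system at scaled densities ``x``.

    ``x`` may be a DeterministicState, a mapping label → density, or a vector
    in canonical order.  With ``mutation_on`` the clonal birth term carries a
    factor (1 − mu) and mutant influx is added; with it off the system is the
    rare-mutation limit.
    """
    arrays = arrays or params.compile()
    if isinstance(x, DeterministicState):
        vec = x.as_vector(arrays)
    elif isinstance(x, dict):
        vec = DeterministicState(x).as_vector(arrays)
    else:
        vec = np.asarray(x, dtype=float)
    if np.any(vec < -1e-8):
        raise ValueError("densities must be non-negative")
    return _field(arrays, np.maximum(vec, 0.0), mutation_on)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def integrate(x0, params: ModelParams, t_grid, *, mutation_on: bool = False,
              rtol: float = 1e-8, atol: float = 1e-10, method: str = "LSODA"):
    """Integrate the deterministic system on ``t_grid``.

    Returns ``(trajectory, info)`` where trajectory has shape
    (len(t_grid), n_traits), clipped at zero within solver tolerance, and
    info reports the terminal derivative norm and solver diagnostics.
    """
    arrays = params.compile()
    if isinstance(x0, DeterministicState):
        x0 = x0.as_vector(arrays)
    elif isinstance(x0, dict):
        x0 = DeterministicState(x0).as_vector(arrays)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial densities must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)

    def rhs(t, y):
        return _field(arrays, np.maximum(y, 0.0), mutation_on)

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message} "
                           f"(nfev={sol.nfev}, last t={sol.t[-1] if len(sol.t) else None})")
    traj = np.clip(sol.y.T, 0.0, None)
    info = {
        "terminal_residual": float(np.max(np.abs(_field(arrays, traj[-1], mutation_on)))),
        "nfev": int(sol.nfev),
        "method": method,
    }
    return traj, info


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------


def _solve_on_support(arrays: ParamArrays, support: np.ndarray,
                      seed_vec: np.ndarray, relax: bool = True) -> np.ndarray | None:
    idx = np.flatnonzero(support)
    if idx.size == 0:
        return np.zeros(arrays.n)

    def restricted(u):
        x = np.zeros(arrays.n)
        x[idx] = u
        return _field(arrays, np.maximum(x, 0.0), False)[idx]

    u0 = seed_vec[idx]
    if relax and idx.size > 1:
        # relax along the restricted flow first: Newton alone is unreliable
        # from generic seeds, but each inventory point attracts within its
        # own invariant subspace
        try:
            sol = solve_ivp(lambda t, u: restricted(np.maximum(u, 0.0)),
                            (0.0, 200.0), u0, method="LSODA",
                            rtol=1e-6, atol=1e-9)
            if sol.success:
                u0 = np.maximum(sol.y[:, -1], 0.0)
        except Exception:
            pass
    sol = root(restricted, u0, method="hybr", tol=1e-12)
    if not sol.success:
        return None
    x = np.zeros(arrays.n)
    x[idx] = sol.x
    return x


def find_fixed_points(params: ModelParams, *, extra_seeds=(),
                      residual_tol: float = RESIDUAL_TOL,
                      dedup_tol: float = DEDUP_TOL,
                      classify: bool = True,
                      max_support_size: int | None = None) -> list[FixedPoint]:
    """Locate fixed points of the mutation-off system by support enumeration.

    Every subset of traits is tried as a candidate support (the others pinned
    at zero), seeded from a few density scales; solutions must be
    non-negative, zero off-support, and satisfy the *full* vector field to
    ``residual_tol``.  Near-duplicates are merged.  User seeds in
    ``extra_seeds`` (full-length density vectors) are attempted as-is.
    """
    arrays = params.compile()
    n = arrays.n
    labels = arrays.labels
    candidates: list[np.ndarray] = []

    supports = itertools.product([0, 1], repeat=n)
    for pattern in supports:
        support = np.array(pattern, dtype=bool)
        if max_support_size is not None and support.sum() > max_support_size:
            continue
        for scale in (0.5, 1.5, 0.05):
            seed = np.full(n, scale)
            x = _solve_on_support(arrays, support, seed)
            if x is None:
                continue
            if np.any(x < -1e-9):
                continue
            x = np.maximum(x, 0.0)
            if np.max(np.abs(_field(arrays, x, False))) < residual_tol:
                candidates.append(x)
    for seed in extra_seeds:
        seed = np.asarray(seed, dtype=float)
        support = seed > 0
        x = _solve_on_support(arrays, support, seed)
        if x is not None and np.all(x >= -1e-9):
            x = np.maximum(x, 0.0)
            if np.max(np.abs(_field(arrays, x, False))) < residual_tol:
                candidates.append(x)

    # deduplicate
    points: list[np.ndarray] = []
    for x in candidates:
        if not any(np.max(np.abs(x - y)) < dedup_tol for y in points):
            points.append(x)

    out = []
    for x in points:
        supp = tuple(lab for lab, v in zip(labels, x) if v > dedup_tol)
        fp = FixedPoint(x=x, labels=list(labels),
                        residual=float(np.max(np.abs(_field(arrays, x, False)))),
                        support=supp)
        if classify:
            fp = classify_stability(fp, params)
        out.append(fp)
    out.sort(key=lambda f: (len(f.support), f.name))
    return out


def _jacobian(arrays: ParamArrays, x: np.ndarray) -> np.ndarray:
    n = x.size
    J = np.zeros((n, n))
    for i in range(n):
        h = 1e-6 * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        # central differences; the field tolerates slightly negative entries
        fp_ = _field(arrays, np.maximum(xp, 0.0), False)
        fm_ = _field(arrays, np.maximum(xm, 0.0), False)
        # clipping makes the step one-sided at the x=0 boundary
        denom = xp[i] - max(xm[i], 0.0)
        J[:, i] = (fp_ - fm_) / denom
    return J


def _classify(eigs: np.ndarray, tol: float) -> str:
    re = eigs.real
    if np.all(re < -tol):
        return "stable"
    if np.any(re > tol):
        return "unstable"
    return "marginal"


def classify_stability(fp: FixedPoint, params: ModelParams,
                       restrict_to_support: bool = False,
                       tol: float = STABILITY_TOL) -> FixedPoint:
    """Attach Jacobian spectra and a stability classification to a fixed point.

    The Jacobian is computed by central differences with steps scaled to the
    density magnitude.  A point sitting exactly on a birth-rate floor boundary
    (some phenotype with b(p) equal to its birth-reduction load) makes the
    field non-smooth; such points are classified marginal and flagged.  With
    ``restrict_to_support`` the spectrum of the Jacobian restricted to the
    support's invariant subspace is also recorded.
    """
    arrays = params.compile()
    x = np.asarray(fp.x, dtype=float)
    if fp.residual > 1e-6:
        raise ValueError(f"point residual {fp.residual} too large to classify")
    # floor-boundary detection
    Sb = arrays.cb @ x[:arrays.nc]
    on_floor = np.any(np.abs(arrays.b - Sb) < 1e-10) and np.any(arrays.cb > 0)
    J = _jacobian(arrays, x)
    eigs = np.linalg.eigvals(J)
    fp.eigenvalues = eigs
    fp.classification = "marginal" if on_floor else _classify(eigs, tol)
    if restrict_to_support or fp.restricted_eigenvalues is None:
        idx = [fp.labels.index(lab) for lab in fp.support]
        if idx:
            sub = J[np.ix_(idx, idx)]
            sub_eigs = np.linalg.eigvals(sub)
        else:
            sub_eigs = np.array([])
        fp.restricted_eigenvalues = sub_eigs
        fp.restricted_classification = (
            _classify(sub_eigs, tol) if sub_eigs.size else "stable")
    return fp


def write_fixed_point_report(points, path) -> None:
    """JSON report: support pattern, densities, spectrum, classification."""
    rows = []
    for fp in points:
        rows.append({
            "name": fp.name,
            "support": list(fp.support),
            "densities": {lab: float(v) for lab, v in zip(fp.labels, fp.x)},
            "residual": fp.residual,
            "eigenvalues": [[float(e.real), float(e.imag)]
                            for e in (fp.eigenvalues if fp.eigenvalues is not None else [])],
            "classification": fp.classification,
            "restricted_classification": fp.restricted_classification,
        })
    Path(path).write_text(json.dumps(rows, indent=1, sort_keys=True))
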