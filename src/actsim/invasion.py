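"""Invasion fitness of a rare mutant genotype with phenotype structure.

Until a mutant clone either dies out or reaches a size εK, it is approximated
by a multi-type branching process (MTBP) whose types are the mutant
genotype's phenotypes, living against the resident equilibrium frozen at its
densities.  The clone's mean count vector obeys dn/dt = A n; the clone is
supercritical iff the largest eigenvalue λ₁ of the mean matrix A is strictly
positive, which generalises the scalar invasion fitness (and reduces to it
for a single mutant phenotype).  The normalised Perron right eigenvector v
gives the phenotype composition of a surviving clone at level εK.

Orientation convention: column j of A is the parent type, so
A[i, j] = s(p_j → p_i) off the diagonal and the diagonal carries each
phenotype's net per-capita growth rate minus its total outgoing switch rate.

The module also carries the birth-reducing-competition (BRC) mutation-rate
analysis: with competition acting on the birth rate, the total mutation rate
mu · n · (b − c_b n / K) is quadratic in the population size n, maximal at
n* = bK/(2 c_b), so a population at its equilibrium n̄ can produce fewer
mutants per unit time than a smaller one regrowing after therapy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .gillespie import simulate
from .meanfield import FixedPoint
from .traits import ModelParams, PopulationState

__all__ = [
    "MeanMatrix",
    "InvasionResult",
    "BrcMutationCurve",
    "mean_matrix",
    "invasion_fitness",
    "invasion_mc_oracle",
    "brc_mutation_curve",
    "brc_mutation_experiment",
]


# ---------------------------------------------------------------------------
# mean matrix
# ---------------------------------------------------------------------------


@dataclass
class MeanMatrix:
    """Mean growth generator A of the mutant MTBP (per day), plus the raw
    per-phenotype birth/death/switch rates used to build it (the same rates
    drive the Monte-Carlo oracle)."""

    A: np.ndarray
    phenotypes: list
    genotype: str
    resident: np.ndarray
    birth: np.ndarray      # clonal birth rate per phenotype, (1 - mu) * B_eff
    death: np.ndarray      # total death rate per phenotype
    sigma: np.ndarray      # switch rates, sigma[i, j] = rate p_i -> p_j


def _mutant_rates(params: ModelParams, resident_x: np.ndarray, genotype: str):
    arrays = params.compile()
    nc, nz, nw = arrays.nc, arrays.nz, arrays.nw
    pairs = params.space.cancer_pairs
    idx = [i for i, (g, _) in enumerate(pairs) if g == genotype]
    if not idx:
        raise ValueError(f"genotype {genotype!r} not in trait space")
    xc = resident_x[:nc]
    xz = resident_x[nc:nc + nz]
    xw = resident_x[nc + nz:]
    k = len(idx)
    birth = np.zeros(k)
    death = np.zeros(k)
    sigma = np.zeros((k, k))
    for a, i in enumerate(idx):
        Sb = float(arrays.cb[i] @ xc)
        Sd = float(arrays.c[i] @ xc)
        beff = max(0.0, arrays.b[i] - Sb)
        brc_excess = max(0.0, Sb - arrays.b[i])
        kill = float(arrays.tkill[i] @ xz) if nz else 0.0
        birth[a] = (1.0 - arrays.mu[i]) * beff
        death[a] = arrays.d[i] + Sd + brc_excess + kill
        for bb, j in enumerate(idx):
            if i == j:
                continue
            s = arrays.snat[i, j]
            if nw:
                s += float(np.tensordot(xw, arrays.scyt[:, i, j], axes=1))
            sigma[a, bb] = s
    return idx, birth, death, sigma


def mean_matrix(resident_eq, mutant_genotype: str, params: ModelParams) -> MeanMatrix:
    """Build the MTBP mean matrix for a mutant genotype against a resident
    equilibrium (a FixedPoint or a density vector in canonical order).

    The resident must not populate the mutant genotype.  Column j is the
    parent phenotype: dn/dt = A n for the mean counts n of the clone.
    """
    if isinstance(resident_eq, FixedPoint):
        if resident_eq.residual > 1e-6:
            raise ValueError("resident equilibrium residual too large")
        x = np.asarray(resident_eq.x, dtype=float)
    else:
        x = np.asarray(resident_eq, dtype=float)
    pairs = params.space.cancer_pairs
    idx, birth, death, sigma = _mutant_rates(params, x, mutant_genotype)
    if np.any(x[idx] > 0):
        raise ValueError(
            f"resident equilibrium already populates genotype {mutant_genotype!r}")
    k = len(idx)
    A = np.zeros((k, k))
    for a in range(k):
        A[a, a] = birth[a] - death[a] - sigma[a].sum()
        for bb in range(k):
            if bb != a:
                A[a, bb] = sigma[bb, a]
    phenos = [pairs[i][1] for i in idx]
    return MeanMatrix(A=A, phenotypes=phenos, genotype=mutant_genotype,
                      resident=x, birth=birth, death=death, sigma=sigma)


# ---------------------------------------------------------------------------
# eigen-analysis
# ---------------------------------------------------------------------------


@dataclass
class InvasionResult:
    """λ₁, phenotype proportions v, and the super-criticality/irreducibility flags."""

    lambda1: float
    v: np.ndarray
    supercritical: bool
    irreducible: bool
    phenotypes: list
    eigen_gap: float

    def to_dict(self) -> dict:
        return {
            "lambda1": self.lambda1,
            "v": {p: float(x) for p, x in zip(self.phenotypes, self.v)},
            "supercritical": self.supercritical,
            "irreducible": self.irreducible,
            "eigen_gap": self.eigen_gap,
        }


def invasion_fitness(M: MeanMatrix) -> InvasionResult:
    """Invasion fitness λ₁ (largest-real-part eigenvalue of A) and composition v.

    A is essentially non-negative (off-diagonal entries are switch rates), so
    λ₁ is real.  v is the associated right eigenvector of A normalised to the
    simplex — the asymptotic phenotype composition of a growing clone under
    dn/dt = A n.  Irreducibility is strong connectivity of the positive
    off-diagonal graph; when it fails, v is still returned but flagged.
    """
    A = M.A
    k = A.shape[0]
    eigvals, eigvecs = np.linalg.eig(A)
    order = np.argsort(eigvals.real)[::-1]
    lam = eigvals[order[0]]
    if abs(lam.imag) > 1e-10:
        raise ArithmeticError(
            f"leading eigenvalue has imaginary part {lam.imag}; "
            "mean matrix is not essentially non-negative")
    v = eigvecs[:, order[0]].real
    # Perron vector sign: make the dominant orientation positive
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9):
        # reducible cases can yield mixed signs; clip and flag via graph test
        v = np.maximum(v, 0.0)
    total = v.sum()
    v = v / total if total > 0 else np.full(k, 1.0 / k)
    graph = csr_matrix((A - np.diag(np.diag(A))) > 0)
    ncomp, _ = connected_components(graph, directed=True, connection="strong")
    irreducible = bool(ncomp == 1)
    gap = float(eigvals[order[0]].real - eigvals[order[1]].real) if k > 1 else np.inf
    return InvasionResult(lambda1=float(lam.real), v=v,
                          supercritical=bool(lam.real > 0),
                          irreducible=irreducible,
                          phenotypes=list(M.phenotypes), eigen_gap=gap)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle (resident frozen)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mtbp_runs(birth, death, sigma, start, threshold, n_runs, seed):
    np.random.seed(seed)
    k = birth.shape[0]
    survived = 0
    comp_sum = np.zeros(k)
    n = np.zeros(k, dtype=np.int64)
    for _ in range(n_runs):
        for i in range(k):
            n[i] = 0
        n[start] = 1
        total = 1
        while 0 < total < threshold:
            R = 0.0
            for i in range(k):
                if n[i] > 0:
                    s = birth[i] + death[i]
                    for j in range(k):
                        s += sigma[i, j]
                    R += n[i] * s
            target = np.random.random() * R
            acc = 0.0
            done = False
            for i in range(k):
                if n[i] == 0:
                    continue
                acc += n[i] * birth[i]
                if target < acc:
                    n[i] += 1
                    total += 1
                    done = True
                    break
                acc += n[i] * death[i]
                if target < acc:
                    n[i] -= 1
                    total -= 1
                    done = True
                    break
                for j in range(k):
                    acc += n[i] * sigma[i, j]
                    if target < acc:
                        n[i] -= 1
                        n[j] += 1
                        done = True
                        break
                if done:
                    break
            if not done:  # float roundoff guard: apply the last positive channel
                for i in range(k - 1, -1, -1):
                    if n[i] > 0:
                        n[i] -= 1
                        total -= 1
                        break
        if total >= threshold:
            survived += 1
            for i in range(k):
                comp_sum[i] += n[i] / total
    return survived, comp_sum


def invasion_mc_oracle(resident_eq, mutant_genotype: str, params: ModelParams,
                       *, epsilon: float, n_runs: int, seed: int,
                       K: int | None = None, start_phenotype: str | None = None):
    """Monte-Carlo companion to the MTBP classification.

    Runs the resident-frozen linear birth/death/switch process from a single
    mutant individual until extinction or total size εK.  Returns
    ``(survival_frequency, mean phenotype composition at the hitting time,
    n_surviving)``; the composition is NaN when no run survives.

    Waiting times are irrelevant to hitting probabilities, so the embedded
    jump chain is simulated directly.
    """
    M = mean_matrix(resident_eq, mutant_genotype, params)
    Kv = int(params.K if K is None else K)
    threshold = int(np.ceil(epsilon * Kv))
    if threshold < 10:
        raise ValueError(f"epsilon*K = {threshold} too small to be meaningful (< 10)")
    k = len(M.phenotypes)
    start = 0 if start_phenotype is None else M.phenotypes.index(start_phenotype)
    survived, comp_sum = _mtbp_runs(M.birth, M.death, M.sigma, start, threshold,
                                    int(n_runs), int(seed) % (2 ** 31 - 1))
    freq = survived / n_runs
    comp = comp_sum / survived if survived else np.full(k, np.nan)
    return freq, comp, survived


# ---------------------------------------------------------------------------
# birth-reducing competition and mutation timing
# ---------------------------------------------------------------------------


@dataclass
class BrcMutationCurve:
    """Total mutation rate of a single-type population under BRC.

    rate_at(n) = mu * n * max(0, b - c_b n / K): quadratic in n where the
    birth floor is inactive, zero at n = 0, maximal at n* = bK/(2 c_b).
    The equilibrium count n̄ solves b - c_b n/K = d + c n/K.  The equilibrium
    rate is submaximal with the peak *inside* the growth path (n* < n̄) iff,
    for pure BRC (c = 0), d < b/2.
    """

    b: float
    d: float
    c: float
    c_b: float
    mu: float
    K: int
    n_star: float
    n_bar: float
    submaximal_at_equilibrium: bool

    def rate_at(self, n):
        n = np.asarray(n, dtype=float)
        return self.mu * n * np.maximum(0.0, self.b - self.c_b * n / self.K)


def brc_mutation_curve(b: float, d: float, c: float, c_b: float,
                       mu: float, K: int) -> BrcMutationCurve:
    """Landmarks of the quadratic total-mutation-rate curve (see BrcMutationCurve)."""
    if b <= d:
        raise ValueError(f"b={b} <= d={d}: no positive equilibrium")
    if c_b <= 0:
        raise ValueError("birth-reducing competition requires c_b > 0")
    if c < 0 or mu < 0 or K < 1:
        raise ValueError("c, mu must be non-negative and K >= 1")
    n_star = b * K / (2.0 * c_b)
    n_bar = (b - d) * K / (c + c_b)
    return BrcMutationCurve(b=b, d=d, c=c, c_b=c_b, mu=mu, K=int(K),
                            n_star=n_star, n_bar=n_bar,
                            submaximal_at_equilibrium=bool(n_bar > n_star + 1e-12))


def brc_mutation_experiment(params: ModelParams, *, growth_start: int,
                            duration: float, replicates: int, seed: int,
                            resident_label: str | None = None,
                            equilibrium_start: int | None = None):
    """Paired SSA experiment: cumulative mutation events in a regrowing
    population versus one started at equilibrium, over the same duration.

    Returns ``(mean_mutations_growth, mean_mutations_equilibrium)``.  The
    resident trait defaults to the first cancer trait; the equilibrium start
    defaults to the deterministic n̄ of that trait alone.
    """
    arrays = params.compile()
    label = resident_label or arrays.labels[0]
    i = arrays.labels.index(label)
    if equilibrium_start is None:
        denom = arrays.c[i, i] + arrays.cb[i, i]
        if denom <= 0:
            raise ValueError("resident trait has no self-competition")
        equilibrium_start = int(round((arrays.b[i] - arrays.d[i]) / denom * arrays.K))
    totals = {"growth": 0, "equilibrium": 0}
    for name, n0 in (("growth", growth_start), ("equilibrium", equilibrium_start)):
        for r in range(replicates):
            init = PopulationState(time=0.0, counts={label: int(n0)})
            traj = simulate(init, params, t_max=duration,
                            seed=(seed + r) % (2 ** 31 - 1) if name == "growth"
                            else (seed + 10 ** 6 + r) % (2 ** 31 - 1),
                            record_times=[duration])
            totals[name] += int(traj.cum_mutations[-1])
    return totals["growth"] / replicates, totals["equilibrium"] / replicates
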