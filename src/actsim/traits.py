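"""Trait space and model parameters for the tumour–immune individual-based model.

The model tracks three classes of actors on a finite trait space: cancer cells
carrying a (genotype, phenotype) pair, T-cells of one or more specificities,
and cytokine molecules (e.g. TNF-alpha).  All interaction kernels are stored
densely over the declared trait space; entries that are never set default to
zero.  Populations are integer counts per trait; dividing by the carrying
capacity ``K`` gives the scaled measure used by the deterministic limit.

Canonical trait ordering (genotypes in declared order, phenotypes within each
genotype in declared order, then T-cell types, then cytokine types) fixes the
index layout of every vector and matrix downstream.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TraitSpace",
    "CancerParams",
    "TCellParams",
    "CytokineParams",
    "ModelParams",
    "PopulationState",
    "ParamArrays",
    "validate_parameters",
    "scaled_measure",
]

#: Named rules for rescaling the mutation probability with carrying capacity.
#: ``constant`` keeps mu as given; ``k_log_k`` uses mu_bar / (K * log K), the
#: regime in which O(1) mutations occur while a population grows by order K.
MU_SCALING_RULES = ("constant", "k_log_k")


# ---------------------------------------------------------------------------
# trait space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSpace:
    """Finite trait space: cancer (genotype, phenotype) pairs, T-cells, cytokines.

    Phenotype identifiers must be globally unique across genotypes, so a
    phenotype id doubles as the label of its cancer trait.
    """

    genotypes: tuple[str, ...]
    phenotypes_of: Mapping[str, tuple[str, ...]]
    tcell_types: tuple[str, ...] = ()
    cytokine_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(
            self,
            "phenotypes_of",
            {g: tuple(ps) for g, ps in self.phenotypes_of.items()},
        )
        object.__setattr__(self, "tcell_types", tuple(self.tcell_types))
        object.__setattr__(self, "cytokine_types", tuple(self.cytokine_types))

    # -- canonical ordering -------------------------------------------------

    @property
    def cancer_pairs(self) -> list[tuple[str, str]]:
        """(genotype, phenotype) pairs in canonical order."""
        return [(g, p) for g in self.genotypes for p in self.phenotypes_of.get(g, ())]

    @property
    def phenotypes(self) -> list[str]:
        return [p for _, p in self.cancer_pairs]

    @property
    def labels(self) -> list[str]:
        """All trait labels in canonical order (phenotypes, T-cells, cytokines)."""
        return self.phenotypes + list(self.tcell_types) + list(self.cytokine_types)

    @property
    def n_cancer(self) -> int:
        return len(self.cancer_pairs)

    @property
    def n_tcell(self) -> int:
        return len(self.tcell_types)

    @property
    def n_cytokine(self) -> int:
        return len(self.cytokine_types)

    @property
    def n_traits(self) -> int:
        return self.n_cancer + self.n_tcell + self.n_cytokine

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def genotype_of(self, phenotype: str) -> str | None:
        for g, ps in self.phenotypes_of.items():
            if phenotype in ps:
                return g
        return None


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


def _float_dict(d: Mapping | None) -> dict:
    return {k: float(v) for k, v in (d or {}).items()}


@dataclass
class CancerParams:
    """Rates and kernels of the cancer-cell class.

    All rates are per day; interaction coefficients are per day per unit of
    scaled density (counts / K).  Missing kernel entries are zero.

    b, d           natural birth / death rate per phenotype
    c              death-increasing competition kernel (p, p')
    c_b            birth-reducing competition kernel (p, p'); any excess of
                   the reduction beyond the birth rate acts as extra death
    t_kill         therapy kernel (p, z): kill rate by T-cells of type z
    kill_burst     (p, z, w): cytokines of type w released per kill, integer
    s_nat          natural phenotype switch kernel (p, p'), same genotype only
    s_cyt          cytokine-induced switch kernel (w, p, p'), same genotype
    mu             per-genotype probability that a birth is a mutation
    m_law          mutation law: (g, p) -> {(g', p') -> prob}, no self-mass
    """

    b: dict = field(default_factory=dict)
    d: dict = field(default_factory=dict)
    c: dict = field(default_factory=dict)
    c_b: dict = field(default_factory=dict)
    t_kill: dict = field(default_factory=dict)
    kill_burst: dict = field(default_factory=dict)
    s_nat: dict = field(default_factory=dict)
    s_cyt: dict = field(default_factory=dict)
    mu: dict = field(default_factory=dict)
    m_law: dict = field(default_factory=dict)


@dataclass
class TCellParams:
    """T-cell rates: natural birth/death plus prey-dependent reproduction.

    d_T is an effective death rate folding in exhaustion.  t_prod (z, p) is
    the extra reproduction rate per unit scaled density of prey phenotype p;
    rep_burst (z, w) cytokines are released at each reproduction event.
    """

    b_T: dict = field(default_factory=dict)
    d_T: dict = field(default_factory=dict)
    t_prod: dict = field(default_factory=dict)
    rep_burst: dict = field(default_factory=dict)


@dataclass
class CytokineParams:
    """Cytokine decay rates; molecules are produced only at kill/reproduction."""

    d_W: dict = field(default_factory=dict)


@dataclass
class ModelParams:
    """Complete parameter set: trait space, kernels, and carrying capacity K."""

    space: TraitSpace
    cancer: CancerParams = field(default_factory=CancerParams)
    tcells: TCellParams = field(default_factory=TCellParams)
    cytokines: CytokineParams = field(default_factory=CytokineParams)
    K: int = 1
    mu_scaling: str = "constant"

    def effective_mu(self, genotype: str) -> float:
        """Mutation probability for a genotype after applying the K-scaling rule."""
        mu = float(self.cancer.mu.get(genotype, 0.0))
        if self.mu_scaling == "k_log_k":
            if self.K < 3:
                raise ValueError("k_log_k scaling requires K >= 3")
            mu = mu / (self.K * math.log(self.K))
        return min(mu, 1.0)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready dict with stable key ordering (canonical trait order)."""

        def enc(d: Mapping) -> dict:
            out = {}
            for k in sorted(d, key=repr):
                v = d[k]
                key = "|".join(k) if isinstance(k, tuple) else str(k)
                out[key] = enc(v) if isinstance(v, Mapping) else v
            return out

        return {
            "space": {
                "genotypes": list(self.space.genotypes),
                "phenotypes_of": {g: list(ps) for g, ps in self.space.phenotypes_of.items()},
                "tcell_types": list(self.space.tcell_types),
                "cytokine_types": list(self.space.cytokine_types),
            },
            "cancer": {k: enc(getattr(self.cancer, k)) for k in (
                "b", "d", "c", "c_b", "t_kill", "kill_burst", "s_nat", "s_cyt", "mu", "m_law")},
            "tcells": {k: enc(getattr(self.tcells, k)) for k in (
                "b_T", "d_T", "t_prod", "rep_burst")},
            "cytokines": {"d_W": enc(self.cytokines.d_W)},
            "K": int(self.K),
            "mu_scaling": self.mu_scaling,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParams":
        def dec(d: Mapping) -> dict:
            out = {}
            for key, v in d.items():
                k = tuple(key.split("|")) if "|" in key else key
                out[k] = dec(v) if isinstance(v, Mapping) else v
            return out

        sp = data["space"]
        space = TraitSpace(
            genotypes=tuple(sp["genotypes"]),
            phenotypes_of={g: tuple(ps) for g, ps in sp["phenotypes_of"].items()},
            tcell_types=tuple(sp.get("tcell_types", ())),
            cytokine_types=tuple(sp.get("cytokine_types", ())),
        )
        ca = data.get("cancer", {})
        # m_law decodes to {(g,p): {(g',p'): prob}}
        m_law = {}
        for key, row in dec(ca.get("m_law", {})).items():
            m_law[key] = row
        cancer = CancerParams(
            b=dec(ca.get("b", {})), d=dec(ca.get("d", {})),
            c=dec(ca.get("c", {})), c_b=dec(ca.get("c_b", {})),
            t_kill=dec(ca.get("t_kill", {})), kill_burst=dec(ca.get("kill_burst", {})),
            s_nat=dec(ca.get("s_nat", {})), s_cyt=dec(ca.get("s_cyt", {})),
            mu=dec(ca.get("mu", {})), m_law=m_law,
        )
        tc = data.get("tcells", {})
        tcells = TCellParams(
            b_T=dec(tc.get("b_T", {})), d_T=dec(tc.get("d_T", {})),
            t_prod=dec(tc.get("t_prod", {})), rep_burst=dec(tc.get("rep_burst", {})),
        )
        cyt = CytokineParams(d_W=dec(data.get("cytokines", {}).get("d_W", {})))
        return cls(space=space, cancer=cancer, tcells=tcells, cytokines=cyt,
                   K=int(data.get("K", 1)), mu_scaling=data.get("mu_scaling", "constant"))

    def fingerprint(self) -> str:
        """Stable hash of the parameter set (used in trajectory sidecars)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def compile(self, K: int | None = None) -> "ParamArrays":
        return ParamArrays.from_params(self, K=K)


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------


@dataclass
class PopulationState:
    """Integer individual counts per trait at a time point (time in days)."""

    time: float
    counts: dict

    @classmethod
    def from_vector(cls, time: float, vec: Sequence[int], space: TraitSpace) -> "PopulationState":
        return cls(time=float(time), counts={lab: int(n) for lab, n in zip(space.labels, vec)})

    def as_vector(self, space: TraitSpace) -> np.ndarray:
        return np.array([int(self.counts.get(lab, 0)) for lab in space.labels], dtype=np.int64)

    def total(self) -> int:
        return int(sum(self.counts.values()))


def scaled_measure(state: PopulationState, K: int) -> dict:
    """Scaled measure: counts divided by the carrying capacity K."""
    if K <= 0:
        raise ValueError(f"invalid carrying capacity K={K}; must be >= 1")
    return {lab: n / K for lab, n in state.counts.items()}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_nonneg(report: list, d: Mapping, path: str, integer: bool = False) -> None:
    for k, v in d.items():
        if not np.isfinite(v) or v < 0:
            report.append(f"{path}[{k!r}]: must be finite and >= 0, got {v}")
        elif integer and int(v) != v:
            report.append(f"{path}[{k!r}]: must be an integer count, got {v}")


def validate_parameters(params: ModelParams) -> list[str]:
    """Check every structural constraint; return a list of violations (empty = valid).

    Violations are data, not exceptions: each entry names the offending path.
    """
    report: list[str] = []
    sp = params.space

    # --- trait space -------------------------------------------------------
    if not sp.genotypes:
        report.append("space.genotypes: empty")
    for name, seq in (("genotypes", sp.genotypes), ("tcell_types", sp.tcell_types),
                      ("cytokine_types", sp.cytokine_types)):
        if len(set(seq)) != len(seq):
            report.append(f"space.{name}: duplicate identifiers")
    for g in sp.genotypes:
        ps = sp.phenotypes_of.get(g, ())
        if not ps:
            report.append(f"space.phenotypes_of[{g!r}]: genotype has no phenotypes")
        if len(set(ps)) != len(ps):
            report.append(f"space.phenotypes_of[{g!r}]: duplicate phenotypes")
    for g in sp.phenotypes_of:
        if g not in sp.genotypes:
            report.append(f"space.phenotypes_of[{g!r}]: unknown genotype")
    phenos = sp.phenotypes
    if len(set(phenos)) != len(phenos):
        report.append("space: phenotype identifiers must be unique across genotypes")
    labels = sp.labels
    if len(set(labels)) != len(labels):
        report.append("space: trait labels collide across classes")

    pheno_set = set(phenos)
    z_set = set(sp.tcell_types)
    w_set = set(sp.cytokine_types)
    pairs = set(sp.cancer_pairs)
    geno_of = {p: g for g, ps in sp.phenotypes_of.items() for p in ps}

    ca = params.cancer
    # --- simple non-negativity ---------------------------------------------
    for attr in ("b", "d", "c", "c_b", "t_kill", "s_nat", "s_cyt"):
        _check_nonneg(report, getattr(ca, attr), f"cancer.{attr}")
    _check_nonneg(report, ca.kill_burst, "cancer.kill_burst", integer=True)
    _check_nonneg(report, params.tcells.b_T, "tcells.b_T")
    _check_nonneg(report, params.tcells.d_T, "tcells.d_T")
    _check_nonneg(report, params.tcells.t_prod, "tcells.t_prod")
    _check_nonneg(report, params.tcells.rep_burst, "tcells.rep_burst", integer=True)
    _check_nonneg(report, params.cytokines.d_W, "cytokines.d_W")

    # --- keys on declared traits --------------------------------------------
    for attr in ("b", "d"):
        for p in getattr(ca, attr):
            if p not in pheno_set:
                report.append(f"cancer.{attr}[{p!r}]: unknown phenotype")
    for attr in ("c", "c_b"):
        for key in getattr(ca, attr):
            if not (isinstance(key, tuple) and len(key) == 2 and set(key) <= pheno_set):
                report.append(f"cancer.{attr}[{key!r}]: key must be a (phenotype, phenotype) pair")
    for key in ca.t_kill:
        if not (isinstance(key, tuple) and len(key) == 2
                and key[0] in pheno_set and key[1] in z_set):
            report.append(f"cancer.t_kill[{key!r}]: key must be (phenotype, tcell_type)")
    for key in ca.kill_burst:
        if not (isinstance(key, tuple) and len(key) == 3 and key[0] in pheno_set
                and key[1] in z_set and key[2] in w_set):
            report.append(f"cancer.kill_burst[{key!r}]: key must be (phenotype, tcell, cytokine)")
    for key in params.tcells.t_prod:
        if not (isinstance(key, tuple) and len(key) == 2
                and key[0] in z_set and key[1] in pheno_set):
            report.append(f"tcells.t_prod[{key!r}]: key must be (tcell_type, phenotype)")
    for key in params.tcells.rep_burst:
        if not (isinstance(key, tuple) and len(key) == 2
                and key[0] in z_set and key[1] in w_set):
            report.append(f"tcells.rep_burst[{key!r}]: key must be (tcell_type, cytokine)")
    for z in params.tcells.b_T:
        if z not in z_set:
            report.append(f"tcells.b_T[{z!r}]: unknown T-cell type")
    for z in params.tcells.d_T:
        if z not in z_set:
            report.append(f"tcells.d_T[{z!r}]: unknown T-cell type")
    for w in params.cytokines.d_W:
        if w not in w_set:
            report.append(f"cytokines.d_W[{w!r}]: unknown cytokine")

    # --- switch kernels: same genotype, no diagonal --------------------------
    for key, val in ca.s_nat.items():
        if not (isinstance(key, tuple) and len(key) == 2 and set(key) <= pheno_set):
            report.append(f"cancer.s_nat[{key!r}]: key must be a (phenotype, phenotype) pair")
            continue
        p, q = key
        if p == q and val != 0:
            report.append(f"cancer.s_nat[{key!r}]: diagonal switch entries must be absent or zero")
        elif p != q and geno_of.get(p) != geno_of.get(q):
            report.append(f"cancer.s_nat[{key!r}]: switching never changes genotype")
    for key, val in ca.s_cyt.items():
        if not (isinstance(key, tuple) and len(key) == 3 and key[0] in w_set
                and key[1] in pheno_set and key[2] in pheno_set):
            report.append(f"cancer.s_cyt[{key!r}]: key must be (cytokine, phenotype, phenotype)")
            continue
        _, p, q = key
        if p == q and val != 0:
            report.append(f"cancer.s_cyt[{key!r}]: diagonal switch entries must be absent or zero")
        elif p != q and geno_of.get(p) != geno_of.get(q):
            report.append(f"cancer.s_cyt[{key!r}]: switching never changes genotype")

    # --- mutation probability and law ----------------------------------------
    for g, mu in ca.mu.items():
        if g not in sp.genotypes:
            report.append(f"cancer.mu[{g!r}]: unknown genotype")
        elif not (0.0 <= mu <= 1.0):
            report.append(f"cancer.mu[{g!r}]: must lie in [0, 1], got {mu}")
    for src, row in ca.m_law.items():
        if src not in pairs:
            report.append(f"cancer.m_law[{src!r}]: source is not a declared (genotype, phenotype)")
            continue
        total = 0.0
        for dst, prob in row.items():
            if dst not in pairs:
                report.append(f"cancer.m_law[{src!r}][{dst!r}]: target not in trait space")
                continue
            if prob < 0:
                report.append(f"cancer.m_law[{src!r}][{dst!r}]: negative probability")
            if dst == src and prob != 0:
                report.append(f"cancer.m_law[{src!r}]: self-mutation mass must be zero")
            total += prob
        if abs(total - 1.0) > 1e-9:
            report.append(f"cancer.m_law[{src!r}]: row sums to {total}, expected 1")
    for g in sp.genotypes:
        if ca.mu.get(g, 0.0) > 0:
            for p in sp.phenotypes_of.get(g, ()):
                if (g, p) not in ca.m_law:
                    report.append(
                        f"cancer.m_law: missing row for ({g!r}, {p!r}) though mu[{g!r}] > 0")

    # --- scalar parameters ----------------------------------------------------
    if params.K < 1:
        report.append(f"K: must be a positive integer, got {params.K}")
    if params.mu_scaling not in MU_SCALING_RULES:
        report.append(f"mu_scaling: unknown rule {params.mu_scaling!r}; "
                      f"expected one of {MU_SCALING_RULES}")
    return report


# ---------------------------------------------------------------------------
# dense array compilation (engine-facing)
# ---------------------------------------------------------------------------


@dataclass
class ParamArrays:
    """Dense numpy view of ModelParams over the canonical trait ordering.

    Index layout: cancer traits 0..nc-1, T-cells nc..nc+nz-1, cytokines after.
    Mutation probabilities are per cancer trait (inherited from the genotype,
    after the mu_scaling rule); ``m_cum`` holds cumulative mutation-law rows.
    """

    labels: list
    nc: int
    nz: int
    nw: int
    K: int
    b: np.ndarray
    d: np.ndarray
    c: np.ndarray
    cb: np.ndarray
    tkill: np.ndarray        # (nc, nz)
    kburst: np.ndarray       # (nc, nz, nw) int64
    snat: np.ndarray         # (nc, nc) source -> destination
    scyt: np.ndarray         # (nw, nc, nc)
    mu: np.ndarray           # (nc,)
    m_cum: np.ndarray        # (nc, nc) cumulative rows
    bT: np.ndarray
    dT: np.ndarray
    tprod: np.ndarray        # (nz, nc)
    rburst: np.ndarray       # (nz, nw) int64
    dW: np.ndarray
    genotype_id: np.ndarray  # (nc,) int

    @property
    def n(self) -> int:
        return self.nc + self.nz + self.nw

    @classmethod
    def from_params(cls, params: ModelParams, K: int | None = None) -> "ParamArrays":
        sp = params.space
        K = int(params.K if K is None else K)
        if K < 1:
            raise ValueError(f"invalid carrying capacity K={K}")
        pairs = sp.cancer_pairs
        phenos = [p for _, p in pairs]
        nc, nz, nw = len(pairs), sp.n_tcell, sp.n_cytokine
        pi = {p: i for i, p in enumerate(phenos)}
        zi = {z: i for i, z in enumerate(sp.tcell_types)}
        wi = {w: i for i, w in enumerate(sp.cytokine_types)}
        pair_i = {pair: i for i, pair in enumerate(pairs)}
        ca = params.cancer

        b = np.array([ca.b.get(p, 0.0) for p in phenos], dtype=float)
        d = np.array([ca.d.get(p, 0.0) for p in phenos], dtype=float)
        c = np.zeros((nc, nc))
        cb = np.zeros((nc, nc))
        for (p, q), v in ca.c.items():
            c[pi[p], pi[q]] = v
        for (p, q), v in ca.c_b.items():
            cb[pi[p], pi[q]] = v
        tkill = np.zeros((nc, nz))
        for (p, z), v in ca.t_kill.items():
            tkill[pi[p], zi[z]] = v
        kburst = np.zeros((nc, nz, nw), dtype=np.int64)
        for (p, z, w), v in ca.kill_burst.items():
            kburst[pi[p], zi[z], wi[w]] = int(v)
        snat = np.zeros((nc, nc))
        for (p, q), v in ca.s_nat.items():
            snat[pi[p], pi[q]] = v
        np.fill_diagonal(snat, 0.0)
        scyt = np.zeros((nw, nc, nc))
        for (w, p, q), v in ca.s_cyt.items():
            scyt[wi[w], pi[p], pi[q]] = v

        # per-trait mutation probability and cumulative law rows
        eff_params = ModelParams(space=sp, cancer=ca, tcells=params.tcells,
                                 cytokines=params.cytokines, K=K,
                                 mu_scaling=params.mu_scaling)
        mu = np.array([eff_params.effective_mu(g) for g, _ in pairs], dtype=float)
        m = np.zeros((nc, nc))
        for src, row in ca.m_law.items():
            if src in pair_i:
                for dst, prob in row.items():
                    if dst in pair_i:
                        m[pair_i[src], pair_i[dst]] = prob
        m_cum = np.cumsum(m, axis=1)

        tc = params.tcells
        bT = np.array([tc.b_T.get(z, 0.0) for z in sp.tcell_types], dtype=float)
        dT = np.array([tc.d_T.get(z, 0.0) for z in sp.tcell_types], dtype=float)
        tprod = np.zeros((nz, nc))
        for (z, p), v in tc.t_prod.items():
            tprod[zi[z], pi[p]] = v
        rburst = np.zeros((nz, nw), dtype=np.int64)
        for (z, w), v in tc.rep_burst.items():
            rburst[zi[z], wi[w]] = int(v)
        dW = np.array([params.cytokines.d_W.get(w, 0.0) for w in sp.cytokine_types],
                      dtype=float)
        geno_index = {g: i for i, g in enumerate(sp.genotypes)}
        genotype_id = np.array([geno_index[g] for g, _ in pairs], dtype=np.int64)

        return cls(labels=sp.labels, nc=nc, nz=nz, nw=nw, K=K, b=b, d=d, c=c, cb=cb,
                   tkill=tkill, kburst=kburst, snat=snat, scyt=scyt, mu=mu,
                   m_cum=m_cum, bT=bT, dT=dT, tprod=tprod, rburst=rburst, dW=dW,
                   genotype_id=genotype_id)
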