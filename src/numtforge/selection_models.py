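"""Maximum-likelihood codon substitution models on a fixed tree.

The engine is the Goldman-Yang (GY94) family: a reversible Markov chain over
the sense codons of a genetic code (61 under the standard code, 60 under the
vertebrate mitochondrial code) in which single-nucleotide changes occur at
rate proportional to the target codon frequency, multiplied by kappa for
transitions and by omega = dN/dS for nonsynonymous changes.  On top of that
engine the module implements the model suite used to interrogate selection on
a numt-resident gene:

==================  =============================================================
one_ratio           one omega for the whole tree
two_ratio           separate omega for numt-clade vs background branches
two_ratio_fixed     numt omega fixed to 1 (neutral numt evolution)
M1a                 site classes: purifying (0<omega<1) + neutral (omega=1)
M2a                 M1a plus a positive-selection class (omega>=1)
cladeC              3 site classes; the third has independent omegas per
                    branch partition (clade model C)
cladeC_fixed        cladeC with the numt omega of the divergent class fixed to 1
==================  =============================================================

Log-likelihoods are computed by Felsenstein pruning with per-node scaling;
transition matrices come from the eigendecomposition of the symmetrised
generator.  Nested models are compared with chi-square likelihood ratio tests.

Scaling convention: every site-class generator is normalised to one expected
substitution per codon per unit branch length under its own stationary
distribution, so branch lengths read as substitutions/codon in all classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .phylo import NUMT, TreeNode
from .seqio_codes import GeneticCode, VERTEBRATE_MITO_CODE

__all__ = [
    "CodonModelSpec",
    "ModelParams",
    "CodonMSA",
    "FitResult",
    "LRTResult",
    "MODEL_KINDS",
    "build_rate_matrix",
    "log_likelihood",
    "fit",
    "lrt",
]

logger = logging.getLogger(__name__)

MODEL_KINDS = (
    "one_ratio",
    "two_ratio",
    "two_ratio_fixed",
    "M1a",
    "M2a",
    "cladeC",
    "cladeC_fixed",
)

# kinds whose likelihood depends on the numt/background branch partition
PARTITIONED_KINDS = {"two_ratio", "two_ratio_fixed", "cladeC", "cladeC_fixed"}

OMEGA_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (0.05, 100.0)
BL_BOUNDS = (1e-8, 20.0)


# ---------------------------------------------------------------------------
# codon-state machinery


class CodonStates:
    """Sense-codon state space of a genetic code with single-step topology."""

    _cache: dict = {}

    def __new__(cls, code: GeneticCode):
        key = code.name
        if key not in cls._cache:
            obj = super().__new__(cls)
            obj._build(code)
            cls._cache[key] = obj
        return cls._cache[key]

    def _build(self, code: GeneticCode):
        self.code = code
        self.codons = code.sense_codons
        self.n = len(self.codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        pairs_i, pairs_j, is_ts, is_syn = [], [], [], []
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diff = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diff) != 1:
                    continue
                pairs_i.append(i)
                pairs_j.append(j)
                is_ts.append(diff[0] in transitions)
                is_syn.append(code.table[ci] == code.table[cj])
        self.pi_idx = np.array(pairs_i)
        self.pj_idx = np.array(pairs_j)
        self.is_transition = np.array(is_ts, dtype=bool)
        self.is_synonymous = np.array(is_syn, dtype=bool)


def build_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs: np.ndarray,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
) -> np.ndarray:
    """GY94 generator over the sense codons, scaled to mean rate 1.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for single-nt
    neighbours, 0 for multi-nt changes; rows sum to zero.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    st = CodonStates(code)
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (st.n,) or not np.isclose(pi.sum(), 1.0):
        raise ValueError(f"codon_freqs must be a {st.n}-vector summing to 1")
    q = np.zeros((st.n, st.n))
    rate = pi[st.pj_idx].copy()
    rate[st.is_transition] *= kappa
    rate[~st.is_synonymous] *= omega
    q[st.pi_idx, st.pj_idx] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return q / mu


def _transition_matrix_factory(q: np.ndarray, pi: np.ndarray):
    """Closure t -> P(t) = exp(Qt) via the symmetrised eigendecomposition."""
    sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
    sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    sym = 0.5 * (sym + sym.T)
    lam, u = np.linalg.eigh(sym)
    left = u / sqrt_pi[:, None]   # D^{-1/2} U
    right = (u * sqrt_pi[:, None]).T  # U' D^{1/2}

    def pmat(t: float) -> np.ndarray:
        p = (left * np.exp(lam * t)) @ right
        np.maximum(p, 0.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    return pmat


# ---------------------------------------------------------------------------
# model specification and parameters


@dataclass(frozen=True)
class CodonModelSpec:
    """Which model of the suite to evaluate/fit, and under which code/freqs.

    ``freq_scheme`` is one of ``equal``, ``F1x4``, ``F3x4`` (codon frequencies
    taken as empirical functions of the alignment, codeml-style, never
    optimised).
    """

    kind: str
    code: GeneticCode = VERTEBRATE_MITO_CODE
    freq_scheme: str = "F3x4"

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; one of {MODEL_KINDS}")
        if self.freq_scheme not in ("equal", "F1x4", "F3x4"):
            raise ValueError("freq_scheme must be equal, F1x4 or F3x4")

    @property
    def n_site_classes(self) -> int:
        return {"M1a": 2, "M2a": 3, "cladeC": 3, "cladeC_fixed": 3}.get(self.kind, 1)

    @property
    def n_free_model_params(self) -> int:
        """Free parameters beyond kappa and branch lengths (for LRT df)."""
        return {
            "one_ratio": 1,
            "two_ratio": 2,
            "two_ratio_fixed": 1,
            "M1a": 2,
            "M2a": 4,
            "cladeC": 5,
            "cladeC_fixed": 4,
        }[self.kind]

    @property
    def uses_partition(self) -> bool:
        return self.kind in PARTITIONED_KINDS


@dataclass
class ModelParams:
    """Concrete parameter values: per-class proportions and omegas per partition."""

    kappa: float
    proportions: np.ndarray   # (K,)
    omega_background: np.ndarray  # (K,)
    omega_numt: np.ndarray        # (K,)

    def __post_init__(self):
        self.proportions = np.atleast_1d(np.asarray(self.proportions, float))
        self.omega_background = np.atleast_1d(np.asarray(self.omega_background, float))
        self.omega_numt = np.atleast_1d(np.asarray(self.omega_numt, float))
        if not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        if (self.proportions < 0).any():
            raise ValueError("class proportions must be non-negative")


def default_params(spec: CodonModelSpec) -> ModelParams:
    """Sensible starting values for each model kind."""
    k = 2.0
    if spec.kind == "one_ratio":
        return ModelParams(k, [1.0], [0.2], [0.2])
    if spec.kind == "two_ratio":
        return ModelParams(k, [1.0], [0.2], [0.5])
    if spec.kind == "two_ratio_fixed":
        return ModelParams(k, [1.0], [0.2], [1.0])
    if spec.kind == "M1a":
        return ModelParams(k, [0.7, 0.3], [0.1, 1.0], [0.1, 1.0])
    if spec.kind == "M2a":
        return ModelParams(k, [0.6, 0.3, 0.1], [0.1, 1.0, 2.0], [0.1, 1.0, 2.0])
    if spec.kind == "cladeC":
        return ModelParams(k, [0.5, 0.2, 0.3], [0.1, 1.0, 0.3], [0.1, 1.0, 1.5])
    if spec.kind == "cladeC_fixed":
        return ModelParams(k, [0.5, 0.2, 0.3], [0.1, 1.0, 0.3], [0.1, 1.0, 1.0])
    raise AssertionError(spec.kind)


@dataclass
class FitResult:
    spec: CodonModelSpec
    log_likelihood: float
    params: ModelParams
    tree: TreeNode  # with fitted branch lengths
    n_restarts: int
    converged: bool
    grad_norm: float

    @property
    def logL(self) -> float:
        return self.log_likelihood


@dataclass
class LRTResult:
    null_logL: float
    alt_logL: float
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class CodonMSA:
    """An in-frame multiple alignment of coding sequences (no gaps allowed)."""

    names: list
    seqs: list

    def __post_init__(self):
        if len(self.names) != len(self.seqs):
            raise ValueError("names/seqs length mismatch")
        lens = {len(s) for s in self.seqs}
        if len(lens) != 1:
            raise ValueError("all sequences must have equal length")
        (length,) = lens
        if length % 3:
            raise ValueError("alignment length must be divisible by 3")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def state_matrix(self, code: GeneticCode) -> np.ndarray:
        """(n_taxa, n_sites) integer states; -1 marks missing/untranslatable."""
        st = CodonStates(code)
        mat = np.full((len(self.seqs), self.n_codons), -1, dtype=np.int32)
        n_missing = 0
        for r, s in enumerate(self.seqs):
            for c in range(self.n_codons):
                codon = s[3 * c : 3 * c + 3]
                idx = st.index.get(codon, -1)
                if idx < 0:
                    n_missing += 1
                mat[r, c] = idx
        if n_missing:
            logger.info(
                "%d codon cells untranslatable under %s; treated as missing data",
                n_missing, code.name,
            )
        return mat

    def codon_frequencies(self, spec: CodonModelSpec) -> np.ndarray:
        st = CodonStates(spec.code)
        if spec.freq_scheme == "equal":
            return np.full(st.n, 1.0 / st.n)
        base_idx = {b: i for i, b in enumerate("ACGT")}
        if spec.freq_scheme == "F1x4":
            counts = np.zeros(4)
            for s in self.seqs:
                for b in s:
                    if b in base_idx:
                        counts[base_idx[b]] += 1
            f = counts / counts.sum()
            pi = np.array(
                [f[base_idx[c[0]]] * f[base_idx[c[1]]] * f[base_idx[c[2]]]
                 for c in st.codons]
            )
        else:  # F3x4
            counts = np.zeros((3, 4))
            for s in self.seqs:
                for i, b in enumerate(s):
                    if b in base_idx:
                        counts[i % 3, base_idx[b]] += 1
            f = counts / counts.sum(axis=1, keepdims=True)
            pi = np.array(
                [f[0, base_idx[c[0]]] * f[1, base_idx[c[1]]] * f[2, base_idx[c[2]]]
                 for c in st.codons]
            )
        pi = np.maximum(pi, 1e-10)
        return pi / pi.sum()


# ---------------------------------------------------------------------------
# likelihood


class _LikelihoodEngine:
    """Caches tree traversal order and site patterns for repeated evaluation."""

    def __init__(self, tree: TreeNode, msa: CodonMSA, spec: CodonModelSpec):
        leaf_names = tree.leaf_names()
        if sorted(leaf_names) != sorted(msa.names):
            raise ValueError("tree leaves and alignment taxa must coincide")
        if spec.uses_partition:
            classes = {b.branch_class for b in tree.branches()}
            if NUMT not in classes:
                raise ValueError(
                    f"model {spec.kind!r} needs at least one numt-labelled branch"
                )
        self.spec = spec
        self.states = CodonStates(spec.code)
        self.tree = tree
        self.pi = msa.codon_frequencies(spec)

        mat = msa.state_matrix(spec.code)
        order = {n: i for i, n in enumerate(msa.names)}
        mat = mat[[order[n] for n in leaf_names]]
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_taxa, n_patterns)
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        self.n_sites = mat.shape[1]

        self.postorder = [n for n in tree.postorder()]
        self.leaf_row = {id(n): i for i, n in enumerate(tree.leaves())}
        self.branch_nodes = tree.branches()

        # leaf partials are one-hot (missing -> all ones); precompute
        n = self.states.n
        self.leaf_partials = {}
        for node in tree.leaves():
            row = self.patterns[self.leaf_row[id(node)]]
            part = np.zeros((self.n_patterns, n))
            miss = row < 0
            part[np.arange(self.n_patterns)[~miss], row[~miss]] = 1.0
            part[miss] = 1.0
            self.leaf_partials[id(node)] = part

    def class_generators(self, params: ModelParams):
        """Per site class, (pmat_bg, pmat_numt) transition-matrix factories."""
        out = []
        cache = {}
        for k in range(len(params.proportions)):
            pair = []
            for w in (params.omega_background[k], params.omega_numt[k]):
                key = round(float(w), 12)
                if key not in cache:
                    q = build_rate_matrix(params.kappa, w, self.pi, self.spec.code)
                    cache[key] = _transition_matrix_factory(q, self.pi)
                pair.append(cache[key])
            out.append(tuple(pair))
        return out

    def _prune_class(self, pmat_bg, pmat_numt, lengths) -> np.ndarray:
        """log site-pattern likelihood vector for one site class."""
        log_scale = np.zeros(self.n_patterns)
        partial = {}
        for node in self.postorder:
            if node.is_leaf:
                partial[id(node)] = self.leaf_partials[id(node)]
                continue
            acc = None
            for child in node.children:
                t = lengths[id(child)]
                pm = pmat_numt(t) if child.branch_class == NUMT else pmat_bg(t)
                term = partial.pop(id(child)) @ pm.T
                acc = term if acc is None else acc * term
            mx = acc.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            acc /= mx[:, None]
            log_scale += np.log(mx)
            partial[id(node)] = acc
        root = partial[id(self.postorder[-1])]
        site_l = root @ self.pi
        return np.log(np.maximum(site_l, 1e-300)) + log_scale

    def log_likelihood(self, params: ModelParams, lengths=None) -> float:
        if lengths is None:
            lengths = {id(b): b.length for b in self.branch_nodes}
        gens = self.class_generators(params)
        logs = np.empty((len(gens), self.n_patterns))
        for k, (pb, pn) in enumerate(gens):
            logs[k] = self._prune_class(pb, pn, lengths)
        logp = np.log(np.maximum(params.proportions, 1e-300))[:, None]
        m = (logs + logp).max(axis=0)
        mix = m + np.log(np.exp(logs + logp - m).sum(axis=0))
        return float((mix * self.counts).sum())


def log_likelihood(
    tree: TreeNode, msa: CodonMSA, spec: CodonModelSpec, params: ModelParams
) -> float:
    """Felsenstein-pruning log-likelihood of the alignment under the model.

    Branch lengths are taken from the tree; the branch partition from each
    node's ``branch_class``.
    """
    return _LikelihoodEngine(tree, msa, spec).log_likelihood(params)


# ---------------------------------------------------------------------------
# fitting


class _Packer:
    """Maps the free parameters of a model kind to/from a bounded flat vector."""

    def __init__(self, spec: CodonModelSpec, n_branches: int):
        self.spec = spec
        self.n_branches = n_branches
        self.bounds = [(np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1]))]
        lo, hi = np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1])
        kind = spec.kind
        self.omega_slots = {
            "one_ratio": [("shared", (lo, hi))],
            "two_ratio": [("bg", (lo, hi)), ("numt", (lo, hi))],
            "two_ratio_fixed": [("bg", (lo, hi))],
            "M1a": [("w0", (lo, 0.0))],
            "M2a": [("w0", (lo, 0.0)), ("w2", (0.0, hi))],
            "cladeC": [("w0", (lo, 0.0)), ("wbg3", (lo, hi)), ("wnumt3", (lo, hi))],
            "cladeC_fixed": [("w0", (lo, 0.0)), ("wbg3", (lo, hi))],
        }[kind]
        self.bounds += [b for _, b in self.omega_slots]
        self.n_prop = {1: 0, 2: 1, 3: 2}[spec.n_site_classes]
        self.bounds += [(-12.0, 12.0)] * self.n_prop
        self.bounds += [(np.log(BL_BOUNDS[0]), np.log(BL_BOUNDS[1]))] * n_branches

    def pack(self, params: ModelParams, lengths: np.ndarray) -> np.ndarray:
        x = [np.log(params.kappa)]
        vals = {
            "shared": params.omega_background[0],
            "bg": params.omega_background[0],
            "numt": params.omega_numt[0],
            "w0": params.omega_background[0],
            "w2": params.omega_background[-1],
            "wbg3": params.omega_background[-1],
            "wnumt3": params.omega_numt[-1],
        }
        for name, (lo, hi) in self.omega_slots:
            x.append(np.clip(np.log(max(vals[name], 1e-6)), lo, hi))
        if self.n_prop:
            p = np.maximum(params.proportions, 1e-8)
            ref = np.log(p[-1])
            x += [np.clip(np.log(p[k]) - ref, -12, 12) for k in range(self.n_prop)]
        x += list(np.log(np.clip(lengths, *BL_BOUNDS)))
        return np.array(x)

    def unpack(self, x: np.ndarray):
        kappa = float(np.exp(x[0]))
        n_om = len(self.omega_slots)
        om = {name: float(np.exp(v)) for (name, _), v in zip(self.omega_slots, x[1 : 1 + n_om])}
        i = 1 + n_om
        logits = np.concatenate([x[i : i + self.n_prop], [0.0]])
        ex = np.exp(logits - logits.max())
        props = ex / ex.sum()
        i += self.n_prop
        lengths = np.exp(x[i:])
        kind = self.spec.kind
        if kind == "one_ratio":
            params = ModelParams(kappa, [1.0], [om["shared"]], [om["shared"]])
        elif kind == "two_ratio":
            params = ModelParams(kappa, [1.0], [om["bg"]], [om["numt"]])
        elif kind == "two_ratio_fixed":
            params = ModelParams(kappa, [1.0], [om["bg"]], [1.0])
        elif kind == "M1a":
            params = ModelParams(kappa, props, [om["w0"], 1.0], [om["w0"], 1.0])
        elif kind == "M2a":
            params = ModelParams(
                kappa, props, [om["w0"], 1.0, om["w2"]], [om["w0"], 1.0, om["w2"]]
            )
        elif kind == "cladeC":
            params = ModelParams(
                kappa, props, [om["w0"], 1.0, om["wbg3"]], [om["w0"], 1.0, om["wnumt3"]]
            )
        else:  # cladeC_fixed
            params = ModelParams(
                kappa, props, [om["w0"], 1.0, om["wbg3"]], [om["w0"], 1.0, 1.0]
            )
        return params, lengths


def fit(
    tree: TreeNode,
    msa: CodonMSA,
    spec: CodonModelSpec,
    n_restarts: int = 3,
    seed: int = 0,
    extra_starts: list | None = None,
    maxiter: int = 400,
) -> FitResult:
    """Fit the model by bounded quasi-Newton (L-BFGS-B) over kappa, omegas,
    class proportions (softmax) and all branch lengths, multi-start.

    ``extra_starts`` may carry (ModelParams, lengths-array) pairs, e.g. a
    nested null fit's solution, which guarantees the nesting inequality
    logL(alt) >= logL(null) up to optimizer tolerance.
    """
    engine = _LikelihoodEngine(tree, msa, spec)
    branch_nodes = engine.branch_nodes
    packer = _Packer(spec, len(branch_nodes))
    rng = np.random.default_rng(seed)

    init_lengths = np.array(
        [b.length if b.length > 0 else 0.05 for b in branch_nodes]
    )
    starts = [packer.pack(default_params(spec), init_lengths)]
    for _ in range(max(n_restarts - 1, 0)):
        jitter = rng.normal(0.0, 0.5, size=starts[0].shape)
        starts.append(starts[0] + jitter)
    for extra in extra_starts or []:
        p, lens = extra
        starts.append(packer.pack(p, lens))

    ids = [id(b) for b in branch_nodes]

    def negloglik(x):
        params, lengths = packer.unpack(x)
        ldict = dict(zip(ids, lengths))
        try:
            return -engine.log_likelihood(params, ldict)
        except (ValueError, FloatingPointError):
            return 1e12

    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in packer.bounds], [b[1] for b in packer.bounds])
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=packer.bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res

    params, lengths = packer.unpack(best.x)
    fitted_tree = tree.copy()
    for node, t in zip(fitted_tree.branches(), lengths):
        node.length = float(t)
    converged = bool(best.success) or best.fun < 1e11
    if not converged:
        logger.warning("fit(%s) did not converge: %s", spec.kind, best.message)
    return FitResult(
        spec=spec,
        log_likelihood=-float(best.fun),
        params=params,
        tree=fitted_tree,
        n_restarts=len(starts),
        converged=converged,
        grad_norm=float(np.abs(getattr(best, "jac", np.array([np.nan]))).max()),
    )


def fit_lengths(result: FitResult) -> np.ndarray:
    return np.array([b.length for b in result.tree.branches()])


def lrt(null_fit, alt_fit, df: int | None = None, tol: float = 0.05) -> LRTResult:
    """Likelihood ratio test of nested fits (or raw logL values).

    Accepts FitResult objects or plain floats.  The statistic 2(logL_alt -
    logL_null) is clamped at zero; an alternative worse than the null beyond
    ``tol`` log units raises, as that signals a broken nesting or a failed
    optimisation.
    """
    null_l = null_fit.log_likelihood if isinstance(null_fit, FitResult) else float(null_fit)
    alt_l = alt_fit.log_likelihood if isinstance(alt_fit, FitResult) else float(alt_fit)
    if df is None:
        if not (isinstance(null_fit, FitResult) and isinstance(alt_fit, FitResult)):
            raise ValueError("df must be given when fits are plain logL values")
        df = alt_fit.spec.n_free_model_params - null_fit.spec.n_free_model_params
    if df < 1:
        raise ValueError("df must be >= 1")
    if alt_l < null_l - tol:
        raise ValueError(
            f"nesting violated: alt logL {alt_l:.6f} < null logL {null_l:.6f}"
        )
    statistic = max(2.0 * (alt_l - null_l), 0.0)
    p = float(stats.chi2.sf(statistic, df))
    return LRTResult(null_logL=null_l, alt_logL=alt_l, statistic=statistic, df=df, p_value=p)
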