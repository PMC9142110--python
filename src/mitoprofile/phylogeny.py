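"""Concatenated-PCG maximum-likelihood phylogenetics under GTR+I+G.

The substitution model is the general time-reversible rate matrix with
stationary frequencies π, six exchangeabilities (GT fixed to 1 for
identifiability), a proportion of invariant sites p_inv, and gamma rate
heterogeneity discretized into k equal-probability categories represented by
their category means. The rate matrix is scaled so the expected substitution
rate is 1 across the whole I+G mixture, making branch lengths expected
substitutions per site.

Likelihoods are computed by Felsenstein pruning over unique site patterns
with per-pattern rescaling. Tree search is neighbor joining on
Jukes–Cantor distances followed by nearest-neighbor-interchange (NNI)
hill climbing; node support comes from nonparametric bootstrap resampling
of alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .align import Alignment, concatenate  # noqa: F401  (concatenate re-exported)
from .model import MitoError
from .tree import Node, Tree, collapse_short_branches

STATES = "ACGT"
_CODE = {b: i for i, b in enumerate(STATES)}
MISSING = 4
EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
#: distance assigned to saturated (p >= 0.75) sequence pairs
JC_SATURATION_CAP = 5.0


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class PhyloModel:
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    exch: np.ndarray = field(default_factory=lambda: np.ones(6))
    p_inv: float = 0.0
    alpha: float = 1.0
    k: int = 4

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exch = np.asarray(self.exch, dtype=float)
        if self.freqs.shape != (4,) or not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-8):
            raise MitoError("frequencies must be 4 values summing to 1")
        if self.exch.shape != (6,) or np.any(self.exch <= 0):
            raise MitoError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if not 0 <= self.p_inv < 1:
            raise MitoError("p_inv must lie in [0, 1)")
        if self.alpha <= 0:
            raise MitoError("gamma shape must be positive")
        self.exch = self.exch / self.exch[5]  # GT == 1

    # -- rate matrix ---------------------------------------------------
    def q_matrix(self) -> np.ndarray:
        """GTR generator normalized to mean rate 1 (before the I+G mixture)."""
        r = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(idx, self.exch):
            r[i, j] = r[j, i] = x
        q = r * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        return q / mu

    def category_rates(self) -> np.ndarray:
        """Mean rates of k equal-probability gamma categories (mean 1),
        scaled by 1/(1-p_inv) so the I+G mixture has mean rate 1."""
        a = self.alpha
        edges = special.gammaincinv(a, np.linspace(0, 1, self.k + 1)) / a
        cdf_ap1 = special.gammainc(a + 1, edges * a)
        rates = self.k * np.diff(cdf_ap1)
        rates = rates / rates.mean()
        return rates / (1.0 - self.p_inv)

    def eigensystem(self):
        q = self.q_matrix()
        sp = np.sqrt(self.freqs)
        b = (q * sp[:, None]) / sp[None, :]
        b = (b + b.T) / 2  # clean symmetrization noise
        w, u = np.linalg.eigh(b)
        left = u.T * sp[None, :]  # U^T D
        right = u / sp[:, None]  # D^-1 U
        return w, right, left

    def copy(self) -> "PhyloModel":
        return PhyloModel(self.freqs.copy(), self.exch.copy(), self.p_inv, self.alpha, self.k)


def transition_matrix(eig, t: float) -> np.ndarray:
    w, right, left = eig
    p = (right * np.exp(w * t)[None, :]) @ left
    return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# alignment encoding
# ---------------------------------------------------------------------------


def encode_alignment(aln: Alignment) -> tuple[list[str], np.ndarray]:
    taxa = aln.taxa
    mat = np.empty((len(taxa), aln.length), dtype=np.int8)
    for r, t in enumerate(taxa):
        mat[r] = [_CODE.get(b, MISSING) for b in aln[t]]
    return taxa, mat


def compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return patterns, weights.astype(float)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class _LikelihoodEngine:
    """Pruning likelihood over fixed patterns; model/eigensystem cached."""

    def __init__(self, aln: Alignment, model: PhyloModel):
        self.model = model
        self.taxa, mat = encode_alignment(aln)
        self.patterns, self.weights = compress_patterns(mat)
        self.nsites = aln.length
        self._leaf_cache: dict[str, np.ndarray] = {}
        self.refresh_model()
        # invariant-site term: pi of the shared state, when one exists
        npat = self.patterns.shape[1]
        self.inv_term = np.zeros(npat)
        for p in range(npat):
            col = self.patterns[:, p]
            obs = set(col[col != MISSING])
            if len(obs) == 1:
                self.inv_term[p] = model.freqs[obs.pop()]
            elif len(obs) == 0:
                self.inv_term[p] = 1.0

    def refresh_model(self) -> None:
        self.eig = self.model.eigensystem()
        self.rates = self.model.category_rates()
        self._leaf_cache.clear()

    def _leaf_partial(self, taxon: str) -> np.ndarray:
        if taxon not in self._leaf_cache:
            row = self.patterns[self.taxa.index(taxon)]
            part = np.zeros((row.size, 4))
            obs = row != MISSING
            part[np.arange(row.size)[obs], row[obs]] = 1.0
            part[~obs] = 1.0
            self._leaf_cache[taxon] = part
        return self._leaf_cache[taxon]

    def loglik(self, tree: Tree) -> float:
        k = self.model.k
        npat = self.patterns.shape[1]
        logscale = np.zeros(npat)
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                partials[id(node)] = np.broadcast_to(
                    self._leaf_partial(node.name), (k, npat, 4)
                )
                continue
            part = np.ones((k, npat, 4))
            for child in node.children:
                cp = partials.pop(id(child))
                for c in range(k):
                    p = transition_matrix(self.eig, self.rates[c] * max(child.length, 0.0))
                    part[c] *= cp[c] @ p.T
            scale = part.max(axis=(0, 2))
            scale = np.where(scale > 0, scale, 1.0)
            part /= scale[None, :, None]
            logscale += np.log(scale)
            partials[id(node)] = part
        root = partials[id(tree.root)]
        var = (root * self.model.freqs[None, None, :]).sum(axis=2).mean(axis=0)
        p_inv = self.model.p_inv
        with np.errstate(divide="ignore"):
            log_var = np.log((1.0 - p_inv) * var) + logscale
            if p_inv > 0:
                log_inv = np.where(
                    self.inv_term > 0, np.log(p_inv * self.inv_term), -np.inf
                )
                log_site = np.logaddexp(log_var, log_inv)
            else:
                log_site = log_var
        if np.any(~np.isfinite(log_site)):
            raise MitoError("site likelihood underflow despite scaling")
        return float(log_site @ self.weights)


def loglik(tree: Tree, aln: Alignment, model: PhyloModel) -> float:
    """Log-likelihood of an alignment on a tree under GTR+I+G."""
    _check_taxa(tree, aln)
    return _LikelihoodEngine(aln, model).loglik(tree)


def _check_taxa(tree: Tree, aln: Alignment) -> None:
    if set(tree.taxa()) != set(aln.taxa):
        raise MitoError("tree taxa and alignment taxa differ")


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


def jc_distance(a: str, b: str) -> float:
    """Jukes–Cantor distance with pairwise deletion of gap/N sites; mismatch
    fractions at or beyond the p=3/4 singularity return a saturation cap."""
    if len(a) != len(b):
        raise MitoError("sequences differ in length")
    diff = comparable = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in STATES and y in STATES:
            comparable += 1
            diff += x != y
    if comparable == 0:
        raise MitoError("no comparable sites")
    p = diff / comparable
    if p >= 0.75:
        return JC_SATURATION_CAP
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def distance_matrix(aln: Alignment) -> tuple[list[str], np.ndarray]:
    taxa = aln.taxa
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(aln[taxa[i]], aln[taxa[j]])
    return taxa, d


def nj(dist: np.ndarray, taxa: list[str]) -> Tree:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to 0."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or not np.allclose(dist, dist.T):
        raise MitoError("distance matrix must be square and symmetric")
    if np.any(np.diag(dist) != 0):
        raise MitoError("distance matrix diagonal must be zero")
    n = len(taxa)
    if n < 3:
        raise MitoError("neighbor joining needs >= 3 taxa")
    nodes = [Node(t) for t in taxa]
    d = dist.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.add(nodes[i])
        parent.add(nodes[j])
        new = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(nodes)] = new
        d[: len(nodes), -1] = new
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    i, j, k = active
    root = Node()
    nodes[i].length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    for x in (i, j, k):
        root.add(nodes[x])
    return Tree(root)


def nj_tree(aln: Alignment) -> Tree:
    taxa, d = distance_matrix(aln)
    return nj(d, taxa)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def _optimize_branch_lengths(engine: _LikelihoodEngine, tree: Tree, xatol: float = 1e-3) -> float:
    best = engine.loglik(tree)
    for node in tree.postorder():
        if node is tree.root:
            continue
        x0 = node.length

        def nll(x: float) -> float:
            node.length = x
            return -engine.loglik(tree)

        res = optimize.minimize_scalar(
            nll, bounds=(1e-8, 10.0), method="bounded", options={"xatol": xatol, "maxiter": 16}
        )
        if -res.fun >= best:
            best = -res.fun
            node.length = float(res.x)
        else:  # keep the previous value on a failed line search
            node.length = x0
    return best


def _optimize_model(engine: _LikelihoodEngine, tree: Tree, optimize_exch: bool = True) -> float:
    model = engine.model

    def set_rates(z) -> None:
        model.alpha = float(np.clip(np.exp(z[0]), 1e-3, 1e4))
        model.p_inv = float(1 / (1 + np.exp(-z[1])))
        engine.refresh_model()

    def nll_rates(z) -> float:
        set_rates(z)
        return -engine.loglik(tree)

    z0 = [math.log(model.alpha), math.log(model.p_inv / (1 - model.p_inv)) if model.p_inv > 0 else -3.0]
    res = optimize.minimize(nll_rates, z0, method="Nelder-Mead",
                            options={"maxiter": 50, "xatol": 1e-3, "fatol": 1e-5})
    set_rates(res.x if -res.fun >= -nll_rates(z0) else z0)
    best = engine.loglik(tree)
    if optimize_exch:
        def set_exch(z) -> None:
            model.exch = np.append(np.exp(np.clip(z, -7, 7)), 1.0)
            engine.refresh_model()

        def nll_exch(z) -> float:
            set_exch(z)
            return -engine.loglik(tree)

        z0 = np.log(model.exch[:5])
        res = optimize.minimize(nll_exch, z0, method="Nelder-Mead",
                                options={"maxiter": 90, "xatol": 1e-3, "fatol": 1e-5})
        if -res.fun >= best:
            set_exch(res.x)
            best = -res.fun
        else:
            set_exch(z0)
    return best


def empirical_frequencies(aln: Alignment) -> np.ndarray:
    _, mat = encode_alignment(aln)
    counts = np.array([(mat == i).sum() for i in range(4)], dtype=float)
    counts = np.maximum(counts, 1.0)
    return counts / counts.sum()


@dataclass
class FitResult:
    tree: Tree
    model: PhyloModel
    loglik: float
    converged: bool
    rounds: int


def fit(
    tree: Tree,
    aln: Alignment,
    model: PhyloModel | None = None,
    tol: float = 1e-4,
    max_rounds: int = 12,
    optimize_exch: bool = True,
) -> FitResult:
    """Coordinate-ascent optimization of branch lengths and GTR+I+G
    parameters on a fixed topology. Stationary frequencies are empirical
    (+F). The accepted log-likelihood is non-decreasing per step; converged
    when a full round improves it by less than ``tol``."""
    _check_taxa(tree, aln)
    tree = tree.copy()
    if model is None:
        model = PhyloModel(freqs=empirical_frequencies(aln))
    else:
        model = model.copy()
    engine = _LikelihoodEngine(aln, model)
    best = engine.loglik(tree)
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        ll = _optimize_branch_lengths(engine, tree)
        ll = _optimize_model(engine, tree, optimize_exch=optimize_exch)
        if ll < best - 1e-9:
            raise MitoError("likelihood decreased during coordinate ascent")
        if ll - best < tol:
            best = ll
            converged = True
            break
        best = ll
    return FitResult(tree, model, best, converged, rounds)


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------


def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _nni_moves(tree: Tree) -> list[tuple[Node, Node, Node]]:
    """(edge child node v, inner child, outer sibling) triples; swapping the
    two rearranges around the internal edge parent(v)–v."""
    moves = []
    for v in tree.postorder():
        if v.is_leaf or v is tree.root:
            continue
        u = v.parent
        siblings = [c for c in u.children if c is not v]
        if u is tree.root and len(u.children) == 3:
            moves.extend((v, v.children[1], s) for s in siblings)
        elif siblings:
            s = siblings[0]
            moves.extend((v, child, s) for child in v.children)
    return moves


def nni_search(
    tree: Tree,
    aln: Alignment,
    model: PhyloModel,
    max_sweeps: int = 8,
    min_gain: float = 1e-3,
    engine: _LikelihoodEngine | None = None,
) -> tuple[Tree, float]:
    """NNI hill climbing: each candidate rearrangement is scored after
    re-optimizing the central edge; the best improving move is applied until
    a sweep yields no gain."""
    _check_taxa(tree, aln)
    tree = tree.copy()
    engine = engine or _LikelihoodEngine(aln, model)
    current = engine.loglik(tree)
    for _ in range(max_sweeps):
        best_gain = 0.0
        best_move = None
        for v, child, sib in _nni_moves(tree):
            old_len = v.length
            _swap_subtrees(child, sib)

            def nll(x: float) -> float:
                v.length = x
                return -engine.loglik(tree)

            res = optimize.minimize_scalar(
                nll, bounds=(1e-8, 10.0), method="bounded",
                options={"xatol": 1e-3, "maxiter": 16},
            )
            gain = -res.fun - current
            if gain > best_gain:
                best_gain = gain
                best_move = (v, child, sib, float(res.x))
            _swap_subtrees(child, sib)
            v.length = old_len
        if best_move is None or best_gain < min_gain:
            break
        v, child, sib, x = best_move
        _swap_subtrees(child, sib)
        v.length = x
        current = engine.loglik(tree)
    return tree, current


def search(
    aln: Alignment,
    model: PhyloModel | None = None,
    refit: bool = True,
    fit_rounds: int = 4,
) -> FitResult:
    """Full ML pipeline: NJ start tree, branch-length/model fit, NNI climb."""
    start = nj_tree(aln)
    result = fit(start, aln, model, max_rounds=fit_rounds)
    tree, ll = nni_search(result.tree, aln, result.model)
    if refit:
        result2 = fit(tree, aln, result.model, max_rounds=2, optimize_exch=False)
        if result2.loglik >= ll:
            collapse_short_branches(result2.tree, eps=1e-7)
            return FitResult(result2.tree, result2.model, result2.loglik, result2.converged, result2.rounds)
    collapse_short_branches(tree, eps=1e-7)
    return FitResult(tree, result.model, ll, True, 0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap(
    aln: Alignment,
    model: PhyloModel,
    b: int = 100,
    seed: int = 0,
    tree: Tree | None = None,
    nni: bool = True,
) -> Tree:
    """Nonparametric bootstrap: resample columns with replacement, re-run the
    tree search per replicate, and annotate each internal split of the
    reference tree with the percentage of replicates containing it."""
    if b < 1:
        raise MitoError("bootstrap needs B >= 1 replicates")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = search(aln, model).tree
    else:
        tree = tree.copy()
    ref_splits = tree.splits()
    if not ref_splits:
        raise MitoError("reference tree has no resolved internal splits (star-like)")
    counts = {s: 0 for s in ref_splits}
    taxa = aln.taxa
    seqs = [aln[t] for t in taxa]
    L = aln.length
    for _ in range(b):
        idx = rng.integers(0, L, size=L)
        rep = Alignment({t: "".join(s[i] for i in idx) for t, s in zip(taxa, seqs)})
        rep_tree = nj_tree(rep)
        if nni:
            rep_tree, _ = nni_search(rep_tree, rep, model, max_sweeps=3)
        rep_splits = rep_tree.splits()
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    _annotate_support(tree, {s: 100.0 * c / b for s, c in counts.items()})
    return tree


def _annotate_support(tree: Tree, support: dict[frozenset, float]) -> None:
    all_taxa = frozenset(tree.taxa())
    below: dict[int, frozenset] = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.name])
            continue
        below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
        side = below[id(n)]
        other = all_taxa - side
        if len(side) >= 2 and len(other) >= 2:
            key = side if side in support else other
            if key in support:
                n.support = support[key]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate(tree: Tree, model: PhyloModel, nsites: int, rng) -> Alignment:
    """Evolve site-independent sequences along the tree under the model:
    root drawn from π; a site is invariant with probability p_inv, else gets
    a gamma-category rate; no indels."""
    eig = model.eigensystem()
    cat_rates = model.category_rates()
    u = rng.random(nsites)
    site_rates = np.where(
        u < model.p_inv,
        0.0,
        cat_rates[rng.integers(0, model.k, size=nsites)],
    )
    distinct = np.unique(site_rates)
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, size=nsites, p=model.freqs)
    }
    order = tree.postorder()[::-1]  # preorder
    for node in order:
        for child in node.children:
            parent_state = states[id(node)]
            child_state = parent_state.copy()
            for r in distinct:
                mask = site_rates == r
                if r == 0.0 or not mask.any():
                    continue
                p = transition_matrix(eig, r * max(child.length, 0.0))
                cum = np.cumsum(p, axis=1)
                draws = rng.random(mask.sum())
                rows = cum[parent_state[mask]]
                child_state[mask] = (draws[:, None] > rows).sum(axis=1)
            states[id(child)] = child_state
    seqs = {}
    for leaf in tree.leaves():
        seqs[leaf.name] = "".join(STATES[s] for s in states[id(leaf)])
    return Alignment(seqs)
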