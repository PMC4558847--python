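"""Maximum-likelihood phylogenetic inference on fixed topologies.

Site likelihoods are computed with the pruning algorithm, mixing equally
over discrete-Γ rate categories and treating gaps (and unknown characters)
as missing data: a leaf with a gap contributes a partial-likelihood vector
of ones.  Alignment columns are compressed to unique site patterns.

Branch lengths are optimized jointly by L-BFGS-B using *analytic*
gradients obtained from inside/outside partial vectors: for an edge e with
inside vector U_e, outside vector F_e and per-category transition matrix
P_c(t), the per-site likelihood is F_eᵀ P_c U_e for every edge (the pulley
principle), and its derivative is r_c · F_eᵀ Q P_c U_e, which reuses the
already-computed P_c U_e.  The Γ shape and the GTR exchangeabilities, when
estimated, join the same optimization with central-difference gradient
components.  State frequencies are never optimized: following standard
practice they are taken from observed counts (or from the model itself).

Trees whose root has degree two are collapsed to the equivalent unrooted
form before fitting, since only the sum of the two root edges is
identifiable under a reversible model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .msa import GAP, Msa
from .substitution import (
    GTR_PAIRS,
    GammaRates,
    NT_ALPHABET,
    SubstitutionModel,
    discretize_gamma,
)
from .trees import Node, PhyloTree

#: Trees within this many log-likelihood units of the best share the win.
LNL_TIE_TOLERANCE = 1e-2

_BL_BOUNDS = (1e-9, 20.0)


class InputError(ValueError):
    pass


@dataclass
class FitResult:
    """Output of a (possibly optimization-free) likelihood evaluation."""

    log_likelihood: float
    per_site_log_likelihoods: np.ndarray
    tree: PhyloTree
    branch_lengths: dict          # sorted-leaf-tuple of child clade -> length
    model_estimates: dict         # e.g. {"gamma_shape": ..., "exchangeabilities": ...}
    frequencies: np.ndarray
    converged: bool = True
    n_iter: int = 0
    message: str = ""


@dataclass
class TopologyChoice:
    """Per-candidate weights under the equal-split tie rule."""

    weights: np.ndarray
    winners: list
    tolerance: float

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def observed_frequencies(msa: Msa, alphabet: str) -> np.ndarray:
    """Observed-count state frequencies; zero counts floored at 1e-6."""
    counts = np.zeros(len(alphabet))
    index = {ch: i for i, ch in enumerate(alphabet)}
    for row in msa.rows:
        for ch in row:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        raise InputError("alignment contains no characters from the alphabet")
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, 1e-6)
    return freqs / freqs.sum()


def _clade_key(node):
    if node.is_leaf:
        return (node.name,)
    return tuple(sorted(l.name for l in PhyloTree.leaves(_FakeTree(node))))


class _FakeTree:
    # minimal shim so PhyloTree.leaves/postorder logic can run on a subtree
    def __init__(self, root):
        self.root = root

    postorder = PhyloTree.postorder
    leaves = PhyloTree.leaves


def _unroot_if_degree_two(tree: PhyloTree) -> PhyloTree:
    tree = tree.copy()
    root = tree.root
    if len(root.children) != 2:
        return tree
    c1, c2 = root.children
    keep, merge = (c1, c2) if not c1.is_leaf else (c2, c1)
    merge.length = c1.length + c2.length
    keep.parent = None
    keep.add(merge)
    keep.length = 0.0
    return PhyloTree(keep)


class _Engine:
    """Pattern-compressed pruning likelihood with analytic branch gradients."""

    def __init__(self, msa: Msa, tree: PhyloTree, alphabet: str):
        named = [n for n in tree.postorder() if n.name in set(msa.taxa)]
        taxa = [n.name for n in named]
        if set(taxa) != set(msa.taxa) or len(
            [n for n in tree.postorder() if n.is_leaf]
        ) != len([n for n in named if n.is_leaf]):
            raise InputError("alignment taxa do not match tree leaves")
        self.alphabet = alphabet
        s = len(alphabet)
        index = {ch: i for i, ch in enumerate(alphabet)}
        mat = np.empty((len(taxa), msa.n_columns), dtype=np.int8)
        for r, t in enumerate(taxa):
            mat[r] = [index.get(ch, s) for ch in msa.row(t)]
        cols, inverse, counts = np.unique(
            mat.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = cols.T          # (ntaxa, npat)
        self.weights = counts.astype(float)
        self.inverse = inverse
        self.n_sites = msa.n_columns

        self.nodes = tree.postorder()   # root last
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root_index = len(self.nodes) - 1
        self.children = [
            [self.node_index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.leaf_row = {}
        for r, node in enumerate(named):
            self.leaf_row[self.node_index[id(node)]] = r
        self.tree = tree

    def branch_vector(self) -> np.ndarray:
        return np.array(
            [n.length for n in self.nodes[:-1]]
        )

    def set_branch_vector(self, t):
        for n, x in zip(self.nodes[:-1], t):
            n.length = float(x)

    def compute(self, t, model, rates, want_grad=False, want_sites=False):
        """Return (lnl, grad | None, per_site_lnl | None)."""
        s = model.n_states
        k = len(rates)
        m = self.patterns.shape[1]
        pi = model.frequencies
        w, right, left = model._eigen
        # per-edge, per-category transition matrices (augmented with a ones
        # column so a missing state gathers a vector of ones at leaves)
        P = np.empty((self.root_index, k, s, s))
        for e in range(self.root_index):
            te = max(float(t[e]), 0.0)
            for c in range(k):
                M = (right * np.exp(w * te * rates[c])[None, :]) @ left
                np.clip(M, 0.0, None, out=M)
                P[e, c] = M / M.sum(axis=1, keepdims=True)

        def indicator(v):
            chars = self.patterns[self.leaf_row[v]]
            E = np.zeros((s + 1, m))
            E[chars, np.arange(m)] = 1.0
            E[s] = 0.0
            E[:s, chars == s] = 1.0  # missing data: all states allowed
            return E[:s]

        A = [None] * self.root_index  # A[v] = P_v U_v, shape (k, s, m)
        U_root = None
        for v, node_children in enumerate(self.children):
            if not node_children and v in self.leaf_row:
                # plain leaf: gather from P augmented with a ones column
                chars = self.patterns[self.leaf_row[v]]
                Paug = np.concatenate([P[v], np.ones((k, s, 1))], axis=2)
                A[v] = Paug[:, :, chars]
                continue
            U = A[node_children[0]].copy()
            for c in node_children[1:]:
                U *= A[c]
            if v in self.leaf_row:  # labeled internal node (unrooted 2-taxon case)
                U *= indicator(v)[None, :, :]
            if v == self.root_index:
                U_root = U
                break
            Av = np.empty((k, s, m))
            for c in range(k):
                Av[c] = P[v, c] @ U[c]
            A[v] = Av

        Lc = np.einsum("x,kxm->km", pi, U_root)     # (k, m)
        site = Lc.mean(axis=0)                      # equal category probs
        site = np.maximum(site, 1e-300)
        log_site = np.log(site)
        lnl = float(self.weights @ log_site)

        per_site = log_site[self.inverse] if want_sites else None
        if not want_grad:
            return lnl, None, per_site

        Q = model.rate_matrix
        grad = np.zeros(self.root_index)
        # outside pass: O[v] per category, shape (k, s, m)
        O = [None] * len(self.nodes)
        O_root = np.broadcast_to(pi[None, :, None], (k, s, m))
        if self.root_index in self.leaf_row:
            O_root = O_root * indicator(self.root_index)[None, :, :]
        O[self.root_index] = O_root
        order = list(range(len(self.nodes) - 1, -1, -1))  # preorder
        for p in order:
            kids = self.children[p]
            if not kids:
                continue
            Op = O[p]
            n_kids = len(kids)
            # sibling products via prefix/suffix
            prefix = [None] * n_kids
            suffix = [None] * n_kids
            acc = None
            for i, cidx in enumerate(kids):
                prefix[i] = acc
                acc = A[cidx] if acc is None else acc * A[cidx]
            acc = None
            for i in range(n_kids - 1, -1, -1):
                suffix[i] = acc
                acc = A[kids[i]] if acc is None else A[kids[i]] * acc
            for i, v in enumerate(kids):
                F = Op
                if prefix[i] is not None:
                    F = F * prefix[i]
                if suffix[i] is not None:
                    F = F * suffix[i]
                # gradient: sum_c r_c/k * F·(Q A_v) ; likelihood check F·A_v
                QA = np.einsum("xy,kym->kxm", Q, A[v])
                num = np.einsum(
                    "kxm,kxm,k->m", F, QA, np.asarray(rates) / k
                )
                grad[v] = float(self.weights @ (num / site))
                if not self.nodes[v].is_leaf:
                    Ov = np.empty((k, s, m))
                    for c in range(k):
                        Ov[c] = P[v, c].T @ F[c]
                    if v in self.leaf_row:
                        Ov *= indicator(v)[None, :, :]
                    O[v] = Ov
            O[p] = None
        return lnl, grad, per_site


def _result_from_engine(eng, lnl, per_site, model, shape, exch, freqs,
                        converged=True, n_iter=0, message=""):
    tree = eng.tree
    branch = {}
    for n in tree.postorder():
        if n is tree.root:
            continue
        branch[_clade_key(n)] = n.length
    return FitResult(
        log_likelihood=lnl,
        per_site_log_likelihoods=per_site,
        tree=tree,
        branch_lengths=branch,
        model_estimates={"gamma_shape": shape, "exchangeabilities": exch},
        frequencies=freqs,
        converged=converged,
        n_iter=n_iter,
        message=message,
    )


def log_likelihood(
    msa: Msa,
    tree: PhyloTree,
    model: SubstitutionModel,
    gamma: GammaRates,
    frequencies=None,
) -> FitResult:
    """Likelihood at the tree's current branch lengths (no optimization).

    With ``frequencies=None`` the model's own stationary distribution is
    used; pass observed-count frequencies for a +F-style evaluation.
    """
    if frequencies is not None:
        model = model.with_frequencies(frequencies)
    eng = _Engine(msa, tree.copy(), model.alphabet)
    lnl, _, per_site = eng.compute(
        eng.branch_vector(), model, gamma.category_rates, want_sites=True
    )
    return _result_from_engine(
        eng, lnl, per_site, model, gamma.shape, None, model.frequencies
    )


def optimize_branch_lengths(
    msa: Msa,
    topology: PhyloTree,
    model: SubstitutionModel,
    gamma: GammaRates,
    estimate_shape: bool = True,
    estimate_exchangeabilities: bool = False,
    use_observed_frequencies: bool = True,
    start: float | None = None,
    max_iter: int = 500,
) -> FitResult:
    """ML branch lengths (and optionally Γ shape / GTR exchangeabilities).

    The topology is fixed; its current branch lengths seed the optimizer
    unless ``start`` gives a uniform starting length.  Non-convergence is
    reported on the result (``converged=False``), not raised.
    """
    if estimate_exchangeabilities and model.alphabet != NT_ALPHABET:
        raise InputError("exchangeability estimation is for nucleotide models")
    freqs = (
        observed_frequencies(msa, model.alphabet)
        if use_observed_frequencies
        else model.frequencies
    )
    base_exch = np.array(
        [model.exchangeabilities[i, j] for i, j in GTR_PAIRS]
    ) if model.alphabet == NT_ALPHABET else None

    work = _unroot_if_degree_two(topology)
    eng = _Engine(msa, work, model.alphabet)
    t0 = eng.branch_vector()
    if start is not None:
        t0 = np.full_like(t0, start)
    t0 = np.clip(t0, 1e-6, _BL_BOUNDS[1])
    nb = len(t0)

    aux_names = []
    aux0 = []
    if estimate_shape:
        aux_names.append("shape")
        aux0.append(np.log(gamma.shape))
    if estimate_exchangeabilities:
        for idx in (0, 2, 3, 4, 5):  # AG fixed to 1
            aux_names.append(f"r{idx}")
            aux0.append(np.log(base_exch[idx]))
    x0 = np.concatenate([t0, aux0])

    def unpack(x):
        t = x[:nb]
        pos = nb
        shape = gamma.shape
        exch = None
        if estimate_shape:
            shape = float(np.exp(x[pos]))
            pos += 1
        cur_model = model.with_frequencies(freqs)
        if estimate_exchangeabilities:
            r6 = base_exch.copy()
            for j, idx in enumerate((0, 2, 3, 4, 5)):
                r6[idx] = np.exp(x[pos + j])
            r6[1] = 1.0
            R = np.zeros((4, 4))
            for val, (i, jj) in zip(r6, GTR_PAIRS):
                R[i, jj] = R[jj, i] = val
            cur_model = SubstitutionModel(NT_ALPHABET, R, freqs)
            exch = r6
        rates = discretize_gamma(shape, gamma.ncat).category_rates
        return t, cur_model, rates, shape, exch

    cache = {}

    def value_and_grad(x):
        key = x.tobytes()
        if key in cache:
            return cache[key]
        t, cur_model, rates, shape, exch = unpack(x)
        lnl, gbr, _ = eng.compute(t, cur_model, rates, want_grad=True)
        g = np.empty_like(x)
        g[:nb] = -gbr
        h = 1e-4
        for j in range(nb, len(x)):
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            lp = eng.compute(*_eval_args(xp))[0]
            lm = eng.compute(*_eval_args(xm))[0]
            g[j] = -(lp - lm) / (2 * h)
        out = (-lnl, g)
        if len(cache) > 8:
            cache.clear()
        cache[key] = out
        return out

    def _eval_args(x):
        t, cur_model, rates, _, _ = unpack(x)
        return t, cur_model, rates

    bounds = [_BL_BOUNDS] * nb
    for name in aux_names:
        if name == "shape":
            bounds.append((np.log(0.02), np.log(100.0)))
        else:
            bounds.append((np.log(1e-4), np.log(1e4)))

    res = minimize(
        value_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    t, cur_model, rates, shape, exch = unpack(res.x)
    eng.set_branch_vector(t)
    lnl, _, per_site = eng.compute(t, cur_model, rates, want_sites=True)
    converged = bool(res.success) or "CONVERGENCE" in str(res.message).upper()
    return _result_from_engine(
        eng, lnl, per_site, cur_model, shape, exch, freqs,
        converged=converged, n_iter=int(res.nit), message=str(res.message),
    )


def select_topology(
    msa: Msa,
    candidates,
    model: SubstitutionModel,
    gamma: GammaRates,
    tolerance: float = LNL_TIE_TOLERANCE,
    **fit_kwargs,
):
    """Fit every candidate topology; split the win among likelihood ties.

    Candidates whose optimized log-likelihood is within ``tolerance``
    (default 0.01) of the maximum are weighted equally; the rest get zero.
    Returns ``(TopologyChoice, [FitResult, ...])``.
    """
    if len(candidates) < 1:
        raise InputError("at least one candidate topology required")
    fits = [
        optimize_branch_lengths(msa, cand, model, gamma, **fit_kwargs)
        for cand in candidates
    ]
    lnls = np.array([f.log_likelihood for f in fits])
    best = lnls.max()
    winners = [i for i in range(len(fits)) if best - lnls[i] <= tolerance]
    weights = np.zeros(len(fits))
    weights[winners] = 1.0 / len(winners)
    return TopologyChoice(weights, winners, tolerance), fits


# ---------------------------------------------------------------------------
# Fitch parsimony


def _binarize_root(tree: PhyloTree) -> PhyloTree:
    tree = tree.copy()
    root = tree.root
    while len(root.children) > 2:
        a = root.children.pop()
        b = root.children.pop()
        joint = Node(length=0.0)
        joint.add(a)
        joint.add(b)
        root.add(joint)
    return PhyloTree(tree.root)


def fitch_parsimony(msa: Msa, topology: PhyloTree) -> int:
    """Fitch count of state changes; gaps are missing (compatible with all)."""
    tree = _binarize_root(topology)
    eng = _Engine(msa, tree, _infer_alphabet(msa))
    s = len(eng.alphabet)
    full = (1 << s) - 1
    masks = {}
    changes = np.zeros(eng.patterns.shape[1], dtype=np.int64)
    def leaf_mask(v):
        chars = eng.patterns[eng.leaf_row[v]].astype(np.int64)
        return np.where(chars >= s, full, 1 << chars)

    for v, kids in enumerate(eng.children):
        if not kids:
            masks[v] = leaf_mask(v)
            continue
        mk = masks.pop(kids[0])
        rest = [masks.pop(c) for c in kids[1:]]
        if v in eng.leaf_row:  # labeled internal node (unrooted 2-taxon case)
            rest.append(leaf_mask(v))
        for other in rest:
            inter = mk & other
            union = mk | other
            miss = inter == 0
            changes += miss
            mk = np.where(miss, union, inter)
        masks[v] = mk
    return int(changes @ eng.weights.astype(np.int64))


def _infer_alphabet(msa: Msa) -> str:
    from .substitution import AA_ALPHABET

    chars = set("".join(msa.rows)) - {GAP}
    return NT_ALPHABET if chars <= set(NT_ALPHABET) else AA_ALPHABET


def mp_select(msa: Msa, candidates) -> TopologyChoice:
    """Most-parsimonious candidate(s); exact ties split equally."""
    scores = np.array([fitch_parsimony(msa, c) for c in candidates])
    best = scores.min()
    winners = [i for i in range(len(scores)) if scores[i] == best]
    weights = np.zeros(len(scores))
    weights[winners] = 1.0 / len(winners)
    return TopologyChoice(weights, winners, 0.0)
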