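"""Indel-aware sequence simulation with a recorded true alignment.

Sequences evolve down a tree under a reversible substitution model with
discrete-Γ among-site rates, plus a reversible indel process: insertions and
deletions each arise at ``rel_rate`` (default 0.05) times the substitution
rate per site, with truncated power-law (Zipf) lengths.  Substitutions are
applied exactly via the transition matrix between indel events of a
Gillespie walk along each branch, so there is no time-discretization error.

Every site carries a globally unique homology identifier; identifiers born
at the root or by insertion are threaded through the tree, which yields the
true alignment (each surviving identifier is one column) used as ground
truth by all downstream error metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, Msa
from .substitution import GammaRates, SubstitutionModel, transition_probs
from .trees import PhyloTree, write_newick


@dataclass(frozen=True)
class IndelParams:
    """Indel process parameters.

    ``rel_rate`` applies separately to insertions and to deletions, each
    relative to the (unit) substitution rate; ``length_shape`` is the Zipf
    exponent; ``max_length`` truncates lengths (20 aa / 60 nt in the study).
    """

    rel_rate: float = 0.05
    length_shape: float = 1.7
    max_length: int = 20

    def __post_init__(self):
        if self.rel_rate < 0:
            raise ValueError("rel_rate must be >= 0")
        if self.length_shape <= 1:
            raise ValueError("length_shape must exceed 1")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")

    @property
    def length_pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_length + 1, dtype=float)
        w = k ** (-self.length_shape)
        return w / w.sum()


def default_indel_params(alphabet_size: int) -> IndelParams:
    """Study defaults: truncation 20 for amino acids, 60 for nucleotides."""
    return IndelParams(max_length=60 if alphabet_size == 4 else 20)


NO_INDELS = IndelParams(rel_rate=0.0)


def sample_indel_length(params: IndelParams, rng: np.random.Generator) -> int:
    """One draw from the truncated Zipf length distribution, in [1, max]."""
    return int(rng.choice(params.max_length, p=params.length_pmf)) + 1


@dataclass
class _Seq:
    """A lineage's sequence: states, Γ categories and homology ids per site."""

    states: np.ndarray   # int8
    cats: np.ndarray     # int8
    ids: np.ndarray      # int64

    def __len__(self):
        return len(self.states)


class _ColumnOrder:
    """Global left-to-right order of homology columns (doubly linked list)."""

    _HEAD = -1

    def __init__(self, initial_ids):
        self.nxt = {}
        self.prv = {}
        prev = self._HEAD
        for i in initial_ids:
            self.nxt[prev] = i
            self.prv[i] = prev
            prev = int(i)
        self.nxt[prev] = None

    def insert_after(self, anchor, new_ids):
        """Insert ``new_ids`` (in order) right after column ``anchor``.

        ``anchor=-1`` inserts at the global left edge (used when an
        insertion lands before a lineage's first site and that site is the
        current global head; otherwise the caller anchors on the left
        neighbour's id).
        """
        prev = int(anchor)
        follower = self.nxt[prev]
        for i in new_ids:
            i = int(i)
            self.nxt[prev] = i
            self.prv[i] = prev
            prev = i
        self.nxt[prev] = follower
        if follower is not None:
            self.prv[follower] = prev

    def to_list(self):
        out = []
        cur = self.nxt[self._HEAD]
        while cur is not None:
            out.append(cur)
            cur = self.nxt[cur]
        return out


@dataclass
class TrueAlignedSim:
    """Simulation output: leaf sequences plus the recorded true alignment."""

    tree: PhyloTree
    sequences: dict            # taxon -> ungapped str
    alignment: Msa             # the true alignment (source="true")
    column_ids: list           # homology id per alignment column
    site_categories: dict      # homology id -> Γ category index
    root_length: int
    seed: int

    def homology_tsv(self) -> str:
        lines = ["column\thomology_id\tgamma_category"]
        for j, hid in enumerate(self.column_ids):
            lines.append(f"{j}\t{hid}\t{self.site_categories[hid]}")
        return "\n".join(lines) + "\n"

    def tree_newick(self) -> str:
        return write_newick(self.tree)


class _Evolver:
    def __init__(self, model, gamma, indels, rng):
        self.model = model
        self.gamma = gamma
        self.indels = indels
        self.rng = rng
        self.next_id = 0
        self.order = None
        self._length_pmf = indels.length_pmf if indels.rel_rate > 0 else None

    def fresh_ids(self, k):
        ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        return ids

    def root_sequence(self, length) -> _Seq:
        pi = self.model.frequencies
        states = self.rng.choice(self.model.n_states, size=length, p=pi).astype(np.int8)
        cats = self.rng.integers(self.gamma.ncat, size=length).astype(np.int8)
        ids = self.fresh_ids(length)
        self.order = _ColumnOrder(ids)
        return _Seq(states, cats, ids)

    def _substitute(self, seq: _Seq, dt: float):
        if dt <= 0 or len(seq) == 0:
            return
        u = self.rng.random(len(seq))
        for c, rate in enumerate(self.gamma.category_rates):
            mask = seq.cats == c
            if not mask.any():
                continue
            cum = np.cumsum(transition_probs(self.model, dt, rate), axis=1)
            rows = cum[seq.states[mask]]
            new = (u[mask, None] > rows).sum(axis=1)
            seq.states[mask] = np.minimum(new, self.model.n_states - 1).astype(np.int8)

    def _insert(self, seq: _Seq) -> _Seq:
        slot = int(self.rng.integers(len(seq) + 1))
        k = int(self.rng.choice(self.indels.max_length, p=self._length_pmf)) + 1
        states = self.rng.choice(
            self.model.n_states, size=k, p=self.model.frequencies
        ).astype(np.int8)
        cats = self.rng.integers(self.gamma.ncat, size=k).astype(np.int8)
        ids = self.fresh_ids(k)
        anchor = int(seq.ids[slot - 1]) if slot > 0 else self.order.prv[int(seq.ids[0])] if len(seq) else -1
        self.order.insert_after(anchor, ids)
        return _Seq(
            np.insert(seq.states, slot, states),
            np.insert(seq.cats, slot, cats),
            np.insert(seq.ids, slot, ids),
        )

    def _delete(self, seq: _Seq) -> _Seq:
        start = int(self.rng.integers(len(seq)))
        k = int(self.rng.choice(self.indels.max_length, p=self._length_pmf)) + 1
        stop = min(start + k, len(seq))
        keep = np.ones(len(seq), dtype=bool)
        keep[start:stop] = False
        return _Seq(seq.states[keep], seq.cats[keep], seq.ids[keep])

    def evolve_branch(self, parent: _Seq, branch_length: float) -> _Seq:
        """Evolve a copy of ``parent`` along one branch (Gillespie walk)."""
        seq = _Seq(parent.states.copy(), parent.cats.copy(), parent.ids.copy())
        if branch_length == 0:
            return seq
        remaining = branch_length
        rel = self.indels.rel_rate
        while True:
            total = 2.0 * rel * len(seq)
            dt = self.rng.exponential(1.0 / total) if total > 0 else np.inf
            if dt >= remaining:
                self._substitute(seq, remaining)
                return seq
            self._substitute(seq, dt)
            remaining -= dt
            if self.rng.random() < 0.5:
                seq = self._insert(seq)
            elif len(seq):
                seq = self._delete(seq)


def evolve_branch(
    parent_states,
    parent_cats,
    branch_length: float,
    model: SubstitutionModel,
    gamma: GammaRates,
    indels: IndelParams,
    rng: np.random.Generator,
):
    """Evolve one sequence along one branch.

    Returns ``(child_states, child_cats, homology_map)`` where
    ``homology_map[j]`` is the parent site index that child site ``j``
    descends from, or -1 for inserted sites.
    """
    ev = _Evolver(model, gamma, indels, rng)
    n = len(parent_states)
    ev.next_id = n
    parent = _Seq(
        np.asarray(parent_states, dtype=np.int8),
        np.asarray(parent_cats, dtype=np.int8),
        np.arange(n, dtype=np.int64),
    )
    ev.order = _ColumnOrder(parent.ids)
    child = ev.evolve_branch(parent, branch_length)
    hmap = np.where(child.ids < n, child.ids, -1)
    return child.states, child.cats, hmap


def simulate(
    tree: PhyloTree,
    model: SubstitutionModel,
    gamma: GammaRates,
    indels: IndelParams,
    root_length: int,
    seed: int,
) -> TrueAlignedSim:
    """Simulate sequences on ``tree`` and record the true alignment.

    The root sequence is drawn from the stationary distribution with
    uniform Γ-category assignments; each branch is evolved independently
    given its parent.  Reproducible for a given seed.
    """
    if root_length < 1:
        raise ValueError("root_length must be >= 1")
    rng = np.random.default_rng(seed)
    ev = _Evolver(model, gamma, indels, rng)
    seqs = {}

    def walk(node, seq):
        if node.is_leaf:
            seqs[node.name] = seq
            return
        for child in node.children:
            walk(child, ev.evolve_branch(seq, child.length))

    walk(tree.root, ev.root_sequence(root_length))

    taxa = [leaf.name for leaf in tree.leaves()]
    present = set()
    for s in seqs.values():
        present.update(s.ids.tolist())
    column_ids = [i for i in ev.order.to_list() if i in present]
    col_index = {hid: j for j, hid in enumerate(column_ids)}
    alphabet = model.alphabet
    rows = []
    for t in taxa:
        row = [GAP] * len(column_ids)
        s = seqs[t]
        for st, hid in zip(s.states, s.ids):
            row[col_index[hid]] = alphabet[st]
        rows.append("".join(row))
    cats = {}
    for s in seqs.values():
        for hid, c in zip(s.ids.tolist(), s.cats.tolist()):
            cats[hid] = c
    alignment = Msa(taxa, rows, source="true")
    sequences = {t: r.replace(GAP, "") for t, r in zip(taxa, rows)}
    return TrueAlignedSim(
        tree=tree,
        sequences=sequences,
        alignment=alignment,
        column_ids=column_ids,
        site_categories=cats,
        root_length=root_length,
        seed=seed,
    )
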