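"""A self-contained progressive multiple sequence aligner.

This is a deliberately transparent stand-in for the progressive MSA tools
whose downstream effects the package studies: k-mer distances feed a
neighbor-joining (or UPGMA) guide tree, and profiles are merged leaf-to-root
by pairwise profile–profile global alignment with affine gap penalties
("once a gap, always a gap").  Substitution scores are log-odds derived from
the same substitution-model family used for simulation, evaluated at a
reference distance.  It is not a replica of any published tool.

An adapter for external command-line aligners is also provided; nothing in
the package requires it.
"""

from __future__ import annotations

import io
import os
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .msa import GAP, Msa
from .substitution import SubstitutionModel, transition_probs
from .trees import PhyloTree, read_newick

__all__ = [
    "AlignerConfig",
    "AlignerError",
    "kmer_distance_matrix",
    "build_guide_tree",
    "progressive_align",
    "extract_subalignment",
    "external_align",
]


class AlignerError(RuntimeError):
    pass


@dataclass
class AlignerConfig:
    """Configuration of the builtin aligner.

    ``k`` defaults to 6 for nucleotides and 3 for amino acids; scores are
    integer log-odds (×10) from the model at reference distance 1.0.
    """

    model: SubstitutionModel
    k: int | None = None
    gap_open: float = -11.0
    gap_extend: float = -1.0
    guide_method: str = "nj"
    reference_distance: float = 1.0

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.k is None:
            self.k = 6 if self.model.n_states == 4 else 3
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.guide_method not in ("nj", "upgma"):
            raise ValueError("guide_method must be 'nj' or 'upgma'")

    @property
    def score_matrix(self) -> np.ndarray:
        P = transition_probs(self.model, self.reference_distance)
        pi = self.model.frequencies
        return np.round(10.0 * np.log(P / pi[None, :]))


def kmer_distance_matrix(seqs: dict, k: int) -> tuple:
    """Shared-k-mer distances: d = 1 − common/(min(len) − k + 1).

    Common k-mers are counted as multisets.  Returns (names, matrix).
    """
    names = list(seqs)
    for n in names:
        if len(seqs[n]) < k:
            raise AlignerError(f"sequence {n!r} shorter than k={k}")
    counters = {
        n: Counter(seqs[n][i : i + k] for i in range(len(seqs[n]) - k + 1))
        for n in names
    }
    D = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            common = sum((counters[a] & counters[b]).values())
            denom = min(len(seqs[a]), len(seqs[b])) - k + 1
            D[i, j] = D[j, i] = 1.0 - common / denom
    return names, D


def build_guide_tree(names, dist, method: str = "nj") -> PhyloTree:
    """Guide tree from a distance matrix (NJ default, or UPGMA).

    Negative NJ branch lengths are clamped to zero; ties break
    deterministically by input taxon order.
    """
    dist = np.asarray(dist, float)
    if dist.shape != (len(names), len(names)) or not np.allclose(dist, dist.T):
        raise AlignerError("distance matrix must be symmetric over the taxa")
    if len(names) == 2:
        from .trees import Node

        r = Node()
        r.add(Node(names[0], dist[0, 1] / 2))
        r.add(Node(names[1], dist[0, 1] / 2))
        return PhyloTree(r)
    if method == "nj":
        from skbio import DistanceMatrix
        from skbio.tree import nj as _nj

        tn = _nj(DistanceMatrix(dist, ids=list(names)))
        buf = io.StringIO()
        tn.write(buf)
        tree = read_newick(buf.getvalue().strip())
    elif method == "upgma":
        from scipy.cluster.hierarchy import average, to_tree
        from scipy.spatial.distance import squareform

        Z = average(squareform(dist, checks=False))
        root = to_tree(Z)
        from .trees import Node

        def conv(cn, parent_height):
            if cn.is_leaf():
                return Node(names[cn.id], parent_height)
            node = Node(length=parent_height - cn.dist / 2)
            node.add(conv(cn.left, cn.dist / 2))
            node.add(conv(cn.right, cn.dist / 2))
            return node

        r = Node()
        for ch in (root.left, root.right):
            r.add(conv(ch, root.dist / 2))
        tree = PhyloTree(r)
    else:
        raise AlignerError(f"unknown guide method {method!r}")
    for node in tree.postorder():
        if node.length < 0:
            node.length = 0.0
    return tree


@njit(cache=False)
def _affine_dp(S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    """Gotoh affine-gap global alignment over a column-score matrix.

    Returns traceback instructions as an array of moves
    (0 = diagonal, 1 = gap in second profile, 2 = gap in first profile),
    reversed, plus the optimal score.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in profile b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in profile a (consume b)
    TM = np.zeros((n + 1, m + 1), dtype=np.int8)
    TX = np.zeros((n + 1, m + 1), dtype=np.int8)
    TY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        TX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        TY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[i - 1, j - 1]
            best = M[i - 1, j - 1]
            tb = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                tb = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                tb = 2
            M[i, j] = best + s
            TM[i, j] = tb
            ox = M[i - 1, j] + gap_open
            ex = X[i - 1, j] + gap_extend
            if ox >= ex:
                X[i, j] = ox
                TX[i, j] = 0
            else:
                X[i, j] = ex
                TX[i, j] = 1
            oy = M[i, j - 1] + gap_open
            ey = Y[i, j - 1] + gap_extend
            if oy >= ey:
                Y[i, j] = oy
                TY[i, j] = 0
            else:
                Y[i, j] = ey
                TY[i, j] = 2
    # traceback
    moves = np.empty(n + m, dtype=np.int8)
    nmov = 0
    i, j = n, m
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    while i > 0 or j > 0:
        if state == 0:
            prev = TM[i, j]
            moves[nmov] = 0
            nmov += 1
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            prev = TX[i, j]
            moves[nmov] = 1
            nmov += 1
            i -= 1
            state = 0 if prev == 0 else 1
        else:
            prev = TY[i, j]
            moves[nmov] = 2
            nmov += 1
            j -= 1
            state = 0 if prev == 0 else 2
    return moves[:nmov], score


class _Profile:
    __slots__ = ("taxa", "rows", "freqs")

    def __init__(self, taxa, rows, freqs):
        self.taxa = taxa
        self.rows = rows
        self.freqs = freqs  # (ncol, nstates) residue freqs; gap mass excluded


def _profile_from_rows(taxa, rows, index, s):
    ncol = len(rows[0])
    F = np.zeros((ncol, s))
    for row in rows:
        for j, ch in enumerate(row):
            i = index.get(ch)
            if i is not None:
                F[j, i] += 1.0
    return _Profile(taxa, rows, F / len(rows))


def _merge(pa: _Profile, pb: _Profile, M, gap_open, gap_extend, index, s):
    S = (pa.freqs @ M) @ pb.freqs.T
    moves, score = _affine_dp(S, gap_open, gap_extend)
    moves = moves[::-1]
    rows_a = ["".join(_thread(r, moves, (0, 1))) for r in pa.rows]
    rows_b = ["".join(_thread(r, moves, (0, 2))) for r in pb.rows]
    taxa = pa.taxa + pb.taxa
    rows = rows_a + rows_b
    return _profile_from_rows(taxa, rows, index, s), score


def _thread(row, moves, consuming):
    out = []
    pos = 0
    for mv in moves:
        if mv in consuming:
            out.append(row[pos])
            pos += 1
        else:
            out.append(GAP)
    return out


def progressive_align(
    seqs: dict,
    config: AlignerConfig,
    guide_tree: PhyloTree | None = None,
):
    """Progressive profile–profile alignment of ``seqs``.

    Without a guide tree, one is estimated from k-mer distances.  Returns
    ``(Msa, guide_tree_used)``; fully deterministic for a given input.
    """
    if len(seqs) < 2:
        raise AlignerError("at least two sequences required")
    if guide_tree is None:
        names, D = kmer_distance_matrix(seqs, config.k)
        guide_tree = build_guide_tree(names, D, config.guide_method)
    alphabet = config.model.alphabet
    index = {ch: i for i, ch in enumerate(alphabet)}
    s = len(alphabet)
    M = config.score_matrix

    def build(node) -> _Profile:
        if node.is_leaf:
            return _profile_from_rows([node.name], [seqs[node.name]], index, s)
        prof = build(node.children[0])
        for child in node.children[1:]:
            prof, _ = _merge(
                prof, build(child), M, config.gap_open, config.gap_extend,
                index, s,
            )
        return prof

    prof = build(guide_tree.root)
    order = [t for t in seqs if t in prof.taxa]
    rows = [prof.rows[prof.taxa.index(t)] for t in order]
    keep = [j for j in range(len(rows[0])) if any(r[j] != GAP for r in rows)]
    rows = ["".join(r[j] for j in keep) for r in rows]
    return Msa(order, rows, source="builtin"), guide_tree


def pairwise_alignment_score(a: str, b: str, config: AlignerConfig) -> float:
    """Optimal affine-gap global alignment score of two sequences."""
    alphabet = config.model.alphabet
    index = {ch: i for i, ch in enumerate(alphabet)}
    s = len(alphabet)
    pa = _profile_from_rows(["a"], [a], index, s)
    pb = _profile_from_rows(["b"], [b], index, s)
    Smat = (pa.freqs @ config.score_matrix) @ pb.freqs.T
    _, score = _affine_dp(Smat, config.gap_open, config.gap_extend)
    return float(score)


def extract_subalignment(msa: Msa, taxa) -> Msa:
    """Rows restricted to ``taxa``; columns left all-gap are removed."""
    return msa.subset(list(taxa))


def external_align(seqs: dict, command_template: str, tool_name: str = "external") -> Msa:
    """Run an external aligner via a command template.

    The template must contain ``{in}`` and ``{out}`` placeholders for the
    input (unaligned FASTA) and output (aligned FASTA) paths.
    """
    if "{in}" not in command_template or "{out}" not in command_template:
        raise AlignerError("command template must contain {in} and {out}")
    from .msa import write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        inp = os.path.join(tmp, "in.fasta")
        out = os.path.join(tmp, "out.fasta")
        with open(inp, "w") as fh:
            fh.write(write_fasta(seqs))
        cmd = command_template.replace("{in}", inp).replace("{out}", out)
        try:
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
        except OSError as exc:
            raise AlignerError(f"failed to launch external aligner: {exc}")
        if proc.returncode != 0:
            raise AlignerError(
                f"external aligner failed (exit {proc.returncode}): {proc.stderr[:500]}"
            )
        if not os.path.exists(out):
            raise AlignerError("external aligner produced no output file")
        with open(out) as fh:
            text = fh.read()
    try:
        return Msa.from_fasta(text, source=f"external:{tool_name}")
    except ValueError as exc:
        raise AlignerError(f"unparseable aligner output: {exc}")
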