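"""Alignment error metrics based on pairwise homology statements.

An alignment is decomposed, for every ordered taxon pair (x, y), into one
statement per residue of x: either an *aligned pair* — residue i of x shares
a column with residue j of y (indices in the degapped sequences) — or a
*gap event* — residue i of x faces a gap in y, labeled by the index of y's
last residue before that column (so the label is invariant to padding
columns).  The symmetric difference of two alignments' statement sets,
normalized by the union, gives a d_ssp-style alignment distance: zero iff
the alignments assert identical homologies, symmetric, and sensitive to gap
placement.  Aligned-pair statements alone give sum-of-pairs true/false
positive and false negative scores against the true alignment.
"""

from __future__ import annotations

import numpy as np

from .msa import GAP, Msa

__all__ = [
    "homology_pairs",
    "msa_distance",
    "homology_scores",
    "alignment_length",
]


def _residue_maps(msa: Msa):
    """Per row: residue index at each column (-1 at gaps) and the index of
    the previous residue (-1 before the first)."""
    res_at = []
    prev_res = []
    for row in msa.rows:
        arr = np.fromiter((c != GAP for c in row), dtype=bool, count=len(row))
        csum = np.cumsum(arr)
        res_at.append(np.where(arr, csum - 1, -1))
        prev_res.append(csum - 1)  # at a gap column: index of last residue before it
    return res_at, prev_res


def homology_pairs(msa: Msa) -> set:
    """The alignment's full homology-statement set.

    Statements are tuples ``("p", x, y, i, j)`` for aligned pairs and
    ``("g", x, y, i, j_prev)`` for residue i of x opposite a gap in y.
    Every residue of x appears in exactly one statement per ordered pair.
    """
    res_at, prev_res = _residue_maps(msa)
    out = set()
    n = msa.n_taxa
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            x, y = msa.taxa[a], msa.taxa[b]
            ra, rb, pb = res_at[a], res_at[b], prev_res[b]
            mask = ra >= 0
            paired = rb >= 0
            for i, j in zip(ra[mask & paired], rb[mask & paired]):
                out.add(("p", x, y, int(i), int(j)))
            for i, j in zip(ra[mask & ~paired], pb[mask & ~paired]):
                out.add(("g", x, y, int(i), int(j)))
    return out


def _check_same_sequences(a: Msa, b: Msa):
    if set(a.taxa) != set(b.taxa):
        raise ValueError("alignments must cover the same taxa")
    da, db = a.degapped(), b.degapped()
    for t in a.taxa:
        if da[t] != db[t]:
            raise ValueError(f"degapped sequences differ for taxon {t!r}")


def msa_distance(a: Msa, b: Msa) -> float:
    """Symmetric-difference homology distance in [0, 1]; 0 iff identical."""
    _check_same_sequences(a, b)
    sa, sb = homology_pairs(a), homology_pairs(b)
    union = len(sa | sb)
    return len(sa ^ sb) / union if union else 0.0


def _aligned_pairs(msa: Msa) -> set:
    """Unordered aligned residue pairs {(x, i), (y, j)}."""
    res_at, _ = _residue_maps(msa)
    out = set()
    n = msa.n_taxa
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = res_at[a], res_at[b]
            both = (ra >= 0) & (rb >= 0)
            x, y = msa.taxa[a], msa.taxa[b]
            for i, j in zip(ra[both], rb[both]):
                out.add((x, int(i), y, int(j)))
    return out


def homology_scores(test: Msa, truth: Msa) -> dict:
    """Sum-of-pairs scores of ``test`` against the true alignment.

    Returns counts ``tp`` (shared aligned pairs), ``fp`` (asserted only by
    the test), ``fn`` (asserted only by the truth) and the rates
    ``spfn = fn/(tp+fn)`` and ``spfp = fp/(tp+fp)``.
    """
    _check_same_sequences(test, truth)
    pt, pr = _aligned_pairs(test), _aligned_pairs(truth)
    tp = len(pt & pr)
    fp = len(pt - pr)
    fn = len(pr - pt)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "spfn": fn / (tp + fn) if tp + fn else 0.0,
        "spfp": fp / (tp + fp) if tp + fp else 0.0,
    }


def alignment_length(msa: Msa) -> int:
    """Number of alignment columns."""
    return msa.n_columns
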