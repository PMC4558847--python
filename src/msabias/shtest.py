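"""RELL-based Shimodaira–Hasegawa test over candidate topologies.

The test asks, for each candidate tree k, whether its log-likelihood
deficit δ_k = lnL_max − lnL_k is larger than expected under the least
favourable null hypothesis that all candidates are equally good.  The null
distribution is built by RELL resampling: bootstrap site indices with
replacement, sum each candidate's per-site log-likelihoods, center each
candidate's replicate scores on its own replicate mean, and take the
distribution of centered maxima.  p_k is the fraction of replicates whose
null δ exceeds (≥, conservative) the observed δ_k; the ML tree always gets
p = 1 and can never be rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SHResult", "sh_test", "rejection_frequency"]


@dataclass
class SHResult:
    p_values: np.ndarray
    rejected: np.ndarray
    alpha: float
    n_bootstrap: int
    seed: int
    best_index: int


def sh_test(
    per_site_lnl,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SHResult:
    """SH test from a (candidates × sites) per-site log-likelihood matrix."""
    L = np.asarray(per_site_lnl, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 1:
        raise ValueError("need a (>=2 candidates, >=1 sites) matrix")
    K, m = L.shape
    totals = L.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals.max() - totals

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_bootstrap, m))
    boot = L[:, idx].sum(axis=2)              # (K, B)
    centered = boot - boot.mean(axis=1, keepdims=True)
    null_delta = centered.max(axis=0)[None, :] - centered  # (K, B)
    p = (null_delta >= delta[:, None]).mean(axis=1)
    return SHResult(
        p_values=p,
        rejected=p < alpha,
        alpha=alpha,
        n_bootstrap=n_bootstrap,
        seed=seed,
        best_index=best,
    )


def rejection_frequency(results, labels) -> dict:
    """Per-class rejection rates over many SH results.

    ``labels`` gives one class label per candidate (e.g. "LBA"/"non-LBA",
    shared across results).  Returns class -> fraction of candidate
    instances rejected.
    """
    if not results:
        raise ValueError("no results given")
    labels = list(labels)
    counts = {lab: 0 for lab in labels}
    totals = {lab: 0 for lab in labels}
    for res in results:
        if len(res.rejected) != len(labels):
            raise ValueError("result/label length mismatch")
        for lab, rej in zip(labels, res.rejected):
            totals[lab] += 1
            counts[lab] += bool(rej)
    return {lab: counts[lab] / totals[lab] for lab in totals}
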