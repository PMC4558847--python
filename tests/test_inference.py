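import itertools

import numpy as np
import pytest

import msabias as mb
from msabias.inference import InputError
from msabias.msa import Msa


def _oracle_4taxon(msa, tree_lens, model, gamma):
    """Exhaustive-enumeration likelihood for the unrooted quartet
    ((a,b)I, c, d) rooted at the trifurcation; gaps marginalized."""
    t_a, t_b, t_i, t_c, t_d = tree_lens
    alphabet = model.alphabet
    idx = {ch: i for i, ch in enumerate(alphabet)}
    s = len(alphabet)
    pi = model.frequencies
    total = 0.0
    for site in range(msa.n_columns):
        obs = {t: msa.row(t)[site] for t in msa.taxa}

        def leaf_vec(ch):
            if ch == "-":
                return np.ones(s)
            v = np.zeros(s)
            v[idx[ch]] = 1.0
            return v

        site_l = 0.0
        for rate, prob in zip(gamma.category_rates, gamma.category_probs):
            Pa = mb.transition_probs(model, t_a, rate)
            Pb = mb.transition_probs(model, t_b, rate)
            Pi = mb.transition_probs(model, t_i, rate)
            Pc = mb.transition_probs(model, t_c, rate)
            Pd = mb.transition_probs(model, t_d, rate)
            va, vb = leaf_vec(obs["a"]), leaf_vec(obs["b"])
            vc, vd = leaf_vec(obs["c"]), leaf_vec(obs["d"])
            acc = 0.0
            for x in range(s):
                inner = sum(
                    Pi[x, y] * (Pa[y] @ va) * (Pb[y] @ vb) for y in range(s)
                )
                acc += pi[x] * inner * (Pc[x] @ vc) * (Pd[x] @ vd)
            site_l += prob * acc
        total += np.log(site_l)
    return total


def test_two_taxon_closed_form(gtr, gamma1):
    msa = Msa(["a", "b"], ["ACGT", "AGGT"])
    tree = mb.read_newick("(a:0.1,b:0.3);")
    fit = mb.log_likelihood(msa, tree, gtr, gamma1)
    P = mb.transition_probs(gtr, 0.4)
    pi = gtr.frequencies
    idx = {c: i for i, c in enumerate("ACGT")}
    want = sum(
        np.log(pi[idx[x]] * P[idx[x], idx[y]])
        for x, y in zip("ACGT", "AGGT")
    )
    assert np.isclose(fit.log_likelihood, want, atol=1e-10)


def test_pruning_matches_exhaustive_oracle(gtr, gamma4):
    msa = Msa(
        ["a", "b", "c", "d"],
        ["ACG-TA", "A-GCTT", "GCGCT-", "ACACTA"],
    )
    tree = mb.read_newick("((a:0.12,b:0.27):0.09,c:0.31,d:0.18);")
    fit = mb.log_likelihood(msa, tree, gtr, gamma4)
    want = _oracle_4taxon(msa, (0.12, 0.27, 0.09, 0.31, 0.18), gtr, gamma4)
    assert np.isclose(fit.log_likelihood, want, atol=1e-9)
    assert np.isclose(fit.per_site_log_likelihoods.sum(), want, atol=1e-9)


def test_pulley_principle(gtr, gamma4):
    """Reversibility: the likelihood is invariant to root placement."""
    msa = Msa(["a", "b", "c", "d"], ["ACGT", "AGGT", "GCTT", "ACTA"])
    reps = [
        "((a:0.1,b:0.2):0.1,(c:0.3,d:0.25):0.05);",
        "((a:0.1,b:0.2):0.15,(c:0.3,d:0.25):0.0);",
        "((a:0.1,b:0.2):0.0,(c:0.3,d:0.25):0.15);",
        "(((a:0.1,b:0.2):0.15,c:0.3):0.125,d:0.125);",
        "((a:0.1,b:0.2):0.15,c:0.3,d:0.25);",
    ]
    lnls = [
        mb.log_likelihood(msa, mb.read_newick(nwk), gtr, gamma4).log_likelihood
        for nwk in reps
    ]
    assert np.allclose(lnls, lnls[0], atol=1e-9)


def test_optimize_recovers_branch_length(gtr, gamma1):
    tree = mb.read_newick("(a:0.25,b:0.25);")
    ts = mb.simulate(tree, gtr, gamma1, mb.NO_INDELS, 20000, seed=17)
    fit = mb.optimize_branch_lengths(
        ts.alignment, tree, gtr, gamma1,
        estimate_shape=False, use_observed_frequencies=False,
    )
    assert fit.converged
    total = sum(fit.branch_lengths.values())
    assert abs(total - 0.5) < 0.05 * 0.5


def test_optimize_improves_on_start(gtr, gamma4, small_sim):
    tree = mb.make_balanced_tree(2.0)
    start = mb.log_likelihood(small_sim.alignment, tree, gtr, gamma4)
    fit = mb.optimize_branch_lengths(small_sim.alignment, tree, gtr, gamma4)
    assert fit.log_likelihood >= start.log_likelihood - 1e-6
    assert fit.converged
    assert all(v >= 0 for v in fit.branch_lengths.values())
    assert fit.model_estimates["gamma_shape"] > 0


def test_joint_estimation_reports_exchangeabilities(gtr, gamma4):
    tree = mb.make_balanced_tree(2.0)
    ts = mb.simulate(tree, gtr, gamma4, mb.NO_INDELS, 500, seed=3)
    fit = mb.optimize_branch_lengths(
        ts.alignment, tree, gtr, gamma4,
        estimate_shape=True, estimate_exchangeabilities=True,
    )
    r = np.asarray(fit.model_estimates["exchangeabilities"])
    assert r.shape == (6,)
    assert np.isclose(r[1], 1.0)  # r_AG convention
    assert np.all(r > 0)


def test_select_topology_tie_splits_weight(gtr, gamma1):
    msa = Msa(["a", "b", "c", "d"], ["ACGT", "AGGT", "GCTT", "ACTA"])
    t1 = mb.read_newick("((a:0.1,b:0.1):0.05,c:0.1,d:0.1);")
    t2 = mb.read_newick("((a:0.1,b:0.1):0.05,d:0.1,c:0.1);")  # same unrooted tree
    t3 = mb.read_newick("((a:0.1,c:0.1):0.05,b:0.1,d:0.1);")
    choice, fits = mb.select_topology(msa, [t1, t2, t3], gtr, gamma1,
                                      estimate_shape=False)
    assert np.isclose(choice.weights.sum(), 1.0)
    assert np.isclose(choice.weights[0], choice.weights[1])
    assert len(fits) == 3


def _fitch_oracle(msa, tree):
    """Minimum changes by exhaustive assignment of internal-node states."""
    from msabias.inference import _infer_alphabet

    alphabet = _infer_alphabet(msa)
    nodes = tree.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    best_total = 0
    for site in range(msa.n_columns):
        best = np.inf
        for combo in itertools.product(alphabet, repeat=len(internal)):
            assign = dict(zip([id(n) for n in internal], combo))
            changes = 0
            for n in nodes:
                if n is tree.root:
                    continue
                obs_n = (
                    msa.row(n.name)[site] if n.is_leaf else assign[id(n)]
                )
                obs_p = (
                    assign[id(n.parent)]
                    if not n.parent.is_leaf
                    else msa.row(n.parent.name)[site]
                )
                if obs_n != "-" and obs_p != "-" and obs_n != obs_p:
                    changes += 1
            # gaps: treated as compatible with anything => never counted
            if "-" in [msa.row(n.name)[site] for n in nodes if n.is_leaf]:
                pass
            best = min(best, changes)
        best_total += best
    return best_total


def test_fitch_matches_exhaustive_oracle(gtr):
    msa = Msa(["a", "b", "c", "d"], ["ACG-T", "AGGTT", "GC-TA", "ACTTA"])
    tree = mb.read_newick("((a:1,b:1):1,c:1,d:1);")
    assert mb.fitch_parsimony(msa, tree) == _fitch_oracle(msa, tree)


def test_fitch_rerooting_invariance():
    msa = Msa(["a", "b", "c", "d"], ["ACGT", "AGGT", "GCTT", "ACTA"])
    reps = [
        "((a:1,b:1):1,c:1,d:1);",
        "((a:1,b:1):1,(c:1,d:1):1);",
        "(((a:1,b:1):1,c:1):1,d:1);",
    ]
    scores = {mb.fitch_parsimony(msa, mb.read_newick(nwk)) for nwk in reps}
    assert len(scores) == 1


def test_mp_lba_on_extreme_felsenstein_cell(gtr, gamma4):
    """Parsimony picks the long-branch pairing in the deep Felsenstein zone
    even on the true alignment (the classic inconsistency)."""
    cands, correct, lba = mb.felsenstein_candidates(0.025, 1.375, 0.025, 4)
    ts = mb.simulate(cands[correct], gtr, gamma4, mb.NO_INDELS, 3000, seed=8)
    choice = mb.mp_select(ts.alignment, cands)
    assert choice.weights[lba] > choice.weights[correct]


def test_input_validation(gtr, gamma4):
    msa = Msa(["a", "b"], ["ACGT", "AGGT"])
    tree = mb.read_newick("(a:0.1,c:0.1);")
    with pytest.raises(InputError):
        mb.log_likelihood(msa, tree, gtr, gamma4)


def test_observed_frequencies():
    msa = Msa(["a", "b"], ["AAC-", "A-CG"])
    f = mb.observed_frequencies(msa, "ACGT")
    assert np.isclose(f.sum(), 1.0)
    assert f[0] > f[1] > 0
    assert f[3] > 0  # floored, never exactly zero
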