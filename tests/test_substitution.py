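import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

import msabias as mb
from msabias.substitution import GTR_PAIRS, ParameterError, UnsupportedModelError


def rate_matrix_invariants(model):
    Q = model.rate_matrix
    pi = model.frequencies
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    # detailed balance: pi_x Q_xy == pi_y Q_yx
    assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)
    # mean substitution rate one at stationarity
    assert np.isclose(-(pi * np.diag(Q)).sum(), 1.0, atol=1e-12)


def test_gtr_invariants(gtr):
    rate_matrix_invariants(gtr)
    assert gtr.alphabet == "ACGT"
    # stored exchangeabilities honor the r_AG = 1 convention
    assert gtr.exchangeabilities[0, 2] == 1.0


def test_wag_invariants(wag):
    rate_matrix_invariants(wag)
    assert wag.alphabet == mb.AA_ALPHABET
    assert len(wag.alphabet) == 20
    # published WAG values: first exchangeability (A<->R) and frequency of A
    assert np.isclose(wag.exchangeabilities[1, 0], 0.551571)
    assert np.isclose(wag.frequencies[0], 0.0866279, atol=1e-6)


def test_study_gtr_matches_declared_parameters(gtr):
    for val, (i, j) in zip(mb.STUDY_GTR_EXCHANGEABILITIES, GTR_PAIRS):
        assert np.isclose(gtr.exchangeabilities[i, j], val)
    assert np.allclose(gtr.frequencies, mb.STUDY_GTR_FREQUENCIES)


def test_transition_probs_match_expm(gtr, wag):
    for model in (gtr, wag):
        for t in (0.01, 0.3, 2.5):
            P = mb.transition_probs(model, t)
            assert np.allclose(P, expm(model.rate_matrix * t), atol=1e-10)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)


def test_chapman_kolmogorov(gtr, wag):
    for model in (gtr, wag):
        P1 = mb.transition_probs(model, 0.4)
        P2 = mb.transition_probs(model, 0.9)
        P12 = mb.transition_probs(model, 1.3)
        assert np.allclose(P1 @ P2, P12, atol=1e-10)


def test_transition_probs_identity_and_stationary_limit(gtr):
    assert np.array_equal(mb.transition_probs(gtr, 0.0), np.eye(4))
    P = mb.transition_probs(gtr, 500.0)
    assert np.allclose(P, np.tile(gtr.frequencies, (4, 1)), atol=1e-8)


def test_jc_closed_form(jc):
    t = 0.7
    P = mb.transition_probs(jc, t)
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    expect = np.full((4, 4), diff)
    np.fill_diagonal(expect, same)
    assert np.allclose(P, expect, atol=1e-12)


@pytest.mark.parametrize("shape", [0.3, 1.0, 1.8, 5.0])
def test_discretize_gamma_against_quadrature(shape):
    g = mb.discretize_gamma(shape, 4)
    assert np.isclose((g.category_rates * g.category_probs).sum(), 1.0)
    edges = gamma_dist.ppf(np.linspace(0, 1, 5), a=shape, scale=1.0 / shape)
    for k in range(4):
        hi = edges[k + 1] if np.isfinite(edges[k + 1]) else np.inf
        num, _ = quad(
            lambda x: x * gamma_dist.pdf(x, a=shape, scale=1.0 / shape),
            edges[k], hi,
        )
        assert np.isclose(g.category_rates[k], num * 4, rtol=1e-6)
    assert np.all(np.diff(g.category_rates) > 0)


def test_discretize_gamma_single_category():
    g = mb.discretize_gamma(1.8, 1)
    assert g.category_rates.tolist() == [1.0]


def test_with_frequencies_plus_f(wag):
    freqs = np.full(20, 0.05)
    model = wag.with_frequencies(freqs)
    assert np.allclose(model.frequencies, freqs)
    rate_matrix_invariants(model)


def test_parameter_errors():
    with pytest.raises(ParameterError):
        mb.build_gtr([1, 1, 1, 1, 1], [0.25] * 4)
    with pytest.raises(ParameterError):
        mb.build_gtr([1, 1, 1, 1, 1, -2], [0.25] * 4)
    with pytest.raises(ParameterError):
        mb.build_gtr(np.ones(6), [0.3, 0.3, 0.3, 0.3])
    with pytest.raises(UnsupportedModelError):
        mb.build_empirical_aa("LG")
    with pytest.raises(ParameterError):
        mb.discretize_gamma(-1.0, 4)
    with pytest.raises(ParameterError):
        mb.transition_probs(mb.study_gtr_model(), -0.1)
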