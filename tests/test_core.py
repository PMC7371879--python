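"""Forward recursion, log-linear encoding, and the direct-recursion oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import softmax
from scipy.stats import multivariate_normal

import rllgmn as rl
from rllgmn.core import (
    ClassHMMGMM,
    HMMGMMParams,
    ModelShape,
    RLLGMNWeights,
    encode_hmm_gmm,
    expand_input,
    forward_pass,
    posterior_sequence,
    reference_forward,
)
from rllgmn.exceptions import InvalidParameterError
from conftest import random_theta, random_weights


def test_expand_input_worked_values():
    assert np.allclose(expand_input([2.0]), [1, 2, 4])
    assert np.allclose(expand_input([2.0, 3.0]), [1, 2, 3, 4, 6, 9])
    assert ModelShape(2, 1, 1, 4).H == 15
    with pytest.raises(InvalidParameterError):
        expand_input([np.nan])


def test_zero_weights_give_uniform_posteriors():
    sh = ModelShape(2, 2, 2, 3)
    w = RLLGMNWeights(sh, np.zeros(sh.weight_array_shape))
    post = posterior_sequence(np.random.default_rng(0).normal(size=(7, 3)), w)
    assert np.allclose(post, 0.5)


@given(st.integers(0, 10_000))
def test_probability_normalization_property(seed):
    """Layer-4 and layer-5 outputs are probability distributions at every step."""
    rng = np.random.default_rng(seed)
    C, K, M, d = 2, int(rng.integers(1, 4)), int(rng.integers(1, 4)), int(rng.integers(1, 4))
    sh = ModelShape(C, K, M, d)
    w = random_weights(rng, sh, scale=1.0)
    T = int(rng.integers(1, 12))
    tr = forward_pass(rng.normal(0, 1.5, (T, d)), w)
    assert np.max(np.abs(tr.o5.sum(axis=1) - 1.0)) <= 1e-9
    assert np.max(np.abs(tr.o4[1:].sum(axis=(1, 2)) - 1.0)) <= 1e-9
    assert np.all((tr.o4 >= 0) & (tr.o4 <= 1)) and np.all((tr.o5 >= 0) & (tr.o5 <= 1))


@given(st.integers(0, 10_000), st.floats(min_value=-50, max_value=50))
def test_shift_invariance_of_posteriors(seed, shift):
    """Adding a constant to every layer-2 pre-activation changes nothing."""
    rng = np.random.default_rng(seed)
    sh = ModelShape(2, 2, 2, 2)
    w = random_weights(rng, sh)
    seq = rng.normal(0, 1, (5, 2))
    w2 = w.copy()
    w2.w[..., 0] += shift  # constant term shifts every unit's pre-activation
    p1 = posterior_sequence(seq, w)
    p2 = posterior_sequence(seq, w2)
    assert np.allclose(p1, p2, atol=1e-12)


def test_stability_shift_is_max_over_units():
    rng = np.random.default_rng(1)
    sh = ModelShape(2, 2, 1, 2)
    w = random_weights(rng, sh)
    tr = forward_pass(rng.normal(0, 1, (4, 2)), w)
    finite = np.where(np.isfinite(tr.pre_activations), tr.pre_activations, -np.inf)
    assert np.allclose(tr.shifts, finite.max(axis=(1, 2, 3, 4)))
    assert np.max(tr.o2) <= 1.0 + 1e-12


def test_oracle_equivalence_200_random_instances():
    """Encoded network vs direct recursion: max |difference| <= 1e-6."""
    rng = np.random.default_rng(2024)
    max_err = 0.0
    for _ in range(200):
        theta = random_theta(rng)
        T = int(rng.integers(1, 21))
        seq = rng.normal(0, 1, (T, theta.d))
        net = posterior_sequence(seq, encode_hmm_gmm(theta))
        ref = reference_forward(theta, seq)
        max_err = max(max_err, float(np.max(np.abs(net - ref))))
        assert np.max(np.abs(net.sum(axis=1) - 1.0)) <= 1e-9
    assert max_err <= 1e-6


def test_time_homogeneous_encoding_exact_under_column_stochastic_transitions():
    """Without first-step weights the implicit prior is the transition column
    sums; with doubly stochastic transitions, uniform prior, and a state count
    shared across classes the single tensor is already exact."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        theta = random_theta(rng, uniform_pi=True, K_fixed=2)
        for cl in theta.classes:
            K = cl.K  # symmetrize to make the transition matrix doubly stochastic
            cl.trans = np.full((K, K), (1.0 - 0.7) / max(K - 1, 1))
            np.fill_diagonal(cl.trans, 0.7 if K > 1 else 1.0)
        seq = rng.normal(0, 1, (8, theta.d))
        net = posterior_sequence(seq, encode_hmm_gmm(theta, first_step_priors=False))
        ref = reference_forward(theta, seq)
        assert np.max(np.abs(net - ref)) <= 1e-6


def test_encoding_closed_form_standard_normal():
    """d=1, mu=0, Sigma=1, gamma=r=1: coefficients are [-log(2 pi)/2, 0, -1/2]."""
    theta = HMMGMMParams([
        ClassHMMGMM(
            pi=np.array([1.0]), trans=np.array([[1.0]]),
            mixing=[np.array([1.0])], means=[np.zeros((1, 1))],
            covs=[np.eye(1)[None]],
        )
    ])
    w = encode_hmm_gmm(theta, first_step_priors=False)
    expected = np.array([-0.5 * np.log(2 * np.pi), 0.0, -0.5])
    assert np.allclose(w.w[0, 0, 0, 0], expected)  # log gamma = log 1 = 0


def test_transition_row_scaling_cancels():
    """Scaling all transition rows of every class by one constant leaves
    posteriors unchanged (it cancels in the joint normalization)."""
    rng = np.random.default_rng(7)
    theta = random_theta(rng, uniform_pi=True)
    w = encode_hmm_gmm(theta)
    w2 = w.copy()
    w2.w[..., 0] += np.log(3.7)
    w2.w_first[..., 0] += np.log(3.7)
    seq = rng.normal(0, 1, (6, theta.d))
    assert np.allclose(posterior_sequence(seq, w), posterior_sequence(seq, w2), atol=1e-12)


def test_single_step_static_limit_is_quadratic_discriminant_softmax():
    """T=1, K=1, M=1: the posterior is the softmax of per-class
    log prior + Gaussian log-density."""
    rng = np.random.default_rng(11)
    d = 2
    classes = []
    for _ in range(2):
        A = rng.normal(0, 1, (d, d))
        classes.append(ClassHMMGMM(
            pi=np.array([1.0]), trans=np.array([[1.0]]),
            mixing=[np.array([1.0])], means=[rng.normal(0, 1, (1, d))],
            covs=[(A @ A.T + 0.5 * np.eye(d))[None]],
        ))
    theta = HMMGMMParams(classes)
    x = rng.normal(0, 1, (1, d))
    post = posterior_sequence(x, encode_hmm_gmm(theta))
    logd = [
        multivariate_normal.logpdf(x[0], mean=cl.means[0][0], cov=cl.covs[0][0])
        for cl in theta.classes
    ]
    assert np.allclose(post[0], softmax(logd), atol=1e-9)


def test_reference_forward_hand_checkable_two_class_single_gaussian():
    theta = HMMGMMParams([
        ClassHMMGMM(np.array([1.0]), np.array([[1.0]]), [np.array([1.0])],
                    [np.array([[0.0]])], [np.eye(1)[None]]),
        ClassHMMGMM(np.array([1.0]), np.array([[1.0]]), [np.array([1.0])],
                    [np.array([[2.0]])], [np.eye(1)[None]]),
    ])
    x = np.array([[0.5]])
    post = reference_forward(theta, x)
    b1 = np.exp(-0.5 * 0.5**2)
    b2 = np.exp(-0.5 * 1.5**2)
    assert post[0] == pytest.approx([b1 / (b1 + b2), b2 / (b1 + b2)], abs=1e-12)
    assert np.allclose(post.sum(axis=1), 1.0)


def test_reference_forward_emission_scaling_invariance():
    """Multiplying all class-priors (hence all alphas) by a constant cancels."""
    rng = np.random.default_rng(13)
    theta = random_theta(rng)
    seq = rng.normal(0, 1, (6, theta.d))
    p1 = reference_forward(theta, seq, class_priors=[1.0, 1.0])
    p2 = reference_forward(theta, seq, class_priors=[5.0, 5.0])
    assert np.allclose(p1, p2, atol=1e-12)


def test_normalized_vs_unnormalized_recursion_equivalence():
    """Feeding the normalized state posterior back (as the network does)
    instead of the raw forward variable changes nothing: scale cancels."""
    rng = np.random.default_rng(17)
    theta = random_theta(rng, uniform_pi=True)
    seq = rng.normal(0, 1, (10, theta.d))
    net = posterior_sequence(seq, encode_hmm_gmm(theta))     # normalized feedback
    ref = reference_forward(theta, seq)                       # rescaled alphas
    assert np.max(np.abs(net - ref)) < 1e-9


def test_encode_rejects_invalid_parameters():
    rng = np.random.default_rng(19)
    theta = random_theta(rng, d=2)
    bad = random_theta(rng, d=2)
    bad.classes[0].covs[0] = -np.eye(2)[None]
    with pytest.raises(InvalidParameterError):
        encode_hmm_gmm(bad)
    with pytest.raises(InvalidParameterError):
        # zero transition entries cannot be log-linearised
        theta.classes[0].trans = theta.classes[0].trans * 0.0
        theta.classes[0].trans[:, 0] = 1.0
        encode_hmm_gmm(theta)


def test_forward_pass_dimension_mismatch():
    sh = ModelShape(2, 2, 1, 3)
    w = RLLGMNWeights(sh, np.zeros(sh.weight_array_shape))
    with pytest.raises(InvalidParameterError):
        forward_pass(np.zeros((4, 2)), w)


def test_ragged_shapes_supported():
    """Classes may have different state and component counts."""
    rng = np.random.default_rng(23)
    sh = ModelShape(2, [2, 3], [[1, 2], [2, 1, 3]], 2)
    w = random_weights(rng, sh)
    tr = forward_pass(rng.normal(0, 1, (6, 2)), w)
    assert np.allclose(tr.o5.sum(axis=1), 1.0)
    # padded state slots never receive mass
    assert np.all(tr.o4[:, 0, 2] == 0.0)
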