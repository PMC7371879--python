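"""Recurrent log-linearised Gaussian mixture network (R-LLGMN) core.

The network is a continuous-density hidden Markov model whose per-class
transition probabilities, mixture proportions and Gaussian components are
absorbed into a single coefficient tensor through log-linearisation.  A
five-layer recurrent forward pass then computes class posteriors for a
multichannel time series:

* layer 1 expands each input vector ``x(t)`` into
  ``X(t) = [1, x, x_i x_j (i <= j)]`` so that the log of a Gaussian (times a
  transition and a mixing weight) is linear in ``X(t)``;
* layer 2 units are one per (class c, source state k', target state k,
  mixture component m) and exponentiate the inner product with the weights;
* layer 3 sums over source states and mixture components, weighted by the
  previous step's state posteriors (the HMM forward recursion);
* layer 4 normalizes over all (class, state) pairs, yielding the joint
  posterior P(c, k | x(1..t));
* layer 5 sums over states, yielding the class posterior P(c | x(1..t)).

This module also provides the explicit HMM-GMM parameterisation
(:class:`HMMGMMParams`), the exact log-linear encoding of those parameters
into network weights (:func:`encode_hmm_gmm`), and a direct scaled forward
recursion over the explicit parameters (:func:`reference_forward`) used as an
independent oracle for the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import multivariate_normal

from .exceptions import InvalidParameterError, NumericalDegeneracyError

__all__ = [
    "ModelShape",
    "RLLGMNWeights",
    "ClassHMMGMM",
    "HMMGMMParams",
    "ForwardTrace",
    "expand_input",
    "expand_sequence",
    "forward_pass",
    "posterior_sequence",
    "encode_hmm_gmm",
    "reference_forward",
]


def _as_state_counts(C: int, K) -> tuple[int, ...]:
    if np.isscalar(K):
        return (int(K),) * C
    K = tuple(int(k) for k in K)
    if len(K) != C:
        raise InvalidParameterError(f"K must have {C} entries, got {len(K)}")
    return K


def _as_mixture_counts(K: tuple[int, ...], M) -> tuple[tuple[int, ...], ...]:
    if np.isscalar(M):
        return tuple((int(M),) * k for k in K)
    out = []
    for c, row in enumerate(M):
        if np.isscalar(row):
            out.append((int(row),) * K[c])
        else:
            row = tuple(int(m) for m in row)
            if len(row) != K[c]:
                raise InvalidParameterError(
                    f"M[{c}] must have {K[c]} entries, got {len(row)}"
                )
            out.append(row)
    if len(out) != len(K):
        raise InvalidParameterError("M must have one row per class")
    return tuple(out)


@dataclass(frozen=True)
class ModelShape:
    """Hyperparameter skeleton of the network.

    Parameters
    ----------
    C : number of classes (>= 2 in practice; class 2 is "deterioration").
    K : states per class; an int (shared) or a length-C sequence.
    M : Gaussian components per (class, state); an int, a length-C sequence,
        or a nested sequence ``M[c][k]``.
    d : input dimension per time step.

    The expanded input dimension is ``H = 1 + d + d(d+1)/2``.
    """

    C: int
    K: tuple[int, ...]
    M: tuple[tuple[int, ...], ...]
    d: int

    def __init__(self, C: int, K, M, d: int):
        C = int(C)
        d = int(d)
        if C < 1 or d < 1:
            raise InvalidParameterError("C and d must be >= 1")
        Kt = _as_state_counts(C, K)
        Mt = _as_mixture_counts(Kt, M)
        if min(Kt) < 1 or min(min(row) for row in Mt) < 1:
            raise InvalidParameterError("all state/component counts must be >= 1")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "K", Kt)
        object.__setattr__(self, "M", Mt)
        object.__setattr__(self, "d", d)

    @property
    def H(self) -> int:
        return 1 + self.d + self.d * (self.d + 1) // 2

    @property
    def K_max(self) -> int:
        return max(self.K)

    @property
    def M_max(self) -> int:
        return max(max(row) for row in self.M)

    @property
    def state_mask(self) -> np.ndarray:
        """Boolean (C, K_max): which (c, k) states exist."""
        mask = np.zeros((self.C, self.K_max), dtype=bool)
        for c, k in enumerate(self.K):
            mask[c, :k] = True
        return mask

    @property
    def unit_mask(self) -> np.ndarray:
        """Boolean (C, K_max, K_max, M_max): which layer-2 units exist."""
        mask = np.zeros((self.C, self.K_max, self.K_max, self.M_max), dtype=bool)
        for c in range(self.C):
            for k in range(self.K[c]):
                mask[c, : self.K[c], k, : self.M[c][k]] = True
        return mask

    @property
    def weight_array_shape(self) -> tuple[int, int, int, int, int]:
        return (self.C, self.K_max, self.K_max, self.M_max, self.H)

    def n_weights(self) -> int:
        """Number of real coefficients actually present (masked layout)."""
        return int(self.unit_mask.sum()) * self.H


@dataclass
class RLLGMNWeights:
    """Coefficient tensor ``w[c, k', k, m, :]`` over the expanded input.

    Entries outside the shape's unit mask are stored as zero and never used.
    ``w_first``, when present, replaces ``w`` at the first time step only and
    carries the state priors (see :func:`encode_hmm_gmm`).
    """

    shape: ModelShape
    w: np.ndarray
    w_first: np.ndarray | None = None

    def __post_init__(self):
        expected = self.shape.weight_array_shape
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != expected:
            raise InvalidParameterError(
                f"weight array shape {self.w.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.w)):
            raise InvalidParameterError("weights must be finite")
        if self.w_first is not None:
            self.w_first = np.asarray(self.w_first, dtype=float)
            if self.w_first.shape != expected:
                raise InvalidParameterError("w_first shape mismatch")
            if not np.all(np.isfinite(self.w_first)):
                raise InvalidParameterError("w_first must be finite")

    def copy(self) -> "RLLGMNWeights":
        return RLLGMNWeights(
            self.shape,
            self.w.copy(),
            None if self.w_first is None else self.w_first.copy(),
        )


@dataclass
class ClassHMMGMM:
    """Explicit HMM-GMM parameters of one class.

    pi : (K,) state priors, sums to 1.
    trans : (K, K) row-stochastic transition matrix, ``trans[k', k]`` is the
        probability of moving from state k' to state k; strictly positive.
    mixing : per state k, (M_k,) mixture proportions, strictly positive, sum 1.
    means : per state k, (M_k, d) component means.
    covs : per state k, (M_k, d, d) symmetric positive-definite covariances.
    """

    pi: np.ndarray
    trans: np.ndarray
    mixing: list[np.ndarray]
    means: list[np.ndarray]
    covs: list[np.ndarray]

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.mixing = [np.asarray(r, dtype=float) for r in self.mixing]
        self.means = [np.atleast_2d(np.asarray(m, dtype=float)) for m in self.means]
        self.covs = [np.asarray(s, dtype=float) for s in self.covs]

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def d(self) -> int:
        return self.means[0].shape[1]


@dataclass
class HMMGMMParams:
    """Per-class explicit parameters; the oracle and simulator operate on these."""

    classes: list[ClassHMMGMM]

    def __post_init__(self):
        self.validate()

    @property
    def C(self) -> int:
        return len(self.classes)

    @property
    def d(self) -> int:
        return self.classes[0].d

    @property
    def shape(self) -> ModelShape:
        K = [cl.K for cl in self.classes]
        M = [[len(r) for r in cl.mixing] for cl in self.classes]
        return ModelShape(self.C, K, M, self.d)

    def validate(self, atol: float = 1e-8) -> None:
        if not self.classes:
            raise InvalidParameterError("need at least one class")
        d = self.d
        for c, cl in enumerate(self.classes):
            K = cl.K
            if cl.trans.shape != (K, K):
                raise InvalidParameterError(f"class {c}: trans must be {K}x{K}")
            if abs(cl.pi.sum() - 1.0) > atol or np.any(cl.pi < 0):
                raise InvalidParameterError(f"class {c}: pi must be a distribution")
            if np.any(cl.trans <= 0):
                raise InvalidParameterError(
                    f"class {c}: transition entries must be strictly positive"
                )
            if np.max(np.abs(cl.trans.sum(axis=1) - 1.0)) > atol:
                raise InvalidParameterError(f"class {c}: trans rows must sum to 1")
            if not (len(cl.mixing) == len(cl.means) == len(cl.covs) == K):
                raise InvalidParameterError(f"class {c}: per-state lists must have K entries")
            for k in range(K):
                r, mu, sig = cl.mixing[k], cl.means[k], cl.covs[k]
                Mk = len(r)
                if np.any(r <= 0) or abs(r.sum() - 1.0) > atol:
                    raise InvalidParameterError(
                        f"class {c} state {k}: mixing must be strictly positive, sum 1"
                    )
                if mu.shape != (Mk, d):
                    raise InvalidParameterError(f"class {c} state {k}: means must be ({Mk},{d})")
                if sig.shape != (Mk, d, d):
                    raise InvalidParameterError(f"class {c} state {k}: covs must be ({Mk},{d},{d})")
                for m in range(Mk):
                    S = sig[m]
                    if not np.allclose(S, S.T, atol=1e-10):
                        raise InvalidParameterError(
                            f"class {c} state {k} comp {m}: covariance not symmetric"
                        )
                    try:
                        np.linalg.cholesky(S)
                    except np.linalg.LinAlgError as exc:
                        raise InvalidParameterError(
                            f"class {c} state {k} comp {m}: covariance not positive definite"
                        ) from exc


@dataclass
class ForwardTrace:
    """Everything backpropagation-through-time needs from one forward pass.

    All arrays carry a leading time axis of length T.  Layer-2 entries for
    units outside the shape's mask are ``-inf`` (pre-activation) / 0 (output).
    ``o4`` additionally stores the boundary row ``o4[0] = 1`` at index 0, so
    ``o4`` has length T+1 and ``o4[t]`` is the state posterior after step t.
    """

    x_expanded: np.ndarray      # (T, H)
    pre_activations: np.ndarray  # (T, C, K, K, M)
    o2: np.ndarray              # (T, C, K, K, M)
    o3: np.ndarray              # (T, C, K)
    o4: np.ndarray              # (T+1, C, K)
    o5: np.ndarray              # (T, C)
    shifts: np.ndarray          # (T,)


def expand_input(x: Sequence[float]) -> np.ndarray:
    """Quadratically expand one input vector: ``[1, x, x_i x_j (i <= j)]``.

    The upper-triangular products are emitted row-major: (0,0), (0,1), ...,
    (0,d-1), (1,1), ..., (d-1,d-1).  Weight tensors are meaningless under any
    other ordering.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("input vector must be finite")
    return expand_sequence(x[None, :])[0]


def expand_sequence(seq: np.ndarray) -> np.ndarray:
    """Expand a (T, d) sequence to (T, H)."""
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    if not np.all(np.isfinite(seq)):
        raise InvalidParameterError("input sequence must be finite")
    T, d = seq.shape
    iu, ju = np.triu_indices(d)
    return np.concatenate(
        [np.ones((T, 1)), seq, seq[:, iu] * seq[:, ju]], axis=1
    )


def _forward_batch(X3: np.ndarray, weights: RLLGMNWeights):
    """Shared batched recursion over pre-expanded inputs.

    X3 : (n, T, H).  Returns (Z2, S, A, O3, N, shifts) with
    Z2 (n,T,C,K,K,M) layer-2 outputs, S = Z2 summed over m, A (n,T+1,C,K)
    state posteriors including the all-ones boundary, O3 (n,T,C,K),
    N (n,T) normalizers (post-shift), shifts (n,T).
    """
    shape = weights.shape
    n, T, H = X3.shape
    umask = shape.unit_mask
    smask = shape.state_mask

    I2 = np.einsum("nth,ckjmh->ntckjm", X3, weights.w)
    if weights.w_first is not None:
        I2[:, 0] = np.einsum("nh,ckjmh->nckjm", X3[:, 0], weights.w_first)
    I2 = np.where(umask, I2, -np.inf)
    shifts = I2.max(axis=(2, 3, 4, 5))
    Z2 = np.exp(I2 - shifts[:, :, None, None, None, None])
    S = Z2.sum(axis=5)  # (n,T,C,K',K)

    C, Km = shape.C, shape.K_max
    A = np.zeros((n, T + 1, C, Km))
    A[:, 0] = smask.astype(float)
    O3 = np.zeros((n, T, C, Km))
    N = np.zeros((n, T))
    for t in range(T):
        o3 = np.einsum("nck,nckj->ncj", A[:, t], S[:, t])
        norm = o3.sum(axis=(1, 2))
        if not np.all(np.isfinite(norm)) or np.any(norm <= 0.0):
            raise NumericalDegeneracyError(
                f"layer-4 normalizer underflowed or overflowed at step {t + 1}"
            )
        O3[:, t] = o3
        N[:, t] = norm
        A[:, t + 1] = o3 / norm[:, None, None]
    return I2, Z2, S, A, O3, N, shifts


def forward_pass(seq: np.ndarray, weights: RLLGMNWeights) -> ForwardTrace:
    """Run the five-layer recurrent forward pass on one (T, d) sequence."""
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    if seq.shape[1] != weights.shape.d:
        raise InvalidParameterError(
            f"sequence has {seq.shape[1]} channels, model expects {weights.shape.d}"
        )
    X3 = expand_sequence(seq)[None]
    I2, Z2, S, A, O3, N, shifts = _forward_batch(X3, weights)
    return ForwardTrace(
        x_expanded=X3[0],
        pre_activations=I2[0],
        o2=Z2[0],
        o3=O3[0],
        o4=A[0],
        o5=A[0, 1:].sum(axis=2),
        shifts=shifts[0],
    )


def posterior_sequence(seq: np.ndarray, weights: RLLGMNWeights) -> np.ndarray:
    """Per-step class posteriors, a (T, C) row-stochastic matrix."""
    return forward_pass(seq, weights).o5


def posterior_batch(seqs: np.ndarray, weights: RLLGMNWeights) -> np.ndarray:
    """Class posteriors for a stack of equal-length sequences.

    seqs : (n, T, d).  Returns (n, T, C).
    """
    seqs = np.asarray(seqs, dtype=float)
    if seqs.ndim != 3 or seqs.shape[2] != weights.shape.d:
        raise InvalidParameterError("expected (n, T, d) input matching model d")
    n, T, d = seqs.shape
    X3 = expand_sequence(seqs.reshape(n * T, d)).reshape(n, T, -1)
    _, _, _, A, _, _, _ = _forward_batch(X3, weights)
    return A[:, 1:].sum(axis=3)


def _gaussian_log_linear_coeffs(mu: np.ndarray, sigma: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Coefficients (const, linear, quad) s.t. log N(x; mu, sigma) = const +
    linear.x + quad.(upper-tri products of x), matching expand_input order."""
    d = len(mu)
    L = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    S = np.linalg.inv(sigma)
    S = 0.5 * (S + S.T)
    const = -0.5 * (d * np.log(2.0 * np.pi) + logdet + mu @ S @ mu)
    linear = S @ mu
    iu, ju = np.triu_indices(d)
    quad = np.where(iu == ju, -0.5 * S[iu, ju], -S[iu, ju])
    return const, linear, quad


def encode_hmm_gmm(theta: HMMGMMParams, first_step_priors: bool = True) -> RLLGMNWeights:
    """Log-linearise explicit HMM-GMM parameters into network weights.

    For each unit (c, k', k, m) the coefficient vector satisfies
    ``exp(w . X(t)) = gamma^c_{k',k} r_{c,k,m} N(x(t); mu, Sigma)``, so the
    layer-2/3 recursion reproduces the HMM forward variable exactly (up to the
    per-step stability shift, which cancels in the layer-4 normalization).

    The recurrent boundary is all-ones state posteriors, so a time-homogeneous
    tensor implies a first-step prior proportional to the column sums of the
    transition matrix.  With ``first_step_priors=True`` (default) a separate
    first-step tensor is emitted whose constant term is
    ``log(pi_k r_{c,k,m} / K_c)``; summing the all-ones boundary over k' then
    yields exactly ``pi_k b_k(x(1))`` and the encoding is exact for any valid
    theta.  With ``False`` the single tensor is returned as trained networks
    store it; it matches the oracle only when the transition columns each sum
    to 1, the prior is uniform, and all classes share one state count (so the
    implicit 1/K_c factor cancels in the joint normalization).
    """
    theta.validate()
    shape = theta.shape
    w = np.zeros(shape.weight_array_shape)
    w_first = np.zeros(shape.weight_array_shape) if first_step_priors else None
    for c, cl in enumerate(theta.classes):
        K = cl.K
        if np.any(cl.pi <= 0):
            raise InvalidParameterError(
                f"class {c}: zero prior entries cannot be log-linearised"
            )
        for k in range(K):
            for m, r in enumerate(cl.mixing[k]):
                const, lin, quad = _gaussian_log_linear_coeffs(
                    cl.means[k][m], cl.covs[k][m]
                )
                coeff = np.concatenate([[const + np.log(r)], lin, quad])
                for kp in range(K):
                    w[c, kp, k, m] = coeff
                    w[c, kp, k, m, 0] += np.log(cl.trans[kp, k])
                    if w_first is not None:
                        w_first[c, kp, k, m] = coeff
                        w_first[c, kp, k, m, 0] += np.log(cl.pi[k] / K)
    return RLLGMNWeights(shape, w, w_first)


def reference_forward(
    theta: HMMGMMParams,
    seq: np.ndarray,
    class_priors: Sequence[float] | None = None,
) -> np.ndarray:
    """Class posteriors by the direct scaled forward recursion (the oracle).

    ``a^c_k(1) = P(c) pi^c_k b^c_k(x(1))``, then
    ``a^c_k(t) = sum_k' a^c_k'(t-1) gamma^c_{k',k} b^c_k(x(t))``; posteriors
    are the joint normalization of ``a`` over all (c, k).  A common rescale is
    applied each step (it cancels in the normalization).  ``class_priors``
    defaults to uniform over classes.
    """
    theta.validate()
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    T, d = seq.shape
    if d != theta.d:
        raise InvalidParameterError("sequence dimension does not match theta")
    C = theta.C
    if class_priors is None:
        priors = np.full(C, 1.0 / C)
    else:
        priors = np.asarray(class_priors, dtype=float)
        priors = priors / priors.sum()

    # per-class emission densities b^c_k(x(t)), (T, K_c)
    b = []
    for cl in theta.classes:
        bc = np.zeros((T, cl.K))
        for k in range(cl.K):
            for m, r in enumerate(cl.mixing[k]):
                bc[:, k] += r * multivariate_normal.pdf(
                    seq, mean=cl.means[k][m], cov=cl.covs[k][m]
                )
        b.append(bc)

    alpha = [priors[c] * theta.classes[c].pi * b[c][0] for c in range(C)]
    post = np.zeros((T, C))
    for t in range(T):
        if t > 0:
            alpha = [
                (alpha[c] @ theta.classes[c].trans) * b[c][t] for c in range(C)
            ]
        total = sum(a.sum() for a in alpha)
        if total <= 0.0 or not np.isfinite(total):
            raise NumericalDegeneracyError(
                f"forward normalizer degenerate at step {t + 1}"
            )
        post[t] = [a.sum() / total for a in alpha]
        alpha = [a / total for a in alpha]
    return post
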