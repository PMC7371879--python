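"""Maximum-likelihood training of the recurrent network.

The objective is the negative log-likelihood of the teacher class at the
final step of each sequence,

    J = - sum_n sum_c Y^(n)_c log O5_c(T)^(n),

minimised by full-batch gradient descent with exact gradients obtained by
backpropagation through time (BPTT) through the recurrent dependence of the
layer-4 state posteriors on the previous step.  Training is restarted from
several random initialisations and the restart with the lowest final J wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ModelShape, RLLGMNWeights, expand_sequence, _forward_batch
from .exceptions import InvalidParameterError, RLLGMNError

logger = logging.getLogger(__name__)

_LOG_FLOOR = -745.0  # ~log of the smallest positive double

__all__ = ["TrainingConfig", "TrainingResult", "loss_J", "bptt_gradient", "train"]


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the gradient-descent loop.

    ``restarts`` defaults to 5, the customary number of independent
    initialisations for this network family.  ``pin_unit`` zeroes (and keeps
    at zero) the last layer-2 unit of the last class to remove the softmax
    gauge freedom; training works either way.
    """

    learning_rate: float = 0.05
    max_epochs: int = 1000
    tol: float = 1e-6
    restarts: int = 5
    init_range: float = 0.1
    seed: int = 0
    pin_unit: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise InvalidParameterError("learning_rate must be positive")
        if self.max_epochs < 1 or self.restarts < 1:
            raise InvalidParameterError("max_epochs and restarts must be >= 1")
        if self.init_range < 0 or self.tol < 0:
            raise InvalidParameterError("init_range and tol must be >= 0")


@dataclass
class TrainingResult:
    weights: RLLGMNWeights
    trajectories: list[list[float]]
    final_losses: list[float]
    best_restart: int
    seed: int
    converged: bool
    failed_restarts: list[int] = field(default_factory=list)


def _dataset_arrays(dataset, shape: ModelShape):
    """Group sequences by length into (X3, y) batches of expanded inputs.

    Returns a list of (X3 (n,T,H), y (n,) zero-based class indices).
    """
    groups: dict[int, list[tuple[np.ndarray, int]]] = {}
    for fs in dataset:
        x = np.atleast_2d(np.asarray(fs.x, dtype=float))
        if x.shape[1] != shape.d:
            raise InvalidParameterError(
                f"sequence has d={x.shape[1]}, model expects {shape.d}"
            )
        label = int(fs.label)
        if not 1 <= label <= shape.C:
            raise InvalidParameterError(f"label {label} outside 1..{shape.C}")
        groups.setdefault(x.shape[0], []).append((x, label - 1))
    out = []
    for T in sorted(groups):
        xs, ys = zip(*groups[T])
        n = len(xs)
        X3 = expand_sequence(np.stack(xs).reshape(n * T, shape.d)).reshape(n, T, -1)
        out.append((X3, np.asarray(ys, dtype=int)))
    return out


def _loss_and_grad_batch(X3, y, weights: RLLGMNWeights, want_grad: bool):
    """Loss (and exact gradient) over one equal-length batch."""
    n, T, H = X3.shape
    _, Z2, S, A, O3, N, _ = _forward_batch(X3, weights)
    A_T = A[:, T]                       # (n, C, K)
    O5 = A_T.sum(axis=2)                # (n, C)
    p = O5[np.arange(n), y]
    J = float(-np.sum(np.maximum(np.log(np.maximum(p, 1e-323)), _LOG_FLOOR)))
    if np.any(p <= 0.0):
        logger.warning("teacher-class posterior underflowed; loss clamped")
    if not want_grad:
        return J, None

    grad = np.zeros_like(weights.w)
    # dJ/dA[T][c,k] = -Y_c / O5_c
    G = np.zeros_like(A_T)
    G[np.arange(n), y, :] = -1.0 / np.maximum(p, 1e-300)[:, None]
    smask = weights.shape.state_mask
    G *= smask  # only existing states carry gradient
    for t in range(T, 0, -1):
        At = A[:, t]
        # normalization backprop: A = O3 / N with N = sum O3
        inner = np.einsum("nck,nck->n", G, At)
        dO3 = (G - inner[:, None, None]) / N[:, t - 1][:, None, None]
        Ap = A[:, t - 1]
        # dJ/dI2[c,k',k,m] = dO3[c,k] * A_prev[c,k'] * Z2[c,k',k,m]
        dI2 = dO3[:, :, None, :, None] * Ap[:, :, :, None, None] * Z2[:, t - 1]
        grad += np.einsum("nckjm,nh->ckjmh", dI2, X3[:, t - 1])
        # dJ/dA_prev[c,k'] = sum_k dO3[c,k] * sum_m Z2[c,k',k,m]
        G = np.einsum("ncj,nckj->nck", dO3, S[:, t - 1])
    return J, grad


def loss_J(dataset, weights: RLLGMNWeights) -> float:
    """Negative log-likelihood of teacher classes at the final step.

    Additive over sequences; a saturated output (posterior 0 for the teacher
    class) contributes the clamped value ``-log`` floored at -745 rather than
    infinity.
    """
    if weights.w_first is not None:
        raise InvalidParameterError("training operates on time-homogeneous weights")
    total = 0.0
    for X3, y in _dataset_arrays(dataset, weights.shape):
        J, _ = _loss_and_grad_batch(X3, y, weights, want_grad=False)
        total += J
    return total


def bptt_gradient(dataset, weights: RLLGMNWeights) -> np.ndarray:
    """Exact gradient of :func:`loss_J` w.r.t. every coefficient.

    Same index layout as ``weights.w``; entries for units outside the shape
    mask are zero.  The per-step stability shift needs no gradient: the
    layer-4 normalization is exactly invariant to it.
    """
    if weights.w_first is not None:
        raise InvalidParameterError("training operates on time-homogeneous weights")
    grad = np.zeros_like(weights.w)
    for X3, y in _dataset_arrays(dataset, weights.shape):
        _, g = _loss_and_grad_batch(X3, y, weights, want_grad=True)
        grad += g
    return grad


def _loss_and_grad(dataset_arrays, weights):
    total, grad = 0.0, np.zeros_like(weights.w)
    for X3, y in dataset_arrays:
        J, g = _loss_and_grad_batch(X3, y, weights, want_grad=True)
        total += J
        grad += g
    return total, grad


def train(dataset, shape: ModelShape, cfg: TrainingConfig | None = None) -> TrainingResult:
    """Fit the network by restarted full-batch gradient descent.

    Each restart draws initial coefficients uniformly from
    ``[-init_range, init_range]`` with its own substream of ``cfg.seed``,
    descends until ``|ΔJ| < tol`` or ``max_epochs``, and the restart with the
    lowest final J is returned.  Fully deterministic given (dataset, cfg).
    """
    if cfg is None:
        cfg = TrainingConfig()
    if not dataset:
        raise InvalidParameterError("dataset must be non-empty")
    labels = {int(fs.label) for fs in dataset}
    if len(labels) < 2:
        raise InvalidParameterError("training data must contain at least two classes")
    arrays = _dataset_arrays(dataset, shape)
    umask = shape.unit_mask

    pin_index = None
    if cfg.pin_unit:
        c = shape.C - 1
        k = shape.K[c] - 1
        pin_index = (c, k, k, shape.M[c][k] - 1)

    trajectories: list[list[float]] = []
    finals: list[float] = []
    candidates: list[RLLGMNWeights | None] = []
    converged_flags: list[bool] = []
    failed: list[int] = []
    for r in range(cfg.restarts):
        rng = np.random.default_rng([int(cfg.seed) % (2**31), r])
        w = rng.uniform(-cfg.init_range, cfg.init_range, shape.weight_array_shape)
        w *= umask[..., None]
        if pin_index is not None:
            w[pin_index] = 0.0
        weights = RLLGMNWeights(shape, w)
        traj: list[float] = []
        converged = False
        ok = True
        lr = cfg.learning_rate
        J, g = _loss_and_grad(arrays, weights)
        if not np.isfinite(J):
            ok = False
        for _epoch in range(cfg.max_epochs if ok else 0):
            traj.append(J)
            if pin_index is not None:
                g[pin_index] = 0.0
            # monotone step: halve the step until J does not increase
            accepted = False
            for _ in range(60):
                trial = RLLGMNWeights(shape, weights.w - lr * g)
                with np.errstate(over="ignore", invalid="ignore"):
                    try:
                        J_new, g_new = _loss_and_grad(arrays, trial)
                    except RLLGMNError:
                        J_new = np.inf
                if np.isfinite(J_new) and J_new <= J:
                    accepted = True
                    break
                lr *= 0.5
            if not accepted:
                converged = True  # no descent direction at machine precision
                break
            delta = J - J_new
            weights, J, g = trial, J_new, g_new
            lr = min(lr * 1.1, 100.0 * cfg.learning_rate)
            if delta < cfg.tol:
                converged = True
                break
        if ok:
            traj.append(J)
            trajectories.append(traj)
            finals.append(J)
            candidates.append(weights)
            converged_flags.append(converged)
        else:
            logger.warning("restart %d diverged; discarded", r)
            trajectories.append(traj)
            finals.append(np.inf)
            candidates.append(None)
            converged_flags.append(False)
            failed.append(r)
    if all(c is None for c in candidates):
        raise RLLGMNError("all training restarts diverged")
    best = int(np.argmin(finals))
    logger.info(
        "training done: best restart %d, final J per restart %s", best,
        [f"{v:.4g}" for v in finals],
    )
    return TrainingResult(
        weights=candidates[best],
        trajectories=trajectories,
        final_losses=finals,
        best_restart=best,
        seed=cfg.seed,
        converged=converged_flags[best],
        failed_restarts=failed,
    )
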