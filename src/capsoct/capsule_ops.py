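"""Capsule-network primitives.

A capsule is a group of units whose activity vector encodes an entity's pose;
the vector's Euclidean length encodes the probability that the entity exists.
This module implements the primitives those semantics rest on:

* ``squash_original`` — v = (|s|^2 / (1 + |s|^2)) * s/|s|, the nonlinearity
  that maps any vector to the same direction with norm in [0, 1).
* ``squash_power``    — v = (|s|^n / (1 + |s|^n)) * s/|s|; for n > 2 it grows
  more slowly than the original near |s| = 0, suppressing small activations
  (it reduces to the original squash at n = 2).
* ``coupling``        — routing logits -> coupling coefficients, either
  softmax-normalised over parent capsules or elementwise sigmoid.
* ``route``           — dynamic routing by agreement: iteratively weight each
  lower capsule's prediction by its agreement (dot product) with the parent
  output.
* ``margin_loss``     — per-class squared hinge on capsule lengths with
  margins m+/m- and down-weight lambda for absent classes.

All operations accept either plain numpy arrays (returned as arrays) or
autodiff :class:`~capsoct.autodiff.Tensor` objects (returned as tensors, with
gradients flowing through the last routing iteration as in the standard
implementation).  A small epsilon (``NORM_EPS``) stabilises every norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, softmax as _softmax

NORM_EPS = 1e-7

__all__ = [
    "NORM_EPS",
    "SquashSpec",
    "MarginLossParams",
    "RoutingState",
    "squash_original",
    "squash_power",
    "apply_squash",
    "coupling",
    "predictions",
    "route",
    "margin_loss",
    "capsule_lengths",
]


@dataclass(frozen=True)
class SquashSpec:
    """Which squash nonlinearity to use; ``exponent`` applies to 'power'."""

    kind: str = "original"
    exponent: float = 3.0

    def __post_init__(self):
        if self.kind not in ("original", "power"):
            raise ValueError("kind must be 'original' or 'power'")
        if self.exponent <= 0:
            raise ValueError("power-squash exponent must be > 0")


@dataclass(frozen=True)
class MarginLossParams:
    """Margins and absent-class down-weight of the capsule margin loss."""

    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_: float = 0.5

    def __post_init__(self):
        if not (0 < self.m_minus < self.m_plus < 1):
            raise ValueError("require 0 < m_minus < m_plus < 1")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")


@dataclass
class RoutingState:
    """Final routing logits/couplings plus the per-iteration coupling trace."""

    logits: np.ndarray
    couplings: np.ndarray
    iteration: int
    coupling_mode: str
    coupling_history: list = field(default_factory=list)


def _wrap(x):
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _unwrap(t, was_tensor):
    return t if was_tensor else t.data


def safe_norm(x, axis=-1, keepdims=False):
    """Euclidean norm with an epsilon guard against division by zero."""
    t, was = _wrap(x)
    n = ((t * t).sum(axis=axis, keepdims=keepdims) + NORM_EPS**2).sqrt()
    return _unwrap(n, was)


def squash_original(s, axis=-1):
    """v = (|s|^2 / (1 + |s|^2)) * s / |s|;  zero maps to zero."""
    t, was = _wrap(s)
    n = ((t * t).sum(axis=axis, keepdims=True) + NORM_EPS**2).sqrt()
    return _unwrap(t * (n / (1.0 + n * n)), was)


def squash_power(s, exponent=3.0, axis=-1):
    """v = (|s|^n / (1 + |s|^n)) * s / |s| for n > 0; equals the original at n=2."""
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    t, was = _wrap(s)
    n = ((t * t).sum(axis=axis, keepdims=True) + NORM_EPS**2).sqrt()
    return _unwrap(t * (n ** (exponent - 1.0) / (1.0 + n**exponent)), was)


def apply_squash(s, spec: SquashSpec, axis=-1):
    if spec.kind == "original":
        return squash_original(s, axis=axis)
    return squash_power(s, exponent=spec.exponent, axis=axis)


def coupling(b, mode="softmax"):
    """Routing logits -> coupling coefficients.

    softmax: normalised over the parent (last) axis, so each lower capsule's
    couplings sum to 1.  sigmoid: independent per pair, each in (0, 1).
    """
    t, was = _wrap(b)
    if mode == "softmax":
        return _unwrap(_softmax(t, axis=-1), was)
    if mode == "sigmoid":
        return _unwrap(t.sigmoid(), was)
    raise ValueError(f"unknown coupling mode: {mode!r}")


def predictions(u, W):
    """Prediction vectors u_hat[..., i, j, :] = W[i, j] @ u[..., i, :].

    u : (..., N_lower, D_lower) lower-capsule poses.
    W : (N_lower, N_upper, D_upper, D_lower) transformation matrices.
    """
    from .autodiff import einsum

    ut, was_u = _wrap(u)
    Wt, was_W = _wrap(W)
    if ut.ndim == 2:
        out = einsum("ijud,id->iju", Wt, ut)
    else:
        out = einsum("ijud,bid->biju", Wt, ut)
    return _unwrap(out, was_u or was_W)


def route(u_hat, r=3, mode="softmax", squash: SquashSpec = SquashSpec()):
    """Dynamic routing by agreement.

    u_hat : (..., N_lower, N_upper, D_upper) prediction vectors.
    r : number of routing iterations (>= 1); logits start at zero.

    Per iteration: c = coupling(b); s_j = sum_i c_ij * u_hat_j|i;
    v_j = squash(s_j); b_ij += v_j . u_hat_j|i.  Returns the parent capsules
    after ``r`` iterations and the final :class:`RoutingState`.  Gradients
    propagate through the final weighted sum (earlier iterations use detached
    predictions, the standard stop-gradient treatment).
    """
    if r < 1:
        raise ValueError("need at least one routing iteration")
    uh, was = _wrap(u_hat)
    if uh.ndim < 3:
        raise ValueError("u_hat must have shape (..., N_lower, N_upper, D_upper)")
    uh_stop = uh.detach()
    b = Tensor(np.zeros(uh.shape[:-1], dtype=uh.data.dtype))
    history = []
    v = None
    for it in range(r):
        c = coupling(b, mode)
        history.append(c.data.copy())
        src = uh if it == r - 1 else uh_stop
        s = (c.reshape(*c.shape, 1) * src).sum(axis=-3)
        v = apply_squash(s, squash, axis=-1)
        if it < r - 1:
            # agreement a_ij = v_j . u_hat_j|i accumulates into the logits
            agreement = (uh_stop * _expand_parent(v, uh.ndim)).sum(axis=-1)
            b = b + agreement
    state = RoutingState(
        logits=b.data.copy(),
        couplings=history[-1].copy(),
        iteration=r,
        coupling_mode=mode,
        coupling_history=history,
    )
    return _unwrap(v, was), state


def _expand_parent(v, uhat_ndim):
    # v: (..., N_upper, D_upper) -> (..., 1, N_upper, D_upper) to broadcast
    # against u_hat's lower-capsule axis
    return v.reshape(*v.shape[:-2], 1, *v.shape[-2:])


def margin_loss(v_norms, labels, params: MarginLossParams = MarginLossParams()):
    """Margin loss on class-capsule lengths, averaged over the batch.

    l_k = T_k max(0, m+ - |v_k|)^2 + lambda (1 - T_k) max(0, |v_k| - m-)^2

    v_norms : (k,) or (batch, k) capsule lengths in [0, 1).
    labels  : one-hot of the same shape (validated).
    """
    t, was = _wrap(v_norms)
    T = np.asarray(labels, dtype=np.float64)
    if T.shape != t.shape:
        raise ValueError("labels must have the same shape as v_norms")
    if not np.all((T == 0) | (T == 1)) or not np.allclose(T.sum(axis=-1), 1.0):
        raise ValueError("labels must be one-hot")
    Tt = Tensor(T.astype(t.data.dtype))
    present = (Tensor(np.array(params.m_plus, dtype=t.data.dtype)) - t).relu() ** 2
    absent = (t - Tensor(np.array(params.m_minus, dtype=t.data.dtype))).relu() ** 2
    per_class = Tt * present + params.lambda_ * (1.0 - Tt) * absent
    per_sample = per_class.sum(axis=-1)
    out = per_sample.mean() if per_sample.ndim else per_sample
    return _unwrap(out, was)


def capsule_lengths(v, axis=-1):
    """Per-capsule Euclidean lengths; argmax over classes is the prediction."""
    return safe_norm(v, axis=axis, keepdims=False)
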