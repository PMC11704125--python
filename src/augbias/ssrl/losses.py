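"""The five SSRL objectives, written against the autodiff tensor API.

Formulations follow the canonical definitions of the respective methods:

* ``simclr`` — normalized-temperature cross entropy (NT-Xent) over the 2N
  concatenated views, every non-positive acting as a negative;
* ``moco_v2`` — InfoNCE of queries against momentum-encoder keys, with a
  persistent queue of past keys as negatives (queue held in ``state``);
* ``byol`` — mean squared error between L2-normalized online predictions and
  target projections (no negatives; the trainer maintains the EMA target);
* ``vicreg`` — invariance (MSE) + variance hinge (std below 1 penalized) +
  covariance (off-diagonal suppression), weighted 25 / 25 / 1;
* ``barlow_twins`` — cross-correlation of batch-standardized embeddings pushed
  to the identity, off-diagonal weight 5e-3.

Each loss returns a scalar Tensor plus the (possibly updated) state dict.
"""

from __future__ import annotations

import numpy as np

from ..nn import autodiff as ad
from ..nn.autodiff import Tensor

__all__ = ["compute_ssrl_loss", "METHODS"]

METHODS = ("simclr", "moco_v2", "byol", "vicreg", "barlow_twins")

_EPS = 1e-12


def _coerce(z) -> Tensor:
    return z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))


def _l2_normalize(z: Tensor) -> Tensor:
    norm = ad.sqrt((z**2).sum(axis=1, keepdims=True) + _EPS)
    return z / norm


def _check(z1: Tensor, z2: Tensor, method: str):
    if z1.shape != z2.shape:
        raise ValueError("z1 and z2 must have the same shape")
    if z1.ndim != 2:
        raise ValueError("embeddings must be (batch, dim)")
    if z1.shape[0] < 2 and method in ("simclr", "vicreg", "barlow_twins"):
        raise ValueError(f"{method} requires batch size >= 2")


def _row_logsumexp(sim: Tensor) -> Tensor:
    """Stable row-wise log-sum-exp; the max shift is treated as a constant."""
    m = sim.data.max(axis=1, keepdims=True)
    return ad.log(ad.exp(sim - m).sum(axis=1, keepdims=True)) + m


def _simclr(z1: Tensor, z2: Tensor, temperature: float) -> Tensor:
    n = z1.shape[0]
    z = ad.concat([_l2_normalize(z1), _l2_normalize(z2)], axis=0)
    sim = (z @ z.T) * (1.0 / temperature)
    # exclude self-similarity from the denominator
    self_mask = np.full((2 * n, 2 * n), 0.0)
    np.fill_diagonal(self_mask, -1e9)
    sim = sim + self_mask
    pos_mask = np.zeros((2 * n, 2 * n))
    idx = np.arange(n)
    pos_mask[idx, idx + n] = 1.0
    pos_mask[idx + n, idx] = 1.0
    pos = (sim * pos_mask).sum(axis=1, keepdims=True)
    lse = _row_logsumexp(sim)
    return (lse - pos).mean()


def _infonce_queue(q: Tensor, k: Tensor, queue: np.ndarray | None,
                   temperature: float) -> Tensor:
    qn = _l2_normalize(q)
    kn = Tensor(_l2_normalize(_coerce(k).detach()).data)  # keys carry no gradient
    pos = (qn * kn.data).sum(axis=1, keepdims=True) * (1.0 / temperature)
    if queue is not None and len(queue):
        neg = (qn @ queue.T) * (1.0 / temperature)
    else:
        # bootstrap: other in-batch keys act as negatives
        neg_data = qn.data @ kn.data.T
        neg = (qn @ kn.data.T) * (1.0 / temperature)
        mask = np.zeros_like(neg_data)
        np.fill_diagonal(mask, -1e9)
        neg = neg + mask
    logits = ad.concat([pos, neg], axis=1)
    lse = _row_logsumexp(logits)
    return (lse - pos).mean()


def _byol(p: Tensor, t: Tensor) -> Tensor:
    pn = _l2_normalize(p)
    tn = _l2_normalize(_coerce(t).detach())
    return ((pn - Tensor(tn.data)) ** 2).sum(axis=1).mean()


def _vicreg(z1: Tensor, z2: Tensor, inv_w: float, var_w: float, cov_w: float) -> Tensor:
    n, d = z1.shape
    inv = ((z1 - z2) ** 2).mean()
    loss = inv * inv_w

    def var_cov(z: Tensor):
        mu = z.mean(axis=0, keepdims=True)
        zc = z - mu
        var = (zc**2).sum(axis=0) * (1.0 / (n - 1))
        std = ad.sqrt(var + 1e-4)
        v = ad.relu(1.0 - std).mean()
        cov = (zc.T @ zc) * (1.0 / (n - 1))
        off = cov * (1.0 - np.eye(d))
        c = (off**2).sum() * (1.0 / d)
        return v, c

    v1, c1 = var_cov(z1)
    v2, c2 = var_cov(z2)
    return loss + var_w * (v1 + v2) + cov_w * (c1 + c2)


def _barlow(z1: Tensor, z2: Tensor, lam: float) -> Tensor:
    n, d = z1.shape

    def standardize(z: Tensor) -> Tensor:
        mu = z.mean(axis=0, keepdims=True)
        zc = z - mu
        sd = ad.sqrt((zc**2).mean(axis=0, keepdims=True) + _EPS)
        return zc / sd

    c = (standardize(z1).T @ standardize(z2)) * (1.0 / n)
    eye = np.eye(d)
    on_diag = ((c - eye) * eye) ** 2
    off_diag = (c * (1.0 - eye)) ** 2
    return on_diag.sum() + lam * off_diag.sum()


def compute_ssrl_loss(method: str, z1, z2, state: dict | None = None, *,
                      temperature: float | None = None,
                      vicreg_weights: tuple = (25.0, 25.0, 1.0),
                      barlow_lambda: float = 5e-3,
                      queue_len: int = 256) -> tuple[Tensor, dict]:
    """Scalar loss Tensor plus updated state for one batch of paired embeddings.

    ``z1``/``z2`` are (batch, dim) projected embeddings of the two views. For
    ``moco_v2``, ``z1`` are online queries and ``z2`` momentum keys (treated as
    constants; the state carries the negative queue, which is updated here).
    For ``byol``, ``z1`` are online predictions and ``z2`` target projections
    (treated as constants).
    """
    if method not in METHODS:
        raise ValueError(f"unknown SSRL method {method!r}")
    z1, z2 = _coerce(z1), _coerce(z2)
    _check(z1, z2, method)
    state = dict(state or {})

    if temperature is None:
        temperature = 0.2 if method == "moco_v2" else 0.5

    if method == "simclr":
        loss = _simclr(z1, z2, temperature)
    elif method == "moco_v2":
        queue = state.get("queue")
        loss = _infonce_queue(z1, z2, queue, temperature)
        keys = _l2_normalize(z2.detach()).data
        queue = keys if queue is None else np.concatenate([queue, keys])[-queue_len:]
        state["queue"] = queue
    elif method == "byol":
        loss = _byol(z1, z2)
    elif method == "vicreg":
        iw, vw, cw = vicreg_weights
        loss = _vicreg(z1, z2, iw, vw, cw)
    else:  # barlow_twins
        loss = _barlow(z1, z2, barlow_lambda)

    if not np.isfinite(loss.data):
        raise FloatingPointError(f"{method} loss is not finite")
    return loss, state
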