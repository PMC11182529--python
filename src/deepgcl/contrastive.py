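"""Batchwise contrastive loss aligning topology and structure views.

For sample i the anchor is its topology embedding; the positive is its
own (projected) structure embedding and the other samples in the batch
act as negatives.  Two denominators are supported:

* ``as_printed`` (default): the positive term is added inside the sum
  over batch members, so it appears N times in the denominator.
* ``standard_infonce``: the positive appears exactly once and the other
  N-1 samples are the negatives.

The total loss is the *mean* of the per-sample losses: minimizing it
pulls the two views of the same pair together.  (Negating the mean would
make the objective unbounded below, so the mean convention is used.)
"""

from __future__ import annotations

import warnings

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import ConfigError

_EPS = 1e-12

CONTRASTIVE_MODES = ("as_printed", "standard_infonce")


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity with epsilon-guarded norms."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        warnings.warn("cosine_sim: zero-norm vector, epsilon-stabilized", stacklevel=2)
    return float(u @ v / ((nu + _EPS) * (nv + _EPS)))


def _row_normalize(z: Tensor) -> Tensor:
    norms = ((z * z).sum(axis=1, keepdims=True) + _EPS) ** 0.5
    return z / norms


def contrastive_loss(
    z_t: Tensor,
    z_c: Tensor,
    temperature: float = 0.5,
    mode: str = "as_printed",
) -> Tensor:
    """Mean per-sample contrastive loss between two (N, e) view batches."""
    if temperature <= 0:
        raise ConfigError(f"temperature must be positive, got {temperature}")
    if mode not in CONTRASTIVE_MODES:
        raise ConfigError(f"unknown contrastive mode: {mode!r}")
    if z_t.shape != z_c.shape:
        raise ValueError(f"view shapes differ: {z_t.shape} vs {z_c.shape}")
    n = z_t.shape[0]
    zt_n = _row_normalize(z_t)
    zc_n = _row_normalize(z_c)
    sims = (zt_n @ zc_n.T) * (1.0 / temperature)  # (N, N), sims[i, k]
    pos = (zt_n * zc_n).sum(axis=1, keepdims=True) * (1.0 / temperature)  # (N, 1)

    if mode == "as_printed":
        # denominator_i = sum_k exp(s_ik) + N * exp(s_ii)
        logits = ad.concat([sims, pos + float(np.log(n))], axis=1)
    else:
        logits = sims
    # stable log-sum-exp with a detached per-row shift
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    lse = ((logits - shift).exp().sum(axis=1, keepdims=True)).log() + shift
    per_sample = lse - pos
    return per_sample.mean()


def contrastive_loss_value(
    z_t: np.ndarray,
    z_c: np.ndarray,
    temperature: float = 0.5,
    mode: str = "as_printed",
) -> float:
    """Convenience wrapper evaluating the loss on plain arrays."""
    return float(
        contrastive_loss(Tensor(z_t), Tensor(z_c), temperature, mode).data
    )
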