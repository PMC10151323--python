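"""Hitting-time likelihood and ranking losses for the discrete-time model.

Both operate on batches of pmf grids ``y`` of shape (n, K, T) together with
discretized outcomes (event code 0=censored/1..K, bin index).

* ``likelihood_loss``: mean over the batch of ``-log y[k_i][t_i]`` for a
  patient with event ``k_i`` in bin ``t_i`` and ``-log S(t_i)`` for a
  patient censored in bin ``t_i`` (survival = mass in bins strictly after
  ``t_i``).  Probabilities are floored at 1e-12 before the logarithm.
* ``ranking_loss``: for every event ``k`` and ordered pair (i, j) with
  ``k_i = k`` and ``t_i < t_j``, the penalty
  ``exp(-(CIF_k(t_i|x_i) - CIF_k(t_i|x_j)) / sigma)``, averaged over valid
  pairs so the term does not rescale with batch size.
* ``total_loss``: ``alpha * likelihood + (1 - alpha) * ranking``.

Each function can also return the gradient with respect to ``y`` for the
training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "likelihood_loss",
    "ranking_loss",
    "total_loss",
    "PROB_FLOOR",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LossConfig:
    """Mixing weight and ranking kernel scale."""

    alpha: float = 0.5
    sigma: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _check(pmf, event, bins):
    pmf = np.asarray(pmf, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    bins = np.asarray(bins, dtype=np.int64)
    n, K, T = pmf.shape
    if event.shape != (n,) or bins.shape != (n,):
        raise ValueError("event/bin arrays must align with the batch")
    if (bins < 0).any() or (bins >= T).any():
        raise ValueError("bin index out of range for the pmf grid")
    if (event < 0).any() or (event > K).any():
        raise ValueError("event code out of range")
    return pmf, event, bins, n, K, T


def likelihood_loss(pmf, event, bins, return_grad=False):
    """Negative log-likelihood of the observed hitting times."""
    pmf, event, bins, n, K, T = _check(pmf, event, bins)
    grad = np.zeros_like(pmf) if return_grad else None
    loss = 0.0
    uncens = event > 0
    idx = np.flatnonzero(uncens)
    p_ev = pmf[idx, event[idx] - 1, bins[idx]]
    loss += -np.log(np.maximum(p_ev, PROB_FLOOR)).sum()
    if return_grad and len(idx):
        ok = p_ev >= PROB_FLOOR
        grad[idx[ok], event[idx[ok]] - 1, bins[idx[ok]]] = -1.0 / (n * p_ev[ok])
    for i in np.flatnonzero(~uncens):
        s = pmf[i, :, bins[i] + 1 :].sum()
        loss += -np.log(max(s, PROB_FLOOR))
        if return_grad and s >= PROB_FLOOR:
            grad[i, :, bins[i] + 1 :] = -1.0 / (n * s)
    loss /= n
    return (loss, grad) if return_grad else loss


def ranking_loss(pmf, event, bins, sigma=0.1, return_grad=False):
    """Event-specific pairwise ranking penalty, averaged over valid pairs."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pmf, event, bins, n, K, T = _check(pmf, event, bins)
    F = np.cumsum(pmf, axis=2)
    total = 0.0
    n_pairs = 0
    dF = np.zeros_like(F) if return_grad else None
    for k in range(K):
        cases = np.flatnonzero(event == k + 1)
        if len(cases) == 0:
            continue
        ti = bins[cases]
        a = F[cases, k, ti]  # (m,)
        b = F[:, k, :][:, ti].T  # b[p, j] = CIF_k(t_p | x_j)
        valid = bins[None, :] > ti[:, None]  # (m, n)
        eta = np.where(valid, np.exp(-(a[:, None] - b) / sigma), 0.0)
        total += eta.sum()
        n_pairs += int(valid.sum())
        if return_grad:
            da = -eta.sum(axis=1) / sigma
            np.add.at(dF[:, k, :], (cases, ti), da)
            np.add.at(dF[:, k, :].T, ti, eta / sigma)
    if n_pairs == 0:
        return (0.0, np.zeros_like(pmf)) if return_grad else 0.0
    loss = total / n_pairs
    if return_grad:
        dF /= n_pairs
        grad = np.flip(np.cumsum(np.flip(dF, axis=2), axis=2), axis=2)
        return loss, grad
    return loss


def total_loss(pmf, event, bins, cfg: LossConfig = LossConfig(), return_grad=False):
    """``alpha * likelihood + (1 - alpha) * ranking``."""
    if return_grad:
        l1, g1 = likelihood_loss(pmf, event, bins, return_grad=True)
        l2, g2 = ranking_loss(pmf, event, bins, cfg.sigma, return_grad=True)
        return cfg.alpha * l1 + (1 - cfg.alpha) * l2, cfg.alpha * g1 + (1 - cfg.alpha) * g2
    l1 = likelihood_loss(pmf, event, bins)
    l2 = ranking_loss(pmf, event, bins, cfg.sigma)
    return cfg.alpha * l1 + (1 - cfg.alpha) * l2
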