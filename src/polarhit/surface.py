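"""Per-patient risk surfaces: joint (event, time) probability mass.

The model emits, per patient, a ``K x T`` grid ``y[k][t]`` — the joint
probability of event ``k`` hitting in bin ``t`` — normalized over all cells.
Cumulative incidence and survival are derived:

``CIF_k(t) = sum_{s<=t} y[k][s]``   and   ``S(t) = 1 - sum_k CIF_k(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RiskSurface", "cif_from_pmf", "survival_from_pmf"]


def cif_from_pmf(pmf: np.ndarray) -> np.ndarray:
    """Cumulative incidence per cause; cumulative sum over the time axis."""
    return np.cumsum(pmf, axis=-1)


def survival_from_pmf(pmf: np.ndarray) -> np.ndarray:
    """Event-free survival ``S(t) = 1 - sum_k CIF_k(t)``, clipped at 0."""
    s = 1.0 - cif_from_pmf(pmf).sum(axis=-2)
    return np.clip(s, 0.0, 1.0)


@dataclass
class RiskSurface:
    """Validated container for one batch of pmf grids, shape (n, K, T)."""

    pmf: np.ndarray
    atol: float = 1e-6

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=np.float64)
        if self.pmf.ndim != 3:
            raise ValueError("pmf must have shape (n_patients, K, T)")
        if (self.pmf < -self.atol).any():
            raise ValueError("pmf has negative cells")
        total = self.pmf.sum(axis=(1, 2))
        if not np.allclose(total, 1.0, atol=self.atol):
            raise ValueError("pmf does not sum to 1 over all event-time cells")

    @property
    def n_events(self) -> int:
        return self.pmf.shape[1]

    @property
    def n_bins(self) -> int:
        return self.pmf.shape[2]

    def cif(self) -> np.ndarray:
        return cif_from_pmf(self.pmf)

    def survival(self) -> np.ndarray:
        return survival_from_pmf(self.pmf)
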