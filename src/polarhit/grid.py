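"""Discrete time grid shared by the model output, losses and metrics.

Follow-up time is discretized into bins of ``bin_width_days`` (30 days by
default), with a grid point at time 0 and one every bin width up to the
horizon.  Bin ``t`` covers the right-closed interval ``((t-1)*w, t*w]`` days
and day 0 falls in bin 0.  With the default horizon of 3,900 days and 30-day
bins the grid has 131 columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TimeGrid", "build_time_grid", "discretize_time"]

DEFAULT_HORIZON_DAYS = 3_900
DEFAULT_BIN_WIDTH_DAYS = 30


@dataclass(frozen=True)
class TimeGrid:
    """Bin structure for discrete-time survival quantities.

    Attributes
    ----------
    bin_width_days : int
        Width of every interval in days.
    horizon_days : int
        Maximum follow-up time represented by the grid.
    """

    bin_width_days: int = DEFAULT_BIN_WIDTH_DAYS
    horizon_days: int = DEFAULT_HORIZON_DAYS

    def __post_init__(self) -> None:
        if self.bin_width_days <= 0:
            raise ValueError("bin_width_days must be positive")
        if self.horizon_days < self.bin_width_days:
            raise ValueError("horizon_days must be at least one bin width")

    @property
    def n_bins(self) -> int:
        """Number of probability columns (grid points)."""
        return self.horizon_days // self.bin_width_days + 1

    def bin_of(self, time_days: float) -> int:
        """Map a time in days onto its bin index, clamped to the last bin."""
        return discretize_time(time_days, self)

    def bin_times(self):
        """Days corresponding to each grid point (0, w, 2w, ...)."""
        import numpy as np

        return np.arange(self.n_bins) * self.bin_width_days


def build_time_grid(
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    bin_width_days: int = DEFAULT_BIN_WIDTH_DAYS,
) -> TimeGrid:
    """Construct a :class:`TimeGrid`, validating its invariants."""
    return TimeGrid(bin_width_days=bin_width_days, horizon_days=horizon_days)


def discretize_time(time_days: float, grid: TimeGrid) -> int:
    """Bin index of ``time_days`` on ``grid``.

    Day 0 maps to bin 0; bin ``t`` covers days ``((t-1)*w, t*w]``.  Times
    beyond the horizon are clamped to the last bin.
    """
    if time_days < 0:
        raise ValueError(f"time_days must be non-negative, got {time_days}")
    return min(math.ceil(time_days / grid.bin_width_days), grid.n_bins - 1)
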