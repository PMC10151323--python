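"""Cohort-level domain types and rules: event adjudication, labeling,
imputation, normalization and stratified splitting.

Events follow the registry convention: every patient contributes the first
adverse event only (all-cause death, acute coronary syndrome, or coronary
revascularization), otherwise right-censoring at last follow-up.  Same-day
ties are resolved with the precedence death > ACS > revascularization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import TimeGrid, discretize_time

__all__ = [
    "EventKind",
    "EVENT_NAMES",
    "CAUSES",
    "CLINICAL_FEATURES",
    "BINARY_FEATURES",
    "OutcomeRecord",
    "adjudicate_events",
    "outcomes_to_arrays",
    "Imputer",
    "Normalizer",
    "stratified_kfold",
    "filter_early_revasc",
    "label_fixed_time",
]


class EventKind(IntEnum):
    """First-event type; integer codes are the model's cause indices + 1."""

    CENSORED = 0
    ACS = 1
    DEATH = 2
    REVASCULARIZATION = 3


EVENT_NAMES = {
    EventKind.CENSORED: "censored",
    EventKind.ACS: "ACS",
    EventKind.DEATH: "death",
    EventKind.REVASCULARIZATION: "revascularization",
}
_NAME_TO_KIND = {v: k for k, v in EVENT_NAMES.items()}

#: The competing causes, in cause-index order (0, 1, 2).
CAUSES = ("ACS", "death", "revascularization")

# Same-day adjudication precedence: death beats everything, ACS beats
# revascularization.
_PRECEDENCE = {
    EventKind.DEATH: 0,
    EventKind.ACS: 1,
    EventKind.REVASCULARIZATION: 2,
}

#: Clinical covariates, in column order.  The 15th slot is configurable; the
#: default is left-ventricular ejection fraction.
CLINICAL_FEATURES = (
    "age",
    "sex_male",
    "bmi",
    "prior_pci",
    "prior_cabg",
    "prior_tavr",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "family_history",
    "stress_pharmacologic",
    "resting_hr",
    "peak_stress_hr",
    "peak_stress_sbp",
    "lvef",
)

BINARY_FEATURES = (
    "sex_male",
    "prior_pci",
    "prior_cabg",
    "prior_tavr",
    "hypertension",
    "diabetes",
    "dyslipidemia",
    "family_history",
    "stress_pharmacologic",
)


@dataclass(frozen=True)
class OutcomeRecord:
    """Adjudicated first event (or censoring) for one patient."""

    event_kind: EventKind
    time_days: int

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("time_days must be non-negative")

    def bin_index(self, grid: TimeGrid) -> int:
        return discretize_time(self.time_days, grid)


def _as_kind(kind) -> EventKind:
    if isinstance(kind, EventKind):
        return kind
    if isinstance(kind, str):
        try:
            return _NAME_TO_KIND[kind]
        except KeyError:
            raise ValueError(f"unknown event kind {kind!r}") from None
    return EventKind(kind)


def adjudicate_events(
    raw_events: Iterable[tuple], last_followup_day: int
) -> OutcomeRecord:
    """Reduce a patient's raw event list to the single first event.

    The earliest event wins; same-day ties are resolved with the precedence
    death > ACS > revascularization.  A patient with no events is censored at
    ``last_followup_day``.

    Parameters
    ----------
    raw_events : iterable of (kind, day)
        ``kind`` may be an :class:`EventKind`, its integer code or its name.
    last_followup_day : int
        End of follow-up; must not precede any event.
    """
    events = [(_as_kind(k), int(d)) for k, d in raw_events]
    for kind, day in events:
        if day < 0:
            raise ValueError(f"event day must be non-negative, got {day}")
        if day > last_followup_day:
            raise ValueError(
                f"{EVENT_NAMES[kind]} at day {day} is after the end of "
                f"follow-up (day {last_followup_day})"
            )
        if kind == EventKind.CENSORED:
            raise ValueError("censoring is derived, not a raw event")
    if last_followup_day < 0:
        raise ValueError("last_followup_day must be non-negative")
    if not events:
        return OutcomeRecord(EventKind.CENSORED, int(last_followup_day))
    kind, day = min(events, key=lambda e: (e[1], _PRECEDENCE[e[0]]))
    return OutcomeRecord(kind, day)


def outcomes_to_arrays(
    outcomes: pd.DataFrame, grid: TimeGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (event_code, time_days, bin_index) arrays from an outcomes frame.

    ``outcomes`` needs columns ``event_kind`` (names or codes) and
    ``time_days``.
    """
    kinds = outcomes["event_kind"]
    if kinds.dtype == object:
        event = kinds.map(lambda s: int(_as_kind(s))).to_numpy(dtype=np.int64)
    else:
        event = kinds.to_numpy(dtype=np.int64)
    time_days = outcomes["time_days"].to_numpy(dtype=np.int64)
    bins = np.minimum(
        np.ceil(time_days / grid.bin_width_days).astype(np.int64),
        grid.n_bins - 1,
    )
    return event, time_days, bins


# ---------------------------------------------------------------------------
# Imputation and normalization


@dataclass
class Imputer:
    """Train-set mean/mode imputation for the clinical table.

    Continuous features get the training mean of non-missing values;
    categorical (binary) features get the training mode, with the smallest
    value winning ties.  Non-missing entries are never modified.
    """

    binary_features: Sequence[str] | None = None
    statistics_: dict = field(default_factory=dict, repr=False)
    kinds_: dict = field(default_factory=dict, repr=False)

    def fit(self, X: pd.DataFrame) -> "Imputer":
        binary = set(
            self.binary_features
            if self.binary_features is not None
            else _detect_binary(X)
        )
        self.statistics_ = {}
        self.kinds_ = {}
        for col in X.columns:
            vals = X[col].dropna()
            if vals.empty:
                raise ValueError(f"feature {col!r} is entirely missing in training data")
            if col in binary:
                counts = vals.value_counts()
                top = counts[counts == counts.max()].index.min()
                self.statistics_[col] = top
                self.kinds_[col] = "categorical"
            else:
                self.statistics_[col] = float(vals.mean())
                self.kinds_[col] = "continuous"
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not self.statistics_:
            raise RuntimeError("Imputer is not fitted")
        out = X.copy()
        for col, stat in self.statistics_.items():
            out[col] = out[col].fillna(stat)
        return out

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def _detect_binary(X: pd.DataFrame) -> list[str]:
    known = [c for c in X.columns if c in BINARY_FEATURES]
    if known:
        return known
    out = []
    for col in X.columns:
        vals = X[col].dropna().unique()
        if len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            out.append(col)
    return out


@dataclass
class Normalizer:
    """Scale model inputs using training statistics only.

    Polar-map pixels (0-100 scale) are divided by 100.  Continuous clinical
    features are standardized with the training mean and SD; binary features
    pass through unchanged.  A constant continuous feature is centered only,
    with a warning.
    """

    binary_features: Sequence[str] | None = None
    mean_: pd.Series | None = field(default=None, repr=False)
    scale_: pd.Series | None = field(default=None, repr=False)

    def fit(self, clinical: pd.DataFrame) -> "Normalizer":
        binary = set(
            self.binary_features
            if self.binary_features is not None
            else _detect_binary(clinical)
        )
        mean = {}
        scale = {}
        for col in clinical.columns:
            if col in binary:
                mean[col] = 0.0
                scale[col] = 1.0
            else:
                mu = float(clinical[col].mean())
                sd = float(clinical[col].std(ddof=0))
                if sd == 0.0:
                    warnings.warn(
                        f"feature {col!r} is constant in training data; "
                        "centering without scaling"
                    )
                    sd = 1.0
                mean[col] = mu
                scale[col] = sd
        self.mean_ = pd.Series(mean)
        self.scale_ = pd.Series(scale)
        return self

    def transform_clinical(self, clinical: pd.DataFrame) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Normalizer is not fitted")
        cols = list(self.mean_.index)
        arr = clinical[cols].to_numpy(dtype=np.float64)
        return (arr - self.mean_.to_numpy()) / self.scale_.to_numpy()

    @staticmethod
    def transform_maps(maps: np.ndarray) -> np.ndarray:
        """Scale 0-100 polar-map pixels into [0, 1]."""
        return np.asarray(maps, dtype=np.float64) / 100.0


# ---------------------------------------------------------------------------
# Splitting, filtering, labeling


def stratified_kfold(
    outcomes: pd.DataFrame, k: int = 10, seed: int = 0
) -> np.ndarray:
    """Assign each patient a fold id in ``{0..k-1}``, stratified by event kind.

    Within each event-kind stratum patients are shuffled and dealt
    round-robin, so fold sizes per stratum differ by at most one patient.
    Deterministic for a given seed.
    """
    n = len(outcomes)
    if n < k:
        raise ValueError(f"cohort of {n} patients cannot be split into {k} folds")
    kinds = outcomes["event_kind"]
    if kinds.dtype == object:
        strata = kinds.map(lambda s: int(_as_kind(s))).to_numpy()
    else:
        strata = kinds.to_numpy()
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    offset = 0
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if len(idx) < k:
            warnings.warn(
                f"stratum {s} has fewer patients ({len(idx)}) than folds ({k}); "
                "distributing round-robin"
            )
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # rotate so small strata do not pile on fold 0
    return fold


def filter_early_revasc(
    outcomes: pd.DataFrame, window_days: int = 180
) -> np.ndarray:
    """Boolean keep-mask removing first-event revascularizations within
    ``window_days`` of the scan (sensitivity analysis)."""
    event, time_days, _ = outcomes["event_kind"], outcomes["time_days"], None
    if event.dtype == object:
        is_revasc = event == "revascularization"
    else:
        is_revasc = event == int(EventKind.REVASCULARIZATION)
    early = is_revasc & (time_days <= window_days)
    return ~early.to_numpy()


def label_fixed_time(
    outcomes: pd.DataFrame,
    t_days: int,
    event_kind: str = "MACE",
    grid: TimeGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels for fixed-time AUC analysis at ``t_days``.

    Positive if the specified event (any event for ``"MACE"``) occurred at or
    before ``t_days``; negative if the patient was followed beyond ``t_days``
    without it.  Patients censored before ``t_days`` without an event are
    excluded via the returned mask, as are patients whose competing first
    event precedes ``t_days`` (for a cause-specific analysis they are neither
    cases nor observable controls).

    Returns
    -------
    labels : int array (n,)
    include : bool array (n,)
    """
    if grid is not None and t_days > grid.horizon_days:
        raise ValueError(f"t_days={t_days} is beyond the grid horizon")
    event, time_days, _ = outcomes_to_arrays(
        outcomes, grid or TimeGrid()
    )
    if event_kind == "MACE":
        is_target = event > 0
    else:
        code = int(_as_kind(event_kind))
        is_target = event == code
    is_other_event = (event > 0) & ~is_target

    labels = (is_target & (time_days <= t_days)).astype(np.int64)
    followed_past = time_days > t_days
    include = (labels == 1) | followed_past
    # competing events before t: excluded from the cause-specific analysis
    include &= ~(is_other_event & (time_days <= t_days))
    return labels, include
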