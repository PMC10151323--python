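"""Censoring-aware evaluation metrics.

* cumulative/dynamic AUC with inverse-probability-of-censoring weights
  (IPCW): discrimination between patients failing by time ``t`` and those
  still event-free beyond ``t``, as a curve over ``t``;
* time-dependent concordance: among comparable pairs, the patient failing
  earlier should have the higher predicted incidence at their failure time;
* fixed-time AUC with DeLong comparison of paired markers;
* percentile bootstrap confidence intervals (100 resamples by default).

For event-specific metrics, competing first events are censored at their
event time (cause-specific convention).  Ties in any concordance indicator
count one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import norm, rankdata

from .cohort import EventKind, outcomes_to_arrays
from .grid import TimeGrid

__all__ = [
    "CensoringModel",
    "MetricCurve",
    "fit_censoring_km",
    "cumulative_dynamic_auc",
    "td_concordance",
    "fixed_time_auc",
    "delong_compare",
    "bootstrap_ci",
    "default_eval_times",
]

_EVENT_CODE = {
    "ACS": int(EventKind.ACS),
    "death": int(EventKind.DEATH),
    "revascularization": int(EventKind.REVASCULARIZATION),
}


def _event_time(outcomes: pd.DataFrame, grid: TimeGrid | None = None):
    return outcomes_to_arrays(outcomes, grid or TimeGrid())[:2]


@dataclass
class CensoringModel:
    """Kaplan-Meier estimate of the censoring survival function G(t)."""

    kmf: KaplanMeierFitter = field(repr=False)

    def survival(self, times) -> np.ndarray:
        return self.kmf.survival_function_at_times(np.asarray(times)).to_numpy()

    def weights(self, times) -> np.ndarray:
        """IPCW weights 1/G(t); error where G has hit zero."""
        g = self.survival(times)
        if (g <= 0).any():
            bad = np.asarray(times)[g <= 0]
            raise ValueError(
                f"censoring survival is zero at required time(s) {bad[:5]}; "
                "restrict evaluation times"
            )
        return 1.0 / g


def fit_censoring_km(outcomes: pd.DataFrame) -> CensoringModel:
    """Kaplan-Meier for the censoring distribution (events are treated as
    censored observations of the censoring time)."""
    event, time = _event_time(outcomes)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=(event == 0).astype(int))
    return CensoringModel(kmf=kmf)


@dataclass
class MetricCurve:
    """A metric evaluated over time, with optional bootstrap bounds."""

    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def mean_over(self, max_days: float = 183.0) -> float:
        """Mean of the defined estimates over times up to ``max_days``
        (the first six months by default)."""
        sel = (self.times <= max_days) & ~np.isnan(self.estimate)
        if not sel.any():
            return float("nan")
        return float(self.estimate[sel].mean())


def _risk_at_times(risks, n: int, n_times: int) -> np.ndarray:
    r = np.asarray(risks, dtype=float)
    if r.ndim == 1:
        return np.broadcast_to(r[:, None], (n, n_times))
    if r.shape != (n, n_times):
        raise ValueError("risks must be (n,) or (n, n_times)")
    return r


def cumulative_dynamic_auc(
    risks,
    outcomes: pd.DataFrame,
    event_kind: str,
    times,
    censoring: CensoringModel | None = None,
) -> MetricCurve:
    """IPCW cumulative/dynamic AUC curve.

    ``risks`` is either one score per patient or an ``(n, len(times))``
    matrix of time-resolved scores (e.g. predicted CIF at each evaluation
    time).  Cases at time ``t`` are patients with the target event at
    ``tau_i <= t``, weighted ``1/G(tau_i)``; controls are patients observed
    beyond ``t``.  Ties in the ranking indicator count one half.  Times with
    no cases or no controls yield NaN (marked, not fabricated).
    """
    times = np.asarray(times, dtype=float)
    event, time = _event_time(outcomes)
    if event_kind == "MACE":
        delta = event > 0
    else:
        delta = event == _EVENT_CODE[event_kind]
    n = len(event)
    risk_mat = _risk_at_times(risks, n, len(times))
    if censoring is None:
        censoring = fit_censoring_km(outcomes)
    w_case = np.zeros(n)
    w_case[delta] = censoring.weights(time[delta])

    auc = np.full(len(times), np.nan)
    for m, t in enumerate(times):
        cases = delta & (time <= t)
        controls = time > t
        if not cases.any() or not controls.any():
            continue
        r = risk_mat[:, m]
        rc = r[cases]
        wc = w_case[cases]
        rj = r[controls]
        # pairwise concordance via ranks: for each case, count controls below
        order = np.argsort(rj, kind="mergesort")
        rj_sorted = rj[order]
        lo = np.searchsorted(rj_sorted, rc, side="left")
        hi = np.searchsorted(rj_sorted, rc, side="right")
        conc = lo + 0.5 * (hi - lo)
        auc[m] = float((wc * conc).sum() / (wc.sum() * len(rj)))
    return MetricCurve(times=times, estimate=auc)


def td_concordance(
    surfaces,
    outcomes: pd.DataFrame,
    event_kind: str,
    grid: TimeGrid | None = None,
) -> float:
    """Time-dependent concordance for one cause.

    ``surfaces`` is the pmf array (n, K, T) (or an object with ``.pmf``),
    or directly a per-patient incidence matrix (n, T) for the cause.  A pair
    (i, j) is comparable when i experienced the target event at ``tau_i``
    and j was still under observation beyond ``tau_i``; it is concordant
    when ``CIF_k(t_i | x_i) > CIF_k(t_i | x_j)``, ties count one half.
    """
    pmf = getattr(surfaces, "pmf", surfaces)
    pmf = np.asarray(pmf, dtype=float)
    grid = grid or TimeGrid()
    event, time, bins = outcomes_to_arrays(outcomes, grid)
    if pmf.ndim == 3:
        k = _EVENT_CODE[event_kind] - 1
        cif = np.cumsum(pmf[:, k, :], axis=1)
    elif pmf.ndim == 2:
        cif = pmf  # already a per-patient incidence matrix for the cause
    else:
        raise ValueError("surfaces must be (n, K, T) pmf or (n, T) incidence")
    delta = event == _EVENT_CODE[event_kind]

    num = 0.0
    den = 0
    for i in np.flatnonzero(delta):
        at_risk = time > time[i]
        if not at_risk.any():
            continue
        ri = cif[i, bins[i]]
        rj = cif[at_risk, bins[i]]
        num += float((rj < ri).sum()) + 0.5 * float((rj == ri).sum())
        den += int(at_risk.sum())
    if den == 0:
        raise ValueError(f"no comparable pairs for event {event_kind!r}")
    return num / den


def fixed_time_auc(labels, scores) -> float:
    """Mann-Whitney AUC with tie correction."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("fixed-time AUC needs both cases and controls")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _midrank_structure(pos, neg):
    """DeLong placement values V10 (cases) and V01 (controls)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rk = rankdata(allv)
    rk_pos = rankdata(pos)
    rk_neg = rankdata(neg)
    v10 = (rk[:m] - rk_pos) / n
    v01 = 1.0 - (rk[m:] - rk_neg) / m
    return v10, v01


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong comparison of two paired markers on the same labels.

    Returns ``(auc_a, auc_b, p)`` with a two-sided normal p-value for the
    AUC difference; identical markers give a difference of zero and p = 1.
    """
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("DeLong comparison needs both cases and controls")
    aucs = []
    v10s, v01s = [], []
    for s in (np.asarray(scores_a, float), np.asarray(scores_b, float)):
        v10, v01 = _midrank_structure(s[pos], s[neg])
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(v10.mean())
    v10s = np.vstack(v10s)
    v01s = np.vstack(v01s)
    s10 = np.cov(v10s)
    s01 = np.cov(v01s)
    cov = s10 / v10s.shape[1] + s01 / v01s.shape[1]
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


def bootstrap_ci(
    metric_fn,
    n: int,
    B: int = 100,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[float, float, float]:
    """Percentile bootstrap over patient-level resamples.

    ``metric_fn`` maps an index array (a resample of ``range(n)``) to a
    scalar; resamples on which it raises or returns NaN are redrawn up to
    ``max_retries`` times each (logged as a warning).

    Returns ``(mean, lower, upper)`` with 2.5/97.5 percentile bounds.
    """
    rng = np.random.default_rng(seed)
    vals = []
    n_redrawn = 0
    for _ in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                v = float(metric_fn(idx))
            except Exception:
                v = float("nan")
            if np.isfinite(v):
                vals.append(v)
                break
            n_redrawn += 1
        else:
            raise RuntimeError("metric undefined on too many bootstrap resamples")
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} bootstrap resamples with undefined metric")
    vals = np.asarray(vals)
    return float(vals.mean()), float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def default_eval_times(
    outcomes: pd.DataFrame, step_days: int = 30, upper_quantile: float = 0.95
) -> np.ndarray:
    """Evaluation grid from the first observed event to the ``upper_quantile``
    of follow-up, keeping the censoring survival strictly positive."""
    event, time = _event_time(outcomes)
    if not (event > 0).any():
        raise ValueError("cohort has no events")
    lo = time[event > 0].min()
    hi = np.quantile(time, upper_quantile)
    start = max(step_days, int(np.ceil(lo / step_days)) * step_days)
    return np.arange(start, hi, step_days, dtype=float)
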