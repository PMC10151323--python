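"""Synthetic cohort generator with known ground-truth hazards.

Emulates the statistical structure the risk model assumes, with full oracle
access for testing:

* clinical covariates with registry-like marginals (age ~64, 57% male, 26%
  diabetes, ...), correlated through a Gaussian copula (age with resting
  heart rate; defect occurrence with prior PCI);
* polar-map stacks = smooth radial template (normal zones near 75-100 on the
  0-100 scale) minus a localized Gaussian-shaped defect, plus pixel noise;
  the true defect extent ``E`` is the fraction of perfusion pixels the
  noiseless defect pushes below a threshold fraction of the template;
* competing-risks event times drawn from discrete cause-specific hazards
  ``h_k(t|x) = logistic(b_k0(t) + beta_k' x + gamma_k E)`` on a 30-day grid,
  with independent dropout and administrative censoring.

Because the hazards are known, cumulative incidence functions are available
analytically and serve as oracles:
``CIF_k(t|x) = sum_{s<=t} h_k(s|x) * prod_{u<s}(1 - sum_j h_j(u|x))``.

Default coefficients are calibrated so that over five years roughly 5-6% of
patients die, ~3% have an acute coronary syndrome and ~7% undergo
revascularization, mirroring the derivation-cohort prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .cohort import BINARY_FEATURES, CAUSES, CLINICAL_FEATURES
from .grid import TimeGrid
from .io import MAP_SHAPE, Cohort

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "defect_driven_config",
    "generate_clinical",
    "generate_polar_maps",
    "compute_hazards",
    "sample_outcomes",
    "generate_cohort",
    "true_cif",
    "polar_map_template",
]

# Marginals loosely matched to the derivation cohort's Table-1-style summary.
_CONT_MARGINALS = {
    "age": (64.0, 12.0, 25.0, 95.0),
    "bmi": (27.8, 4.8, 15.0, 55.0),
    "resting_hr": (69.0, 13.0, 35.0, 130.0),
    "peak_stress_hr": (119.0, 32.0, 50.0, 220.0),
    "peak_stress_sbp": (150.0, 28.0, 70.0, 260.0),
    "lvef": (60.0, 12.0, 10.0, 85.0),
}
_BIN_PREVALENCE = {
    "sex_male": 0.57,
    "prior_pci": 0.19,
    "prior_cabg": 0.083,
    "prior_tavr": 0.002,
    "hypertension": 0.63,
    "diabetes": 0.26,
    "dyslipidemia": 0.63,
    "family_history": 0.28,
    "stress_pharmacologic": 0.52,
}

# Cause-specific log-odds per standardized covariate, CLINICAL_FEATURES order.
_DEFAULT_BETAS = {
    "ACS": np.array(
        [0.25, 0.40, 0.0, 0.70, 0.40, 0.20, 0.30, 0.30, 0.30, 0.10,
         0.40, 0.0, -0.35, -0.10, -0.20]
    ),
    "death": np.array(
        [0.90, 0.15, -0.10, 0.10, 0.20, 0.30, 0.20, 0.35, 0.0, -0.10,
         0.70, 0.30, -0.45, -0.35, -0.50]
    ),
    "revascularization": np.array(
        [0.15, 0.60, 0.0, 0.50, 0.30, 0.0, 0.20, 0.30, 0.40, -0.10,
         0.20, 0.05, -0.10, 0.0, -0.15]
    ),
}
_DEFAULT_GAMMAS = {"ACS": 3.0, "death": 2.0, "revascularization": 5.0}
# Per-bin baseline log-odds; calibrated against the target five-year
# prevalences by simulation at n=200,000 (see docs/methods.md).
_DEFAULT_INTERCEPTS = {"ACS": -7.54, "death": -7.50, "revascularization": -6.63}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 1000
    seed: int = 0
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(30, 1890))
    continuous_marginals: Mapping = field(
        default_factory=lambda: dict(_CONT_MARGINALS)
    )
    binary_prevalence: Mapping = field(
        default_factory=lambda: dict(_BIN_PREVALENCE)
    )
    # copula correlations
    corr_age_resting_hr: float = 0.30
    corr_defect_prior_pci: float = 0.45
    # defect geometry on the 28 x 36 (radius x angle) raster
    defect_probability: float = 0.40
    amplitude_range: tuple = (25.0, 65.0)
    sigma_r_range: tuple = (2.0, 6.0)
    sigma_theta_range: tuple = (2.0, 7.0)
    channel_defect_weights: tuple = (1.0, 0.6, 0.6, 0.3, 0.4)
    noise_sd: float = 2.0
    extent_threshold: float = 0.3  # defect depth, as fraction of template
    # hazard model
    betas: Mapping = field(default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_BETAS.items()})
    gammas: Mapping = field(default_factory=lambda: dict(_DEFAULT_GAMMAS))
    intercepts: Mapping = field(default_factory=lambda: dict(_DEFAULT_INTERCEPTS))
    # censoring
    followup_min_days: int = 1095
    followup_max_days: int = 1825
    dropout_hazard: float = 0.003  # per 30-day bin
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for name, p in self.binary_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        lo, hi = self.amplitude_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValueError("amplitude_range must lie within [0, 100]")
        for cause in CAUSES:
            if len(np.asarray(self.betas[cause])) != len(CLINICAL_FEATURES):
                raise ValueError(f"beta vector for {cause} must have length 15")


def default_config(n_patients: int = 1000, seed: int = 0, **overrides) -> SyntheticConfig:
    return replace(SyntheticConfig(n_patients=n_patients, seed=seed), **overrides)


def defect_driven_config(n_patients: int = 1000, seed: int = 0, **overrides) -> SyntheticConfig:
    """Conditions in which the perfusion-defect extent dominates all hazards.

    Clinical effects are attenuated and the defect effects amplified, so an
    image-aware model has a genuine advantage over a clinical-only one.
    """
    cfg = SyntheticConfig(n_patients=n_patients, seed=seed)
    betas = {k: 0.3 * np.asarray(v, dtype=float) for k, v in cfg.betas.items()}
    gammas = {"ACS": 6.0, "death": 7.0, "revascularization": 9.0}
    intercepts = {"ACS": -7.45, "death": -7.10, "revascularization": -6.77}
    cfg = replace(
        cfg,
        betas=betas,
        gammas=gammas,
        intercepts=intercepts,
        defect_probability=0.6,
        **overrides,
    )
    return cfg


@dataclass
class SyntheticTruth:
    """Oracle: per-patient discrete cause-specific hazards and defect extent."""

    hazards: np.ndarray  # (n, K, T)
    extent: np.ndarray  # (n,)
    grid: TimeGrid

    def __post_init__(self) -> None:
        if (self.hazards < 0).any() or (self.hazards > 1).any():
            raise ValueError("hazards must lie in [0, 1]")
        if (self.hazards.sum(axis=1) > 1.0 + 1e-12).any():
            raise ValueError("total hazard exceeds 1 in some bin")

    def cif(self) -> np.ndarray:
        """Analytic cumulative incidence, shape (n, K, T)."""
        total = self.hazards.sum(axis=1)  # (n, T)
        surv_before = np.cumprod(1.0 - total, axis=1)
        surv_before = np.concatenate(
            [np.ones_like(surv_before[:, :1]), surv_before[:, :-1]], axis=1
        )
        return np.cumsum(self.hazards * surv_before[:, None, :], axis=2)

    def survival(self) -> np.ndarray:
        """Analytic event-free survival S(t), shape (n, T)."""
        return np.cumprod(1.0 - self.hazards.sum(axis=1), axis=1)


def true_cif(truth: SyntheticTruth, patient: int, event: str, t_bin: int) -> float:
    """Oracle CIF for one patient, cause and bin index."""
    if event not in CAUSES:
        raise ValueError(f"unknown event {event!r}; expected one of {CAUSES}")
    k = CAUSES.index(event)
    return float(truth.cif()[patient, k, t_bin])


# ---------------------------------------------------------------------------
# Covariates


def generate_clinical(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the complete (pre-missingness) clinical table and defect flags."""
    n = config.n_patients
    # Gaussian copula over (age, resting_hr, defect_latent, pci_latent)
    r1, r2 = config.corr_age_resting_hr, config.corr_defect_prior_pci
    corr = np.array(
        [
            [1.0, r1, 0.0, 0.0],
            [r1, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, r2],
            [0.0, 0.0, r2, 1.0],
        ]
    )
    z = rng.multivariate_normal(np.zeros(4), corr, size=n, method="cholesky")

    cols = {}
    for name in CLINICAL_FEATURES:
        if name in config.continuous_marginals:
            mu, sd, lo, hi = config.continuous_marginals[name]
            if name == "age":
                draw = mu + sd * z[:, 0]
            elif name == "resting_hr":
                draw = mu + sd * z[:, 1]
            else:
                draw = mu + sd * rng.standard_normal(n)
            cols[name] = np.clip(np.round(draw, 1), lo, hi)
        else:
            p = config.binary_prevalence[name]
            if name == "prior_pci":
                cols[name] = (z[:, 3] < ndtri(p)).astype(float)
            else:
                cols[name] = (rng.random(n) < p).astype(float)
    has_defect = z[:, 2] < ndtri(config.defect_probability)
    return pd.DataFrame(cols, columns=list(CLINICAL_FEATURES)), has_defect


# ---------------------------------------------------------------------------
# Polar maps


def polar_map_template() -> np.ndarray:
    """Smooth noiseless normal template, shape (5, 28, 36), 0-100 scale."""
    r = np.arange(28)[:, None] / 27.0
    theta = np.arange(36)[None, :] * (2.0 * np.pi / 36.0)
    shape = -8.0 * r**2 + 2.0 * np.cos(theta)
    base = np.array([92.0, 88.0, 86.0, 82.0, 85.0])
    return base[:, None, None] + shape[None, :, :]


def draw_defects(
    config: SyntheticConfig, has_defect: np.ndarray, rng: np.random.Generator
) -> dict:
    """Draw per-patient defect geometry (amplitude 0 when no defect)."""
    n = len(has_defect)
    return {
        "amplitude": np.where(
            has_defect, rng.uniform(*config.amplitude_range, size=n), 0.0
        ),
        "sigma_r": rng.uniform(*config.sigma_r_range, size=n),
        "sigma_theta": rng.uniform(*config.sigma_theta_range, size=n),
        "center_r": rng.uniform(4.0, 24.0, size=n),
        "center_theta": rng.uniform(0.0, 36.0, size=n),
    }


def _defect_bumps(defects: dict, idx: slice) -> np.ndarray:
    """Noiseless defect fields for a slice of patients, shape (m, 28, 36)."""
    rr = np.arange(28)[None, :, None]
    tt = np.arange(36)[None, None, :]
    ct = defects["center_theta"][idx, None, None]
    dtheta = np.minimum(np.abs(tt - ct), 36.0 - np.abs(tt - ct))
    return defects["amplitude"][idx, None, None] * np.exp(
        -0.5
        * (
            (rr - defects["center_r"][idx, None, None]) ** 2
            / defects["sigma_r"][idx, None, None] ** 2
            + dtheta**2 / defects["sigma_theta"][idx, None, None] ** 2
        )
    )


def true_extent(config: SyntheticConfig, defects: dict) -> np.ndarray:
    """Defect extent: fraction of perfusion pixels whose noiseless defect
    depth exceeds ``extent_threshold`` times the template."""
    perf_template = polar_map_template()[0]
    n = len(defects["amplitude"])
    extent = np.empty(n)
    for lo in range(0, n, 4096):
        sl = slice(lo, min(lo + 4096, n))
        bump = _defect_bumps(defects, sl)
        extent[sl] = (bump > config.extent_threshold * perf_template).mean(
            axis=(1, 2)
        )
    return extent


def render_polar_maps(
    config: SyntheticConfig, defects: dict, rng: np.random.Generator
) -> np.ndarray:
    """Render noisy polar-map stacks (n, 5, 28, 36) from defect geometry."""
    template = polar_map_template()
    weights = np.asarray(config.channel_defect_weights)
    n = len(defects["amplitude"])
    maps = np.empty((n, *MAP_SHAPE))
    for lo in range(0, n, 2048):
        sl = slice(lo, min(lo + 2048, n))
        bump = _defect_bumps(defects, sl)
        noise = rng.normal(0.0, config.noise_sd, size=(bump.shape[0], *MAP_SHAPE))
        maps[sl] = np.clip(
            template[None]
            - weights[None, :, None, None] * bump[:, None, :, :]
            + noise,
            0.0,
            100.0,
        )
    return maps


def generate_polar_maps(
    config: SyntheticConfig,
    has_defect: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Polar-map stacks on the 0-100 scale and true defect extents ``E``."""
    defects = draw_defects(config, has_defect, rng)
    extent = true_extent(config, defects)
    maps = render_polar_maps(config, defects, rng)
    return maps, extent


# ---------------------------------------------------------------------------
# Outcomes


def _standardize(config: SyntheticConfig, clinical: pd.DataFrame) -> np.ndarray:
    """Population-standardized covariates used inside the hazard model."""
    out = np.empty((len(clinical), len(CLINICAL_FEATURES)))
    for j, name in enumerate(CLINICAL_FEATURES):
        x = clinical[name].to_numpy(dtype=float)
        if name in config.continuous_marginals:
            mu, sd, _, _ = config.continuous_marginals[name]
            out[:, j] = (x - mu) / sd
        else:
            out[:, j] = x - config.binary_prevalence[name]
    return out


def compute_hazards(
    config: SyntheticConfig, clinical: pd.DataFrame, extent: np.ndarray
) -> np.ndarray:
    """True discrete cause-specific hazards, shape (n, K, T)."""
    xs = _standardize(config, clinical)
    T = config.grid.n_bins
    n = len(clinical)
    hazards = np.empty((n, len(CAUSES), T))
    for k, cause in enumerate(CAUSES):
        b0 = np.broadcast_to(np.asarray(config.intercepts[cause], dtype=float), (T,))
        lp = xs @ np.asarray(config.betas[cause], dtype=float)
        lp = lp + config.gammas[cause] * extent
        hazards[:, k, :] = expit(b0[None, :] + lp[:, None])
    if (hazards.sum(axis=1) > 1.0).any():
        raise ValueError("configuration yields total per-bin hazard above 1")
    return hazards


def _day_within_bin(bins: np.ndarray, width: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform integer day inside each right-closed bin; bin 0 is day 0."""
    lo = (bins - 1) * width + 1
    day = rng.integers(lo, bins * width, endpoint=True)
    return np.where(bins == 0, 0, day)


def sample_outcomes(
    config: SyntheticConfig,
    clinical: pd.DataFrame,
    extent: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw first-event outcomes from the true hazards.

    At each bin, conditional on surviving all earlier bins, cause ``k`` fires
    with probability ``h_k(t|x)``; the joint probability of cell ``(k, t)``
    is therefore ``h_k(t|x) * prod_{s<t}(1 - sum_j h_j(s|x))``, which is
    sampled directly from the analytic joint distribution.  Independent
    censoring comes from a per-bin dropout hazard and an administrative
    follow-up window; the earliest of event and censoring is recorded.
    """
    hazards = compute_hazards(config, clinical, extent)
    truth = SyntheticTruth(hazards=hazards, extent=extent, grid=config.grid)
    n, K, T = hazards.shape
    w = config.grid.bin_width_days

    total = hazards.sum(axis=1)
    surv_before = np.concatenate(
        [np.ones((n, 1)), np.cumprod(1.0 - total, axis=1)[:, :-1]], axis=1
    )
    joint = hazards * surv_before[:, None, :]  # (n, K, T)
    flat = joint.reshape(n, K * T)
    cdf = np.cumsum(flat, axis=1)
    u = rng.random(n)  # mass above cdf[:, -1] means "no event by horizon"
    cell = (cdf < u[:, None]).sum(axis=1)
    has_event = cell < K * T
    ev_cause = np.where(has_event, cell // T, -1)
    ev_bin = np.where(has_event, cell % T, T - 1)
    ev_day = _day_within_bin(ev_bin, w, rng)
    ev_day = np.where(has_event, ev_day, np.iinfo(np.int64).max // 2)

    admin_day = rng.integers(
        config.followup_min_days, config.followup_max_days, size=n, endpoint=True
    )
    if config.dropout_hazard > 0:
        drop_bin = rng.geometric(config.dropout_hazard, size=n)  # 1-based
        drop_day = drop_bin * w - rng.integers(0, w, size=n)
    else:
        drop_day = np.full(n, np.iinfo(np.int64).max // 2)
    censor_day = np.minimum(admin_day, drop_day)

    observed_event = has_event & (ev_day <= censor_day)
    time_days = np.where(observed_event, ev_day, censor_day)
    kind = np.where(
        observed_event,
        np.array(CAUSES, dtype=object)[np.clip(ev_cause, 0, K - 1)],
        "censored",
    )
    outcomes = pd.DataFrame(
        {"event_kind": kind, "time_days": time_days.astype(np.int64)}
    )
    return outcomes, truth


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, SyntheticTruth]:
    """End-to-end draw: clinical table, polar maps, outcomes, truth oracle.

    Missing values (NaN) are injected into a subset of clinical columns at
    ``missing_rate`` after the hazards are computed from the complete data.
    """
    rng = np.random.default_rng(config.seed)
    clinical, has_defect = generate_clinical(config, rng)
    maps, extent = generate_polar_maps(config, has_defect, rng)
    outcomes, truth = sample_outcomes(config, clinical, extent, rng)

    observed = clinical.copy()
    if config.missing_rate > 0:
        for col in ("bmi", "resting_hr", "peak_stress_hr", "peak_stress_sbp", "lvef"):
            mask = rng.random(len(observed)) < config.missing_rate
            observed.loc[mask, col] = np.nan

    ids = np.array([f"P{i:06d}" for i in range(config.n_patients)])
    cohort = Cohort(
        ids=ids,
        clinical=observed.set_axis(ids, axis=0),
        maps=maps,
        outcomes=outcomes,
    )
    return cohort, truth
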