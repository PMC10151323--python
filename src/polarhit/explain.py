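"""Per-patient risk explanation and counterfactual simulation.

The explained scalar is the time-averaged cumulative incidence of one event
("average risk").  Players in the attribution game are the 15 clinical
features plus the 5 polar-map channels treated as atomic units (a channel
is either the patient's pixels or a background patient's pixels); with a
marginal-expectation value function, atomic channel players are equivalent
to summing per-pixel attributions over the channel.

Two estimators are provided: exact Shapley values by subset enumeration
(used when grouping brings the player count to 12 or fewer) and a
Monte-Carlo permutation estimate with a standard error.  Both satisfy the
efficiency axiom: attributions sum to ``f(x) - E[f]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .cohort import CAUSES
from .io import CHANNEL_NAMES

__all__ = [
    "average_risk",
    "Attribution",
    "exact_shapley",
    "mc_shapley",
    "shapley_attributions",
    "waterfall_data",
    "counterfactual_delta",
    "patient_curves",
]


def _event_index(event) -> int:
    if isinstance(event, str):
        if event not in CAUSES:
            raise ValueError(f"unknown event {event!r}; expected one of {CAUSES}")
        return CAUSES.index(event)
    return int(event)


def average_risk(surface, event) -> float:
    """Mean of the event's cumulative incidence over all grid bins.

    ``surface`` is a (K, T) pmf grid, an (n, K, T) batch (averaged over
    patients is NOT done — pass one patient), or an object with ``.pmf``.
    """
    pmf = np.asarray(getattr(surface, "pmf", surface), dtype=float)
    if pmf.ndim == 3:
        if pmf.shape[0] != 1:
            raise ValueError("average_risk explains a single patient")
        pmf = pmf[0]
    k = _event_index(event)
    return float(np.cumsum(pmf[k]).mean())


# ---------------------------------------------------------------------------
# Shapley estimators over a generic value function


def exact_shapley(value_fn, n_players: int) -> np.ndarray:
    """Exact Shapley values by enumeration of all 2^n coalitions."""
    if n_players > 20:
        raise ValueError("exact enumeration is limited to 20 players")
    values = {}
    players = range(n_players)
    for size in range(n_players + 1):
        for coal in combinations(players, size):
            mask = np.zeros(n_players, dtype=bool)
            mask[list(coal)] = True
            values[coal] = value_fn(mask)
    phi = np.zeros(n_players)
    n_fact = factorial(n_players)
    for i in players:
        others = [p for p in players if p != i]
        for size in range(n_players):
            w = factorial(size) * factorial(n_players - size - 1) / n_fact
            for coal in combinations(others, size):
                with_i = tuple(sorted((*coal, i)))
                phi[i] += w * (values[with_i] - values[coal])
    return phi


def mc_shapley(
    value_fn, n_players: int, n_permutations: int = 128, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo permutation estimate of Shapley values.

    Averages marginal contributions over random player orderings; returns
    ``(phi, se)`` where ``se`` is the Monte-Carlo standard error per player.
    Exactly efficient in expectation; each permutation's contributions sum
    to ``v(full) - v(empty)`` exactly, so the efficiency axiom holds for the
    estimate itself.
    """
    rng = rng or np.random.default_rng()
    contribs = np.zeros((n_permutations, n_players))
    for p in range(n_permutations):
        order = rng.permutation(n_players)
        mask = np.zeros(n_players, dtype=bool)
        prev = value_fn(mask)
        for i in order:
            mask[i] = True
            cur = value_fn(mask)
            contribs[p, i] = cur - prev
            prev = cur
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return phi, se


# ---------------------------------------------------------------------------
# Model-facing attribution


@dataclass
class Attribution:
    """Signed per-player contributions to one patient's average risk."""

    features: list
    contributions: np.ndarray
    expected_value: float
    final_value: float
    event: str
    standard_errors: np.ndarray | None = None

    def efficiency_gap(self) -> float:
        return float(self.final_value - self.expected_value - self.contributions.sum())

    def ordered(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"feature": self.features, "contribution": self.contributions}
        )
        df["direction"] = np.where(
            df["contribution"] >= 0, "risk-increasing", "risk-decreasing"
        )
        return df.reindex(
            df["contribution"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)


def _player_names(model) -> list:
    names = list(model.feature_names_in_)
    if model.use_images:
        names += [f"map:{c}" for c in CHANNEL_NAMES]
    return names


def shapley_attributions(
    model,
    patient_maps,
    patient_clinical,
    background,
    event,
    groups: dict | None = None,
    n_permutations: int = 128,
    seed: int = 0,
) -> Attribution:
    """Shapley attribution of one patient's average event risk.

    ``background`` is a ``(maps, clinical DataFrame)`` tuple of training
    patients defining the marginal expectation; ``v(S)`` replaces the
    features outside coalition ``S`` with each background patient's values
    and averages the model's average-risk output over the background.
    ``groups`` optionally maps player names to group labels; if grouping
    leaves at most 12 players the exact enumerating estimator is used,
    otherwise the Monte-Carlo permutation estimator with
    ``n_permutations`` orderings.
    """
    bg_maps, bg_clin = background
    if len(bg_clin) == 0:
        raise ValueError("background set is empty")
    bg_clin = bg_clin.reset_index(drop=True)
    n_bg = len(bg_clin)
    names = _player_names(model)
    n_clin = len(model.feature_names_in_)
    k = _event_index(event)

    if groups:
        labels = [groups.get(nm, nm) for nm in names]
    else:
        labels = list(names)
    uniq = list(dict.fromkeys(labels))
    member = {g: [i for i, l in enumerate(labels) if l == g] for g in uniq}

    pat_clin = np.asarray(patient_clinical, dtype=float).reshape(-1)
    bg_clin_arr = bg_clin.to_numpy(dtype=float)
    if model.use_images:
        pat_maps = np.asarray(patient_maps, dtype=float)
        bg_maps_arr = np.asarray(bg_maps, dtype=float)

    def value_fn(group_mask) -> float:
        mask = np.zeros(len(names), dtype=bool)
        for g, on in zip(uniq, group_mask):
            if on:
                mask[member[g]] = True
        clin = bg_clin_arr.copy()
        clin[:, mask[:n_clin]] = pat_clin[mask[:n_clin]]
        clin_df = pd.DataFrame(clin, columns=model.feature_names_in_)
        if model.use_images:
            maps = bg_maps_arr.copy()
            ch = mask[n_clin:]
            maps[:, ch, :, :] = pat_maps[ch, :, :]
            pmf = model.predict_pmf((maps, clin_df))
        else:
            pmf = model.predict_pmf(clin_df)
        return float(np.cumsum(pmf[:, k, :], axis=1).mean(axis=1).mean())

    n_players = len(uniq)
    ev = value_fn(np.zeros(n_players, dtype=bool))
    fx = value_fn(np.ones(n_players, dtype=bool))
    if n_players <= 12:
        phi = exact_shapley(value_fn, n_players)
        se = None
    else:
        phi, se = mc_shapley(
            value_fn, n_players, n_permutations, np.random.default_rng(seed)
        )
    return Attribution(
        features=uniq,
        contributions=phi,
        expected_value=ev,
        final_value=fx,
        event=event if isinstance(event, str) else CAUSES[k],
        standard_errors=se,
    )


def waterfall_data(attr: Attribution, top_n: int = 10) -> pd.DataFrame:
    """Waterfall-ordered explanation record.

    Rows are ordered by absolute contribution (descending), truncated to
    ``top_n`` with a residual "all others" row; the running total starts at
    the population expected value and ends exactly at the patient's final
    value.
    """
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    ordered = attr.ordered()
    shown = ordered.iloc[:top_n]
    rest = ordered.iloc[top_n:]
    rows = shown.to_dict("records")
    if len(rest):
        resid = float(rest["contribution"].sum())
        rows.append(
            {
                "feature": "all others",
                "contribution": resid,
                "direction": "risk-increasing" if resid >= 0 else "risk-decreasing",
            }
        )
    df = pd.DataFrame(rows)
    df["running_total"] = attr.expected_value + df["contribution"].cumsum()
    df.attrs["expected_value"] = attr.expected_value
    df.attrs["final_value"] = attr.final_value
    return df


def counterfactual_delta(
    model, patient_maps, patient_clinical, modifications: dict, event
) -> dict:
    """What-if simulation: percent risk reduction under feature modification.

    ``modifications`` maps clinical feature names to replacement values (on
    the raw scale); maps are left unchanged and the model's stored training
    statistics re-normalize the modified values.  Returns the percent change
    ``100 * (f_before - f_after) / f_before`` of the average event risk plus
    the full before/after CIF curves for all events.
    """
    for name in modifications:
        if name not in model.feature_names_in_:
            raise ValueError(f"unknown clinical feature {name!r}")
    row = pd.DataFrame(
        [np.asarray(patient_clinical, dtype=float)], columns=model.feature_names_in_
    )
    modified = row.copy()
    for name, val in modifications.items():
        modified[name] = float(val)
    k = _event_index(event)

    def _predict(clin_df):
        if model.use_images:
            maps = np.asarray(patient_maps, dtype=float)[None]
            return model.predict_pmf((maps, clin_df))[0]
        return model.predict_pmf(clin_df)[0]

    pmf_before = _predict(row)
    pmf_after = _predict(modified)
    f_before = float(np.cumsum(pmf_before[k]).mean())
    f_after = float(np.cumsum(pmf_after[k]).mean())
    if f_before == 0:
        raise ZeroDivisionError("baseline average risk is zero; delta undefined")
    return {
        "event": CAUSES[k],
        "percent_change": 100.0 * (f_before - f_after) / f_before,
        "risk_before": f_before,
        "risk_after": f_after,
        "cif_before": np.cumsum(pmf_before, axis=1),
        "cif_after": np.cumsum(pmf_after, axis=1),
    }


def patient_curves(pmf_sets: list, patient: int) -> dict:
    """Per-event CIF curves for one patient across an ensemble of models.

    ``pmf_sets`` holds one (n, K, T) array per model.  Returns, per event,
    the per-model curves and their mean at each bin.
    """
    if len(pmf_sets) == 0:
        raise ValueError("need predictions from at least one model")
    curves = np.stack(
        [np.cumsum(np.asarray(p)[patient], axis=1) for p in pmf_sets]
    )  # (n_models, K, T)
    out = {}
    for k, cause in enumerate(CAUSES):
        out[cause] = {
            "models": curves[:, k, :],
            "mean": curves[:, k, :].mean(axis=0),
        }
    return out
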