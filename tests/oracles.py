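"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the mathematical definitions,
without reference to the package implementations it checks: plain loops
over patients, pairs, coalitions and event paths.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np


def brute_likelihood(pmf, event, bins, floor=1e-12):
    """Mean negative log-likelihood, one patient at a time."""
    n = len(event)
    total = 0.0
    for i in range(n):
        if event[i] > 0:
            p = pmf[i][event[i] - 1][bins[i]]
        else:
            p = sum(
                pmf[i][k][t]
                for k in range(len(pmf[i]))
                for t in range(len(pmf[i][k]))
                if t > bins[i]
            )
        total += -math.log(max(p, floor))
    return total / n


def brute_ranking(pmf, event, bins, sigma):
    """Mean pairwise ranking penalty over all valid (event, pair) triples."""
    pmf = np.asarray(pmf, dtype=float)
    n, K, T = pmf.shape
    cif = np.cumsum(pmf, axis=2)
    total = 0.0
    count = 0
    for k in range(K):
        for i in range(n):
            if event[i] != k + 1:
                continue
            for j in range(n):
                if bins[j] > bins[i]:
                    a = cif[i, k, bins[i]]
                    b = cif[j, k, bins[i]]
                    total += math.exp(-(a - b) / sigma)
                    count += 1
    return total / count if count else 0.0


def brute_cif_by_paths(hazards):
    """CIF by exhaustive enumeration of event paths on a (K, T) hazard table.

    For each cause k and bin t: probability of surviving every bin before t
    (no cause fires) times the probability that k fires at t.
    """
    hazards = np.asarray(hazards, dtype=float)
    K, T = hazards.shape
    cif = np.zeros((K, T))
    for k in range(K):
        acc = 0.0
        for t in range(T):
            surv = 1.0
            for u in range(t):
                surv *= 1.0 - hazards[:, u].sum()
            acc += surv * hazards[k, t]
            cif[k, t] = acc
    return cif


def harrell_c(times, events, scores):
    """Classical concordance index with 0.5 for ties, pairwise loops."""
    num = 0.0
    den = 0
    n = len(times)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if times[j] > times[i]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


def brute_weighted_cauc(risks, times, is_case, weights, t):
    """Cumulative/dynamic AUC at one time by explicit double loop."""
    num = 0.0
    den_case = 0.0
    n_ctrl = 0
    for j in range(len(times)):
        if times[j] > t:
            n_ctrl += 1
    for i in range(len(times)):
        if not (is_case[i] and times[i] <= t):
            continue
        den_case += weights[i]
        for j in range(len(times)):
            if times[j] > t:
                if risks[i] > risks[j]:
                    num += weights[i]
                elif risks[i] == risks[j]:
                    num += 0.5 * weights[i]
    return num / (den_case * n_ctrl)


def brute_auc(labels, scores):
    """AUC by enumerating all case-control pairs."""
    num = 0.0
    den = 0
    for i in range(len(labels)):
        if not labels[i]:
            continue
        for j in range(len(labels)):
            if labels[j]:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def brute_shapley(value_fn, n_players):
    """Shapley values by averaging marginals over every ordering (n! total)."""
    phi = np.zeros(n_players)
    orders = list(permutations(range(n_players)))
    for order in orders:
        mask = np.zeros(n_players, dtype=bool)
        prev = value_fn(mask)
        for i in order:
            mask = mask.copy()
            mask[i] = True
            cur = value_fn(mask)
            phi[i] += cur - prev
            prev = cur
    return phi / len(orders)


def efron_partial_loglik(beta, x, times, events):
    """Efron-corrected Cox partial log-likelihood for a single covariate."""
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in sorted(set(times[events.astype(bool)])):
        D = np.flatnonzero((times == t) & events.astype(bool))
        R = np.flatnonzero(times >= t)
        theta_r = np.exp(beta * x[R]).sum()
        theta_d = np.exp(beta * x[D]).sum()
        d = len(D)
        ll += beta * x[D].sum()
        for ell in range(d):
            ll -= math.log(theta_r - (ell / d) * theta_d)
    return ll
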