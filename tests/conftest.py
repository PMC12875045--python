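"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately coded from first principles, independent of
the package's implementation paths (different root finders, brute-force
enumeration, direct set algebra), so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from evmacro import quant_core, synthetic_data as sd


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_sim():
    """A small complete simulated report + truth + sample sheet."""
    cfg = sd.SimulationConfig(n_proteins=300, seed=42)
    report, truth = sd.simulate_report(cfg)
    return cfg, report, truth, sd.sample_sheet_for(cfg)


@pytest.fixture(scope="session")
def quant_matrix(small_sim):
    cfg, report, truth, sheet = small_sim
    rep = quant_core.validate_report(report, sheet)
    mat = quant_core.filter_protein_groups(rep)
    mat = quant_core.median_center(mat)
    return quant_core.impute_missing(mat, seed=7)


@pytest.fixture(scope="session")
def annotation():
    genes = [f"G{i:04d}" for i in range(300)]
    weights = {"1a": 0.1, "1b": 0.1, "2a": 0.1, "2b": 0.15, "3a": 0.05,
               "4a": 0.15, "5a": 0.15, "unannotated": 0.2}
    return sd.simulate_annotation(genes, weights, seed=9)


# ------------------------------------------------- independent oracles

def moderated_t_oracle(matrix: pd.DataFrame, cols_a, cols_b):
    """Empirical-Bayes moderated t via brentq trigamma inversion.

    Independent of the package's Newton-based route: solves the moment
    equations with a bracketing root finder and recomputes every statistic
    from scratch.
    """
    a = matrix[list(cols_a)].to_numpy(float)
    b = matrix[list(cols_b)].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    dg = na + nb - 2
    lfc = a.mean(1) - b.mean(1)
    s2 = (a.var(1, ddof=1) * (na - 1) + b.var(1, ddof=1) * (nb - 1)) / dg

    z = np.log(s2)
    e = z - special.digamma(dg / 2) + np.log(dg / 2)
    evar = e.var(ddof=1) - special.polygamma(1, dg / 2)
    if evar <= 0:
        d0, s0 = np.inf, np.exp(e.mean())
    else:
        y = optimize.brentq(
            lambda v: special.polygamma(1, v) - evar, 1e-8, 1e8, xtol=1e-14
        )
        d0 = 2 * y
        s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
    post = (d0 * s0 + dg * s2) / (d0 + dg) if np.isfinite(d0) else np.full_like(s2, s0)
    t = lfc / np.sqrt(post * (1 / na + 1 / nb))
    if np.isfinite(d0):
        p = 2 * stats.t.sf(np.abs(t), df=d0 + dg)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    return {"d0": d0, "s0_sq": s0, "t": t, "p": p, "lfc": lfc}


def bh_oracle(p):
    """Direct step-up rule: q_(i) = min_{j>=i} min(1, p_(j) n / j)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_pos, i in enumerate(order):
        cands = [
            min(1.0, p[j] * n / (jpos + 1))
            for jpos, j in enumerate(order)
            if jpos >= rank_pos
        ]
        q[i] = min(cands)
    return q


def hypergeom_enumeration_oracle(universe, term, query_size, k_observed):
    """P(overlap >= k) by enumerating every query draw from the universe."""
    universe = sorted(universe)
    term = set(term)
    hits = 0
    total = 0
    for draw in combinations(universe, query_size):
        total += 1
        if len(set(draw) & term) >= k_observed:
            hits += 1
    return hits / total


def cox_breslow_loglik_oracle(beta, time, event, x):
    """Breslow partial log-likelihood, coded directly from its definition."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def logrank_chi2_lifelines(time, event, group):
    from lifelines.statistics import logrank_test

    g = np.asarray(group, bool)
    res = logrank_test(
        np.asarray(time)[~g], np.asarray(time)[g],
        event_observed_A=np.asarray(event)[~g],
        event_observed_B=np.asarray(event)[g],
    )
    return float(res.test_statistic)
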