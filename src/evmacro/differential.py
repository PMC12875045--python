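"""Empirical-Bayes moderated two-group differential-abundance testing.

Per protein g, with an equal-variance two-group design (n_a vs n_b
samples), the pooled residual variance s_g^2 has d_g = n_a + n_b - 2
degrees of freedom. The empirical-Bayes model places a scaled inverse
chi-square prior on the true variances, with prior df d0 and prior value
s0^2 estimated from the observed log variances by moment matching:

    z_g = log s_g^2,   e_g = z_g - psi(d_g/2) + log(d_g/2)
    var(e) - mean(trigamma(d_g/2)) = trigamma(d0/2)
    mean(e) = log s0^2 + psi(d0/2) - log(d0/2)

(psi = digamma; the trigamma equation is inverted by Newton iteration).
The posterior variance shrinks each s_g^2 toward s0^2,

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),

and the moderated t = log2FC / (s~_g sqrt(1/n_a + 1/n_b)) is referred to a
t distribution with d0 + d_g df. Discoveries are controlled by
Benjamini–Hochberg FDR at 0.05 (a differentially abundant protein, DAP,
has adjusted p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModerationFit",
    "fit_moderated_t",
    "bh_adjust",
    "call_daps",
    "trigamma_inverse",
]


@dataclass
class ModerationFit:
    """Estimated empirical-Bayes hyperparameters and per-protein variances."""

    d0: float  # prior df (may be inf)
    s0_sq: float  # prior variance
    s_sq: pd.Series  # per-protein pooled residual variance
    d_g: float  # residual df (common to all proteins)

    @property
    def posterior_var(self) -> pd.Series:
        if np.isinf(self.d0):
            return pd.Series(self.s0_sq, index=self.s_sq.index)
        return (self.d0 * self.s0_sq + self.d_g * self.s_sq) / (self.d0 + self.d_g)


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y scale."""
    if x <= 0:
        return np.inf
    # trigamma(y) ~ 1/y for large y: start there
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def _fit_f_dist(s_sq: np.ndarray, d_g: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0_sq) from observed variances."""
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s_sq[ok])
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, d_g / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(float(evar))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated_t(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, ModerationFit]:
    """Moderated t contrast of group_a vs group_b sample columns.

    ``matrix`` is a protein x sample log2 DataFrame. Effects are
    log2FC = mean(A) - mean(B). ``d0_override`` forces the prior df
    (0 recovers the ordinary t; inf the fully pooled limit). Returns the
    per-protein result table (log2FC, t, P.Value, adj.P.Val, dap,
    direction) and the :class:`ModerationFit`.
    """
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 samples")
    d_g = float(n_a + n_b - 2)

    lfc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s_sq = ss / d_g

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = _fit_f_dist(s_sq[s_sq > 0], d_g) if (s_sq > 0).any() else (np.inf, 1.0)
    elif not (s_sq > 0).any():
        warnings.warn("all residual variances zero; falling back to d0 = inf")
        d0, s0_sq = np.inf, float(np.mean(s_sq) or 1.0)
    else:
        d0, s0_sq = _fit_f_dist(s_sq, d_g)

    fit = ModerationFit(
        d0=d0, s0_sq=s0_sq, s_sq=pd.Series(s_sq, index=matrix.index), d_g=d_g
    )
    post = fit.posterior_var.to_numpy()
    se = np.sqrt(post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df_total = d_g + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    q = bh_adjust(p)
    res = pd.DataFrame(
        {
            "logFC": lfc,
            "t": t,
            "P.Value": p,
            "adj.P.Val": q,
            "dap": q < alpha,
            "direction": np.where(lfc >= 0, "up-in-A", "up-in-B"),
        },
        index=matrix.index,
    )
    return res, fit


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order preserved.

    q_(i) = min over j >= i of min(1, p_(j) * n / j) on the sorted scale;
    ties broken by stable sort.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def call_daps(result: pd.DataFrame, alpha: float = 0.05) -> tuple[set, set]:
    """Split significant proteins by direction: (up-in-A, up-in-B)."""
    sig = result[result["adj.P.Val"] < alpha]
    up_a = set(sig.index[sig["logFC"] > 0])
    up_b = set(sig.index[sig["logFC"] < 0])
    return up_a, up_b
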