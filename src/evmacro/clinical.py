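"""Survival-association screening and expression-correlation statistics.

Covers the clinically oriented analyses of the pipeline: univariate Cox
proportional-hazards screening of protein levels against relapse-free
survival (RFS), quantile-split Kaplan–Meier comparison with the log-rank
test, a two-group plasma marker screen (Mann–Whitney), simple linear
regression of paired expression profiles, and the bootstrap gene-set
correlation test (is the observed correlation of a marker set better than
that of random gene sets of the same size?).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = [
    "cox_univariate",
    "logrank",
    "km_quantile_split",
    "plasma_marker_screen",
    "regress_paired_expression",
    "bootstrap_geneset_correlation",
]


# ---------------------------------------------------------------- Cox PH

def _cox_loglik(beta: float, t, e, x, ties: str):
    """Log partial likelihood, score and information for one covariate."""
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    ll = 0.0
    score = 0.0
    info = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        dead = (t == ut) & (e == 1)
        d = int(dead.sum())
        s0 = w[at_risk].sum()
        s1 = (w[at_risk] * x[at_risk]).sum()
        s2 = (w[at_risk] * x[at_risk] ** 2).sum()
        xsum = x[dead].sum()
        if ties == "breslow":
            ll += beta * xsum - d * np.log(s0)
            score += xsum - d * s1 / s0
            info += d * (s2 / s0 - (s1 / s0) ** 2)
        elif ties == "efron":
            d0 = w[dead].sum()
            d1 = (w[dead] * x[dead]).sum()
            d2 = (w[dead] * x[dead] ** 2).sum()
            ll += beta * xsum
            for j in range(d):
                f = j / d
                z0 = s0 - f * d0
                z1 = s1 - f * d1
                z2 = s2 - f * d2
                ll -= np.log(z0)
                score += xsum / d - z1 / z0
                info += z2 / z0 - (z1 / z0) ** 2
        else:
            raise ValueError("ties must be 'breslow' or 'efron'")
    return ll, score, info


def cox_univariate(
    cohort: pd.DataFrame,
    protein: str,
    time_col: str = "time_months",
    event_col: str = "event",
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> dict:
    """Univariate Cox proportional-hazards fit for one protein.

    Newton iteration on the partial likelihood (Breslow tie handling by
    default, Efron optional). Returns HR = exp(beta), a 95% Wald CI and the
    two-sided Wald p. Requires >= 2 events and a non-constant level.
    """
    t = cohort[time_col].to_numpy(dtype=float)
    e = cohort[event_col].to_numpy(dtype=int)
    x = cohort[protein].to_numpy(dtype=float)
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {protein!r} is constant")
    beta = 0.0
    for _ in range(max_iter):
        ll, score, info = _cox_loglik(beta, t, e, x, ties)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    _, _, info = _cox_loglik(beta, t, e, x, ties)
    se = float(np.sqrt(1.0 / info)) if info > 0 else np.inf
    z = beta / se if se > 0 else 0.0
    return {
        "protein": protein,
        "beta": float(beta),
        "HR": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
        "se": se,
        "p": float(2.0 * stats.norm.sf(abs(z))),
    }


# ------------------------------------------------------------- log-rank / KM

def logrank_statistic(time, event, group) -> float:
    """Two-group log-rank chi-square statistic (>= 0)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    obs = 0.0
    exp = 0.0
    var = 0.0
    for ut in np.unique(time[event == 1]):
        at_risk = time >= ut
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dead = (time == ut) & (event == 1)
        d = dead.sum()
        d1 = (dead & (group == 1)).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float((obs - exp) ** 2 / var)


def logrank(time, event, group, method: str = "asymptotic") -> dict:
    """Two-group log-rank test.

    ``method="asymptotic"`` refers the statistic to chi-square(1);
    ``method="exact"`` enumerates every group labeling of the same sizes
    and reports the proportion with a statistic >= the observed one
    (feasible for small cohorts; intended for n <= ~10).
    """
    group = np.asarray(group, dtype=int)
    chi2 = logrank_statistic(time, event, group)
    if method == "asymptotic":
        p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    elif method == "exact":
        n = len(group)
        n1 = int(group.sum())
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            lab = np.zeros(n, dtype=int)
            lab[list(idx)] = 1
            total += 1
            if logrank_statistic(time, event, lab) >= chi2 - 1e-12:
                hits += 1
        p = hits / total
    else:
        raise ValueError("method must be 'asymptotic' or 'exact'")
    return {"chi2": chi2, "p": p, "method": method}


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve via lifelines."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": kmf.event_table["at_risk"].reindex(surv.index).to_numpy(),
        }
    )
    return out


def km_quantile_split(
    cohort: pd.DataFrame,
    protein: str,
    quantile: float = 0.5,
    time_col: str = "time_months",
    event_col: str = "event",
    method: str = "asymptotic",
) -> dict:
    """Split subjects into low/high by a protein-level quantile, compare KM.

    "High" subjects exceed the quantile value. Returns per-group KM curves,
    the median survival per group (first time S(t) <= 0.5, NaN if never
    reached), the log-rank chi2/p and the Cox HR of high vs low.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    level = cohort[protein].to_numpy(dtype=float)
    thr = float(np.quantile(level, quantile))
    high = level > thr
    if high.all() or (~high).all():
        raise ValueError("degenerate split: one group is empty")
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy(dtype=int)

    curves = {}
    medians = {}
    for name, sel in [("low", ~high), ("high", high)]:
        cur = km_curve(time[sel], event[sel])
        curves[name] = cur
        below = cur[cur["survival"] <= 0.5]
        medians[name] = float(below["time"].iloc[0]) if len(below) else float("nan")

    lr = logrank(time, event, high.astype(int), method=method)
    split = cohort[[time_col, event_col]].copy()
    split["high"] = high.astype(float)
    hr = cox_univariate(split, "high", time_col=time_col, event_col=event_col)
    return {
        "threshold": thr,
        "quantile": quantile,
        "curves": curves,
        "median_survival": medians,
        "logrank_chi2": lr["chi2"],
        "logrank_p": lr["p"],
        "split_hr": hr["HR"],
    }


# -------------------------------------------------------------- screens

def plasma_marker_screen(
    case: pd.DataFrame, control: pd.DataFrame, exact_max_n: int = 12
) -> pd.DataFrame:
    """Per-protein two-sided Mann–Whitney screen of case vs control levels.

    ``case`` and ``control`` are subject x protein tables sharing columns.
    Exact enumeration is used when the combined sample size is <=
    ``exact_max_n`` (and the data are tie-free); otherwise the normal
    approximation with tie correction. All-tied proteins get p = 1 with a
    flag. Adds BH q and the direction of the case median shift.
    """
    proteins = [c for c in case.columns if c in control.columns]
    if len(case) < 3 or len(control) < 3:
        raise ValueError("need >= 3 subjects per group")
    rows = []
    for p in proteins:
        a = case[p].dropna().to_numpy(dtype=float)
        b = control[p].dropna().to_numpy(dtype=float)
        all_tied = np.ptp(np.concatenate([a, b])) == 0
        if all_tied:
            u, pval, method = len(a) * len(b) / 2.0, 1.0, "degenerate"
        else:
            has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            if len(a) + len(b) <= exact_max_n and not has_ties:
                method = "exact"
            else:
                method = "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            u, pval = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "protein": p,
                "U": u,
                "p": pval,
                "method": method,
                "direction": "up-in-case"
                if np.median(a) >= np.median(b)
                else "down-in-case",
                "all_tied": all_tied,
            }
        )
    out = pd.DataFrame(rows).set_index("protein")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def regress_paired_expression(
    x, y, log10: bool = False
) -> dict:
    """Ordinary least-squares regression of y on x with a slope t-test.

    With ``log10=True`` both profiles are log10-transformed first (the
    convention for TPM-scale expression). Returns slope, intercept, R^2 and
    the two-sided p of the slope (t with n - 2 df).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if log10:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log10 transform requires positive values")
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": len(x),
    }


def bootstrap_geneset_correlation(
    x: pd.Series,
    y: pd.Series,
    markers,
    n_boot: int = 100_000,
    seed: int = 0,
    log10: bool = False,
    plus_one: bool = False,
) -> dict:
    """Is a marker set's cross-profile correlation better than random sets'?

    Computes the observed Pearson correlation of the two profiles over the
    marker genes, then draws ``n_boot`` random gene sets of identical size
    (without replacement within a draw) from the shared universe and
    reports the empirical one-sided p: the fraction of draws whose
    correlation is >= the observed one. ``plus_one`` switches to the
    (hits + 1)/(n_boot + 1) convention.
    """
    common = x.index.intersection(y.index)
    x = x.reindex(common).astype(float)
    y = y.reindex(common).astype(float)
    if log10:
        x, y = np.log10(x), np.log10(y)
    markers = [m for m in markers]
    if len(markers) > len(common):
        raise ValueError("marker set larger than the shared gene universe")
    missing = set(markers) - set(common)
    if missing:
        raise ValueError(f"marker gene(s) not in both profiles: {sorted(missing)[:5]}")
    pos = {g: i for i, g in enumerate(common)}
    midx = np.array([pos[m] for m in markers])
    xv, yv = x.to_numpy(), y.to_numpy()

    def pearson_rows(ix: np.ndarray) -> np.ndarray:
        a = xv[ix]
        b = yv[ix]
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean(axis=-1, keepdims=True)
        num = (a * b).sum(axis=-1)
        den = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        return r

    r_obs = float(pearson_rows(midx[None, :])[0])
    rng = np.random.default_rng(seed)
    m, n = len(markers), len(common)
    # vectorized sampling without replacement within each draw, chunked to
    # bound memory at ~chunk x n floats
    chunk = max(1, min(n_boot, int(4e6 // max(n, 1))))
    parts = []
    done = 0
    while done < n_boot:
        size = min(chunk, n_boot - done)
        keys = rng.random((size, n))
        draws = np.argpartition(keys, m - 1, axis=1)[:, :m]
        parts.append(pearson_rows(draws))
        done += size
    r_null = np.concatenate(parts)
    hits = int((r_null >= r_obs - 1e-15).sum())
    if plus_one:
        p = (hits + 1) / (n_boot + 1)
    else:
        p = hits / n_boot
    return {
        "r_observed": r_obs,
        "n_boot": n_boot,
        "hits": hits,
        "p": float(p),
        "null_mean": float(r_null.mean()),
        "null_r": r_null,
    }
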