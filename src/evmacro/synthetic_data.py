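"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design of the EV-proteome analysis this
package implements: three macrophage subtypes (M1-like, M2-like, TAM-like)
in unpaired biological triplicates, log-normal MaxLFQ protein intensities
with planted group effects on a subset of proteins, intensity-dependent
(missing-not-at-random) dropout, per-run precursor counts and run-specific
protein q-values, MISEV-style category annotation, exponential relapse
times with log-linear protein hazards, and Gaussian-mixture particle sizes
inside the 40–200 nm nano-flow-cytometry window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .misev import SUBCATEGORIES

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_report",
    "simulate_annotation",
    "simulate_category_report",
    "simulate_cohort",
    "simulate_paired_expression",
    "simulate_size_events",
]

#: Bit-exact DIA-NN "report.tsv" dialect column names.
REPORT_COLUMNS = [
    "Run",
    "Protein.Group",
    "Genes",
    "Precursor.Id",
    "Protein.Q.Value",
    "PG.MaxLFQ",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the precursor-report generator.

    Defaults reproduce the study conditions: 3 subtypes x 3 donors,
    10% planted differentially abundant proteins (DAPs) per pairwise
    contrast at |log2FC| = 2 with within-group SD 0.5.
    """

    n_proteins: int = 2000
    groups: tuple[str, ...] = ("M1", "M2", "TAM")
    donors_per_group: int = 3
    dap_fraction: float = 0.1
    effect_size: float = 2.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    missing_mnar_strength: float = 1.0
    precursor_lambda: float = 4.0
    q_fail_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0 or self.donors_per_group <= 0:
            raise ValueError("n_proteins and donors_per_group must be positive")
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for name, frac in [
            ("dap_fraction", self.dap_fraction),
            ("missing_rate", self.missing_rate),
            ("q_fail_fraction", self.q_fail_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.precursor_lambda <= 0:
            raise ValueError("precursor_lambda must be positive")
        if self.missing_mnar_strength < 0:
            raise ValueError("missing_mnar_strength must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: true per-contrast effects and q-failed records.

    ``true_lfc[(A, B)]`` maps protein -> true log2(A) - log2(B); planted
    DAPs are exactly the nonzero entries and carry |lfc| = effect_size.
    """

    group_means: pd.DataFrame  # protein x group true log2 means
    true_lfc: dict[tuple[str, str], pd.Series]
    dap_sets: dict[tuple[str, str], set[str]]
    q_failed: pd.Index  # index of q-failing rows in the report

    def contrasts(self) -> list[tuple[str, str]]:
        return list(self.true_lfc)


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, by resampling zeros."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def _calibrate_mnar_intercept(
    log2_intensity: np.ndarray, slope: float, target_rate: float
) -> float:
    """Solve a in mean(sigmoid(a - slope * y)) = target_rate by bisection.

    The mean drop probability is increasing in a, so bisection converges.
    """
    if target_rate <= 0:
        return -np.inf
    if target_rate >= 1:
        return np.inf

    def mean_rate(a: float) -> float:
        z = a - slope * log2_intensity
        return float(np.mean(1.0 / (1.0 + np.exp(-z))))

    lo, hi = -50.0, 50.0 + slope * float(np.max(np.abs(log2_intensity)))
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_report(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format DIA-NN-style precursor report plus ground truth.

    Each protein may be assigned (with probability 1.5 x dap_fraction) a
    single group in which its true log2 mean is shifted by +-effect_size;
    a pairwise contrast then has planted-DAP probability dap_fraction and
    every planted DAP has |true log2FC| exactly effect_size. Intensities
    are log-normal (base 2); whole (protein, run) cells drop out with
    logistic probability sigma(a - b*log2 intensity), with the intercept a
    calibrated by bisection so the overall missing rate hits
    ``missing_rate``. Each surviving cell contributes one record per
    precursor (zero-truncated Poisson count), all sharing the protein-level
    MaxLFQ value; a ``q_fail_fraction`` of records receive a run-specific
    protein q-value >= 0.01.

    Returns the report (columns exactly ``REPORT_COLUMNS``) and the
    :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    groups = list(config.groups)
    proteins = np.array([f"P{i:05d}" for i in range(n)])
    genes = np.array([f"GENE{i:05d}" for i in range(n)])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    # Plant effects: one group per selected protein, shifted +-effect_size.
    p_assign = min(1.0, 1.5 * config.dap_fraction)
    assigned = rng.random(n) < p_assign
    which_group = rng.integers(0, len(groups), size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    offsets = np.zeros((n, len(groups)))
    offsets[assigned, which_group[assigned]] = (
        sign[assigned] * config.effect_size
    )

    group_means = pd.DataFrame(
        baseline[:, None] + offsets, index=proteins, columns=groups
    )

    true_lfc: dict[tuple[str, str], pd.Series] = {}
    dap_sets: dict[tuple[str, str], set[str]] = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            lfc = pd.Series(offsets[:, groups.index(a)] - offsets[:, groups.index(b)],
                            index=proteins)
            true_lfc[(a, b)] = lfc
            dap_sets[(a, b)] = set(proteins[lfc.to_numpy() != 0.0])

    runs = [f"{g}_D{d + 1}" for g in groups for d in range(config.donors_per_group)]
    run_group = np.repeat(np.arange(len(groups)), config.donors_per_group)

    # protein x run true log2 intensity with within-group noise
    y = (
        group_means.to_numpy()[:, run_group]
        + rng.normal(0.0, config.noise_sd, size=(n, len(runs)))
    )

    a = _calibrate_mnar_intercept(
        y.ravel(), config.missing_mnar_strength, config.missing_rate
    )
    if np.isinf(a) and a < 0:
        observed = np.ones_like(y, dtype=bool)
    else:
        drop_p = 1.0 / (1.0 + np.exp(-(a - config.missing_mnar_strength * y)))
        observed = rng.random(size=y.shape) >= drop_p

    np_counts = _zero_truncated_poisson(rng, config.precursor_lambda, n * len(runs))
    np_counts = np_counts.reshape(n, len(runs))

    prot_idx, run_idx = np.nonzero(observed)
    counts = np_counts[prot_idx, run_idx]
    rec_prot = np.repeat(prot_idx, counts)
    rec_run = np.repeat(run_idx, counts)
    prec_no = np.concatenate([np.arange(1, c + 1) for c in counts]) if len(counts) else np.array([], int)

    n_rec = len(rec_prot)
    q_fail = rng.random(n_rec) < config.q_fail_fraction
    qvals = np.where(
        q_fail,
        rng.uniform(0.01, 1.0, size=n_rec),
        rng.uniform(0.0, 0.01, size=n_rec),
    )

    report = pd.DataFrame(
        {
            "Run": np.array(runs)[rec_run],
            "Protein.Group": proteins[rec_prot],
            "Genes": genes[rec_prot],
            "Precursor.Id": [
                f"{p}_PREC{j}" for p, j in zip(proteins[rec_prot], prec_no)
            ],
            "Protein.Q.Value": qvals,
            "PG.MaxLFQ": np.exp2(y[rec_prot, rec_run]),
        }
    )
    truth = GroundTruth(
        group_means=group_means,
        true_lfc=true_lfc,
        dap_sets=dap_sets,
        q_failed=report.index[q_fail],
    )
    return report, truth


def sample_sheet_for(config: SimulationConfig) -> pd.DataFrame:
    """Run -> (group, donor) mapping matching :func:`simulate_report`."""
    rows = [
        {"Run": f"{g}_D{d + 1}", "group": g, "donor": f"D{d + 1}"}
        for g in config.groups
        for d in range(config.donors_per_group)
    ]
    return pd.DataFrame(rows)


def simulate_annotation(
    genes: Sequence[str],
    category_weights: Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each gene one MISEV subcategory (or leave it unannotated).

    ``category_weights`` maps subcategory codes (plus the pseudo-label
    ``"unannotated"``) to sampling weights; weights are normalized
    internally. Returns a table with columns gene/uniprot/subcategory/source
    containing only the annotated genes, mirroring the curated-list layout.
    """
    labels = list(category_weights)
    for lab in labels:
        if lab != "unannotated" and lab not in SUBCATEGORIES:
            raise ValueError(f"unknown MISEV subcategory: {lab!r}")
    w = np.asarray([category_weights[lab] for lab in labels], dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and sum to > 0")
    rng = np.random.default_rng(seed)
    draw = rng.choice(len(labels), size=len(genes), p=w / w.sum())
    rows = []
    for g, k in zip(genes, draw):
        lab = labels[k]
        if lab == "unannotated":
            continue
        rows.append(
            {
                "gene": g,
                "uniprot": f"Q{abs(hash(g)) % 100000:05d}",
                "subcategory": lab,
                "source": "simulated",
            }
        )
    return pd.DataFrame(rows, columns=["gene", "uniprot", "subcategory", "source"])


def simulate_category_report(
    annotation: pd.DataFrame,
    groups: Sequence[str] = ("M1", "M2", "TAM"),
    donors_per_group: int = 3,
    precursor_lambda: float = 8.0,
    endo_share_ratio: Mapping[str, float] | None = None,
    reference_group: str = "TAM",
    seed: int = 0,
) -> pd.DataFrame:
    """Precursor report with a planted endosomal (cat 1 + 2a) %Np shift.

    For a group with target share ratio r relative to the reference, the
    precursor rate of endosomal proteins is multiplied by m solving
    m*f / (m*f + 1 - f) = r*f where f is the baseline endosomal share of
    proteins; the resulting per-sample endosomal %Np then has expectation
    r times the reference's. All intensities are nuisance here (constant),
    only precursor counts matter for %Np.
    """
    from .misev import MisevOntology

    onto = MisevOntology()
    genes = annotation["gene"].to_numpy()
    sub = annotation["subcategory"].to_numpy()
    endo = np.array([onto.is_endosomal(s) for s in sub])
    f = endo.mean()
    if f in (0.0, 1.0):
        raise ValueError("annotation must contain endosomal and non-endosomal genes")
    endo_share_ratio = dict(endo_share_ratio or {})

    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        r = endo_share_ratio.get(g, 1.0)
        target = r * f
        if not 0 < target < 1:
            raise ValueError(f"target endosomal share {target} outside (0,1)")
        m = target * (1 - f) / (f * (1 - target))
        lam = np.where(endo, m * precursor_lambda, precursor_lambda)
        for d in range(donors_per_group):
            run = f"{g}_D{d + 1}"
            counts = rng.poisson(lam)
            for gene, c in zip(genes, counts):
                for j in range(c):
                    rows.append(
                        {
                            "Run": run,
                            "Protein.Group": gene,
                            "Genes": gene,
                            "Precursor.Id": f"{gene}_PREC{j + 1}",
                            "Protein.Q.Value": 0.001,
                            "PG.MaxLFQ": 1000.0,
                        }
                    )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def simulate_cohort(
    n_subjects: int,
    hazard_betas: Mapping[str, float],
    censor_rate: float = 0.2,
    baseline_rate: float = 1.0 / 24.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential relapse cohort with log-linear protein hazards.

    Protein levels are standard normal; subject i relapses at rate
    baseline_rate * exp(sum_p beta_p * level_ip). Censoring is independent
    exponential with rate chosen so the expected censored fraction is
    ``censor_rate`` (all-censored when 1, none when 0). Times in months.

    Returns columns: subject_id, time_months, event, then one column per
    protein; true hazard ratio per protein is exp(beta).
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    prots = list(hazard_betas)
    X = rng.standard_normal((n_subjects, len(prots)))
    beta = np.asarray([hazard_betas[p] for p in prots])
    rate = baseline_rate * np.exp(X @ beta if prots else np.zeros(n_subjects))
    t_event = rng.exponential(1.0 / rate)
    if censor_rate >= 1.0:
        time = rng.exponential(1.0 / baseline_rate, size=n_subjects)
        event = np.zeros(n_subjects, dtype=int)
    elif censor_rate <= 0.0:
        time, event = t_event, np.ones(n_subjects, dtype=int)
    else:
        # with matched exponential rates, P(censored) = rc/(rc + rate)
        c_rate = rate * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    out = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n_subjects)],
            "time_months": time,
            "event": event,
        }
    )
    for j, p in enumerate(prots):
        out[p] = X[:, j]
    return out


def simulate_paired_expression(
    n_genes: int,
    marker_set_size: int,
    marker_correlation: float,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Two matched expression profiles sharing a latent signal on markers.

    Marker genes draw a common latent value mixed so the population
    correlation across the pair equals ``marker_correlation``; non-markers
    are independent across the pair. Values are on a log10-like continuous
    scale. Returns (x, y, marker_genes).
    """
    if marker_set_size > n_genes:
        raise ValueError("marker_set_size must be <= n_genes")
    if not -1.0 <= marker_correlation <= 1.0:
        raise ValueError("marker_correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    markers = list(rng.choice(genes, size=marker_set_size, replace=False))
    x = rng.standard_normal(n_genes)
    y = rng.standard_normal(n_genes)
    idx = np.array([genes.index(m) for m in markers])
    if len(idx):
        rho = marker_correlation
        shared = rng.standard_normal(len(idx))
        sgn = np.sign(rho) if rho != 0 else 0.0
        a = np.sqrt(abs(rho))
        x[idx] = a * shared + np.sqrt(1 - abs(rho)) * rng.standard_normal(len(idx))
        y[idx] = sgn * a * shared + np.sqrt(1 - abs(rho)) * rng.standard_normal(len(idx))
    x = x + rng.normal(0.0, noise_sd, size=n_genes)
    y = y + rng.normal(0.0, noise_sd, size=n_genes)
    return (
        pd.Series(x, index=genes, name="x"),
        pd.Series(y, index=genes, name="y"),
        markers,
    )


def simulate_size_events(
    components: Sequence[tuple[float, float, float]],
    n_events: int = 5000,
    window: tuple[float, float] = (40.0, 200.0),
    seed: int = 0,
) -> np.ndarray:
    """Gaussian-mixture particle sizes truncated to the instrument window.

    ``components`` is a list of (mean nm, sd nm, weight); weights must sum
    to 1. Truncation to ``window`` is applied by rejection, matching a
    nano-flow cytometer calibrated for 40–200 nm single-particle analysis.
    """
    if not components:
        raise ValueError("at least one mixture component required")
    means, sds, weights = map(np.asarray, zip(*components))
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("component weights must sum to 1")
    lo, hi = window
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while len(out) < n_events:
        k = rng.choice(len(components), size=2 * n_events, p=weights / weights.sum())
        draw = rng.normal(means[k], np.maximum(sds[k], 1e-12))
        draw = draw[(draw >= lo) & (draw <= hi)]
        out = np.concatenate([out, draw])
    return out[:n_events]
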