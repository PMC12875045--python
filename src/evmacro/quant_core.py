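"""DIA-NN report ingestion, filtering, median centering and imputation.

The quantification contract: starting from a long-format DIA-NN
``report.tsv`` (one row per run x protein group x precursor, carrying the
run-specific protein q-value and the protein-level MaxLFQ intensity),
produce a protein x sample log2-intensity matrix in which

- records with protein q-value >= 0.01 are treated as undetected,
- a protein is retained within a subtype iff at least half of that
  subtype's donors support it with Np >= 3 q-passing precursors,
- sample columns are median-centered to the common median, and
- remaining missing cells are imputed from a down-shifted normal fitted to
  each sample's observed intensity distribution (the "lower limit of
  detection" convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterSpec",
    "ProteinQuantMatrix",
    "read_report",
    "write_report",
    "filter_protein_groups",
    "median_center",
    "impute_missing",
    "detection_sets",
]

REQUIRED_COLUMNS = [
    "Run",
    "Protein.Group",
    "Genes",
    "Precursor.Id",
    "Protein.Q.Value",
    "PG.MaxLFQ",
]


@dataclass(frozen=True)
class FilterSpec:
    """Detection filter: q < q_max and Np >= min_precursors in at least
    ceil(min_donor_fraction x donors) donors of a group."""

    q_max: float = 0.01
    min_precursors: int = 3
    min_donor_fraction: float = 0.5
    per_group: bool = True  # False: apply the donor rule over all samples

    def __post_init__(self):
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must lie in (0, 1]")
        if self.min_precursors < 1:
            raise ValueError("min_precursors must be >= 1")
        if not 0 < self.min_donor_fraction <= 1:
            raise ValueError("min_donor_fraction must lie in (0, 1]")


@dataclass
class ProteinQuantMatrix:
    """Protein x sample log2 matrix with provenance.

    ``values``: log2 intensities (NaN where missing pre-imputation);
    ``mask``: True where a cell was imputed (empty/False pre-imputation);
    ``np_table``: protein x sample q-passing precursor counts;
    ``samples``: sample metadata indexed by run with group/donor columns;
    ``detected``: protein x group boolean detection flags from the filter.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    np_table: pd.DataFrame
    samples: pd.DataFrame
    detected: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def group_columns(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])


def read_report(path, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Read and validate a DIA-NN-style report against a sample sheet.

    ``sample_sheet`` maps Run -> (group, donor). Rows with missing required
    fields are rejected with their row index; runs absent from the sheet,
    non-numeric or non-positive intensities, and q-values outside [0, 1]
    raise. Returns the report with ``group`` and ``donor`` columns merged in.
    """
    rep = pd.read_csv(path, sep="\t")
    return validate_report(rep, sample_sheet)


def validate_report(rep: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(rep.columns)
    if missing:
        raise ValueError(f"report missing columns: {sorted(missing)}")
    na = rep[REQUIRED_COLUMNS].isna().any(axis=1)
    if na.any():
        raise ValueError(f"rows with missing required fields: "
                         f"{list(rep.index[na][:5])}")
    q = pd.to_numeric(rep["Protein.Q.Value"], errors="coerce")
    inten = pd.to_numeric(rep["PG.MaxLFQ"], errors="coerce")
    if q.isna().any() or ((q < 0) | (q > 1)).any():
        raise ValueError("Protein.Q.Value must be numeric in [0, 1]")
    if inten.isna().any():
        raise ValueError("PG.MaxLFQ must be numeric")
    if (inten <= 0).any():
        raise ValueError("PG.MaxLFQ must be positive (log scale downstream)")
    dup = rep.duplicated(subset=["Run", "Protein.Group", "Precursor.Id"])
    if dup.any():
        raise ValueError("duplicate (Run, Protein.Group, Precursor.Id) records")
    sheet = sample_sheet.set_index("Run")
    unknown = set(rep["Run"]) - set(sheet.index)
    if unknown:
        raise ValueError(f"run(s) missing from sample sheet: {sorted(unknown)}")
    rep = rep.copy()
    rep["Protein.Q.Value"] = q
    rep["PG.MaxLFQ"] = inten
    rep["group"] = rep["Run"].map(sheet["group"])
    rep["donor"] = rep["Run"].map(sheet["donor"])
    return rep


def write_report(rep: pd.DataFrame, path) -> None:
    rep[REQUIRED_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_protein_groups(
    report: pd.DataFrame, spec: FilterSpec = FilterSpec()
) -> ProteinQuantMatrix:
    """Apply the q-value + precursor-support detection filter.

    Records with q >= q_max count as undetected. Within each group a
    protein is detected iff the number of donors (runs) with Np >=
    min_precursors is at least ceil(min_donor_fraction x donors in group).
    The returned matrix holds the union over groups of detected proteins,
    with log2 MaxLFQ where any q-passing record exists and NaN elsewhere;
    per-group detection flags ride along for set analyses.
    """
    if report.empty:
        raise ValueError("empty report")
    if "group" not in report.columns:
        raise ValueError("report must be validated (read_report) first")
    ok = report[report["Protein.Q.Value"] < spec.q_max]

    runs = report[["Run", "group", "donor"]].drop_duplicates().set_index("Run")
    runs = runs.sort_index()

    np_table = (
        ok.groupby(["Protein.Group", "Run"])["Precursor.Id"]
        .nunique()
        .unstack(fill_value=0)
        .reindex(columns=runs.index, fill_value=0)
    )

    groups = list(dict.fromkeys(runs["group"]))
    detected = {}
    if spec.per_group:
        for g in groups:
            cols = runs.index[runs["group"] == g]
            need = math.ceil(spec.min_donor_fraction * len(cols))
            support = (np_table[cols] >= spec.min_precursors).sum(axis=1)
            detected[g] = support >= need
    else:
        need = math.ceil(spec.min_donor_fraction * len(runs))
        support = (np_table >= spec.min_precursors).sum(axis=1)
        for g in groups:
            detected[g] = support >= need
    det = pd.DataFrame(detected)
    keep = det.index[det.any(axis=1)]

    log2 = ok.assign(log2=np.log2(ok["PG.MaxLFQ"]))
    values = (
        log2.groupby(["Protein.Group", "Run"])["log2"]
        .median()
        .unstack()
        .reindex(index=keep, columns=runs.index)
    )
    npt = np_table.reindex(index=keep, columns=runs.index, fill_value=0)
    mask = pd.DataFrame(False, index=keep, columns=runs.index)
    return ProteinQuantMatrix(
        values=values, mask=mask, np_table=npt, samples=runs,
        detected=det.loc[keep],
    )


def median_center(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Shift each sample so its observed median equals the grand median.

    The grand median is the median of the pre-centering per-sample medians;
    missing cells are untouched. Idempotent, and preserves within-sample
    differences exactly.
    """
    vals = matrix.values
    obs_counts = vals.notna().sum(axis=0)
    if (obs_counts == 0).any():
        bad = list(obs_counts.index[obs_counts == 0])
        raise ValueError(f"sample(s) with zero observed values: {bad}")
    medians = vals.median(axis=0, skipna=True)
    grand = medians.median()
    centered = vals.sub(medians - grand, axis=1)
    return ProteinQuantMatrix(
        values=centered, mask=matrix.mask.copy(), np_table=matrix.np_table,
        samples=matrix.samples, detected=matrix.detected,
    )


def impute_missing(
    matrix: ProteinQuantMatrix,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
    seed: int = 0,
) -> ProteinQuantMatrix:
    """Down-shifted-normal imputation of missing cells.

    Each missing cell in sample s is drawn from
    Normal(mu_s - shift_sd * sigma_s, (width_sd * sigma_s)^2) where mu_s and
    sigma_s are the observed mean/SD of that sample — mimicking intensities
    near the instrument's lower limit of detection. The mask records
    exactly the imputed cells; observed cells are never altered.
    """
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    mask = pd.DataFrame(False, index=vals.index, columns=vals.columns)
    for col in vals.columns:
        v = vals[col]
        obs = v.dropna()
        miss = v.index[v.isna()]
        if len(miss) == 0:
            continue
        if len(obs) < 2:
            raise ValueError(f"sample {col!r} has < 2 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - shift_sd * sd, width_sd * sd, size=len(miss))
        vals.loc[miss, col] = draws
        mask.loc[miss, col] = True
    return ProteinQuantMatrix(
        values=vals, mask=mask, np_table=matrix.np_table,
        samples=matrix.samples, detected=matrix.detected,
    )


def detection_sets(matrix: ProteinQuantMatrix) -> dict[str, set[str]]:
    """Per-group detected sets plus their intersection (core) and union.

    The "core" is the set of proteins detectable irrespective of subtype;
    the "merged" set is everything detected anywhere.
    """
    if matrix.detected.empty:
        raise ValueError("matrix carries no detection flags (run the filter first)")
    out: dict[str, set[str]] = {}
    groups = list(matrix.detected.columns)
    for g in groups:
        out[g] = set(matrix.detected.index[matrix.detected[g]])
    core = set.intersection(*(out[g] for g in groups)) if groups else set()
    merged = set.union(*(out[g] for g in groups)) if groups else set()
    out["core"] = core
    out["merged"] = merged
    return out
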