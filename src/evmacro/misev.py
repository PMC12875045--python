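"""MISEV-2023 protein categorization and %Np category statistics.

The MISEV (Minimal Information for Studies of Extracellular Vesicles) 2023
guidelines organize EV-associated proteins into five main categories:

1. transmembrane proteins associated with plasma membrane and/or endosomes
2. cytosolic proteins recovered in EVs (2a: linked to EV biogenesis)
3. major non-EV co-isolated structures (3a lipoproteins, 3b ribonucleo-
   protein complexes, 3c exomere/supermere components)
4. proteins of intracellular compartments other than plasma membrane or
   endosomes (4b: mitochondrial, MitoCarta-style)
5. secreted proteins and/or proteins of the EV corona

Categories 1 and 2a jointly act as the canonical "EV panel" of endosomal
origin. A proteome is summarized per sample as %Np: the percentage of the
sample's precursor count carried by proteins of each (sub)category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SUBCATEGORIES",
    "MisevOntology",
    "load_annotation",
    "write_annotation",
    "annotate_proteome",
    "ev_panel",
    "category_np_fraction",
    "endosomal_ratio",
    "marker_panel_summary",
]

#: subcategory code -> main category
SUBCATEGORIES: dict[str, str] = {
    "1a": "1",
    "1b": "1",
    "2a": "2",
    "2b": "2",
    "3a": "3",
    "3b": "3",
    "3c": "3",
    "4a": "4",
    "4b": "4",
    "5a": "5",
    "5b": "5",
    "5c": "5",
}

DESCRIPTIONS: dict[str, str] = {
    "1a": "multi-pass transmembrane, plasma membrane/endosomes",
    "1b": "single-pass transmembrane, plasma membrane/endosomes",
    "2a": "cytosolic, linked to EV biogenesis (ESCRT etc.)",
    "2b": "cytosolic, other EV-recovered",
    "3a": "lipoproteins (non-EV co-isolates)",
    "3b": "ribonucleoprotein complexes (non-EV co-isolates)",
    "3c": "exomere/supermere-enriched components",
    "4a": "non-endosomal organelles (ER, Golgi, nucleus)",
    "4b": "mitochondrial (MitoCarta-style)",
    "5a": "corona-associated secreted proteins",
    "5b": "secreted, other",
    "5c": "adhesion / extracellular-matrix proteins",
}

#: endosomal-origin panel: main category 1 plus subcategory 2a
_ENDOSOMAL_SUBS = frozenset({"1a", "1b", "2a"})


@dataclass(frozen=True)
class MisevOntology:
    """Fixed subcategory -> main-category roll-up."""

    def main_of(self, subcategory: str) -> str:
        try:
            return SUBCATEGORIES[subcategory]
        except KeyError:
            raise ValueError(f"unknown MISEV subcategory: {subcategory!r}") from None

    def is_endosomal(self, subcategory: str) -> bool:
        """Category 1 or 2a: the canonical EV panel of endosomal origin."""
        return subcategory in _ENDOSOMAL_SUBS

    @property
    def subcategories(self) -> tuple[str, ...]:
        return tuple(SUBCATEGORIES)

    @property
    def main_categories(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(SUBCATEGORIES.values()))


def load_annotation(path) -> pd.DataFrame:
    """Read a gene -> MISEV subcategory table (TSV).

    Requires columns gene / subcategory (uniprot and source optional).
    Gene symbols are upper-cased for case-insensitive matching; duplicated
    genes and unknown subcategory codes are rejected.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(ann)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = {"gene", "subcategory"} - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    ann = ann.copy()
    ann["gene"] = ann["gene"].astype(str).str.upper()
    ann["subcategory"] = ann["subcategory"].astype(str)
    bad = ~ann["subcategory"].isin(SUBCATEGORIES)
    if bad.any():
        row = ann[bad].iloc[0]
        raise ValueError(
            f"unknown MISEV subcategory {row['subcategory']!r} for gene {row['gene']!r}"
        )
    dup = ann["gene"].duplicated()
    if dup.any():
        raise ValueError(f"duplicated gene(s) in annotation: "
                         f"{sorted(ann.loc[dup, 'gene'].unique())[:5]}")
    if "uniprot" not in ann.columns:
        ann["uniprot"] = ""
    if "source" not in ann.columns:
        ann["source"] = ""
    return ann[["gene", "uniprot", "subcategory", "source"]]


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def annotate_proteome(
    proteins, annotation: pd.DataFrame
) -> tuple[dict[str, set[str]], set[str]]:
    """Partition a proteome into per-subcategory members and unannotated.

    Matching is case-insensitive on gene symbol. Returns
    (subcategory -> member set, unannotated set); every protein lands in at
    most one subcategory because the annotation enforces one row per gene.
    """
    lookup = dict(zip(annotation["gene"], annotation["subcategory"]))
    per_cat: dict[str, set[str]] = {sub: set() for sub in SUBCATEGORIES}
    unannotated: set[str] = set()
    for p in proteins:
        sub = lookup.get(str(p).upper())
        if sub is None:
            unannotated.add(p)
        else:
            per_cat[sub].add(p)
    return per_cat, unannotated


def ev_panel(annotation: pd.DataFrame) -> set[str]:
    """Genes of endosomal origin: main category 1 plus subcategory 2a."""
    mask = annotation["subcategory"].isin(_ENDOSOMAL_SUBS)
    return set(annotation.loc[mask, "gene"])


def category_np_fraction(
    report: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str = "main",
    q_max: float = 0.01,
    mode: str = "counts",
) -> pd.DataFrame:
    """Per-sample %Np contribution of each MISEV (sub)category.

    %Np = 100 x (precursor count of annotated proteins in the category) /
    (total precursor count in the sample), counting distinct q-passing
    precursors per protein per run (``mode="counts"``, the default literal
    reading of "% of number of precursors"); ``mode="intensity"`` uses the
    summed MaxLFQ intensity share instead. The unannotated remainder is
    reported as its own column, so each row sums to 100.
    """
    if level not in ("main", "sub"):
        raise ValueError("level must be 'main' or 'sub'")
    if mode not in ("counts", "intensity"):
        raise ValueError("mode must be 'counts' or 'intensity'")
    rec = report[report["Protein.Q.Value"] < q_max]
    rec = rec.drop_duplicates(subset=["Run", "Protein.Group", "Precursor.Id"]).copy()
    if rec.empty:
        raise ValueError("no q-passing records in report")
    lookup = dict(zip(annotation["gene"], annotation["subcategory"]))
    genes = rec["Genes"].astype(str).str.upper()
    sub = genes.map(lookup)
    key = sub if level == "sub" else sub.map(SUBCATEGORIES)
    rec["category"] = key.fillna("unannotated")
    if mode == "counts":
        weight = pd.Series(1.0, index=rec.index)
    else:
        weight = rec["PG.MaxLFQ"].astype(float)
    rec["w"] = weight
    totals = rec.groupby("Run")["w"].sum()
    if (totals <= 0).any():
        raise ValueError("sample with zero precursors")
    tab = rec.pivot_table(
        index="Run", columns="category", values="w", aggfunc="sum", fill_value=0.0
    )
    out = 100.0 * tab.div(totals, axis=0)
    order = [c for c in (
        SUBCATEGORIES if level == "sub" else dict.fromkeys(SUBCATEGORIES.values())
    ) if c in out.columns]
    if "unannotated" in out.columns:
        order += ["unannotated"]
    return out[order]


def endosomal_ratio(
    report: pd.DataFrame,
    annotation: pd.DataFrame,
    sample_groups: pd.Series,
    reference_group: str = "TAM",
    q_max: float = 0.01,
) -> pd.Series:
    """Per-sample endosomal-contribution ratio.

    The endosomal %Np of a sample (categories 1 and 2a combined) divided by
    the mean endosomal %Np of the reference group's samples; reference
    samples therefore average to 1 by construction.
    """
    subtab = category_np_fraction(report, annotation, level="sub", q_max=q_max)
    endo_cols = [c for c in subtab.columns if c in _ENDOSOMAL_SUBS]
    endo = subtab[endo_cols].sum(axis=1)
    groups = sample_groups.reindex(endo.index)
    ref = endo[groups == reference_group]
    if len(ref) == 0:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    denom = ref.mean()
    if denom == 0:
        raise ValueError("reference group has zero endosomal %Np")
    return endo / denom


def marker_panel_summary(
    matrix: pd.DataFrame, panel
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Row z-scores (population SD) of panel genes across samples.

    Returns (z-matrix, missing panel genes, zero-variance genes whose rows
    were set to 0).
    """
    panel = [str(g) for g in panel]
    upper = {str(i).upper(): i for i in matrix.index}
    present = [upper[g.upper()] for g in panel if g.upper() in upper]
    absent = [g for g in panel if g.upper() not in upper]
    sub = matrix.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    sd = sd.replace(0.0, np.nan)
    z = sub.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return z, absent, flat
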