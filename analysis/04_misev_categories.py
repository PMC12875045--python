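"""MISEV-2023 categorization of the quantified EV proteome.

Annotates the retained proteins, computes the per-sample %Np contribution
of each main category, the canonical EV panel (categories 1 + 2a), the
endosomal-contribution ratio normalized to the TAM-like samples, and row
z-scores for the EV panel across samples.
"""

from pathlib import Path

import pandas as pd

from evmacro import misev

DATA = Path("results/data")
QUANT = Path("results/quant")
OUT = Path("results/misev")
OUT.mkdir(parents=True, exist_ok=True)

report = pd.read_csv(DATA / "report.tsv", sep="\t")
annotation = misev.load_annotation(DATA / "annotation.tsv")
matrix = pd.read_csv(QUANT / "matrix.tsv", sep="\t", index_col=0)
sheet = pd.read_csv(DATA / "sample_sheet.tsv", sep="\t").set_index("Run")

retained = report[report["Protein.Group"].isin(matrix.index)]
per_cat, unannotated = misev.annotate_proteome(
    matrix.index.str.replace("P", "GENE", regex=False), annotation
)
n_matched = sum(len(s) for s in per_cat.values())
print(f"{n_matched} of {len(matrix)} retained proteins MISEV-annotated "
      f"({len(unannotated)} unannotated)")

main = misev.category_np_fraction(retained, annotation, level="main")
main.to_csv(OUT / "main_np.tsv", sep="\t")
sub = misev.category_np_fraction(retained, annotation, level="sub")
sub.to_csv(OUT / "sub_np.tsv", sep="\t")
group_mean = main.groupby(sheet["group"]).mean()
print("mean %Np per main category by subtype:")
print(group_mean.round(2).to_string())

ratio = misev.endosomal_ratio(retained, annotation, sheet["group"], "TAM")
ratio.to_csv(OUT / "endosomal_ratio.tsv", sep="\t", header=["ratio"])
by_group = ratio.groupby(sheet["group"]).mean()
print("endosomal-contribution ratio (cat 1+2a %Np / TAM mean):")
print(by_group.round(3).to_string())

panel = misev.ev_panel(annotation)
pd.Series(sorted(panel)).to_csv(OUT / "ev_panel.tsv", sep="\t",
                                index=False, header=False)
matrix_genes = matrix.copy()
matrix_genes.index = matrix.index.str.replace("P", "GENE", regex=False)
z, absent, flat = misev.marker_panel_summary(matrix_genes, sorted(panel))
z.to_csv(OUT / "ev_panel_zscores.tsv", sep="\t")
print(f"EV panel: {len(panel)} genes ({len(z)} quantified, "
      f"{len(absent)} absent from matrix)")
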