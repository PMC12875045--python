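"""Over-representation analysis of the unique TAM-EV signature.

Builds a gene-set collection from the simulated MISEV categories (a
category is "enriched" if the signature over-draws from it), uses the
merged detected proteome as the background universe, and runs the
hypergeometric ORA with the standard parameters (term size 15-500,
p < 0.05, BH q < 0.20).
"""

from pathlib import Path

import pandas as pd

from evmacro import enrichment as en
from evmacro.misev import SUBCATEGORIES, load_annotation

DATA = Path("results/data")
QUANT = Path("results/quant")
SIG = Path("results/signatures")
OUT = Path("results/enrichment")
OUT.mkdir(parents=True, exist_ok=True)

annotation = load_annotation(DATA / "annotation.tsv")
merged = pd.read_csv(QUANT / "detected_merged.tsv", sep="\t", header=None)[0]
universe = set(merged.str.replace("P", "GENE", regex=False))

sets = {}
for cat in ("1", "2", "3", "4", "5"):
    members = set(
        annotation.loc[
            annotation["subcategory"].map(SUBCATEGORIES) == cat, "gene"
        ]
    )
    if members:
        sets[f"MISEV_cat{cat}"] = members
collection = en.GeneSetCollection(sets=sets, universe=universe)
en.write_gmt(collection, OUT / "misev_sets.gmt")

tam_unique = pd.read_csv(SIG / "tam_unique.tsv", sep="\t", header=None)[0]
query = set(tam_unique.str.replace("P", "GENE", regex=False)) & universe

res = en.ora(query, collection, min_size=15, max_size=500,
             p_cut=0.05, q_cut=0.20)
res.to_csv(OUT / "ora_tam_unique.tsv", sep="\t", index=False)
print(f"query: {len(query)} genes against universe of {len(universe)}")
print(f"tested {len(res)} terms; {int(res['reported'].sum())} pass "
      "p < 0.05 and q < 0.20")
if len(res):
    top = res.iloc[0]
    print(f"top term: {top['term']} (overlap {top['overlap']}/{top['set_size']}, "
          f"p = {top['p']:.3g}, q = {top['q']:.3g})")
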