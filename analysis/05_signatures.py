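"""Derive the pro-/anti-inflammatory and TAM-EV signatures by set logic.

Combines the three contrasts: up-in-M1 (pro) and up-in-M2 (anti) from the
M1-vs-M2 contrast, and the union of up-in-TAM calls (TAM-enriched). The
unique TAM signature excludes pro/anti members; partition identities are
checked and a prognosis split against the Cox screen is prepared.
"""

import json
from pathlib import Path

import pandas as pd

from evmacro import signatures as sg

DIFF = Path("results/differential")
OUT = Path("results/signatures")
OUT.mkdir(parents=True, exist_ok=True)

tabs = {
    name: pd.read_csv(DIFF / f"contrast_{name}.tsv", sep="\t", index_col=0)
    for name in ("M1_vs_M2", "TAM_vs_M1", "TAM_vs_M2")
}
s = sg.derive_signatures(tabs["M1_vs_M2"], tabs["TAM_vs_M1"], tabs["TAM_vs_M2"])

counts = s.counts()
(OUT / "counts.json").write_text(json.dumps(counts, indent=2))
for name in counts:
    pd.Series(sorted(getattr(s, name))).to_csv(
        OUT / f"{name}.tsv", sep="\t", index=False, header=False
    )

print("signature sizes:", counts)
assert s.tam_unique | s.tam_pro | s.tam_anti == s.tam_enriched
assert len(s.pro) == len(s.m1_sig) + len(s.tam_pro)
assert len(s.anti) == len(s.m2_sig) + len(s.tam_anti)
print("partition identities hold: "
      f"{counts['tam_unique']} + {counts['tam_pro']} + {counts['tam_anti']} "
      f"= {counts['tam_enriched']} (TAM-enriched); "
      f"{counts['pro']} - {counts['tam_pro']} = {counts['m1_sig']} (M1 exclusive)")
if s.direction_conflicts:
    print(f"note: {len(s.direction_conflicts)} proteins significant in "
          "opposite TAM directions were excluded from TAM-enriched")
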