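"""Generate every synthetic input of the study design.

Emulates three macrophage subtypes (M1-, M2-, TAM-like) in biological
triplicate: a DIA-NN-style precursor report with planted differential
abundance and MNAR dropout, a MISEV annotation table, a relapse cohort
with log-linear protein hazards, a paired expression profile sharing a
correlated marker panel, and nano-flow-cytometry size events.

Writes results/data/ and the ground truth needed by later steps.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from evmacro import misev, synthetic_data as sd

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2026

cfg = sd.SimulationConfig(n_proteins=2000, seed=SEED)
report, truth = sd.simulate_report(cfg)
report.to_csv(OUT / "report.tsv", sep="\t", index=False)
sd.sample_sheet_for(cfg).to_csv(OUT / "sample_sheet.tsv", sep="\t", index=False)
truth.group_means.to_csv(OUT / "true_group_means.tsv", sep="\t")
for (a, b), daps in truth.dap_sets.items():
    pd.Series(sorted(daps)).to_csv(
        OUT / f"true_daps_{a}_vs_{b}.tsv", sep="\t", index=False, header=False
    )

genes = sorted(report["Genes"].unique())
weights = {"1a": 0.04, "1b": 0.06, "2a": 0.08, "2b": 0.07, "3a": 0.02,
           "3b": 0.03, "3c": 0.04, "4a": 0.08, "4b": 0.06, "5a": 0.05,
           "5b": 0.04, "5c": 0.03, "unannotated": 0.40}
annotation = sd.simulate_annotation(genes, weights, seed=SEED + 1)
misev.write_annotation(annotation, OUT / "annotation.tsv")

betas = {"PROT_RISK": float(np.log(3.0)), "PROT_PROT": float(np.log(0.5)),
         "PROT_NULL": 0.0}
cohort = sd.simulate_cohort(400, betas, censor_rate=0.2, seed=SEED + 2)
cohort.to_csv(OUT / "cohort.tsv", sep="\t", index=False)
(OUT / "cohort_true_hr.json").write_text(
    json.dumps({p: float(np.exp(b)) for p, b in betas.items()}, indent=2)
)

x, y, markers = sd.simulate_paired_expression(
    n_genes=500, marker_set_size=30, marker_correlation=0.8, seed=SEED + 3
)
pd.DataFrame({"x": x, "y": y}).to_csv(OUT / "paired_expression.tsv", sep="\t")
pd.Series(markers).to_csv(OUT / "markers.tsv", sep="\t", index=False, header=False)

events = sd.simulate_size_events(
    [(65.0, 12.0, 0.4), (55.0, 8.0, 0.3), (62.0, 11.0, 0.3)],
    n_events=5000, seed=SEED + 4,
)
np.savetxt(OUT / "events.tsv", events, header="size_nm", comments="")

print(f"precursor report: {len(report)} records over "
      f"{report['Run'].nunique()} runs, {cfg.n_proteins} proteins")
print(f"planted DAPs per contrast: "
      f"{ {f'{a}_vs_{b}': len(v) for (a, b), v in truth.dap_sets.items()} }")
print(f"annotation: {len(annotation)} of {len(genes)} genes MISEV-annotated")
print(f"cohort: {len(cohort)} subjects, {int(cohort['event'].sum())} relapses")
print(f"events: {len(events)} particle sizes in "
      f"[{events.min():.1f}, {events.max():.1f}] nm")
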