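# evmacro

Analysis pipeline for label-free DIA proteomes of macrophage-derived
extracellular vesicles (EVs), built for the comparison of M1-like
(pro-inflammatory), M2-like (anti-inflammatory) and tumor-associated
macrophage-like (TAM) subtypes in unpaired biological triplicates. It
covers the full path from a DIA-NN-style precursor report to biological
conclusions — differential abundance, MISEV-2023 composition, derived EV
signatures, functional enrichment and clinical association — together with
nano-flow-cytometry particle statistics and a synthetic-data generator that
makes every stage testable against a known ground truth.

## What it computes

**Quantification** (`evmacro.quant_core`). Records with run-specific
protein q-value ≥ 0.01 are treated as undetected; a protein is retained
within a subtype iff Np ≥ 3 q-passing precursors support it in at least
half of that subtype's donors. Retained log2 MaxLFQ columns are
median-centered to the common median and missing cells are imputed from a
down-shifted normal, N(μ_s − 1.8σ_s, (0.3σ_s)²), fitted per sample.

**Differential abundance** (`evmacro.differential`). Empirical-Bayes
moderated t: the pooled per-protein variance s²_g (d_g df) is shrunk toward
a prior s²_0 with df d₀ estimated by moment matching of log s²_g,

    s̃²_g = (d₀·s²₀ + d_g·s²_g) / (d₀ + d_g),
    t_g = (x̄_A − x̄_B) / (s̃_g·√(1/n_A + 1/n_B)),   t_g ~ t(d₀ + d_g),

with Benjamini–Hochberg control; a protein is a DAP when adjusted p < 0.05.

**MISEV-2023 composition** (`evmacro.misev`). Each protein maps to one of
twelve subcategories (1a…5c); per sample, %Np is the percentage of the
sample's precursor count carried by each category, and the endosomal
contribution ratio is the cat 1 ∪ 2a %Np normalized by the TAM-group mean.

**Signatures** (`evmacro.signatures`). Pro = up in M1 vs M2, anti = up in
M2; TAM-enriched = union of up-in-TAM calls from both TAM contrasts; the
unique TAM signature removes pro/anti members. Partition identities
(tam_unique ⊎ tam_pro ⊎ tam_anti = tam_enriched, |pro| = |m1_sig| +
|tam_pro|) hold exactly.

**Enrichment** (`evmacro.enrichment`). Hypergeometric ORA over GMT gene
sets against a detected-proteome universe (term size 15–500, p < 0.05,
BH q < 0.20).

**Clinical screens** (`evmacro.clinical`). Univariate Cox
proportional-hazards screening (Newton on the partial likelihood, Breslow
ties), quantile-split Kaplan–Meier with log-rank (exact permutation branch
for tiny cohorts), Mann–Whitney plasma marker screening, OLS regression of
paired expression profiles, and a bootstrap test asking whether a marker
set's cross-profile Pearson correlation beats that of random gene sets of
the same size.

**Particles** (`evmacro.ev_metrics`). Particle release per seeded cell,
Gaussian least-squares fits to 40–200 nm size histograms, detergent-lysis
fold change, protein/particle mass ratio.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted effects (run them in order from the repository root):

```sh
python analysis/01_simulate.py
python analysis/02_quantify.py
python analysis/03_differential.py
...
python analysis/08_particles.py
```

Representative output:

```
retained 1895 protein groups (1356 missing cells imputed)
  core (all subtypes): 835; merged: 1895
M1 vs M2: 115 DAPs (54 up in M1, 61 up in M2); prior df d0 = 4.90;
  recovery of planted truth 60.5%, empirical FDR 0.0%
signature sizes: {'pro': 54, 'anti': 61, 'tam_enriched': 102,
  'tam_unique': 64, 'tam_pro': 16, 'tam_anti': 22, 'm1_sig': 38, 'm2_sig': 39}
partition identities hold: 64 + 16 + 22 = 102 (TAM-enriched)
median-split KM on PROT_RISK: median RFS 6.5 (high) vs 34.7 (low) months;
  log-rank p = 8.78e-22, split HR 3.05
Gaussian fit: mean 59.9 nm, SD 11.5 nm; sample median 60.6 nm
```

Reading this: of 2,000 simulated proteins, 1,895 pass the detection filter
and 835 are detected in every subtype ("core"). The M1-vs-M2 contrast
calls 115 DAPs with essentially no false discoveries; recovery of the
planted truth is ~60% here because intensity-dependent (MNAR) dropout and
down-shifted imputation inflate the variance of low-abundance proteins —
on complete data the same test recovers ≥ 95% (see the acceptance suite).
The signature arithmetic partitions exactly, and a protein with a planted
hazard ratio separates median relapse-free survival 6.5 vs 34.7 months.

A `evmacro` CLI exposes the same stages (`evmacro simulate report`,
`evmacro quant process`, `evmacro diffexp`, `evmacro ora`,
`evmacro survival km`, `evmacro run --config pipeline.toml`, …).

## Layout

```
src/evmacro/        library (all computation)
analysis/           numbered narrative drivers writing results/
tests/              pytest suite incl. the acceptance property gate
scripts/acceptance.py
docs/methods.md     model and design notes
```
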