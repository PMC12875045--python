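# Methods

## Scope and model

The package analyzes label-free data-independent-acquisition (DIA)
proteomes of small extracellular vesicles (EVs) released by three
macrophage subtypes (M1-like, M2-like, TAM-like), three donors each,
unpaired. The quantification unit entering the pipeline is the protein
group's MaxLFQ intensity per run plus the set of q-passing precursors
supporting it; protein inference and MaxLFQ computation themselves are
upstream (DIA-NN territory) and out of scope.

## Detection filtering

A record counts as detected only when its run-specific protein q-value is
below `q_max` (default 0.01). Within each subtype, a protein is retained
iff at least ⌈`min_donor_fraction` × donors⌉ donors support it with
Np ≥ `min_precursors` q-passing precursors (defaults 0.5 and 3; with three
donors the threshold is 2). The rule is applied per subtype and the
retained matrix is the union over subtypes, which is what makes per-subtype
detection counts and a cross-subtype "core" (intersection) meaningful; a
global mode (`per_group=False`) is available. Filtering is monotone:
relaxing `q_max` or `min_precursors` can only grow the retained set.

## Normalization and imputation

Columns are log2 MaxLFQ. Each sample is shifted so its observed median
equals the grand median of the pre-centering sample medians — idempotent,
and exactly preserving within-sample differences. Missing cells are then
drawn from N(μ_s − 1.8σ_s, (0.3σ_s)²), where μ_s, σ_s are the sample's
observed mean and SD: the widely used down-shifted-normal convention for
intensities near the lower limit of detection. The 1.8/0.3 constants are
exposed (`shift_sd`, `width_sd`). Imputation happens on the whole matrix
before any contrast is subset, and an imputation mask is kept so downstream
consumers can distinguish measured from imputed cells.

## Moderated differential testing

For a two-group contrast the pooled variance s²_g has d_g = n_A + n_B − 2
df. Writing z_g = log s²_g and e_g = z_g − ψ(d_g/2) + log(d_g/2), the prior
df solves trigamma(d₀/2) = Var(e) − trigamma(d_g/2) (Newton inversion of
the trigamma; the test suite re-derives it with a bracketing solver), and
log s²₀ = mean(e) + ψ(d₀/2) − log(d₀/2). When the moment variance is
non-positive the prior is effectively infinite: all variances are pooled.
The moderated t uses the posterior variance and d₀ + d_g df, two-sided.
Multiplicity is controlled by the Benjamini–Hochberg step-up rule
(implemented directly — it is a contract of this package — and
cross-checked against statsmodels); DAP means adjusted p < 0.05.

Design choices: single two-group contrasts with equal-variance pooling, no
covariates or variance trends. A forced-d₀ mode (`d0_override`) exposes the
ordinary-t (d₀ = 0) and fully pooled (d₀ = ∞) limits, used as identities in
the tests. The three pairwise contrasts are fit independently; a shared
three-group variance fit would share d₀ across contrasts but cannot be
distinguished by the available outputs, and pairwise is the simpler
default.

## MISEV-2023 categorization and %Np

Twelve subcategories (1a, 1b, 2a, 2b, 3a, 3b, 3c, 4a, 4b, 5a, 5b, 5c) roll
up to five main categories; one subcategory per gene is enforced at load
(overlapping secreted/lipoprotein terms must be resolved in the annotation
itself, category 3a being reserved for lipoproteins). Matching is
case-insensitive on gene symbol with no alias expansion — alias tables
drift and would make results irreproducible; unmatched proteins are
reported, not guessed.

%Np for a category in a sample is 100 × (distinct q-passing precursors of
annotated proteins in the category) / (total distinct q-passing precursors
in the sample). Counts are the literal reading of "% of number of
precursors"; an intensity-share mode (`mode="intensity"`) is provided.
Subcategory values sum exactly to their main category and all categories
plus the unannotated remainder sum to 100. The endosomal-contribution
ratio divides a sample's cat 1 ∪ 2a %Np by the arithmetic mean (a median
would also be defensible; the mean keeps the reference group averaging to
exactly 1) of the reference (TAM) samples.

## Signature set logic

With contrasts oriented so positive log2FC means "up in the first-named
group": pro = up-in-M1 (M1 vs M2), anti = up-in-M2; TAM-enriched = union of
up-in-TAM calls from TAM-vs-M1 and TAM-vs-M2. Proteins significantly up in
TAM in one contrast but down in the other are contradictory, excluded from
TAM-enriched and reported separately. The remaining derived sets are pure
set algebra, so the partition identities hold exactly on every run and are
asserted in tests and drivers.

## Over-representation analysis

p = P(X ≥ k) under Hypergeom(|universe|, |term ∩ universe|, |query|); term
sizes are measured after intersection with the universe and restricted to
[15, 500]; BH is computed across tested terms only; reported terms satisfy
p < 0.05 and BH q < 0.20. Gene sets come from user-supplied GMT files —
no ontology downloads, no DAG reasoning — keeping runs reproducible. The
"q-value" here is BH-adjusted p.

## Clinical statistics

*Cox.* Univariate proportional-hazards fits by Newton iteration on the
partial likelihood, Breslow tie handling by default (Efron optional; ties
are rare in continuous levels). SE from the observed information; Wald CI
and p. Univariate screening of a hazard that truly depends on several
proteins estimates marginal, attenuated associations — the synthetic
cohort driver demonstrates this deliberately.

*Kaplan–Meier / log-rank.* Product-limit curves via lifelines; the
two-group log-rank statistic is computed directly (hypergeometric variance
form) and referred to χ²(1), or, for very small cohorts, to the exact
permutation distribution over all group labelings of the same sizes
(`method="exact"`). Median survival is the first time S(t) ≤ 0.5, flagged
undefined when never reached. Split quantile defaults to the median.

*Plasma screen.* Two-sided Mann–Whitney per protein: exact enumeration
when the combined n ≤ 12 and tie-free, otherwise the continuity-corrected
normal approximation with tie correction (which deviates from the exact
tail by up to ~0.016 at n = 12 — the cost of the approximation, not a
bug); all-tied inputs get p = 1 with a flag; BH across proteins.

*Bootstrap gene-set correlation.* Observed Pearson r over the marker set;
null from `n_boot` random gene sets of identical size drawn without
replacement within each draw (default 100,000); empirical
p = #{r_null ≥ r_obs}/n_boot, without the +1 correction by default
(`plus_one` switches to (hits+1)/(n_boot+1)). p = 0 is therefore possible
and means "no random set matched"; the resolution is 1/n_boot.

## Particle metrics

Sizes outside the 40–200 nm instrument window are rejected at load with a
count. Size distributions are uniform-width histograms of relative
frequencies with a nonlinear least-squares Gaussian (amplitude, mean, SD)
initialized at the sample moments — fitting the binned curve matches how
such distributions are summarized in practice; the sample median is
reported alongside. Release = concentration × dilution × volume / cells
seeded; lysis fold change = (treated − untreated)/untreated, so a 76% drop
reads −0.76 and complete lysis −1.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study's design parameters: 3 subtypes × 3
donors; log-normal (base-2) protein intensities (baseline mean 20, SD 2);
planted group effects of |log2FC| = 2 at within-group SD 0.5 on 10% of
proteins per contrast (each affected protein is shifted in exactly one
subtype, keeping group means consistent and per-contrast planted fractions
at their nominal value); zero-truncated Poisson precursor counts (mean 4);
5% of records failing the q threshold; MNAR dropout that is logistic in
log2 intensity, with slope `missing_mnar_strength` and intercept calibrated
by bisection to a 10% overall missing rate; exponential relapse times with
log-linear protein hazards and independent exponential censoring matched to
a target censored fraction; Gaussian-mixture particle sizes truncated by
rejection to 40–200 nm.

It does **not** emulate: correlated proteins or donor (batch) effects,
precursor-level intensity variation within a protein (all precursors of a
run share the protein MaxLFQ, as in a protein-level report), peptide
sequences or spectra, non-proportional hazards, or instrument drift.
Passing tests therefore certify the statistical machinery under the
declared design, not robustness to structured real-data artifacts.
Separately, `simulate_category_report` plants a multiplicative precursor-
rate boost on endosomal (cat 1 ∪ 2a) proteins, solved analytically so a
group's expected endosomal %Np share is a chosen multiple of the
reference's — the testbed for the contribution ratio.

## Numerical notes and known limitations

- Seeds: every generator and every stochastic stage takes an explicit seed;
  identical config + seed is byte-identical output (asserted in tests).
- Degenerate inputs: columns with no observations refuse centering; samples
  with < 2 observed values refuse imputation; constant covariates and
  event-free cohorts refuse Cox; zero-variance z-score rows are flagged and
  set to 0; single-bin histograms refuse fitting.
- BH ties are broken by stable sort, making adjusted values deterministic.
- The moment estimate of d₀ is infinite when observed log-variances are
  less dispersed than the sampling noise floor (common for homoscedastic
  simulations at small d_g); the limit is handled, and the normal reference
  distribution is used.
- Problem sizes in the drivers and acceptance script (2,000 proteins,
  400-subject cohorts, 5,000 particle events, 100,000 bootstrap draws) were
  chosen to estimate every reported quantity with comfortable Monte Carlo
  margin while keeping a full run in seconds to minutes on one CPU.
- Gene-symbol matching is exact-after-casefold; no alias resolution.
- The analysis-project shape (numbered drivers over a library) is the
  intended usage; the CLI mirrors the same stages for shell use.
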