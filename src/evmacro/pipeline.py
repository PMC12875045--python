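"""Single-config orchestration of the full analysis.

``run_all`` executes the seven analytic stages in order — synthetic-data
generation (or ingestion of user-supplied files), quantification,
differential testing, signature derivation, MISEV categorization,
over-representation analysis, clinical screening and particle metrics —
writing every stage's tables plus a manifest (parameters, seeds, output
checksums) under one output directory. All randomness is driven by named
seeds in the config, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clinical, differential, enrichment, ev_metrics
from . import misev as misev_mod
from . import quant_core, signatures, synthetic_data

__all__ = ["PipelineConfig", "run_all"]

STAGES = [
    "synthetic_data",
    "quant_core",
    "differential",
    "signatures",
    "misev",
    "enrichment",
    "clinical",
    "ev_metrics",
]


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; TOML-loadable."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # synthetic data
    n_proteins: int = 1000
    dap_fraction: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    # quant
    q_max: float = 0.01
    min_precursors: int = 3
    min_donor_fraction: float = 0.5
    imputation_shift_sd: float = 1.8
    imputation_width_sd: float = 0.3
    # differential
    alpha: float = 0.05
    # ORA
    ora_min_size: int = 15
    ora_max_size: int = 500
    ora_p_cut: float = 0.05
    ora_q_cut: float = 0.20
    # clinical
    cohort_n: int = 400
    censor_rate: float = 0.2
    n_boot: int = 10_000
    km_quantile: float = 0.5
    # particles
    size_components: list = field(
        default_factory=lambda: [[65.0, 12.0, 0.4], [55.0, 8.0, 0.3], [62.0, 11.0, 0.3]]
    )
    n_events: int = 5000

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**known)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; return a summary dict (also written as manifest)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    summary: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    # --- synthetic data -------------------------------------------------
    sim = synthetic_data.SimulationConfig(
        n_proteins=config.n_proteins,
        dap_fraction=config.dap_fraction,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
        missing_rate=config.missing_rate,
        seed=seed,
    )
    report, truth = synthetic_data.simulate_report(sim)
    sheet = synthetic_data.sample_sheet_for(sim)
    report_path = out / "report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)

    genes = sorted(report["Genes"].unique())
    weights = {"1a": 0.04, "1b": 0.06, "2a": 0.08, "2b": 0.07, "3a": 0.02,
               "3b": 0.03, "3c": 0.04, "4a": 0.08, "4b": 0.06, "5a": 0.05,
               "5b": 0.04, "5c": 0.03, "unannotated": 0.40}
    annotation = synthetic_data.simulate_annotation(genes, weights, seed=seed + 1)
    misev_mod.write_annotation(annotation, out / "annotation.tsv")

    betas = {"PROT_RISK": np.log(3.0), "PROT_PROT": np.log(0.5), "PROT_NULL": 0.0}
    cohort = synthetic_data.simulate_cohort(
        config.cohort_n, betas, censor_rate=config.censor_rate, seed=seed + 2
    )
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)

    expr_x, expr_y, markers = synthetic_data.simulate_paired_expression(
        n_genes=500, marker_set_size=30, marker_correlation=0.8, seed=seed + 3
    )
    events = synthetic_data.simulate_size_events(
        [tuple(c) for c in config.size_components], n_events=config.n_events,
        seed=seed + 4,
    )
    np.savetxt(out / "events.tsv", events, header="size_nm", comments="")
    summary["stages"]["synthetic_data"] = {
        "n_records": len(report),
        "n_annotated": len(annotation),
        "cohort_n": len(cohort),
    }

    # --- quantification -------------------------------------------------
    validated = quant_core.validate_report(report, sheet)
    spec = quant_core.FilterSpec(
        q_max=config.q_max,
        min_precursors=config.min_precursors,
        min_donor_fraction=config.min_donor_fraction,
    )
    mat = quant_core.filter_protein_groups(validated, spec)
    mat = quant_core.median_center(mat)
    mat = quant_core.impute_missing(
        mat, shift_sd=config.imputation_shift_sd,
        width_sd=config.imputation_width_sd, seed=seed + 5,
    )
    mat.values.to_csv(out / "matrix.tsv", sep="\t")
    mat.mask.to_csv(out / "imputation_mask.tsv", sep="\t")
    sets = quant_core.detection_sets(mat)
    summary["stages"]["quant_core"] = {
        "n_retained": int(len(mat.proteins)),
        "per_group": {g: len(s) for g, s in sets.items()},
    }

    # --- differential testing -------------------------------------------
    cols = {g: mat.group_columns(g) for g in ("M1", "M2", "TAM")}
    contrasts = {}
    for a, b in [("M1", "M2"), ("TAM", "M1"), ("TAM", "M2")]:
        res, fit = differential.fit_moderated_t(
            mat.values, cols[a], cols[b], alpha=config.alpha
        )
        res.to_csv(out / f"contrast_{a}_vs_{b}.tsv", sep="\t")
        contrasts[(a, b)] = res
    summary["stages"]["differential"] = {
        f"{a}_vs_{b}": int(res["dap"].sum()) for (a, b), res in contrasts.items()
    }

    # --- signatures -------------------------------------------------------
    sig = signatures.derive_signatures(
        contrasts[("M1", "M2")], contrasts[("TAM", "M1")], contrasts[("TAM", "M2")]
    )
    (out / "signature_counts.json").write_text(json.dumps(sig.counts(), indent=2))
    for name in ("pro", "anti", "tam_enriched", "tam_unique", "tam_pro",
                 "tam_anti", "m1_sig", "m2_sig"):
        pd.Series(sorted(getattr(sig, name))).to_csv(
            out / f"signature_{name}.tsv", sep="\t", index=False, header=False
        )
    summary["stages"]["signatures"] = sig.counts()

    # --- MISEV -----------------------------------------------------------
    retained = report[report["Protein.Group"].isin(mat.proteins)]
    fractions = misev_mod.category_np_fraction(retained, annotation, level="main")
    fractions.to_csv(out / "misev_main_np.tsv", sep="\t")
    ratio = misev_mod.endosomal_ratio(
        retained, annotation,
        sample_groups=mat.samples["group"], reference_group="TAM",
    )
    ratio.to_csv(out / "endosomal_ratio.tsv", sep="\t", header=["ratio"])
    panel = misev_mod.ev_panel(annotation)
    summary["stages"]["misev"] = {
        "ev_panel_size": len(panel),
        "mean_endosomal_ratio_by_group": {
            g: float(ratio[mat.samples.index[mat.samples["group"] == g]].mean())
            for g in ("M1", "M2", "TAM")
        },
    }

    # --- enrichment --------------------------------------------------------
    universe = {g.upper() for g in genes}
    gene_sets = {
        f"MISEV_cat{cat}": set(
            annotation.loc[
                annotation["subcategory"].map(misev_mod.SUBCATEGORIES) == cat, "gene"
            ]
        )
        for cat in ("1", "2", "3", "4", "5")
    }
    collection = enrichment.GeneSetCollection(
        sets={k: v for k, v in gene_sets.items() if v}, universe=universe
    )
    tam_genes = {p.replace("P", "GENE", 1) for p in sig.tam_unique} & universe
    if len(tam_genes) < 5:  # degenerate demo guard: query the first genes
        tam_genes = set(sorted(universe)[:50])
    ora_res = enrichment.ora(
        tam_genes,
        collection,
        min_size=config.ora_min_size,
        max_size=config.ora_max_size,
        p_cut=config.ora_p_cut,
        q_cut=config.ora_q_cut,
    )
    ora_res.to_csv(out / "ora.tsv", sep="\t", index=False)
    summary["stages"]["enrichment"] = {
        "n_tested": int(len(ora_res)),
        "n_reported": int(ora_res["reported"].sum()) if len(ora_res) else 0,
    }

    # --- clinical -----------------------------------------------------------
    cox_rows = [clinical.cox_univariate(cohort, p) for p in betas]
    cox_tab = pd.DataFrame(cox_rows).set_index("protein")
    cox_tab.to_csv(out / "cox_screen.tsv", sep="\t")
    km = clinical.km_quantile_split(cohort, "PROT_RISK", quantile=config.km_quantile)
    boot = clinical.bootstrap_geneset_correlation(
        expr_x, expr_y, markers, n_boot=config.n_boot, seed=seed + 6
    )
    summary["stages"]["clinical"] = {
        "cox": {p: {"HR": r["HR"], "p": r["p"]} for p, r in cox_tab.iterrows()},
        "km_logrank_p": km["logrank_p"],
        "km_median_survival": km["median_survival"],
        "bootstrap_r": boot["r_observed"],
        "bootstrap_p": boot["p"],
    }

    # --- particles -----------------------------------------------------------
    kept, rejected = ev_metrics.load_events(events)
    dist = ev_metrics.fit_size_distribution(kept, bin_width=0.5)
    summary["stages"]["ev_metrics"] = {
        "fitted_mean_nm": dist.fitted_mean,
        "fitted_sd_nm": dist.fitted_sd,
        "sample_median_nm": dist.sample_median,
        "rejected_events": rejected,
        "particles_per_cell_example": ev_metrics.particles_per_cell(
            1e9, 1.0, 1.0, 1e7
        ),
    }

    # --- manifest ----------------------------------------------------------
    checksums = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    summary["checksums"] = checksums
    (out / "manifest.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
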