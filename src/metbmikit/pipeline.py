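"""End-to-end orchestration: simulate/load -> preprocess -> variance
explained -> metBMI -> risk models -> panel -> mediation, with one master
seed fanned out to per-stage streams, structured logging and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import derive_seed, logger
from .io import read_cohort, read_layer, write_cohort, write_layer
from .mediation import classify_linkages, prefilter_candidates, run_grids
from .metbmi import (balanced_strata_sample, fit_metbmi, predict_metbmi,
                     residualize_and_classify, select_bmi_metabolites,
                     split_train_test)
from .panel import assemble_panel, iterative_sparse_stability, shadow_feature_selection
from .preprocess import counts_to_clr
from .risk import three_model_comparison
from .simulate import GeneratorConfig, generate_cohort
from .variance import nested_cv_r2

_DEFAULTS = dict(
    # stage toggles
    do_variance=True, do_metbmi=True, do_risk=True, do_panel=False, do_mediation=True,
    # generator (used when no input paths are given)
    n_samples=800, n_metabolites=300, n_species=150, n_modules=50,
    n_proteins=100, n_phenotypes=20, bmi_r2=0.40, n_informative=None,
    # paths (optional; override the generator)
    metabolome_path=None, species_path=None, cohort_path=None,
    # thresholds — defaults echo the published analysis constants
    prevalence=0.05, rho_threshold=0.1, q_threshold=0.05,
    residual_low=-2.5, residual_high=2.5,
    n_boot=200, shadow_runs=999, stability_resamples=10,
    k_outer=10, k_inner=10, train_fraction=0.75, grid_length=100,
    penalty="ridge", panel_importance="permutation_trees",
    mediation_max_features=10,
    seed=0,
)


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None


def validate_config(raw: dict | None) -> RunConfig:
    """Normalize a raw config mapping: unknown keys rejected, defaults
    filled, contradictions and bad units reported together."""
    raw = dict(raw or {})
    errors = [f"unknown config key {k!r}" for k in raw if k not in _DEFAULTS]
    values = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}
    if values["n_boot"] < 1:
        errors.append("n_boot must be positive")
    if not 0 < values["train_fraction"] < 1:
        errors.append("train_fraction must be in (0, 1)")
    if not 0 <= values["prevalence"] <= 1:
        errors.append("prevalence must be in [0, 1]")
    if not (values["residual_low"] < 0 < values["residual_high"]):
        errors.append("residual cuts must straddle 0 (kg/m^2 units)")
    if values["do_mediation"] and values["rho_threshold"] is None:
        errors.append("mediation enabled but correlation pre-filter disabled")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return RunConfig(values)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig | dict | None, outdir) -> dict:
    """Run all enabled stages, writing TSV/JSON artifacts and a manifest.

    Each stage's outputs are the next stage's inputs; any stage failure
    aborts with the stage name after writing a partial manifest.
    """
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    manifest = {"config": dict(cfg.values), "software_version": __version__,
                "stages": {}, "seed_ledger": {"master": seed}, "input_digests": {}}
    t_all = time.time()
    current_stage = "setup"

    def record(stage, t0, **counts):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **counts}

    try:
        # ---- inputs -----------------------------------------------------
        current_stage = "simulate/load"
        t0 = time.time()
        if cfg.metabolome_path:
            metabolome = read_layer(cfg.metabolome_path, "metabolome", "log")
            species = read_layer(cfg.species_path, "species", "counts") if cfg.species_path else None
            cohort = read_cohort(cfg.cohort_path)
            for p_key in ("metabolome_path", "species_path", "cohort_path"):
                if cfg.values[p_key]:
                    manifest["input_digests"][p_key] = _digest(Path(cfg.values[p_key]))
        else:
            gen_seed = derive_seed(seed, "simulate")
            manifest["seed_ledger"]["simulate"] = gen_seed
            n_inf = cfg.n_informative
            if n_inf is None:
                # keep the cohort-default informative fraction (267/300)
                n_inf = max(1, min(267, round(0.89 * cfg.n_metabolites)))
            gcfg = GeneratorConfig(
                n_samples=cfg.n_samples, n_metabolites=cfg.n_metabolites,
                n_species=cfg.n_species, n_modules=cfg.n_modules,
                n_proteins=cfg.n_proteins, n_phenotypes=cfg.n_phenotypes,
                n_informative_metabolites=n_inf,
                bmi_r2_from_metabolome=cfg.bmi_r2, seed=gen_seed)
            layers, cohort, truth = generate_cohort(gcfg)
            metabolome, species = layers["metabolome"], layers["species"]
            truth_dir = outdir / "truth"
            truth_dir.mkdir(exist_ok=True)
            truth.to_json(truth_dir / "truth.json")
            write_layer(metabolome, outdir / "metabolome.tsv")
            write_layer(species, outdir / "species_counts.tsv")
            write_cohort(cohort, outdir / "cohort.tsv")
        met_df = metabolome.to_frame()
        record("simulate/load", t0, n_samples=len(cohort), n_metabolites=met_df.shape[1])

        # ---- preprocess --------------------------------------------------
        current_stage = "preprocess"
        t0 = time.time()
        clr_df = None
        if species is not None:
            clr = counts_to_clr(species, cfg.prevalence)
            clr_df = clr.to_frame()
            write_layer(clr, outdir / "species_clr.tsv")
        record("preprocess", t0,
               n_species_kept=0 if clr_df is None else clr_df.shape[1])

        # ---- variance explained ------------------------------------------
        if cfg.do_variance:
            current_stage = "variance-explained"
            t0 = time.time()
            vseed = derive_seed(seed, "variance")
            manifest["seed_ledger"]["variance"] = vseed
            res = nested_cv_r2(cohort["BMI"].to_numpy(), metabolome,
                               penalty_kind=cfg.penalty, k_outer=cfg.k_outer,
                               k_inner=cfg.k_inner, grid_length=cfg.grid_length,
                               seed=vseed, target_name="BMI")
            with open(outdir / "variance_explained.json", "w") as fh:
                json.dump({"target": "BMI", "layer": res.layer_name,
                           "penalty": res.penalty_kind,
                           "median_r2": res.median_r2,
                           "per_fold_r2": res.per_fold_r2.tolist()}, fh, indent=2)
            record("variance-explained", t0, median_r2=round(res.median_r2, 4))

        # ---- metBMI ------------------------------------------------------
        metbmi_series = None
        model = None
        if cfg.do_metbmi:
            current_stage = "metbmi"
            t0 = time.time()
            mseed = derive_seed(seed, "metbmi")
            manifest["seed_ledger"]["metbmi"] = mseed
            pre = select_bmi_metabolites(met_df, cohort["BMI"],
                                         cfg.rho_threshold, cfg.q_threshold)
            pool = balanced_strata_sample(cohort, seed=mseed)
            train, test, extended = split_train_test(pool, cohort,
                                                     cfg.train_fraction, seed=mseed)
            model = fit_metbmi(met_df, cohort, pre["metabolite"].tolist(),
                               train, test, non_test_ids=[s for s in extended if s not in test],
                               penalty=cfg.penalty, grid_length=cfg.grid_length,
                               seed=mseed)
            model.strata_counts = pool.strata_counts
            model.to_json(outdir / "metbmi_model.json")
            metbmi_series = predict_metbmi(model, met_df)
            classification = residualize_and_classify(
                metbmi_series, cohort, cfg.residual_low, cfg.residual_high)
            enriched = cohort.join(classification.table)
            write_cohort(enriched, outdir / "cohort_classified.tsv")
            cohort = enriched
            record("metbmi", t0, n_prefilter=len(pre), pool=len(pool.pool_ids),
                   test_r2=round(model.test_r2, 4),
                   group_sizes=classification.group_sizes)

        # ---- risk models -------------------------------------------------
        if cfg.do_risk and metbmi_series is not None:
            current_stage = "risk"
            t0 = time.time()
            outcome_cols = [c for c in cohort.columns
                            if set(pd.unique(cohort[c].dropna())) <= {0, 1}
                            and c != "sex" and cohort[c].nunique() == 2]
            rows = []
            for outcome in outcome_cols:
                try:
                    res = three_model_comparison(cohort, outcome)
                except ValueError as exc:
                    logger.warning("risk model skipped for %s: %s", outcome, exc)
                    continue
                for spec_name in ("bmi_only", "metbmi_only", "nested"):
                    r = res[spec_name]
                    for _, orow in r.odds_ratios.iterrows():
                        rows.append({"outcome": outcome, "model": spec_name,
                                     **orow.to_dict(), "deviance": r.deviance,
                                     "n_used": r.n_used,
                                     "lrt_p": res["lrt_nested_vs_bmi"].p})
            pd.DataFrame(rows).to_csv(outdir / "risk_models.tsv", sep="\t", index=False)
            record("risk", t0, n_outcomes=len(outcome_cols))

        # ---- panel -------------------------------------------------------
        if cfg.do_panel and model is not None:
            current_stage = "panel"
            t0 = time.time()
            pseed = derive_seed(seed, "panel")
            manifest["seed_ledger"]["panel"] = pseed
            Xp = met_df.loc[model.train_ids, model.prefilter_ids]
            yp = cohort.loc[model.train_ids, "BMI"]
            selector = shadow_feature_selection(Xp, yp, n_runs=cfg.shadow_runs,
                                                seed=pseed,
                                                importance=cfg.panel_importance)
            freqs = iterative_sparse_stability(Xp, yp,
                                               n_resamples=cfg.stability_resamples,
                                               seed=pseed)
            panel = assemble_panel(selector, freqs, met_df, cohort,
                                   model.train_ids, model.test_ids, seed=pseed)
            pd.DataFrame({
                "feature": panel.final_panel,
                "status": ["confirmed"] * len(panel.final_panel),
                "frequency": [freqs.get(f, np.nan) for f in panel.final_panel],
                "rank": range(1, len(panel.final_panel) + 1),
            }).to_csv(outdir / "panel.tsv", sep="\t", index=False)
            with open(outdir / "panel_r2.json", "w") as fh:
                json.dump({"panel_r2": panel.panel_r2,
                           "full_model_r2": panel.full_model_r2,
                           "panel_size": len(panel.final_panel)}, fh, indent=2)
            record("panel", t0, panel_size=len(panel.final_panel))

        # ---- mediation ---------------------------------------------------
        if cfg.do_mediation and clr_df is not None:
            current_stage = "mediation"
            t0 = time.time()
            dseed = derive_seed(seed, "mediation")
            manifest["seed_ledger"]["mediation"] = dseed
            kmax = cfg.mediation_max_features
            micro = clr_df.iloc[:, :kmax]
            metab = met_df.iloc[:, :kmax]
            pheno_cols = [c for c in cohort.columns if c.startswith("pheno_")][:kmax]
            pheno = cohort[pheno_cols] if pheno_cols else cohort[["BMI"]]
            pre = prefilter_candidates(micro, metab, pheno,
                                       cfg.rho_threshold, cfg.q_threshold)
            records = run_grids(pre.triples, micro, metab, pheno,
                                n_boot=cfg.n_boot, seed=dseed)
            records.to_csv(outdir / "grid_records.tsv", sep="\t", index=False)
            if records.empty:
                linkages = pd.DataFrame(columns=["exposure", "mediator", "outcome",
                                                 "linkage_class", "rule"])
            else:
                linkages = classify_linkages(records)
            linkages.to_csv(outdir / "linkages.tsv", sep="\t", index=False)
            record("mediation", t0, n_triples=len(pre.triples),
                   n_linkages=int((linkages["linkage_class"] != "none").sum())
                   if len(linkages) else 0)
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        manifest["total_seconds"] = round(time.time() - t_all, 3)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("pipeline complete in %.1f s", manifest["total_seconds"])
    return manifest
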