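"""End-to-end pipeline: peaks -> QC'd traits -> scans -> discrimination ->
selection -> rapid-progressor comparison, with a reconciling manifest.

Every stage writes tab-delimited text (or JSON) under the configured output
directory; the manifest accounts for every row excluded at every filter so
`input = analysed + excluded` holds throughout.  All randomness flows from
the config seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discrimination import evaluate_pair
from .glycomics import (
    PeakAnnotation, TraitMatrix, build_trait_definitions, derive_traits,
    filter_robust, normalize_total_area, robustness, rank_normal_transform,
)
from .io import PipelineConfig, write_table
from .progression import (
    ProgressionError, compare_with_without_glycans, default_zoo,
    label_rapid_progressors, run_cv,
)
from .selection import bootstrap_importance, forward_llr_select
from .survival import (
    ModelSpec, association_scan, build_design, fit_cox_records, ph_diagnostics,
    predict_risk,
)

logger = logging.getLogger(__name__)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def compute_traits(peak_table: pd.DataFrame, config: PipelineConfig):
    """Glycomics stage: normalize, derive, robustness-filter; returns
    (TraitMatrix, accounting dict)."""
    annotation = (PeakAnnotation.from_tsv(config.annotation)
                  if config.annotation else PeakAnnotation.default())
    definitions = build_trait_definitions(annotation)
    norm = normalize_total_area(peak_table)
    traits = derive_traits(norm, definitions)
    is_std = traits["is_standard"].astype(bool)
    rob = robustness(traits[is_std], traits[~is_std])
    matrix = filter_robust(
        TraitMatrix(traits[~is_std].copy(), rob), config.robustness_threshold
    )
    acct = {
        "wells_in": int(len(peak_table)),
        "wells_excluded_zero_area": int(len(peak_table) - len(norm)),
        "standard_wells": int(is_std.sum()),
        "cohort_samples": int((~is_std).sum()),
        "traits_total": len(matrix.trait_names),
        "traits_retained": len(matrix.retained_names),
    }
    return matrix, acct


def run_pipeline(config: PipelineConfig,
                 peak_table: pd.DataFrame | None = None,
                 clinical: pd.DataFrame | None = None) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    from .io import read_clinical_table, read_peak_table

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if peak_table is None:
        peak_table = read_peak_table(config.peak_table)
    if clinical is None:
        clinical = read_clinical_table(config.clinical_table)

    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # ------------------------------------------------------------------ QC
    matrix, acct = compute_traits(peak_table, config)
    manifest["stages"]["glycomics"] = acct
    qc = pd.DataFrame({
        "trait": matrix.trait_names,
        "robustness": [matrix.robustness[t] for t in matrix.trait_names],
        "retained": [int(t in matrix.retained_names) for t in matrix.trait_names],
    })
    write_table(qc, out / "robustness.tsv")
    write_table(matrix.values, out / "traits.tsv")

    # ------------------------------------------------------- association scans
    scans = []
    for outcome in config.outcomes:
        for model in config.models:
            for stratum in config.strata:
                spec = ModelSpec(model, outcome, stratum, config.transform)
                scans.append(association_scan(matrix, clinical, spec))
    scan_df = pd.concat(scans, ignore_index=True)
    write_table(scan_df, out / "association_scan.tsv")
    ok = scan_df["status"] == "ok"
    manifest["stages"]["association_scan"] = {
        "fits_attempted": int(len(scan_df)),
        "fits_ok": int(ok.sum()),
        "fits_failed": int((~ok).sum()),
        "significant_q05": int((scan_df.loc[ok, "q"] < 0.05).sum()),
    }
    _manhattan_plot(scan_df, out / "association_manhattan.png")

    # --------------------------------------------------------- discrimination
    fit_iii = fit_cox_records(clinical, ("age", "sex", "stage", "bmi", "crp_gt10"),
                              outcome="all")
    fit_ii = fit_cox_records(clinical, ("age", "sex", "stage"), outcome="all")
    cc = clinical.dropna(subset=["bmi"])
    d3 = build_design(cc, ("age", "sex", "stage", "bmi", "crp_gt10"))
    d2 = build_design(cc, ("age", "sex", "stage"))
    risk = fit_iii.linear_predictor(d3[fit_iii.covariates])
    p3 = predict_risk(fit_iii, d3[fit_iii.covariates], config.horizon_years)
    p2 = predict_risk(fit_ii, d2[fit_ii.covariates], config.horizon_years)
    report = evaluate_pair(risk, p3, p2, cc["time"], cc["event_all"].astype(bool),
                           config.horizon_years)
    ph = ph_diagnostics(
        fit_iii, d3[fit_iii.covariates].to_numpy(), cc["time"].to_numpy(),
        cc["event_all"].to_numpy(bool),
    )
    disc = {"model": "III vs II, all-cause", **report.to_dict(),
            "ph_p": ph.to_dict()}
    _write_json(disc, out / "discrimination.json")
    manifest["stages"]["discrimination"] = {
        "n_complete_case": int(len(cc)),
        "n_dropped_missing": int(len(clinical) - len(cc)),
    }

    # -------------------------------------------------------------- selection
    retained = matrix.retained_names
    tvals = matrix.values.set_index("sample_id")[retained]
    tvals = tvals.reindex(clinical["sample_id"]).set_axis(clinical.index)
    tvals = tvals.apply(lambda c: rank_normal_transform(c), axis=0)
    sel_cc = clinical.dropna(subset=["bmi"]).index
    sel_cc = sel_cc[tvals.loc[sel_cc].notna().all(axis=1)]
    base = build_design(clinical.loc[sel_cc], ("age", "sex", "stage"))
    ranking = bootstrap_importance(
        tvals.loc[sel_cc], clinical.loc[sel_cc, "time"],
        clinical.loc[sel_cc, "event_all"].astype(bool),
        n_boot=config.n_boot, seed=config.seed,
        max_estimators=150, inner_folds=config.inner_folds,
    )
    sel = forward_llr_select(
        ranking, tvals.loc[sel_cc], base,
        clinical.loc[sel_cc, "time"], clinical.loc[sel_cc, "event_all"],
        alpha=config.selection_alpha,
    )
    sel_table = pd.DataFrame({
        "trait": ranking.order,
        "mean_importance": [ranking.importance[t] for t in ranking.order],
        "selection_frequency": [ranking.selection_frequency[t]
                                for t in ranking.order],
    })
    write_table(sel_table, out / "selection_importance.tsv")
    write_table(sel.steps, out / "selection_steps.tsv")
    manifest["stages"]["selection"] = {
        "n_analysed": int(len(sel_cc)),
        "n_dropped": int(len(clinical) - len(sel_cc)),
        "selected": sel.selected,
    }

    # ------------------------------------------------- progression comparison
    zoo = default_zoo()
    prog: dict = {}
    clinical_cols = ["age", "sex_num", "crp_gt10", "bmi"]
    feats = clinical.copy()
    feats["sex_num"] = (feats["sex"] == "F").astype(float)
    feats = pd.concat([feats[["age", "sex_num", "crp_gt10", "bmi"]],
                       tvals], axis=1)
    feats["bmi"] = feats["bmi"].fillna(feats["bmi"].median())
    for stage in (1, 2, 3, 4):
        try:
            lab = label_rapid_progressors(clinical, stage)
        except ProgressionError as exc:
            prog[f"stage{stage}"] = {"skipped": str(exc)}
            continue
        idx = lab.labels.index
        if lab.labels.sum() < config.cv_folds or (
            len(idx) - lab.labels.sum() < config.cv_folds
        ):
            prog[f"stage{stage}"] = {
                "skipped": "cross-validation not possible: too few events "
                           "per fold in this stage"
            }
            continue
        sub = feats.loc[idx].dropna(axis=1, how="all")
        cv = run_cv(zoo, sub, lab.labels.to_numpy(), clinical_cols,
                    [c for c in retained if c in sub.columns],
                    n_runs=config.cv_runs, n_folds=config.cv_folds,
                    seed=config.seed)
        comp = compare_with_without_glycans(cv, zoo)
        prog[f"stage{stage}"] = {
            "cutoff_years": lab.cutoff_years,
            "n": int(len(idx)), "n_rapid": int(lab.labels.sum()),
            **comp.to_dict(),
        }
    _write_json(prog, out / "progression_comparison.json")
    manifest["stages"]["progression"] = {
        k: ("skipped" if "skipped" in v else "compared") for k, v in prog.items()
    }

    _write_json(manifest, out / "manifest.json")
    return manifest


def _manhattan_plot(scan_df: pd.DataFrame, path) -> None:
    """Manhattan-style -log10(q) summary of one scan family."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = scan_df[(scan_df["status"] == "ok") & (scan_df["model"] == "II")
                  & (scan_df["stratum"] == "whole")]
    if sub.empty:
        sub = scan_df[scan_df["status"] == "ok"]
    if sub.empty:
        return
    fig, ax = plt.subplots(figsize=(10, 4))
    for outcome, color in (("all", "tab:red"), ("crc", "tab:blue")):
        s = sub[sub["outcome"] == outcome]
        if s.empty:
            continue
        x = np.arange(len(s))
        ax.scatter(x, -np.log10(s["q"].clip(lower=1e-300)), s=14, c=color,
                   label=f"{outcome}-cause")
    ax.axhline(-np.log10(0.05), ls="--", c="grey", lw=1)
    ax.set_xlabel("glycan trait")
    ax.set_ylabel("-log10(q)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
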