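"""End-to-end pipeline orchestration over on-disk artefacts.

Stages (each resumable: a stage whose output directory already contains a
manifest is skipped): simulate -> scrub -> fit-gec -> hierarchy ->
harmonize -> stats -> classify.  Every stage writes TSV outputs plus a JSON
run manifest into its own subdirectory of the run directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gec, hierarchy as hier, io as tio
from .harmonize import harmonize
from .hopf import HopfParameters, estimate_node_frequencies
from .staging import ClassifierConfig, monte_carlo_evaluate
from .stats import fdr_bh, permutation_group_test
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("trophicbrain")

DEFAULT_STAGES = ("simulate", "scrub", "fit-gec", "hierarchy",
                  "harmonize", "stats", "classify")


def _stage_done(stage_dir: Path) -> bool:
    return (stage_dir / "manifest.json").exists()


def _save_cohort_with_sc(bundle, cohort_dir: Path) -> None:
    bundle.save(cohort_dir)
    C = bundle.truth["network"].coupling
    sc = ((C + C.T) > 0).astype(float)
    pd.DataFrame(sc, index=bundle.region_ids, columns=bundle.region_ids).to_csv(
        cohort_dir / "sc.tsv", sep="\t")


def stage_simulate(run_dir: Path, config: dict, seed: int) -> Path:
    out = run_dir / "cohort"
    if _stage_done(out):
        log.info("simulate: cohort already present, skipping")
        return out
    cfg = CohortConfig(**{**config.get("simulate", {}), "seed": seed})
    bundle = generate_cohort(cfg)
    _save_cohort_with_sc(bundle, out)
    tio.write_manifest(out, "simulate", config.get("simulate", {}),
                       seeds={"seed": seed})
    return out


def stage_scrub(run_dir: Path, cohort_dir: Path, config: dict) -> Path:
    out = run_dir / "scrubbed"
    if _stage_done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    ts_dir = cohort_dir / "timeseries"
    conf_dir = cohort_dir / "confounds"
    exclusions = []
    for f in sorted(ts_dir.glob("*.tsv")):
        ts, regions = tio.read_timeseries(f)
        conf_file = conf_dir / f.name
        if conf_file.exists():
            conf = pd.read_csv(conf_file, sep="\t")
            res = tio.apply_scrubbing(
                ts, tio.ConfoundTable(conf["fd_mm"], conf["dvars_std"]),
                **config.get("scrub", {}))
            if res.excluded:
                exclusions.append(dict(subject=f.stem, reason=res.reason))
                log.warning("scrub: excluded %s (%s)", f.stem, res.reason)
                continue
            ts = res.timeseries
        tio.write_timeseries(out / f.name, ts, regions)
    tio.write_manifest(out, "scrub", config.get("scrub", {}),
                       exclusions=exclusions)
    return out


def stage_fit_gec(run_dir: Path, ts_dir: Path, sc_path: Path, config: dict) -> Path:
    out = run_dir / "gec"
    if _stage_done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    fit_cfg = gec.FitConfig(**config.get("fit", {}))
    hopf_cfg = config.get("hopf", {})
    tr = float(config.get("tr_seconds", 3.0))
    sc = pd.read_csv(sc_path, sep="\t", index_col=0)
    regions = list(sc.columns)

    subject_stats, omegas = {}, {}
    for f in sorted(ts_dir.glob("*.tsv")):
        ts, ts_regions = tio.read_timeseries(f)
        if ts_regions != regions:
            raise ValueError(f"region ordering of {f} does not match the SC matrix")
        subject_stats[f.stem] = gec.compute_empirical_stats(
            ts, fit_cfg.tau_trs, shrink=fit_cfg.shrink_nonreversibility)
        omegas[f.stem] = estimate_node_frequencies(ts, tr)
    omega = np.mean(list(omegas.values()), axis=0)
    params = HopfParameters(
        a=hopf_cfg.get("a", -0.02), omega=omega,
        sigma=hopf_cfg.get("sigma", 0.01), tau=fit_cfg.tau_trs)

    group_result, results = gec.fit_cohort(
        subject_stats, sc.to_numpy(), params, tr, config=fit_cfg)
    pd.DataFrame(group_result.coupling, index=regions, columns=regions).to_csv(
        out / "group_gec.tsv", sep="\t")
    trace_rows, failures = [], []
    for subject, res in results.items():
        if isinstance(res, Exception):
            failures.append(dict(subject=subject, error=str(res)))
            log.error("fit-gec: %s failed: %s", subject, res)
            continue
        pd.DataFrame(res.coupling, index=regions, columns=regions).to_csv(
            out / f"{subject}.tsv", sep="\t")
        trace_rows.append(dict(subject=subject, n_iter=res.n_iter,
                               converged=res.converged, error=res.final_error))
    pd.DataFrame(trace_rows).to_csv(out / "fit_trace.tsv", sep="\t", index=False)
    tio.write_manifest(out, "fit-gec", config.get("fit", {}),
                       inputs=[sc_path], exclusions=failures)
    return out


def stage_hierarchy(run_dir: Path, gec_dir: Path, mapping: pd.Series,
                    config: dict) -> Path:
    out = run_dir / "hierarchy"
    if _stage_done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    levels, globals_rows = {}, []
    for f in sorted(gec_dir.glob("sub-*.tsv")):
        W = pd.read_csv(f, sep="\t", index_col=0)
        res = hier.trophic_analysis(W.to_numpy(), region_ids=W.columns)
        levels[f.stem] = pd.Series(res.h, index=W.columns)
        globals_rows.append(dict(subject=f.stem, F0=res.F0,
                                 directedness=res.directedness,
                                 asymmetry=res.asymmetry))
    level_table = pd.DataFrame(levels).T
    level_table.index.name = "subject"
    level_table.to_csv(out / "trophic_levels.tsv", sep="\t")
    pd.DataFrame(globals_rows).set_index("subject").to_csv(
        out / "global_metrics.tsv", sep="\t")
    net_table = level_table.T.groupby(mapping.reindex(level_table.columns)).mean().T
    net_table.index.name = "subject"
    net_table.to_csv(out / "network_levels.tsv", sep="\t")
    tio.write_manifest(out, "hierarchy", {})
    return out


def stage_harmonize(run_dir: Path, hier_dir: Path, metadata: pd.DataFrame,
                    mapping: pd.Series, config: dict) -> Path:
    out = run_dir / "harmonized"
    if _stage_done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    covars = config.get("harmonize", {}).get(
        "covariates", ["age", "gender", "education", "group"])
    levels = pd.read_csv(hier_dir / "trophic_levels.tsv", sep="\t",
                         index_col="subject")
    harmonized, _, excluded = harmonize(levels, metadata.loc[levels.index],
                                        covariate_cols=covars)
    harmonized.to_csv(out / "trophic_levels.tsv", sep="\t")
    net = harmonized.T.groupby(mapping.reindex(harmonized.columns)).mean().T
    net.index.name = "subject"
    net.to_csv(out / "network_levels.tsv", sep="\t")
    glob = pd.read_csv(hier_dir / "global_metrics.tsv", sep="\t",
                       index_col="subject")
    meta_kept = metadata.loc[harmonized.index]
    gh, _, _ = harmonize(glob.loc[harmonized.index, ["directedness", "asymmetry"]],
                         meta_kept, covariate_cols=covars)
    gh[["directedness"]].to_csv(out / "directedness.tsv", sep="\t")
    tio.write_manifest(out, "harmonize", {"covariates": covars},
                       exclusions=[dict(subject=s, reason="unique site")
                                   for s in excluded])
    return out


def stage_stats(run_dir: Path, harm_dir: Path, metadata: pd.DataFrame,
                config: dict, seed: int) -> Path:
    out = run_dir / "stats"
    if _stage_done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    scfg = config.get("stats", {})
    contrast = scfg.get("contrast", ["HC-", "AD+"])
    n_perm = int(scfg.get("n_perm", 10_000))
    net = pd.read_csv(harm_dir / "network_levels.tsv", sep="\t", index_col="subject")
    direct = pd.read_csv(harm_dir / "directedness.tsv", sep="\t", index_col="subject")
    feats = net.join(direct)
    meta = metadata.loc[feats.index]
    sel = meta["group"].isin(contrast)
    from .harmonize import build_covariates

    cov = build_covariates(meta[sel], ["age", "gender", "education"])
    rows = []
    for i, col in enumerate(feats.columns):
        res = permutation_group_test(
            feats.loc[sel.index[sel], col], meta.loc[sel.index[sel], "group"],
            covariates=cov, n_perm=n_perm, seed=seed + i)
        rows.append(dict(unit=col, stat=res.observed_stat, p=res.p_value,
                         coefficient=res.coefficient))
    table = pd.DataFrame(rows)
    table["significant"], table["p_adj"] = fdr_bh(table["p"])
    table.to_csv(out / "group_compare.tsv", sep="\t", index=False)
    tio.write_manifest(out, "stats", scfg, seeds={"seed": seed})
    return out


def stage_classify(run_dir: Path, harm_dir: Path, metadata: pd.DataFrame,
                   config: dict, seed: int) -> Path:
    out = run_dir / "classify"
    if _stage_done(out):
        return out
    out.mkdir(parents=True, exist_ok=True)
    ccfg_dict = dict(config.get("classify", {}))
    contrast = ccfg_dict.pop("contrast", ["HC-", "AD+"])
    ccfg = ClassifierConfig(**{**ccfg_dict, "seed": seed})
    levels = pd.read_csv(harm_dir / "trophic_levels.tsv", sep="\t",
                         index_col="subject")
    net = pd.read_csv(harm_dir / "network_levels.tsv", sep="\t", index_col="subject")
    direct = pd.read_csv(harm_dir / "directedness.tsv", sep="\t", index_col="subject")
    feats = levels.join(net, rsuffix="_net").join(direct)
    meta = metadata.loc[feats.index]
    sel = meta["group"].isin(contrast)
    report = monte_carlo_evaluate(
        feats[sel].to_numpy(), meta.loc[sel, "group"].to_numpy(), ccfg,
        feature_names=list(feats.columns))
    (out / "report.json").write_text(json.dumps(dict(
        contrast=contrast,
        metrics_mean=report.metrics_mean.to_dict(),
        metrics_sd=report.metrics_sd.to_dict(),
        permutation_p_median=report.permutation_p_median,
        permutation_p_iqr=report.permutation_p_iqr,
        n_failed_iterations=report.n_failed_iterations,
    ), indent=2))
    pd.DataFrame(dict(fpr=report.roc_fpr_grid, tpr=report.roc_tpr_mean)).to_csv(
        out / "roc_mean.tsv", sep="\t", index=False)
    report.confusion_proportions.to_csv(out / "confusion.tsv", sep="\t")
    report.shap_importance.rename("mean_abs_shap").to_csv(
        out / "shap_importance.tsv", sep="\t")
    tio.write_manifest(out, "classify", ccfg_dict, seeds={"seed": seed})
    return out


def pipeline_run(config: dict, run_dir, stages=DEFAULT_STAGES) -> dict:
    """Run the ordered pipeline; each stage resumes from on-disk artefacts.

    Returns a dict of stage name -> output directory.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    outputs = {}

    cohort_dir = run_dir / "cohort"
    if "simulate" in stages:
        cohort_dir = stage_simulate(run_dir, config, seed)
        outputs["simulate"] = cohort_dir
    elif "cohort_dir" in config:
        cohort_dir = Path(config["cohort_dir"])
    metadata = pd.read_csv(cohort_dir / "metadata.tsv", sep="\t",
                           index_col="subject")
    mapping = pd.read_csv(cohort_dir / "network_mapping.tsv", sep="\t",
                          index_col=0)["network"]

    ts_dir = cohort_dir / "timeseries"
    if "scrub" in stages:
        ts_dir = stage_scrub(run_dir, cohort_dir, config)
        outputs["scrub"] = ts_dir
    if "fit-gec" in stages:
        outputs["fit-gec"] = stage_fit_gec(run_dir, ts_dir,
                                           cohort_dir / "sc.tsv", config)
    if "hierarchy" in stages:
        outputs["hierarchy"] = stage_hierarchy(
            run_dir, run_dir / "gec", mapping, config)
    if "harmonize" in stages:
        outputs["harmonize"] = stage_harmonize(
            run_dir, run_dir / "hierarchy", metadata, mapping, config)
    if "stats" in stages:
        outputs["stats"] = stage_stats(run_dir, run_dir / "harmonized",
                                       metadata, config, seed)
    if "classify" in stages:
        outputs["classify"] = stage_classify(run_dir, run_dir / "harmonized",
                                             metadata, config, seed)
    return outputs
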