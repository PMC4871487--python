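"""Configuration-driven orchestration: simulate -> build features -> fit ->
select -> targets -> validate.

Each stage reads its inputs from and writes its outputs to the run directory,
so any stage can be re-run from cached intermediates (``resume=True`` skips
stages whose outputs already exist).  One master seed deterministically spawns
per-stage, per-sample and per-regulator child seeds; a rerun with the same
configuration and seed reproduces every result table byte for byte.  The
manifest records the configuration, seeds, stage outputs and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import REGULATOR_CLASSES, RunConfig, stable_seed
from .features import build_feature_counts, merge_identical_features
from .lasso import RegressionFit, fit_lasso, select_lambda_cv
from .selective import count_selections, estimate_sigma, rank_regulators, selective_pvalues
from .synthetic import (
    SyntheticTruth,
    draw_truth,
    generate_expression,
    generate_features,
    generate_matched_lfc,
    generate_sequences,
)
from .targets import discover_targets, ecdf_groups, make_validation_groups, overlap_report

logger = logging.getLogger(__name__)

_STAGE_OUTPUTS = {
    "simulate": ["features.tsv", "expression.tsv", "truth.json", "lfc.tsv"],
    "build_features": ["sequences.fasta", "annotations.tsv", "features_rebuilt.tsv"],
    "preprocess": ["features_model.tsv"],
    "fit": ["fits.json", "coefficients.tsv"],
    "select": ["selection_table.tsv"],
    "targets": ["targets.tsv"],
    "validate": ["validation.json"],
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _outputs_exist(outdir: Path, stage: str) -> bool:
    return all((outdir / f).exists() for f in _STAGE_OUTPUTS[stage])


def run(config: RunConfig, outdir: str | Path | None = None,
        resume: bool = False) -> dict:
    """Execute the configured stages; returns the manifest (also on disk)."""
    outdir = Path(outdir or config.outdir or "regnet_run")
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)

    # validate stage inputs are resolvable before any stage executes
    produced = set()
    for stage in stages:
        needs = {
            "simulate": [],
            "build_features": ["simulate"],
            "preprocess": ["simulate"],
            "fit": ["simulate"],
            "select": ["simulate", "fit"],
            "targets": ["simulate", "fit", "select"],
            "validate": ["simulate", "targets"],
        }[stage]
        for dep in needs:
            if dep not in produced and dep not in stages and not _outputs_exist(outdir, dep):
                raise StageError(
                    f"stage {stage!r} needs outputs of {dep!r}, which is neither "
                    f"scheduled nor present in {outdir}")
        produced.add(stage)

    manifest: dict = {
        "config": json.loads(json.dumps(_config_dict(config))),
        "seed": config.seed,
        "stages": {},
    }
    for stage in stages:
        if resume and _outputs_exist(outdir, stage):
            manifest["stages"][stage] = {"skipped": True}
            continue
        fn = globals()[f"_stage_{stage}"]
        try:
            info = fn(config, outdir) or {}
        except Exception as exc:
            _write_manifest(manifest, outdir)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        info["outputs"] = {
            f: _sha256(outdir / f) for f in _STAGE_OUTPUTS[stage]
            if (outdir / f).exists()
        }
        manifest["stages"][stage] = info
    _write_manifest(manifest, outdir)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["stages"] = list(config.stages)
    return d


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    sim = config.simulation
    features = generate_features(sim)
    truth = draw_truth(features, sim)
    expr = generate_expression(features, truth, sim)
    lfc = generate_matched_lfc(truth, list(features.values.index), sim)
    rio.write_feature_tsv(features, outdir / "features.tsv")
    rio.write_expression_tsv(expr, outdir / "expression.tsv")
    truth.to_json(outdir / "truth.json")
    lfc.to_csv(outdir / "lfc.tsv", sep="\t", float_format="%.10g")
    return {"n_genes": sim.n_genes, "n_samples": sim.n_samples,
            "active_regulators": sorted(truth.active_regulators)}


def _stage_build_features(config: RunConfig, outdir: Path) -> dict:
    sim = config.simulation
    features = rio.read_feature_tsv(outdir / "features.tsv")
    bundle = generate_sequences(features, sim)
    rio.write_fasta(bundle.sequences, outdir / "sequences.fasta")
    rio.write_annotations(bundle.annotations, outdir / "annotations.tsv")
    for cls in REGULATOR_CLASSES:
        if bundle.pfms.get(cls):
            rio.write_jaspar(bundle.pfms[cls],
                             outdir / f"pfm_{cls.lower()}.jaspar")
    rio.write_bed(bundle.dnase_peaks, outdir / "dnase.bed")
    rio.write_bed(bundle.clip_peaks, outdir / "clip.bed")

    counts = build_feature_counts(
        bundle.sequences, bundle.annotations, bundle.pfms,
        promoter_flank=bundle.promoter_flank, fimo_p=bundle.fimo_p,
        rbp_top_kmers=bundle.rbp_top_kmers,
        mirna_top_kmers=bundle.mirna_top_kmers,
        dnase_peaks=bundle.dnase_peaks, clip_peaks=bundle.clip_peaks,
        tf_no_peak_mode="drop", rbp_no_peak_mode="pass")
    from .features import assemble_feature_matrix

    rebuilt = assemble_feature_matrix(counts, features.values["CNV"],
                                      features.values["METH"],
                                      genes=list(features.values.index))
    rio.write_feature_tsv(rebuilt, outdir / "features_rebuilt.tsv")
    planted = features.values[rebuilt.values.columns]
    exact = bool(np.array_equal(planted.to_numpy(), rebuilt.values.to_numpy()))
    if not exact:
        logger.warning("rebuilt feature matrix differs from planted counts")
    return {"roundtrip_exact": exact,
            "n_rebuilt_features": rebuilt.values.shape[1]}


def _stage_preprocess(config: RunConfig, outdir: Path) -> dict:
    # synthetic expression is already on the log2-TPM scale; this stage
    # collapses duplicate feature columns before modelling
    features = rio.read_feature_tsv(outdir / "features.tsv")
    merged = merge_identical_features(features)
    rio.write_feature_tsv(merged, outdir / "features_model.tsv")
    return {"n_features": merged.values.shape[1],
            "n_merged_away": features.values.shape[1] - merged.values.shape[1]}


def _model_matrix(outdir: Path):
    path = outdir / "features_model.tsv"
    if not path.exists():
        path = outdir / "features.tsv"
    fm = rio.read_feature_tsv(path)
    return merge_identical_features(fm)


def _stage_fit(config: RunConfig, outdir: Path) -> dict:
    fm = _model_matrix(outdir)
    expr = rio.read_expression_tsv(outdir / "expression.tsv")
    X = fm.values
    fits_meta: dict = {"feature_names": list(X.columns), "fits": {}}
    rows = []
    for s in expr.samples:
        y = expr.values[s]
        sel = select_lambda_cv(X, y, K=config.folds,
                               seed=stable_seed(config.seed, "fit", s))
        fit = fit_lasso(X, y, sel.lam, sample=s)
        fits_meta["fits"][s] = {
            "intercept": fit.intercept,
            "lambda": fit.lam,
            "coefficients": dict(sorted(fit.coefficients.items())),
            "kkt_residual": fit.kkt_residual,
        }
        rows.append({"sample": s, "feature": "(intercept)",
                     "coefficient": fit.intercept})
        rows += [{"sample": s, "feature": f, "coefficient": w}
                 for f, w in sorted(fit.coefficients.items())]
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fits_meta, fh, indent=1, sort_keys=True)
    pd.DataFrame(rows).to_csv(outdir / "coefficients.tsv", sep="\t",
                              index=False, float_format="%.10g")
    return {"n_fits": len(expr.samples)}


def _load_fits(outdir: Path) -> tuple[list[str], dict[str, RegressionFit]]:
    with open(outdir / "fits.json") as fh:
        meta = json.load(fh)
    names = meta["feature_names"]
    fits = {
        s: RegressionFit(intercept=d["intercept"],
                         coefficients=d["coefficients"],
                         lam=d["lambda"], feature_names=names, sample=s)
        for s, d in meta["fits"].items()
    }
    return names, fits


def _stage_select(config: RunConfig, outdir: Path) -> dict:
    fm = _model_matrix(outdir)
    expr = rio.read_expression_tsv(outdir / "expression.tsv")
    _, fits = _load_fits(outdir)
    X = fm.values
    results = []
    for s in expr.samples:
        y = expr.values[s]
        sigma = estimate_sigma(X, y, active=fits[s].active_set)
        res = selective_pvalues(X, y, fits[s].lam, sigma, sample=s)
        results.append(res)
    table = count_selections(results, alpha=config.alpha,
                             feature_names=list(X.columns),
                             classes=fm.classes)
    table.to_csv(outdir / "selection_table.tsv", sep="\t", index=False,
                 float_format="%.10g")
    return {"n_samples": len(results)}


def _stage_targets(config: RunConfig, outdir: Path) -> dict:
    fm = _model_matrix(outdir)
    expr = rio.read_expression_tsv(outdir / "expression.tsv")
    _, fits = _load_fits(outdir)
    table = pd.read_csv(outdir / "selection_table.tsv", sep="\t")
    reg_table = table[table["class"].isin(REGULATOR_CLASSES)]
    candidates = rank_regulators(reg_table, config.resolved_min_samples())
    chosen = list(candidates["regulator"].head(config.max_target_regulators))
    X = fm.values
    ys = [expr.values[s].to_numpy() for s in expr.samples]
    fit_list = [fits[s] for s in expr.samples]
    frames = []
    for reg in chosen:
        calls = discover_targets(
            X, ys, fit_list, reg, B=config.permutations,
            seed=stable_seed(config.seed, "targets", reg),
            q_threshold=config.q_threshold)
        frames.append(calls[calls["is_target"]])
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["regulator", "gene", "delta_error",
                                      "p_emp", "q_value", "is_target"]))
    out.to_csv(outdir / "targets.tsv", sep="\t", index=False,
               float_format="%.10g")
    return {"regulators_tested": chosen,
            "n_targets_called": int(len(out))}


def _stage_validate(config: RunConfig, outdir: Path) -> dict:
    fm = _model_matrix(outdir)
    truth = SyntheticTruth.from_json(outdir / "truth.json")
    calls = pd.read_csv(outdir / "targets.tsv", sep="\t")
    lfc = pd.read_csv(outdir / "lfc.tsv", sep="\t", index_col="gene")
    report: dict = {"overlap": {}, "ecdf_ks": []}
    for reg, grp in calls.groupby("regulator"):
        predicted = set(grp["gene"])
        reference = truth.target_sets.get(reg, set())
        report["overlap"][reg] = overlap_report(predicted, reference)
    # ECDF comparison for the regulator whose targets the LFC table shifts
    lfc_reg = sorted(truth.active_regulators)[0] if truth.active_regulators else None
    if lfc_reg is not None and lfc_reg in fm.values.columns:
        predicted = set(calls.loc[calls["regulator"] == lfc_reg, "gene"])
        motif_genes = set(fm.values.index[fm.values[lfc_reg] > 0])
        groups = make_validation_groups(list(fm.values.index),
                                        truth.target_sets[lfc_reg],
                                        predicted, motif_genes)
        res = ecdf_groups(lfc["lfc"], groups)
        report["ecdf_ks"] = res["ks"].to_dict(orient="records")
        report["ecdf_group_sizes"] = res["group_sizes"]
        report["lfc_regulator"] = lfc_reg
    with open(outdir / "validation.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return {"n_regulators_validated": len(report["overlap"])}
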