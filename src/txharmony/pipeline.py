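"""End-to-end orchestration: simulate/ingest -> harmonize -> select ->
train/evaluate -> importance -> enrichment -> report.

Every stochastic stage draws its seed from a named substream of the master
seed, so results are bit-reproducible and insensitive to reordering of
unrelated stages.  All estimable transform parameters (coverage threshold,
size-factor reference, z-score moments, mRMR selection) are fit on training
samples only; the test side is touched exclusively through already-frozen
parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from txharmony import enrichment as enr
from txharmony import harmonize as hz
from txharmony import importance as imp
from txharmony import io
from txharmony import models as mdl
from txharmony import selection as sel
from txharmony import simulate as sim
from txharmony.errors import ConfigurationError, StageError

__all__ = ["RunConfig", "RunArtifacts", "run_pipeline", "write_report"]

log = logging.getLogger("txharmony")

_STAGES = (
    "simulate",
    "outliers",
    "split",
    "filter",
    "standardize",
    "mrmr",
    "cv_curve",
    "models",
    "baseline",
    "importance",
    "expansion",
    "enrichment",
)


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    input_dir: str | None = None  # required in files mode
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    min_count: int = 5
    coverage_rule: str = "mean"
    coverage_theta: float | None = None
    pca_sd_mult: float = 3.0
    rin_sd_mult: float = 2.0
    train_frac: float = 0.8
    k_max: int | None = None  # None: number of training samples
    elbow_mode: str = "kneedle"  # "kneedle" | "manual"
    manual_k: int | None = None
    n_folds: int = 5
    n_baseline: int = 1000
    n_pfi_repeats: int = 100
    gsea_weight: float = 1.0
    n_perm: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    sets_per_signal: int = 5
    enrichment_min_study_n: int = 10
    expansion_anchor: str | None = None  # files mode: anchor/regulator pair for
    expansion_target: str | None = None  # calibrating the expansion size
    sig_cutoff: float = 0.1
    loose_cutoff: float = 0.9
    seed: int = 0
    outdir: str = "txharmony_run"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode: {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ConfigurationError("files mode requires input_dir")
        if self.elbow_mode == "manual" and not self.manual_k:
            raise ConfigurationError("manual elbow mode requires manual_k")
        self.sim.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["studies"] = [dataclasses.asdict(s) for s in self.sim.studies]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        simd = d.pop("sim", {})
        studies = tuple(
            sim.StudyTemplate(**{**s, "ages_weeks": tuple(s["ages_weeks"])})
            for s in simd.pop("studies", [])
        ) or sim.DEFAULT_COHORT
        if "baseline_log2_mean_range" in simd:
            simd["baseline_log2_mean_range"] = tuple(simd["baseline_log2_mean_range"])
        return cls(sim=sim.SimConfig(studies=studies, **simd), **d)

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # hash the scientific parameters, not the output location
        return hashlib.sha256(repr(sorted(d.items(), key=lambda kv: kv[0])).encode()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    outdir: Path
    summary: dict
    paths: dict[str, str]
    checksums: dict[str, str]


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Named per-stage seeds fanned out from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for name, c in zip(_STAGES, children)
    }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute all stages in order and write every intermediate under ``outdir``.

    A failing stage aborts with a :class:`StageError` naming the stage;
    artifacts written before the failure are retained together with a
    ``FAILED`` marker file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    paths: dict[str, str] = {}
    summary: dict = {"config_hash": config.content_hash(), "seed": config.seed}

    def save(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        paths[name] = str(path)

    stage = "inputs"
    try:
        # ------------------------------------------------------------------ inputs
        if config.mode == "synthetic":
            stage = "simulate"
            cfg = dataclasses.replace(config.sim, seed=seeds["simulate"] if config.sim.seed == 0 else config.sim.seed)
            bundles, truth = sim.generate_multistudy_counts(cfg)
            pseudogenes, gene_sets = sim.generate_gene_annotation(
                truth, sets_per_signal=config.sets_per_signal, seed=seeds["simulate"]
            )
            truth.to_json(outdir / "ground_truth.json")
            paths["ground_truth.json"] = str(outdir / "ground_truth.json")
            anchor, target = truth.anchor_gene, truth.regulator_gene
        else:
            stage = "ingest"
            indir = Path(config.input_dir)
            bundles, _ = sim.read_cohort(indir)
            truth = None
            pseudogenes = io.read_pseudogene_list(indir / "pseudogenes.txt")
            gene_sets = io.read_gmt(indir / "gene_sets.gmt")
            anchor, target = config.expansion_anchor, config.expansion_target
        meta_all = pd.concat([b.metadata for b in bundles])
        summary["n_samples_input"] = int(len(meta_all))
        summary["n_genes_input"] = int(len(bundles[0].gene_ids))
        log.info("inputs: %d studies, %d samples, %d genes", len(bundles), len(meta_all), len(bundles[0].gene_ids))

        # ---------------------------------------------------------------- outliers
        stage = "outliers"
        pc = hz.pooled_raw_pc_scores(bundles)
        global_rin = float(meta_all["rin"].mean()) if "rin" in meta_all else None
        excluded: list[str] = []
        reports = {}
        for b in bundles:
            rep = hz.flag_outliers(
                b, pc, pca_sd_mult=config.pca_sd_mult,
                rin_sd_mult=config.rin_sd_mult, global_rin_mean=global_rin,
            )
            reports[b.study_id] = rep
            excluded += rep.excluded_samples
        io.write_json(
            {sid: rep.flags["reason"][rep.flags["excluded"]].to_dict() for sid, rep in reports.items()},
            outdir / "outliers.json",
        )
        paths["outliers.json"] = str(outdir / "outliers.json")
        bundles = [
            sim.StudyBundle(
                b.study_id,
                b.counts.drop(columns=[s for s in excluded if s in b.counts.columns]),
                b.metadata.drop(index=[s for s in excluded if s in b.metadata.index]),
            )
            for b in bundles
        ]
        meta = pd.concat([b.metadata for b in bundles])
        summary["n_outliers_removed"] = len(excluded)
        summary["n_samples"] = int(len(meta))
        summary["global_rin_mean"] = global_rin
        log.info("outliers: removed %d samples, %d remain", len(excluded), len(meta))

        # ------------------------------------------------------------------- split
        stage = "split"
        split = mdl.split_balanced(meta, frac=config.train_frac, seed=seeds["split"])
        split.assignment.to_csv(outdir / "split.tsv", sep="\t")
        paths["split.tsv"] = str(outdir / "split.tsv")
        n_train = len(split.train_samples)
        summary["n_train"] = n_train
        summary["n_test"] = len(split.test_samples)

        # ------------------------------------------------------------------ filter
        stage = "filter"
        mask = hz.filter_genes(
            bundles,
            pseudogenes,
            min_count=config.min_count,
            coverage_rule=config.coverage_rule,
            theta=config.coverage_theta,
            samples=split.train_samples,
        )
        io.write_json(
            {"kept": mask.kept, "threshold": mask.threshold,
             "n_removed": len(mask.removed),
             "removed_reasons": pd.Series(list(mask.removed.values())).value_counts().to_dict()},
            outdir / "gene_filter.json",
        )
        paths["gene_filter.json"] = str(outdir / "gene_filter.json")
        summary["coverage_threshold"] = mask.threshold
        summary["n_genes_retained"] = len(mask.kept)
        summary["gene_reduction_pct"] = round(100.0 * (1 - len(mask.kept) / len(bundles[0].gene_ids)), 1)
        log.info("filter: kept %d genes (threshold %.3f, %.1f%% reduction)",
                 len(mask.kept), mask.threshold, summary["gene_reduction_pct"])

        # raw-count PCA diagnostic on the retained universe
        pooled_raw = pd.concat([b.counts.loc[mask.kept] for b in bundles], axis=1).T
        raw_pca = hz.pca_diagnostics(
            pooled_raw, {"study": meta["study_id"], "class": meta["class"]}
        )
        summary["raw_pc12_variance_pct"] = round(100.0 * float(raw_pca.explained_variance_ratio[:2].sum()), 1)
        summary["raw_silhouette_study"] = raw_pca.silhouettes["study"]
        summary["raw_silhouette_class"] = raw_pca.silhouettes["class"]

        # ------------------------------------------------------------- standardize
        stage = "standardize"
        z_by_study: dict[str, pd.DataFrame] = {}
        params_by_study: dict[str, hz.StandardizationParams] = {}
        provenance: list[dict] = []
        hz.record_transform(provenance, "filter_genes", {"threshold": mask.threshold})
        train_set = set(split.train_samples)
        for b in bundles:
            counts = b.counts.loc[mask.kept]
            study_train = [s for s in b.sample_ids if s in train_set]
            sf = hz.size_factors_mor(counts, reference_samples=study_train)
            normed = hz.apply_size_factors(counts, sf)
            Z, params = hz.standardize_study(normed, train_samples=study_train)
            z_by_study[b.study_id] = Z
            params_by_study[b.study_id] = params
        hz.record_transform(provenance, "mor_log2_zscore", {"per_study": True})
        dropped = hz.zero_variance_genes(params_by_study)
        if dropped:
            z_by_study = {sid: Z.drop(index=sorted(dropped)) for sid, Z in z_by_study.items()}
            log.info("standardize: dropped %d zero-variance genes globally", len(dropped))
        summary["n_zero_variance_dropped"] = len(dropped)
        hm = hz.merge_studies(z_by_study, meta, provenance=provenance)
        hm.X.to_csv(outdir / "harmonized.tsv", sep="\t")
        paths["harmonized.tsv"] = str(outdir / "harmonized.tsv")
        io.write_json(
            {sid: {"mu_sha": p.content_hash()} for sid, p in params_by_study.items()},
            outdir / "standardization_params.json",
        )
        paths["standardization_params.json"] = str(outdir / "standardization_params.json")

        harm_pca = hz.pca_diagnostics(
            hm.X, {"study": meta["study_id"], "class": meta["class"]}
        )
        summary["harmonized_pc12_variance_pct"] = round(100.0 * float(harm_pca.explained_variance_ratio[:2].sum()), 1)
        summary["harmonized_silhouette_study"] = harm_pca.silhouettes["study"]
        summary["harmonized_silhouette_class"] = harm_pca.silhouettes["class"]

        X_train = hm.X.loc[split.train_samples]
        X_test = hm.X.loc[split.test_samples]
        y_ser = pd.Series(hm.y, index=hm.X.index)
        y_train = y_ser.loc[split.train_samples].to_numpy()
        y_test = y_ser.loc[split.test_samples].to_numpy()

        # -------------------------------------------------------------------- mRMR
        stage = "mrmr"
        k_max = config.k_max or min(n_train, X_train.shape[1])
        trace = sel.mrmr_select(X_train, y_train, k_max=k_max)
        trace.to_frame().to_csv(outdir / "mrmr_trace.tsv", sep="\t", index=False)
        paths["mrmr_trace.tsv"] = str(outdir / "mrmr_trace.tsv")

        stage = "cv_curve"
        specs = {k: s.with_seed(seeds["models"]) for k, s in mdl.DEFAULT_SPECS.items()}
        curve = sel.cv_accuracy_curve(
            X_train, y_train, trace, specs, n_folds=config.n_folds, seed=seeds["cv_curve"]
        )
        curve.to_csv(outdir / "cv_curve.tsv", sep="\t", index=False)
        paths["cv_curve.tsv"] = str(outdir / "cv_curve.tsv")
        try:
            k_star = sel.select_elbow(curve, mode=config.elbow_mode, manual_k=config.manual_k)
        except Exception:
            if config.manual_k:
                k_star = config.manual_k
            else:
                raise
        summary["k_star"] = int(k_star)
        log.info("selection: k_max=%d, elbow k*=%d", k_max, k_star)

        # ------------------------------------------------------------------ models
        stage = "models"
        panel = trace.genes[:k_star]
        fitted = {name: mdl.train_classifier(X_train[panel], y_train, spec) for name, spec in specs.items()}
        evals = {name: mdl.roc_auc(m, X_test[panel], y_test) for name, m in fitted.items()}
        io.write_json({n: e.to_dict() for n, e in evals.items()}, outdir / "model_evals.json")
        paths["model_evals.json"] = str(outdir / "model_evals.json")
        for name, e in evals.items():
            summary[f"auc_{name}"] = round(e.auc, 4)
            summary[f"accuracy_{name}"] = round(e.accuracy, 4)

        stage = "baseline"
        baseline = mdl.random_feature_baseline(
            hm.X, hm.y, split, k=k_star, specs=specs,
            n_iter=config.n_baseline, seed=seeds["baseline"],
        )
        delong = {}
        for name in specs:
            summary[f"baseline_mean_auc_{name}"] = round(baseline.means[name], 4)
            med = baseline.median_iteration(name)
            subset = baseline.subsets[med]
            base_model = mdl.train_classifier(X_train[subset], y_train, specs[name])
            base_eval = mdl.roc_auc(base_model, X_test[subset], y_test)
            delong[name] = mdl.delong_test(evals[name], base_eval)
            summary[f"delong_p_{name}"] = delong[name]["p"]
        io.write_json(
            {"means": baseline.means, "delong": delong,
             "aucs": {n: a.tolist() for n, a in baseline.aucs.items()}},
            outdir / "baseline.json",
        )
        paths["baseline.json"] = str(outdir / "baseline.json")

        # PCA of the mRMR panel: class structure should now dominate
        panel_pca = hz.pca_diagnostics(hm.X[panel], {"study": meta["study_id"], "class": meta["class"]})
        summary["mrmr_silhouette_study"] = panel_pca.silhouettes["study"]
        summary["mrmr_silhouette_class"] = panel_pca.silhouettes["class"]
        summary["mrmr_pc1_variance_pct"] = round(100.0 * float(panel_pca.explained_variance_ratio[0]), 1)

        # -------------------------------------------------------------- importance
        stage = "importance"
        tables = [
            imp.permutation_importance(
                fitted[name], X_test[panel], y_test,
                n_repeats=config.n_pfi_repeats, seed=seeds["importance"],
            )
            for name in specs
        ]
        conc = imp.rank_concordance(tables, mrmr_order=panel)
        conc.table.to_csv(outdir / "concordance.tsv", sep="\t")
        paths["concordance.tsv"] = str(outdir / "concordance.tsv")
        summary["top_concordant_genes"] = conc.top_concordant[:5]

        # --------------------------------------------------------------- expansion
        stage = "expansion"
        if anchor and target and anchor in hm.X.columns and target in hm.X.columns:
            exp_k = imp.calibrate_expansion_k(hm.X, anchor, target)
        else:
            exp_k = max(1, int(round(0.125 * hm.X.shape[1])))  # ~250 of 2000 default
        exp_k = min(exp_k, hm.X.shape[1] - 1)
        summary["expansion_k"] = int(exp_k)
        expansion = {
            f"expanded_{g}": imp.expand_correlated_set(hm.X, g, exp_k) for g in panel[:10]
        }
        io.write_gmt(expansion, outdir / "expanded_sets.gmt")
        paths["expanded_sets.gmt"] = str(outdir / "expanded_sets.gmt")

        # -------------------------------------------------------------- enrichment
        stage = "enrichment"
        svm_full = mdl.train_classifier(X_train, y_train, specs["svm"])
        merged_rank = enr.svm_coefficient_rank(svm_full)
        merged_res = enr.gsea_preranked(
            merged_rank, gene_sets, p=config.gsea_weight, n_perm=config.n_perm,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            seed=seeds["enrichment"],
        )
        single_res: dict[str, enr.EnrichmentResult] = {}
        for b in bundles:
            if len(b.metadata) < config.enrichment_min_study_n:
                continue
            counts = b.counts.loc[mask.kept]
            sf = hz.size_factors_mor(counts)
            ranked = enr.fold_change_rank(
                sim.StudyBundle(b.study_id, counts, b.metadata), sf
            )
            # restrict to the merged universe so overlap compares like with like
            ranked = enr.RankedList(
                metric=ranked.metric.loc[ranked.metric.index.intersection(merged_rank.metric.index)],
                source=ranked.source,
            )
            single_res[b.study_id] = enr.gsea_preranked(
                ranked, gene_sets, p=config.gsea_weight, n_perm=config.n_perm,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                seed=seeds["enrichment"],
            )
        merged_res.table.to_csv(outdir / "enrichment_merged.tsv", sep="\t")
        paths["enrichment_merged.tsv"] = str(outdir / "enrichment_merged.tsv")
        for sid, res in single_res.items():
            res.table.to_csv(outdir / f"enrichment_{sid}.tsv", sep="\t")
            paths[f"enrichment_{sid}.tsv"] = str(outdir / f"enrichment_{sid}.tsv")
        overlap = enr.overlap_analysis(
            single_res, merged_res, sig_cutoff=config.sig_cutoff, loose_cutoff=config.loose_cutoff
        )
        overlap.table.to_csv(outdir / "overlap.tsv", sep="\t")
        paths["overlap.tsv"] = str(outdir / "overlap.tsv")
        summary["merged_significant_sets"] = int(len(merged_res.significant(config.sig_cutoff)))
        summary["single_significant_sets"] = {
            sid: int(len(res.significant(config.sig_cutoff))) for sid, res in single_res.items()
        }
        if truth is not None:
            sig = merged_res.significant(config.sig_cutoff)
            summary["merged_signal_sets_significant"] = int(
                sum(1 for s in sig if s.startswith("signal_"))
            )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    io.write_json(summary, outdir / "summary.json")
    paths["summary.json"] = str(outdir / "summary.json")
    config.to_yaml(outdir / "config.yaml")
    paths["config.yaml"] = str(outdir / "config.yaml")
    checksums = {name: _checksum(Path(p)) for name, p in sorted(paths.items())}
    io.write_json(checksums, outdir / "checksums.json")
    artifacts = RunArtifacts(outdir=outdir, summary=summary, paths=paths, checksums=checksums)
    write_report(artifacts, outdir / "report.md")
    return artifacts


def write_report(artifacts: RunArtifacts, path: str | Path) -> None:
    """Render a human-readable run report from stored artifacts only."""
    s = artifacts.summary
    outdir = artifacts.outdir
    missing = [n for n in ("summary.json", "overlap.tsv", "cv_curve.tsv") if not (outdir / n).exists()]
    if missing:
        raise StageError("report", f"missing artifacts: {', '.join(missing)}")
    overlap = pd.read_csv(outdir / "overlap.tsv", sep="\t", index_col=0)

    lines = [
        "# txharmony run report",
        "",
        f"config hash: `{s['config_hash']}`  seed: {s['seed']}",
        "",
        "## Cohort",
        f"- samples in: {s['n_samples_input']}; outliers removed: {s['n_outliers_removed']}; "
        f"analyzed: {s['n_samples']} (train {s['n_train']} / test {s['n_test']})",
        f"- genes in: {s['n_genes_input']}; retained after pseudogene/coverage filtering: "
        f"{s['n_genes_retained']} ({s['gene_reduction_pct']}% reduction, "
        f"coverage threshold {s['coverage_threshold']:.3f})",
        "",
        "## PCA diagnostics (silhouette on PC1-2)",
        f"- raw counts: study {s['raw_silhouette_study']:.3f} vs class {s['raw_silhouette_class']:.3f} "
        f"(PC1+2 variance {s['raw_pc12_variance_pct']}%)",
        f"- harmonized: study {s['harmonized_silhouette_study']:.3f} vs class {s['harmonized_silhouette_class']:.3f}",
        f"- mRMR panel: study {s['mrmr_silhouette_study']:.3f} vs class {s['mrmr_silhouette_class']:.3f}",
        "",
        "## Feature selection",
        f"- elbow k* = {s['k_star']} (CV curve in cv_curve.tsv)",
        "",
        "## Classification (holdout)",
        "| model | AUC | baseline mean AUC | DeLong p |",
        "|---|---|---|---|",
    ]
    for name in ("rf", "svm", "lda"):
        lines.append(
            f"| {name.upper()} | {s[f'auc_{name}']:.3f} | "
            f"{s[f'baseline_mean_auc_{name}']:.3f} | {s[f'delong_p_{name}']:.3g} |"
        )
    lines += [
        "",
        "## Top concordant genes",
        "- " + ", ".join(s["top_concordant_genes"]),
        "",
        f"## Enrichment overlap (single vs merged, cutoffs {0.1}/{0.9})",
        "```",
        overlap.to_string(),
        "```",
        "",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
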