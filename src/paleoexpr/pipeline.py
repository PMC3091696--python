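"""End-to-end pipeline orchestration: configuration, staging, manifest.

A run executes simulate (optional) -> background-correct -> quantile-normalize
-> summarize -> QC -> stage -> DE -> cluster -> enrich -> wgd, writing every
intermediate table under the output directory plus a JSON manifest (inputs,
parameters, seed, per-stage status and timing) and a short human-readable
report.  Identical configuration and seed reproduce numeric outputs exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import ClusterSet, correlation_distance, cut_clusters, hclust_complete, select_variable_genes
from .datatypes import GeneMatrix, MORPHOLOGY_COLS, ProbeMatrix, validate_sample_sheet
from .diffexpr import DEConfig, TimecourseModel
from .enrich import EnrichmentConfig, permutation_enrichment
from .platform import background_correct
from .preprocess import qc_samples, quantile_normalize, stage_samples, summarize_genes
from .simdata import SimConfig, simulate_dataset
from .simdata import io as sim_io
from .wgd import analyze_wgd

logger = logging.getLogger("paleoexpr")

STAGES = (
    "simulate",
    "background_correct",
    "quantile_normalize",
    "summarize",
    "qc",
    "stage",
    "de",
    "cluster",
    "enrich",
    "wgd",
)

_CLUSTER_K = {"autogamy": 6, "reciliation": 3, "exocytosis": 2}


@dataclass
class PipelineConfig:
    """One analysis run: inputs (or a simulation), method switches, outputs."""

    experiment: str = "autogamy"
    out_dir: str = "paleoexpr_run"
    seed: int = 0
    # inputs; ignored when simulate is set
    probe_matrix: str | None = None
    probes: str | None = None
    sample_sheet: str | None = None
    families: str | None = None
    subsets: dict[str, str] = field(default_factory=dict)
    simulate: SimConfig | None = None
    # method switches
    input_scale: str = "log2"
    run_background_correction: bool = False
    de_method: str = "treat"
    fold_change: float | None = 2.0
    fdr: float = 0.05
    n_clusters: int | None = None
    n_select: int | None = None
    n_permutations: int = 1000
    simulate_only: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "simulate" in data and data["simulate"] is not None:
            sim = dict(data["simulate"])
            sim.setdefault("seed", data.get("seed", 0))
            data["simulate"] = SimConfig(**sim)
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "experiment": config.experiment,
        "seed": config.seed,
        "parameters": {
            "de_method": config.de_method,
            "fold_change": config.fold_change,
            "fdr": config.fdr,
            "n_clusters": config.n_clusters,
            "n_permutations": config.n_permutations,
            "input_scale": config.input_scale,
            "run_background_correction": config.run_background_correction,
        },
        "stages": {},
    }
    state: dict = {}

    def run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            status = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(out, manifest)
            raise StageError(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"status": status or "completed", "seconds": round(dt, 3)}
        logger.info("stage %-18s %s (%.2fs)", name, status or "completed", dt)

    # -- simulate -----------------------------------------------------------
    def stage_simulate() -> str:
        if config.simulate is None:
            state["dataset"] = None
            return "skipped (using provided inputs)"
        sim_dir = out / "sim"
        sim_dir.mkdir(exist_ok=True)
        ds = simulate_dataset(config.simulate, config.experiment)
        state["dataset"] = ds
        state["probe_matrix"] = ds.probe_matrix
        state["sheet"] = ds.sample_sheet
        state["families"] = ds.families
        sim_io.write_probe_matrix(ds.probe_matrix, sim_dir / "probe_matrix.tsv")
        sim_io.write_sample_sheet(ds.sample_sheet, sim_dir / "sample_sheet.tsv")
        sim_io.write_probes(ds.probes, sim_dir / "probes.tsv")
        sim_io.write_families(ds.families, sim_dir / "families.tsv")
        sim_io.write_truth(ds.truth, sim_dir / "truth_genes.tsv", sim_dir / "truth_pairs.tsv")
        if ds.transcripts:
            sim_io.write_transcripts(ds.transcripts, sim_dir / "transcripts.fasta")
        return "completed"

    run_stage("simulate", stage_simulate)
    if config.simulate_only:
        _write_manifest(out, manifest)
        return manifest

    if config.simulate is None:
        state["probe_matrix"] = sim_io.read_probe_matrix(
            config.probe_matrix, scale=config.input_scale
        )
        state["sheet"] = sim_io.read_sample_sheet(config.sample_sheet)
        state["families"] = (
            sim_io.read_families(config.families) if config.families else None
        )

    # -- background correction ---------------------------------------------
    def stage_background() -> str:
        if not config.run_background_correction:
            return "completed (pass-through: input already background-corrected)"
        state["probe_matrix"] = background_correct(state["probe_matrix"])
        return "completed"

    run_stage("background_correct", stage_background)

    # -- quantile normalization --------------------------------------------
    def stage_qnorm() -> None:
        pm = state["probe_matrix"]
        state["probe_matrix"] = ProbeMatrix(
            values=quantile_normalize(pm.values), probe_genes=pm.probe_genes
        )
        sim_io.write_probe_matrix(state["probe_matrix"], out / "probe_matrix_normalized.tsv")

    run_stage("quantile_normalize", stage_qnorm)

    # -- gene summarization --------------------------------------------------
    def stage_summarize() -> None:
        state["gene_matrix"] = summarize_genes(state["probe_matrix"], state["sheet"])
        sim_io.write_gene_matrix(state["gene_matrix"].values, out / "gene_matrix.tsv")

    run_stage("summarize", stage_summarize)

    # -- QC -------------------------------------------------------------------
    def stage_qc() -> str:
        report = qc_samples(state["gene_matrix"])
        report.samples.to_csv(out / "qc_samples.tsv", sep="\t")
        report.replicate_r.to_csv(out / "qc_replicates.tsv", sep="\t", index=False)
        state["qc"] = report
        n_fail = int((~report.samples["passed"]).sum())
        return "completed" if n_fail == 0 else f"completed ({n_fail} samples flagged)"

    run_stage("qc", stage_qc)

    # -- morphology staging ---------------------------------------------------
    def stage_stage() -> str:
        if config.experiment != "autogamy":
            return "skipped (staging applies to autogamy only)"
        stages = stage_samples(state["sheet"])
        stages.to_csv(out / "sample_stages.tsv", sep="\t", header=True)
        state["stages"] = stages
        return "completed"

    run_stage("stage", stage_stage)

    # -- differential expression ---------------------------------------------
    def stage_de() -> None:
        model = TimecourseModel(state["gene_matrix"], merge_dev23=True)
        res = model.fit(
            method=config.de_method, fold_change=config.fold_change, fdr=config.fdr
        )
        state["de"] = res
        res.table().to_csv(out / "de_table.tsv", sep="\t", index_label="gene_id")
        summary = {
            "method": res.result.method,
            "fdr": config.fdr,
            "fold_change": config.fold_change,
            "n_genes": int(len(res.result.gene_p)),
            "n_de": int(res.result.de.sum()),
            "d0": float(res.d0) if np.isfinite(res.d0) else "inf",
            "s02": float(res.s02),
        }
        (out / "de_summary.json").write_text(json.dumps(summary, indent=2))

    run_stage("de", stage_de)

    # -- clustering -----------------------------------------------------------
    def stage_cluster() -> str:
        res = state["de"]
        de_genes = sorted(res.de_genes())
        if config.n_select is not None:
            de_genes = select_variable_genes(
                state["gene_matrix"].values.loc[de_genes], min(config.n_select, len(de_genes))
            )
        k = config.n_clusters or _CLUSTER_K[config.experiment]
        if len(de_genes) < max(k, 3):
            state["clusters"] = None
            return f"skipped (only {len(de_genes)} DE genes)"
        gm = state["gene_matrix"]
        dist = correlation_distance(gm.values.loc[de_genes], axis="genes", method="pearson")
        dend = hclust_complete(dist)
        archetypes = None
        if config.simulate is not None:
            archetypes = {
                k_: list(v)
                for k_, v in config.simulate.archetypes[config.experiment].items()
            }
        clusters = cut_clusters(dend, k, gene_matrix=gm, archetypes=archetypes)
        state["clusters"] = clusters
        assign = pd.DataFrame(
            {
                "cluster": clusters.assignments,
                "name": clusters.named_assignments(),
            }
        )
        assign.to_csv(out / "clusters.tsv", sep="\t", index_label="gene_id")
        if clusters.mean_profiles is not None:
            clusters.mean_profiles.to_csv(out / "cluster_profiles_mean.tsv", sep="\t")
            clusters.sd_profiles.to_csv(out / "cluster_profiles_sd.tsv", sep="\t")
        return "completed"

    run_stage("cluster", stage_cluster)

    # -- enrichment -----------------------------------------------------------
    def stage_enrich() -> str:
        res = state["de"]
        universe = list(state["gene_matrix"].values.index)
        subsets: dict[str, list[str]] = {}
        for name, path in config.subsets.items():
            subsets[name] = [
                line.strip() for line in Path(path).read_text().splitlines() if line.strip()
            ]
        ds = state.get("dataset")
        if not subsets and ds is not None:
            truth_de = ds.truth.de_genes()
            rng = np.random.default_rng(config.seed)
            size = min(200, len(truth_de))
            if size == 0:
                return "skipped (no subsets configured)"
            subsets["truth_de_sample"] = sorted(
                rng.choice(np.asarray(truth_de, dtype=object), size=size, replace=False)
            )
        if not subsets:
            return "skipped (no subsets configured)"
        labels = res.de_genes()
        results = {}
        for name, genes in subsets.items():
            cfg = EnrichmentConfig(
                n_permutations=config.n_permutations,
                mode="label",
                seed=config.seed,
            )
            enr = permutation_enrichment(genes, universe, None, cfg, de_labels=labels)
            results[name] = enr.to_dict()
        (out / "enrichment.json").write_text(json.dumps(results, indent=2))
        state["enrichment"] = results
        return "completed"

    run_stage("enrich", stage_enrich)

    # -- wgd ------------------------------------------------------------------
    def stage_wgd() -> str:
        if state.get("families") is None:
            return "skipped (no ohnolog families provided)"
        if state.get("clusters") is None:
            return "skipped (no clusters)"
        clusters: ClusterSet = state["clusters"]
        de_genes = sorted(set(clusters.assignments.index))
        report = analyze_wgd(
            de_genes,
            clusters,
            state["families"],
            all_genes=list(state["gene_matrix"].values.index),
            set_name=config.experiment,
        )
        report.retention.to_csv(out / "retention_table.tsv", sep="\t")
        for lev, summ in report.summaries.items():
            summ.to_csv(out / f"ohnolog_classification_wgd{lev}.tsv", sep="\t")
        (out / "wgd_summary.json").write_text(json.dumps(report.to_json_dict(), indent=2))
        state["wgd"] = report
        return "completed"

    run_stage("wgd", stage_wgd)

    _write_manifest(out, manifest)
    _write_report(out, manifest, state)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _write_report(out: Path, manifest: dict, state: dict) -> None:
    lines = [f"paleoexpr {manifest['version']} run report", ""]
    lines.append(f"experiment: {manifest['experiment']}  seed: {manifest['seed']}")
    for stage, info in manifest["stages"].items():
        lines.append(f"  {stage:<20} {info['status']}")
    if state.get("qc") is not None:
        qc = state["qc"]
        lines.append("")
        lines.append(
            f"QC: {int(qc.samples['passed'].sum())}/{len(qc.samples)} samples passed; "
            f"min replicate r = {qc.min_replicate_r():.3f}"
        )
    if state.get("de") is not None:
        res = state["de"]
        lines.append(f"DE genes: {int(res.result.de.sum())} / {len(res.result.de)}")
    if state.get("clusters") is not None:
        sizes = state["clusters"].sizes()
        lines.append("clusters: " + ", ".join(f"{n}={c}" for n, c in sizes.items()))
    if state.get("wgd") is not None:
        bounds = state["wgd"].bounds
        lines.append(
            "subfunctionalization upper bounds (%): "
            + ", ".join(f"WGD{lev}={b:.1f}" for lev, b in bounds.items())
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict[str, str]) -> pd.DataFrame:
    """Schema and cross-reference checks over a set of input files.

    ``paths`` may contain: probe_matrix, probes, sample_sheet, families,
    transcripts.  Returns a report frame (check, passed, detail); never
    raises on bad content.
    """
    checks: list[dict] = []

    def record(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"check": name, "passed": bool(passed), "detail": detail})

    probes = matrix = sheet = families_df = transcripts = None
    if "probes" in paths:
        try:
            probes = pd.read_csv(paths["probes"], sep="\t")
            need = {"probe_id", "gene_id", "strand", "offset", "sequence"}
            missing = need - set(probes.columns)
            record("probes:columns", not missing, f"missing {sorted(missing)}" if missing else "")
            if not missing:
                badlen = probes["sequence"].str.len() != 50
                record(
                    "probes:length50",
                    not badlen.any(),
                    f"{int(badlen.sum())} probes not 50 nt" if badlen.any() else "",
                )
                per_gene = probes.groupby("gene_id").size()
                off = per_gene[per_gene != 6]
                record(
                    "probes:six_per_gene",
                    len(off) == 0,
                    f"{len(off)} genes without exactly 6 probes" if len(off) else "",
                )
        except Exception as exc:  # noqa: BLE001
            record("probes:read", False, str(exc))
    if "probe_matrix" in paths:
        try:
            matrix = pd.read_csv(paths["probe_matrix"], sep="\t", index_col="probe_id")
            record("probe_matrix:gene_column", "gene_id" in matrix.columns)
            value_cols = [c for c in matrix.columns if c != "gene_id"]
            finite = np.isfinite(matrix[value_cols].to_numpy(dtype=float)).all()
            record("probe_matrix:finite", bool(finite))
        except Exception as exc:  # noqa: BLE001
            record("probe_matrix:read", False, str(exc))
    if "sample_sheet" in paths:
        try:
            sheet = pd.read_csv(paths["sample_sheet"], sep="\t", index_col="sample_id")
            try:
                validate_sample_sheet(sheet)
                record("sample_sheet:schema", True)
            except ValueError as exc:
                record("sample_sheet:schema", False, str(exc))
        except Exception as exc:  # noqa: BLE001
            record("sample_sheet:read", False, str(exc))
    if "families" in paths:
        try:
            families_df = pd.read_csv(paths["families"], sep="\t", keep_default_na=False)
            need = {"gene_id", "family_id", "wgd_path"}
            missing = need - set(families_df.columns)
            record("families:columns", not missing, f"missing {sorted(missing)}" if missing else "")
        except Exception as exc:  # noqa: BLE001
            record("families:read", False, str(exc))
    if "transcripts" in paths:
        try:
            transcripts = sim_io.read_transcripts(paths["transcripts"])
            record("transcripts:read", True, f"{len(transcripts)} sequences")
        except Exception as exc:  # noqa: BLE001
            record("transcripts:read", False, str(exc))

    # cross references
    if probes is not None and matrix is not None and "gene_id" in getattr(matrix, "columns", []):
        unknown = set(matrix.index) - set(probes["probe_id"])
        record(
            "xref:matrix_probes_in_design",
            not unknown,
            f"{len(unknown)} matrix probes absent from probe design" if unknown else "",
        )
    if probes is not None and transcripts is not None:
        missing = set(probes["gene_id"]) - set(transcripts)
        record(
            "xref:probe_genes_have_transcripts",
            not missing,
            f"{len(missing)} probe genes lack transcripts" if missing else "",
        )
    if probes is not None and families_df is not None and "gene_id" in families_df:
        missing = set(probes["gene_id"]) - set(families_df["gene_id"])
        record(
            "xref:probe_genes_in_families",
            not missing,
            f"{len(missing)} probe genes absent from families" if missing else "",
        )
    if matrix is not None and sheet is not None:
        value_cols = [c for c in matrix.columns if c != "gene_id"]
        missing = set(value_cols) - set(sheet.index)
        record(
            "xref:matrix_samples_in_sheet",
            not missing,
            f"samples {sorted(missing)} absent from sheet" if missing else "",
        )
    return pd.DataFrame(checks, columns=["check", "passed", "detail"])
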