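"""End-to-end orchestration: simulate/load -> QC -> encode -> rank &
permutation test -> univariate stats & clusters -> reference matching ->
report.

A run is fully described by a :class:`RunConfig` (inputs are either file
paths or a simulation config, never both) and is deterministic for a fixed
seed: the top-level seed fans out to per-stage sub-seeds in a fixed order
(simulation, model) so stages can be re-run in isolation. Every stage
writes its interface files into the output directory; a JSON manifest
records the configuration, per-stage counts and stage order, and a summary
JSON collects the headline numbers (observed accuracy, permutation p, top
clusters with group frequencies, reference comparison).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import ModelConfig, cv_accuracy, permutation_test, rank_features
from .encoding import GeneEventMatrix, encode, write_feature_dictionary
from .errors import ConfigError, PipelineError, ValidationError
from .matching import compare_with_reference, match_triple, write_assignments
from .segments import (
    GenomicInterval,
    QCThresholds,
    landscape_filter,
    qc_filter,
    read_gene_catalog,
    read_segments,
    write_gene_catalog,
    write_segments,
)
from .simulate import (
    SimulationConfig,
    mrd_labels,
    read_samples,
    simulate_study,
    write_samples,
)
from .stats import (
    annotate_cluster_frequencies,
    association_table,
    detect_clusters,
    frequency_table,
    region_summary,
)

log = logging.getLogger("cnaforest")


@dataclass(frozen=True)
class StatsOptions:
    adjust_method: str = "bh"
    max_gap: int = 1_000_000
    min_genes: int = 5


@dataclass(frozen=True)
class InputPaths:
    segments: str
    catalog: str
    samples: str
    reference_segments: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: InputPaths | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    model: ModelConfig = field(default_factory=ModelConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    match_method: str = "greedy"
    #: Drop the reference pool entirely: matching and comparison outputs are
    #: disabled; all patient-side outputs are unchanged bit-for-bit (the
    #: simulator draws patients and references from separate seed streams).
    include_references: bool = True
    figures: bool = False

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of 'simulation' or 'inputs' must be supplied"
            )


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML key-value document."""
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {
        "out_dir": doc.get("out_dir", "results"),
        "seed": int(doc.get("seed", 0)),
        "figures": bool(doc.get("figures", False)),
        "match_method": doc.get("match_method", "greedy"),
    }
    if "simulation" in doc:
        kwargs["simulation"] = SimulationConfig(**doc["simulation"])
    if "inputs" in doc:
        kwargs["inputs"] = InputPaths(**doc["inputs"])
    if "qc" in doc:
        kwargs["qc"] = QCThresholds(**doc["qc"])
    if "model" in doc:
        kwargs["model"] = ModelConfig(**doc["model"])
    if "stats" in doc:
        kwargs["stats"] = StatsOptions(**doc["stats"])
    return RunConfig(**kwargs)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunManifest:
    """Echo of the configuration plus per-stage bookkeeping."""

    version: str
    seed: int
    config: dict
    stage_order: list[str]
    counts: dict[str, int]
    complete: bool = False

    def write(self, path: Path) -> None:
        with path.open("w") as fh:
            json.dump(_jsonable(dataclasses.asdict(self)), fh, indent=2,
                      sort_keys=True)
            fh.write("\n")


def run(config: RunConfig) -> RunManifest:
    """Execute all stages, writing every interface file under ``out_dir``.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    manifest written so far is flagged incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config=_jsonable(config),
        stage_order=[],
        counts={},
    )
    manifest_path = out / "manifest.json"

    def stage(name):
        manifest.stage_order.append(name)
        log.info("stage=%s", name)

    try:
        # ---- inputs ------------------------------------------------------
        if config.simulation is not None:
            stage("simulate")
            sim = replace(config.simulation, seed=config.seed)
            study = simulate_study(sim)
            catalog = study.catalog
            patients = study.patients
            patient_segments = study.patient_segments
            references = study.references
            reference_segments = study.reference_segments
            if not config.include_references:
                references, reference_segments = [], []
            write_gene_catalog(catalog, out / "catalog.bed")
            write_samples(patients, out / "samples.tsv")
            write_segments(patient_segments, out / "segments.tsv")
            if references:
                write_samples(patients + references,
                              out / "samples_with_references.tsv")
                write_segments(reference_segments,
                               out / "reference_segments.tsv")
        else:
            stage("load")
            catalog = read_gene_catalog(config.inputs.catalog)
            records = read_samples(config.inputs.samples)
            patients = [r for r in records if r.cohort == "patient"]
            references = [r for r in records if r.cohort == "reference"]
            patient_segments = read_segments(config.inputs.segments)
            reference_segments = (
                read_segments(config.inputs.reference_segments)
                if config.inputs.reference_segments else []
            )
            if not config.include_references:
                references, reference_segments = [], []
        manifest.counts["patients"] = len(patients)
        manifest.counts["references"] = len(references)
        manifest.counts["segments_raw"] = len(patient_segments)
        manifest.counts["reference_segments_raw"] = len(reference_segments)

        # ---- QC + landscape ---------------------------------------------
        stage("qc")
        patient_segments = qc_filter(patient_segments, config.qc)
        reference_segments = qc_filter(reference_segments, config.qc)
        manifest.counts["segments_qc"] = len(patient_segments)
        manifest.counts["reference_segments_qc"] = len(reference_segments)
        write_segments(landscape_filter(patient_segments, config.qc),
                       out / "landscape_segments.tsv")

        # ---- encoding ----------------------------------------------------
        stage("encode")
        sample_ids = [p.sample_id for p in patients]
        matrix = encode(patient_segments, catalog, sample_ids)
        manifest.counts["encoded_samples"] = len(matrix.sample_ids)
        manifest.counts["features"] = len(matrix.features)
        matrix.write_wide(out / "matrix.tsv")
        write_feature_dictionary(matrix.features, catalog,
                                 out / "features.tsv")
        labels = mrd_labels(patients, sample_ids)

        ref_matrix = None
        if references:
            ref_ids = [r.sample_id for r in references]
            ref_matrix = encode(reference_segments, catalog, ref_ids)

        # ---- classifier --------------------------------------------------
        stage("rank")
        model = replace(config.model, seed=config.seed)
        ranking = rank_features(matrix, labels, model)
        ranking.to_csv(out / "importance.tsv", sep="\t", index=False)

        stage("permutation_test")
        perm = permutation_test(matrix, labels, model)
        with (out / "permutation.json").open("w") as fh:
            json.dump(
                {
                    "observed_accuracy": perm.observed_accuracy,
                    "p_value": perm.p_value,
                    "null_accuracies": list(perm.null_accuracies),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

        # ---- univariate stats & clusters ---------------------------------
        stage("stats")
        top_ids = list(ranking.feature_id)
        assoc = association_table(matrix, labels, top_ids,
                                  method=config.stats.adjust_method)
        freqs = frequency_table(matrix, labels, ref_matrix,
                                feature_ids=top_ids)
        assoc = assoc.merge(freqs, left_on="feature_id", right_index=True)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)

        stage("clusters")
        clusters = detect_clusters(ranking, catalog,
                                   max_gap=config.stats.max_gap,
                                   min_genes=config.stats.min_genes)
        clusters = annotate_cluster_frequencies(clusters, matrix, labels,
                                                ref_matrix)
        manifest.counts["clusters"] = len(clusters)
        with (out / "clusters.json").open("w") as fh:
            json.dump([_jsonable(c) for c in clusters], fh, indent=2,
                      sort_keys=True)
            fh.write("\n")

        # region summaries (per cluster, per group that has segments)
        stage("region_summary")
        pos_ids = {p.sample_id for p in patients if p.mrd_status == "positive"}
        neg_ids = {p.sample_id for p in patients if p.mrd_status == "negative"}
        ref_ids_set = {r.sample_id for r in references}
        all_segments = list(patient_segments) + list(reference_segments)
        summaries = []
        for c in clusters:
            region = GenomicInterval(c.chrom, c.start, c.end)
            for group, ids in (("mrd_pos", pos_ids), ("mrd_neg", neg_ids),
                               ("reference", ref_ids_set)):
                if not ids:
                    continue
                try:
                    part = region_summary(all_segments, region,
                                          c.canon_event, catalog,
                                          {group: ids})
                except ValidationError:
                    continue  # group carries no qualifying segment
                part = part.reset_index()
                part.insert(0, "cluster", c.label)
                summaries.append(part)
        if summaries:
            pd.concat(summaries).to_csv(out / "region_summaries.tsv",
                                        sep="\t", index=False)

        # heatmap matrix: samples MRD+ then MRD-, features by rank
        order = np.argsort(~labels, kind="stable")
        heat = matrix.to_frame().iloc[order][top_ids]
        heat.index.name = "sample_id"
        heat.to_csv(out / "heatmap_matrix.tsv", sep="\t")

        # ---- reference comparison ----------------------------------------
        if references and ref_matrix is not None:
            stage("match")
            matched = match_triple(patients, references,
                                   method=config.match_method)
            write_assignments(matched, patients, references,
                              out / "matched_references.tsv")
            manifest.counts["matched_references"] = len(
                matched.reference_ids()
            )
            comparison = compare_with_reference(matrix, ref_matrix, top_ids)
            comparison.to_csv(out / "reference_comparison.tsv", sep="\t")
        else:
            matched = None

        # ---- summary -----------------------------------------------------
        stage("report")
        summary = {
            "observed_accuracy": perm.observed_accuracy,
            "permutation_p_value": perm.p_value,
            "n_features": len(matrix.features),
            "clusters": [
                {
                    "label": c.label,
                    "event": c.canon_event,
                    "n_genes": len(c.feature_ids),
                    "freq_mrd_pos": c.freq_mrd_pos,
                    "freq_mrd_neg": c.freq_mrd_neg,
                    "freq_reference": c.freq_reference,
                }
                for c in clusters
            ],
            "matching_mean_age_diff": (matched.quality if matched else None),
        }
        with (out / "summary.json").open("w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")

        if config.figures:
            stage("figures")
            _write_figures(out, perm, heat, clusters)

        manifest.complete = True
        manifest.write(manifest_path)
        return manifest
    except Exception as exc:  # annotate with the failing stage
        failed = manifest.stage_order[-1] if manifest.stage_order else "setup"
        manifest.complete = False
        try:
            manifest.write(manifest_path)
        except OSError:
            pass
        raise PipelineError(failed, exc) from exc


def _write_figures(out: Path, perm, heat, clusters) -> None:
    """Optional artifacts: permutation-null histogram, presence heatmap,
    cluster frequency bars. Import kept local so headless batch runs never
    touch matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(perm.null_accuracies, bins=20, color="#4878b0",
            label="permutation null")
    ax.axvline(perm.observed_accuracy, color="red", linestyle="--",
               label=f"observed = {perm.observed_accuracy:.2f}")
    ax.set_xlabel("cross-validated accuracy")
    ax.set_ylabel("permutations")
    ax.legend()
    fig.savefig(out / "permutation_null.png", dpi=120,
                bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 5))
    ax.imshow(heat.to_numpy(), aspect="auto", cmap="Purples",
              interpolation="nearest")
    ax.set_xlabel("top features (by rank)")
    ax.set_ylabel("samples (MRD+ then MRD-)")
    fig.savefig(out / "heatmap.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    if clusters:
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(clusters))
        for off, (attr, color) in enumerate(
            (("freq_mrd_pos", "#c23b3b"), ("freq_mrd_neg", "#e0c04a"),
             ("freq_reference", "#4a9a5b"))
        ):
            vals = [getattr(c, attr) or 0.0 for c in clusters]
            ax.bar(x + 0.25 * off, vals, width=0.25, color=color,
                   label=attr.removeprefix("freq_"))
        ax.set_xticks(x + 0.25)
        ax.set_xticklabels([f"{c.label}\n{c.canon_event}" for c in clusters],
                           fontsize=8)
        ax.set_ylabel("carrier frequency")
        ax.legend()
        fig.savefig(out / "cluster_frequencies.png", dpi=120,
                    bbox_inches="tight")
        plt.close(fig)
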