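"""End-to-end orchestration: simulate/load -> clonotype -> gate -> DE ->
panel -> interactions, with a JSON manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clonotypes import (
    assign_clonality,
    assignments_to_frame,
    clonotypes_to_frame,
    dominant_clone,
    group_clonotypes,
    stats_to_frame,
)
from .de import DEThresholds, de_to_frame, deg_count_per_cluster, gate_subsets, log_normalize
from .interactions import bundled_pairs_path, interaction_deltas, read_pairs, score_interactions
from .io import (
    ContigRecord,
    CountMatrix,
    FormatError,
    read_contigs,
    read_counts,
    read_metadata,
    write_table,
)
from .panel import consistent_panel, panel_to_frame, per_patient_clone_de, specificity_check
from .synthetic import SyntheticConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

DEFAULT_LESION_GROUPS = {
    "palpable": ["plaque", "tumor"],
    "flat": ["patch"],
}


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "clonoscope_run"
    simulate: dict | None = None
    inputs: dict | None = None  # counts/features/barcodes/metadata/contigs paths
    lesion_groups: dict = field(default_factory=lambda: dict(DEFAULT_LESION_GROUPS))
    clone_thresholds: dict = field(default_factory=lambda: {"min_abs_logfc": 0.3, "alpha": 0.05, "min_pct": 0.1})
    microenv_thresholds: dict = field(default_factory=lambda: {"min_abs_logfc": 0.25, "alpha": 0.05, "min_pct": 0.1})
    gating: dict = field(default_factory=lambda: {"cd4": "CD4", "cd8a": "CD8A", "foxp3": "FOXP3"})
    interactions: dict = field(default_factory=lambda: {"pairs": None, "n_perm": 1000, "min_frac": 0.1})
    scope: str = "patient"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValidationError("config must provide either 'simulate' or 'inputs'")
        if self.simulate is not None and self.inputs is not None:
            raise ValidationError("config must provide only one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            required = ("counts", "features", "barcodes", "metadata", "contigs")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ValidationError(f"inputs missing keys: {missing}")
            for k in required:
                if not Path(self.inputs[k]).exists():
                    raise ValidationError(f"input file does not exist: {self.inputs[k]}")
        pairs = self.interactions.get("pairs")
        if pairs is not None and not Path(pairs).exists():
            raise ValidationError(f"pair list does not exist: {pairs}")
        if self.scope not in ("patient", "sample"):
            raise ValidationError("scope must be 'patient' or 'sample'")


def validate_inputs(
    cm: CountMatrix, metadata: pd.DataFrame, contigs: list[ContigRecord]
) -> dict:
    """Cross-check consistency; report-only (never raises)."""
    report: dict[str, list] = {
        "orphan_contig_barcodes": [],
        "metadata_cells_missing_from_counts": [],
        "count_cells_missing_from_metadata": [],
        "empty_clusters": [],
    }
    count_cells = set(cm.cells)
    meta_cells = set(metadata["cell_id"])
    report["orphan_contig_barcodes"] = sorted({r.cell_id for r in contigs} - meta_cells)
    report["metadata_cells_missing_from_counts"] = sorted(meta_cells - count_cells)
    report["count_cells_missing_from_metadata"] = sorted(count_cells - meta_cells)
    report["empty_clusters"] = sorted(
        c for c, n in metadata.groupby("cluster").size().items() if n == 0
    )
    report["clean"] = not any(v for v in report.values() if isinstance(v, list))
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    Intermediate tables are written under config.out_dir; the manifest
    records the seed, stage timings, and a checksum for every output file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    timings = manifest["stages"]

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s finished in %.2fs", name, timings[name])

        return _Timer()

    # --- load or simulate ---------------------------------------------------
    with stage("input"):
        if config.simulate is not None:
            syn = SyntheticConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
            if isinstance(syn.samples_per_patient, list):
                syn.samples_per_patient = tuple(syn.samples_per_patient)
            if isinstance(syn.nb_mean_log_range, list):
                syn.nb_mean_log_range = tuple(syn.nb_mean_log_range)
            if isinstance(syn.subset_props, list):
                syn.subset_props = tuple(tuple(x) for x in syn.subset_props)
            if isinstance(syn.progressed_classes, list):
                syn.progressed_classes = frozenset(syn.progressed_classes)
            if isinstance(syn.chains, list):
                syn.chains = tuple(syn.chains)
            if isinstance(syn.extra_genes, list):
                syn.extra_genes = tuple(syn.extra_genes)
            cm, metadata, contig_frame, gt = simulate_dataset(syn)
            write_dataset(out / "synthetic", cm, metadata, contig_frame, gt)
            contig_frame.to_csv(out / "synthetic" / "contigs.csv", index=False)
            contigs = read_contigs(out / "synthetic" / "contigs.csv")
        else:
            cm = read_counts(
                config.inputs["counts"], config.inputs["features"], config.inputs["barcodes"]
            )
            metadata = read_metadata(config.inputs["metadata"])
            contigs = read_contigs(config.inputs["contigs"])
        manifest["n_cells"] = cm.n_cells
        manifest["n_genes"] = cm.n_genes

    with stage("validate"):
        report = validate_inputs(cm, metadata, contigs)
        _write(out / "validation_report.json", report, manifest)

    with stage("normalize"):
        cm = log_normalize(cm)
        metadata = metadata[metadata["cell_id"].isin(set(cm.cells))].reset_index(drop=True)

    # --- clonotypes ----------------------------------------------------------
    with stage("clonotype"):
        clonotypes = group_clonotypes(contigs)
        stats = dominant_clone(clonotypes, metadata, scope=config.scope)
        assignments = assign_clonality(clonotypes, stats, metadata)
        _write_df(out / "clones.tsv", clonotypes_to_frame(clonotypes), manifest)
        _write_df(out / "clone_stats.tsv", stats_to_frame(stats), manifest)

    with stage("gate"):
        assignments = gate_subsets(cm, assignments, **config.gating)
        _write_df(out / "assignments.tsv", assignments_to_frame(assignments), manifest)

    class_a = set(config.lesion_groups["palpable"])
    class_b = set(config.lesion_groups["flat"])
    clone_thr = DEThresholds(**config.clone_thresholds)
    micro_thr = DEThresholds(**config.microenv_thresholds)

    with stage("deg_per_cluster"):
        deg_counts = deg_count_per_cluster(cm, metadata, class_a, class_b, micro_thr)
        _write(out / "deg_counts.json", deg_counts, manifest)

    with stage("panel"):
        per_patient = per_patient_clone_de(cm, metadata, assignments, class_a, class_b, clone_thr)
        for patient, results in per_patient.items():
            _write_df(out / f"de_{patient}.tsv", de_to_frame(results), manifest)
        panels = {}
        for direction in ("down", "up"):
            panel = consistent_panel(per_patient, direction)
            panels[direction] = panel
            _write_df(out / f"panel_{direction}.tsv", panel_to_frame(panel), manifest)
        spec = specificity_check(cm, metadata, assignments, panels["down"], class_a, class_b, clone_thr)
        _write(out / "specificity.json", spec, manifest)
        manifest["panel_down"] = panels["down"].genes
        manifest["panel_up"] = panels["up"].genes
        manifest["specificity"] = spec

    with stage("interactions"):
        pairs_path = config.interactions.get("pairs") or bundled_pairs_path()
        pairs = read_pairs(pairs_path)
        pairs = [p for p in pairs if cm.has_gene(p.ligand_gene) and cm.has_gene(p.receptor_gene)]
        n_perm = int(config.interactions.get("n_perm", 1000))
        min_frac = float(config.interactions.get("min_frac", 0.1))
        pos = {c: i for i, c in enumerate(cm.cells)}
        subset_of = {a.cell_id: a.subset for a in assignments}
        scores_by_sample: dict[str, pd.DataFrame] = {}
        sample_pairs = []
        all_scores = []
        for patient, pgrp in metadata.groupby("patient_id", sort=True):
            palpable_samples = sorted(pgrp.loc[pgrp["lesion_class"].isin(class_a), "sample_id"].unique())
            flat_samples = sorted(pgrp.loc[pgrp["lesion_class"].isin(class_b), "sample_id"].unique())
            for sample, sgrp in pgrp.groupby("sample_id", sort=True):
                idx = np.array([pos[c] for c in sgrp["cell_id"]])
                sub = CountMatrix(
                    genes=list(cm.genes),
                    cells=list(sgrp["cell_id"]),
                    counts=cm.counts[:, idx],
                )
                sub.normalized = cm.normalized[:, idx]
                clusters = [
                    "Malignant" if subset_of.get(c) == "malignant" else cl
                    for c, cl in zip(sgrp["cell_id"], sgrp["cluster"])
                ]
                if pairs:
                    df = score_interactions(
                        sub, np.asarray(clusters), pairs, n_perm=n_perm,
                        seed=config.seed, min_frac=min_frac,
                    )
                else:
                    df = pd.DataFrame()
                df.insert(0, "sample_id", sample) if not df.empty else None
                scores_by_sample[sample] = df
                if not df.empty:
                    all_scores.append(df)
            if palpable_samples and flat_samples:
                sample_pairs.append((patient, palpable_samples[0], flat_samples[0]))
        scores_df = pd.concat(all_scores, ignore_index=True) if all_scores else pd.DataFrame()
        _write_df(out / "interactions.tsv", scores_df, manifest)
        clean_scores = {
            s: df.drop(columns=["sample_id"]) for s, df in scores_by_sample.items() if not df.empty
        }
        deltable = [sp_ for sp_ in sample_pairs if sp_[1] in clean_scores and sp_[2] in clean_scores]
        deltas = interaction_deltas(clean_scores, deltable) if deltable else pd.DataFrame()
        _write_df(out / "interaction_deltas.tsv", deltas, manifest)

    with stage("manifest"):
        for p in sorted((out / "synthetic").glob("*")) if config.simulate is not None else []:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, default=_json_default)
            fh.write("\n")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _write(path: Path, obj, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)
        fh.write("\n")
    manifest["outputs"][path.name] = _sha256(path)


def _write_df(path: Path, df: pd.DataFrame, manifest: dict) -> None:
    write_table(df, path, format="tsv")
    manifest["outputs"][path.name] = _sha256(path)
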