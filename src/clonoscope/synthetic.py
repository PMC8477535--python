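"""Synthetic paired scRNA-seq + TCR datasets with planted clonal structure.

The generator emulates the post-QC state of a multi-patient study: for each
patient a set of lesion samples, each containing one expanded (dominant)
clonotype shared across that patient's samples, a polyclonal T-cell
background split into gateable subsets, and non-T cells. Counts are
negative-binomial with log-normal library-size factors; a configurable set
of genes is down/up-regulated in dominant-clone cells of "progressed"
lesion classes only, so downstream differential expression has a known
ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, ContigRecord, contigs_to_frame, write_counts, write_table

import scipy.sparse as sp

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: lesion classes treated as "progressed" (palpable) by default
DEFAULT_PROGRESSED = frozenset({"plaque", "tumor", "erythroderma"})

#: polyclonal background composition (helper, cytotoxic, regulatory)
DEFAULT_SUBSET_PROPS = (("helper", 0.5), ("cytotoxic", 0.3), ("regulatory", 0.2))


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    n_patients: int = 3
    samples_per_patient: tuple[str, ...] = ("patch", "plaque")
    cells_per_sample: int = 400
    n_genes: int = 1000
    nb_mean_log_range: tuple[float, float] = (np.log(0.5), np.log(4.0))
    nb_dispersion: float = 2.0
    clone_fraction: float = 0.5
    tcr_detection_rate: float = 1.0
    allelic_exclusion_rate: float = 0.0
    planted_effects: dict[str, float] = field(default_factory=dict)
    marker_genes: dict[str, str] = field(
        default_factory=lambda: {"cd4": "CD4", "cd8a": "CD8A", "foxp3": "FOXP3"}
    )
    seed: int = 0
    # secondary knobs, defaults chosen to keep fixtures unambiguous
    t_cell_fraction: float = 0.75
    subset_props: tuple[tuple[str, float], ...] = DEFAULT_SUBSET_PROPS
    progressed_classes: frozenset[str] = DEFAULT_PROGRESSED
    chains: tuple[str, str] = ("TRA", "TRB")  # (alpha-like, beta-like); use (TRG, TRD) for gamma-delta
    marker_mean: float = 30.0
    libsize_sigma: float = 0.25
    extra_genes: tuple[str, ...] = ()
    planted_gene_mean: float | None = None  # fixed NB baseline mean for planted genes

    def validate(self) -> None:
        if self.n_patients <= 0 or self.cells_per_sample <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_patients, cells_per_sample and n_genes must be positive")
        if not self.samples_per_patient:
            raise ConfigurationError("samples_per_patient must be non-empty")
        if not (0.0 < self.clone_fraction < 1.0):
            raise ConfigurationError("clone_fraction must lie in (0, 1)")
        if not (0.0 < self.tcr_detection_rate <= 1.0):
            raise ConfigurationError("tcr_detection_rate must lie in (0, 1]")
        if not (0.0 <= self.allelic_exclusion_rate < 1.0):
            raise ConfigurationError("allelic_exclusion_rate must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not (0.0 < self.t_cell_fraction <= 1.0):
            raise ConfigurationError("t_cell_fraction must lie in (0, 1]")
        genes = set(self.gene_names())
        missing = [g for g in self.planted_effects if g.upper() not in genes]
        if missing:
            raise ConfigurationError(f"planted genes not in gene list: {missing}")
        if self.chains not in (("TRA", "TRB"), ("TRG", "TRD")):
            raise ConfigurationError("chains must be (TRA, TRB) or (TRG, TRD)")

    def gene_names(self) -> list[str]:
        """Deterministic gene list: gating + extra genes first, then fillers.

        planted_effects keys must name genes from this list (gating/extra
        symbols or GENEnnnnn fillers); unknown names are a configuration
        error, caught by validate().
        """
        named: list[str] = []
        for g in list(self.marker_genes.values()) + list(self.extra_genes):
            gu = g.upper()
            if gu not in named:
                named.append(gu)
        n_fill = self.n_genes - len(named)
        if n_fill < 0:
            raise ConfigurationError("n_genes smaller than the number of named genes")
        fillers = [f"GENE{i:05d}" for i in range(n_fill)]
        return named + fillers


@dataclass
class GroundTruth:
    """Per-cell truth recorded by the generator."""

    cell_id: list[str]
    is_t_cell: list[bool]
    tcr_detected: list[bool]
    clone_member: list[bool]
    subset: list[str]  # malignant / helper / cytotoxic / regulatory / non_t
    clone_beta: dict[str, str]  # patient -> clone beta-like CDR3
    clone_alpha_primary: dict[str, str]
    clone_alpha_secondary: dict[str, str]
    planted_effects: dict[str, float]
    progressed_classes: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_cdr3(rng: np.random.Generator, length_range=(10, 16)) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "C" + "".join(rng.choice(list(AA_ALPHABET), size=n - 2)) + "F"


def _allocate(n: int, fractions: Sequence[float]) -> list[int]:
    """Deterministic largest-remainder allocation of n items into groups."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (counts, metadata, contig table, ground truth).

    Counts are genes x cells, NB(mean, dispersion) with per-cell library-size
    factors. Each patient carries one dominant clonotype shared across their
    samples; planted effects multiply the NB mean by exp(lfc) in
    dominant-clone cells of progressed lesion classes only. Cell counts per
    compartment are allocated deterministically (largest remainder), so tiny
    fixtures are exactly checkable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    alpha_chain, beta_chain = config.chains

    cd4 = config.marker_genes["cd4"].upper()
    cd8a = config.marker_genes["cd8a"].upper()
    foxp3 = config.marker_genes["foxp3"].upper()
    marker_idx = {cd4: gene_index[cd4], cd8a: gene_index[cd8a], foxp3: gene_index[foxp3]}

    lo, hi = config.nb_mean_log_range
    base_mean = np.exp(rng.uniform(lo, hi, size=len(genes)))
    # gating markers are near-binary: zero baseline everywhere, high mean in
    # the intended subset only (set per cell below)
    for g in marker_idx.values():
        base_mean[g] = 0.0
    if config.planted_gene_mean is not None:
        for g in config.planted_effects:
            base_mean[gene_index[g.upper()]] = config.planted_gene_mean

    subset_names = [s for s, _ in config.subset_props]
    subset_fracs = [f for _, f in config.subset_props]

    patients = [f"P{i + 1}" for i in range(config.n_patients)]
    clone_beta = {p: _random_cdr3(rng) for p in patients}
    clone_alpha1 = {p: _random_cdr3(rng) for p in patients}
    clone_alpha2 = {p: _random_cdr3(rng) for p in patients}

    cell_ids: list[str] = []
    meta_rows: list[dict] = []
    contig_rows: list[ContigRecord] = []
    gt_is_t: list[bool] = []
    gt_detected: list[bool] = []
    gt_clone: list[bool] = []
    gt_subset: list[str] = []

    planted_idx = {gene_index[g.upper()]: lfc for g, lfc in config.planted_effects.items()}

    cell_counter = 0
    n_cells_total = config.n_patients * len(config.samples_per_patient) * config.cells_per_sample

    # NB-mean multiplier matrix restricted to planted genes (dense, small)
    planted_gene_idx = sorted(planted_idx)
    mult_planted = np.ones((len(planted_gene_idx), n_cells_total))
    marker_mean_matrix = np.zeros((3, n_cells_total))  # rows: cd4, cd8a, foxp3

    for p_i, patient in enumerate(patients):
        for s_i, lesion in enumerate(config.samples_per_patient):
            sample_id = f"{patient}_S{s_i + 1}"
            n = config.cells_per_sample
            n_t = int(round(config.t_cell_fraction * n))
            n_non_t = n - n_t
            n_detected = int(round(config.tcr_detection_rate * n_t))
            n_clone = int(round(config.clone_fraction * n_detected))
            n_poly = n_detected - n_clone
            n_undetected = n_t - n_detected
            poly_alloc = _allocate(n_poly, subset_fracs)
            # undetected T cells get subsets too (they are T cells without contigs)
            und_alloc = _allocate(n_undetected, subset_fracs)
            progressed = lesion in config.progressed_classes

            roles: list[tuple[str, bool, bool]] = []  # (subset, clone, detected)
            roles += [("malignant", True, True)] * n_clone
            for name, k in zip(subset_names, poly_alloc):
                roles += [(name, False, True)] * k
            for name, k in zip(subset_names, und_alloc):
                roles += [(name, False, False)] * k
            roles += [("non_t", False, False)] * n_non_t

            for subset, is_clone, detected in roles:
                idx = cell_counter
                cid = f"{sample_id}_C{idx:06d}"
                cell_ids.append(cid)
                is_t = subset != "non_t"
                cluster = {
                    "malignant": "T-clone",
                    "helper": "T-helper",
                    "cytotoxic": "T-cytotoxic",
                    "regulatory": "T-reg",
                    "non_t": "Fibroblast",
                }[subset]
                meta_rows.append(
                    {
                        "cell_id": cid,
                        "sample_id": sample_id,
                        "patient_id": patient,
                        "lesion_class": lesion,
                        "cluster": cluster,
                    }
                )
                gt_is_t.append(is_t)
                gt_detected.append(bool(detected and is_t))
                gt_clone.append(is_clone)
                gt_subset.append(subset)

                # gating markers: CD4 on malignant/helper/regulatory, CD8A on
                # cytotoxic, FOXP3 on regulatory; zero elsewhere
                if subset in ("malignant", "helper", "regulatory"):
                    marker_mean_matrix[0, idx] = config.marker_mean
                if subset == "cytotoxic":
                    marker_mean_matrix[1, idx] = config.marker_mean
                if subset == "regulatory":
                    marker_mean_matrix[2, idx] = config.marker_mean

                if is_clone and progressed:
                    for row_i, g_i in enumerate(planted_gene_idx):
                        mult_planted[row_i, idx] = np.exp(planted_idx[g_i])

                if detected and is_t:
                    if is_clone:
                        contig_rows.append(
                            ContigRecord(cid, beta_chain, clone_beta[patient], True, int(rng.integers(5, 40)))
                        )
                        contig_rows.append(
                            ContigRecord(cid, alpha_chain, clone_alpha1[patient], True, int(rng.integers(3, 25)))
                        )
                    else:
                        contig_rows.append(
                            ContigRecord(cid, beta_chain, _random_cdr3(rng), True, int(rng.integers(2, 15)))
                        )
                        contig_rows.append(
                            ContigRecord(cid, alpha_chain, _random_cdr3(rng), True, int(rng.integers(1, 10)))
                        )
                cell_counter += 1

    n_cells = cell_counter
    size_factors = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))

    theta = config.nb_dispersion
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    planted_pos = {g: r for r, g in enumerate(planted_gene_idx)}
    marker_rows = {marker_idx[cd4]: 0, marker_idx[cd8a]: 1, marker_idx[foxp3]: 2}

    for g_i in range(len(genes)):
        if g_i in marker_rows:
            mu = marker_mean_matrix[marker_rows[g_i]] * size_factors
        else:
            mu = base_mean[g_i] * size_factors
            if g_i in planted_pos:
                mu = mu * mult_planted[planted_pos[g_i]]
        counts_g = np.zeros(n_cells, dtype=np.int64)
        nz_mu = mu > 0
        if nz_mu.any():
            p = theta / (theta + mu[nz_mu])
            counts_g[nz_mu] = rng.negative_binomial(theta, p)
        nz = np.nonzero(counts_g)[0]
        if nz.size:
            rows.append(np.full(nz.size, g_i, dtype=np.int64))
            cols.append(nz)
            vals.append(counts_g[nz])

    if rows:
        counts = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(genes), n_cells),
            dtype=np.int64,
        )
    else:
        counts = sp.csr_matrix((len(genes), n_cells), dtype=np.int64)

    cm = CountMatrix(genes=genes, cells=cell_ids, counts=counts)
    metadata = pd.DataFrame(meta_rows)
    contigs = contigs_to_frame(contig_rows)
    gt = GroundTruth(
        cell_id=cell_ids,
        is_t_cell=gt_is_t,
        tcr_detected=gt_detected,
        clone_member=gt_clone,
        subset=gt_subset,
        clone_beta=clone_beta,
        clone_alpha_primary=clone_alpha1,
        clone_alpha_secondary=clone_alpha2,
        planted_effects={g.upper(): float(v) for g, v in config.planted_effects.items()},
        progressed_classes=sorted(config.progressed_classes),
    )
    contigs = plant_allelic_exclusion(contigs, config, ground_truth=gt)
    return cm, metadata, contigs, gt


def plant_allelic_exclusion(
    contigs: pd.DataFrame, config: SyntheticConfig, ground_truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Give a fixed fraction of dominant-clone cells a secondary alpha CDR3.

    All clone cells keep the shared beta-like chain; a deterministically
    chosen ``allelic_exclusion_rate`` fraction of them (rounded) gains one
    additional alpha-like contig with a distinct CDR3, mirroring incomplete
    allelic exclusion. Clone cells are located by the per-patient clone beta
    CDR3 (from ground truth when given, else the most common beta per
    patient inferred from barcodes of the form ``P<k>_...``).
    """
    if config.allelic_exclusion_rate >= 1.0:
        raise ConfigurationError("allelic_exclusion_rate must be < 1")
    if config.allelic_exclusion_rate == 0.0 or contigs.empty:
        return contigs
    alpha_chain, beta_chain = config.chains
    rng = np.random.default_rng(config.seed + 1)

    if ground_truth is not None:
        clone_beta = ground_truth.clone_beta
        clone_alpha2 = ground_truth.clone_alpha_secondary
    else:
        beta_df = contigs[contigs["chain"] == beta_chain].copy()
        beta_df["patient"] = beta_df["barcode"].str.split("_").str[0]
        clone_beta = (
            beta_df.groupby("patient")["cdr3"].agg(lambda s: s.value_counts().idxmax()).to_dict()
        )
        clone_alpha2 = {p: _random_cdr3(rng) for p in clone_beta}

    extra_rows = []
    for patient, beta_cdr3 in clone_beta.items():
        cells = sorted(
            contigs.loc[
                (contigs["chain"] == beta_chain) & (contigs["cdr3"] == beta_cdr3), "barcode"
            ].unique()
        )
        cells = [c for c in cells if c.startswith(patient + "_")] or cells
        n_secondary = int(round(config.allelic_exclusion_rate * len(cells)))
        secondary = clone_alpha2[patient]
        for cid in cells[:n_secondary]:
            extra_rows.append(
                {
                    "barcode": cid,
                    "chain": alpha_chain,
                    "cdr3": secondary,
                    "productive": True,
                    "umis": int(rng.integers(1, 10)),
                }
            )
    if not extra_rows:
        return contigs
    out = pd.concat([contigs, pd.DataFrame(extra_rows)], ignore_index=True)
    return out.sort_values(["barcode", "chain", "cdr3"], kind="stable").reset_index(drop=True)


def write_dataset(
    out_dir: str | Path,
    cm: CountMatrix,
    metadata: pd.DataFrame,
    contigs: pd.DataFrame,
    ground_truth: GroundTruth,
) -> dict[str, Path]:
    """Write the full synthetic dataset as plain-text files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "metadata": out / "metadata.csv",
        "contigs": out / "contigs.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_counts(cm, paths["mtx"], paths["features"], paths["barcodes"])
    metadata.to_csv(paths["metadata"], index=False)
    contigs.to_csv(paths["contigs"], index=False)
    ground_truth.to_json(paths["ground_truth"])
    return paths
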