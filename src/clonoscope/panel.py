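"""Cross-patient direction-consistent marker panels.

Per patient, differential expression is computed within the malignant
(dominant-clone) cells between two lesion-class groups; the panel is the
strict intersection of genes significant with the same sign in every
patient. A specificity check re-runs the same comparison inside each gated
benign subset and reports whether any panel gene is consistently regulated
there as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonotypes import CloneAssignment
from .de import DEResult, DEThresholds, CLONE_THRESHOLDS, de_genes
from .io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class MarkerPanel:
    direction: str  # up | down
    genes: list[str]
    per_patient: dict[str, dict[str, DEResult]] = field(default_factory=dict)
    specificity: dict[str, dict] = field(default_factory=dict)


def _cells_of(
    norm: CountMatrix,
    metadata: pd.DataFrame,
    assignments: list[CloneAssignment],
    subset: str,
    patient: str,
    classes: set[str],
) -> np.ndarray:
    pos = {c: i for i, c in enumerate(norm.cells)}
    by_cell = {a.cell_id: a for a in assignments}
    sel = []
    for row in metadata.itertuples(index=False):
        if row.patient_id != patient or row.lesion_class not in classes:
            continue
        a = by_cell.get(row.cell_id)
        if a is None or a.subset != subset:
            continue
        i = pos.get(row.cell_id)
        if i is not None:
            sel.append(i)
    return np.array(sel, dtype=int)


def per_patient_subset_de(
    norm: CountMatrix,
    metadata: pd.DataFrame,
    assignments: list[CloneAssignment],
    class_a: set[str],
    class_b: set[str],
    thresholds: DEThresholds = CLONE_THRESHOLDS,
    subset: str = "malignant",
) -> dict[str, list[DEResult]]:
    """DE within one gated subset between two lesion-class groups, per patient.

    Patients without cells of the subset in both classes are skipped with a
    warning.
    """
    out: dict[str, list[DEResult]] = {}
    for patient in sorted(metadata["patient_id"].unique()):
        a = _cells_of(norm, metadata, assignments, subset, patient, class_a)
        b = _cells_of(norm, metadata, assignments, subset, patient, class_b)
        if a.size == 0 or b.size == 0:
            logger.warning(
                "patient %s skipped: no %s cells in both class groups (%d vs %d)",
                patient, subset, a.size, b.size,
            )
            continue
        out[patient] = de_genes(norm, a, b, thresholds)
    if not out:
        logger.warning("no eligible patient for per-patient %s DE", subset)
    return out


def per_patient_clone_de(
    norm: CountMatrix,
    metadata: pd.DataFrame,
    assignments: list[CloneAssignment],
    class_a: set[str],
    class_b: set[str],
    thresholds: DEThresholds = CLONE_THRESHOLDS,
) -> dict[str, list[DEResult]]:
    """Per-patient DE of malignant-clone cells, class_a vs class_b."""
    return per_patient_subset_de(
        norm, metadata, assignments, class_a, class_b, thresholds, subset="malignant"
    )


def consistent_panel(
    per_patient_results: dict[str, list[DEResult]],
    direction: str,
    min_patients: int | None = None,
) -> MarkerPanel:
    """Genes significant with the given sign in every patient.

    min_patients relaxes the strict intersection to "at least k of n
    patients" (off by default: k = n).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(per_patient_results) < 2:
        raise ValueError("need results from at least 2 patients")
    n = len(per_patient_results)
    k = n if min_patients is None else min_patients

    per_gene: dict[str, dict[str, DEResult]] = {}
    for patient, results in per_patient_results.items():
        for r in results:
            if r.direction == direction:
                per_gene.setdefault(r.gene, {})[patient] = r
    genes = [g for g, by_pat in per_gene.items() if len(by_pat) >= k]
    # exclude genes significant with the opposite sign in any patient
    opposite = {
        r.gene
        for results in per_patient_results.values()
        for r in results
        if r.direction != direction
    }
    genes = [g for g in genes if g not in opposite]
    genes.sort(key=lambda g: (max(r.p_adj for r in per_gene[g].values()), g))
    return MarkerPanel(
        direction=direction,
        genes=genes,
        per_patient={g: per_gene[g] for g in genes},
    )


BENIGN_SUBSETS = ("helper", "regulatory", "cytotoxic")


def specificity_check(
    norm: CountMatrix,
    metadata: pd.DataFrame,
    assignments: list[CloneAssignment],
    panel: MarkerPanel,
    class_a: set[str],
    class_b: set[str],
    thresholds: DEThresholds = CLONE_THRESHOLDS,
) -> dict[str, dict]:
    """Is any panel gene consistently regulated inside the benign subsets?

    For each benign subset the per-patient DE is re-run; a panel gene's flag
    is True only when it is significant with the panel's direction in every
    patient within that subset. The subset's own full consistent panel is
    reported alongside. Subsets empty in some patient are marked
    not-evaluable (evaluable=False).
    """
    out: dict[str, dict] = {}
    n_patients = metadata["patient_id"].nunique()
    for subset in BENIGN_SUBSETS:
        results = per_patient_subset_de(
            norm, metadata, assignments, class_a, class_b, thresholds, subset=subset
        )
        if len(results) < n_patients:
            out[subset] = {"evaluable": False, "gene_flags": {}, "consistent_panel": []}
            continue
        if panel.genes:
            sub_panel = consistent_panel(results, panel.direction)
            flags = {g: (g in sub_panel.genes) for g in panel.genes}
            full = sub_panel.genes
        else:
            flags = {}
            full = consistent_panel(results, panel.direction).genes if len(results) >= 2 else []
        out[subset] = {"evaluable": True, "gene_flags": flags, "consistent_panel": full}
    panel.specificity = out
    return out


def panel_to_frame(panel: MarkerPanel) -> pd.DataFrame:
    rows = []
    for g in panel.genes:
        for patient, r in sorted(panel.per_patient.get(g, {}).items()):
            rows.append(
                {
                    "gene": g,
                    "direction": panel.direction,
                    "patient_id": patient,
                    "logFC": r.logfc,
                    "p": r.p,
                    "p_adj": r.p_adj,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "direction", "patient_id", "logFC", "p", "p_adj"])
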