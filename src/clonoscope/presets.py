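"""Bundled configurations for the demonstration dataset.

The demo emulates a three-patient paired-lesion study: one flat (patch) and
one palpable (plaque) sample per patient, 300 dominant-clone cells per
lesion class per patient, and a six-gene panel planted as clone-restricted
downregulation (natural-log fold change -0.8) in the palpable lesions.
"""

from __future__ import annotations

import numpy as np

from .synthetic import SyntheticConfig

#: six-gene demonstration panel planted as clone-restricted downregulation
DEMO_PANEL = ("CXCR4", "CD69", "HSPA1A", "ZFP36", "IL7R", "TXNIP")

#: genes referenced by the bundled ligand-receptor demo list that are not in
#: the planted panel
DEMO_INTERACTION_GENES = ("CXCL12", "CCL5", "CCR4", "SELL", "CD34", "MIF", "CD74")


def demo_config(seed: int = 1, planted_lfc: float = -0.8) -> SyntheticConfig:
    """Three patients, patch + plaque, 300 clone cells per class per patient.

    cells_per_sample=800 with t_cell_fraction=0.75 gives 600 T cells per
    sample; with full TCR detection and clone_fraction=0.5 that is exactly
    300 dominant-clone and 300 polyclonal cells per sample, plus 200 non-T
    cells for the microenvironment.
    """
    return SyntheticConfig(
        n_patients=3,
        samples_per_patient=("patch", "plaque"),
        cells_per_sample=800,
        n_genes=2000,
        nb_mean_log_range=(np.log(0.5), np.log(4.0)),
        nb_dispersion=2.0,
        clone_fraction=0.5,
        tcr_detection_rate=1.0,
        allelic_exclusion_rate=0.3,
        planted_effects={g: planted_lfc for g in DEMO_PANEL},
        seed=seed,
        t_cell_fraction=0.75,
        extra_genes=DEMO_PANEL + DEMO_INTERACTION_GENES,
        planted_gene_mean=5.0,  # panel genes are abundant transcripts
    )


def demo_run_config_dict(seed: int = 1, out_dir: str = "clonoscope_run") -> dict:
    """RunConfig payload (JSON-serializable) for the bundled demo run."""
    cfg = demo_config(seed=seed)
    return {
        "seed": seed,
        "out_dir": out_dir,
        "simulate": {
            "n_patients": cfg.n_patients,
            "samples_per_patient": list(cfg.samples_per_patient),
            "cells_per_sample": cfg.cells_per_sample,
            "n_genes": cfg.n_genes,
            "nb_mean_log_range": list(cfg.nb_mean_log_range),
            "nb_dispersion": cfg.nb_dispersion,
            "clone_fraction": cfg.clone_fraction,
            "tcr_detection_rate": cfg.tcr_detection_rate,
            "allelic_exclusion_rate": cfg.allelic_exclusion_rate,
            "planted_effects": dict(cfg.planted_effects),
            "seed": seed,
            "extra_genes": list(cfg.extra_genes),
            "planted_gene_mean": cfg.planted_gene_mean,
        },
        "interactions": {"pairs": None, "n_perm": 200, "min_frac": 0.1},
    }
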