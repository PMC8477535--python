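import numpy as np
import pytest

from clonoscope import (
    ContigRecord,
    assign_clonality,
    dominant_clone,
    gate_subsets,
    group_clonotypes,
    log_normalize,
    simulate_dataset,
)
from clonoscope.presets import demo_config
from clonoscope.io import read_contigs


def contig_records(frame):
    """Convert a synthetic contig DataFrame into ContigRecord objects."""
    return [
        ContigRecord(r.barcode, r.chain, r.cdr3, bool(r.productive), int(r.umis))
        for r in frame.itertuples(index=False)
    ]


class Dataset:
    """Simulated dataset with the downstream stages pre-computed."""

    def __init__(self, config):
        self.config = config
        cm, self.metadata, self.contig_frame, self.ground_truth = simulate_dataset(config)
        self.cm = log_normalize(cm)
        self.contigs = contig_records(self.contig_frame)
        self.clonotypes = group_clonotypes(self.contigs)
        self.stats = dominant_clone(self.clonotypes, self.metadata)
        self.assignments = assign_clonality(self.clonotypes, self.stats, self.metadata)
        self.assignments = gate_subsets(self.cm, self.assignments)

    def cells_where(self, **conditions):
        """Column indices of cells matching metadata equality conditions."""
        pos = {c: i for i, c in enumerate(self.cm.cells)}
        sel = self.metadata
        for col, val in conditions.items():
            vals = val if isinstance(val, (set, list, tuple)) else {val}
            sel = sel[sel[col].isin(vals)]
        return np.array([pos[c] for c in sel["cell_id"] if c in pos])

    def subset_cells(self, subset, **conditions):
        by_cell = {a.cell_id: a.subset for a in self.assignments}
        idx = self.cells_where(**conditions)
        return np.array([i for i in idx if by_cell.get(self.cm.cells[i]) == subset])


@pytest.fixture(scope="session")
def small_config():
    # demo design (300 clone cells per lesion class per patient) with a
    # reduced gene space to keep the suite fast
    cfg = demo_config(seed=1)
    cfg.n_genes = 600
    return cfg


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return Dataset(small_config)
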