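"""Clonotype grouping, dominant-clone calling and per-cell clonality labels.

Cells are grouped by CDR3 amino-acid sequence with the beta-like chain
(TRB, or TRD for gamma-delta data) as the primary key: cells sharing any
beta CDR3 belong to one clonotype (transitive closure over shared beta
chains), and merging accumulates the alpha-like CDR3s so a clone expressing
two alpha variants over one beta chain stays a single clone. Cells with
only alpha chains join the unique existing clonotype containing all their
alpha CDR3s, otherwise found a new one keyed by their alpha set.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io import ContigRecord

logger = logging.getLogger(__name__)

BETA_LIKE = frozenset({"TRB", "TRD"})
ALPHA_LIKE = frozenset({"TRA", "TRG"})

#: cells with more beta-like chains than this are treated as putative doublets
MAX_BETA_CHAINS = 2


@dataclass
class Clonotype:
    clone_id: str
    beta_cdr3s: frozenset[str]
    alpha_cdr3s: frozenset[str]
    member_cells: frozenset[str]
    umis: int = 0

    @property
    def size(self) -> int:
        return len(self.member_cells)

    def sort_key(self) -> tuple:
        """Deterministic ranking: size desc, UMI sum desc, smallest beta CDR3."""
        anchor = min(self.beta_cdr3s) if self.beta_cdr3s else min(self.alpha_cdr3s)
        return (-self.size, -self.umis, anchor)


@dataclass
class CloneStats:
    patient_id: str
    sample_id: str
    clone_id: str
    n_clone_cells: int
    n_tcr_cells: int

    @property
    def fraction(self) -> float:
        return self.n_clone_cells / self.n_tcr_cells


@dataclass
class CloneAssignment:
    cell_id: str
    clonality: str  # dominant | polyclonal | no_tcr
    clone_id: str | None = None
    subset: str | None = None  # filled by gating


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_clonotypes(contigs: list[ContigRecord]) -> list[Clonotype]:
    """Group productive contigs into clonotypes.

    Returns clonotypes sorted by (size desc, UMI sum desc, smallest beta
    CDR3); clone ids are assigned in that order. Cells whose alpha chains
    match two or more distinct beta-defined clonotypes are left unassigned
    (logged, not duplicated); cells with more than MAX_BETA_CHAINS beta
    chains are dropped as putative doublets.
    """
    by_cell: dict[str, list[ContigRecord]] = defaultdict(list)
    for rec in contigs:
        by_cell[rec.cell_id].append(rec)

    uf = _UnionFind()
    cell_betas: dict[str, list[str]] = {}
    cell_alphas: dict[str, list[str]] = {}
    cell_umis: dict[str, int] = {}
    doublets = []
    for cid, recs in by_cell.items():
        betas = sorted({r.cdr3_aa for r in recs if r.chain in BETA_LIKE})
        alphas = sorted({r.cdr3_aa for r in recs if r.chain in ALPHA_LIKE})
        if len(betas) > MAX_BETA_CHAINS:
            doublets.append(cid)
            continue
        cell_betas[cid] = betas
        cell_alphas[cid] = alphas
        cell_umis[cid] = sum(r.umis for r in recs)
        for b in betas:
            uf.find(b)
        for b in betas[1:]:
            uf.union(betas[0], b)
    if doublets:
        logger.warning("dropped %d putative doublets (> %d beta chains)", len(doublets), MAX_BETA_CHAINS)

    # beta-keyed components
    comp_cells: dict[str, set[str]] = defaultdict(set)
    comp_betas: dict[str, set[str]] = defaultdict(set)
    comp_alphas: dict[str, set[str]] = defaultdict(set)
    comp_umis: dict[str, int] = defaultdict(int)
    alpha_only: list[str] = []
    for cid in sorted(cell_betas):
        betas = cell_betas[cid]
        if not betas:
            if cell_alphas[cid]:
                alpha_only.append(cid)
            continue
        root = uf.find(betas[0])
        comp_cells[root].add(cid)
        comp_betas[root].update(betas)
        comp_alphas[root].update(cell_alphas[cid])
        comp_umis[root] += cell_umis[cid]

    # alpha-only cells: join the unique component containing all their alphas
    new_groups: dict[frozenset[str], set[str]] = defaultdict(set)
    unassigned = []
    for cid in alpha_only:
        alphas = set(cell_alphas[cid])
        hits = [root for root in comp_cells if alphas <= comp_alphas[root]]
        if len(hits) == 1:
            root = hits[0]
            comp_cells[root].add(cid)
            comp_umis[root] += cell_umis[cid]
        elif len(hits) == 0:
            new_groups[frozenset(alphas)].add(cid)
        else:
            unassigned.append(cid)
    if unassigned:
        logger.warning(
            "left %d alpha-only cells unassigned (alphas match >=2 beta-defined clonotypes)",
            len(unassigned),
        )

    clonotypes: list[Clonotype] = []
    for root, cells in comp_cells.items():
        clonotypes.append(
            Clonotype(
                clone_id="",
                beta_cdr3s=frozenset(comp_betas[root]),
                alpha_cdr3s=frozenset(comp_alphas[root]),
                member_cells=frozenset(cells),
                umis=comp_umis[root],
            )
        )
    for alphas, cells in new_groups.items():
        clonotypes.append(
            Clonotype(
                clone_id="",
                beta_cdr3s=frozenset(),
                alpha_cdr3s=alphas,
                member_cells=frozenset(cells),
                umis=sum(cell_umis[c] for c in cells),
            )
        )
    clonotypes.sort(key=Clonotype.sort_key)
    for i, ct in enumerate(clonotypes):
        ct.clone_id = f"CT{i + 1:05d}"
    return clonotypes


def dominant_clone(
    clonotypes: list[Clonotype], metadata: pd.DataFrame, scope: str = "patient"
) -> list[CloneStats]:
    """Identify the top expanded clone per patient (or per sample).

    With scope="patient" a patient's samples are pooled to pick the clone,
    and its fraction of TCR+ cells is then reported per sample. Ties break
    by total UMI count, then by lexicographically smallest beta CDR3.
    Returns an empty list (with a warning) when no TCR+ cells are in scope.
    """
    if scope not in ("patient", "sample"):
        raise ValueError(f"scope must be 'patient' or 'sample', got {scope!r}")
    cell_info = metadata.set_index("cell_id")[["patient_id", "sample_id"]]
    known = set(cell_info.index)

    cell_clone: dict[str, Clonotype] = {}
    for ct in clonotypes:
        for cid in ct.member_cells:
            cell_clone[cid] = ct
    skipped = [c for c in cell_clone if c not in known]
    if skipped:
        logger.warning("%d TCR+ cells not present in metadata; skipped", len(skipped))

    tcr_cells = [c for c in cell_clone if c in known]
    if not tcr_cells:
        logger.warning("no TCR-positive cells in scope; empty dominant-clone result")
        return []

    df = pd.DataFrame(
        {
            "cell_id": tcr_cells,
            "patient_id": [cell_info.at[c, "patient_id"] for c in tcr_cells],
            "sample_id": [cell_info.at[c, "sample_id"] for c in tcr_cells],
            "clone_id": [cell_clone[c].clone_id for c in tcr_cells],
        }
    )
    clone_by_id = {ct.clone_id: ct for ct in clonotypes}
    group_col = "patient_id" if scope == "patient" else "sample_id"

    stats: list[CloneStats] = []
    for _, grp in df.groupby(group_col, sort=True):
        sizes = grp.groupby("clone_id").size()
        best = min(
            sizes.index,
            key=lambda cid: (-sizes[cid], -clone_by_id[cid].umis, _beta_anchor(clone_by_id[cid])),
        )
        for sample_id, sgrp in grp.groupby("sample_id", sort=True):
            stats.append(
                CloneStats(
                    patient_id=str(sgrp["patient_id"].iloc[0]),
                    sample_id=str(sample_id),
                    clone_id=best,
                    n_clone_cells=int((sgrp["clone_id"] == best).sum()),
                    n_tcr_cells=len(sgrp),
                )
            )
    return stats


def _beta_anchor(ct: Clonotype) -> str:
    return min(ct.beta_cdr3s) if ct.beta_cdr3s else min(ct.alpha_cdr3s)


def assign_clonality(
    clonotypes: list[Clonotype], dominant: list[CloneStats], metadata: pd.DataFrame
) -> list[CloneAssignment]:
    """Label every metadata cell dominant / polyclonal / no_tcr.

    The partition is exhaustive and disjoint over metadata cells; contig
    cells absent from metadata are logged and skipped.
    """
    dominant_ids = {(s.patient_id, s.clone_id) for s in dominant}
    dom_by_patient = {p: cid for p, cid in dominant_ids}
    cell_clone: dict[str, str] = {}
    for ct in clonotypes:
        for cid in ct.member_cells:
            cell_clone[cid] = ct.clone_id

    known = set(metadata["cell_id"])
    orphans = set(cell_clone) - known
    if orphans:
        logger.warning("%d contig cells not in metadata; skipped", len(orphans))

    out: list[CloneAssignment] = []
    for row in metadata.itertuples(index=False):
        cid = row.cell_id
        clone = cell_clone.get(cid)
        if clone is None:
            out.append(CloneAssignment(cell_id=cid, clonality="no_tcr"))
        elif dom_by_patient.get(row.patient_id) == clone:
            out.append(CloneAssignment(cell_id=cid, clonality="dominant", clone_id=clone))
        else:
            out.append(CloneAssignment(cell_id=cid, clonality="polyclonal", clone_id=clone))
    return out


def alpha_variant_shares(
    clonotypes: list[Clonotype],
    contigs: list[ContigRecord],
    clone_id: str,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Share of each alpha-CDR3 variant among alpha-bearing cells of a clone.

    Reported per sample when metadata is given, else over all member cells.
    Supports tracking of incomplete allelic exclusion (two alpha variants
    over one shared beta chain).
    """
    ct = next((c for c in clonotypes if c.clone_id == clone_id), None)
    if ct is None:
        raise KeyError(f"unknown clone_id {clone_id!r}")
    members = ct.member_cells
    cell_alphas: dict[str, set[str]] = defaultdict(set)
    for rec in contigs:
        if rec.cell_id in members and rec.chain in ALPHA_LIKE:
            cell_alphas[rec.cell_id].add(rec.cdr3_aa)
    if metadata is not None:
        sample_of = metadata.set_index("cell_id")["sample_id"].to_dict()
    else:
        sample_of = {}
    rows = []
    by_sample: dict[str, list[str]] = defaultdict(list)
    for cid in cell_alphas:
        by_sample[sample_of.get(cid, "all")].append(cid)
    for sample, cells in sorted(by_sample.items()):
        variants = sorted({a for c in cells for a in cell_alphas[c]})
        for v in variants:
            n_with = sum(1 for c in cells if v in cell_alphas[c])
            rows.append(
                {
                    "sample_id": sample,
                    "clone_id": clone_id,
                    "alpha_cdr3": v,
                    "n_cells": n_with,
                    "n_alpha_cells": len(cells),
                    "share": n_with / len(cells),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "clone_id", "alpha_cdr3", "n_cells", "n_alpha_cells", "share"])


def clonotypes_to_frame(clonotypes: list[Clonotype]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clone_id": ct.clone_id,
                "size": ct.size,
                "umis": ct.umis,
                "beta_cdr3s": ";".join(sorted(ct.beta_cdr3s)),
                "alpha_cdr3s": ";".join(sorted(ct.alpha_cdr3s)),
            }
            for ct in clonotypes
        ],
        columns=["clone_id", "size", "umis", "beta_cdr3s", "alpha_cdr3s"],
    )


def assignments_to_frame(assignments: list[CloneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": a.cell_id,
                "clonality": a.clonality,
                "clone_id": a.clone_id or "",
                "subset": a.subset or "",
            }
            for a in assignments
        ],
        columns=["cell_id", "clonality", "clone_id", "subset"],
    )


def stats_to_frame(stats: list[CloneStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "sample_id": s.sample_id,
                "clone_id": s.clone_id,
                "n_clone_cells": s.n_clone_cells,
                "n_tcr_cells": s.n_tcr_cells,
                "fraction": s.fraction,
            }
            for s in stats
        ],
        columns=["patient_id", "sample_id", "clone_id", "n_clone_cells", "n_tcr_cells", "fraction"],
    )
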