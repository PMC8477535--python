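"""Readers and writers for the standard formats the pipeline touches.

All readers validate strictly and raise :class:`FormatError` rather than
silently coercing malformed input. The in-memory orientation of count
matrices is fixed as genes x cells; MTX files written cells x genes are
transposed on ingest when the barcode count matches the row dimension.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_CHAINS = frozenset({"TRA", "TRB", "TRG", "TRD"})
CDR3_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

LESION_CLASSES = frozenset(
    {"patch", "plaque", "tumor", "erythroderma", "nonlesional", "healthy", "followup"}
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class CountMatrix:
    """Sparse genes x cells raw count matrix with an optional normalized view."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    normalized: sp.csr_matrix | None = None
    _gene_index: dict[str, int] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.genes = [g.upper() for g in self.genes]
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise FormatError(f"duplicate gene symbol after upper-casing: {dup!r}")
        dup = _first_duplicate(self.cells)
        if dup is not None:
            raise FormatError(f"duplicate cell barcode: {dup!r}")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count entries")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_row(self, gene: str, normalized: bool = False) -> np.ndarray:
        """Dense 1-D expression vector of one gene across all cells."""
        i = self._gene_index.get(gene.upper())
        if i is None:
            raise KeyError(f"gene {gene!r} not in matrix")
        mat = self.normalized if normalized else self.counts
        if normalized and mat is None:
            raise ValueError("matrix has no normalized view; call log_normalize first")
        return np.asarray(mat[i].todense()).ravel()

    def has_gene(self, gene: str) -> bool:
        return gene.upper() in self._gene_index

    def gene_idx(self, gene: str) -> int:
        i = self._gene_index.get(gene.upper())
        if i is None:
            raise KeyError(f"gene {gene!r} not in matrix")
        return i


@dataclass(frozen=True)
class ContigRecord:
    """One productive TCR chain observed in one cell."""

    cell_id: str
    chain: str
    cdr3_aa: str
    productive: bool
    umis: int

    def __post_init__(self):
        if self.chain not in VALID_CHAINS:
            raise FormatError(f"invalid chain {self.chain!r}")
        if not CDR3_RE.match(self.cdr3_aa):
            raise FormatError(f"invalid CDR3 amino-acid sequence {self.cdr3_aa!r}")
        if self.umis < 0:
            raise FormatError(f"negative UMI count for cell {self.cell_id!r}")


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_symbol_column(path: str | Path) -> list[str]:
    """Features/barcodes TSV: last useful column is the symbol (10x dialect:
    id <tab> symbol [<tab> type])."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            out.append(cols[1] if len(cols) >= 2 else cols[0])
    return out


def read_counts(
    mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> CountMatrix:
    """Read a MatrixMarket count matrix with its features and barcodes files.

    The matrix may be stored genes x cells or cells x genes; the orientation
    is resolved against the features/barcodes lengths.
    """
    for p in (mtx_path, features_path, barcodes_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # noqa: BLE001 - normalize into FormatError
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz:
        if np.any(mat.data < 0):
            raise FormatError("negative entries in count matrix")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError("non-integer entries in count matrix")
    genes = _read_symbol_column(features_path)
    with open(barcodes_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    dup = _first_duplicate(barcodes)
    if dup is not None:
        raise FormatError(f"duplicate barcode in barcodes file: {dup!r}")
    n_g, n_c = len(genes), len(barcodes)
    if mat.shape == (n_g, n_c):
        pass
    elif mat.shape == (n_c, n_g):
        mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {n_g} genes x {n_c} cells "
            f"nor its transpose"
        )
    counts = sp.csr_matrix(mat, dtype=np.int64)
    return CountMatrix(genes=genes, cells=barcodes, counts=counts)


_TRUE_STRINGS = {"true", "t", "1", "yes"}
_FALSE_STRINGS = {"false", "f", "0", "no", "none", ""}


def _parse_productive(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise FormatError(f"cannot parse productive flag {value!r}")


REQUIRED_CONTIG_COLUMNS = ("barcode", "chain", "cdr3", "productive", "umis")


def read_contigs(csv_path: str | Path) -> list[ContigRecord]:
    """Read a 10x-style VDJ contig annotation CSV.

    Non-productive rows and rows without a usable CDR3 amino-acid sequence
    are dropped; chains outside TRA/TRB/TRG/TRD are dropped with a warning.
    """
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig file {csv_path} missing required columns: {missing}")
    records: list[ContigRecord] = []
    n_bad_chain = 0
    for row in df.itertuples(index=False):
        if not _parse_productive(row.productive):
            continue
        cdr3 = str(row.cdr3).strip()
        if cdr3 in ("", "None", "nan") or not CDR3_RE.match(cdr3):
            continue
        chain = str(row.chain).strip().upper()
        if chain not in VALID_CHAINS:
            n_bad_chain += 1
            continue
        records.append(
            ContigRecord(
                cell_id=str(row.barcode),
                chain=chain,
                cdr3_aa=cdr3,
                productive=True,
                umis=int(float(row.umis)),
            )
        )
    if n_bad_chain:
        logger.warning("dropped %d contigs with chain outside %s", n_bad_chain, sorted(VALID_CHAINS))
    return records


def contigs_to_frame(records: Iterable[ContigRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "barcode": r.cell_id,
                "chain": r.chain,
                "cdr3": r.cdr3_aa,
                "productive": r.productive,
                "umis": r.umis,
            }
            for r in records
        ],
        columns=["barcode", "chain", "cdr3", "productive", "umis"],
    )


REQUIRED_METADATA_COLUMNS = ("cell_id", "sample_id", "patient_id", "lesion_class", "cluster")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata file {path} missing required columns: {missing}")
    dup = _first_duplicate(list(df["cell_id"]))
    if dup is not None:
        raise FormatError(f"duplicate cell_id in metadata: {dup!r}")
    bad = set(df["lesion_class"]) - LESION_CLASSES
    if bad:
        raise FormatError(f"unknown lesion classes: {sorted(bad)}")
    return df


def _format_float(x) -> str:
    return f"{float(x):.10g}"


def write_table(records, path: str | Path, format: str = "tsv", columns: list[str] | None = None) -> None:
    """Write a list of dicts (or a DataFrame) as TSV or JSON.

    Floats are serialized with 10 significant digits so round-trips are
    lossless at the precision the pipeline reports. An empty input with a
    known schema (DataFrame or explicit columns) yields a header-only file.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unsupported format {format!r}")
    if isinstance(records, pd.DataFrame):
        if columns is None:
            columns = list(records.columns)
        records = records.to_dict(orient="records")
    records = list(records)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, default=_json_default)
            fh.write("\n")
        return
    if not records:
        path.write_text("\t".join(columns) + "\n" if columns else "")
        return
    cols = columns if columns is not None else list(records[0].keys())
    lines = ["\t".join(cols)]
    for rec in records:
        vals = []
        for c in cols:
            v = rec[c]
            if isinstance(v, (float, np.floating)):
                vals.append(_format_float(v))
            else:
                vals.append(str(v))
        lines.append("\t".join(vals))
    path.write_text("\n".join(lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(
    cm: CountMatrix, mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> None:
    """Write genes x cells counts as integer MatrixMarket plus TSV sidecars."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts), field="integer")
    with open(features_path, "w") as fh:
        for g in cm.genes:
            fh.write(f"{g}\t{g}\n")
    with open(barcodes_path, "w") as fh:
        for b in cm.cells:
            fh.write(b + "\n")
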