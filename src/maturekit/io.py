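"""Readers and writers for the text formats used across the toolkit.

TSV is the canonical tabular format; MatrixMarket (MTX plus row/column name
sidecars) is accepted for sparse matrices. BED6 carries peak sets
(0-based, half-open; score column = significance), bedGraph carries score
tracks. Every writer emits a provenance comment block (lines starting with
``#``) that readers skip, so stripping comments yields clean TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__
from .containers import CellMatrix, CountMatrix
from .errors import ParseError
from .intervals import PEAK_COLUMNS, sort_peaks


def provenance_header(seed: int | None = None, config_hash: str | None = None) -> list[str]:
    lines = [f"# maturekit {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}")
    return lines


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(
    frame: pd.DataFrame,
    path,
    index_label: str | None = None,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_header(seed, cfg_hash):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index_label=index_label)


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(path, metadata_path) -> CountMatrix:
    """Read a gene x sample count matrix (TSV or MTX triplet) plus metadata.

    For MTX, ``path`` points at the ``.mtx`` file and gene/sample names are
    read from ``<path>.rows`` / ``<path>.cols`` (one name per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        frame = _read_mtx(path)
    else:
        frame = _read_counts_tsv(path)
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", index_col=0)
    _validate_counts(frame, path)
    try:
        return CountMatrix(frame, meta)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame.index.name = None
    frame.columns.name = None
    return frame


def _read_mtx(path: Path) -> pd.DataFrame:
    matrix = scipy.io.mmread(path)
    rows = Path(str(path) + ".rows").read_text().split()
    cols = Path(str(path) + ".cols").read_text().split()
    dense = np.asarray(matrix.todense() if scipy.sparse.issparse(matrix) else matrix)
    if dense.shape != (len(rows), len(cols)):
        raise ParseError(
            f"{path}: matrix shape {dense.shape} does not match "
            f"{len(rows)} row names x {len(cols)} column names"
        )
    return pd.DataFrame(dense.astype(np.int64), index=rows, columns=cols)


def _validate_counts(frame: pd.DataFrame, path: Path) -> None:
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()[:3]
        raise ParseError(f"{path}: duplicate gene IDs {dupes}")
    if frame.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample IDs")
    arr = frame.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{path}: non-numeric counts")
    neg = np.argwhere(arr < 0)
    if neg.size:
        g, s = neg[0]
        raise ParseError(
            f"{path}: negative count at gene {frame.index[g]!r}, sample {frame.columns[s]!r}"
        )


def write_counts(matrix: CountMatrix, path, metadata_path, mtx: bool = False) -> None:
    path = Path(path)
    if mtx:
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(matrix.counts.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(matrix.counts.index) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(matrix.counts.columns) + "\n")
    else:
        write_table(matrix.counts, path, index_label="gene_id")
    write_table(matrix.metadata, metadata_path, index_label="sample")


def read_cells(path, metadata_path) -> CellMatrix:
    """Read a cell x gene matrix (TSV or MTX triplet) plus cell metadata.

    Metadata needs columns ``cluster`` and optionally ``cholinergic`` (a
    per-cell copy of its cluster's flag).
    """
    path = Path(path)
    frame = _read_mtx(path) if path.suffix == ".mtx" else pd.read_csv(
        path, sep="\t", comment="#", index_col=0
    )
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", index_col=0)
    if "cluster" not in meta.columns:
        raise ParseError(f"{metadata_path}: missing 'cluster' column")
    flags = None
    if "cholinergic" in meta.columns:
        flags = (
            meta.groupby("cluster")["cholinergic"]
            .agg(lambda s: bool(s.astype(bool).any()))
            .to_frame("cholinergic")
        )
    return CellMatrix(frame, meta["cluster"], flags)


def write_cells(cells: CellMatrix, path, metadata_path) -> None:
    write_table(cells.counts, path, index_label="cell_id")
    meta = cells.clusters.to_frame("cluster")
    if cells.cluster_flags is not None and "cholinergic" in cells.cluster_flags.columns:
        meta["cholinergic"] = (
            cells.cluster_flags["cholinergic"].reindex(cells.clusters).to_numpy().astype(int)
        )
    write_table(meta, metadata_path, index_label="cell_id")


# ---------------------------------------------------------------------------
# BED and TSS
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into a peak frame; missing names/scores get defaults."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] else f"peak{lineno}"
            try:
                score = float(parts[4]) if len(parts) > 4 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            records.append(
                {"chrom": parts[0], "start": start, "end": end, "name": name, "score": score}
            )
    return sort_peaks(pd.DataFrame(records, columns=list(PEAK_COLUMNS)))


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks = sort_peaks(peaks)
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score:g}\t.\n")


def read_tss(path) -> pd.DataFrame:
    """4-column TSV: gene_id, chrom, tss (0-based), strand."""
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["gene_id", "chrom", "tss", "strand"],
        header=None,
        dtype={"gene_id": str, "chrom": str, "strand": str},
    )
    if frame.iloc[0]["gene_id"] == "gene_id":  # header row present
        frame = frame.iloc[1:].reset_index(drop=True)
    frame["tss"] = frame["tss"].astype(int)
    if (frame["tss"] < 0).any():
        raise ParseError(f"{path}: negative TSS position")
    return frame


def write_tss(tss: pd.DataFrame, path) -> None:
    tss[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom<TAB>size")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# DE results
# ---------------------------------------------------------------------------

def write_de(de, path, seed: int | None = None) -> None:
    write_table(de.table, path, index_label="gene_id", seed=seed)


def read_de_table(path) -> pd.DataFrame:
    frame = read_table(path)
    required = {"log2_fc", "p_value", "call"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing DE columns {sorted(missing)}")
    return frame
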