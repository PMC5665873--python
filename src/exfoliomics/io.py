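"""Readers and writers for count matrices, metadata and result tables.

Counts travel as TSV (genes in rows, header row of sample ids) or as
MatrixMarket coordinate files accompanied by plain-text row/column index
files (``<stem>.mtx`` + ``<stem>.genes.txt`` + ``<stem>.samples.txt``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from exfoliomics.matrix import METADATA_COLUMNS, CountMatrix

PathLike = Union[str, Path]


def read_counts_tsv(path: PathLike, metadata: Optional[PathLike] = None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    samples = read_metadata_tsv(metadata) if metadata is not None else None
    return CountMatrix(counts, samples)


def write_counts_tsv(cm: CountMatrix, path: PathLike) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(stem: PathLike, metadata: Optional[PathLike] = None) -> CountMatrix:
    stem = Path(stem)
    mat = scipy.io.mmread(stem.with_suffix(".mtx")).toarray()
    genes = stem.with_suffix(".genes.txt").read_text().split()
    samples_ids = stem.with_suffix(".samples.txt").read_text().split()
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples_ids)
    samples = read_metadata_tsv(metadata) if metadata is not None else None
    return CountMatrix(counts, samples)


def write_counts_mtx(cm: CountMatrix, stem: PathLike) -> None:
    stem = Path(stem)
    sparse = scipy.sparse.coo_matrix(cm.counts.to_numpy())
    scipy.io.mmwrite(str(stem.with_suffix(".mtx")), sparse)
    stem.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
    stem.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")


def read_metadata_tsv(path: PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    return meta


def write_metadata_tsv(samples: pd.DataFrame, path: PathLike) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path: PathLike) -> list[str]:
    """One gene id per line; blank lines ignored."""
    return [line for line in Path(path).read_text().split() if line]


def write_gene_list(genes, path: PathLike) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_marker_panel(path: PathLike) -> dict[str, list[str]]:
    """Marker panel as JSON mapping or two-column TSV (cell_type, gene_id)."""
    path = Path(path)
    if path.suffix == ".json":
        panel = json.loads(path.read_text())
        return {k: list(v) for k, v in panel.items()}
    table = pd.read_csv(path, sep="\t")
    if not {"cell_type", "gene_id"} <= set(table.columns):
        raise ValueError("marker panel TSV needs columns cell_type, gene_id")
    return {
        cell_type: sub["gene_id"].tolist()
        for cell_type, sub in table.groupby("cell_type", sort=True)
    }


def write_marker_panel(panel: dict[str, list[str]], path: PathLike) -> None:
    rows = [
        {"cell_type": ct, "gene_id": g} for ct in sorted(panel) for g in panel[ct]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj
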