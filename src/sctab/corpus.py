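"""Corpus construction: normalization, filtering, splitting, streaming.

A corpus is a cell x gene count matrix (:class:`CellByGeneMatrix`) plus a
per-cell metadata table (a :class:`pandas.DataFrame` with columns
``cell_id, cell_type, donor_id, assay, dataset_id, is_primary, tissue``),
aligned row-for-row.

The construction pipeline mirrors how large public corpora are prepared for
cross-donor cell-type classifiers: keep primary 10x data whose label is a
subtype of the root term, drop cell types that are too rare (cells or
donors) or too unspecific (shallow in the ontology), split by *donor* so
that generalization to unseen individuals is what is measured, and stream
the result chunk-wise from a columnar on-disk store.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from sctab.ontology import OntologyGraph

__all__ = [
    "RECORD_COLUMNS",
    "TENX_ASSAYS",
    "CellByGeneMatrix",
    "FilterParams",
    "FilterReport",
    "SplitAssignment",
    "normalize",
    "filter_corpus",
    "donor_split",
    "subsample",
    "write_chunk_store",
    "stream_batches",
    "align_genes",
]

RECORD_COLUMNS = (
    "cell_id",
    "cell_type",
    "donor_id",
    "assay",
    "dataset_id",
    "is_primary",
    "tissue",
)

#: 10x Genomics assays admitted by filter criterion 2.
TENX_ASSAYS = frozenset(
    {
        "10x 5' v2",
        "10x 3' v3",
        "10x 3' v2",
        "10x 5' v1",
        "10x 3' v1",
        "10x 3' transcription profiling",
        "10x 5' transcription profiling",
    }
)

SIZE_FACTOR = 10_000.0


@dataclass
class CellByGeneMatrix:
    """Expression over a fixed, ordered gene vocabulary.

    ``layer`` records whether ``values`` holds raw counts (non-negative
    integers) or size-factor-normalized log1p expression.  Column order is
    the order of ``gene_ids``.
    """

    values: np.ndarray | sparse.spmatrix
    gene_ids: np.ndarray
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{len(self.gene_ids)} gene ids"
            )
        if self.layer not in ("raw", "normalized"):
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset(self, rows: np.ndarray) -> "CellByGeneMatrix":
        return CellByGeneMatrix(self.values[rows], self.gene_ids, self.layer)


def validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table is missing columns: {missing}")
    if records["cell_id"].duplicated().any():
        raise ValueError("cell_id values are not unique")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise size-factor normalization to 10,000 counts followed by log1p.

    Zero-total rows are returned as all-zero.  Used both by corpus
    preparation and inside model forward passes.
    """
    x = np.asarray(x, dtype=np.float64)
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(totals > 0, SIZE_FACTOR * x / totals, 0.0)
    return np.log1p(scaled)


def normalize(matrix: CellByGeneMatrix) -> CellByGeneMatrix:
    """Return a normalized copy of a raw-count matrix.

    Each row x becomes ``log1p(10,000 * x / sum(x))``, so ``expm1`` of a
    nonzero row sums back to the size factor.  Normalizing an
    already-normalized layer is rejected rather than silently applied twice.
    """
    if matrix.layer != "raw":
        raise ValueError("matrix is already normalized; refusing to double-normalize")
    dense = matrix.dense()
    if (dense < 0).any():
        raise ValueError("raw counts contain negative entries")
    n_zero = int((dense.sum(axis=1) == 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} cells have zero total counts; returned as all-zero")
    return CellByGeneMatrix(
        normalize_rows(dense).astype(np.float32), matrix.gene_ids, "normalized"
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterParams:
    """Thresholds of the six corpus-filter criteria.

    The cell-type-level thresholds (min_cells, min_donors, min_ancestors)
    are dataset dependent; the defaults are the values used for the
    full-scale public corpus.
    """

    require_primary: bool = True
    assays: frozenset[str] = TENX_ASSAYS
    min_cells: int = 5000
    min_donors: int = 30
    min_ancestors: int = 7
    drop_zero_count_cells: bool = False


@dataclass
class FilterReport:
    """Per-criterion removal accounting for one filter run."""

    input_cells: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_cell_types: dict[str, list[str]] = field(default_factory=dict)
    surviving_cells: int = 0
    surviving_cell_types: list[str] = field(default_factory=list)
    unresolvable_terms: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "cells_removed": v} for k, v in self.removed.items()]
        rows.append({"criterion": "surviving", "cells_removed": self.surviving_cells})
        return pd.DataFrame(rows)


_CRITERIA = (
    "1_primary_data",
    "2_assay",
    "3_subtype_of_root",
    "4_min_cells",
    "5_min_donors",
    "6_min_ancestors",
)


def filter_corpus(
    matrix: CellByGeneMatrix,
    records: pd.DataFrame,
    graph: OntologyGraph,
    params: FilterParams | None = None,
) -> tuple[CellByGeneMatrix, pd.DataFrame, FilterReport]:
    """Apply the six corpus-construction criteria in order.

    1. primary data only; 2. 10x assays only; 3. cell type is a subtype of
    the graph root; 4. each cell type has >= min_cells cells; 5. each cell
    type spans >= min_donors donors; 6. each cell type has >= min_ancestors
    transitive ancestors in the ontology.  Criteria 4-6 drop *all* cells of
    a failing type and are re-applied until a fixed point.

    Cells whose cell_type is absent from the ontology are dropped and
    reported.  Raises if nothing survives.
    """
    params = params or FilterParams()
    validate_records(records)
    if len(records) != matrix.n_cells:
        raise ValueError("records not aligned to matrix rows")

    report = FilterReport(input_cells=len(records))
    keep = np.ones(len(records), dtype=bool)
    records = records.reset_index(drop=True)

    def drop(mask_removed: np.ndarray, criterion: str) -> None:
        newly = keep & mask_removed
        report.removed[criterion] = report.removed.get(criterion, 0) + int(newly.sum())
        keep[newly] = False

    # criterion 1: primary data only
    if params.require_primary:
        drop(~records["is_primary"].to_numpy(dtype=bool), _CRITERIA[0])
    else:
        report.removed[_CRITERIA[0]] = 0

    # criterion 2: admitted assays
    drop(~records["assay"].isin(params.assays).to_numpy(), _CRITERIA[1])

    # criterion 3: label resolvable and a subtype of the root
    types = records["cell_type"].to_numpy(dtype=object)
    resolvable = np.array([t in graph for t in types])
    report.unresolvable_terms = sorted(set(types[keep & ~resolvable]))
    drop(~resolvable, "3_unresolvable_term")
    is_sub = {
        t: graph.is_subtype(t, graph.root) for t in set(types[keep & resolvable])
    }
    drop(
        np.array([not is_sub.get(t, False) for t in types]),
        _CRITERIA[2],
    )

    if params.drop_zero_count_cells:
        totals = np.asarray(matrix.values.sum(axis=1)).ravel()
        drop(totals == 0, "zero_count_cells")

    # criteria 4-6: cell-type level, iterated to a fixed point
    for crit in (_CRITERIA[3], _CRITERIA[4], _CRITERIA[5]):
        report.removed[crit] = 0
        report.removed_cell_types[crit] = []
    changed = True
    while changed:
        changed = False
        sub = records.loc[keep]
        by_type = sub.groupby("cell_type", sort=True)
        n_cells = by_type.size()
        n_donors = by_type["donor_id"].nunique()
        for crit, failing in (
            (_CRITERIA[3], set(n_cells.index[n_cells < params.min_cells])),
            (_CRITERIA[4], set(n_donors.index[n_donors < params.min_donors])),
            (
                _CRITERIA[5],
                {
                    t
                    for t in n_cells.index
                    if graph.ancestor_count(t) < params.min_ancestors
                },
            ),
        ):
            if failing:
                drop(records["cell_type"].isin(failing).to_numpy(), crit)
                report.removed_cell_types[crit].extend(sorted(failing))
                changed = True
                break  # re-evaluate counts from scratch, preserving order

    report.surviving_cells = int(keep.sum())
    report.surviving_cell_types = sorted(records.loc[keep, "cell_type"].unique())
    if report.surviving_cells == 0:
        raise ValueError(f"no cells survive filtering; report: {report.removed}")

    idx = np.flatnonzero(keep)
    return matrix.subset(idx), records.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# donor split
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Donor -> {train, val, test} partition."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def donors(self, split: str) -> list[str]:
        return sorted(d for d, s in self.assignment.items() if s == split)

    def split_of_cells(self, records: pd.DataFrame) -> pd.Series:
        return records["donor_id"].map(self.assignment)

    def cell_indices(self, records: pd.DataFrame, split: str) -> np.ndarray:
        return np.flatnonzero((self.split_of_cells(records) == split).to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["donor_id", "split"]
        )


def donor_split(
    donors: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Partition donors into train/val/test by a seeded uniform shuffle.

    Every cell of a donor follows its donor, so validation and test donors
    are never seen during training.  Sizes are floor(fraction * n) for val
    and test with the remainder going to train.
    """
    donors = list(dict.fromkeys(donors))  # unique, order-preserving
    if len(donors) < 3:
        raise ValueError("need at least 3 donors to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(donors)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(donors))
    assignment: dict[str, str] = {}
    for d in order[: n - n_val - n_test]:
        assignment[d] = "train"
    for d in order[n - n_val - n_test : n - n_test]:
        assignment[d] = "val"
    for d in order[n - n_test :]:
        assignment[d] = "test"
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


# ---------------------------------------------------------------------------
# incremental subsampling
# ---------------------------------------------------------------------------

def subsample(
    records: pd.DataFrame,
    mode: str,
    fractions: Sequence[float],
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """Incremental cell- or donor-level subsampling.

    Returns, per fraction, the row indices of the selected cells.  Subsets
    are nested: the 15% subset is contained in the 30% subset, because all
    fractions are prefixes of one seeded permutation.
    """
    fr = list(fractions)
    if any(not (0 < f <= 1) for f in fr) or fr != sorted(fr) or len(set(fr)) != len(fr):
        raise ValueError(f"fractions must be strictly ascending in (0, 1]: {fractions}")
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    if mode == "cell":
        order = rng.permutation(len(records))
        for f in fr:
            k = int(round(f * len(records)))
            out[f] = np.sort(order[:k])
    elif mode == "donor":
        donors = np.array(sorted(records["donor_id"].unique()), dtype=object)
        order = rng.permutation(donors)
        donor_col = records["donor_id"].to_numpy(dtype=object)
        for f in fr:
            k = int(round(f * len(donors)))
            chosen = set(order[:k])
            out[f] = np.flatnonzero([d in chosen for d in donor_col])
    else:
        raise ValueError(f"mode must be 'cell' or 'donor', got {mode!r}")
    return out


# ---------------------------------------------------------------------------
# chunked on-disk store and block-shuffled streaming
# ---------------------------------------------------------------------------

def write_chunk_store(
    matrix: CellByGeneMatrix,
    records: pd.DataFrame,
    path: str | Path,
    chunk_size: int = 4096,
) -> Path:
    """Write the corpus as fixed-size row chunks in Parquet.

    Each chunk file holds ``chunk_size`` consecutive cells (the last one the
    remainder) with metadata columns plus the expression row as a float32
    list column.  Chunked storage is what makes block-wise shuffled
    streaming possible for bigger-than-memory corpora.
    """
    import pyarrow as pa
    import pyarrow.parquet as pq

    validate_records(records)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dense = matrix.dense().astype(np.float32)
    n = matrix.n_cells
    manifest = {
        "n_cells": n,
        "chunk_size": int(chunk_size),
        "layer": matrix.layer,
        "gene_ids": [str(g) for g in matrix.gene_ids],
    }
    import json

    (path / "manifest.json").write_text(json.dumps(manifest))
    n_chunks = (n + chunk_size - 1) // chunk_size
    for ci in range(n_chunks):
        lo, hi = ci * chunk_size, min((ci + 1) * chunk_size, n)
        block = records.iloc[lo:hi]
        table = pa.table(
            {
                **{c: pa.array(block[c].tolist()) for c in RECORD_COLUMNS},
                "x": pa.FixedSizeListArray.from_arrays(
                    pa.array(dense[lo:hi].ravel(), type=pa.float32()),
                    matrix.n_genes,
                ),
            }
        )
        pq.write_table(table, path / f"chunk-{ci:05d}.parquet")
    return path


@dataclass
class Batch:
    x: np.ndarray
    cell_ids: np.ndarray
    cell_types: np.ndarray
    donor_ids: np.ndarray


def _read_chunk(path: Path, n_genes: int) -> tuple[np.ndarray, pd.DataFrame]:
    import pyarrow.parquet as pq

    try:
        table = pq.read_table(path)
        x = np.asarray(table["x"].combine_chunks().flatten(), dtype=np.float32)
        meta = table.select(list(RECORD_COLUMNS)).to_pandas()
        x = x.reshape(len(meta), n_genes)
    except Exception as exc:  # corrupt file, wrong schema, short flat array
        raise IOError(f"corrupted chunk {path.name}: {exc}") from exc
    return x, meta


def stream_batches(
    store: str | Path,
    batch_size: int,
    shuffle_buffer: int = 0,
    seed: int = 0,
) -> Iterator[Batch]:
    """Yield block-shuffled batches from a chunk store, one epoch.

    Whole chunks are read in a seeded random order; rows accumulate in a
    buffer of at least ``shuffle_buffer`` rows which is shuffled before
    batches are emitted.  Every row is yielded exactly once per epoch and
    the sequence is deterministic given the seed.
    """
    import json

    store = Path(store)
    manifest = json.loads((store / "manifest.json").read_text())
    n_genes = len(manifest["gene_ids"])
    if manifest["chunk_size"] < batch_size:
        raise ValueError("chunk_size must be >= batch_size")
    chunk_files = sorted(store.glob("chunk-*.parquet"))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chunk_files))

    buf_x: list[np.ndarray] = []
    buf_meta: list[pd.DataFrame] = []

    def buffered() -> int:
        return sum(len(m) for m in buf_meta)

    def emit(final: bool) -> Iterator[Batch]:
        x = np.concatenate(buf_x) if buf_x else np.empty((0, n_genes), np.float32)
        meta = (
            pd.concat(buf_meta, ignore_index=True)
            if buf_meta
            else pd.DataFrame(columns=list(RECORD_COLUMNS))
        )
        perm = rng.permutation(len(meta))
        x, meta = x[perm], meta.iloc[perm].reset_index(drop=True)
        n_full = len(meta) if final else (len(meta) // batch_size) * batch_size
        for lo in range(0, n_full, batch_size):
            hi = min(lo + batch_size, n_full)
            yield Batch(
                x=x[lo:hi],
                cell_ids=meta["cell_id"].to_numpy()[lo:hi],
                cell_types=meta["cell_type"].to_numpy()[lo:hi],
                donor_ids=meta["donor_id"].to_numpy()[lo:hi],
            )
        buf_x.clear()
        buf_meta.clear()
        if not final and n_full < len(meta):
            buf_x.append(x[n_full:])
            buf_meta.append(meta.iloc[n_full:].reset_index(drop=True))

    for ci in order:
        x, meta = _read_chunk(chunk_files[ci], n_genes)
        buf_x.append(x)
        buf_meta.append(meta)
        if buffered() >= max(shuffle_buffer, batch_size):
            yield from emit(final=False)
    yield from emit(final=True)


# ---------------------------------------------------------------------------
# gene-vocabulary alignment for query data
# ---------------------------------------------------------------------------

def align_genes(
    matrix: CellByGeneMatrix, vocabulary: Sequence[str]
) -> CellByGeneMatrix:
    """Project a matrix onto a reference gene vocabulary.

    Shared genes are reordered to the vocabulary; genes missing from the
    query are zero-filled.  A warning is raised when coverage drops below
    80%, since zero-filling many genes degrades predictions.
    """
    vocab = np.asarray(list(vocabulary), dtype=object)
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    shared = [g for g in vocab if g in pos]
    coverage = len(shared) / len(vocab)
    if coverage < 0.8:
        warnings.warn(
            f"only {coverage:.0%} of the reference vocabulary is present in the query"
        )
    dense = matrix.dense()
    out = np.zeros((matrix.n_cells, len(vocab)), dtype=dense.dtype)
    for j, g in enumerate(vocab):
        if g in pos:
            out[:, j] = dense[:, pos[g]]
    return CellByGeneMatrix(out, vocab, matrix.layer)
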