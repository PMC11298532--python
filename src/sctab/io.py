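"""Readers and writers for corpora and reports.

A corpus directory bundles what one analysis stage hands to the next:

- ``corpus.h5ad``    — AnnData with raw counts (CSR) and the per-cell
  metadata table in ``.obs``;
- ``ontology.tsv``   — (child, parent) ``is_a`` edge list;
- ``meta.json``      — root term, layer, holdout types, provenance.

Matrix Market (+ TSV metadata) import/export is provided for
interoperability with non-HDF5 pipelines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from sctab.corpus import CellByGeneMatrix, RECORD_COLUMNS, validate_records
from sctab.ontology import OntologyGraph

__all__ = [
    "write_corpus_dir",
    "read_corpus_dir",
    "write_matrix_market",
    "read_matrix_market",
]


def write_corpus_dir(
    path: str | Path,
    matrix: CellByGeneMatrix,
    records: pd.DataFrame,
    graph: OntologyGraph | None = None,
    meta: dict | None = None,
) -> Path:
    import anndata as ad

    validate_records(records)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    x = matrix.values
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    obs = records.set_index("cell_id")[list(RECORD_COLUMNS[1:])].copy()
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(
        X=x.astype(np.float32).tocsr(),
        obs=obs,
        var=pd.DataFrame(index=pd.Index([str(g) for g in matrix.gene_ids], name="gene_id")),
    )
    adata.write_h5ad(path / "corpus.h5ad")
    if graph is not None:
        pd.DataFrame(graph.edges(), columns=["child", "parent"]).to_csv(
            path / "ontology.tsv", sep="\t", index=False
        )
    full_meta = {"layer": matrix.layer, "root": graph.root if graph else None}
    full_meta.update(meta or {})
    (path / "meta.json").write_text(json.dumps(full_meta, indent=1))
    return path


def read_corpus_dir(
    path: str | Path,
) -> tuple[CellByGeneMatrix, pd.DataFrame, OntologyGraph | None, dict]:
    import anndata as ad

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    adata = ad.read_h5ad(path / "corpus.h5ad")
    values = adata.X
    if sparse.issparse(values):
        values = values.tocsr()
    if meta.get("layer", "raw") == "raw":
        values = values.astype(np.int64) if not sparse.issparse(values) else values
    matrix = CellByGeneMatrix(
        values, adata.var_names.to_numpy(dtype=object), meta.get("layer", "raw")
    )
    records = adata.obs.reset_index(names="cell_id")[list(RECORD_COLUMNS)].copy()
    for col in RECORD_COLUMNS:
        if col != "is_primary":
            records[col] = records[col].astype(object)
    records["is_primary"] = records["is_primary"].astype(bool)
    graph = None
    if (path / "ontology.tsv").exists() and meta.get("root"):
        edges = pd.read_csv(path / "ontology.tsv", sep="\t")
        graph = OntologyGraph.from_edges(
            edges.itertuples(index=False, name=None), meta["root"]
        )
    return matrix, records, graph, meta


def write_matrix_market(
    prefix: str | Path, matrix: CellByGeneMatrix, records: pd.DataFrame
) -> None:
    """``<prefix>.mtx`` + ``<prefix>.genes.tsv`` + ``<prefix>.obs.tsv``."""
    from scipy.io import mmwrite

    prefix = Path(prefix)
    x = matrix.values
    mmwrite(str(prefix) + ".mtx", sparse.coo_matrix(x))
    pd.Series(matrix.gene_ids, name="gene_id").to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False
    )
    records.to_csv(str(prefix) + ".obs.tsv", sep="\t", index=False)


def read_matrix_market(
    prefix: str | Path, layer: str = "raw"
) -> tuple[CellByGeneMatrix, pd.DataFrame]:
    from scipy.io import mmread

    prefix = str(Path(prefix))
    x = sparse.csr_matrix(mmread(prefix + ".mtx"))
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene_id"].to_numpy(object)
    records = pd.read_csv(
        prefix + ".obs.tsv", sep="\t", dtype={c: object for c in RECORD_COLUMNS if c != "is_primary"}
    )
    records["is_primary"] = records["is_primary"].astype(bool)
    return CellByGeneMatrix(x, genes, layer), records
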