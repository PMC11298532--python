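"""Seeded synthetic ontologies and scRNA-seq corpora.

The generator emulates the statistical structure the annotation method
assumes: every cell type has an expression program (with planted marker
genes), every donor adds a batch-effect shift in log-mean space, counts are
negative-binomial with a log-normal library size, a fraction of cells may
carry a coarsened (ancestor) label, and chosen cell types can be held out
of the training label universe while remaining present in the data.

Named presets (:func:`standard_fixtures`) pin the corpora used throughout
the test suite:

- ``separable-small``: well-separated types, the training smoke corpus;
- ``donor-shift``: strong donor batch effects, for augmentation benefit;
- ``granularity-mixed``: coarsened labels, for ontology-corrected metrics;
- ``holdout-type``: an unseen cell type, for uncertainty scoring;
- ``filter-edge``: hand-built boundary cases for the corpus filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from sctab.corpus import CellByGeneMatrix, RECORD_COLUMNS
from sctab.ontology import OntologyGraph

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "SyntheticCorpus",
    "generate_ontology",
    "generate_corpus",
    "standard_fixtures",
    "generate_preset",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic corpus.

    ``donor_shift_scale`` is the standard deviation of per-donor additive
    shifts in log-mean space; 0 makes donors exchangeable.  ``dispersion``
    is the negative-binomial dispersion (1/size), shared across genes.
    ``library_size`` holds (mu, sigma) of the log-normal per-cell total.
    """

    n_genes: int = 2000
    ontology_depth: int = 4
    ontology_branching: int = 2
    n_cell_types: int = 8
    n_donors: int = 20
    cells_per_donor: int = 1000
    marker_genes_per_type: int = 20
    marker_strength: float = 3.0
    donor_shift_scale: float = 0.2
    donor_shift_frac: float = 0.25   # fraction of genes a donor's shift touches
    dispersion: float = 0.15
    library_size: tuple[float, float] = (float(np.log(3000.0)), 0.25)
    frac_coarse_labels: float = 0.0
    holdout_types: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_coarse_labels < 1):
            raise ValueError("frac_coarse_labels must be in [0, 1)")
        for name in (
            "n_genes",
            "n_cell_types",
            "n_donors",
            "cells_per_donor",
            "marker_genes_per_type",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated corpus."""

    fine_types: np.ndarray          # true leaf term per cell
    assigned_labels: np.ndarray     # possibly coarsened label per cell
    donors: np.ndarray
    marker_genes: dict[str, np.ndarray]   # type -> marker gene indices
    donor_shifts: dict[str, np.ndarray]   # donor -> shift vector (log space)
    holdout_types: list[str] = field(default_factory=list)


@dataclass
class SyntheticCorpus:
    """A generated corpus bundle: counts, metadata, truth, and its ontology."""

    matrix: CellByGeneMatrix
    records: pd.DataFrame
    truth: SyntheticTruth
    graph: OntologyGraph
    spec: SyntheticSpec


def generate_ontology(spec: SyntheticSpec) -> OntologyGraph:
    """Complete rooted tree with CL-style ids.

    Depth ``d`` and branching ``b`` give (b^(d+1) - 1) / (b - 1) terms; the
    root is ``CL:0000000`` and children are numbered breadth-first.
    """
    b, d = spec.ontology_branching, spec.ontology_depth
    g = nx.DiGraph()
    root = "CL:0000000"
    g.add_node(root)
    frontier = [root]
    counter = 1
    for _ in range(d):
        nxt = []
        for parent in frontier:
            for _ in range(b):
                child = f"CL:{counter:07d}"
                counter += 1
                g.add_edge(child, parent)
                nxt.append(child)
        frontier = nxt
    return OntologyGraph(g, root)


def _leaves(graph: OntologyGraph) -> list[str]:
    return sorted(t for t in graph.terms if not graph.children(t))


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Draw a corpus from the generative model.

    Per type c: log-mean program mu_c = baseline + marker boost; per donor
    d: shift delta_d ~ N(0, donor_shift_scale^2) per gene.  A cell of
    (c, d) draws counts ~ NB(mean = L * softmax(mu_c + delta_d),
    dispersion) with L log-normal.  ``frac_coarse_labels`` of cells are
    relabeled to a random proper ancestor of their true type (the root
    excluded); the last ``holdout_types`` types are flagged as absent from
    the training label universe.
    """
    rng = np.random.default_rng(spec.seed)
    graph = generate_ontology(spec)
    leaves = _leaves(graph)
    if spec.n_cell_types > len(leaves):
        raise ValueError(
            f"{spec.n_cell_types} cell types requested but the ontology has "
            f"only {len(leaves)} leaves"
        )
    types = list(rng.choice(leaves, size=spec.n_cell_types, replace=False))
    donors = [f"donor{j:03d}" for j in range(spec.n_donors)]

    baseline = rng.normal(0.0, 0.5, size=spec.n_genes)
    marker_pool = rng.permutation(spec.n_genes)
    markers: dict[str, np.ndarray] = {}
    programs: dict[str, np.ndarray] = {}
    for k, t in enumerate(types):
        lo = k * spec.marker_genes_per_type
        hi = lo + spec.marker_genes_per_type
        if hi > spec.n_genes:
            raise ValueError("not enough genes for disjoint marker sets")
        markers[t] = np.sort(marker_pool[lo:hi])
        prog = baseline.copy()
        prog[markers[t]] += spec.marker_strength
        programs[t] = prog
    # batch effects touch a gene subset per donor, like chemistry/ambient
    # effects concentrated on particular transcripts
    shifts: dict[str, np.ndarray] = {}
    for d in donors:
        delta = rng.normal(0.0, spec.donor_shift_scale, size=spec.n_genes)
        if spec.donor_shift_frac < 1.0:
            off = rng.random(spec.n_genes) >= spec.donor_shift_frac
            delta[off] = 0.0
        shifts[d] = delta

    n_cells = spec.n_donors * spec.cells_per_donor
    cell_types = np.empty(n_cells, dtype=object)
    cell_donors = np.empty(n_cells, dtype=object)
    counts = np.empty((n_cells, spec.n_genes), dtype=np.int64)
    libs = np.exp(rng.normal(spec.library_size[0], spec.library_size[1], size=n_cells))

    r = 1.0 / spec.dispersion
    i = 0
    for d in donors:
        assigned = rng.choice(len(types), size=spec.cells_per_donor)
        for k in range(len(types)):
            idx = np.flatnonzero(assigned == k)
            if len(idx) == 0:
                continue
            logits = programs[types[k]] + shifts[d]
            rate = np.exp(logits - logits.max())
            rate /= rate.sum()
            means = libs[i + idx, None] * rate[None, :]
            p = r / (r + means)
            counts[i + idx] = rng.negative_binomial(r, p)
            cell_types[i + idx] = types[k]
            cell_donors[i + idx] = d
        i += spec.cells_per_donor

    assigned_labels = cell_types.copy()
    if spec.frac_coarse_labels > 0:
        n_coarse = int(round(spec.frac_coarse_labels * n_cells))
        chosen = rng.choice(n_cells, size=n_coarse, replace=False)
        for ci in chosen:
            anc = sorted(graph.ancestors(cell_types[ci]) - {graph.root})
            if anc:
                assigned_labels[ci] = anc[rng.integers(len(anc))]

    holdout = types[len(types) - spec.holdout_types :] if spec.holdout_types else []

    records = pd.DataFrame(
        {
            "cell_id": [f"cell{i:07d}" for i in range(n_cells)],
            "cell_type": assigned_labels,
            "donor_id": cell_donors,
            "assay": "10x 3' v3",
            "dataset_id": "synthetic-dataset-0",
            "is_primary": True,
            "tissue": "synthetic tissue",
        }
    )[list(RECORD_COLUMNS)]

    matrix = CellByGeneMatrix(
        counts, np.array([f"ENSG{g:011d}" for g in range(spec.n_genes)]), "raw"
    )
    truth = SyntheticTruth(
        fine_types=cell_types,
        assigned_labels=assigned_labels,
        donors=cell_donors,
        marker_genes=markers,
        donor_shifts=shifts,
        holdout_types=list(holdout),
    )
    return SyntheticCorpus(matrix, records, truth, graph, spec)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_PRESETS: dict[str, SyntheticSpec] = {
    "separable-small": SyntheticSpec(
        n_genes=2000,
        ontology_depth=4,
        ontology_branching=2,
        n_cell_types=8,
        n_donors=20,
        cells_per_donor=1000,
        marker_genes_per_type=20,
        marker_strength=3.0,
        donor_shift_scale=0.2,
        dispersion=0.15,
        seed=11,
    ),
    "donor-shift": SyntheticSpec(
        n_genes=400,
        ontology_depth=3,
        ontology_branching=2,
        n_cell_types=5,
        n_donors=16,
        cells_per_donor=250,
        marker_genes_per_type=8,
        marker_strength=2.0,
        donor_shift_scale=1.0,
        dispersion=0.3,
        library_size=(float(np.log(2000.0)), 0.25),
        seed=23,
    ),
    "granularity-mixed": SyntheticSpec(
        n_genes=300,
        ontology_depth=3,
        ontology_branching=2,
        n_cell_types=6,
        n_donors=10,
        cells_per_donor=200,
        marker_genes_per_type=8,
        marker_strength=2.5,
        donor_shift_scale=0.3,
        dispersion=0.3,
        library_size=(float(np.log(2000.0)), 0.25),
        frac_coarse_labels=0.3,
        seed=37,
    ),
    "holdout-type": SyntheticSpec(
        n_genes=400,
        ontology_depth=3,
        ontology_branching=2,
        n_cell_types=6,
        n_donors=16,
        cells_per_donor=250,
        marker_genes_per_type=8,
        marker_strength=1.8,
        donor_shift_scale=0.8,
        dispersion=0.4,
        library_size=(float(np.log(2000.0)), 0.25),
        holdout_types=1,
        seed=41,
    ),
    # parameters below are placeholders; the corpus is hand-built around the
    # documented filter boundaries (4,999/5,000 cells; 29/30 donors; <7 ancestors)
    "filter-edge": SyntheticSpec(
        n_genes=20,
        ontology_depth=8,
        ontology_branching=2,
        n_cell_types=5,
        n_donors=40,
        cells_per_donor=1,
        marker_genes_per_type=1,
        seed=53,
    ),
}


def standard_fixtures() -> dict[str, SyntheticSpec]:
    """Named, versioned preset specs; each regenerates identically."""
    return {name: replace(spec) for name, spec in _PRESETS.items()}


def _generate_filter_edge(spec: SyntheticSpec) -> SyntheticCorpus:
    """Hand-built corpus probing every corpus-filter boundary.

    Types (on a depth-8 binary-tree ontology, so leaves have 8 ancestors):

    - ``at_cells``     5,000 cells / 40 donors  -> survives (criterion 4 boundary)
    - ``below_cells``  4,999 cells / 40 donors  -> removed by criterion 4
    - ``at_donors``    5,200 cells / 30 donors  -> survives (criterion 5 boundary)
    - ``below_donors`` 5,200 cells / 29 donors  -> removed by criterion 5
    - ``shallow``      5,200 cells / 40 donors on a depth-3 term (<7
      ancestors) -> removed by criterion 6
    - ``misc``         6,000 cells / 40 donors, of which 100 are
      non-primary and 100 use a non-10x assay -> survives with 5,800 cells
    """
    rng = np.random.default_rng(spec.seed)
    graph = generate_ontology(spec)
    leaves = _leaves(graph)
    depth3 = sorted(
        t for t in graph.terms if graph.ancestor_count(t) == 3 and graph.children(t)
    )
    plan = [
        ("at_cells", leaves[0], 5000, 40),
        ("below_cells", leaves[1], 4999, 40),
        ("at_donors", leaves[2], 5200, 30),
        ("below_donors", leaves[3], 5200, 29),
        ("shallow", depth3[0], 5200, 40),
        ("misc", leaves[4], 6000, 40),
    ]
    rows = []
    for name, term, n_cells, n_donors in plan:
        donor_ids = [f"{name}-donor{j:03d}" for j in range(n_donors)]
        for i in range(n_cells):
            rows.append(
                {
                    "cell_id": f"{name}-cell{i:05d}",
                    "cell_type": term,
                    "donor_id": donor_ids[i % n_donors],
                    "assay": "10x 3' v3",
                    "dataset_id": "synthetic-dataset-filter",
                    "is_primary": True,
                    "tissue": "synthetic tissue",
                }
            )
    records = pd.DataFrame(rows)[list(RECORD_COLUMNS)]
    misc = np.flatnonzero((records["cell_id"].str.startswith("misc")).to_numpy())
    records.loc[misc[:100], "is_primary"] = False
    records.loc[misc[100:200], "assay"] = "Smart-seq2"

    counts = rng.poisson(2.0, size=(len(records), spec.n_genes)).astype(np.int64)
    matrix = CellByGeneMatrix(
        counts, np.array([f"ENSG{g:011d}" for g in range(spec.n_genes)]), "raw"
    )
    truth = SyntheticTruth(
        fine_types=records["cell_type"].to_numpy(),
        assigned_labels=records["cell_type"].to_numpy(),
        donors=records["donor_id"].to_numpy(),
        marker_genes={},
        donor_shifts={},
    )
    return SyntheticCorpus(matrix, records, truth, graph, spec)


def generate_preset(name: str) -> SyntheticCorpus:
    """Generate one of the named standard fixtures."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    spec = replace(_PRESETS[name])
    if name == "filter-edge":
        return _generate_filter_edge(spec)
    return generate_corpus(spec)
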