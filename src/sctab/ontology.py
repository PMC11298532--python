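"""Cell-type ontology handling.

The Cell Ontology (CL) is a DAG of cell-type terms linked by ``is_a``
relations.  This module loads it (OBO 1.2 flat files or OBO-Graphs JSON),
restricts it to the subtree below a chosen root (typically ``native cell``),
and provides the queries the rest of the package needs: subtype tests,
ancestor counts, information-content (IC) scores, and the fine-to-coarse
label mapping used for coarse-grained evaluation.

Conventions
-----------
Edges are stored child -> parent, so *ancestors* of a term are the nodes
reachable from it.  Only ``is_a`` edges are retained; every other relation
type present in the source file is dropped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "OntologyGraph",
    "TermStats",
    "CoarseMap",
    "load_ontology",
    "information_content",
    "build_coarse_map",
    "aggregate_predictions",
]


class OntologyError(ValueError):
    """Raised for malformed ontologies or unknown terms."""


@dataclass(frozen=True)
class TermStats:
    """Per-term summary statistics.

    ``information_content`` lives in [0, 100]; 100 marks a maximally
    specific term (no subclasses), low values mark broad terms.
    """

    term: str
    n_ancestors: int
    n_descendants: int
    information_content: float


@dataclass
class CoarseMap:
    """Fine -> coarse label assignment.

    ``mapping`` sends each observed fine term to the coarse candidate
    (IC <= ``threshold``) among its ancestors-or-self with the highest IC.
    Terms with no candidate ancestor are listed in ``unmapped``.
    """

    mapping: dict[str, str]
    threshold: float = 60.0
    unmapped: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> str:
        return self.mapping[term]

    def __contains__(self, term: str) -> bool:
        return term in self.mapping


class OntologyGraph:
    """A rooted DAG of cell-type terms with child -> parent ``is_a`` edges."""

    def __init__(self, graph: nx.DiGraph, root: str):
        if root not in graph:
            raise OntologyError(f"root term {root!r} not present in graph")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology contains a cycle through edge {cycle[0][:2]}")
        self._g = graph
        self.root = root
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], root: str, extra_terms: Iterable[str] = ()
    ) -> "OntologyGraph":
        """Build from (child, parent) ``is_a`` pairs."""
        g = nx.DiGraph()
        g.add_node(root)
        for t in extra_terms:
            g.add_node(t)
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g, root)

    def edges(self) -> list[tuple[str, str]]:
        """All (child, parent) pairs."""
        return sorted(self._g.edges())

    # -- basic accessors ---------------------------------------------------
    @property
    def terms(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_terms(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def _require(self, term: str) -> None:
        if term not in self._g:
            raise OntologyError(f"unknown ontology term: {term!r}")

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All transitive ancestors of ``term`` (term itself excluded)."""
        self._require(term)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._g, term))
            self._ancestor_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """All transitive descendants of ``term`` (term itself excluded)."""
        self._require(term)
        return frozenset(nx.ancestors(self._g, term))

    def ancestor_count(self, term: str) -> int:
        return len(self.ancestors(term))

    def descendant_count(self, term: str) -> int:
        return len(self.descendants(term))

    def is_subtype(self, a: str, b: str) -> bool:
        """True iff ``a`` equals ``b`` or is a transitive descendant of ``b``.

        A CD4-positive, alpha-beta T cell *is a* T cell; the converse is
        false.
        """
        self._require(a)
        self._require(b)
        return a == b or b in self.ancestors(a)

    def restricted_to(self, new_root: str) -> "OntologyGraph":
        """Subgraph of terms that are ``new_root`` or its descendants."""
        self._require(new_root)
        keep = set(self.descendants(new_root)) | {new_root}
        return OntologyGraph(self._g.subgraph(keep).copy(), new_root)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _graph_from_obo(path: Path) -> nx.DiGraph:
    import obonet

    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return g


def _graph_from_obographs(path: Path) -> nx.DiGraph:
    with open(path) as fh:
        doc = json.load(fh)

    def short_id(uri: str) -> str:
        # http://purl.obolibrary.org/obo/CL_0000084 -> CL:0000084
        tail = uri.rsplit("/", 1)[-1]
        return tail.replace("_", ":", 1) if "_" in tail and ":" not in tail else tail

    g = nx.DiGraph()
    for graph in doc.get("graphs", []):
        for node in graph.get("nodes", []):
            if node.get("type", "CLASS") == "CLASS":
                g.add_node(short_id(node["id"]))
        for edge in graph.get("edges", []):
            if edge.get("pred") in ("is_a", "rdfs:subClassOf"):
                sub, obj = short_id(edge["sub"]), short_id(edge["obj"])
                g.add_node(sub)
                g.add_node(obj)
                g.add_edge(sub, obj)
    return g


def load_ontology(source: str | Path, root_term: str) -> OntologyGraph:
    """Load an ontology and restrict it to ``root_term`` and its descendants.

    Parameters
    ----------
    source
        Path to an OBO 1.2 flat file (``.obo``) or an OBO-Graphs JSON file
        (``.json``).
    root_term
        Term id of the subtree root, e.g. ``CL:0000003`` (native cell).

    Only ``is_a`` edges are retained.  Raises :class:`OntologyError` on
    cyclic input or a missing root.
    """
    path = Path(source)
    if path.suffix == ".json":
        g = _graph_from_obographs(path)
    else:
        g = _graph_from_obo(path)
    if root_term not in g:
        raise OntologyError(f"root term {root_term!r} not found in {path.name}")
    full = OntologyGraph(g, root_term)
    return full.restricted_to(root_term)


# ---------------------------------------------------------------------------
# information content
# ---------------------------------------------------------------------------

def information_content(
    graph: OntologyGraph,
    override: Mapping[str, float] | None = None,
) -> dict[str, TermStats]:
    """Score every term's specificity on a [0, 100] scale.

    The default, count-based surrogate is

        IC(t) = 100 * (1 - log(1 + n_descendants(t)) / log(1 + n_terms)),

    which gives 100 to terms with no subclasses and decreases monotonically
    towards the root.  Precomputed scores (e.g. Ubergraph's) may be passed
    as ``override`` and take precedence term by term.
    """
    if graph.n_terms == 0:
        raise OntologyError("empty ontology graph")
    denom = math.log(1 + graph.n_terms)
    stats: dict[str, TermStats] = {}
    for term in graph.terms:
        n_desc = graph.descendant_count(term)
        if override is not None and term in override:
            ic = float(override[term])
        else:
            ic = 100.0 * (1.0 - math.log(1 + n_desc) / denom)
        stats[term] = TermStats(
            term=term,
            n_ancestors=graph.ancestor_count(term),
            n_descendants=n_desc,
            information_content=ic,
        )
    return stats


def build_coarse_map(
    graph: OntologyGraph,
    stats: Mapping[str, TermStats],
    observed_terms: Iterable[str],
    threshold: float = 60.0,
) -> CoarseMap:
    """Assign each observed term to a coarse label.

    Candidate coarse labels are the terms with IC <= ``threshold``.  Each
    observed term goes to the candidate among its ancestors-or-self with the
    *highest* IC (alpha-beta T cell -> T cell rather than lymphocyte); ties
    are broken by lexicographically smallest term id.  Observed terms with
    no candidate ancestor are reported in ``unmapped``.
    """
    candidates = {t for t, s in stats.items() if s.information_content <= threshold}
    if not candidates:
        raise OntologyError(
            f"no term has information content <= {threshold}; "
            "raise the threshold or supply override scores"
        )
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for term in observed_terms:
        if term not in graph:
            raise OntologyError(f"observed term {term!r} not in ontology")
        pool = ({term} | set(graph.ancestors(term))) & candidates
        if not pool:
            unmapped.append(term)
            continue
        # max IC, then lexicographic term id for determinism
        mapping[term] = min(
            pool, key=lambda t: (-stats[t].information_content, t)
        )
    return CoarseMap(mapping=mapping, threshold=threshold, unmapped=sorted(unmapped))


def aggregate_predictions(preds: Sequence[str], coarse_map: CoarseMap) -> list[str]:
    """Map fine-grained predictions element-wise to their coarse labels."""
    missing = sorted({p for p in preds if p not in coarse_map})
    if missing:
        raise OntologyError(f"terms not covered by the coarse map: {missing}")
    return [coarse_map[p] for p in preds]


# ---------------------------------------------------------------------------
# tab-delimited serialization
# ---------------------------------------------------------------------------

def write_term_stats(stats: Mapping[str, TermStats], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (s.term, s.n_ancestors, s.n_descendants, s.information_content)
            for s in stats.values()
        ],
        columns=["term_id", "n_ancestors", "n_descendants", "information_content"],
    ).sort_values("term_id").to_csv(path, sep="\t", index=False)


def read_term_stats(path: str | Path) -> dict[str, TermStats]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"term_id": str})
    return {
        r.term_id: TermStats(
            term=r.term_id,
            n_ancestors=int(r.n_ancestors),
            n_descendants=int(r.n_descendants),
            information_content=float(r.information_content),
        )
        for r in df.itertuples()
    }


def write_coarse_map(cmap: CoarseMap, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(cmap.mapping.items()), columns=["term_id", "coarse_term_id"]
    ).to_csv(path, sep="\t", index=False)


def read_coarse_map(path: str | Path, threshold: float = 60.0) -> CoarseMap:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return CoarseMap(
        mapping=dict(zip(df["term_id"], df["coarse_term_id"])), threshold=threshold
    )
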