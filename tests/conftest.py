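"""Shared fixtures.

The heavy, trained-model fixtures are session-scoped: one training run
feeds both the acceptance checks and the unit tests that inspect the
trained model (attention masks, partition invariance, ...).
"""

from __future__ import annotations

import numpy as np
import pytest

from sctab.ontology import OntologyGraph


@pytest.fixture(scope="session")
def chain_graph() -> OntologyGraph:
    """root <- A <- B <- C linear chain."""
    return OntologyGraph.from_edges(
        [("CL:A", "CL:root"), ("CL:B", "CL:A"), ("CL:C", "CL:B")], "CL:root"
    )


@pytest.fixture(scope="session")
def tcell_graph() -> OntologyGraph:
    """Miniature immune-cell DAG with real CL term ids.

    native cell <- lymphocyte <- {T cell <- {alpha-beta T cell <- CD4+/CD8+},
    B cell}; plus myeloid as an unrelated branch.
    """
    NATIVE, LYMPH, T, AB_T, CD4, CD8, B, MYELOID = (
        "CL:0000003",  # native cell
        "CL:0000542",  # lymphocyte
        "CL:0000084",  # T cell
        "CL:0000789",  # alpha-beta T cell
        "CL:0000624",  # CD4-positive, alpha-beta T cell
        "CL:0000625",  # CD8-positive, alpha-beta T cell
        "CL:0000236",  # B cell
        "CL:0000763",  # myeloid cell
    )
    edges = [
        (LYMPH, NATIVE),
        (MYELOID, NATIVE),
        (T, LYMPH),
        (B, LYMPH),
        (AB_T, T),
        (CD4, AB_T),
        (CD8, AB_T),
    ]
    return OntologyGraph.from_edges(edges, NATIVE)


@pytest.fixture(scope="session")
def diamond_graph() -> OntologyGraph:
    """root <- {P1, P2} <- leaf (two paths; shared ancestors counted once)."""
    return OntologyGraph.from_edges(
        [
            ("CL:P1", "CL:root"),
            ("CL:P2", "CL:root"),
            ("CL:leaf", "CL:P1"),
            ("CL:leaf", "CL:P2"),
        ],
        "CL:root",
    )


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Random rooted DAG: each non-root term gets 1-2 parents among the
    earlier terms, so reachability to the root is guaranteed."""
    terms = [f"CL:{i:04d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[p]))
    return OntologyGraph.from_edges(edges, terms[0])


# ---------------------------------------------------------------------------
# heavy, session-scoped experiment fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def separable_run():
    """Reduced scTab + linear baseline trained on ``separable-small``."""
    from sctab.experiments import separable_benchmark

    return separable_benchmark(seed=1, return_models=True)


@pytest.fixture(scope="session")
def augmentation_run():
    from sctab.experiments import augmentation_benchmark

    return augmentation_benchmark(seed=1, n_seeds=5)


@pytest.fixture(scope="session")
def uncertainty_run():
    from sctab.experiments import uncertainty_benchmark

    return uncertainty_benchmark(seed=1, n_ensembles=3, n_members=5)


@pytest.fixture(scope="session")
def variance_run():
    from sctab.experiments import variance_diagnostic

    return variance_diagnostic(seed=1)
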