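"""Donor-difference data augmentation.

The augmentation simulates how a cell's expression would look in another
donor: for each cell type observed in two donors, the difference of the
(normalized-expression) donor centroids is a candidate augmentation
vector.  During training a random vector is added to or subtracted from a
cell's normalized expression, extending the training domain towards unseen
donors.

Vector construction (all on the training split only):

1. subsample cells with an even distribution across cell types;
2. mean centroids per (cell type, donor);
3. all ordered donor-pair centroid differences within each cell type;
4. zero every entry in [-zero_band, zero_band] (sparsification);
5. clamp entries to [-vector_clamp, vector_clamp] (outlier removal);
6. k-means over the difference vectors; retain only vectors from clusters
   with more than ``min_cluster_size`` members (these are the cell-type
   *independent* directions), then sample ``n_vectors`` of them.

The variance diagnostic :func:`variance_r2` fits, per gene, ordinary least
squares of normalized expression on one-hot cell type + one-hot donor and
averages the per-gene R^2 — augmentation should lower it only mildly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score

__all__ = [
    "AugmentationConfig",
    "AugmentationVectorSet",
    "VarianceDecompositionResult",
    "compute_augmentation_vectors",
    "augment",
    "variance_r2",
]


@dataclass
class AugmentationConfig:
    """Parameters of the six-step vector construction.

    Defaults are the full-scale values; :meth:`scaled` shrinks the size
    parameters proportionally for toy corpora.
    """

    n_subsample: int = 500_000
    zero_band: float = 0.25
    vector_clamp: float = 1.5
    n_clusters: int = 50
    min_cluster_size: int = 2000
    n_vectors: int = 5000
    expr_clamp: tuple[float, float] = (0.0, 9.0)
    min_cells: int = 10          # centroid support per (type, donor)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zero_band >= self.vector_clamp:
            raise ValueError("zero_band must be smaller than vector_clamp")
        if self.expr_clamp[0] < 0:
            raise ValueError("expression clamp lower bound must be >= 0")

    def scaled(self, factor: float) -> "AugmentationConfig":
        """Shrink all size parameters by ``factor`` (0 < factor <= 1)."""
        return replace(
            self,
            n_subsample=max(int(self.n_subsample * factor), 100),
            min_cluster_size=max(int(self.min_cluster_size * factor), 2),
            n_vectors=max(int(self.n_vectors * factor), 10),
            n_clusters=max(int(round(self.n_clusters * factor)), 2),
        )


@dataclass
class AugmentationVectorSet:
    """Precomputed augmentation vectors plus their provenance."""

    vectors: np.ndarray                  # n_vectors x genes
    provenance: pd.DataFrame             # cell_type, donor_a, donor_b per vector
    cluster_ids: np.ndarray
    config: AugmentationConfig

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]


def compute_augmentation_vectors(
    X_norm: np.ndarray,
    records: pd.DataFrame,
    config: AugmentationConfig | None = None,
) -> AugmentationVectorSet:
    """Run the six-step construction on a normalized training corpus.

    ``X_norm`` rows must be normalized expression of the *training* split;
    ``records`` supplies ``cell_type`` and ``donor_id`` per row.
    """
    config = config or AugmentationConfig()
    rng = np.random.default_rng(config.seed)
    X_norm = np.asarray(X_norm)
    types = records["cell_type"].to_numpy(dtype=object)
    donors = records["donor_id"].to_numpy(dtype=object)

    # step 1: even subsample across cell types
    unique_types = sorted(set(types))
    quota = max(config.n_subsample // len(unique_types), 1)
    chosen: list[np.ndarray] = []
    for t in unique_types:
        idx = np.flatnonzero(types == t)
        if len(idx) >= quota:
            chosen.append(rng.choice(idx, size=quota, replace=False))
        else:
            chosen.append(rng.choice(idx, size=quota, replace=True))
    sel = np.concatenate(chosen)

    # step 2: centroids per (cell type, donor) with enough support
    sub = pd.DataFrame({"cell_type": types[sel], "donor_id": donors[sel], "row": sel})
    centroids: dict[str, dict[str, np.ndarray]] = {}
    for (t, d), grp in sub.groupby(["cell_type", "donor_id"], sort=True):
        if len(grp) >= config.min_cells:
            centroids.setdefault(t, {})[d] = X_norm[grp["row"].to_numpy()].mean(axis=0)

    # step 3: ordered donor-pair differences within each cell type
    diffs, prov = [], []
    for t in sorted(centroids):
        ds = sorted(centroids[t])
        for a in ds:
            for b in ds:
                if a != b:
                    diffs.append(centroids[t][a] - centroids[t][b])
                    prov.append((t, a, b))
    if not diffs:
        raise ValueError(
            "no cell type is observed in two donors with enough cells; "
            "cannot compute augmentation vectors"
        )
    D = np.asarray(diffs)

    # steps 4-5: band-zeroing then clamping
    D[np.abs(D) <= config.zero_band] = 0.0
    np.clip(D, -config.vector_clamp, config.vector_clamp, out=D)

    # step 6: keep vectors from prominent k-means clusters only
    n_clusters = min(config.n_clusters, len(D))
    km = KMeans(
        n_clusters=n_clusters,
        n_init=10,
        tol=1e-4,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(D)
    sizes = np.bincount(km.labels_, minlength=n_clusters)
    keep_clusters = np.flatnonzero(sizes > config.min_cluster_size)
    if len(keep_clusters) == 0:
        raise ValueError(
            f"no k-means cluster exceeds min_cluster_size={config.min_cluster_size}; "
            "reduce the threshold (e.g. via AugmentationConfig.scaled)"
        )
    pool = np.flatnonzero(np.isin(km.labels_, keep_clusters))
    k = min(config.n_vectors, len(pool))
    picked = np.sort(rng.choice(pool, size=k, replace=False))

    return AugmentationVectorSet(
        vectors=D[picked],
        provenance=pd.DataFrame(
            [prov[i] for i in picked], columns=["cell_type", "donor_a", "donor_b"]
        ),
        cluster_ids=km.labels_[picked],
        config=config,
    )


def augment(
    x: np.ndarray,
    vectors: AugmentationVectorSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one random signed augmentation vector per observation.

    ``x`` is normalized expression (a row or a batch).  The result is
    clamped to the expression interval (default [0, 9]), preserving
    non-negativity.  Training-time only; never applied at evaluation.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != vectors.vectors.shape[1]:
        raise ValueError(
            f"gene dimension mismatch: batch has {x.shape[1]}, "
            f"vectors have {vectors.vectors.shape[1]}"
        )
    idx = rng.integers(vectors.n_vectors, size=x.shape[0])
    sign = rng.choice([-1.0, 1.0], size=x.shape[0])
    lo, hi = vectors.config.expr_clamp
    return np.clip(x + sign[:, None] * vectors.vectors[idx], lo, hi)


@dataclass
class VarianceDecompositionResult:
    """Average per-gene R^2 of expression ~ 1 + cell type + donor."""

    r2: float
    design: str = "intercept + onehot(cell_type) + onehot(donor), drop-first"


def variance_r2(
    X_norm: np.ndarray,
    records: pd.DataFrame,
) -> VarianceDecompositionResult:
    """How much expression variance cell type and donor explain.

    Ordinary least squares of every gene's normalized expression on
    intercept + one-hot(cell type) + one-hot(donor); the score is the
    uniform average over genes of per-gene R^2.  Drop-first encoding keeps
    the design non-singular.
    """
    types = pd.Categorical(records["cell_type"])
    donors = pd.Categorical(records["donor_id"])
    if len(types.categories) < 2 or len(donors.categories) < 2:
        raise ValueError("need at least 2 cell types and 2 donors")
    design = np.hstack(
        [
            pd.get_dummies(types, drop_first=True).to_numpy(dtype=np.float64),
            pd.get_dummies(donors, drop_first=True).to_numpy(dtype=np.float64),
        ]
    )
    fit = LinearRegression().fit(design, np.asarray(X_norm))
    pred = fit.predict(design)
    r2 = float(r2_score(np.asarray(X_norm), pred, multioutput="uniform_average"))
    return VarianceDecompositionResult(r2=r2)
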