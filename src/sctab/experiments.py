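"""Canonical benchmark protocols on the standard synthetic fixtures.

Each function runs one self-contained experiment end-to-end — generate the
preset corpus, split by donor, train, measure — and returns a flat dict of
numbers.  The test suite and the reproduction script both call these, so
the measured quantities are always produced by the same code path.

Problem sizes are deliberately small (hundreds to thousands of cells, a
reduced-width classifier) so that every protocol runs in minutes on one
CPU; the corresponding full-scale defaults live in the config classes.
"""

from __future__ import annotations

import numpy as np

from sctab.augmentation import (
    AugmentationConfig,
    augment,
    compute_augmentation_vectors,
    variance_r2,
)
from sctab.corpus import FilterParams, donor_split, filter_corpus, normalize_rows
from sctab.evaluation import ontology_macro_f1
from sctab.model import LinearConfig, LinearModel, ScTabConfig, ScTabModel
from sctab.synthetic import generate_preset
from sctab.uncertainty import (
    G1,
    G2,
    G3,
    assign_groups,
    ensemble_predict,
    separation_rocauc,
)

__all__ = [
    "separable_benchmark",
    "augmentation_benchmark",
    "variance_diagnostic",
    "uncertainty_benchmark",
    "filter_boundary_check",
]

#: reduced classifier for toy corpora (full-scale: n_d=128, n_a=64)
REDUCED_SCTAB = dict(n_d=32, n_a=16, max_epochs=10, patience=4, batch_size=512)
SMALL_SCTAB = dict(
    n_d=16, n_a=8, max_epochs=25, patience=25, batch_size=256, virtual_batch_size=128
)
#: augmentation-vector construction scaled to thousands of training cells
TOY_AUG = dict(n_subsample=2000, n_clusters=8, min_cluster_size=20, n_vectors=200)


def separable_benchmark(seed: int = 1, return_models: bool = False) -> dict[str, object]:
    """Held-out-donor parameter recovery on the ``separable-small`` preset.

    Trains a reduced-width scTab and the linear baseline on the train
    donors and reports ontology-corrected macro F1 on the test donors.
    """
    c = generate_preset("separable-small")
    split = donor_split(sorted(set(c.records["donor_id"])), seed=seed)
    te = split.cell_indices(c.records, "test")
    truth = c.records["cell_type"].to_numpy()[te]

    sctab = ScTabModel.from_split(
        c.matrix, c.records, split, config=ScTabConfig(**REDUCED_SCTAB)
    ).fit(seed=seed)
    f1_sctab = ontology_macro_f1(
        sctab.predict(c.matrix.subset(te)), truth, c.graph
    ).macro_f1

    linear = LinearModel.from_split(
        c.matrix, c.records, split,
        config=LinearConfig(max_epochs=40, patience=8, batch_size=512),
    ).fit(seed=seed)
    f1_linear = ontology_macro_f1(
        linear.predict(c.matrix.subset(te)), truth, c.graph
    ).macro_f1
    out: dict[str, object] = {
        "sctab_macro_f1": f1_sctab,
        "linear_macro_f1": f1_linear,
        "n_test_cells": int(len(te)),
    }
    if return_models:
        out.update(corpus=c, split=split, sctab=sctab, linear=linear)
    return out


def augmentation_benchmark(seed: int = 1, n_seeds: int = 5) -> dict[str, object]:
    """Does donor-difference augmentation improve held-out-donor F1?

    On the ``donor-shift`` preset, scTab is trained with and without
    augmentation under ``n_seeds`` paired seeds.  Reports the per-seed F1
    pairs, the win rate, and the mean training loss of both arms (the
    augmented arm trains at a higher loss — the regularization signature).
    """
    c = generate_preset("donor-shift")
    split = donor_split(sorted(set(c.records["donor_id"])), seed=seed)
    tr = split.cell_indices(c.records, "train")
    te = split.cell_indices(c.records, "test")
    truth = c.records["cell_type"].to_numpy()[te]
    Xn = normalize_rows(c.matrix.dense()).astype(np.float32)
    vecs = compute_augmentation_vectors(
        Xn[tr],
        c.records.iloc[tr].reset_index(drop=True),
        AugmentationConfig(**TOY_AUG, seed=seed),
    )
    f1_with, f1_without, loss_with, loss_without = [], [], [], []
    for k in range(n_seeds):
        run_seed = seed + 1000 * k
        for use_aug in (False, True):
            cfg = ScTabConfig(**SMALL_SCTAB, augment_training_data=use_aug)
            model = ScTabModel.from_split(
                c.matrix, c.records, split, config=cfg,
                augmentation=vecs if use_aug else None,
            )
            res = model.fit(seed=run_seed)
            f1 = ontology_macro_f1(
                res.predict(c.matrix.subset(te)), truth, c.graph
            ).macro_f1
            (f1_with if use_aug else f1_without).append(f1)
            (loss_with if use_aug else loss_without).append(
                float(res.history["train_loss"].mean())
            )
    wins = sum(w > wo for w, wo in zip(f1_with, f1_without))
    return {
        "f1_with": f1_with,
        "f1_without": f1_without,
        "win_rate": wins / n_seeds,
        "mean_f1_with": float(np.mean(f1_with)),
        "mean_f1_without": float(np.mean(f1_without)),
        "mean_train_loss_with": float(np.mean(loss_with)),
        "mean_train_loss_without": float(np.mean(loss_without)),
        "n_vectors": vecs.n_vectors,
    }


def variance_diagnostic(seed: int = 1) -> dict[str, float]:
    """Variance decomposition R^2 before and after augmentation.

    Includes a noiseless control corpus whose expression is an exact
    function of (cell type, donor) — its R^2 must be 1 — and the
    ``donor-shift`` preset, where augmentation lowers R^2 because the added
    vectors are not attributable to the true type/donor labels.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    # noiseless control: x = mu_type + delta_donor exactly
    n_types, n_donors, n_genes, reps = 4, 6, 50, 25
    mus = rng.normal(1.5, 0.5, size=(n_types, n_genes))
    deltas = rng.normal(0.0, 0.3, size=(n_donors, n_genes))
    rows, meta = [], []
    for t in range(n_types):
        for d in range(n_donors):
            for _ in range(reps):
                rows.append(mus[t] + deltas[d])
                meta.append({"cell_type": f"T{t}", "donor_id": f"D{d}"})
    r2_noiseless = variance_r2(np.asarray(rows), pd.DataFrame(meta)).r2

    c = generate_preset("donor-shift")
    split = donor_split(sorted(set(c.records["donor_id"])), seed=seed)
    tr = split.cell_indices(c.records, "train")
    Xn = normalize_rows(c.matrix.dense()[tr])
    rec = c.records.iloc[tr].reset_index(drop=True)
    r2_raw = variance_r2(Xn, rec).r2
    vecs = compute_augmentation_vectors(
        Xn.astype(np.float32), rec, AugmentationConfig(**TOY_AUG, seed=seed)
    )
    r2_aug = variance_r2(augment(Xn, vecs, rng), rec).r2
    return {
        "r2_noiseless": r2_noiseless,
        "r2_raw": r2_raw,
        "r2_augmented": r2_aug,
    }


def uncertainty_benchmark(
    seed: int = 1, n_ensembles: int = 3, n_members: int = 5
) -> dict[str, object]:
    """Deep-ensemble uncertainty separation on the ``holdout-type`` preset.

    One cell type is excluded from the training label universe.  Per
    ensemble: ``n_members`` scTab replicas differing only in seed are
    trained; test cells are split into Group 1 (correct), Group 2
    (incorrect, trained type) and Group 3 (type absent from training);
    ROC-AUC of the uncertainty score separates G2 and G3 from G1.
    """
    c = generate_preset("holdout-type")
    holdout = list(c.truth.holdout_types)
    split = donor_split(sorted(set(c.records["donor_id"])), seed=seed)
    labels = c.records["cell_type"].to_numpy()
    tr = split.cell_indices(c.records, "train")
    va = split.cell_indices(c.records, "val")
    te = split.cell_indices(c.records, "test")
    tr_keep = tr[~np.isin(labels[tr], holdout)]
    va_keep = va[~np.isin(labels[va], holdout)]
    auc_g2, auc_g3 = [], []
    for e in range(n_ensembles):
        members = []
        for k in range(n_members):
            cfg = ScTabConfig(**{**SMALL_SCTAB, "max_epochs": 18, "patience": 18})
            model = ScTabModel(
                c.matrix.subset(tr_keep),
                c.records.iloc[tr_keep].reset_index(drop=True),
                c.matrix.subset(va_keep),
                c.records.iloc[va_keep].reset_index(drop=True),
                config=cfg,
            )
            members.append(model.fit(seed=seed + 1000 * e + k))
        ens = ensemble_predict(members, c.matrix.subset(te))
        groups = assign_groups(
            ens.labels, labels[te], c.graph, members[0].classes_
        )
        auc_g2.append(separation_rocauc(ens.uncertainty, groups, G2))
        auc_g3.append(separation_rocauc(ens.uncertainty, groups, G3))
    return {
        "rocauc_g1_vs_g2": auc_g2,
        "rocauc_g1_vs_g3": auc_g3,
        "min_rocauc_g1_vs_g2": float(min(auc_g2)),
        "min_rocauc_g1_vs_g3": float(min(auc_g3)),
    }


def filter_boundary_check() -> dict[str, object]:
    """Exercise the corpus filters on the ``filter-edge`` preset.

    The preset plants types exactly at and just below the cell-count,
    donor-count, and ontology-depth thresholds; the check reports which
    boundary types survive.
    """
    c = generate_preset("filter-edge")
    _, records, report = filter_corpus(
        c.matrix, c.records, c.graph, FilterParams()
    )
    survivors = set(report.surviving_cell_types)
    plan = {
        "at_cells": True,       # exactly 5,000 cells
        "below_cells": False,   # 4,999 cells
        "at_donors": True,      # exactly 30 donors
        "below_donors": False,  # 29 donors
        "shallow": False,       # 3 ontology ancestors
        "misc": True,
    }
    type_of = dict(
        zip(
            c.records["cell_id"].str.rsplit("-", n=1).str[0],
            c.records["cell_type"],
        )
    )
    outcome = {name: (type_of[name] in survivors) for name in plan}
    return {
        "as_designed": outcome == plan,
        "outcome": outcome,
        "surviving_cells": report.surviving_cells,
        "removed": dict(report.removed),
    }
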