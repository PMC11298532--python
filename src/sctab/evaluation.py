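"""Ontology-corrected classification metrics.

Author annotations differ in granularity, so exact label matching is the
wrong scoring rule.  A prediction is *right* if it equals the annotated
term or is a subtype of it (predicting "CD4-positive, alpha-beta T cell"
for a cell annotated "T cell" is right); predicting an *ancestor* of the
annotation is wrong (predicting "T cell" for a "CD4-positive, alpha-beta
T cell" loses information the author supplied), as is any unrelated term.

Confusion bookkeeping: a right prediction is credited to the truth class
(tp for the truth term); a wrong prediction is a false positive for the
predicted term and a false negative for the truth term.  Per-class
F1 = 2tp / (2tp + fp + fn) with 0/0 -> 0; the macro F1 is the unweighted
mean over classes with support in the truth set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from sctab.ontology import CoarseMap, OntologyGraph, aggregate_predictions

__all__ = [
    "EvaluationReport",
    "ontology_correct",
    "ontology_macro_f1",
    "grouped_macro_f1",
    "coarse_evaluate",
    "signature_separation",
]


@dataclass
class EvaluationReport:
    """Per-class precision/recall/F1 plus the macro F1."""

    per_class: pd.DataFrame     # index: cell type; columns: precision, recall, f1, support
    macro_f1: float
    grouping: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.per_class


def ontology_correct(pred: str, truth: str, graph: OntologyGraph) -> bool:
    """Right iff ``pred`` equals ``truth`` or is a subtype of it."""
    return graph.is_subtype(pred, truth)


def ontology_macro_f1(
    preds: Sequence[str],
    truths: Sequence[str],
    graph: OntologyGraph,
) -> EvaluationReport:
    preds = list(preds)
    truths = list(truths)
    if not preds or len(preds) != len(truths):
        raise ValueError("predictions and truths must be equally long and non-empty")
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    support: dict[str, int] = {}
    # cache subtype decisions per (pred, truth) pair
    verdict: dict[tuple[str, str], bool] = {}
    for p, t in zip(preds, truths):
        support[t] = support.get(t, 0) + 1
        key = (p, t)
        ok = verdict.get(key)
        if ok is None:
            ok = verdict[key] = ontology_correct(p, t, graph)
        if ok:
            tp[t] = tp.get(t, 0) + 1
        else:
            fp[p] = fp.get(p, 0) + 1
            fn[t] = fn.get(t, 0) + 1
    classes = sorted(support)
    rows = []
    for c in classes:
        tpc, fpc, fnc = tp.get(c, 0), fp.get(c, 0), fn.get(c, 0)
        prec = tpc / (tpc + fpc) if tpc + fpc else 0.0
        rec = tpc / (tpc + fnc) if tpc + fnc else 0.0
        f1 = 2 * tpc / (2 * tpc + fpc + fnc) if 2 * tpc + fpc + fnc else 0.0
        rows.append(
            {"cell_type": c, "precision": prec, "recall": rec, "f1": f1,
             "support": support[c]}
        )
    per_class = pd.DataFrame(rows).set_index("cell_type")
    return EvaluationReport(
        per_class=per_class, macro_f1=float(per_class["f1"].mean())
    )


def grouped_macro_f1(
    preds: Sequence[str],
    truths: Sequence[str],
    graph: OntologyGraph,
    group_labels: Sequence[str],
) -> dict[str, float]:
    """Macro F1 recomputed within each group (tissue, assay, organ, ...)."""
    preds = np.asarray(list(preds), dtype=object)
    truths = np.asarray(list(truths), dtype=object)
    groups = np.asarray(list(group_labels), dtype=object)
    if not (len(preds) == len(truths) == len(groups)):
        raise ValueError("group labels must align with predictions")
    out: dict[str, float] = {}
    for g in sorted(set(groups)):
        m = groups == g
        if not m.any():
            continue
        out[g] = ontology_macro_f1(preds[m], truths[m], graph).macro_f1
    return out


def coarse_evaluate(
    preds: Sequence[str],
    truths: Sequence[str],
    coarse_map: CoarseMap,
    graph: OntologyGraph,
) -> EvaluationReport:
    """Evaluate after mapping both predictions and truths to coarse labels.

    All predictions of subtypes of a coarse term count as predicting that
    term, so sibling confusions below one coarse parent become correct.
    """
    return ontology_macro_f1(
        aggregate_predictions(list(preds), coarse_map),
        aggregate_predictions(list(truths), coarse_map),
        graph,
    )


def signature_separation(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_test: np.ndarray,
    y_test: Sequence[str],
    gene_ids: Sequence[str],
    gene_subset: Sequence[str],
    target_type: str,
) -> tuple[float, float]:
    """How well a gene signature separates one cell type from the rest.

    A one-vs-rest logistic regression is fitted on the training cells
    restricted to ``gene_subset`` and scored by the area under the
    precision-recall curve (AUPRC) on both splits; a small train-test gap
    means the signature generalizes.
    """
    gene_ids = np.asarray(list(gene_ids), dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in gene_subset if g not in pos]
    if missing:
        raise ValueError(f"genes not in vocabulary: {missing[:5]}")
    cols = np.array([pos[g] for g in gene_subset])
    y_tr = np.asarray(list(y_train), dtype=object) == target_type
    y_te = np.asarray(list(y_test), dtype=object) == target_type
    if not y_tr.any() or not y_te.any():
        raise ValueError(f"target type {target_type!r} absent from a split")
    clf = LogisticRegression(max_iter=2000)
    clf.fit(np.asarray(X_train)[:, cols], y_tr)
    auprc_train = float(
        average_precision_score(y_tr, clf.predict_proba(np.asarray(X_train)[:, cols])[:, 1])
    )
    auprc_test = float(
        average_precision_score(y_te, clf.predict_proba(np.asarray(X_test)[:, cols])[:, 1])
    )
    return auprc_train, auprc_test
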