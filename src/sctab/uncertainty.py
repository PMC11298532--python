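"""Deep-ensemble uncertainty quantification.

Prediction uncertainty is ``1 - max(p)`` where ``p`` is the class
probability vector averaged over an ensemble of independently initialized
and trained replicas.  To judge the scores, test cells are split into
three groups: correct predictions (Group 1, the reference), incorrect
predictions on trained cell types (Group 2), and cells whose type is
absent from the training label universe (Group 3, out-of-distribution).
Separation of Group 2 or 3 from Group 1 by the uncertainty score is
summarized as a ROC-AUC: 0.5 means no separation, 1.0 perfect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from sctab.corpus import CellByGeneMatrix
from sctab.evaluation import ontology_correct
from sctab.model import FitResults
from sctab.ontology import OntologyGraph

__all__ = [
    "EnsemblePrediction",
    "GroupAssignment",
    "ensemble_predict",
    "assign_groups",
    "separation_rocauc",
]

G1, G2, G3 = "G1_correct", "G2_incorrect", "G3_absent"


@dataclass
class EnsemblePrediction:
    """Averaged member probabilities and the derived uncertainty."""

    mean_probs: np.ndarray       # cells x classes
    classes_: np.ndarray
    member_count: int

    @property
    def uncertainty(self) -> np.ndarray:
        return 1.0 - self.mean_probs.max(axis=1)

    @property
    def labels(self) -> np.ndarray:
        return self.classes_[np.argmax(self.mean_probs, axis=1)]


@dataclass
class GroupAssignment:
    """Exhaustive, disjoint per-cell group labels."""

    groups: np.ndarray           # entries in {G1, G2, G3}

    def mask(self, name: str) -> np.ndarray:
        return self.groups == name


def ensemble_predict(
    members: Sequence[FitResults],
    matrix: CellByGeneMatrix,
) -> EnsemblePrediction:
    """Average per-member softmax probabilities (arithmetic mean)."""
    if not members:
        raise ValueError("empty ensemble")
    ref = members[0].classes_
    for m in members[1:]:
        if not np.array_equal(m.classes_, ref):
            raise ValueError("ensemble members disagree on the class set")
    probs = np.mean([m.predict_proba(matrix) for m in members], axis=0)
    return EnsemblePrediction(
        mean_probs=probs, classes_=ref, member_count=len(members)
    )


def assign_groups(
    preds: Sequence[str],
    truths: Sequence[str],
    graph: OntologyGraph,
    training_label_set: Sequence[str],
    exclude_subtypes_of_trained: bool = True,
) -> GroupAssignment:
    """Split cells into correct / incorrect / absent-from-training.

    A cell is Group 3 when its true type is not in the training label set
    — and, by default, also not a subtype of any trained label, since the
    ontology-corrected metric could still score such cells as correct.
    Group 3 membership depends only on the training label universe, never
    on the predictions.  Remaining cells are Group 1 if the
    ontology-corrected verdict is right, Group 2 otherwise.
    """
    trained = set(training_label_set)
    preds = list(preds)
    truths = list(truths)
    out = np.empty(len(truths), dtype=object)
    absent_cache: dict[str, bool] = {}
    for i, (p, t) in enumerate(zip(preds, truths)):
        absent = absent_cache.get(t)
        if absent is None:
            absent = t not in trained
            if absent and exclude_subtypes_of_trained:
                absent = not any(graph.is_subtype(t, lab) for lab in trained)
            absent_cache[t] = absent
        if absent:
            out[i] = G3
        elif ontology_correct(p, t, graph):
            out[i] = G1
        else:
            out[i] = G2
    return GroupAssignment(groups=out)


def separation_rocauc(
    uncertainty: np.ndarray,
    groups: GroupAssignment,
    positive: str,
) -> float:
    """ROC-AUC of the uncertainty score for ``positive`` (G2 or G3) vs G1.

    Invariant to strictly monotone transforms of the score; equals the
    Mann-Whitney U statistic normalized by the product of group sizes.
    """
    if positive not in (G2, G3):
        raise ValueError(f"positive must be {G2!r} or {G3!r}")
    u = np.asarray(uncertainty, dtype=float)
    pos = groups.mask(positive)
    ref = groups.mask(G1)
    if not pos.any() or not ref.any():
        raise ValueError(f"need non-empty {positive} and {G1} groups")
    sel = pos | ref
    return float(roc_auc_score(pos[sel], u[sel]))
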