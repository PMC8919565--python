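"""Majority vote and closed-form ensemble probability.

The per-family prediction is the mode of the three base classifiers'
binary labels (with three voters there is never a tie).  The ensemble
probability is the chance that at least two of three independent
Bernoulli(p_i) classifiers fire:

    Pr = p1 p2 p3 + p1 p2 q3 + p1 q2 p3 + q1 p2 p3,   q_i = 1 - p_i

It is high iff at least two of the p_i are high, mirroring the vote.
Membership in the predicted set is decided by the vote; the probability
is kept as the ranking/ROC score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from famvote.features import FeatureVector
from famvote.models import FamilyClassifierTrio, classifier_probability


def vote(c1: bool, c2: bool, c3: bool) -> bool:
    """Majority (plurality) vote of three binary labels."""
    return (int(c1) + int(c2) + int(c3)) >= 2


def ensemble_probability(p1: float, p2: float, p3: float) -> float:
    """Probability that >= 2 of 3 independent Bernoulli(p_i) fire."""
    for p in (p1, p2, p3):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
    q1, q2, q3 = 1.0 - p1, 1.0 - p2, 1.0 - p3
    return p1 * p2 * p3 + p1 * p2 * q3 + p1 * q2 * p3 + q1 * p2 * p3


@dataclass(frozen=True)
class EnsemblePrediction:
    family: str
    votes: tuple[bool, bool, bool]
    y_hat: bool
    p: tuple[float, float, float]
    pr_ensemble: float


@dataclass
class PredictionSet:
    """Per-sequence set of positively voted families with their scores."""

    sequence_id: str
    predictions: list[EnsemblePrediction]  # all families, for ROC scoring

    @property
    def predicted(self) -> list[EnsemblePrediction]:
        pos = [p for p in self.predictions if p.y_hat]
        return sorted(pos, key=lambda p: (-p.pr_ensemble, p.family))

    @property
    def predicted_families(self) -> set[str]:
        return {p.family for p in self.predictions if p.y_hat}

    @property
    def pred_count(self) -> int:
        return len(self.predicted_families)

    def score_for(self, family: str) -> float:
        for p in self.predictions:
            if p.family == family:
                return p.pr_ensemble
        raise KeyError(family)


def predict_families(
    v: FeatureVector, trios: Sequence[FamilyClassifierTrio]
) -> PredictionSet:
    """Run every family's trio on one feature vector."""
    preds: list[EnsemblePrediction] = []
    for trio in trios:
        ps, ds = classifier_probability(trio, v)
        votes = tuple(bool(d > 0) for d in ds)
        preds.append(
            EnsemblePrediction(
                family=trio.family,
                votes=votes,
                y_hat=vote(*votes),
                p=tuple(float(p) for p in ps),
                pr_ensemble=ensemble_probability(*ps),
            )
        )
    return PredictionSet(v.sequence_id, preds)


def propagate_hierarchy(
    leaf_predictions: PredictionSet,
    hierarchy: Mapping[str, tuple[str, str]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Bottom-up propagation: union of parents, max probability.

    Returns (parent_level, grandparent_level) maps of id -> score.
    """
    parents: dict[str, float] = {}
    grandparents: dict[str, float] = {}
    for pred in leaf_predictions.predicted:
        if pred.family not in hierarchy:
            raise ValueError(f"leaf {pred.family!r} missing from hierarchy")
        parent, grandparent = hierarchy[pred.family]
        parents[parent] = max(parents.get(parent, 0.0), pred.pr_ensemble)
        grandparents[grandparent] = max(
            grandparents.get(grandparent, 0.0), pred.pr_ensemble
        )
    return parents, grandparents


def write_predictions(prediction_sets: Sequence[PredictionSet], path: str | Path) -> None:
    """TSV: sequence_id, predCount, semicolon-joined family:pr pairs."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tpredCount\tpredictions\n")
        for ps in prediction_sets:
            pairs = ";".join(
                f"{p.family}:{p.pr_ensemble:.6f}" for p in ps.predicted
            )
            fh.write(f"{ps.sequence_id}\t{ps.pred_count}\t{pairs}\n")
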