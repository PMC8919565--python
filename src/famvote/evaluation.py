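"""Evaluation protocols: identity binning, predCount accuracy, ROC/AUC.

Three protocols are implemented:

* identity to the training set — each test sequence is aligned against
  all training sequences plus the profile seed sequences; the identity
  of the best-bit hit is kept only when the alignment spans at least
  ``min_aln_len`` residues (default 100), otherwise the sequence is
  left unassigned.  Identity bins are half-open: (0,30], (30,40],
  (40,70], (70,100].
* predCount-stratified accuracy — a sequence counts as correct when
  its true family is among the predicted set; with ``discard_over``
  set (hierarchical-data mode), any prediction set larger than the
  cutoff counts as wrong regardless of content.
* per-family ROC/AUC over the ensemble probability, including the
  novel-family protocol where each family's positives are pooled with
  sequences from families never used in training (all of which should
  be scored low).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from famvote.ensemble import PredictionSet, predict_families
from famvote.features import FeatureVector
from famvote.homology import ScoringParams, _make_aligner, smith_waterman
from famvote.models import FamilyClassifierTrio
from famvote.seqio import NOVEL, LabeledSequence

IDENTITY_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 30.0),
    (30.0, 40.0),
    (40.0, 70.0),
    (70.0, 100.0),
)
UNASSIGNED = "unassigned"

PREDCOUNT_BINS = ("1", "2", "3", "4", "5", ">5", "0")


def identity_bin_label(identity: float | None) -> str:
    """Half-open bin label (lo, hi] for a percent identity, or unassigned."""
    if identity is None:
        return UNASSIGNED
    for lo, hi in IDENTITY_BINS:
        if lo < identity <= hi:
            return f"({lo:g},{hi:g}]"
    return UNASSIGNED


def identity_to_training(
    test_seq: LabeledSequence,
    training_seqs: Sequence[LabeledSequence],
    seed_seqs: Sequence[LabeledSequence] = (),
    min_aln_len: int = 100,
    params: ScoringParams | None = None,
) -> float | None:
    """Identity of the best-bit alignment spanning >= min_aln_len columns.

    Mirrors the train/test homology protocol: the test sequence is
    aligned against every training and seed sequence, the best hit by
    bit-score among alignments of qualifying length supplies the
    identity; None when no alignment qualifies.
    """
    pool = list(training_seqs) + list(seed_seqs)
    if not pool:
        raise ValueError("empty training/seed collections")
    params = params or ScoringParams()
    aligner = _make_aligner(params)
    # score-only pass first, then full alignments in descending score
    # order until one satisfies the length rule
    scored = []
    for ref in pool:
        s = aligner.score(test_seq.residues, ref.residues)
        if s > 0:
            scored.append((s, ref.id, ref))
    scored.sort(key=lambda t: (-t[0], t[1]))
    for _, _, ref in scored:
        hit = smith_waterman(test_seq, ref, params, _aligner=aligner)
        if hit is not None and hit.aln_length >= min_aln_len:
            return hit.identity_pct
    return None


def predcount_bin(n: int) -> str:
    if n == 0:
        return "0"
    return str(n) if n <= 5 else ">5"


@dataclass
class EvaluationReport:
    """Accuracy tables plus per-family ROC results."""

    overall_accuracy: float
    n_sequences: int
    by_predcount: dict[str, tuple[int, int]]  # bin -> (correct, total)
    by_identity: dict[str, tuple[int, int]]  # bin -> (correct, total)
    by_predcount_identity: dict[tuple[str, str], tuple[int, int]]
    per_family_auc: dict[str, float] = field(default_factory=dict)

    def accuracy(self, table: str, key) -> float | None:
        counts = getattr(self, table)[key]
        return counts[0] / counts[1] if counts[1] else None


def accuracy_by_predcount(
    predictions: Sequence[PredictionSet],
    truth: Mapping[str, str],
    identity_bins: Mapping[str, str] | None = None,
    discard_over: int | None = None,
) -> EvaluationReport:
    """predCount- and identity-binned accuracy.

    A sequence is correct iff its true family is in its predicted set;
    sets larger than ``discard_over`` (when set) count as wrong.
    """
    by_pc: dict[str, list[int]] = {}
    by_id: dict[str, list[int]] = {}
    by_both: dict[tuple[str, str], list[int]] = {}
    n_correct = 0
    for ps in predictions:
        if ps.sequence_id not in truth:
            raise ValueError(f"no truth label for {ps.sequence_id!r}")
        true_fam = truth[ps.sequence_id]
        predicted = ps.predicted_families
        if true_fam == NOVEL:
            correct = not predicted
        else:
            correct = true_fam in predicted
        if discard_over is not None and ps.pred_count > discard_over:
            correct = False
        pc = predcount_bin(ps.pred_count)
        ib = (identity_bins or {}).get(ps.sequence_id, UNASSIGNED)
        for table, key in ((by_pc, pc), (by_id, ib)):
            cell = table.setdefault(key, [0, 0])
            cell[0] += int(correct)
            cell[1] += 1
        cell = by_both.setdefault((pc, ib), [0, 0])
        cell[0] += int(correct)
        cell[1] += 1
        n_correct += int(correct)
    n = len(predictions)
    return EvaluationReport(
        overall_accuracy=n_correct / n if n else float("nan"),
        n_sequences=n,
        by_predcount={k: tuple(v) for k, v in by_pc.items()},
        by_identity={k: tuple(v) for k, v in by_id.items()},
        by_predcount_identity={k: tuple(v) for k, v in by_both.items()},
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC sweep over unique score thresholds and trapezoidal AUC.

    Ties are grouped into one threshold step, so the AUC equals the
    Mann–Whitney concordance probability with half credit for ties.
    Raises on single-class labels.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0 or len(np.unique(y)) < 2:
        raise ValueError("roc_auc needs both positive and negative labels")
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    curve = [(float(t), float(tp), float(fp)) for t, tp, fp in zip(thresholds, tpr, fpr)]
    return curve, auc


def per_family_auc(
    predictions: Sequence[PredictionSet], truth: Mapping[str, str], families: Sequence[str]
) -> dict[str, float]:
    """One-vs-rest AUC of each family's ensemble probability."""
    out: dict[str, float] = {}
    for fam in families:
        scores = [ps.score_for(fam) for ps in predictions]
        labels = [int(truth[ps.sequence_id] == fam) for ps in predictions]
        if len(set(labels)) < 2:
            warnings.warn(f"family {fam!r} has a single class; AUC skipped")
            continue
        _, auc = roc_auc(scores, labels)
        out[fam] = auc
    return out


def novel_family_eval(
    novel_vectors: Sequence[FeatureVector],
    positive_vectors_by_family: Mapping[str, Sequence[FeatureVector]],
    trios: Sequence[FamilyClassifierTrio],
) -> dict[str, float]:
    """Per-family AUC with novel-family sequences as the negative pool.

    For each trained family, its positive test sequences are pooled
    with all sequences from families never used in training; a good
    model scores every novel sequence low, giving AUC near 1.
    """
    if not novel_vectors:
        raise ValueError("novel set is empty")
    trio_by_family = {t.family: t for t in trios}
    out: dict[str, float] = {}
    for fam, trio in sorted(trio_by_family.items()):
        positives = list(positive_vectors_by_family.get(fam, ()))
        if not positives:
            warnings.warn(f"family {fam!r} has no positive test sequences; skipped")
            continue
        scores, labels = [], []
        for v in positives:
            ps = predict_families(v, [trio])
            scores.append(ps.score_for(fam))
            labels.append(1)
        for v in novel_vectors:
            ps = predict_families(v, [trio])
            scores.append(ps.score_for(fam))
            labels.append(0)
        _, auc = roc_auc(scores, labels)
        out[fam] = auc
    return out
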