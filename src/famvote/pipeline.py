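"""End-to-end glue: featurize a dataset, train all trios, predict, score.

This is the programmatic counterpart of the command-line workflow
(simulate -> featurize -> train -> predict -> evaluate) used by the
benchmark runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from famvote import evaluation, features, homology, models, profiles
from famvote.ensemble import PredictionSet, predict_families
from famvote.seqio import FamilyDataset, LabeledSequence, make_folds


@dataclass
class FeatureContext:
    """Everything needed to turn a raw sequence into a feature vector."""

    db: homology.ReferenceDB
    profile_models: list[profiles.ProfileModel]
    family_order: list[str]

    @property
    def profile_order(self) -> list[str]:
        return [p.profile_id for p in self.profile_models]

    def featurize(self, seq: LabeledSequence) -> features.FeatureVector:
        fam_hits = homology.search_reference_db(seq, self.db)
        prof_hits = {
            p.profile_id: profiles.score_profile(seq, p) for p in self.profile_models
        }
        return features.assemble(
            seq.id, fam_hits, prof_hits, self.family_order, self.profile_order
        )

    def featurize_all(
        self, seqs: Sequence[LabeledSequence]
    ) -> list[features.FeatureVector]:
        return [self.featurize(s) for s in seqs]


def build_feature_context(
    training: FamilyDataset,
    seed_alignments: Mapping[str, Sequence[str]],
    n_ref: int = 10,
    seed: int = 0,
    params: homology.ScoringParams | None = None,
    calibrate: bool = True,
    n_shuffles: int = 200,
) -> FeatureContext:
    """Reference DB from the training split + calibrated profiles."""
    db = homology.build_reference_db(training, n_ref=n_ref, seed=seed, params=params)
    profile_models = []
    for i, name in enumerate(sorted(seed_alignments)):
        prof = profiles.build_profile(seed_alignments[name], profile_id=name)
        if calibrate:
            prof = profiles.calibrate_null(
                prof, n_shuffles=max(100, n_shuffles), seed=seed + i
            )
        profile_models.append(prof)
    return FeatureContext(db, profile_models, list(training.families))


def train_all_trios(
    training_vectors: Sequence[features.FeatureVector],
    labels: Mapping[str, str],
    family_order: Sequence[str],
    profile_order: Sequence[str],
    spec: models.TrainingSpec | None = None,
) -> list[models.FamilyClassifierTrio]:
    spec = spec or models.TrainingSpec()
    return [
        models.train_trio(fam, training_vectors, labels, spec, family_order, profile_order)
        for fam in family_order
    ]


@dataclass
class BenchmarkResult:
    report: evaluation.EvaluationReport
    per_family_auc: dict[str, float]
    novel_auc: dict[str, float]
    predictions: list[PredictionSet]
    identity_bins: dict[str, str] = field(default_factory=dict)


def run_benchmark(
    dataset: FamilyDataset,
    novel: FamilyDataset,
    seed_alignments: Mapping[str, Sequence[str]],
    seed: int = 0,
    k_folds: int = 3,
    test_fold: int = 0,
    n_ref: int = 10,
    spec: models.TrainingSpec | None = None,
    compute_identity: bool = False,
    min_aln_len: int = 100,
    discard_over: int | None = None,
) -> BenchmarkResult:
    """One train/test round of the full pipeline on a labeled dataset.

    The dataset is split by stratified folds (one fold held out for
    test), featurized against a reference DB built from the training
    split, all per-family trios are trained, and test plus novel
    sequences are predicted and scored.
    """
    ds = make_folds(dataset, k_folds, seed)
    train_ds, test_ds = ds.train_test_split(test_fold)
    ctx = build_feature_context(train_ds, seed_alignments, n_ref=n_ref, seed=seed)

    labels = {s.id: s.family for s in dataset.sequences}
    train_vecs = ctx.featurize_all(train_ds.sequences)
    test_vecs = ctx.featurize_all(test_ds.sequences)
    novel_vecs = ctx.featurize_all(novel.sequences)

    trio_spec = spec or models.TrainingSpec(seed=seed)
    trios = train_all_trios(
        train_vecs, labels, ctx.family_order, ctx.profile_order, trio_spec
    )

    predictions = [predict_families(v, trios) for v in test_vecs]

    identity_bins: dict[str, str] = {}
    if compute_identity:
        seed_seqs = [
            LabeledSequence(f"{name}_row{i}", row, "SEED")
            for name, rows in sorted(seed_alignments.items())
            for i, row in enumerate(rows)
        ]
        for s in test_ds.sequences:
            ident = evaluation.identity_to_training(
                s, train_ds.sequences, seed_seqs, min_aln_len=min_aln_len
            )
            identity_bins[s.id] = evaluation.identity_bin_label(ident)

    report = evaluation.accuracy_by_predcount(
        predictions, labels, identity_bins or None, discard_over=discard_over
    )
    fam_auc = evaluation.per_family_auc(predictions, labels, ctx.family_order)
    report.per_family_auc = fam_auc

    novel_auc: dict[str, float] = {}
    if len(novel_vecs) > 0:
        positives_by_family: dict[str, list[features.FeatureVector]] = {}
        for s, v in zip(test_ds.sequences, test_vecs):
            positives_by_family.setdefault(s.family, []).append(v)
        novel_auc = evaluation.novel_family_eval(novel_vecs, positives_by_family, trios)

    return BenchmarkResult(report, fam_auc, novel_auc, predictions, identity_bins)
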