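"""Per-family training: negative subsampling, 9:1 weighting, three SVMs.

For a target family, all of its training members are positives; each
other family contributes at most ``n_neg_per_family`` (default 10)
seeded-uniformly sampled negatives.  With N=1000 families of 200
members this shrinks the negative set from ~200,000 to ~10,000 — a
factor of 20.  The residual imbalance is handled in the loss, not by
resampling: every positive example carries 9x the weight of a negative.

Each of the three linear classifiers (squared hinge loss, L2 penalty)
is trained on its own feature subset after per-feature standardization.
Probabilities are Platt-style sigmoids sigma(A*d + B) fit on decision
values from an internal 3-fold split, so calibration never sees its own
training decisions; the binary vote itself is sign(d) and therefore
independent of calibration.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from famvote.features import FeatureVector, subset_for_model

MODEL_IDS = (1, 2, 3)


@dataclass(frozen=True)
class TrainingSpec:
    n_neg_per_family: int = 10
    positive_weight: float = 9.0
    negative_weight: float = 1.0
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neg_per_family < 1:
            raise ValueError("n_neg_per_family must be >= 1")
        if self.positive_weight <= 0 or self.negative_weight <= 0:
            raise ValueError("example weights must be positive")


@dataclass
class LinearModel:
    """One standardized linear classifier with its sigmoid calibrator."""

    weights: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    calib_a: float
    calib_b: float

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        z = (x - self.scaler_mean) / self.scaler_scale
        return z @ self.weights + self.intercept

    def probability(self, x: np.ndarray) -> np.ndarray:
        d = self.decision(x)
        return 1.0 / (1.0 + np.exp(-(self.calib_a * d + self.calib_b)))


@dataclass
class FamilyClassifierTrio:
    family: str
    models: dict[int, LinearModel]
    spec: TrainingSpec
    family_order: list[str]
    profile_order: list[str]
    positive_ids: list[str] = field(default_factory=list)
    negative_ids: list[str] = field(default_factory=list)


def sample_training_set(
    target_family: str,
    features: Sequence[FeatureVector],
    labels: Mapping[str, str],
    spec: TrainingSpec,
) -> tuple[list[FeatureVector], np.ndarray, np.ndarray]:
    """Positives + per-family subsampled negatives, with example weights.

    Returns (examples, y, sample_weight) where y is +1/-1.  Negatives
    are drawn without replacement per negative family; families smaller
    than ``n_neg_per_family`` contribute all their members.
    """
    rng = random.Random(spec.seed)
    positives = [v for v in features if labels[v.sequence_id] == target_family]
    if not positives:
        raise ValueError(f"no positive training examples for {target_family!r}")
    by_family: dict[str, list[FeatureVector]] = {}
    for v in features:
        fam = labels[v.sequence_id]
        if fam != target_family:
            by_family.setdefault(fam, []).append(v)
    negatives: list[FeatureVector] = []
    for fam in sorted(by_family):
        members = sorted(by_family[fam], key=lambda v: v.sequence_id)
        take = min(spec.n_neg_per_family, len(members))
        negatives.extend(rng.sample(members, take))
    examples = positives + negatives
    y = np.array([1] * len(positives) + [-1] * len(negatives))
    w = np.where(y > 0, spec.positive_weight, spec.negative_weight).astype(float)
    return examples, y, w


def _fit_platt(
    decisions: np.ndarray, y: np.ndarray, sample_weight: np.ndarray
) -> tuple[float, float]:
    """Sigmoid calibration p = sigma(A*d + B) via 1-D logistic fit."""
    lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
    lr.fit(decisions.reshape(-1, 1), (y > 0).astype(int), sample_weight=sample_weight)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def _fit_one_model(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, spec: TrainingSpec
) -> LinearModel:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Z = (X - mean) / scale

    svc = LinearSVC(C=spec.C, loss="squared_hinge", random_state=spec.seed)
    svc.fit(Z, y, sample_weight=w)

    # held-out decision values for calibration: 3-fold internal split
    n_splits = min(3, int(np.bincount((y > 0).astype(int)).min()))
    if n_splits >= 2:
        dec = np.empty(len(y))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
        for tr, te in skf.split(Z, y):
            fold_svc = LinearSVC(
                C=spec.C, loss="squared_hinge", random_state=spec.seed
            )
            fold_svc.fit(Z[tr], y[tr], sample_weight=w[tr])
            dec[te] = fold_svc.decision_function(Z[te])
    else:
        dec = svc.decision_function(Z)
    a, b = _fit_platt(dec, y, w)
    return LinearModel(
        weights=svc.coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
        calib_a=a,
        calib_b=b,
    )


def train_trio(
    target_family: str,
    features: Sequence[FeatureVector],
    labels: Mapping[str, str],
    spec: TrainingSpec,
    family_order: Sequence[str],
    profile_order: Sequence[str],
) -> FamilyClassifierTrio:
    """Train the three per-family classifiers on their feature subsets."""
    examples, y, w = sample_training_set(target_family, features, labels, spec)
    if len(set(y)) < 2:
        raise ValueError(
            f"degenerate single-class training set for {target_family!r}"
        )
    models: dict[int, LinearModel] = {}
    for model_id in MODEL_IDS:
        X = np.vstack(
            [subset_for_model(v, target_family, model_id, family_order) for v in examples]
        )
        models[model_id] = _fit_one_model(X, y, w, spec)
    return FamilyClassifierTrio(
        family=target_family,
        models=models,
        spec=spec,
        family_order=list(family_order),
        profile_order=list(profile_order),
        positive_ids=[v.sequence_id for v, yy in zip(examples, y) if yy > 0],
        negative_ids=[v.sequence_id for v, yy in zip(examples, y) if yy < 0],
    )


def classifier_probability(
    trio: FamilyClassifierTrio, v: FeatureVector
) -> tuple[np.ndarray, np.ndarray]:
    """Per-classifier (p1,p2,p3) and the raw decision values (d1,d2,d3)."""
    n_expected = 2 * len(trio.profile_order) + 3 * len(trio.family_order)
    if len(v) != n_expected:
        raise ValueError(
            f"feature vector length {len(v)} does not match trio "
            f"{trio.family!r} (expected {n_expected}); check family/profile orders"
        )
    ps, ds = [], []
    for model_id in MODEL_IDS:
        x = subset_for_model(v, trio.family, model_id, trio.family_order)
        model = trio.models[model_id]
        ds.append(float(model.decision(x)[0]))
        ps.append(float(model.probability(x)[0]))
    return np.array(ps), np.array(ds)


def write_trio(trio: FamilyClassifierTrio, path: str | Path) -> None:
    payload = {
        "family": trio.family,
        "spec": {
            "n_neg_per_family": trio.spec.n_neg_per_family,
            "positive_weight": trio.spec.positive_weight,
            "negative_weight": trio.spec.negative_weight,
            "C": trio.spec.C,
            "seed": trio.spec.seed,
        },
        "family_order": trio.family_order,
        "profile_order": trio.profile_order,
        "positive_ids": trio.positive_ids,
        "negative_ids": trio.negative_ids,
        "models": {
            str(k): {
                "weights": m.weights.tolist(),
                "intercept": m.intercept,
                "scaler_mean": m.scaler_mean.tolist(),
                "scaler_scale": m.scaler_scale.tolist(),
                "calib_a": m.calib_a,
                "calib_b": m.calib_b,
            }
            for k, m in trio.models.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_trio(path: str | Path) -> FamilyClassifierTrio:
    with open(path) as fh:
        d = json.load(fh)
    models = {
        int(k): LinearModel(
            np.asarray(m["weights"]),
            m["intercept"],
            np.asarray(m["scaler_mean"]),
            np.asarray(m["scaler_scale"]),
            m["calib_a"],
            m["calib_b"],
        )
        for k, m in d["models"].items()
    }
    return FamilyClassifierTrio(
        family=d["family"],
        models=models,
        spec=TrainingSpec(**d["spec"]),
        family_order=d["family_order"],
        profile_order=d["profile_order"],
        positive_ids=d["positive_ids"],
        negative_ids=d["negative_ids"],
    )
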