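"""Fixed-length feature vectors and the three model-specific subsets.

The full vector concatenates, in fixed family order, a per-family
triple (bit-score, -log10 E-value, percent identity) from the
alignment search — 3N values — and, in fixed profile order, a
per-profile pair (bit-score, -log10 E-value) — 2M values.  Missing
hits are imputed as zeros: 0 bits, E-value >= 1, identity 0, i.e. the
natural "no similarity" point.

The three per-family classifiers see different slices:

  model 1: profile block + all family triples          (2M + 3N)
  model 2: profile block + the target family's triple  (2M + 3)
  model 3: the target family's triple alone            (3)

Model 1 sees the target family's similarity plus every other family's
dissimilarity; models 2 and 3 drop the dissimilarity block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from famvote.homology import AlignmentHit
from famvote.profiles import ProfileHit

#: E-values are floored here before the -log10 transform.
E_VALUE_FLOOR = 1e-180

FAMILY_FEATURES = ("bit", "neglog_e", "identity")
PROFILE_FEATURES = ("bit", "neglog_e")


def neglog_e(e_value: float) -> float:
    """-log10 of the floored E-value, clipped to be >= 0."""
    return max(0.0, -np.log10(max(e_value, E_VALUE_FLOOR)))


@dataclass(frozen=True)
class FeatureVector:
    sequence_id: str
    blast_block: np.ndarray  # (3N,)
    profile_block: np.ndarray  # (2M,)
    family_present: np.ndarray  # (N,) bool
    profile_present: np.ndarray  # (M,) bool

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.profile_block, self.blast_block])

    def __len__(self) -> int:
        return self.blast_block.size + self.profile_block.size


def assemble(
    seq_id: str,
    family_hits: Mapping[str, AlignmentHit],
    profile_hits: Mapping[str, ProfileHit],
    family_order: Sequence[str],
    profile_order: Sequence[str],
    raw_evalues: bool = False,
) -> FeatureVector:
    """Assemble one fixed-length feature vector.

    ``raw_evalues=True`` stores E-values untransformed (deviation knob;
    the default -log10 encoding keeps the feature numerically tame).
    """
    fam_index = {f: i for i, f in enumerate(family_order)}
    prof_index = {p: i for i, p in enumerate(profile_order)}
    unknown = set(family_hits) - set(fam_index)
    if unknown:
        raise ValueError(f"hits for families not in family_order: {sorted(unknown)}")
    unknown = set(profile_hits) - set(prof_index)
    if unknown:
        raise ValueError(f"hits for profiles not in profile_order: {sorted(unknown)}")

    transform = (lambda e: e) if raw_evalues else neglog_e
    blast = np.zeros(3 * len(family_order))
    fam_present = np.zeros(len(family_order), dtype=bool)
    for fam, hit in family_hits.items():
        i = fam_index[fam]
        blast[3 * i : 3 * i + 3] = (
            hit.bit_score,
            transform(hit.e_value),
            hit.identity_pct,
        )
        fam_present[i] = True
    profile = np.zeros(2 * len(profile_order))
    prof_present = np.zeros(len(profile_order), dtype=bool)
    for pid, hit in profile_hits.items():
        i = prof_index[pid]
        profile[2 * i : 2 * i + 2] = (hit.bit_score, transform(hit.e_value))
        prof_present[i] = True
    return FeatureVector(seq_id, blast, profile, fam_present, prof_present)


def subset_for_model(
    v: FeatureVector,
    target_family: str,
    model_id: int,
    family_order: Sequence[str],
) -> np.ndarray:
    """Slice the feature subset classifier ``model_id`` trains on."""
    try:
        i = list(family_order).index(target_family)
    except ValueError:
        raise ValueError(f"{target_family!r} not in family order") from None
    triple = v.blast_block[3 * i : 3 * i + 3]
    if model_id == 1:
        return v.full
    if model_id == 2:
        return np.concatenate([v.profile_block, triple])
    if model_id == 3:
        return triple.copy()
    raise ValueError(f"unknown model_id {model_id!r} (expected 1, 2 or 3)")


def subset_length(model_id: int, n_families: int, n_profiles: int) -> int:
    """Expected feature-subset length: 2M+3N, 2M+3, or 3."""
    if model_id == 1:
        return 2 * n_profiles + 3 * n_families
    if model_id == 2:
        return 2 * n_profiles + 3
    if model_id == 3:
        return 3
    raise ValueError(f"unknown model_id {model_id!r}")


def feature_frame(
    vectors: Sequence[FeatureVector],
    family_order: Sequence[str],
    profile_order: Sequence[str],
) -> pd.DataFrame:
    """Feature matrix as a DataFrame (rows = sequences, named columns)."""
    columns = [f"{p}:{f}" for p in profile_order for f in PROFILE_FEATURES]
    columns += [f"{fam}:{f}" for fam in family_order for f in FAMILY_FEATURES]
    data = np.vstack([v.full for v in vectors]) if vectors else np.empty((0, len(columns)))
    return pd.DataFrame(data, index=[v.sequence_id for v in vectors], columns=columns)


def write_features(
    vectors: Sequence[FeatureVector],
    family_order: Sequence[str],
    profile_order: Sequence[str],
    tsv_path: str | Path,
    orders_path: str | Path,
) -> None:
    frame = feature_frame(vectors, family_order, profile_order)
    frame.to_csv(tsv_path, sep="\t", index_label="sequence_id")
    with open(orders_path, "w") as fh:
        json.dump(
            {
                "family_order": list(family_order),
                "profile_order": list(profile_order),
                "e_value_transform": "neglog10",
            },
            fh,
            indent=2,
        )


def read_features(
    tsv_path: str | Path, orders_path: str | Path
) -> tuple[list[FeatureVector], list[str], list[str]]:
    orders_path = Path(orders_path)
    if not orders_path.exists():
        raise FileNotFoundError(
            f"{orders_path} missing: rerun featurize to regenerate the "
            "column-order sidecar"
        )
    with open(orders_path) as fh:
        orders = json.load(fh)
    family_order = orders["family_order"]
    profile_order = orders["profile_order"]
    frame = pd.read_csv(tsv_path, sep="\t", index_col="sequence_id")
    n_prof = 2 * len(profile_order)
    vectors = []
    for seq_id, row in zip(frame.index, frame.to_numpy()):
        profile_block = row[:n_prof]
        blast_block = row[n_prof:]
        vectors.append(
            FeatureVector(
                str(seq_id),
                blast_block,
                profile_block,
                blast_block.reshape(-1, 3).any(axis=1),
                profile_block.reshape(-1, 2).any(axis=1),
            )
        )
    return vectors, family_order, profile_order
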