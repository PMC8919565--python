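"""Position-specific profile scores used as the M "profile features".

Each profile is an ungapped position-specific score model built from a
seed alignment: per match column, log2 odds of the observed residue
frequency (with pseudocounts) against a background distribution.  A
sequence's bit-score against a profile is the best log-odds sum over
all placements of the profile along the sequence (local in the
sequence, global in the profile).  E-values come from an exponential
tail fitted to scores of shuffled background sequences, so that the
score->E map is monotone and roughly calibrated:

    E(s) = n_models_equiv * exp(-(s - mu) / beta)

These profiles are deliberately simpler than full profile HMMs (no
insert/delete states): they only have to supply a bit-score/E-value
pair per model as classifier features, and externally computed HMMER
scores can be substituted via :func:`parse_hmmscan_domtblout`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from famvote.seqio import LabeledSequence
from famvote.synthetic import AA, _AA_IDX

UNIFORM_BACKGROUND = np.full(len(AA), 1.0 / len(AA))

#: Effective number of models in the search, used to scale E-values.
DEFAULT_N_MODELS_EQUIV = 1.0


@dataclass(frozen=True)
class ProfileModel:
    profile_id: str
    match_log_odds: np.ndarray  # (length, 20) log2(emission/background)
    background: np.ndarray  # (20,)
    null_mu: float | None = None
    null_beta: float | None = None
    n_models_equiv: float = DEFAULT_N_MODELS_EQUIV

    def __post_init__(self) -> None:
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if self.match_log_odds.ndim != 2 or self.match_log_odds.shape[1] != len(AA):
            raise ValueError("match_log_odds must be (length, 20)")

    @property
    def length(self) -> int:
        return self.match_log_odds.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.null_mu is not None and self.null_beta is not None


@dataclass(frozen=True)
class ProfileHit:
    profile_id: str
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0.0:
            raise ValueError("e_value must be >= 0")


def build_profile(
    seed_alignment: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    profile_id: str = "profile",
) -> ProfileModel:
    """Build a profile from aligned rows ('-' gaps allowed).

    Columns with more than 50% gap characters are dropped.  The match
    score of residue a at column i is

        log2( (count(i,a) + pseudocount * bg(a)) / (total_i + pseudocount) / bg(a) )

    so a residue observed exactly at background frequency scores 0.
    """
    if not seed_alignment:
        raise ValueError("seed alignment needs at least one row")
    width = len(seed_alignment[0])
    if any(len(row) != width for row in seed_alignment):
        raise ValueError("ragged seed alignment: rows differ in length")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    n_rows = len(seed_alignment)
    cols: list[np.ndarray] = []
    for i in range(width):
        column = [row[i].upper() for row in seed_alignment]
        gaps = sum(c in "-." for c in column)
        if gaps > 0.5 * n_rows:
            continue
        counts = np.zeros(len(AA))
        total = 0
        for c in column:
            if c in _AA_IDX:
                counts[_AA_IDX[c]] += 1
                total += 1
        freq = (counts + pseudocount * bg) / (total + pseudocount)
        cols.append(np.log2(freq / bg))
    if not cols:
        raise ValueError("all columns were gap-majority; empty profile")
    return ProfileModel(profile_id, np.vstack(cols), bg)


def _encode(residues: str) -> np.ndarray:
    # 'X' scores 0 everywhere: treat it as an extra index mapped to a
    # zero column appended to the score matrix
    return np.array([_AA_IDX.get(c, len(AA)) for c in residues], dtype=np.intp)


def _window_scores(profile: ProfileModel, residues: str) -> np.ndarray:
    """Log-odds sum for every placement of profile vs sequence."""
    idx = _encode(residues)
    M = np.hstack([profile.match_log_odds, np.zeros((profile.length, 1))])
    L, W = len(idx), profile.length
    if L >= W:
        windows = np.lib.stride_tricks.sliding_window_view(idx, W)  # (L-W+1, W)
        return M[np.arange(W)[None, :], windows].sum(axis=1)
    # sequence shorter than profile: slide the sequence along the profile
    offsets = W - L + 1
    scores = np.empty(offsets)
    for o in range(offsets):
        scores[o] = M[np.arange(o, o + L), idx].sum()
    return scores


def score_profile(sequence: LabeledSequence, profile: ProfileModel) -> ProfileHit:
    """Best-placement log-odds bit-score, with E-value if calibrated."""
    bit = float(_window_scores(profile, sequence.residues).max())
    if profile.calibrated:
        e_value = profile.n_models_equiv * math.exp(
            -(bit - profile.null_mu) / profile.null_beta
        )
        e_value = max(e_value, 0.0)
    else:
        e_value = math.nan
    return ProfileHit(profile.profile_id, bit, e_value)


def calibrate_null(
    profile: ProfileModel,
    n_shuffles: int = 1000,
    seed: int = 0,
    null_length: int = 300,
    tail_fraction: float = 0.2,
    n_models_equiv: float = DEFAULT_N_MODELS_EQUIV,
) -> ProfileModel:
    """Fit an exponential upper tail to scores of random background sequences.

    The top ``tail_fraction`` of null scores are regressed as
    ln(exceedance) ~ -(s - mu)/beta; E-values then follow
    E(s) = n_models_equiv * exp(-(s - mu)/beta).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(AA), size=(n_shuffles, null_length), p=profile.background)
    seqs = ["".join(AA[i] for i in row) for row in draws]
    scores = np.array(
        [
            _window_scores(profile, s).max()
            for s in seqs
        ]
    )
    if np.ptp(scores) < 1e-12:
        raise ValueError(
            "degenerate null score distribution; increase n_shuffles or "
            "null_length"
        )
    order = np.sort(scores)[::-1]
    k = max(int(round(tail_fraction * n_shuffles)), 10)
    top = order[:k]
    # empirical exceedance probability of the i-th largest score
    exceed = (np.arange(1, k + 1)) / n_shuffles
    slope, intercept = np.polyfit(top, np.log(exceed), 1)
    if slope >= 0:
        raise ValueError("null tail not decaying; increase n_shuffles")
    beta = -1.0 / slope
    mu = intercept * beta
    return replace(
        profile, null_mu=float(mu), null_beta=float(beta),
        n_models_equiv=float(n_models_equiv),
    )


def parse_hmmscan_domtblout(path: str | Path) -> Iterator[ProfileHit]:
    """Parse HMMER3 hmmscan --domtblout into per-(query, model) hits.

    Keeps the full-sequence bit score and E-value (columns 8 and 7,
    1-based), de-duplicated across domain rows of the same pair.
    """
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 23:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 23 whitespace-separated "
                    f"fields, got {len(parts)}"
                )
            model, query = parts[0], parts[3]
            key = (query, model)
            if key in seen:
                continue
            seen.add(key)
            try:
                e_full = float(parts[6])
                bit_full = float(parts[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            yield ProfileHit(model, bit_full, e_full)


def write_profile(profile: ProfileModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "profile_id": profile.profile_id,
                "match_log_odds": profile.match_log_odds.tolist(),
                "background": profile.background.tolist(),
                "null_mu": profile.null_mu,
                "null_beta": profile.null_beta,
                "n_models_equiv": profile.n_models_equiv,
            },
            fh,
        )


def read_profile(path: str | Path) -> ProfileModel:
    with open(path) as fh:
        d = json.load(fh)
    return ProfileModel(
        d["profile_id"],
        np.asarray(d["match_log_odds"], float),
        np.asarray(d["background"], float),
        d["null_mu"],
        d["null_beta"],
        d["n_models_equiv"],
    )
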