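"""Synthetic protein-family benchmark generator.

Each family descends from a randomized positional profile (a categorical
emission per column, peaked according to a per-column conservation
weight).  Members are drawn from the profile and then mutated with a
per-site substitution/indel process, so the realized identity between a
member and its family's consensus is controlled by the substitution
rate: a rate r gives an expected identity of roughly 100*(1-r)% on
conserved columns.  Mixing divergence specs therefore lets a benchmark
populate the twilight-zone identity bins (<=30%, 30-40%) on demand, and
families generated from disjoint profiles provide "novel" negatives
that were never seen in training.

This is deliberately not a phylogenetic simulator: there is no tree and
no empirical rate matrix.  The generator only has to place test
sequences at controllable identity to the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from famvote.seqio import NOVEL, FamilyDataset, LabeledSequence

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA)}


@dataclass(frozen=True)
class FamilyProfile:
    """Positional emission model for one family.

    emission[i] is the length-20 categorical distribution of column i;
    conservation[i] in [0, 1] records how peaked that column is.
    """

    family: str
    emission: np.ndarray  # (length, 20)
    conservation: np.ndarray  # (length,)

    def __post_init__(self) -> None:
        if self.emission.ndim != 2 or self.emission.shape[1] != len(AA):
            raise ValueError("emission must be (length, 20)")
        if self.emission.shape[0] < 1:
            raise ValueError("profile length must be >= 1")
        sums = self.emission.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each position's emission must sum to 1")

    @property
    def length(self) -> int:
        return self.emission.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA[i] for i in self.emission.argmax(axis=1))


@dataclass(frozen=True)
class DivergenceSpec:
    """Per-site mutation process applied to an emitted member."""

    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    max_indel_len: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")
        if not (0.0 <= self.indel_rate <= 1.0):
            raise ValueError("indel_rate must be in [0, 1]")
        if self.substitution_rate + self.indel_rate > 1.0:
            raise ValueError("substitution_rate + indel_rate must be <= 1")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


#: Default divergence mixture: mostly easy members, a mid shell, and a
#: twilight tail sized so ~12% of members fall at <=40% identity to the
#: family consensus.
DEFAULT_DIVERGENCE_BINS: tuple[tuple[DivergenceSpec, float], ...] = (
    (DivergenceSpec(substitution_rate=0.05, indel_rate=0.01), 0.58),
    (DivergenceSpec(substitution_rate=0.40, indel_rate=0.01), 0.30),
    (DivergenceSpec(substitution_rate=0.68, indel_rate=0.01), 0.12),
)


def sample_profile(
    length: int,
    conservation_range: tuple[float, float],
    seed: int,
    family: str = "profile",
) -> FamilyProfile:
    """Draw a random family profile.

    Each column gets a conservation weight c uniform in the given range
    and an emission c * delta(consensus residue) + (1-c) * Dirichlet(1).
    A column with c >= 0.9 therefore puts >= 0.9 mass on one residue,
    and c = 1 is fully degenerate.
    """
    lo, hi = conservation_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"invalid conservation range [{lo}, {hi}]")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    conservation = rng.uniform(lo, hi, size=length)
    consensus = rng.integers(0, len(AA), size=length)
    noise = rng.dirichlet(np.ones(len(AA)), size=length)
    emission = (1.0 - conservation)[:, None] * noise
    emission[np.arange(length), consensus] += conservation
    emission /= emission.sum(axis=1, keepdims=True)
    return FamilyProfile(family, emission, conservation)


def emit_member(
    profile: FamilyProfile,
    div: DivergenceSpec,
    seed: int,
    seq_id: str = "member",
) -> LabeledSequence:
    """Emit one member: draw per-column, substitute, then apply indels."""
    rng = np.random.default_rng(seed)
    L = profile.length
    # positional draw
    u = rng.random((L, 1))
    idx = (profile.emission.cumsum(axis=1) > u).argmax(axis=1)
    # substitutions: uniform over the 19 other residues
    sub_mask = rng.random(L) < div.substitution_rate
    shift = rng.integers(1, len(AA), size=L)
    idx = np.where(sub_mask, (idx + shift) % len(AA), idx)
    residues = [AA[i] for i in idx]
    if div.indel_rate > 0.0:
        out: list[str] = []
        for ch in residues:
            if rng.random() < div.indel_rate:
                ln = min(int(rng.geometric(0.5)), div.max_indel_len)
                if rng.random() < 0.5:
                    # deletion: drop this residue (and up to ln-1 following
                    # ones are handled by independent events; single-site
                    # deletion keeps the expected length near L)
                    continue
                out.append(ch)
                out.extend(AA[j] for j in rng.integers(0, len(AA), size=ln))
            else:
                out.append(ch)
        residues = out if out else [residues[0]]
    return LabeledSequence(seq_id, "".join(residues), profile.family)


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length ungapped strings."""
    if len(a) != len(b):
        raise ValueError("hamming_identity needs equal-length strings")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def _emit_seed_alignment(
    profile: FamilyProfile, n_rows: int, rng: np.random.Generator
) -> list[str]:
    # seed rows are emitted without indels, so the stack of rows is a
    # valid (gap-free) alignment of equal-length strings
    spec = DivergenceSpec(substitution_rate=0.05, indel_rate=0.0)
    rows = []
    for i in range(n_rows):
        s = emit_member(profile, spec, int(rng.integers(0, 2**31)), f"seed{i}")
        rows.append(s.residues)
    return rows


def generate_benchmark(
    n_families: int,
    members_per_family: int,
    divergence_bins: tuple[tuple[DivergenceSpec, float], ...] = DEFAULT_DIVERGENCE_BINS,
    n_novel_families: int = 0,
    novel_members_per_family: int = 10,
    n_profile_models: int = 8,
    overlap_fraction: float = 0.2,
    seed: int = 0,
    length_range: tuple[int, int] = (160, 220),
    conservation_range: tuple[float, float] = (0.85, 1.0),
    seed_alignment_rows: int = 5,
) -> tuple[FamilyDataset, FamilyDataset, dict[str, list[str]]]:
    """Generate a labeled benchmark plus novel families and profile seeds.

    Returns ``(dataset, novel, seed_alignments)`` where ``dataset`` has
    ``n_families`` families of ``members_per_family`` members each (the
    divergence of each member drawn from the weighted mixture),
    ``novel`` holds sequences from ``n_novel_families`` families built
    from disjoint profiles and labeled NOVEL, and ``seed_alignments``
    maps profile-model ids to equal-length aligned rows — a fraction
    ``overlap_fraction`` of them derived from main-dataset family
    profiles, the rest from independent profiles.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must be in [0, 1]")
    if members_per_family < 13:
        raise ValueError(
            "members_per_family must be >= 13 (10 references + 3-fold CV)"
        )
    if n_profile_models < 1:
        raise ValueError("n_profile_models must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, w in divergence_bins], dtype=float)
    weights = weights / weights.sum()
    specs = [s for s, _ in divergence_bins]

    def _make_family(name: str) -> FamilyProfile:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        return sample_profile(
            length, conservation_range, int(rng.integers(0, 2**31)), family=name
        )

    profiles = [_make_family(f"F{i:03d}") for i in range(n_families)]
    sequences: list[LabeledSequence] = []
    for prof in profiles:
        for j in range(members_per_family):
            spec = specs[int(rng.choice(len(specs), p=weights))]
            sequences.append(
                emit_member(
                    prof, spec, int(rng.integers(0, 2**31)), f"{prof.family}_m{j:03d}"
                )
            )
    dataset = FamilyDataset(sequences, [p.family for p in profiles])

    novel_seqs: list[LabeledSequence] = []
    for i in range(n_novel_families):
        prof = _make_family(NOVEL)
        for j in range(novel_members_per_family):
            spec = specs[int(rng.choice(len(specs), p=weights))]
            novel_seqs.append(
                emit_member(
                    prof, spec, int(rng.integers(0, 2**31)), f"NOV{i:02d}_m{j:03d}"
                )
            )
    novel = FamilyDataset(novel_seqs, [])

    seed_alignments: dict[str, list[str]] = {}
    n_overlap = int(round(overlap_fraction * n_profile_models))
    for m in range(n_profile_models):
        if m < n_overlap and n_families > 0:
            src = profiles[m % n_families]
        else:
            src = _make_family(f"ind{m}")
        seed_alignments[f"P{m:02d}"] = _emit_seed_alignment(
            src, seed_alignment_rows, rng
        )
    return dataset, novel, seed_alignments


def write_seed_alignments(seed_alignments: dict[str, list[str]], directory) -> None:
    """Write each seed alignment as aligned FASTA (equal-length rows)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, rows in sorted(seed_alignments.items()):
        with open(directory / f"{name}.afa", "w") as fh:
            for i, row in enumerate(rows):
                fh.write(f">{name}_row{i}\n{row}\n")


def read_seed_alignments(directory) -> dict[str, list[str]]:
    from pathlib import Path

    from Bio import SeqIO

    out: dict[str, list[str]] = {}
    for path in sorted(Path(directory).glob("*.afa")):
        rows = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
        out[path.stem] = rows
    return out
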