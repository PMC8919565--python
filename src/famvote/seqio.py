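"""Sequence/label I/O and stratified cross-validation folds.

Datasets are plain FASTA plus a two-column sidecar TSV (``sequence_id
<tab> family_id``).  When no sidecar is given the family label is taken
from the header token after the final ``|``.  Family order is always
lexicographic: downstream feature columns are indexed by family, so the
order must be reproducible across runs and machines.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Sentinel family label for sequences from families excluded from training.
NOVEL = "NOVEL"

#: The 20 canonical amino acids plus the ambiguity code 'X'.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class LabeledSequence:
    """One amino-acid sequence with its family label."""

    id: str
    residues: str
    family: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        for pos, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FamilyDataset:
    """A collection of labeled sequences with a fixed family order.

    ``families`` defines feature-column order (N = ``len(families)``).
    Sequences labeled :data:`NOVEL` are allowed and never appear in
    ``families``.
    """

    sequences: list[LabeledSequence]
    families: list[str]
    hierarchy: dict[str, tuple[str, str]] | None = None
    folds: dict[str, int] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.id in seen:
                raise ValueError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)
        fams = set(self.families)
        for seq in self.sequences:
            if seq.family != NOVEL and seq.family not in fams:
                raise ValueError(
                    f"sequence {seq.id!r} labeled {seq.family!r} which is not "
                    "in the family list"
                )

    @property
    def n_families(self) -> int:
        return len(self.families)

    def __len__(self) -> int:
        return len(self.sequences)

    def by_family(self) -> dict[str, list[LabeledSequence]]:
        out: dict[str, list[LabeledSequence]] = {f: [] for f in self.families}
        for seq in self.sequences:
            out.setdefault(seq.family, []).append(seq)
        return out

    def subset(self, ids: Iterable[str]) -> "FamilyDataset":
        """Restrict to the given ids, keeping family order and fold map."""
        keep = set(ids)
        seqs = [s for s in self.sequences if s.id in keep]
        folds = None
        if self.folds is not None:
            folds = {s.id: self.folds[s.id] for s in seqs if s.id in self.folds}
        return FamilyDataset(seqs, list(self.families), self.hierarchy, folds)

    def train_test_split(self, test_fold: int) -> tuple["FamilyDataset", "FamilyDataset"]:
        """Split by the fold map: ``test_fold`` out, the rest in."""
        if self.folds is None:
            raise ValueError("dataset has no fold assignment; call make_folds first")
        train = [s.id for s in self.sequences if self.folds[s.id] != test_fold]
        test = [s.id for s in self.sequences if self.folds[s.id] == test_fold]
        return self.subset(train), self.subset(test)


def _family_from_header(header: str) -> str:
    # fallback rule: family token after the final '|'
    if "|" not in header:
        raise ValueError(
            f"header {header!r} has no '|' family token and no sidecar label"
        )
    return header.rsplit("|", 1)[1]


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, family) TSV with no header."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            seq_id, family = parts
            if seq_id in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {seq_id!r}")
            labels[seq_id] = family
    return labels


def read_labeled_fasta(
    fasta_path: str | Path,
    labels: str | Path | Mapping[str, str] | None = None,
) -> FamilyDataset:
    """Read a FASTA file plus labels into a :class:`FamilyDataset`.

    ``labels`` may be a sidecar TSV path, an in-memory mapping, or None
    (header rule: family is the token after the final ``|``).  Family
    order in the result is lexicographic regardless of file order.
    """
    if labels is None:
        label_map: Mapping[str, str] | None = None
    elif isinstance(labels, (str, Path)):
        label_map = read_labels_tsv(labels)
    else:
        label_map = labels

    sequences: list[LabeledSequence] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if label_map is not None:
            try:
                family = label_map[record.id]
            except KeyError:
                raise ValueError(f"no label for sequence {record.id!r}") from None
        else:
            family = _family_from_header(record.id)
        sequences.append(LabeledSequence(record.id, str(record.seq).upper(), family))

    families = sorted({s.family for s in sequences} - {NOVEL})
    return FamilyDataset(sequences, families)


def write_labeled_fasta(
    dataset: FamilyDataset,
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    line_width: int = 60,
) -> None:
    """Write sequences as FASTA and (optionally) the sidecar labels TSV."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in dataset.sequences
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for s in dataset.sequences:
                fh.write(f"{s.id}\t{s.family}\n")


def write_fold_map(dataset: FamilyDataset, path: str | Path) -> None:
    if dataset.folds is None:
        raise ValueError("dataset has no folds to write")
    with open(path, "w") as fh:
        for s in dataset.sequences:
            fh.write(f"{s.id}\t{dataset.folds[s.id]}\n")


def read_fold_map(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = int(parts[1])
    return out


def make_folds(dataset: FamilyDataset, k: int, seed: int) -> FamilyDataset:
    """Assign stratified k-fold indices, one per sequence.

    Each family's members are shuffled (seeded) and dealt round-robin
    across folds, so per-family fold sizes differ by at most one.  Novel
    sequences are excluded from the fold map.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    rng = random.Random(seed)
    too_small = [
        fam for fam, members in dataset.by_family().items()
        if fam != NOVEL and len(members) < k
    ]
    if too_small:
        raise ValueError(
            f"families smaller than k={k}: {sorted(too_small)}"
        )
    folds: dict[str, int] = {}
    for fam in dataset.families:
        ids = sorted(s.id for s in dataset.sequences if s.family == fam)
        rng.shuffle(ids)
        for i, seq_id in enumerate(ids):
            folds[seq_id] = i % k
    return replace(dataset, folds=folds)
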