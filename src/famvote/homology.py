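"""Per-family local-alignment similarity features.

A small reference database (default 10 sequences per family, so 10N
sequences for N families) is searched with affine-gap Smith–Waterman
under BLOSUM62.  Raw alignment scores are normalized to bit-scores and
E-values with Karlin–Altschul statistics

    bit = (lambda * S - ln K) / ln 2
    E   = m * n * 2^(-bit)

where m is the query length and n the total residue count of the
database.  Per query, at most one hit per family is kept: the
maximum-bit-score hit among that family's references that passes the
E-value threshold.  The same family->hit map can alternatively be fed
from external BLAST tabular output (outfmt 6) via
:func:`parse_blast_tabular`.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from famvote.seqio import FamilyDataset, LabeledSequence

# gapped BLOSUM62 (open 11 / extend 1) Karlin-Altschul constants
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_E_THRESHOLD = 10.0


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment hit of a query against a reference sequence."""

    query_id: str
    subject_id: str
    subject_family: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_pct: float
    aln_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must be in [0, 100]")
        if self.e_value < 0.0:
            raise ValueError("e_value must be >= 0")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")


@dataclass
class ScoringParams:
    matrix: str = DEFAULT_MATRIX
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_k: float = DEFAULT_K
    e_threshold: float = DEFAULT_E_THRESHOLD


@dataclass
class ReferenceDB:
    """n_ref reference sequences per family plus the scoring parameters."""

    references: list[LabeledSequence]
    params: ScoringParams
    n_ref: int

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.references)

    @property
    def families(self) -> list[str]:
        return sorted({s.family for s in self.references})

    def reference_ids(self) -> set[str]:
        return {s.id for s in self.references}


def build_reference_db(
    dataset: FamilyDataset,
    n_ref: int = 10,
    seed: int = 0,
    params: ScoringParams | None = None,
) -> ReferenceDB:
    """Sample ``n_ref`` reference sequences per family (seeded).

    The sampled sequences remain part of the training set; their ids
    are recoverable via :meth:`ReferenceDB.reference_ids`.
    """
    rng = random.Random(seed)
    by_family = dataset.by_family()
    short = sorted(
        fam for fam in dataset.families if len(by_family.get(fam, [])) < n_ref
    )
    if short:
        raise ValueError(f"families with fewer than {n_ref} members: {short}")
    refs: list[LabeledSequence] = []
    for fam in dataset.families:
        members = sorted(by_family[fam], key=lambda s: s.id)
        refs.extend(rng.sample(members, n_ref))
    return ReferenceDB(refs, params or ScoringParams(), n_ref)


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.mode = "local"
    # BLAST convention: a gap of length L costs open + L * extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def score_statistics(
    raw_score: int,
    query_len: int,
    db_residues: int,
    karlin_lambda: float = DEFAULT_LAMBDA,
    karlin_k: float = DEFAULT_K,
) -> tuple[float, float]:
    """Karlin–Altschul bit-score and E-value for a raw alignment score."""
    if karlin_lambda <= 0 or karlin_k <= 0:
        raise ValueError("lambda and K must be positive")
    if raw_score < 1 or query_len < 1 or db_residues < 1:
        raise ValueError("raw_score, query_len and db_residues must be >= 1")
    bit = (karlin_lambda * raw_score - math.log(karlin_k)) / math.log(2.0)
    e_value = query_len * db_residues * 2.0 ** (-bit)
    return bit, e_value


def smith_waterman(
    query: LabeledSequence,
    subject: LabeledSequence,
    params: ScoringParams | None = None,
    query_len: int | None = None,
    db_residues: int | None = None,
    _aligner: Align.PairwiseAligner | None = None,
) -> AlignmentHit | None:
    """Optimal affine-gap local alignment of query against subject.

    Returns None (no hit) when the optimal local score is <= 0, i.e.
    the best local alignment is empty.  Identity is counted over all
    alignment columns including gapped ones.  Bit-score/E-value use the
    given search-space sizes (defaults: query length x subject length).
    """
    params = params or ScoringParams()
    aligner = _aligner if _aligner is not None else _make_aligner(params)
    alignments = aligner.align(query.residues, subject.residues)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    raw = int(round(aln.score))
    if raw <= 0:
        return None
    counts = aln.counts()
    aln_length = int(aln.length)
    bit, e_value = score_statistics(
        raw,
        query_len if query_len is not None else len(query),
        db_residues if db_residues is not None else len(subject),
        params.karlin_lambda,
        params.karlin_k,
    )
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        subject_family=subject.family,
        raw_score=raw,
        bit_score=bit,
        e_value=e_value,
        identity_pct=100.0 * counts.identities / aln_length,
        aln_length=aln_length,
    )


def _better(a: AlignmentHit, b: AlignmentHit) -> AlignmentHit:
    """Deterministic best-hit tie-break: bit, then E-value, then id."""
    if a.bit_score != b.bit_score:
        return a if a.bit_score > b.bit_score else b
    if a.e_value != b.e_value:
        return a if a.e_value < b.e_value else b
    return a if a.subject_id <= b.subject_id else b


def reduce_best_per_family(
    hits: Iterable[AlignmentHit], e_threshold: float = DEFAULT_E_THRESHOLD
) -> dict[str, AlignmentHit]:
    """Keep at most one hit per family: the best-bit hit passing E <= cutoff."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if hit.e_value > e_threshold:
            continue
        fam = hit.subject_family
        best[fam] = hit if fam not in best else _better(hit, best[fam])
    return best


def search_reference_db(
    query: LabeledSequence,
    db: ReferenceDB,
    e_threshold: float | None = None,
) -> dict[str, AlignmentHit]:
    """Search all references; return the best passing hit per family.

    Raw scores against every reference are computed score-only first;
    the full alignment (for identity and length) is only produced for
    the best-scoring reference of each family.  Bit-score is monotone
    in raw score, so the per-family argmax is unchanged.
    """
    if not db.references:
        raise ValueError("reference database is empty")
    params = db.params
    cutoff = params.e_threshold if e_threshold is None else e_threshold
    aligner = _make_aligner(params)
    n = db.total_residues

    best_raw: dict[str, tuple[float, str, LabeledSequence]] = {}
    for ref in db.references:
        raw = aligner.score(query.residues, ref.residues)
        if raw <= 0:
            continue
        prev = best_raw.get(ref.family)
        # higher raw wins; ties broken toward lexicographically smaller id
        if prev is None or (raw, prev[1]) > (prev[0], ref.id):
            best_raw[ref.family] = (raw, ref.id, ref)
    out: dict[str, AlignmentHit] = {}
    for fam, (_, _, ref) in best_raw.items():
        hit = smith_waterman(
            query, ref, params, query_len=len(query), db_residues=n, _aligner=aligner
        )
        if hit is not None and hit.e_value <= cutoff:
            out[fam] = hit
    return out


_BLAST6_COLUMNS = 12


def parse_blast_tabular(
    path: str | Path, family_of_subject: Mapping[str, str]
) -> Iterator[AlignmentHit]:
    """Parse BLAST outfmt-6 rows (default 12 columns) into hits.

    Raw score is not present in the default column set; it is
    back-computed from the bit-score so the dataclass stays complete.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _BLAST6_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_BLAST6_COLUMNS} columns, "
                    f"got {len(parts)}"
                )
            qseqid, sseqid = parts[0], parts[1]
            if sseqid not in family_of_subject:
                raise ValueError(
                    f"{path}:{lineno}: subject {sseqid!r} has no family mapping"
                )
            bit = float(parts[11])
            raw = max(1, int(round((bit * math.log(2.0) + math.log(DEFAULT_K))
                                   / DEFAULT_LAMBDA)))
            yield AlignmentHit(
                query_id=qseqid,
                subject_id=sseqid,
                subject_family=family_of_subject[sseqid],
                raw_score=raw,
                bit_score=bit,
                e_value=float(parts[10]),
                identity_pct=float(parts[2]),
                aln_length=int(parts[3]),
            )


def write_reference_db(db: ReferenceDB, fasta_path: str | Path, params_path: str | Path) -> None:
    from famvote.seqio import write_labeled_fasta

    ds = FamilyDataset(db.references, db.families)
    write_labeled_fasta(ds, fasta_path, Path(fasta_path).with_suffix(".labels.tsv"))
    with open(params_path, "w") as fh:
        json.dump(
            {
                "matrix": db.params.matrix,
                "gap_open": db.params.gap_open,
                "gap_extend": db.params.gap_extend,
                "karlin_lambda": db.params.karlin_lambda,
                "karlin_k": db.params.karlin_k,
                "e_threshold": db.params.e_threshold,
                "n_ref": db.n_ref,
            },
            fh,
            indent=2,
        )


def read_reference_db(fasta_path: str | Path, params_path: str | Path) -> ReferenceDB:
    from famvote.seqio import read_labeled_fasta

    with open(params_path) as fh:
        meta = json.load(fh)
    ds = read_labeled_fasta(
        fasta_path, Path(fasta_path).with_suffix(".labels.tsv")
    )
    params = ScoringParams(
        matrix=meta["matrix"],
        gap_open=meta["gap_open"],
        gap_extend=meta["gap_extend"],
        karlin_lambda=meta["karlin_lambda"],
        karlin_k=meta["karlin_k"],
        e_threshold=meta["e_threshold"],
    )
    return ReferenceDB(ds.sequences, params, meta["n_ref"])
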