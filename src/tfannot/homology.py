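"""Local alignment search against a labeled protein database.

Stands in for the BLAST scan feeding the bit-score percentile and PSSM
features: optimal Smith–Waterman alignment under BLOSUM62 with affine gaps,
Karlin–Altschul conversion of raw scores to bit scores, and import/export of
12-column tabular hit files so externally produced hit lists can be used
instead.

Raw scores follow the BLAST convention: a gap of length ``g`` costs
``gap_open + g * gap_extend`` (default 11 + g).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin–Altschul constants.

    Defaults are the BLAST protein defaults: BLOSUM62 with gap open 11,
    gap extend 1, and the published gapped Karlin–Altschul constants
    lambda = 0.267, K = 0.041 for that scheme.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        self.matrix = substitution_matrices.load(self.matrix_name)

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # Biopython charges open_gap_score for the first gapped position;
        # BLAST charges open + extend for a length-1 gap.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class AlignmentHit:
    """One database hit: subject identity, labels, raw and bit score."""

    subject_id: str
    raw_score: float
    bits: float
    label: Optional[str] = None
    superclass: Optional[str] = None
    #: optional residue-level alignment: list of (query_pos, subject_residue),
    #: 0-based query positions; populated when the search keeps alignments
    aligned_pairs: Optional[list] = None


@dataclass
class HitList:
    """Hits for one query, sorted by bit score descending."""

    query_id: str
    hits: list[AlignmentHit] = field(default_factory=list)
    scheme: Optional[ScoringScheme] = None

    def __len__(self):
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def sort(self) -> "HitList":
        self.hits.sort(key=lambda h: (-h.bits, h.subject_id))
        return self


def local_align(query: str, subject: str, scheme: Optional[ScoringScheme] = None,
                aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Optimal local alignment raw score of two sequences.

    The raw score S is the sum of substitution-matrix scores over aligned
    residue pairs minus the affine gap costs.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = (scheme or ScoringScheme()).aligner()
    return float(aligner.score(query, subject))


def raw_to_bits(raw_score: float, scheme: ScoringScheme) -> float:
    """Karlin–Altschul bit score: (lambda * S - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)


def bits_to_raw(bits: float, scheme: ScoringScheme) -> float:
    """Inverse of :func:`raw_to_bits`."""
    return (bits * math.log(2.0) + math.log(scheme.K)) / scheme.lam


def _aligned_pairs(alignment) -> list:
    pairs = []
    target = alignment.target
    query_seq = alignment.query
    for (tstart, tend), (qstart, qend) in zip(*alignment.aligned):
        for off in range(tend - tstart):
            pairs.append((tstart + off, query_seq[qstart + off]))
    return pairs


def search(query: ProteinRecord, db: Sequence[ProteinRecord],
           scheme: Optional[ScoringScheme] = None, min_bits: float = 0.0,
           exclude_self: bool = True, keep_alignments: bool = False) -> HitList:
    """Align ``query`` against every database record and collect hits.

    Hits with bit score >= ``min_bits`` are returned sorted by bit score
    descending, carrying the database records' class labels.  With
    ``exclude_self`` any record whose id equals the query id is skipped, so
    the database effectively never contains the input sequence itself.
    """
    if not db:
        raise ValueError("empty database")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    hits = []
    qseq = query.canonical_sequence()
    for rec in db:
        if exclude_self and rec.id == query.id:
            continue
        if keep_alignments:
            alns = aligner.align(qseq, rec.canonical_sequence())
            raw = float(alns.score)
        else:
            raw = local_align(qseq, rec.canonical_sequence(), aligner=aligner)
        bits = raw_to_bits(raw, scheme)
        if bits < min_bits:
            continue
        hit = AlignmentHit(subject_id=rec.id, raw_score=raw, bits=bits,
                           label=rec.label, superclass=rec.superclass)
        if keep_alignments:
            hit.aligned_pairs = _aligned_pairs(alns[0])
        hits.append(hit)
    return HitList(query_id=query.id, hits=hits, scheme=scheme).sort()


OUTFMT6_COLUMNS = ("qseqid sseqid pident length mismatch gapopen "
                   "qstart qend sstart send evalue bitscore").split()


def export_tabular_hits(hitlist: HitList, path) -> None:
    """Write a hit list as 12-column BLAST-style tabular output.

    Columns with no meaning for score-only hits (pident, mismatch, ...) are
    written as zeros; the e-value column is written as NA (e-values are not
    computed — filtering is by bit score only).
    """
    with open(path, "w") as fh:
        for hit in hitlist:
            row = [hitlist.query_id, hit.subject_id, "0.0", "0", "0", "0",
                   "0", "0", "0", "0", "NA", f"{hit.bits:.6f}"]
            fh.write("\t".join(row) + "\n")


def ingest_tabular_hits(path, label_map: dict,
                        scheme: Optional[ScoringScheme] = None) -> HitList:
    """Read a 12-column tabular hit file (BLAST outfmt-6 dialect).

    ``label_map`` maps subject id to a label — either ``"TF"``/``"non-TF"``
    or a ``(label, superclass)`` tuple.  Subjects absent from the map are
    dropped (count logged).  Raw scores are back-computed from the bit
    scores under ``scheme``.
    """
    scheme = scheme or ScoringScheme()
    hits = []
    query_id = None
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(cols)}")
            qid, sid = cols[0], cols[1]
            if query_id is None:
                query_id = qid
            try:
                bits = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad bit score "
                                 f"{cols[11]!r}") from exc
            if sid not in label_map:
                dropped += 1
                continue
            entry = label_map[sid]
            if isinstance(entry, tuple):
                label, superclass = entry
            else:
                label, superclass = entry, None
            hits.append(AlignmentHit(subject_id=sid,
                                     raw_score=bits_to_raw(bits, scheme),
                                     bits=bits, label=label,
                                     superclass=superclass))
    if dropped:
        logger.info("ingest_tabular_hits: dropped %d hits with unknown "
                    "subjects", dropped)
    return HitList(query_id=query_id or "", hits=hits, scheme=scheme).sort()


def read_label_map(path) -> dict:
    """Read a two/three-column TSV (subject id, label[, superclass])."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) >= 3 and cols[2]:
                out[cols[0]] = (cols[1], cols[2])
            else:
                out[cols[0]] = cols[1]
    return out
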