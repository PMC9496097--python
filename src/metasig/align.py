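"""Optimal local alignment with identity / coverage bookkeeping.

Wraps Biopython's :class:`Bio.Align.PairwiseAligner` (Smith-Waterman with
affine gaps). Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend``, so the protein defaults (BLOSUM62, 11/1) score
like a standard protein similarity search.

Percent identity is ``100 * matches / aligned columns`` where columns include
gap positions inside the local alignment span. Relative alignment length
(coverage) is the fraction of the *subject* (reference) sequence consumed by
the alignment, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import PROTEIN_ALPHABET


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    percent_identity: float
    relative_alignment_length: float
    query_range: tuple[int, int]
    subject_range: tuple[int, int]


def make_protein_aligner(matrix: str = "BLOSUM62",
                         gap_open: float = 11.0,
                         gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # PairwiseAligner charges open on the first gapped column; shift so a
    # length-L gap costs gap_open + L * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{label}: invalid residues {sorted(bad)}")


def local_align(query: str, subject: str,
                aligner: Align.PairwiseAligner | None = None,
                query_id: str = "query", subject_id: str = "subject") -> AlignmentHit:
    """Best local alignment of ``query`` against ``subject``.

    Returns a zero-score hit (identity and coverage 0) when no positive-scoring
    local alignment exists.
    """
    _check_protein(query, query_id)
    _check_protein(subject, subject_id)
    if aligner is None:
        aligner = make_protein_aligner()
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentHit(query_id, subject_id, 0.0, 0.0, 0.0, (0, 0), (0, 0))
    aln = alignments[0]
    counts = aln.counts()  # gaps / identities / mismatches within the local span
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qblocks, sblocks = aln.aligned
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
    coverage = 100.0 * (send - sstart) / len(subject)
    return AlignmentHit(query_id, subject_id, float(aln.score), identity, coverage,
                        (qstart, qend), (sstart, send))
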