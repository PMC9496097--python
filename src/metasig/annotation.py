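"""ORF discovery on contigs and protein annotation against the enzyme catalog.

ORFs are ATG-to-stop spans found in all six reading frames (the longest ORF
per in-frame stop: the first ATG after the previous stop). Each ORF's
translation is locally aligned against the catalog proteins and annotated to
the best-scoring hit that reaches the admission thresholds of percent
identity >= 60 and relative alignment length >= 90 (coverage of the
reference protein). A shared amino-acid k-mer prefilter keeps the exhaustive
alignment desk-scale without changing which hits can pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import AlignmentHit, local_align, make_protein_aligner
from .catalog import Catalog
from .seqio import revcomp, translate

logger = logging.getLogger(__name__)

START_CODON = 14          # ATG encoded as 4*4*A + 4*T + G with A,C,G,T=0..3
STOP_CODONS = frozenset((48, 50, 56))  # TAA, TAG, TGA
_ENC = np.full(256, 4, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i


@dataclass
class Orf:
    orf_id: str
    contig_id: str
    start: int           # 0-based half-open, forward-strand coordinates
    end: int
    strand: str          # '+' or '-'
    frame: int           # 0-2 on the scanned strand
    aa_sequence: str     # stop excluded
    nt_sequence: str     # coding strand, stop included


@dataclass
class GeneAnnotation:
    orf: Orf
    entry_id: str
    enzyme_name: str
    hit: AlignmentHit

    @property
    def orf_id(self) -> str:
        return self.orf.orf_id

    @property
    def contig_id(self) -> str:
        return self.orf.contig_id


def _scan_strand(codes: np.ndarray, frame: int):
    """Yield (start_codon_idx, stop_codon_idx) pairs on one strand/frame.

    Codon positions are indices into the codon grid of this frame. A codon
    containing a non-ACGT base breaks the frame: no ORF spans it.
    """
    usable = (len(codes) - frame) // 3
    if usable <= 0:
        return
    c = codes[frame:frame + 3 * usable].reshape(usable, 3)
    invalid = (c == 4).any(axis=1)
    vals = c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
    is_stop = np.isin(vals, tuple(STOP_CODONS)) & ~invalid
    is_break = is_stop | invalid
    is_atg = (vals == START_CODON) & ~invalid
    atg_pos = np.flatnonzero(is_atg)
    prev = -1
    for b in np.flatnonzero(is_break):
        if is_stop[b]:
            i = np.searchsorted(atg_pos, prev + 1)
            if i < len(atg_pos) and atg_pos[i] < b:
                yield int(atg_pos[i]), int(b)
        prev = b


def find_orfs(contig_id: str, sequence: str, min_nt_length: int = 150) -> list[Orf]:
    """All-frame ORF scan of one contig.

    Reported length includes the stop codon; ORFs without an in-frame stop
    inside the contig are not reported. Reverse-strand ORFs are expressed in
    forward coordinates with strand '-'.
    """
    orfs = []
    L = len(sequence)
    seqs = {"+": sequence, "-": revcomp(sequence)}
    n = 0
    for strand in "+-":
        s = seqs[strand]
        codes = _ENC[np.frombuffer(s.encode(), dtype=np.uint8)]
        for frame in range(3):
            for a, b in _scan_strand(codes, frame):
                start_nt = frame + 3 * a
                end_nt = frame + 3 * (b + 1)
                if end_nt - start_nt < min_nt_length:
                    continue
                nt = s[start_nt:end_nt]
                if strand == "-":
                    start_fwd, end_fwd = L - end_nt, L - start_nt
                else:
                    start_fwd, end_fwd = start_nt, end_nt
                aa = translate(nt)[:-1]
                orfs.append(Orf(f"{contig_id}:orf{n:04d}", contig_id,
                                start_fwd, end_fwd, strand, frame, aa, nt))
                n += 1
    return orfs


class CatalogSearcher:
    """Alignment of ORF translations against a catalog with a k-mer prefilter.

    An ORF is aligned to a catalog entry only when the two share at least one
    exact amino-acid ``prefilter_k``-mer and the ORF is long enough for the
    coverage threshold to be attainable. With the default k=6 this removes
    essentially all spurious random-ORF alignments while homologs above the
    admission identity threshold always share many exact 6-mers.
    """

    def __init__(self, catalog: Catalog, prefilter_k: int = 6,
                 matrix: str = "BLOSUM62", gap_open: float = 11.0,
                 gap_extend: float = 1.0):
        self.catalog = catalog
        self.k = prefilter_k
        self.aligner = make_protein_aligner(matrix, gap_open, gap_extend)
        self._kmers: dict[str, set[str]] = {}
        for entry in catalog:
            seq = entry.protein_sequence
            for i in range(len(seq) - prefilter_k + 1):
                self._kmers.setdefault(seq[i:i + prefilter_k], set()).add(entry.entry_id)

    def candidates(self, aa: str) -> set[str]:
        found: set[str] = set()
        for i in range(len(aa) - self.k + 1):
            hit = self._kmers.get(aa[i:i + self.k])
            if hit:
                found |= hit
        return found


def passes_thresholds(hit: AlignmentHit, identity_min: float = 60.0,
                      coverage_min: float = 90.0) -> bool:
    """Admission rule for catalog hits: identity >= identity_min AND relative
    alignment length >= coverage_min (both inclusive)."""
    return (hit.percent_identity >= identity_min and
            hit.relative_alignment_length >= coverage_min)


def annotate_orfs(orfs: list[Orf], catalog: Catalog,
                  identity_min: float = 60.0, coverage_min: float = 90.0,
                  searcher: CatalogSearcher | None = None) -> list[GeneAnnotation]:
    """Annotate ORFs with their best passing catalog hit.

    A hit passes iff percent identity >= ``identity_min`` and relative
    alignment length (percent of the reference protein covered) >=
    ``coverage_min``. Among passing hits the best raw score wins; ties break
    to higher identity, then lexicographic entry id. ORFs with no passing
    hit are left unannotated.
    """
    if len(catalog) == 0:
        logger.warning("annotate_orfs: empty catalog, all ORFs unannotated")
        return []
    if searcher is None:
        searcher = CatalogSearcher(catalog)
    annotations = []
    for orf in orfs:
        best = None
        for entry_id in sorted(searcher.candidates(orf.aa_sequence)):
            entry = searcher.catalog.get(entry_id)
            ref_len = len(entry.protein_sequence)
            if 100.0 * len(orf.aa_sequence) < coverage_min * ref_len:
                continue  # coverage threshold unattainable
            hit = local_align(orf.aa_sequence, entry.protein_sequence,
                              searcher.aligner, orf.orf_id, entry_id)
            if not passes_thresholds(hit, identity_min, coverage_min):
                continue
            if best is None or (hit.raw_score, hit.percent_identity, _neg(entry_id)) > \
                    (best.raw_score, best.percent_identity, _neg(best.subject_id)):
                best = hit
        if best is not None:
            entry = searcher.catalog.get(best.subject_id)
            annotations.append(GeneAnnotation(orf, entry.entry_id, entry.enzyme_name, best))
    return annotations


class _neg:
    """Order-reversing wrapper so lexicographically *lowest* id wins a max()."""

    def __init__(self, value: str):
        self.value = value

    def __lt__(self, other):
        return self.value > other.value

    def __gt__(self, other):
        return self.value < other.value

    def __eq__(self, other):
        return self.value == other.value
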