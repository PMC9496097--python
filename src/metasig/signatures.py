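"""Signature pairs (taxon; gene): contig taxonomy joined with gene annotations.

Contigs carrying annotated ORFs are classified with the k-mer classifier at
a permissive confidence of 0.01; contigs left unclassified are discarded.
Contigs classified above the species rank get a second chance through a
nucleotide alignment against the reference genomes, accepted only when the
best identity is strictly greater than 90% (alignments with identity <= 90%
are filtered out). The surviving (taxon, enzyme) combinations become
signature pairs whose per-sample abundance is the sum of the normalized
abundances of their contributing ORFs; pairs present in fewer than half of
the samples are excluded from comparative analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .profiling import UNCLASSIFIED, KmerIndex, classify, prevalence_filter
from .seqio import revcomp

_CIGAR = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ContigTaxon:
    contig_id: str
    taxon_id: str | None          # the accepted call (species or genus id), or None
    species_id: str | None
    genus_id: str | None
    assignment_route: str          # 'kmer_classifier' | 'fallback_alignment' | 'discarded'
    reason: str = ""
    fallback_identity: float | None = None


def _infix_identity(query: str, target: str) -> float:
    """Percent identity of the best infix (glocal) alignment of query in target.

    Computed with edlib over both strands; identity is matches over alignment
    columns of the best-edit-distance placement.
    """
    best = 0.0
    for q in (query, revcomp(query)):
        res = edlib.align(q, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        columns = sum(int(n) for n, _ in _CIGAR.findall(res["cigar"]))
        if columns == 0:
            continue
        identity = 100.0 * (columns - res["editDistance"]) / columns
        best = max(best, identity)
    return best


def assign_contig_taxon(contig_id: str, sequence: str, kmer_index: KmerIndex,
                        reference_genomes, confidence: float = 0.01,
                        fallback_identity_min: float = 90.0) -> ContigTaxon:
    """Taxonomic call for one contig, with the alignment fallback.

    Route 'kmer_classifier' when the classifier settles the call;
    'fallback_alignment' when a genome alignment with identity strictly
    above ``fallback_identity_min`` supplies the species; 'discarded' when
    the classifier returns UNCLASSIFIED (or the contig is shorter than k).
    """
    taxonomy = kmer_index.taxonomy
    if len(sequence) < kmer_index.k:
        return ContigTaxon(contig_id, None, None, None, "discarded",
                           f"shorter than k={kmer_index.k}")
    cls = classify(sequence, kmer_index, confidence)
    if cls.taxon == UNCLASSIFIED:
        return ContigTaxon(contig_id, None, None, None, "discarded", "unclassified")
    rank = taxonomy.rank(cls.taxon)
    species = cls.taxon if rank == "species" else None
    genus = taxonomy.ancestor_at(cls.taxon, "genus")
    if species is not None:
        return ContigTaxon(contig_id, cls.taxon, species, genus, "kmer_classifier")
    # no species-level call: nucleotide alignment against reference genomes
    best_id, best_sp = 0.0, None
    for genome in reference_genomes:
        sp, seq = (genome if isinstance(genome, tuple)
                   else (genome.species_taxon, genome.sequence))
        identity = _infix_identity(sequence, seq)
        if identity > best_id:
            best_id, best_sp = identity, sp
    if best_sp is not None and best_id > fallback_identity_min:
        return ContigTaxon(contig_id, best_sp, best_sp,
                           taxonomy.ancestor_at(best_sp, "genus"),
                           "fallback_alignment", fallback_identity=best_id)
    reason = (f"fallback identity {best_id:.1f} <= {fallback_identity_min:g}"
              if best_sp is not None else "no fallback alignment")
    if genus is not None:
        return ContigTaxon(contig_id, genus, None, genus, "kmer_classifier", reason)
    return ContigTaxon(contig_id, cls.taxon, None, None, "kmer_classifier",
                       f"call above genus; {reason}")


@dataclass
class SignatureTable:
    level: str
    abundance: pd.DataFrame               # (taxon, gene) MultiIndex x samples
    provenance: dict[tuple[str, str], list[str]]  # pair -> contributing ORF ids
    all_pairs: pd.DataFrame = field(default=None, repr=False)  # before prevalence filter


def build_signatures(annotations: list[GeneAnnotation],
                     contig_taxa: dict[str, ContigTaxon],
                     normalized_orf_abundances: pd.DataFrame,
                     level: str, min_prevalence: float = 0.5) -> SignatureTable:
    """Assemble (taxon; gene) pairs at 'genus' or 'species' level.

    A pair's abundance in a sample is the sum of the normalized abundances of
    every ORF annotated to that enzyme on a contig assigned to that taxon at
    the requested level; ORFs on discarded contigs are excluded. Pairs are
    then prevalence-filtered (detected in >= ``min_prevalence`` of samples).
    """
    if level not in ("genus", "species"):
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    rows: dict[tuple[str, str], np.ndarray] = {}
    provenance: dict[tuple[str, str], list[str]] = {}
    n_samples = normalized_orf_abundances.shape[1]
    for ann in annotations:
        ct = contig_taxa.get(ann.contig_id)
        if ct is None:
            raise ValueError(f"no ContigTaxon record for contig {ann.contig_id!r}")
        if ct.assignment_route == "discarded":
            continue
        taxon = ct.species_id if level == "species" else ct.genus_id
        if taxon is None:
            continue
        if ann.orf_id not in normalized_orf_abundances.index:
            continue
        key = (taxon, ann.enzyme_name)
        vec = normalized_orf_abundances.loc[ann.orf_id].to_numpy(dtype=float)
        if key in rows:
            rows[key] = rows[key] + vec
        else:
            rows[key] = vec.copy()
        provenance.setdefault(key, []).append(ann.orf_id)
    if rows:
        table = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=normalized_orf_abundances.columns)
        table.index = pd.MultiIndex.from_tuples(table.index, names=["taxon", "gene"])
        table = table.sort_index()
    else:
        table = pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["taxon", "gene"]),
            columns=normalized_orf_abundances.columns, dtype=float)
    filtered = prevalence_filter(table, min_prevalence) if n_samples else table
    return SignatureTable(level, filtered, provenance, all_pairs=table)


NC = "N.C."      # median in the control (HC) group is 0: ratio non-countable
UNDEF = "UNDEF"  # median in the case (PwD) group is 0: log undefined


def log_median_ratio(pair_abundances, group_labels, case: str = "PwD",
                     control: str = "HC") -> float | str:
    """log10 of the case/control median-abundance ratio for one pair.

    Returns the literal flag 'N.C.' when the control median is 0 (including
    the both-zero case) and 'UNDEF' when only the case median is 0.
    """
    values = np.asarray(pair_abundances, dtype=float)
    labels = np.asarray(group_labels)
    x = values[labels == case]
    y = values[labels == control]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one sample")
    med_case, med_ctrl = np.median(x), np.median(y)
    if med_ctrl == 0:
        return NC
    if med_case == 0:
        return UNDEF
    return float(np.log10(med_case / med_ctrl))


def log_ratio_matrix(table: SignatureTable, group_labels: pd.Series,
                     case: str = "PwD", control: str = "HC") -> pd.DataFrame:
    """Gene x taxon matrix of log10 median ratios with literal 'N.C.' flags.

    Mirrors the heatmap layout used to report signature changes: one row per
    enzyme gene, one column per taxon, cells holding the log ratio, 'N.C.'
    (control median 0) or 'UNDEF' (case median 0).
    """
    labels = group_labels.loc[table.abundance.columns].to_numpy()
    cells = {}
    for (taxon, gene), row in table.abundance.iterrows():
        cells.setdefault(gene, {})[taxon] = log_median_ratio(
            row.to_numpy(), labels, case, control)
    return pd.DataFrame(cells).T.sort_index()


def audit_table(contig_taxa: dict[str, ContigTaxon]) -> pd.DataFrame:
    """Per-contig audit log: route, accepted taxon, reason."""
    return pd.DataFrame(
        [{"contig_id": ct.contig_id, "route": ct.assignment_route,
          "taxon": ct.taxon_id or "", "species": ct.species_id or "",
          "genus": ct.genus_id or "", "reason": ct.reason,
          "fallback_identity": ("" if ct.fallback_identity is None
                                else round(ct.fallback_identity, 2))}
         for ct in contig_taxa.values()]
    ).set_index("contig_id").sort_index()
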