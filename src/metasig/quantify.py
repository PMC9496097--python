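"""Per-sample ORF abundances: seeded exact-k-mer read mapping + TMM.

Reads are assigned to the ORF nucleotide sequence sharing the most canonical
``k_seed``-mers, provided that count exceeds half the read's k-mers (ties
break to the lexicographically lowest ORF id). Counts are normalized between
samples with the Trimmed Mean of M-values (TMM): per-library scaling factors
from doubly trimmed, inverse-variance-weighted log-ratios against a
reference sample, rescaled to geometric mean 1. Normalized abundances are
counts per million of the effective (factor-adjusted) library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiling import canonical_kmers

logger = logging.getLogger(__name__)


@dataclass
class MappingStats:
    assigned: int
    unassigned: int
    skipped: int  # reads shorter than k_seed

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.skipped


def build_orf_kmer_index(orf_nt_sequences: dict[str, str], k_seed: int = 15):
    """k-mer index over *representative* ORF sequences.

    ORFs with byte-identical sequences always tie in shared-k-mer count, and
    the tie-break hands the read to the lexicographically lowest id — so
    identical ORFs are collapsed onto their lowest-id representative up
    front, preserving the assignment semantics exactly while keeping the
    index small when the same gene is rediscovered in many samples.
    """
    rep_of: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    for orf_id in sorted(orf_nt_sequences):
        seq = orf_nt_sequences[orf_id]
        rep_of[orf_id] = by_seq.setdefault(seq, orf_id)
    index: dict[str, list[str]] = {}
    for seq, rep in by_seq.items():
        for km in set(k for k in canonical_kmers(seq, k_seed) if k is not None):
            index.setdefault(km, []).append(rep)
    for lst in index.values():
        lst.sort()
    return index


def map_reads(reads, orf_nt_sequences: dict[str, str], k_seed: int = 15,
              index=None) -> tuple[dict[str, int], MappingStats]:
    """Assign reads to ORFs by shared canonical k-mer count.

    ``reads``: iterable of sequences or (name, seq[, qual]) tuples. A read is
    assigned to the ORF sharing the most k-mers with it iff that count
    exceeds half of the read's k-mers; ties go to the lowest ORF id.
    """
    if index is None:
        index = build_orf_kmer_index(orf_nt_sequences, k_seed)
    counts = {orf_id: 0 for orf_id in orf_nt_sequences}
    assigned = unassigned = skipped = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        if len(seq) < k_seed:
            skipped += 1
            continue
        kmers = canonical_kmers(seq, k_seed)
        tally: dict[str, int] = {}
        for km in kmers:
            if km is None:
                continue
            for orf_id in index.get(km, ()):
                tally[orf_id] = tally.get(orf_id, 0) + 1
        if not tally:
            unassigned += 1
            continue
        best = max(tally.values())
        if best * 2 <= len(kmers):
            unassigned += 1
            continue
        winner = min(o for o, c in tally.items() if c == best)
        counts[winner] += 1
        assigned += 1
    return counts, MappingStats(assigned, unassigned, skipped)


def count_matrix(per_sample_counts: dict[str, dict[str, int]],
                 library_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Feature x sample integer count table; columns ordered by sample id.

    ``library_sizes`` (total reads per sample, including unassigned) is
    attached as ``df.attrs['library_sizes']`` when provided.
    """
    df = pd.DataFrame(per_sample_counts).fillna(0).astype(int)
    df = df.sort_index()[sorted(df.columns)]
    if library_sizes is not None:
        df.attrs["library_sizes"] = dict(library_sizes)
    return df


@dataclass
class NormalizationFactors:
    factors: pd.Series  # per-sample positive factor, geometric mean 1
    reference: str


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                abs_trim: float = 0.05) -> NormalizationFactors:
    """Trimmed Mean of M-values scaling factors.

    The reference is the sample whose upper-quartile/library-size ratio is
    closest to the mean such ratio. For each sample, over features with
    nonzero counts in both the sample and the reference, the log2 ratio M and
    log2 average abundance A are doubly trimmed (``logratio_trim`` of M at
    each end, ``abs_trim`` of A at each end) and the surviving M values are
    averaged with inverse delta-method variance weights. Factors are rescaled
    to geometric mean 1. Samples with fewer than 5 doubly surviving features
    get factor 1 with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("every sample needs at least one nonzero feature")
    uq = np.quantile(y, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts.columns[ref_idx]
    yr, nr = y[:, ref_idx], lib[ref_idx]
    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        yk, nk = y[:, j], lib[j]
        ok = (yk > 0) & (yr > 0)
        n = int(ok.sum())
        if n < 5:
            logger.warning("tmm_factors: sample %s has %d shared features; factor 1",
                           counts.columns[j], n)
            continue
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        v = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m = np.floor(n * logratio_trim) + 1
        lo_a = np.floor(n * abs_trim) + 1
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        if keep.sum() < 5:
            logger.warning("tmm_factors: sample %s has %d surviving features; factor 1",
                           counts.columns[j], int(keep.sum()))
            continue
        # inverse-variance weighting: v is the delta-method variance of M
        logf[j] = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    factors = 2.0 ** (logf - logf.mean())
    return NormalizationFactors(pd.Series(factors, index=counts.columns), str(ref))


def normalize(counts: pd.DataFrame, factors: NormalizationFactors,
              library_sizes: dict[str, float] | None = None,
              scale: float = 1e6) -> pd.DataFrame:
    """Relative abundances a_gk = scale * y_gk / (N_k * f_k).

    Library sizes default to ``counts.attrs['library_sizes']`` when present,
    else the column sums of the counted features.
    """
    if library_sizes is None:
        library_sizes = counts.attrs.get("library_sizes")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes, dtype=float).loc[counts.columns]
    eff = lib * factors.factors.loc[counts.columns]
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    return counts / eff * scale


def gene_level(orf_abundance: pd.DataFrame,
               orf_to_enzyme: dict[str, str]) -> pd.DataFrame:
    """Sum ORF-level abundances into enzyme (gene) level rows.

    ORFs without an annotation are dropped.
    """
    annotated = orf_abundance.loc[orf_abundance.index.intersection(orf_to_enzyme)]
    if annotated.empty:
        return pd.DataFrame(columns=orf_abundance.columns)
    return annotated.groupby(lambda o: orf_to_enzyme[o]).sum().sort_index()
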