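"""k-mer LCA taxonomic classification and abundance profiling.

A reference index maps every canonical k-mer of the reference genomes to the
lowest common ancestor (LCA) of the species containing it. A sequence is
classified by tallying its k-mer hits over the taxonomy, picking the
candidate with the highest root-to-node accumulated weight, and raising the
call toward the root until the confidence — the fraction of all queried
k-mers that fall inside the assigned clade — reaches the threshold. Reads
are profiled at a confidence of 0.5; contigs (for signature reconstruction)
at 0.01.

Sample profiles redistribute reads assigned at supra-species ranks down to
species in proportion to the reads directly assigned to those species in the
same sample, and report relative abundances over classified reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .seqio import revcomp
from .taxonomy import RANK_DEPTH, TaxonomyTree

UNCLASSIFIED = "UNCLASSIFIED"

_VALID = frozenset("ACGT")


def canonical_kmers(seq: str, k: int) -> list[str | None]:
    """Canonical (lexicographic min of k-mer / reverse complement) k-mers.

    Positions whose k-mer contains a non-ACGT character yield None.
    """
    seq = seq.upper()
    rc = revcomp(seq)
    n = len(seq)
    clean = _VALID.issuperset(seq)
    out = []
    for i in range(n - k + 1):
        kmer = seq[i:i + k]
        if not clean and not _VALID.issuperset(kmer):
            out.append(None)
            continue
        rkmer = rc[n - k - i:n - i]
        out.append(kmer if kmer <= rkmer else rkmer)
    return out


@dataclass
class Classification:
    taxon: str            # taxon_id or UNCLASSIFIED
    confidence: float
    n_kmers_queried: int


class KmerIndex:
    """Canonical k-mer -> LCA taxon map over a reference genome set."""

    def __init__(self, k: int, mapping: dict[str, str], taxonomy: TaxonomyTree,
                 species: list[str]):
        if k < 11 or k % 2 == 0:
            raise ValueError("k must be odd and >= 11")
        self.k = k
        self.mapping = mapping
        self.taxonomy = taxonomy
        self.species = sorted(species)  # species with indexed genomes

    def __len__(self) -> int:
        return len(self.mapping)


def build_index(genomes, taxonomy: TaxonomyTree, k: int = 31) -> KmerIndex:
    """Index reference genomes: each k-mer maps to the LCA of its carriers.

    ``genomes`` is an iterable of objects with ``species_taxon`` and
    ``sequence`` attributes (or (species_id, sequence) tuples).
    """
    mapping: dict[str, str] = {}
    species = []
    for genome in genomes:
        if isinstance(genome, tuple):
            sp, seq = genome
        else:
            sp, seq = genome.species_taxon, genome.sequence
        if sp not in taxonomy:
            raise ValueError(f"species {sp!r} not in taxonomy")
        if len(seq) < k:
            raise ValueError(f"k={k} larger than genome of {sp}")
        species.append(sp)
        for kmer in set(km for km in canonical_kmers(seq, k) if km is not None):
            cur = mapping.get(kmer)
            if cur is None:
                mapping[kmer] = sp
            elif cur != sp:
                mapping[kmer] = taxonomy.lca([cur, sp])
    return KmerIndex(k, mapping, taxonomy, species)


def classify(sequence: str, index: KmerIndex,
             confidence_threshold: float = 0.5) -> Classification:
    """Classify one sequence against the index.

    The candidate is the hit taxon with the highest accumulated root-to-node
    k-mer weight (ties resolved to the LCA of the tied candidates); it is
    then raised toward the root until the clade contains at least
    ``confidence_threshold`` of all queried k-mers, or declared UNCLASSIFIED
    if even the root cannot.
    """
    k = index.k
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    taxonomy = index.taxonomy
    kmers = canonical_kmers(sequence, k)
    n_queried = len(kmers)
    weights: Counter[str] = Counter()
    for km in kmers:
        if km is None:
            continue
        taxon = index.mapping.get(km)
        if taxon is not None:
            weights[taxon] += 1
    if not weights:
        return Classification(UNCLASSIFIED, 0.0, n_queried)
    # candidates: hit taxa that are not strict ancestors of other hit taxa
    hit_paths = {t: taxonomy.ancestors(t) for t in weights}
    ancestors_of_hits = set()
    for t, path in hit_paths.items():
        ancestors_of_hits.update(path[:-1])
    candidates = [t for t in weights if t not in ancestors_of_hits]
    path_weight = {t: sum(weights.get(a, 0) for a in hit_paths[t])
                   for t in candidates}
    best = max(path_weight.values())
    tied = [t for t in candidates if path_weight[t] == best]
    node = tied[0] if len(tied) == 1 else taxonomy.lca(tied)
    # clade weight at every ancestor of every hit taxon
    clade: Counter[str] = Counter()
    for t, w in weights.items():
        for a in hit_paths[t]:
            clade[a] += w
    while True:
        conf = clade.get(node, 0) / n_queried
        if conf >= confidence_threshold:
            return Classification(node, conf, n_queried)
        parent = taxonomy.node(node).parent
        if parent is None:
            return Classification(UNCLASSIFIED, 0.0, n_queried)
        node = parent


@dataclass
class AbundanceProfile:
    level: str
    abundances: pd.Series  # taxon_id -> relative abundance over classified mass
    n_reads_classified: int
    n_reads_total: int


def profile_sample(reads, index: KmerIndex,
                   confidence_threshold: float = 0.5) -> AbundanceProfile:
    """Species-level relative abundance profile of one sample's reads.

    ``reads`` is an iterable of sequences or (name, sequence[, qual]) tuples.
    Reads classified at supra-species ranks are redistributed over the
    descendant species proportionally to this sample's directly assigned
    species counts; clades with no direct species counts fall back to a
    uniform split over their indexed species.
    """
    taxonomy = index.taxonomy
    counts: Counter[str] = Counter()
    n_total = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        n_total += 1
        if len(seq) < index.k:
            continue
        cls = classify(seq, index, confidence_threshold)
        if cls.taxon != UNCLASSIFIED:
            counts[cls.taxon] += 1
    n_classified = sum(counts.values())
    if n_classified == 0:
        return AbundanceProfile("species", pd.Series(dtype=float), 0, n_total)
    direct = {t: c for t, c in counts.items() if taxonomy.rank(t) == "species"}
    mass: Counter[str] = Counter(direct)
    indexed = set(index.species)
    for taxon, c in counts.items():
        if taxonomy.rank(taxon) == "species":
            continue
        descendants = [s for s in taxonomy.species_under(taxon) if s in indexed]
        if not descendants:
            continue  # no indexed species below: mass dropped, conservation noted
        w = np.array([direct.get(s, 0) for s in descendants], dtype=float)
        if w.sum() == 0:
            w = np.ones(len(descendants))
        w = w / w.sum()
        for s, frac in zip(descendants, w):
            mass[s] += c * frac
    total = sum(mass.values())
    ab = pd.Series({t: v / total for t, v in sorted(mass.items())}, dtype=float)
    return AbundanceProfile("species", ab, n_classified, n_total)


def aggregate_level(profile: AbundanceProfile, rank: str,
                    taxonomy: TaxonomyTree) -> AbundanceProfile:
    """Sum child abundances into their ancestors at ``rank``; mass conserved."""
    if rank not in RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    agg: dict[str, float] = {}
    for taxon, value in profile.abundances.items():
        anc = taxonomy.ancestor_at(taxon, rank)
        if anc is None:  # node already above the requested rank
            anc = taxon
        agg[anc] = agg.get(anc, 0.0) + value
    return AbundanceProfile(rank, pd.Series(dict(sorted(agg.items())), dtype=float),
                            profile.n_reads_classified, profile.n_reads_total)


def aggregate_matrix(matrix: pd.DataFrame, taxonomy: TaxonomyTree,
                     rank: str) -> pd.DataFrame:
    """Aggregate a taxon x sample matrix to ``rank`` by summing descendants."""
    if rank not in RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    mapper = {t: (taxonomy.ancestor_at(t, rank) or t) for t in matrix.index}
    return matrix.groupby(mapper).sum().sort_index()


def prevalence_filter(feature_matrix: pd.DataFrame,
                      min_fraction: float = 0.5) -> pd.DataFrame:
    """Drop features detected in fewer than ceil(min_fraction * n_samples) samples.

    Columns are samples (the combined cohort); a feature counts as detected
    in a sample when its value is nonzero.
    """
    if feature_matrix.shape[1] == 0 or feature_matrix.shape[0] == 0:
        return feature_matrix.copy()
    need = ceil(min_fraction * feature_matrix.shape[1])
    detected = (feature_matrix != 0).sum(axis=1)
    return feature_matrix.loc[detected >= need].copy()


def profile_matrix(samples_reads: dict[str, list], index: KmerIndex,
                   confidence_threshold: float = 0.5) -> pd.DataFrame:
    """Species x sample relative-abundance matrix over several samples."""
    cols = {}
    for sample_id, reads in samples_reads.items():
        profile = profile_sample(reads, index, confidence_threshold)
        cols[sample_id] = profile.abundances
    return pd.DataFrame(cols).fillna(0.0).sort_index()
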