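"""k-mer LCA classifier: index correctness, confidence semantics, profiles."""

import numpy as np
import pytest

from metasig.profiling import (UNCLASSIFIED, AbundanceProfile, aggregate_level,
                               build_index, canonical_kmers, classify,
                               prevalence_filter, profile_sample)
from metasig.seqio import revcomp
from metasig.taxonomy import TaxonomyTree

import pandas as pd


def _tiny_taxonomy():
    return TaxonomyTree.from_lineages(
        {"gA_s1": "gA", "gA_s2": "gA", "gB_s1": "gB"})


def _random_genomes(rng, lengths):
    return [("gA_s1", _dna(rng, lengths[0])), ("gA_s2", _dna(rng, lengths[1])),
            ("gB_s1", _dna(rng, lengths[2]))]


def _dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestIndex:
    def test_unique_genome_all_kmers_map_to_species(self):
        rng = np.random.default_rng(0)
        tax = _tiny_taxonomy()
        seq = _dna(rng, 300)
        idx = build_index([("gA_s1", seq)], tax, k=21)
        kmers = set(km for km in canonical_kmers(seq, 21))
        assert len(idx) == len(kmers)
        assert set(idx.mapping.values()) == {"gA_s1"}

    def test_shared_region_maps_to_genus_lca(self):
        rng = np.random.default_rng(1)
        tax = _tiny_taxonomy()
        shared = _dna(rng, 80)
        g1 = _dna(rng, 200) + shared
        g2 = shared + _dna(rng, 200)
        idx = build_index([("gA_s1", g1), ("gA_s2", g2)], tax, k=21)
        shared_kmers = set(canonical_kmers(shared, 21))
        for km in shared_kmers:
            assert idx.mapping[km] == "gA"

    def test_index_equals_bruteforce_lca_oracle(self):
        """Every key's taxon equals the LCA (computed by brute force over the
        genome set) of the species whose genome contains the k-mer."""
        rng = np.random.default_rng(2)
        tax = _tiny_taxonomy()
        shared = _dna(rng, 60)
        genomes = [("gA_s1", _dna(rng, 150) + shared),
                   ("gA_s2", shared + _dna(rng, 150)),
                   ("gB_s1", _dna(rng, 100) + shared[:40] + _dna(rng, 60))]
        k = 15
        idx = build_index(genomes, tax, k=k)
        per_genome = {sp: set(canonical_kmers(seq, k)) for sp, seq in genomes}
        for km, taxon in idx.mapping.items():
            carriers = [sp for sp, kms in per_genome.items() if km in kms]
            assert taxon == tax.lca(carriers)

    def test_even_or_small_k_rejected(self):
        tax = _tiny_taxonomy()
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            build_index([("gA_s1", _dna(rng, 100))], tax, k=20)


class TestClassify:
    def test_exact_substring_full_confidence(self):
        rng = np.random.default_rng(4)
        tax = _tiny_taxonomy()
        genomes = _random_genomes(rng, (500, 500, 500))
        idx = build_index(genomes, tax, k=21)
        read = genomes[0][1][100:250]
        cls = classify(read, idx, 0.5)
        assert cls.taxon == "gA_s1"
        assert cls.confidence == pytest.approx(1.0)

    def test_half_hits_below_threshold_unclassified(self):
        """A read whose k-mers hit a species for only half its length cannot
        reach confidence 0.6 anywhere, including the root."""
        rng = np.random.default_rng(5)
        tax = _tiny_taxonomy()
        genome = _dna(rng, 500)
        idx = build_index([("gA_s1", genome)], tax, k=21)
        # 70 bases from the genome + 70 novel bases: about half the k-mers hit
        read = genome[10:80] + _dna(rng, 70)
        cls_low = classify(read, idx, 0.3)
        cls_high = classify(read, idx, 0.6)
        assert cls_low.taxon == "gA_s1"
        assert cls_high.taxon == UNCLASSIFIED
        assert cls_high.confidence == 0.0

    def test_sibling_overlap_read_assigned_to_genus(self):
        """A read spanning a region shared by two sibling species lands on
        their genus; the confidence equals the hand-computed k-mer tally."""
        rng = np.random.default_rng(6)
        tax = _tiny_taxonomy()
        shared = _dna(rng, 120)
        g1 = _dna(rng, 300) + shared
        g2 = shared + _dna(rng, 300)
        k = 21
        idx = build_index([("gA_s1", g1), ("gA_s2", g2)], tax, k=k)
        read = shared[10:110]
        cls = classify(read, idx, 0.5)
        assert cls.taxon == "gA"
        # manual walk: every k-mer of the read is inside the shared region
        expect = sum(1 for km in canonical_kmers(read, k)
                     if idx.mapping.get(km) == "gA") / (len(read) - k + 1)
        assert cls.confidence == pytest.approx(expect)
        assert cls.confidence == pytest.approx(1.0)

    def test_too_short_sequence_errors(self):
        rng = np.random.default_rng(7)
        tax = _tiny_taxonomy()
        idx = build_index([("gA_s1", _dna(rng, 100))], tax, k=21)
        with pytest.raises(ValueError):
            classify("ACGT", idx, 0.5)

    def test_classified_count_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        tax = _tiny_taxonomy()
        genomes = _random_genomes(rng, (600, 600, 600))
        idx = build_index(genomes, tax, k=21)
        reads = []
        for sp, seq in genomes:
            for i in range(0, 400, 40):
                # half-genomic, half-random chimeras at varying proportions
                take = 30 + (i % 70)
                reads.append(seq[i:i + take] + _dna(rng, 100 - take))
        prev = None
        for thr in (0.01, 0.2, 0.4, 0.6, 0.8, 1.0):
            n = sum(classify(r, idx, thr).taxon != UNCLASSIFIED for r in reads)
            if prev is not None:
                assert n <= prev
            prev = n


class TestProfile:
    def test_single_species_reads(self):
        rng = np.random.default_rng(9)
        tax = _tiny_taxonomy()
        genomes = _random_genomes(rng, (500, 500, 500))
        idx = build_index(genomes, tax, k=21)
        reads = [genomes[0][1][i:i + 100] for i in range(0, 390, 10)]
        prof = profile_sample(reads, idx, 0.5)
        assert dict(prof.abundances) == {"gA_s1": 1.0}
        assert prof.n_reads_classified == len(reads)

    def test_two_species_ratio(self):
        rng = np.random.default_rng(10)
        tax = _tiny_taxonomy()
        genomes = _random_genomes(rng, (800, 800, 800))
        idx = build_index(genomes, tax, k=21)
        reads = [genomes[0][1][i:i + 100] for i in range(0, 640, 8)] + \
                [genomes[2][1][i:i + 100] for i in range(0, 160, 8)]
        prof = profile_sample(reads, idx, 0.5)
        assert prof.abundances["gA_s1"] == pytest.approx(0.8)
        assert prof.abundances["gB_s1"] == pytest.approx(0.2)

    def test_redistribution_closed_form(self):
        """10 genus-level reads split over species with direct counts (30, 10)
        add (7.5, 2.5)."""
        rng = np.random.default_rng(11)
        tax = _tiny_taxonomy()
        shared = _dna(rng, 200)
        g1 = _dna(rng, 600) + shared
        g2 = shared + _dna(rng, 600)
        idx = build_index([("gA_s1", g1), ("gA_s2", g2)], tax, k=21)
        reads = [g1[i:i + 100] for i in range(0, 300, 10)]          # 30 -> s1
        reads += [g2[250 + i:350 + i] for i in range(0, 100, 10)]   # 10 -> s2
        reads += [shared[i:i + 100] for i in range(0, 100, 10)]     # 10 -> genus
        prof = profile_sample(reads, idx, 0.5)
        total = 50.0
        assert prof.abundances["gA_s1"] == pytest.approx((30 + 7.5) / total)
        assert prof.abundances["gA_s2"] == pytest.approx((10 + 2.5) / total)

    def test_empty_reads(self):
        rng = np.random.default_rng(12)
        tax = _tiny_taxonomy()
        idx = build_index([("gA_s1", _dna(rng, 100))], tax, k=21)
        prof = profile_sample([], idx)
        assert prof.n_reads_total == 0
        assert prof.abundances.empty


class TestAggregate:
    def test_species_to_genus(self):
        tax = _tiny_taxonomy()
        prof = AbundanceProfile("species",
                                pd.Series({"gA_s1": 0.6, "gA_s2": 0.4}), 10, 10)
        out = aggregate_level(prof, "genus", tax)
        assert dict(out.abundances) == {"gA": pytest.approx(1.0)}

    def test_composition_and_conservation(self):
        tax = _tiny_taxonomy()
        rng = np.random.default_rng(13)
        v = rng.random(3)
        v = v / v.sum()
        prof = AbundanceProfile(
            "species", pd.Series(dict(zip(["gA_s1", "gA_s2", "gB_s1"], v))), 5, 5)
        genus = aggregate_level(prof, "genus", tax)
        phylum_direct = aggregate_level(prof, "phylum", tax)
        phylum_via_genus = aggregate_level(genus, "phylum", tax)
        assert phylum_direct.abundances.equals(phylum_via_genus.abundances)
        assert phylum_direct.abundances.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_rank_errors(self):
        tax = _tiny_taxonomy()
        prof = AbundanceProfile("species", pd.Series({"gA_s1": 1.0}), 1, 1)
        with pytest.raises(ValueError):
            aggregate_level(prof, "kingdom", tax)


class TestPrevalenceFilter:
    @pytest.mark.parametrize("nonzero,kept", [(3, False), (4, True), (0, False)])
    def test_boundary_3_vs_4_of_8(self, nonzero, kept):
        row = [1.0] * nonzero + [0.0] * (8 - nonzero)
        df = pd.DataFrame([row], index=["t"], columns=[f"s{i}" for i in range(8)])
        out = prevalence_filter(df, 0.5)
        assert ("t" in out.index) is kept

    def test_empty_matrix(self):
        df = pd.DataFrame()
        assert prevalence_filter(df, 0.5).empty
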