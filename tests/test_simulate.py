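"""Synthetic cohort generator: determinism, planted structure, eligibility."""

import numpy as np
import pytest

from metasig.align import local_align
from metasig.seqio import revcomp, translate
from metasig.simulate import (CohortDesign, default_species_layout,
                              generate_reference_set, simulate_clinical_scores,
                              simulate_cohort, simulate_contigs, simulate_reads,
                              synthetic_catalog, validate_inclusion)


class TestReferenceSet:
    def test_deterministic(self, small_catalog, species_layout):
        planted = {s: [small_catalog.entries[0].entry_id]
                   for s in sorted(species_layout)}
        _, g1 = generate_reference_set(small_catalog, species_layout, planted,
                                       genome_length=8000, seed=5)
        _, g2 = generate_reference_set(small_catalog, species_layout, planted,
                                       genome_length=8000, seed=5)
        assert [g.sequence for g in g1] == [g.sequence for g in g2]

    def test_exact_identity_band_gives_byte_equal_translation(
            self, small_catalog, species_layout):
        planted = {s: [small_catalog.entries[1].entry_id]
                   for s in sorted(species_layout)}
        _, genomes = generate_reference_set(small_catalog, species_layout, planted,
                                            genome_length=8000,
                                            identity_band=(100, 100), seed=6)
        for g in genomes:
            pg = g.planted_genes[0]
            nt = g.sequence[pg.start:pg.end]
            if pg.strand == "-":
                nt = revcomp(nt)
            assert translate(nt)[:-1] == \
                small_catalog.get(pg.entry_id).protein_sequence

    def test_divergence_band_measured_by_aligner(self, small_catalog,
                                                 species_layout):
        """Planted-locus translations align to their catalog protein with
        identity inside the configured band."""
        planted = {s: [small_catalog.entries[i % 6].entry_id]
                   for i, s in enumerate(sorted(species_layout))}
        _, genomes = generate_reference_set(small_catalog, species_layout, planted,
                                            genome_length=8000,
                                            identity_band=(75, 85), seed=9)
        for g in genomes:
            for pg in g.planted_genes:
                nt = g.sequence[pg.start:pg.end]
                if pg.strand == "-":
                    nt = revcomp(nt)
                hit = local_align(translate(nt)[:-1],
                                  small_catalog.get(pg.entry_id).protein_sequence)
                assert 75 <= hit.percent_identity <= 85

    def test_oversized_gene_rejected(self, small_catalog, species_layout):
        planted = {sorted(species_layout)[0]: [small_catalog.entries[0].entry_id]}
        with pytest.raises(ValueError):
            generate_reference_set(small_catalog, species_layout, planted,
                                   genome_length=600, seed=1)


class TestCohort:
    def test_compositions_normalized_and_deterministic(self, small_design):
        s1 = simulate_cohort(small_design)
        s2 = simulate_cohort(small_design)
        for a, b in zip(s1, s2):
            assert a.true_composition == b.true_composition
            assert sum(a.true_composition.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_fold_change_recovered_at_large_n(self, species_layout):
        species = sorted(species_layout)
        # plant the effect on a rare species: for a dominant one the
        # renormalization of compositions would shrink the realized ratio
        design = CohortDesign(species=species, n_control=200, n_case=200,
                              log_mean={species[2]: -2.5},
                              planted_species_effects={species[2]: 4.0}, seed=3)
        samples = simulate_cohort(design)
        hc = np.array([s.true_composition[species[2]] for s in samples
                       if s.group == "HC"])
        pwd = np.array([s.true_composition[species[2]] for s in samples
                        if s.group == "PwD"])
        assert 3.0 <= np.median(pwd) / np.median(hc) <= 5.0

    def test_null_design_rejects_at_nominal_rate(self, species_layout):
        """With all fold-changes 1 the groups are exchangeable: Mann-Whitney
        on one species rejects at ~5% over repeated cohorts."""
        from metasig.stats import mann_whitney
        species = sorted(species_layout)
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            design = CohortDesign(species=species, n_control=10, n_case=10,
                                  seed=seed)
            samples = simulate_cohort(design)
            x = [s.true_composition[species[0]] for s in samples if s.group == "PwD"]
            y = [s.true_composition[species[0]] for s in samples if s.group == "HC"]
            _, p = mann_whitney(x, y)
            rejections += p < 0.05
        rate = rejections / n_rep
        ci = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= ci


class TestContigsAndReads:
    def test_contigs_are_exact_substrings(self, reference_set, small_design):
        _, genomes = reference_set
        comp = {g.species_taxon: 1 / len(genomes) for g in genomes}
        contigs = simulate_contigs(genomes, comp, small_design, seed=11)
        by_sp = {g.species_taxon: g.sequence for g in genomes}
        assert len(contigs) == small_design.n_contigs
        for name, seq in contigs:
            sp = name.split("|")[2]
            assert seq in by_sp[sp]

    def test_zero_abundance_species_yields_no_contigs(self, reference_set,
                                                      small_design):
        _, genomes = reference_set
        comp = {g.species_taxon: 0.0 for g in genomes}
        comp[genomes[0].species_taxon] = 1.0
        contigs = simulate_contigs(genomes, comp, small_design, seed=2)
        assert all(name.split("|")[2] == genomes[0].species_taxon
                   for name, _ in contigs)

    def test_contig_counts_proportional_to_abundance(self, reference_set,
                                                     species_layout):
        _, genomes = reference_set
        design = CohortDesign(species=sorted(species_layout), n_contigs=1000,
                              contig_length_range=(400, 900), seed=0)
        comp = {g.species_taxon: 0.0 for g in genomes}
        comp[genomes[0].species_taxon] = 0.8
        comp[genomes[1].species_taxon] = 0.2
        contigs = simulate_contigs(genomes, comp, design, seed=13)
        n0 = sum(1 for name, _ in contigs
                 if name.split("|")[2] == genomes[0].species_taxon)
        # binomial 99% CI around 800 of 1000
        ci = 2.576 * np.sqrt(1000 * 0.8 * 0.2)
        assert abs(n0 - 800) <= ci

    def test_error_free_reads_are_substrings(self, reference_set, small_design):
        import dataclasses
        _, genomes = reference_set
        design = dataclasses.replace(small_design, error_rate=0.0)
        reads = simulate_reads([(g.species_taxon, g.sequence) for g in genomes],
                               design, seed=4)
        seqs = {g.species_taxon: g.sequence for g in genomes}
        for name, seq, qual in reads:
            src = seqs[name.split("|")[2]]
            assert seq in src or revcomp(seq) in src
            assert len(qual) == len(seq)

    def test_reads_deterministic(self, reference_set, small_design):
        _, genomes = reference_set
        srcs = [(g.species_taxon, g.sequence) for g in genomes]
        assert simulate_reads(srcs, small_design, seed=8) == \
            simulate_reads(srcs, small_design, seed=8)

    def test_error_rate_realized(self, reference_set, species_layout):
        _, genomes = reference_set
        design = CohortDesign(species=sorted(species_layout), read_length=100,
                              error_rate=0.01, depth=10000, seed=0)
        g = genomes[0]
        reads = simulate_reads([(g.species_taxon, g.sequence)], design, seed=21)
        total_mm = 0
        for name, seq, _ in reads:
            fields = name.split("|")
            start, strand = int(fields[-2]), fields[-1]
            truth = g.sequence[start:start + 100]
            if strand == "-":
                truth = revcomp(truth)
            total_mm += sum(1 for a, b in zip(truth, seq) if a != b)
        mean_mm = total_mm / len(reads)
        ci = 2.576 * np.sqrt(100 * 0.01 * 0.99 / len(reads))
        assert abs(mean_mm - 1.0) <= ci

    def test_read_longer_than_sources_errors(self, reference_set, species_layout):
        design = CohortDesign(species=sorted(species_layout), read_length=100,
                              seed=0)
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads([("x", "ACGT" * 10)], design, seed=1)


class TestClinicalScores:
    def test_hc_always_eligible(self):
        for sev in np.linspace(0, 1, 21):
            s = simulate_clinical_scores("HC", float(sev))
            assert s["CES-D"] < 18 and s["GAD-7"] < 5
            assert validate_inclusion(s, "HC")[0]

    def test_pwd_always_eligible(self):
        for sev in np.linspace(0, 1, 21):
            s = simulate_clinical_scores("PwD", float(sev))
            assert s["HAMD-17"] >= 14 and s["CES-D"] >= 27 and s["GAD-7"] < 10
            assert validate_inclusion(s, "PwD")[0]

    def test_monotone_in_severity(self):
        lo = simulate_clinical_scores("PwD", 0.0)
        hi = simulate_clinical_scores("PwD", 1.0)
        assert all(hi[k] >= lo[k] for k in lo)

    @pytest.mark.parametrize("scores,group,accepted,reason_part", [
        ({"HAMD-17": 14, "CES-D": 27, "GAD-7": 9}, "PwD", True, "meets"),
        ({"HAMD-17": 13, "CES-D": 40, "GAD-7": 5}, "PwD", False, "HAMD-17"),
        ({"HAMD-17": 0, "CES-D": 18, "GAD-7": 0}, "HC", False, "CES-D"),
        ({"HAMD-17": 0, "CES-D": 5, "GAD-7": 1}, "HC", True, "meets"),
    ])
    def test_inclusion_boundaries(self, scores, group, accepted, reason_part):
        ok, reason = validate_inclusion(scores, group)
        assert ok is accepted
        assert reason_part in reason

    def test_out_of_range_scores_error(self):
        with pytest.raises(ValueError, match="instrument range"):
            validate_inclusion({"HAMD-17": 60, "CES-D": 10, "GAD-7": 1}, "HC")
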