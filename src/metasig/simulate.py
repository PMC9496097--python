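"""Synthetic two-group metagenomic cohort generator.

Emulates the statistical structure of a case/control shotgun-metagenome
study of depression: reference genomes carrying planted catalog genes,
log-normal species compositions with planted group fold-changes, error-free
contigs sampled from the genomes (assembly itself is out of scope), reads
with substitution errors, and clinical severity scores (CES-D, GAD-7,
HAMD-17) that satisfy the cohorts' eligibility windows. Every generator is a
pure function of its configuration and seed, and every contig and read name
carries its source, so downstream classification and signature recovery can
be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .catalog import Catalog, EnzymeEntry
from .seqio import revcomp, translate
from .taxonomy import TaxonomyTree

AA = "ACDEFGHIKLMNPQRSTVWY"

SCORE_RANGES = {"CES-D": (0, 60), "GAD-7": (0, 21), "HAMD-17": (0, 52)}

# PwD eligibility (patients with depression) and HC (healthy control) windows
PWD_CRITERIA = "HAMD-17 >= 14, CES-D >= 27, GAD-7 < 10"
HC_CRITERIA = "CES-D < 18, GAD-7 < 5"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _STANDARD.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = sorted(_STANDARD.stop_codons)

# Enzyme / metabolite / role vocabulary for the synthetic catalog. Names follow
# the neuroactive-pathway enzymes commonly profiled in gut-brain-axis studies.
DEFAULT_ENZYMES = [
    ("glutamate decarboxylase", "GABA", "synthesis"),
    ("gamma-aminobutyrate antiporter", "GABA", "transport"),
    ("butyryl-CoA dehydrogenase", "butyrate", "synthesis"),
    ("butyrate kinase", "butyrate", "synthesis"),
    ("glutamine synthetase", "glutamine", "synthesis"),
    ("glutamate synthase subunit gltB", "glutamate", "synthesis"),
    ("asparagine synthetase asnA", "asparagine", "synthesis"),
    ("argininosuccinate lyase", "arginine", "synthesis"),
    ("spermidine synthase", "spermidine", "synthesis"),
    ("serotonin N-acetyltransferase", "melatonin", "synthesis"),
    ("linoleic acid isomerase", "conjugated linoleic acid", "synthesis"),
    ("estradiol 17-beta-dehydrogenase", "17-beta-estradiol", "degradation"),
    ("phosphotransacetylase", "acetate", "synthesis"),
    ("serine hydroxymethyltransferase", "serine", "synthesis"),
    ("catalase", "hydrogen peroxide", "degradation"),
    ("histidine ammonia-lyase", "histamine", "degradation"),
    ("methylaspartate ammonia-lyase", "glutamate", "degradation"),
    ("glutamate mutase subunit glmE", "glutamate", "degradation"),
]

DEFAULT_GENERA = ("Faecalibacterium", "Roseburia", "Coprococcus",
                  "Escherichia", "Alistipes", "Bacteroides")


def synthetic_catalog(n_enzymes: int = 12, orthologs_per_enzyme: int = 1,
                      length_range: tuple[int, int] = (220, 320),
                      genera=DEFAULT_GENERA, seed: int = 0) -> Catalog:
    """A synthetic stand-in catalog of random proteins with realistic metadata.

    Sequences are uniform random amino acids (first residue M); only the
    metadata vocabulary is domain-realistic. Useful wherever tests or demos
    need a catalog without shipping real reference proteins.
    """
    if n_enzymes > len(DEFAULT_ENZYMES):
        raise ValueError(f"at most {len(DEFAULT_ENZYMES)} distinct enzymes available")
    rng = np.random.default_rng(seed)
    entries = []
    for i, (name, metabolite, role) in enumerate(DEFAULT_ENZYMES[:n_enzymes]):
        for j in range(orthologs_per_enzyme):
            genus = genera[(i + j) % len(genera)]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "M" + "".join(rng.choice(list(AA), size=length - 1))
            entries.append(EnzymeEntry(f"E{i:03d}.{j}", name, metabolite, role,
                                       genus, seq))
    return Catalog(entries)


@dataclass(frozen=True)
class PlantedGene:
    entry_id: str
    start: int       # 0-based, forward strand
    end: int         # half-open; includes the stop codon
    strand: str      # '+' or '-'
    aa_identity: float  # planted identity vs the catalog protein, percent


@dataclass
class ReferenceGenome:
    species_taxon: str
    sequence: str
    planted_genes: list[PlantedGene] = field(default_factory=list)


def _mutate_to_band(protein: str, band: tuple[float, float], rng) -> tuple[str, float]:
    """Substitute residues so identity to ``protein`` lies inside ``band``.

    The first residue (M) and a 3-residue flank at each end are kept intact so
    that a local alignment spans the full protein and measures the planted
    identity exactly. Returns (mutated protein, realized identity percent).
    """
    lo, hi = band
    L = len(protein)
    target = float(rng.uniform(lo, hi))
    m = int(round(L * (1.0 - target / 100.0)))
    # realized identity must stay inside the band after rounding
    while m > 0 and 100.0 * (L - m) / L < lo:
        m -= 1
    while 100.0 * (L - m) / L > hi and m < L:
        m += 1
    eligible = np.arange(3, L - 3)
    if m > len(eligible):
        raise ValueError("identity band too low for protein length")
    sites = rng.choice(eligible, size=m, replace=False) if m else np.array([], dtype=int)
    seq = list(protein)
    for pos in sites:
        choices = [a for a in AA if a != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(seq), 100.0 * (L - m) / L


def _reverse_translate(protein: str, rng) -> str:
    codons = [_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein]
    codons.append(_STOPS[int(rng.integers(len(_STOPS)))])
    return "".join(codons)


def _random_dna(n: int, rng) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_reference_set(catalog: Catalog, species_to_genus: dict[str, str],
                           planted_genes: dict[str, list[str]],
                           genome_length: int = 12000,
                           identity_band: tuple[float, float] = (80.0, 100.0),
                           seed: int = 0,
                           genus_to_phylum: dict[str, str] | None = None,
                           ) -> tuple[TaxonomyTree, list[ReferenceGenome]]:
    """Build a taxonomy and divergent reference genomes with planted genes.

    Each genome is an i.i.d. random backbone into which the requested catalog
    genes are inserted as ATG...stop loci whose translation matches the
    catalog protein at an identity drawn from ``identity_band``. Codon choice
    is randomized per locus, so two species planted with the same protein
    still diverge at the nucleotide level.
    """
    if len(species_to_genus) < 2 or len(set(species_to_genus.values())) < 2:
        raise ValueError("need at least 2 species across at least 2 genera")
    taxonomy = TaxonomyTree.from_lineages(species_to_genus, genus_to_phylum)
    rng = np.random.default_rng(seed)
    genomes = []
    for species in sorted(species_to_genus):
        backbone = _random_dna(genome_length, rng)
        entry_ids = planted_genes.get(species, [])
        gene_seqs = []
        for entry_id in entry_ids:
            protein = catalog.get(entry_id).protein_sequence
            nt_len = 3 * (len(protein) + 1)
            if nt_len > genome_length:
                raise ValueError(f"gene {entry_id} ({nt_len} nt) exceeds genome length")
            if 10 * nt_len > genome_length:
                raise ValueError(
                    f"genome length {genome_length} < 10x gene length for {entry_id}")
            mutated, identity = _mutate_to_band(protein, identity_band, rng)
            gene_seqs.append((entry_id, _reverse_translate(mutated, rng), identity))
        seq = list(backbone)
        planted = []
        n_blocks = max(1, len(gene_seqs))
        block = genome_length // n_blocks
        for i, (entry_id, nt, identity) in enumerate(gene_seqs):
            if len(nt) > block:
                raise ValueError(f"gene {entry_id} does not fit its placement block")
            offset = int(rng.integers(0, block - len(nt) + 1))
            start = i * block + offset
            strand = "+" if rng.random() < 0.5 else "-"
            insert = nt if strand == "+" else revcomp(nt)
            seq[start:start + len(nt)] = insert
            planted.append(PlantedGene(entry_id, start, start + len(nt), strand, identity))
        genomes.append(ReferenceGenome(species, "".join(seq), planted))
    return taxonomy, genomes


@dataclass
class CohortDesign:
    """Specification of a synthetic case/control cohort.

    Fold-changes are multiplicative case/control effects: species effects act
    on the log-normal composition mean, gene effects act on contig coverage
    over the planted locus conditional on the species' abundance (so a gene
    can change copy-number-like without moving its host species).
    """
    species: list[str]
    n_control: int = 38
    n_case: int = 36
    log_mean: dict[str, float] | float = 0.0
    log_sd: dict[str, float] | float = 0.6
    planted_species_effects: dict[str, float] = field(default_factory=dict)
    planted_gene_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    read_length: int = 150
    error_rate: float = 0.005
    depth: int = 2000          # expected reads per sample
    n_contigs: int = 200       # contigs per sample
    contig_length_range: tuple[int, int] = (500, 2000)
    seed: int = 0

    def __post_init__(self):
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 samples per group")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")
        for fc in list(self.planted_species_effects.values()) + \
                list(self.planted_gene_effects.values()):
            if fc <= 0:
                raise ValueError("fold-changes must be positive")

    def mean_for(self, species: str) -> float:
        if isinstance(self.log_mean, dict):
            return self.log_mean.get(species, 0.0)
        return float(self.log_mean)

    def sd_for(self, species: str) -> float:
        if isinstance(self.log_sd, dict):
            return self.log_sd.get(species, 0.6)
        return float(self.log_sd)


def default_species_layout(n_species: int = 10, n_genera: int = 5) -> dict[str, str]:
    """Synthetic species names mapped round-robin onto genera."""
    return {f"g{i % n_genera:02d}_s{i // n_genera:02d}": f"g{i % n_genera:02d}"
            for i in range(n_species)}


@dataclass
class SampleRecord:
    sample_id: str
    group: str                               # 'HC' or 'PwD'
    true_composition: dict[str, float]
    scores: dict[str, int]
    sex: str = "F"
    age: int = 30
    bmi: float = 23.0
    contigs: list[tuple[str, str]] = field(default_factory=list)
    reads: list[tuple[str, str, str]] = field(default_factory=list)


def simulate_clinical_scores(group: str, latent_severity: float,
                             seed: int | None = None) -> dict[str, int]:
    """Integer severity scores, monotone in ``latent_severity``.

    The mapping is a deterministic monotone transform of the latent severity
    onto each instrument's eligibility window (randomness enters through the
    latent severity draw upstream): PwD samples always satisfy HAMD-17 >= 14,
    CES-D >= 27 and GAD-7 < 10; HC samples always satisfy CES-D < 18 and
    GAD-7 < 5.
    """
    if not 0.0 <= latent_severity <= 1.0:
        raise ValueError("latent_severity must lie in [0, 1]")
    s = latent_severity
    if group == "PwD":
        return {"CES-D": 27 + round(s * 25), "GAD-7": 2 + round(s * 7),
                "HAMD-17": 14 + round(s * 14)}
    if group == "HC":
        return {"CES-D": round(s * 17), "GAD-7": round(s * 4),
                "HAMD-17": round(s * 8)}
    raise ValueError(f"unknown group {group!r}")


def validate_inclusion(scores: dict[str, int], group_claim: str) -> tuple[bool, str]:
    """Apply the cohort eligibility criteria; returns (accepted, reason)."""
    for name, (lo, hi) in SCORE_RANGES.items():
        if name not in scores:
            raise ValueError(f"missing score {name}")
        if not lo <= scores[name] <= hi:
            raise ValueError(f"{name}={scores[name]} outside instrument range [{lo},{hi}]")
    if group_claim == "PwD":
        if scores["HAMD-17"] < 14:
            return False, "HAMD-17 >= 14 violated"
        if scores["CES-D"] < 27:
            return False, "CES-D >= 27 violated"
        if scores["GAD-7"] >= 10:
            return False, "GAD-7 < 10 violated"
        return True, "meets PwD criteria"
    if group_claim == "HC":
        if scores["CES-D"] >= 18:
            return False, "CES-D < 18 violated"
        if scores["GAD-7"] >= 5:
            return False, "GAD-7 < 5 violated"
        return True, "meets HC criteria"
    raise ValueError(f"unknown group {group_claim!r}")


def simulate_cohort(design: CohortDesign, seed: int | None = None) -> list[SampleRecord]:
    """Draw per-sample compositions, groups, demographics and severity scores.

    Species relative abundances are log-normal; case samples' log-means are
    shifted by log(fold-change) for planted species; each composition is
    normalized to sum to 1. Contigs and reads are filled in separately.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    species = list(design.species)
    mu = np.array([design.mean_for(s) for s in species])
    sd = np.array([design.sd_for(s) for s in species])
    shift = np.array([math.log(design.planted_species_effects.get(s, 1.0))
                      for s in species])
    samples = []
    layout = [("HC", i) for i in range(design.n_control)] + \
             [("PwD", i) for i in range(design.n_case)]
    for group, i in layout:
        logs = rng.normal(mu + (shift if group == "PwD" else 0.0), sd)
        ab = np.exp(logs)
        ab = ab / ab.sum()
        severity = float(rng.beta(2, 4)) if group == "PwD" else float(rng.beta(1.2, 5))
        scores = simulate_clinical_scores(group, severity)
        samples.append(SampleRecord(
            sample_id=f"{group}{i:03d}",
            group=group,
            true_composition=dict(zip(species, ab)),
            scores=scores,
            sex="M" if rng.random() < 0.5 else "F",
            age=int(rng.integers(18, 55)),
            bmi=float(np.clip(rng.normal(23.0, 3.0), 16, 39).round(1)),
        ))
    return samples


def simulate_contigs(genomes: list[ReferenceGenome], composition: dict[str, float],
                     design: CohortDesign, seed: int,
                     gene_effects: dict[tuple[str, str], float] | None = None,
                     sample_id: str = "S") -> list[tuple[str, str]]:
    """Error-free contigs sampled from genomes in proportion to abundance.

    Contigs are verbatim substrings (assembly is assumed error-free). Gene
    fold-change effects are realized by over/under-sampling contigs that
    overlap the planted locus, which changes the locus' coverage without
    moving the species' total contig count.
    """
    lo, hi = design.contig_length_range
    by_species = {g.species_taxon: g for g in genomes}
    names = [s for s in composition if composition[s] > 0 and s in by_species]
    for s in names:
        if hi > len(by_species[s].sequence):
            raise ValueError(f"contig_length_range exceeds genome length for {s}")
    if not names:
        return []
    rng = np.random.default_rng(seed)
    probs = np.array([composition[s] for s in names])
    probs = probs / probs.sum()
    counts = rng.multinomial(design.n_contigs, probs)
    contigs = []
    idx = 0
    for s, n in zip(names, counts):
        genome = by_species[s]
        loci = []
        if gene_effects:
            for pg in genome.planted_genes:
                fold = gene_effects.get((s, pg.entry_id), 1.0)
                if fold != 1.0:
                    loci.append((pg.start, pg.end, fold))
        bound = max([1.0] + [f for _, _, f in loci])
        accepted = 0
        while accepted < n:
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(genome.sequence) - length + 1))
            w = 1.0
            for a, b, fold in loci:
                if start < b and start + length > a:
                    w *= fold
            if w < bound and rng.random() >= w / bound:
                continue
            contigs.append((f"{sample_id}|c{idx:05d}|{s}|{start}-{start + length}",
                            genome.sequence[start:start + length]))
            idx += 1
            accepted += 1
    return contigs


def simulate_reads(sources: list[tuple[str, str]], design: CohortDesign,
                   seed: int, sample_id: str = "S") -> list[tuple[str, str, str]]:
    """Fixed-length reads with i.i.d. substitution errors from contigs or genomes.

    The expected total read count is ``design.depth``; reads are drawn from
    sources in proportion to their number of valid start positions, from a
    random strand, with constant Phred-33 quality 'I'.
    """
    rl = design.read_length
    usable = [(name, seq) for name, seq in sources if len(seq) >= rl]
    if sources and not usable:
        raise ValueError(f"read_length {rl} exceeds every source length")
    if not usable:
        return []
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(design.depth))
    if n == 0:
        return []
    weights = np.array([len(seq) - rl + 1 for _, seq in usable], dtype=float)
    src_idx = rng.choice(len(usable), size=n, p=weights / weights.sum())
    u_start = rng.random(n)
    flip = rng.random(n) < 0.5
    err_mask = rng.random((n, rl)) < design.error_rate
    n_err = int(err_mask.sum())
    err_shift = rng.integers(1, 4, size=n_err)  # offset to a different base
    base_to_int = {"A": 0, "C": 1, "G": 2, "T": 3}
    int_to_base = "ACGT"
    qual = "I" * rl
    reads = []
    e = 0
    for i in range(n):
        name, seq = usable[src_idx[i]]
        start = int(u_start[i] * (len(seq) - rl + 1))
        frag = seq[start:start + rl]
        if flip[i]:
            frag = revcomp(frag)
        errs = np.flatnonzero(err_mask[i])
        if errs.size:
            chars = list(frag)
            for pos in errs:
                chars[pos] = int_to_base[(base_to_int[chars[pos]] + err_shift[e]) % 4]
                e += 1
            frag = "".join(chars)
        strand = "-" if flip[i] else "+"
        reads.append((f"{sample_id}|r{i:06d}|{name}|{start}|{strand}", frag, qual))
    return reads


@dataclass
class CohortBundle:
    design: CohortDesign
    taxonomy: TaxonomyTree
    genomes: list[ReferenceGenome]
    catalog: Catalog
    samples: list[SampleRecord]

    @property
    def metadata(self) -> pd.DataFrame:
        rows = [{"sample_id": s.sample_id, "group": s.group, "sex": s.sex,
                 "age": s.age, "BMI": s.bmi, **s.scores} for s in self.samples]
        return pd.DataFrame(rows).set_index("sample_id")


def generate_cohort(design: CohortDesign, catalog: Catalog,
                    species_to_genus: dict[str, str] | None = None,
                    planted_genes: dict[str, list[str]] | None = None,
                    genome_length: int = 12000,
                    identity_band: tuple[float, float] = (80.0, 100.0),
                    with_reads: bool = True) -> CohortBundle:
    """End-to-end cohort: reference set, compositions, contigs and reads.

    ``planted_genes`` defaults to one catalog entry per species, assigned
    round-robin, so every species contributes at least one potential
    signature pair.
    """
    if species_to_genus is None:
        species_to_genus = {s: s.split("_")[0] for s in design.species}
    if planted_genes is None:
        entry_ids = [e.entry_id for e in catalog]
        planted_genes = {s: [entry_ids[i % len(entry_ids)]]
                         for i, s in enumerate(sorted(design.species))}
    root_seq = np.random.SeedSequence(design.seed)
    ref_seed, cohort_seed, *sample_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root_seq.spawn(
            2 + 2 * (design.n_control + design.n_case))]
    taxonomy, genomes = generate_reference_set(
        catalog, species_to_genus, planted_genes, genome_length,
        identity_band, seed=ref_seed)
    samples = simulate_cohort(design, seed=cohort_seed)
    for i, sample in enumerate(samples):
        effects = design.planted_gene_effects if sample.group == "PwD" else None
        sample.contigs = simulate_contigs(
            genomes, sample.true_composition, design, sample_seeds[2 * i],
            gene_effects=effects, sample_id=sample.sample_id)
        if with_reads:
            sample.reads = simulate_reads(sample.contigs, design,
                                          sample_seeds[2 * i + 1],
                                          sample_id=sample.sample_id)
    return CohortBundle(design, taxonomy, genomes, catalog, samples)


def simulate_severity_linked_abundance(rho_spearman: float, n: int, seed: int,
                                       log_sd: float = 0.6,
                                       scale: float = 100.0,
                                       ) -> tuple[np.ndarray, np.ndarray]:
    """A pair-abundance vector and HAMD-17 scores with a planted Spearman rank
    correlation.

    The rank dependence is induced with the Iman-Conover method: exact normal
    scores are rotated (via Cholesky factors of their empirical and the target
    correlation matrices) so that the *sample* correlation of the scores hits
    the target, and the marginals — log-normal abundances and integer
    HAMD-17 in the patient window 14..28 — are then reordered to match those
    score ranks. The realized sample Spearman therefore sits at the target up
    to the small attenuation from integer-score ties, rather than fluctuating
    with the O(1/sqrt(n)) noise a population-level copula plant would have.
    """
    if not -1.0 < rho_spearman < 1.0:
        raise ValueError("rho_spearman must lie in (-1, 1)")
    from scipy.stats import norm, rankdata
    rng = np.random.default_rng(seed)
    scores = norm.ppf(np.arange(1, n + 1) / (n + 1.0))
    S = np.column_stack([rng.permutation(scores), rng.permutation(scores)])
    E = np.linalg.cholesky(np.corrcoef(S.T))
    P = np.linalg.cholesky(np.array([[1.0, rho_spearman], [rho_spearman, 1.0]]))
    S = S @ np.linalg.inv(E).T @ P.T
    sev_rank = rankdata(S[:, 0], method="ordinal")    # 1..n
    ab_rank = rankdata(S[:, 1], method="ordinal")
    hamd = 14 + np.round(14.0 * (sev_rank - 1) / (n - 1)).astype(int)
    ab_quantiles = scale * np.exp(log_sd * scores)    # sorted marginal
    abundance = ab_quantiles[ab_rank - 1]
    return abundance, hamd
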