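"""Reference catalog of enzyme orthologs for neuroactive-metabolite pathways.

The catalog holds amino-acid sequences of bacterial enzymes that synthesize,
degrade, or transport neuroactive compounds (GABA, butyrate, glutamate,
melatonin precursors, ...), each tagged with the enzyme name, the metabolite,
the reaction role, and the genus the ortholog came from. Downstream, ORFs
predicted on metagenomic contigs are annotated against these sequences.

On disk a catalog is a protein FASTA (headers are entry ids) plus a TSV
metadata table with one row per entry; both may be gzip-compressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .align import local_align, make_protein_aligner
from .seqio import PROTEIN_ALPHABET, open_text, read_fasta, write_fasta

logger = logging.getLogger(__name__)

ROLES = ("synthesis", "degradation", "transport")

METADATA_COLUMNS = ("entry_id", "enzyme_name", "metabolite", "role", "source_genus")


@dataclass(frozen=True)
class EnzymeEntry:
    entry_id: str
    enzyme_name: str
    metabolite: str
    role: str
    source_genus: str
    protein_sequence: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"{self.entry_id}: role {self.role!r} not in {ROLES}")
        if not self.protein_sequence:
            raise ValueError(f"{self.entry_id}: empty protein sequence")
        bad = set(self.protein_sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"{self.entry_id}: invalid amino acids {sorted(bad)}")


@dataclass
class Catalog:
    entries: list[EnzymeEntry] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.entry_id in seen:
                raise ValueError(f"duplicate entry_id {e.entry_id!r}")
            seen.add(e.entry_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, entry_id: str) -> EnzymeEntry:
        return self._by_id[entry_id]

    @property
    def _by_id(self) -> dict[str, EnzymeEntry]:
        return {e.entry_id: e for e in self.entries}

    @property
    def enzyme_index(self) -> dict[str, list[str]]:
        """enzyme_name -> entry ids, in catalog order."""
        index: dict[str, list[str]] = {}
        for e in self.entries:
            index.setdefault(e.enzyme_name, []).append(e.entry_id)
        return index

    def entries_for_enzyme(self, enzyme_name: str) -> list[EnzymeEntry]:
        return [e for e in self.entries if e.enzyme_name == enzyme_name]


def load_catalog(fasta_path, metadata_table_path) -> Catalog:
    """Load a catalog from a protein FASTA + TSV metadata table.

    FASTA records and metadata rows must match 1:1 by entry id.
    """
    seqs = dict_from_fasta(fasta_path)
    meta = pd.read_csv(metadata_table_path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table missing columns {missing}")
    ids = list(meta["entry_id"])
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate entry_id in metadata: {dupes}")
    if set(ids) != set(seqs):
        raise ValueError(
            "FASTA/metadata mismatch: "
            f"only-in-fasta={sorted(set(seqs) - set(ids))[:5]}, "
            f"only-in-table={sorted(set(ids) - set(seqs))[:5]}"
        )
    entries = [
        EnzymeEntry(row.entry_id, row.enzyme_name, row.metabolite, row.role,
                    row.source_genus, seqs[row.entry_id])
        for row in meta.itertuples(index=False)
    ]
    return Catalog(entries)


def dict_from_fasta(fasta_path) -> dict[str, str]:
    records = read_fasta(fasta_path)
    ids = [name for name, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate entry_id in FASTA: {dupes}")
    return dict(records)


def write_catalog(catalog: Catalog, fasta_path, metadata_table_path) -> None:
    write_fasta(((e.entry_id, e.protein_sequence) for e in catalog), fasta_path)
    meta = pd.DataFrame(
        [(e.entry_id, e.enzyme_name, e.metabolite, e.role, e.source_genus)
         for e in catalog],
        columns=list(METADATA_COLUMNS),
    )
    with open_text(metadata_table_path, "wt") as fh:
        meta.to_csv(fh, sep="\t", index=False)


def extend_catalog(catalog: Catalog, candidate_sequences,
                   identity_min: float = 60.0, coverage_min: float = 90.0,
                   aligner=None) -> Catalog:
    """Admit candidate orthologs into a copy of ``catalog``.

    A candidate (an :class:`EnzymeEntry` carrying its claimed enzyme name and
    source genus) is admitted iff its best local alignment against an existing
    entry of the same enzyme reaches ``identity_min`` percent identity and
    ``coverage_min`` percent of the reference length. Sequences byte-identical
    to an existing entry are silently deduplicated. Candidates naming an
    unknown enzyme are rejected with a logged reason, not an error.
    """
    if not (0 < identity_min <= 100 and 0 < coverage_min <= 100):
        raise ValueError("thresholds must lie in (0, 100]")
    if aligner is None:
        aligner = make_protein_aligner()
    entries = list(catalog.entries)
    known_seqs = {e.protein_sequence for e in entries}
    known_ids = {e.entry_id for e in entries}
    index = {name: [e for e in entries if e.enzyme_name == name]
             for name in {e.enzyme_name for e in entries}}
    for cand in candidate_sequences:
        if cand.protein_sequence in known_seqs:
            logger.info("extend_catalog: %s deduplicated (identical sequence)", cand.entry_id)
            continue
        refs = index.get(cand.enzyme_name)
        if not refs:
            logger.warning("extend_catalog: %s rejected (enzyme %r not in catalog)",
                           cand.entry_id, cand.enzyme_name)
            continue
        best = None
        for ref in refs:
            hit = local_align(cand.protein_sequence, ref.protein_sequence, aligner,
                              cand.entry_id, ref.entry_id)
            if best is None or hit.raw_score > best.raw_score:
                best = hit
        if best.percent_identity >= identity_min and best.relative_alignment_length >= coverage_min:
            entry = cand
            if entry.entry_id in known_ids:
                entry = replace(entry, entry_id=f"{entry.entry_id}.1")
            entries.append(entry)
            known_seqs.add(entry.protein_sequence)
            known_ids.add(entry.entry_id)
            index.setdefault(entry.enzyme_name, []).append(entry)
        else:
            logger.info(
                "extend_catalog: %s rejected (best identity %.1f, coverage %.1f vs %s)",
                cand.entry_id, best.percent_identity, best.relative_alignment_length,
                best.subject_id)
    return Catalog(entries)


def summarize_catalog(catalog: Catalog) -> dict[str, int]:
    return {
        "sequences": len(catalog),
        "enzymes": len({e.enzyme_name for e in catalog}),
        "metabolites": len({e.metabolite for e in catalog}),
        "genera": len({e.source_genus for e in catalog}),
    }
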