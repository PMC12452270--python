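"""Curation of the verified eukaryotic glycoside-hydrolase reference database.

Public GH sequence databases are skewed toward fungi and higher plants and
contain many entries whose own endogeneity was never verified.  A reference
entry is retained only if it has a public reference AND at least one piece
of evidence of genomic origin: direct derivation from an assembled genome,
cDNA aligned/hybridized to a genomic template, RNA from a clean culture or
tissue, or close phylogenetic homology to a genome-verified relative.
Evidence codes are supplied as pre-digested data; evaluating the literature
itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .gh_catalog import EnzymeType
from .io_formats import write_fasta, TranscriptRecord


class EvidenceCode(str, Enum):
    GENOMIC_ASSEMBLY = "GENOMIC_ASSEMBLY"
    CDNA_GENOME_ALIGNED = "CDNA_GENOME_ALIGNED"
    CLEAN_RNA_SOURCE = "CLEAN_RNA_SOURCE"
    PHYLO_HOMOLOGY = "PHYLO_HOMOLOGY"


@dataclass(frozen=True)
class ReferenceEntry:
    accession: str
    peptide: str
    superfamily: str
    ghf: str
    enzyme_type: EnzymeType
    has_public_reference: bool = True
    evidence_codes: frozenset[EvidenceCode] = frozenset()


@dataclass(frozen=True)
class CurationDecision:
    retained: bool
    reason: str  # "retained" | "no_reference" | "no_evidence"


def curate_entry(entry: ReferenceEntry) -> CurationDecision:
    """Apply the evidence-of-endogeneity criteria to one entry.

    No public reference -> excluded (origin unverifiable); no evidence code
    -> excluded ("one or more" methods required); otherwise retained.
    """
    if not entry.has_public_reference:
        return CurationDecision(False, "no_reference")
    if not entry.evidence_codes:
        return CurationDecision(False, "no_evidence")
    return CurationDecision(True, "retained")


@dataclass
class VerifiedDB:
    """Retained reference entries grouped by (enzyme type, GH family)."""

    groups: dict[tuple[EnzymeType, str], list[ReferenceEntry]]
    summary: pd.DataFrame  # per enzyme type: total, retained

    def entries(self) -> list[ReferenceEntry]:
        return [e for group in self.groups.values() for e in group]

    def accessions(self) -> set[str]:
        return {e.accession for e in self.entries()}

    def superfamily_of(self) -> dict[str, str]:
        return {e.accession: e.superfamily for e in self.entries()}

    def summary_cell(self, enzyme_type: EnzymeType) -> str:
        """``total(retained)`` display, e.g. ``3(2)``."""
        row = self.summary.loc[enzyme_type.value]
        return f"{row['total']}({row['retained']})"


def build_verified_db(entries: Sequence[ReferenceEntry]) -> VerifiedDB:
    """Curate all entries and group the retained ones by enzyme type and
    GH family, with a per-type total(retained) summary."""
    seen: set[str] = set()
    for entry in entries:
        if entry.accession in seen:
            raise ValueError(f"duplicate accession {entry.accession!r}")
        seen.add(entry.accession)

    groups: dict[tuple[EnzymeType, str], list[ReferenceEntry]] = {}
    counts = {etype.value: {"total": 0, "retained": 0} for etype in EnzymeType}
    for entry in entries:
        counts[entry.enzyme_type.value]["total"] += 1
        if curate_entry(entry).retained:
            counts[entry.enzyme_type.value]["retained"] += 1
            groups.setdefault((entry.enzyme_type, entry.ghf), []).append(entry)
    summary = pd.DataFrame.from_dict(counts, orient="index")
    summary.index.name = "enzyme_type"
    return VerifiedDB(groups=groups, summary=summary)


# ---------------------------------------------------------------------------
# On-disk form: raw catalog TSV in, verified FASTA + metadata TSV out
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "accession", "peptide", "superfamily", "ghf", "enzyme_type",
    "has_public_reference", "evidence_codes",
]


def read_reference_catalog(path: str | Path) -> list[ReferenceEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ReferenceEntry(
            accession=row.accession,
            peptide=row.peptide,
            superfamily=row.superfamily,
            ghf=row.ghf,
            enzyme_type=EnzymeType(row.enzyme_type),
            has_public_reference=row.has_public_reference.lower()
            in {"true", "1", "yes"},
            evidence_codes=frozenset(
                EvidenceCode(c) for c in row.evidence_codes.split(";") if c
            ),
        )
        for row in df.itertuples()
    ]


def write_reference_catalog(
    entries: Iterable[ReferenceEntry], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as out:
        out.write("\t".join(CATALOG_COLUMNS) + "\n")
        for e in entries:
            codes = ";".join(sorted(c.value for c in e.evidence_codes))
            out.write(
                f"{e.accession}\t{e.peptide}\t{e.superfamily}\t{e.ghf}\t"
                f"{e.enzyme_type.value}\t{str(e.has_public_reference).lower()}\t"
                f"{codes}\n"
            )


def write_verified_db(db: VerifiedDB, fasta_path: str | Path,
                      metadata_path: str | Path) -> None:
    entries = sorted(db.entries(), key=lambda e: e.accession)
    write_fasta(
        [
            TranscriptRecord(e.accession, gene_id=e.accession, peptide=e.peptide)
            for e in entries
        ],
        fasta_path,
    )
    with open(metadata_path, "w", newline="\n") as out:
        out.write("accession\tsuperfamily\tghf\tenzyme_type\n")
        for e in entries:
            out.write(
                f"{e.accession}\t{e.superfamily}\t{e.ghf}\t{e.enzyme_type.value}\n"
            )
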