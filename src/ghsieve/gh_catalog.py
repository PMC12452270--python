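"""Seven-enzyme EC catalog and keyword-based candidate extraction.

The packaged catalog lists, for each of the seven targeted glycoside
hydrolase types (cellulase, xylanase, pectinase, chitinase, mannanase,
fucosidase, laminarinase), its EC numbers and the alternative enzyme names
from the Enzyme Nomenclature Database.  Those names are the keywords used
to pull candidate transcripts out of merged annotation text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import TranscriptRecord, gene_id_of


class EnzymeType(str, Enum):
    CELLULASE = "CELLULASE"
    XYLANASE = "XYLANASE"
    PECTINASE = "PECTINASE"
    CHITINASE = "CHITINASE"
    MANNANASE = "MANNANASE"
    FUCOSIDASE = "FUCOSIDASE"
    LAMINARINASE = "LAMINARINASE"


ENZYME_TYPES: tuple[EnzymeType, ...] = tuple(EnzymeType)

_EC_PATTERN = re.compile(r"^EC3\.2\.1\.\d+$")
_SEPARATORS = re.compile(r"[-,\s]+")


@dataclass(frozen=True)
class EnzymeCatalogEntry:
    """One EC number with its enzyme type and alternative-name keywords."""

    enzyme_type: EnzymeType
    ec_number: str
    alternative_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not _EC_PATTERN.match(self.ec_number):
            raise ValueError(f"EC number {self.ec_number!r} not of form EC3.2.1.<n>")
        if not self.alternative_names:
            raise ValueError(f"{self.ec_number}: alternative_names must be non-empty")


@dataclass
class CandidateSet:
    """Transcripts (and their isoform groups) matched per enzyme type.

    A transcript may belong to several enzyme types; it is kept in each.
    """

    transcripts: dict[EnzymeType, set[str]] = field(default_factory=dict)

    def genes(self) -> dict[EnzymeType, set[str]]:
        return {
            etype: {gene_id_of(t) for t in tids}
            for etype, tids in self.transcripts.items()
        }

    def all_transcripts(self) -> set[str]:
        out: set[str] = set()
        for tids in self.transcripts.values():
            out |= tids
        return out

    def counts(self) -> dict[EnzymeType, tuple[int, int]]:
        """Per type: (transcript count, gene count)."""
        genes = self.genes()
        return {
            etype: (len(tids), len(genes[etype]))
            for etype, tids in self.transcripts.items()
        }


def load_catalog(path: str | Path | None = None) -> list[EnzymeCatalogEntry]:
    """Load the enzyme catalog (the packaged seven-type fixture by default)."""
    if path is None:
        source = resources.files("ghsieve").joinpath("data/enzyme_catalog.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = text.splitlines()
    header = lines[0].split("\t")
    if header != ["enzyme_type", "ec_number", "alternative_name"]:
        raise ValueError(f"unexpected catalog header {header}")
    grouped: dict[tuple[EnzymeType, str], list[str]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        etype, ec, name = line.split("\t")
        grouped.setdefault((EnzymeType(etype), ec), []).append(name)
    return [
        EnzymeCatalogEntry(etype, ec, tuple(names))
        for (etype, ec), names in grouped.items()
    ]


def normalize_keyword(text: str) -> str:
    """Lowercase and collapse hyphens, commas and whitespace runs to single
    spaces, so e.g. ``Endo-1,4-beta-Xylanase`` and ``endo 1,4 beta xylanase``
    normalize identically."""
    return _SEPARATORS.sub(" ", text.lower()).strip()


def build_keyword_index(
    catalog: Sequence[EnzymeCatalogEntry],
) -> dict[str, set[EnzymeType]]:
    """Map every normalized alternative name to the enzyme types it flags.

    The same name may legitimately appear under several EC numbers (and even
    several enzyme types, e.g. alpha-L-fucosidase); duplicates merge.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    index: dict[str, set[EnzymeType]] = {}
    for entry in catalog:
        for name in entry.alternative_names:
            index.setdefault(normalize_keyword(name), set()).add(entry.enzyme_type)
    return index


def keyword_matches(keyword_norm: str, annotation_norm: str) -> bool:
    """Normalized-substring match with a word-boundary guard: the keyword's
    first token must start, and its last token end, on a token boundary of
    the annotation.  ``laminarinase-like`` (-> ``laminarinase like``) still
    matches ``laminarinase``, but ``mannase`` cannot fire inside an
    unrelated longer token."""
    return f" {keyword_norm} " in f" {annotation_norm} "


def extract_gh_candidates(
    annotations: Mapping[str, str],
    index: Mapping[str, set[EnzymeType]],
) -> CandidateSet:
    """Assign each transcript to every enzyme type whose keyword occurs in
    its merged annotation text.  Transcripts matching nothing are absent."""
    result = CandidateSet(transcripts={etype: set() for etype in EnzymeType})
    for tid in sorted(annotations):
        text_norm = normalize_keyword(annotations[tid])
        padded = f" {text_norm} "
        for keyword, etypes in index.items():
            if f" {keyword} " in padded:
                for etype in etypes:
                    result.transcripts[etype].add(tid)
    return result


def dedupe_candidates(
    candidates: CandidateSet,
    transcripts: Iterable[TranscriptRecord],
    by: str = "peptide",
) -> CandidateSet:
    """Collapse redundant sequences within each enzyme type.

    Redundancy is exact sequence identity (peptide by default, nucleotide
    when ``by="nucleotide"``); the lexicographically smallest transcript id
    survives.  Candidate transcripts without a sequence record are kept.
    """
    if by not in {"peptide", "nucleotide"}:
        raise ValueError(f"unknown redundancy criterion {by!r}")
    seq_of = {
        rec.transcript_id: (rec.peptide if by == "peptide" else rec.nucleotide)
        for rec in transcripts
    }
    deduped = CandidateSet(transcripts={})
    for etype, tids in candidates.transcripts.items():
        survivors: dict[str, str] = {}  # sequence -> smallest transcript id
        no_sequence: set[str] = set()
        for tid in sorted(tids):
            seq = seq_of.get(tid)
            if not seq:
                no_sequence.add(tid)
            elif seq not in survivors:
                survivors[seq] = tid
        deduped.transcripts[etype] = set(survivors.values()) | no_sequence
    return deduped
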