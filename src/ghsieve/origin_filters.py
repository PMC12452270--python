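"""Hit-table screening stages.

These are the similarity-based stages of the decontamination pipeline:
top-hit selection, prokaryotic flagging, host-genome verification,
nearest-GH-family assignment, and threshold-parameterized extraction
(including the stricter 1e-30 variant used for cellulosome scaffolding
candidates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import HitRecord, Superkingdom

PROKARYOTIC_SUPERKINGDOMS = {Superkingdom.BACTERIA, Superkingdom.ARCHAEA}

UNKNOWN_GHF = "UNKNOWN"


@dataclass
class ThresholdConfig:
    """E-value and support thresholds of the screening stages.

    Defaults follow the study design: 1e-5 for sequence-database and
    genome-verification hits, 1e-10 for domain hits, a strict <1e-30 for
    scaffolding extraction, and a 50% bootstrap cutoff for tree collapsing.
    """

    evalue_annotation: float = 1e-5
    evalue_domain: float = 1e-10
    evalue_genome: float = 1e-5
    evalue_scaffolding: float = 1e-30
    support_threshold: int = 50

    def __post_init__(self) -> None:
        for name in ("evalue_annotation", "evalue_domain", "evalue_genome",
                     "evalue_scaffolding"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support_threshold must be in [0, 100]")


@dataclass(frozen=True)
class OriginLabel:
    """Final five-way origin call for one candidate transcript.

    PC: prokaryotic contamination; G: host, genome-verified; E: host,
    phylogenetically verified; EC: eukaryotic contamination; U: unique
    (no hit in any family of the verified reference database).
    """

    value: str
    rationale: str = ""
    review_flag: bool = False

    CATEGORIES = ("PC", "G", "E", "EC", "U")

    def __post_init__(self) -> None:
        if self.value not in self.CATEGORIES:
            raise ValueError(f"unknown origin label {self.value!r}")


def group_hits_by_query(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    grouped: dict[str, list[HitRecord]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def select_top_hit(hits: Sequence[HitRecord]) -> HitRecord | None:
    """Best hit for one query: minimal e-value, ties broken by maximal
    bitscore, then lexicographically smallest subject id.  None if empty."""
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def flag_prokaryotic(
    candidates: Iterable[str],
    hit_table: Iterable[HitRecord],
) -> tuple[set[str], set[str]]:
    """Partition candidates into (flagged prokaryotic, retained).

    A candidate is flagged iff its top hit is to Bacteria or Archaea.
    Candidates with no hits at all are retained: only positive prokaryotic
    evidence excludes a transcript.
    """
    grouped = group_hits_by_query(hit_table)
    flagged: set[str] = set()
    retained: set[str] = set()
    for tid in candidates:
        top = select_top_hit(grouped.get(tid, []))
        if top is not None and top.subject_superkingdom in PROKARYOTIC_SUPERKINGDOMS:
            flagged.add(tid)
        else:
            retained.add(tid)
    return flagged, retained


def verify_host_genome(
    candidates: Iterable[str],
    genome_hits: Iterable[HitRecord],
    cfg: ThresholdConfig | None = None,
) -> set[str]:
    """Candidates with at least one host-genome hit at e-value <= the genome
    threshold (inclusive) are classified host-genome-verified (label G)."""
    cfg = cfg or ThresholdConfig()
    grouped = group_hits_by_query(genome_hits)
    return {
        tid
        for tid in candidates
        if any(h.evalue <= cfg.evalue_genome for h in grouped.get(tid, []))
    }


def assign_nearest_ghf(
    candidate: str,
    refdb_hits: Sequence[HitRecord],
    cfg: ThresholdConfig | None = None,
) -> str:
    """GH family of the candidate's top hit against the verified reference
    database, or ``UNKNOWN`` when no hit passes the annotation threshold.

    UNKNOWN-family candidates end the pipeline with label U.
    """
    cfg = cfg or ThresholdConfig()
    mine = [
        h for h in refdb_hits
        if h.query_id == candidate and h.evalue <= cfg.evalue_annotation
    ]
    top = select_top_hit(mine)
    if top is None or not top.subject_ghf:
        return UNKNOWN_GHF
    return top.subject_ghf


def extract_by_threshold(
    hit_table: Iterable[HitRecord], evalue_cutoff: float
) -> set[str]:
    """Queries having at least one hit with e-value strictly below the
    cutoff (the scaffolding search uses <1e-30)."""
    return {h.query_id for h in hit_table if h.evalue < evalue_cutoff}
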