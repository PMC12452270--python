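"""Readers and writers for the formats the pipeline touches.

All tabular output is TSV with a fixed column order and ``"\\n"`` line
endings so that reruns diff bit-for-bit.  Taxonomy travels with the hit
tables as extra columns (the ``outfmt6_tax`` dialect) rather than being
resolved against a live service, which keeps every run offline and
deterministic.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

#: Trinity-style isoform suffix; stripping it yields the gene (isoform group) id.
ISOFORM_SUFFIX = re.compile(r"_i\d+$")

#: Standard 12-column BLAST tabular layout (``-outfmt 6``).
OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

#: Extension carrying subject taxonomy and GH-family metadata.
OUTFMT6_TAX_COLUMNS = OUTFMT6_COLUMNS + ["superkingdom", "superfamily", "ghf"]

NOT_DETECTED = "ND"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class Superkingdom(str, Enum):
    BACTERIA = "Bacteria"
    ARCHAEA = "Archaea"
    EUKARYOTA = "Eukaryota"
    UNKNOWN = "Unknown"


class TrueOrigin(str, Enum):
    """Planted ground-truth origin of a synthetic transcript."""

    HOST = "HOST"
    PROKARYOTE = "PROKARYOTE"
    FUNGUS = "FUNGUS"
    OTHER_EUKARYOTE = "OTHER_EUKARYOTE"


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript / predicted ORF."""

    transcript_id: str
    gene_id: str
    peptide: str = ""
    nucleotide: str | None = None
    true_origin: TrueOrigin | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError(f"{self.transcript_id}: gene_id must be non-empty")
        bad = set(self.peptide) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.transcript_id}: peptide contains non-amino-acid "
                f"characters {sorted(bad)}"
            )


def gene_id_of(transcript_id: str) -> str:
    """Isoform group of a transcript id: strip a trailing ``_i<digits>``."""
    return ISOFORM_SUFFIX.sub("", transcript_id)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit (BLAST tabular row)."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    subject_superkingdom: Superkingdom = Superkingdom.UNKNOWN
    subject_superfamily: str = ""
    subject_ghf: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if self.bitscore < 0:
            raise ValueError(f"bitscore must be >= 0, got {self.bitscore}")


class LeafKind(str, Enum):
    QUERY = "QUERY"
    REFERENCE = "REFERENCE"


@dataclass(frozen=True)
class LeafAnnotation:
    kind: LeafKind
    superfamily: str = ""
    genome_verified: bool = False


@dataclass
class TreeNode:
    """Node of a rooted support tree.

    ``support`` is the bootstrap percentage attached to the edge above this
    node (absent for leaves, the root, and unlabeled edges).
    """

    name: str | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def copy(self) -> "TreeNode":
        return TreeNode(
            name=self.name,
            support=self.support,
            children=[c.copy() for c in self.children],
        )


@dataclass
class SupportTree:
    """Rooted tree with per-edge bootstrap supports and annotated leaves."""

    root: TreeNode
    leaf_annotation: dict[str, LeafAnnotation]

    def __post_init__(self) -> None:
        names = [leaf.name for leaf in self.root.leaves()]
        if len(names) != len(set(names)):
            raise FormatError("duplicate leaf labels in tree")
        for name in names:
            if name not in self.leaf_annotation:
                raise FormatError(f"leaf {name!r} missing from annotation table")
        for node in _walk(self.root):
            if node.support is not None and not 0 <= node.support <= 100:
                raise FormatError(f"support {node.support} outside [0, 100]")

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def copy(self) -> "SupportTree":
        return SupportTree(self.root.copy(), dict(self.leaf_annotation))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def _walk(node: TreeNode) -> Iterable[TreeNode]:
    stack = [node]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(cur.children)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-transcript expression / secretion summary row."""

    transcript_id: str
    tpm: float
    signal_peptide: bool
    enzyme_type: str
    origin_label: str

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"{self.transcript_id}: TPM must be >= 0")

    @property
    def log2_tpm(self) -> float | None:
        """log2(TPM), or None when the transcript was not detected (TPM=0)."""
        return math.log2(self.tpm) if self.tpm > 0 else None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a peptide FASTA into TranscriptRecords.

    The header token before the first whitespace is the transcript id; the
    gene id is derived by stripping a Trinity-style ``_i<digits>`` isoform
    suffix when present.
    """
    with _open_text(path) as handle:
        text = handle.read()
    # SeqIO silently drops leading junk; report it with a line number instead.
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FormatError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        break
    records = [
        TranscriptRecord(
            transcript_id=rec.id,
            gene_id=gene_id_of(rec.id),
            peptide=str(rec.seq).upper(),
        )
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        log.warning("read_fasta: %s contained no sequences", path)
    seen: set[str] = set()
    for rec in records:
        if rec.transcript_id in seen:
            raise FormatError(f"{path}: duplicate transcript id {rec.transcript_id!r}")
        seen.add(rec.transcript_id)
    return records


def write_fasta(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as out:
        for rec in records:
            out.write(f">{rec.transcript_id}\n{rec.peptide}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def parse_hit_table(path: str | Path, dialect: str = "outfmt6_tax") -> list[HitRecord]:
    """Parse a BLAST tabular file (``outfmt6`` or ``outfmt6_tax`` dialect).

    Row order is preserved; comment lines starting with ``#`` are skipped.
    """
    if dialect == "outfmt6":
        columns = OUTFMT6_COLUMNS
    elif dialect == "outfmt6_tax":
        columns = OUTFMT6_TAX_COLUMNS
    else:
        raise ValueError(f"unknown hit-table dialect {dialect!r}")

    with _open_text(path) as handle:
        lines = handle.read().splitlines()

    records: list[HitRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise FormatError(
                f"{path}: row {lineno}: expected {len(columns)} columns, "
                f"got {len(fields)}"
            )
        row = dict(zip(columns, fields))
        try:
            evalue = float(row["evalue"])
            pident = float(row["pident"])
            bitscore = float(row["bitscore"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: non-numeric field ({exc})")
        kingdom = row.get("superkingdom", "").strip()
        records.append(
            HitRecord(
                query_id=row["qseqid"],
                subject_id=row["sseqid"],
                percent_identity=pident,
                evalue=evalue,
                bitscore=bitscore,
                subject_superkingdom=(
                    Superkingdom(kingdom) if kingdom else Superkingdom.UNKNOWN
                ),
                subject_superfamily=row.get("superfamily", "").strip(),
                subject_ghf=row.get("ghf", "").strip() or None,
            )
        )
    return records


def write_hit_table(
    hits: Sequence[HitRecord], path: str | Path, dialect: str = "outfmt6_tax"
) -> None:
    """Write hits in BLAST tabular form (placeholder alignment coordinates)."""
    with open(path, "w", newline="\n") as out:
        for h in hits:
            base = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.3f}",
                "0", "0", "0", "0", "0", "0", "0",
                f"{h.evalue:.6g}",
                f"{h.bitscore:.1f}",
            ]
            if dialect == "outfmt6_tax":
                base += [
                    h.subject_superkingdom.value,
                    h.subject_superfamily,
                    h.subject_ghf or "",
                ]
            out.write("\t".join(base) + "\n")


# ---------------------------------------------------------------------------
# Newick with support values
# ---------------------------------------------------------------------------

def parse_newick_support(
    path_or_text: str | Path,
    annotation_table: Mapping[str, LeafAnnotation],
) -> SupportTree:
    """Parse a single Newick tree whose internal node labels are bootstrap
    supports (the IQ-TREE / consensus dialect; support attaches to the edge
    above the labeled node).

    Non-numeric internal labels yield an absent support with a warning.
    Every leaf must appear in ``annotation_table``.
    """
    text = str(path_or_text)
    if "(" not in text:  # treat as a path
        with _open_text(path_or_text) as handle:
            text = handle.read()
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(name=str(name).replace(" ", "_"))
        node = TreeNode(children=[convert(c) for c in dnode.child_nodes()])
        label = dnode.label
        if label is not None:
            try:
                node.support = int(round(float(label)))
            except ValueError:
                log.warning(
                    "non-numeric internal node label %r: support left absent", label
                )
        return node

    root = convert(dtree.seed_node)
    for leaf in root.leaves():
        if leaf.name not in annotation_table:
            raise FormatError(f"leaf {leaf.name!r} missing from annotation table")
    return SupportTree(root=root, leaf_annotation=dict(annotation_table))


LEAF_ANNOTATION_COLUMNS = ["leaf", "kind", "superfamily", "genome_verified"]


def read_leaf_annotations(path: str | Path) -> dict[str, LeafAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(LEAF_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return {
        row.leaf: LeafAnnotation(
            kind=LeafKind(row.kind),
            superfamily=row.superfamily,
            genome_verified=str(row.genome_verified).lower() in {"true", "1", "yes"},
        )
        for row in df.itertuples()
    }


def write_leaf_annotations(
    annotations: Mapping[str, LeafAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as out:
        out.write("\t".join(LEAF_ANNOTATION_COLUMNS) + "\n")
        for leaf in sorted(annotations):
            ann = annotations[leaf]
            out.write(
                f"{leaf}\t{ann.kind.value}\t{ann.superfamily}\t"
                f"{str(ann.genome_verified).lower()}\n"
            )


# ---------------------------------------------------------------------------
# Expression / annotation tables
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = [
    "transcript_id", "tpm", "signal_peptide", "enzyme_type", "origin_label",
]


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        ExpressionRecord(
            transcript_id=row.transcript_id,
            tpm=float(row.tpm),
            signal_peptide=str(row.signal_peptide).lower() in {"true", "1", "yes"},
            enzyme_type=row.enzyme_type,
            origin_label=row.origin_label,
        )
        for row in df.itertuples()
    ]


def write_expression_table(
    records: Sequence[ExpressionRecord], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as out:
        out.write("\t".join(EXPRESSION_COLUMNS) + "\n")
        for rec in records:
            out.write(
                f"{rec.transcript_id}\t{rec.tpm:.6g}\t"
                f"{str(rec.signal_peptide).lower()}\t{rec.enzyme_type}\t"
                f"{rec.origin_label}\n"
            )


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Trinotate-style table: transcript_id TAB merged annotation text."""
    annotations: dict[str, str] = {}
    with _open_text(path) as handle:
        header = handle.readline()
        if not header.startswith("transcript_id\t"):
            raise FormatError(f"{path}: expected header 'transcript_id\\tannotation'")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise FormatError(f"{path}: row {lineno}: expected 2 columns")
            annotations[parts[0]] = parts[1]
    return annotations


def write_annotation_table(annotations: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as out:
        out.write("transcript_id\tannotation\n")
        for tid in sorted(annotations):
            out.write(f"{tid}\t{annotations[tid]}\n")


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

ORIGIN_CATEGORIES = ["PC", "G", "E", "EC", "U"]


def format_log2_tpm_cell(log2_tpm: float | None) -> str:
    """One heatmap cell: log2(TPM) to 1 decimal, blank when it would round
    to 0 at that precision (i.e. for values strictly inside (-0.05, 0.05)),
    and ``ND`` for undetected (TPM = 0) transcripts."""
    if log2_tpm is None:
        return NOT_DETECTED
    if -0.05 < log2_tpm < 0.05:
        return ""
    return f"{log2_tpm:.1f}"


def write_heatmap_table(
    records: Sequence[ExpressionRecord], path: str | Path
) -> None:
    """Per-transcript log2(TPM) table mirroring the published heatmap's
    rounding rule (1 decimal; near-zero cells left blank)."""
    with open(path, "w", newline="\n") as out:
        out.write("transcript_id\tenzyme_type\torigin_label\tlog2_tpm\n")
        for rec in sorted(records, key=lambda r: (r.enzyme_type, r.transcript_id)):
            out.write(
                f"{rec.transcript_id}\t{rec.enzyme_type}\t{rec.origin_label}\t"
                f"{format_log2_tpm_cell(rec.log2_tpm)}\n"
            )


def write_partition_report(
    labels: Mapping[str, str],
    enzyme_types: Mapping[str, str],
    path: str | Path,
) -> pd.DataFrame:
    """Five-way origin partition counts per enzyme type.

    ``labels`` maps transcript_id -> one of PC/G/E/EC/U; ``enzyme_types``
    maps transcript_id -> enzyme type.  The derived ``eukaryotic`` column is
    G+E+U and ``prokaryotic_side`` is PC+EC, matching the published grouping
    of the five categories.
    """
    missing = set(enzyme_types) - set(labels)
    if missing:
        raise ValueError(f"labels missing for candidates: {sorted(missing)[:5]}")
    rows: dict[str, dict[str, int]] = {}
    for tid, etype in enzyme_types.items():
        row = rows.setdefault(etype, {c: 0 for c in ORIGIN_CATEGORIES})
        label = labels[tid]
        if label not in row:
            raise ValueError(f"unknown origin label {label!r} for {tid}")
        row[label] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "enzyme_type"
    df["total"] = df[ORIGIN_CATEGORIES].sum(axis=1)
    df["eukaryotic"] = df[["G", "E", "U"]].sum(axis=1)
    df["prokaryotic_side"] = df[["PC", "EC"]].sum(axis=1)
    with open(path, "w", newline="\n") as out:
        df.to_csv(out, sep="\t", lineterminator="\n")
    return df
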