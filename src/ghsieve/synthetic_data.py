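"""Synthetic contaminated-transcriptome generator with planted ground truth.

The generator emulates the structure of a de novo transcriptome assembled
from a cultured protist: host glycoside-hydrolase (GH) gene families plus
planted prokaryotic, fungal and other-eukaryote contaminant transcripts,
together with every table the screening pipeline consumes — annotation
text, similarity-hit tables, host-genome hits, reference catalogs,
per-family trees, and expression / signal-peptide tables linked through a
known logistic relationship.

Sequences within one GH family share a random ancestral peptide; each
superfamily's references and each transcript are produced by i.i.d.
substitution at configured divergences, so similarity ordering (and hence
every threshold decision) is controlled by construction.  Surrogate
e-values are a fixed monotone function of percent identity
(``1e-(identity/2)``): real e-values depend on database size, but only
ordering and thresholds matter to the pipeline.

Everything is driven by a single integer seed; two runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gh_catalog import ENZYME_TYPES, EnzymeType, load_catalog
from .io_formats import (
    ExpressionRecord,
    HitRecord,
    LeafAnnotation,
    LeafKind,
    Superkingdom,
    SupportTree,
    TranscriptRecord,
    TreeNode,
    TrueOrigin,
)
from .refdb_curation import EvidenceCode, ReferenceEntry

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: GH family labels assigned to simulated families, echoing prominent
#: families of the seven enzyme types (GHF5 cellulase, GHF10 xylanase,
#: GHF28 pectinase, GHF18 chitinase, GHF2 mannanase, GHF29 fucosidase,
#: GHF16 laminarinase).
GHF_LABELS = ("GHF5", "GHF10", "GHF28", "GHF18", "GHF2", "GHF29", "GHF16")

DECOY_VOCABULARY = (
    "hypothetical protein", "protein kinase", "serine threonine phosphatase",
    "ABC transporter permease", "40S ribosomal protein", "zinc finger domain",
    "DEAD-box RNA helicase", "DNA polymerase delta subunit", "histone H2B",
    "alpha tubulin", "actin related protein", "myosin heavy chain",
    "G protein coupled receptor", "heat shock chaperone", "ubiquitin ligase",
    "cytochrome c oxidase", "NADH dehydrogenase subunit", "elongation factor",
    "proteasome regulatory subunit", "calcium binding EF-hand protein",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic contaminated transcriptome.

    Counts and divergences are the generator's defaults for the standard
    study: 60 host GH transcripts, 20 prokaryotic and 10 + 10 eukaryotic
    contaminants, host divergence 0.10 from the family reference point and
    0.15 for contaminants, bootstrap 95 on true edges and 30 on planted
    distractor edges.
    """

    seed: int
    n_host_gh: int = 60
    n_prok: int = 20
    n_fungal: int = 10
    n_other_euk: int = 10
    n_decoy: int = 20
    n_families: int = 7
    family_length: int = 120
    divergence: Mapping[str, float] = field(
        default_factory=lambda: {
            "HOST": 0.10, "PROKARYOTE": 0.15, "FUNGUS": 0.15,
            "OTHER_EUKARYOTE": 0.15,
        }
    )
    superfamily_divergence: float = 0.25
    bacterial_divergence: float = 0.45
    refs_per_superfamily: int = 2
    excluded_refs_per_family: int = 1
    genome_families: int | None = None  # default: n_families // 2
    genome_member_interval: int = 2  # every k-th host in a genome family hits
    distractor_families: int | None = None  # default: n_families // 2
    isoform_interval: int = 5  # every k-th host transcript is an isoform
    support_high: int = 95
    support_low: int = 30
    beta0: float = -1.0
    beta1: float = 0.0
    beta1_by_type: Mapping[str, float] = field(
        default_factory=lambda: {"CELLULASE": 1.2, "CHITINASE": 1.2}
    )
    tpm_logmean: float = 2.0
    tpm_logsd: float = 3.0
    tpm_zero_fraction: float = 0.05
    identity_floor: float = 10.0
    host_superfamily: str = "Foraminifera"
    fungal_superfamily: str = "Fungi"
    other_euk_superfamily: str = "Viridiplantae"
    prok_superfamily: str = "Proteobacteria"

    def __post_init__(self) -> None:
        for name in ("n_host_gh", "n_prok", "n_fungal", "n_other_euk",
                     "n_decoy", "n_families", "family_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for origin, d in self.divergence.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"divergence[{origin}] outside [0, 1]")
        for name in ("support_high", "support_low"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} outside [0, 100]")

    @property
    def contaminant_superfamilies(self) -> frozenset[str]:
        """Superfamilies the planted eukaryotic contaminants derive from —
        the contamination-prone taxa of the synthetic study."""
        return frozenset({self.fungal_superfamily, self.other_euk_superfamily})

    def n_genome_families(self) -> int:
        return (self.n_families // 2 if self.genome_families is None
                else self.genome_families)

    def n_distractor_families(self) -> int:
        return (self.n_families // 2 if self.distractor_families is None
                else self.distractor_families)


@dataclass(frozen=True)
class SimReference:
    """One reference sequence of the simulated general protein database."""

    accession: str
    peptide: str
    superkingdom: Superkingdom
    superfamily: str
    ghf: str


@dataclass
class SimFamily:
    index: int
    ghf: str
    enzyme_type: EnzymeType
    ancestor: str
    euk_refs: list[SimReference]
    bacterial_refs: list[SimReference]
    catalog_entries: list[ReferenceEntry]  # includes curation-destined rejects
    genome_verified: bool
    has_distractor: bool


@dataclass
class SimulatedFamilies:
    families: list[SimFamily]

    def catalog(self) -> list[ReferenceEntry]:
        return [e for fam in self.families for e in fam.catalog_entries]

    def all_references(self) -> list[SimReference]:
        """General database: eukaryotic plus bacterial references."""
        return [r for fam in self.families
                for r in fam.euk_refs + fam.bacterial_refs]

    def verified_references(self) -> list[SimReference]:
        """References of the verified eukaryotic GH database."""
        retained = {
            e.accession for fam in self.families for e in fam.catalog_entries
            if e.has_public_reference and e.evidence_codes
        }
        return [r for fam in self.families for r in fam.euk_refs
                if r.accession in retained]

    def family_of_ghf(self) -> dict[str, SimFamily]:
        return {fam.ghf: fam for fam in self.families}


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))


def mutate(peptide: str, divergence: float, rng: np.random.Generator) -> str:
    """I.i.d. substitution: each position is replaced, with probability
    ``divergence``, by a uniformly random different amino acid."""
    out = list(peptide)
    for i in range(len(out)):
        if rng.random() < divergence:
            choices = AA20.replace(out[i], "")
            out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def substitute_exactly(peptide: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``k`` distinct positions (isoform variants must
    differ from their sibling so redundancy removal keeps both)."""
    out = list(peptide)
    for i in rng.choice(len(out), size=min(k, len(out)), replace=False):
        choices = AA20.replace(out[i], "")
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def percent_identity(a: str, b: str) -> float:
    """Exact per-position identity of equal-length sequences, in percent."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 0.0
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def surrogate_evalue(identity_pct: float) -> float:
    """Deterministic stand-in for a database e-value: ``10^(-identity/2)``,
    so 100% identity maps to 1e-50 and the 10% floor to 1e-5."""
    return 10.0 ** (-0.5 * identity_pct)


# ---------------------------------------------------------------------------
# Families and references
# ---------------------------------------------------------------------------

def simulate_families(cfg: SimulationConfig) -> SimulatedFamilies:
    """Simulate the GH families and their reference sequences.

    Each family gets a random ancestral peptide; eukaryotic references
    (fungal and green-plant superfamilies) diverge from it at the
    superfamily divergence, bacterial references further out.  Evidence
    codes and reference flags are assigned so that the designated excluded
    entries fail curation deterministically.
    """
    rng = np.random.default_rng(cfg.seed)
    n_genome = cfg.n_genome_families()
    n_distract = cfg.n_distractor_families()
    families: list[SimFamily] = []
    for i in range(cfg.n_families):
        ghf = (GHF_LABELS[i] if i < len(GHF_LABELS) else f"GHF{100 + i}")
        etype = ENZYME_TYPES[i % len(ENZYME_TYPES)]
        ancestor = _random_peptide(rng, cfg.family_length)

        euk_refs: list[SimReference] = []
        entries: list[ReferenceEntry] = []
        evidence_cycle = list(EvidenceCode)
        for s_idx, sfam in enumerate(
            (cfg.fungal_superfamily, cfg.other_euk_superfamily)
        ):
            for j in range(cfg.refs_per_superfamily):
                acc = f"{ghf}_{sfam[:4].lower()}{j}"
                pep = mutate(ancestor, cfg.superfamily_divergence, rng)
                euk_refs.append(
                    SimReference(acc, pep, Superkingdom.EUKARYOTA, sfam, ghf)
                )
                entries.append(
                    ReferenceEntry(
                        accession=acc, peptide=pep, superfamily=sfam, ghf=ghf,
                        enzyme_type=etype, has_public_reference=True,
                        evidence_codes=frozenset(
                            {evidence_cycle[(i + s_idx + j) % len(evidence_cycle)]}
                        ),
                    )
                )
        for j in range(cfg.excluded_refs_per_family):
            acc = f"{ghf}_excl{j}"
            pep = mutate(ancestor, cfg.superfamily_divergence, rng)
            no_ref = (i + j) % 2 == 0
            entries.append(
                ReferenceEntry(
                    accession=acc, peptide=pep,
                    superfamily=cfg.fungal_superfamily, ghf=ghf,
                    enzyme_type=etype, has_public_reference=not no_ref,
                    evidence_codes=(
                        frozenset({EvidenceCode.GENOMIC_ASSEMBLY})
                        if no_ref else frozenset()
                    ),
                )
            )
        bacterial = [
            SimReference(
                f"{ghf}_bact{j}",
                mutate(ancestor, cfg.bacterial_divergence, rng),
                Superkingdom.BACTERIA, cfg.prok_superfamily, "",
            )
            for j in range(cfg.refs_per_superfamily)
        ]
        families.append(
            SimFamily(
                index=i, ghf=ghf, enzyme_type=etype, ancestor=ancestor,
                euk_refs=euk_refs, bacterial_refs=bacterial,
                catalog_entries=entries,
                genome_verified=i < n_genome,
                has_distractor=i >= cfg.n_families - n_distract,
            )
        )
    return SimulatedFamilies(families)


# ---------------------------------------------------------------------------
# Transcripts, annotations and planted truth
# ---------------------------------------------------------------------------

@dataclass
class SimTranscriptome:
    transcripts: list[TranscriptRecord]
    annotations: dict[str, str]
    family_of: dict[str, SimFamily]           # GH transcripts only
    expected_label: dict[str, str]            # planted five-way truth
    genome_hit_ids: set[str]                  # hosts planted with genome hits

    def candidates(self) -> list[str]:
        return sorted(self.family_of)


def _keyword_for(etype: EnzymeType, idx: int, catalog_names) -> str:
    names = catalog_names[etype]
    return names[idx % len(names)]


def simulate_transcriptome(
    cfg: SimulationConfig, families: SimulatedFamilies
) -> SimTranscriptome:
    """Simulate host, contaminant and decoy transcripts with annotations.

    Every planted GH transcript's annotation text contains one catalog
    keyword for its enzyme type; decoy annotations contain none.  A host
    transcript every ``isoform_interval`` positions is emitted as a second
    isoform of the preceding host gene.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    catalog_names = {
        entry.enzyme_type: []
        for entry in load_catalog()
    }
    for entry in load_catalog():
        catalog_names[entry.enzyme_type].extend(entry.alternative_names)

    fams = families.families
    transcripts: list[TranscriptRecord] = []
    annotations: dict[str, str] = {}
    family_of: dict[str, SimFamily] = {}
    expected: dict[str, str] = {}
    genome_ids: set[str] = set()

    def add_gh(tid: str, peptide: str, fam: SimFamily, origin: TrueOrigin,
               label: str) -> None:
        rec = TranscriptRecord(
            transcript_id=tid, gene_id=tid.rsplit("_i", 1)[0],
            peptide=peptide, true_origin=origin,
        )
        transcripts.append(rec)
        kw = _keyword_for(fam.enzyme_type, len(annotations), catalog_names)
        annotations[tid] = f"{kw}, putative; glycoside hydrolase family protein"
        family_of[tid] = fam
        expected[tid] = label

    # hosts ---------------------------------------------------------------
    gene_counter = 0
    prev_host: tuple[str, SimFamily, str] | None = None  # (peptide, fam, label)
    host_index_in_family: dict[int, int] = {}
    for j in range(cfg.n_host_gh):
        is_isoform = (
            cfg.isoform_interval > 0
            and j % cfg.isoform_interval == cfg.isoform_interval - 1
            and prev_host is not None
        )
        if is_isoform:
            pep0, fam, label = prev_host
            peptide = substitute_exactly(pep0, 2, rng)
            tid = f"t{gene_counter - 1:04d}_i2"
        else:
            fam = fams[j % len(fams)]
            # host sequences diverge from the family's eukaryotic reference
            # point (the ancestor) at the host divergence
            peptide = mutate(fam.ancestor, cfg.divergence["HOST"], rng)
            label = "G" if fam.genome_verified else "E"
            tid = f"t{gene_counter:04d}_i1"
            gene_counter += 1
            prev_host = (peptide, fam, label)
        add_gh(tid, peptide, fam, TrueOrigin.HOST, label)
        k = host_index_in_family.setdefault(fam.index, 0)
        host_index_in_family[fam.index] += 1
        if fam.genome_verified and k % cfg.genome_member_interval == 0:
            genome_ids.add(tid)

    # contaminants --------------------------------------------------------
    def contaminant_block(n: int, origin: TrueOrigin, source_of) -> None:
        nonlocal gene_counter
        for j in range(n):
            fam = fams[j % len(fams)]
            source = source_of(fam)
            peptide = mutate(source, cfg.divergence[origin.value], rng)
            tid = f"t{gene_counter:04d}_i1"
            gene_counter += 1
            add_gh(tid, peptide, fam, origin,
                   "PC" if origin is TrueOrigin.PROKARYOTE else "EC")

    contaminant_block(cfg.n_prok, TrueOrigin.PROKARYOTE,
                      lambda fam: fam.bacterial_refs[0].peptide)
    contaminant_block(cfg.n_fungal, TrueOrigin.FUNGUS,
                      lambda fam: fam.euk_refs[0].peptide)
    contaminant_block(cfg.n_other_euk, TrueOrigin.OTHER_EUKARYOTE,
                      lambda fam: fam.euk_refs[cfg.refs_per_superfamily].peptide)

    # decoys --------------------------------------------------------------
    for j in range(cfg.n_decoy):
        tid = f"t{gene_counter:04d}_i1"
        gene_counter += 1
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid, gene_id=tid.rsplit("_i", 1)[0],
                peptide=_random_peptide(rng, cfg.family_length),
            )
        )
        annotations[tid] = DECOY_VOCABULARY[j % len(DECOY_VOCABULARY)]

    return SimTranscriptome(
        transcripts=transcripts, annotations=annotations,
        family_of=family_of, expected_label=expected,
        genome_hit_ids=genome_ids,
    )


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def simulate_hit_table(
    transcripts: Iterable[TranscriptRecord],
    references: Sequence[SimReference],
    cfg: SimulationConfig,
) -> list[HitRecord]:
    """All-vs-all similarity hits with surrogate e-values.

    Percent identity is exact per-position comparison (sequences share one
    length by construction); pairs below the identity floor are omitted,
    mirroring a search reporting nothing past its threshold.
    """
    hits: list[HitRecord] = []
    for rec in transcripts:
        if not rec.peptide:
            continue
        for ref in references:
            ident = percent_identity(rec.peptide, ref.peptide)
            if ident < cfg.identity_floor:
                continue
            hits.append(
                HitRecord(
                    query_id=rec.transcript_id,
                    subject_id=ref.accession,
                    percent_identity=ident,
                    evalue=surrogate_evalue(ident),
                    bitscore=2.0 * ident,
                    subject_superkingdom=ref.superkingdom,
                    subject_superfamily=ref.superfamily,
                    subject_ghf=ref.ghf or None,
                )
            )
    return hits


def simulate_genome_hits(
    transcriptome: SimTranscriptome, cfg: SimulationConfig
) -> list[HitRecord]:
    """Host-genome hit table: the designated host transcripts of
    genome-verified families receive one strong hit against a host genome
    fragment; everything else is absent."""
    return [
        HitRecord(
            query_id=tid,
            subject_id=f"host_genome_frag_{i:03d}",
            percent_identity=90.0,
            evalue=1e-20,
            bitscore=180.0,
            subject_superkingdom=Superkingdom.EUKARYOTA,
            subject_superfamily=cfg.host_superfamily,
        )
        for i, tid in enumerate(sorted(transcriptome.genome_hit_ids))
    ]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(
    cfg: SimulationConfig,
    fam: SimFamily,
    transcriptome: SimTranscriptome,
    mode: str = "planted",
) -> SupportTree:
    """Per-family support tree over the family's eukaryotic-side query
    transcripts and its verified references.

    PLANTED mode builds the true clade topology directly: host queries
    monophyletic, each contaminant group nested inside its source
    superfamily's reference clade, ``support_high`` on true edges, and one
    spurious ``support_low`` edge (grouping the host clade with the fungal
    clade) in designated distractor families.  DISTANCE mode derives the
    topology by neighbor joining from p-distances on the simulated
    peptides.
    """
    members = {
        tid: rec
        for rec in transcriptome.transcripts
        if (tid := rec.transcript_id) in transcriptome.family_of
        and transcriptome.family_of[tid].index == fam.index
        and rec.true_origin is not TrueOrigin.PROKARYOTE
    }
    annotation: dict[str, LeafAnnotation] = {
        tid: LeafAnnotation(kind=LeafKind.QUERY) for tid in members
    }
    refs = [r for r in fam.euk_refs]
    for ref in refs:
        annotation[ref.accession] = LeafAnnotation(
            kind=LeafKind.REFERENCE, superfamily=ref.superfamily
        )

    if mode == "distance":
        leaves = {tid: rec.peptide for tid, rec in members.items()}
        leaves.update({r.accession: r.peptide for r in refs})
        root = _neighbor_joining(leaves, cfg.support_high)
        return SupportTree(root, annotation)
    if mode != "planted":
        raise ValueError(f"unknown tree mode {mode!r}")

    def origin_of(tid: str) -> TrueOrigin:
        return members[tid].true_origin

    hosts = sorted(t for t in members if origin_of(t) is TrueOrigin.HOST)
    fungal = sorted(t for t in members if origin_of(t) is TrueOrigin.FUNGUS)
    plants = sorted(
        t for t in members if origin_of(t) is TrueOrigin.OTHER_EUKARYOTE
    )

    def clade(children: list[TreeNode], support: int) -> TreeNode:
        return TreeNode(support=support, children=children)

    def leaf(name: str) -> TreeNode:
        return TreeNode(name=name)

    def ref_clade(sfam: str, queries: list[str]) -> TreeNode:
        ref_leaves = [leaf(r.accession) for r in refs if r.superfamily == sfam]
        children = list(ref_leaves)
        if queries:
            if len(queries) == 1:
                children.append(leaf(queries[0]))
            else:
                children.append(
                    clade([leaf(q) for q in queries], cfg.support_high)
                )
        return clade(children, cfg.support_high)

    host_clade = (
        clade([leaf(t) for t in hosts], cfg.support_high) if len(hosts) > 1
        else leaf(hosts[0]) if hosts else None
    )
    fungal_clade = ref_clade(cfg.fungal_superfamily, fungal)
    plant_clade = ref_clade(cfg.other_euk_superfamily, plants)

    top: list[TreeNode] = []
    if host_clade is not None and fam.has_distractor:
        top.append(clade([host_clade, fungal_clade], cfg.support_low))
    else:
        if host_clade is not None:
            top.append(host_clade)
        top.append(fungal_clade)
    top.append(plant_clade)
    return SupportTree(TreeNode(children=top), annotation)


def _neighbor_joining(leaves: Mapping[str, str], support: int) -> TreeNode:
    """Neighbor joining on p-distances via scikit-bio, converted to a rooted
    TreeNode with the given support on internal edges."""
    import skbio

    names = sorted(leaves)
    if len(names) < 4:
        raise ValueError("DISTANCE mode needs at least 4 leaves")
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - percent_identity(leaves[names[i]], leaves[names[j]]) / 100.0
            dm[i, j] = dm[j, i] = d
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=names))

    def convert(node) -> TreeNode:
        if node.is_tip():
            return TreeNode(name=node.name)
        return TreeNode(
            support=support, children=[convert(c) for c in node.children]
        )

    root = convert(sk_tree.root())
    root.support = None  # root has no edge above it
    return root


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    transcripts: Sequence[TranscriptRecord],
    cfg: SimulationConfig,
    enzyme_type_of: Mapping[str, str],
    origin_label_of: Mapping[str, str] | None = None,
) -> list[ExpressionRecord]:
    """Expression and signal-peptide tables under a known logistic link.

    log2(TPM) is Normal(tpm_logmean, tpm_logsd); a ``tpm_zero_fraction`` of
    transcripts is set undetected (TPM = 0).  Signal-peptide presence is
    Bernoulli(logistic(beta0 + beta1 * log2 TPM)) with per-enzyme-type
    slope overrides (positive for cellulase and chitinase by default, zero
    elsewhere, echoing the association the pipeline is meant to detect).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    records: list[ExpressionRecord] = []
    for rec in transcripts:
        tid = rec.transcript_id
        if tid not in enzyme_type_of:
            continue
        etype = str(enzyme_type_of[tid])
        beta1 = cfg.beta1_by_type.get(etype, cfg.beta1)
        log2_tpm = rng.normal(cfg.tpm_logmean, cfg.tpm_logsd)
        undetected = rng.random() < cfg.tpm_zero_fraction
        tpm = 0.0 if undetected else float(2.0 ** log2_tpm)
        eta = cfg.beta0 + (0.0 if undetected else beta1 * log2_tpm)
        p = 1.0 / (1.0 + math.exp(-eta))
        records.append(
            ExpressionRecord(
                transcript_id=tid,
                tpm=tpm,
                signal_peptide=bool(rng.random() < p),
                enzyme_type=etype,
                origin_label=(origin_label_of or {}).get(tid, "E"),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Every input of one synthetic study, plus the planted truth."""

    cfg: SimulationConfig
    families: SimulatedFamilies
    transcriptome: SimTranscriptome
    general_hits: list[HitRecord]
    refdb_hits: list[HitRecord]
    genome_hits: list[HitRecord]
    trees: dict[str, SupportTree]  # keyed by GH family label
    expression: list[ExpressionRecord]


def simulate_study(cfg: SimulationConfig, tree_mode: str = "planted") -> SyntheticStudy:
    families = simulate_families(cfg)
    transcriptome = simulate_transcriptome(cfg, families)
    general_hits = simulate_hit_table(
        transcriptome.transcripts, families.all_references(), cfg
    )
    refdb_hits = simulate_hit_table(
        transcriptome.transcripts, families.verified_references(), cfg
    )
    genome_hits = simulate_genome_hits(transcriptome, cfg)
    trees = {
        fam.ghf: simulate_tree(cfg, fam, transcriptome, mode=tree_mode)
        for fam in families.families
    }
    enzyme_type_of = {
        tid: fam.enzyme_type.value
        for tid, fam in transcriptome.family_of.items()
    }
    expression = simulate_expression(
        transcriptome.transcripts, cfg, enzyme_type_of,
        origin_label_of=transcriptome.expected_label,
    )
    return SyntheticStudy(
        cfg=cfg, families=families, transcriptome=transcriptome,
        general_hits=general_hits, refdb_hits=refdb_hits,
        genome_hits=genome_hits, trees=trees, expression=expression,
    )
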