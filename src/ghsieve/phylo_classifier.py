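"""Endogeneity decisions on bootstrap-collapsed phylogenies.

Each gene tree mixes query transcripts with reference sequences whose
superfamily (Fungi, Viridiplantae, Metazoa, ...) is known.  After edges
with weak bootstrap support are collapsed into polytomies, every query
leaf is classified by the composition of its phylogenetic neighborhood:

For a query leaf ``q``, let ``Cq`` be the maximal clade containing ``q``
whose leaves are all queries, ``M`` the smallest ancestor of ``Cq``
containing at least one reference leaf, and ``S`` the set of superfamilies
among ``M``'s reference leaves.  Then:

(a) if any leaf of ``Cq`` is genome-verified, the entire clade is host
    in origin (label G) — the clade-rescue rule;
(b) else if ``S`` is a single contamination-prone superfamily (Fungi by
    default), the clade is eukaryotic contamination (EC);
(c) else if ``S`` is a single non-prone superfamily, the clade is host
    with a review flag (E) by default, or EC in strict mode — a tightly
    clustering non-fungal neighbor is weaker contamination evidence;
(d) else (mixed backbone), the clade is host (E); flagged for review only
    when its stem edge lacks retained bootstrap support.

All leaves of one ``Cq`` receive identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io_formats import LeafKind, SupportTree, TreeNode
from .origin_filters import OriginLabel, ThresholdConfig

DEFAULT_PRONE_TAXA = frozenset({"Fungi"})


@dataclass(frozen=True)
class CladeDecision:
    leaf: str
    label: OriginLabel
    enclosing_superfamilies: frozenset[str]
    stem_supported: bool

    def __post_init__(self) -> None:
        if self.label.value not in {"G", "E", "EC"}:
            raise ValueError(f"tree classification cannot yield {self.label.value}")
        if not self.label.rationale:
            raise ValueError("rationale must be non-empty")


def collapse_low_support(tree: SupportTree, threshold: int) -> SupportTree:
    """Contract every internal edge whose bootstrap support is below the
    threshold; the collapsed node's children reattach to its parent,
    forming polytomies.  Edges with absent support are retained, and
    leaves are never removed."""
    if not 0 <= threshold <= 101:
        raise ValueError("collapse threshold must be in [0, 101]")

    def rebuild(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return TreeNode(name=node.name, support=node.support)
        new_children: list[TreeNode] = []
        for child in node.children:
            rebuilt = rebuild(child)
            collapse = (
                not rebuilt.is_leaf
                and rebuilt.support is not None
                and rebuilt.support < threshold
            )
            if collapse:
                new_children.extend(rebuilt.children)
            else:
                new_children.append(rebuilt)
        return TreeNode(name=node.name, support=node.support, children=new_children)

    return SupportTree(rebuild(tree.root), dict(tree.leaf_annotation))


def classify_origins(
    tree: SupportTree,
    cfg: ThresholdConfig | None = None,
    prone_taxa: frozenset[str] | set[str] = DEFAULT_PRONE_TAXA,
    strict_mode: bool = False,
) -> dict[str, CladeDecision]:
    """Classify every query leaf of a (collapsed) support tree.

    Returns one CladeDecision per query leaf; leaves sharing a maximal
    pure-query clade share a label.  Raises if the tree contains no
    reference leaf (nothing to classify against).
    """
    cfg = cfg or ThresholdConfig()
    prone = frozenset(prone_taxa)
    ann = tree.leaf_annotation

    parent: dict[int, TreeNode | None] = {id(tree.root): None}
    ref_superfamilies: dict[int, frozenset[str]] = {}
    n_refs: dict[int, int] = {}
    genome_flag: dict[int, bool] = {}

    def scan(node: TreeNode) -> tuple[frozenset[str], int, bool]:
        if node.is_leaf:
            a = ann[node.name]
            is_ref = a.kind is LeafKind.REFERENCE
            sfams = frozenset({a.superfamily}) if is_ref else frozenset()
            result = (sfams, int(is_ref), a.genome_verified)
        else:
            sfams, refs, flag = frozenset(), 0, False
            for child in node.children:
                parent[id(child)] = node
                cs, cr, cf = scan(child)
                sfams |= cs
                refs += cr
                flag = flag or cf
        if not node.is_leaf:
            result = (sfams, refs, flag)
        ref_superfamilies[id(node)], n_refs[id(node)], genome_flag[id(node)] = result
        return result

    scan(tree.root)
    if n_refs[id(tree.root)] == 0:
        raise ValueError("unclassifiable: no references in tree")

    decisions: dict[str, CladeDecision] = {}
    decided_clades: dict[int, tuple[OriginLabel, frozenset[str], bool]] = {}

    for leaf in tree.root.leaves():
        if ann[leaf.name].kind is not LeafKind.QUERY:
            continue
        # Cq: maximal ancestor containing no reference leaf.
        cq: TreeNode = leaf
        while True:
            up = parent[id(cq)]
            if up is None or n_refs[id(up)] > 0:
                break
            cq = up
        if id(cq) not in decided_clades:
            decided_clades[id(cq)] = _decide(
                cq, parent, ref_superfamilies, genome_flag, cfg, prone, strict_mode
            )
        label, sfams, stem_supported = decided_clades[id(cq)]
        decisions[leaf.name] = CladeDecision(
            leaf=leaf.name,
            label=label,
            enclosing_superfamilies=sfams,
            stem_supported=stem_supported,
        )
    return decisions


def _decide(
    cq: TreeNode,
    parent: Mapping[int, TreeNode | None],
    ref_superfamilies: Mapping[int, frozenset[str]],
    genome_flag: Mapping[int, bool],
    cfg: ThresholdConfig,
    prone: frozenset[str],
    strict_mode: bool,
) -> tuple[OriginLabel, frozenset[str], bool]:
    # M: smallest ancestor of Cq containing a reference leaf.
    m = parent[id(cq)]
    while m is not None and not ref_superfamilies[id(m)]:
        m = parent[id(m)]
    assert m is not None  # guaranteed: the tree has reference leaves
    sfams = ref_superfamilies[id(m)]
    stem_supported = (
        cq.support is not None and cq.support >= cfg.support_threshold
    )

    if genome_flag[id(cq)]:  # (a) clade rescue
        label = OriginLabel(
            "G",
            rationale="clade contains a genome-verified transcript; "
            "entire clade regarded as host in origin",
        )
    elif len(sfams) == 1:
        (sfam,) = sfams
        if sfam in prone:  # (b)
            label = OriginLabel(
                "EC",
                rationale=f"clade nests within {sfam} references only; "
                "classified as eukaryotic contamination",
            )
        elif strict_mode:  # (c), strict
            label = OriginLabel(
                "EC",
                rationale=f"clade nests within {sfam} references only "
                "(strict mode: single foreign superfamily treated as "
                "contamination)",
            )
        else:  # (c), default
            label = OriginLabel(
                "E",
                rationale=f"clade neighbors a single non-prone superfamily "
                f"({sfam}); retained as host in origin pending review",
                review_flag=True,
            )
    else:  # (d) mixed backbone
        label = OriginLabel(
            "E",
            rationale="query clade hangs on a backbone mixing superfamilies "
            f"({', '.join(sorted(sfams))}); host in origin",
            review_flag=not stem_supported,
        )
    return label, sfams, stem_supported
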