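"""Independent oracles used by the test suite.

These deliberately re-derive expected results by the most literal route
available — per-leaf ancestor scans for the clade classifier, exhaustive
enumeration of annotated topologies, and nested grid search for the
logistic MLE — and share no code with the implementation paths they check.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations_with_replacement, product

import numpy as np

from ghsieve.io_formats import LeafAnnotation, LeafKind, SupportTree, TreeNode

# ---------------------------------------------------------------------------
# Brute-force clade classifier
# ---------------------------------------------------------------------------


def _leaves_under(node: TreeNode) -> list[TreeNode]:
    if node.is_leaf:
        return [node]
    out = []
    for child in node.children:
        out.extend(_leaves_under(child))
    return out


def _path_to_leaf(root: TreeNode, leaf: TreeNode) -> list[TreeNode]:
    if root is leaf:
        return [root]
    for child in root.children:
        sub = _path_to_leaf(child, leaf)
        if sub:
            return [root] + sub
    return []


def oracle_classify(
    tree: SupportTree,
    support_threshold: int = 50,
    prone: frozenset[str] = frozenset({"Fungi"}),
    strict_mode: bool = False,
) -> dict[str, tuple[str, bool]]:
    """Literal application of the clade rules: returns
    ``{query leaf: (label, review_flag)}``.

    For each query leaf, walk the root-to-leaf path to find the maximal
    all-query ancestor (Cq), then the smallest reference-containing
    ancestor (M), and apply, in order: genome rescue; single prone
    superfamily -> EC; single non-prone superfamily -> EC in strict mode
    else E with review; mixed superfamilies -> E, review iff Cq's stem
    edge lacks retained support.
    """
    ann = tree.leaf_annotation
    all_leaves = _leaves_under(tree.root)
    if not any(ann[l.name].kind is LeafKind.REFERENCE for l in all_leaves):
        raise ValueError("unclassifiable: no references in tree")

    out: dict[str, tuple[str, bool]] = {}
    for leaf in all_leaves:
        if ann[leaf.name].kind is not LeafKind.QUERY:
            continue
        path = _path_to_leaf(tree.root, leaf)
        # Cq: the highest node on the path whose subtree holds no reference
        cq = leaf
        for node in path:
            members = _leaves_under(node)
            if all(ann[m.name].kind is LeafKind.QUERY for m in members):
                cq = node
                break
        # M: the lowest ancestor of Cq (strictly above it) with a reference
        cq_index = path.index(cq)
        m = None
        for node in reversed(path[:cq_index]):
            members = _leaves_under(node)
            if any(ann[x.name].kind is LeafKind.REFERENCE for x in members):
                m = node
                break
        assert m is not None
        superfamilies = {
            ann[x.name].superfamily
            for x in _leaves_under(m)
            if ann[x.name].kind is LeafKind.REFERENCE
        }
        genome_rescued = any(
            ann[x.name].genome_verified for x in _leaves_under(cq)
        )
        stem_supported = (
            cq.support is not None and cq.support >= support_threshold
        )
        if genome_rescued:
            out[leaf.name] = ("G", False)
        elif len(superfamilies) == 1:
            only = next(iter(superfamilies))
            if only in prone or strict_mode:
                out[leaf.name] = ("EC", False)
            else:
                out[leaf.name] = ("E", True)
        else:
            out[leaf.name] = ("E", not stem_supported)
    return out


# ---------------------------------------------------------------------------
# Exhaustive enumeration of annotated rooted topologies
# ---------------------------------------------------------------------------

#: Leaf states: plain query, genome-verified query, and references of a
#: contamination-prone (Fungi) and a non-prone (Metazoa) superfamily.
LEAF_COLORS = ("Q", "Qg", "F", "M")


def _partitions(n: int, max_part: int | None = None):
    """Non-increasing integer partitions of n with at least 2 parts."""
    max_part = n - 1 if max_part is None else min(max_part, n - 1)

    def rec(remaining: int, cap: int):
        if remaining == 0:
            yield ()
            return
        for part in range(min(cap, remaining), 0, -1):
            for rest in rec(remaining - part, part):
                yield (part,) + rest

    for parts in rec(n, max_part):
        if len(parts) >= 2:
            yield parts


@lru_cache(maxsize=None)
def colored_topologies(n: int) -> tuple:
    """All canonical rooted multifurcating topologies with ``n`` leaves,
    each leaf carrying one of the four colors.  Trees are nested tuples:
    a leaf is ``("leaf", color)``, an internal node ``("node", children)``
    with children sorted for canonicity."""
    if n == 1:
        return tuple(("leaf", c) for c in LEAF_COLORS)
    out = set()
    for parts in _partitions(n):
        sizes: dict[int, int] = {}
        for p in parts:
            sizes[p] = sizes.get(p, 0) + 1
        pools = [
            list(combinations_with_replacement(colored_topologies(s), m))
            for s, m in sorted(sizes.items())
        ]
        for chosen in product(*pools):
            children = tuple(sorted(c for group in chosen for c in group))
            out.add(("node", children))
    return tuple(sorted(out))


def build_support_tree(shape, internal_support: int | None) -> SupportTree:
    """Materialize a tuple topology as a SupportTree with every internal
    edge carrying ``internal_support`` (or none)."""
    annotation: dict[str, LeafAnnotation] = {}
    counter = [0]

    def build(node, is_root: bool) -> TreeNode:
        kind, payload = node
        if kind == "leaf":
            counter[0] += 1
            name = f"x{counter[0]}"
            if payload in ("Q", "Qg"):
                annotation[name] = LeafAnnotation(
                    kind=LeafKind.QUERY, genome_verified=payload == "Qg"
                )
            else:
                annotation[name] = LeafAnnotation(
                    kind=LeafKind.REFERENCE,
                    superfamily="Fungi" if payload == "F" else "Metazoa",
                )
            return TreeNode(name=name)
        children = [build(c, False) for c in payload]
        return TreeNode(
            support=None if is_root else internal_support, children=children
        )

    root = build(shape, True)
    return SupportTree(root, annotation)


def shape_colors(shape) -> list[str]:
    kind, payload = shape
    if kind == "leaf":
        return [payload]
    out = []
    for child in payload:
        out.extend(shape_colors(child))
    return out


# ---------------------------------------------------------------------------
# Grid-search logistic MLE
# ---------------------------------------------------------------------------


def grid_search_logistic(
    x: np.ndarray,
    y: np.ndarray,
    b0_range=(-6.0, 6.0),
    b1_range=(-6.0, 6.0),
    grid: int = 25,
    rounds: int = 10,
) -> tuple[float, float]:
    """Nested grid-search maximizer of the Bernoulli log-likelihood under
    the logistic curve: evaluate a grid, zoom on the best cell, repeat.
    Resolution after the final round is far below 1e-4."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo0, hi0 = b0_range
    lo1, hi1 = b1_range
    best = (0.0, 0.0)
    for _ in range(rounds):
        b0s = np.linspace(lo0, hi0, grid)
        b1s = np.linspace(lo1, hi1, grid)
        eta = (
            b0s[:, None, None]
            + b1s[None, :, None] * x[None, None, :]
        )
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-9, 1 - 1e-9)
        ll = np.sum(
            y[None, None, :] * np.log(p)
            + (1 - y[None, None, :]) * np.log1p(-p),
            axis=2,
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(b0s[i]), float(b1s[j]))
        step0 = (hi0 - lo0) / (grid - 1)
        step1 = (hi1 - lo1) / (grid - 1)
        lo0, hi0 = best[0] - 2 * step0, best[0] + 2 * step0
        lo1, hi1 = best[1] - 2 * step1, best[1] + 2 * step1
    return best
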