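"""Genealogy-versus-phylogeny concordance via tanglegram crossing counts.

The composite NRY tree has the Y-SNP haplogroup hierarchy as its backbone
and, inside each haplogroup, a minimum-spanning subtree of the Y-STR
haplotypes rooted at the modal haplotype; every profiled man is one leaf.
Each leaf links to a genealogy category (village, ancestral family or
extended family).  Concordance is measured as the minimum number of
pairwise crossings of the link lines when the category axis may be
reordered freely and the tree leaves may be reordered only by rotating
internal nodes.

Minimising one-sided crossings is NP-hard in general, so the optimiser
alternates barycenter-style passes over tree nodes and the category axis,
replacing the heuristic with exhaustive search whenever a node has few
children; the permutation null re-runs the same optimiser on shuffled
leaf-to-category assignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import IslandLineagesError, StrProfile
from .network import str_distance

__all__ = [
    "LayoutNode",
    "ConcordanceResult",
    "DegenerateDesignError",
    "build_nry_tree",
    "count_crossings",
    "optimize_layout",
    "permutation_test",
]


class DegenerateDesignError(IslandLineagesError, ValueError):
    """The design cannot support the test (e.g. a single category)."""


@dataclass
class LayoutNode:
    """A rotatable tree node; leaves carry a ``sample_id``."""

    name: str
    children: list["LayoutNode"] = field(default_factory=list)
    sample_id: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.sample_id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.sample_id]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def internal_nodes(self) -> list["LayoutNode"]:
        out = [] if self.is_leaf else [self]
        for child in self.children:
            out.extend(child.internal_nodes())
        return out


# --------------------------------------------------------------------------
# Composite NRY tree
# --------------------------------------------------------------------------

def build_nry_tree(
    snp_backbone: Sequence[str],
    profiles: Sequence[StrProfile],
) -> LayoutNode:
    """Composite NRY tree: haplogroup backbone + within-haplogroup Y-STR
    minimum spanning subtrees rooted at the modal haplotype.

    Ties in MST construction break by (distance, lexicographic haplotype
    pair); haplogroup nodes attach in backbone order; leaves are the
    profiled men (one per nuclear family).
    """
    backbone = list(snp_backbone)
    unknown = sorted({p.haplogroup for p in profiles} - set(backbone))
    if unknown:
        raise HaplogroupBackboneError(f"haplogroups missing from the backbone: {unknown}")
    root = LayoutNode("NRY")
    for hg in backbone:
        members = [p for p in profiles if p.haplogroup == hg]
        if not members:
            continue
        root.children.append(_haplogroup_subtree(hg, members))
    return root


class HaplogroupBackboneError(IslandLineagesError, KeyError):
    """A profile's haplogroup label is absent from the backbone."""


def _haplogroup_subtree(name: str, members: Sequence[StrProfile]) -> LayoutNode:
    by_hap: dict[tuple, list[StrProfile]] = {}
    for p in members:
        by_hap.setdefault((p.vector(), p.dys385), []).append(p)
    keys = sorted(by_hap)
    rep = {k: by_hap[k][0] for k in keys}

    # Deterministic Kruskal MST over distinct haplotypes.
    edges = sorted(
        (str_distance(rep[u], rep[v]), u, v) for u, v in itertools.combinations(keys, 2)
    )
    comp = {k: k for k in keys}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    adjacency: dict[tuple, list[tuple]] = {k: [] for k in keys}
    for _, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            comp[ru] = rv
            adjacency[u].append(v)
            adjacency[v].append(u)

    # Root at the modal haplotype (largest frequency, then smallest vector).
    modal = max(keys, key=lambda k: (len(by_hap[k]), [-x for x in k[0] + k[1]]))

    def subtree(key: tuple, parent: tuple | None) -> LayoutNode:
        node = LayoutNode(f"{name}|{'-'.join(map(str, key[0]))}")
        for p in sorted(by_hap[key], key=lambda p: p.sample_id):
            node.children.append(LayoutNode(p.sample_id, sample_id=p.sample_id))
        for nbr in sorted(adjacency[key]):
            if nbr != parent:
                node.children.append(subtree(nbr, key))
        return node

    top = LayoutNode(name)
    top.children.append(subtree(modal, None))
    return top


# --------------------------------------------------------------------------
# Crossing count
# --------------------------------------------------------------------------

def count_crossings(
    category_order: Sequence,
    leaf_order: Sequence[str],
    links: Sequence[tuple],
) -> int:
    """Number of link pairs (i, j) whose category and leaf orders disagree.

    A link pair crosses iff ``(pos_cat_i - pos_cat_j) * (pos_leaf_i -
    pos_leaf_j) < 0``; links sharing a category never cross.
    """
    cat_pos = {c: i for i, c in enumerate(category_order)}
    leaf_pos = {l: i for i, l in enumerate(leaf_order)}
    missing = [l for _, l in links if l not in leaf_pos]
    if missing:
        raise IslandLineagesError(f"leaves missing from the order: {missing[:5]}")
    missing_cat = [c for c, _ in links if c not in cat_pos]
    if missing_cat:
        raise IslandLineagesError(f"categories missing from the order: {missing_cat[:5]}")
    c = np.asarray([cat_pos[cat] for cat, _ in links])
    l = np.asarray([leaf_pos[leaf] for _, leaf in links])
    dc = c[:, None] - c[None, :]
    dl = l[:, None] - l[None, :]
    return int(np.count_nonzero((dc * dl) < 0) // 2)


# --------------------------------------------------------------------------
# Layout optimisation
# --------------------------------------------------------------------------

def _pair_cost_matrix(groups: Sequence[np.ndarray]) -> np.ndarray:
    """C[a, b] = crossings contributed when group a precedes group b:
    the number of pairs (x in a, y in b) with pos(x) > pos(y) strictly."""
    k = len(groups)
    sorted_groups = [np.sort(g) for g in groups]
    c = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            if a != b and len(groups[a]) and len(groups[b]):
                c[a, b] = np.searchsorted(sorted_groups[b], groups[a], side="left").sum()
    return c


def _best_order(cost: np.ndarray, exhaustive_limit: int) -> list[int]:
    """Order of indices minimising the sum of pairwise precedence costs.

    Exact subset-DP for small k; barycenter seeding plus adjacent-swap and
    single-insertion local search otherwise."""
    k = cost.shape[0]
    if k <= 1:
        return list(range(k))
    if k <= exhaustive_limit:
        full = (1 << k) - 1
        dp = np.full(1 << k, np.inf)
        choice = np.full(1 << k, -1, dtype=int)
        dp[0] = 0.0
        for mask in range(full):
            base = dp[mask]
            if not np.isfinite(base):
                continue
            placed = [i for i in range(k) if mask >> i & 1]
            for j in range(k):
                if mask >> j & 1:
                    continue
                new = base + sum(cost[i, j] for i in placed)
                nm = mask | (1 << j)
                if new < dp[nm]:
                    dp[nm] = new
                    choice[nm] = j
        order = []
        mask = full
        while mask:
            j = int(choice[mask])
            order.append(j)
            mask &= ~(1 << j)
        order.reverse()
        return order

    # Barycenter-style seed (net precedence wins), then single-element
    # insertion local search with O(k) incremental deltas per element.
    net = cost - cost.T
    order = sorted(range(k), key=lambda i: (net[i].sum(), i))
    improved = True
    while improved:
        improved = False
        for idx in range(k):
            item = order[idx]
            rest = order[:idx] + order[idx + 1 :]
            # f(p): item's crossing contribution when inserted at slot p of
            # `rest`; f(p+1) - f(p) = cost[rest[p], item] - cost[item, rest[p]].
            f = float(sum(cost[item, r] for r in rest))
            best_pos, best_f = 0, f
            for p, r in enumerate(rest):
                f += cost[r, item] - cost[item, r]
                if f < best_f - 1e-9:
                    best_f, best_pos = f, p + 1
            if best_pos != idx and best_f < float("inf"):
                current_f = float(
                    sum(cost[r, item] for r in rest[:idx])
                    + sum(cost[item, r] for r in rest[idx:])
                )
                if best_f < current_f - 1e-9:
                    rest.insert(best_pos, item)
                    order = rest
                    improved = True
    return order


def _subtree_positions(node: LayoutNode, pos_of_leaf: Mapping[str, int]) -> np.ndarray:
    return np.asarray([pos_of_leaf[l] for l in node.leaves() if l in pos_of_leaf])


def _reorder_tree(tree: LayoutNode, leaf_to_cat_pos: Mapping[str, int],
                  exhaustive_limit: int) -> None:
    for node in tree.internal_nodes():
        if len(node.children) < 2:
            continue
        groups = [_subtree_positions(ch, leaf_to_cat_pos) for ch in node.children]
        cost = _pair_cost_matrix(groups)
        order = _best_order(cost, exhaustive_limit)
        node.children = [node.children[i] for i in order]


def _leaf_orders(node: LayoutNode) -> Iterable[list[str]]:
    """All leaf orders reachable by rotating internal nodes."""
    if node.is_leaf:
        yield [node.sample_id]
        return
    child_orders = [list(_leaf_orders(ch)) for ch in node.children]
    for perm in itertools.permutations(range(len(node.children))):
        for combo in itertools.product(*(child_orders[i] for i in perm)):
            yield [leaf for part in combo for leaf in part]


def _rotation_count(tree: LayoutNode, cap: int) -> int:
    total = 1
    for node in tree.internal_nodes():
        for k in range(2, len(node.children) + 1):
            total *= k
            if total > cap:
                return total
    return total


def _joint_exhaustive(
    tree: LayoutNode,
    links: Sequence[tuple],
    categories: Sequence,
    exhaustive_limit: int,
) -> tuple[list, list[str], int]:
    """Global minimum over all rotations x category orders (small instances).

    For each reachable leaf order the optimal category order is solved
    exactly by the subset DP, so the returned crossing count is the true
    minimum."""
    leaf_to_cat = {leaf: cat for cat, leaf in links}
    best: tuple[list, list[str], int] | None = None
    for leaf_order in _leaf_orders(tree):
        leaf_pos = {l: i for i, l in enumerate(leaf_order)}
        groups = [
            np.asarray([leaf_pos[leaf] for leaf, cat in leaf_to_cat.items() if cat == c])
            for c in categories
        ]
        order = _best_order(_pair_cost_matrix(groups), exhaustive_limit)
        cat_order = [categories[i] for i in order]
        crossings = count_crossings(cat_order, leaf_order, links)
        if best is None or crossings < best[2]:
            best = (cat_order, leaf_order, crossings)
    return best


def optimize_layout(
    tree: LayoutNode,
    links: Sequence[tuple],
    exhaustive_limit: int = 6,
    max_rounds: int = 20,
) -> tuple[list, list[str], int]:
    """Alternating crossing minimisation of category order and leaf order.

    The tree topology is fixed; only internal-node rotations reorder the
    leaves.  Nodes (or category axes) with at most ``exhaustive_limit``
    elements are solved exactly by subset DP; larger ones use barycenter
    seeding with local search; instances whose whole rotation space is
    small are solved by joint exhaustive search.  Returns
    ``(category_order, leaf_order, crossings)`` for the best layout found,
    never worse than the identity layout.
    """
    import copy

    tree = copy.deepcopy(tree)  # rotations must not mutate the caller's tree
    leaf_to_cat = {leaf: cat for cat, leaf in links}
    categories = sorted(set(leaf_to_cat.values()), key=str)
    if (
        len(categories) <= exhaustive_limit
        and _rotation_count(tree, 720) <= 720
    ):
        return _joint_exhaustive(tree, links, categories, exhaustive_limit)
    cat_order = list(categories)

    best = (list(cat_order), tree.leaves(),
            count_crossings(cat_order, tree.leaves(), links))
    for _ in range(max_rounds):
        cat_pos = {c: i for i, c in enumerate(cat_order)}
        leaf_cat_pos = {leaf: cat_pos[cat] for leaf, cat in leaf_to_cat.items()}
        _reorder_tree(tree, leaf_cat_pos, exhaustive_limit)
        leaf_order = tree.leaves()

        leaf_pos = {l: i for i, l in enumerate(leaf_order)}
        groups = [
            np.asarray([leaf_pos[leaf] for leaf, cat in leaf_to_cat.items() if cat == c])
            for c in categories
        ]
        cost = _pair_cost_matrix(groups)
        order = _best_order(cost, exhaustive_limit)
        cat_order = [categories[i] for i in order]

        crossings = count_crossings(cat_order, leaf_order, links)
        if crossings < best[2]:
            best = (list(cat_order), list(leaf_order), crossings)
        else:
            break
    return best


# --------------------------------------------------------------------------
# Permutation test
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    crossings: int
    category_order: tuple
    leaf_order: tuple[str, ...]
    p: float
    n_perm: int
    seed: int | None


def permutation_test(
    tree: LayoutNode,
    links: Sequence[tuple],
    n_perm: int = 1000,
    seed: int | None = None,
    reoptimize: bool = True,
    strict_less: bool = True,
) -> ConcordanceResult:
    """Monte Carlo leaf-permutation test of genealogy-phylogeny concordance.

    The observed statistic is the optimised crossing count; the null
    shuffles the leaf-to-category assignment.  By default each permutation
    is re-optimised (conservative) and the P-value counts permutations
    with strictly fewer crossings, with the ``(b+1)/(n+1)`` correction;
    ``strict_less=False`` switches to <= for sensitivity analysis, and
    ``reoptimize=False`` freezes the observed orders.
    """
    cats = [cat for cat, _ in links]
    leaves = [leaf for _, leaf in links]
    if len(set(cats)) < 2:
        raise DegenerateDesignError("the permutation test needs >= 2 categories")
    if len(set(leaves)) != len(leaves):
        raise IslandLineagesError("every leaf must appear in exactly one link")

    cat_order, leaf_order, observed = optimize_layout(tree, links)
    rng = np.random.default_rng(seed)
    shuffled = list(cats)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(shuffled)
        perm_links = list(zip(shuffled, leaves))
        if reoptimize:
            _, _, crossings = optimize_layout(tree, perm_links)
        else:
            crossings = count_crossings(cat_order, leaf_order, perm_links)
        if (crossings < observed) if strict_less else (crossings <= observed):
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ConcordanceResult(observed, tuple(cat_order), tuple(leaf_order), p, n_perm, seed)
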