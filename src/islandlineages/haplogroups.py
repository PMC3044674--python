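"""Rule-based mtDNA haplogroup assignment on a diagnostic-variant tree.

A haplogroup tree is a rooted hierarchy in which each named clade carries
the diagnostic variants that arose on the branch leading to it.  A sample
is assigned to the node that maximises ``matches - misses`` over the
variants accumulated along the root path; missing path variants are
tolerated (they may be back-mutations or fall in unsequenced fragments)
and are reported so that reverse mutations stay visible in the output.

The packaged tree fixture (``data/phylotree_subset_synthetic.yaml``)
covers the clades observed in the Yami and Ivatan island populations.  Its
B4a1a4 motif (np 4025 plus the 16360A transversion) follows the published
Yami/Ivatan survey;
the remaining branch motifs are illustrative placeholders in
Phylotree-style notation, not a mirror of the published Phylotree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .core_io import (
    IslandLineagesError,
    MtSample,
    Variant,
    _data_path,
    load_reference,
    parse_variant_token,
)

__all__ = [
    "HaplogroupNode",
    "Assignment",
    "TreeSpecError",
    "HaplogroupLookupError",
    "load_haplogroup_tree",
    "load_packaged_tree",
    "assign_haplogroup",
    "assign_samples",
    "screen_marker",
]


class TreeSpecError(IslandLineagesError, ValueError):
    """The haplogroup tree specification is malformed."""


class HaplogroupLookupError(IslandLineagesError, KeyError):
    """A haplogroup name is absent from the tree."""


@dataclass
class HaplogroupNode:
    """One clade: name, branch-defining variants, children."""

    name: str
    defining_variants: tuple[Variant, ...] = ()
    children: list["HaplogroupNode"] = field(default_factory=list)

    def walk(self) -> Iterable[tuple["HaplogroupNode", tuple[Variant, ...], int]]:
        """Yield (node, path variants from the root, depth) preorder."""
        stack = [(self, self.defining_variants, 0)]
        while stack:
            node, path, depth = stack.pop()
            yield node, path, depth
            for child in reversed(node.children):
                stack.append((child, path + child.defining_variants, depth + 1))

    def find(self, name: str) -> "HaplogroupNode":
        for node, _, _ in self.walk():
            if node.name == name:
                return node
        raise HaplogroupLookupError(name)

    def descendant_names(self, name: str) -> frozenset[str]:
        """``name`` and every clade nested inside it."""
        start = self.find(name)
        return frozenset(node.name for node, _, _ in start.walk())


@dataclass(frozen=True)
class Assignment:
    """Result of scoring one sample against the tree.

    ``missing_variants`` are path-defining variants absent from the sample;
    each is a potential back-mutation (or unsequenced site), mirrored in
    ``back_mutation_flags``.
    """

    sample_id: str
    haplogroup: str
    matched_variants: frozenset[Variant]
    missing_variants: frozenset[Variant]
    score: int

    @property
    def back_mutation_flags(self) -> tuple[str, ...]:
        return tuple(sorted(f"@{v}" for v in self.missing_variants))


def _build_node(
    spec: Mapping,
    reference: str,
    seen_names: set[str],
    inherited: frozenset[Variant],
    is_root: bool,
) -> HaplogroupNode:
    if not isinstance(spec, Mapping) or "name" not in spec:
        raise TreeSpecError(f"node spec must be a mapping with a 'name': {spec!r}")
    name = str(spec["name"])
    if name in seen_names:
        raise TreeSpecError(f"duplicate haplogroup name {name!r}")
    seen_names.add(name)
    tokens = spec.get("variants") or []
    variants = tuple(parse_variant_token(str(t), reference) for t in tokens)
    if is_root and variants:
        raise TreeSpecError("the root node must not carry defining variants")
    repeated = inherited.intersection(variants)
    if repeated:
        raise TreeSpecError(
            f"node {name!r} repeats ancestral defining variants: "
            f"{sorted(str(v) for v in repeated)}"
        )
    node = HaplogroupNode(name, variants)
    child_inherited = inherited | set(variants)
    for child_spec in spec.get("children") or []:
        node.children.append(
            _build_node(child_spec, reference, seen_names, child_inherited, False)
        )
    return node


def load_haplogroup_tree(spec, reference: str | None = None) -> HaplogroupNode:
    """Build and validate a haplogroup tree from a nested mapping or YAML path.

    The spec is ``{name, variants: [tokens], children: [...]}`` nested;
    names must be unique, the root carries no variants, and no node may
    repeat an ancestor's defining variant.
    """
    if reference is None:
        reference = load_reference()
    if not isinstance(spec, Mapping):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    return _build_node(spec, reference, set(), frozenset(), True)


def load_packaged_tree() -> HaplogroupNode:
    """The packaged study-clade subtree fixture."""
    return load_haplogroup_tree(_data_path("phylotree_subset_synthetic.yaml"))


def assign_haplogroup(
    variants: Iterable[Variant],
    tree: HaplogroupNode,
    sample_id: str = "",
) -> Assignment:
    """Deepest node maximising ``|matched| - |missing|`` along the root path.

    Ties are broken by greater depth, then lexicographically smaller name.
    An empty variant set legally lands on the root.
    """
    sample = frozenset(variants)
    best: tuple[int, int, str] | None = None
    best_result: tuple[str, frozenset, frozenset, int] | None = None
    for node, path, depth in tree.walk():
        path_set = frozenset(path)
        matched = path_set & sample
        missing = path_set - sample
        score = len(matched) - len(missing)
        key = (-score, -depth, node.name)
        if best is None or key < best:
            best = key
            best_result = (node.name, matched, missing, score)
    name, matched, missing, score = best_result
    return Assignment(sample_id, name, matched, missing, score)


def assign_samples(samples: Iterable[MtSample], tree: HaplogroupNode) -> dict[str, Assignment]:
    return {s.sample_id: assign_haplogroup(s.variants, tree, s.sample_id) for s in samples}


def screen_marker(
    samples: Sequence[MtSample],
    assignments: Mapping[str, Assignment],
    marker: Variant,
    within: str,
    tree: HaplogroupNode,
) -> dict[str, tuple[int, int]]:
    """Per-population (carriers, screened) counts of ``marker`` among samples
    assigned to haplogroup ``within`` or any clade nested inside it."""
    clade_names = tree.descendant_names(within)
    table: dict[str, tuple[int, int]] = {}
    for s in samples:
        assignment = assignments.get(s.sample_id)
        if assignment is None or assignment.haplogroup not in clade_names:
            continue
        carriers, screened = table.get(s.population, (0, 0))
        table[s.population] = (carriers + (1 if marker in s.variants else 0), screened + 1)
    return table
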