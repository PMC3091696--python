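"""Ohnolog family trees from three nested whole-genome duplications.

Each ancestral gene passes through the old (level 3), intermediate (level 2)
and recent (level 1) WGD in that order.  At each WGD every surviving lineage
duplicates; the pair then resolves before the next event: with probability
``p_level`` both copies are kept, otherwise exactly one survives.  A family is
never lost outright, so the configured probability equals the expected
fraction of duplication events at that level still present in two copies —
the statistic reported genome-wide as 51% / 24% / 8% for the recent,
intermediate and old WGD.

A family is a binary tree whose internal nodes are the duplication events at
which *both* copies survived (levels strictly decrease from root to leaf) and
whose leaves are present-day genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np

from .config import SimConfig

#: WGD levels ordered oldest-first as applied during simulation.
_LEVELS_OLD_TO_RECENT = (3, 2, 1)


@dataclass(frozen=True)
class GeneLeaf:
    """A present-day gene at the tip of an ohnolog family tree."""

    gene_id: str

    def leaves(self) -> list[str]:
        return [self.gene_id]


@dataclass(frozen=True)
class DupNode:
    """A WGD duplication event whose two descendant lineages both survive.

    ``level`` is 1 for the recent, 2 for the intermediate and 3 for the old
    WGD; levels strictly decrease from the root towards the leaves.
    """

    level: int
    left: "TreeNode"
    right: "TreeNode"

    def leaves(self) -> list[str]:
        return self.left.leaves() + self.right.leaves()


TreeNode = Union[GeneLeaf, DupNode]


@dataclass
class OhnologFamily:
    """All present-day descendants of one ancestral gene."""

    family_id: str
    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def __len__(self) -> int:
        return len(self.leaves())


@dataclass
class RetentionTally:
    """Duplication-event bookkeeping: per WGD level (1..3), the number of
    duplication events and how many resolved with both copies kept."""

    events: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    both_kept: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})

    def fraction(self, level: int) -> float:
        if self.events[level] == 0:
            return float("nan")
        return self.both_kept[level] / self.events[level]


def simulate_genome(
    config: SimConfig,
) -> tuple[list[OhnologFamily], list[str], RetentionTally]:
    """Simulate ohnolog families through three successive WGDs.

    Returns the families, the flat list of present-day gene ids, and the
    per-level duplication/retention tally used for calibration checks.
    """
    rng = np.random.default_rng(config.seed)
    p = {1: config.retention_probs[0], 2: config.retention_probs[1],
         3: config.retention_probs[2]}
    tally = RetentionTally()
    families: list[OhnologFamily] = []
    genes: list[str] = []
    counter = 0

    for fam_idx in range(config.n_ancestral):
        family_id = f"FAM{fam_idx:05d}"
        # Lineages are grown as a tree of None-placeholder leaves, then the
        # placeholders are renamed to stable gene ids left-to-right.
        root: TreeNode = GeneLeaf("")
        for level in _LEVELS_OLD_TO_RECENT:
            root = _duplicate_lineages(root, level, p[level], rng, tally)
        root, counter = _assign_ids(root, counter)
        fam = OhnologFamily(family_id, root)
        families.append(fam)
        genes.extend(fam.leaves())
    return families, genes, tally


def _duplicate_lineages(
    node: TreeNode,
    level: int,
    p_keep_both: float,
    rng: np.random.Generator,
    tally: RetentionTally,
) -> TreeNode:
    """Apply one WGD to every current lineage (leaf) of the tree."""
    if isinstance(node, DupNode):
        return DupNode(
            node.level,
            _duplicate_lineages(node.left, level, p_keep_both, rng, tally),
            _duplicate_lineages(node.right, level, p_keep_both, rng, tally),
        )
    tally.events[level] += 1
    if rng.random() < p_keep_both:
        tally.both_kept[level] += 1
        return DupNode(level, GeneLeaf(""), GeneLeaf(""))
    # exactly one copy survives; which one is immaterial for an unlabeled
    # placeholder lineage, so the lineage simply continues
    return node


def _assign_ids(node: TreeNode, counter: int) -> tuple[TreeNode, int]:
    if isinstance(node, GeneLeaf):
        return GeneLeaf(f"G{counter:06d}"), counter + 1
    left, counter = _assign_ids(node.left, counter)
    right, counter = _assign_ids(node.right, counter)
    return DupNode(node.level, left, right), counter


# ---------------------------------------------------------------------------
# Tree traversal helpers shared with the wgd module


def iter_nodes(node: TreeNode) -> Iterator[TreeNode]:
    yield node
    if isinstance(node, DupNode):
        yield from iter_nodes(node.left)
        yield from iter_nodes(node.right)


def leaf_paths(family: OhnologFamily) -> dict[str, list[tuple[int, str]]]:
    """Per leaf gene, the root-to-leaf path as (WGD level, side) steps.

    ``side`` is "L" or "R".  Singleton families yield an empty path.
    """
    paths: dict[str, list[tuple[int, str]]] = {}

    def walk(node: TreeNode, path: list[tuple[int, str]]) -> None:
        if isinstance(node, GeneLeaf):
            paths[node.gene_id] = list(path)
            return
        walk(node.left, path + [(node.level, "L")])
        walk(node.right, path + [(node.level, "R")])

    walk(family.root, [])
    return paths


def family_from_paths(
    family_id: str, paths: dict[str, list[tuple[int, str]]]
) -> OhnologFamily:
    """Rebuild a family tree from per-leaf (level, side) paths."""
    if len(paths) == 1 and next(iter(paths.values())) == []:
        return OhnologFamily(family_id, GeneLeaf(next(iter(paths))))

    def build(sub: dict[str, list[tuple[int, str]]]) -> TreeNode:
        if len(sub) == 1:
            gene, path = next(iter(sub.items()))
            if path:
                raise ValueError(f"dangling path {path} for single leaf {gene}")
            return GeneLeaf(gene)
        level = max(step[0] for path in sub.values() for step in path[:1])
        left = {g: p[1:] for g, p in sub.items() if p and p[0] == (level, "L")}
        right = {g: p[1:] for g, p in sub.items() if p and p[0] == (level, "R")}
        if not left or not right or len(left) + len(right) != len(sub):
            raise ValueError(f"inconsistent paths in family {family_id}")
        return DupNode(level, build(left), build(right))

    return OhnologFamily(family_id, build(paths))


def encode_path(path: list[tuple[int, str]]) -> str:
    return "/".join(f"{level}{side}" for level, side in path)


def decode_path(text: str) -> list[tuple[int, str]]:
    if not text:
        return []
    return [(int(step[:-1]), step[-1]) for step in text.split("/")]
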