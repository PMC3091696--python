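"""Ohnolog retention and cluster-concordance classification across three WGDs.

For a differentially expressed gene, its ohnologs at a WGD level are the
present-day descendants of the sister lineage of the duplication node at that
level on the gene's root-to-leaf path (at most 1 for the recent WGD, 2 for
the intermediate, 4 for the old).  Retention of a gene set is the fraction of
genes with at least one such relative.  Classifying each relative as being in
the same co-expression cluster, a different cluster, or no cluster yields the
Table-style concordance categories; the "different cluster" percentage is an
upper bound on the subfunctionalization rate, since adjacent-archetype
splits and annotation noise also land there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import ClusterSet
from .simdata.genome import DupNode, GeneLeaf, OhnologFamily, TreeNode, leaf_paths

WGD_LEVELS = (1, 2, 3)

#: Mutually exclusive concordance categories per WGD level, in report order.
CATEGORIES = {
    1: ("same cluster", "different cluster", "not in cluster"),
    2: (
        "both in same cluster",
        "one in same cluster",
        "different cluster",
        "none in cluster",
    ),
    3: ("one or more same cluster", "different cluster", "none in cluster"),
}

_MAX_RELATIVES = {1: 1, 2: 2, 3: 4}


class FamilyIndex:
    """Gene -> (family, root-to-leaf path) lookup over ohnolog families."""

    def __init__(self, families: list[OhnologFamily]):
        self.families = {f.family_id: f for f in families}
        self._paths: dict[str, tuple[str, list[tuple[int, str]]]] = {}
        for fam in families:
            for gene, path in leaf_paths(fam).items():
                self._paths[gene] = (fam.family_id, path)

    def __contains__(self, gene: str) -> bool:
        return gene in self._paths

    def relatives(self, gene: str, level: int) -> set[str]:
        """Present-day ohnologs of ``gene`` created at the given WGD level."""
        if level not in WGD_LEVELS:
            raise ValueError(f"level must be in {WGD_LEVELS}")
        if gene not in self._paths:
            raise KeyError(f"unknown gene {gene!r}")
        family_id, path = self._paths[gene]
        node: TreeNode = self.families[family_id].root
        for lev, side in path:
            assert isinstance(node, DupNode)
            if lev == level:
                sister = node.right if side == "L" else node.left
                out = set(sister.leaves())
                assert len(out) <= _MAX_RELATIVES[level]
                return out
            node = node.left if side == "L" else node.right
        return set()


def wgd_relatives(
    gene: str, families: list[OhnologFamily] | FamilyIndex, level: int
) -> set[str]:
    """Ohnologs of one gene at one WGD level (empty if that copy was lost)."""
    index = families if isinstance(families, FamilyIndex) else FamilyIndex(families)
    return index.relatives(gene, level)


def retention_rate(
    genes: list[str], families: list[OhnologFamily] | FamilyIndex, level: int
) -> float:
    """Fraction of the gene set with >= 1 retained ohnolog at the level."""
    index = families if isinstance(families, FamilyIndex) else FamilyIndex(families)
    if not genes:
        return float("nan")
    return float(np.mean([len(index.relatives(g, level)) > 0 for g in genes]))


def retention_table(
    gene_sets: dict[str, list[str]], families: list[OhnologFamily] | FamilyIndex
) -> pd.DataFrame:
    """Per gene set, retention fraction at each WGD level plus the set size."""
    index = families if isinstance(families, FamilyIndex) else FamilyIndex(families)
    rows = {}
    for name, genes in gene_sets.items():
        rows[name] = {
            f"WGD{lev}": retention_rate(genes, index, lev) for lev in WGD_LEVELS
        }
        rows[name]["genes"] = len(genes)
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_ohnologs(
    de_genes: list[str],
    cluster_set: ClusterSet,
    families: list[OhnologFamily] | FamilyIndex,
    level: int,
) -> pd.Series:
    """Concordance category for each DE gene with >= 1 ohnolog at the level.

    Relative states are "same" (shares the gene's cluster), "different"
    (in another cluster) or "unclustered"; mixed states resolve by the
    precedence all-same > any-same > any-different > none, the reading most
    charitable to concordance.  Genes without an ohnolog at the level are
    excluded, not categorized.
    """
    index = families if isinstance(families, FamilyIndex) else FamilyIndex(families)
    clustered = cluster_set.assignments
    out: dict[str, str] = {}
    for gene in de_genes:
        if gene not in clustered.index:
            raise KeyError(f"DE gene {gene!r} absent from the cluster set")
        rels = index.relatives(gene, level)
        if not rels:
            continue
        own = clustered[gene]
        states = [
            "same"
            if (r in clustered.index and clustered[r] == own)
            else ("different" if r in clustered.index else "unclustered")
            for r in sorted(rels)
        ]
        out[gene] = _categorize(states, level)
    return pd.Series(out, name=f"wgd{level}_category", dtype=object)


def _categorize(states: list[str], level: int) -> str:
    any_same = "same" in states
    all_same = all(s == "same" for s in states)
    any_diff = "different" in states
    if level == 1:
        (state,) = states
        return {
            "same": "same cluster",
            "different": "different cluster",
            "unclustered": "not in cluster",
        }[state]
    if level == 2:
        if all_same:
            return "both in same cluster"
        if any_same:
            return "one in same cluster"
        if any_diff:
            return "different cluster"
        return "none in cluster"
    if any_same:
        return "one or more same cluster"
    if any_diff:
        return "different cluster"
    return "none in cluster"


def summarize_classification(
    classification: pd.Series | dict[str, int], level: int
) -> pd.DataFrame:
    """Counts and one-decimal percentages per category at one WGD level.

    Accepts either a per-gene category Series (from ``classify_ohnologs``)
    or already-tallied {category: count} totals; the denominator is the
    number of genes with an ohnolog at the level.
    """
    if isinstance(classification, pd.Series):
        if classification.empty:
            raise ValueError("empty classification")
        counts = classification.value_counts().to_dict()
    else:
        if not classification:
            raise ValueError("empty classification")
        counts = dict(classification)
    unknown = set(counts) - set(CATEGORIES[level])
    if unknown:
        raise ValueError(f"unknown categories for WGD{level}: {sorted(unknown)}")
    total = sum(counts.values())
    rows = []
    for cat in CATEGORIES[level]:
        n = int(counts.get(cat, 0))
        rows.append(
            {"category": cat, "count": n, "percent": round(100.0 * n / total, 1)}
        )
    out = pd.DataFrame(rows).set_index("category")
    out.attrs["denominator"] = total
    out.attrs["level"] = level
    return out


def subfunctionalization_bound(
    summary_or_classification: pd.DataFrame | pd.Series, level: int
) -> float:
    """The "different cluster" percentage at a level: an upper bound on the
    subfunctionalization rate among retained ohnolog pairs of that age."""
    if isinstance(summary_or_classification, pd.Series):
        summary = summarize_classification(summary_or_classification, level)
    else:
        summary = summary_or_classification
    return float(summary.loc["different cluster", "percent"])


@dataclass
class WGDReport:
    """Retention table plus per-level classification summaries and bounds."""

    retention: pd.DataFrame
    summaries: dict[int, pd.DataFrame]
    bounds: dict[int, float]

    def to_json_dict(self) -> dict:
        return {
            "retention": {
                name: {k: (float(v) if isinstance(v, float) else int(v)) for k, v in row.items()}
                for name, row in self.retention.to_dict(orient="index").items()
            },
            "classification": {
                f"WGD{lev}": {
                    "denominator": int(s.attrs["denominator"]),
                    "counts": {c: int(n) for c, n in s["count"].items()},
                    "percent": {c: float(p) for c, p in s["percent"].items()},
                }
                for lev, s in self.summaries.items()
            },
            "subfunctionalization_upper_bound_percent": {
                f"WGD{lev}": float(b) for lev, b in self.bounds.items()
            },
        }


def analyze_wgd(
    de_genes: list[str],
    cluster_set: ClusterSet,
    families: list[OhnologFamily],
    all_genes: list[str] | None = None,
    set_name: str = "experiment",
) -> WGDReport:
    """Full ohnolog analysis of one experiment's DE gene set."""
    index = FamilyIndex(families)
    gene_sets = {set_name: list(de_genes)}
    if all_genes is not None:
        gene_sets["genome"] = list(all_genes)
    retention = retention_table(gene_sets, index)
    summaries: dict[int, pd.DataFrame] = {}
    bounds: dict[int, float] = {}
    for lev in WGD_LEVELS:
        cls = classify_ohnologs(de_genes, cluster_set, index, lev)
        if cls.empty:
            continue
        summaries[lev] = summarize_classification(cls, lev)
        bounds[lev] = subfunctionalization_bound(summaries[lev], lev)
    return WGDReport(retention=retention, summaries=summaries, bounds=bounds)
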