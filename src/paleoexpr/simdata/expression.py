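"""Ground-truth time-course expression profiles for simulated ohnolog families.

Differential expression is assigned at the family level: a DE family carries a
named archetype (e.g. "early_peak"), and the archetype propagates down the
family tree.  At each duplication node of WGD level k the derived lineage
diverges to a *different* archetype with probability
``frac_subfunctionalized[k-1]`` — the generative counterpart of
subfunctionalization read out downstream as ohnologs falling into different
co-expression clusters.  A configurable fraction of retained ohnologs
pseudogenizes: flat profile at a reduced baseline, emulating decaying gene
copies that never enter any cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TIMEPOINTS, SimConfig
from .genome import DupNode, GeneLeaf, OhnologFamily, TreeNode

FLAT = "flat"
_EXP_SALT = {"autogamy": 11, "reciliation": 12, "exocytosis": 13}


@dataclass
class TruthTable:
    """Ground truth of a simulated expression experiment.

    genes:
        DataFrame indexed by gene id with columns ``family_id``, ``archetype``
        ("flat" for non-responsive genes), ``pseudogene`` (bool) and
        ``baseline`` (basal log2 level).
    pairs:
        One row per retained duplication event: ``level`` (1 recent .. 3 old),
        representative genes of the two descendant lineages, and
        ``subfunctionalized`` — True when the lineages were assigned distinct
        archetypes (and neither representative pseudogenized).
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    experiment: str = "autogamy"

    def de_genes(self) -> list[str]:
        mask = (self.genes["archetype"] != FLAT) & ~self.genes["pseudogene"]
        return list(self.genes.index[mask])


def simulate_expression(
    families: list[OhnologFamily],
    config: SimConfig,
    experiment: str = "autogamy",
) -> tuple[TruthTable, pd.DataFrame]:
    """Assign archetypes and return (truth, gene x time point log2 means)."""
    if experiment not in TIMEPOINTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; expected one of {sorted(TIMEPOINTS)}"
        )
    archetypes = dict(config.archetypes[experiment])
    names = sorted(archetypes)
    timepoints = TIMEPOINTS[experiment]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _EXP_SALT[experiment]])
    )

    gene_rows: list[dict] = []
    pair_rows: list[dict] = []

    for fam in families:
        is_de = rng.random() < config.frac_de
        fam_arch = names[rng.integers(len(names))] if is_de else FLAT
        assignments: dict[str, str] = {}

        def walk(node: TreeNode, arch: str) -> None:
            if isinstance(node, GeneLeaf):
                assignments[node.gene_id] = arch
                return
            right_arch = arch
            diverged = False
            if arch != FLAT:
                frac = config.frac_subfunctionalized[node.level - 1]
                if rng.random() < frac:
                    others = [n for n in names if n != arch]
                    right_arch = others[rng.integers(len(others))]
                    diverged = True
            walk(node.left, arch)
            walk(node.right, right_arch)
            pair_rows.append(
                {
                    "family_id": fam.family_id,
                    "level": node.level,
                    "gene_a": _first_leaf(node.left),
                    "gene_b": _first_leaf(node.right),
                    "subfunctionalized": diverged,
                }
            )

        walk(fam.root, fam_arch)
        n_leaves = len(assignments)
        for gene_id, arch in assignments.items():
            pseudo = n_leaves > 1 and rng.random() < config.frac_pseudogene
            baseline = rng.normal(config.baseline_mean, config.baseline_sd)
            if pseudo:
                arch = FLAT
                baseline -= config.pseudogene_drop
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "family_id": fam.family_id,
                    "archetype": arch,
                    "pseudogene": pseudo,
                    "baseline": baseline,
                }
            )

    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    pairs = pd.DataFrame(
        pair_rows,
        columns=["family_id", "level", "gene_a", "gene_b", "subfunctionalized"],
    )
    if len(pairs):
        # a drawn divergence is only observable if neither lineage decays
        pseudo = genes["pseudogene"]
        observable = ~pseudo.reindex(pairs["gene_a"]).to_numpy() & ~pseudo.reindex(
            pairs["gene_b"]
        ).to_numpy()
        pairs["subfunctionalized"] &= observable

    offsets = np.zeros((len(genes), len(timepoints)))
    for i, arch in enumerate(genes["archetype"]):
        if arch != FLAT:
            offsets[i] = np.asarray(archetypes[arch], dtype=float)
    means = pd.DataFrame(
        genes["baseline"].to_numpy()[:, None] + offsets,
        index=genes.index,
        columns=timepoints,
    )
    return TruthTable(genes=genes, pairs=pairs, experiment=experiment), means


def _first_leaf(node: TreeNode) -> str:
    while isinstance(node, DupNode):
        node = node.left
    return node.gene_id
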