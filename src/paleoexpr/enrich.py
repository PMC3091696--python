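"""Random-gene-set permutation enrichment and cross-experiment overlap.

To test a gene subset (e.g. known ciliary proteins), differential expression
is evaluated on an expression set built from the subset alone (retaining
statistical power after multiple-testing correction) and the observed DE
count is compared with the counts in random same-size gene sets: the
enrichment ratio is observed / mean(null counts) and the empirical p-value is
add-one corrected, so 1000 permutations can report at best p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import GeneMatrix
from .diffexpr import DEConfig, estimate_ebayes, fit_timecourse, moderated_tests


@dataclass
class EnrichmentConfig:
    """Permutation-enrichment settings.

    ``mode`` selects how a set's DE count is scored: "refit" reruns the full
    moderated-test chain on the set-only matrix; "label" counts members of a
    precomputed DE label set.  ``adjusted`` applies the within-set BH
    correction to the 0.05 threshold (the conservative reading of a bare
    "p-value < 0.05"); raw p-values are selectable.
    """

    n_permutations: int = 1000
    threshold: float = 0.05
    adjusted: bool = True
    mode: str = "refit"
    seed: int = 0
    de_config: DEConfig = field(default_factory=DEConfig)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.mode not in ("refit", "label"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class EnrichmentResult:
    """Observed subset DE count against its permutation null."""

    observed: int
    null_counts: np.ndarray
    subset_size: int
    n_permutations: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def ratio(self) -> float:
        mean = self.null_mean
        return float("inf") if mean == 0 and self.observed > 0 else (
            1.0 if mean == 0 else self.observed / mean
        )

    @property
    def p_value(self) -> float:
        exceed = int(np.sum(self.null_counts >= self.observed))
        return (1 + exceed) / (1 + self.n_permutations)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "ratio": self.ratio,
            "p_value": self.p_value,
            "subset_size": self.subset_size,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def subset_de_count(
    subset: list[str],
    gene_matrix: GeneMatrix | None,
    config: EnrichmentConfig,
    de_labels: set[str] | None = None,
) -> int:
    """Number of differentially expressed genes within a subset.

    refit mode: fit, moderate and BH-adjust on the subset-only matrix and
    count genes under the threshold.  label mode: count subset members of a
    precomputed DE label set.
    """
    if len(subset) == 0:
        raise ValueError("empty subset")
    if config.mode == "label":
        if de_labels is None:
            raise ValueError("label mode requires a DE label set")
        return len(set(subset) & de_labels)
    if gene_matrix is None:
        raise ValueError("refit mode requires a gene matrix")
    missing = set(subset) - set(gene_matrix.values.index)
    if missing:
        raise ValueError(f"{len(missing)} subset genes absent from the matrix")
    sub_matrix = GeneMatrix(
        values=gene_matrix.values.loc[list(subset)],
        sample_sheet=gene_matrix.sample_sheet,
    )
    fit = fit_timecourse(sub_matrix, config.de_config)
    result = moderated_tests(fit, estimate_ebayes(fit), config.de_config)
    pvals = result.fdr if config.adjusted else result.gene_p
    return int((pvals < config.threshold).sum())


def permutation_enrichment(
    subset: list[str],
    universe: list[str],
    gene_matrix: GeneMatrix | None,
    config: EnrichmentConfig,
    de_labels: set[str] | None = None,
) -> EnrichmentResult:
    """Score a subset against random same-size draws from the universe."""
    subset = list(dict.fromkeys(subset))
    universe = list(dict.fromkeys(universe))
    if not set(subset) <= set(universe):
        raise ValueError("subset must be contained in the universe")
    if len(subset) > len(universe):
        raise ValueError("subset larger than universe")
    observed = subset_de_count(subset, gene_matrix, config, de_labels)
    rng = np.random.default_rng(config.seed)
    universe_arr = np.asarray(universe, dtype=object)
    null = np.empty(config.n_permutations, dtype=int)
    for i in range(config.n_permutations):
        draw = rng.choice(universe_arr, size=len(subset), replace=False)
        null[i] = subset_de_count(list(draw), gene_matrix, config, de_labels)
    return EnrichmentResult(
        observed=observed,
        null_counts=null,
        subset_size=len(subset),
        n_permutations=config.n_permutations,
        seed=config.seed,
    )


def overlap_sets(de_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Venn-partition cardinalities for >= 2 DE gene sets.

    One row per non-empty combination of experiments: the count of genes in
    all named sets and in none of the others (the exclusive Venn region),
    plus the plain intersection count for the same combination.
    """
    if len(de_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(de_sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(de_sets[n] for n in combo))
            others = set().union(*(de_sets[n] for n in names if n not in combo))
            rows.append(
                {
                    "sets": "&".join(combo),
                    "degree": r,
                    "exclusive": len(inter - others),
                    "intersection": len(inter),
                }
            )
    return pd.DataFrame(rows)
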