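"""Core in-memory containers shared across pipeline stages.

Matrices are pandas DataFrames (rows = probes or genes, columns = samples, log2
scale unless declared otherwise); the sample sheet is a DataFrame indexed by
sample id carrying experiment, time point, replicate group, collection time and
nuclear-morphology fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPERIMENTS = ("autogamy", "reciliation", "exocytosis")

#: Nuclear morphology classes scored on autogamy samples.
MORPHOLOGY_COLS = (
    "vegetative",
    "meiosis",
    "skein",
    "fragmented",
    "anlagen",
    "karyonide",
)

SAMPLE_SHEET_COLS = (
    "experiment",
    "timepoint",
    "replicate_group",
    "hours",
) + MORPHOLOGY_COLS

#: Tolerance on morphology fractions summing to one.
MORPHOLOGY_SUM_TOL = 0.05


@dataclass
class ProbeMatrix:
    """Probe x sample intensity matrix with the probe -> gene map.

    ``scale`` declares whether ``values`` holds log2 or linear intensities.
    """

    values: pd.DataFrame
    probe_genes: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        missing = self.values.index.difference(self.probe_genes.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} probes missing from the probe->gene map "
                f"(e.g. {missing[0]!r})"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneMatrix:
    """Gene x sample log2 signal matrix linked to its sample sheet."""

    values: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("gene matrix contains non-finite values")
        missing = self.values.columns.difference(self.sample_sheet.index)
        if len(missing):
            raise ValueError(f"samples absent from sample sheet: {list(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def timepoints(self) -> pd.Series:
        return self.sample_sheet.loc[self.values.columns, "timepoint"]


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    """Raise on malformed sample sheets (missing columns, bad fractions)."""
    missing = [c for c in ("experiment", "timepoint", "replicate_group") if c not in sheet]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad = set(sheet["experiment"]) - set(EXPERIMENTS)
    if bad:
        raise ValueError(f"unknown experiments in sample sheet: {sorted(bad)}")
    morph = [c for c in MORPHOLOGY_COLS if c in sheet]
    if morph:
        frac = sheet[morph].fillna(0.0)
        if (frac.to_numpy() < 0).any() or (frac.to_numpy() > 1).any():
            raise ValueError("morphology fractions must lie in [0, 1]")
        total = frac.sum(axis=1)
        over = total > 1.0 + MORPHOLOGY_SUM_TOL
        if over.any():
            raise ValueError(
                "morphology fractions sum above 1 for samples: "
                f"{list(sheet.index[over])}"
            )
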