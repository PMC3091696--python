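"""Normalization, gene-level summarization, QC and morphology-based staging.

The arrays that enter one analysis are quantile-normalized together; gene
signals are the median of the gene's 6 probe signals; sample QC requires an
approximately symmetric log2 density centered between 9 and 11 and reports
Pearson correlations between biological replicates (0.84-0.99 on well-behaved
data).  Autogamy samples are assigned to developmental stages (VEG, MEI, FRAG,
DEV1, DEV2, DEV3) from their scored nuclear-morphology fractions; DEV2 vs
DEV3 cannot be separated by morphology and is resolved only by collection
time (~10 h apart).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import GeneMatrix, MORPHOLOGY_SUM_TOL, ProbeMatrix

AUTOGAMY_STAGES = ("VEG", "MEI", "FRAG", "DEV1", "DEV2", "DEV3")

#: Hours separating a DEV3 collection from the DEV2 collections.
DEV3_MIN_HOURS_AFTER_DEV2 = 10.0


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean distribution of order
    statistics; ties within a sample receive the mean of the reference values
    at their tied ranks.  Row/column labels are preserved."""
    if values.shape[1] < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return values.copy()
    x = values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = np.empty(len(reference), dtype=float)
        ranks[order[:, j]] = reference
        # average reference values over runs of tied input values
        col = x[:, j]
        sorted_vals = col[order[:, j]]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        for grp in np.split(order[:, j], boundaries):
            if len(grp) > 1:
                ranks[grp] = ranks[grp].mean()
        out[:, j] = ranks
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def summarize_genes(matrix: ProbeMatrix, sample_sheet: pd.DataFrame) -> GeneMatrix:
    """Gene signal = median of the gene's probe signals, per sample.

    Genes with some probes missing use the median of the available ones;
    genes with zero probes are excluded (warned).
    """
    if matrix.scale != "log2":
        raise ValueError("summarize_genes expects log2 probe signals")
    genes = matrix.probe_genes.loc[matrix.values.index]
    medians = matrix.values.groupby(genes).median()
    mapped_genes = set(matrix.probe_genes)
    dropped = mapped_genes - set(medians.index)
    if dropped:
        warnings.warn(f"{len(dropped)} genes had no probes and were excluded")
    medians.index.name = "gene_id"
    return GeneMatrix(values=medians, sample_sheet=sample_sheet)


@dataclass
class QCReport:
    """Per-sample density QC and within-replicate-group correlations."""

    samples: pd.DataFrame  # index sample, cols: center, symmetry, passed
    replicate_r: pd.DataFrame  # cols: group, sample_a, sample_b, pearson_r

    def all_passed(self) -> bool:
        return bool(self.samples["passed"].all())

    def min_replicate_r(self) -> float:
        return float(self.replicate_r["pearson_r"].min()) if len(self.replicate_r) else float("nan")


def _density_center(x: np.ndarray, binwidth: float = 0.1) -> float:
    """Histogram mode of a log2 signal vector at 0.1-log2-unit bins."""
    lo, hi = float(x.min()), float(x.max())
    nbins = max(1, int(np.ceil((hi - lo) / binwidth)))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, lo + nbins * binwidth))
    k = int(np.argmax(counts))
    return float((edges[k] + edges[k + 1]) / 2)


def qc_samples(
    gene_matrix: GeneMatrix,
    center_range: tuple[float, float] = (9.0, 11.0),
    symmetry_tol: float = 0.5,
) -> QCReport:
    """Density-profile QC plus replicate Pearson correlations.

    A sample passes when its density mode lies inside ``center_range`` and
    |mean - median| <= ``symmetry_tol`` (an asymmetry proxy).  Correlations
    are computed on gene signals for every pair within a replicate group.
    """
    rows = []
    for sample in gene_matrix.samples:
        x = gene_matrix.values[sample].to_numpy()
        center = _density_center(x)
        symmetry = abs(float(np.mean(x)) - float(np.median(x)))
        rows.append(
            {
                "sample_id": sample,
                "center": center,
                "symmetry": symmetry,
                "passed": center_range[0] <= center <= center_range[1]
                and symmetry <= symmetry_tol,
            }
        )
    samples = pd.DataFrame(rows).set_index("sample_id")

    pairs = []
    groups = gene_matrix.sample_sheet.loc[gene_matrix.samples, "replicate_group"]
    for group, members in groups.groupby(groups):
        for a, b in combinations(members.index, 2):
            r = float(
                np.corrcoef(
                    gene_matrix.values[a].to_numpy(), gene_matrix.values[b].to_numpy()
                )[0, 1]
            )
            pairs.append({"group": group, "sample_a": a, "sample_b": b, "pearson_r": r})
    replicate_r = pd.DataFrame(
        pairs, columns=["group", "sample_a", "sample_b", "pearson_r"]
    )
    return QCReport(samples=samples, replicate_r=replicate_r)


def stage_sample(
    morphology: Mapping[str, float],
    hours: float | None = None,
    dev2_hours: float | None = None,
) -> str:
    """Assign one autogamy sample to a developmental stage.

    The cascade follows the most developmentally informative marker first:
    anlagen (new developing macronuclei) separate DEV2 (>= 70%) from DEV1
    (10-70%); old-MAC fragmentation (>= 30%) marks FRAG; >= 20% meiotic cells
    without fragmentation marks MEI; the near-absence of any of these marks
    VEG.  DEV3 is indistinguishable from DEV2 by morphology and is assigned
    only when collection-time metadata places the sample >= ~10 h after the
    DEV2 samples.  Samples falling between the printed stage ranges get the
    nearest stage so staging is total on the morphology simplex.
    """
    m = {k: float(morphology.get(k, 0.0) or 0.0) for k in
         ("vegetative", "meiosis", "skein", "fragmented", "anlagen", "karyonide")}
    for k, v in m.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"morphology fraction {k}={v} outside [0, 1]")
    if sum(m.values()) > 1.0 + MORPHOLOGY_SUM_TOL:
        raise ValueError(f"morphology fractions sum to {sum(m.values()):.3f} > 1")

    if m["anlagen"] >= 0.70:
        if (
            hours is not None
            and dev2_hours is not None
            and hours - dev2_hours >= DEV3_MIN_HOURS_AFTER_DEV2
        ):
            return "DEV3"
        return "DEV2"
    if m["anlagen"] >= 0.10:
        return "DEV1"
    if m["fragmented"] >= 0.30:
        return "FRAG"
    if m["meiosis"] >= 0.20 and m["fragmented"] < 0.10:
        return "MEI"
    if m["meiosis"] + m["fragmented"] + m["anlagen"] < 0.05:
        return "VEG"
    # between printed ranges: fall back on the dominant marker
    if m["meiosis"] + m["fragmented"] + m["anlagen"] < 0.20:
        return "VEG"
    return "MEI" if m["meiosis"] >= m["fragmented"] else "FRAG"


def stage_samples(sheet: pd.DataFrame) -> pd.Series:
    """Stage every autogamy sample in a sheet from its morphology fractions.

    DEV2 collection time is taken as the earliest hour among samples whose
    morphology alone says DEV2/DEV3; later samples >= ~10 h after it become
    DEV3.
    """
    auto = sheet[sheet["experiment"] == "autogamy"]
    hours = auto["hours"] if "hours" in auto else pd.Series(index=auto.index, dtype=float)
    morph_stage = {
        s: stage_sample(auto.loc[s].to_dict()) for s in auto.index
    }
    dev2_like = [s for s, st in morph_stage.items() if st == "DEV2"]
    dev2_hours = (
        float(hours.loc[dev2_like].min()) if dev2_like and hours.notna().any() else None
    )
    out = {}
    for s in auto.index:
        h = float(hours.loc[s]) if s in hours.index and pd.notna(hours.loc[s]) else None
        out[s] = stage_sample(auto.loc[s].to_dict(), hours=h, dev2_hours=dev2_hours)
    return pd.Series(out, name="stage")
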