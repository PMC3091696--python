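"""Probe-level signal simulation: affinities, noise, cross-hybridization.

Each sample's probe signal is the gene's true log2 mean at the sample's time
point, plus a fixed per-probe affinity offset (shared across samples, so it
cancels in replicate correlations and in within-gene contrasts), plus a linear
-scale cross-hybridization contribution from the recent-WGD paralog when the
paralog's transcript matches the probe's window within the hybridization
mismatch ceiling, plus per-measurement Gaussian noise.  Baselines default to a
log2 center of 10 so sample signal densities land in the 9-11 QC window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import MORPHOLOGY_COLS, ProbeMatrix
from .config import TIMEPOINTS, SimConfig
from .genome import DupNode, GeneLeaf, OhnologFamily, iter_nodes
from .sequences import PROBE_LEN, Probe

#: Collection times (hours) attached to autogamy samples; DEV3 is taken ~10 h
#: after DEV2, the only way the two stages can be told apart.
_AUTOGAMY_HOURS = {"VEG": 0.0, "MEI": 5.0, "FRAG": 8.0, "DEV1": 12.0,
                   "DEV2": 17.0, "DEV3": 27.0}
_OTHER_HOURS = {
    "reciliation": {"T0": 0.0, "T30": 0.5, "T120": 2.0},
    "exocytosis": {"T0": 0.0, "T40": 0.67, "T210": 3.5},
}

# Per-stage nuclear morphology sampling ranges (uniform within the printed
# observed range for each autogamy stage).
_MORPH_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "VEG": {},
    "MEI": {"meiosis": (0.20, 0.39), "fragmented": (0.0, 0.03),
            "skein": (0.0, 0.05)},
    "FRAG": {"meiosis": (0.20, 0.29), "fragmented": (0.37, 0.43),
             "anlagen": (0.0, 0.05)},
    "DEV1": {"fragmented": (0.35, 0.56), "anlagen": (0.35, 0.51)},
    "DEV2": {"anlagen": (0.73, 0.98), "karyonide": (0.0, 0.02)},
    "DEV3": {"anlagen": (0.73, 0.98), "karyonide": (0.0, 0.15)},
}


def make_sample_sheet(
    experiment: str, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample sheet for one experiment: replicates per time point plus
    (for autogamy) morphology fractions drawn within each stage's range."""
    rows = []
    for tp in TIMEPOINTS[experiment]:
        for rep in range(1, config.n_replicates + 1):
            row = {
                "sample_id": f"{experiment[:3]}_{tp}_r{rep}",
                "experiment": experiment,
                "timepoint": tp,
                "replicate_group": tp,
                "hours": (
                    _AUTOGAMY_HOURS[tp]
                    if experiment == "autogamy"
                    else _OTHER_HOURS[experiment][tp]
                ),
            }
            for col in MORPHOLOGY_COLS:
                row[col] = 0.0
            if experiment == "autogamy":
                total = 0.0
                for col, (lo, hi) in _MORPH_RANGES[tp].items():
                    hi = min(hi, 0.98 - total)
                    val = rng.uniform(lo, max(lo, hi))
                    row[col] = val
                    total += val
                row["vegetative"] = max(0.0, 1.0 - total)
            rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def _recent_pairs(families: list[OhnologFamily]) -> dict[str, str]:
    """gene -> its recent-WGD partner, for every retained level-1 pair."""
    partner: dict[str, str] = {}
    for fam in families:
        for node in iter_nodes(fam.root):
            if isinstance(node, DupNode) and node.level == 1:
                a, b = node.left, node.right
                assert isinstance(a, GeneLeaf) and isinstance(b, GeneLeaf)
                partner[a.gene_id] = b.gene_id
                partner[b.gene_id] = a.gene_id
    return partner


def _window_mismatches(
    seq_a: str, seq_b: str, offset: int, length: int = PROBE_LEN
) -> int:
    a = np.frombuffer(seq_a.encode(), dtype="S1")[offset : offset + length]
    b = np.frombuffer(seq_b.encode(), dtype="S1")[offset : offset + length]
    return int((a != b).sum())


def simulate_probe_signals(
    means: pd.DataFrame,
    probes: list[Probe],
    config: SimConfig,
    experiment: str = "autogamy",
    families: list[OhnologFamily] | None = None,
    transcripts: dict[str, str] | None = None,
) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Simulate the probe x sample log2 matrix and its sample sheet.

    ``means`` is the gene x time point matrix of true log2 levels.  When
    ``families`` and ``transcripts`` are supplied, recent-WGD paralog pairs
    contribute cross-hybridization signal to each other's probes wherever the
    paralog transcript matches the probe window at <= crosshyb_max_mismatch
    mismatches.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 21, {"autogamy": 0, "reciliation": 1,
                                                 "exocytosis": 2}[experiment]])
    )
    sheet = make_sample_sheet(experiment, config, rng)
    probe_ids = [p.probe_id for p in probes]
    gene_ids = [p.gene_id for p in probes]
    missing = set(gene_ids) - set(means.index)
    if missing:
        raise ValueError(f"{len(missing)} probe genes lack expression profiles")

    gene_rows = means.loc[gene_ids]  # probe-aligned gene means (P x T)
    tp_idx = [list(means.columns).index(tp) for tp in sheet["timepoint"]]
    base = gene_rows.to_numpy()[:, tp_idx]  # P x S

    # cross-hybridization from recent paralogs (linear-scale mixing)
    if families is not None and transcripts is not None and config.crosshyb_weight > 0:
        partner_map = _recent_pairs(families)
        xhyb_rows, xhyb_genes = [], []
        for i, p in enumerate(probes):
            mate = partner_map.get(p.gene_id)
            if mate is None:
                continue
            mism = _window_mismatches(
                transcripts[p.gene_id], transcripts[mate], p.offset
            )
            if mism <= config.crosshyb_max_mismatch:
                xhyb_rows.append(i)
                xhyb_genes.append(mate)
        if xhyb_rows:
            mate_base = means.loc[xhyb_genes].to_numpy()[:, tp_idx]
            linear = np.exp2(base).astype(float)
            linear[xhyb_rows] += config.crosshyb_weight * np.exp2(mate_base)
            base = np.log2(linear)

    affinity = rng.normal(0.0, config.probe_affinity_sd, size=len(probes))
    noise = rng.normal(0.0, config.noise_sd, size=base.shape)
    values = pd.DataFrame(
        base + affinity[:, None] + noise, index=probe_ids, columns=sheet.index
    )
    matrix = ProbeMatrix(
        values=values,
        probe_genes=pd.Series(gene_ids, index=probe_ids, name="gene_id"),
        scale="log2",
    )
    return matrix, sheet
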