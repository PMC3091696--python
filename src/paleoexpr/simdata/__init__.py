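"""Synthetic paleopolyploid expression data with known ground truth."""

from dataclasses import dataclass

import pandas as pd

from .config import ARCHETYPE_COUNTS, DEFAULT_ARCHETYPES, TIMEPOINTS, SimConfig
from .expression import FLAT, TruthTable, simulate_expression
from .genome import (
    DupNode,
    GeneLeaf,
    OhnologFamily,
    RetentionTally,
    iter_nodes,
    leaf_paths,
    simulate_genome,
)
from .sequences import (
    PROBE_LEN,
    PROBES_PER_GENE,
    Probe,
    design_probes,
    reverse_complement,
    simulate_transcripts,
    simulate_transcripts_probes,
)
from .signals import make_sample_sheet, simulate_probe_signals
from ..datatypes import ProbeMatrix


@dataclass
class SimulatedDataset:
    """A complete simulated experiment bundle."""

    config: SimConfig
    experiment: str
    families: list[OhnologFamily]
    genes: list[str]
    tally: RetentionTally
    transcripts: dict[str, str]
    probes: list[Probe]
    truth: TruthTable
    means: pd.DataFrame
    probe_matrix: ProbeMatrix
    sample_sheet: pd.DataFrame


def simulate_dataset(
    config: SimConfig,
    experiment: str = "autogamy",
    with_sequences: bool = True,
) -> SimulatedDataset:
    """Run the full generator: genome -> sequences -> expression -> signals.

    ``with_sequences=False`` skips transcript/probe sequence simulation and
    cross-hybridization (probes are still laid out 6 per gene) for analyses
    that only need expression-level structure.
    """
    families, genes, tally = simulate_genome(config)
    truth, means = simulate_expression(families, config, experiment)
    if with_sequences:
        transcripts, probes = simulate_transcripts_probes(families, config)
    else:
        transcripts = {}
        probes = [
            Probe(f"{g}_p{i + 1}", g, "+" if i % 2 == 0 else "-", i * PROBE_LEN, "N" * PROBE_LEN)
            for g in genes
            for i in range(PROBES_PER_GENE)
        ]
    probe_matrix, sheet = simulate_probe_signals(
        means,
        probes,
        config,
        experiment,
        families=families if with_sequences else None,
        transcripts=transcripts if with_sequences else None,
    )
    return SimulatedDataset(
        config=config,
        experiment=experiment,
        families=families,
        genes=genes,
        tally=tally,
        transcripts=transcripts,
        probes=probes,
        truth=truth,
        means=means,
        probe_matrix=probe_matrix,
        sample_sheet=sheet,
    )


__all__ = [
    "ARCHETYPE_COUNTS",
    "DEFAULT_ARCHETYPES",
    "TIMEPOINTS",
    "SimConfig",
    "FLAT",
    "TruthTable",
    "simulate_expression",
    "DupNode",
    "GeneLeaf",
    "OhnologFamily",
    "RetentionTally",
    "iter_nodes",
    "leaf_paths",
    "simulate_genome",
    "PROBE_LEN",
    "PROBES_PER_GENE",
    "Probe",
    "design_probes",
    "reverse_complement",
    "simulate_transcripts",
    "simulate_transcripts_probes",
    "make_sample_sheet",
    "simulate_probe_signals",
    "SimulatedDataset",
    "simulate_dataset",
]
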