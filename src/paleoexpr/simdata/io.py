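"""Plain-text serialization of simulated datasets.

All tables are TSV; transcripts are FASTA.  Probe offsets are 0-based,
half-open.  Ohnolog families are encoded one leaf per row with a
root-to-leaf path of (WGD level, side) steps, e.g. ``2L/1R``; singleton
families have an empty path.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..datatypes import ProbeMatrix
from .expression import TruthTable
from .genome import OhnologFamily, decode_path, encode_path, family_from_paths, leaf_paths
from .sequences import Probe


def write_transcripts(transcripts: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in sorted(transcripts.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transcripts(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_probes(probes: list[Probe], path) -> None:
    pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "gene_id": p.gene_id,
                "strand": p.strand,
                "offset": p.offset,
                "sequence": p.sequence,
            }
            for p in probes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_probes(path) -> list[Probe]:
    df = pd.read_csv(path, sep="\t", dtype={"offset": int})
    return [
        Probe(r.probe_id, r.gene_id, r.strand, int(r.offset), r.sequence)
        for r in df.itertuples()
    ]


def write_probe_matrix(matrix: ProbeMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_id", matrix.probe_genes.loc[out.index])
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_probe_matrix(path, scale: str = "log2") -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    genes = df.pop("gene_id")
    return ProbeMatrix(values=df, probe_genes=genes, scale=scale)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_families(families: list[OhnologFamily], path) -> None:
    rows = []
    for fam in families:
        for gene, p in sorted(leaf_paths(fam).items()):
            rows.append(
                {"gene_id": gene, "family_id": fam.family_id, "wgd_path": encode_path(p)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_families(path) -> list[OhnologFamily]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    families = []
    for family_id, grp in df.groupby("family_id", sort=True):
        paths = {r.gene_id: decode_path(r.wgd_path) for r in grp.itertuples()}
        families.append(family_from_paths(family_id, paths))
    return families


def write_truth(truth: TruthTable, genes_path, pairs_path) -> None:
    truth.genes.to_csv(genes_path, sep="\t", index_label="gene_id")
    truth.pairs.to_csv(pairs_path, sep="\t", index=False)


def read_truth(genes_path, pairs_path, experiment: str = "autogamy") -> TruthTable:
    return TruthTable(
        genes=pd.read_csv(genes_path, sep="\t", index_col="gene_id"),
        pairs=pd.read_csv(pairs_path, sep="\t"),
        experiment=experiment,
    )


def write_gene_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
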