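"""Synthetic AT-rich transcripts and a 6-probe-per-gene oligonucleotide design.

Transcripts are drawn base-by-base at the configured GC fraction (default 0.30,
the AT-rich regime of the study genome).  Probes are 50-mers chosen from
non-overlapping windows preferring GC content near the platform target
(default 0.36), three per strand.  Ohnologs diverge by point substitution at
each duplication node so that recent pairs share a configurable identity
(default 95%), which is what makes cross-hybridization exercisable: at 95%
identity a 50-mer probe sees ~2.5 mismatches on its paralog's transcript,
inside the 5-mismatch hybridization envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .genome import DupNode, GeneLeaf, OhnologFamily, TreeNode

PROBE_LEN = 50
PROBES_PER_GENE = 6
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class Probe:
    """A 50 nt perfect-match probe on a gene transcript.

    ``offset`` is the 0-based start of the probe's window on the transcript
    (half-open); for minus-strand probes ``sequence`` is the reverse
    complement of that window.
    """

    probe_id: str
    gene_id: str
    strand: str
    offset: int
    sequence: str

    @property
    def gc(self) -> float:
        return (self.sequence.count("G") + self.sequence.count("C")) / len(
            self.sequence
        )


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Byte array of A/C/G/T with P(G or C) = gc."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=probs)]


def _mutate(
    seq: np.ndarray, n_subs: int, gc: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute exactly n_subs distinct positions to a different base.

    Replacement bases are drawn from the background composition (restricted
    to differing bases) so repeated rounds of divergence do not drift the GC
    content away from the configured target.
    """
    out = seq.copy()
    if n_subs == 0:
        return out
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        keep = _BASES != out[p]
        w = probs[keep]
        out[p] = rng.choice(_BASES[keep], p=w / w.sum())
    return out


def simulate_transcripts(
    families: list[OhnologFamily], config: SimConfig
) -> dict[str, str]:
    """One transcript per present-day gene, evolved along each family tree.

    At a duplication node of level k one descendant lineage accumulates
    substitutions so the pair's identity at the split equals
    ``pair_identity[k-1]`` exactly; recent (level 1) splits are terminal, so
    recent pairs retain that identity in the present-day sequences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    length = config.transcript_length
    transcripts: dict[str, str] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if isinstance(node, GeneLeaf):
            transcripts[node.gene_id] = seq.tobytes().decode()
            return
        identity = config.pair_identity[node.level - 1]
        n_subs = int(round((1.0 - identity) * length))
        walk(node.left, seq)
        walk(node.right, _mutate(seq, n_subs, config.gc_orf, rng))

    for fam in families:
        walk(fam.root, _random_sequence(length, config.gc_orf, rng))
    return transcripts


def design_probes(transcripts: dict[str, str], config: SimConfig) -> list[Probe]:
    """Select 6 non-overlapping 50-mers per transcript, 3 per strand.

    Candidate windows are ranked by |window GC - gc_probe| (ties by offset)
    and picked greedily subject to non-overlap; strands alternate along the
    transcript so each strand carries 3 probes.
    """
    probes: list[Probe] = []
    for gene_id in sorted(transcripts):
        seq = transcripts[gene_id]
        offsets = _select_windows(seq, config.gc_probe)
        for i, off in enumerate(offsets):
            strand = "+" if i % 2 == 0 else "-"
            window = seq[off : off + PROBE_LEN]
            probes.append(
                Probe(
                    probe_id=f"{gene_id}_p{i + 1}",
                    gene_id=gene_id,
                    strand=strand,
                    offset=off,
                    sequence=window if strand == "+" else reverse_complement(window),
                )
            )
    return probes


def _select_windows(seq: str, gc_target: float) -> list[int]:
    if len(seq) < PROBES_PER_GENE * PROBE_LEN:
        raise ValueError(
            f"transcript of length {len(seq)} too short for "
            f"{PROBES_PER_GENE} non-overlapping {PROBE_LEN}-mers"
        )
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = np.isin(arr, np.array([b"G", b"C"], dtype="S1")).astype(int)
    window_gc = np.convolve(is_gc, np.ones(PROBE_LEN, dtype=int), "valid") / PROBE_LEN
    order = np.lexsort((np.arange(len(window_gc)), np.abs(window_gc - gc_target)))
    chosen: list[int] = []
    for off in order:
        if all(abs(int(off) - c) >= PROBE_LEN for c in chosen):
            chosen.append(int(off))
            if len(chosen) == PROBES_PER_GENE:
                break
    return sorted(chosen)


def simulate_transcripts_probes(
    families: list[OhnologFamily], config: SimConfig
) -> tuple[dict[str, str], list[Probe]]:
    """Transcripts plus the full probe design for a simulated genome."""
    transcripts = simulate_transcripts(families, config)
    return transcripts, design_probes(transcripts, config)
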