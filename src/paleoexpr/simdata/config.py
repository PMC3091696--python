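"""Configuration for the synthetic paleopolyploid expression data generator.

The generator emulates a single-channel oligonucleotide platform interrogating
a genome shaped by three successive whole-genome duplications (WGDs): an AT-rich
gene complement, six 50-mer probes per gene (three per strand), time-course
expression archetypes with biological replicates, and ground-truth labels
(retention, differential expression, subfunctionalization, pseudogenization)
for parameter-recovery benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

# Time point labels per experiment.  Autogamy stages follow the nuclear
# morphology staging (vegetative, meiosis, old-MAC fragmentation, three
# developmental points with DEV2/DEV3 separated only by collection time).
TIMEPOINTS: dict[str, list[str]] = {
    "autogamy": ["VEG", "MEI", "FRAG", "DEV1", "DEV2", "DEV3"],
    "reciliation": ["T0", "T30", "T120"],
    "exocytosis": ["T0", "T40", "T210"],
}

# Named mean log2 offsets (relative to each gene's basal level) at the
# experiment's time points.  Autogamy carries 6 archetypes, reciliation 3,
# exocytosis 2, matching the co-expression cluster structure of the study
# system.
DEFAULT_ARCHETYPES: dict[str, dict[str, list[float]]] = {
    "autogamy": {
        "early_peak": [0.0, 3.0, 3.0, 1.0, 0.0, 0.0],
        "early_induction": [0.0, 2.0, 2.5, 2.5, 2.5, 2.5],
        "intermediate_induction": [0.0, 0.5, 1.5, 3.0, 3.0, 2.5],
        "late_induction": [0.0, 0.0, 0.0, 0.5, 2.5, 3.0],
        "early_repression": [0.0, -2.0, -2.5, -2.5, -2.5, -2.5],
        "late_repression": [0.0, 0.0, -0.5, -1.5, -2.5, -3.0],
    },
    "reciliation": {
        "early_peak": [0.0, 3.0, 1.0],
        "gradual_induction": [0.0, 1.5, 3.0],
        "repression": [0.0, -1.5, -2.5],
    },
    "exocytosis": {
        "induced": [0.0, 2.0, 3.0],
        "repressed": [0.0, -1.5, -2.5],
    },
}

#: Expected archetype counts per experiment (autogamy 6, reciliation 3,
#: exocytosis 2).
ARCHETYPE_COUNTS = {"autogamy": 6, "reciliation": 3, "exocytosis": 2}


def _as_float_tuple(value, n: int, name: str) -> tuple[float, ...]:
    if isinstance(value, (int, float)):
        value = (float(value),) * n
    out = tuple(float(v) for v in value)
    if len(out) != n:
        raise ValueError(f"{name} must have {n} entries, got {len(out)}")
    return out


@dataclass
class SimConfig:
    """All knobs of the synthetic data generator.

    Parameters
    ----------
    n_ancestral:
        Number of pre-duplication ancestral genes.
    retention_probs:
        Probability that *both* copies of a duplication event survive, per
        WGD, ordered (recent, intermediate, old).  The genome-wide estimates
        for the study system are (0.51, 0.24, 0.08).
    archetypes:
        Mapping experiment -> {archetype name -> mean log2 offsets per time
        point}.  Defaults reproduce the named cluster structure (autogamy 6,
        reciliation 3, exocytosis 2).
    frac_de:
        Fraction of ohnolog families assigned a non-flat archetype.
    frac_subfunctionalized:
        Per-WGD-depth fraction (recent, intermediate, old) of retained pairs
        whose two lineages are given divergent archetypes.
    frac_pseudogene:
        Fraction of retained (non-singleton) present-day genes whose
        expression has decayed: flat, low baseline, non-responsive.
    baseline_mean, baseline_sd:
        Parameters of the basal log2 expression distribution (normal on the
        log2 scale, i.e. log-normal intensities); the mean calibrates sample
        signal densities to center between 9 and 11.
    noise_sd:
        Per-probe, per-sample Gaussian noise sd on the log2 scale.
    probe_affinity_sd:
        Sd of each probe's fixed additive affinity offset (log2 scale);
        shared across samples, so it cancels in replicate correlations.
    n_replicates:
        Biological replicates per time point (>= 2 so replicate QC is
        possible).
    gc_orf, gc_probe:
        Target GC fraction of transcripts (AT-rich, 0.30) and of the selected
        probe windows (0.36).
    transcript_length:
        Transcript length in nt; must fit 6 non-overlapping 50-mers.
    pair_identity:
        Target pairwise sequence identity of ohnologs per WGD depth
        (recent, intermediate, old).
    crosshyb_weight:
        Linear-scale fractional contribution of a cross-hybridizing
        near-identical paralog transcript to a probe's signal.
    crosshyb_max_mismatch:
        Mismatch ceiling below which a paralog window cross-hybridizes.
    pseudogene_drop:
        log2 units subtracted from a pseudogene's baseline.
    seed:
        Mandatory RNG seed; identical configs reproduce outputs exactly.
    """

    n_ancestral: int = 2000
    retention_probs: tuple[float, float, float] = (0.51, 0.24, 0.08)
    archetypes: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=lambda: DEFAULT_ARCHETYPES
    )
    frac_de: float = 0.3
    frac_subfunctionalized: tuple[float, float, float] = (0.05, 0.10, 0.15)
    frac_pseudogene: float = 0.1
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.25
    probe_affinity_sd: float = 0.5
    n_replicates: int = 3
    gc_orf: float = 0.30
    gc_probe: float = 0.36
    transcript_length: int = 1500
    pair_identity: tuple[float, float, float] = (0.95, 0.75, 0.65)
    crosshyb_weight: float = 0.3
    crosshyb_max_mismatch: int = 5
    pseudogene_drop: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.retention_probs = _as_float_tuple(
            self.retention_probs, 3, "retention_probs"
        )
        self.frac_subfunctionalized = _as_float_tuple(
            self.frac_subfunctionalized, 3, "frac_subfunctionalized"
        )
        self.pair_identity = _as_float_tuple(self.pair_identity, 3, "pair_identity")
        for name, vals in [
            ("retention_probs", self.retention_probs),
            ("frac_subfunctionalized", self.frac_subfunctionalized),
            ("pair_identity", self.pair_identity),
            ("frac_de", (self.frac_de,)),
            ("frac_pseudogene", (self.frac_pseudogene,)),
            ("gc_orf", (self.gc_orf,)),
            ("gc_probe", (self.gc_probe,)),
        ]:
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} values must lie in [0, 1], got {v}")
        if self.n_ancestral < 1:
            raise ValueError("n_ancestral must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 to permit replicate QC")
        if self.noise_sd < 0 or self.probe_affinity_sd < 0:
            raise ValueError("noise/affinity sd must be non-negative")
        if self.transcript_length < 6 * 50:
            raise ValueError(
                "transcript_length must accommodate 6 non-overlapping 50-mers"
            )
        for exp, expected in ARCHETYPE_COUNTS.items():
            if exp in self.archetypes and len(self.archetypes[exp]) != expected:
                raise ValueError(
                    f"{exp} must define {expected} archetypes, "
                    f"got {len(self.archetypes[exp])}"
                )
        for exp, profs in self.archetypes.items():
            ntp = len(TIMEPOINTS[exp])
            for name, prof in profs.items():
                if len(prof) != ntp:
                    raise ValueError(
                        f"archetype {exp}/{name} must have {ntp} time points"
                    )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        data["archetypes"] = {
            exp: {name: list(prof) for name, prof in profs.items()}
            for exp, profs in self.archetypes.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
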