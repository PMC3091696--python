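"""Synthetic-data generator: genome, sequences, expression, signals."""

import numpy as np
import pandas as pd
import pytest

from paleoexpr.simdata import (
    PROBE_LEN,
    PROBES_PER_GENE,
    SimConfig,
    simulate_dataset,
    simulate_expression,
    simulate_genome,
    simulate_probe_signals,
    simulate_transcripts_probes,
)
from paleoexpr.simdata.genome import (
    DupNode,
    decode_path,
    encode_path,
    family_from_paths,
    iter_nodes,
    leaf_paths,
)
from paleoexpr.simdata.sequences import reverse_complement


class TestGenome:
    def test_full_retention_doubles_three_times(self):
        fams, genes, _ = simulate_genome(SimConfig(n_ancestral=10, retention_probs=(1, 1, 1), seed=0))
        assert len(fams) == 10
        assert all(len(f) == 8 for f in fams)
        assert len(genes) == 80

    def test_zero_retention_keeps_singletons(self):
        fams, genes, _ = simulate_genome(SimConfig(n_ancestral=10, retention_probs=(0, 0, 0), seed=0))
        assert all(len(f) == 1 for f in fams)
        assert len(genes) == 10

    def test_no_family_is_ever_lost(self):
        fams, _, _ = simulate_genome(SimConfig(n_ancestral=300, seed=7))
        assert all(len(f) >= 1 for f in fams)

    def test_retention_recovers_configured_probabilities(self):
        """Both-copy survival per WGD matches 51/24/8% within 3 binomial sd."""
        cfg = SimConfig(n_ancestral=20000, retention_probs=(0.51, 0.24, 0.08), seed=1)
        _, _, tally = simulate_genome(cfg)
        for level, p in zip((1, 2, 3), cfg.retention_probs):
            n = tally.events[level]
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(tally.fraction(level) - p) < 3 * sd

    def test_levels_strictly_decrease_toward_leaves(self):
        fams, _, _ = simulate_genome(SimConfig(n_ancestral=200, seed=3))
        for fam in fams:
            for node in iter_nodes(fam.root):
                if isinstance(node, DupNode):
                    for child in (node.left, node.right):
                        if isinstance(child, DupNode):
                            assert child.level < node.level

    def test_same_seed_reproduces_genome(self):
        cfg = SimConfig(n_ancestral=100, seed=42)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert [f.leaves() for f in a[0]] == [f.leaves() for f in b[0]]

    def test_path_roundtrip(self):
        fams, _, _ = simulate_genome(SimConfig(n_ancestral=50, seed=9))
        for fam in fams:
            paths = leaf_paths(fam)
            rebuilt = family_from_paths(fam.family_id, {
                g: decode_path(encode_path(p)) for g, p in paths.items()
            })
            assert leaf_paths(rebuilt) == paths

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(retention_probs=(1.2, 0.2, 0.1))


class TestSequences:
    def test_six_probes_three_per_strand(self):
        cfg = SimConfig(n_ancestral=5, retention_probs=(0, 0, 0), seed=2)
        fams, genes, _ = simulate_genome(cfg)
        _, probes = simulate_transcripts_probes(fams, cfg)
        assert len(probes) == PROBES_PER_GENE * len(genes)
        df = pd.DataFrame([(p.gene_id, p.strand, len(p.sequence)) for p in probes],
                          columns=["gene", "strand", "length"])
        assert (df["length"] == PROBE_LEN).all()
        per_strand = df.groupby(["gene", "strand"]).size()
        assert (per_strand == 3).all()

    def test_probe_windows_do_not_overlap(self):
        cfg = SimConfig(n_ancestral=10, seed=5)
        fams, _, _ = simulate_genome(cfg)
        _, probes = simulate_transcripts_probes(fams, cfg)
        by_gene: dict[str, list[int]] = {}
        for p in probes:
            by_gene.setdefault(p.gene_id, []).append(p.offset)
        for offsets in by_gene.values():
            offsets.sort()
            assert all(b - a >= PROBE_LEN for a, b in zip(offsets, offsets[1:]))

    def test_transcript_gc_matches_target(self):
        cfg = SimConfig(n_ancestral=1200, retention_probs=(0.3, 0.2, 0.1), seed=6)
        fams, genes, _ = simulate_genome(cfg)
        from paleoexpr.simdata import simulate_transcripts

        tx = simulate_transcripts(fams, cfg)
        assert len(tx) == len(genes)
        gc = np.mean([
            (s.count("G") + s.count("C")) / len(s) for s in tx.values()
        ])
        assert abs(gc - cfg.gc_orf) < 0.01

    def test_probe_gc_biased_toward_platform_target(self):
        cfg = SimConfig(n_ancestral=200, retention_probs=(0, 0, 0), seed=8)
        fams, _, _ = simulate_genome(cfg)
        _, probes = simulate_transcripts_probes(fams, cfg)
        mean_gc = np.mean([p.gc for p in probes])
        assert abs(mean_gc - cfg.gc_probe) < 0.02
        assert mean_gc > cfg.gc_orf + 0.03  # probes are GC-enriched vs ORFs

    def test_identical_twins_match_at_zero_mismatches(self):
        """At 100% identity every probe's window recurs exactly in the twin."""
        cfg = SimConfig(n_ancestral=4, retention_probs=(1, 0, 0), seed=3,
                        pair_identity=(1.0, 1.0, 1.0))
        fams, _, _ = simulate_genome(cfg)
        tx, probes = simulate_transcripts_probes(fams, cfg)
        for fam in fams:
            a, b = fam.leaves()
            assert tx[a] == tx[b]
        for p in probes:
            window = p.sequence if p.strand == "+" else reverse_complement(p.sequence)
            assert window in tx[p.gene_id]

    def test_recent_pair_identity_is_exact(self):
        cfg = SimConfig(n_ancestral=6, retention_probs=(1, 0, 0), seed=4)
        fams, _, _ = simulate_genome(cfg)
        tx, _ = simulate_transcripts_probes(fams, cfg)
        for fam in fams:
            a, b = fam.leaves()
            ident = np.mean([x == y for x, y in zip(tx[a], tx[b])])
            assert ident == pytest.approx(cfg.pair_identity[0], abs=1e-9)

    def test_short_transcript_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(transcript_length=200)


class TestExpression:
    def test_no_de_means_all_flat(self):
        cfg = SimConfig(n_ancestral=50, frac_de=0.0, seed=1)
        fams, _, _ = simulate_genome(cfg)
        truth, means = simulate_expression(fams, cfg)
        assert (truth.genes["archetype"] == "flat").all()
        assert np.allclose(means.to_numpy(), means.to_numpy()[:, [0]])

    def test_zero_subfunctionalization_keeps_pairs_concordant(self):
        cfg = SimConfig(n_ancestral=300, frac_de=1.0, frac_pseudogene=0.0,
                        frac_subfunctionalized=(0, 0, 0), seed=2)
        fams, _, _ = simulate_genome(cfg)
        truth, _ = simulate_expression(fams, cfg)
        arch = truth.genes["archetype"]
        for row in truth.pairs.itertuples():
            assert arch[row.gene_a] == arch[row.gene_b]
            assert not row.subfunctionalized

    def test_planted_divergence_fraction_recovered(self):
        """5% per-pair divergence at the recent WGD shows in the truth flags."""
        cfg = SimConfig(n_ancestral=20000, frac_de=1.0, frac_pseudogene=0.0,
                        frac_subfunctionalized=(0.05, 0, 0), seed=3)
        fams, _, _ = simulate_genome(cfg)
        truth, _ = simulate_expression(fams, cfg)
        wgd1 = truth.pairs.query("level == 1")
        assert abs(wgd1["subfunctionalized"].mean() - 0.05) < 0.02

    def test_subfunctionalized_pairs_have_distinct_archetypes(self):
        cfg = SimConfig(n_ancestral=500, frac_de=0.8, seed=4,
                        frac_subfunctionalized=(0.3, 0.2, 0.2))
        fams, _, _ = simulate_genome(cfg)
        truth, _ = simulate_expression(fams, cfg)
        arch = truth.genes["archetype"]
        sub = truth.pairs.query("subfunctionalized")
        assert len(sub) > 0
        assert (arch[sub["gene_a"]].to_numpy() != arch[sub["gene_b"]].to_numpy()).all()

    def test_pseudogenes_are_flat_and_low(self):
        cfg = SimConfig(n_ancestral=400, frac_de=1.0, frac_pseudogene=0.4, seed=5)
        fams, _, _ = simulate_genome(cfg)
        truth, means = simulate_expression(fams, cfg)
        pseudo = truth.genes.query("pseudogene")
        assert len(pseudo) > 0
        assert (pseudo["archetype"] == "flat").all()
        assert pseudo["baseline"].mean() < truth.genes.query("~pseudogene")["baseline"].mean() - 2

    def test_unknown_experiment_rejected(self):
        cfg = SimConfig(n_ancestral=5, seed=0)
        fams, _, _ = simulate_genome(cfg)
        with pytest.raises(ValueError, match="unknown experiment"):
            simulate_expression(fams, cfg, "mitosis")

    @pytest.mark.parametrize("experiment,n_arch", [
        ("autogamy", 6), ("reciliation", 3), ("exocytosis", 2),
    ])
    def test_archetype_counts_per_experiment(self, experiment, n_arch):
        cfg = SimConfig(n_ancestral=300, frac_de=1.0, frac_pseudogene=0.0, seed=6)
        fams, _, _ = simulate_genome(cfg)
        truth, _ = simulate_expression(fams, cfg, experiment)
        used = set(truth.genes["archetype"]) - {"flat"}
        assert len(used) == n_arch


class TestSignals:
    def test_noise_free_probes_equal_true_means(self):
        cfg = SimConfig(n_ancestral=20, retention_probs=(0, 0, 0), seed=7,
                        noise_sd=0.0, probe_affinity_sd=0.0, crosshyb_weight=0.0)
        ds = simulate_dataset(cfg, "autogamy", with_sequences=False)
        tp = ds.sample_sheet["timepoint"]
        for sample in ds.probe_matrix.samples:
            expected = ds.means.loc[ds.probe_matrix.probe_genes, tp[sample]]
            assert np.allclose(ds.probe_matrix.values[sample].to_numpy(),
                               expected.to_numpy())

    def test_replicates_correlate_at_least_084(self, small_gene_matrix):
        from paleoexpr.preprocess import qc_samples

        report = qc_samples(small_gene_matrix)
        assert report.min_replicate_r() >= 0.84

    def test_seed_determinism_bitwise(self):
        cfg = SimConfig(n_ancestral=30, seed=11)
        a = simulate_dataset(cfg, "autogamy")
        b = simulate_dataset(cfg, "autogamy")
        assert a.probe_matrix.values.equals(b.probe_matrix.values)
        assert a.sample_sheet.equals(b.sample_sheet)

    def test_density_centers_in_qc_window(self, small_dataset):
        from paleoexpr.preprocess import _density_center

        for sample in small_dataset.probe_matrix.samples:
            c = _density_center(small_dataset.probe_matrix.values[sample].to_numpy())
            assert 9.0 <= c <= 11.0

    def test_crosshyb_raises_probe_signal_of_silent_twin(self):
        """A flat gene with a strongly induced identical twin picks up signal."""
        cfg = SimConfig(n_ancestral=40, retention_probs=(1, 0, 0), seed=13,
                        pair_identity=(1.0, 1.0, 1.0), noise_sd=0.0,
                        probe_affinity_sd=0.0, frac_de=0.0, frac_pseudogene=0.0)
        fams, _, _ = simulate_genome(cfg)
        truth, means = simulate_expression(fams, cfg)
        # plant one induced gene whose twin stays flat
        a, b = fams[0].leaves()
        means.loc[a] = means.loc[a] + np.array([0, 4, 4, 4, 4, 4])
        tx, probes = simulate_transcripts_probes(fams, cfg)
        pm, sheet = simulate_probe_signals(means, probes, cfg, "autogamy",
                                           families=fams, transcripts=tx)
        twin_probe = next(p.probe_id for p in probes if p.gene_id == b)
        veg = sheet.index[sheet["timepoint"] == "VEG"][0]
        mei = sheet.index[sheet["timepoint"] == "MEI"][0]
        assert pm.values.loc[twin_probe, mei] > pm.values.loc[twin_probe, veg] + 0.5

    def test_morphology_fractions_valid_and_stageable(self, small_dataset):
        from paleoexpr.datatypes import MORPHOLOGY_COLS
        from paleoexpr.preprocess import stage_samples

        sheet = small_dataset.sample_sheet
        frac = sheet[list(MORPHOLOGY_COLS)]
        assert (frac.to_numpy() >= 0).all()
        assert (frac.sum(axis=1) <= 1.05).all()
        staged = stage_samples(sheet)
        assert (staged == sheet["timepoint"]).all()
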