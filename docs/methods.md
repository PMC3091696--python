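# Methods

## The study system and what the package computes

*Paramecium tetraurelia* retains ohnologs — paralogs created by whole-genome
duplication — from three nested WGD events (recent, intermediate, old). A
single-channel oligonucleotide platform with 6 probes per gene was used to
profile three time courses: autogamy (the self-fertilization sexual process,
staged VEG → MEI → FRAG → DEV1 → DEV2 → DEV3 by nuclear morphology),
reciliation after chemical deciliation, and recovery from massive trichocyst
exocytosis. The scientific payoff is downstream of the expression analysis:
if WGD duplicates had partitioned their ancestral functions
(subfunctionalization), ohnologs of differentially expressed genes would fall
into *different* co-expression clusters. The package computes that
classification and reports the "different cluster" percentage explicitly as
an **upper bound** on the subfunctionalization rate — adjacent-archetype
splits, cluster instability and annotation noise all land in the same
category, so the true rate can only be lower.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
for every calibration and recovery check.

**Genome.** Each of `n_ancestral` genes passes through the old, intermediate
and recent WGD in that order. At each WGD every surviving lineage duplicates
and the pair resolves *before* the next event: both copies are kept with
probability `retention_probs[k]`, otherwise exactly one survives (a family is
never wholly lost). This makes the configured probability equal, in
expectation, to the fraction of duplication events at that level still
present in two copies — the statistic quoted genome-wide as 51% / 24% / 8% —
so the calibration check is a direct binomial comparison. Families are
binary trees whose internal nodes are the both-copies-kept duplications;
levels strictly decrease from root to leaf.

**Sequences.** Transcripts (default 1500 nt) are drawn base-by-base at
`gc_orf` = 0.30, the AT-rich regime of the genome. At a duplication node of
level k one descendant accumulates exactly `(1 - pair_identity[k-1]) × L`
substitutions, with replacement bases drawn from the background composition
so GC does not drift. Defaults (0.95, 0.75, 0.65): the recent-pair identity
is the value the platform design worried about (a 50-mer sees ~2.5 mismatches
on a 95%-identical paralog, inside the 5-mismatch hybridization envelope),
while the deeper defaults are chosen low enough that only recent pairs
cross-hybridize, matching the observation that multi-target probes almost
always involve recent ohnologs. Six non-overlapping 50-mer probes per
transcript are picked greedily by |window GC − 0.36|, alternating strands —
reproducing the platform's GC bias (probes 36% vs ORFs 30%).

**Expression.** A fraction `frac_de` (default 0.3) of families is assigned a
named archetype: mean log2 offsets over the experiment's time points
(autogamy 6 archetypes: early peak, early/intermediate/late induction,
early/late repression; reciliation 3; exocytosis 2). Offsets peak at ±3 log2
units, the scale of a strongly responsive transcript. The archetype
propagates down the family tree; at each duplication node of level k the
derived lineage switches to a different archetype with probability
`frac_subfunctionalized[k-1]` (defaults 0.05 / 0.10 / 0.15, mirroring the
observed per-level different-cluster ranges). A fraction `frac_pseudogene`
(default 0.1) of non-singleton genes pseudogenizes: flat profile at a
baseline lowered by 3 log2 units, emulating decaying copies that never enter
a cluster.

**Signals.** Probe signal = gene log2 mean at the sample's time point + a
fixed per-probe affinity offset (sd 0.5, shared across samples, so it cancels
in replicate correlations and contrasts) + linear-scale cross-hybridization
(weight 0.3) from the recent paralog wherever its colinear window is within 5
mismatches + Gaussian noise (sd 0.25). Baselines are normal on the log2
scale (mean 10, sd 1), putting sample density modes inside the 9–11 QC
window. Defaults keep replicate Pearson r above the 0.84 floor of the
original QC (noise and affinity magnitudes are not published; these values
were fixed once to land replicate r in the printed 0.84–0.99 band).
Autogamy sample sheets carry nuclear-morphology fractions drawn uniformly
within each stage's printed observed range; DEV3 differs from DEV2 only by a
collection time ~10 h later, because the stages are morphologically
indistinguishable.

**What the generator does not emulate:** introns and annotation-error modes
(split genes, wrong starts), germline-genome rearrangements,
sequence-evolution models beyond fixed per-level identity, per-sample
technical effects (scaling, spatial artifacts), and additive optical
background (signals emulate the *deposited*, already background-corrected
intensities). Passing tests therefore demonstrate correctness of the
statistical machinery under idealized technical conditions, not robustness
to real-array artifacts.

## Platform assessment and background correction

A probe "hybridizes" to every transcript containing a window (either strand
by default) within Hamming distance 5; ambiguous bases count as mismatches,
and a transcript is counted once regardless of how many windows match.
Matching is a one-hot inner product (all windows × all probes per
transcript), verified against an exhaustive sliding-window scan.

Background correction follows the RMA convolution model: observed intensity
X = S + B with S ~ Exponential(α) and B ~ Normal(μ, σ²). Each observation is
replaced by E[S | X = x] = m + σ·φ(m/σ)/Φ(m/σ), m = x − μ − σ²/α — a
truncated-normal mean, strictly positive and monotone in x (computed in log
space deep in the tail). Parameters are estimated per sample by mode/tail
heuristics (μ = KDE mode, σ = lower-tail rms, α = upper-tail mean) refined by
Nelder–Mead maximum likelihood under the convolution density; the refinement
is what makes corrected values track simulated true signals demonstrably
better than raw values. The pipeline applies this stage only when the input
is declared raw/linear, since the simulator emulates already-corrected
signals.

## Preprocessing

Quantile normalization forces every array in an analysis onto the mean
distribution of order statistics; ties receive the mean reference value over
their tied ranks, making the operation deterministic and idempotent. Gene
signal is the median of the gene's available probe signals. QC passes a
sample when its log2 density mode (0.1-unit histogram bins) lies in [9, 11]
and |mean − median| ≤ 0.5 (the symmetry tolerance is this package's choice;
only the center criterion is published). Staging is an anlagen-first
cascade — DEV2 if anlagen ≥ 70%, DEV1 if ≥ 10%, FRAG if fragmentation ≥ 30%,
MEI if meiosis ≥ 20% without fragmentation, VEG if all markers < 5% — with a
nearest-stage fallback so the function is total on the morphology simplex;
DEV3 requires collection-time metadata.

**A caution learned from the generator:** with ~30% of genes strongly and
asymmetrically regulated, quantile normalization measurably distorts
unchanged genes (spurious |logFC| up to ~1.5 in the tails of a simulated
autogamy course), because the equal-distribution assumption is violated.
This is a property of the method, not of the implementation; analyses of
data with massive asymmetric change should treat normalized fold changes
near the threshold with suspicion. For this reason the package's null
calibration and recovery tests run on un-normalized simulated signals (the
generator plants no per-sample effects, so normalization is a no-op at
best there).

## Differential expression

Per gene, a one-way cell-means fit over time-point levels (DEV2 and DEV3
merged for autogamy, since expression cannot resolve them) gives level means,
residual variance s²_g and residual df d_g. The variance prior (d₀, s₀²) is
estimated by moment-matching log s²_g to the log scaled-F distribution
implied by the hierarchical model (digamma/trigamma inversion; zero variances
shifted by 10⁻² × the smallest positive variance; no excess dispersion ⇒
d₀ = ∞ with s₀² the plain mean). The posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) yields moderated t statistics on
d₀ + d_g df for every level pair.

For the fold-change-threshold test the point null is replaced by
|logFC| ≤ τ and p = P(T ≥ (|logFC|−τ)/se) + P(T ≥ (|logFC|+τ)/se); at τ = 0
this reduces exactly to the ordinary moderated test, at the boundary with
vanishing se it approaches 0.5, and the DE call additionally requires a
fitted |logFC| > τ. Thresholds are specified on the natural scale (1.5, 2)
and converted to log2.

The published analysis says only that differential expression was sought
"between any two time points"; the per-gene combination used here is
explicit and conservative: gene p = (min over contrasts) × (number of
contrasts), capped at 1 (Bonferroni over contrasts), then
Benjamini–Hochberg across genes. An F-test would be an alternative reading;
the Bonferroni-then-BH rule was chosen because it yields a per-contrast
decision structure (needed for "up-regulated only" set operations) while
still controlling gene-level FDR.

## Clustering

The most differentially expressed genes (selection by max − min log2 signal
when a fixed-size set is wanted) are clustered by complete linkage on
1 − Pearson distance; samples on 1 − Spearman. Zero-variance vectors sit at
distance 1 from everything. Agglomeration is delegated to a standard
NN-chain implementation and its merge heights are oracle-tested against
exhaustive agglomeration; cutting at k uses the maxclust criterion, and cuts
are nested by construction. Cluster names are assigned by greedily matching
cluster mean profiles (replicate-averaged, for display and naming only — the
clustering itself sees all samples) to archetype templates by Pearson
correlation; unmatched clusters keep ordinal names. k comes from the
experiment (6 / 3 / 2), not from an optimality criterion.

## Permutation enrichment

A subset's DE count is computed by refitting the whole moderated chain on
the subset-only matrix (retaining power after within-subset BH correction;
thresholding raw p instead is selectable, since the published "p < 0.05" is
ambiguous) and compared against `n_permutations` random same-size draws from
the analyzed universe. The enrichment ratio is observed / null mean; the
empirical p uses the add-one correction (1 + #{null ≥ obs})/(1 + N), so 1000
permutations can report at best p < 0.001 — matching how the original
enrichments (25-fold for ciliary proteins, 60-fold for trichocyst matrix
proteins) were quoted. A "label" mode that counts members of a precomputed
DE set provides the fast path and the cross-mode consistency oracle.

## Ohnolog bookkeeping

A gene's ohnologs at level k are the present-day descendants of the sister
lineage of the level-k duplication node on its root-to-leaf path (≤ 1 / 2 / 4
for k = 1 / 2 / 3; empty if that copy was lost). Retention of a gene set is
the fraction with ≥ 1 such relative — note this gene-level statistic
(genome-wide ~61% at the recent WGD, because a retained pair contributes two
genes) is distinct from the event-level 51% both-copies statistic; both are
implemented. Classification of a DE gene's relatives uses the precedence
all-in-same > one-in-same > different > none. The precedence for mixed
relative states is not published; the most concordance-charitable rule was
chosen, consistent with reading the different-cluster percentages as upper
envelopes. Relatives outside the clustered set (including pseudogenizing
copies) are "not in cluster". Category counts always sum to the
genes-with-ohnolog denominator, and percentages are reported to one decimal.

## Problem sizes and numerical choices

Test and acceptance runs use 400–1500 ancestral genes for
recovery checks (chosen so binomial/clustering error stays well inside the
stated tolerances), 20,000 for the retention calibration, 2000 genes × 20
replicate datasets for null FDR calibration, and 5000 variances for
hyperparameter recovery. Seeds are fixed throughout; identical configuration
and seed reproduce every output byte-for-byte. Trigamma inversion uses
Newton iteration to 10⁻⁸ relative tolerance; t tails with infinite df fall
back to the normal; the normexp posterior uses `log_ndtr` to stay finite for
strongly negative arguments.

## Known limitations

- The subfunctionalization bound inherits cluster instability: when two
  archetypes are highly correlated, complete linkage can split or merge
  them, inflating the bound. This is faithful to the original design (the
  published values are explicitly upper envelopes) but means the bound
  should not be read as an estimate.
- Quantile normalization under massive asymmetric change distorts unchanged
  genes (see Preprocessing).
- Cross-hybridization is modeled only between recent paralogs via their
  colinear windows; a diverged paralog that gained a matching window
  elsewhere would be missed by the generator (not by the platform checker,
  which scans all windows).
- The refit enrichment mode re-estimates the variance prior inside each
  subset; for subsets of a few dozen genes the prior is noisy and the DE
  count correspondingly variable.
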