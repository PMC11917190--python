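# Methods

## The measurement being modelled

A one-viewpoint 4C-seq experiment circularizes chromatin around a chosen
restriction fragment (here, a promoter viewpoint) and sequences its
ligation partners. After alignment, the data reduce to a count per
restriction-fragment end: how often that end was captured in contact with
the viewpoint. Contact frequency decays steeply and monotonically with
genomic distance; regulatory contacts appear as localized excursions above
that decay. The package's job is to model the decay, call the excursions,
and compare them across cell lines and against chromatin marks.

## Fragment map and fragment-end accounting

The genome is digested in silico with NlaIII (CATG, cutting after the
motif, leaving a 3′ CATG overhang) and DpnII (GATC, cutting before the
motif, 5′ overhang). This cut-point convention means fragment ends carry
the recognition motif exactly as in a real 4C library, and it makes toy
examples reproducible: in `TTCATGTTTTGATCTTTTCATGTT` the cuts fall at
6, 10 and 22. Fragments are flagged invalid when blind (both flanks the
same enzyme — such fragments cannot arise from a primary/secondary
ligation junction), shorter than 40 bp (too short to map reliably), or
overlapping the ±5 kb viewpoint exclusion zone (dominated by
self-ligation). Exclusion uses any-overlap semantics (conservative); a
midpoint mode is available. Nothing is deleted — flags only — so the
filtering is auditable.

A valid fragment has exactly one NlaIII-derived end, so all profile
arrays hold one value per valid fragment, anchored at the NlaIII-side
boundary; distances to the viewpoint are measured from that anchor.

## Profile processing

Counts are scaled to a fixed library size (10⁶ by default; the constant
is arbitrary and cancels in every downstream ratio) and smoothed with a
30-fragment running mean, centered as 15 left + self + 14 right. At array
edges the window shrinks symmetrically — both sides are truncated by the
same deficit — so every index keeps a defined value and no NA propagates
into the caller. Replicate agreement is summarized as the Pearson
correlation of 5 kb-binned profiles over ±1 Mb (400 bins; a fragment end
contributes to the bin containing its fragment midpoint).

## Background model and interaction criteria

The background is a non-increasing isotonic regression (pool-adjacent-
violators, via scikit-learn) of the smoothed mean-of-replicates signal on
absolute distance, fitted separately for the upstream and downstream arms
because 4C decay is asymmetric around viewpoints. Isotonic regression is
attractive here because it assumes only monotonicity, not a parametric
decay shape; its cost is that a sustained peak is partially absorbed into
the fit (the fit rises to the pooled mean around the peak), which
attenuates but does not erase large excursions.

A fragment end within ±1 Mb is called interacting when all four criteria
hold:

1. **Reproducibility** — its smoothed signal exceeds the fitted
   background in every replicate (at least two replicates are required).
2. **Viewpoint fraction** — its smoothed mean exceeds 2.5% of the fitted
   background at the viewpoint-adjacent fragment. Implementing the
   threshold against the fitted viewpoint value makes it scale-free in
   library size.
3. **Signal-to-noise** — its residual z-score (smoothed mean minus
   background, over the per-arm residual sd) reaches `snr_k`.
4. **Local coverage** — the fraction of covered (nonzero pooled raw
   count) fragment ends in a centered 30-fragment window reaches the
   upper quartile of the scores over all fragments in the analysis
   window. This guards against calls in sparsely covered stretches.

Called fragments no more than 40 bp apart merge into pCREs.

### Calibration of the signal-to-noise threshold

The z threshold is the one tunable without an external standard, so it is
calibrated on background-only simulations at the package's study
conditions (below): smoothing over 30 fragments autocorrelates the
residuals and the coverage criterion is saturated when coverage is deep,
so at z ≥ 2.0 about 2% of background fragments are called. The default is
`snr_k = 2.5`, which brings the background call rate to ~0.8% of
in-window fragments (20 seeds) while keeping planted-interaction
sensitivity at 0.98 and interval precision at 1.0. The threshold remains
exposed in `CallerConfig`/the pipeline config.

### Resolution of calls

A caller operating on a w-fragment smoothed profile cannot localize peak
boundaries more finely than about w/2 fragments: planted-interaction
signal bleeds into flanking fragments and occasionally produces a
separate merged region a few hundred bp outside the true interval.
Recovery is therefore scored by `synthetic_data.interval_recovery` with a
slack of 15 valid fragments (half the smoothing window) around each true
interval for precision; sensitivity is strict (a true interval counts as
recovered only if a pCRE overlaps it directly).

## Differential classification

Classes are anchored on the expressing cell line: an expressing pCRE is
*shared* when it overlaps (≥ 1 bp by default) a pCRE of at least one
baseline line, else *gained*; baseline pCREs overlapping no expressing
pCRE are *lost*, after merging mutually overlapping baseline regions so
each lost region is counted once. With these definitions
|shared| + |gained| + |lost| always equals the number of distinct regions
across cell lines — an invariant the tests verify against a brute-force
oracle. Distance classes use the pCRE midpoint: near < 0.2 Mb,
medium 0.2–0.5 Mb (both boundaries inclusive), far > 0.5 Mb. Distance
densities are plain Gaussian kernel means with a bandwidth in bp (the
estimator is the literal kernel-sum formula, so tests can check it
exactly). The promoter/exonic/non-coding annotator is deliberately
simple: gene models are BED6 records whose span doubles as the exonic
region, with a strand-adjusted promoter window (default −1000/+100 bp
around the TSS) and precedence promoter > exonic > non-coding.

## Permutation enrichment

The observed statistic is the number of query regions (one pCRE class)
overlapping ≥ 1 reference peak. The null re-places every query region
uniformly at random in the analysis universe (default: the ±1 Mb window),
preserving lengths and permitting overlaps among placed regions — the
simplest exactly specifiable randomization; circular or masked
randomization is out of scope. Empirical p-values use the add-one
estimator, so the minimum attainable p at n permutations is 1/(n+1), and
enrichment and depletion are two one-sided tests. FDR control is
Benjamini–Hochberg over all tests of one invocation, and replicate
results for a mark × cell × class are aggregated as arithmetic means of
z and FDR, mirroring how multi-replicate proportional-overlap results are
usually reported. Type-I calibration at the study conditions: 3.5–4% of
planted-null runs reject at α = 0.05 (slightly conservative, as expected
for a discrete null).

## Rebinning correlation

Scored region sets (pCREs with their peak signal; ChIP peaks with their
score) are rebinned at 100 bp over the chromosome with the ceiling
convention (the final partial bin is kept — required to reproduce a
1,708,060-bin tiling of a 170,805,979 bp chromosome). Scores become
standardized percentiles within each sample (average-tie rank divided by
n, in (0, 1]); a bin overlapped by several regions of one sample takes the
maximum percentile, preserving the strongest signal per locus. Bins no
sample touches are removed before computing the pairwise Pearson matrix;
the display order comes from average-linkage clustering on 1 − r.
Percentiles are computed within-sample (not pooled), so each sample's
scale is rank-normalized independently.

## Oligo analysis

k-mers (k = 6 and 7 by default) are counted at every window on both
strands and collapsed to a canonical form (lexicographic minimum of the
k-mer and its reverse complement), so `AAAAAA` in a 6 bp input counts
twice — once per strand. Both-strand counting doubles every genomic
occurrence, which would double the variance relative to a binomial model
on window-strand trials; the upper-tail test therefore runs on the
occurrence scale (windows on one strand, counts halved) while
expectations are reported on the both-strand scale. The background is an
order-0 model estimated from the input (pooled with its reverse
complement, hence strand-symmetric) or uniform. E-values multiply p by
the number of possible canonical k-mers ((4ᵏ + 4^(k/2))/2 for even k),
giving ~1 expected false E < 1 hit on neutral input (measured 0.3–0.5
over 50 seeds). Overlap dependence between windows is ignored, as in
classical oligo-analysis; p-values for self-overlapping oligos
(homopolymers) are approximate. Significant oligos are greedily assembled
into consensus count matrices by longest exact consensus overlap
(≥ k − 2), considering both orientations — a deliberate simplification of
full motif-matrix clustering.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the package's study conditions: a 1.2 Mb
genome with the viewpoint centered; 2 NlaIII + 2 DpnII sites per kb
(≈ 4,800 fragments, ≈ 2,100 valid fragment ends — the background
sequence is scrubbed of natural motifs and a binomially sampled number of
sites is planted by substitution, so densities are controlled exactly);
contact means 100 · (1 + |d|/50 kb)^(−1), chosen to give deep coverage
near the viewpoint decaying to ~8 counts at 600 kb, similar in shape to
merged normalized viewpoint profiles; negative-binomial noise with
dispersion k = 5 (variance μ + μ²/5, i.e. strongly overdispersed;
k → ∞ recovers Poisson), drawn independently per replicate; two
replicates. Planted interactions multiply the mean of a ±10-fragment
neighbourhood by a fold factor (≥ 5 in recovery experiments). ChIP peak
sets place a controlled fraction of peaks on distinct query regions and
the rest uniformly.

Not emulated: ligation-junction and PCR artefacts, undigested or
self-ligated backbone fragments, mappability variation, trans contacts,
and replicate-specific library biases. Passing recovery tests therefore
demonstrates the statistical machinery under the stated noise model, not
robustness to every artefact of real libraries — on real data the
viewpoint-exclusion zone, the blind-fragment filter and the coverage
criterion carry the load those artefacts create.

Problem sizes in tests and the acceptance script (20 simulation seeds for
caller recovery, 10 for enrichment recovery, 200 null runs at 1,000
permutations, 50 calibration seeds) are the package's chosen defaults for
routine verification; all scale linearly if larger designs are wanted.

## Numerical and degenerate-input choices

Zero-variance vectors yield NaN correlations (reported as missing) rather
than errors; a degenerate permutation null (sd = 0) reports p without z;
an all-zero profile refuses to normalize; records falling in invalid
fragments are dropped and counted, not silently discarded; quantile ties
in the coverage criterion pass (≥, not >), which matters when coverage
saturates; isotonic fits are clipped at zero (counts cannot be negative);
merging uses gap ≤ 40 bp ("not more than"), so 41 bp gaps stay separate;
the d = 200 kb and d = 500 kb distance boundaries belong to the medium
class. All coordinates are 0-based half-open; all randomness flows from
one seed through named SeedSequence substreams, making every pipeline run
bit-reproducible.

## Known limitations

- The caller's criteria are thresholds on smoothed values against a
  shared mean-of-replicates background fit; rank-based multi-replicate
  statistics (as in dedicated 4C peak callers) are out of scope.
- Isotonic backgrounds absorb part of very broad enrichment domains,
  biasing their called extent conservatively.
- The enrichment null ignores chromatin accessibility structure: regions
  are re-placed uniformly, not within matched accessible space.
- The promoter annotator knows nothing of UTRs, TTS windows or multi-exon
  structure.
- Oligo p-values ignore occurrence dependence; for highly self-
  overlapping motifs the binomial tail is anticonservative.
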