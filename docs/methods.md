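# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generators, and the numerical and design choices behind
`methylhist`.

## Per-cytosine statistics

For each cytosine the input is (mc, t) per sample: methylated and total
read counts. The methylation level is mc/t, defined as 0 when t = 0; such
sites are retained (they keep the positional structure of the track) but
are inert because every statistic weights them by the coverage weight

    w(t) = 2 / (1 + exp(-t / scale)) - 1,   scale = 10 reads.

w is 0 at zero coverage, ~0.46 at 10×, ~0.91 at 30×, and saturates below 1.
The scale default matches typical WGBS depth: weights discriminate strongly
in the 0–30× range where sampling noise changes fastest.

**Replicated designs.** The group difference at a site is tested by
weighted logistic regression of group label (binary outcome) on methylation
level (continuous predictor), with the coverage weights entering as
observation weights in the log-likelihood. The p-value is the χ²(1) tail of
the deviance difference against the intercept-only model. Numerics:

- the slope carries a ridge penalty λ = 1e-4 (the intercept is free, so the
  null fit stays the exact weighted mean). Perfectly separating sites —
  common at strongly differential cytosines — then converge to finite
  estimates instead of diverging;
- the likelihood-ratio statistic is computed from the *unpenalized*
  log-likelihood at the penalized estimates and clipped at 0. For
  well-conditioned fits the penalty perturbs the statistic only at second
  order (~1e-8); for separated fits it acts as a mild, deterministic
  regularizer;
- damped Newton iterations (cap 50, step cap 10, linear predictor clipped
  at ±35) run vectorized across all sites of a chromosome at once, which is
  what makes genome-scale calling cheap;
- p-values are clipped to [1e-300, 1]. A site where one group has zero
  total weight carries no evidence and returns p = 1 with a warning.

**Single replicates.** With one sample per group the test is the two-sided
two-proportion z-test with pooled variance:
z = (m₁ − m₂)/√(p̂(1 − p̂)(1/t₁ + 1/t₂)), p̂ = (mc₁ + mc₂)/(t₁ + t₂);
degenerate pools (p̂ ∈ {0, 1}) give p = 1. A replicated group paired with a
singleton group falls back to this test on per-group pooled counts, since
the regression's degrees of freedom collapse.

Group mean levels m₁, m₂ are coverage-weighted means of replicate levels,
consistent with the weighted regression.

## Histogram features

Each site's bin value is b = |m₁ − m₂|·e^(1−p) ∈ [0, e]. Per chromosome,
the b track is smoothed by a centered moving average over 3 cytosines
(index-based, not bp-based; the window shrinks symmetrically at chromosome
ends rather than padding with invented data) and then min-max scaled to
[0, 1]; a constant track scales to all-zero. Scaling happens after
smoothing.

For every site, the w surrounding sites (w odd; truncated at chromosome
ends) vote into a 10-bin histogram over [0, 1]: site j contributes
v = 1 − |l_j − l_c|/d to bin min(⌊b_s,j·10⌋, 9) when its distance from the
center is below d, so b_s = 1.0 lands in the top bin and the center site
always votes with weight 1. The tally is normalized to sum to one; a window
with zero total vote returns the all-zero sentinel, which still receives a
(low) calibrated score downstream. Defaults: w = 11 for CG, 51 for CH
(non-CG sites are denser but individually weaker), d = 250 bp,
bins = 10, smoothing span 3. The vectorized window sweep is exactly
equivalent to the per-site definition (tested against a brute-force
oracle).

## Classifier and calibration

Every cytosine inside a labeled region is one training sample. The
classifier is a linear soft-margin SVM (hinge loss, C = 1.0,
class-balanced weights — DMR cytosines are the rarer class in realistic
training data), followed by Platt scaling: a one-dimensional logistic fit
of the training decision values against the labels, giving scores in
(0, 1). Trained models serialize to a versioned JSON file; loading
reproduces scores bitwise at the serialized precision.

Region-level training filters (CG: DMR mean difference > 0.3, non-DMR
< 0.1, lengths 500–2500 bp; CH: > 0.05 / < 0.02, 500–5000 bp) are applied
to candidates before labeling. A region's "average methylation difference"
is computed as |mean over its sites of (m₁ − m₂)| — the difference of the
region's average levels. The signed mean cancels per-site sampling noise;
the mean of per-site absolute differences would be inflated by ~0.1 at 10×
coverage and would make the non-DMR ceiling nearly unsatisfiable.

## DMR assembly

Candidates are sites with score strictly above the cutoff (default 0.1);
consecutive candidates closer than 500 bp (bp distance between candidate
positions) merge into a preliminary region. All sites inside the span —
including sub-threshold ones — are members, because boundary refinement
speaks about consecutive cytosines. Refinement trims each edge inward to
the first/last run of k = 3 consecutive members with raw (pre-smoothing)
bin value b ≥ 0.1; a region with no such run is discarded, so single-site
regions never survive. Refinement can only narrow a region, and raising the
b-threshold yields a nested subset of (possibly further-trimmed) regions.

Reported intervals are 0-based half-open, spanning first to last member
site. Summaries per region: member count, per-group mean levels, mean
per-site |m₁ − m₂|, mean score, and direction (hyper/hypo with respect to
group 1; a zero difference is labeled hyper by convention). The optional
post-filters keep regions with strictly more than `min_sites` members and
region-level delta (|mean m₁ − mean m₂|) strictly above `min_delta`; the
operational choice used for noisy comparisons is min_sites = 5,
min_delta = 0.2.

**Multi-group / time-series.** With n ≥ 3 groups, every one of the C(n, 2)
pairs is scored with the same trained model on a shared master site index;
the final per-site score is the sum of pair scores, and the candidate
cutoff scales to 0.1·C(n, 2) to preserve per-pair semantics. Refinement
uses, per site, the maximum b over pairs (the region should survive if any
pair supports it), which makes multi-group boundaries slightly laxer than
pairwise ones. Output rows carry each pair's mean signed difference and
direction over member sites.

## Synthetic data

**Benchmark generator.** Truth regions (equal numbers of DMRs and
non-DMRs, default lengths uniform in 500–2500 bp) alternate along a single
synthetic chromosome, separated by 1500 bp spacers — three times the
merge gap, so truth regions cannot fuse in a call. Site positions follow
geometric gaps (mean 100 bp, a CG-dyad-like density); coverage is negative
binomial (mean 10, size 5) per site and replicate; methylated counts are
binomial with a per-site, per-replicate beta-distributed success
probability: Beta(6, 1.5) in group 1 vs Beta(1.5, 6) in group 2 inside
DMRs (means 0.8/0.2); background either fixed at 0.7 (class 1) or drawn
independently from Beta(2, 2) per site and replicate (class 2 — high
biological variability within and between groups, which is what makes
class 2 much harder). A flag shares the class-2 background draw across
replicates and groups instead. Truth intervals are recorded as the tight
span of the sites they contain, matching how calls report their bounds, so
overlap evaluation is not biased by site-free flanking sequence. Everything
is reproducible from a single seed.

What this generator does *not* emulate: real coverage profiles and their
genomic covariates, CpG-island clustering of site density, strand-level
counts (sites are emitted as combined CG dyads), chromosome heterogeneity,
and bisulfite conversion error. Passing benchmarks therefore demonstrate
correctness of the method under the stated beta-binomial conditions, not
performance on any particular biological dataset.

**Training-genome generator.** Emulates the construction of training labels
from orthogonal data: candidate DMRs carry graded strong effects (region
delta uniform in 0.5–0.8, per-site beta draws at concentration 7.5 around
levels 0.5 ± delta/2), reflecting that a supervised caller is trained on
high-confidence differential regions; the background mixes quiet
fixed-level segments with beta-noise segments at concentrations 20 and 4,
the noisy majority centered near level 0.5 where beta variance peaks, so
the classifier sees hard negative windows. Spacer segments between
candidates are themselves emitted as non-DMR candidates, putting
DMR-flanking windows among the negatives — analogous to real background
regions adjacent to differential peaks, and important for sharp boundary
behavior. The region-level filters above are then applied verbatim, so
emitted labels satisfy them exactly. During development, a variant with
weak graded effects (0.1–0.7) over a mostly quiet background produced a
classifier whose boundary sat inside the class-2 noise distribution
(class-2 precision ~0.45); the final composition was chosen to cover the
background variability the method is expected to face.

## Evaluation

Reciprocal overlap of two intervals is min(ov/len_a, ov/len_b) — both
intervals must be covered to the stated fraction. TPR at stringency f is
the fraction of truth regions hit by at least one prediction at reciprocal
overlap ≥ f; PPV the fraction of predictions hitting at least one truth
region. Many-to-one matches count once per truth in TPR and once per
fragment in PPV; fragmented predictions are not merged before matching.
PPV is 0 when nothing is predicted. Curves are swept over 50–100% in 5%
steps and are non-increasing by construction. `replicate_study` repeats
simulate→call over consecutive seeds and reports mean ± SD per threshold.
Boundary displacement is counted in cytosine positions between true and
predicted edges, for truths matched at ≥ 50% reciprocal overlap.

## Problem sizes and observed behavior

The shipped tests and the acceptance script run at desk scale: training
genomes of 200 DMR + 300 non-DMR candidates (~23k sites), benchmarks of
100 + 100 regions (~6k sites), and a ~50k-site null genome; the whole
acceptance run takes a few seconds on one CPU because all per-site
statistics and window sweeps are vectorized. Under these conditions the
pipeline typically reaches class-1 TPR/PPV ≈ 0.92–0.97 / 0.90–0.92 at 50%
reciprocal overlap (TPR ≈ 0.8 at 80%), class-2 TPR ≈ 0.90–0.95 with PPV
≈ 0.72–0.83 depending on the training-genome seed, median boundary
displacement 0 sites, at most a couple of null-genome calls after the
strict post-filters, and transfer AUC > 0.99 on a genome with halved site
density and doubled coverage. Class-2 precision is the most seed-sensitive
quantity: its false positives come from chance spatial clusters of large
beta-noise differences, and their rejection depends on exactly where the
trained margin falls.

## Known limitations

- The calibrated score threshold (0.1) and b-threshold (0.1) are tuned for
  the default conditions above; very deep or very shallow coverage shifts the
  background b distribution and may warrant adjusting `b_threshold`.
- The χ²(1) reference for the 6-observation LRT is asymptotic; per-site
  p-values are heuristic evidence weights feeding the feature, not
  calibrated significance calls, and no multiple-testing correction is
  applied or intended.
- Chromosome-wise min-max scaling ties b_s to the strongest site on the
  chromosome; a chromosome with no true signal stretches its noise to
  [0, 1], which is why the strict post-filters matter for null data.
- CH calling shares the CG code path with wider windows; it is exercised by
  the training-filter tests but not benchmarked at CH-realistic densities.
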