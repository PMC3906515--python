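# Methods

## The experimental layout being modeled

Three RNA samples exist: astrocytes cultured alone and then cold-jetted
(AA-CJ), neuron-astrocyte co-culture (CC), and co-culture after cold-jet
removal of neurons (CC-CJ).  Four two-color hybridizations are used, two
per design:

| arrays | Cy5 (red)    | Cy3 (green) | purpose |
|--------|--------------|-------------|---------|
| 1, 2   | AA-CJ        | CC-CJ       | neuron-induced astrocyte regulation |
| 3, 4   | CC           | CC-CJ       | cold-jet depletion / contamination |

CC-CJ is Cy3 in both designs.  M values are oriented per design so that
positive M means "up in the first-named sample": up in CC-CJ (regulation
arrays) or up in CC, i.e. removed by the cold jet (depletion arrays).

## Synthetic data model

Per gene g: astrocyte abundance is lognormal, log2 ~ N(8, 1.5²) in
arbitrary fluorescence units.  Co-cultured astrocytes express
`astro_alone·2^β`, with β = 0 except for the astro_up / astro_down classes,
whose |β| ~ U(0.6, 1.4)·`effect_size_log2` (default 2.5, so |β| ∈ [1.5, 3.5]
— two- to ten-fold changes, the range a threshold-based screen is meant to
catch).  Neuron-enriched genes express in neurons at
`astro·2^enrich`, enrich ~ U(1.2, 2.2)·`effect_size_log2`, and their
astrocyte abundance is drawn from the low tail (log2 shifted by −3.75,
half the spread) — low but not zero, so the efficiency estimator's
background subtraction is exercised.  All other genes get a low neuronal
background (log2 shifted by −4).

Samples are mixed by RNA mass with neuronal fraction c (default 0.4,
a free parameter of the model: the true neuron:astrocyte RNA proportion in
such co-cultures is not known) and removal efficiency r (default 0.9):

    AA    = astro_alone
    CC    = (1−c)·astro_cocultured + c·neuron
    CC-CJ = (1−c)·astro_cocultured + c·(1−r)·neuron

then each sample is rescaled to equal total mass, mimicking the fixed RNA
input of array labeling.  This rescaling is what makes the efficiency
estimator's cross-array background subtraction meaningful.

Measurement: per-probe lognormal affinities (log2 sd 0.25) shared across
arrays — they cancel exactly in M and only spread A; per-channel lognormal
noise (log2 sd 0.2, typical of replicate spot variability on commercial
two-color platforms); per-array channel gains (log2 sd 0.15); and a
polynomial dye bias applied to the red channel, by default quadratic
b(z) = 0.3 − 0.15 z − 0.1 z² on the standardized noise-free A, producing
the curved MA trend that intensity-dependent normalization targets.
Defaults: 10,000 genes × 2 probes (a desk-scale stand-in for a 4x44K
chip), 3% neuron-enriched, 2% astro-up, 1% astro-down genes.

What the generator does **not** emulate: biological replicate variation
(the two replicate arrays share underlying abundances and differ only in
measurement noise), spatial/print-tip artifacts, saturation and censoring,
background fluorescence, and correlated probe failure.  Passing tests
therefore demonstrate correctness of the estimators under a clean
two-color error model, not robustness to every artifact of real scans.

## Normalization

The dye-bias trend is a robust local-linear (tricube, lowess) regression of
M on A with span 0.3 and 3 robustifying reweighting iterations, evaluated
with a 1%-of-range interpolation grid; normalization subtracts the
interpolated trend, leaving A untouched.  Ties in A are ordered by probe id
for reproducibility.  Full OLIN (generalized-cross-validated window widths,
permutation tests) is deliberately not reproduced: the selection criteria —
the computation this package exists for — operate on any debiased M, and
span/iterations are exposed in the configuration.

Two hardening steps protect the fit from regulated probes, which in this
design are *not* symmetric noise: residual neuronal transcripts concentrate
at low A (their astrocyte abundance is low) and can reach ~50% of probes in
the lowest intensity percentiles, enough to locally mask lowess's
residual-based robust weights.

1. **Global pre-trim**: probes with |M − median| > 3 robust SDs
   (MAD·1.4826) are excluded from fitting.  Being global, the cut cannot be
   masked by local contamination.
2. **Iterated reject-and-refit**: after fitting, probes with residuals
   beyond 2 robust SDs are discarded and the trend refit (3 passes).

Both radii are floored at regulation scale (1.0 and 0.1 log2 respectively):
rejection exists to peel off regulated probes, and dye-bias-sized residuals
are never rejected — this keeps the procedure exact on noise-free inputs.
With labels known (fitting on true null probes only) the worst per-decile
null-gene bias is ≈ 0.03; the label-blind procedure achieves ≈ 0.04–0.05,
close to that floor.  At the extreme low-intensity edge a residual few
hundredths of a log2 unit of over-subtraction remains — an inherent limit
of location normalization when one gene class dominates an intensity range.

Between-array scaling divides each array's M by its MAD-based robust scale
and multiplies by the geometric mean of all arrays' scales.  Selection by
mean ± 2·SD is invariant under any common positive rescaling of an array's
M, so the ordering of scaling and thresholding is immaterial; scaling is
kept because it makes reported M magnitudes comparable across arrays.
An array with zero robust scale is left unscaled with a warning.

## Selection

Criterion 1 uses the sample SD (n−1 denominator; immaterial at 20k probes
but fixed for reproducibility) over all retained probes, with inclusive
boundaries.  Criterion 2 intersects per-probe calls across the two
replicate arrays, recording opposite-direction calls as discordant.
Criterion 3 collapses probes to genes: by default a gene survives when its
called probes agree in direction ("unanimity"); a stricter variant
requiring every sibling probe to pass the thresholds itself is selectable.
The gene-level M is the mean over the gene's probes of the replicate-mean M.

Criterion 4 — the contamination filter — has a genuinely ambiguous verbal
form ("only included when downregulation … was less than the mean − 2·SD").
The implemented default removes an up-candidate when its cold-jet depletion
(probe-mean M on the CC vs CC-CJ arrays, positive = higher in CC) reaches
the +2·SD cutoff on **both** contamination arrays, mirroring criterion 2's
both-replicates logic (single-array mode available).  This reading matches
the filter's stated purpose: a transcript that is both "up" in cold-jetted
co-culture versus pure astrocytes *and* strongly depleted by the cold jet
is residual neuronal RNA.  The literal alternate reading (keep only
extreme-depletion candidates) would retain exactly the genes the filter is
meant to discard; it is implemented behind `criterion4_mode="require_extreme"`
for comparison.  Down-regulated candidates are never filtered.  Genes
absent from the contamination arrays cannot be tested and are kept with a
warning.

## Removal efficiency

The estimator follows the fluorescence arithmetic of the depletion design:
for a set of neuron-enriched probes (default: the 40 most cold-jet-depleted),

    residual%_p = 100 · (F_CCCJ,p − F_AA,p) / (F_CC,p − F_AA,p)
    removal%    = 100 − median(residual%)

Residuals are clipped to [0, 100] before summarizing (noise can push
individual probes outside the physical range) and probes whose denominator
falls below a positivity floor are skipped and counted.  The median is the
default summary (mean by flag): it is robust to ratio blow-ups at small
background-subtracted denominators.

Single-channel fluorescence lives on different physical arrays (F_AA on the
red channel of arrays 1–2; F_CC, F_CCCJ on arrays 3–4), so channels are
first made comparable: each channel vector is scaled so its 75th percentile
over *unselected* probes matches the geometric mean across channels, after
correcting the red channel for the fitted dye-bias trend (so corrected
channel ratios reproduce normalized M).  Replicate channels are averaged
per sample.

Ranking probes by observed depletion on the same channels that enter the
residual formula creates a winner's-curse coupling: probes that look most
depleted are partly those whose CC-CJ fluorescence was low by chance, which
deflates the residual (by ≈ 8 percentage points at r = 0.5 in simulation).
The estimator therefore works cross-replicate by default: probes are ranked
on one depletion array and measured on the other array's channels, and the
two folds' per-probe residuals are pooled before taking the median.  With
this scheme the seed-averaged estimate recovers 100·r within ≈ 2.5
percentage points over r ∈ {0.5, 0.7, 0.9, 0.99} at c = 0.4.

## Concordance

Spearman's ρ (average-rank tie handling) between same-sample channels of
replicate arrays, computed on raw, non-normalized fluorescence restricted
to regulated probes (as identified on the regulation arrays).  Constant
vectors yield an undefined ρ, reported as NaN.

## GO overrepresentation

The ontology is read as an `is_a` DAG (obsolete terms dropped; cycles are
an error).  Annotations follow the true-path rule: each gene's term set is
closed over ancestors before testing.  Each term with at least
`min_term_size` (default 3) annotated universe genes is scored with the
one-sided hypergeometric upper tail of its 2×2 table — classic per-term
Fisher, with no DAG decorrelation ("elim"/"weight" style algorithms are an
explicit non-goal).  The default universe is all genes on the chip
(configurable); report tables screen at raw p < 0.005, and an optional
Benjamini–Hochberg column can be emitted as a clearly non-screening extra.

## Numerical and degenerate-input choices

- Intensity floor 1.0 before logs; probes with both channels below it are
  dropped and counted, a single low channel is floored.
- Zero-variance M (constant array) sets a degenerate flag (tolerance
  1e-12 relative to the mean, since float SD of a constant vector is at
  epsilon scale, not zero) and produces no calls.
- Trend fitting requires ≥ 50 probes; fewer is an error advising raw-M
  analysis.
- `rank_top` breaks |M| ties by gene id; trend-fit ties in A by probe id;
  enrichment ties in p by term id — all orderings are deterministic.
- All randomness flows through a single integer seed; identical
  (config, seed) produces byte-identical fixtures.

## Problem sizes used in tests and the reproduction script

The default simulation (10k genes × 2 probes) is the unit at which all
truth-recovery properties are measured; the removal-recovery grid uses
4 r-values × 10 seeds of that size, and the I/O, pipeline and GO tests use
1000–2000-gene experiments.  These sizes give the selection statistics and
the binomial null-calibration bands enough resolution while keeping a full
reproduction run at about half a minute.

## Known limitations

- Replicates share biological truth; concordance numbers are therefore
  optimistic relative to real biological replicates.
- Location normalization cannot fully separate dye bias from real signal
  where neuron-enriched probes dominate an intensity range (see above);
  the residual is a few hundredths of a log2 unit at the low-A edge.
- The contamination fraction c is a model parameter, not an estimated
  quantity; the efficiency estimator recovers r, not c.
- Gene counts from any real re-analysis depend on normalization settings
  not fixed by the selection rules themselves (span, iterations, scaling);
  the threshold criteria are scale-invariant but not smoother-invariant.
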