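# Methods

This note records the statistical model the package implements, the
defaults it ships, what the simulator does and does not emulate, and the
design decisions taken where more than one convention was defensible.

## Quantification model

A qPCR reaction with per-cycle amplification factor *E* turns an initial
template quantity *N₀* into *N₀·E^c* after *c* cycles, so the
quantification cycle satisfies Cq ≈ const − log_E(N₀). Two consequences
drive everything downstream:

* **Calibration.** Regressing Cq on log10 of a dilution series' relative
  input gives slope −1/log10(E), hence E = 10^(−1/slope) and percent
  efficiency (E − 1)·100. A perfect doubler has slope −3.3219; slopes
  slightly steeper than that produce efficiencies a few points above 100%,
  which is ordinary fit noise, not a physical super-doubling. The fit is
  plain OLS (`scipy.stats.linregress`) on all points — replicate Cq values
  are *not* pre-averaged, preserving the series' error structure — with no
  weighting or outlier rejection; r² is the squared Pearson correlation.
* **Relative quantities.** Technical replicates are averaged on the Cq
  scale (where noise is approximately additive; sd uses the n−1
  denominator, and pairs with no non-missing Cq are dropped with a
  warning rather than propagated). The mean Cq then maps to
  Q_s = E^(Cq_min − Cq_s), rescaled so each gene's maximum across samples
  is 1. The anchor cancels in every downstream ratio; translation
  invariance of Q under a constant Cq shift is property-tested. Genes
  without a fitted standard curve default to E = 2 (100% efficiency), a
  documented assumption that can be overridden per gene.

## Stability analysis

Pairwise variation V_jk is the n−1 standard deviation over samples of
log2(Q_j/Q_k); M_j is the mean of V_jk over k ≠ j. Stepwise exclusion
removes the argmax-M gene each round (ties broken lexicographically and
recorded in the report) until two genes remain; at n = 2 the survivors
share a single V and are reported as rank-tied, displayed in lexicographic
order. Log base 2 is used throughout — any fixed base scales all M
proportionally, so the base is recorded in the report.

**Reference selection.** The selected set is the top three genes of the
stability ranking (configurable via `n_select`) whose M in the round where
they were last evaluated is below the threshold (default 0.5); genes at or
above it are dropped with a warning. We deliberately do not select *every*
gene whose last-evaluated M is below threshold: a gene's last evaluation
happens in an ever-smaller panel where M values shrink mechanically (in
its final round a mid-noise gene is compared only against the quiet
survivors), so a "all below-threshold genes" rule would sweep mid-stability
genes into the reference set and defeat the point of the ranking. Fixing
the set size at three and applying the threshold as a veto matches how the
stability workflow is used in practice. The V_{n/n+1} statistic for
choosing the optimal number of references is intentionally out of scope.

The geometric mean defining NF accepts two or more references as intended
usage; a single-gene "NF" is allowed (it reduces exactly to single-gene
normalization, an identity that is tested) but warns, and an empty set is
an error.

## Normalization strategies

`single`, `nf` and `ear` all divide the target's Q by a per-sample
reference value; `ear` is computationally the single-gene path with the
pooled-Alu assay as reference, and the strategy plus reference genes are
recorded in every output row so provenance survives the CSV boundary.
Normalized values are not rescaled to a calibrator sample by default; an
optional flag divides by the cohort median, which centres displays at 1
without changing any between-sample ratio. Strategy comparison reports
Pearson r (two-sided p via the t transform), both medians and per-sample
ratios, and requires at least three shared samples.

## Melt-curve QC

The dissociation trace is differenced by central finite differences on the
interior grid points (no smoothing by default; an optional odd-width
moving average is available for noisy traces — transparency beats
polish for a QC transform). Peaks are local maxima of −dF/dT with
prominence at least 20% of the well's own global maximum, making calls
invariant to plate-level fluorescence gain. Pooled-repeat products
legitimately show several peaks, so the QC rule is replicate concordance:
every replicate pair of a sample must have the same peak count with
matched peaks (temperature-sorted positional pairing) within 0.5 °C;
a single replicate is "indeterminate", not a pass. The expected
pooled-assay peak position ships as an editable default of 88.69 °C.

## In-silico PCR

The forward primer is matched on the plus strand and the reverse primer as
its reverse complement downstream; the product spans the forward site's
first base through the reverse site's last base, reported 1-based
inclusive. Matching is exact by default; with a mismatch budget,
mismatches are never accepted in the 3′-terminal three bases of either
primer (polymerase extension requires a matched 3′ end), and IUPAC codes
in primers match their degenerate sets. All forward/reverse pairings with
non-overlapping sites within the product-size cap (default 2000 bp) are
reported sorted by start; panel validation passes a pair only on exactly
one hit of the expected length, flagging multiple hits as ambiguous.
Templates are transcripts, so only the plus strand is searched unless the
genomic both-strand flag is set. Thermodynamic Tm prediction and
genome-scale repeat annotation are out of scope.

## Statistics

* **Pearson r** delegates to `scipy.stats.pearsonr` (two-sided p from the
  t transform); zero-variance input is an error, not r = NaN.
* **Mann-Whitney U** is exact for tie-free samples with n1 + n2 ≤ 16: the
  two-sided p is P(|U − n1·n2/2| ≥ |u_obs − n1·n2/2|) under full
  enumeration of the C(n1+n2, n1) rank assignments. Ties or larger samples
  switch to the normal approximation with tie and continuity corrections
  (via scipy), and the result records which path ran. The cutoff balances
  enumeration cost (C(16,8) = 12 870) against the quality of the
  approximation; tests cross-check the exact path against both a
  brute-force oracle and scipy's independent exact implementation.
* **Box summaries** use linear-interpolation (type-7) percentiles — no
  convention was mandated, so the choice is recorded here and in the
  dataclass docstring — with 10th/90th-percentile whiskers reported only
  for n ≥ 10, matching the plotting convention for small expression
  cohorts.

## The simulator

`simulate_experiment` encodes the multiplicative-biology / additive-cycle
error structure qPCR assumes: per-gene biology and per-sample loading are
Gaussian on the log2 quantity scale; technical error is Gaussian on the Cq
scale per well. The defaults define the study conditions used throughout
the tests:

| parameter | default | meaning |
| --- | --- | --- |
| n_samples | 10 | cohort size (small human cohort) |
| gene panel | 6 refs + BDNF | bio sd 0.05/0.05/0.05 (GNB2L1, HPRT1, YWHAZ), 0.3 (B2M), 0.4 (GAPDH), 0.5 (ACTB); target BDNF sd 0.5 |
| loading_sd_log2 | 0.5 | per-sample cDNA input spread (~1.4-fold) |
| technical_sd_cq | 0.1 | per-well Cq noise, cycles |
| rt × pcr replicates | 2 × 3 | six independent measurements per pair |
| ear_components | 500 | pooled Alu-bearing transcripts |
| ear_component_sd_log2 | 0.3 | per-transcript biological noise |
| amplification_factor | 2.0 | simulation truth; quantification default |
| baseline_cq | 34 | anchors typical Cq to ~18–35 (cancels downstream) |

The EAR signal is the *sum* of the component transcripts' quantities
(baseline abundances drawn once per transcriptome, per-sample noise per
component), so its log2 sd shrinks roughly as 1/√n_components; with 500
components it sits well under 0.3× the median reference-gene sd, the
quantitative form of the pooling argument. The target gene carries
ordinary between-subject biological variability (sd 0.5) but no
dysregulation by default: "constant expression" here means constant in
expectation, not zero variance — with a literally zero-variance target,
any two normalized series would be pure technical noise and their
correlation uninformative about normalization quality. The loading-removal
property is instead tested with a dedicated zero-variance target, where a
CV comparison is well posed.

What the simulator does **not** emulate: correlated regulation between
reference genes (all biological noise is independent, which flatters M
slightly), amplification inhibitors, inter-plate effects and calibrators,
RT-step biases shared within an RT replicate, non-Gaussian outliers, and
sequence-level Alu subfamily structure (the pooled-quantity model stands
in for repeat biology). Passing tests therefore demonstrate correctness of
the algorithms under the stated error model, not robustness to every
artefact of bench data.

`simulate_dilution_series` and `simulate_melt` follow the same pattern
(pure functions of their arguments and a seed); melt components are
logistic decays, so −dF/dT peaks exactly at each component's Tm with
height weight/(4·width).

## Problem sizes

Stochastic properties are checked at 100 seeds of the default ten-sample
configuration (stability recovery, EAR pooling, CV reduction, slope
recovery), 200 random matrices for the stability oracle, and ≤ 10
combined observations for exhaustive Mann-Whitney enumeration; the whole
suite runs in well under a minute on one core.

## Known limitations

* Stability analysis assumes all quantities positive and present; samples
  missing any panel gene must be dropped before ranking.
* The exact Mann-Whitney path requires tie-free data; heavily tied small
  samples get the corrected approximation, which is conservative there.
* Amplicon prediction validates primer placement and product length only;
  it says nothing about secondary structure, dimers or Tm.
* The melt peak matcher pairs peaks positionally after sorting; pathological
  cases (two peaks closer than the tolerance) can pass concordance while
  being biologically distinct products.
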