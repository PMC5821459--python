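# Methods

This note documents the statistical models behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Input model and filtering

The universal input is a quantified protein-group table: one row per group
with a gene symbol, an unnormalized heavy/light SILAC ratio *r*, a
razor+unique peptide count, and "+"-convention contaminant and
reverse-decoy flags.  Filtering removes contaminants, decoys, rows with
fewer than 2 razor+unique peptides (configurable), and rows without a
usable ratio; each removal is logged under exactly one reason, so the
reasons partition the removed set.  Ratios of 0 or ∞ (one-label-only
detections) are treated as missing rather than mapped to fractions 0/1,
which would otherwise dominate every distance computation downstream;
they are logged at parse time.  Ambiguous groups ("A;B;C") are collapsed
to the first symbol with the full membership preserved in a side column;
duplicate symbols within one file keep the record with the most
razor+unique peptides (ties: first occurrence), logged.

The heavy fraction *h = r/(1+r)* is a bijection (0,∞)→(0,1); the condition
fraction resolves the label-swap orientation (*h* if the condition was
heavy-labelled in that mixture, 1−*h* otherwise), so the two conditions'
fractions sum to exactly 1 by construction.  Proteins quantified in only
one of the two swapped mixtures have no defined 2-D coordinate; they are
excluded from the merged coordinates and listed in a drop log.

## RNase-sensitivity radial statistic

Coordinates are translated so the unchanged population sits at the origin.
The default center estimator is the component-wise median: the sensitive
proteins are a displaced minority, and the median resists them without any
tuning; mean and KDE-mode estimators are selectable.  With radial
distances *d_i*, the conventional threshold fits a normal to the distance
distribution, τ = μ + z(α)·σ with α = 10⁻³, and flags proteins strictly
outside the circle (a point exactly on the circle is not flagged).

That normal fit is a display convention, not a calibrated test: if the
null scatter is isotropic Gaussian with per-axis SD *s*, the distances are
Rayleigh(*s*), and the normal τ = (1.2533 + 3.0902·0.6551)·s ≈ 3.28·s
carries true tail mass exp(−3.28²/2) ≈ 4.6×10⁻³ — 4.6-fold anti-
conservative at nominal 10⁻³.  The package therefore also provides
`law="rayleigh"` (scale MLE σ̂ = √(mean d²/2), τ = σ̂·√(−2 ln α)), which is
exact under the isotropic null, and a half-normal option.  The normal law
remains the default for fidelity to the conventional presentation; all
calibration claims in the test suite are made for the Rayleigh law, the
only law for which they are well-posed.  Per-protein nominal p-values use
the upper tail of whichever law is selected.

An optional direction filter restricts flags to the quadrant of control
(BSA) enrichment on both swap axes; it is off by default, since the
conventional presentation marks every point outside the circle.

The relative sensitivity of two proteins is reported under three candidate
conventions (ratio of radial distances, or of either single axis), because
the choice is not uniquely determined by the quantity itself.

## Split-tandem anchor normalization and cluster proximity

Per swap axis, elution fractions are mapped by the affine
*f(v) = a·v + b* solving *f(v_anchor) = 1* and *f(m) = m* (*m* the axis
median): *a = (1−m)/(v_anchor−m)*, *b = m(1−a)*.  The map is computed in
the centered form *a·(v−m) + m*, which is exact at the median and
well-conditioned; anchors within 10⁻³ of the median are rejected as
degenerate (the map's slope diverges and the normalization is
meaningless there).  Affine maps preserve ratios of differences, so
cluster-tightness rankings are unchanged whenever the two axes share a
common scale.

Cluster proximity π of a k-protein set defaults to the diameter (maximum
pairwise Euclidean distance) — the most conservative tightness measure and
directly interpretable on the coordinate scale; mean pairwise distance and
smallest-enclosing-circle radius are selectable and recorded in output.
The empirical probability is the fraction of all C(n, k) k-subsets of the
plotted proteins with π ≤ π_observed (inclusive ties — conservative; the
observed subset counts itself, so p ≥ 1/C(n, k)).  Exact enumeration is
used up to a configurable subset cap (default 10⁸, enumerated in
vectorized chunks); beyond it, uniform Monte-Carlo sampling with the
add-one rule p = (1+hits)/(1+samples) and a recorded seed.  The candidate
universe defaults to all plotted (post-filter, both-swap) proteins, and
probabilities may be computed on raw or anchor-normalized coordinates;
the pipeline records which was used (normalized by default).

## Catalytic-mutant shift tests

Each replicate mixes light-labelled mutant capture against heavy-labelled
wild type, so *h* reads as relative retention by wild type.  Replicates
are aligned by the bait: h′ = h − (h_bait − 0.5), an exact translation
that preserves all pairwise differences and pins the bait at 0.5.  Values
that leave [0,1] after shifting are logged but used unclipped — clipping
would bias the per-protein means that the tests consume.  Tests run on the
shifted-fraction scale (one-sample t against 0.5 per protein within each
mutant; Welch between mutants, pooled-variance optional), with BH
correction over the family of proteins present in ≥2 replicates;
zero-variance proteins are flagged degenerate and excluded from the BH
family rather than given artificial p-values.  Recovery folds
v_i = r_bait/r_i (bait ≡ 1, scale-invariant within a replicate) are for
display: aligned histograms with bin edges anchored at 0 (width 2 by
default) and a "crisscross" count of proteins whose EN and RT positions
fall on opposite sides of the bait.

## Exchange kinetics

Heavy-fraction trajectories at t = {0, 30, 300, 1800} s (t = 0 is the
untreated capture) are compared by cosine distance, which is invariant to
uniform rescaling of a trajectory — clusters therefore reflect decay
*shape*, not amplitude.  Only proteins quantified at every time point
enter (dropped rows are logged); all-zero trajectories are excluded since
cosine distance is undefined for them.  Hierarchical clustering (average
linkage) is cut into k = 3 classes by default, renumbered by decreasing
mean terminal heavy fraction so class 1 is the most stable.  The
time-resolved pair distance is implemented as cumulative-prefix cosine
distances (prefix t₁..t_j, j ≥ 2); per-interval and distance-to-reference
readings are plausible alternatives, so the construction is named in the
output metadata.

## Multi-assay integration

Each experiment contributes a per-protein profile vector (replicate or
time-point values).  For a protein pair, the experiments containing both
are concatenated and Euclidean and cosine distances taken on the
concatenation; pairs sharing no experiment are flagged missing.  Observed
Euclidean distances are min-max rescaled onto [δ, 0.9] with δ = 10⁻³ — the
open lower endpoint of the (0, 0.9) target range must be realized by a
positive number for the subsequent log to be finite; δ is configurable and
recorded.  Missing pairs receive Euclidean component exactly 1 and cosine
component 1 (the cosine value for such pairs is otherwise undefined; 1
places them at the far end of the scale, and the choice is recorded in
output metadata).  The fused distance is log(E′·max(C, δ)), min-max
rescaled onto [0,1]; log and min-max are monotone, so the fused distance
is a rank-preserving transform of the product E′·C.  Experiment columns
are z-scored within each experiment before distances by default, keeping
heterogeneous assay scales commensurate; a raw mode is available.
Clustering is hierarchical (average linkage), cut to k = 5 groups by
default.

## Nuclei-pair spatial resampling

Within each microscope field the marker-positive nuclei are paired by
mutual nearest neighbours (each reciprocal pair contributes one distance);
all-pairs and greedy-closest-pair rules are available and the rule used is
recorded.  Fields with fewer than two positives are skipped and logged.
The null resamples, per field and per round (default 1000 rounds), x
nuclei uniformly without replacement from all nuclei in that field (x =
that field's positive count) and applies the same pairing rule; distances
pool across fields and rounds.  Per-pair empirical p-values use the
add-one rule (never exactly 0) with a Bonferroni factor defaulting to the
number of observed pairs; the pooled observed and null distributions are
compared by Welch's t-test.  Fields are treated as observed windows
exactly as given — no edge correction.

## Synthetic-data generator

The generator emulates the data structure every stage consumes, with
planted truth returned alongside:

- **Swap experiments**: per-protein true condition fractions perturbed by
  logit-normal noise independently per mixture (noise on the logit scale
  keeps fractions inside (0,1); the default SD of 0.15 logits ≈ 0.037 on
  the fraction scale at h = 0.5, a typical replicate spread for
  well-quantified SILAC ratios).  Ratios are emitted on the H/L scale
  consistent with each mixture's label design; 5 contaminant, 5 reverse
  and 5 one-peptide decoy rows are injected per table.
- **Planted cast**: a 7-member cytoplasmic RNP module (bait ORF2p, ORF1p,
  MOV10, UPF1, ZCCHC3, PABPC1/4) and a 16-member nuclear module whose
  first three members (PURA/PURB/PCNA) form a tight co-partitioning triple
  (a shared noise draw per mixture plus 0.02-logit individual jitter).
  True elution fractions mirror the biological setting: ORF1p 0.95 (the
  anchor), ORF2p 0.26, UPF1 0.55, PCNA 0.13.  RNase displacement defaults
  to 0.20 radially toward BSA, with UPF1 planted at 62% of the
  ORF1/MOV10/ZCCHC3 sensitivity; the sensitive set and per-protein scales
  are overridable for calibration studies.
- **Mutant experiments**: class-specific signed shifts of ±0.15 around
  0.5 (cytoplasmic down in EN⁻ and up in RT⁻; nuclear the reverse), 0.05
  fraction-scale replicate noise, and a uniform ±0.08 replicate-level bait
  offset that exercises the shift normalization; the bait itself sits at
  exactly 0.5 + offset.
- **Time courses**: h(t) = (1−b)·e^(−kt) + b with three planted classes
  (k = 10⁻⁴/10⁻³/10⁻² s⁻¹, b = 0.20/0.10/0.05, 10 proteins each) and
  0.02 truncated-normal noise; h(0) = 1 noiselessly (fully heavy at
  capture).
- **Nuclei fields**: spatial Poisson nuclei (default 10⁻⁴ nuclei/µm² over
  500×500 µm fields — mean nearest-neighbour spacing 0.5/√λ = 50 µm);
  positives flagged independently (null mode) or planted as pairs at a
  stated displacement (post-mitotic daughter nuclei, default 10 µm).

What the generator does *not* emulate: peptide-level quantification noise,
ratio-intensity dependence, shared-peptide group ambiguity beyond the
symbol convention, spatial inhomogeneity of nuclei within a field, and
any between-assay correlation beyond the planted module structure.
Passing tests therefore demonstrate that the statistics behave correctly
under the stated noise models and recover effects of the stated sizes —
not that real acquisitions meet those models.

All generators are pure functions of (design, seed); identical inputs give
byte-identical outputs, and the pipeline manifest hashes every artifact so
end-to-end determinism is checkable.

## Problem sizes and numerical choices

Calibration and recovery studies in the test suite and acceptance script
use sizes chosen so each completes in seconds while keeping Monte-Carlo
error well inside the margins being asserted: 5000-protein null swap
experiments for type-I calibration (binomial 99% band), 20-protein planted
modules for recovery, 200 null / 100 planted simulations at 200 resampling
rounds for the nuclei test, and 10⁵ samples for Monte-Carlo proximity
probabilities (4 binomial SDs agreement with exact enumeration).
Hierarchical clustering delegates to scipy's deterministic agglomeration;
with average linkage on continuous data, exact distance ties are
measure-zero, and determinism across runs is asserted by test.  Proximity
tie comparison is inclusive with a 10⁻¹² absolute guard; the boundary of
the radial significance circle is exclusive.  Welch degrees of freedom are
computed on max-normalized variance weights, which is scale-invariant and
immune to underflow for extreme variance magnitudes.

## Known limitations

- The cluster-proximity metric is not uniquely determined by the
  scientific question; the diameter default is one defensible choice among
  several, all of which are implemented and recorded in output, and
  different metrics can rank borderline clusters differently.
- The time-resolved pair-distance construction (cumulative prefix) is one
  of several readings, flagged in metadata.
- The nuclei test treats "1000" as resampling rounds and pools distances
  across fields before the Welch comparison; per-field testing is not
  implemented.
- Analysis of externally deposited proteomics datasets requires those
  tables to be supplied as input; the package reads the standard
  protein-group table dialect but never downloads anything.
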