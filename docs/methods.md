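# Methods

This note documents the statistical models, conventions, and design
choices behind the package, and what the synthetic-data generator does and
does not emulate.

## Study design being emulated

The analysis chain targets a multi-organ hyperthermia design: conscious
rats heated to a maximal core temperature of 41.8 °C (T_c,Max), sampled at
T_c,Max and after 24 h and 48 h of recovery, six heated and six
time-matched control animals per time point, four organs (heart, liver,
lung, kidney) profiled by expression arrays, and heart tissue additionally
profiled by 8-plex iTRAQ shotgun proteomics. At 48 h a subgroup of heated
animals (half, by default) carries histopathological cardiac injury; that
binary label is an *input* to the analysis, not something the package
infers.

## Differential expression

Modeling is on log2 intensities. An optional additive offset (default 16)
can be applied to linear intensities first as a variance-stabilizing
transform for near-zero values. The non-specific pre-filter ranks features
by their variance over all of an organ's samples, computed by default on
the log2 scale so that the ranking reflects relative change rather than
baseline magnitude, and keeps the upper half (ties at the median are
kept).

Per feature, a two-factor cell-means model (arm × time with interaction)
is fitted over all of the organ's samples; the residual variance is pooled
across the six cells. The reported p-value is the t-test of the
heat-vs-control contrast at the requested time point with N − (number of
cells) degrees of freedom; with a single time point this reduces exactly
to the pooled-variance two-sample t-test, which the tests verify. The
contrast structure (per-time heat effect within a full interaction model)
is this package's choice — differential calls are reported per time point,
so a time-specific contrast is the natural reading of a two-way ANOVA per
organ. Whether multiplicity correction should pool across time points is
genuinely open; it is applied per organ-time contrast here.

Fold change is the ratio of geometric group means (the exponentiated log2
least-squares mean difference), reported in the signed-ratio convention
(r ≥ 1 as +r, r < 1 as −1/r, so |FC| ≥ 1 always). The significance rule is
|FC| ≥ 2 (boundary inclusive, reading "two-fold cutoff" as ≥) AND
Benjamini–Hochberg q < 0.05 (strict). Features with zero pooled residual
variance are flagged degenerate and given p = 0 (means differ) or p = 1
(means equal) rather than dropped, so noiseless synthetic constructions
remain exact. The consensus set at a time point is the plain intersection
of per-organ significant feature sets.

`benjamini_hochberg` implements the step-up rule directly
(q_(i) = min_{j≥i} p_(j)·n/j on sorted p, mapped back, clipped to [0,1]);
the test suite checks it against an O(n²) literal implementation and
against statsmodels.

## Self-organizing map and injury anchoring

Transcripts are the mapped observations; the animals (samples) of the
chosen organ/time are the dimensions, so a node collects genes with a
shared across-animal pattern. Profiles are z-scored per feature before
training so codebook distances are comparable across expression
magnitudes. Training is classical online Kohonen: codebook initialized
from randomly drawn input rows, per-epoch shuffled presentation,
best-matching-unit update with a Gaussian grid neighborhood, learning rate
and radius decaying exponentially (defaults: 4×4 grid, 200 epochs, initial
rate 0.5, initial radius = half the larger grid dimension, three
e-foldings of decay). All of these are configurable because the original
software's settings are not published; node counts from any particular
tool are therefore a qualitative, not exact, reference point. Assignment
is nearest-prototype in Euclidean distance with ties broken toward the
lowest node index.

Anchoring operationalizes "nodes common to the injured animals" as a
separation score: per node, the mean over member features of (mean z in
injured samples − mean z in uninjured samples). Nodes with |s| ≥ 1 (one
SD, configurable) are reported with direction sign(s). On synthetic data
the planted up/down injury nodes are recovered completely; a small
fraction of null features co-clusters into anchored nodes because
unit-variance noise patterns occasionally resemble the injury pattern —
the tests bound this contamination rather than pretending it is zero.

## Over-representation analysis

Given query Q ⊆ background B and a GMT collection, each term's membership
is intersected with B (size K), the overlap with Q is k, and
p = P(X ≥ k) for X hypergeometric(N = |B|, K, n = |Q|), computed with
scipy and verified against exhaustive enumeration in the tests. The
enrichment score is pinned to fold enrichment ES = (k/n)/(K/N) and labeled
as such in outputs, since "enrichment score" semantics differ between
tools. Reporting filters are the conjunction K < 500 (strict), k ≥ 4,
ES > 2 (strict), p < 0.05 (strict). The background defaults, in the
pipeline, to the features surviving the variance filter for the organ.

## iTRAQ quantitation

Isotope-impurity correction solves observed = Cᵀ·true per row for a
user-supplied square correction matrix C (rows: true channel; columns:
observed channel; row sums ≤ 1.05); negative solutions are clamped to
zero and flagged. Median normalization proceeds in two stages: within
each run every channel is scaled so its median equals the run's grand
median (defined as the median of its channel medians, which makes the
transform exactly idempotent), then runs are scaled to a common global
median and the result is expressed relative to it, so every output
channel median is exactly 1 and the transform is invariant to globally
rescaling the input. Units are therefore "relative to the global median";
all downstream use is ratio-based. Median normalization assumes the bulk
of the proteome is unchanged — with a large changed fraction or a small
(≲200-protein) proteome whose intensities span several decades, the
channel median becomes a chunky order statistic and can shift ratios by
several percent, which matters near the ±1.1 boundary. The synthetic
study conditions use ≥300 proteins with a changed minority for this
reason.

Rollup: per peptide observation, channel ratios against the designated
reference channel; per protein and channel, the median over peptide
observations, with the reference ratio exactly 1 by construction.
Differential proteins satisfy |FC| ≥ 1.3 (boundary inclusive) against
either the pooled reference channel or a designated time-matched control
channel — both comparisons are supported since the original convention is
not stated. Scaffold-style identification-probability filters (peptide
≥ 0.95, protein ≥ 0.99 with ≥ 2 peptides) are applied to provided
probability columns when present; probability computation itself is
upstream of this package.

Top3 abundance: per (protein, peptide), the maximum precursor intensity
within each fraction (repeated reports, e.g. extra charge states, are
redundant) is kept and summed across fractions; a protein's abundance is
the sum of its three largest peptide totals, and proteins with fewer than
three distinct peptides are omitted. "Top three most abundant peptide
ions" is read as top three peptides after this aggregation, consistent
with the per-peptide max/sum rules.

## Calibration and supersaturation

Concentrations come from ordinary least squares on
(log10 Top3 intensity, log10 known concentration) over calibrant proteins
(≥ 3 required; a Theil–Sen robust option exists but OLS is the tested
default, as the original fit form is unstated). The calibrant table is a
required input — the literature concentrations of the seven human
homologs are not bundled. σ_raw = Z_agg + log10 c, with the log base
pinned to 10 following the supersaturation literature (configurable for
sensitivity analysis); σ_f subtracts the median σ_raw over all detected
proteins, so median(σ_f) = 0 exactly in every run. Both the unfolded
(Z_agg) and native-state (Z^SC_agg) propensity variants are accepted as
tagged inputs with identical arithmetic; computing propensity from
sequence is out of scope — scores are consumed as supplied. Group labels:
changed ⇔ |FC| ≥ 1.3, unchanged ⇔ |FC| ≤ 1.1, and the (1.1, 1.3) gap is
an explicit "excluded" group rather than silently dropped. Group
contrasts use one-way ANOVA (F clamped at 0 against roundoff) with
Bonferroni-adjusted pairwise pooled-variance t-tests; with two groups
F = t² exactly.

## Concordance

Proteins map to gene symbols through a user-supplied two-column table
(case-insensitive); multiple probes per gene collapse to the probe of
maximal |FC|, and multiple proteins per gene each emit their own pair.
Categories: both significant (|protein FC| ≥ 1.3 and |gene FC| ≥ 2);
protein significant with mapped sub-threshold gene; significant gene with
no significant protein partner; significant protein with no mapping.
Sub-threshold proteins are never emitted on their own, mirroring the
quadrant-plot semantics. Subcellular localization is a pass-through
annotation column when provided, never computed.

## Synthetic-data generator

Expression: each feature gets a per-organ baseline log2 level
~ N(8, 1.5²); every sample adds independent N(0, noise_sd²) log2 noise
and the planted effects — consensus fold changes for heated samples at
the first time point, ±2 log2 units for the injury nodes in injured
heated animals at the last time point — and values are exponentiated to
the linear scale. Defaults: 4 organs × 3 time points × 6 animals per arm,
half of the heated 48 h animals injured (sampled without replacement;
controls are never injured — the occasional injured control seen in real
cohorts is noted but not emulated). Consensus effects are drawn
log-uniform between 2^1.2 and 2^4.5 (≈2.3- to 23-fold): the planted set
must consist of genuine all-organ ≥2-fold responders, so the draw stays
clear of the calling boundary; the upper range matches the bulk of
heat-shock/apoptosis-regulation effect sizes, with the most extreme
published inductions (50–200-fold) not represented by default. The array
noise magnitude of the original study is unknown; noise_sd (default 0.1
log2 units) is an exposed parameter, not a claim about the study.

Proteomics: true concentrations are log-uniform over 1e−9..1e−4 M;
each peptide has a fixed log-normal response factor (SD 0.5 by default)
shared across channels, making Top3 a meaningful relative estimator.
Chromatographic fractionation splits a peptide's base intensity over 1–3
fractions with Dirichlet weights summing to one, and a second charge
state within a fraction is a redundant report at reduced intensity, so
the fraction-max/sum rule recovers the base intensity exactly at zero
noise and the noiseless Top3 rank order equals the concentration rank
order. Reporter channels encode per-condition ratios; changed proteins
alternate up/down at 2-fold by default and carry Z_agg ~ N(δ, 1) versus
N(0, 1) for unchanged, planting a supersaturation gap of known size δ.
The seven calibrants take their true concentrations as "known" and are
kept out of the changed group so calibration is stable.

What the generator does *not* emulate: probe-level array artifacts,
cross-array batch effects, correlated gene modules outside the planted
sets, missing peptides, ratio compression from co-isolation, peptide
misidentification, or multiple acquisition runs by default. Passing tests
therefore demonstrate correctness of the analysis arithmetic and
calibrated behavior under idealized noise, not robustness to every real
microarray/MS artifact.

## Problem sizes and numerics

The test suite and the acceptance script use desk-scale problems chosen
to keep planted-signal inference well-posed: 1000 transcripts (78-gene
consensus, 100-gene injury nodes) per expression study, 200–600-protein
proteomes, 10–50 replicate seeds per Monte-Carlo check. Determinism is
seed-driven throughout (`numpy.random.default_rng`); identical
configuration and seed reproduce outputs byte-for-byte, which the
pipeline tests assert. Degenerate inputs (zero variance, zero reference
channel, empty groups, singular correction matrices) raise typed errors
or are flagged rather than silently propagating NaNs.

## Known limitations

- The two printed summary-table fixtures are transcriptions; one
  transcript identifier is truncated in the available source text and was
  completed from the table's consistent 8-digit pattern.
- Absolute σ_f values depend entirely on the user-supplied calibrant
  concentrations and propensity scores; only relative contrasts are
  meaningful within a run.
- The SOM anchoring threshold (1 SD) is a heuristic; node membership near
  the threshold is sensitive to training stochasticity across seeds.
- Printed organism-level result counts from the original deposited
  datasets (per-organ DE counts, SOM node sizes, supplementary protein
  counts) require those deposits and are not reproduced here.
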