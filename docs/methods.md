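# Methods

This note documents the analysis pipeline, the synthetic data model behind
its validation, the defaults and the numerical choices. Units are seconds
and centimetres throughout; all timestamps are session-relative.

## Position preprocessing

The 2-D tracking cloud is projected onto its first principal axis and
min–max scaled so the observed extremes map to [0, L] (L = 170 cm by
default); orientation is fixed so the first half-track excursion runs low to
high. Instantaneous speed is the magnitude of the central-difference
velocity (one-sided at the trace ends), smoothed with a Hamming window of
0.3 s (unit-sum kernel, renormalised at the edges so a constant speed is
preserved exactly). Analysis samples must exceed 3 cm/s (strict) and lie
within [9, L − 9] cm (inclusive): the reward zones at both ends are excluded
to keep consummatory behaviour and rest-associated activity (e.g.
sharp-wave-ripple bursts) out of the rate maps.

Laps are segmented by reward-margin crossings: a lap runs from leaving one
9 cm end zone to entering the opposite one, so lap geometry and the analysis
mask share one definition of "track end". Excursions that return to the same
zone (mid-track turn-arounds) are discarded from the lap list but their
samples may still enter directional occupancy via the instantaneous movement
direction — rate maps are filtered by speed and zone, not by lap
completeness; laps matter only for trial-resolved statistics. The track is
binned at 3 cm into ⌈L/3⌉ half-open bins (the last closed), 57 bins at
170 cm.

## Single-cell metrics

Occupancy per bin and direction is the summed dwell time (half the span
between neighbouring samples) of mask-passing samples. Spikes are placed at
the linearly interpolated track coordinate at their timestamp; the nearest
position sample decides mask and direction membership. Bins never visited
get rate 0 and a flag (not NaN), and are excluded from spatial information.

- **Pyramidal screen.** Units are kept when their mean rate pooled across
  both sessions of a day lies in the closed band [0.1, 6] Hz. Refractory
  period and cluster-stability checks belong to spike sorting, upstream of
  this package.
- **Spatial information** uses the standard per-spike form
  SI = Σ P_i (R_i/R̄) log₂(R_i/R̄) on *unsmoothed* profiles. A first-order
  finite-sampling correction — subtracting (m − 1)/(2 N ln 2) with m occupied
  bins and N spikes — is available behind `bias_correction=True`; the default
  is the uncorrected form. Per cell, the session-level SI is the larger of
  the two directional values.
- **Place-field size** is the length of the maximal contiguous run of bins
  at or above 20% of the peak rate that contains the global peak bin
  (whole bins; the default resolution is therefore 3 cm). An interpolated
  variant refines the two borders by the sub-bin crossing of the 20% level.
  On 3 cm bins the whole-bin width of a noiseless σ = 9 cm Gaussian field
  quantises to 30–33 cm around the analytic 2σ√(2 ln 5) = 32.3 cm; with
  realistic spike counts (20 laps) sampling noise at the field borders
  narrows the measured width by roughly one further bin, so cohort medians
  sit at the lower edge of the analytic band.
- **Overlap index.** Each directional profile is area-normalised to sum to
  the bin count, and OI = 2 Σ min(P̂ᴿ, P̂ᴸ)/Σ(P̂ᴿ + P̂ᴸ), which reduces to
  Σ min/N_bins: 1 for identical profiles, 0 for disjoint supports,
  symmetric, scale-invariant in each argument.
- **Classification.** A direction is *valid* when its peak is ≥ 1.2 Hz and
  the peak bin lies outside the reward margins. Two valid directions →
  bidirectional (OBC if OI > 0.4, else NOBC); exactly one → UC; otherwise
  NCC (including the case where every supra-threshold peak sits inside a
  reward zone). The mixed case — both directions supra-threshold but one
  peaked inside the margin — counts the margin-peaked direction as invalid
  and classifies UC; this case is not pinned by any published rule and the
  choice is recorded here. For two-category summaries NOBC merges into UC
  (its prominent field is effectively one-directional).
- **Directionality index.** DI = |r_A − r_B|/(r_A + r_B) from the two mean
  lap rates of one trial; a trial pairs consecutive opposite-direction laps
  in temporal order (an odd trailing lap is dropped). Population values are
  the mean over cells with defined DI per trial; first-three/last-three trial
  averages summarise within-session growth. Lap rates use the whole lap
  interval (spikes/duration) — the lap itself is already restricted to
  traversal behaviour.
- **Centre of mass** is rate-weighted over the full profile with bin centres
  (i + 0.5)·3 cm; the COM distance between the directions is a field-size-
  independent measure of directional separation.
- **Normalised firing rate** divides a cell's per-lap rates by its maximum
  over all laps of both sessions, making rate time courses comparable across
  cells and run counts.

## Population-vector analysis

Profiles are smoothed with a 6 cm Gaussian (kernel truncated at 4σ,
edge-renormalised) and peak-normalised — this smoothing exists only here —
then stacked into an (n_bins × n_cells) matrix per direction. Cells silent
in a direction keep an all-zero column so cell ordering stays aligned.
Entry (i, j) of the cross-direction matrix Pearson-correlates bin i's
population vector in one direction with bin j's in the other; zero-variance
bin vectors give missing entries, excluded pairwise. The scalar summary is
the maximum over positional offsets of the mean along the diagonal band at
that offset ("averaged off-diagonal areas"); bands shorter than 5 entries
are ignored so a single corner coefficient cannot win the maximum. A
row-max-mean alternative (`method="rowmax"`) is provided for sensitivity
analysis. Identical directional codes score 1 at offset 0; orthogonal codes
score near the correlation noise floor (≈ 1/√n_cells).

## Bootstrap schemes and conventional statistics

All schemes use 10000 resamples by default, strict exceedance counting
(ties are non-exceeding, so complete separation reports p = 0) and report a
(k+1)/(n+1)-corrected p alongside the raw proportion. Every result is
bit-reproducible under a seed.

1. **Between-group**: resample one group's per-cell metric with replacement
   at full size; p = proportion of resample means strictly beyond the fixed
   reference (the other group's mean) in the stated direction.
2. **Within-group, subsampled**: resample both conditions down to a common
   cell count (typically the smaller group's); p = proportion of mean
   differences (novel − familiar) beyond zero in the stated direction.
3. **Proportion**: resample a class-label list; the category count of such
   a resample is exactly Binomial(n, p̂), so resampled fractions are drawn
   from that distribution directly.

Calibration note: scheme 1 (and 3) is referenced to a *fixed* value. Its
p-value is uniform under the null only when that reference is the null
population value; refereeing against another finite random sample inflates
the variance of the comparison (the p becomes Φ of a variance-2 normal
score) and is not a calibrated test by construction. The validation suite
therefore drives the null calibration with the true null mean/proportion as
reference. Calibration sample sizes are 50 values for the mean schemes and
400 labels for the proportion scheme — with far fewer labels the resampled
fractions are so coarsely discrete that the p distribution visibly steps,
which would fail a uniformity check for reasons unrelated to correctness.

The conventional layer wraps statsmodels/scipy: two-way fixed-effects ANOVA
(group × session) with type-II partial sums of squares and sum-to-zero
contrasts (identical to the textbook decomposition when balanced, well
defined for the unbalanced cell counts of pooled populations), Tukey HSD or
Holm-corrected Welch t-tests over the four design cells, a 2×2 chi-squared
test of proportions without continuity correction, and the linear model
DI ~ trial × session whose interaction coefficient is the difference of
per-trial slopes between the two sessions. Cells are treated as independent
units, as is conventional for this analysis; animal-level nesting is a known
limitation, not modelled.

## Synthetic data model

The generator produces what the analysis assumes and nothing more:

- **Trajectory**: piecewise end-to-end traversals at a per-lap speed drawn
  from a normal truncated below at 4 cm/s, with sub-threshold pauses
  (default 2 s) at the reward ends; 50 Hz sampling (dt = 0.02 s) and
  sub-millimetre positional jitter. Defaults per group × session follow the
  recorded behaviour the generator emulates: 13.9 ± 5.0 / 9.45 ± 2.0 cm/s
  (control familiar/novel) and 14.2 ± 4.0 / 9.01 ± 1.9 cm/s (transgenic).
- **Tuning**: each cell has Gaussian directional tuning
  λ = baseline + peak·exp(−(s − c)²/2σ²) with per-direction centres. A
  directionality parameter κ ∈ [0, 1] attenuates the non-preferred
  direction's tuning by (1 − κ): κ = 0 is direction-blind, κ = 1
  one-directional. κ grows linearly with lap index at rate γ (clipped to
  [0, 1]), the simplest mechanism producing a monotone DI time course.
- **Spiking**: inhomogeneous Poisson per position sample
  (counts ~ Poisson(λ·dt), times jittered within the step; error above
  λ·dt = 1, warning above 0.3). No refractoriness, bursting or theta
  modulation — every statistic computed here is rate-based, so these
  omissions do not affect what the validation can conclude, but they do mean
  that passing tests say nothing about spike-timing phenomena in real data.
- **Cohort structure**: per animal, one familiar and one novel session share
  unit identities; novel sessions re-draw field centres (global remapping)
  and per-session tuning. Cell parameters: peak ~ U(2, 12) Hz, baseline
  0.05 Hz (a realistic out-of-field rate for CA1 pyramidal cells; much
  higher values would let uniform baseline spikes bias full-profile COM
  estimates toward mid-track), centres uniform at least 15 cm from the track
  ends, κ ~ U(0, 0.4) for bidirectional cells with an 80% chance the two
  directional centres coincide. Group × session conditions: field widths
  σ = 5.2/6.8/7.1/10.7 cm (control-familiar/control-novel/transgenic-
  familiar/transgenic-novel; the transgenic-novel widening is ~1.6× the
  control-novel width), unidirectional fractions 0.29/0.22/0.25/0.12, and
  drift γ = 0.005/0.015/0.005/0 per lap — the flat transgenic-novel drift
  is the generative counterpart of impaired directional refinement in a new
  environment.
- **Determinism**: identical cohort spec and seed give byte-identical
  sessions (seed streams are spawned per animal).

## Validation design

Problem sizes were chosen so the whole suite runs in minutes on one core:
cohorts of 5 animals × 30 cells per group at 20 laps for parameter-recovery
and contrast tests (100 seeded replicates per contrast), 100-cell single
sessions for the population-vector contrast, and 1000 replicates × 1000
resamples for bootstrap calibration.

The parameter-recovery cohort fixes σ = 9 cm (zero spread), a 30%
unidirectional fraction, γ = 0, and keeps field centres at least 2σ from the
reward margins: a field straddling the excluded zone cannot express its full
width or an unbiased centre in the measurable profile, so admitting
truncated fields would measure experiment geometry rather than estimator
error. Recovery checks: field centres via COM (median error < 3 cm),
field widths via the whole-bin place-field size (cohort median within the
analytic 30–36 cm band — see the quantisation/narrowing note above), and
the generating mixture via classification (within the binomial 95% CI).

What the synthetic model does **not** emulate — and what passing tests
therefore do not certify on real data: lap-to-lap field drift other than the
κ mechanism, theta-scale temporal structure, interneurons, ripples/replay,
behavioural irregularity beyond speed variation and pauses, and any
animal-level (hierarchical) variance component.

## Degenerate inputs and tie-breaks

Silent cells/directions raise a typed "metric undefined" error and are
reported as NaN by the pipeline rather than silently dropped; all-zero
profiles cannot be normalised (error); a profile with tied peaks takes the
first (leftmost) peak bin; occupancy-free bins are flagged and excluded from
SI; bootstrap exceedance uses strict inequalities; the chi-squared test
returns p = 1 when both proportions are degenerate on the same side.
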