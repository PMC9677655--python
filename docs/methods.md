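# Methods

`patsep` implements a single-neuron pattern-separation analysis for
dentate gyrus slice experiments, together with the behavioral analyses
that typically accompany it (open field, novel object exploration and
recognition, immediate-early-gene cell densities), and synthetic-data
generators that stand in for the recorded neurons, the video tracker
and the histology. This note documents the models, the conventions
chosen where the underlying experimental literature leaves them open,
and what the synthetic generators do and do not emulate.

## Spike trains and binning

A spike train is a strictly increasing sequence of times in
`[0, duration)`; empty trains are valid. Binned counts use half-open
bins `[k·w, (k+1)·w)` with 0-based indices, so a 2-s sweep at the
default 10 ms width has exactly 200 bins. A spike at exactly
`t = duration` is rejected by validation rather than assigned to a
bin — this removes the only boundary ambiguity in the binning
convention. The number of bins is `ceil(duration / bin_width)`; a
ragged final bin is permitted (and logged) so the bin-width sweep
{5, 10, 20, 50, 100 ms} works for non-divisible widths. Spike times are
stored as floats and written to CSV at 6 decimal places (1 µs), finer
than the 10 kHz sampling of the recordings this format models.

## Similarity metrics

All three metrics operate on binned count vectors `a`, `b`:

* **R** — Pearson correlation of the counts. Undefined when either
  vector is constant (e.g. an empty sweep).
* **NDP** — normalized dot product `a·b / (‖a‖‖b‖)`, the cosine of the
  angle between the vectors; 0 means no co-occupied bin
  (orthogonalized patterns), 1 means colinear. Undefined at zero norm.
* **SF** — scaling factor `min(‖a‖,‖b‖) / max(‖a‖,‖b‖)`. The
  smaller-over-larger convention makes SF symmetric and bounded by 1;
  SF near 1 with low NDP means the cell rescales activity rather than
  reshaping it. Undefined when either train is empty.

Undefined values are represented as NaN, excluded from every mean, and
counted explicitly in each summary (`n_undefined`), so sparse sweeps
never bias averages silently.

For one recording, the input similarity of a train pair (i, j) is the
metric on the two input vectors; the output similarity is the mean of
the metric over all cross pairs of their evoked sweeps (10 repetitions
each → 100 cross pairs). Same-input sweep pairs are reserved for a
separate reliability diagnostic and never enter the output similarity.
Output similarity below input similarity (below the identity line) is
pattern separation; above it, convergence.

**Numerical detail.** All count vectors of one cell — inputs and
sweeps — enter a single stacked metric-matrix computation, so identical
vectors always map to bit-identical similarity values regardless of
BLAS blocking; and a mean over all-equal values returns that value
exactly. Together these make the identity-responder diagonal
(`s_output = s_input`) exact to the last bit, which the tests assert.

## Spike-pattern statistics

* **Firing rate**: spikes per sweep, also expressed in Hz
  (count / duration).
* **Response windows**: each stimulus at time `t` owns the window
  `[t, min(t + cap, t_next, duration))`. The cap defaults to 50 ms —
  at 10 Hz Poisson stimulation the median inter-stimulus interval is
  ≈ 69 ms, so the cap bites only on long gaps — and is configurable.
* **Spike probability**: fraction of stimuli (across all sweeps) whose
  window contains ≥ 1 output spike. Recordings outside the 30–80%
  range used to titrate stimulation intensity fail QC, are excluded
  from group summaries, and are logged.
* **pBurst**: fraction of stimuli with ≥ 2 output spikes in their
  window (a time-window definition; per-cell value is the mean over
  sweeps).
* **Compactness** = occupied bins / total bins; **occupancy** =
  spikes / occupied bins (undefined for empty trains).
* **Dispersion**: across a recording's output sweeps, the mean
  compactness ("binwise compactness") and the *variation* of occupancy
  and firing rate, operationalized as the mean absolute pairwise
  difference of the per-sweep values over all sweep pairs. A
  coefficient-of-variation alternative would be easy to add; mean
  absolute pairwise difference was chosen because it is well defined
  for values near zero and matches the pairwise-comparison framing of
  the dispersion analysis. Empty sweeps are excluded from occupancy
  pairs and counted.

## Inference

* **ANCOVA** on the pooled (s_input, s_output) points of the two
  housing groups (SH, EE). Two OLS models are fitted with explicit
  design matrices: the parallel-lines model
  `s_output ~ 1 + s_input + group` whose group-coefficient t-test is
  the headline group effect, and the interaction model adding
  `s_input × group` whose interaction t-test reports slope
  heterogeneity. Per-group simple-regression slopes and intercepts are
  reported alongside. Note the design pools 10 pair points per cell;
  points within a cell are correlated, so with real multi-cell data
  the pooled ANCOVA is anticonservative with respect to cells as the
  unit of inference — this mirrors the field's design and is not
  corrected here (no mixed-effects modelling; a stated non-goal).
* **t-tests**: classical two-sided one- and two-sample t-tests (pooled
  variance). Degenerate zero-variance samples with equal means report
  t = 0, p = 1 by convention (logged). No multiple-testing correction
  is applied across the three similarity metrics.
* **Two-way ANOVA + Tukey HSD** for IEG densities, factors housing ×
  condition, type-II sums of squares, all four design cells required.
  The unit of analysis is the per-animal mean density (per-image
  analysis is possible by passing the per-image table). A
  zero-variance response reports all p = 1 (logged).

Simulation-based calibration is part of the test suite: type-I error
of each test is checked to lie in [0.03, 0.07] at α = 0.05 over 2000
null replicates, and the ANCOVA detects a 0.05 intercept offset
(σ = 0.03, n = 150/group) with ≥ 90% power.

## Behavior

Arena analyses assume a 40 × 40 cm box. Dwell times are
sample-weighted: each sample carries the interval to the next one, so
zone times partition the trace duration exactly. Defaults chosen where
the tracking software's internal settings are unreported:

* mobility threshold 2 cm/s (step speed at or above counts as mobile);
* center zone = central 50% of each side (20 × 20 cm, 25% of the
  area);
* object exploration zone = 4 cm radius circle around each object
  center (≈ 2 cm beyond a small object's footprint); overlapping zones
  assign a sample to the nearest center and are warned about.

The NOR discrimination index is `novel / (novel + familiar)` with 0.5
as chance; a trial with zero total exploration is undefined, excluded
and logged. IEG densities are count / GCL-area per image (cells/mm²),
averaged per animal, then per group. The post-task fixation delay is
treated as metadata only and never used computationally.

## Synthetic data

The generators define the simulated study's conditions; they emulate
the statistical structure the analysis relies on, not the biophysics.

**Correlated input trains.** Mother-train thinning: a mother Poisson
train at rate `rate / p` is copied into each child by keeping each
mother spike independently with probability `p`, then adding Gaussian
latency jitter. Without jitter, shared thinning gives the pairwise
binned-count correlation a closed form — exactly `p` — which serves as
the oracle for the generator's tests. `p` is calibrated by bisection
(bracket `target ± 0.15`, 200 Monte-Carlo sets per probe, fixed
internal RNG stream so calibration is deterministic per parameter set
and cached); candidate sets are then rejection-sampled with the
caller's seed until the realized mean pairwise R at the analysis bin
width lies within `target ± tolerance` (defaults 0.76 ± 0.02 at 10 ms)
and every train's count is within ±40% of `rate × duration`. The
rejection budget is 10,000 candidates, after which a calibration error
with the probe curve is raised. Jitter SD defaults to 1 ms: at 10 ms
bins the achievable correlation ceiling is roughly
`p · (1 − E|Δ|/w)` with Δ the difference of two jitters, so 1 ms keeps
the calibrated `p` (≈ 0.85) comfortably inside the bisection bracket
while still decoupling shared spikes at fine bin widths.

**Granule-cell responder.** Per input spike: a response spike with
probability `p_spike` (default 0.5, the center of the 30–80% QC
window) at latency ~ Normal(4 ms, 1 ms) truncated at zero; a burst
doublet 3 ms later with probability 0.15; a 2 ms refractory filter; an
independent spontaneous Poisson background at 0.2 Hz (slice
preparations are nearly silent). The `identity()` configuration
(p = 1, zero latency, no extras, no refractoriness, no background)
reproduces its input exactly and anchors the diagonal tests. The
responder is a phenomenological point-process model: it has no
membrane dynamics, synaptic depression or inhibition, so it cannot —
and is not meant to — reproduce the small real SH/EE differences in
output similarity.

**Trajectories.** A reflected Ornstein–Uhlenbeck velocity walk
(relaxation 0.5 s, stationary per-component SD 8 cm/s, giving mean
speeds ≈ 10 cm/s) with a two-state rest/mobile Markov chain (mean rest
bout 2 s) occupying the requested rest fraction, and optional constant
drift toward an attraction point. It produces realistic distance,
mobility and dwell statistics but no thigmotaxis, grooming or
wall-following structure; center-zone dwell of this walk therefore
differs from a uniform-position baseline, and geometry tests use
uniform samples instead.

**NOR and IEG tables.** NOR trials draw a DI from a truncated normal
(defaults 0.66, SD 0.10, n = 12 per group) and split a log-normal
total exploration time (~40 s) accordingly. IEG counts are
Poisson(area × density) with per-(group, condition) densities
defaulting to a novelty-task effect with no housing effect (cFOS
0.36/0.66/0.26/0.60 and NPAS4 0.16/0.43/0.24/0.42 cells/mm² for
SH-HC/SH-NOE/EE-HC/EE-NOE), 4 animals per cell and 10 images per
animal with log-normal GCL areas around 2 mm². The area and image
count are not experimentally reported quantities; they were fixed once
by a normal-approximation power calculation so that the generator's
stated condition effect is reliably detectable at the per-animal level
of analysis, and the tests then verify ≥ 90% empirical power with the
housing factor held at its nominal false-positive rate.

Every generator consumes a single seeded NumPy `Generator` per call,
is bit-reproducible under a fixed seed, and exposes its configuration
(and calibration results) as metadata for JSON sidecars.

## Pipeline

`run_pipeline` simulates a full study: per-cell input sets and
recordings for both groups (default 15 cells/group, matching a typical
slice-study yield), similarity and pattern-summary tables, group
inference, the behavioral arm, figures, and a text report, in a fixed
directory layout with seed and config-hash provenance columns on every
table. Child seeds derive from `numpy.random.SeedSequence`, so reruns
with the same configuration are byte-identical; partial reruns
(`from_stage=...`) reuse upstream outputs unchanged. Both groups use
identical responder parameters by default — an honest null — since
fitting the real housing effect is out of scope.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to make their statistical
bands sharp at interactive runtimes: 2000 replicates for type-I error
bands, 500 for the ANCOVA power check, 1000 sets for the thinning
oracle, 20 replicate cells per latency-jitter level, 10⁵ samples for
the uniform-dwell geometry check. Thresholds follow the corresponding
binomial or Monte-Carlo error, not the observed values.

## Known limitations

* The ANCOVA treats pooled pair points as independent (see above).
* The responder and trajectory models are phenomenological; passing
  tests demonstrate the analysis chain is correct and calibrated, not
  that real granule cells or mice behave like the generators.
* Sample Pearson correlation on 200 bins carries a small finite-sample
  bias (≲ 0.006 at the protocol's operating point); the calibration
  targets the realized sample statistic, as the stimulation protocol
  itself does, so this bias is absorbed rather than corrected.
* `p_burst` uses a time-window definition of burstiness; window-free
  (ISI-based) definitions would differ for high spontaneous rates.
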