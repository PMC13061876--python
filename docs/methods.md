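# Methods

This note documents the models, defaults and numerical choices behind
`ifmicrostate`, and what the synthetic validation does and does not show.

## Signal preparation

Recordings are band-pass filtered to the analysis band with a 4th-order
Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero phase and
effective magnitude order 8.  Zero-phase filtering is a requirement, not
a convenience: any group delay would bias the instantaneous phase and
hence every IF estimate downstream.  The default band is 4–13 Hz
(theta–alpha); an alpha-only analysis is the same code path with an
8–13 Hz `BandSpec`.  Five seconds are trimmed from each end after
filtering so that filter and Hilbert edge transients never reach the
analysis; with the default 60-s segments at 200 Hz this leaves 10,000
usable samples.  Hardware filtering of the acquisition system is treated
as a property of the input and not re-applied, and the package assumes
artifact-free segments (no automatic artifact rejection).

## Instantaneous frequency

Per channel, the analytic signal is computed by FFT-based Hilbert
transform over the full trimmed segment (no windowing).  The wrapped
phase is the elementwise argument, unwrapped by removing 2π branch cuts,
and differentiated with central differences at interior samples and
one-sided differences at the ends (`np.gradient`); central differences
have lower bias than forward differences and are exact for the linear
phase of a stationary tone.  The raw IF is smoothed with a running
median whose window is `round(window_ms·fs/1000)` samples forced odd by
rounding up — 21 samples for the default 100 ms at 200 Hz.  The median
is centered and length-preserving; at the edges it is taken over the
samples actually available rather than over invented padding.
Out-of-band or negative IF excursions that survive the median (phase
slips) are retained, not clipped: the median filter is the only
mitigation applied.

On noiseless tones at 5–12 Hz the end-to-end error is below 0.05 Hz over
the central 80% of samples, and below 0.01 Hz for a 60-s linear chirp's
interior; these bounds are asserted in the test suite.

## State model

At each time point the channel vector is centered and divided by its
population (N-denominator) standard deviation across channels — the row
*is* the whole electrode population at that instant, so the sample
correction would be misplaced.  Rows with (near-)zero spatial variance
are flagged degenerate, excluded from fitting, and treated as sequence
breaks so no spurious transition bridges the gap.

The pooled normalized vectors of *all* participants of both groups are
clustered with k-means (k-means++ seeding, 20 restarts, Euclidean
distance), and the centroids initialize the emission means of a
first-order Gaussian HMM with diagonal covariance (z-scored inputs make
unit-scale diagonal a natural starting point; spherical or full
covariance would be a one-line change in the `hmmlearn` backend).
Baum–Welch runs with per-participant sequence lengths so transitions are
never counted across participant boundaries, a relative log-likelihood
tolerance of 1e-4, and a 200-iteration cap; convergence status, seed and
the full log-likelihood trace are stored in `fit_log_`.  Emission means
are re-estimated by EM from the k-means initialization by default; a
`freeze_means=True` option keeps them pinned at the centroids for the
stricter "centroids are the states" reading.  The transition matrix is
initialized sticky (0.8 on the diagonal) because microstates persist for
tens of samples; EM moves it freely from there.

One model is fitted for the whole cohort and shared by both groups;
individual state sequences are then decoded per participant with
Viterbi, which respects the first-order temporal continuity the HMM
exists to enforce (posterior-argmax decoding would optimize per-sample
accuracy at the cost of fragmenting episodes).

State identities are made reproducible by canonical reordering after
fitting: states are ranked by descending pooled occupancy of the
training decoding, ties broken by the first-channel centroid value.
Refits from different seeds on the same data produce matching labels
without any post-hoc matching.

Model order is selected from information criteria computed for each
candidate K: `AIC = 2p − 2lnL`, `BIC = p·ln(n) − 2lnL` with
`p = (K−1) + K(K−1) + 2KD` free parameters (initial distribution,
transitions, diagonal-Gaussian means and variances) and `n` the pooled
sample count.  The elbow is formalized as the K maximizing the discrete
second difference of the BIC curve (AIC is emitted alongside so the
choice is auditable); ties resolve to the smallest K.

## Dynamics metrics

Episodes are maximal runs of one label; durations are run length over
sampling rate.  Mean dwell time averages episode durations per state;
episodes truncated by the segment boundaries are included (segments are
long relative to dwell times and no censoring rule is imposed).
Occupancy is the fraction of total time per state — the time-fraction
formula is implemented under the name `occupancy`; the episode *rate*
(episodes per second) is provided separately as `episode_rate` for the
"occurrence" reading of state frequency.  Transition probabilities count
every consecutive sample pair including self-transitions and normalize
each row by its outgoing total.  States never visited have occupancy 0
but *missing* (NaN) dwell time and transition rows — absence of evidence
is not an estimate of zero.  The identities `f_i = N_i·D_i/T` and
`D_i → 1/((1−P(i→i))·fs)` (long sequences) tie the three metrics
together and are asserted in the tests against an independent
brute-force counter.

## Group statistics

Metric values are log-transformed before testing to reduce skew.  Zero
transition probabilities would break the log; they are floored at the
participant's smallest observable nonzero probability,
`1/(total transitions)`, and flagged in the output.  Normality of the
log values is assessed per group with the D'Agostino–Pearson omnibus
test at α = 0.05; the parametric path is taken only if both groups pass.
The parametric test defaults to Welch's t (the groups are typically
unbalanced); Student's t is a config switch.  Groups smaller than 8 or
degenerate fall back to Mann–Whitney with a warning.  Cohen's d is
reported on the original metric scale with (n−1)-weighted pooled SD even
when the test ran on logs, signed so that positive means the second
group is larger; group roles follow order of appearance in the input
table (the reference group first).  Benjamini–Hochberg runs within three
families — dwell across the K states, occupancy across the K states,
transitions across the full K×K set — at q < 0.05.  Under a true null
each family's probability of any finding is the nominal 0.05; with three
families the overall per-replicate rate is correspondingly ≈ 0.14, which
is a property of the family definition, not an inflation of any single
family's error rate.

Design helpers: the a-priori sample size search evaluates the exact
noncentral-t power of the two-sided two-sample t test at integer n and
returns the smallest n per group reaching the target (26 per group for
d = 0.8, α = 0.05, power = 0.80); η² converts to Cohen's d as
`d = 2·sqrt(η²/(1−η²))`; the 2×2 sex-distribution test is Pearson's χ²
without continuity correction.

## Synthetic cohorts

The simulator generates, per participant, a first-order Markov chain
over K states and renders each channel as a unit-amplitude,
*phase-continuous* sinusoid whose instantaneous frequency is
`base_freq + offset_i(state(t))`, plus white Gaussian noise.  Phase
accumulates as the integral of IF, so state switches leave no amplitude
discontinuity and the spatial IF pattern of the active state is ground
truth by construction.  Defaults mirror a two-group resting-state study:
29 + 18 participants, 16 channels of the 10–20 set, 200 Hz, 60 s,
K = 5, base frequency 8.5 Hz (the center of the theta–alpha band),
offset patterns bounded by 1 Hz with occipital-lead, frontal-lead,
lateral, central and saddle geometries, self-transitions 0.94 with the
second group's state 1 at 0.95 and state 5 at 0.928 (the direction and
scale of a realistic age contrast), and noise_sd 0.2 relative to the
unit oscillation amplitude.  Per-participant random streams are spawned
from `SeedSequence((master, group, participant))`, making cohorts
bit-reproducible with no stream collisions.

What the simulator does *not* emulate: volume conduction and realistic
sensor covariance, 1/f background activity, amplitude dynamics,
artifacts, or drowsiness.  Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the stated observation
model, not performance on real EEG.

## The dwell-time / bandwidth resolution limit

One property of the default conditions deserves emphasis.  With
self-transitions of 0.94 at 200 Hz, episodes last 16.7 samples (83 ms)
on average.  A frequency switch is an FM event whose sidebands extend
far beyond the 4–13 Hz analysis band (Carson's rule with ~12 Hz
modulation rates); band-pass filtering removes exactly the spectral
content that localizes the switch, blurring every transition over
roughly ±5 samples, and the 21-sample median window cannot restore it.
About 8% of samples lie in episodes shorter than the blur scale and are
unrecoverable in principle.  Measured on noiseless data with an oracle
decoder that knows the true patterns and dynamics, per-sample decoding
accuracy is capped near 0.87 with the band-pass in place (≈ 0.92–0.97
without it); the fitted pipeline reaches this ceiling to within ~0.03.
The same blur inflates fitted self-transition probabilities by ~0.03 and
causes the information-criterion curve to keep improving past the true
K (extra states absorb transition-blend patterns), so the BIC elbow can
land below the generating state count.  Consequences: decoded dwell
times are upward-biased relative to generating values at these
conditions, and between-group *contrasts* (which affect both groups'
biases similarly) remain detectable while absolute values should be
interpreted with the blur in mind.  Longer dwells, wider bands, or
higher sampling rates all relax the limit.

## Problem sizes used in validation

The test battery scales the heavy checks to keep a full run inside a few
minutes on one CPU: the state-recovery suite uses the full 47-participant
cohort at 20 s per participant (10 s usable after trims) and a K = 2..8
criterion scan; the null-calibration suite uses 500 replicates of
label-sequence cohorts at 10,000 samples (the usable 50 s at 200 Hz)
without signal synthesis, which exercises the metrics → statistics path
exactly.  Metric functions are verified exactly against a brute-force
counter on 1,000 random sequences, and the BH implementation against a
brute-force step-up on 1,000 random p-vectors.
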