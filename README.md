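# ifmicrostate

Instantaneous-frequency (IF) microstate analysis of multichannel
resting-state EEG: Hilbert-based IF extraction, hidden-Markov-model state
segmentation, state-dynamics metrics, and FDR-corrected group statistics,
together with a Markov-switching oscillation simulator that provides
ground-truth cohorts for validation.

## The problem

Conventional EEG microstates segment the scalp field into brief periods
with a quasi-stable *amplitude* topography.  This package implements a
complementary definition in which the spatial pattern of *instantaneous
frequency* — which channels oscillate slightly faster or slower than the
scalp average at each moment — defines the states.  Frequency gradients
(e.g., occipital lead / frontal lag of the alpha rhythm) carry information
about phase leading and lagging across the scalp that amplitude
topographies do not, and their temporal dynamics (how long each pattern
dwells, how often it occurs, where it transitions) can differ between
participant groups.

The intended users are EEG researchers comparing state dynamics between
two groups of participants (e.g., age groups or patients vs. controls)
from sensor-level recordings.

## The method

For each channel *i* of a band-limited recording (4–13 Hz theta–alpha by
default), the analytic signal `a_i(t)` is computed by Hilbert transform,
and the instantaneous frequency is the derivative of the unwrapped phase,

    IF_i(t) = (1/2π) d/dt unwrap[arg a_i(t)]    [Hz],

smoothed with a 100-ms running median to suppress phase slips.  At every
sample the channel vector is centered and z-scored across channels
(population SD), leaving only the spatial *shape* of the IF field.  The
normalized vectors of all participants of both groups are pooled,
clustered with k-means, and the centroids initialize a first-order
Gaussian HMM (diagonal covariance) fitted by Baum–Welch with participant
boundaries respected.  One shared model serves both groups — this
prevents group-specific state reorganization — and each participant's
state sequence is decoded individually with Viterbi.  Model order is
chosen from the AIC/BIC curve over a candidate range (elbow = maximum
discrete second difference).

From each decoded sequence the package computes, per state *i*:

* mean dwell time `D_i = (1/N_i) Σ_e d_{i,e}` (mean episode duration, s),
* occupancy `f_i = Σ_e d_{i,e} / T` (fraction of total time),
* transition probabilities `P(i→j) = N_{i→j} / Σ_k N_{i→k}`
  (consecutive-sample counts, self-transitions included).

Group comparison: metrics are log-transformed (zero transition
probabilities floored at the participant's smallest observable
probability and flagged), normality is gated per group with the
D'Agostino–Pearson test, Welch's t (or Mann–Whitney U when normality
fails) yields two-sided p-values, Benjamini–Hochberg controls FDR at
q < 0.05 within each family (dwell, occupancy, K×K transitions), and
effects are reported as pooled-SD Cohen's d plus signed significance
scores `sign(Δ)·(−log10 p)`.

## Worked example

Cohort-design helpers and a ground-truth group comparison at study scale
(29 vs. 18 participants, 50 s of usable signal at 200 Hz, five states;
the second group's state 1 is stickier, 0.95 vs. 0.94, and its state 5
less sticky, 0.928):

```python
import ifmicrostate as ifm
from ifmicrostate.dynamics import compute_metrics, metrics_frame, transitions_frame
from ifmicrostate.states import StateSequence
from ifmicrostate.stats import compare_cohort, power_analysis_n, chi_square_2x2

n, total = power_analysis_n(d=0.8, alpha=0.05, power=0.80)
print(f"required sample size: {n} per group ({total} total)")
chi2, p = chi_square_2x2([[14, 15], [7, 11]])
print(f"sex distribution: chi2 = {chi2:.3f}, p = {p:.3f}")

spec = ifm.default_cohort_spec(seed=1)   # 29 + 18 participants, K = 5
mets = []
for g, (n_g, markov, name) in enumerate(zip(spec.n_per_group, spec.group_markov,
                                            spec.group_labels)):
    chains = ifm.sample_markov_chains(markov, 10_000, n_g, seed=100 + g)
    for i, labels in enumerate(chains):
        seq = StateSequence(labels=labels, fs_hz=spec.fs_hz,
                            participant_id=f"{name}_{i}", group=name)
        mets.append(compute_metrics(seq, spec.n_states))
res = compare_cohort(metrics_frame(mets), transitions_frame(mets))
print(res[res["significant"]][["metric", "state", "from_state", "to_state",
                               "p_raw", "q_fdr", "cohens_d"]])
```

Output:

```
required sample size: 26 per group (52 total)
sex distribution: chi2 = 0.396, p = 0.529
    metric  state  from_state  to_state        p_raw        q_fdr  cohens_d
     dwell    1.0         NaN       NaN 1.682456e-09 8.412279e-09  2.388066
     dwell    5.0         NaN       NaN 2.736706e-05 6.841765e-05 -1.477645
 occupancy    1.0         NaN       NaN 2.639765e-08 1.319882e-07  2.026581
 occupancy    5.0         NaN       NaN 1.074394e-04 2.685984e-04 -1.392752
transition    NaN         1.0       1.0 6.334291e-10 1.583573e-08  2.188390
...
transition    NaN         5.0       5.0 6.186508e-05 5.155423e-04 -1.513635
```

The comparison recovers exactly the planted contrast: the second group
dwells longer in state 1 and shorter in state 5 (positive/negative
Cohen's d), with matching occupancy and self-transition differences —
the directions the metrics are designed to detect.

The full signal-level pipeline (simulate → band-pass → IF → HMM →
metrics → statistics) runs as one command:

```bash
ifstate run-full --out results/run1 --seed 7
```

which writes `model.json`, `sequences.csv`, `metrics.csv`,
`transitions.csv`, `comparisons.csv`, `signed_scores.csv`,
`state_maps.csv` and a provenance record.  Individual stages
(`simulate`, `preprocess`, `extract-if`, `fit`, `decode`, `metrics`,
`compare`) are also exposed; see `ifstate --help`.

## Limitations

Decoded-state accuracy against ground truth is physically limited by the
interaction of short dwell times with band-limiting: see
`docs/methods.md` for a quantitative account, along with all modeling
assumptions and defaults.
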