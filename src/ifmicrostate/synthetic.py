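"""Markov-switching oscillation simulator with known ground truth.

The study's recordings are not public, so every downstream stage is
exercised on synthetic cohorts for which the state sequence, the spatial
IF patterns and the generating Markov chain are known exactly.

Observation model
-----------------
A first-order Markov chain over K states drives, for each channel i, the
instantaneous frequency

    f_i(t) = base_freq + offset_i(state(t))        [Hz],

and the channel signal is a unit-amplitude, *phase-continuous* sinusoid

    x_i(t) = cos( 2*pi * cumsum(f_i)/fs + phi0_i ) + noise,

with white Gaussian noise of standard deviation ``noise_sd``.  Phase
accumulates as the integral of instantaneous frequency, so frequency
switches leave no amplitude discontinuity and the per-channel IF pattern
of the active state is, by construction, the ground truth the extraction
and segmentation stages must recover.

The two groups share the same spatial patterns and differ only in their
transition matrices, mirroring a shared-state / different-dynamics design.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .io import DEFAULT_CHANNELS, EEGRecording, write_recording_csv

__all__ = [
    "StatePatternSpec",
    "MarkovSpec",
    "SyntheticCohortSpec",
    "GroundTruth",
    "default_patterns",
    "sticky_markov",
    "default_cohort_spec",
    "sample_markov_chain",
    "sample_markov_chains",
    "synthesize_recording",
    "make_cohort",
    "write_cohort",
]

_PROB_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class StatePatternSpec:
    """Spatial IF pattern of one state: per-channel offsets (Hz) on top of
    the carrier frequency."""

    state_id: int
    channel_freq_offsets: tuple[float, ...]

    def __post_init__(self):
        off = np.asarray(self.channel_freq_offsets, dtype=float)
        if not np.all(np.isfinite(off)):
            raise ValueError(f"state {self.state_id}: non-finite offsets")
        object.__setattr__(self, "channel_freq_offsets", tuple(off))


@dataclasses.dataclass(frozen=True)
class MarkovSpec:
    """First-order Markov chain: K states, row-stochastic transitions."""

    n_states: int
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray | None = None

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix shape mismatch")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > _PROB_TOL):
            raise ValueError("transition_matrix rows must sum to 1")
        pi0 = self.initial_distribution
        if pi0 is None:
            pi0 = np.full(self.n_states, 1.0 / self.n_states)
        pi0 = np.asarray(pi0, dtype=float)
        if pi0.shape != (self.n_states,) or np.any(pi0 < 0) or \
                abs(pi0.sum() - 1.0) > _PROB_TOL:
            raise ValueError("initial_distribution must be a probability "
                             "vector of length n_states")
        object.__setattr__(self, "transition_matrix", P)
        object.__setattr__(self, "initial_distribution", pi0)


@dataclasses.dataclass(frozen=True)
class SyntheticCohortSpec:
    """Everything needed to generate a two-group cohort.

    ``n_per_group`` gives the group sizes (group A, group B); the groups
    differ only through ``group_markov``.  ``noise_sd`` is relative to the
    unit oscillation amplitude.
    """

    n_per_group: tuple[int, int]
    group_markov: tuple[MarkovSpec, MarkovSpec]
    base_freq_hz: float = 8.5
    noise_sd: float = 0.2
    fs_hz: float = 200.0
    duration_s: float = 60.0
    seed: int = 0
    group_labels: tuple[str, str] = ("younger", "middle_aged")
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group sizes must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.group_markov[0].n_states != self.group_markov[1].n_states:
            raise ValueError("both groups must share the same state count")

    @property
    def n_states(self) -> int:
        return self.group_markov[0].n_states

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclasses.dataclass
class GroundTruth:
    """Generating truth attached to one synthetic recording."""

    state_sequence: np.ndarray  # labels 1..K, one per sample
    pattern_specs: tuple[StatePatternSpec, ...]
    markov_spec: MarkovSpec | None = None


# ---------------------------------------------------------------------------
# default study-scale configuration

# Coarse 10-20 scalp coordinates (x: left -1 .. right +1, y: posterior -1 ..
# anterior +1) used only to lay out physiologically shaped patterns.
_COORDS = {
    "Fp1": (-0.3, 1.0), "Fp2": (0.3, 1.0),
    "F7": (-0.8, 0.6), "F3": (-0.4, 0.6), "Fz": (0.0, 0.6),
    "F4": (0.4, 0.6), "F8": (0.8, 0.6),
    "C3": (-0.4, 0.0), "C4": (0.4, 0.0),
    "T5": (-0.8, -0.6), "P3": (-0.4, -0.6), "Pz": (0.0, -0.6),
    "P4": (0.4, -0.6), "T6": (0.8, -0.6),
    "O1": (-0.3, -1.0), "O2": (0.3, -1.0),
}


def default_patterns(
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS,
    amplitude_hz: float = 1.0,
) -> tuple[StatePatternSpec, ...]:
    """Five spatial IF patterns at study scale.

    State 1: occipital lead / frontal lag (posterior channels faster) — the
    hallmark pattern attributed to shorter posterior corticothalamic
    delays.  State 2: its reversal (frontal lead).  State 3: left-right
    gradient.  State 4: central fast, periphery slow.  State 5: saddle
    (lateral frontal + midline posterior fast).  Offsets are bounded by
    ``amplitude_hz``.
    """
    xy = np.array([_COORDS[c] for c in channel_labels])
    x, y = xy[:, 0], xy[:, 1]
    shapes = [
        -y,                       # occipital (y=-1) lead
        +y,                       # frontal lead
        -x,                       # left lead
        1.0 - (x**2 + y**2),      # central bump
        x**2 - y**2,              # saddle
    ]
    out = []
    for k, s in enumerate(shapes, start=1):
        s = s - s.mean()
        s = s / np.max(np.abs(s)) * amplitude_hz
        out.append(StatePatternSpec(k, tuple(s)))
    return tuple(out)


def sticky_markov(n_states: int,
                  self_prob: float | np.ndarray) -> MarkovSpec:
    """Chain with given per-state self-transition probabilities and uniform
    off-diagonal mass."""
    p = np.broadcast_to(np.asarray(self_prob, dtype=float), (n_states,))
    P = np.empty((n_states, n_states))
    for i in range(n_states):
        P[i] = (1.0 - p[i]) / (n_states - 1)
        P[i, i] = p[i]
    return MarkovSpec(n_states, P)


def default_cohort_spec(seed: int = 0, *, n_per_group=(29, 18),
                        duration_s: float = 60.0,
                        noise_sd: float = 0.2) -> SyntheticCohortSpec:
    """Study-scale cohort: 29 younger vs 18 middle-aged participants,
    16 channels, 200 Hz, K=5.

    Younger group: all self-transitions 0.94.  Middle-aged group: state 1
    stickier (0.95) and state 5 less sticky (0.928), the direction and
    scale of the reported age contrast.
    """
    young = sticky_markov(5, 0.94)
    middle = sticky_markov(5, np.array([0.95, 0.94, 0.94, 0.94, 0.928]))
    return SyntheticCohortSpec(
        n_per_group=tuple(n_per_group),
        group_markov=(young, middle),
        duration_s=duration_s,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sampling and synthesis

def sample_markov_chains(spec: MarkovSpec, n_samples: int, n_chains: int,
                         seed) -> np.ndarray:
    """Sample ``n_chains`` independent label sequences (1..K), vectorized
    across chains.  ``seed`` may be an int or a ``numpy`` Generator."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    K = spec.n_states
    cum_init = np.cumsum(spec.initial_distribution)
    cum_P = np.cumsum(spec.transition_matrix, axis=1)
    u = rng.random((n_samples, n_chains))
    states = np.empty((n_samples, n_chains), dtype=np.int64)
    states[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, n_samples):
        # inverse-CDF step, vectorized over chains
        states[t] = (u[t][:, None] >= cum_P[states[t - 1]]).sum(axis=1)
    return (states + 1).T.clip(1, K)


def sample_markov_chain(spec: MarkovSpec, n_samples: int, seed) -> np.ndarray:
    """Sample one label sequence (values 1..K); reproducible for a fixed
    seed."""
    return sample_markov_chains(spec, n_samples, 1, seed)[0]


def synthesize_recording(
    patterns: tuple[StatePatternSpec, ...],
    truth_sequence: np.ndarray,
    cohort: SyntheticCohortSpec,
    participant_seed,
    participant_id: str = "",
    group: str = "",
) -> tuple[EEGRecording, GroundTruth]:
    """Render one participant's signal from a state-label sequence.

    Each channel is a unit-amplitude sinusoid whose instantaneous frequency
    is ``base_freq + offset_i(state(t))``; phase is continuous across state
    switches (cumulative integral of IF).  Gaussian noise of sd
    ``noise_sd`` is added.  Initial phases are random per channel.
    """
    seq = np.asarray(truth_sequence, dtype=int)
    K = len(patterns)
    by_id = {p.state_id: p for p in patterns}
    if sorted(by_id) != list(range(1, K + 1)):
        raise ValueError("patterns must cover state ids 1..K exactly once")
    if seq.min() < 1 or seq.max() > K:
        raise ValueError("truth_sequence labels outside 1..K")
    offsets = np.array([by_id[k].channel_freq_offsets
                        for k in range(1, K + 1)])  # K x C
    n_ch = offsets.shape[1]
    if n_ch != len(cohort.channel_labels):
        raise ValueError("pattern channel count does not match cohort")
    f_inst = cohort.base_freq_hz + offsets[seq - 1].T  # C x T
    if f_inst.min() <= 0 or f_inst.max() >= cohort.fs_hz / 2:
        raise ValueError("instantaneous frequency leaves (0, fs/2)")
    rng = participant_seed if isinstance(participant_seed, np.random.Generator) \
        else np.random.default_rng(participant_seed)
    phi0 = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
    phase = phi0 + 2 * np.pi * np.cumsum(f_inst, axis=1) / cohort.fs_hz
    x = np.cos(phase)
    if cohort.noise_sd > 0:
        x = x + rng.normal(0.0, cohort.noise_sd, size=x.shape)
    rec = EEGRecording(
        data=x, fs_hz=cohort.fs_hz, channel_labels=cohort.channel_labels,
        participant_id=participant_id, group=group,
    )
    return rec, GroundTruth(seq.copy(), tuple(patterns))


def make_cohort(
    cohort: SyntheticCohortSpec,
    patterns: tuple[StatePatternSpec, ...] | None = None,
) -> list[tuple[EEGRecording, GroundTruth]]:
    """Generate the full two-group cohort.

    Both groups share the spatial patterns; the contrast lives entirely in
    the group transition matrices.  Per-participant randomness is spawned
    deterministically from ``(master seed, group index, participant
    index)``, so the cohort is bit-reproducible and participants never
    share a stream.
    """
    if patterns is None:
        patterns = default_patterns(cohort.channel_labels)
    out: list[tuple[EEGRecording, GroundTruth]] = []
    for g, (n, markov, label) in enumerate(
            zip(cohort.n_per_group, cohort.group_markov, cohort.group_labels)):
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence((cohort.seed, g, i)))
            seq = sample_markov_chain(markov, cohort.n_samples, rng)
            rec, truth = synthesize_recording(
                patterns, seq, cohort, rng,
                participant_id=f"{label}_{i:03d}", group=label)
            truth.markov_spec = markov
            out.append((rec, truth))
    return out


def write_cohort(cohort_data, out_dir: str | Path,
                 cohort: SyntheticCohortSpec | None = None) -> None:
    """Write each participant as CSV plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, truth in cohort_data:
        write_recording_csv(rec, out_dir / f"{rec.participant_id}.csv")
        sidecar = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "fs_hz": rec.fs_hz,
            "state_sequence": truth.state_sequence.tolist(),
            "patterns": {
                p.state_id: list(p.channel_freq_offsets)
                for p in truth.pattern_specs
            },
            "transition_matrix": truth.markov_spec.transition_matrix.tolist(),
        }
        with open(out_dir / f"{rec.participant_id}.truth.json", "w") as fh:
            json.dump(sidecar, fh)
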