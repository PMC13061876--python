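"""Temporal dynamics of decoded state sequences.

Per participant and state i the metrics are

* mean dwell time  D_i = (1/N_i) * sum_e d_{i,e}  — the average duration
  (seconds) of the N_i uninterrupted episodes of state i;
* occupancy        f_i = sum_e d_{i,e} / T        — the fraction of the
  total duration T spent in state i;
* transition probabilities  P(i->j) = N_{i->j} / sum_k N_{i->k}, counted
  over consecutive sample pairs *including* self-transitions.

Episodes truncated by the segment boundaries are included in the dwell
average (segments are long relative to dwell times, so no censoring rule
is applied).  States never visited have occupancy 0 and a *missing*
(NaN) dwell time; transition rows with no outgoing pair are missing, not
zero.  An episode *rate* (episodes per second) is provided alongside for
the "occurrence" reading of state frequency.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .states import StateSequence

__all__ = [
    "DynamicsMetrics",
    "episodes",
    "mean_dwell",
    "occupancy",
    "transition_probabilities",
    "compute_metrics",
    "metrics_frame",
    "transitions_frame",
]


@dataclasses.dataclass
class DynamicsMetrics:
    """Per-participant dynamics summary over states 1..K."""

    n_states: int
    mean_dwell_s: np.ndarray        # (K,), NaN where never visited
    occupancy: np.ndarray           # (K,), sums to 1
    n_episodes: np.ndarray          # (K,), ints
    episode_rate: np.ndarray        # (K,), episodes per second
    episode_durations: dict         # state -> array of d_{i,e} (seconds)
    transition_matrix: np.ndarray   # (K, K), NaN rows where unvisited
    transition_counts: np.ndarray   # (K, K) ints
    total_duration_s: float
    participant_id: str = ""
    group: str = ""


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (state of each run, length of each run)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, labels.size]
    return labels[starts], ends - starts


def episodes(seq: StateSequence, n_states: int | None = None) -> dict:
    """Per-state list of episode durations in seconds."""
    states, lengths = _runs(seq.labels)
    K = n_states or int(seq.labels.max())
    durs = {k: lengths[states == k] / seq.fs_hz for k in range(1, K + 1)}
    return durs


def mean_dwell(seq: StateSequence, n_states: int | None = None) -> np.ndarray:
    """Mean episode duration per state (seconds); NaN for absent states."""
    durs = episodes(seq, n_states)
    return np.array([d.mean() if d.size else np.nan
                     for d in durs.values()])


def occupancy(seq: StateSequence, n_states: int | None = None) -> np.ndarray:
    """Fraction of total time per state; 0 for absent states."""
    K = n_states or int(seq.labels.max())
    counts = np.bincount(seq.labels, minlength=K + 1)[1:K + 1]
    return counts / seq.labels.size


def transition_probabilities(
    seq: StateSequence, n_states: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical transition matrix and raw pair counts.

    Counts every consecutive sample pair (self-transitions included);
    rows of states with no outgoing pair are NaN.
    """
    labels = np.asarray(seq.labels, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 samples for transitions")
    K = n_states or int(labels.max())
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (labels[:-1] - 1, labels[1:] - 1), 1)
    out_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = counts / out_tot
    P[out_tot[:, 0] == 0] = np.nan
    return P, counts


def compute_metrics(seq: StateSequence,
                    n_states: int | None = None) -> DynamicsMetrics:
    """All dynamics metrics of one decoded sequence."""
    K = n_states or int(seq.labels.max())
    durs = episodes(seq, K)
    n_ep = np.array([d.size for d in durs.values()])
    T = seq.labels.size / seq.fs_hz
    P, counts = transition_probabilities(seq, K)
    return DynamicsMetrics(
        n_states=K,
        mean_dwell_s=mean_dwell(seq, K),
        occupancy=occupancy(seq, K),
        n_episodes=n_ep,
        episode_rate=n_ep / T,
        episode_durations=durs,
        transition_matrix=P,
        transition_counts=counts,
        total_duration_s=T,
        participant_id=seq.participant_id,
        group=seq.group,
    )


def metrics_frame(metrics: list[DynamicsMetrics]) -> pd.DataFrame:
    """Tidy per-state metrics table (one row per participant x state)."""
    rows = []
    for m in metrics:
        for k in range(m.n_states):
            rows.append({
                "participant_id": m.participant_id, "group": m.group,
                "state": k + 1,
                "dwell_s": m.mean_dwell_s[k],
                "occupancy": m.occupancy[k],
                "n_episodes": int(m.n_episodes[k]),
                "episode_rate": m.episode_rate[k],
            })
    return pd.DataFrame(rows)


def transitions_frame(metrics: list[DynamicsMetrics]) -> pd.DataFrame:
    """Tidy transition table (one row per participant x ordered pair)."""
    rows = []
    for m in metrics:
        for i in range(m.n_states):
            for j in range(m.n_states):
                rows.append({
                    "participant_id": m.participant_id, "group": m.group,
                    "from_state": i + 1, "to_state": j + 1,
                    "probability": m.transition_matrix[i, j],
                    "count": int(m.transition_counts[i, j]),
                    "n_outgoing": int(m.transition_counts[i].sum()),
                })
    return pd.DataFrame(rows)
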