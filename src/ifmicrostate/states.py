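"""IF microstate definition and segmentation.

At every time point the 16-channel IF vector is reduced to its spatial
shape: the mean across electrodes is subtracted and the deviations are
z-scored (population standard deviation — the row *is* the electrode
population at that instant).  The normalized vectors of all participants
of both groups are pooled, clustered with k-means (Euclidean distance),
and the centroids initialize a first-order Gaussian hidden Markov model
fitted by Baum-Welch on the pooled sequences, with participant boundaries
respected.  One shared model serves both groups — fitting a single model
on the combined data prevents group-specific state reorganization and
keeps state identities comparable — and each participant's state sequence
is then decoded individually by Viterbi.

Model order is chosen from AIC/BIC curves over a candidate range: the
elbow is the K maximizing the discrete second difference of the criterion
(BIC by default).
"""

from __future__ import annotations

import dataclasses
import json
from collections import deque
from pathlib import Path

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .frequency import IFSeries

__all__ = [
    "SpatialPatternSeries",
    "StateSequence",
    "SpatialNormalizer",
    "spatial_normalize",
    "MicrostateHMM",
    "kmeans_init",
    "fit_hmm",
    "decode",
    "hmm_n_parameters",
    "select_n_states",
    "elbow_point",
    "match_labels",
    "save_model",
    "load_model",
]


@dataclasses.dataclass
class SpatialPatternSeries:
    """Per-timepoint spatially z-scored IF vectors (samples x channels).

    ``degenerate`` flags rows whose spatial variance was (near) zero; such
    rows carry no shape information and are excluded from model fitting.
    """

    z: np.ndarray
    participant_id: str = ""
    group: str = ""
    fs_hz: float = float("nan")
    degenerate: np.ndarray | None = None

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(self.z.shape[0], dtype=bool)


@dataclasses.dataclass
class StateSequence:
    """Decoded per-sample state labels, 1..K."""

    labels: np.ndarray
    participant_id: str = ""
    group: str = ""
    fs_hz: float = float("nan")


def spatial_normalize(if_values: np.ndarray | IFSeries,
                      eps: float = 1e-12) -> SpatialPatternSeries:
    """Row-wise center and z-score across channels.

    Accepts an ``IFSeries`` (channels x samples) or a samples x channels
    array.  Rows with spatial standard deviation below ``eps`` are flagged
    degenerate and set to zero rather than divided.
    """
    meta = {}
    if isinstance(if_values, IFSeries):
        meta = dict(participant_id=if_values.participant_id,
                    group=if_values.group, fs_hz=if_values.fs_hz)
        X = if_values.if_hz.T
    else:
        X = np.asarray(if_values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a samples x channels matrix with >= 2 channels")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population (N) standard deviation
    degenerate = sd[:, 0] < eps
    sd = np.where(sd < eps, 1.0, sd)
    z = (X - mu) / sd
    z[degenerate] = 0.0
    return SpatialPatternSeries(z=z, degenerate=degenerate, **meta)


class SpatialNormalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`spatial_normalize`.

    After ``transform`` the mask of degenerate rows of the last input is
    available as ``degenerate_mask_``.
    """

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        res = spatial_normalize(X, eps=self.eps)
        self.degenerate_mask_ = res.degenerate
        return res.z


# ---------------------------------------------------------------------------
# HMM

class _FullHistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the entire log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.history = deque()


def kmeans_init(pooled_z: np.ndarray, n_states: int, seed,
                n_init: int = 20) -> np.ndarray:
    """K-means (k-means++, Euclidean) centroids of the pooled z vectors."""
    pooled_z = np.asarray(pooled_z, dtype=float)
    if n_states > pooled_z.shape[0]:
        raise ValueError("more clusters requested than pooled samples")
    km = KMeans(n_clusters=n_states, n_init=n_init, random_state=seed)
    km.fit(pooled_z)
    return km.cluster_centers_


def hmm_n_parameters(n_states: int, n_channels: int) -> int:
    """Free parameters of a K-state diagonal-Gaussian HMM on D channels:
    (K-1) initial + K(K-1) transition + 2KD emission means/variances."""
    K, D = n_states, n_channels
    return (K - 1) + K * (K - 1) + 2 * K * D


class MicrostateHMM(BaseEstimator):
    """Shared-across-groups Gaussian HMM over spatial IF patterns.

    scikit-learn style estimator.  ``fit`` pools all sequences (pass
    per-participant lengths so no transition is counted across a
    participant boundary), initializes emission means at k-means centroids
    of the pooled data, and runs Baum-Welch with diagonal-covariance
    Gaussian emissions.  After fitting, states are reordered canonically:
    descending pooled occupancy of the Viterbi decoding of the training
    data, ties broken by the first-channel centroid value.  ``predict``
    returns the Viterbi path (0-based, sklearn convention; domain wrappers
    report 1-based labels).

    Parameters
    ----------
    n_states : int, default 5
        Number of microstates K.
    n_kmeans_init : int, default 20
        k-means restarts for the initialization.
    max_iter : int, default 200
        Baum-Welch iteration cap.
    tol : float, default 1e-4
        Log-likelihood convergence tolerance.
    freeze_means : bool, default False
        Keep emission means frozen at the k-means centroids (the stricter
        reading of "centroids as states"); by default means are
        re-estimated by EM from that initialization.
    min_covar : float, default 1e-3
        Variance floor of the diagonal emissions.
    random_state : int or None
        Master seed for k-means and EM.

    Attributes
    ----------
    centroids_ : (K, D) k-means initial centroids, canonically ordered.
    means_, variances_ : (K, D) fitted emission parameters.
    transmat_ : (K, K) fitted transition matrix.
    startprob_ : (K,) fitted initial distribution.
    fit_log_ : dict with seed, iteration count, convergence flag and the
        full log-likelihood trace.
    """

    def __init__(self, n_states: int = 5, n_kmeans_init: int = 20,
                 max_iter: int = 200, tol: float = 1e-4,
                 freeze_means: bool = False, min_covar: float = 1e-3,
                 random_state=None):
        self.n_states = n_states
        self.n_kmeans_init = n_kmeans_init
        self.max_iter = max_iter
        self.tol = tol
        self.freeze_means = freeze_means
        self.min_covar = min_covar
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X, lengths=None):
        X = np.asarray(X, dtype=float)
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        K = self.n_states
        centroids = kmeans_init(X, K, self.random_state,
                                n_init=self.n_kmeans_init)
        hmm = GaussianHMM(
            n_components=K, covariance_type="diag",
            n_iter=self.max_iter, tol=self.tol,
            min_covar=self.min_covar,
            init_params="",
            params="stc" if self.freeze_means else "stmc",
            random_state=self.random_state,
        )
        hmm.startprob_ = np.full(K, 1.0 / K)
        # sticky start: microstates persist for tens of samples
        transmat0 = np.full((K, K), 0.2 / (K - 1))
        np.fill_diagonal(transmat0, 0.8)
        hmm.transmat_ = transmat0
        hmm.means_ = centroids.copy()
        hmm.covars_ = np.ones((K, X.shape[1]))
        hmm.monitor_ = _FullHistoryMonitor(hmm.tol, hmm.n_iter)
        hmm.fit(X, lengths=lengths)
        trace = list(hmm.monitor_.history)
        if not np.all(np.isfinite(trace)):
            bad = int(np.flatnonzero(~np.isfinite(trace))[0])
            raise FloatingPointError(
                f"non-finite log-likelihood at EM iteration {bad}")
        self._hmm = hmm
        self.centroids_ = centroids
        self._canonical_reorder(X, lengths)
        self.n_features_in_ = X.shape[1]
        self.fit_log_ = {
            "seed": self.random_state,
            "n_iter": len(trace),
            "converged": bool(hmm.monitor_.converged),
            "loglik_trace": [float(v) for v in trace],
        }
        return self

    def _canonical_reorder(self, X, lengths):
        """Relabel states by descending pooled occupancy (ties: ascending
        first-channel centroid), so identities are stable across runs."""
        path = self._hmm.predict(X, lengths=lengths)
        occ = np.bincount(path, minlength=self.n_states) / len(path)
        order = np.lexsort((self.centroids_[:, 0], -occ))
        hmm = self._hmm
        hmm.startprob_ = hmm.startprob_[order]
        hmm.transmat_ = hmm.transmat_[np.ix_(order, order)]
        hmm.means_ = hmm.means_[order]
        hmm.covars_ = np.asarray(
            [np.diag(c) for c in hmm.covars_])[order]
        self.centroids_ = self.centroids_[order]

    # -- fitted accessors -------------------------------------------------
    @property
    def startprob_(self):
        return self._hmm.startprob_

    @property
    def transmat_(self):
        return self._hmm.transmat_

    @property
    def means_(self):
        return self._hmm.means_

    @property
    def variances_(self):
        return np.asarray([np.diag(c) for c in self._hmm.covars_])

    # -- inference --------------------------------------------------------
    def predict(self, X, lengths=None):
        """Viterbi most-probable state path (0-based labels)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model fitted on {self.n_features_in_} channels, "
                f"got {X.shape[1]}")
        return self._hmm.predict(X, lengths=lengths)

    def score(self, X, lengths=None):
        """Total log-likelihood of the sequences under the model."""
        return self._hmm.score(np.asarray(X, dtype=float), lengths=lengths)

    def aic(self, X, lengths=None):
        p = hmm_n_parameters(self.n_states, self.n_features_in_)
        return 2 * p - 2 * self.score(X, lengths)

    def bic(self, X, lengths=None):
        X = np.asarray(X, dtype=float)
        p = hmm_n_parameters(self.n_states, self.n_features_in_)
        return p * np.log(X.shape[0]) - 2 * self.score(X, lengths)


# ---------------------------------------------------------------------------
# functional surface

def _pool(series: list[SpatialPatternSeries]):
    """Concatenate sequences, dropping degenerate rows; a dropped row also
    splits its sequence so no spurious transition bridges the gap."""
    chunks, lengths = [], []
    for s in series:
        good = ~s.degenerate
        # contiguous runs of good rows
        edges = np.flatnonzero(np.diff(np.r_[0, good.view(np.int8), 0]))
        for start, stop in zip(edges[::2], edges[1::2]):
            chunks.append(s.z[start:stop])
            lengths.append(stop - start)
    if not chunks:
        raise ValueError("no usable (non-degenerate) samples to fit on")
    return np.vstack(chunks), lengths


def fit_hmm(series: list[SpatialPatternSeries], n_states: int = 5,
            seed=None, **kwargs) -> MicrostateHMM:
    """Fit the shared microstate model on pooled participant sequences."""
    X, lengths = _pool(series)
    model = MicrostateHMM(n_states=n_states, random_state=seed, **kwargs)
    return model.fit(X, lengths=lengths)


def decode(model: MicrostateHMM,
           participant: SpatialPatternSeries) -> StateSequence:
    """Viterbi-decode one participant under the shared model (labels 1..K)."""
    labels = model.predict(participant.z) + 1
    return StateSequence(labels=labels,
                         participant_id=participant.participant_id,
                         group=participant.group, fs_hz=participant.fs_hz)


def elbow_point(ks: np.ndarray, criterion: np.ndarray) -> int:
    """K maximizing the discrete second difference of the criterion curve.

    Requires at least 3 candidates; ties resolve to the smallest K.
    """
    ks = np.asarray(ks)
    c = np.asarray(criterion, dtype=float)
    if len(ks) < 3:
        raise ValueError("elbow undefined for fewer than 3 candidate K")
    d2 = c[:-2] - 2 * c[1:-1] + c[2:]
    return int(ks[1:-1][int(np.argmax(d2))])


def select_n_states(series: list[SpatialPatternSeries],
                    k_range=range(2, 11), seed=None,
                    criterion: str = "bic",
                    **kwargs) -> tuple[pd.DataFrame, int]:
    """AIC/BIC model-order scan.

    Fits one model per candidate K and returns the full criterion curve
    (k, log_likelihood, n_params, aic, bic) plus the elbow of the chosen
    criterion (maximum discrete second difference).
    """
    ks = sorted(k_range)
    X, lengths = _pool(series)
    rows = []
    for k in ks:
        m = MicrostateHMM(n_states=k, random_state=seed, **kwargs)
        m.fit(X, lengths=lengths)
        ll = m.score(X, lengths=lengths)
        p = hmm_n_parameters(k, X.shape[1])
        rows.append({
            "k": k, "log_likelihood": ll, "n_params": p,
            "aic": 2 * p - 2 * ll,
            "bic": p * np.log(X.shape[0]) - 2 * ll,
        })
    curve = pd.DataFrame(rows)
    best = elbow_point(curve["k"].to_numpy(),
                       curve[criterion].to_numpy())
    return curve, best


def match_labels(true_labels: np.ndarray,
                 decoded_labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal global permutation of decoded labels onto true labels
    (Hungarian assignment on the confusion matrix).

    Returns the permuted decoded labels and the resulting accuracy.
    Both inputs are 1-based.
    """
    t = np.asarray(true_labels, dtype=int)
    d = np.asarray(decoded_labels, dtype=int)
    K = max(t.max(), d.max())
    conf = np.zeros((K, K))
    np.add.at(conf, (d - 1, t - 1), 1)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    remapped = perm[d - 1] + 1
    return remapped, float(np.mean(remapped == t))


# ---------------------------------------------------------------------------
# serialization

def save_model(model: MicrostateHMM, path: str | Path) -> None:
    payload = {
        "n_states": model.n_states,
        "centroids": model.centroids_.tolist(),
        "startprob": model.startprob_.tolist(),
        "transmat": model.transmat_.tolist(),
        "means": model.means_.tolist(),
        "variances": model.variances_.tolist(),
        "fit_log": model.fit_log_,
        "params": model.get_params(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> MicrostateHMM:
    payload = json.loads(Path(path).read_text())
    model = MicrostateHMM(**payload["params"])
    K = payload["n_states"]
    means = np.asarray(payload["means"], dtype=float)
    hmm = GaussianHMM(n_components=K, covariance_type="diag",
                      init_params="", min_covar=model.min_covar)
    hmm.startprob_ = np.asarray(payload["startprob"], dtype=float)
    hmm.transmat_ = np.asarray(payload["transmat"], dtype=float)
    hmm.means_ = means
    hmm.covars_ = np.asarray(payload["variances"], dtype=float)
    model._hmm = hmm
    model.centroids_ = np.asarray(payload["centroids"], dtype=float)
    model.fit_log_ = payload["fit_log"]
    model.n_features_in_ = means.shape[1]
    return model
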