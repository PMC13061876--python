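"""End-to-end run orchestration.

``run_full`` drives simulate (or load) -> band-pass -> trim -> IF
extraction -> spatial normalization -> shared HMM fit (fixed K or AIC/BIC
scan) -> per-participant Viterbi decoding -> dynamics metrics -> group
statistics, writing every artifact plus a provenance record (config echo
and master seed) so a rerun is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, states, stats, synthetic
from .frequency import extract_if
from .io import EEGRecording, read_recording
from .preprocessing import BandSpec, bandpass, trim_edges

__all__ = ["RunConfig", "run_full", "export_state_maps", "load_config"]

# analysis defaults: 4-13 Hz band, 5-s edge trims, 100-ms median,
# 200 Hz / 60 s recordings
@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    band_low_hz: float = 4.0
    band_high_hz: float = 13.0
    trim_s: float = 5.0
    median_ms: float = 100.0
    fs_hz: float = 200.0
    duration_s: float = 60.0
    n_states: int | None = 5          # fixed K ...
    k_range: tuple[int, int] | None = None  # ... or (lo, hi) scan
    seed: int = 0
    input_dir: str | None = None      # read recordings instead of simulating
    n_per_group: tuple[int, int] = (29, 18)
    noise_sd: float = 0.2
    test: str = "auto"                # auto | welch | student
    alpha: float = 0.05
    fdr_q: float = 0.05
    hmm_max_iter: int = 200
    hmm_tol: float = 1e-4
    n_kmeans_init: int = 20

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unspecified keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("n_per_group", "k_range"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _load_inputs(config: RunConfig):
    """Either simulate the default cohort or read recordings from disk."""
    if config.input_dir is None:
        spec = synthetic.default_cohort_spec(
            seed=config.seed, n_per_group=config.n_per_group,
            duration_s=config.duration_s, noise_sd=config.noise_sd)
        return [rec for rec, _ in synthetic.make_cohort(spec)]
    recs = []
    for path in sorted(Path(config.input_dir).iterdir()):
        if path.suffix.lower() in (".csv", ".edf"):
            recs.append(read_recording(path, fs_hz=config.fs_hz))
    if not recs:
        raise FileNotFoundError(
            f"no .csv/.edf recordings in {config.input_dir}")
    return recs


def export_state_maps(model: states.MicrostateHMM,
                      channel_labels,
                      pattern_series: list[states.SpatialPatternSeries]
                      | None = None,
                      sequences: list[states.StateSequence]
                      | None = None) -> pd.DataFrame:
    """Per-state centroid table, optionally with group-averaged patterns.

    One row per (state, source); columns are the channel labels.  Sources
    are the model centroids and, when decoded data are supplied, the mean
    z-scored pattern within each decoded state per group.
    """
    rows = []
    for k in range(model.n_states):
        rows.append({"state": k + 1, "source": "centroid",
                     **dict(zip(channel_labels, model.centroids_[k]))})
        rows.append({"state": k + 1, "source": "emission_mean",
                     **dict(zip(channel_labels, model.means_[k]))})
    if pattern_series is not None and sequences is not None:
        by_group: dict[str, dict[int, list]] = {}
        for s, q in zip(pattern_series, sequences):
            acc = by_group.setdefault(s.group, {})
            for k in range(1, model.n_states + 1):
                sel = q.labels == k
                if sel.any():
                    acc.setdefault(k, []).append(s.z[sel].mean(axis=0))
        for group, acc in sorted(by_group.items()):
            for k, vecs in sorted(acc.items()):
                rows.append({"state": k, "source": f"group_mean:{group}",
                             **dict(zip(channel_labels,
                                        np.mean(vecs, axis=0)))})
    return pd.DataFrame(rows)


def run_full(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the whole pipeline; returns the in-memory result bundle.

    Artifacts written to ``out_dir``: ``model.json``, ``sequences.csv``,
    ``metrics.csv``, ``transitions.csv``, ``comparisons.csv``,
    ``signed_scores.csv``, ``state_maps.csv``, ``selection_curve.csv``
    (when a K scan is requested), ``provenance.yaml`` and
    ``run_report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"warnings": [], "stage": None}

    def _stage(name):
        report["stage"] = name
        return name

    try:
        _stage("load")
        recordings = _load_inputs(config)
        _stage("preprocess")
        band = BandSpec(config.band_low_hz, config.band_high_hz)
        prepared = [trim_edges(bandpass(r, band), config.trim_s)
                    for r in recordings]
        _stage("extract_if")
        series = [states.spatial_normalize(
            extract_if(r, median_ms=config.median_ms)) for r in prepared]
        n_degenerate = int(sum(s.degenerate.sum() for s in series))
        if n_degenerate:
            report["warnings"].append(
                f"{n_degenerate} degenerate (zero-variance) samples excluded")
        _stage("fit")
        hmm_kwargs = dict(max_iter=config.hmm_max_iter, tol=config.hmm_tol,
                          n_kmeans_init=config.n_kmeans_init)
        curve = None
        if config.k_range is not None:
            lo, hi = config.k_range
            curve, k_best = states.select_n_states(
                series, range(lo, hi + 1), seed=config.seed, **hmm_kwargs)
            curve.to_csv(out / "selection_curve.csv", index=False)
        else:
            k_best = config.n_states
        model = states.fit_hmm(series, n_states=k_best, seed=config.seed,
                               **hmm_kwargs)
        if not model.fit_log_["converged"]:
            report["warnings"].append("EM hit max_iter without converging")
        states.save_model(model, out / "model.json")
        _stage("decode")
        sequences = [states.decode(model, s) for s in series]
        seq_rows = pd.concat(
            [pd.DataFrame({"participant_id": q.participant_id,
                           "sample_index": np.arange(q.labels.size),
                           "label": q.labels}) for q in sequences],
            ignore_index=True)
        seq_rows.to_csv(out / "sequences.csv", index=False)
        _stage("metrics")
        metrics = [dynamics.compute_metrics(q, model.n_states)
                   for q in sequences]
        mframe = dynamics.metrics_frame(metrics)
        tframe = dynamics.transitions_frame(metrics)
        mframe.to_csv(out / "metrics.csv", index=False)
        tframe.to_csv(out / "transitions.csv", index=False)
        _stage("compare")
        comparisons = stats.compare_cohort(
            mframe, tframe, test=config.test,
            alpha=config.alpha, fdr_q=config.fdr_q)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        score, mask = stats.signed_significance_map(
            comparisons, model.n_states)
        pd.DataFrame(score).to_csv(out / "signed_scores.csv", index=False)
        _stage("export")
        maps = export_state_maps(model, prepared[0].channel_labels,
                                 series, sequences)
        maps.to_csv(out / "state_maps.csv", index=False)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{report['stage']}': {exc}") from exc

    (out / "provenance.yaml").write_text(
        yaml.safe_dump({"config": config.to_dict(),
                        "master_seed": config.seed}))
    report["stage"] = "done"
    report["n_participants"] = len(recordings)
    report["selected_k"] = int(model.n_states)
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return {
        "model": model, "sequences": sequences, "metrics": metrics,
        "metrics_frame": mframe, "transitions_frame": tframe,
        "comparisons": comparisons, "signed_scores": score,
        "significance_mask": mask, "selection_curve": curve,
        "state_maps": maps, "report": report,
    }
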