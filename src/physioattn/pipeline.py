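"""End-to-end orchestration: synthesize → preprocess → features → evaluate.

A single :class:`PipelineConfig` carries every tunable.  Constants that are
fixed by the method itself — 10 s analysis windows, 1 Hz S-transform voice
step, the Delta…Gamma band edges, the band→wavelet plan, 5 decomposition
levels — default to those fixed values; the remaining knobs (smoothing frame,
filter order, entropy bins, classifier settings, synthesis parameters) are
free choices documented in the methods note.

Identical config + seed ⇒ identical feature tables and reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import ecg as ecg_mod
from . import eeg as eeg_mod
from .classify import CLASSIFIER_NAMES, EvaluationReport, evaluate_loso
from .ecg_features import extract_ecg_features
from .eeg_features import DEFAULT_WAVELET_PLAN, WaveletPlan, extract_eeg_features
from .io import FeatureTable, Modality, Recording, ValidationError, write_feature_table
from .stockwell import stransform, window_signal
from .synth import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "ecg_feature_rows", "eeg_feature_rows"]

logger = logging.getLogger("physioattn")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, serializable to/from a flat dict."""

    # synthesis
    n_subjects: int = 21
    segment_duration_s: float = 1200.0
    ecg_rate_hz: float = 128.0
    eeg_rate_hz: float = 1000.0
    effect_size: float = 1.0
    noise_sd: float = 0.05
    baseline_wander_amplitude: float = 0.3
    seed: int = 0
    # ECG preprocessing
    sg_window: int = 15
    sg_order: int = 3
    # S-transform
    window_duration_s: float = 10.0   # method-fixed
    st_freq_step_hz: float = 1.0      # method-fixed
    st_include_dc: bool = True
    # EEG bands / wavelets
    eeg_filter_order: int = 4
    eeg_zero_phase: bool = True
    dwt_levels: int = 5               # method-fixed
    entropy_bins: int | None = None   # None → Rice rule
    centered_rms: bool = False
    # classification
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    rf_n_estimators: int = 100
    tree_max_depth: int | None = None
    weighted_average: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "classifiers" in data:
            data = {**data, "classifiers": tuple(data["classifiers"])}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(d["classifiers"])
        return d

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_subjects=self.n_subjects,
            segment_duration_s=self.segment_duration_s,
            ecg_rate_hz=self.ecg_rate_hz,
            eeg_rate_hz=self.eeg_rate_hz,
            seed=self.seed,
            effect_size=self.effect_size,
            noise_sd=self.noise_sd,
            baseline_wander_amplitude=self.baseline_wander_amplitude,
        )

    def wavelet_plan(self) -> WaveletPlan:
        return WaveletPlan(
            wavelets=DEFAULT_WAVELET_PLAN.wavelets, levels=self.dwt_levels
        )


def ecg_feature_rows(recording: Recording, config: PipelineConfig) -> list[dict]:
    """Preprocess one ECG recording and extract per-window feature rows."""
    if recording.modality is not Modality.ECG:
        raise ValidationError(
            f"ECG pipeline got a {recording.modality.value} recording "
            f"({recording.subject_id})"
        )
    smoothed = ecg_mod.sgolay_smooth(recording.samples, config.sg_window, config.sg_order)
    cleaned = ecg_mod.remove_baseline(smoothed, recording.sampling_rate_hz)
    clean_rec = dataclasses.replace(recording, samples=cleaned)
    rows: list[dict] = []
    start = 0
    for label, segment in ecg_mod.split_segments(clean_rec):
        windows = window_signal(
            segment, label, recording.subject_id, recording.sampling_rate_hz,
            duration_s=config.window_duration_s, start_index=start,
        )
        dropped = segment.size - len(windows) * int(
            round(recording.sampling_rate_hz * config.window_duration_s)
        )
        logger.info(
            "ECG %s/%s: %d windows, %d trailing samples dropped",
            recording.subject_id, label, len(windows), dropped,
        )
        for win in windows:
            st = stransform(win, config.st_freq_step_hz, include_dc=True)
            feats = extract_ecg_features(st, include_dc=config.st_include_dc)
            rows.append(
                {
                    "subject_id": win.subject_id,
                    "window_index": win.window_index,
                    "label": win.label,
                    **feats,
                }
            )
        start += len(windows)
    return rows


def eeg_feature_rows(recording: Recording, config: PipelineConfig) -> list[dict]:
    """Band-split one EEG recording and extract per-window feature rows."""
    if recording.modality is not Modality.EEG:
        raise ValidationError(
            f"EEG pipeline got a {recording.modality.value} recording "
            f"({recording.subject_id})"
        )
    bands = eeg_mod.extract_bands(
        recording, order=config.eeg_filter_order, zero_phase=config.eeg_zero_phase
    )
    rate = recording.sampling_rate_hz
    plan = config.wavelet_plan()
    rows: list[dict] = []
    start = 0
    for ann in recording.annotations:
        i0 = int(ann.start_s * rate)
        i1 = int(ann.end_s * rate)
        band_segments = {name: sig[i0:i1] for name, sig in bands.items()}
        seg_rows = extract_eeg_features(
            band_segments, ann.label, recording.subject_id, rate,
            plan=plan, window_duration_s=config.window_duration_s,
            start_index=start, bins=config.entropy_bins,
            centered_rms=config.centered_rms,
        )
        logger.info(
            "EEG %s/%s: %d windows", recording.subject_id, ann.label, len(seg_rows)
        )
        rows.extend(seg_rows)
        start += len(seg_rows)
    return rows


def build_feature_table(
    recordings: list[Recording], modality: Modality, config: PipelineConfig
) -> FeatureTable:
    extract = ecg_feature_rows if Modality(modality) is Modality.ECG else eeg_feature_rows
    rows: list[dict] = []
    for rec in recordings:
        rows.extend(extract(rec, config))
    return FeatureTable.from_rows(rows)


def run_pipeline(
    config: PipelineConfig,
    modality: Modality | str,
    recordings: list[Recording] | None = None,
    out_dir: str | Path | None = None,
) -> EvaluationReport:
    """Run the full chain for one modality and return the evaluation report.

    When ``recordings`` is omitted a synthetic cohort is generated from the
    config.  ``out_dir`` (optional) receives ``features_<modality>.csv`` and
    ``report_<modality>.json``.
    """
    modality = Modality(modality)
    if recordings is None:
        recordings = generate_cohort(config.synthetic_config(), modality)
    table = build_feature_table(recordings, modality, config)
    report = evaluate_loso(
        table,
        classifiers=config.classifiers,
        seed=config.seed,
        rf_n_estimators=config.rf_n_estimators,
        max_depth=config.tree_max_depth,
        weighted=config.weighted_average,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_feature_table(table, out_dir / f"features_{modality.value.lower()}.csv")
        (out_dir / f"report_{modality.value.lower()}.json").write_text(
            json.dumps(report.to_dict(percent=True), indent=2) + "\n"
        )
    return report
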