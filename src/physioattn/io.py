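"""Plain-text I/O for recordings, annotations, and feature tables.

The on-disk dialect is deliberately simple and versionable:

* a **signal file**: one sample per line (optionally ``time,value`` — the last
  column is the sample), plain decimal text;
* a **sidecar file**: JSON holding ``subject_id``, ``modality``,
  ``sampling_rate_hz`` and the labelled ``segments`` list;
* a **feature table**: comma-delimited text whose header is
  ``subject_id,window_index,label`` followed by the feature names in a fixed
  order.  Undefined statistics (log of a zero variance, autocorrelation of a
  constant) are serialized as the sentinel ``NA``, never as a silent zero.

Annotation intervals are half-open ``[start_s, end_s)`` in seconds from the
start of the recording.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "SegmentAnnotation",
    "Recording",
    "FeatureTable",
    "ParseError",
    "ValidationError",
    "ATTENTION",
    "NONATTENTION",
    "LABELS",
    "NA_SENTINEL",
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
]

#: Supervision labels: "attention" marks the engaging-stimulus intervals,
#: "nonattention" the monotonous ones.
ATTENTION = "attention"
NONATTENTION = "nonattention"
LABELS = (ATTENTION, NONATTENTION)

#: Text sentinel for undefined feature values.
NA_SENTINEL = "NA"

#: Reserved feature-table columns preceding the feature block.
INDEX_COLUMNS = ("subject_id", "window_index", "label")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class Modality(str, Enum):
    ECG = "ECG"
    EEG = "EEG"


@dataclass(frozen=True)
class SegmentAnnotation:
    """One labelled half-open time interval ``[start_s, end_s)``."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"annotation label must be one of {LABELS}, got {self.label!r}"
            )
        if not (self.start_s >= 0):
            raise ValidationError(f"start_s must be >= 0, got {self.start_s}")
        if not (self.end_s > self.start_s):
            raise ValidationError(
                f"end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )


@dataclass
class Recording:
    """A single-channel physiological recording with segment annotations.

    Samples are microvolt-scale raw values; units are carried, not
    interpreted.  Annotations must lie within the recording and must not
    overlap one another.
    """

    subject_id: str
    modality: Modality
    samples: np.ndarray
    sampling_rate_hz: float
    annotations: list[SegmentAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not (self.sampling_rate_hz > 0):
            raise ValidationError(
                f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}"
            )
        dur = self.duration_s
        for ann in self.annotations:
            if ann.end_s > dur + 1e-9:
                raise ValidationError(
                    f"annotation [{ann.start_s}, {ann.end_s}) exceeds recording "
                    f"duration {dur:.6g} s"
                )
        ordered = sorted(self.annotations, key=lambda a: a.start_s)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start_s < prev.end_s - 1e-9:
                raise ValidationError(
                    f"annotations overlap: [{prev.start_s}, {prev.end_s}) and "
                    f"[{nxt.start_s}, {nxt.end_s})"
                )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass
class FeatureTable:
    """Windows × named features, with subject / window / label index columns.

    Backed by a :class:`pandas.DataFrame` whose first three columns are
    ``subject_id``, ``window_index``, ``label`` and whose remaining columns are
    the feature values (floats; NaN encodes the undefined-value sentinel).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if cols[: len(INDEX_COLUMNS)] != list(INDEX_COLUMNS):
            raise ValidationError(
                f"feature table must start with columns {INDEX_COLUMNS}, got {cols[:3]}"
            )
        names = self.feature_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate feature names: {dupes}")
        for reserved in INDEX_COLUMNS:
            if reserved in names:
                raise ValidationError(f"feature name {reserved!r} is reserved")
        feat = self.frame[names]
        if len(feat) and not feat.map(
            lambda v: isinstance(v, (int, float, np.floating, np.integer))
        ).all().all():
            raise ValidationError("feature values must be numeric (NaN for NA)")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in INDEX_COLUMNS]

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subject_id"]))

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_rows(
        cls, rows: Iterable[dict], feature_names: Sequence[str] | None = None
    ) -> "FeatureTable":
        """Build a table from per-window dicts holding index keys + features."""
        rows = list(rows)
        if feature_names is None:
            if not rows:
                raise ValidationError("feature_names required for an empty table")
            feature_names = [k for k in rows[0] if k not in INDEX_COLUMNS]
        for name in feature_names:
            if name in INDEX_COLUMNS:
                raise ValidationError(f"feature name {name!r} is reserved")
        frame = pd.DataFrame(rows, columns=[*INDEX_COLUMNS, *feature_names])
        return cls(frame)


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def _parse_signal_lines(text: str, path: Path) -> np.ndarray:
    values: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        token = line.split(",")[-1].strip() if "," in line else line.split()[-1]
        try:
            values.append(float(token))
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed numeric value on line {lineno}: {raw!r}"
            ) from exc
    if not values:
        raise ParseError(f"{path}: signal file contains no samples")
    return np.asarray(values, dtype=float)


def read_recording(signal_path: str | Path, annotation_path: str | Path) -> Recording:
    """Read a signal file plus its JSON sidecar into a validated Recording.

    The sidecar may declare ``n_samples``; if present it is checked against
    the actual line count so truncated files never pass silently.
    """
    signal_path = Path(signal_path)
    annotation_path = Path(annotation_path)
    samples = _parse_signal_lines(signal_path.read_text(), signal_path)
    try:
        meta = json.loads(annotation_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{annotation_path}: invalid JSON sidecar: {exc}") from exc
    for key in ("subject_id", "modality", "sampling_rate_hz", "segments"):
        if key not in meta:
            raise ParseError(f"{annotation_path}: sidecar missing key {key!r}")
    declared = meta.get("n_samples")
    if declared is not None and int(declared) != samples.size:
        raise ValidationError(
            f"{signal_path}: sidecar declares {declared} samples "
            f"but file holds {samples.size}"
        )
    annotations = [
        SegmentAnnotation(seg["label"], float(seg["start_s"]), float(seg["end_s"]))
        for seg in meta["segments"]
    ]
    return Recording(
        subject_id=str(meta["subject_id"]),
        modality=Modality(meta["modality"]),
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        annotations=annotations,
    )


def write_recording(
    recording: Recording, signal_path: str | Path, annotation_path: str | Path
) -> None:
    """Write a Recording as a one-sample-per-line file plus JSON sidecar."""
    signal_path = Path(signal_path)
    annotation_path = Path(annotation_path)
    lines = "\n".join(repr(float(v)) for v in recording.samples)
    signal_path.write_text(lines + "\n")
    meta = {
        "subject_id": recording.subject_id,
        "modality": recording.modality.value,
        "sampling_rate_hz": recording.sampling_rate_hz,
        "n_samples": int(recording.samples.size),
        "segments": [
            {"label": a.label, "start_s": a.start_s, "end_s": a.end_s}
            for a in recording.annotations
        ],
    }
    annotation_path.write_text(json.dumps(meta, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write the table as comma-delimited text with the ``NA`` sentinel."""
    table.frame.to_csv(path, index=False, na_rep=NA_SENTINEL)


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    frame = pd.read_csv(
        path, keep_default_na=False, na_values=[NA_SENTINEL], dtype={"subject_id": str}
    )
    if "window_index" in frame.columns and len(frame):
        frame["window_index"] = frame["window_index"].astype(int)
    for col in frame.columns:
        if col not in INDEX_COLUMNS:
            frame[col] = frame[col].astype(float)
    return FeatureTable(frame)
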