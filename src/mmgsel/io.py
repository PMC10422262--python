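"""Plain-text I/O: recording CSV + sidecar JSON, annotations, feature CSV.

Formats
-------
* Recording: CSV with one header row of channel names, one column per
  channel, one row per sample; the sampling rate and channel list live in a
  sidecar JSON ``{"fs": 250, "channels": [...]}``.
* Segment annotations: JSON list of
  ``{"start": int, "end": int, "label": str, "condition": str}`` with
  0-based half-open sample ranges.
* Feature matrix: CSV whose first column is the label, remaining columns
  the named features; round-trips losslessly through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .preprocess import LabeledSegment, MultichannelRecording, Segment


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_recording(rec: MultichannelRecording, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(rec.data, columns=rec.channel_names).to_csv(csv_path, index=False)
    with open(_sidecar(csv_path), "w") as fh:
        json.dump({"fs": rec.fs, "channels": rec.channel_names}, fh)


def load_recording(csv_path) -> MultichannelRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    with open(_sidecar(csv_path)) as fh:
        meta = json.load(fh)
    return MultichannelRecording(
        data=df.to_numpy(dtype=float),
        fs=float(meta["fs"]),
        channel_names=list(meta.get("channels", df.columns)),
    )


def save_segments(segments: list[LabeledSegment], path) -> None:
    records = [
        {
            "start": int(ls.segment.start),
            "end": int(ls.segment.end),
            "label": ls.label,
            "condition": ls.condition,
        }
        for ls in segments
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def load_segments(path, rec: MultichannelRecording) -> list[LabeledSegment]:
    """Re-attach stored annotations to a recording's samples."""
    with open(path) as fh:
        records = json.load(fh)
    out = []
    for r in records:
        s, e = int(r["start"]), int(r["end"])
        seg = Segment(start=s, end=e, data=rec.data[s:e])
        out.append(LabeledSegment(segment=seg, label=r["label"], condition=r.get("condition", "")))
    return out


def feature_matrix_to_csv(fm: FeatureMatrix, path) -> None:
    df = pd.DataFrame(fm.X, columns=fm.names)
    df.insert(0, "label", fm.y)
    df.to_csv(path, index=False)


def feature_matrix_from_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    y = df.pop("label").to_numpy()
    return FeatureMatrix(X=df.to_numpy(dtype=float), names=list(df.columns), y=y)


def confusion_to_csv(percent: np.ndarray, classes, path) -> None:
    """Write a row-normalized percent confusion matrix, targets as rows."""
    df = pd.DataFrame(percent, index=list(classes), columns=list(classes))
    df.index.name = "target"
    df.to_csv(path, float_format="%.2f")
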