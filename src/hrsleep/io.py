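"""Readers, writers and run manifests.

All artifacts are delimited text: device exports are heterogeneous, so
plain CSV with ISO-8601 timezone-naive timestamps is the device-agnostic
common denominator.  Heart-rate files carry a ``timestamp,hr`` header;
label files carry ``timestamp,label`` with label in {0, 1, NA}.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import AlgorithmParams, SleepAnnotation
from .ts_core import HRSeries, InputFormatError, InsufficientDataError, LabelSeries, regularize

logger = logging.getLogger(__name__)

__all__ = [
    "read_hr_file",
    "read_label_file",
    "write_label_file",
    "write_hr_file",
    "write_windows_table",
    "write_outputs",
    "params_to_dict",
    "params_from_dict",
]

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


def read_hr_file(
    path, epoch_length: int | None = None, max_gap: float = 5.0, subject_id: str | None = None
) -> HRSeries:
    """Read a ``timestamp,hr`` file and return a regularized series.

    If ``epoch_length`` is omitted it is inferred as the modal spacing of
    the timestamps.  ``NA`` or blank heart-rate fields become missing
    epochs.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("timestamp", "hr"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise InsufficientDataError(f"{path}: no data rows")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise InputFormatError(f"{path}: unparseable timestamp: {exc}") from exc
    hr = pd.to_numeric(df["hr"], errors="coerce").to_numpy()
    if epoch_length is None:
        diffs = np.diff(np.sort(ts.to_numpy().astype("datetime64[s]").astype(np.int64)))
        diffs = diffs[diffs > 0]
        if diffs.size == 0:
            raise InsufficientDataError(f"{path}: cannot infer epoch length")
        vals, counts = np.unique(diffs, return_counts=True)
        epoch_length = int(vals[np.argmax(counts)])
    series = regularize(
        list(zip(ts, hr)), epoch_length, max_gap=max_gap,
        subject_id=subject_id if subject_id is not None else path.stem,
    )
    logger.info(
        "%s: %d rows -> %d epochs (%d missing), span %s .. %s",
        path.name, len(df), len(series), series.n_missing,
        series.times[0], series.times[-1],
    )
    return series


def read_label_file(path) -> LabelSeries:
    """Read a ``timestamp,label`` file (label in {0, 1, NA})."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("timestamp", "label"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise InsufficientDataError(f"{path}: no data rows")
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    lab = pd.to_numeric(df["label"], errors="coerce").to_numpy()
    if len(ts) > 1:
        spacing = int((ts[1] - ts[0]).total_seconds())
    else:
        spacing = 60
    return LabelSeries(spacing, ts, lab)


def write_label_file(labels: LabelSeries, path) -> None:
    path = Path(path)
    lab = pd.Series(labels.labels).map(
        lambda v: "NA" if not np.isfinite(v) else str(int(v))
    )
    pd.DataFrame(
        {"timestamp": labels.times.strftime(_TIME_FMT), "label": lab}
    ).to_csv(path, index=False)


def write_hr_file(series: HRSeries, path) -> None:
    path = Path(path)
    hr = pd.Series(series.hr).map(lambda v: "NA" if not np.isfinite(v) else f"{v:.3f}")
    pd.DataFrame(
        {"timestamp": series.times.strftime(_TIME_FMT), "hr": hr}
    ).to_csv(path, index=False)


def windows_frame(annotations: list[SleepAnnotation]) -> pd.DataFrame:
    """Per-day windows table for a subject's annotations."""
    rows = []
    for ann in annotations:
        rows.append(
            {
                "subject": ann.subject_id,
                "day": ann.day.day_index,
                "onset": ann.onset.strftime(_TIME_FMT) if ann.detected else "NA",
                "offset": ann.offset.strftime(_TIME_FMT) if ann.detected else "NA",
                "tst_min": round(ann.tst, 2),
                "n_naps": len(ann.naps),
                "n_awakenings": len(ann.awakenings),
                "polyphasic_flag": int(ann.polyphasic),
            }
        )
    return pd.DataFrame(rows)


def write_windows_table(annotations: list[SleepAnnotation], path) -> None:
    windows_frame(annotations).to_csv(path, index=False)


def params_to_dict(params: AlgorithmParams) -> dict:
    d = dataclasses.asdict(params)
    d["day_start"] = params.day_start.strftime("%H:%M")
    d["daytime_span"] = [t.strftime("%H:%M") for t in params.daytime_span]
    return d


def params_from_dict(d: dict) -> AlgorithmParams:
    d = dict(d)
    if "day_start" in d and isinstance(d["day_start"], str):
        d["day_start"] = _dt.time.fromisoformat(d["day_start"])
    if "daytime_span" in d:
        d["daytime_span"] = tuple(
            _dt.time.fromisoformat(t) if isinstance(t, str) else t
            for t in d["daytime_span"]
        )
    return AlgorithmParams(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    annotations: list[SleepAnnotation],
    out_dir,
    params: AlgorithmParams,
    input_paths=(),
    metrics: pd.DataFrame | None = None,
    epoch_labels: LabelSeries | None = None,
) -> dict:
    """Write windows table, optional labels/metrics and a run manifest.

    The manifest records the effective parameters and input checksums so a
    run is reproducible byte-for-byte from (inputs, config).  Returns the
    manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_windows_table(annotations, out_dir / "windows.csv")
    if epoch_labels is not None:
        write_label_file(epoch_labels, out_dir / "labels.csv")
    if metrics is not None:
        metrics.to_csv(out_dir / "metrics.csv", index=False)
    manifest = {
        "params": params_to_dict(params),
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths},
        "n_days": len(annotations),
        "n_detected": sum(a.detected for a in annotations),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
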