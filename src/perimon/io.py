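"""Readers and writers for the on-disk fixture layout.

A fixture directory mirrors what the collection backend would persist:

    fixture/
      ppg/<participant>/session_<start_min>.csv   (timestamp_ms,ppg)
      actigraphy/<participant>.csv                (timestamp_min,counts,steps)
      cohort.csv                                  (participant_id,date,wear_h,answered,bp_count)
      meta.csv                                    (participant_id,enrollment_gw,delivery_date)
      truth.json                                  (generator ground truth, optional)

Everything is plain CSV/JSON so fixtures stay inspectable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quality import NnSeries, PpgStream, QualityLabel

__all__ = [
    "read_ppg_csv",
    "write_ppg_csv",
    "write_nn_csv",
    "write_quality_json",
    "read_activity_csv",
    "write_activity_csv",
    "read_cohort_csv",
    "write_json",
]


def read_ppg_csv(path: str | Path, nominal_rate: float = 20.0) -> PpgStream:
    """Read one session's PPG stream (columns ``timestamp_ms,ppg``)."""
    df = pd.read_csv(path)
    if not {"timestamp_ms", "ppg"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns timestamp_ms,ppg")
    return PpgStream(
        df["timestamp_ms"].to_numpy(dtype=float),
        df["ppg"].to_numpy(dtype=float),
        nominal_rate,
    )


def write_ppg_csv(path: str | Path, timestamps_ms: np.ndarray, samples: np.ndarray) -> None:
    pd.DataFrame({"timestamp_ms": np.round(timestamps_ms, 3), "ppg": np.round(samples, 5)}).to_csv(
        path, index=False
    )


def write_nn_csv(path: str | Path, nn: NnSeries) -> None:
    """NN series as ``beat_time_ms,nn_ms`` rows (retained intervals only)."""
    pd.DataFrame(
        {"beat_time_ms": np.round(nn.nn_times_ms, 3), "nn_ms": np.round(nn.nn_ms, 3)}
    ).to_csv(path, index=False)


def write_quality_json(path: str | Path, labels: list[QualityLabel]) -> None:
    payload = [
        {
            "start_ms": lab.start_ms,
            "end_ms": lab.end_ms,
            "label": "reliable" if lab.reliable else "unreliable",
            "reasons": list(lab.reasons),
        }
        for lab in labels
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"timestamp_min", "counts"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns timestamp_min,counts[,steps]")
    if "steps" not in df.columns:
        df["steps"] = 0
    return df


def write_activity_csv(path: str | Path, epochs: pd.DataFrame) -> None:
    epochs[["timestamp_min", "counts", "steps"]].to_csv(path, index=False)


def read_cohort_csv(records_path: str | Path, meta_path: str | Path):
    from .adherence import CohortTimeline

    return CohortTimeline(pd.read_csv(records_path), pd.read_csv(meta_path))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def write_json(path: str | Path, payload) -> None:
    """Deterministic JSON writer (sorted keys, no wallclock metadata)."""
    Path(path).write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True) + "\n")
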