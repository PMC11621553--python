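"""Readers and writers for the package's on-disk formats.

Traces travel as long-format CSV (nucleus_id, time_s, intensity, plus
optional group/stage columns), ground truth as a JSON sidecar, stacks as
multi-page grayscale TIFF (16-bit by default) and masks as 8-bit 0/255 TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InvalidParameterError
from .imaging import ImageStack, ROIMask
from .traces import FluorescenceTrace


def write_traces_csv(traces: Iterable[FluorescenceTrace], path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "nucleus_id": t.nucleus_id,
                    "time_s": t.times,
                    "intensity": t.values,
                    "group": t.group,
                    "stage": t.stage,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["nucleus_id", "time_s", "intensity", "group", "stage"]
    )
    df.to_csv(path, index=False)


def read_traces_csv(path, dt: Optional[float] = None) -> list[FluorescenceTrace]:
    """Read a long-format trace table; dt inferred from time_s when omitted."""
    df = pd.read_csv(path)
    required = {"nucleus_id", "time_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"trace CSV lacks columns: {sorted(missing)}")
    traces = []
    for nid, sub in df.groupby("nucleus_id", sort=True):
        sub = sub.sort_values("time_s")
        times = sub["time_s"].to_numpy(dtype=float)
        if dt is None:
            diffs = np.diff(times)
            if diffs.size == 0:
                raise InvalidParameterError(f"nucleus {nid!r} has a single sample")
            step = float(np.median(diffs))
            if not np.allclose(diffs, step, rtol=1e-6, atol=1e-9):
                raise InvalidParameterError(f"nucleus {nid!r} is not uniformly sampled")
        else:
            step = dt
        def _label(col: str) -> str:
            if col not in sub:
                return ""
            v = sub[col].iloc[0]
            return "" if pd.isna(v) else str(v)

        traces.append(
            FluorescenceTrace(
                nucleus_id=str(nid),
                values=sub["intensity"].to_numpy(dtype=float),
                dt=step,
                group=_label("group"),
                stage=_label("stage"),
            )
        )
    return traces


def write_ground_truth_json(truths: dict, path) -> None:
    """Ground-truth sidecar: {nucleus_id: {spike_times, per_spike_amplitude}}."""
    payload = {
        nid: {
            "spike_times": list(map(float, gt.spike_times)),
            "per_spike_amplitude": list(map(float, gt.per_spike_amplitude)),
        }
        for nid, gt in truths.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def save_stack(stack: ImageStack, path, dtype=np.uint16) -> None:
    data = stack.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.round(data), info.min, info.max).astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")


def load_stack(path, axis: str = "z") -> ImageStack:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, axis=axis)


def save_mask(mask: ROIMask, path) -> None:
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255), photometric="minisblack")


def load_mask(path, provenance: str = "supplied") -> ROIMask:
    data = tifffile.imread(path)
    return ROIMask(mask=data > 0, provenance=provenance)


def write_summary_tables(freq: pd.DataFrame, amp: pd.DataFrame, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "frequency_csv": out / "frequency.csv",
        "amplitude_csv": out / "amplitude.csv",
        "frequency_json": out / "frequency.json",
        "amplitude_json": out / "amplitude.json",
    }
    freq.to_csv(paths["frequency_csv"], index=False)
    amp.to_csv(paths["amplitude_csv"], index=False)
    paths["frequency_json"].write_text(freq.to_json(orient="records", indent=2))
    paths["amplitude_json"].write_text(amp.to_json(orient="records", indent=2))
    return {k: str(v) for k, v in paths.items()}
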