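"""File formats: multi-channel TIFF + JSON sidecars, line tables, tidy CSVs.

Conventions
-----------
* Image stacks are written one TIFF per replicate with axis order CZYX
  (channel, z, row, column), float32, accompanied by a ``<stem>.json``
  sidecar declaring the axis order, channel labels and pixel size.
* Profiles and averages travel as tidy CSV:
  ``stack_id,line_label,channel,position_px,value`` for profiles and
  ``channel,position_px,mean,sem,n`` for averages; both round-trip through
  their readers without loss.
* Line endpoints are a delimited table with columns
  ``stack_id,label,start_row,start_col,end_row,end_col,linewidth,medial_end``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .alignment import AverageProfile, PeakFit
from .imaging import ImageStack, LineSpec, NormalizedProfile
from .synthetic import GroundTruth

__all__ = [
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_linespecs",
    "write_linespecs",
    "profiles_to_frame",
    "frame_to_profiles",
    "write_profiles",
    "read_profiles",
    "average_to_frame",
    "frame_to_average",
    "write_average",
    "read_average",
    "write_json",
    "sha256_file",
]

LINES_COLUMNS = [
    "stack_id",
    "label",
    "start_row",
    "start_col",
    "end_row",
    "end_col",
    "linewidth",
    "medial_end",
]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write one stack as CZYX float32 TIFF plus a JSON sidecar; returns the TIFF path."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels.astype(np.float32), photometric="minisblack")
    sidecar = {
        "axes": "CZYX",
        "channel_labels": list(stack.channel_labels),
        "pixel_size_um": stack.pixel_size,
        "stack_id": stack.stack_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF written by :func:`write_stack`, using its JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path} for image {path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("axes") != "CZYX":
        raise ValueError(f"unsupported axis order {sidecar.get('axes')!r} in {sidecar_path}")
    pixels = np.asarray(tifffile.imread(path), dtype=float)
    if pixels.ndim == 3:  # single-channel writers may squeeze C
        pixels = pixels[None]
    return ImageStack(
        pixels=pixels,
        channel_labels=tuple(sidecar["channel_labels"]),
        pixel_size=sidecar.get("pixel_size_um"),
        stack_id=sidecar.get("stack_id", path.stem),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "records": [dataclasses.asdict(r) for r in truth.records],
        "lines": [dataclasses.asdict(line) for line in truth.lines],
        "jitters": list(truth.jitters),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def write_linespecs(lines: dict[str, Sequence[LineSpec]], path: str | Path) -> Path:
    """Write a {stack_id: [LineSpec, ...]} mapping as a delimited line table."""
    rows = []
    for stack_id, specs in lines.items():
        for s in specs:
            rows.append(
                {
                    "stack_id": stack_id,
                    "label": s.label,
                    "start_row": s.start[0],
                    "start_col": s.start[1],
                    "end_row": s.end[0],
                    "end_col": s.end[1],
                    "linewidth": s.linewidth,
                    "medial_end": s.medial_end,
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=LINES_COLUMNS).to_csv(path, index=False)
    return path


def read_linespecs(path: str | Path) -> dict[str, list[LineSpec]]:
    df = pd.read_csv(path)
    missing = set(LINES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"line table {path} is missing columns: {sorted(missing)}")
    out: dict[str, list[LineSpec]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.stack_id), []).append(
            LineSpec(
                start=(float(row.start_row), float(row.start_col)),
                end=(float(row.end_row), float(row.end_col)),
                linewidth=int(row.linewidth),
                label=str(row.label),
                medial_end=str(row.medial_end),
            )
        )
    return out


def profiles_to_frame(profiles: Iterable[NormalizedProfile]) -> pd.DataFrame:
    """Tidy frame with one row per (stack, line, channel, position)."""
    frames = []
    for p in profiles:
        for ci, label in enumerate(p.channel_labels):
            frames.append(
                pd.DataFrame(
                    {
                        "stack_id": p.source[0],
                        "line_label": p.source[1],
                        "channel": label,
                        "position_px": p.positions,
                        "value": p.values[ci],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def frame_to_profiles(df: pd.DataFrame) -> list[NormalizedProfile]:
    """Rebuild profiles from the tidy CSV layout (norm_params are not stored)."""
    required = {"stack_id", "line_label", "channel", "position_px", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table is missing columns: {sorted(missing)}")
    out = []
    for (stack_id, line_label), sub in df.groupby(["stack_id", "line_label"], sort=False):
        labels = list(dict.fromkeys(sub["channel"]))
        positions = np.sort(sub["position_px"].unique())
        values = np.vstack(
            [
                sub.loc[sub["channel"] == lab].sort_values("position_px")["value"].to_numpy()
                for lab in labels
            ]
        )
        out.append(
            NormalizedProfile(
                positions=positions,
                values=values,
                channel_labels=tuple(labels),
                norm_params=None,
                source=(str(stack_id), str(line_label)),
            )
        )
    return out


# %.17g guarantees float64 -> text -> float64 round-trips exactly
_FLOAT_FMT = "%.17g"


def write_profiles(profiles: Iterable[NormalizedProfile], path: str | Path) -> Path:
    path = Path(path)
    profiles_to_frame(profiles).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_profiles(path: str | Path) -> list[NormalizedProfile]:
    # round_trip parsing pairs with the %.17g writer for lossless CSV cycles
    return frame_to_profiles(pd.read_csv(path, float_precision="round_trip"))


def average_to_frame(avg: AverageProfile) -> pd.DataFrame:
    frames = []
    for ci, label in enumerate(avg.channel_labels):
        frames.append(
            pd.DataFrame(
                {
                    "channel": label,
                    "position_px": avg.grid,
                    "mean": avg.means[ci],
                    "sem": avg.sems[ci],
                    "n": avg.n,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_average(df: pd.DataFrame) -> AverageProfile:
    required = {"channel", "position_px", "mean", "sem", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"average table is missing columns: {sorted(missing)}")
    labels = list(dict.fromkeys(df["channel"]))
    grid = np.sort(df["position_px"].unique())
    means = np.empty((len(labels), grid.size))
    sems = np.empty_like(means)
    for ci, lab in enumerate(labels):
        sub = df.loc[df["channel"] == lab].sort_values("position_px")
        means[ci] = sub["mean"].to_numpy()
        sems[ci] = sub["sem"].to_numpy()
    return AverageProfile(
        grid=grid,
        means=means,
        sems=sems,
        n=int(df["n"].iloc[0]),
        channel_labels=tuple(labels),
    )


def write_average(avg: AverageProfile, path: str | Path) -> Path:
    path = Path(path)
    average_to_frame(avg).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_average(path: str | Path) -> AverageProfile:
    return frame_to_average(pd.read_csv(path, float_precision="round_trip"))


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def fits_to_dict(fits: dict[str, PeakFit]) -> dict:
    return {image_id: fit.to_dict() for image_id, fit in fits.items()}


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
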