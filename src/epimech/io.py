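"""Readers and writers for the pipeline's on-disk formats.

Vertex tracks travel as long-format CSV with columns

    track_id, frame, time_s, vertex, x_um, y_um, phase

one row per (frame, vertex); ``vertex`` is 1 or 2 and ``phase`` is ``pre``
or ``post``. The ablation frame of a track is inferred as its last ``pre``
frame. Frames are 0-based, ``time_s`` is relative to acquisition start,
and coordinates are physical um with the origin at the top-left pixel
centre.

Image stacks travel as multi-page TIFF; the pixel size is resolved from
the TIFF resolution tags (ImageJ-style, written by :func:`write_stack`),
or from an explicit override, and it is an error to have neither. Clone
measurements and tidy condition tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .linescan import ImageStack
from .morphometry import CloneMeasurementSet
from .recoil import VertexTrack
from .stats import GroupComparison

__all__ = [
    "TRACK_COLUMNS",
    "SCHEMA_VERSION",
    "read_vertex_tracks",
    "write_tracks",
    "read_stack",
    "write_stack",
    "read_clone_sets",
    "write_clone_sets",
    "read_tidy_groups",
    "comparison_to_dict",
]

TRACK_COLUMNS = ["track_id", "frame", "time_s", "vertex", "x_um", "y_um", "phase"]
SCHEMA_VERSION = "1"


def write_tracks(tracks: Sequence[VertexTrack], path: str | Path) -> None:
    """Write vertex tracks as long-format CSV (schema above)."""
    rows = []
    for tr in tracks:
        for i in range(tr.n_frames):
            phase = "pre" if i <= tr.ablation_frame else "post"
            for v, xy in ((1, tr.vertex1_xy[i]), (2, tr.vertex2_xy[i])):
                rows.append((tr.track_id, int(tr.frames[i]), tr.times[i],
                             v, xy[0], xy[1], phase))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    # default float repr round-trips exactly; do not truncate coordinates
    df.to_csv(path, index=False)


def read_vertex_tracks(path: str | Path) -> list[VertexTrack]:
    """Parse and validate vertex tracks from CSV.

    Raises descriptive errors naming the offending track and row for
    missing columns, a ``post`` frame preceding a ``pre`` frame, or a
    track with fewer than 2 post-ablation frames.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_phase = ~df["phase"].isin(["pre", "post"])
    if bad_phase.any():
        row = int(df.index[bad_phase][0])
        raise ValueError(f"{path}: row {row}: phase must be 'pre' or 'post'")

    tracks = []
    for track_id, g in df.groupby("track_id", sort=False):
        g = g.sort_values(["frame", "vertex"])
        frames = np.sort(g["frame"].unique())
        per_frame_phase = g.groupby("frame")["phase"].first()
        phases = per_frame_phase.loc[frames].to_numpy()
        if "pre" not in phases:
            raise ValueError(f"track {track_id!r}: no pre-ablation frame")
        last_pre_pos = int(np.max(np.nonzero(phases == "pre")[0]))
        if "post" in phases[:last_pre_pos + 1]:
            first_bad_frame = frames[np.nonzero(phases[:last_pre_pos + 1] == "post")[0][0]]
            row = int(g.index[(g["frame"] == first_bad_frame)][0])
            raise ValueError(
                f"track {track_id!r}: row {row}: 'post' frame {first_bad_frame} "
                f"precedes a 'pre' frame")
        n_post = int(np.sum(phases == "post"))
        if n_post < 2:
            raise ValueError(f"track {track_id!r}: fewer than 2 post-ablation frames")

        times = np.empty(frames.size)
        v_xy = {1: np.empty((frames.size, 2)), 2: np.empty((frames.size, 2))}
        for k, f in enumerate(frames):
            sub = g[g["frame"] == f]
            times[k] = sub["time_s"].iloc[0]
            for v in (1, 2):
                vr = sub[sub["vertex"] == v]
                if len(vr) != 1:
                    raise ValueError(
                        f"track {track_id!r}: frame {f}: expected exactly one "
                        f"row for vertex {v}")
                v_xy[v][k] = (vr["x_um"].iloc[0], vr["y_um"].iloc[0])
        try:
            tracks.append(VertexTrack(track_id=str(track_id), times=times,
                                      vertex1_xy=v_xy[1], vertex2_xy=v_xy[2],
                                      ablation_frame=last_pre_pos, frames=frames))
        except ValueError as e:
            raise ValueError(f"track {track_id!r}: {e}") from e
    return tracks


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as ImageJ-style TIFF carrying pixel size and z-step."""
    data = stack.data.astype(np.float32)
    tifffile.imwrite(path, data, imagej=True,
                     resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
                     metadata={"spacing": stack.z_step, "unit": "um",
                               "axes": "ZYX"})


def read_stack(path: str | Path, pixel_size: float | None = None,
               z_step: float | None = None) -> ImageStack:
    """Read a TIFF z-stack, resolving the pixel size.

    Resolution tags win; an explicit ``pixel_size`` override is used when
    tags are absent; with neither the read fails.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        meta = tf.imagej_metadata or {}
        tag_px = None
        if "XResolution" in page.tags:
            num, denom = page.tags["XResolution"].value
            # a bare (1, 1) without any unit metadata is the writer default,
            # not a calibration
            if num > 0 and not ((num, denom) == (1, 1) and "unit" not in meta):
                tag_px = denom / num
    resolved_px = tag_px if tag_px else pixel_size
    if resolved_px is None:
        raise ValueError(f"{path}: no resolution tags and no pixel_size override")
    resolved_z = meta.get("spacing", z_step) or 0.5
    if data.ndim == 2:
        data = data[None, ...]
    return ImageStack(data=np.asarray(data, dtype=float),
                      pixel_size=float(resolved_px), z_step=float(resolved_z))


CLONE_COLUMNS = ["unit_id", "cell_id", "group", "value", "measure_kind"]


def write_clone_sets(sets: Sequence[CloneMeasurementSet], path: str | Path) -> None:
    rows = []
    for s in sets:
        for grp, vals in (("clone", s.clone_values), ("control", s.control_values)):
            for i, v in enumerate(vals):
                rows.append((s.unit_id, f"{grp}-{i:03d}", grp, v, s.measure_kind))
    pd.DataFrame(rows, columns=CLONE_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.9g")


def read_clone_sets(path: str | Path) -> list[CloneMeasurementSet]:
    df = pd.read_csv(path)
    missing = [c for c in CLONE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sets = []
    for unit_id, g in df.groupby("unit_id", sort=False):
        kinds = g["measure_kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"unit {unit_id!r}: mixed measure_kind values")
        clone = g.loc[g["group"] == "clone", "value"].to_numpy()
        control = g.loc[g["group"] == "control", "value"].to_numpy()
        if clone.size == 0 or control.size == 0:
            raise ValueError(f"unit {unit_id!r}: needs both clone and control cells")
        sets.append(CloneMeasurementSet(unit_id=str(unit_id), clone_values=clone,
                                        control_values=control,
                                        measure_kind=str(kinds[0])))
    return sets


def read_tidy_groups(path: str | Path) -> dict[str, np.ndarray]:
    """Tidy (condition, unit_id, value) CSV -> {condition: values}."""
    df = pd.read_csv(path)
    for c in ("condition", "value"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    return {str(cond): g["value"].to_numpy(dtype=float)
            for cond, g in df.groupby("condition", sort=False)}


def comparison_to_dict(cmp: GroupComparison) -> dict:
    """JSON-ready report of a two-group comparison."""
    return {
        "schema_version": SCHEMA_VERSION,
        "labels": list(cmp.labels),
        "means": list(cmp.means),
        "sds": list(cmp.sds),
        "ns": list(cmp.ns),
        "percent_change": cmp.percent_change,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "test_name": cmp.test_name,
        "stars": cmp.stars,
        "degenerate": cmp.degenerate,
        "notes": cmp.notes,
    }
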