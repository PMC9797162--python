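"""File exchange: TIFF frames, metadata/trajectory CSVs, template banks.

Projection frames are written as 16-bit grayscale TIFF with a linear
scale factor recorded in the frame metadata CSV (columns: frame_index,
pair_index, energy_label, angle_deg, time_s, filename, scale).
Trajectories (simulated or KF-estimated) share one CSV schema so the
metric code consumes either interchangeably.  Template banks are a
directory of float32 TIFFs plus an index CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import GroundTruthTrajectory, ProjectionPair
from .tracking import TemplateBank, TemplateEntry, TrackResult

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_trajectory",
    "read_trajectory",
    "write_track_result",
    "read_track_result",
    "write_template_bank",
    "read_template_bank",
]

_UINT16_MAX = 65535


def write_sequence(directory, pairs: list[ProjectionPair], gt: GroundTruthTrajectory | None = None):
    """Write frames as 16-bit TIFFs plus frame metadata (and GT) CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    frame_index = 0
    for pair in pairs:
        for label, image in (("high", pair.high), ("low", pair.low)):
            peak = float(image.max())
            scale = peak / _UINT16_MAX if peak > 0 else 1.0
            scaled = np.clip(np.round(image / scale), 0, _UINT16_MAX).astype(np.uint16)
            name = f"frame_{frame_index:05d}_{label}.tif"
            tifffile.imwrite(directory / name, scaled)
            rows.append(
                dict(
                    frame_index=frame_index,
                    pair_index=pair.index,
                    energy_label=label,
                    angle_deg=pair.angle_deg,
                    time_s=pair.time_s,
                    filename=name,
                    scale=scale,
                )
            )
            frame_index += 1
    pd.DataFrame(rows).to_csv(directory / "frames.csv", index=False)
    if gt is not None:
        write_trajectory(directory / "ground_truth.csv", gt)


def read_sequence(directory) -> list[ProjectionPair]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "frames.csv")
    pairs: dict[int, dict] = {}
    for _, row in meta.iterrows():
        image = tifffile.imread(directory / row["filename"]).astype(float) * row["scale"]
        entry = pairs.setdefault(
            int(row["pair_index"]), dict(angle_deg=row["angle_deg"], time_s=row["time_s"])
        )
        entry[row["energy_label"]] = image
    return [
        ProjectionPair(i, d["time_s"], d["angle_deg"], d["high"], d["low"])
        for i, d in sorted(pairs.items())
    ]


def write_trajectory(path, gt: GroundTruthTrajectory) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(gt)),
            "time_s": gt.time_s,
            "angle_deg": gt.angle_deg,
            "u_mm": gt.u_mm,
            "v_mm": gt.v_mm,
        }
    ).to_csv(path, index=False)


def read_trajectory(path) -> GroundTruthTrajectory:
    df = pd.read_csv(path)
    return GroundTruthTrajectory(
        df["time_s"].to_numpy(),
        df["angle_deg"].to_numpy(),
        df["u_mm"].to_numpy(),
        df["v_mm"].to_numpy(),
    )


def write_track_result(path, track: TrackResult) -> None:
    track.to_dataframe().to_csv(path, index=False)


def read_track_result(path) -> TrackResult:
    df = pd.read_csv(path)
    return TrackResult(
        frame_index=df["frame_index"].to_numpy(),
        angle_deg=df["angle_deg"].to_numpy(dtype=float),
        u_mm=df["tracked_u_mm"].to_numpy(dtype=float),
        v_mm=df["tracked_v_mm"].to_numpy(dtype=float),
        ncc_peak=df["ncc_peak"].to_numpy(dtype=float),
        missing=df["missing"].to_numpy(dtype=bool),
        template_angle=df["template_angle"].to_numpy(),
    )


def write_template_bank(directory, bank: TemplateBank) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for angle in bank.angles():
        entry = bank.entries[angle]
        name = f"template_{angle:03d}.tif"
        # store the padded context; the matching core is recovered from
        # the origin/shape columns on read
        stored = entry.context if entry.context is not None else entry.pixels
        tifffile.imwrite(directory / name, stored.astype(np.float32))
        rows.append(
            dict(
                angle_deg=angle,
                filename=name,
                offset_row_px=entry.offset_row,
                offset_col_px=entry.offset_col,
                pixel_spacing_mm=entry.pixel_spacing,
                ref_u_mm=entry.ref_u_mm,
                ref_v_mm=entry.ref_v_mm,
                core_row0=entry.context_origin[0] if entry.context is not None else 0,
                core_col0=entry.context_origin[1] if entry.context is not None else 0,
                core_rows=entry.pixels.shape[0],
                core_cols=entry.pixels.shape[1],
            )
        )
    pd.DataFrame(rows).to_csv(directory / "index.csv", index=False)


def read_template_bank(directory) -> TemplateBank:
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv")
    entries = {}
    for _, row in index.iterrows():
        angle = int(row["angle_deg"])
        context = tifffile.imread(directory / row["filename"]).astype(float)
        r0, c0 = int(row.get("core_row0", 0)), int(row.get("core_col0", 0))
        nr = int(row.get("core_rows", context.shape[0]))
        nc = int(row.get("core_cols", context.shape[1]))
        core = context[r0 : r0 + nr, c0 : c0 + nc]
        entries[angle] = TemplateEntry(
            angle_deg=angle,
            pixels=core,
            offset_row=float(row["offset_row_px"]),
            offset_col=float(row["offset_col_px"]),
            pixel_spacing=float(row["pixel_spacing_mm"]),
            ref_u_mm=float(row["ref_u_mm"]),
            ref_v_mm=float(row["ref_v_mm"]),
            context=context,
            context_origin=(r0, c0),
        )
    return TemplateBank(entries)
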