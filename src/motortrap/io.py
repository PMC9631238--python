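"""File formats: trap traces (HDF5/TSV), event tables, track and linescan CSV.

Small plain-text formats carry their calibration in ``# key=value`` header
lines so a file is self-describing; HDF5 traces store the same metadata as
attributes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import KymoCalibration, LinescanSeries, MotorPath, TrackROI, TrapTrace

__all__ = [
    "write_trace_hdf5", "read_trace_hdf5",
    "write_trace_tsv", "read_trace_tsv",
    "write_motor_path_tsv", "read_motor_path_tsv",
    "write_tracks_csv", "read_tracks_csv",
    "write_linescans_csv", "read_linescans_csv",
    "read_imagej_points",
]


def write_trace_hdf5(trace: TrapTrace, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("position_nm", data=trace.position)
        d.attrs["sample_rate_hz"] = trace.sample_rate
        d.attrs["stiffness_pN_per_nm"] = trace.trap_stiffness
        if "seed" in trace.metadata:
            d.attrs["seed"] = trace.metadata["seed"]


def read_trace_hdf5(path: str | Path) -> TrapTrace:
    with h5py.File(path, "r") as f:
        d = f["position_nm"]
        meta = {k: v for k, v in d.attrs.items()
                if k not in ("sample_rate_hz", "stiffness_pN_per_nm")}
        return TrapTrace(
            position=d[()],
            sample_rate=float(d.attrs["sample_rate_hz"]),
            trap_stiffness=float(d.attrs["stiffness_pN_per_nm"]),
            metadata=meta,
        )


def _read_header(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_trace_tsv(trace: TrapTrace, path: str | Path) -> None:
    """Two-column TSV (time_s, position_nm) with calibration header lines."""
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# sample_rate_hz={trace.sample_rate}\n")
        f.write(f"# stiffness_pN_per_nm={trace.trap_stiffness}\n")
        f.write("time_s\tposition_nm\n")
        t = trace.times()
        for ti, xi in zip(t, trace.position):
            f.write(f"{ti:.6f}\t{xi:.4f}\n")


def read_trace_tsv(path: str | Path) -> TrapTrace:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return TrapTrace(
        position=df["position_nm"].to_numpy(),
        sample_rate=float(meta["sample_rate_hz"]),
        trap_stiffness=float(meta["stiffness_pN_per_nm"]),
    )


def write_motor_path_tsv(path_obj: MotorPath, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": path_obj.times,
        "kind": path_obj.kinds,
        "motor_position_nm": path_obj.positions,
        "force_pN": path_obj.forces,
    })
    df.to_csv(path, sep="\t", index=False)


def read_motor_path_tsv(path: str | Path, duration: float,
                        step_size: float = 8.2) -> MotorPath:
    df = pd.read_csv(path, sep="\t")
    return MotorPath(
        times=df["time_s"].to_numpy(),
        kinds=list(df["kind"]),
        positions=df["motor_position_nm"].to_numpy(),
        forces=df["force_pN"].to_numpy(),
        duration=duration,
        step_size=step_size,
    )


def write_tracks_csv(tracks: list[TrackROI], cal: KymoCalibration,
                     path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# nm_per_pixel={cal.nm_per_pixel}\n")
        f.write(f"# s_per_frame={cal.s_per_frame}\n")
        f.write(f"# plus_end_direction={cal.plus_end_direction}\n")
        f.write("track_id,frame,x_px,mt_id,label,day\n")
        for i, roi in enumerate(tracks):
            for frame, x in roi.vertices:
                f.write(f"{i},{frame:g},{x:.4f},{roi.mt_id},"
                        f"{roi.label or ''},{roi.day or ''}\n")


def read_tracks_csv(path: str | Path) -> tuple[list[TrackROI], KymoCalibration]:
    path = Path(path)
    meta = _read_header(path)
    cal = KymoCalibration(
        nm_per_pixel=float(meta.get("nm_per_pixel", 162.0)),
        s_per_frame=float(meta.get("s_per_frame", 0.2)),
        plus_end_direction=int(meta.get("plus_end_direction", 1)),
    )
    df = pd.read_csv(path, comment="#")
    tracks = []
    for _, sub in df.groupby("track_id", sort=True):
        label = sub["label"].iloc[0] if "label" in sub and pd.notna(sub["label"].iloc[0]) else None
        day = sub["day"].iloc[0] if "day" in sub and pd.notna(sub["day"].iloc[0]) else None
        tracks.append(TrackROI(
            vertices=sub[["frame", "x_px"]].to_numpy(),
            mt_id=int(sub["mt_id"].iloc[0]) if "mt_id" in sub else 0,
            label=label, day=day,
        ))
    return tracks, cal


def write_linescans_csv(series: list[LinescanSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, pos, inten in zip(s.times, s.positions, s.intensities):
            for p, v in zip(pos, inten):
                rows.append((s.cell_id, t, p, v))
    pd.DataFrame(rows, columns=["cell_id", "time_min", "position_norm", "intensity"]) \
        .to_csv(path, index=False)


def read_linescans_csv(path: str | Path) -> list[LinescanSeries]:
    df = pd.read_csv(path)
    series = []
    for cell, sub in df.groupby("cell_id", sort=True):
        times, positions, intensities = [], [], []
        for t, tsub in sub.groupby("time_min", sort=True):
            times.append(t)
            positions.append(tsub["position_norm"].to_numpy())
            intensities.append(tsub["intensity"].to_numpy())
        series.append(LinescanSeries(cell_id=int(cell), times=np.array(times),
                                     positions=positions, intensities=intensities))
    return series


def read_imagej_points(path: str | Path, mt_id: int = 0) -> TrackROI:
    """Convert an ImageJ-style XY point list (one ``x y`` pair per line,
    x = frame, y = position in px) into a :class:`TrackROI`."""
    pts = np.loadtxt(path, ndmin=2)
    if pts.shape[1] < 2:
        raise ValueError("expected two columns: frame and x_px")
    return TrackROI(vertices=pts[:, :2], mt_id=mt_id)
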