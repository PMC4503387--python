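"""CSV readers/writers for the table formats shared across stages.

Column schemas and units are documented in FORMATS.md.  Positions are
always μm; track times are minutes, waveform times seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contraction import MotionWaveform
from .exceptions import InsufficientDataError
from .tracks import CellTrack

TRACK_COLUMNS = ["cell_id", "frame", "t_min", "x_um", "y_um"]


def write_tracks_csv(tracks: list[CellTrack], path) -> None:
    rows = []
    for tr in tracks:
        for k, (t, (x, y)) in enumerate(zip(tr.times, tr.positions)):
            rows.append({"cell_id": tr.cell_id, "frame": k, "t_min": t,
                         "x_um": x, "y_um": y, "region": tr.region or ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path) -> list[CellTrack]:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracks CSV missing columns: {missing}")
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        region = None
        if "region" in grp.columns:
            vals = grp["region"].dropna().astype(str)
            vals = vals[vals != ""]
            if len(vals):
                region = vals.iloc[0]
        tracks.append(CellTrack(
            cell_id=cell_id,
            times=grp["t_min"].to_numpy(),
            positions=grp[["x_um", "y_um"]].to_numpy(),
            region=region,
        ))
    if not tracks:
        raise InsufficientDataError(f"no tracks in {path}")
    return tracks


def write_nuclei_csv(nuclei: pd.DataFrame, path) -> None:
    nuclei.to_csv(path, index=False)


def read_nuclei_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"nuclei CSV missing column {col!r}")
    return df


def write_waveform_csv(waveform: MotionWaveform, path) -> None:
    pd.DataFrame({
        "t_s": waveform.times,
        "mean_speed_um_per_s": waveform.mean_speed,
        "valid": waveform.valid.astype(int),
    }).to_csv(path, index=False)


def write_heatmap_csv(matrix: np.ndarray, path) -> None:
    pd.DataFrame(matrix).to_csv(path, index=False, header=False)
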