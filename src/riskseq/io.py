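"""Readers and writers for the tabular dialects the pipeline consumes.

All formats are plain CSV: wide pose tables (optionally DeepLabCut-style
multi-row headers), BORIS-style behavioral annotation exports, and
Neurophotometrics-style interleaved photometry streams with a LedState
flag column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .maze import MazeGeometry, PoseTrack
from .photometry import CH_REFERENCE, CH_SIGNAL, PhotometrySession
from .sequences import make_event_table

__all__ = [
    "read_pose_csv",
    "write_pose_csv",
    "read_boris_csv",
    "write_boris_csv",
    "read_photometry_csv",
    "write_photometry_csv",
    "load_config",
    "geometry_from_config",
]

_KEYPOINTS = ("centroid", "head", "tailbase")

# Neurophotometrics LedState convention: 1 = 415 nm, 2 = 470 nm
DEFAULT_LED_MAP = {1: CH_REFERENCE, 2: CH_SIGNAL}


def read_pose_csv(
    path,
    fps: float = 30.0,
    likelihood_min: float = 0.6,
    dialect: str = "wide",
) -> PoseTrack:
    """Read a frame-wise pose table.

    ``dialect='wide'`` expects one header row with ``<keypoint>_x``,
    ``<keypoint>_y`` (optionally ``<keypoint>_likelihood``) plus
    ``bbox_width`` / ``bbox_height``; ``dialect='dlc'`` expects the
    DeepLabCut 3-row header (scorer / bodyparts / coords). Times come
    from a ``time`` column if present, else ``frame / fps`` with 0-based
    frames. Keypoint samples below ``likelihood_min`` are linearly
    interpolated.
    """
    if dialect == "dlc":
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        df = pd.DataFrame(index=raw.index)
        scorer = raw.columns.get_level_values(0)[0]
        for kp in _KEYPOINTS:
            for coord in ("x", "y", "likelihood"):
                col = (scorer, kp, coord)
                if col in raw.columns:
                    df[f"{kp}_{coord}"] = raw[col].to_numpy()
        for extra in ("bbox_width", "bbox_height"):
            for c in raw.columns:
                if c[1] == extra or c[0] == extra:
                    df[extra] = raw[c].to_numpy()
                    break
        df = df.reset_index(drop=True)
    elif dialect == "wide":
        df = pd.read_csv(path)
    else:
        raise ValueError("dialect must be 'wide' or 'dlc'")

    n = len(df)
    time = df["time"].to_numpy(dtype=float) if "time" in df else np.arange(n) / fps

    def interp_low_confidence(vals: np.ndarray, lik: np.ndarray | None) -> np.ndarray:
        if lik is None:
            return vals
        good = lik >= likelihood_min
        if good.all():
            return vals
        if not good.any():
            raise ValueError("all samples below the likelihood threshold")
        idx = np.arange(n)
        return np.interp(idx, idx[good], vals[good])

    coords = {}
    for kp in _KEYPOINTS:
        lik = df[f"{kp}_likelihood"].to_numpy(dtype=float) if f"{kp}_likelihood" in df else None
        x = interp_low_confidence(df[f"{kp}_x"].to_numpy(dtype=float), lik)
        y = interp_low_confidence(df[f"{kp}_y"].to_numpy(dtype=float), lik)
        coords[kp] = np.column_stack([x, y])

    width = df["bbox_width"].to_numpy(dtype=float) if "bbox_width" in df else np.full(n, np.nan)
    height = df["bbox_height"].to_numpy(dtype=float) if "bbox_height" in df else np.full(n, np.nan)
    return PoseTrack(
        time=time,
        centroid=coords["centroid"],
        head=coords["head"],
        tailbase=coords["tailbase"],
        bbox_width=width,
        bbox_height=height,
    )


def write_pose_csv(track: PoseTrack, path) -> None:
    track.to_dataframe().to_csv(path, index=False)


def read_boris_csv(path, subject: str | None = None) -> pd.DataFrame:
    """Read a BORIS-style export (Time, Subject, Behavior, Status).

    POINT rows map to single events; START/STOP pairs map to an event at
    the START time (the paired STOP is informational). Behavior labels
    are normalized to the internal vocabulary.
    """
    df = pd.read_csv(path)
    need = {"Time", "Behavior", "Status"}
    if not need.issubset(df.columns):
        raise ValueError(f"BORIS export needs columns {sorted(need)}")
    if subject is not None and "Subject" in df:
        df = df[df["Subject"] == subject]
    label_map = {
        "risk assessment": "risk_assessment",
        "risk_assessment": "risk_assessment",
        "sequence start": "sequence_start",
        "sequence_start": "sequence_start",
        "center cross": "center_cross",
        "center_cross": "center_cross",
        "sequence stop": "sequence_stop",
        "sequence_stop": "sequence_stop",
    }
    keep = df["Status"].str.upper().isin(["POINT", "START"])
    df = df[keep]
    times = df["Time"].to_numpy(dtype=float)
    behaviors = []
    for b in df["Behavior"]:
        key = str(b).strip().lower()
        if key not in label_map:
            raise ValueError(f"unknown BORIS behavior label {b!r}")
        behaviors.append(label_map[key])
    order = np.argsort(times, kind="stable")
    return make_event_table(times[order], [behaviors[i] for i in order], source="manual")


def write_boris_csv(events: pd.DataFrame, path, subject: str = "subject1") -> None:
    out = pd.DataFrame(
        {
            "Time": events["time"],
            "Subject": subject,
            "Behavior": events["behavior"].str.replace("_", " "),
            "Status": "POINT",
        }
    )
    out.to_csv(path, index=False)


def read_photometry_csv(
    path,
    region_column: str | None = None,
    led_map: dict[int, str] | None = None,
    animal: str = "animal0",
    hemisphere: str = "left",
    channel_rate: float = 40.0,
) -> PhotometrySession:
    """Read a Neurophotometrics-style CSV (FrameCounter, SystemTimestamp,
    LedState, one column per region). ``led_map`` demultiplexes LedState
    codes to channels; unknown codes are dropped."""
    df = pd.read_csv(path)
    led_col = "LedState" if "LedState" in df.columns else "Flags"
    need = {"FrameCounter", "SystemTimestamp", led_col}
    if not need.issubset(df.columns):
        raise ValueError(f"photometry CSV needs columns {sorted(need)}")
    led_map = led_map or DEFAULT_LED_MAP
    if region_column is None:
        candidates = [c for c in df.columns if c not in need]
        if not candidates:
            raise ValueError("no region column found")
        region_column = candidates[0]
    channel = df[led_col].map(led_map)
    keep = channel.notna()
    records = pd.DataFrame(
        {
            "frame_counter": df.loc[keep, "FrameCounter"].to_numpy(),
            "time": df.loc[keep, "SystemTimestamp"].to_numpy(dtype=float),
            "channel": channel[keep].to_numpy(),
            "fluorescence": df.loc[keep, region_column].to_numpy(dtype=float),
        }
    )
    return PhotometrySession(
        records=records,
        animal=animal,
        hemisphere=hemisphere,
        channel_rate=channel_rate,
    )


def write_photometry_csv(
    session: PhotometrySession, path, region_column: str = "Region0G"
) -> None:
    inverse = {CH_REFERENCE: 1, CH_SIGNAL: 2}
    out = pd.DataFrame(
        {
            "FrameCounter": session.records["frame_counter"],
            "SystemTimestamp": session.records["time"],
            "LedState": session.records["channel"].map(inverse),
            region_column: session.records["fluorescence"],
        }
    )
    out.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def geometry_from_config(config: dict) -> MazeGeometry:
    """Build maze geometry from nested config keys
    (geometry.arm_length_cm, geometry.center_side_cm, zones.*)."""
    geo = config.get("geometry", {})
    zones = config.get("zones", {})
    return MazeGeometry(
        arm_length=geo.get("arm_length_cm", 27.8),
        center_side=geo.get("center_side_cm", 7.8),
        closed_axis=geo.get("closed_axis", "y"),
        start_zone_fraction=zones.get("start_fraction", 0.5),
        proximal_fraction=zones.get("proximal_fraction", 0.5),
        stop_threshold_fraction=zones.get("stop_fraction", 0.5),
    )
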