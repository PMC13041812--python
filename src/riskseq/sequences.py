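"""Segmentation of continuous maze sessions into risk-ranked sequences.

A sequence opens when the animal sits in the distal zone of a closed arm
oriented and moving toward the maze center, and closes when it crosses
the stop threshold of a non-originating arm. Risk-assessment events are
consumed from an annotation table (manual or simulated), never inferred
from pose. The four types form a 2x2 rule table over terminal-arm kind
(closed / open) and presence of proximal open-arm risk events:

===============  ===========  =====
terminal arm     risk events  type
===============  ===========  =====
closed           0            C->C
closed           >=1          NoGo
open             >=1          Go
open             0            C->O
===============  ===========  =====
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze import MazeGeometry

logger = logging.getLogger(__name__)

SEQ_CC = "C->C"
SEQ_NOGO = "NoGo"
SEQ_GO = "Go"
SEQ_CO = "C->O"
SEQUENCE_TYPES = (SEQ_CC, SEQ_NOGO, SEQ_GO, SEQ_CO)

EVENT_BEHAVIORS = ("risk_assessment", "sequence_start", "center_cross", "sequence_stop")

__all__ = [
    "SEQ_CC",
    "SEQ_NOGO",
    "SEQ_GO",
    "SEQ_CO",
    "SEQUENCE_TYPES",
    "EVENT_BEHAVIORS",
    "make_event_table",
    "validate_event_table",
    "Sequence",
    "SequenceTable",
    "detect_sequences",
    "classify_sequence",
    "sequence_metrics",
    "risk_assessment_index",
    "counts_by_type",
]


def make_event_table(times, behaviors, source: str = "manual") -> pd.DataFrame:
    """Build a tidy event table (time, behavior, source)."""
    df = pd.DataFrame({"time": np.asarray(times, dtype=float), "behavior": list(behaviors)})
    df["source"] = source
    validate_event_table(df)
    return df


def validate_event_table(events: pd.DataFrame, session_span: tuple[float, float] | None = None) -> None:
    if not {"time", "behavior"}.issubset(events.columns):
        raise ValueError("event table needs 'time' and 'behavior' columns")
    t = events["time"].to_numpy(dtype=float)
    if len(t) > 1 and (np.diff(t) < 0).any():
        raise ValueError("event times must be non-decreasing")
    bad = set(events["behavior"]) - set(EVENT_BEHAVIORS)
    if bad:
        raise ValueError(f"unknown behavior labels: {sorted(bad)}")
    if session_span is not None and len(t):
        lo, hi = session_span
        if t.min() < lo or t.max() > hi:
            raise ValueError(
                f"events outside session span [{lo}, {hi}]: "
                f"range [{t.min()}, {t.max()}]"
            )


@dataclass
class Sequence:
    """One detected risk-ranked sequence."""

    type: str
    origin_arm: str
    terminal_arm: str
    t_start: float
    t_center: float | None
    t_first_risk: float | None
    t_stop: float
    n_risk_events: int = 0

    def __post_init__(self) -> None:
        if self.type not in SEQUENCE_TYPES:
            raise ValueError(f"unknown sequence type {self.type!r}")
        if not self.t_start < self.t_stop:
            raise ValueError("t_start must precede t_stop")
        if self.type in (SEQ_NOGO, SEQ_GO) and self.t_first_risk is None:
            raise ValueError(f"{self.type} sequences require t_first_risk")
        if self.type in (SEQ_CC, SEQ_CO) and self.t_first_risk is not None:
            raise ValueError(f"{self.type} sequences must not carry t_first_risk")

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def anchor(self) -> float | None:
        """Alignment anchor: center cross for C->C, first risk event for
        NoGo/Go, undefined for C->O."""
        if self.type == SEQ_CC:
            return self.t_center
        if self.type in (SEQ_NOGO, SEQ_GO):
            return self.t_first_risk
        return None


@dataclass
class SequenceTable:
    """All sequences of one animal's session."""

    sequences: list[Sequence] = field(default_factory=list)
    animal: str = "animal0"

    def __len__(self) -> int:
        return len(self.sequences)

    def counts_by_type(self) -> dict[str, int]:
        return counts_by_type(self)

    def risk_index(self) -> float:
        return risk_assessment_index(self)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "animal": self.animal,
                "type": s.type,
                "origin_arm": s.origin_arm,
                "terminal_arm": s.terminal_arm,
                "t_start": s.t_start,
                "t_center": s.t_center,
                "t_first_risk": s.t_first_risk,
                "t_stop": s.t_stop,
                "n_risk_events": s.n_risk_events,
            }
            for s in self.sequences
        ]
        cols = [
            "animal", "type", "origin_arm", "terminal_arm",
            "t_start", "t_center", "t_first_risk", "t_stop", "n_risk_events",
        ]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SequenceTable":
        animal = str(df["animal"].iloc[0]) if len(df) else "animal0"
        seqs = [
            Sequence(
                type=row["type"],
                origin_arm=row["origin_arm"],
                terminal_arm=row["terminal_arm"],
                t_start=float(row["t_start"]),
                t_center=None if pd.isna(row["t_center"]) else float(row["t_center"]),
                t_first_risk=None if pd.isna(row["t_first_risk"]) else float(row["t_first_risk"]),
                t_stop=float(row["t_stop"]),
                n_risk_events=int(row["n_risk_events"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(sequences=seqs, animal=animal)


def classify_sequence(
    terminal_kind: str,
    n_risk_events: int,
) -> str:
    """Rule table mapping terminal-arm kind x risk-event presence to a
    sequence type."""
    if terminal_kind not in ("closed", "open"):
        raise ValueError("terminal_kind must be 'closed' or 'open'")
    if terminal_kind == "closed":
        return SEQ_NOGO if n_risk_events >= 1 else SEQ_CC
    return SEQ_GO if n_risk_events >= 1 else SEQ_CO


def detect_sequences(
    features: pd.DataFrame,
    events: pd.DataFrame,
    geometry: MazeGeometry,
    *,
    min_gate_frames: int = 3,
    animal: str = "animal0",
) -> SequenceTable:
    """Scan a frame-feature table for risk-ranked sequences.

    The start gate requires the centroid in a closed-distal zone with the
    heading within +/-90 degrees of the to-center direction AND a positive
    velocity component toward the center, sustained for
    ``min_gate_frames`` consecutive frames. The sequence closes at the
    first frame at or beyond the stop threshold of a non-originating arm.
    Unresolved sequences at session end are dropped with a log record;
    open-arm-originating excursions are logged, not classified.
    """
    required = {"time", "zone_region", "zone_arm", "heading", "centroid_x", "centroid_y"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    t = features["time"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 frames")
    validate_event_table(events, session_span=(float(t[0]), float(t[-1])))

    pos = features[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    region = features["zone_region"].to_numpy(dtype=object)
    arm = features["zone_arm"].to_numpy(dtype=object)
    heading = np.radians(features["heading"].to_numpy(dtype=float))
    hvec = np.column_stack([np.cos(heading), np.sin(heading)])

    dt = np.diff(t)
    vel = np.zeros_like(pos)
    vel[1:] = np.diff(pos, axis=0) / dt[:, None]
    if len(vel) > 1:
        vel[0] = vel[1]

    dist = np.linalg.norm(pos, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        to_center = np.where(dist[:, None] > 1e-9, -pos / np.maximum(dist, 1e-9)[:, None], 0.0)
    head_ok = np.einsum("ij,ij->i", hvec, to_center) >= 0.0
    vel_ok = np.einsum("ij,ij->i", vel, to_center) > 0.0
    defined = region != "off-maze"

    gate_closed = (region == "closed-distal") & head_ok & vel_ok & defined
    gate_open = (region == "open-distal") & head_ok & vel_ok & defined

    # distance along the arm axis a frame occupies (0 where no arm)
    axis_is_x = np.array([a is not None and a[1] == "x" for a in arm])
    along = np.where(axis_is_x, np.abs(pos[:, 0]), np.abs(pos[:, 1]))

    risk_times = events.loc[events["behavior"] == "risk_assessment", "time"].to_numpy(dtype=float)

    def sustained(gate: np.ndarray, i: int) -> bool:
        j = i + min_gate_frames
        return j <= len(gate) and bool(gate[i:j].all())

    sequences: list[Sequence] = []
    n = len(t)
    i = 0
    while i < n:
        if gate_open[i] and sustained(gate_open, i):
            logger.info(
                "open-arm-originating excursion at t=%.3f s left unclassified", t[i]
            )
            # skip past this run so it is logged once
            while i < n and gate_open[i]:
                i += 1
            continue
        if not (gate_closed[i] and sustained(gate_closed, i)):
            i += 1
            continue
        t_start = float(t[i])
        origin_arm = arm[i]
        t_center: float | None = None
        j = i + 1
        closed_at = None
        while j < n:
            if t_center is None and region[j] == "center":
                t_center = float(t[j])
            if (
                arm[j] is not None
                and arm[j] != origin_arm
                and along[j] >= geometry.stop_distance
            ):
                closed_at = j
                break
            j += 1
        if closed_at is None:
            logger.warning(
                "sequence opened at t=%.3f s never crossed a stop threshold; dropped",
                t_start,
            )
            break
        t_stop = float(t[closed_at])
        terminal_arm = arm[closed_at]
        in_window = (risk_times >= t_start) & (risk_times < t_stop)
        valid_risk: list[float] = []
        for rt in risk_times[in_window]:
            k = int(np.searchsorted(t, rt, side="right")) - 1
            k = max(k, 0)
            if region[k] == "open-proximal":
                valid_risk.append(float(rt))
            else:
                warnings.warn(
                    f"risk-assessment event at t={rt:.3f} s lies in zone "
                    f"{region[k]!r}, not the proximal open arm; ignored for "
                    "classification",
                    stacklevel=2,
                )
        seq_type = classify_sequence(geometry.arm_of(terminal_arm), len(valid_risk))
        sequences.append(
            Sequence(
                type=seq_type,
                origin_arm=origin_arm,
                terminal_arm=terminal_arm,
                t_start=t_start,
                t_center=t_center,
                t_first_risk=valid_risk[0] if valid_risk and seq_type in (SEQ_NOGO, SEQ_GO) else None,
                t_stop=t_stop,
                n_risk_events=len(valid_risk),
            )
        )
        i = closed_at + 1
    return SequenceTable(sequences=sequences, animal=animal)


def sequence_metrics(seq: Sequence, features: pd.DataFrame) -> dict[str, float]:
    """Per-sequence duration, mean speed, and mean aspect ratio over the
    frames in ``[t_start, t_stop)``."""
    t = features["time"].to_numpy(dtype=float)
    mask = (t >= seq.t_start) & (t < seq.t_stop)
    if not mask.any():
        raise ValueError(
            f"no frames in [{seq.t_start}, {seq.t_stop}) for metrics"
        )
    sl = features.loc[mask]
    return {
        "duration": seq.duration,
        "mean_speed": float(sl["speed"].mean()),
        "mean_aspect_ratio": float(sl["aspect_ratio"].mean()),
    }


def risk_assessment_index(table: SequenceTable) -> float:
    """Proportion of sequences involving risk assessment (NoGo + Go)
    relative to all sequences."""
    if len(table) == 0:
        raise ValueError(
            "no sequences detected in this session; cannot compute a risk "
            "assessment index (this is not an I/O failure)"
        )
    counts = counts_by_type(table)
    return (counts[SEQ_NOGO] + counts[SEQ_GO]) / len(table)


def counts_by_type(table: SequenceTable) -> dict[str, int]:
    """Sequence counts keyed by all four types (absent types report 0)."""
    counts = {st: 0 for st in SEQUENCE_TYPES}
    for s in table.sequences:
        counts[s.type] += 1
    return counts
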