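"""Event-aligned extraction, binning, and epoch summaries of zdF/F.

Each aligned trace is one observational unit keyed by
animal x hemisphere x event number. The window is [-3, +3) s around the
anchor, split into 90 half-open 1/15-s bins whose nominal centers sit at
left edge + 1/30 s. Bin values are means of the raw zdF/F samples that
fall in each bin; each extracted window is Gaussian-smoothed at the
native channel rate before binning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scistats

from .photometry import ProcessedTrace, smooth_gaussian
from .sequences import SEQ_CC, SEQ_GO, SEQ_NOGO, SequenceTable

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRule",
    "PeriEventUnit",
    "EpochSpec",
    "align_events",
    "align_traces",
    "units_to_dataframe",
    "units_from_dataframe",
    "epoch_means",
    "epoch_comparison",
]


@dataclass(frozen=True)
class AlignmentRule:
    """Anchor choice per sequence type plus window geometry.

    C->C aligns to the center crossing; NoGo and Go align to the onset of
    the first risk-assessment event. C->O has no defined anchor and is
    excluded.
    """

    window: tuple[float, float] = (-3.0, 3.0)
    bin_width: float = 1.0 / 15.0
    smooth_sigma: float = 4.0
    included_types: tuple[str, ...] = (SEQ_CC, SEQ_NOGO, SEQ_GO)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < 0 < hi:
            raise ValueError("window must contain 0")
        n = (hi - lo) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin_width must divide the window span")

    @property
    def n_bins(self) -> int:
        lo, hi = self.window
        return int(round((hi - lo) / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        lo, hi = self.window
        return lo + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges[:-1] + self.bin_width / 2.0


@dataclass
class PeriEventUnit:
    """One event-aligned, binned trace."""

    animal: str
    hemisphere: str
    event: int
    sequence_type: str
    bin_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bin_times) != len(self.values):
            raise ValueError("bin_times and values must have equal length")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.animal, self.hemisphere, self.event)


@dataclass(frozen=True)
class EpochSpec:
    """Pre / peri / post epoch intervals (closed-left, open-right) within
    the peri-event window."""

    pre: tuple[float, float] = (-3.0, -0.5)
    peri: tuple[float, float] = (-0.5, 0.5)
    post: tuple[float, float] = (0.5, 3.0)

    def intervals(self) -> dict[str, tuple[float, float]]:
        return {"pre": self.pre, "peri": self.peri, "post": self.post}


def align_events(
    trace: ProcessedTrace,
    sequences: SequenceTable,
    rule: AlignmentRule | None = None,
) -> list[PeriEventUnit]:
    """Align one fiber's zdF/F to the anchored sequences of its session.

    Events whose window would leave the recorded session are dropped with
    a log record; sequences without an anchor (or of an excluded type)
    are skipped with a warning in the log.
    """
    rule = rule or AlignmentRule()
    t = trace.time
    z = trace.zdff
    lo, hi = rule.window
    units: list[PeriEventUnit] = []
    for ev, seq in enumerate(sequences.sequences):
        if seq.type not in rule.included_types:
            logger.info("sequence %d (%s) excluded from alignment by rule", ev, seq.type)
            continue
        anchor = seq.anchor
        if anchor is None:
            logger.warning(
                "sequence %d (%s, t_start=%.2f s) missing its anchor; skipped",
                ev, seq.type, seq.t_start,
            )
            continue
        if anchor + lo < t[0] or anchor + hi > t[-1]:
            logger.info(
                "event %d at t=%.2f s: peri-event window leaves the session; dropped",
                ev, anchor,
            )
            continue
        mask = (t >= anchor + lo) & (t < anchor + hi)
        tw = t[mask] - anchor
        zw = smooth_gaussian(z[mask], rule.smooth_sigma)
        idx = np.floor((tw - lo) / rule.bin_width).astype(int)
        idx = np.clip(idx, 0, rule.n_bins - 1)
        sums = np.bincount(idx, weights=zw, minlength=rule.n_bins)
        counts = np.bincount(idx, minlength=rule.n_bins)
        if (counts == 0).any():
            logger.warning(
                "event %d at t=%.2f s: %d empty bins; dropped",
                ev, anchor, int((counts == 0).sum()),
            )
            continue
        units.append(
            PeriEventUnit(
                animal=trace.animal,
                hemisphere=trace.hemisphere,
                event=ev,
                sequence_type=seq.type,
                bin_times=rule.bin_centers,
                values=sums / counts,
            )
        )
    return units


def align_traces(
    traces: list[ProcessedTrace],
    sequences: SequenceTable,
    rule: AlignmentRule | None = None,
) -> list[PeriEventUnit]:
    """Align every hemisphere's trace, yielding one unit per anchored
    sequence x hemisphere."""
    units: list[PeriEventUnit] = []
    for trace in traces:
        units.extend(align_events(trace, sequences, rule))
    keys = [u.key for u in units]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate unit keys (animal, hemisphere, event)")
    return units


def units_to_dataframe(units: list[PeriEventUnit]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "animal": u.animal,
                "hemisphere": u.hemisphere,
                "event": u.event,
                "sequence_type": u.sequence_type,
                "bin_time": u.bin_times,
                "zdff": u.values,
            }
        )
        for u in units
    ]
    if not frames:
        return pd.DataFrame(
            columns=["animal", "hemisphere", "event", "sequence_type", "bin_time", "zdff"]
        )
    return pd.concat(frames, ignore_index=True)


def units_from_dataframe(df: pd.DataFrame) -> list[PeriEventUnit]:
    units = []
    for (animal, hemi, ev), grp in df.groupby(["animal", "hemisphere", "event"], sort=True):
        grp = grp.sort_values("bin_time")
        units.append(
            PeriEventUnit(
                animal=str(animal),
                hemisphere=str(hemi),
                event=int(ev),
                sequence_type=str(grp["sequence_type"].iloc[0]),
                bin_times=grp["bin_time"].to_numpy(),
                values=grp["zdff"].to_numpy(),
            )
        )
    return units


def epoch_means(units: list[PeriEventUnit], spec: EpochSpec | None = None) -> pd.DataFrame:
    """Per-unit mean zdF/F over the bins whose centers fall in each epoch
    interval (closed-left, open-right)."""
    spec = spec or EpochSpec()
    if not units:
        raise ValueError("no units given")
    window = (units[0].bin_times.min(), units[0].bin_times.max())
    for name, (lo, hi) in spec.intervals().items():
        if lo < window[0] - 1.0 or hi > window[1] + 1.0:
            raise ValueError(f"epoch {name} ({lo}, {hi}) lies outside the window")
    rows = []
    for u in units:
        for name, (lo, hi) in spec.intervals().items():
            mask = (u.bin_times >= lo) & (u.bin_times < hi)
            if not mask.any():
                raise ValueError(f"epoch {name} covers no bins")
            rows.append(
                {
                    "animal": u.animal,
                    "hemisphere": u.hemisphere,
                    "event": u.event,
                    "sequence_type": u.sequence_type,
                    "epoch": name,
                    "mean_zdff": float(u.values[mask].mean()),
                    "n_bins": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def epoch_comparison(
    units: list[PeriEventUnit],
    epoch: str,
    spec: EpochSpec | None = None,
    level: str = "bin",
) -> dict:
    """One-way comparison of one epoch's zdF/F across sequence types.

    ``level='bin'`` uses each in-epoch bin value as an observation
    (matching a bin-level denominator df); ``level='unit'`` first
    averages within units. Pairwise follow-up p-values are
    Benjamini-Hochberg adjusted.
    """
    spec = spec or EpochSpec()
    if epoch not in spec.intervals():
        raise ValueError(f"unknown epoch {epoch!r}")
    lo, hi = spec.intervals()[epoch]
    groups: dict[str, list[float]] = {}
    for u in units:
        mask = (u.bin_times >= lo) & (u.bin_times < hi)
        vals = u.values[mask]
        if level == "bin":
            groups.setdefault(u.sequence_type, []).extend(vals.tolist())
        elif level == "unit":
            groups.setdefault(u.sequence_type, []).append(float(vals.mean()))
        else:
            raise ValueError("level must be 'bin' or 'unit'")
    groups = {k: np.asarray(v) for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 sequence types with >= 2 observations")
    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("all observations identical; F statistic undefined")
    F, p = scistats.f_oneway(*arrays)
    if not np.isfinite(F):
        raise ValueError("degenerate groups: F statistic undefined")
    from .behavior_stats import bh_adjust

    names = sorted(groups)
    raw = []
    pairs = []
    for a, b in itertools.combinations(names, 2):
        _, pp = scistats.ttest_ind(groups[a], groups[b])
        raw.append(float(pp))
        pairs.append((a, b))
    adj = bh_adjust(raw)
    return {
        "F": float(F),
        "p": float(p),
        "df_between": len(groups) - 1,
        "df_within": int(sum(len(a) for a in arrays) - len(groups)),
        "pairwise": {pair: {"p_raw": r, "p_fdr": q} for pair, r, q in zip(pairs, raw, adj)},
    }
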