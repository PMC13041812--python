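"""Dual-wavelength fluorescence preprocessing to session-normalized zdF/F.

Pipeline order: zero-phase low-pass on both channels at the native
channel rate -> robust (RANSAC) linear scaling of the reference channel
to the signal channel -> dF/F against the fitted reference -> z-scoring
within animal across the whole session (pooling hemispheres). Gaussian
smoothing is deliberately deferred to peri-event extraction, where it is
applied per event window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

CH_SIGNAL = "signal_470"
CH_REFERENCE = "reference_415"

__all__ = [
    "CH_SIGNAL",
    "CH_REFERENCE",
    "PhotometrySession",
    "PreprocessConfig",
    "ProcessedTrace",
    "lowpass_zero_phase",
    "fit_isosbestic",
    "compute_dff",
    "zscore_within_animal",
    "smooth_gaussian",
    "preprocess_session",
    "preprocess_animal",
    "qc_report",
]


@dataclass
class PhotometrySession:
    """Interleaved two-channel fluorescence recording for one fiber.

    ``records`` is a tidy frame with columns frame_counter, time,
    channel (signal_470 / reference_415) and fluorescence.
    """

    records: pd.DataFrame
    animal: str = "animal0"
    hemisphere: str = "left"
    channel_rate: float = 40.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"frame_counter", "time", "channel", "fluorescence"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"photometry records missing columns: {sorted(missing)}")
        for ch in (CH_SIGNAL, CH_REFERENCE):
            t = self.channel_times(ch)
            if len(t) and (np.diff(t) <= 0).any():
                raise ValueError(f"{ch} timestamps must be strictly increasing")

    def channel_times(self, channel: str) -> np.ndarray:
        m = self.records["channel"] == channel
        return self.records.loc[m, "time"].to_numpy(dtype=float)

    def channel_values(self, channel: str) -> np.ndarray:
        m = self.records["channel"] == channel
        return self.records.loc[m, "fluorescence"].to_numpy(dtype=float)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing hyperparameters.

    The RANSAC residual threshold is ``ransac_residual_threshold`` times
    the robust scale (1.4826 x MAD) of the residuals of an initial
    least-squares fit.
    """

    lowpass_cutoff: float = 10.0
    filter_order: int = 4
    ransac_residual_threshold: float = 1.0
    ransac_max_iter: int = 100
    ransac_seed: int = 0
    smooth_sigma: float = 4.0
    inlier_fraction_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if self.lowpass_cutoff <= 0:
            raise ValueError("lowpass_cutoff must be positive")


@dataclass
class ProcessedTrace:
    """Session-long motion-corrected, normalized trace for one fiber."""

    time: np.ndarray
    dff: np.ndarray
    zdff: np.ndarray
    fit_slope: float
    fit_intercept: float
    inlier_fraction: float
    session_mean: float
    session_sd: float
    animal: str = "animal0"
    hemisphere: str = "left"
    channel_rate: float = 40.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "hemisphere": self.hemisphere,
                "time": self.time,
                "dff": self.dff,
                "zdff": self.zdff,
            }
        )


def lowpass_zero_phase(trace: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The effective magnitude response is the squared Butterworth response
    ``|H|^2 = 1 / (1 + (f/fc)^(2*order))``; net phase is zero and length
    is preserved.
    """
    trace = np.asarray(trace, dtype=float)
    nyquist = rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz for a {rate} Hz stream"
        )
    if len(trace) <= 3 * (order + 1):
        raise ValueError("trace too short for the requested filter order")
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, trace)


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def fit_isosbestic(
    reference: np.ndarray,
    signal: np.ndarray,
    config: PreprocessConfig | None = None,
) -> tuple[float, float, np.ndarray]:
    """Robustly scale the reference channel to the signal channel.

    RANSAC line fit of ``signal ~ reference``: repeatedly fit candidate
    lines through 2 random points, score by inlier count against a
    robust residual threshold, then refit ordinary least squares on the
    best consensus set. Deterministic given ``ransac_seed``. Returns
    (slope, intercept, inlier mask).
    """
    config = config or PreprocessConfig()
    reference = np.asarray(reference, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if reference.shape != signal.shape:
        raise ValueError("reference and signal must have equal length")
    n = len(reference)
    if n < 100:
        raise ValueError("need at least 100 samples for a robust fit")
    if np.ptp(reference) == 0 or np.var(reference) == 0:
        raise ValueError("flat isosbestic channel: reference has zero variance")

    # initial least-squares fit sets the robust residual scale
    slope0, intercept0 = np.polyfit(reference, signal, 1)
    resid0 = signal - (slope0 * reference + intercept0)
    scale = 1.4826 * _mad(resid0)
    thresh = config.ransac_residual_threshold * scale
    # floor keeps the noise-free case (all residuals ~0) numerically sane
    thresh = max(thresh, 1e-9 * max(1.0, float(np.median(np.abs(signal)))))

    rng = np.random.default_rng(config.ransac_seed)
    best_mask = np.abs(resid0) <= thresh
    best_count = int(best_mask.sum())
    best_rss = float((resid0[best_mask] ** 2).sum()) if best_count else np.inf
    for _ in range(config.ransac_max_iter):
        i, j = rng.choice(n, size=2, replace=False)
        dx = reference[j] - reference[i]
        if dx == 0:
            continue
        a = (signal[j] - signal[i]) / dx
        b = signal[i] - a * reference[i]
        resid = signal - (a * reference + b)
        mask = np.abs(resid) <= thresh
        count = int(mask.sum())
        rss = float((resid[mask] ** 2).sum())
        if count > best_count or (count == best_count and rss < best_rss):
            best_mask, best_count, best_rss = mask, count, rss
    if best_count < 2:
        raise RuntimeError("RANSAC found no consensus set")
    slope, intercept = np.polyfit(reference[best_mask], signal[best_mask], 1)
    inlier_fraction = best_count / n
    if inlier_fraction < config.inlier_fraction_floor:
        warnings.warn(
            f"isosbestic fit inlier fraction {inlier_fraction:.2f} below "
            f"floor {config.inlier_fraction_floor}; inspect the recording",
            stacklevel=2,
        )
    return float(slope), float(intercept), best_mask


def compute_dff(signal: np.ndarray, fitted_reference: np.ndarray) -> np.ndarray:
    """dF/F = (signal - fitted reference) / fitted reference, elementwise."""
    signal = np.asarray(signal, dtype=float)
    fitted_reference = np.asarray(fitted_reference, dtype=float)
    bad = int((fitted_reference <= 0).sum())
    if bad:
        raise ValueError(
            f"fitted reference contains {bad} non-positive sample(s); "
            "cannot form dF/F"
        )
    return (signal - fitted_reference) / fitted_reference


def zscore_within_animal(traces: list[np.ndarray]) -> tuple[list[np.ndarray], float, float]:
    """Z-score one animal's dF/F traces with pooled session statistics.

    All traces (e.g. both hemispheres) are pooled to compute one mean and
    one standard deviation, which are then applied identically to each
    trace. Returns (zscored traces, mean, sd).
    """
    arrs = [np.asarray(t, dtype=float) for t in traces]
    pooled = np.concatenate(arrs)
    mean = float(pooled.mean())
    sd = float(pooled.std())
    if sd == 0:
        raise ValueError("zero variance across the session; cannot z-score")
    return [(a - mean) / sd for a in arrs], mean, sd


def smooth_gaussian(trace: np.ndarray, sigma: float) -> np.ndarray:
    """1-D Gaussian smoothing (reflect padding); sigma 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    trace = np.asarray(trace, dtype=float)
    if sigma == 0:
        return trace.copy()
    return gaussian_filter1d(trace, sigma=sigma, mode="reflect")


def _corrected_dff(
    session: PhotometrySession, config: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    t_sig = session.channel_times(CH_SIGNAL)
    sig = session.channel_values(CH_SIGNAL)
    ref = session.channel_values(CH_REFERENCE)
    m = min(len(sig), len(ref))
    if m == 0:
        raise ValueError("session is missing one of the two channels")
    t_sig, sig, ref = t_sig[:m], sig[:m], ref[:m]
    sig_f = lowpass_zero_phase(sig, config.lowpass_cutoff, session.channel_rate, config.filter_order)
    ref_f = lowpass_zero_phase(ref, config.lowpass_cutoff, session.channel_rate, config.filter_order)
    slope, intercept, mask = fit_isosbestic(ref_f, sig_f, config)
    fitted = slope * ref_f + intercept
    dff = compute_dff(sig_f, fitted)
    return t_sig, dff, slope, intercept, float(mask.mean())


def preprocess_session(
    session: PhotometrySession, config: PreprocessConfig | None = None
) -> ProcessedTrace:
    """Run the full single-fiber pipeline on one session.

    A session whose corrected dF/F is constant to within 1e-9 (e.g. a
    noise-free null recording) yields an all-zero zdF/F with a warning
    instead of a zero-variance error.
    """
    config = config or PreprocessConfig()
    t, dff, slope, intercept, inlier_frac = _corrected_dff(session, config)
    mean = float(dff.mean())
    sd = float(dff.std())
    if sd < 1e-12 and np.max(np.abs(dff - mean)) < 1e-9:
        warnings.warn(
            "corrected dF/F is constant; emitting all-zero zdF/F", stacklevel=2
        )
        zdff = dff - mean
    else:
        (zdff,), mean, sd = zscore_within_animal([dff])
    return ProcessedTrace(
        time=t,
        dff=dff,
        zdff=zdff,
        fit_slope=slope,
        fit_intercept=intercept,
        inlier_fraction=inlier_frac,
        session_mean=mean,
        session_sd=sd,
        animal=session.animal,
        hemisphere=session.hemisphere,
        channel_rate=session.channel_rate,
    )


def preprocess_animal(
    sessions: list[PhotometrySession], config: PreprocessConfig | None = None
) -> list[ProcessedTrace]:
    """Preprocess all fibers of one animal, z-scoring with pooled
    within-animal statistics across hemispheres."""
    config = config or PreprocessConfig()
    if not sessions:
        raise ValueError("no sessions given")
    animals = {s.animal for s in sessions}
    if len(animals) > 1:
        raise ValueError(f"sessions span multiple animals: {sorted(animals)}")
    parts = [_corrected_dff(s, config) for s in sessions]
    zs, mean, sd = zscore_within_animal([p[1] for p in parts])
    return [
        ProcessedTrace(
            time=p[0],
            dff=p[1],
            zdff=z,
            fit_slope=p[2],
            fit_intercept=p[3],
            inlier_fraction=p[4],
            session_mean=mean,
            session_sd=sd,
            animal=s.animal,
            hemisphere=s.hemisphere,
            channel_rate=s.channel_rate,
        )
        for s, p, z in zip(sessions, parts, zs)
    ]


def qc_report(
    session: PhotometrySession,
    trace: ProcessedTrace,
    out_path: str,
    config: PreprocessConfig | None = None,
) -> dict:
    """Automated stand-in for visual fit inspection: writes an overlay
    figure and returns summary metrics (inlier fraction, fit R^2)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or PreprocessConfig()
    sig = session.channel_values(CH_SIGNAL)
    ref = session.channel_values(CH_REFERENCE)
    m = min(len(sig), len(ref))
    sig_f = lowpass_zero_phase(sig[:m], config.lowpass_cutoff, session.channel_rate, config.filter_order)
    ref_f = lowpass_zero_phase(ref[:m], config.lowpass_cutoff, session.channel_rate, config.filter_order)
    fitted = trace.fit_slope * ref_f + trace.fit_intercept
    resid = sig_f - fitted
    ss_res = float((resid**2).sum())
    ss_tot = float(((sig_f - sig_f.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    axes[0].plot(trace.time[:m], sig_f, lw=0.5, label="signal (470-like)")
    axes[0].plot(trace.time[:m], fitted, lw=0.5, label="scaled reference")
    axes[0].legend(loc="upper right")
    axes[0].set_ylabel("fluorescence (a.u.)")
    axes[1].plot(trace.time, trace.zdff, lw=0.5, color="k")
    axes[1].set_ylabel("zdF/F")
    axes[1].set_xlabel("time (s)")
    fig.suptitle(f"{trace.animal} {trace.hemisphere}: inliers "
                 f"{trace.inlier_fraction:.2f}, R2 {r2:.3f}")
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    metrics = {"inlier_fraction": trace.inlier_fraction, "fit_r2": r2}
    if trace.inlier_fraction < config.inlier_fraction_floor:
        logger.warning("QC: inlier fraction below floor for %s/%s", trace.animal, trace.hemisphere)
    return metrics
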