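"""Sequence-resolved time-course modeling and uncertainty.

Two complementary routes:

* a marginal regression of binned zdF/F on cubic B-spline time terms
  interacted with sequence type, estimated by generalized estimating
  equations with an AR(1) working correlation over the within-unit bins
  and a robust sandwich covariance, with joint Wald chi-square tests on
  coefficient blocks; and
* a cluster bootstrap that resamples whole animals with replacement,
  carrying all of their peri-event traces, to produce percentile
  confidence bands around per-type mean time courses and time-resolved
  one-sample / pairwise significance intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scistats
from scipy.interpolate import BSpline

import statsmodels.api as sm

from .perievent import PeriEventUnit
from .sequences import SEQ_CC, SEQ_GO, SEQ_NOGO

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "GEEFit",
    "WaldResult",
    "BootstrapBands",
    "SignificanceInterval",
    "bspline_basis",
    "build_design",
    "fit_gee",
    "wald_joint",
    "bootstrap_timecourse",
    "one_sample_significance",
    "pairwise_band_difference",
    "simulate_units",
]


@dataclass(frozen=True)
class ModelSpec:
    """Design of the spline x sequence marginal model."""

    spline_df: int = 4
    degree: int = 3
    sequence_levels: tuple[str, ...] = (SEQ_CC, SEQ_NOGO, SEQ_GO)

    def __post_init__(self) -> None:
        if self.spline_df < 2:
            raise ValueError("spline_df must be >= 2")
        if len(self.sequence_levels) < 1:
            # a single level is allowed for intercept + spline-only designs
            raise ValueError("need at least 1 sequence level")
        if self.spline_df < self.degree:
            raise ValueError("spline_df must be >= spline degree")


def bspline_basis(x: np.ndarray, df: int = 4, degree: int = 3) -> np.ndarray:
    """Cubic B-spline basis with ``df`` columns, intercept excluded.

    Interior knots (df - degree of them) are placed at quantiles of
    ``x``; boundary knots at the extremes. The full (df + 1)-function
    partition-of-unity basis is built and its first function dropped, so
    the returned columns together with an explicit intercept span the
    same space.
    """
    x = np.asarray(x, dtype=float)
    n_interior = df - degree
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs) if n_interior else np.array([])
    lo, hi = float(x.min()), float(x.max())
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    dm = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree, extrapolate=False).toarray()
    return dm[:, 1:]


def build_design(
    units: list[PeriEventUnit], spec: ModelSpec | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Stack units into (design matrix, response, unit grouping, within-
    unit time index).

    Columns: intercept, (levels - 1) type indicators (first level is the
    reference), ``spline_df`` time columns, and their interactions -
    1 + 2 + 4 + 8 = 15 columns for the default spec.
    """
    spec = spec or ModelSpec()
    present = {u.sequence_type for u in units}
    for lvl in spec.sequence_levels:
        if lvl not in present:
            raise ValueError(f"sequence level {lvl!r} has zero units")
    units = [u for u in units if u.sequence_type in spec.sequence_levels]
    n_bins = len(units[0].bin_times)
    for u in units:
        if len(u.bin_times) != n_bins:
            raise ValueError("all units must share the bin grid")
    bin_times = units[0].bin_times
    S = bspline_basis(bin_times, spec.spline_df, spec.degree)

    ref = spec.sequence_levels[0]
    nonref = list(spec.sequence_levels[1:])
    cols = (
        ["Intercept"]
        + [f"type[{lvl}]" for lvl in nonref]
        + [f"s{j + 1}" for j in range(spec.spline_df)]
        + [f"type[{lvl}]:s{j + 1}" for lvl in nonref for j in range(spec.spline_df)]
    )
    blocks = []
    y = []
    groups = []
    times = []
    for g, u in enumerate(units):
        X = np.zeros((n_bins, len(cols)))
        X[:, 0] = 1.0
        if u.sequence_type != ref:
            k = nonref.index(u.sequence_type)
            X[:, 1 + k] = 1.0
        off = 1 + len(nonref)
        X[:, off : off + spec.spline_df] = S
        if u.sequence_type != ref:
            k = nonref.index(u.sequence_type)
            ioff = off + spec.spline_df + k * spec.spline_df
            X[:, ioff : ioff + spec.spline_df] = S
        blocks.append(X)
        y.append(u.values)
        groups.append(np.full(n_bins, g))
        times.append(np.arange(n_bins))
    design = pd.DataFrame(np.vstack(blocks), columns=cols)
    return design, np.concatenate(y), np.concatenate(groups), np.concatenate(times)


@dataclass
class GEEFit:
    """Fitted marginal model: coefficients, sandwich covariance, and the
    working AR(1) parameter.

    ``cov`` is the plain robust (sandwich) covariance used by default;
    ``cov_naive`` is the model-based covariance and ``cov_bc`` the
    Mancl-DeRouen bias-reduced sandwich, both kept for small-sample
    inference and diagnostics.
    """

    params: pd.Series
    cov: pd.DataFrame
    cov_naive: pd.DataFrame
    cov_bc: pd.DataFrame
    ar1_rho: float
    n_units: int
    n_obs: int
    converged: bool

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)

    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)


@dataclass
class WaldResult:
    statistic: float
    df: int
    p: float
    columns: tuple[str, ...]


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_gee(
    design: pd.DataFrame,
    response: np.ndarray,
    groups: np.ndarray,
    time_index: np.ndarray | None = None,
    maxiter: int = 60,
) -> GEEFit:
    """Fit the Gaussian identity-link GEE with AR(1) working correlation
    over the equally spaced within-unit bins and robust covariance."""
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dep = _dependent_columns(X, list(design.columns))
        raise ValueError(f"rank-deficient design; dependent columns: {dep}")
    if time_index is None:
        time_index = np.concatenate(
            [np.arange((groups == g).sum()) for g in pd.unique(groups)]
        )
    model = sm.GEE(
        response,
        X,
        groups=groups,
        time=np.asarray(time_index, dtype=int),
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Autoregressive(grid=True),
    )
    # bias_reduced makes statsmodels compute all three covariances
    res = model.fit(maxiter=maxiter, cov_type="bias_reduced")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("GEE did not converge within %d iterations", maxiter)
    rho = float(np.atleast_1d(res.cov_struct.dep_params)[0])
    idx = design.columns

    def frame(a):
        return pd.DataFrame(a, index=idx, columns=idx)

    return GEEFit(
        params=pd.Series(res.params, index=idx),
        cov=frame(res.cov_robust),
        cov_naive=frame(res.cov_naive),
        cov_bc=frame(res.cov_robust_bc),
        ar1_rho=rho,
        n_units=int(len(np.unique(groups))),
        n_obs=int(len(response)),
        converged=converged,
    )


def wald_joint(
    fit: GEEFit,
    columns: list[str],
    cov: str = "robust",
    reference: str = "chi2",
) -> WaldResult:
    """Joint Wald test that the selected coefficient block is zero.

    ``cov`` selects the covariance ('robust' sandwich by default,
    'bias_reduced' Mancl-DeRouen, or 'naive' model-based). The default
    ``reference='chi2'`` compares the statistic to chi-square(df);
    ``reference='f'`` applies the Hotelling small-sample scaling
    ``stat * (K - df) / (df * (K - 1))`` against F(df, K - df) with K
    the number of clusters, which keeps multi-df tests calibrated at
    modest cluster counts. df is the rank of the block.
    """
    if not columns:
        raise ValueError("empty column selection")
    missing = [c for c in columns if c not in fit.columns]
    if missing:
        raise ValueError(f"unknown columns: {missing}")
    covs = {"robust": fit.cov, "bias_reduced": fit.cov_bc, "naive": fit.cov_naive}
    if cov not in covs:
        raise ValueError("cov must be 'robust', 'bias_reduced' or 'naive'")
    b = fit.params[columns].to_numpy()
    V = covs[cov].loc[columns, columns].to_numpy()
    Vinv = np.linalg.pinv(V)
    stat = float(b @ Vinv @ b)
    df = int(np.linalg.matrix_rank(V))
    if reference == "chi2":
        p = float(scistats.chi2.sf(stat, df))
    elif reference == "f":
        K = fit.n_units
        if K <= df:
            raise ValueError("F reference needs more clusters than tested df")
        fstat = stat * (K - df) / (df * (K - 1))
        p = float(scistats.f.sf(fstat, df, K - df))
    else:
        raise ValueError("reference must be 'chi2' or 'f'")
    return WaldResult(statistic=stat, df=df, p=p, columns=tuple(columns))


def interaction_columns(spec: ModelSpec | None = None) -> list[str]:
    """Names of the type x spline interaction columns of the default
    reference-coded design."""
    spec = spec or ModelSpec()
    return [
        f"type[{lvl}]:s{j + 1}"
        for lvl in spec.sequence_levels[1:]
        for j in range(spec.spline_df)
    ]


# ---------------------------------------------------------------------------
# cluster bootstrap


@dataclass
class SignificanceInterval:
    contrast: str
    t_start: float
    t_end: float


@dataclass
class BootstrapBands:
    """Per sequence-type percentile bands of the mean time course."""

    bin_times: np.ndarray
    types: tuple[str, ...]
    mean: dict[str, np.ndarray]
    lo95: dict[str, np.ndarray]
    hi95: dict[str, np.ndarray]
    lo99: dict[str, np.ndarray]
    hi99: dict[str, np.ndarray]
    n_resamples: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for tp in self.types:
            frames.append(
                pd.DataFrame(
                    {
                        "sequence_type": tp,
                        "bin_time": self.bin_times,
                        "mean": self.mean[tp],
                        "lo95": self.lo95[tp],
                        "hi95": self.hi95[tp],
                        "lo99": self.lo99[tp],
                        "hi99": self.hi99[tp],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _group_units(units: list[PeriEventUnit], types: tuple[str, ...]):
    """Per-animal, per-type sums and counts for fast animal resampling."""
    animals = sorted({u.animal for u in units})
    n_bins = len(units[0].bin_times)
    sums = {tp: np.zeros((len(animals), n_bins)) for tp in types}
    counts = {tp: np.zeros(len(animals)) for tp in types}
    aidx = {a: i for i, a in enumerate(animals)}
    for u in units:
        if u.sequence_type not in sums:
            continue
        sums[u.sequence_type][aidx[u.animal]] += u.values
        counts[u.sequence_type][aidx[u.animal]] += 1
    return animals, sums, counts


def _resample_means(
    sums: np.ndarray, counts: np.ndarray, draw_counts: np.ndarray
) -> np.ndarray:
    """Mean time course over the units of a with-replacement animal
    resample, given per-animal draw multiplicities (R x A)."""
    num = draw_counts @ sums
    den = draw_counts @ counts
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den[:, None]


def bootstrap_timecourse(
    units: list[PeriEventUnit],
    n_resamples: int = 1000,
    seed: int = 0,
    types: tuple[str, ...] | None = None,
) -> BootstrapBands:
    """Animal-level bootstrap of per-type mean time courses.

    Each resample draws animals with replacement and carries all of their
    units (with multiplicity); per-type means are recomputed per
    resample and summarized by 95% and 99% percentile bands.
    Deterministic given ``seed``.
    """
    if not units:
        raise ValueError("no units given")
    if types is None:
        types = tuple(sorted({u.sequence_type for u in units}))
    animals, sums, counts = _group_units(units, types)
    if len(animals) < 2:
        raise ValueError("cannot resample one cluster: need >= 2 animals")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(animals), size=(n_resamples, len(animals)))
    draw_counts = np.stack(
        [np.bincount(d, minlength=len(animals)) for d in draws]
    ).astype(float)
    bin_times = units[0].bin_times
    mean, lo95, hi95, lo99, hi99 = {}, {}, {}, {}, {}
    for tp in types:
        if counts[tp].sum() == 0:
            raise ValueError(f"sequence type {tp!r} has no units")
        dist = _resample_means(sums[tp], counts[tp], draw_counts)
        mean[tp] = sums[tp].sum(axis=0) / counts[tp].sum()
        lo95[tp] = np.nanpercentile(dist, 2.5, axis=0)
        hi95[tp] = np.nanpercentile(dist, 97.5, axis=0)
        lo99[tp] = np.nanpercentile(dist, 0.5, axis=0)
        hi99[tp] = np.nanpercentile(dist, 99.5, axis=0)
    return BootstrapBands(
        bin_times=bin_times,
        types=types,
        mean=mean,
        lo95=lo95,
        hi95=hi95,
        lo99=lo99,
        hi99=hi99,
        n_resamples=n_resamples,
        seed=seed,
    )


def _merge_significant_bins(
    bin_times: np.ndarray, sig: np.ndarray, contrast: str, min_bins: int
) -> list[SignificanceInterval]:
    intervals: list[SignificanceInterval] = []
    i = 0
    n = len(sig)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < n and sig[j]:
            j += 1
        if j - i >= min_bins:
            intervals.append(
                SignificanceInterval(contrast, float(bin_times[i]), float(bin_times[j - 1]))
            )
        else:
            logger.info(
                "%s: isolated significant run of %d bin(s) at %.2f s suppressed",
                contrast, j - i, bin_times[i],
            )
        i = j
    return intervals


def one_sample_significance(
    bands: BootstrapBands, level: int = 99, min_bins: int = 2
) -> list[SignificanceInterval]:
    """Contiguous bins where the chosen band excludes zero, per type."""
    if level == 99:
        lo, hi = bands.lo99, bands.hi99
    elif level == 95:
        lo, hi = bands.lo95, bands.hi95
    else:
        raise ValueError("level must be 95 or 99")
    out: list[SignificanceInterval] = []
    for tp in bands.types:
        sig = (lo[tp] > 0) | (hi[tp] < 0)
        out.extend(_merge_significant_bins(bands.bin_times, sig, tp, min_bins))
    return out


def pairwise_band_difference(
    units: list[PeriEventUnit],
    pair: tuple[str, str],
    n_resamples: int = 1000,
    seed: int = 0,
    level: int = 95,
    min_bins: int = 2,
    method: str = "bands",
) -> tuple[pd.DataFrame, list[SignificanceInterval]]:
    """Time-resolved pairwise contrast between two types' mean courses.

    Both type means are recomputed within each animal-level resample.
    ``method='bands'`` (default) subtracts the two types' percentile
    bands: a bin is significant when the bands separate
    (``lo_a - hi_b > 0`` or ``hi_a - lo_b < 0``), a conservative rule.
    ``method='diff'`` forms the percentile band of the per-resample
    difference and marks bins where it excludes zero. Returns
    (band table, intervals).
    """
    type_a, type_b = pair
    present = {u.sequence_type for u in units}
    for tp in pair:
        if tp not in present:
            raise ValueError(f"sequence type {tp!r} absent from units")
    animals, sums, counts = _group_units(units, (type_a, type_b))
    if len(animals) < 2:
        raise ValueError("cannot resample one cluster: need >= 2 animals")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(animals), size=(n_resamples, len(animals)))
    draw_counts = np.stack(
        [np.bincount(d, minlength=len(animals)) for d in draws]
    ).astype(float)
    dist_a = _resample_means(sums[type_a], counts[type_a], draw_counts)
    dist_b = _resample_means(sums[type_b], counts[type_b], draw_counts)
    alpha = (100 - level) / 2.0
    if method == "diff":
        diff = dist_a - dist_b
        lo = np.nanpercentile(diff, alpha, axis=0)
        hi = np.nanpercentile(diff, 100 - alpha, axis=0)
    elif method == "bands":
        lo_a = np.nanpercentile(dist_a, alpha, axis=0)
        hi_a = np.nanpercentile(dist_a, 100 - alpha, axis=0)
        lo_b = np.nanpercentile(dist_b, alpha, axis=0)
        hi_b = np.nanpercentile(dist_b, 100 - alpha, axis=0)
        lo = lo_a - hi_b
        hi = hi_a - lo_b
    else:
        raise ValueError("method must be 'bands' or 'diff'")
    obs = (
        sums[type_a].sum(axis=0) / counts[type_a].sum()
        - sums[type_b].sum(axis=0) / counts[type_b].sum()
    )
    bin_times = units[0].bin_times
    contrast = f"{type_a} - {type_b}"
    sig = (lo > 0) | (hi < 0)
    intervals = _merge_significant_bins(bin_times, sig, contrast, min_bins)
    band = pd.DataFrame(
        {"contrast": contrast, "bin_time": bin_times, "diff": obs, "lo": lo, "hi": hi}
    )
    return band, intervals


# ---------------------------------------------------------------------------
# simulation helpers used by calibration tests and validation scripts


def ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series of marginal standard deviation ``sd``."""
    e = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    out[0] = e[0]
    innov_scale = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov_scale * e[i]
    return out


def simulate_units(
    n_animals: int,
    units_per_animal: int,
    profiles: dict[str, np.ndarray],
    bin_times: np.ndarray,
    rho: float = 0.9,
    noise_sd: float = 1.0,
    animal_sd: float = 0.0,
    seed: int = 0,
) -> list[PeriEventUnit]:
    """Generate peri-event units with known per-type mean profiles plus
    AR(1) within-unit noise and optional animal-level offsets."""
    rng = np.random.default_rng(seed)
    types = list(profiles)
    units: list[PeriEventUnit] = []
    n_bins = len(bin_times)
    for a in range(n_animals):
        offset = rng.normal(0.0, animal_sd) if animal_sd > 0 else 0.0
        for ev in range(units_per_animal):
            tp = types[(a * units_per_animal + ev) % len(types)]
            noise = ar1_noise(rng, n_bins, rho, noise_sd)
            units.append(
                PeriEventUnit(
                    animal=f"m{a}",
                    hemisphere="left",
                    event=ev,
                    sequence_type=tp,
                    bin_times=bin_times,
                    values=profiles[tp] + offset + noise,
                )
            )
    return units
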