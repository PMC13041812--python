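"""Group-level statistics for behavioral tables.

Long-format tables carry one row per (animal, group, within-factor
level, value). Mixed ANOVAs and one-way ANOVAs with FDR-corrected
pairwise follow-ups match the analyses applied to occupancy, locomotion
time courses, per-sequence metrics, sequence counts, and the
risk-assessment index.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as scistats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "mixed_anova",
    "oneway_anova_fdr",
    "ks_two_sample",
    "bin_session_features",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "factor",
    between: str = "group",
    subject: str = "animal",
) -> pd.DataFrame:
    """Two-way mixed ANOVA (between-group x within-factor).

    Requires every animal to cover every within-factor level. Returns
    the pingouin ANOVA table (rows: between, within, interaction) with
    sphericity-corrected p-values when available.
    """
    import pingouin as pg

    levels = set(table[within].unique())
    for animal, grp in table.groupby(subject):
        missing = levels - set(grp[within])
        if missing:
            raise ValueError(
                f"animal {animal!r} is missing within levels {sorted(missing)}"
            )
    per_animal_groups = table.groupby(subject)[between].nunique()
    if (per_animal_groups > 1).any():
        bad = per_animal_groups[per_animal_groups > 1].index.tolist()
        raise ValueError(f"animals assigned to multiple groups: {bad}")
    if table[between].nunique() < 2:
        raise ValueError("need at least 2 between groups")
    if np.ptp(table[dv].to_numpy(dtype=float)) == 0:
        raise ValueError("all values identical; F statistics undefined")
    aov = pg.mixed_anova(
        data=table, dv=dv, within=within, between=between, subject=subject,
        correction=True,
    )
    if not np.isfinite(aov["F"]).all():
        raise ValueError("degenerate design: F statistic undefined")
    return aov


def oneway_anova_fdr(
    table: pd.DataFrame, dv: str = "value", between: str = "group"
) -> dict:
    """One-way ANOVA plus Benjamini-Hochberg-adjusted pairwise t-tests."""
    groups = {
        str(name): grp[dv].to_numpy(dtype=float)
        for name, grp in table.groupby(between)
        if len(grp) >= 2
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    F, p = scistats.f_oneway(*groups.values())
    names = sorted(groups)
    pairs, raw = [], []
    for a, b in itertools.combinations(names, 2):
        _, pp = scistats.ttest_ind(groups[a], groups[b])
        pairs.append((a, b))
        raw.append(float(pp))
    adj = bh_adjust(raw)
    n = sum(len(v) for v in groups.values())
    return {
        "F": float(F),
        "p": float(p),
        "df_between": len(groups) - 1,
        "df_within": n - len(groups),
        "pairwise": {
            pair: {"p_raw": r, "p_fdr": float(q)} for pair, r, q in zip(pairs, raw, adj)
        },
    }


def ks_two_sample(values_a, values_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (max ECDF gap, asymptotic p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = scistats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def bin_session_features(
    features: pd.DataFrame,
    columns: list[str],
    bin_width: float = 5.0,
) -> pd.DataFrame:
    """Average frame-wise features into fixed-width session time bins,
    yielding a long table (time_bin, column, value) for time-course
    ANOVAs."""
    t = features["time"].to_numpy(dtype=float)
    idx = np.floor((t - t[0]) / bin_width).astype(int)
    out = features[columns].copy()
    out["time_bin"] = idx * bin_width + t[0] + bin_width / 2.0
    long = out.melt(id_vars="time_bin", var_name="feature", value_name="value")
    return (
        long.groupby(["time_bin", "feature"], as_index=False)["value"].mean()
    )
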