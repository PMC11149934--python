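"""Cohort-level trend estimation: Pearson fits against age, within-group
z-transforms, per-region degree slopes and per-frequency PSD-age
correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

CHILD_MAX_AGE = 18.0  # synthetic-world child/adult split


@dataclass
class FitResult:
    """Least-squares line y = slope * x + intercept with Pearson R^2 and a
    two-sided p-value from the t distribution (n - 2 df)."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int

    @property
    def r2(self) -> float:
        return self.r**2


def pearson_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 finite observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = sstats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=int(x.size),
    )


def age_groups(ages: np.ndarray, child_max: float = CHILD_MAX_AGE) -> np.ndarray:
    return np.where(np.asarray(ages, float) < child_max, "child", "adult")


def zscore_within_groups(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Map each group to mean 0, sample SD 1 (used to pool child and adult
    subgroups without the age confound)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in np.unique(groups):
        sel = groups == g
        v = values[sel]
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} is constant")
        out[sel] = (v - v.mean()) / sd
    return out


def degree_age_slopes(degree: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    """Per-region linear fit of node degree against age.

    ``degree`` is subjects x regions; returns one row per region with
    slope, r2 and p.
    """
    rows = []
    for region in degree.columns:
        fit = pearson_fit(ages, degree[region].to_numpy())
        rows.append({"region": region, "slope": fit.slope, "r2": fit.r2, "p": fit.p})
    return pd.DataFrame(rows).set_index("region")


def psd_age_correlation(
    psds: np.ndarray,
    ages: np.ndarray,
    freqs: np.ndarray,
    alpha: float = 0.01,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-frequency Pearson correlation of burst-state PSD with age.

    Frequencies with p < alpha are flagged (uncorrected by default, to
    match the per-frequency convention; ``correction='fdr_bh'`` applies
    Benjamini-Hochberg instead).
    """
    psds = np.asarray(psds, float)
    if psds.shape[1] != len(freqs):
        raise ValueError("PSD matrix and frequency grid disagree")
    r = np.empty(len(freqs))
    p = np.empty(len(freqs))
    for j in range(len(freqs)):
        fit = pearson_fit(ages, psds[:, j])
        r[j], p[j] = fit.r, fit.p
    if correction == "fdr_bh":
        flagged = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    elif correction is None:
        flagged = p < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return pd.DataFrame({"freq": freqs, "r": r, "p": p, "flagged": flagged}).set_index("freq")


def metric_age_fits(table: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """Pearson fit of each cohort metric against age."""
    rows = []
    for m in metrics:
        fit = pearson_fit(table["age"].to_numpy(), table[m].to_numpy())
        rows.append(
            {"metric": m, "slope": fit.slope, "intercept": fit.intercept,
             "r": fit.r, "r2": fit.r2, "p": fit.p, "n": fit.n}
        )
    return pd.DataFrame(rows).set_index("metric")


def cross_metric_association(
    table: pd.DataFrame, x: str = "beta_mod", y: str = "delta_p"
) -> FitResult:
    """Association between two metrics after within-group (child/adult)
    z-transforms — the age-confound-controlled analysis."""
    groups = age_groups(table["age"].to_numpy())
    zx = zscore_within_groups(table[x].to_numpy(), groups)
    zy = zscore_within_groups(table[y].to_numpy(), groups)
    return pearson_fit(zx, zy)
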