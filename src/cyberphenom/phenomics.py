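"""Growth-curve and morphology phenomics.

Raw OD610 time series become specific growth rates via a sliding-window
log-linear fit (maximum slope of ln(OD) vs time over windows passing an
R^2 gate), then YPD-normalized relative fitness.  Replicated morphology
tables become Wald Z-scores against a reference strain from a one-way
Gaussian fixed-effect model per trait.  A thin exact/asymptotic
Wilcoxon-Mann-Whitney wrapper serves the group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

OD_FLOOR = 1e-3  # floor for OD - blank before the log, avoids -inf


@dataclass
class GrowthRateResult:
    """Specific growth rate of one curve (1/h) with fit diagnostics."""

    mu: float
    r_squared: float
    window_start_h: float
    no_growth: bool


@dataclass
class FitnessMatrix:
    """Strains x conditions mean relative growth rates (condition mu / YPD
    mu), with the replicate-level ratios retained.  The reference
    condition is excluded from ``matrix``."""

    matrix: pd.DataFrame
    replicate_ratios: pd.DataFrame  # long: strain, condition, replicate, relative_rate
    reference_condition: str


@dataclass
class TraitZMatrix:
    """Strains x traits Wald Z-scores versus the reference strain."""

    matrix: pd.DataFrame
    reference_strain: str
    dropped_traits: list[str]


def growth_rate(
    time_h: np.ndarray,
    od: np.ndarray,
    blank: float = 0.0,
    window_points: int = 13,
    min_od: float = 0.03,
    r2_min: float = 0.95,
) -> GrowthRateResult:
    """Maximum sliding-window slope of ln(OD - blank) vs time.

    Every run of ``window_points`` consecutive samples whose
    blank-subtracted OD exceeds ``min_od`` is fit by least squares; the
    growth rate is the largest slope among windows with R^2 >= ``r2_min``.
    If no window reaches a positive slope at that R^2, the result is 0
    with the no-growth flag set.
    """
    t = np.asarray(time_h, dtype=float)
    y_raw = np.asarray(od, dtype=float) - blank
    if len(t) != len(y_raw):
        raise ValueError("time and OD arrays differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if window_points < 3:
        raise ValueError("window_points must be at least 3")
    usable = y_raw > min_od
    if usable.sum() < window_points:
        return GrowthRateResult(0.0, np.nan, np.nan, True)
    y = np.log(np.maximum(y_raw, OD_FLOOR))

    best_mu, best_r2, best_t0 = 0.0, np.nan, np.nan
    w = window_points
    for i in range(len(t) - w + 1):
        if not usable[i : i + w].all():
            continue
        tw, yw = t[i : i + w], y[i : i + w]
        tc = tw - tw.mean()
        yc = yw - yw.mean()
        sxx = (tc**2).sum()
        slope = (tc * yc).sum() / sxx
        ss_res = ((yc - slope * tc) ** 2).sum()
        ss_tot = (yc**2).sum()
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        if slope > best_mu and r2 >= r2_min:
            best_mu, best_r2, best_t0 = slope, r2, tw[0]
    if best_mu <= 0:
        return GrowthRateResult(0.0, np.nan, np.nan, True)
    return GrowthRateResult(float(best_mu), float(best_r2), float(best_t0), False)


def growth_rates_table(
    curves: pd.DataFrame,
    blank: float = 0.0,
    window_points: int = 13,
    min_od: float = 0.03,
    r2_min: float = 0.95,
) -> pd.DataFrame:
    """Apply :func:`growth_rate` to every (strain, condition, replicate)
    curve of a long-format table; returns strain/condition/replicate/mu."""
    rows = []
    for (strain, cond, rep), grp in curves.groupby(["strain", "condition", "replicate"], sort=False):
        grp = grp.sort_values("time_h")
        res = growth_rate(
            grp["time_h"].to_numpy(), grp["od"].to_numpy(),
            blank=blank, window_points=window_points, min_od=min_od, r2_min=r2_min,
        )
        rows.append((strain, cond, rep, res.mu, res.no_growth))
    return pd.DataFrame(rows, columns=["strain", "condition", "replicate", "mu", "no_growth"])


def normalize_fitness(rates: pd.DataFrame, reference: str = "YPD") -> FitnessMatrix:
    """Replicate-matched YPD normalization of growth rates.

    Each replicate's rate in a condition is divided by the same
    replicate's rate in the reference condition, then averaged over
    replicates.  The reference column is dropped from the analysis
    matrix (it is identically 1).
    """
    if reference not in set(rates["condition"]):
        raise ValueError(f"reference condition {reference!r} not measured")
    ref = rates[rates["condition"] == reference].set_index(["strain", "replicate"])["mu"]
    zero_ref = ref[ref <= 0]
    if len(zero_ref):
        names = sorted({s for s, _ in zero_ref.index})
        raise ValueError(f"zero reference-condition growth rate for strain(s): {', '.join(names)}")
    out = rates.copy()
    out["relative_rate"] = out["mu"].to_numpy() / ref.reindex(
        pd.MultiIndex.from_frame(out[["strain", "replicate"]])
    ).to_numpy()
    matrix = (
        out[out["condition"] != reference]
        .pivot_table(index="strain", columns="condition", values="relative_rate", aggfunc="mean")
    )
    return FitnessMatrix(
        matrix=matrix,
        replicate_ratios=out[["strain", "condition", "replicate", "relative_rate"]],
        reference_condition=reference,
    )


def morphology_zscores(traits: pd.DataFrame, reference_strain: str) -> TraitZMatrix:
    """Wald Z-scores of every strain against the reference, per trait.

    For each trait a one-way fixed-effect Gaussian model over strains is
    fit (OLS with treatment coding relative to the reference strain); the
    Z-score is the Wald statistic of each strain's contrast, i.e.
    (mean_s - mean_ref) / SE with the SE from the pooled residual
    variance.  The reference row is exactly zero.  Traits with zero
    pooled variance are dropped with a warning.
    """
    strains = list(pd.unique(traits["strain"]))
    if reference_strain not in strains:
        raise ValueError(f"reference strain {reference_strain!r} absent from trait table")
    z_cols = {}
    dropped = []
    for trait, grp in traits.groupby("trait", sort=False):
        groups = grp.groupby("strain")["value"]
        resid_ss = ((grp["value"] - groups.transform("mean")) ** 2).sum()
        if resid_ss <= 0:
            logger.warning("morphology_zscores: trait %s has zero pooled variance, dropped", trait)
            dropped.append(trait)
            continue
        cat = pd.Categorical(
            grp["strain"], categories=[reference_strain] + [s for s in strains if s != reference_strain]
        )
        X = sm.add_constant(pd.get_dummies(cat, drop_first=True).astype(float))
        fit = sm.OLS(grp["value"].to_numpy(), X.to_numpy()).fit()
        z = pd.Series(0.0, index=strains)
        z.loc[X.columns[1:]] = fit.tvalues[1:]
        z_cols[trait] = z
    matrix = pd.DataFrame(z_cols)
    matrix.index.name = "strain"
    return TraitZMatrix(matrix=matrix, reference_strain=reference_strain, dropped_traits=dropped)


def wilcoxon_mw(
    group_a: np.ndarray, group_b: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U, P).

    ``mode='auto'`` uses the exact null distribution (full enumeration)
    when n_A + n_B <= 30 and the data are tie-free, otherwise the normal
    approximation with tie and continuity corrections.  ``'exact'`` and
    ``'asymptotic'`` force the respective method.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if mode == "auto":
        method = "exact" if (a.size + b.size <= 30 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))
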