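"""Diet-quality scoring and grouped income regressions.

Per-capita daily intake is compared with the recommended ranges of the
Chinese Food Guide Pagoda (2022). A household-category observation is
"insufficient" below the lower bound, "excess" above the upper bound and
"adequate" inside the range (bounds inclusive). The dietary-deviation score
is the distance to the violated bound divided by the interval midpoint
m = (lower+upper)/2:

    score = (lower - c)/m   if c < lower
          = 0               if lower <= c <= upper
          = (c - upper)/m   if c > upper

non-negative, continuous, and piecewise linear with slopes -1/m, 0, +1/m.

Grouped regressions re-use the threshold model's fixed-effects structure
(household demeaning, wave dummies, province-cluster-robust CR1 errors) to
estimate income effects on amounts, shares and deviations separately for the
low-income (hhinc <= gamma) and high-income (hhinc > gamma) groups, plus
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .reference import RECOMMENDED_RANGES_G
from .threshold import (
    ThresholdModel,
    WithinDesign,
    _independent_columns,
    cluster_robust_cov,
)

__all__ = [
    "RecommendedRange",
    "DeviationScore",
    "default_ranges",
    "ranges_from_csv",
    "per_capita_daily",
    "classify_adequacy",
    "deviation",
    "group_regression",
    "group_difference_test",
]


@dataclass(frozen=True)
class RecommendedRange:
    """Recommended per-capita daily intake interval, g/day."""

    category: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(
                f"need 0 < lower < upper, got [{self.lower}, {self.upper}]"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class DeviationScore:
    category: str
    score: float
    adequacy: str  # insufficient | adequate | excess


def default_ranges() -> dict[str, RecommendedRange]:
    """Pagoda ranges for the six aggregated categories."""
    return {
        c: RecommendedRange(c, lo, hi) for c, (lo, hi) in RECOMMENDED_RANGES_G.items()
    }


def ranges_from_csv(path) -> dict[str, RecommendedRange]:
    df = pd.read_csv(path, comment="#")
    return {
        r.category: RecommendedRange(r.category, float(r.lower), float(r.upper))
        for r in df.itertuples()
    }


def per_capita_daily(annual_kg, hhsize=1.0):
    """Annual household kg -> per-capita g/day: kg * 1000 / 365 / hhsize."""
    hhsize = np.asarray(hhsize, dtype=float)
    if (hhsize < 1).any():
        raise ValueError("hhsize must be >= 1")
    return np.asarray(annual_kg, dtype=float) * 1000.0 / 365.0 / hhsize


def classify_adequacy(consumption: float, rng: RecommendedRange) -> str:
    """insufficient / adequate / excess; bounds count as adequate."""
    if consumption < 0:
        raise ValueError("consumption must be >= 0")
    if consumption < rng.lower:
        return "insufficient"
    if consumption > rng.upper:
        return "excess"
    return "adequate"


def deviation(consumption: float, rng: RecommendedRange) -> DeviationScore:
    """Non-negative midpoint-normalized distance to the recommended interval.

    Zero exactly on the interval (score == 0 iff adequate), continuous at
    both bounds.
    """
    label = classify_adequacy(consumption, rng)
    m = rng.midpoint
    if label == "insufficient":
        score = (rng.lower - consumption) / m
    elif label == "excess":
        score = (consumption - rng.upper) / m
    else:
        score = 0.0
    return DeviationScore(rng.category, float(score), label)


def deviation_frame(daily: pd.DataFrame, ranges=None) -> pd.DataFrame:
    """Vectorized deviation scores/labels for a wide g/day table.

    ``daily`` has one ``<category>`` column per scored category; returns
    ``<category>_dev`` and ``<category>_adequacy`` columns.
    """
    ranges = ranges or default_ranges()
    out = daily.copy()
    for c, r in ranges.items():
        if c not in daily.columns:
            continue
        v = daily[c].to_numpy(dtype=float)
        score = np.where(
            v < r.lower, (r.lower - v) / r.midpoint,
            np.where(v > r.upper, (v - r.upper) / r.midpoint, 0.0),
        )
        out[f"{c}_dev"] = score
        out[f"{c}_adequacy"] = np.where(
            v < r.lower, "insufficient", np.where(v > r.upper, "excess", "adequate")
        )
    return out


# ---------------------------------------------------------------------------
# Grouped income regressions
# ---------------------------------------------------------------------------

def _fe_income_fit(df: pd.DataFrame, outcome: str, model: ThresholdModel) -> dict:
    """Within (household FE + wave dummies) regression of ``outcome`` on
    income and the controls; returns the income coefficient with CR1
    province-clustered inference."""
    spec = ThresholdModel(
        dependent=outcome,
        threshold_var=model.threshold_var,
        regime_var=model.regime_var,
        controls=model.controls,
        household=model.household,
        time=model.time,
        cluster=model.cluster,
        include_age_sq=model.include_age_sq,
    )
    # group splits routinely leave some households with a single wave;
    # dropping them silently is the expected behaviour here
    design = WithinDesign(df, spec, warn_singletons=False)
    X = np.column_stack([design.rt, design.Wt])
    keep = _independent_columns(X)
    if 0 not in keep:  # income itself must stay identified
        raise ValueError("income has no independent within variation")
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, design.yt, rcond=None)
    resid = design.yt - X @ beta
    cov = cluster_robust_cov(X, resid, design.cluster_codes)
    se = float(np.sqrt(cov[0, 0]))
    t = beta[0] / se if se > 0 else np.nan
    from scipy import stats as sps

    G = len(design.clusters)
    p = 2.0 * sps.t.sf(abs(t), df=G - 1) if np.isfinite(t) else np.nan
    return {
        "coef_income": float(beta[0]),
        "se": se,
        "t": float(t),
        "p": float(p),
        "n": design.n,
    }


def _pooled_income_fit(df: pd.DataFrame, outcome: str, model: ThresholdModel) -> dict:
    """Pooled OLS (no household FE) with controls, wave dummies, intercept."""
    y = df[outcome].to_numpy(dtype=float)
    cols = [df[model.regime_var].to_numpy(dtype=float)]
    names = ["income"]
    for c in model.control_names:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    waves = np.sort(df[model.time].unique())
    for w in waves[1:]:
        cols.append((df[model.time] == w).to_numpy(dtype=float))
        names.append(f"wave_{w}")
    X = sm.add_constant(np.column_stack(cols))
    res = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": df[model.cluster].to_numpy()}
    )
    return {
        "coef_income": float(res.params[1]),
        "se": float(res.bse[1]),
        "t": float(res.tvalues[1]),
        "p": float(res.pvalues[1]),
        "n": int(res.nobs),
    }


def group_regression(
    panel: pd.DataFrame,
    outcome: str,
    gamma: float,
    model: ThresholdModel | None = None,
    fixed_effects: bool = True,
    min_group_obs: int = 30,
) -> pd.DataFrame:
    """Income effect on ``outcome`` for low-income (hhinc <= gamma),
    high-income (hhinc > gamma) and pooled samples.

    ``outcome`` can be a total/category amount (kg), a percentage-point
    share, or a deviation score — any column of ``panel``. Returns a tidy
    frame (outcome, group, coef_income, se, t, p, n). Refuses groups with
    fewer than ``min_group_obs`` observations.
    """
    model = model or ThresholdModel()
    if outcome not in panel.columns:
        raise ValueError(f"panel lacks outcome column {outcome!r}")
    groups = {
        "low": panel[panel[model.threshold_var] <= gamma],
        "high": panel[panel[model.threshold_var] > gamma],
        "pooled": panel,
    }
    rows = []
    fitter = _fe_income_fit if fixed_effects else _pooled_income_fit
    for gname, df in groups.items():
        if len(df) < min_group_obs:
            raise ValueError(
                f"group {gname!r} has {len(df)} observations (< {min_group_obs}); "
                "refusing to fit"
            )
        res = fitter(df, outcome, model)
        rows.append({"outcome": outcome, "group": gname, **res})
    return pd.DataFrame(rows)


def group_difference_test(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    cluster_ids: np.ndarray | pd.Series,
) -> dict:
    """Two-sided test of equal group means with cluster-robust errors.

    Regresses the outcome on a group indicator; the indicator's
    cluster-robust t statistic gives the p-value. Degenerate (zero-variance)
    outcomes return p = NaN with ``degenerate = True`` rather than a
    fabricated number.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    cl = np.asarray(cluster_ids)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    for lab in labels:
        if len(np.unique(cl[g == lab])) < 2:
            raise ValueError(f"group {lab!r} spans fewer than 2 clusters")
    ind = (g == labels[1]).astype(float)
    diff = float(y[ind == 1].mean() - y[ind == 0].mean())
    if np.ptp(y) == 0:
        return {"diff": diff, "se": np.nan, "t": np.nan, "p": np.nan,
                "degenerate": True, "groups": list(labels)}
    X = sm.add_constant(ind)
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": cl})
    return {
        "diff": diff,
        "se": float(res.bse[1]),
        "t": float(res.tvalues[1]),
        "p": float(res.pvalues[1]),
        "degenerate": False,
        "groups": list(labels),
    }
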