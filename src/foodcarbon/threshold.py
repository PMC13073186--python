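"""Fixed-effects panel threshold regression (Hansen-style).

Model: for household i in wave t,

    y_it = b0 + b_low * q_it * 1{q_it <= gamma} + b_high * q_it * 1{q_it > gamma}
              + Z_it theta + mu_i + lambda_t + eps_it

with household fixed effects mu_i absorbed by within-demeaning, year effects
lambda_t as wave dummies, and the threshold gamma estimated by concentrated
least squares: for each candidate gamma on a trimmed grid of observed values
of the threshold variable, slopes are profiled out by OLS and gamma_hat
minimizes the residual sum of squares S1(gamma).

Inference:

* number of thresholds — sequential sup-F tests, F_m = (S_{m-1} - S_m)/s2,
  with p-values from a fixed-regressor residual bootstrap that resamples
  household residual blocks (or flips signs province-wise) while holding the
  regressors fixed;
* the threshold itself — likelihood-ratio inversion: LR(gamma) =
  (S1(gamma) - S1(gamma_hat))/s2 and the confidence set
  {gamma : LR(gamma) <= -2 ln(1 - sqrt(1-alpha))};
* slopes and controls — cluster-robust (CR1) sandwich standard errors at the
  province level.

The grid search is algebraically exact: only the low-regime column
q * 1{q <= gamma} varies with gamma (the design span is
[q, q*1{q<=gamma}, Z, wave dummies]), so all gamma-invariant columns are
orthogonalized once and each candidate costs one projection.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

__all__ = [
    "ThresholdModel",
    "ThresholdFit",
    "ThresholdNumberTest",
    "WithinDesign",
    "within_transform",
    "concentrated_ssr",
    "estimate_threshold",
    "threshold_number_test",
    "lr_confidence_set",
    "lr_critical_value",
    "cluster_robust_cov",
    "fit_report",
    "format_report",
    "parse_report",
]

DEFAULT_CONTROLS = ("hhsize", "age06", "age65", "age", "edu", "marriage")


@dataclass(frozen=True)
class ThresholdModel:
    """Specification of the threshold regression."""

    dependent: str = "ghg"
    threshold_var: str = "hhinc"
    regime_var: str = "hhinc"
    controls: tuple[str, ...] = DEFAULT_CONTROLS
    household: str = "household_id"
    time: str = "wave"
    cluster: str = "province_id"
    include_age_sq: bool = False

    @property
    def control_names(self) -> tuple[str, ...]:
        if self.include_age_sq and "age_sq" not in self.controls:
            return self.controls + ("age_sq",)
        return self.controls


class WithinDesign:
    """Within-transformed (household-demeaned) design for a panel.

    Holds the demeaned dependent, threshold variable, controls and wave
    dummies; exposes the demeaning operator and an orthonormal basis of the
    gamma-invariant columns for fast concentrated least squares.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        model: ThresholdModel | None = None,
        warn_singletons: bool = True,
    ):
        model = model or ThresholdModel()
        self.model = model
        need = [model.dependent, model.threshold_var, model.regime_var,
                model.household, model.time, *model.control_names]
        missing = [c for c in need if c not in panel.columns]
        if missing:
            raise ValueError(f"panel lacks columns {missing}")
        df = panel.sort_values([model.household, model.time]).reset_index(drop=True)

        sizes = df.groupby(model.household, sort=False)[model.time].size()
        singles = sizes[sizes < 2].index
        if len(singles) > 0:
            if warn_singletons:
                warnings.warn(
                    f"dropping {len(singles)} household(s) observed in a "
                    "single wave (fixed effect absorbs everything)",
                    stacklevel=2,
                )
            df = df[~df[model.household].isin(singles)].reset_index(drop=True)
        if df.empty:
            raise ValueError("no households with >= 2 waves")

        self.frame = df
        self.households, self.codes = np.unique(
            df[model.household].to_numpy(), return_inverse=True
        )
        self.n = len(df)
        self.n_households = len(self.households)
        self.counts = np.bincount(self.codes).astype(float)
        if model.cluster in df.columns:
            self.clusters, self.cluster_codes = np.unique(
                df[model.cluster].to_numpy(), return_inverse=True
            )
        else:
            self.clusters, self.cluster_codes = None, None

        self.y_raw = df[model.dependent].to_numpy(dtype=float)
        self.q = df[model.threshold_var].to_numpy(dtype=float)
        self.r = df[model.regime_var].to_numpy(dtype=float)
        if np.ptp(self.q) == 0:
            raise ValueError("threshold variable has zero variance")

        waves = np.sort(df[model.time].unique())
        self.waves = waves
        wave_cols = [
            (df[model.time].to_numpy() == w).astype(float) for w in waves[1:]
        ]
        ctrl_cols = [df[c].to_numpy(dtype=float) for c in model.control_names]
        self.W_names = list(model.control_names) + [f"wave_{w}" for w in waves[1:]]
        self.W_raw = (
            np.column_stack(ctrl_cols + wave_cols)
            if ctrl_cols or wave_cols
            else np.empty((self.n, 0))
        )

        self.yt = self.demean(self.y_raw)
        self.qt = self.demean(self.q)
        self.rt = self.demean(self.r)
        Wt = self.demean(self.W_raw)
        # a control constant within every household is absorbed by the FE
        norms = np.einsum("ij,ij->j", Wt, Wt)
        keep = norms > 1e-10 * self.n
        if not keep.all():
            dropped = [n for n, k in zip(self.W_names, keep) if not k]
            warnings.warn(
                f"dropping controls with no within-household variation: {dropped}",
                stacklevel=2,
            )
        self.Wt = Wt[:, keep]
        self.W_names = [n for n, k in zip(self.W_names, keep) if k]
        self.W_raw = self.W_raw[:, keep]
        self.tss_within = float(self.yt @ self.yt)
        self._sorted_q = np.sort(self.q)

    # -- operators -----------------------------------------------------------
    def demean(self, v: np.ndarray) -> np.ndarray:
        """Remove household means (columnwise for 2-D input)."""
        v = np.asarray(v, dtype=float)
        if v.ndim == 1:
            m = np.bincount(self.codes, weights=v) / self.counts
            return v - m[self.codes]
        M = np.zeros((self.n_households, v.shape[1]))
        np.add.at(M, self.codes, v)
        M /= self.counts[:, None]
        return v - M[self.codes]

    def regime_columns(self, gamma: float) -> tuple[np.ndarray, np.ndarray]:
        """Raw low/high regime slope columns at ``gamma``."""
        low = self.q <= gamma
        return self.r * low, self.r * ~low

    def basis(self, extra_raw: list[np.ndarray] | None = None) -> np.ndarray:
        """Orthonormal basis of the demeaned gamma-invariant columns
        [controls, wave dummies, regime variable] (+ demeaned extras,
        e.g. previously fixed threshold columns)."""
        cols = [self.Wt, self.rt[:, None]]
        if extra_raw:
            cols.append(self.demean(np.column_stack(extra_raw)))
        A = np.hstack(cols)
        Qm, R, _ = scipy.linalg.qr(A, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        tol = d.max() * max(A.shape) * np.finfo(float).eps if d.size else 0.0
        rank = int((d > tol).sum())
        return Qm[:, :rank]

    # -- grid ----------------------------------------------------------------
    def build_grid(
        self,
        trim: float = 0.01,
        min_share: float = 0.05,
        max_grid: int | None = None,
        min_regime_obs: int | None = None,
    ) -> np.ndarray:
        """Candidate thresholds: unique observed values of the threshold
        variable between the trim quantiles, each leaving at least
        ``max(min_share * n, min_regime_obs)`` observations in both regimes.
        """
        lo, hi = np.quantile(self.q, [trim, 1.0 - trim])
        vals = np.unique(self.q)
        vals = vals[(vals >= lo) & (vals <= hi)]
        # each regime needs more observations than the regression has
        # parameters (two slopes + controls + wave dummies)
        floor = max(int(np.ceil(min_share * self.n)), self.Wt.shape[1] + 3)
        if min_regime_obs is not None:
            floor = max(floor, min_regime_obs)
        n_low = np.searchsorted(self._sorted_q, vals, side="right")
        ok = (n_low >= floor) & (self.n - n_low >= floor)
        vals = vals[ok]
        if max_grid is not None and len(vals) > max_grid:
            idx = np.unique(np.linspace(0, len(vals) - 1, max_grid).astype(int))
            vals = vals[idx]
        return vals

    def n_low(self, gammas: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._sorted_q, np.atleast_1d(gammas), side="right")


def within_transform(panel: pd.DataFrame, model: ThresholdModel | None = None) -> WithinDesign:
    """Household-demeaned design (year effects enter as demeaned wave
    dummies). Demeaning is idempotent and maps within-household constants to
    zero columns."""
    return WithinDesign(panel, model)


# ---------------------------------------------------------------------------
# Concentrated least squares
# ---------------------------------------------------------------------------

def _profile_ssr(
    design: WithinDesign,
    grid: np.ndarray,
    Y: np.ndarray,
    Qb: np.ndarray,
    block: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """SSR(gamma, column of Y) on the within design, profiling slopes out.

    ``Y`` is (n, R) on the demeaned scale; ``Qb`` an orthonormal basis of the
    gamma-invariant columns. Returns (ssr (G, R), base (R,)) where ``base``
    is the SSR of the gamma-free (restricted) model.
    """
    Y = np.atleast_2d(Y.T).T if Y.ndim == 1 else Y
    Yp = Y - Qb @ (Qb.T @ Y)
    base = np.einsum("ij,ij->j", Yp, Yp)
    G, R = len(grid), Y.shape[1]
    ssr = np.empty((G, R))
    for s in range(0, G, block):
        gs = grid[s : s + block]
        X1 = design.r[:, None] * (design.q[:, None] <= gs[None, :])
        X1t = design.demean(X1)
        X1p = X1t - Qb @ (Qb.T @ X1t)
        norms = np.einsum("ij,ij->j", X1p, X1p)
        num = X1p.T @ Yp  # (g, R)
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(norms[:, None] > 1e-12, num**2 / norms[:, None], 0.0)
        ssr[s : s + block] = np.maximum(base[None, :] - gain, 0.0)
    return ssr, base


def concentrated_ssr(
    panel_or_design: pd.DataFrame | WithinDesign,
    model: ThresholdModel | None = None,
    gamma: float = 0.0,
    min_share: float = 0.05,
) -> float:
    """S1(gamma): residual sum of squares of the within regression with the
    slope split at ``gamma``, computed by a direct least-squares solve.

    Returns +inf when either regime holds fewer observations than the
    regime-share floor or than the regressor count (infeasible candidate,
    excluded from any argmin).
    """
    design = (
        panel_or_design
        if isinstance(panel_or_design, WithinDesign)
        else WithinDesign(panel_or_design, model)
    )
    n_low = int(design.n_low(np.array([gamma]))[0])
    k = design.Wt.shape[1] + 2
    floor = max(int(np.ceil(min_share * design.n)), k + 1)
    if n_low < floor or design.n - n_low < floor:
        return np.inf
    x1, x2 = design.regime_columns(gamma)
    X = np.column_stack([design.demean(x1), design.demean(x2), design.Wt])
    resid = design.yt - X @ np.linalg.lstsq(X, design.yt, rcond=None)[0]
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class ThresholdFit:
    """Estimated single-threshold model on the within-transformed panel."""

    gamma_hat: float
    coef: pd.Series
    se: pd.Series
    tstat: pd.Series
    pvalue: pd.Series
    const: float
    ssr: float
    sigma2: float
    adj_r2: float
    n_obs: int
    n_households: int
    n_clusters: int
    dof: int
    lr_curve: pd.DataFrame  # columns: gamma, ssr, lr
    model: ThresholdModel
    alpha: float = 0.05
    #: sorted unique values of the threshold variable; S1 is a step function
    #: constant between adjacent values, so each accepted candidate x_(k)
    #: represents the whole interval [x_(k), x_(k+1))
    support: np.ndarray | None = None

    @property
    def beta_low(self) -> float:
        return float(self.coef["income_low"])

    @property
    def beta_high(self) -> float:
        return float(self.coef["income_high"])

    def confidence_set(self, alpha: float | None = None) -> tuple[float, float]:
        return lr_confidence_set(self, alpha if alpha is not None else self.alpha)

    def to_dict(self) -> dict:
        lo, hi = self.confidence_set()
        return {
            "gamma_hat": self.gamma_hat,
            "gamma_ci": [lo, hi],
            "alpha": self.alpha,
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "tstat": self.tstat.to_dict(),
            "pvalue": self.pvalue.to_dict(),
            "const": self.const,
            "ssr": self.ssr,
            "sigma2": self.sigma2,
            "adj_r2": self.adj_r2,
            "n_obs": self.n_obs,
            "n_households": self.n_households,
            "n_clusters": self.n_clusters,
        }


@dataclass
class ThresholdNumberTest:
    """Sequential bootstrap tests for 1, 2, 3 thresholds."""

    stages: list[dict] = field(default_factory=list)
    n_boot: int = 0
    scheme: str = "household"

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def p_value(self, m: int) -> float:
        for s in self.stages:
            if s["n_thresholds"] == m:
                return s["p_value"]
        raise KeyError(f"no stage for {m} thresholds")

    def to_dict(self) -> dict:
        return {"n_boot": self.n_boot, "scheme": self.scheme, "stages": self.stages}


# ---------------------------------------------------------------------------
# Cluster-robust covariance
# ---------------------------------------------------------------------------

def cluster_robust_cov(
    X: np.ndarray, resid: np.ndarray, cluster_ids: np.ndarray
) -> np.ndarray:
    """CR1 sandwich covariance.

    cov = c * (X'X)^-1 (sum_g X_g' e_g e_g' X_g) (X'X)^-1 with the
    small-sample factor c = G/(G-1) * (N-1)/(N-k). With every observation
    its own cluster this reduces to the HC1-style heteroskedasticity-robust
    estimator times N/(N-1).
    """
    X = np.asarray(X, dtype=float)
    resid = np.asarray(resid, dtype=float)
    ids = np.asarray(cluster_ids)
    _, codes = np.unique(ids, return_inverse=True)
    G = codes.max() + 1
    if G < 2:
        raise ValueError("cluster-robust covariance needs >= 2 clusters")
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    S = np.zeros((G, k))
    np.add.at(S, codes, X * resid[:, None])
    meat = S.T @ S
    c = (G / (G - 1)) * ((n - 1) / (n - k))
    return c * XtX_inv @ meat @ XtX_inv


# ---------------------------------------------------------------------------
# Threshold estimation
# ---------------------------------------------------------------------------

def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR),
    preserving original order."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    return np.sort(piv[:rank])


def lr_critical_value(alpha: float) -> float:
    """Asymptotic LR critical value -2 ln(1 - sqrt(1 - alpha))."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return -2.0 * np.log(1.0 - np.sqrt(1.0 - alpha))


def estimate_threshold(
    panel: pd.DataFrame | WithinDesign,
    model: ThresholdModel | None = None,
    trim: float = 0.01,
    min_share: float = 0.05,
    max_grid: int | None = None,
    alpha: float = 0.05,
    dof_adjust: bool = True,
) -> ThresholdFit:
    """Concentrated grid search for the threshold, then a full refit.

    gamma_hat is the grid argmin of S1 (ties to the smallest candidate); the
    refit at gamma_hat yields slopes/controls with province-cluster-robust
    CR1 standard errors, the within adjusted R^2, and the LR curve over the
    grid for confidence-set inversion. ``dof_adjust`` selects
    s2 = S1/(N - n_households - k) (default) versus s2 = S1/N.
    """
    design = panel if isinstance(panel, WithinDesign) else WithinDesign(panel, model)
    grid = design.build_grid(trim=trim, min_share=min_share, max_grid=max_grid)
    if len(grid) == 0:
        raise RuntimeError("no feasible threshold candidate after trimming")
    Qb = design.basis()
    ssr, _ = _profile_ssr(design, grid, design.yt[:, None], Qb)
    ssr = ssr[:, 0]
    idx = int(np.argmin(ssr))  # first minimum = smallest gamma on ties
    gamma_hat = float(grid[idx])
    S1 = float(ssr[idx])

    # full refit at gamma_hat
    x1, x2 = design.regime_columns(gamma_hat)
    X = np.column_stack([design.demean(x1), design.demean(x2), design.Wt])
    names = ["income_low", "income_high", *design.W_names]
    keep = _independent_columns(X)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear regressors: {dropped}", stacklevel=2)
        X = X[:, keep]
        names = [names[j] for j in keep]
        x_raw_cols = np.column_stack([x1, x2, design.W_raw])[:, keep]
    else:
        x_raw_cols = np.column_stack([x1, x2, design.W_raw])
    beta, *_ = np.linalg.lstsq(X, design.yt, rcond=None)
    resid = design.yt - X @ beta
    k = X.shape[1]
    dof = design.n - design.n_households - k
    if dof <= 0:
        raise RuntimeError("non-positive residual degrees of freedom")
    sigma2 = S1 / dof if dof_adjust else S1 / design.n
    if design.cluster_codes is None:
        raise ValueError(f"panel lacks cluster column {design.model.cluster!r}")
    cov = cluster_robust_cov(X, resid, design.cluster_codes)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    G = len(design.clusters)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=G - 1)
    adj_r2 = 1.0 - (S1 / dof) / (design.tss_within / (design.n - design.n_households))
    const = float(design.y_raw.mean() - x_raw_cols.mean(axis=0) @ beta)
    lr = (ssr - S1) / sigma2 if sigma2 > 0 else np.where(ssr > S1, np.inf, 0.0)
    curve = pd.DataFrame({"gamma": grid, "ssr": ssr, "lr": lr})
    return ThresholdFit(
        gamma_hat=gamma_hat,
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        tstat=pd.Series(tstat, index=names),
        pvalue=pd.Series(pval, index=names),
        const=const,
        ssr=S1,
        sigma2=sigma2,
        adj_r2=float(adj_r2),
        n_obs=design.n,
        n_households=design.n_households,
        n_clusters=G,
        dof=dof,
        lr_curve=curve,
        model=design.model,
        alpha=alpha,
        support=np.unique(design.q),
    )


def lr_confidence_set(fit: ThresholdFit, alpha: float = 0.05) -> tuple[float, float]:
    """Interval hull of {gamma : LR(gamma) <= -2 ln(1 - sqrt(1-alpha))}.

    Never empty: LR(gamma_hat) = 0 by construction. Because S1 is a step
    function constant between adjacent observed values of the threshold
    variable, an accepted candidate x_(k) stands for every gamma in
    [x_(k), x_(k+1)); the upper endpoint is therefore extended to the next
    observed support value above the largest accepted candidate.
    """
    c = lr_critical_value(alpha)
    inside = fit.lr_curve.loc[fit.lr_curve["lr"] <= c, "gamma"]
    lo, hi = float(inside.min()), float(inside.max())
    if fit.support is not None:
        above = fit.support[fit.support > hi]
        if above.size:
            hi = float(above.min())
    return lo, hi


# ---------------------------------------------------------------------------
# Number-of-thresholds bootstrap test
# ---------------------------------------------------------------------------

def _resample_residual_blocks(
    design: WithinDesign,
    resid: np.ndarray,
    rng: np.random.Generator,
    n_boot: int,
    scheme: str,
) -> np.ndarray:
    """(n, n_boot) matrix of bootstrap dependents on the demeaned scale,
    holding regressors fixed.

    household: resample whole household residual blocks with replacement
    (balanced panel required — blocks must align with the fixed T-row slots).
    province: cluster wild bootstrap (Rademacher sign flip per province),
    which respects arbitrary within-province correlation.
    """
    if scheme == "household":
        if np.ptp(design.counts) != 0:
            raise ValueError(
                "household-block residual bootstrap requires a balanced panel; "
                "use scheme='province'"
            )
        T = int(design.counts[0])
        E = resid.reshape(design.n_households, T)
        idx = rng.integers(0, design.n_households, (n_boot, design.n_households))
        return E[idx].reshape(n_boot, design.n).T
    elif scheme == "province":
        if design.cluster_codes is None:
            raise ValueError("panel lacks a cluster column")
        Gc = design.cluster_codes.max() + 1
        signs = rng.choice([-1.0, 1.0], size=(n_boot, Gc))
        return resid[:, None] * signs[:, design.cluster_codes].T
    raise ValueError("scheme must be 'household' or 'province'")


def threshold_number_test(
    panel: pd.DataFrame | WithinDesign,
    model: ThresholdModel | None = None,
    n_boot: int = 200,
    max_thresholds: int = 3,
    seed: int | np.random.Generator = 0,
    scheme: str = "household",
    trim: float = 0.01,
    min_share: float = 0.05,
    max_grid: int | None = None,
    dof_adjust: bool = True,
    refine: bool = True,
) -> ThresholdNumberTest:
    """Sequential bootstrap tests for the number of thresholds (up to 3).

    Stage m tests (m-1) vs m thresholds: F_m = (S_{m-1} - S_m)/s2_m with
    s2_m = S_m/dof, S_{m-1} the null-model SSR holding the previously found
    thresholds fixed, and S_m minimized over the feasible grid for the new
    threshold. The bootstrap resamples the null model's residual blocks,
    keeping all regressors fixed; p = fraction of bootstrap F >= observed F.
    A perfectly fitting alternative (S_m = 0) is treated as maximal evidence
    (F = +inf, p = 0 unless bootstrap F is also infinite).

    After each accepted stage the previously found thresholds are refined one
    pass (each re-searched holding the others fixed) before conditioning the
    next stage, while the stage's F statistic itself holds prior thresholds
    at their conditioning values.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} gives coarse p-value resolution (1/{n_boot})",
            stacklevel=2,
        )
    design = panel if isinstance(panel, WithinDesign) else WithinDesign(panel, model)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    base_grid = design.build_grid(trim=trim, min_share=min_share, max_grid=max_grid)
    if len(base_grid) == 0:
        raise RuntimeError("no feasible threshold candidate after trimming")
    floor = int(np.ceil(min_share * design.n))
    n_low_grid = design.n_low(base_grid)

    def feasible(prior: list[float]) -> np.ndarray:
        """Candidates keeping every regime's share >= min_share given the
        already-fixed thresholds."""
        if not prior:
            return base_grid
        P = np.sort(design.n_low(np.asarray(prior)))
        cand = n_low_grid[:, None]
        allc = np.sort(
            np.concatenate([np.broadcast_to(P, (len(base_grid), len(P))), cand], axis=1),
            axis=1,
        )
        edges = np.concatenate(
            [
                np.zeros((len(base_grid), 1), dtype=int),
                allc,
                np.full((len(base_grid), 1), design.n, dtype=int),
            ],
            axis=1,
        )
        ok = (np.diff(edges, axis=1) >= floor).all(axis=1)
        ok &= ~np.isin(base_grid, prior)
        return base_grid[ok]

    def search(prior: list[float], Y: np.ndarray, Qb: np.ndarray, cand: np.ndarray):
        ssr, base = _profile_ssr(design, cand, Y, Qb)
        return ssr, base

    out = ThresholdNumberTest(n_boot=n_boot, scheme=scheme)
    gammas: list[float] = []
    for m in range(1, max_thresholds + 1):
        extra = [design.regime_columns(g)[0] for g in gammas] or None
        Qb = design.basis(extra_raw=extra)
        cand = feasible(gammas)
        if len(cand) == 0:
            warnings.warn(f"no feasible candidate for threshold {m}; stopping",
                          stacklevel=2)
            break
        resid_null = design.yt - Qb @ (Qb.T @ design.yt)
        Ystar = _resample_residual_blocks(design, resid_null, rng, n_boot, scheme)
        Ystar = design.demean(Ystar)
        # observed data and all bootstrap draws share the candidate design,
        # so one profiled pass covers every column
        Yall = np.column_stack([design.yt, Ystar])
        ssr_all, base_all = search(gammas, Yall, Qb, cand)
        ssr_obs, base_obs = ssr_all[:, 0], base_all[0]
        idx = int(np.argmin(ssr_obs))
        gam_m, S_m = float(cand[idx]), float(ssr_obs[idx])
        S_prev = float(base_obs)
        k_m = Qb.shape[1] + 1
        dof_m = design.n - design.n_households - k_m
        sigma2 = S_m / dof_m if dof_adjust else S_m / design.n
        F = (S_prev - S_m) / sigma2 if sigma2 > 0 else (
            np.inf if S_prev > S_m else 0.0
        )

        ssr_b, base_b = ssr_all[:, 1:], base_all[1:]
        S_m_b = ssr_b.min(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2_b = S_m_b / dof_m if dof_adjust else S_m_b / design.n
            Fb = np.where(sigma2_b > 0, (base_b - S_m_b) / sigma2_b,
                          np.where(base_b > S_m_b, np.inf, 0.0))
        p = float(np.mean(Fb >= F))
        out.stages.append(
            {
                "n_thresholds": m,
                "gamma": gam_m,
                "gammas": sorted(gammas + [gam_m]),
                "F": float(F),
                "p_value": p,
                "ssr_null": S_prev,
                "ssr_alt": S_m,
                "n_boot": n_boot,
            }
        )
        gammas.append(gam_m)
        if refine and len(gammas) > 1:
            for j in range(len(gammas)):
                others = [g for i, g in enumerate(gammas) if i != j]
                Qj = design.basis(
                    extra_raw=[design.regime_columns(g)[0] for g in others] or None
                )
                cj = feasible(others)
                if len(cj) == 0:
                    continue
                sj, _ = search(others, design.yt[:, None], Qj, cj)
                gammas[j] = float(cj[int(np.argmin(sj[:, 0]))])
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def fit_report(fit: ThresholdFit, test: ThresholdNumberTest | None = None) -> pd.DataFrame:
    """Tidy results table (variable, coefficient, t, p, stars) plus the
    summary rows (N, adjusted R^2, threshold and its LR confidence interval,
    and the single-threshold bootstrap p-value when a test is supplied).
    Serializes losslessly to CSV (see :func:`parse_report`)."""
    rows = []
    for name in fit.coef.index:
        rows.append(
            {
                "variable": name,
                "coefficient": fit.coef[name],
                "t_stat": fit.tstat[name],
                "p_value": fit.pvalue[name],
                "stars": _stars(fit.pvalue[name]),
            }
        )
    rows.append({"variable": "_cons", "coefficient": fit.const,
                 "t_stat": np.nan, "p_value": np.nan, "stars": ""})
    lo, hi = fit.confidence_set()
    summary = {
        "N": fit.n_obs,
        "adj_R2": fit.adj_r2,
        "threshold": fit.gamma_hat,
        "threshold_ci_low": lo,
        "threshold_ci_high": hi,
    }
    if test is not None and test.stages:
        summary["p_single_threshold"] = test.p_value(1)
    for kname, v in summary.items():
        rows.append({"variable": kname, "coefficient": v, "t_stat": np.nan,
                     "p_value": np.nan, "stars": ""})
    return pd.DataFrame(rows)


def format_report(fit: ThresholdFit, test: ThresholdNumberTest | None = None) -> str:
    """Human-readable coefficient table with t-statistics in parentheses and
    significance stars at the 0.10/0.05/0.01 levels."""
    buf = io.StringIO()
    print("Panel threshold regression (household & year FE, "
          f"cluster-robust SEs over {fit.n_clusters} provinces)", file=buf)
    lo, hi = fit.confidence_set()
    print(f"threshold gamma = {fit.gamma_hat:.4f}  "
          f"{100 * (1 - fit.alpha):.0f}% CI [{lo:.4f}, {hi:.4f}]", file=buf)
    if test is not None and test.stages:
        for s in test.stages:
            print(
                f"  {s['n_thresholds']} threshold(s): F = {s['F']:.2f}, "
                f"bootstrap p = {s['p_value']:.3f} ({s['n_boot']} reps)",
                file=buf,
            )
    print(f"{'variable':<14}{'coef':>12}  t-stat", file=buf)
    for name in fit.coef.index:
        stars = _stars(fit.pvalue[name])
        print(
            f"{name:<14}{fit.coef[name]:>12.4f}{stars:<4}"
            f"({fit.tstat[name]:.2f})",
            file=buf,
        )
    print(f"{'_cons':<14}{fit.const:>12.4f}", file=buf)
    print(f"N = {fit.n_obs}   adj. R2 = {fit.adj_r2:.3f}", file=buf)
    print("* p<0.10, ** p<0.05, *** p<0.01", file=buf)
    return buf.getvalue()


def parse_report(csv_text: str) -> pd.DataFrame:
    """Read back a CSV serialization of :func:`fit_report`."""
    return pd.read_csv(io.StringIO(csv_text))
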