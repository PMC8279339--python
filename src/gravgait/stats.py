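"""Repeated-measures statistics: per-variable linear mixed models and
Benjamini-Hochberg control over the gravity-effect family.

The model for each dependent variable is a participant-random-intercept
LMM with categorical gravity-level and speed fixed effects (optionally
their interaction), fitted by restricted maximum likelihood.  Because the
only random effect is the intercept, the REML criterion is profiled down
to a one-dimensional optimization over the variance ratio
``theta = var(participant) / var(residual)``; the gravity main effect is
then tested with a GLS Wald F statistic using containment denominator
degrees of freedom.  "Repeated factors" are thus modelled as compound
symmetry within participant, the minimal faithful covariance structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import f as f_dist

from gravgait.errors import DegenerateFitError, InvalidParameterError


@dataclass
class LmmSpec:
    """Model specification for one dependent variable."""

    response: str
    gravity_col: str = "gravity_level"
    speed_col: str = "target_speed"
    participant_col: str = "participant_id"
    interaction: bool = False
    speed_continuous: bool = False
    ddf_method: str = "containment"    # "containment" | "residual"
    theta_fixed: float | None = None   # fix var ratio (0 -> OLS/GLS check)


@dataclass
class LmmResult:
    pvalue: float
    fvalue: float
    df_num: int
    df_den: int
    sigma2_resid: float
    sigma2_participant: float
    theta: float
    coefficients: dict[str, float]
    n_obs: int


def _design(df: pd.DataFrame, spec: LmmSpec
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[int]]:
    y = df[spec.response].to_numpy(float)
    ok = np.isfinite(y)
    df = df.loc[ok]
    y = y[ok]
    g_levels = sorted(df[spec.gravity_col].unique())
    if len(g_levels) < 2:
        raise DegenerateFitError("need >= 2 gravity levels with data")
    cols = [np.ones(len(df))]
    names = ["intercept"]
    g_idx = []
    g_dummies = {}
    for lev in g_levels[1:]:
        d = (df[spec.gravity_col] == lev).to_numpy(float)
        g_dummies[lev] = d
        g_idx.append(len(cols))
        cols.append(d)
        names.append(f"gravity[{lev}]")
    if spec.speed_continuous:
        s_dummies = {"lin": df[spec.speed_col].to_numpy(float)}
        cols.append(s_dummies["lin"])
        names.append("speed")
    else:
        s_levels = sorted(df[spec.speed_col].unique())
        s_dummies = {}
        for lev in s_levels[1:]:
            d = (df[spec.speed_col] == lev).to_numpy(float)
            s_dummies[lev] = d
            cols.append(d)
            names.append(f"speed[{lev}]")
    if spec.interaction:
        for glev, gd in g_dummies.items():
            for slev, sd in s_dummies.items():
                cols.append(gd * sd)
                names.append(f"gravity[{glev}]:speed[{slev}]")
    X = np.column_stack(cols)
    groups, _ = pd.factorize(df[spec.participant_col])
    return y, X, groups, names, g_idx


def _gls_pieces(y, X, groups, theta):
    """Sufficient statistics for GLS with V = I + theta * ZZ' (block
    compound symmetry): X'V^-1X, X'V^-1y, y'V^-1y, log|V|."""
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    logdet = 0.0
    if theta > 0:
        for gval in np.unique(groups):
            idx = groups == gval
            ni = int(idx.sum())
            w = theta / (1.0 + ni * theta)
            sx = X[idx].sum(axis=0)
            sy = float(y[idx].sum())
            XtX -= w * np.outer(sx, sx)
            Xty -= w * sx * sy
            yty -= w * sy * sy
            logdet += np.log1p(ni * theta)
    return XtX, Xty, yty, logdet


def _profile_reml(theta, y, X, groups):
    n, p = X.shape
    XtX, Xty, yty, logdet = _gls_pieces(y, X, groups, theta)
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(f"singular design: {exc}") from exc
    quad = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
    quad = max(quad, 0.0)
    sigma2 = quad / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise DegenerateFitError("singular design matrix")
    if sigma2 <= 0:
        return np.inf, beta, sigma2, XtX
    crit = logdet + logdet_xvx + (n - p) * np.log(sigma2)
    return crit, beta, sigma2, XtX


def fit_lmm(df: pd.DataFrame, spec: LmmSpec) -> LmmResult:
    """Fit the random-intercept LMM by profiled REML and test the gravity
    main effect.

    A gravity level with no observations is dropped with a warning; zero
    residual variance raises :class:`DegenerateFitError`.
    """
    expected = set(df[spec.gravity_col].unique())
    present = set(df.loc[np.isfinite(df[spec.response].to_numpy(float)),
                         spec.gravity_col].unique())
    if present < expected:
        warnings.warn(
            f"{spec.response}: gravity level(s) {sorted(expected - present)} "
            f"have no data; fitting on the remaining levels",
            stacklevel=2)
    y, X, groups, names, g_idx = _design(df, spec)
    n, p = X.shape
    n_groups = len(np.unique(groups))

    if spec.theta_fixed is not None:
        theta = float(spec.theta_fixed)
    else:
        res = optimize.minimize_scalar(
            lambda t: _profile_reml(np.exp(t), y, X, groups)[0],
            bounds=(-15.0, 15.0), method="bounded",
            options={"xatol": 1e-8})
        theta = float(np.exp(res.x))
        # boundary check: no participant variance
        if _profile_reml(0.0, y, X, groups)[0] <= res.fun:
            theta = 0.0
    _, beta, sigma2, XtViX = _profile_reml(theta, y, X, groups)
    scale = float(np.mean(y ** 2)) + 1e-300
    if sigma2 <= 1e-12 * scale:
        raise DegenerateFitError("zero residual variance: degenerate fit")

    cov = sigma2 * np.linalg.inv(XtViX)
    bL = beta[g_idx]
    covL = cov[np.ix_(g_idx, g_idx)]
    q = len(g_idx)
    fval = float(bL @ np.linalg.solve(covL, bL)) / q
    if spec.ddf_method == "containment":
        ddf = n - p - (n_groups - 1)
    elif spec.ddf_method == "residual":
        ddf = n - p
    else:
        raise InvalidParameterError(f"unknown ddf method {spec.ddf_method!r}")
    if ddf < 1:
        raise DegenerateFitError("no residual degrees of freedom")
    pval = float(f_dist.sf(fval, q, ddf))
    return LmmResult(
        pvalue=pval, fvalue=fval, df_num=q, df_den=int(ddf),
        sigma2_resid=float(sigma2),
        sigma2_participant=float(theta * sigma2), theta=float(theta),
        coefficients=dict(zip(names, beta.tolist())), n_obs=int(n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p'_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidParameterError("p_values must be a nonempty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


#: The dependent-variable inventory of the gravity-effect family
#: (group, label, feature-table column); 26 tests in total.
TABLE2_INVENTORY: list[tuple[str, str, str]] = [
    ("Force", "Maximum vertical", "peak_vertical_grf"),
    ("Force", "Maximum braking", "peak_braking"),
    ("Force", "Maximum accelerating", "peak_accelerating"),
    ("Force", "Maximum absolute medial-lateral", "peak_abs_ml"),
    ("Moment", "Hip flexion", "peak_hip_flexion_moment"),
    ("Moment", "Knee extension (early-mid stance)", "peak_knee_ext_moment_early"),
    ("Moment", "Knee extension (transition)", "peak_knee_ext_moment_transition"),
    ("Moment", "Ankle plantarflexion", "peak_ankle_pf_moment"),
    ("Power", "Hip generation", "peak_hip_power_gen"),
    ("Power", "Knee generation (early-mid stance)", "peak_knee_power_gen_early"),
    ("Power", "Knee absorption (transition)", "peak_knee_power_abs_transition"),
    ("Power", "Ankle generation", "peak_ankle_power_gen"),
    ("Stance phase RMS EMG", "Rectus femoris", "stance_rms_rectus_femoris"),
    ("Stance phase RMS EMG", "Vastus lateralis", "stance_rms_vastus_lateralis"),
    ("Stance phase RMS EMG", "Vastus medialis", "stance_rms_vastus_medialis"),
    ("Stance phase RMS EMG", "Biceps femoris", "stance_rms_biceps_femoris"),
    ("Stance phase RMS EMG", "Lateral gastrocnemius",
     "stance_rms_lateral_gastrocnemius"),
    ("Stance phase RMS EMG", "Medial gastrocnemius",
     "stance_rms_medial_gastrocnemius"),
    ("Stance phase RMS EMG", "Soleus", "stance_rms_soleus"),
    ("Stance phase RMS EMG", "Tibialis anterior", "stance_rms_tibialis_anterior"),
    ("Swing phase RMS EMG", "Rectus femoris", "swing_rms_rectus_femoris"),
    ("Swing phase RMS EMG", "Vastus lateralis", "swing_rms_vastus_lateralis"),
    ("Swing phase RMS EMG", "Vastus medialis", "swing_rms_vastus_medialis"),
    ("Swing phase RMS EMG", "Biceps femoris", "swing_rms_biceps_femoris"),
    ("Swing phase RMS EMG", "Tibialis anterior", "swing_rms_tibialis_anterior"),
    ("Spatial", "Right stride length", "stride_length_norm"),
]


@dataclass
class StatsReport:
    """Per-variable gravity-effect tests with BH adjustment."""

    table: pd.DataFrame = field(repr=False)
    family_size: int = 0
    missing: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def to_jsonable(self) -> dict:
        return {
            "alpha": self.alpha,
            "family_size": self.family_size,
            "missing": self.missing,
            "rows": self.table.to_dict(orient="records"),
        }


def run_table2(features: pd.DataFrame, alpha: float = 0.05,
               interaction: bool = False) -> StatsReport:
    """One LMM per inventory variable; BH across the full gravity-effect
    family; significance flagged at adjusted p < ``alpha``.

    Variables absent from ``features`` are reported as missing (with a
    warning) and the adjustment runs over the present family.
    """
    rows = []
    missing = []
    for group, label, col in TABLE2_INVENTORY:
        if col not in features.columns:
            missing.append(col)
            continue
        res = fit_lmm(features, LmmSpec(response=col, interaction=interaction))
        rows.append({"group": group, "variable": label, "column": col,
                     "p_raw": res.pvalue, "fvalue": res.fvalue,
                     "df_num": res.df_num, "df_den": res.df_den})
    if missing:
        warnings.warn(
            f"missing feature column(s): {', '.join(missing)}; adjusting "
            f"over the {len(rows)} present tests", stacklevel=2)
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    return StatsReport(table=table, family_size=len(table), missing=missing,
                       alpha=alpha)
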