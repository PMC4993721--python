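"""Stress-response kinetics: wilting onset, asymptotic regression, phase clustering.

The central model is the three-parameter asymptotic (monomolecular) law

    Y = theta1 - theta2 * exp(-theta3 * X) + eps

with ``Y`` leaf temperature (°C), ``X`` time since wilting onset (h),
``theta1`` the equilibrium temperature the leaf relaxes towards, ``theta2``
the total amplitude of the rise and ``theta3`` the first-order rate (1/h).
A leaf that has lost evaporative cooling equilibrates with ambient air
following this law; a leaf that still regulates its stomata shows a rate so
small that the curve is indistinguishable from a straight line over the
observation window.

Fitting uses iterative nonlinear least squares.  Because the near-linear
regime is badly conditioned (theta1 and theta2 are individually enormous
while their difference is tame), the fit augments a damped least-squares
polish with a variable-projection profile over theta3: for fixed theta3 the
model is linear in (theta1, theta2), so the profiled residual sum of squares
is a smooth 1-D function that can be bracketed and minimised reliably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientDataError, ValidationError

N_PARAMS = 3

#: Default comparison window (h) for asymptotic-vs-linear classification.
DEFAULT_HORIZON_H = 8.0

#: theta3 * horizon below this -> curve indistinguishable from linear.
NEAR_LINEAR_PRODUCT = 0.5

#: Jacobian condition number above which the fit is flagged ill-conditioned.
ILL_CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class AsymptoticParams:
    """Parameters of the asymptotic law ``theta1 - theta2*exp(-theta3*x)``."""

    theta1: float
    theta2: float
    theta3: float
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.theta3 <= 0:
            raise ValidationError(f"theta3 must be positive, got {self.theta3}")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], dtype=float)


def evaluate_asymptotic(params: AsymptoticParams | Sequence[float],
                        x_hours: np.ndarray | float) -> np.ndarray | float:
    """Model value theta1 - theta2*exp(-theta3*x) at time(s) ``x_hours``."""
    if isinstance(params, AsymptoticParams):
        t1, t2, t3 = params.theta1, params.theta2, params.theta3
    else:
        t1, t2, t3 = params
    return t1 - t2 * np.exp(-t3 * np.asarray(x_hours, dtype=float))


def _default_start(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Start rule: theta1=max(y), theta2=range(y), theta3=1/range(x)."""
    span = x.max() - x.min()
    theta3 = 1.0 / span if span > 0 else 1.0
    return np.array([y.max(), y.max() - y.min(), theta3])


def _profile_linear(theta3: float, x: np.ndarray, y: np.ndarray):
    """For fixed theta3 solve the linear subproblem in (theta1, theta2)."""
    basis = np.column_stack([np.ones_like(x), -np.exp(-theta3 * x)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = y - basis @ coef
    return float(resid @ resid), coef


class AsymptoticStressModel:
    """Asymptotic stress-kinetics model for a leaf-temperature trajectory.

    Parameters
    ----------
    x_hours
        Times in hours since wilting onset; non-negative, strictly increasing.
    temps
        Leaf temperatures, °C.

    Examples
    --------
    >>> x = np.arange(0, 8.5, 0.5)
    >>> y = 31.83 - 4.0 * np.exp(-0.523 * x)
    >>> res = AsymptoticStressModel(x, y).fit()
    >>> round(res.predicted_equilibrium, 1)
    31.8
    """

    def __init__(self, x_hours, temps):
        x = np.asarray(x_hours, dtype=float)
        y = np.asarray(temps, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValidationError("x_hours and temps must be 1-D arrays of equal length")
        if x.size < N_PARAMS:
            raise ValidationError(
                f"need at least {N_PARAMS} points to identify {N_PARAMS} parameters"
            )
        if x.size < 5:
            raise InsufficientDataError(
                f"need >= 5 points for a meaningful fit, got {x.size}"
            )
        if np.any(x < 0):
            raise ValidationError("times must be non-negative (hours since onset)")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValidationError("non-finite values in input")
        self.x = x
        self.y = y

    # -- constructors --------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time_h",
                       temp_col: str = "leaf_temp") -> "AsymptoticStressModel":
        d = df[[time_col, temp_col]].dropna().sort_values(time_col)
        return cls(d[time_col].to_numpy(), d[temp_col].to_numpy())

    @classmethod
    def from_time_series(cls, series: pd.DataFrame, onset_min: float,
                         horizon_h: float = DEFAULT_HORIZON_H,
                         resample_min: float = 30.0) -> "AsymptoticStressModel":
        """Build from a plant time series (``time_min``/``leaf_temp`` columns).

        Times are re-anchored to hours since ``onset_min``, restricted to
        ``[0, horizon_h]`` and block-averaged into ``resample_min`` bins
        (30-min means by default).
        """
        d = series[["time_min", "leaf_temp"]].dropna().copy()
        d["time_h"] = (d["time_min"] - onset_min) / 60.0
        d = d[(d["time_h"] >= 0) & (d["time_h"] <= horizon_h)]
        if resample_min and resample_min > 0:
            step_h = resample_min / 60.0
            d["bin"] = np.floor(d["time_h"] / step_h).astype(int)
            d = d.groupby("bin", as_index=False).agg(
                time_h=("time_h", "mean"), leaf_temp=("leaf_temp", "mean"))
        if len(d) < 5:
            raise InsufficientDataError(
                f"only {len(d)} post-onset observations within {horizon_h} h"
            )
        return cls(d["time_h"].to_numpy(), d["leaf_temp"].to_numpy())

    # -- fitting -------------------------------------------------------

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return evaluate_asymptotic(theta, self.x) - self.y

    def _jacobian(self, theta: np.ndarray) -> np.ndarray:
        _, t2, t3 = theta
        e = np.exp(-t3 * self.x)
        return np.column_stack([np.ones_like(self.x), -e, t2 * self.x * e])

    def fit(self, start: AsymptoticParams | Sequence[float] | None = None,
            max_iter: int = 500, rss_tol: float = 1e-10,
            grad_tol: float = 1e-8) -> "AsymptoticStressResults":
        """Iterative least squares with a variable-projection safeguard.

        Runs a damped least-squares polish from ``start`` (default start rule
        if omitted), profiles theta3 over a log grid with the linear
        subproblem solved exactly, and keeps whichever candidate attains the
        lower residual sum of squares.
        """
        x, y = self.x, self.y
        theta0 = (start.as_array() if isinstance(start, AsymptoticParams)
                  else np.asarray(start, dtype=float) if start is not None
                  else _default_start(x, y))

        n_iter = 0

        def polish(t0: np.ndarray):
            nonlocal n_iter
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.least_squares(
                    self._residuals, t0, jac=self._jacobian,
                    method="trf", bounds=([-np.inf, -np.inf, 1e-12], np.inf),
                    xtol=1e-14, ftol=rss_tol * 1e-2, gtol=grad_tol * 1e-4,
                    max_nfev=max_iter * 4,
                )
            n_iter += sol.nfev
            return sol

        candidates = [polish(theta0)]

        # Variable projection: profile RSS over theta3 (model linear given theta3).
        span = max(x.max() - x.min(), 1e-9)
        grid = np.geomspace(1e-4 / span * 8, 50.0 / span, 120)
        rss_grid = np.array([_profile_linear(t3, x, y)[0] for t3 in grid])
        k = int(np.argmin(rss_grid))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        bracket = optimize.minimize_scalar(
            lambda lt3: _profile_linear(np.exp(lt3), x, y)[0],
            bounds=(np.log(lo), np.log(hi)), method="bounded",
            options={"xatol": 1e-14},
        )
        t3_star = float(np.exp(bracket.x))
        _, coef = _profile_linear(t3_star, x, y)
        candidates.append(polish(np.array([coef[0], coef[1], t3_star])))

        best = min(candidates, key=lambda s: float(s.fun @ s.fun))
        theta = best.x
        resid = -best.fun  # observed minus fitted
        rss = float(best.fun @ best.fun)
        jac = self._jacobian(theta)
        grad_norm = float(np.linalg.norm(jac.T @ best.fun))
        converged = bool(best.status > 0)

        dof = max(x.size - N_PARAMS, 1)
        sigma2 = rss / dof
        jtj = jac.T @ jac
        cond = float(np.linalg.cond(jac))
        try:
            cov = np.linalg.inv(jtj) * sigma2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * sigma2
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))

        params = AsymptoticParams(
            theta1=float(theta[0]), theta2=float(theta[1]), theta3=float(theta[2]),
            residual_sd=float(np.sqrt(sigma2)),
        )
        return AsymptoticStressResults(
            model=self, params=params, bse=bse, cov_params=cov, rss=rss,
            converged=converged, n_iter=n_iter, grad_norm=grad_norm,
            resid=resid, ill_conditioned=cond > ILL_CONDITION_LIMIT,
            condition_number=cond,
        )


@dataclass
class AsymptoticStressResults:
    """Fit results: estimates, uncertainties and residual diagnostics."""

    model: AsymptoticStressModel
    params: AsymptoticParams
    bse: np.ndarray
    cov_params: np.ndarray
    rss: float
    converged: bool
    n_iter: int
    grad_norm: float
    resid: np.ndarray
    ill_conditioned: bool
    condition_number: float
    _diagnostics: dict | None = field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return self.params.as_array()

    @property
    def predicted_equilibrium(self) -> float:
        """Equilibrium temperature the model relaxes to (= theta1), °C."""
        return self.params.theta1

    @property
    def nobs(self) -> int:
        return self.model.x.size

    def predict(self, x_hours) -> np.ndarray:
        return evaluate_asymptotic(self.params, x_hours)

    @property
    def shape_class(self) -> str:
        return classify_response_shape(self)

    def residual_diagnostics(self) -> dict:
        """Normality (Shapiro-Wilk) and independence (Durbin-Watson) checks.

        Degenerate (numerically zero) residuals pass trivially.
        """
        if self._diagnostics is not None:
            return self._diagnostics
        r = self.resid
        if np.std(r) < 1e-9:
            diag = {"normality_p": float("nan"), "normality_pass": True,
                    "durbin_watson": float("nan"), "independence_pass": True,
                    "degenerate": True}
        else:
            shapiro_p = float(stats.shapiro(r).pvalue)
            num = float(np.sum(np.diff(r) ** 2))
            dw = num / float(r @ r)
            diag = {"normality_p": shapiro_p, "normality_pass": shapiro_p > 0.05,
                    "durbin_watson": dw,
                    "independence_pass": 1.0 < dw < 3.0,
                    "degenerate": False}
        self._diagnostics = diag
        return diag

    def summary(self) -> str:
        d = self.residual_diagnostics()
        lines = [
            "Asymptotic stress-kinetics fit",
            "  model: Y = theta1 - theta2*exp(-theta3*X)",
            f"  n obs: {self.nobs}   converged: {self.converged}   "
            f"iterations (fn evals): {self.n_iter}",
            f"  RSS: {self.rss:.6g} °C²   residual sd: {self.params.residual_sd:.4g} °C",
            "",
            "  param      estimate      std err",
            f"  theta1   {self.params.theta1:10.4f}   {self.bse[0]:10.4g}   (°C, asymptote)",
            f"  theta2   {self.params.theta2:10.4f}   {self.bse[1]:10.4g}   (°C, amplitude)",
            f"  theta3   {self.params.theta3:10.5f}  {self.bse[2]:10.4g}   (1/h, rate)",
            "",
            f"  predicted equilibrium: {self.predicted_equilibrium:.2f} °C",
            f"  shape class ({DEFAULT_HORIZON_H:g} h horizon): {self.shape_class}",
            f"  residuals: normality pass={d['normality_pass']}, "
            f"independence pass={d['independence_pass']}",
        ]
        if self.ill_conditioned:
            lines.append(
                f"  WARNING: ill-conditioned fit (cond(J) = {self.condition_number:.2g}); "
                "the response is near-linear and theta1/theta2 are weakly identified"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = self.residual_diagnostics()
        return {
            "theta1": self.params.theta1, "theta2": self.params.theta2,
            "theta3": self.params.theta3,
            "bse": [float(v) for v in self.bse],
            "residual_sd": self.params.residual_sd,
            "rss": self.rss, "converged": self.converged, "n_iter": self.n_iter,
            "predicted_equilibrium": self.predicted_equilibrium,
            "shape_class": self.shape_class,
            "ill_conditioned": self.ill_conditioned,
            "diagnostics": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                            for k, v in d.items()},
        }

    def plot(self, ax=None):
        """Observed points and fitted curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x, self.model.y, "o", label="observed")
        xs = np.linspace(self.model.x.min(), self.model.x.max(), 200)
        ax.plot(xs, self.predict(xs), "-", label="fitted")
        ax.set_xlabel("time since wilting onset (h)")
        ax.set_ylabel("leaf temperature (°C)")
        ax.legend()
        return ax


def fit_asymptotic(x_hours, temps, start=None, **kwargs) -> AsymptoticStressResults:
    """Convenience wrapper: build the model and fit in one call."""
    return AsymptoticStressModel(x_hours, temps).fit(start=start, **kwargs)


def classify_response_shape(fit: AsymptoticStressResults | AsymptoticParams,
                            horizon_h: float = DEFAULT_HORIZON_H) -> str:
    """``near_linear`` when theta3*horizon < 0.5, else ``asymptotic``.

    Over an observation window short relative to the relaxation time the
    exponential is indistinguishable from a straight line; the boundary is
    exclusive (product exactly 0.5 classifies as asymptotic).
    """
    theta3 = fit.theta3 if isinstance(fit, AsymptoticParams) else fit.params.theta3
    return "near_linear" if theta3 * horizon_h < NEAR_LINEAR_PRODUCT else "asymptotic"


# ---------------------------------------------------------------------------
# Wilting-onset detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetResult:
    """Detected wilting onset ('hour 0' anchor) and detector diagnostics."""

    onset_min: float | None
    method: str | None            # 'turgor_rate' | 'delta_rise' | None
    peak_rate_pct_per_h: float | None
    threshold_pct_per_h: float


def _contiguous_runs(t: np.ndarray, max_gap_min: float) -> list[np.ndarray]:
    if t.size == 0:
        return []
    breaks = np.where(np.diff(t) > max_gap_min)[0]
    return [np.asarray(idx) for idx in np.split(np.arange(t.size), breaks + 1)]


def detect_wilting_onset(series: pd.DataFrame, window_min: float = 120.0,
                         rate_threshold_pct_per_h: float = 15.0,
                         sustain_min: float = 30.0,
                         delta_rise_threshold_c: float = -1.0) -> OnsetResult:
    """Detect the start of rapid turgor loss in a plant time series.

    Parameters
    ----------
    series
        DataFrame with ``time_min`` and ``turgor`` columns; optional
        ``is_day`` restricts the search to lit periods (day/night steps in
        leaf angle would otherwise masquerade as wilts) and optional
        ``leaf_air_delta`` enables the fallback rule.
    window_min
        Minimum series span; shorter input raises ``InsufficientDataError``.

    Onset is the first time the centred finite-difference turgor drop rate
    exceeds ``rate_threshold_pct_per_h`` and keeps exceeding it for at least
    ``sustain_min``.  If turgor never crosses, the fallback is the first
    sustained rise of the leaf-air difference above ``delta_rise_threshold_c``
    (the leaf approaching thermal equilibrium with the air).
    """
    d = series.sort_values("time_min")
    t_all = d["time_min"].to_numpy(dtype=float)
    if t_all.size < 3 or (t_all[-1] - t_all[0]) < window_min:
        raise InsufficientDataError(
            f"series spans {0 if t_all.size == 0 else t_all[-1] - t_all[0]:.0f} min "
            f"< required window {window_min:.0f} min"
        )
    if "is_day" in d.columns:
        d = d[d["is_day"].astype(bool)]

    cadence = np.median(np.diff(t_all)) if t_all.size > 1 else 10.0
    max_gap = 1.5 * cadence

    def first_sustained(t: np.ndarray, ok: np.ndarray) -> float | None:
        # earliest t0 with the condition holding at every sample in [t0, t0+sustain]
        for i in np.flatnonzero(ok):
            j = np.searchsorted(t, t[i] + sustain_min, side="left")
            if j >= t.size:
                break
            if t[j] - t[i] >= sustain_min - 1e-9 and ok[i:j + 1].all():
                return float(t[i])
        return None

    peak_rate = None
    dd = d.dropna(subset=["turgor"]) if "turgor" in d.columns else d.iloc[0:0]
    if len(dd) >= 3:
        t = dd["time_min"].to_numpy(dtype=float)
        u = dd["turgor"].to_numpy(dtype=float)
        for idx in _contiguous_runs(t, max_gap):
            if idx.size < 3:
                continue
            ti, ui = t[idx], u[idx]
            rate = np.full(ti.size, np.nan)
            rate[1:-1] = (ui[2:] - ui[:-2]) / ((ti[2:] - ti[:-2]) / 60.0)
            drop = -rate  # %/h, positive = falling turgor
            run_peak = np.nanmax(drop) if np.isfinite(drop).any() else None
            if run_peak is not None:
                peak_rate = run_peak if peak_rate is None else max(peak_rate, run_peak)
            ok = np.where(np.isnan(drop), False, drop > rate_threshold_pct_per_h)
            # a one-frame cliff (step drop) registers even without a centred window
            step = np.zeros_like(ok)
            step[1:] = (ui[:-1] - ui[1:]) / ((ti[1:] - ti[:-1]) / 60.0) > \
                max(rate_threshold_pct_per_h * 4, 100.0)
            if step.any():
                k = int(np.flatnonzero(step)[0])
                return OnsetResult(float(ti[k]), "turgor_rate",
                                   peak_rate, rate_threshold_pct_per_h)
            hit = first_sustained(ti, ok)
            if hit is not None:
                return OnsetResult(hit, "turgor_rate", peak_rate,
                                   rate_threshold_pct_per_h)

    if "leaf_air_delta" in d.columns:
        dd = d.dropna(subset=["leaf_air_delta"])
        t = dd["time_min"].to_numpy(dtype=float)
        delta = dd["leaf_air_delta"].to_numpy(dtype=float)
        for idx in _contiguous_runs(t, max_gap):
            ti = t[idx]
            ok = delta[idx] > delta_rise_threshold_c
            hit = first_sustained(ti, ok)
            if hit is not None:
                return OnsetResult(hit, "delta_rise", peak_rate,
                                   rate_threshold_pct_per_h)

    return OnsetResult(None, None, peak_rate, rate_threshold_pct_per_h)


def cluster_phases(times_h, window=(-4.0, 6.0)) -> pd.DataFrame:
    """Label times (hours since onset) as before/after wilting.

    Times below 0 are ``before_wilt``, at or above 0 ``after_wilt``; points
    outside ``window`` are excluded and flagged.
    """
    t = np.asarray(times_h, dtype=float)
    lo, hi = window
    labels = np.where(t < 0, "before_wilt", "after_wilt")
    included = (t >= lo) & (t <= hi)
    return pd.DataFrame({"time_h": t, "phase": labels, "included": included})


# ---------------------------------------------------------------------------
# Turgor-temperature relationship
# ---------------------------------------------------------------------------

@dataclass
class TurgorTemperatureRelation:
    """Lowess curve(s), per-group OLS slopes and the slope-difference test."""

    curves: dict          # group -> DataFrame(temp, turgor_smooth)
    slopes: dict          # group -> (slope %/°C, std err)
    slope_difference: float | None
    p_value: float | None
    temp_range: tuple[float, float]
    span: float
    n_used: dict


def turgor_temperature_relation(turgor, leaf_temp, groups=None,
                                temp_range: tuple[float, float] = (28.5, 31.0),
                                span: float = 0.5, robust_iters: int = 2,
                                min_pairs: int = 10) -> TurgorTemperatureRelation:
    """Locally weighted turgor-vs-temperature curve plus OLS slope comparison.

    Observations are restricted to ``temp_range`` (°C).  For each group a
    lowess smooth (tricube weights, fraction ``span``, ``robust_iters``
    robustifying iterations) and an ordinary least-squares slope are
    computed; with exactly two groups the slope difference is tested via the
    interaction term of a two-group linear model.
    """
    import statsmodels.api as sm
    from statsmodels.nonparametric.smoothers_lowess import lowess

    u = np.asarray(turgor, dtype=float)
    temp = np.asarray(leaf_temp, dtype=float)
    g = (np.asarray(groups) if groups is not None
         else np.full(u.shape, "all", dtype=object))
    keep = np.isfinite(u) & np.isfinite(temp) & \
        (temp >= temp_range[0]) & (temp <= temp_range[1])
    u, temp, g = u[keep], temp[keep], g[keep]

    curves, slopes, n_used = {}, {}, {}
    for name in pd.unique(g):
        sel = g == name
        if sel.sum() < min_pairs:
            raise InsufficientDataError(
                f"group {name!r}: {int(sel.sum())} pairs in {temp_range} °C window "
                f"(need >= {min_pairs})"
            )
        sm_xy = lowess(u[sel], temp[sel], frac=span, it=robust_iters,
                       return_sorted=True)
        curves[name] = pd.DataFrame(
            {"temp": sm_xy[:, 0], "turgor_smooth": sm_xy[:, 1]})
        ols = sm.OLS(u[sel], sm.add_constant(temp[sel])).fit()
        slopes[name] = (float(ols.params[1]), float(ols.bse[1]))
        n_used[name] = int(sel.sum())

    slope_diff = p_value = None
    names = list(curves)
    if len(names) == 2:
        ind = (g == names[1]).astype(float)
        design = np.column_stack([np.ones_like(temp), temp, ind, temp * ind])
        ols = sm.OLS(u, design).fit()
        slope_diff = float(ols.params[3])
        p_value = float(ols.pvalues[3])
    return TurgorTemperatureRelation(
        curves=curves, slopes=slopes, slope_difference=slope_diff,
        p_value=p_value, temp_range=temp_range, span=span, n_used=n_used)
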