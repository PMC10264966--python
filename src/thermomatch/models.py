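"""Model fitting: Sharpe-Schoolfield TPCs and linear rate models.

Both models are scikit-learn style estimators (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn pipelines and model selection; the module-level
functions ``fit_tpc``, ``fit_linear_rate``, ``bootstrap_cis`` and
``predict_grid`` are thin wrappers over them taking the package's
:class:`~thermomatch.rates.RateEstimate` collections.

The TPC fit is bounded nonlinear least squares with seeded multistart; the
curve is parameterised internally as (r_tref, Ea, Eh - Ea, th) so the
Eh > Ea invariant (and hence a well-defined optimum) holds throughout the
search. Confidence intervals come from a case-resampling bootstrap:
replicate rows are resampled with replacement, the model refit from the
point estimate, and percentile intervals taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm

from .constants import ABS_ZERO_C, DEFAULT_TREF_C
from .errors import FitError, InputError
from .rates import RateEstimate
from .tpc import TPCParams, mrp_of, sharpe_schoolfield, topt_of

__all__ = [
    "SharpeSchoolfieldRegressor",
    "TemperatureLinearModel",
    "PredictionGrid",
    "case_resampling_ci",
    "fit_tpc",
    "fit_linear_rate",
    "bootstrap_cis",
    "predict_grid",
]


def _as_temperature_vector(X) -> np.ndarray:
    """Accept a 1-D temperature array or a single-column 2-D design matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise InputError("temperature design matrix must have one column")
        X = X[:, 0]
    elif X.ndim != 1:
        raise InputError("temperatures must be 1-D or a single column")
    return X


class SharpeSchoolfieldRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the Sharpe-Schoolfield TPC.

    Parameters
    ----------
    tref : float
        Standardisation temperature (degC). Ea, Eh, th and Topt are
        invariant to it; only r_tref rescales.
    n_starts : int
        Number of multistart initialisations: one data-driven start plus
        ``n_starts - 1`` seeded random draws with Ea in ``ea_range``,
        Eh in (Ea + eh_margin, eh_max), th in ``th_range`` (kelvin), and
        r_tref log-uniform around the data scale. The reported fit has the
        minimal SSE among converged starts.
    random_state : int or None
        Seed for the multistart draws.

    Attributes
    ----------
    r_tref_, ea_, eh_, th_ : float
        Fitted curve parameters (th_ in kelvin).
    topt_, mrp_ : float
        Derived optimum temperature (degC) and maximum rate of performance,
        via the closed form.
    sse_ : float
        Residual sum of squares at the optimum.
    flags_ : dict
        Diagnostics, e.g. ``no_high_temperature_decline`` when the data show
        no post-optimum decline and th is pinned at its bound, or
        ``flat_sse_landscape`` when distinct optima tie on SSE.
    ci_ : dict
        Percentile bootstrap CIs per parameter, set by ``bootstrap_ci``.
    """

    _TH_BOUNDS = (270.0, 350.0)

    def __init__(self, tref=DEFAULT_TREF_C, n_starts=20,
                 ea_range=(0.2, 3.0), eh_margin=0.1, eh_max=25.0,
                 th_range=(280.0, 330.0), random_state=None):
        self.tref = tref
        self.n_starts = n_starts
        self.ea_range = ea_range
        self.eh_margin = eh_margin
        self.eh_max = eh_max
        self.th_range = th_range
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _residuals(self, p, t_c, y):
        r_tref, ea, de, th = p
        return sharpe_schoolfield(t_c, r_tref, ea, ea + de, th, self.tref) - y

    def _bounds(self, scale):
        lo = [scale * 1e-9, 0.01, 1e-3, self._TH_BOUNDS[0]]
        hi = [scale * 1e6, 12.0, 60.0, self._TH_BOUNDS[1]]
        return lo, hi

    def _solve(self, x0, t_c, y, scale):
        lo, hi = self._bounds(scale)
        x0 = np.clip(x0, lo, hi)
        return least_squares(self._residuals, x0, bounds=(lo, hi),
                             args=(t_c, y), xtol=1e-15, ftol=1e-15, gtol=1e-15,
                             max_nfev=2000)

    def _starts(self, t_c, y, scale):
        rng = np.random.default_rng(self.random_state)
        th0 = float(t_c[np.argmax(y)]) + ABS_ZERO_C
        # data-driven start: optimum near the empirical argmax, moderate slopes
        starts = [np.array([max(scale * 1e-3, abs(np.median(y))), 0.6, 1.0, th0])]
        for _ in range(max(0, self.n_starts - 1)):
            ea = rng.uniform(*self.ea_range)
            eh = rng.uniform(ea + self.eh_margin, self.eh_max)
            th = rng.uniform(*self.th_range)
            r = scale * 10.0 ** rng.uniform(-2.0, 1.0)
            starts.append(np.array([r, ea, eh - ea, th]))
        return starts

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        t_c = _as_temperature_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t_c.shape:
            raise InputError("X and y lengths differ")
        if np.unique(t_c).size < 5:
            raise FitError("need >= 5 distinct assay temperatures for a TPC fit")
        if np.all(y <= 0):
            warnings.warn("all rates non-positive; fitting on raw values",
                          stacklevel=2)
        scale = float(np.max(np.abs(y)))
        if scale == 0.0:
            raise FitError("all rates are zero; nothing to fit")

        results = []
        for x0 in self._starts(t_c, y, scale):
            try:
                res = self._solve(x0, t_c, y, scale)
            except Exception:  # numerical failure on one start is tolerable
                continue
            if res.success and np.all(np.isfinite(res.x)):
                results.append(res)
        if not results:
            raise FitError("no multistart candidate converged")
        results.sort(key=lambda r: float(r.cost))
        best = results[0]
        self._set_fitted(best.x, t_c, y)
        self.flags_ = {}
        if len(results) > 1:
            second = results[1]
            if (abs(second.cost - best.cost) <= 1e-3 * max(best.cost, 1e-300)
                    and np.max(np.abs(second.x - best.x)
                               / np.maximum(np.abs(best.x), 1e-12)) > 0.05):
                self.flags_["flat_sse_landscape"] = True
        if (self.th_ >= self._TH_BOUNDS[1] - 1.0
                or self.topt_ >= float(np.max(t_c))):
            # no decline at high temperature: the inactivation term is
            # unidentified and th/Eh sit at their bounds
            self.flags_["no_high_temperature_decline"] = True
        return self

    def _set_fitted(self, x, t_c, y):
        r_tref, ea, de, th = (float(v) for v in x)
        self.r_tref_, self.ea_, self.eh_, self.th_ = r_tref, ea, ea + de, th
        self.topt_ = topt_of(self.ea_, self.eh_, self.th_)
        self.mrp_ = mrp_of(self.params_)
        resid = self._residuals(x, t_c, y)
        self.sse_ = float(resid @ resid)
        self.residual_sd_ = float(np.std(resid, ddof=min(4, resid.size - 1)))
        self.n_obs_ = int(t_c.size)
        self.n_features_in_ = 1

    @property
    def params_(self) -> TPCParams:
        check_is_fitted(self, "ea_")
        return TPCParams(self.r_tref_, self.ea_, self.eh_, self.th_, self.tref)

    def predict(self, X):
        check_is_fitted(self, "ea_")
        return np.asarray(sharpe_schoolfield(_as_temperature_vector(X),
                                             *self.params_))

    def bootstrap_ci(self, X, y, n_boot=999, level=0.95, random_state=None):
        """Case-resampling bootstrap CIs; stores and returns ``ci_``."""
        self.ci_ = case_resampling_ci(self, X, y, n_boot=n_boot, level=level,
                                      random_state=random_state)
        return self.ci_


def case_resampling_ci(fitted: SharpeSchoolfieldRegressor, X, y, *,
                       n_boot=999, level=0.95, random_state=None):
    """Percentile bootstrap CIs for (r_tref, ea, eh, th, topt, mrp).

    Cases (replicate rows) are resampled with replacement and the curve
    refit starting from the point estimate. ``n_boot = 0`` returns the
    degenerate interval at the point estimate. More than 20% failed refits
    triggers a widened-interval warning.
    """
    check_is_fitted(fitted, "ea_")
    t_c = _as_temperature_vector(X)
    y = np.asarray(y, dtype=float)
    point = {"r_tref": fitted.r_tref_, "ea": fitted.ea_, "eh": fitted.eh_,
             "th": fitted.th_, "topt": fitted.topt_, "mrp": fitted.mrp_}
    if n_boot == 0:
        return {k: (v, v, level) for k, v in point.items()}
    rng = np.random.default_rng(random_state)
    x_point = np.array([fitted.r_tref_, fitted.ea_, fitted.eh_ - fitted.ea_,
                        fitted.th_])
    scale = float(np.max(np.abs(y)))
    draws = {k: [] for k in point}
    n_fail = 0
    n = t_c.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tb, yb = t_c[idx], y[idx]
        if np.unique(tb).size < 5:
            n_fail += 1
            continue
        try:
            res = fitted._solve(x_point, tb, yb, scale)
        except Exception:
            n_fail += 1
            continue
        if not (res.success and np.all(np.isfinite(res.x))):
            n_fail += 1
            continue
        r, ea, de, th = (float(v) for v in res.x)
        draws["r_tref"].append(r)
        draws["ea"].append(ea)
        draws["eh"].append(ea + de)
        draws["th"].append(th)
        try:
            p = TPCParams(r, ea, ea + de, th, fitted.tref)
            draws["topt"].append(topt_of(ea, ea + de, th))
            draws["mrp"].append(mrp_of(p))
        except Exception:
            draws["topt"].append(np.nan)
            draws["mrp"].append(np.nan)
    if n_fail > 0.2 * n_boot:
        warnings.warn(f"{n_fail}/{n_boot} bootstrap refits failed; "
                      "intervals may be wider than nominal", stacklevel=2)
    alpha = (1.0 - level) / 2.0
    out = {}
    for k, v in draws.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            out[k] = (np.nan, np.nan, level)
        else:
            out[k] = (float(np.quantile(v, alpha)),
                      float(np.quantile(v, 1.0 - alpha)), level)
    return out


class TemperatureLinearModel(RegressorMixin, BaseEstimator):
    """OLS rate-on-temperature line with an optional zero-slope refit.

    With ``constrain="auto"`` (the default), a slope whose p-value is at or
    above ``alpha`` is judged temperature-independent and the model is refit
    with the slope constrained to zero, i.e. intercept = sample mean — the
    standard treatment for ingestion that shows no thermal dependence.
    """

    def __init__(self, alpha=0.05, constrain="auto"):
        self.alpha = alpha
        self.constrain = constrain

    def fit(self, X, y):
        t_c = _as_temperature_vector(X)
        y = np.asarray(y, dtype=float)
        if t_c.size < 3:
            raise InputError("need >= 3 points for a linear rate model")
        res = sm.OLS(y, sm.add_constant(t_c)).fit()
        self.intercept_, self.slope_ = (float(v) for v in res.params)
        self.slope_se_ = float(res.bse[1])
        self.p_value_ = float(res.pvalues[1])
        self.r_squared_ = float(res.rsquared)
        self.f_stat_ = float(res.fvalue)
        self.df_ = (int(res.df_model), int(res.df_resid))
        self.constrained_zero_ = False
        if self.constrain == "always" or (
                self.constrain == "auto" and self.p_value_ >= self.alpha):
            self.slope_ = 0.0
            self.intercept_ = float(np.mean(y))
            self.constrained_zero_ = True
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * _as_temperature_vector(X)


@dataclass(frozen=True)
class PredictionGrid:
    """A model evaluated on a fine, fixed-step temperature grid (degC)."""

    temperatures: np.ndarray
    values: np.ndarray
    step: float = 0.001

    def __post_init__(self):
        if not np.all(np.diff(self.temperatures) > 0):
            raise InputError("grid temperatures must be strictly increasing")
        if self.temperatures.shape != self.values.shape:
            raise InputError("grid and values lengths differ")


def predict_grid(model, t_min: float, t_max: float, step: float = 0.001) -> PredictionGrid:
    """Evaluate a fitted model (or plain callable) on an inclusive fine grid.

    The grid runs from ``t_min`` to ``t_max`` inclusive (within one step) at
    the stated precision; 14-42 degC at 0.001 gives 28001 points.
    """
    if not t_min < t_max:
        raise InputError("need t_min < t_max")
    n = int(round((t_max - t_min) / step))
    temps = t_min + step * np.arange(n + 1)
    fn = model.predict if hasattr(model, "predict") else model
    values = np.asarray(fn(temps), dtype=float)
    return PredictionGrid(temps, values, step)


# ---------------------------------------------------------------------------
# RateEstimate-facing wrappers

def _xy(rates: Iterable[RateEstimate]):
    rates = list(rates)
    if not rates:
        raise InputError("empty rate collection")
    units = {r.units for r in rates}
    if len(units) > 1:
        raise InputError(f"mixed units in one rate collection: {units}")
    t = np.array([r.temperature_c for r in rates], dtype=float)
    y = np.array([r.value for r in rates], dtype=float)
    return t, y


def fit_tpc(rates: Sequence[RateEstimate], tref=DEFAULT_TREF_C,
            multistart=20, seed=None) -> SharpeSchoolfieldRegressor:
    t, y = _xy(rates)
    return SharpeSchoolfieldRegressor(tref=tref, n_starts=multistart,
                                      random_state=seed).fit(t, y)


def bootstrap_cis(fit: SharpeSchoolfieldRegressor, rates: Sequence[RateEstimate],
                  n_boot=999, level=0.95, seed=None):
    t, y = _xy(rates)
    return fit.bootstrap_ci(t, y, n_boot=n_boot, level=level, random_state=seed)


def fit_linear_rate(rates: Sequence[RateEstimate], alpha=0.05,
                    constrain="auto") -> TemperatureLinearModel:
    t, y = _xy(rates)
    return TemperatureLinearModel(alpha=alpha, constrain=constrain).fit(t, y)
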