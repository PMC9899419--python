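"""Logistic accumulation kinetics for grain filling.

The content of dry matter or of a mineral element in a developing grain is
modelled with the three-parameter logistic curve

    W(x) = a / (1 + exp(-k (x - x_c)))

where ``W`` is content per grain at ``x`` DAF, ``a`` is the asymptotic
maximum content reached over grain filling, ``k`` (d-1) is the exponential
growth rate, and ``x_c`` is the inflection time. The accumulation rate is
the first derivative,

    dW/dx = a k e^{-k(x-x_c)} / (1 + e^{-k(x-x_c)})^2,

which is symmetric about ``x_c`` and peaks there with value ``a k / 4``.
Whether an element's rate peaks before, inside, or after the sampling
window is what distinguishes early, mid, and sustained accumulation
patterns (see :mod:`grainfill.patterns`).

The public surface follows the Model/Results convention: build a
:class:`LogisticGrowthModel` from observations (or a
:class:`~grainfill.design.GrainContentSeries`), call :meth:`fit`, and work
with the returned :class:`LogisticGrowthResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .design import GrainContentSeries
from .exceptions import NotConvergedError, ValidationError

__all__ = [
    "logistic",
    "logistic_rate",
    "LogisticGrowthModel",
    "LogisticGrowthResults",
    "RateCurve",
    "fit_logistic",
]


def logistic(x, a, k, x_c):
    """Three-parameter logistic content curve W(x)."""
    x = np.asarray(x, dtype=float)
    z = np.clip(-k * (x - x_c), -700.0, 700.0)
    out = a / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def logistic_rate(x, a, k, x_c):
    """Accumulation rate dW/dx of the logistic curve (content d-1)."""
    x = np.asarray(x, dtype=float)
    z = -np.abs(k * (x - x_c))  # symmetric in the sign of (x - x_c)
    e = np.exp(z)
    out = a * k * e / (1.0 + e) ** 2
    return out if out.ndim else float(out)


def _jacobian(x, a, k, x_c):
    z = np.clip(-k * (x - x_c), -700.0, 700.0)
    s = 1.0 / (1.0 + np.exp(z))  # logistic(x)/a
    sq = s * (1.0 - s)
    da = s
    dk = a * (x - x_c) * sq
    dxc = -a * k * sq
    return np.column_stack([da, dk, dxc])


@dataclass
class RateCurve:
    """Accumulation rate evaluated on a grid, with its closed-form peak."""

    x: np.ndarray
    rate: np.ndarray
    t_peak: float
    peak_rate: float


class LogisticGrowthModel:
    """Nonlinear least-squares logistic fit of content on time.

    Observations are fit at replicate level, unweighted: every replicate
    measurement contributes one residual, which yields honest residual
    degrees of freedom for the confidence bands.

    Parameters
    ----------
    x : array-like
        Sampling times (DAF), one per observation.
    w : array-like
        Contents (>= 0), same length as ``x``.
    """

    def __init__(self, x, w):
        x = np.asarray(x, dtype=float)
        w = np.asarray(w, dtype=float)
        if x.shape != w.shape or x.ndim != 1:
            raise ValidationError("x and w must be 1-d arrays of equal length")
        if len(np.unique(x)) < 4:
            raise ValidationError(
                "logistic fitting requires >= 4 distinct time points"
            )
        if np.any(w < 0) or not np.any(w > 0):
            raise ValidationError("contents must be >= 0 with at least one > 0")
        self.x = x
        self.w = w

    @classmethod
    def from_series(cls, series: GrainContentSeries) -> "LogisticGrowthModel":
        m = cls(series.daf, series.value)
        m.series = series
        return m

    # -- initialization -----------------------------------------------------
    def _start_params(self):
        x, w = self.x, self.w
        a0 = 1.05 * float(np.max(w))
        # replicate means per distinct time, for the half-max crossing
        ts = np.unique(x)
        means = np.array([w[x == t].mean() for t in ts])
        half = a0 / 2.0
        if means[0] >= half:
            xc0 = float(ts[0]) - 1.0  # inflection before the window
        elif means[-1] <= half:
            xc0 = float(ts[-1]) + 1.0
        else:
            idx = int(np.argmax(means >= half))
            t_lo, t_hi = ts[idx - 1], ts[idx]
            m_lo, m_hi = means[idx - 1], means[idx]
            frac = (half - m_lo) / (m_hi - m_lo) if m_hi > m_lo else 0.5
            xc0 = float(t_lo + frac * (t_hi - t_lo))
        # k0 from the slope of logit(W/a0) against x
        p = np.clip(means / a0, 1e-6, 1 - 1e-6)
        lo = np.log(p / (1 - p))
        k0 = float(np.polyfit(ts, lo, 1)[0])
        k0 = min(max(k0, 1e-3), 5.0)
        return np.array([a0, k0, xc0])

    def fit(self, max_iter: int = 500, xtol: float = 1e-8) -> "LogisticGrowthResults":
        """Fit (a, k, x_c) by bounded nonlinear least squares.

        Non-convergence (including unidentifiable flat series) is reported
        through ``converged=False`` on the results, never as an exception.
        """
        x, w = self.x, self.w
        wmax = float(np.max(w))
        t_first, t_last = float(np.min(x)), float(np.max(x))
        # flat series: k is unidentifiable, flag immediately
        if np.ptp(w) <= 1e-12 * max(wmax, 1.0):
            return LogisticGrowthResults(
                self, params=np.array([np.nan] * 3), converged=False,
                message="constant series: growth rate unidentifiable",
            )
        lb = np.array([1e-12, 1e-6, t_first - 30.0])
        ub = np.array([10.0 * wmax, 5.0, t_last + 30.0])
        p0 = np.clip(self._start_params(), lb, ub)

        def resid(p):
            return logistic(x, *p) - w

        def jac(p):
            return _jacobian(x, *p)

        try:
            sol = optimize.least_squares(
                resid, p0, jac=jac, bounds=(lb, ub),
                xtol=xtol, ftol=1e-12, gtol=1e-12, max_nfev=max_iter * 4,
            )
        except Exception as err:  # pragma: no cover - defensive
            return LogisticGrowthResults(
                self, params=np.array([np.nan] * 3), converged=False,
                message=f"optimizer failure: {err}",
            )
        params = sol.x
        ok = bool(sol.success) and np.all(np.isfinite(params))
        # parameters pinned to a bound indicate an unidentifiable fit
        if ok and (params[1] <= lb[1] * 1.01 or params[0] >= ub[0] * 0.999):
            ok = False
        return LogisticGrowthResults(
            self, params=params, converged=ok,
            message=sol.message if hasattr(sol, "message") else "",
        )


class LogisticGrowthResults:
    """Fitted logistic accumulation curve with diagnostics.

    Attributes
    ----------
    a, k, x_c : float
        Asymptotic content, growth rate (d-1), inflection time (DAF).
    converged : bool
        Whether the optimizer converged to an identifiable solution. All
        derived quantities (rate curve, peak rate, bands) require this.
    """

    def __init__(self, model, params, converged, message=""):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.converged = bool(converged)
        self.message = message
        self.nobs = len(model.w)
        self.df_resid = self.nobs - 3
        if self.converged:
            fitted = logistic(model.x, *self.params)
            resid = model.w - fitted
            sse = float(resid @ resid)
            tss = float(np.sum((model.w - model.w.mean()) ** 2))
            self.fittedvalues = fitted
            self.resid = resid
            self.ssr = sse
            self.rsquared = 1.0 - sse / tss if tss > 0 else np.nan
            self.resid_sd = (
                np.sqrt(sse / self.df_resid) if self.df_resid > 0 else np.nan
            )
            J = _jacobian(model.x, *self.params)
            JTJ = J.T @ J
            try:
                cov_unscaled = np.linalg.inv(JTJ)
            except np.linalg.LinAlgError:
                cov_unscaled = np.linalg.pinv(JTJ)
            s2 = sse / self.df_resid if self.df_resid > 0 else 0.0
            self.cov_params = s2 * cov_unscaled
            self.bse = np.sqrt(np.clip(np.diag(self.cov_params), 0, None))
        else:
            self.fittedvalues = None
            self.resid = None
            self.ssr = np.nan
            self.rsquared = np.nan
            self.resid_sd = np.nan
            self.cov_params = np.full((3, 3), np.nan)
            self.bse = np.full(3, np.nan)

    # -- parameter accessors -------------------------------------------------
    @property
    def a(self) -> float:
        return float(self.params[0])

    @property
    def k(self) -> float:
        return float(self.params[1])

    @property
    def x_c(self) -> float:
        return float(self.params[2])

    def _require_converged(self):
        if not self.converged:
            raise NotConvergedError(
                f"operation requires a converged fit ({self.message})"
            )

    def predict(self, x):
        self._require_converged()
        return logistic(np.asarray(x, dtype=float), *self.params)

    # -- accumulation rate ----------------------------------------------------
    def rate_curve(self, x) -> RateCurve:
        """Accumulation rate dW/dx on a grid, with the closed-form peak."""
        self._require_converged()
        x = np.asarray(x, dtype=float)
        t_peak, peak = self.peak_rate()
        return RateCurve(x=x, rate=logistic_rate(x, *self.params),
                         t_peak=t_peak, peak_rate=peak)

    def peak_rate(self) -> tuple[float, float]:
        """(t_peak, peak rate): the rate maximum is at x_c with value a*k/4."""
        self._require_converged()
        return self.x_c, self.a * self.k / 4.0

    # -- uncertainty -----------------------------------------------------------
    def conf_band(self, x, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the mean content curve.

        Linearizes the curve in the parameters (delta method) and applies
        the t quantile at ``level`` with the fit's residual degrees of
        freedom. The band always contains the fitted curve, has zero width
        for a noiseless fit, and widens away from the data.
        """
        self._require_converged()
        if not 0.0 < level < 1.0:
            raise ValidationError("confidence level must be in (0, 1)")
        if self.df_resid < 1:
            raise ValidationError("confidence band requires >= 1 residual df")
        x = np.asarray(x, dtype=float)
        g = _jacobian(x, *self.params)
        var = np.einsum("ij,jk,ik->i", g, self.cov_params, g)
        half = stats.t.ppf(0.5 + level / 2.0, self.df_resid) * np.sqrt(
            np.clip(var, 0, None)
        )
        yhat = logistic(x, *self.params)
        return yhat - half, yhat + half

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = ["Logistic accumulation fit", "=" * 40]
        lines.append(f"converged: {self.converged}   nobs: {self.nobs}")
        if self.converged:
            names = ("a (asymptote)", "k (rate, d-1)", "x_c (DAF)")
            for name, val, se in zip(names, self.params, self.bse):
                lines.append(f"{name:>14s}: {val:12.6g}  (SE {se:.4g})")
            t_peak, peak = self.peak_rate()
            lines.append(f"{'R-squared':>14s}: {self.rsquared:12.6g}")
            lines.append(f"{'residual SD':>14s}: {self.resid_sd:12.6g}")
            lines.append(f"{'peak rate':>14s}: {peak:12.6g} at {t_peak:.3g} DAF")
        else:
            lines.append(f"message: {self.message}")
        return "\n".join(lines)


def fit_logistic(series: GrainContentSeries, **fit_kw) -> LogisticGrowthResults:
    """Convenience wrapper: fit the logistic model to a content series."""
    return LogisticGrowthModel.from_series(series).fit(**fit_kw)
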