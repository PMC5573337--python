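"""Relative net elongation and the two-parameter log-logistic model.

The study endpoint is relative net elongation of wheat roots,

    RNE% = 100 * (RE_t - RE_0) / (RE_c - RE_0),

and every dose-response relationship in the package is the two-parameter
log-logistic curve with asymptotes fixed at 100 and 0,

    R(x) = 100 / (1 + (x / x50) ** beta),

where x is any exposure metric (free-ion activity, toxic units, occupied
site fraction) and x50 the exposure at 50% response.  Fitting is ordinary
nonlinear least squares on the untransformed response with x50
log-parameterised for positivity and a deterministic multi-start grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    DegenerateControlError,
    FitError,
    InvalidInputError,
    NonIdentifiableError,
)

__all__ = [
    "DoseResponseObservation",
    "RootLengthRecord",
    "LogLogisticFit",
    "LogLogisticModel",
    "relative_net_elongation",
    "loglogistic_response",
    "fit_loglogistic",
]


@dataclass(frozen=True)
class DoseResponseObservation:
    """One replicate observation: exposure metric x (activity, TU, ...) and
    response in RNE percent.  Individual replicates may fall outside
    [0, 100]; fitted curves are bounded."""

    x: float
    rne_percent: float
    replicate_id: int = 0
    treatment_label: str = ""

    def __post_init__(self):
        if self.x < 0:
            raise InvalidInputError("exposure x must be >= 0")


@dataclass(frozen=True)
class RootLengthRecord:
    """Raw root lengths (cm): treatment, original, and control."""

    re_t: float
    re_0: float
    re_c: float

    def __post_init__(self):
        if min(self.re_t, self.re_0, self.re_c) < 0:
            raise InvalidInputError("root lengths must be >= 0")


def relative_net_elongation(rec: RootLengthRecord) -> float:
    """RNE% = 100 (RE_t - RE_0)/(RE_c - RE_0); controls must grow."""
    denom = rec.re_c - rec.re_0
    if denom == 0:
        raise DegenerateControlError(
            "control root length equals the original length; RNE undefined"
        )
    return 100.0 * (rec.re_t - rec.re_0) / denom


def loglogistic_response(x, x50: float, beta: float):
    """R(x) = 100/(1 + (x/x50)^beta); strictly decreasing, R(0) = 100."""
    if x50 <= 0:
        raise InvalidInputError(f"x50 must be > 0, got {x50}")
    if beta <= 0:
        raise InvalidInputError(f"beta must be > 0, got {beta}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidInputError("exposure x must be >= 0")
    with np.errstate(divide="ignore", over="ignore"):
        out = 100.0 / (1.0 + (x / x50) ** beta)
    return float(out) if out.ndim == 0 else out


@dataclass
class LogLogisticFit:
    """Results of a log-logistic fit.

    x50 and beta with approximate standard errors (linearised, from the
    Jacobian at the optimum), R^2 and RMSE over the fitted points.
    """

    x50: float
    beta: float
    se_x50: float
    se_beta: float
    r2: float
    rmse: float
    n_points: int
    ss_res: float

    def predict(self, x):
        return loglogistic_response(x, self.x50, self.beta)

    def summary(self) -> str:
        lines = [
            "Log-logistic dose-response fit (upper = 100, lower = 0)",
            f"  n points : {self.n_points}",
            f"  x50      : {self.x50:.6g}  (se {self.se_x50:.3g})",
            f"  beta     : {self.beta:.4g}  (se {self.se_beta:.3g})",
            f"  R^2      : {self.r2:.4f}",
            f"  RMSE     : {self.rmse:.4g} %",
        ]
        return "\n".join(lines)


class LogLogisticModel:
    """Log-logistic dose-response model bound to observations.

    Parameters
    ----------
    x : array-like
        Exposure metric (activity in mol/L, TU, ...); must be >= 0.
        Zero-dose controls are allowed and anchor the upper asymptote.
    response : array-like
        Observed RNE in percent.  Not clipped to [0, 100]: clipping the
        replicate scatter would bias the asymptotes.
    aggregate : {None, "mean"}
        With "mean", replicate responses at identical x are averaged before
        fitting (the study averaged three replicates); default fits all
        points, preserving the error structure.
    """

    def __init__(self, x, response, aggregate: str | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(response, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise InvalidInputError("x and response must be 1-D arrays of equal length")
        if np.any(x < 0):
            raise InvalidInputError("exposure x must be >= 0")
        if aggregate not in (None, "mean"):
            raise InvalidInputError(f"unknown aggregate option {aggregate!r}")
        if aggregate == "mean":
            xs = np.unique(x)
            ys = np.array([y[x == xi].mean() for xi in xs])
            x, y = xs, ys
        self.x, self.y = x, y

    def _check_identifiable(self):
        positive = self.x[self.x > 0]
        if np.unique(positive).size < 4:
            raise NonIdentifiableError(
                "need >= 4 distinct nonzero exposure levels to fit (x50, beta)"
            )
        if not (np.any(self.y > 50.0) and np.any(self.y < 50.0)):
            raise NonIdentifiableError(
                "responses must bracket 50%: all observations fall on one side"
            )

    def fit(self, n_starts: int = 5) -> LogLogisticFit:
        """Multi-start nonlinear least squares on (log10 x50, log beta)."""
        self._check_identifiable()
        x, y = self.x, self.y
        pos = x[x > 0]
        lo, hi = np.log10(pos.min()), np.log10(pos.max())
        # x50 starts: log-spaced across the data; beta starts: moderate slopes
        x50_starts = np.logspace(lo, hi, n_starts)
        beta_starts = (0.5, 1.0, 2.0, 4.0, 8.0)[:n_starts]

        def resid(theta):
            x50, beta = 10.0 ** theta[0], np.exp(theta[1])
            with np.errstate(divide="ignore", over="ignore"):
                pred = 100.0 / (1.0 + (x / x50) ** beta)
            return pred - y

        best = None
        trace = []
        for x50_0 in x50_starts:
            for b0 in beta_starts:
                try:
                    sol = least_squares(
                        resid,
                        x0=[np.log10(x50_0), np.log(b0)],
                        method="lm",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=2000,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    trace.append((x50_0, b0, repr(exc)))
                    continue
                trace.append((x50_0, b0, sol.cost))
                if sol.success and (best is None or sol.cost < best.cost - 1e-15):
                    best = sol
        if best is None:
            raise FitError("log-logistic fit failed from every start", trace)

        x50 = 10.0 ** best.x[0]
        beta = float(np.exp(best.x[1]))
        n, p = y.size, 2
        ss_res = float(2.0 * best.cost)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        rmse = float(np.sqrt(ss_res / n))

        # linearised SEs via the Jacobian in (log10 x50, log beta)
        se_x50 = se_beta = float("nan")
        if n > p:
            J = best.jac
            try:
                cov = np.linalg.inv(J.T @ J) * ss_res / (n - p)
                se_log10_x50 = np.sqrt(max(cov[0, 0], 0.0))
                se_log_beta = np.sqrt(max(cov[1, 1], 0.0))
                se_x50 = float(x50 * np.log(10.0) * se_log10_x50)
                se_beta = float(beta * se_log_beta)
            except np.linalg.LinAlgError:
                pass

        return LogLogisticFit(
            x50=float(x50), beta=beta, se_x50=se_x50, se_beta=se_beta,
            r2=r2, rmse=rmse, n_points=int(n), ss_res=ss_res,
        )

    def plot(self, ax=None, **scatter_kw):
        """Scatter the observations with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fit = self.fit()
        ax.scatter(self.x, self.y, **scatter_kw)
        pos = self.x[self.x > 0]
        grid = np.logspace(np.log10(pos.min()) - 0.5, np.log10(pos.max()) + 0.5, 200)
        ax.plot(grid, fit.predict(grid))
        ax.set_xscale("log")
        ax.set_ylabel("RNE (%)")
        return ax


def fit_loglogistic(points, aggregate: str | None = None,
                    n_starts: int = 5) -> LogLogisticFit:
    """Fit the log-logistic curve to dose-response observations.

    ``points`` is either a pair of arrays (x, response) or an iterable of
    objects/tuples with ``x`` and ``rne_percent`` fields.
    """
    if isinstance(points, tuple) and len(points) == 2:
        x, y = points
    else:
        pts = list(points)
        try:
            x = [p.x for p in pts]
            y = [p.rne_percent for p in pts]
        except AttributeError:
            x = [p[0] for p in pts]
            y = [p[1] for p in pts]
    return LogLogisticModel(x, y, aggregate=aggregate).fit(n_starts=n_starts)
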