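"""Levenberg-Marquardt fitting of the compressed-exponential release model.

The optimizer is implemented directly — damped normal equations with a
gain-ratio damping update and an analytic Jacobian — so that the Jacobian,
the positivity constraint and the convergence rules are all testable. The
three parameters (m_inf, tau0, sigma) are physical positives, so the search
runs in log-parameter space; near-boundary shapes (very large sigma, i.e. an
almost step-like release) then pose no constraint-handling problem.

Model residuals are on the mass scale (micrograms). Goodness of fit is
reported both on that scale and on the normalized released-fraction scale
chi = m/m_inf, where RMSE is dimensionless and comparable across loads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import KineticParams, mass_released

__all__ = [
    "ReleaseSeries",
    "FitResult",
    "FittingError",
    "InsufficientDataError",
    "NoSignalError",
    "initial_guess",
    "fit_release",
    "goodness_of_fit",
    "brute_force_fit",
    "fit_report",
]


class FittingError(ValueError):
    pass


class InsufficientDataError(FittingError):
    pass


class NoSignalError(FittingError):
    pass


@dataclass(frozen=True)
class ReleaseSeries:
    """A time-ordered released-mass series in the bath frame.

    ``times`` in hours (strictly increasing, first point >= 0), ``masses``
    in micrograms (>= 0). ``provenance`` optionally carries one record per
    point (instrument, raw signal, concentration) for traceability.
    """

    times: np.ndarray
    masses: np.ndarray
    provenance: tuple | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        if t.ndim != 1 or m.ndim != 1 or t.size != m.size:
            raise ValueError("times and masses must be 1-D arrays of equal length")
        if t.size and t[0] < 0:
            raise ValueError("times must start at t >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("masses must be >= 0")
        if self.provenance is not None and len(self.provenance) != t.size:
            raise ValueError("provenance must have one record per point")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "masses", m)

    def __len__(self) -> int:
        return self.times.size

    def with_times_scaled(self, factor: float) -> "ReleaseSeries":
        """Same series with times multiplied by `factor` (unit conversion)."""
        return ReleaseSeries(self.times * factor, self.masses, self.provenance)


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    stderr: tuple[float, float, float]
    covariance: np.ndarray  # 3x3, rows/cols ordered (m_inf, tau0, sigma)
    r_squared: float
    rmse: float  # micrograms
    rmse_normalized: float  # on the chi scale, dimensionless
    n_iter: int
    converged: bool
    residuals: np.ndarray  # micrograms, observed - fitted
    message: str = ""

    @property
    def ssr(self) -> float:
        return float(self.residuals @ self.residuals)


def _model_and_jacobian(t: np.ndarray, m_inf: float, tau0: float, sigma: float):
    """Fitted masses and the analytic Jacobian in the original parameters.

    d/dm_inf = chi;  d/dtau0 = -m_inf * e^{-u} * u * sigma/tau0;
    d/dsigma = m_inf * e^{-u} * u * ln(t/tau0),  with u = (t/tau0)^sigma.
    At t = 0 all three derivatives take their limit value 0.
    """
    pos = t > 0
    log_ratio = np.zeros_like(t)
    log_ratio[pos] = np.log(t[pos] / tau0)
    u = np.zeros_like(t)
    u[pos] = np.exp(np.clip(sigma * log_ratio[pos], -745.0, 709.0))
    eu = np.exp(-u)
    c = -np.expm1(-u)
    f = m_inf * c
    J = np.empty((t.size, 3))
    J[:, 0] = c
    J[:, 1] = -m_inf * eu * u * sigma / tau0
    J[:, 2] = m_inf * eu * u * log_ratio
    return f, J


def initial_guess(series: ReleaseSeries) -> KineticParams:
    """Starting triple from the linearized model.

    The plateau is seeded at 1.05x the largest observed mass; with
    chi_hat = m / m_inf0, ordinary least squares on
    ln(-ln(1 - chi_hat)) = sigma*ln t - sigma*ln tau0 over the informative
    band 0.01 < chi_hat < 0.99 yields (sigma, tau0). With fewer than 3
    usable points the guess falls back to sigma = 1 and tau0 = median time.
    """
    m = series.masses
    if not np.any(m > 0):
        raise NoSignalError("all masses are zero; nothing to fit")
    m_inf0 = 1.05 * float(m.max())
    chi_hat = m / m_inf0
    mask = (chi_hat > 0.01) & (chi_hat < 0.99) & (series.times > 0)
    if mask.sum() < 3:
        tau0 = float(np.median(series.times[series.times > 0])) or 1.0
        return KineticParams(m_inf0, tau0, 1.0)
    x = np.log(series.times[mask])
    y = np.log(-np.log1p(-chi_hat[mask]))
    sigma, intercept = np.polyfit(x, y, 1)
    sigma = float(np.clip(sigma, 0.05, 50.0))
    tau0 = float(np.exp(-intercept / sigma))
    tau0 = float(np.clip(tau0, 1e-6, 1e9))
    return KineticParams(m_inf0, tau0, sigma)


def fit_release(
    series: ReleaseSeries,
    init: KineticParams | None = None,
    *,
    sigma_fixed: float | None = None,
    max_iter: int = 200,
    tol_ssr: float = 1e-10,
    tol_grad: float = 1e-10,
) -> FitResult:
    """Levenberg-Marquardt least squares of m_inf*(1 - exp(-(t/tau0)^sigma)).

    Free parameters are optimized in log space (positivity by construction).
    Damping is updated by the gain ratio (Nielsen schedule); an accepted step
    converges the fit when the relative SSR decrease falls below `tol_ssr`
    or the gradient infinity-norm below `tol_grad`. The covariance is
    s^2 (J^T J)^{-1} in the original parameter space with s^2 = SSR/(n-k).

    Passing ``sigma_fixed`` freezes the shape exponent (nested
    simple-exponential model when fixed at 1).
    """
    n = len(series)
    if n <= 3:
        raise InsufficientDataError(f"need more than 3 points to fit, got {n}")
    if n < 5:
        warnings.warn(f"fitting {n} points; at least 5 are recommended", stacklevel=2)
    if init is None:
        init = initial_guess(series)
    t, y = series.times, series.masses

    free = [0, 1] if sigma_fixed is not None else [0, 1, 2]
    p = init.as_array()
    if sigma_fixed is not None:
        if sigma_fixed <= 0:
            raise ValueError("sigma_fixed must be > 0")
        p[2] = sigma_fixed
    theta = np.log(p[free])

    def unpack(th: np.ndarray) -> np.ndarray:
        q = p.copy()
        q[free] = np.exp(np.clip(th, -80.0, 80.0))
        return q

    q = unpack(theta)
    f, J = _model_and_jacobian(t, *q)
    r = y - f
    ssr = float(r @ r)
    Jth = J[:, free] * q[free]  # chain rule d f / d log p = (d f / d p) * p
    A = Jth.T @ Jth
    g = Jth.T @ r
    mu = 1e-3 * max(float(np.max(np.diag(A))), 1e-30)
    nu = 2.0
    converged = False
    message = "max_iter reached without convergence"
    n_iter = 0

    if float(np.max(np.abs(g))) < tol_grad:
        converged, message = True, "gradient norm below tolerance at start"

    while not converged and n_iter < max_iter:
        n_iter += 1
        D = np.diag(np.maximum(np.diag(A), 1e-30))
        try:
            delta = np.linalg.solve(A + mu * D, g)
        except np.linalg.LinAlgError:
            mu *= nu
            nu *= 2.0
            continue
        # at the numerical floor the damped step shrinks to nothing: converged
        if float(np.max(np.abs(delta))) < 1e-14 * (1.0 + float(np.max(np.abs(theta)))):
            converged, message = True, "step size below tolerance"
            break
        theta_new = theta + delta
        q_new = unpack(theta_new)
        f_new, J_new = _model_and_jacobian(t, *q_new)
        r_new = y - f_new
        ssr_new = float(r_new @ r_new)
        predicted = float(delta @ (mu * (np.diag(D) * delta) + g))
        rho = (ssr - ssr_new) / predicted if predicted > 0 else -1.0
        if rho > 0:  # accept
            rel_drop = (ssr - ssr_new) / max(ssr, 1e-300)
            theta, q, ssr, r = theta_new, q_new, ssr_new, r_new
            Jth = J_new[:, free] * q[free]
            A = Jth.T @ Jth
            g = Jth.T @ r
            mu *= max(1.0 / 3.0, 1.0 - (2.0 * rho - 1.0) ** 3)
            nu = 2.0
            if ssr == 0.0:
                converged, message = True, "residuals identically zero"
            elif rel_drop < tol_ssr:
                converged, message = True, "relative SSR change below tolerance"
            elif float(np.max(np.abs(g))) < tol_grad:
                converged, message = True, "gradient norm below tolerance"
        else:
            mu *= nu
            nu *= 2.0
            if mu > 1e30:
                message = "damping diverged; fit stalled"
                break

    params = KineticParams(*np.maximum(q, np.finfo(float).tiny))
    # covariance in the original parameter space
    _, J = _model_and_jacobian(t, *q)
    k = len(free)
    s2 = ssr / (n - k) if n > k else float("nan")
    cov = np.zeros((3, 3))
    Jf = J[:, free]
    try:
        cov_free = s2 * np.linalg.inv(Jf.T @ Jf)
        cov[np.ix_(free, free)] = cov_free
    except np.linalg.LinAlgError:
        cov[:] = np.nan
    with np.errstate(invalid="ignore"):
        stderr = tuple(float(np.sqrt(cov[i, i])) for i in range(3))
    r2, rmse = goodness_of_fit(series, params)
    return FitResult(
        params=params,
        stderr=stderr,
        covariance=cov,
        r_squared=r2,
        rmse=rmse,
        rmse_normalized=rmse / params.m_inf,
        n_iter=n_iter,
        converged=converged,
        residuals=r,
        message=message,
    )


def goodness_of_fit(series: ReleaseSeries, p: KineticParams) -> tuple[float, float]:
    """(R^2, RMSE) of the model `p` against the series.

    R^2 = 1 - SSR/SStot with SStot about the mean mass; RMSE = sqrt(SSR/n)
    in micrograms. For a constant series SStot = 0 and R^2 is returned as
    NaN (flagged missing).
    """
    fitted = mass_released(series.times, p)
    resid = series.masses - fitted
    ssr = float(resid @ resid)
    sstot = float(((series.masses - series.masses.mean()) ** 2).sum())
    r2 = 1.0 - ssr / sstot if sstot > 0 else float("nan")
    return r2, float(np.sqrt(ssr / len(series)))


def brute_force_fit(
    series: ReleaseSeries,
    m_inf_grid: Sequence[float],
    tau0_grid: Sequence[float],
    sigma_grid: Sequence[float],
) -> KineticParams:
    """Exhaustive SSR minimum over a parameter grid (test oracle).

    Enumerates every (m_inf, tau0, sigma) triple on the grid and returns the
    one with the smallest sum of squared residuals. Intended as an
    independent check on the LM optimizer at small n, never for production
    fitting.
    """
    if len(series) > 100:
        raise ValueError("brute force is restricted to small series (n <= 100)")
    mg = np.asarray(m_inf_grid, dtype=float)
    tg = np.asarray(tau0_grid, dtype=float)
    sg = np.asarray(sigma_grid, dtype=float)
    if mg.size == 0 or tg.size == 0 or sg.size == 0:
        raise ValueError("empty parameter grid")
    t = series.times
    pos = t > 0
    logt = np.log(np.where(pos, t, 1.0))
    # u[tau, sigma, time]
    expo = sg[None, :, None] * (logt[None, None, :] - np.log(tg)[:, None, None])
    u = np.where(pos[None, None, :], np.exp(np.clip(expo, -745.0, 709.0)), 0.0)
    chi_grid = -np.expm1(-u)
    fitted = mg[:, None, None, None] * chi_grid[None, :, :, :]
    ssr = ((series.masses[None, None, None, :] - fitted) ** 2).sum(axis=-1)
    i, j, k = np.unravel_index(np.argmin(ssr), ssr.shape)
    return KineticParams(float(mg[i]), float(tg[j]), float(sg[k]))


def fit_report(result: FitResult) -> str:
    """Human-readable fit summary."""
    names = ("m_inf [ug]", "tau0 [h]", "sigma [-]")
    values = result.params.as_array()
    lines = ["parameter        value        stderr"]
    for name, v, se in zip(names, values, result.stderr):
        lines.append(f"{name:<14} {v:>12.6g} {se:>10.3g}")
    lines += [
        f"R^2:             {result.r_squared:.6f}",
        f"RMSE:            {result.rmse:.6g} ug "
        f"({result.rmse_normalized:.6g} on the chi scale)",
        f"iterations:      {result.n_iter}",
        f"converged:       {result.converged} ({result.message})",
        "covariance (m_inf, tau0, sigma):",
    ]
    for row in result.covariance:
        lines.append("  " + "  ".join(f"{v: .4e}" for v in row))
    return "\n".join(lines)
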