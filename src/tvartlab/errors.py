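"""Analytic Ornstein-Uhlenbeck error law and delay sweeps.

Linearizing the model about a stable fixed point x0 gives a multivariate
OU process dx~ = J x~ dt + sigma dW whose conditional covariance over a
horizon dt is sigma^2 * int_0^dt exp(J s) exp(J^T s) ds (Ito isometry).
Its trace gives the prediction MSE

    MSE(dt) = -(sigma^2 / 2) * sum_i (1/lambda_i) * (1 - exp(2 lambda_i dt)),

and with a single mean eigenvalue lambda_bar the per-dimension form

    MSE(dt) ~= -(sigma^2 / (2 lambda_bar)) * (1 - exp(2 lambda_bar dt)).

The module pools Jacobian eigenvalues over the stable fixed points,
sweeps full-rank TVART fits over prediction delays, and fits the
exponential law (or a linear trend, whichever scores higher) to the
measured error curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad_vec
from scipy.linalg import expm
from scipy.optimize import curve_fit

from .attractors import AttractorSet
from .tvart import TVARTConfig, build_windows, fit_tvart, full_rank

__all__ = [
    "EigenSummary",
    "DelaySweepResult",
    "pool_eigenvalues",
    "ou_conditional_covariance",
    "theoretical_mse",
    "mean_eigenvalue_mse",
    "delay_sweep",
    "fit_error_curve",
    "DEFAULT_DELAYS",
]

# delays (in samples) used for the standard sweeps
DEFAULT_DELAYS = (1, 6, 11, 16, 21, 26, 31)


@dataclass
class EigenSummary:
    """Pooled Jacobian spectra over fixed points."""

    eigenvalues: np.ndarray  # complex, pooled over fixed points
    lambda_bar: float  # mean of real parts (1/s)
    lambda_min: float
    lambda_max: float


@dataclass
class DelaySweepResult:
    """Per-delay TVART prediction error and the fitted error law."""

    delays_samples: np.ndarray
    delays_seconds: np.ndarray
    mse: np.ndarray
    fit_amplitude: float = float("nan")
    fit_lambda: float = float("nan")
    fit_r2: float = float("nan")
    model_choice: str = ""


def pool_eigenvalues(attractors: AttractorSet, stable_only: bool = True) -> EigenSummary:
    """Pool Jacobian eigenvalues over (by default, stable) fixed points;
    summary statistics use the real parts."""
    pts = attractors.stable_points if stable_only else attractors.points
    if not pts:
        raise ValueError("no fixed points to pool")
    eigs = np.concatenate([p.eigenvalues for p in pts])
    re = eigs.real
    return EigenSummary(eigs, float(re.mean()), float(re.min()), float(re.max()))


def ou_conditional_covariance(J: np.ndarray, sigma: float, dt: float) -> np.ndarray:
    """Conditional covariance sigma^2 * int_0^dt e^{Js} e^{J^T s} ds.

    Closed form through the unitary eigendecomposition when J is normal;
    adaptive quadrature with matrix exponentials otherwise.  Always
    symmetric positive semidefinite.
    """
    J = np.asarray(J, dtype=float)
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return np.zeros_like(J)
    if np.allclose(J @ J.T, J.T @ J, atol=1e-10 * max(1.0, np.abs(J).max()) ** 2):
        lam, V = np.linalg.eig(J)
        two_re = 2.0 * lam.real
        with np.errstate(divide="ignore", invalid="ignore"):
            diag = np.where(
                np.abs(two_re) < 1e-14, dt, np.expm1(two_re * dt) / np.where(np.abs(two_re) < 1e-14, 1.0, two_re)
            )
        cov = (V * diag) @ V.conj().T
        cov = sigma**2 * cov.real
    else:
        integrand = lambda s: expm(J * s) @ expm(J.T * s)
        val, err = quad_vec(integrand, 0.0, dt, epsabs=1e-10, epsrel=1e-10, norm="max")
        if not np.all(np.isfinite(val)):
            raise RuntimeError(f"quadrature failed (error estimate {err})")
        cov = sigma**2 * val
    return 0.5 * (cov + cov.T)


def theoretical_mse(eigenvalues, sigma: float, dt) -> np.ndarray | float:
    """Trace form of the OU prediction error,

        -(sigma^2/2) * sum_i (1/lambda_i) * (1 - exp(2 lambda_i dt)),

    evaluated with the real parts of ``eigenvalues``.  ``dt`` may be a
    scalar or an array of horizons (seconds).
    """
    if isinstance(eigenvalues, EigenSummary):
        lam = eigenvalues.eigenvalues.real
    else:
        lam = np.real(np.asarray(eigenvalues, dtype=complex))
    dt_arr = np.asarray(dt, dtype=float)
    terms = -(sigma**2 / 2.0) * (1.0 / lam) * (1.0 - np.exp(2.0 * lam * dt_arr[..., None]))
    out = terms.sum(axis=-1)
    return float(out) if np.isscalar(dt) else out


def mean_eigenvalue_mse(lambda_bar: float, sigma: float, dt) -> np.ndarray | float:
    """Single-eigenvalue (per-dimension) form of the error law."""
    dt_arr = np.asarray(dt, dtype=float)
    out = -(sigma**2 / (2.0 * lambda_bar)) * (1.0 - np.exp(2.0 * lambda_bar * dt_arr))
    return float(out) if np.isscalar(dt) else out


def delay_sweep(
    traj,
    delays=DEFAULT_DELAYS,
    config: TVARTConfig | None = None,
) -> DelaySweepResult:
    """Fit one full-rank TVART model per prediction delay and record the
    per-dimension (normalized) MSE."""
    N = traj.states.shape[1]
    base = config if config is not None else TVARTConfig(window_M=100, beta=0.5, eta=0.5)
    base = base.with_(rank_R=full_rank(N))
    delays = np.asarray(delays, dtype=int)
    if np.any(np.diff(delays) <= 0):
        raise ValueError("delays must be strictly increasing")
    mses = []
    for d in delays:
        data = build_windows(traj, base.window_M, int(d))
        try:
            fit = fit_tvart(data, base.with_(delay_steps=int(d)))
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"TVART fit failed at delay {d}") from exc
        mses.append(fit.mse)
    seconds = delays * traj.sampling_period
    return DelaySweepResult(delays, seconds, np.asarray(mses))


def fit_error_curve(delays_seconds, mse) -> dict:
    """Fit mse(dt) = c*(1 - exp(2*lambda*dt)) (c > 0, lambda < 0) by
    nonlinear least squares, and an ordinary linear trend; keep whichever
    explains more variance.

    Returns amplitude, lambda (nan for the linear choice), r2 and
    model_choice; falls back to the linear fit if the optimizer fails.
    """
    dt = np.asarray(delays_seconds, dtype=float)
    y = np.asarray(mse, dtype=float)
    if len(dt) < 4:
        raise ValueError("need at least 4 delay points")

    def law(t, c, lam):
        return c * (1.0 - np.exp(2.0 * lam * t))

    sst = float(np.sum((y - y.mean()) ** 2))

    def r2_of(pred):
        return 1.0 - float(np.sum((y - pred) ** 2)) / sst if sst > 0 else 1.0

    slope, intercept = np.polyfit(dt, y, 1)
    lin_r2 = r2_of(slope * dt + intercept)

    exp_ok = True
    try:
        lam0 = -1.0 / max(dt.mean(), 1e-12)
        popt, _ = curve_fit(
            law, dt, y, p0=[max(y.max(), 1e-12), lam0],
            bounds=([1e-300, -np.inf], [np.inf, -1e-300]), maxfev=20000,
        )
        exp_r2 = r2_of(law(dt, *popt))
    except (RuntimeError, ValueError):
        exp_ok = False
        exp_r2 = -np.inf

    if exp_ok and exp_r2 >= lin_r2:
        return {
            "amplitude": float(popt[0]),
            "lambda": float(popt[1]),
            "r2": float(exp_r2),
            "model_choice": "exponential",
            "fallback": False,
        }
    return {
        "amplitude": float(slope),
        "lambda": float("nan"),
        "r2": float(lin_r2),
        "model_choice": "linear",
        "fallback": not exp_ok,
    }
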