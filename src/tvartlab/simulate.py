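"""Stochastic simulation of the mean-field model.

Trajectories are integrated with the stochastic Heun predictor-corrector
scheme (second order for the deterministic part; for additive noise the
Ito and Stratonovich interpretations coincide).  Both predictor and
corrector share the same Wiener increment, drawn independently per
population with common amplitude ``sigma``:

    S~   = S + f(S) dt + sigma dW
    S(+) = S + (f(S) + f(S~)) dt / 2 + sigma dW,   dW ~ N(0, dt I).

Output is downsampled to the analysis sampling period (default 2 ms for
two-population runs, against an integration step of 0.1 ms) and the
burn-in, if any, is discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _kernels
from .model import ModelParameters, input_coupling_matrix

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "DivergenceError",
    "simulate_heun",
    "simulate_linear_heun",
    "downsample",
    "surrogate_connectivity",
    "write_trajectory",
    "read_trajectory",
    "read_connectivity",
    "write_connectivity",
]

_CHUNK_STEPS = 200_000


class DivergenceError(RuntimeError):
    """Raised when the integrated state leaves the |S| <= 10 guard box."""


@dataclass(frozen=True)
class SimulationSettings:
    """Integration and sampling controls.

    ``downsample_period`` must be an integer multiple of the integration
    step ``dt_int``; ``initial_state`` is either a state vector or the
    string ``"random-uniform"`` (uniform in [0, 1]^N from the run seed).
    """

    dt_int: float = 1e-4
    duration: float = 120.0
    burn_in: float = 0.0
    downsample_period: float = 2e-3
    seed: int = 0
    initial_state: object = "random-uniform"

    def __post_init__(self) -> None:
        if self.dt_int <= 0:
            raise ValueError("dt_int must be positive")
        if self.burn_in < 0 or self.burn_in >= self.duration:
            raise ValueError("burn_in must lie in [0, duration)")
        stride = self.downsample_period / self.dt_int
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError("downsample_period must be an integer multiple of dt_int")

    @property
    def stride(self) -> int:
        return int(round(self.downsample_period / self.dt_int))

    @property
    def n_samples(self) -> int:
        return int(np.floor((self.duration - self.burn_in) / self.downsample_period))

    def with_(self, **kwargs) -> "SimulationSettings":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        init = self.initial_state
        if isinstance(init, np.ndarray):
            init = init.tolist()
        return {
            "dt_int": self.dt_int,
            "duration": self.duration,
            "burn_in": self.burn_in,
            "downsample_period": self.downsample_period,
            "seed": self.seed,
            "initial_state": init,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSettings":
        d = dict(d)
        if isinstance(d.get("initial_state"), list):
            d["initial_state"] = np.asarray(d["initial_state"], dtype=float)
        return cls(**d)


@dataclass
class Trajectory:
    """Uniformly sampled multivariate gating time series."""

    states: np.ndarray  # (n_samples, N)
    sampling_period: float
    params: ModelParameters | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_populations(self) -> int:
        return self.states.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_period


def _resolve_initial_state(settings: SimulationSettings, N: int, rng: np.random.Generator):
    init = settings.initial_state
    if isinstance(init, str):
        if init != "random-uniform":
            raise ValueError(f"unknown initial_state preset {init!r}")
        return rng.uniform(0.0, 1.0, size=N)
    init = np.asarray(init, dtype=float)
    if init.shape != (N,):
        raise ValueError(f"initial_state must have shape ({N},)")
    return init.copy()


def _run_chunked(step_fn, S, n_total_steps, burn_steps, stride, out, amp, N, rng):
    """Drive a compiled chunk kernel through burn-in and recording phases."""
    n_written = 0
    phase = 0
    done = 0
    while done < n_total_steps:
        n = min(_CHUNK_STEPS, n_total_steps - done)
        dW = rng.standard_normal((n, N)) * amp
        if done + n <= burn_steps:
            # burn-in only: record nothing
            _, _, bad = step_fn(S, dW, phase, np.empty((0, N)), 0)
        elif done >= burn_steps:
            phase, n_written, bad = step_fn(S, dW, phase, out, n_written)
        else:
            split = burn_steps - done
            _, _, bad = step_fn(S, dW[:split], 0, np.empty((0, N)), 0)
            if bad < 0:
                phase, n_written, bad = step_fn(S, dW[split:], 0, out, n_written)
                if bad >= 0:
                    bad += split
        if bad >= 0:
            raise DivergenceError(
                f"state diverged (|S| > guard) at integration step {done + bad}"
            )
        done += n
    # state at the final step boundary, if the grid lands there
    if phase == 0 and n_written < out.shape[0]:
        out[n_written] = S
        n_written += 1
    return n_written


def simulate_heun(params: ModelParameters, settings: SimulationSettings) -> Trajectory:
    """Integrate the mean-field SDE and return the downsampled trajectory.

    Bit-reproducible for a fixed seed.  Raises :class:`DivergenceError`
    (naming the step) if any |S_i| exceeds 10.
    """
    N = params.n_populations
    rng = np.random.default_rng(settings.seed)
    S = _resolve_initial_state(settings, N, rng)
    K = input_coupling_matrix(params)
    stride = settings.stride
    n_total = int(round(settings.duration / settings.dt_int))
    burn_steps = int(round(settings.burn_in / settings.dt_int))
    out = np.empty((settings.n_samples, N))
    amp = params.sigma * np.sqrt(settings.dt_int)

    def step(Sv, dW, phase, buf, n_written):
        return _kernels.heun_chunk(
            Sv, K, params.I0, params.tau_s, params.gamma, params.a, params.b,
            params.d, dW, settings.dt_int, stride, phase, buf, n_written,
        )

    n_written = _run_chunked(step, S, n_total, burn_steps, stride, out, amp, N, rng)
    if n_written < out.shape[0]:  # pragma: no cover - defensive
        out = out[:n_written]
    return Trajectory(out, settings.downsample_period, params, settings.seed)


def simulate_linear_heun(A: np.ndarray, sigma: float, settings: SimulationSettings) -> Trajectory:
    """Integrate the linear test SDE dS/dt = A@S + sigma dW/dt.

    Same stepping, sampling and seeding scheme as :func:`simulate_heun`;
    used to validate the integrator against the analytic
    Ornstein-Uhlenbeck conditional covariance.
    """
    A = np.asarray(A, dtype=float)
    N = A.shape[0]
    rng = np.random.default_rng(settings.seed)
    S = _resolve_initial_state(settings, N, rng)
    stride = settings.stride
    n_total = int(round(settings.duration / settings.dt_int))
    burn_steps = int(round(settings.burn_in / settings.dt_int))
    out = np.empty((settings.n_samples, N))
    amp = sigma * np.sqrt(settings.dt_int)

    def step(Sv, dW, phase, buf, n_written):
        return _kernels.heun_linear_chunk(Sv, A, dW, settings.dt_int, stride, phase, buf, n_written)

    n_written = _run_chunked(step, S, n_total, burn_steps, stride, out, amp, N, rng)
    if n_written < out.shape[0]:  # pragma: no cover - defensive
        out = out[:n_written]
    return Trajectory(out, settings.downsample_period, None, settings.seed)


def downsample(traj: Trajectory, stride: int) -> Trajectory:
    """Keep every ``stride``-th sample (starting at index 0)."""
    if not (isinstance(stride, (int, np.integer)) and stride >= 1):
        raise ValueError("stride must be a positive integer")
    return Trajectory(
        traj.states[::stride].copy(),
        traj.sampling_period * stride,
        traj.params,
        traj.seed,
    )


def surrogate_connectivity(N: int, density: float = 0.3, seed: int = 0) -> np.ndarray:
    """Random symmetric surrogate connectome.

    Zero diagonal, nonnegative weights, expected off-diagonal fill equal
    to ``density``, scaled so row sums are O(1).  A stand-in for an
    empirical structural connectivity matrix when none is supplied.
    """
    if N < 2:
        raise ValueError("need N >= 2")
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(N, k=1)
    present = rng.random(len(iu[0])) < density
    weights = rng.uniform(0.5, 1.5, size=len(iu[0])) * present
    C = np.zeros((N, N))
    C[iu] = weights
    C = C + C.T
    mean_row = C.sum(axis=1).mean()
    if mean_row > 0:
        C = C / mean_row
    return C


# ---------------------------------------------------------------------------
# plain-text IO


def write_connectivity(path, C: np.ndarray) -> None:
    np.savetxt(path, np.asarray(C, float), delimiter=",")


def read_connectivity(path) -> np.ndarray:
    C = np.loadtxt(path, delimiter=",", ndmin=2)
    return np.asarray(C, dtype=float)


def write_trajectory(path, traj: Trajectory, settings: SimulationSettings | None = None) -> None:
    """CSV with a pop_i column per population plus a JSON sidecar."""
    path = Path(path)
    header = ",".join(f"pop_{i}" for i in range(traj.n_populations))
    np.savetxt(path, traj.states, delimiter=",", header=header, comments="")
    meta = {
        "sampling_period": traj.sampling_period,
        "seed": traj.seed,
        "params": traj.params.to_dict() if traj.params is not None else None,
        "settings": settings.to_dict() if settings is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    states = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    params = ModelParameters.from_dict(meta["params"]) if meta.get("params") else None
    return Trajectory(states, meta["sampling_period"], params, meta.get("seed"))
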