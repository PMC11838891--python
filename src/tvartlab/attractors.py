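"""Fixed-point landscape of the mean-field model.

Stable equilibria are located by noiseless integration from Latin
hypercube starting points, refined by a damped Newton root solve with a
central-difference Jacobian, deduplicated, and classified by the
eigenvalues of the analytic Jacobian.  Trajectory samples and analysis
windows are labeled by the nearest stable fixed point, which gives the
ground-truth regime sequence against which clustering is scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import qmc

from . import _kernels
from .model import (
    ModelParameters,
    drift_field,
    input_coupling_matrix,
    transfer_rate,
    transfer_rate_derivative,
)
from .simulate import Trajectory

__all__ = [
    "FixedPoint",
    "AttractorSet",
    "analytic_jacobian",
    "find_fixed_points",
    "landscape_sweep",
    "label_by_nearest_attractor",
    "window_attractor_indices",
    "mean_transition_time",
    "save_attractor_set",
    "load_attractor_set",
]

# max|dS/dt| below which noiseless integration counts as converged (1/s)
CONVERGENCE_TOL = 1e-6
# max|dS/dt| required of a refined root
REFINED_TOL = 1e-8


@dataclass(frozen=True)
class FixedPoint:
    """A refined equilibrium S* with its local linearization."""

    location: np.ndarray
    eigenvalues: np.ndarray  # complex spectrum of the Jacobian (1/s)
    stable: bool
    residual: float  # max|drift| at location


@dataclass
class AttractorSet:
    points: list
    dedup_tolerance: float
    params: ModelParameters
    n_seeds: int

    @property
    def stable_points(self) -> list:
        return [p for p in self.points if p.stable]

    @property
    def n_stable(self) -> int:
        return len(self.stable_points)

    def stable_locations(self) -> np.ndarray:
        return np.array([p.location for p in self.stable_points])


def analytic_jacobian(params: ModelParameters, S: np.ndarray) -> np.ndarray:
    """Exact Jacobian dF/dS (1/s) of the drift at state S.

    J_ij = delta_ij * (-1/tau_s - gamma*R_i) + gamma*(1-S_i)*R'(x_i)*K_ij
    with K = J_N*(w I + G C) and R' the input-derivative of the firing
    rate (limit value a/2 at the removable singularity a*x = b).
    """
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("state must be finite")
    K = input_coupling_matrix(params)
    x = K @ S + params.I0
    R = transfer_rate(x, params)
    dR = transfer_rate_derivative(x, params)
    J = params.gamma * (1.0 - S)[:, None] * dR[:, None] * K
    J[np.diag_indices_from(J)] += -1.0 / params.tau_s - params.gamma * R
    return J


def _numerical_jacobian(params: ModelParameters, S: np.ndarray, h: float = 1e-6) -> np.ndarray:
    N = len(S)
    J = np.empty((N, N))
    for j in range(N):
        e = np.zeros(N)
        e[j] = h
        J[:, j] = (drift_field(S + e, params) - drift_field(S - e, params)) / (2 * h)
    return J


def _damped_newton(params: ModelParameters, S0: np.ndarray, max_iter: int = 60) -> np.ndarray | None:
    """Refine a root of the drift; returns None on failure."""
    S = S0.copy()
    f = drift_field(S, params)
    for _ in range(max_iter):
        if np.max(np.abs(f)) < REFINED_TOL:
            return S
        J = _numerical_jacobian(params, S)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(30):
            S_new = S + lam * step
            f_new = drift_field(S_new, params)
            if np.max(np.abs(f_new)) < np.max(np.abs(f)):
                S, f = S_new, f_new
                break
            lam *= 0.5
        else:
            return None
    return S if np.max(np.abs(f)) < REFINED_TOL else None


def find_fixed_points(
    params: ModelParameters,
    n_seeds: int = 40,
    seed: int = 0,
    dedup_tolerance: float = 1e-4,
    integration_dt: float = 1e-3,
    max_time: float = 200.0,
) -> AttractorSet:
    """Enumerate fixed points from Latin hypercube starts in [0, 1]^N.

    Each start is integrated without noise until max|dS/dt| falls below
    the convergence tolerance, then refined by damped Newton with a
    central-difference Jacobian.  Roots closer than ``dedup_tolerance``
    (Euclidean) are merged; unstable roots reached by Newton from
    non-converged starts are kept but flagged.
    """
    N = params.n_populations
    sampler = qmc.LatinHypercube(d=N, seed=seed)
    starts = sampler.random(n_seeds)
    K = input_coupling_matrix(params)
    max_steps = int(max_time / integration_dt)

    roots: list[np.ndarray] = []
    for S0 in starts:
        S = S0.copy()
        converged, _ = _kernels.integrate_to_equilibrium(
            S, K, params.I0, params.tau_s, params.gamma, params.a, params.b,
            params.d, integration_dt, CONVERGENCE_TOL, max_steps, 100,
        )
        refined = _damped_newton(params, S)
        if refined is not None:
            roots.append(refined)

    # deduplicate by Euclidean distance
    unique: list[np.ndarray] = []
    for r in roots:
        if not any(np.linalg.norm(r - u) < dedup_tolerance for u in unique):
            unique.append(r)
    if not unique:
        raise RuntimeError(
            "no fixed points converged; increase n_seeds or max_time"
        )

    points = []
    for S_star in unique:
        J = analytic_jacobian(params, S_star)
        eigs = np.linalg.eigvals(J)
        points.append(
            FixedPoint(
                location=S_star,
                eigenvalues=eigs,
                stable=bool(np.all(eigs.real < 0)),
                residual=float(np.max(np.abs(drift_field(S_star, params)))),
            )
        )
    # deterministic ordering: by location, lexicographic
    points.sort(key=lambda p: tuple(p.location))
    return AttractorSet(points, dedup_tolerance, params, n_seeds)


def landscape_sweep(
    params_template: ModelParameters,
    G_values,
    n_seeds: int = 40,
    seed: int = 0,
) -> list[dict]:
    """Fixed-point census as a function of the global coupling G.

    For each G: the number of stable points, mean and std over attractors
    of the attractor-mean activity, and the per-population std across
    attractors ordered by total incoming connection strength.
    """
    records = []
    in_strength = np.asarray(params_template.C).sum(axis=1)
    order = np.argsort(in_strength)
    for G in G_values:
        if not np.isfinite(G) or G < 0:
            raise ValueError(f"invalid coupling value G={G}")
        p = params_template.with_(G=float(G))
        try:
            aset = find_fixed_points(p, n_seeds=n_seeds, seed=seed)
        except RuntimeError as exc:
            raise RuntimeError(f"fixed-point search failed at G={G}") from exc
        locs = aset.stable_locations()
        mean_act = locs.mean(axis=1)  # per-attractor mean activity
        per_pop_std = locs.std(axis=0) if len(locs) > 1 else np.zeros(locs.shape[1])
        records.append(
            {
                "G": float(G),
                "n_stable": aset.n_stable,
                "mean_activity": float(mean_act.mean()),
                "std_activity": float(mean_act.std()),
                "per_population_std_by_in_strength": per_pop_std[order],
            }
        )
    return records


def label_by_nearest_attractor(traj: Trajectory | np.ndarray, attractors: AttractorSet) -> np.ndarray:
    """Per-sample index of the nearest stable fixed point (Euclidean).

    Ties resolve to the lowest attractor index.
    """
    locs = attractors.stable_locations()
    if len(locs) == 0:
        raise ValueError("attractor set contains no stable points")
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj)
    d = np.linalg.norm(states[:, None, :] - locs[None, :, :], axis=2)
    return np.argmin(d, axis=1)


def window_attractor_indices(
    traj: Trajectory | np.ndarray, attractors: AttractorSet, window_M: int, n_windows: int | None = None
) -> np.ndarray:
    """Per-window attractor index: the attractor closest on average
    over the window's samples (ties to the lowest index)."""
    locs = attractors.stable_locations()
    if len(locs) == 0:
        raise ValueError("attractor set contains no stable points")
    states = traj.states if isinstance(traj, Trajectory) else np.asarray(traj)
    T = states.shape[0] // window_M if n_windows is None else n_windows
    idx = np.empty(T, dtype=int)
    for k in range(T):
        block = states[k * window_M : (k + 1) * window_M]
        d = np.linalg.norm(block[:, None, :] - locs[None, :, :], axis=2)
        idx[k] = int(np.argmin(d.mean(axis=0)))
    return idx


def mean_transition_time(labels: np.ndarray) -> tuple[float, int]:
    """Mean inter-transition interval (in samples) and transition count.

    A transition occurs where consecutive labels differ; the interval is
    the span between the first and last transition divided by count-1.
    With fewer than two transitions the interval is infinite.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    steps = np.flatnonzero(np.diff(labels) != 0) + 1
    count = len(steps)
    if count < 2:
        return float("inf"), count
    return float((steps[-1] - steps[0]) / (count - 1)), count


def save_attractor_set(path, aset: AttractorSet, seed: int | None = None) -> None:
    payload = {
        "dedup_tolerance": aset.dedup_tolerance,
        "n_seeds": aset.n_seeds,
        "seed": seed,
        "params": aset.params.to_dict(),
        "points": [
            {
                "location": p.location.tolist(),
                "eigenvalues_re": p.eigenvalues.real.tolist(),
                "eigenvalues_im": p.eigenvalues.imag.tolist(),
                "stable": p.stable,
                "residual": p.residual,
            }
            for p in aset.points
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_attractor_set(path) -> AttractorSet:
    d = json.loads(Path(path).read_text())
    points = [
        FixedPoint(
            location=np.asarray(p["location"]),
            eigenvalues=np.asarray(p["eigenvalues_re"]) + 1j * np.asarray(p["eigenvalues_im"]),
            stable=bool(p["stable"]),
            residual=float(p["residual"]),
        )
        for p in d["points"]
    ]
    return AttractorSet(points, d["dedup_tolerance"], ModelParameters.from_dict(d["params"]), d["n_seeds"])
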