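"""Time-varying autoregression with low-rank tensors (TVART).

The time series is split into T non-overlapping windows of M samples.
Window k is modeled by an affine autoregression at prediction delay
``delta`` (in samples):

    x(t + delta) ~= A_k x(t) + b_k,

and the stack of system matrices is constrained to a rank-R canonical
polyadic (CP) decomposition

    [A_k | b_k] = U1 @ diag(u3_k) @ U2.T,

with shared left/right spatial modes U1 (N x R), U2 ((N+1) x R; the last
row carries the offsets b_k through a constant-1 row appended to the
predictors) and per-window temporal modes u3_k (rows of U3, T x R).
The factors minimize the regularized cost

    C = 1/2 sum_k ||Y_k - A_k X_k||_F^2
        + 1/(2 eta) (||U1||_F^2 + ||U2||_F^2 + ||U3||_F^2)
        + beta * Rg(U3),

where Rg is either a spline penalty (squared 2-norm of second
differences of the temporal modes) or a total-variation penalty (1-norm
of first differences, handled by iteratively reweighted least squares
with epsilon-smoothing).  Decreasing eta or increasing beta strengthens
the regularization.  Optimization is block-coordinate (alternating
ridge least squares over U1, U2, U3), which makes the cost trace
non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .simulate import Trajectory

__all__ = [
    "TVARTConfig",
    "WindowedData",
    "TVARTFit",
    "build_windows",
    "fit_tvart",
    "reconstruct_system_matrix",
    "predict_and_score",
    "full_rank",
    "save_fit",
    "load_fit",
    "export_temporal_modes",
]

_TV_EPS = 1e-6


@dataclass(frozen=True)
class TVARTConfig:
    """Hyperparameters of a TVART fit.

    ``eta`` is the inverse Tikhonov weight (the ridge coefficient is
    1/(2*eta), so smaller eta regularizes harder); ``beta`` weights the
    temporal penalty on U3.
    """

    window_M: int = 100
    rank_R: int = 2
    delay_steps: int = 1
    eta: float = 0.5
    beta: float = 0.5
    regularization: str = "spline"
    max_iter: int = 60
    rel_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_M < 2:
            raise ValueError("window_M must be >= 2")
        if self.rank_R < 1:
            raise ValueError("rank_R must be >= 1")
        if self.delay_steps < 1:
            raise ValueError("delay_steps must be >= 1")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.regularization not in ("spline", "total_variation"):
            raise ValueError("regularization must be 'spline' or 'total_variation'")

    def with_(self, **kwargs) -> "TVARTConfig":
        return replace(self, **kwargs)


@dataclass
class WindowedData:
    """Per-window predictor/response blocks.

    ``X``: (T, N+1, M) predictors, last row constant 1; ``Y``: (T, N, M)
    responses shifted by ``delay_steps``.
    """

    X: np.ndarray
    Y: np.ndarray
    delay_steps: int
    sampling_period: float | None = None

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def N(self) -> int:
        return self.Y.shape[1]

    @property
    def M(self) -> int:
        return self.X.shape[2]


@dataclass
class TVARTFit:
    """CP factors and fit diagnostics."""

    U1: np.ndarray  # (N, R) left spatial modes
    U2: np.ndarray  # (N+1, R) right spatial modes (last row: offsets)
    U3: np.ndarray  # (T, R) temporal modes
    config: TVARTConfig
    cost_trace: list = field(default_factory=list)
    converged: bool = False
    mse: float = float("nan")
    r2: float = float("nan")

    @property
    def T(self) -> int:
        return self.U3.shape[0]

    @property
    def N(self) -> int:
        return self.U1.shape[0]


def full_rank(N: int) -> int:
    """The unconstrained CP rank for an N-population affine model."""
    return N + 1


def build_windows(traj: Trajectory | np.ndarray, window_M: int, delay_steps: int) -> WindowedData:
    """Split a trajectory into disjoint predictor windows with responses
    shifted by ``delay_steps`` samples.

    Window k uses predictor samples [k*M, (k+1)*M) and response samples
    [k*M + delay, (k+1)*M + delay); the trailing remainder is dropped
    and a constant-1 row is appended to the predictors.
    """
    if isinstance(traj, Trajectory):
        states, period = traj.states, traj.sampling_period
    else:
        states, period = np.asarray(traj, dtype=float), None
    n, N = states.shape
    if delay_steps < 1:
        raise ValueError("delay_steps must be >= 1")
    if n < window_M + delay_steps:
        raise ValueError(
            f"need at least window_M + delay_steps = {window_M + delay_steps} samples, got {n}"
        )
    T = (n - delay_steps) // window_M
    X = np.empty((T, N + 1, window_M))
    Y = np.empty((T, N, window_M))
    for k in range(T):
        lo = k * window_M
        X[k, :N] = states[lo : lo + window_M].T
        X[k, N] = 1.0
        Y[k] = states[lo + delay_steps : lo + delay_steps + window_M].T
    return WindowedData(X, Y, delay_steps, period)


def _penalty_matrix(U3: np.ndarray, config: TVARTConfig) -> tuple[sp.spmatrix | None, float]:
    """Sparse quadratic form Q (window-major vec) for the temporal
    penalty and its current value beta*Rg(U3).

    For total variation this is the IRLS majorizer at the current U3 of
    the epsilon-smoothed 1-norm; its exact minimization cannot increase
    the smoothed cost.
    """
    T, R = U3.shape
    beta = config.beta
    if beta == 0:
        return None, 0.0
    if config.regularization == "spline":
        if T < 3:
            return None, 0.0
        D2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(T - 2, T))
        L = (D2.T @ D2).tocsr()
        Q = 2.0 * beta * sp.kron(L, sp.identity(R), format="csr")
        val = beta * float(np.sum((D2 @ U3) ** 2))
        return Q, val
    # total variation, epsilon-smoothed
    if T < 2:
        return None, 0.0
    D1 = sp.diags([-1.0, 1.0], [0, 1], shape=(T - 1, T))
    diffs = np.diff(U3, axis=0)
    smooth = np.sqrt(diffs**2 + _TV_EPS**2)
    val = beta * float(np.sum(smooth))
    blocks = []
    for r in range(R):
        W = sp.diags(1.0 / (2.0 * smooth[:, r]))
        blocks.append((D1.T @ W @ D1).tocsr())
    # interleave per-column tridiagonal forms into window-major ordering
    Q = sp.lil_matrix((T * R, T * R))
    for r in range(R):
        Lr = blocks[r].tocoo()
        Q[Lr.row * R + r, Lr.col * R + r] = Lr.data
    return (2.0 * beta * Q.tocsr()), val


def _tv_value(U3: np.ndarray, config: TVARTConfig) -> float:
    """Current temporal-penalty value beta*Rg(U3) (smoothed for TV)."""
    if config.beta == 0:
        return 0.0
    if config.regularization == "spline":
        if U3.shape[0] < 3:
            return 0.0
        d2 = np.diff(U3, n=2, axis=0)
        return config.beta * float(np.sum(d2**2))
    if U3.shape[0] < 2:
        return 0.0
    d1 = np.diff(U3, axis=0)
    return config.beta * float(np.sum(np.sqrt(d1**2 + _TV_EPS**2)))


def _cost(Gx, YXT, yy, U1, U2, U3, config) -> float:
    """Eq-18-style regularized cost at the current factors."""
    T = Gx.shape[0]
    fit = 0.0
    for k in range(T):
        A = (U1 * U3[k]) @ U2.T
        fit += yy[k] - 2.0 * float(np.sum(A * YXT[k])) + float(np.sum((A @ Gx[k]) * A))
    ridge = (np.sum(U1**2) + np.sum(U2**2) + np.sum(U3**2)) / (2.0 * config.eta)
    return 0.5 * fit + ridge + _tv_value(U3, config)


def fit_tvart(data: WindowedData, config: TVARTConfig) -> TVARTFit:
    """Alternating ridge least squares for the CP-constrained cost.

    U1 and U2 updates are exact ridge solves; the U3 update solves the
    coupled sparse system including the temporal penalty (closed form
    for the spline penalty, one IRLS majorizer step per sweep for total
    variation).  Stops when the relative cost decrease drops below
    ``rel_tol`` or after ``max_iter`` sweeps.  Deterministic for a fixed
    config seed.
    """
    T, N, M = data.T, data.N, data.M
    R = config.rank_R
    if R > N + 1:
        raise ValueError(f"rank_R must be <= N+1 = {N + 1}")
    if T < 1:
        raise ValueError("no windows to fit")
    inv_eta = 1.0 / config.eta

    # sufficient statistics: everything the ALS needs is Gram matrices
    Gx = np.einsum("tim,tjm->tij", data.X, data.X)  # (T, N+1, N+1)
    YXT = np.einsum("tim,tjm->tij", data.Y, data.X)  # (T, N, N+1)
    yy = np.einsum("tim,tim->t", data.Y, data.Y)  # (T,)

    rng = np.random.default_rng(config.seed)
    U1 = rng.normal(0.0, 1.0 / np.sqrt(R), size=(N, R))
    U2 = rng.normal(0.0, 1.0 / np.sqrt(R), size=(N + 1, R))
    U3 = rng.normal(0.0, 1.0 / np.sqrt(R), size=(T, R))

    cost_trace = [_cost(Gx, YXT, yy, U1, U2, U3, config)]
    converged = False
    for _ in range(config.max_iter):
        # --- U1: ridge solve against Z_k = D_k U2^T X_k
        W = np.einsum("tij,ir,js->trs", Gx, U2, U2)  # U2^T Gx_k U2
        G1 = np.einsum("tr,ts,trs->rs", U3, U3, W)
        rhs1 = np.einsum("tij,jr,tr->ir", YXT, U2, U3)
        try:
            U1 = np.linalg.solve(G1 + inv_eta * np.eye(R), rhs1.T).T
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular normal equations in U1 update; increase the "
                "Tikhonov weight 1/eta (use a smaller eta)"
            ) from exc

        # --- U2: coupled ridge solve (left and right Grams differ per window)
        U1tU1 = U1.T @ U1
        Gk = U3[:, :, None] * U3[:, None, :] * U1tU1[None]
        M2 = np.einsum("tij,trs->irjs", Gx, Gk).reshape((N + 1) * R, (N + 1) * R)
        rhs2 = np.einsum("tji,jr,tr->ir", YXT, U1, U3)  # sum_k X_k Y_k^T U1 D_k
        try:
            u2 = np.linalg.solve(M2 + inv_eta * np.eye((N + 1) * R), rhs2.reshape(-1))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular normal equations in U2 update; increase the "
                "Tikhonov weight 1/eta (use a smaller eta)"
            ) from exc
        U2 = u2.reshape(N + 1, R)

        # --- scale balancing between U1 and U2 (cost can only decrease)
        n1 = np.linalg.norm(U1, axis=0)
        n2 = np.linalg.norm(U2, axis=0)
        ok = (n1 > 1e-12) & (n2 > 1e-12)
        s = np.where(ok, np.sqrt(n2 / np.maximum(n1, 1e-300)), 1.0)
        U1 = U1 * s
        U2 = U2 / s

        # --- U3: per-window Grams coupled by the temporal penalty
        W = np.einsum("tij,ir,js->trs", Gx, U2, U2)
        H = (U1.T @ U1)[None] * W  # (T, R, R) Hadamard Gram
        c = np.einsum("ir,tij,jr->tr", U1, YXT, U2)  # diag(U1^T Y X^T U2)
        Q, _ = _penalty_matrix(U3, config)
        block = sp.block_diag([H[k] for k in range(T)], format="csr")
        Msys = block + inv_eta * sp.identity(T * R, format="csr")
        if Q is not None:
            Msys = Msys + Q
        try:
            u3 = spsolve(Msys.tocsc(), c.reshape(-1))
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                "singular normal equations in U3 update; increase the "
                "Tikhonov weight 1/eta (use a smaller eta)"
            ) from exc
        U3 = u3.reshape(T, R)

        cost = _cost(Gx, YXT, yy, U1, U2, U3, config)
        prev = cost_trace[-1]
        cost_trace.append(cost)
        if prev - cost <= config.rel_tol * max(abs(prev), 1e-30):
            converged = True
            break

    # output convention: unit-norm spatial mode columns, scale in U3
    n1 = np.linalg.norm(U1, axis=0)
    n2 = np.linalg.norm(U2, axis=0)
    ok = (n1 > 1e-12) & (n2 > 1e-12)
    U3 = U3 * np.where(ok, n1 * n2, 1.0)
    U1 = U1 / np.where(ok, n1, 1.0)
    U2 = U2 / np.where(ok, n2, 1.0)

    fit = TVARTFit(U1, U2, U3, config, cost_trace, converged)
    scores = predict_and_score(fit, data)
    fit.mse = scores["mse"]
    fit.r2 = scores["r2"]
    return fit


def reconstruct_system_matrix(fit: TVARTFit, k: int) -> np.ndarray:
    """The affine model [A_k | b_k] = U1 diag(u3_k) U2^T for window k."""
    if not (0 <= k < fit.T):
        raise IndexError(f"window index {k} out of range [0, {fit.T})")
    return (fit.U1 * fit.U3[k]) @ fit.U2.T


def predict_and_score(fit: TVARTFit, data: WindowedData) -> dict:
    """Prediction error of the fitted per-window models.

    ``mse`` is the mean over all (sample, dimension) pairs of the squared
    error — i.e. already per-dimension, directly comparable to the
    per-eigenvalue analytic error law; ``normalized_mse`` is an alias.
    ``r2`` uses the total sum of squares about the per-dimension global
    response mean.
    """
    T, N, M = data.T, data.N, data.M
    sse = 0.0
    for k in range(T):
        P = (fit.U1 * fit.U3[k]) @ fit.U2.T @ data.X[k]
        sse += float(np.sum((data.Y[k] - P) ** 2))
    ybar = data.Y.mean(axis=(0, 2))  # per-dimension global mean
    sst = float(np.sum((data.Y - ybar[None, :, None]) ** 2))
    mse = sse / (T * N * M)
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -float("inf"))
    return {"mse": mse, "normalized_mse": mse, "r2": r2}


def save_fit(path, fit: TVARTFit) -> None:
    """Serialize a fit as a JSON manifest plus a float64 binary blob.

    The blob stores U1, U2, U3 concatenated column-major; the manifest
    records shapes, the config and the cost trace.
    """
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    blob = b"".join(np.asfortranarray(U).tobytes(order="F") for U in (fit.U1, fit.U2, fit.U3))
    path.with_suffix(".bin").write_bytes(blob)
    manifest = {
        "shapes": {"U1": list(fit.U1.shape), "U2": list(fit.U2.shape), "U3": list(fit.U3.shape)},
        "config": dataclasses.asdict(fit.config),
        "cost_trace": list(map(float, fit.cost_trace)),
        "converged": fit.converged,
        "mse": fit.mse,
        "r2": fit.r2,
        "dtype": "float64",
        "order": "F",
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_fit(path) -> TVARTFit:
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    blob = np.frombuffer(path.with_suffix(".bin").read_bytes(), dtype=np.float64)
    factors = []
    off = 0
    for key in ("U1", "U2", "U3"):
        shape = manifest["shapes"][key]
        n = shape[0] * shape[1]
        factors.append(blob[off : off + n].reshape(shape, order="F").copy())
        off += n
    cfg = TVARTConfig(**manifest["config"])
    fit = TVARTFit(*factors, cfg, manifest["cost_trace"], manifest["converged"])
    fit.mse, fit.r2 = manifest["mse"], manifest["r2"]
    return fit


def export_temporal_modes(path, fit: TVARTFit) -> None:
    """CSV export of U3 (one row per window) for external clustering."""
    header = ",".join(f"mode_{r}" for r in range(fit.U3.shape[1]))
    np.savetxt(path, fit.U3, delimiter=",", header=header, comments="")
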