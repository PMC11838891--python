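"""Reduced Wong-Wang mean-field model of coupled neural populations.

The state of each population is its average synaptic gating variable
``S`` (unitless fraction of open channels).  The noiseless dynamics are

    dS/dt = -S/tau_s + gamma * (1 - S) * R(x)
    R(x)  = (a*x - b) / (1 - exp(-d*(a*x - b)))
    x     = w*J_N*S + G*J_N*C@S + I0

where ``R`` is the population firing rate (Hz), ``x`` the total synaptic
input (nA) and ``C`` the structural connectivity between populations.
Depending on the local recurrence ``w``, synaptic coupling ``J_N`` and
global coupling ``G``, the system supports one or several stable
fixed-point attractors; additive white noise of amplitude ``sigma``
induces hopping between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "two_attractor_parameters",
    "four_attractor_parameters",
    "highdim_parameters",
    "transfer_rate",
    "transfer_rate_derivative",
    "drift_field",
    "input_coupling_matrix",
]


@dataclass(frozen=True, eq=False)
class ModelParameters:
    """All constants of the mean-field model plus the connectivity matrix.

    Units: ``tau_s`` s, ``a`` 1/nC, ``b`` Hz, ``d`` s, ``J_N`` nA,
    ``I0`` nA; ``gamma``, ``w``, ``G``, ``sigma`` and ``C`` are unitless.
    ``sigma`` multiplies the Wiener increment dW directly.
    """

    tau_s: float = 0.1
    gamma: float = 0.641
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    w: float = 0.9
    J_N: float = 0.2609
    G: float = 0.32
    I0: float = 0.3
    sigma: float = 0.5
    C: np.ndarray = field(default_factory=lambda: np.array([[0.0, 1.0], [1.0, 0.0]]))

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("connectivity C must be a square matrix")
        if C.shape[0] < 1:
            raise ValueError("need at least one population")
        if np.any(C < 0) or not np.all(np.isfinite(C)):
            raise ValueError("connectivity C must be finite and nonnegative")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.d <= 0:
            raise ValueError("d must be positive")
        object.__setattr__(self, "C", C)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelParameters):
            return NotImplemented
        scalars = ("tau_s", "gamma", "a", "b", "d", "w", "J_N", "G", "I0", "sigma")
        return all(getattr(self, f) == getattr(other, f) for f in scalars) and np.array_equal(
            self.C, other.C
        )

    @property
    def n_populations(self) -> int:
        return self.C.shape[0]

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "tau_s": self.tau_s,
            "gamma": self.gamma,
            "a": self.a,
            "b": self.b,
            "d": self.d,
            "w": self.w,
            "J_N": self.J_N,
            "G": self.G,
            "I0": self.I0,
            "sigma": self.sigma,
            "C": np.asarray(self.C).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        d["C"] = np.asarray(d["C"], dtype=float)
        return cls(**d)


def two_attractor_parameters(sigma: float = 0.5) -> ModelParameters:
    """Two coupled populations with two stable fixed-point attractors.

    The classic binary-choice configuration: w=0.9, J_N=0.2609 nA,
    G=0.32, I0=0.3 nA, C=[[0,1],[1,0]].
    """
    return ModelParameters(w=0.9, J_N=0.2609, G=0.32, I0=0.3, sigma=sigma)


def four_attractor_parameters(sigma: float = 0.5) -> ModelParameters:
    """Two coupled populations with four stable fixed-point attractors
    (w=1.07, J_N=0.29 nA, G=0.03, I0=0.3 nA)."""
    return ModelParameters(w=1.07, J_N=0.29, G=0.03, I0=0.3, sigma=sigma)


def highdim_parameters(C: np.ndarray, G: float = 0.08, sigma: float = 0.5) -> ModelParameters:
    """Parameters for network simulations on an N-population connectome
    (w=0.95, J_N=0.2609 nA, I0=0.32 nA)."""
    return ModelParameters(w=0.95, J_N=0.2609, G=G, I0=0.32, sigma=sigma, C=np.asarray(C, float))


# Below |d*u| = 1e-8 the sigmoid is evaluated by its series around the
# removable singularity at a*x = b.
_SERIES_CUTOFF = 1e-8


def transfer_rate(x: np.ndarray | float, params: ModelParameters) -> np.ndarray:
    """Population firing rate R(x) in Hz for synaptic input ``x`` (nA).

    R(x) = (a*x-b) / (1 - exp(-d*(a*x-b))), continuous (value 1/d) at
    a*x = b, strictly positive and monotone increasing.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("synaptic input must be finite")
    u = params.a * x - params.b
    z = params.d * u
    with np.errstate(over="ignore"):
        denom = -np.expm1(-z)
    small = np.abs(z) < _SERIES_CUTOFF
    out = np.where(small, 1.0 / params.d + u / 2.0, u / np.where(small, 1.0, denom))
    return out


def transfer_rate_derivative(x: np.ndarray | float, params: ModelParameters) -> np.ndarray:
    """dR/dx in Hz/nA, using the stable limit form 1/2 * a at a*x = b."""
    x = np.asarray(x, dtype=float)
    u = params.a * x - params.b
    z = params.d * u
    with np.errstate(over="ignore"):
        em = -np.expm1(-z)  # 1 - exp(-z)
        ez = np.exp(-z)
    small = np.abs(z) < _SERIES_CUTOFF
    safe = np.where(small, 1.0, em)
    # d/du [u / (1 - e^{-du})] = (1 - e^{-du} - d u e^{-du}) / (1 - e^{-du})^2
    dRdu = np.where(small, 0.5 + z / 6.0, (em - z * ez) / (safe * safe))
    return params.a * dRdu


def input_coupling_matrix(params: ModelParameters) -> np.ndarray:
    """The matrix K with x = K@S + I0, i.e. K = J_N*(w*I + G*C)."""
    N = params.n_populations
    return params.J_N * (params.w * np.eye(N) + params.G * params.C)


def drift_field(S: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Deterministic drift dS/dt (1/s) of the mean-field model at state S."""
    S = np.asarray(S, dtype=float)
    if S.shape[-1] != params.n_populations:
        raise ValueError(
            f"state has {S.shape[-1]} populations but C is "
            f"{params.n_populations}x{params.n_populations}"
        )
    if not np.all(np.isfinite(S)):
        raise ValueError("state must be finite")
    x = S @ input_coupling_matrix(params).T + params.I0
    R = transfer_rate(x, params)
    return -S / params.tau_s + params.gamma * (1.0 - S) * R
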