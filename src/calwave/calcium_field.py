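"""Explicit finite-difference integration of the cytosolic calcium field.

The cytosolic calcium concentration is nondimensionalized by the volume
average concentration, ``C = [Ca2+]/[Ca2+]_ave``, and evolves on a periodic
1-D grid according to

    dC/dt = D lap(C) + [(1 + v_r) * (gamma1 * N_open + gamma0)] * (1 - C)
            - p * C^2 / (C^2 + q^2)

where the bracketed term collects channel release (``N_open`` open channels
at a cluster cell) and basal ER leak, and the last term is SERCA pump efflux
with a Hill coefficient of 2.  ``p = p_hat/[Ca2+]_ave`` and
``q = q_hat/[Ca2+]_ave`` are the nondimensional pump capacity and activation
threshold.  Luminal (ER) calcium is held fixed; the (1 - C) factor comes
from eliminating it via the fixed volume average.

Integration is forward Euler with the standard 3-point Laplacian; the
diffusive stability number ``D dt/dx^2`` must stay below 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DynamicsParams",
    "GridSpec",
    "FieldState",
    "IntegrationError",
    "laplacian_periodic",
    "pump_flux",
    "reaction_term",
    "step_field",
    "basal_fixed_point",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Dynamic (field) parameters with the study's standard values.

    Attributes
    ----------
    D:
        Cytosolic calcium diffusion constant (um^2/s).
    v_r:
        ER-to-cytosol volume ratio (dimensionless).
    gamma0:
        Basal ER membrane permeability (s^-1).
    gamma1:
        Maximal flux coefficient per open channel (s^-1).
    p_hat:
        SERCA pump flux capacity (uM/s); the study varies this in
        [1.2, 3.0] uM/s.
    q_hat:
        Pump activation threshold (uM).
    ca_ave:
        Volume-average calcium concentration (uM), the control parameter
        used for nondimensionalization.
    """

    D: float = 25.0
    v_r: float = 0.185
    gamma0: float = 0.02
    gamma1: float = 9.0
    p_hat: float = 1.6
    q_hat: float = 0.01
    ca_ave: float = 1.6

    def __post_init__(self) -> None:
        for name in ("D", "v_r", "gamma0", "gamma1", "p_hat", "q_hat", "ca_ave"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def p(self) -> float:
        """Nondimensional pump capacity p_hat/ca_ave (s^-1)."""
        return self.p_hat / self.ca_ave

    @property
    def q(self) -> float:
        """Nondimensional pump threshold q_hat/ca_ave."""
        return self.q_hat / self.ca_ave


@dataclass(frozen=True)
class GridSpec:
    """Uniform periodic 1-D grid and time step.

    The defaults (dx = 0.18 um, dt = 0.0005 s, 640 cells) give a diffusive
    stability number ``D dt/dx^2 = 25 * 0.0005 / 0.18^2 = 0.386 < 0.5`` for
    the standard diffusion constant.
    """

    dx: float = 0.18
    dt: float = 0.0005
    n_x: int = 640

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.n_x < 3:
            raise ValueError("need at least 3 grid cells")

    @property
    def length(self) -> float:
        """Domain length in um."""
        return self.n_x * self.dx

    def stability_number(self, D: float) -> float:
        """Diffusive Courant number D*dt/dx^2 (must be < 0.5)."""
        return D * self.dt / self.dx ** 2

    def check_stability(self, D: float) -> None:
        s = self.stability_number(D)
        if s >= 0.5:
            raise ValueError(
                f"explicit scheme unstable: D*dt/dx^2 = {s:.3f} >= 0.5")

    def cell_centers(self) -> np.ndarray:
        """Physical coordinates (um) of the cell centers."""
        return (np.arange(self.n_x) + 0.5) * self.dx


@dataclass
class FieldState:
    """Dimensionless calcium field C on the grid at elapsed time t (s)."""

    C: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if not np.all(np.isfinite(self.C)):
            raise ValueError("field contains non-finite values")
        if np.any(self.C < 0):
            raise ValueError("field contains negative concentrations")


class IntegrationError(RuntimeError):
    """Raised when the explicit update produces invalid concentrations."""


def laplacian_periodic(C: np.ndarray, dx: float) -> np.ndarray:
    """3-point second-difference Laplacian with periodic wraparound (um^-2)."""
    C = np.asarray(C, dtype=float)
    return (np.roll(C, 1) + np.roll(C, -1) - 2.0 * C) / dx ** 2


def pump_flux(C, p: float, q: float):
    """SERCA efflux rate p*C^2/(C^2+q^2) (s^-1): Hill-2, saturating at p."""
    C2 = np.square(C)
    return p * C2 / (C2 + q * q)


def reaction_term(C, n_open, params: DynamicsParams):
    """Local (non-diffusive) rate of change of the dimensionless field.

    ``(1 + v_r) * (gamma1 * n_open + gamma0) * (1 - C) - pump_flux(C)``.
    ``n_open`` is the per-cell open-channel count (nonzero only at cluster
    cells).
    """
    release = (1.0 + params.v_r) * (params.gamma1 * np.asarray(n_open, dtype=float)
                                    + params.gamma0)
    return release * (1.0 - np.asarray(C, dtype=float)) - pump_flux(C, params.p, params.q)


def step_field(state: FieldState, n_open_map: np.ndarray,
               params: DynamicsParams, grid: GridSpec) -> FieldState:
    """One forward-Euler step of the reaction-diffusion field.

    Negative or non-finite concentrations abort the run (no silent
    clamping), since they signal an unstable or mis-parameterized scheme.
    """
    grid.check_stability(params.D)
    C = state.C
    dCdt = params.D * laplacian_periodic(C, grid.dx) + reaction_term(C, n_open_map, params)
    C_new = C + grid.dt * dCdt
    if not np.all(np.isfinite(C_new)) or np.any(C_new < 0):
        bad = np.where(~np.isfinite(C_new) | (C_new < 0))[0]
        raise IntegrationError(
            f"invalid concentration at t={state.t + grid.dt:.4f} s in cells "
            f"{bad[:5].tolist()}{'...' if bad.size > 5 else ''}; "
            "reduce dt or check parameters")
    out = FieldState.__new__(FieldState)
    out.C = C_new
    out.t = state.t + grid.dt
    return out


def basal_fixed_point(params: DynamicsParams) -> float:
    """Resting dimensionless concentration C* with all channels closed.

    Solves ``(1 + v_r) * gamma0 * (1 - C) = p C^2/(C^2 + q^2)`` by bracketed
    root finding on (0, 1).  The leak is bounded while the pump grows from
    zero, so exactly one root lies in that interval.
    """
    f = lambda C: float(reaction_term(C, 0.0, params))
    return brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-14)
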