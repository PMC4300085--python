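"""Hybrid stochastic-deterministic simulation of clustered calcium release.

Couples the Markov gating of clustered IP3R channels to the deterministic
reaction-diffusion field, one fixed time step at a time:

1. read the dimensionless field at each cluster cell and convert to uM;
2. advance every subunit of every channel by one linearized Markov step;
3. count open channels per cluster (>= 3 active subunits of 4);
4. advance the field one forward-Euler step with the per-cell open counts.

The run is recorded as an 8-bit kymograph (rows = time, columns = space)
with a linear intensity-to-concentration calibration, mimicking how
confocal linescan data are stored and analyzed.

The subunit update is vectorized over all subunits: per step one uniform
draw per subunit decides between the backward exit, the forward exit and
staying put, with linearized probabilities ``rate * dt``.  Draws are
consumed in a fixed (cluster, channel, subunit) order, so runs are
bit-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

from .calcium_field import (DynamicsParams, FieldState, GridSpec,
                            IntegrationError, basal_fixed_point,
                            laplacian_periodic, reaction_term)
from .receptor_kinetics import (ACTIVE_STATE, DEFAULT_CLUSTER_SIZE,
                                KineticParams, OPEN_THRESHOLD, SubunitState,
                                ignition_point, stationary_distribution)

__all__ = [
    "ClusterLayout",
    "TriggerSpec",
    "SimulationConfig",
    "Kymograph",
    "LayoutError",
    "build_layout",
    "apply_trigger",
    "quantize",
    "dequantize",
    "run_simulation",
]


class LayoutError(ValueError):
    """Raised for infeasible cluster layouts."""


#: default trigger hold time (s); long enough for IP3-bound subunits to
#: activate (timescale 1/(k2*amplitude) ~ 0.07 s at 0.5 uM) but short
#: against the inhibition timescale 1/(k3*amplitude) ~ 0.6 s
DEFAULT_TRIGGER_HOLD = 0.25


@dataclass(frozen=True)
class ClusterLayout:
    """Equally spaced cluster positions on the periodic grid.

    ``cluster_cells`` are grid indices; consecutive clusters are separated
    by ``round(d/dx)`` cells, and the array of clusters is centered in the
    domain so that the middle of the layout coincides with the middle of
    the x-axis (where the trigger is applied).
    """

    d: float                      # requested intercluster distance (um)
    L: float                      # domain length (um)
    cluster_cells: Tuple[int, ...]
    n_channels: int = DEFAULT_CLUSTER_SIZE
    realized_d: float = 0.0       # spacing actually laid down (um)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_cells)


def build_layout(d: float, L: float, dx: float,
                 n_channels: int = DEFAULT_CLUSTER_SIZE) -> ClusterLayout:
    """Place ``floor(L/d)`` clusters at a uniform spacing of ``round(d/dx)`` cells.

    The realized spacing differs from the requested ``d`` by less than half
    a cell.  If the rounded layout would overrun the grid (possible for
    spacings close to the cell size), the cluster count is trimmed to fit.
    """
    if d <= 0 or d >= L:
        raise LayoutError(f"need 0 < d < L, got d={d}, L={L}")
    if d < 2 * dx:
        raise LayoutError(
            f"intercluster distance d={d} um below resolvable minimum 2*dx={2 * dx} um")
    n_x = int(round(L / dx))
    spacing = int(round(d / dx))
    n_clusters = int(np.floor(L / d))
    if (n_clusters - 1) * spacing >= n_x:
        n_clusters = n_x // spacing
    span = (n_clusters - 1) * spacing
    offset = int(round((n_x - span) / 2.0))
    cells = tuple(offset + i * spacing for i in range(n_clusters))
    if len(set(cells)) != len(cells):
        raise LayoutError("cluster cells collide; increase d or refine dx")
    return ClusterLayout(d=d, L=L, cluster_cells=cells, n_channels=n_channels,
                         realized_d=spacing * dx)


@dataclass(frozen=True)
class TriggerSpec:
    """Initial calcium stimulus raising the field to ``amplitude`` uM over
    ``center +/- half_width`` um.

    With ``hold = 0`` the bump is applied once at t = 0 and immediately
    starts diffusing.  A positive ``hold`` clamps the window at the
    amplitude for that many seconds (a focal, sustained stimulus, as
    produced by localized photorelease); the receptor kinetics respond
    to a fast calcium rise much more strongly than to its stationary
    level, so a brief hold is what reliably ignites a wave.
    """

    center: float        # um
    half_width: float    # um
    amplitude: float     # uM
    hold: float = 0.0    # s


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run.

    ``record_stride`` converts integration steps to kymograph rows; the
    default 75 makes one row span 0.0375 s given dt = 0.0005 s, which is
    the row time assumed by the front-angle velocity formula.
    ``record_max`` is the concentration mapped to intensity 255.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    d: float = 2.5                      # intercluster distance (um)
    n_channels: int = DEFAULT_CLUSTER_SIZE
    duration: float = 5.0               # seconds
    seed: int = 0
    triggers: Tuple[TriggerSpec, ...] = ()
    record_stride: int = 75
    record_max: float = 3.2             # uM at intensity 255
    init: str = "primed"                # "primed" | "active" | "x000" | "stationary"
    primed_fraction: float = 0.5        # fraction of clusters starting primed
    start_at_basal: bool = True         # field starts at C* (else at 0);
                                        # ignored by init="active"

    def __post_init__(self) -> None:
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        n_steps = self.duration / self.grid.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("duration must be an integer number of time steps")
        if self.init not in ("primed", "active", "x000", "stationary"):
            raise ValueError(
                "init must be 'primed', 'active', 'x000' or 'stationary'")
        if not (0.0 <= self.primed_fraction <= 1.0):
            raise ValueError("primed_fraction must lie in [0, 1]")
        if self.triggers == ():
            # default: a small held bump just above the event threshold,
            # centered on the domain
            self.triggers = (TriggerSpec(center=self.grid.length / 2.0,
                                         half_width=0.5, amplitude=0.5,
                                         hold=DEFAULT_TRIGGER_HOLD),)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.grid.dt))

    def layout(self) -> ClusterLayout:
        return build_layout(self.d, self.grid.length, self.grid.dx,
                            self.n_channels)


@dataclass
class Kymograph:
    """8-bit space x time record with linear intensity calibration.

    ``pixels[r, c]`` is the quantized concentration at row ``r`` (time
    ``r * dt_row`` seconds) and column ``c`` (position ``(c + 0.5) * dx_pixel``
    um).  Intensity 255 corresponds to ``record_max`` uM.
    """

    pixels: np.ndarray
    dx_pixel: float = 0.18      # um per column
    dt_row: float = 0.0375      # s per row
    record_max: float = 3.2     # uM at intensity 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("kymograph pixels must be 8-bit")
        if self.pixels.ndim != 2:
            raise ValueError("kymograph must be 2-D (time x space)")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def to_ca(self) -> np.ndarray:
        """Calibrated concentration image in uM."""
        return dequantize(self.pixels, self.record_max)

    # -- I/O ---------------------------------------------------------------

    def calibration_dict(self) -> Dict[str, float]:
        return {"dx_pixel_um": self.dx_pixel,
                "dt_row_s": self.dt_row,
                "record_max_uM": self.record_max}

    def save(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the image (TIFF or PNG by extension) plus a JSON sidecar
        holding the pixel calibration."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile
            tifffile.imwrite(path, self.pixels)
        else:
            import imageio.v3 as iio
            iio.imwrite(path, self.pixels)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.calibration_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path, sidecar: str | Path | None = None) -> "Kymograph":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile
            pixels = tifffile.imread(path)
        else:
            import imageio.v3 as iio
            pixels = iio.imread(path)
        pixels = np.asarray(pixels)
        if pixels.ndim == 3:  # collapse an accidental color axis
            pixels = pixels[..., 0]
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
        cal = json.loads(sidecar.read_text())
        return cls(pixels=pixels.astype(np.uint8),
                   dx_pixel=cal["dx_pixel_um"],
                   dt_row=cal["dt_row_s"],
                   record_max=cal["record_max_uM"])


def quantize(ca_row: np.ndarray, record_max: float) -> np.ndarray:
    """Map concentrations (uM) to 8-bit intensities, saturating at record_max."""
    if record_max <= 0:
        raise ValueError("record_max must be positive")
    ca = np.minimum(np.asarray(ca_row, dtype=float), record_max)
    return np.round(255.0 * ca / record_max).astype(np.uint8)


def dequantize(pixels: np.ndarray, record_max: float) -> np.ndarray:
    """Inverse of :func:`quantize` up to half a quantization step."""
    return np.asarray(pixels, dtype=float) * (record_max / 255.0)


def apply_trigger(state: FieldState, trigger: TriggerSpec, grid: GridSpec,
                  ca_ave: float) -> FieldState:
    """Raise the field to the trigger amplitude over the trigger window.

    Cells whose centers fall within ``center +/- half_width`` are set to
    ``amplitude/ca_ave`` (dimensionless); the rest of the field is
    untouched.  Meant to be applied once, at t = 0.
    """
    x = grid.cell_centers()
    mask = np.abs(x - trigger.center) <= trigger.half_width
    if not mask.any():
        raise ValueError("trigger window does not cover any grid cell")
    C = state.C.copy()
    C[mask] = trigger.amplitude / ca_ave
    return FieldState(C=C, t=state.t)


# ---------------------------------------------------------------------------
# vectorized Markov update
# ---------------------------------------------------------------------------

def _rate_tables(kin: KineticParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state forward/backward rate coefficients for the linear chain.

    forward rate = fwd_const[state] + fwd_ca[state] * ca;
    backward rate = bwd[state].  States are coded by SubunitState values.
    """
    fwd_const = np.array([kin.k1 * kin.ip3, 0.0, 0.0, 0.0])
    fwd_ca = np.array([0.0, kin.k2, kin.k3, 0.0])
    bwd = np.array([0.0, kin.k_1, kin.k_2, kin.k_3])
    return fwd_const, fwd_ca, bwd


def _initial_states(config: SimulationConfig, layout: ClusterLayout,
                    basal_ca_uM: float, rng: np.random.Generator) -> np.ndarray:
    """Sample the initial subunit states.

    ``x000`` starts every subunit empty.  ``stationary`` draws subunits
    independently from the stationary law at the basal concentration, and
    ``active`` at the ignition point (the calcium level of peak open
    probability).  The default ``primed`` mimics desynchronized release
    sites: each cluster independently starts either primed (stationary at
    the ignition point, probability ``primed_fraction``) or resting
    (stationary at basal).  Primed clusters fire a puff within the first
    couple of seconds as their activated subunits play out, giving the
    spontaneous event background over which triggered and re-ignited
    waves propagate.
    """
    shape = (layout.n_clusters, layout.n_channels, 4)
    if config.init == "x000":
        return np.zeros(shape, dtype=np.int8)
    if config.init in ("stationary", "active"):
        ca = (ignition_point(config.kinetics) if config.init == "active"
              else basal_ca_uM)
        pi = stationary_distribution(ca, config.kinetics)
        return rng.choice(4, size=shape, p=pi).astype(np.int8)
    # primed: per-cluster Bernoulli mixture of resting and ignition-point law
    pi_rest = stationary_distribution(basal_ca_uM, config.kinetics)
    pi_hot = stationary_distribution(ignition_point(config.kinetics),
                                     config.kinetics)
    states = rng.choice(4, size=shape, p=pi_rest).astype(np.int8)
    hot = rng.random(layout.n_clusters) < config.primed_fraction
    n_hot = int(hot.sum())
    if n_hot:
        states[hot] = rng.choice(4, size=(n_hot,) + shape[1:],
                                 p=pi_hot).astype(np.int8)
    return states


def run_simulation(config: SimulationConfig):
    """Run one hybrid simulation; returns ``(Kymograph, summary dict)``.

    The summary carries per-run provenance and diagnostics: realized
    layout, basal fixed point, stability number, the total open-channel
    count at each recorded row, and the field maximum over the run.
    Identical configs and seeds give bit-identical kymographs.
    """
    grid = config.grid
    dyn = config.dynamics
    grid.check_stability(dyn.D)
    layout = config.layout()
    rng = np.random.default_rng(config.seed)

    c_star = basal_fixed_point(dyn)
    if config.init == "active":
        # field starts at the ignition point along with the receptors
        C0 = ignition_point(config.kinetics) / dyn.ca_ave
    else:
        C0 = c_star if config.start_at_basal else 0.0
    C = np.full(grid.n_x, C0)
    state = FieldState(C=C, t=0.0)
    for trig in config.triggers:
        state = apply_trigger(state, trig, grid, dyn.ca_ave)
    C = state.C

    # held triggers clamp their window for the first `hold` seconds
    x = grid.cell_centers()
    held = [(np.abs(x - t.center) <= t.half_width, t.amplitude / dyn.ca_ave,
             int(round(t.hold / grid.dt)))
            for t in config.triggers if t.hold > 0]

    states = _initial_states(config, layout, c_star * dyn.ca_ave, rng)
    fwd_const, fwd_ca, bwd = _rate_tables(config.kinetics)
    cells = np.asarray(layout.cluster_cells)

    dt = grid.dt
    stride = config.record_stride
    n_steps = config.n_steps
    n_rows = n_steps // stride + 1
    pixels = np.empty((n_rows, grid.n_x), dtype=np.uint8)
    n_open_trace = np.zeros(n_rows, dtype=np.int64)

    n_open_map = np.zeros(grid.n_x)
    release_coef = (1.0 + dyn.v_r)
    p, q = dyn.p, dyn.q
    inv_dx2 = 1.0 / grid.dx ** 2
    max_C = float(C.max())

    row = 0
    pixels[row] = quantize(C * dyn.ca_ave, config.record_max)

    for step in range(1, n_steps + 1):
        # --- gating: one categorical draw per subunit ---------------------
        ca_cluster = C[cells] * dyn.ca_ave                      # uM
        ca_sub = ca_cluster[:, None, None]
        p_fwd = (fwd_const[states] + fwd_ca[states] * ca_sub) * dt
        p_bwd = bwd[states] * dt
        p_tot = p_fwd + p_bwd
        if p_tot.max() >= 1.0:
            raise IntegrationError(
                f"transition probability >= 1 at step {step}; reduce dt")
        u = rng.random(states.shape)
        states = (states
                  + ((u >= p_bwd) & (u < p_tot)).astype(np.int8)
                  - (u < p_bwd).astype(np.int8))

        # --- open-channel counts per cluster ------------------------------
        active_per_channel = (states == int(ACTIVE_STATE)).sum(axis=2)
        n_open = (active_per_channel >= OPEN_THRESHOLD).sum(axis=1)
        n_open_map[:] = 0.0
        n_open_map[cells] = n_open

        # --- field update (forward Euler, periodic Laplacian) --------------
        lap = (np.roll(C, 1) + np.roll(C, -1) - 2.0 * C) * inv_dx2
        release = release_coef * (dyn.gamma1 * n_open_map + dyn.gamma0)
        C2 = C * C
        dCdt = dyn.D * lap + release * (1.0 - C) - p * C2 / (C2 + q * q)
        C = C + dt * dCdt
        for mask, level, hold_steps in held:
            if step <= hold_steps:
                C[mask] = level
        if not np.all(np.isfinite(C)) or np.any(C < 0):
            raise IntegrationError(
                f"invalid concentration at step {step} (t={step * dt:.4f} s)")

        if step % stride == 0:
            row += 1
            pixels[row] = quantize(C * dyn.ca_ave, config.record_max)
            n_open_trace[row] = int(n_open.sum())
        if step % 200 == 0:
            max_C = max(max_C, float(C.max()))

    kymo = Kymograph(pixels=pixels, dx_pixel=grid.dx,
                     dt_row=stride * dt, record_max=config.record_max)
    summary = {
        "seed": config.seed,
        "d_requested": config.d,
        "d_realized": layout.realized_d,
        "n_clusters": layout.n_clusters,
        "n_channels": layout.n_channels,
        "p_hat": dyn.p_hat,
        "basal_C": c_star,
        "basal_ca_uM": c_star * dyn.ca_ave,
        "init": config.init,
        "stability_number": grid.stability_number(dyn.D),
        "n_steps": n_steps,
        "n_rows": n_rows,
        "max_C": max_C,
        "n_open_trace": n_open_trace.tolist(),
    }
    return kymo, summary
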