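"""Wave-front velocity estimation and Luther's-law fitting.

A propagating wave appears in the kymograph as a pair of sloped fronts
leaving the initiation site.  The angle ``alpha`` between the propagation
direction and the horizontal (space) axis gives the front speed

    v_w = dx_pixel / (tan(alpha) * dt_row)

with the default calibration (0.18 um per column, 0.0375 s per row).  The
manual angle measurement of linescan practice is replaced here by a
least-squares fit of the outermost above-threshold column per row, on
each side of the initiation point; per-side angles are averaged and
events with a poor front-line fit are excluded from velocity averages.

Luther's law relates the front speed of an autocatalytic
reaction-diffusion wave to the diffusion constant D and an apparent
first-order rate constant k:  ``v_w = a * sqrt(D k)`` with a
dimensionless prefactor ``a``.  Fitting a plane to the squared mean
velocities over the (d, p) sweep therefore yields an effective
``k(d, p) = v_w^2 / (a^2 D)`` that is linear in the intercluster
distance and the pump strength.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .event_analysis import PROPAGATING, CalciumEvent, classify_events
from .hybrid_simulator import Kymograph

__all__ = [
    "WaveVelocityEstimate",
    "LutherFit",
    "front_angle",
    "velocity_from_angle",
    "wave_velocities",
    "mean_velocity",
    "luther_fit",
]

#: minimum rows an event must span for a front fit
MIN_FRONT_ROWS = 5
#: default per-event front-fit quality gate for velocity averaging
MIN_FRONT_R2 = 0.9


@dataclass
class WaveVelocityEstimate:
    """Velocity of one propagating event derived from its front angle."""

    event_id: int
    alpha: float          # degrees from the space axis
    v_w: float            # um/s
    fit_quality: float    # R^2 of the front-line fit (mean over sides)
    d: float = float("nan")
    p_hat: float = float("nan")


#: fraction of columns next to the apex dropped before the line fit (the
#: profile is flat near the initiation point, e.g. over a trigger window)
FRONT_APEX_TRIM = 0.25
#: minimum columns a front segment must span after trimming
MIN_FRONT_COLS = 8
#: the walk ends once the front fails to advance over this many columns
MAX_STALL_COLS = 40
#: sub-threshold holes in the event narrower than this are bridged
MAX_HOLE_COLS = 5


def _first_passage(rows: np.ndarray, cols: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Earliest row of the event in each occupied column."""
    order = np.lexsort((rows, cols))
    c_sorted, r_sorted = cols[order], rows[order]
    first = np.flatnonzero(np.r_[True, np.diff(c_sorted) != 0])
    return c_sorted[first], r_sorted[first]


def _envelope_segment(t_first: dict, start: int, step: int
                      ) -> Tuple[list, list]:
    """Front trajectory as the running maximum of the first-passage profile.

    Walking outward from the apex, the running maximum tracks the
    advancing front while stepping over regions that fired before the
    front arrived (spontaneous events the wave merged with and
    re-ignited from).  The walk ends when the envelope stalls for
    MAX_STALL_COLS columns (the front died or left the image) or at a
    sub-threshold gap wider than MAX_HOLE_COLS.
    """
    seg_cols: list = []
    seg_rows: list = []
    env = -np.inf
    stall = 0
    hole = 0
    c = start
    while True:
        if c not in t_first:
            hole += 1
            if hole > MAX_HOLE_COLS:
                break
            c += step
            continue
        hole = 0
        t = t_first[c]
        if t > env:
            env = t
            stall = 0
        else:
            stall += 1
            if stall > MAX_STALL_COLS:
                # drop the stalled tail: it is not part of the moving front
                del seg_cols[-stall + 1:], seg_rows[-stall + 1:]
                break
        seg_cols.append(c)
        seg_rows.append(env)
        c += step
    return seg_cols, seg_rows


def _fit_front(cols: np.ndarray, rows: np.ndarray) -> Optional[Tuple[float, float]]:
    """Slope (rows per column) and R^2 of the front line row ~ col."""
    if cols.size < 2 or np.ptp(cols) == 0:
        return None
    A = np.vstack([cols, np.ones_like(cols)]).T.astype(float)
    coef, res, _, _ = np.linalg.lstsq(A, rows.astype(float), rcond=None)
    ss_tot = float(np.sum((rows - rows.mean()) ** 2))
    if ss_tot == 0:
        return None   # front arrives everywhere at once: no resolvable angle
    ss_res = float(res[0]) if res.size else float(np.sum((rows - A @ coef) ** 2))
    return float(coef[0]), 1.0 - ss_res / ss_tot


def front_angle(event: CalciumEvent) -> Tuple[float, float]:
    """Front angle (degrees from the space axis) and its fit quality.

    The measurement follows the wave's first-passage profile: for every
    column of the event, the earliest row at which it exceeds threshold.
    Moving outward from the initiation point (the centroid of the
    event's earliest row), the running maximum of that profile traces
    the advancing front, stepping over pockets that fired before the
    front arrived; the walk ends where the front stalls.  Columns near
    the apex, where the profile is flat, are trimmed, and each side's
    remaining trajectory is fit by least squares.  The per-side angles
    ``arctan(|d row / d col|)`` are averaged; the returned quality is the
    mean R^2 of the side fits.

    Raises ``ValueError`` for events spanning fewer than 5 rows or with
    no usable front segment.
    """
    if event.rows is None or len(event.rows) == 0:
        raise ValueError("event carries no pixel coordinates")
    rows, cols = np.asarray(event.rows), np.asarray(event.cols)
    row_span = rows.max() - rows.min() + 1
    if row_span < MIN_FRONT_ROWS:
        raise ValueError(
            f"event spans {row_span} rows < {MIN_FRONT_ROWS}; front fit unreliable")
    first_row = rows.min()
    init_col = int(round(cols[rows == first_row].mean()))

    fp_cols, fp_rows = _first_passage(rows, cols)
    t_first = dict(zip(fp_cols.tolist(), fp_rows.tolist()))
    if init_col not in t_first:   # centroid fell in a gap; snap to nearest
        init_col = int(fp_cols[np.argmin(np.abs(fp_cols - init_col))])

    sides = []
    for step in (-1, +1):
        seg_cols, seg_rows = _envelope_segment(t_first, init_col, step)
        trim = max(int(len(seg_cols) * FRONT_APEX_TRIM), 1)
        seg_cols, seg_rows = seg_cols[trim:], seg_rows[trim:]
        if len(seg_cols) < MIN_FRONT_COLS:
            continue
        fit = _fit_front(np.asarray(seg_cols), np.asarray(seg_rows))
        if fit is None:
            continue
        slope, r2 = fit
        if abs(slope) < 1e-12:
            continue
        sides.append((math.degrees(math.atan(abs(slope))), r2))
    if not sides:
        raise ValueError("no usable front segment (vertical or unresolved front)")
    alpha = float(np.mean([a for a, _ in sides]))
    quality = float(np.mean([q for _, q in sides]))
    return alpha, quality


def velocity_from_angle(alpha: float, dx_pixel: float = 0.18,
                        dt_row: float = 0.0375) -> float:
    """Front speed (um/s) from the angle to the space axis (degrees).

    ``v_w = dx_pixel / (tan(alpha) * dt_row)``; a steeper (more vertical)
    world-line means a slower wave.
    """
    if not (0.0 < alpha < 90.0):
        raise ValueError(f"front angle must lie in (0, 90) degrees, got {alpha}")
    return dx_pixel / (math.tan(math.radians(alpha)) * dt_row)


def wave_velocities(events: Iterable[CalciumEvent], kymo: Kymograph,
                    criterion: str = "spatial",
                    min_r2: float = MIN_FRONT_R2,
                    d: float = float("nan"),
                    p_hat: float = float("nan")) -> List[WaveVelocityEstimate]:
    """Velocity estimates for the propagating events of one kymograph.

    Only propagating-class events are measured; events whose front fit
    falls below ``min_r2`` or that show no resolvable spatial advance are
    skipped with a warning.  Events wrapping the periodic boundary are
    measured on the front segments inside the image.
    """
    events = classify_events(events)
    key = "spatial_class" if criterion == "spatial" else "cat_class"
    out: List[WaveVelocityEstimate] = []
    for ev in events:
        if getattr(ev, key) != PROPAGATING:
            continue
        try:
            alpha, quality = front_angle(ev)
        except ValueError as exc:
            warnings.warn(f"event {ev.spot_id}: {exc}; skipped")
            continue
        if quality < min_r2:
            warnings.warn(
                f"event {ev.spot_id}: front fit R^2={quality:.2f} < {min_r2}; skipped")
            continue
        v = velocity_from_angle(alpha, kymo.dx_pixel, kymo.dt_row)
        out.append(WaveVelocityEstimate(event_id=ev.spot_id, alpha=alpha,
                                        v_w=v, fit_quality=quality,
                                        d=d, p_hat=p_hat))
    return out


def mean_velocity(estimates: Sequence[WaveVelocityEstimate]) -> Tuple[float, float]:
    """Mean wave velocity and its standard error over one condition.

    With a single estimate the SE is reported as NaN.
    """
    if len(estimates) == 0:
        raise ValueError("no velocity estimates to average")
    v = np.array([e.v_w for e in estimates], dtype=float)
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), se


@dataclass
class LutherFit:
    """Plane fit of squared wave velocity over (d, p) and the derived
    autocatalytic rate constant.

    ``v_w^2(d, p) = beta0 + beta_d * d + beta_p * p`` with standard errors
    from ordinary least squares; dividing by ``a^2 * D`` gives
    ``k(d, p) = k0 + k_d * d + k_p * p`` in s^-1.
    """

    beta0: float
    beta_d: float
    beta_p: float
    se0: float
    se_d: float
    se_p: float
    r2: float
    D: float = 25.0
    a: float = 1.0
    n_points: int = 0

    @property
    def k_coeffs(self) -> Tuple[float, float, float]:
        s = self.a ** 2 * self.D
        return (self.beta0 / s, self.beta_d / s, self.beta_p / s)

    @property
    def k_se(self) -> Tuple[float, float, float]:
        s = self.a ** 2 * self.D
        return (self.se0 / s, self.se_d / s, self.se_p / s)

    def v2(self, d: float, p: float) -> float:
        return self.beta0 + self.beta_d * d + self.beta_p * p

    def k(self, d: float, p: float) -> float:
        k0, kd, kp = self.k_coeffs
        return k0 + kd * d + kp * p

    def to_dict(self) -> dict:
        k0, kd, kp = self.k_coeffs
        return {"beta0": self.beta0, "beta_d": self.beta_d, "beta_p": self.beta_p,
                "se0": self.se0, "se_d": self.se_d, "se_p": self.se_p,
                "r2": self.r2, "D": self.D, "a": self.a,
                "k0": k0, "k_d": kd, "k_p": kp, "n_points": self.n_points}


def luther_fit(points: pd.DataFrame | Sequence[Tuple[float, float, float]],
               D: float = 25.0, a: float = 1.0) -> LutherFit:
    """OLS plane fit of squared mean wave velocity on (1, d, p).

    ``points`` holds one row per sweep condition with columns/fields
    ``(d, p_hat, v_w)`` — the per-condition mean propagating-wave
    velocities.  Requires at least 4 points spanning at least two distinct
    values of each of d and p; a rank-deficient design raises.
    """
    if isinstance(points, pd.DataFrame):
        d_vals = points["d"].to_numpy(float)
        p_vals = points["p_hat"].to_numpy(float)
        v_vals = points["v_w"].to_numpy(float)
    else:
        arr = np.asarray(points, dtype=float)
        d_vals, p_vals, v_vals = arr[:, 0], arr[:, 1], arr[:, 2]
    if d_vals.size < 4:
        raise ValueError("need at least 4 (d, p, v_w) points")
    if np.unique(d_vals).size < 2 or np.unique(p_vals).size < 2:
        raise ValueError("need at least 2 distinct d and 2 distinct p values")
    X = sm.add_constant(np.column_stack([d_vals, p_vals]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: d and p are collinear")
    model = sm.OLS(v_vals ** 2, X).fit()
    b0, bd, bp = model.params
    s0, sd_, sp_ = model.bse
    return LutherFit(beta0=float(b0), beta_d=float(bd), beta_p=float(bp),
                     se0=float(s0), se_d=float(sd_), se_p=float(sp_),
                     r2=float(model.rsquared), D=D, a=a,
                     n_points=int(d_vals.size))
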