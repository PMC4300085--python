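"""Segmentation and classification of calcium release events in kymographs.

The pipeline mirrors a standard particle analysis of linescan images: the
calibrated kymograph is thresholded at 0.3 uM, space-time connected
components (8-connectivity) become events, and each event is measured
(duration, spatial extent, mean concentration, total released calcium
Ca_T) and classified twice:

* spatial criterion — extent < 5 um: puff; 5-25 um: abortive wave;
  > 25 um: propagating wave;
* Ca_T criterion — Ca_T < 200 a.u.: puff; 200-1800 a.u.: abortive;
  > 1800 a.u.: propagating,

where Ca_T is the mean 8-bit intensity of the spot times its pixel area
(arbitrary units).  Components touching the left/right image edges are
merged across the periodic boundary before measuring extent; events
touching the first or last row are flagged as censored (their duration is
a lower bound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import measure

from .hybrid_simulator import Kymograph

__all__ = [
    "PUFF", "ABORTIVE", "PROPAGATING",
    "CalciumEvent", "EventSummary",
    "binarize", "label_events", "classify_spatial", "classify_cat",
    "classify_events", "summarize", "find_dmax", "frontier",
    "events_to_frame",
]

PUFF = "puff"
ABORTIVE = "abortive"
PROPAGATING = "propagating"

#: spatial class bounds (um): < 5 puff, 5-25 abortive (closed), > 25 propagating
SPATIAL_BOUNDS = (5.0, 25.0)
#: Ca_T class bounds (a.u.): < 200 puff, 200-1800 abortive (closed), > 1800 propagating
CAT_BOUNDS = (200.0, 1800.0)

#: binarization threshold on calibrated concentration (uM)
DEFAULT_THRESHOLD_UM = 0.3


@dataclass
class CalciumEvent:
    """One segmented space-time release event.

    ``rows``/``cols`` hold the pixel coordinates of the spot (used by the
    wave-velocity front fit); ``ca_t`` is mean 8-bit intensity times pixel
    area, in arbitrary units, with a calibrated alternative ``ca_t_uM``
    (mean uM times pixel area) also exported.
    """

    spot_id: int
    pixel_count: int
    duration: float          # s
    extent: float            # um
    mean_ca: float           # uM
    mean_intensity: float    # 8-bit a.u.
    ca_t: float              # a.u. (mean intensity x area)
    ca_t_uM: float           # uM x px (calibrated alternative)
    bbox: Tuple[int, int, int, int]   # row_min, row_max, col_min, col_max
    wrapped: bool = False    # crosses the periodic space boundary
    censored: bool = False   # touches first/last time row
    spatial_class: Optional[str] = None
    cat_class: Optional[str] = None
    rows: np.ndarray = field(default=None, repr=False)
    cols: np.ndarray = field(default=None, repr=False)


def binarize(kymo: Kymograph, threshold_ca: float = DEFAULT_THRESHOLD_UM) -> np.ndarray:
    """Boolean mask of pixels whose calibrated concentration exceeds the
    threshold (uM)."""
    if not (0.0 <= threshold_ca <= kymo.record_max):
        raise ValueError(
            f"threshold {threshold_ca} uM outside calibration range "
            f"[0, {kymo.record_max}] uM")
    return kymo.to_ca() > threshold_ca


class _UnionFind:
    def __init__(self):
        self.parent: Dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _circular_extent_cols(occ: np.ndarray) -> int:
    """Number of columns spanned by a wrapped component on a ring.

    Equals the ring size minus the longest circular run of unoccupied
    columns (the component spans everything except its biggest gap).
    """
    n = occ.size
    if occ.all():
        return n
    # rotate so position 0 is unoccupied, then find the longest False run
    start = int(np.argmin(occ))
    rolled = np.roll(occ, -start)
    best = run = 0
    for v in rolled:
        run = run + 1 if not v else 0
        best = max(best, run)
    return n - best


def label_events(mask: np.ndarray, kymo: Kymograph,
                 merge_periodic: bool = True) -> List[CalciumEvent]:
    """Connected-component segmentation of the thresholded kymograph.

    Components use 8-connectivity in (time, space); with
    ``merge_periodic`` components adjacent across the left/right image
    edges are merged before measurement (the simulation domain is a ring).
    Returns one :class:`CalciumEvent` per component; an empty mask yields
    an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != kymo.pixels.shape:
        raise ValueError("mask and kymograph shapes differ")
    labels = measure.label(mask, connectivity=2)
    n_labels = labels.max()
    if n_labels == 0:
        return []

    uf = _UnionFind()
    for lab in range(1, n_labels + 1):
        uf.find(lab)
    n_rows, n_cols = mask.shape
    if merge_periodic and n_cols > 1:
        left, right = labels[:, 0], labels[:, -1]
        for r in range(n_rows):
            if right[r]:
                for rr in (r - 1, r, r + 1):   # 8-connectivity across the wrap
                    if 0 <= rr < n_rows and left[rr]:
                        uf.union(int(right[r]), int(left[rr]))

    rr, cc = np.nonzero(labels)
    roots = np.array([uf.find(int(l)) for l in labels[rr, cc]])
    order = np.argsort(roots, kind="stable")
    rr, cc, roots = rr[order], cc[order], roots[order]
    boundaries = np.flatnonzero(np.diff(roots)) + 1
    groups = np.split(np.arange(roots.size), boundaries)

    ca = kymo.to_ca()
    events: List[CalciumEvent] = []
    for i, idx in enumerate(groups, start=1):
        g_rows, g_cols = rr[idx], cc[idx]
        npx = int(idx.size)
        row_min, row_max = int(g_rows.min()), int(g_rows.max())
        col_min, col_max = int(g_cols.min()), int(g_cols.max())
        wrapped = merge_periodic and (col_min == 0 and col_max == n_cols - 1)
        if wrapped:
            occ = np.zeros(n_cols, dtype=bool)
            occ[g_cols] = True
            extent_cols = _circular_extent_cols(occ)
        else:
            extent_cols = col_max - col_min + 1
        intensities = kymo.pixels[g_rows, g_cols].astype(float)
        mean_int = float(intensities.mean())
        mean_ca = float(ca[g_rows, g_cols].mean())
        events.append(CalciumEvent(
            spot_id=i,
            pixel_count=npx,
            duration=(row_max - row_min + 1) * kymo.dt_row,
            extent=extent_cols * kymo.dx_pixel,
            mean_ca=mean_ca,
            mean_intensity=mean_int,
            ca_t=mean_int * npx,
            ca_t_uM=mean_ca * npx,
            bbox=(row_min, row_max, col_min, col_max),
            wrapped=wrapped,
            censored=(row_min == 0 or row_max == n_rows - 1),
            rows=g_rows,
            cols=g_cols,
        ))
    return events


def classify_spatial(event: CalciumEvent) -> str:
    """Class by spatial extent: < 5 um puff, 5-25 um abortive, > 25 um
    propagating (boundary values count as abortive)."""
    lo, hi = SPATIAL_BOUNDS
    if event.extent < lo:
        return PUFF
    if event.extent <= hi:
        return ABORTIVE
    return PROPAGATING


def classify_cat(event: CalciumEvent) -> str:
    """Class by total calcium Ca_T: < 200 a.u. puff, 200-1800 a.u.
    abortive, > 1800 a.u. propagating (boundaries count as abortive)."""
    lo, hi = CAT_BOUNDS
    if event.ca_t < lo:
        return PUFF
    if event.ca_t <= hi:
        return ABORTIVE
    return PROPAGATING


def classify_events(events: Iterable[CalciumEvent]) -> List[CalciumEvent]:
    """Assign both class labels in place; returns the same list."""
    events = list(events)
    for ev in events:
        ev.spatial_class = classify_spatial(ev)
        ev.cat_class = classify_cat(ev)
    return events


@dataclass
class EventSummary:
    """Per-condition tally of the event hierarchy under one criterion."""

    n_puff: int
    n_aw: int
    n_w: int
    mean_wave_duration: float          # s, over abortive + propagating; NaN if none
    ca_t_by_class: Dict[str, float]    # summed Ca_T (a.u.) per class
    ca_t_total: float
    condition: Tuple[float, float]     # (d um, p_hat uM/s)
    criterion: str                     # "spatial" | "cat"

    @property
    def n_waves(self) -> int:
        """Total wave count (abortive + propagating)."""
        return self.n_aw + self.n_w


def summarize(events: Iterable[CalciumEvent],
              condition: Tuple[float, float] = (np.nan, np.nan),
              criterion: str = "spatial") -> EventSummary:
    """Tally events into the puff/abortive/propagating hierarchy.

    ``criterion`` selects which classification drives the counts.  The
    mean wave duration is taken over abortive plus propagating events and
    reported as NaN when there are none.
    """
    if criterion not in ("spatial", "cat"):
        raise ValueError("criterion must be 'spatial' or 'cat'")
    events = classify_events(events)
    key = "spatial_class" if criterion == "spatial" else "cat_class"
    counts = {PUFF: 0, ABORTIVE: 0, PROPAGATING: 0}
    ca_t = {PUFF: 0.0, ABORTIVE: 0.0, PROPAGATING: 0.0}
    wave_durations: List[float] = []
    for ev in events:
        cls = getattr(ev, key)
        counts[cls] += 1
        ca_t[cls] += ev.ca_t
        if cls in (ABORTIVE, PROPAGATING):
            wave_durations.append(ev.duration)
    return EventSummary(
        n_puff=counts[PUFF], n_aw=counts[ABORTIVE], n_w=counts[PROPAGATING],
        mean_wave_duration=float(np.mean(wave_durations)) if wave_durations else float("nan"),
        ca_t_by_class=ca_t,
        ca_t_total=float(sum(ca_t.values())),
        condition=condition,
        criterion=criterion,
    )


def find_dmax(summaries: Sequence[EventSummary]) -> Optional[float]:
    """Intercluster distance maximizing the total wave count at fixed p.

    Ties break toward the smaller distance.  Returns None (with a warning)
    when no condition produced any wave.
    """
    if len(summaries) < 3:
        raise ValueError("need summaries for at least 3 intercluster distances")
    d_vals = np.array([s.condition[0] for s in summaries])
    counts = np.array([s.n_waves for s in summaries])
    if counts.max() == 0:
        warnings.warn("no waves at any intercluster distance; d_max undefined")
        return None
    order = np.argsort(d_vals)
    d_vals, counts = d_vals[order], counts[order]
    return float(d_vals[np.argmax(counts)])   # argmax takes the first = smallest d


def frontier(summaries: Sequence[EventSummary]) -> pd.DataFrame:
    """Locus in (d, p) where abortive and propagating wave counts balance.

    For each pump strength, the crossing of ``n_w - n_aw`` as a function of
    d is located by linear interpolation; pump strengths without a sign
    change are omitted with a warning.  When several crossings exist the
    smallest d* is reported and flagged.
    """
    rows = []
    by_p: Dict[float, List[EventSummary]] = {}
    for s in summaries:
        by_p.setdefault(s.condition[1], []).append(s)
    for p_hat in sorted(by_p):
        group = sorted(by_p[p_hat], key=lambda s: s.condition[0])
        d = np.array([s.condition[0] for s in group])
        diff = np.array([s.n_w - s.n_aw for s in group], dtype=float)
        crossings = []
        for i in range(len(d) - 1):
            if diff[i] == 0.0:
                crossings.append(float(d[i]))
            elif diff[i] * diff[i + 1] < 0:
                frac = diff[i] / (diff[i] - diff[i + 1])
                crossings.append(float(d[i] + frac * (d[i + 1] - d[i])))
        if diff[-1] == 0.0:
            crossings.append(float(d[-1]))
        if not crossings:
            warnings.warn(f"no n_w = n_aw crossing at p_hat={p_hat}; omitted")
            continue
        rows.append({"p_hat": p_hat, "d_star": min(crossings),
                     "multiple_crossings": len(set(crossings)) > 1})
    return pd.DataFrame(rows, columns=["p_hat", "d_star", "multiple_crossings"])


def events_to_frame(events: Iterable[CalciumEvent]) -> pd.DataFrame:
    """Tabulate events (one row per event) for CSV export."""
    events = classify_events(events)
    recs = []
    for ev in events:
        recs.append({
            "spot_id": ev.spot_id,
            "row_min": ev.bbox[0], "row_max": ev.bbox[1],
            "col_min": ev.bbox[2], "col_max": ev.bbox[3],
            "pixel_count": ev.pixel_count,
            "duration_s": ev.duration,
            "extent_um": ev.extent,
            "mean_ca_uM": ev.mean_ca,
            "mean_intensity_au": ev.mean_intensity,
            "ca_t_au": ev.ca_t,
            "ca_t_uM_px": ev.ca_t_uM,
            "wrapped": ev.wrapped,
            "censored": ev.censored,
            "spatial_class": ev.spatial_class,
            "cat_class": ev.cat_class,
        })
    cols = ["spot_id", "row_min", "row_max", "col_min", "col_max",
            "pixel_count", "duration_s", "extent_um", "mean_ca_uM",
            "mean_intensity_au", "ca_t_au", "ca_t_uM_px", "wrapped",
            "censored", "spatial_class", "cat_class"]
    return pd.DataFrame(recs, columns=cols)
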