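"""Segmental and global myocardial work from strain traces and LV pressure.

Myocardial work couples deformation with afterload: instantaneous power is
the strain rate times the estimated LV pressure, and its time integral over
the work window (mitral valve closure to mitral valve opening) gives work
in mmHg·%.  Sign conventions follow the negative-is-shortening strain
convention: power is defined so physiologic systolic shortening under
pressure counts as positive work.

Constructive and wasted work partition the signed power by cardiac phase:

* systole (MVC -> AVC): shortening is constructive, lengthening is wasted;
* isovolumic relaxation (AVC -> MVO): lengthening is constructive,
  shortening (post-systolic shortening) is wasted.

The work index is the constructive minus the wasted integral, so the
decomposition ``work_index = constructive - wasted`` holds exactly by
construction, and work efficiency ``100 * CW / (CW + WW)`` is bounded in
[0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DomainError,
    IncompleteSegmentationError,
    InsufficientDataError,
    ValidationError,
)
from .pressure import LVPressureCurve, ValveEvents, pressure_at

__all__ = [
    "StrainTrace",
    "SegmentWork",
    "GlobalWorkSet",
    "strain_rate",
    "segment_work",
    "segment_work_matrix",
    "peak_systolic_strain",
    "aggregate_global",
    "subject_work",
    "N_SEGMENTS",
]

#: Standard left-ventricular segmentation (apex counted once).
N_SEGMENTS = 17

#: Default number of points of the uniform work-integration grid.
DEFAULT_GRID_POINTS = 2000


@dataclass(frozen=True)
class StrainTrace:
    """Longitudinal strain time series (%) for one myocardial segment.

    Strain is referenced to cycle start (mitral valve closure), so the
    trace starts near zero; negative values denote shortening.
    """

    segment_id: int
    times: np.ndarray
    strain: np.ndarray

    def __post_init__(self) -> None:
        if not 1 <= int(self.segment_id) <= N_SEGMENTS:
            raise ValidationError(
                f"segment_id must be in 1..{N_SEGMENTS}, got {self.segment_id}"
            )
        if self.times.shape != self.strain.shape:
            raise ValidationError("times and strain must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("strain trace times must be strictly increasing")
        if not np.all(np.isfinite(self.strain)):
            raise ValidationError("strain values must be finite")
        if np.any(np.abs(self.strain) >= 50.0):
            raise ValidationError("longitudinal strain magnitude must be < 50%")


@dataclass(frozen=True)
class SegmentWork:
    """Work decomposition for one segment, all in mmHg·%."""

    segment_id: int
    work_index: float
    constructive: float
    wasted: float


@dataclass(frozen=True)
class GlobalWorkSet:
    """Subject-level work indices: GLS (%), GWI/GCW/GWW (mmHg·%), GWE (%)."""

    gls: float
    gwi: float
    gcw: float
    gww: float
    gwe: float


def strain_rate(trace: StrainTrace) -> np.ndarray:
    """Differentiate strain over time on the trace's own grid (%/s).

    Uses second-order central differences at interior points and one-sided
    differences at the endpoints, exact for linear strain.
    """
    if trace.times.size < 3:
        raise InsufficientDataError(
            f"strain rate needs >= 3 samples, got {trace.times.size}"
        )
    return np.gradient(trace.strain, trace.times)


def _work_grid(events: ValveEvents, n_grid: int) -> tuple[np.ndarray, int, int]:
    """Uniform work grid over [t_mvc, t_mvo] with valve events inserted.

    Returns the grid and the indices of t_avo and t_avc, which bound the
    per-phase derivative and the systole/IVR integration windows.
    """
    if n_grid < 16:
        raise ValidationError(f"work grid needs >= 16 points, got {n_grid}")
    t = np.union1d(
        np.linspace(events.t_mvc, events.t_mvo, n_grid),
        [events.t_avo, events.t_avc],
    )
    i_avo = int(np.searchsorted(t, events.t_avo))
    i_avc = int(np.searchsorted(t, events.t_avc))
    return t, i_avo, i_avc


def segment_work_matrix(
    strain: np.ndarray,
    trace_times: np.ndarray,
    pressure: LVPressureCurve,
    events: ValveEvents,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Work decomposition for a stack of strain traces sharing one time grid.

    ``strain`` has shape (n_segments, n_samples) on ``trace_times``.  All
    traces are resampled to a common uniform work grid, differentiated
    within each cardiac phase (the valve events are genuine breakpoints of
    the deformation, so the derivative is not smeared across them), and
    the signed power ``-dstrain/dt * P(t)`` is partitioned by phase into
    constructive and wasted integrals.

    Returns ``(work_index, constructive, wasted)`` arrays of shape
    (n_segments,), in mmHg·%.
    """
    strain = np.atleast_2d(np.asarray(strain, dtype=float))
    trace_times = np.asarray(trace_times, dtype=float)
    tol = 1e-9 * max(1.0, events.t_mvo)
    if trace_times[0] > events.t_mvc + tol or trace_times[-1] < events.t_mvo - tol:
        raise DomainError(
            "strain trace domain "
            f"[{trace_times[0]}, {trace_times[-1]}] does not cover the work "
            f"window [{events.t_mvc}, {events.t_mvo}]"
        )
    t, i_avo, i_avc = _work_grid(events, n_grid)
    p = pressure_at(pressure, t)

    eps = np.vstack([np.interp(t, trace_times, row) for row in strain])
    if np.any(np.abs(eps[:, 0]) > 0.5):
        raise ValidationError(
            "strain must be referenced to cycle start: |strain(t_mvc)| > 0.5%"
        )

    # signed power with the derivative evaluated independently per phase:
    # the valve events are genuine breakpoints of the deformation, so each
    # phase keeps its own one-sided boundary derivatives
    pos_sys = neg_sys = pos_ivr = neg_ivr = 0.0
    phases = (
        (slice(0, i_avo + 1), "systole"),
        (slice(i_avo, i_avc + 1), "systole"),
        (slice(i_avc, None), "ivr"),
    )
    for sl, phase in phases:
        w = -np.gradient(eps[:, sl], t[sl], axis=1) * p[sl]
        pos = np.trapezoid(np.clip(w, 0.0, None), t[sl], axis=-1)
        neg = np.trapezoid(np.clip(-w, 0.0, None), t[sl], axis=-1)
        if phase == "systole":
            pos_sys, neg_sys = pos_sys + pos, neg_sys + neg
        else:
            pos_ivr, neg_ivr = pos_ivr + pos, neg_ivr + neg

    constructive = pos_sys + neg_ivr  # shortening in systole + lengthening in IVR
    wasted = neg_sys + pos_ivr  # lengthening in systole + shortening in IVR
    return constructive - wasted, constructive, wasted


def segment_work(
    trace: StrainTrace,
    pressure: LVPressureCurve,
    events: ValveEvents,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> SegmentWork:
    """Work decomposition of a single segment over [t_mvc, t_mvo]."""
    wi, cw, ww = segment_work_matrix(
        trace.strain, trace.times, pressure, events, n_grid=n_grid
    )
    return SegmentWork(
        segment_id=trace.segment_id,
        work_index=float(wi[0]),
        constructive=float(cw[0]),
        wasted=float(ww[0]),
    )


def peak_systolic_strain(trace: StrainTrace, events: ValveEvents) -> float:
    """Peak systolic strain: the minimum of strain over [t_mvc, t_avc] (%)."""
    m = (trace.times >= events.t_mvc) & (trace.times <= events.t_avc)
    candidates = [trace.strain[m].min() if m.any() else np.inf]
    # the extremum can sit between samples of a coarse trace only at the
    # window edge, so the interpolated value at AVC is also considered
    candidates.append(float(np.interp(events.t_avc, trace.times, trace.strain)))
    return float(min(candidates))


def aggregate_global(
    seg_works: Sequence[SegmentWork],
    peak_strains: Sequence[float],
    weights: Sequence[float] | None = None,
) -> GlobalWorkSet:
    """Aggregate 17 segmental work sets into subject-level global indices.

    GWI, GCW and GWW are arithmetic means over segments; GWE is
    ``100 * GCW / (GCW + GWW)`` (100 when no work is wasted); GLS is the
    weighted mean of the segmental peak systolic strains, with equal
    weights by default (apex counted once).
    """
    ids = sorted(s.segment_id for s in seg_works)
    if ids != list(range(1, N_SEGMENTS + 1)):
        missing = sorted(set(range(1, N_SEGMENTS + 1)) - set(ids))
        raise IncompleteSegmentationError(
            f"need all {N_SEGMENTS} segments exactly once; missing or "
            f"duplicated: {missing or ids}"
        )
    if len(peak_strains) != N_SEGMENTS:
        raise IncompleteSegmentationError(
            f"need {N_SEGMENTS} peak strains, got {len(peak_strains)}"
        )
    gwi = float(np.mean([s.work_index for s in seg_works]))
    gcw = float(np.mean([s.constructive for s in seg_works]))
    gww = float(np.mean([s.wasted for s in seg_works]))
    gwe = 100.0 if gww == 0.0 else 100.0 * gcw / (gcw + gww)
    gls = float(np.average(np.asarray(peak_strains, dtype=float), weights=weights))
    return GlobalWorkSet(gls=gls, gwi=gwi, gcw=gcw, gww=gww, gwe=gwe)


def subject_work(
    traces: Sequence[StrainTrace],
    pressure: LVPressureCurve,
    events: ValveEvents,
    n_grid: int = DEFAULT_GRID_POINTS,
    gls_weights: Sequence[float] | None = None,
) -> GlobalWorkSet:
    """Full per-subject pipeline: 17 traces -> segmental works -> global set."""
    seg_works = [segment_work(tr, pressure, events, n_grid=n_grid) for tr in traces]
    peaks = {tr.segment_id: peak_systolic_strain(tr, events) for tr in traces}
    ordered = [peaks[i] for i in sorted(peaks)] if len(peaks) == N_SEGMENTS else list(
        peaks.values()
    )
    return aggregate_global(seg_works, ordered, weights=gls_weights)
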