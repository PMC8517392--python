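"""Non-invasive left-ventricular pressure curve construction.

The instantaneous LV pressure over one cardiac cycle is estimated without
catheterisation by taking a fixed, normalized reference pressure shape on
phase-normalized time, stretching each cardiac phase (isovolumic
contraction, ejection, isovolumic relaxation) to the subject's own valve
event timings, and scaling the amplitude so that the peak equals the cuff
systolic pressure measured at the brachial artery.  Peak systolic LV
pressure is assumed equal to peak arterial pressure; the cuff diastolic
pressure is carried for the covariate table but does not enter the curve.

The reference shape is a piecewise raised-cosine template: a half-cosine
rise from 0 to 0.90 during isovolumic contraction, a raised-cosine arch
through the ejection phase peaking at 1.0 at 30% of ejection and falling
to 0.55 at aortic valve closure, and a half-cosine decay to 0.10 at mitral
valve opening.  It is a named module constant so an alternative shape can
be swapped in without touching the scaling machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ResolutionError, TimingError, ValidationError

__all__ = [
    "ValveEvents",
    "CuffPressure",
    "ReferenceTemplate",
    "LVPressureCurve",
    "RAISED_COSINE_TEMPLATE",
    "build_reference_curve",
    "scale_to_cycle",
    "pressure_at",
]


@dataclass(frozen=True)
class ValveEvents:
    """The four valve-event anchor times (seconds) of one cardiac cycle.

    ``t_mvc`` (mitral valve closure) opens the cycle, ``t_avo`` (aortic
    valve opening) ends isovolumic contraction, ``t_avc`` (aortic valve
    closure) ends ejection, and ``t_mvo`` (mitral valve opening) ends
    isovolumic relaxation and closes the work window.
    """

    t_mvc: float
    t_avo: float
    t_avc: float
    t_mvo: float

    def __post_init__(self) -> None:
        times = (self.t_mvc, self.t_avo, self.t_avc, self.t_mvo)
        if not all(math.isfinite(t) for t in times):
            raise TimingError(f"valve-event times must be finite, got {times}")
        if self.t_mvc < 0:
            raise TimingError(f"cycle start must be non-negative, got {self.t_mvc}")
        if not (self.t_mvc < self.t_avo < self.t_avc < self.t_mvo):
            raise TimingError(
                "valve events must satisfy t_mvc < t_avo < t_avc < t_mvo, "
                f"got {times}"
            )

    @property
    def duration(self) -> float:
        """Length of the work window MVC -> MVO in seconds."""
        return self.t_mvo - self.t_mvc

    @property
    def phase_durations(self) -> tuple[float, float, float]:
        """(isovolumic contraction, ejection, isovolumic relaxation) in s."""
        return (
            self.t_avo - self.t_mvc,
            self.t_avc - self.t_avo,
            self.t_mvo - self.t_avc,
        )


@dataclass(frozen=True)
class CuffPressure:
    """Brachial cuff systolic / diastolic pressure in mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValidationError(
                f"cuff pressures must satisfy sbp > dbp > 0, got "
                f"sbp={self.sbp}, dbp={self.dbp}"
            )

    @property
    def pulse_pressure(self) -> float:
        return self.sbp - self.dbp


@dataclass(frozen=True)
class ReferenceTemplate:
    """Closed-form normalized pressure shape on phase-normalized time.

    Phase-normalized time ``u`` runs over [0, 1] with fixed canonical phase
    boundaries: isovolumic contraction on [0, ``ivc_end``], ejection on
    [``ivc_end``, ``eject_end``], isovolumic relaxation on [``eject_end``, 1].
    Values are dimensionless in [0, 1]; multiplying by cuff SBP gives mmHg.
    """

    ivc_end: float = 0.15
    eject_end: float = 0.75
    v_avo: float = 0.90
    v_avc: float = 0.55
    v_mvo: float = 0.10
    peak_frac: float = 0.30  # peak position as a fraction of the ejection phase

    @property
    def peak_phase(self) -> float:
        """Phase-normalized time of the pressure peak."""
        return self.ivc_end + self.peak_frac * (self.eject_end - self.ivc_end)

    @property
    def anchor_phases(self) -> tuple[float, ...]:
        """Phase points that must appear on any sampling grid."""
        return (0.0, self.ivc_end, self.peak_phase, self.eject_end, 1.0)

    def __call__(self, u):
        """Evaluate the template at phase-normalized time(s) ``u`` in [0, 1]."""
        u = np.asarray(u, dtype=float)
        out = np.empty_like(u)

        ivc = u <= self.ivc_end
        x = np.divide(u, self.ivc_end, where=self.ivc_end > 0)
        out[ivc] = self.v_avo * 0.5 * (1.0 - np.cos(np.pi * x[ivc]))

        ej = (u > self.ivc_end) & (u <= self.eject_end)
        x = (u - self.ivc_end) / (self.eject_end - self.ivc_end)
        rising = ej & (x <= self.peak_frac)
        falling = ej & (x > self.peak_frac)
        xr = x / self.peak_frac
        out[rising] = self.v_avo + (1.0 - self.v_avo) * 0.5 * (
            1.0 - np.cos(np.pi * xr[rising])
        )
        xf = (x - self.peak_frac) / (1.0 - self.peak_frac)
        out[falling] = self.v_avc + (1.0 - self.v_avc) * 0.5 * (
            1.0 + np.cos(np.pi * xf[falling])
        )

        ivr = u > self.eject_end
        x = (u - self.eject_end) / (1.0 - self.eject_end)
        out[ivr] = self.v_mvo + (self.v_avc - self.v_mvo) * 0.5 * (
            1.0 + np.cos(np.pi * x[ivr])
        )
        return out if out.ndim else float(out)

    def phase_of_time(self, t, events: ValveEvents):
        """Map cycle time(s) ``t`` to phase-normalized time piecewise-affinely.

        Each physiological phase is mapped onto its canonical template
        segment, so stretching phase durations leaves the value at a given
        phase fraction unchanged (time-dilation equivariance).
        """
        t = np.asarray(t, dtype=float)
        e = events
        u = np.empty_like(t)
        bounds = [
            (e.t_mvc, e.t_avo, 0.0, self.ivc_end),
            (e.t_avo, e.t_avc, self.ivc_end, self.eject_end),
            (e.t_avc, e.t_mvo, self.eject_end, 1.0),
        ]
        for lo, hi, ulo, uhi in bounds:
            m = (t >= lo) & (t <= hi)
            u[m] = ulo + (t[m] - lo) / (hi - lo) * (uhi - ulo)
        return u if u.ndim else float(u)

    def time_of_phase(self, u: float, events: ValveEvents) -> float:
        """Inverse of :meth:`phase_of_time` for a scalar phase point."""
        e = events
        if u <= self.ivc_end:
            return e.t_mvc + u / self.ivc_end * (e.t_avo - e.t_mvc)
        if u <= self.eject_end:
            x = (u - self.ivc_end) / (self.eject_end - self.ivc_end)
            return e.t_avo + x * (e.t_avc - e.t_avo)
        x = (u - self.eject_end) / (1.0 - self.eject_end)
        return e.t_avc + x * (e.t_mvo - e.t_avc)


RAISED_COSINE_TEMPLATE = ReferenceTemplate()


@dataclass(frozen=True)
class ReferenceCurve:
    """A sampled reference template: phase grid plus normalized values."""

    phase: np.ndarray
    values: np.ndarray
    template: ReferenceTemplate = field(default=RAISED_COSINE_TEMPLATE)


@dataclass(frozen=True)
class LVPressureCurve:
    """Estimated instantaneous LV pressure P(t) in mmHg over [t_mvc, t_mvo].

    Curves built by :func:`scale_to_cycle` carry their closed-form
    template, which :func:`pressure_at` evaluates exactly; curves built
    from raw samples (``template=None``) are linearly interpolated.
    """

    times: np.ndarray
    pressures: np.ndarray
    events: ValveEvents
    sbp: float
    template: "ReferenceTemplate | None" = None

    def __post_init__(self) -> None:
        if self.times.shape != self.pressures.shape:
            raise ValidationError("times and pressures must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time grid must be strictly increasing")

    def __call__(self, t):
        return pressure_at(self, t)


def build_reference_curve(
    n_samples: int, template: ReferenceTemplate = RAISED_COSINE_TEMPLATE
) -> ReferenceCurve:
    """Sample the normalized reference pressure shape on ``n_samples`` points.

    The grid is uniform on phase-normalized time [0, 1] with the phase
    boundaries and the ejection peak inserted, so the anchors (value 0 at
    mitral valve closure, 1 at the ejection peak) are hit exactly at any
    resolution and two grids agree exactly at shared phase points.
    """
    if not isinstance(n_samples, (int, np.integer)) or n_samples < 16:
        raise ResolutionError(f"n_samples must be an integer >= 16, got {n_samples}")
    u = np.union1d(np.linspace(0.0, 1.0, n_samples), template.anchor_phases)
    return ReferenceCurve(phase=u, values=template(u), template=template)


def scale_to_cycle(
    template: ReferenceCurve | ReferenceTemplate,
    events: ValveEvents,
    cuff: CuffPressure,
    dt: float | None = None,
) -> LVPressureCurve:
    """Stretch the reference shape to a subject's cycle and scale to cuff SBP.

    Each template phase segment is independently time-stretched so its
    boundaries land exactly on the subject's valve events, and the
    amplitude is scaled so the curve peak equals the systolic cuff
    pressure.  The curve is sampled at uniform ``dt`` over
    [t_mvc, t_mvo] with the valve-event and peak times inserted into the
    grid so the phase anchors are represented exactly.

    Parameters
    ----------
    template
        A :class:`ReferenceCurve` (its closed-form template is used) or a
        bare :class:`ReferenceTemplate`.
    events
        Valve-event timings for the cycle.
    cuff
        Cuff pressures; only SBP enters the curve.
    dt
        Sampling step in seconds; defaults to cycle duration / 2000, well
        below echocardiographic frame intervals so downstream integration
        error is strain-resolution-limited.
    """
    shape = template.template if isinstance(template, ReferenceCurve) else template
    if dt is None:
        dt = events.duration / 2000.0
    if not (dt > 0):
        raise ResolutionError(f"dt must be positive, got {dt}")
    if dt >= events.t_avo - events.t_mvc:
        raise ResolutionError(
            f"dt={dt} is too coarse: it must resolve the isovolumic "
            f"contraction phase of duration {events.t_avo - events.t_mvc}"
        )
    grid = np.arange(events.t_mvc, events.t_mvo, dt)
    anchors = [shape.time_of_phase(u, events) for u in shape.anchor_phases]
    t = np.union1d(grid, anchors)  # includes t_mvc, t_avo, t_avc, peak, t_mvo
    pressures = cuff.sbp * shape(shape.phase_of_time(t, events))
    return LVPressureCurve(
        times=t, pressures=pressures, events=events, sbp=cuff.sbp, template=shape
    )


def pressure_at(curve: LVPressureCurve, t):
    """Evaluate the pressure curve at time(s) ``t``.

    Template-backed curves are evaluated through their closed form (so
    grid refinement leaves values unchanged); sample-backed curves are
    linearly interpolated.  Raises :class:`DomainError` for queries
    outside [t_mvc, t_mvo].
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = curve.times[0], curve.times[-1]
    eps = 1e-12 * max(1.0, hi)
    if np.any(t_arr < lo - eps) or np.any(t_arr > hi + eps):
        raise DomainError(
            f"query time outside pressure-curve domain [{lo}, {hi}]"
        )
    t_clip = np.clip(t_arr, lo, hi)
    if curve.template is not None:
        out = curve.sbp * curve.template(curve.template.phase_of_time(
            t_clip, curve.events))
    else:
        out = np.interp(t_clip, curve.times, curve.pressures)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
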