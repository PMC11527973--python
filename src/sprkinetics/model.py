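"""Core data types and forward simulation of SPR sensorgrams.

The binding model is a sum of independent pseudo-first-order (Langmuir)
site classes.  Each class ``i`` binds the flowing analyte at concentration
``C`` with association rate constant ``ka_i`` (M^-1 s^-1), dissociates with
``kd_i`` (s^-1) and saturates at ``rmax_i`` resonance units (RU):

    dR_i/dt = ka_i * C * (rmax_i - R_i) - kd_i * R_i

With ``C`` piecewise constant over the injection schedule this integrates
segment-by-segment in closed form, so an n-site sensorgram is a sum of n
exponential relaxations per phase ("1+1" for n=1, "sum2exp"/heterogeneous
ligand for n=2, "sum3exp" for n=3).  An optional bulk refractive-index
offset is added as a box during injections, and an optional two-compartment
mass-transport limitation (coefficient ``kt``) replaces the closed form by
a quasi-steady-state ODE system.

Units are molar, seconds and RU throughout; no unit inference is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ASSOCIATION",
    "DISSOCIATION",
    "InjectionSegment",
    "InjectionSchedule",
    "Sensorgram",
    "BindingComponent",
    "KineticModel",
    "SurfaceContext",
    "equilibrium_kd",
    "equilibrium_response",
    "simulate_component_association",
    "simulate_component_dissociation",
    "simulate_response",
    "simulate_component_response",
    "simulate_response_transport_limited",
]

ASSOCIATION = "association"
DISSOCIATION = "dissociation"

#: declared instrument sampling range (points per second)
SAMPLING_RATE_RANGE_HZ = (10.0, 40.0)

#: single-cycle titrations are limited to 5 injections and one dissociation
MAX_SINGLE_CYCLE_INJECTIONS = 5


class ScheduleError(ValueError):
    """Raised for injection schedules that violate instrument constraints."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InjectionSegment:
    """One constant-concentration interval of an injection schedule.

    ``kind`` is ``"association"`` (analyte flowing, ``concentration_M > 0``)
    or ``"dissociation"`` (buffer flowing, ``concentration_M == 0``).
    Intervals are half-open ``[start_s, end_s)``: a time point exactly at a
    boundary belongs to the later segment.
    """

    kind: Literal["association", "dissociation"]
    start_s: float
    end_s: float
    concentration_M: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (ASSOCIATION, DISSOCIATION):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ValueError("segment must satisfy end_s > start_s")
        if self.concentration_M < 0:
            raise ValueError("concentration_M must be >= 0")
        if self.kind == DISSOCIATION and self.concentration_M != 0:
            raise ValueError("dissociation segments require concentration_M == 0")
        if self.kind == ASSOCIATION and self.concentration_M == 0:
            raise ValueError("association segments require concentration_M > 0")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered, contiguous association/dissociation segments.

    ``full_kinetics``: one association followed by one dissociation segment
    (one cycle per analyte concentration of a dilution series).
    ``single_cycle``: up to 5 consecutive injections followed by a single
    terminal dissociation, used when dissociation is too slow to regenerate
    the surface between cycles.
    """

    segments: tuple[InjectionSegment, ...]
    schedule_type: Literal["full_kinetics", "single_cycle"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ScheduleError("schedule needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end_s != b.start_s:
                raise ScheduleError("segments must be contiguous")
        n_assoc = sum(s.kind == ASSOCIATION for s in self.segments)
        if self.schedule_type == "full_kinetics":
            kinds = [s.kind for s in self.segments]
            if kinds != [ASSOCIATION, DISSOCIATION]:
                raise ScheduleError(
                    "full_kinetics requires exactly one association followed "
                    "by one dissociation segment"
                )
        elif self.schedule_type == "single_cycle":
            if n_assoc > MAX_SINGLE_CYCLE_INJECTIONS:
                raise ScheduleError(
                    f"single-cycle kinetics are limited to "
                    f"{MAX_SINGLE_CYCLE_INJECTIONS} injections "
                    f"(got {n_assoc})"
                )
            if self.segments[-1].kind != DISSOCIATION or any(
                s.kind == DISSOCIATION for s in self.segments[:-1]
            ):
                raise ScheduleError(
                    "single_cycle requires exactly one terminal dissociation segment"
                )
        else:
            raise ScheduleError(f"unknown schedule_type {self.schedule_type!r}")

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    def segment_index(self, t: np.ndarray) -> np.ndarray:
        """Segment index per time point (half-open convention)."""
        starts = np.array([s.start_s for s in self.segments])
        idx = np.searchsorted(starts, t, side="right") - 1
        return np.clip(idx, 0, len(self.segments) - 1)

    def concentration_at(self, t: np.ndarray) -> np.ndarray:
        conc = np.array([s.concentration_M for s in self.segments])
        return conc[self.segment_index(np.asarray(t, dtype=float))]

    @staticmethod
    def full_kinetics(
        concentration_M: float, t_assoc_s: float, t_dissoc_s: float
    ) -> "InjectionSchedule":
        return InjectionSchedule(
            (
                InjectionSegment(ASSOCIATION, 0.0, t_assoc_s, concentration_M),
                InjectionSegment(
                    DISSOCIATION, t_assoc_s, t_assoc_s + t_dissoc_s, 0.0
                ),
            ),
            "full_kinetics",
        )

    @staticmethod
    def single_cycle(
        concentrations_M: Sequence[float],
        t_inject_s: float,
        t_dissoc_s: float = 600.0,
    ) -> "InjectionSchedule":
        if len(concentrations_M) > MAX_SINGLE_CYCLE_INJECTIONS:
            raise ScheduleError(
                f"single-cycle kinetics are limited to "
                f"{MAX_SINGLE_CYCLE_INJECTIONS} injections "
                f"(got {len(concentrations_M)})"
            )
        segs = []
        t = 0.0
        for c in concentrations_M:
            segs.append(InjectionSegment(ASSOCIATION, t, t + t_inject_s, c))
            t += t_inject_s
        segs.append(InjectionSegment(DISSOCIATION, t, t + t_dissoc_s, 0.0))
        return InjectionSchedule(tuple(segs), "single_cycle")


@dataclass
class Sensorgram:
    """One response-vs-time trace with its schedule and metadata."""

    time_s: np.ndarray
    response_RU: np.ndarray
    schedule: InjectionSchedule
    curve_id: str = ""
    concentration_M: float | None = None
    sampling_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_RU = np.asarray(self.response_RU, dtype=float)
        if self.time_s.ndim != 1 or self.response_RU.shape != self.time_s.shape:
            raise ValueError("time_s and response_RU must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if self.sampling_rate_hz is not None:
            lo, hi = SAMPLING_RATE_RANGE_HZ
            if not lo <= self.sampling_rate_hz <= hi:
                raise ValueError(
                    f"sampling_rate_hz outside instrument range {lo}-{hi} Hz"
                )


@dataclass(frozen=True)
class BindingComponent:
    """One independent site class: ka (M^-1 s^-1), kd (s^-1), rmax (RU)."""

    ka: float
    kd: float
    rmax: float

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise ValueError("ka must be > 0")
        if self.kd < 0:
            raise ValueError("kd must be >= 0")
        if not self.rmax > 0:
            raise ValueError("rmax must be > 0")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant kd/ka (M)."""
        return equilibrium_kd(self)


@dataclass(frozen=True)
class KineticModel:
    """1-3 independent binding components plus optional bulk RI / transport.

    Components are stored in canonical order: ascending kd, the
    slowest-dissociating class first.  ``bulk_ri_RU`` is a refractive-index
    offset present only while an injection runs; ``transport_kt`` (RU M^-1
    s^-1) switches on the two-compartment mass-transport limitation.
    """

    components: tuple[BindingComponent, ...]
    bulk_ri_RU: float = 0.0
    transport_kt: float | None = None

    def __post_init__(self) -> None:
        comps = tuple(sorted(self.components, key=lambda c: c.kd))
        if not 1 <= len(comps) <= 3:
            raise ValueError("KineticModel supports 1-3 components")
        object.__setattr__(self, "components", comps)
        if self.transport_kt is not None and not self.transport_kt > 0:
            raise ValueError("transport_kt must be > 0 when present")

    @property
    def order(self) -> int:
        return len(self.components)

    @property
    def rmax_total(self) -> float:
        return sum(c.rmax for c in self.components)

    def with_transport(self, kt: float | None) -> "KineticModel":
        return replace(self, transport_kt=kt)


@dataclass(frozen=True)
class SurfaceContext:
    """Chip-surface metadata: which fibril at what immobilized density."""

    surface_name: str
    immobilized_density_RU: float
    fibril_name: str = ""
    drift_model: object | None = None

    def __post_init__(self) -> None:
        if not self.immobilized_density_RU > 0:
            raise ValueError("immobilized_density_RU must be > 0")


# ---------------------------------------------------------------------------
# closed-form simulation
# ---------------------------------------------------------------------------


def equilibrium_kd(comp: BindingComponent) -> float:
    """KD = kd/ka; undefined (raises) for an irreversible site (kd == 0)."""
    if comp.kd == 0:
        raise ValueError("equilibrium KD undefined for kd == 0")
    return comp.kd / comp.ka


def equilibrium_response(model: KineticModel, C) -> np.ndarray | float:
    """Steady-state binding isotherm Req(C) = sum_i rmax_i * C / (C + KD_i).

    Irreversible components (kd == 0) saturate fully for any C > 0.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be >= 0")
    req = np.zeros_like(C)
    for c in model.components:
        kobs = c.ka * C + c.kd
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(kobs > 0, c.rmax * c.ka * C / np.where(kobs > 0, kobs, 1.0), 0.0)
        req = req + term
    return req if req.ndim else float(req)


def simulate_component_association(
    comp: BindingComponent, C: float, R0: float, t
) -> np.ndarray | float:
    """Closed-form single-site response during a constant-C injection.

    R(t) = Req + (R0 - Req) * exp(-(ka*C + kd) * t) with
    Req = rmax * ka * C / (ka*C + kd).
    """
    if C < 0:
        raise ValueError("concentration must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if not 0 <= R0 <= comp.rmax:
        raise ValueError("R0 must satisfy 0 <= R0 <= rmax")
    kobs = comp.ka * C + comp.kd
    if kobs == 0:  # kd == 0 and C == 0: nothing moves
        out = np.full_like(t, R0)
        return out if out.ndim else float(out)
    req = comp.rmax * comp.ka * C / kobs
    out = req + (R0 - req) * np.exp(-kobs * t)
    return out if out.ndim else float(out)


def simulate_component_dissociation(
    comp: BindingComponent, R0: float, t
) -> np.ndarray | float:
    """Exponential decay R0 * exp(-kd * t) during buffer flow."""
    if R0 < 0:
        raise ValueError("R0 must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = R0 * np.exp(-comp.kd * t)
    return out if out.ndim else float(out)


def _component_segment_step(
    comp: BindingComponent, C: float, R0: float, dt
) -> np.ndarray | float:
    """Bound level of one component dt after a segment start (any C >= 0)."""
    if C > 0:
        return simulate_component_association(comp, C, R0, dt)
    return simulate_component_dissociation(comp, R0, dt)


def simulate_component_response(
    comp: BindingComponent, schedule: InjectionSchedule, t_grid
) -> np.ndarray:
    """One component's bound level over a whole schedule, chained across
    segment boundaries with continuity of bound mass (starting from R0=0)."""
    t_grid = np.asarray(t_grid, dtype=float)
    _check_grid(schedule, t_grid)
    idx = schedule.segment_index(t_grid)
    out = np.empty_like(t_grid)
    r0 = 0.0
    for i, seg in enumerate(schedule.segments):
        mask = idx == i
        if np.any(mask):
            out[mask] = _component_segment_step(
                comp, seg.concentration_M, r0, t_grid[mask] - seg.start_s
            )
        r0 = float(
            _component_segment_step(comp, seg.concentration_M, r0, seg.duration_s)
        )
    return out


def _check_grid(schedule: InjectionSchedule, t_grid: np.ndarray) -> None:
    if t_grid.size == 0:
        raise ValueError("t_grid is empty")
    if t_grid.min() < schedule.start_s or t_grid.max() > schedule.end_s:
        raise ValueError("t_grid extends outside the schedule span")


def simulate_response(
    model: KineticModel, schedule: InjectionSchedule, t_grid
) -> np.ndarray:
    """Total closed-form response: sum of component traces plus the bulk-RI
    box during association segments.  Independent-site additivity is exact."""
    t_grid = np.asarray(t_grid, dtype=float)
    _check_grid(schedule, t_grid)
    total = np.zeros_like(t_grid)
    for comp in model.components:
        total += simulate_component_response(comp, schedule, t_grid)
    if model.bulk_ri_RU:
        idx = schedule.segment_index(t_grid)
        kinds = np.array([s.kind == ASSOCIATION for s in schedule.segments])
        total = total + model.bulk_ri_RU * kinds[idx]
    return total


# ---------------------------------------------------------------------------
# transport-limited simulation (two-compartment quasi-steady state)
# ---------------------------------------------------------------------------


def _surface_concentration(model: KineticModel, C: float, R: np.ndarray) -> float:
    """Algebraic QSS surface concentration Cs solving
    kt*(C - Cs) = sum_i [ka_i*Cs*(rmax_i - R_i) - kd_i*R_i]."""
    kt = model.transport_kt
    num = kt * C + sum(c.kd * r for c, r in zip(model.components, R))
    den = kt + sum(c.ka * (c.rmax - r) for c, r in zip(model.components, R))
    return num / den


def simulate_response_transport_limited(
    model: KineticModel, schedule: InjectionSchedule, t_grid, rtol: float = 1e-8
) -> np.ndarray:
    """Mass-transport-limited sensorgram.

    Integrates dR_i/dt = ka_i*Cs*(rmax_i - R_i) - kd_i*R_i with the
    quasi-steady-state surface concentration Cs; converges to
    :func:`simulate_response` as kt -> infinity.
    """
    if model.transport_kt is None or not model.transport_kt > 0:
        raise ValueError("model.transport_kt must be present and > 0")
    t_grid = np.asarray(t_grid, dtype=float)
    _check_grid(schedule, t_grid)
    idx = schedule.segment_index(t_grid)
    out = np.zeros((len(model.components), t_grid.size))
    r0 = np.zeros(len(model.components))
    for i, seg in enumerate(schedule.segments):
        C = seg.concentration_M

        def rhs(t, R, C=C):
            cs = _surface_concentration(model, C, R)
            return np.array(
                [c.ka * cs * (c.rmax - r) - c.kd * r for c, r in zip(model.components, R)]
            )

        mask = idx == i
        seg_t = t_grid[mask]
        # evaluate at the in-segment grid points plus the segment end, which
        # carries the state into the next segment
        t_eval = np.unique(np.concatenate([seg_t, [seg.end_s]]))
        sol = solve_ivp(
            rhs,
            (seg.start_s, seg.end_s),
            r0,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"transport ODE integration failed: {sol.message}")
        if seg_t.size:
            pos = np.searchsorted(sol.t, seg_t)
            out[:, mask] = sol.y[:, pos]
        r0 = sol.y[:, -1]
    total = out.sum(axis=0)
    if model.bulk_ri_RU:
        kinds = np.array([s.kind == ASSOCIATION for s in schedule.segments])
        total = total + model.bulk_ri_RU * kinds[idx]
    return total
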