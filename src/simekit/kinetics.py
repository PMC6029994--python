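"""Two-tissue-compartment forward model.

The regional PET signal is modelled as

    E(t) = (1 - V_b) * (C_P ⊛ h)(t) + V_b * C_WB(t)

where ``h`` is the analytic impulse response of the reversible two-tissue
compartment model and ``V_b`` the fractional blood volume (fixed at 5% by
default, never fitted).  Measured frame values are the average of ``E`` over
each acquisition frame.

Numerics: ``C_P`` and ``h`` are evaluated on a uniform fine grid (default
0.01 min), convolved by FFT with trapezoid end corrections, and averaged
within frames via the cumulative trapezoid integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import InvalidParameterError, ScheduleError, UndefinedMetricError

__all__ = [
    "KineticParams",
    "FrameSchedule",
    "RegionTAC",
    "impulse_response",
    "fine_grid",
    "convolve_input",
    "frame_average",
    "model_tac",
    "volume_of_distribution",
    "binding_potential",
]

DEFAULT_VB = 0.05
DEFAULT_FINE_STEP = 0.01  # minutes

#: discriminant threshold below which the repeated-root limit form is used
_REPEATED_ROOT_TOL = 1e-12


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of one region: K1 (mL/cm3/min), k2..k4 (1/min), V_b."""

    k1: float
    k2: float
    k3: float
    k4: float
    vb: float = DEFAULT_VB

    def __post_init__(self) -> None:
        vals = (self.k1, self.k2, self.k3, self.k4, self.vb)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"KineticParams: non-finite value in {vals}")
        if self.k1 < 0 or self.k2 < 0 or self.k3 < 0 or self.k4 < 0:
            raise InvalidParameterError(f"KineticParams: rates must be >= 0, got {vals}")
        if not 0 <= self.vb < 1:
            raise InvalidParameterError(f"KineticParams: vb must be in [0, 1), got {self.vb}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4])


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-PET frames (minutes)."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.shape != durations.shape or starts.ndim != 1 or starts.size == 0:
            raise ScheduleError("FrameSchedule: malformed starts/durations")
        if np.any(durations <= 0):
            raise ScheduleError("FrameSchedule: frame durations must be > 0")
        ends = starts + durations
        if not np.allclose(starts[1:], ends[:-1], atol=1e-9):
            raise ScheduleError("FrameSchedule: frames must be contiguous and non-overlapping")

    @classmethod
    def default(cls) -> "FrameSchedule":
        """35-frame, 90-min schedule: 6x5s, 10x15s, 4x30s, 5x2min, 5x5min, 5x10min."""
        durations = np.concatenate(
            [
                np.full(6, 5.0 / 60.0),
                np.full(10, 15.0 / 60.0),
                np.full(4, 30.0 / 60.0),
                np.full(5, 2.0),
                np.full(5, 5.0),
                np.full(5, 10.0),
            ]
        )
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def t_end(self) -> float:
        return float(self.ends[-1])

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    def truncated(self, t_end: float) -> "FrameSchedule":
        """Keep only frames fully inside [0, t_end]."""
        keep = self.ends <= t_end + 1e-9
        if not np.any(keep):
            raise ScheduleError(f"FrameSchedule: no frames inside [0, {t_end}]")
        return FrameSchedule(self.starts[keep], self.durations[keep])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.durations, other.durations)
        )

    def __hash__(self) -> int:
        return hash((self.starts.tobytes(), self.durations.tobytes()))


@dataclass
class RegionTAC:
    """Frame-averaged activity of one region (kBq/mL)."""

    region: str
    schedule: FrameSchedule
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.schedule.starts.shape:
            raise InvalidParameterError(
                f"RegionTAC {self.region!r}: expected {self.schedule.n_frames} values, "
                f"got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError(f"RegionTAC {self.region!r}: non-finite values")


def impulse_response(kp: KineticParams, t) -> np.ndarray:
    """Analytic impulse response of the two-tissue compartment model.

    ``h(t) = K1/(a2-a1) [(k3+k4-a1) e^{-a1 t} + (a2-k3-k4) e^{-a2 t}]`` with
    ``a_{1,2} = [(k2+k3+k4) ∓ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2``.  Near a
    repeated root the analytic limit ``K1 e^{-a t} (1 + (k3+k4-a) t)`` is used.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("impulse_response: t must be >= 0")
    s = kp.k2 + kp.k3 + kp.k4
    disc = s * s - 4.0 * kp.k2 * kp.k4
    if disc < _REPEATED_ROOT_TOL:
        alpha = s / 2.0
        return kp.k1 * np.exp(-alpha * t) * (1.0 + (kp.k3 + kp.k4 - alpha) * t)
    sq = np.sqrt(disc)
    a1 = (s - sq) / 2.0
    a2 = (s + sq) / 2.0
    return (kp.k1 / (a2 - a1)) * (
        (kp.k3 + kp.k4 - a1) * np.exp(-a1 * t) + (a2 - kp.k3 - kp.k4) * np.exp(-a2 * t)
    )


def fine_grid(t_end: float, step: float = DEFAULT_FINE_STEP) -> np.ndarray:
    """Uniform grid [0, t_end] including the endpoint."""
    n = int(round(t_end / step))
    return np.linspace(0.0, n * step, n + 1)


def convolve_input(cp: np.ndarray, h: np.ndarray, step: float) -> np.ndarray:
    """Trapezoid-corrected discrete convolution ``(cp ⊛ h)`` on a uniform grid."""
    n = cp.size
    full = fftconvolve(cp, h)[:n]
    return step * (full - 0.5 * cp[0] * h - 0.5 * h[0] * cp)


def frame_average(values: np.ndarray, t: np.ndarray, sched: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve within each frame via the cumulative trapezoid."""
    if sched.t_end > t[-1] + 1e-9:
        raise ScheduleError("frame_average: schedule extends past the sampled grid")
    dt = np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * dt * (values[1:] + values[:-1]))])

    def cum_at(x):
        # partial trapezoid up to x from the preceding grid point; exact at nodes
        idx = np.clip(np.searchsorted(t, x, side="right") - 1, 0, t.size - 1)
        vx = np.interp(x, t, values)
        return cum[idx] + 0.5 * (x - t[idx]) * (values[idx] + vx)

    return (cum_at(sched.ends) - cum_at(sched.starts)) / sched.durations


def model_tac(
    parent: Callable[[np.ndarray], np.ndarray],
    wb: Callable[[np.ndarray], np.ndarray],
    kp: KineticParams,
    sched: FrameSchedule,
    step: float = DEFAULT_FINE_STEP,
    region: str = "model",
) -> RegionTAC:
    """Forward-model a regional TAC by frame-averaging E(t).

    ``parent`` and ``wb`` are callables evaluable over [0, schedule end].  In
    original-SIME mode the caller passes the parent curve for ``wb`` as well
    (the whole-blood term is replaced by the parent AIF).
    """
    t_end = sched.t_end
    if hasattr(wb, "t_end") and wb.t_end < t_end - 1e-9:
        raise ScheduleError(
            f"model_tac: schedule end {t_end} min extends past whole-blood domain "
            f"{wb.t_end} min"
        )
    t = fine_grid(t_end, step)
    cp = np.asarray(parent(t), dtype=float)
    h = impulse_response(kp, t)
    conv = convolve_input(cp, h, t[1] - t[0])
    e = (1.0 - kp.vb) * conv + kp.vb * np.asarray(wb(t), dtype=float)
    return RegionTAC(region, sched, frame_average(e, t, sched))


def volume_of_distribution(kp: KineticParams) -> float:
    """Total volume of distribution ``V_T = K1/k2 (1 + k3/k4)`` (mL/cm3)."""
    if kp.k2 <= 0 or kp.k4 <= 0:
        raise UndefinedMetricError(
            f"volume_of_distribution: requires k2 > 0 and k4 > 0, got k2={kp.k2}, k4={kp.k4}"
        )
    return (kp.k1 / kp.k2) * (1.0 + kp.k3 / kp.k4)


def binding_potential(v_t: float, v_nd: float) -> float:
    """Non-displaceable binding potential ``(V_T - V_ND)/V_ND``."""
    if v_nd <= 0:
        raise UndefinedMetricError(f"binding_potential: v_nd must be > 0, got {v_nd}")
    return (v_t - v_nd) / v_nd
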