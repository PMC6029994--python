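"""Parametric arterial-input-function models.

Three building blocks are provided:

* a bolus-shaped parent plasma curve (linear-rise gamma-variate term plus two
  exponentials) used by the unconstrained simultaneous-estimation variant,
* a Hill-type parent fraction describing metabolite build-up, and
* a straight-line plasma-to-whole-blood ratio.

The constrained parent AIF is the product ``C_WB(t) * f_Hill(t) * C_ratio(t)``
of a measured whole-blood curve with the last two models.  All times are in
minutes, activities in kBq/mL, rate constants in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "FengParams",
    "HillParams",
    "RatioParams",
    "WholeBloodCurve",
    "feng_aif",
    "hill_fraction",
    "ratio_line",
    "constrained_parent_aif",
    "aif_jacobian",
]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise InvalidParameterError(f"{name}: non-finite parameter value {v!r}")


@dataclass(frozen=True)
class FengParams:
    """Parameters of the bolus input model.

    ``a1`` is the linear-rise coefficient (kBq/mL/min); ``a2``/``a3`` are
    exponential amplitudes (kBq/mL); ``lam1 > lam2 > lam3 > 0`` are decay
    rates (1/min), ordered so the gamma-variate term is the fast component.
    """

    a1: float
    a2: float
    a3: float
    lam1: float
    lam2: float
    lam3: float

    def __post_init__(self) -> None:
        _require_finite(
            "FengParams", self.a1, self.a2, self.a3, self.lam1, self.lam2, self.lam3
        )
        if self.a1 <= 0:
            raise InvalidParameterError(f"FengParams: a1 must be > 0, got {self.a1}")
        if not (self.lam1 > self.lam2 > self.lam3 > 0):
            raise InvalidParameterError(
                "FengParams: decay rates must satisfy lam1 > lam2 > lam3 > 0, got "
                f"({self.lam1}, {self.lam2}, {self.lam3})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.lam1, self.lam2, self.lam3])


@dataclass(frozen=True)
class HillParams:
    """Hill parent-fraction parameters.

    ``a`` is the asymptotic parent fraction in [0, 1], ``b > 0`` the steepness
    exponent, ``c > 0`` the half-transition scale (min**b).
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        _require_finite("HillParams", self.a, self.b, self.c)
        if not 0 <= self.a <= 1:
            raise InvalidParameterError(f"HillParams: a must be in [0, 1], got {self.a}")
        if self.b <= 0:
            raise InvalidParameterError(f"HillParams: b must be > 0, got {self.b}")
        if self.c <= 0:
            raise InvalidParameterError(f"HillParams: c must be > 0, got {self.c}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])


@dataclass(frozen=True)
class RatioParams:
    """Straight-line plasma-to-whole-blood ratio: ``ratio(t) = d*t + e``."""

    d: float
    e: float

    def __post_init__(self) -> None:
        _require_finite("RatioParams", self.d, self.e)
        if self.e <= 0:
            raise InvalidParameterError(f"RatioParams: e must be > 0, got {self.e}")

    def as_array(self) -> np.ndarray:
        return np.array([self.d, self.e])


class WholeBloodCurve:
    """Whole-blood activity curve evaluable at arbitrary times.

    Linear interpolation between samples; zero before the first sample time
    and constant extrapolation of the last value beyond it.  Evaluation at a
    stored sample time returns the stored activity exactly.
    """

    def __init__(self, times, activities) -> None:
        times = np.asarray(times, dtype=float)
        activities = np.asarray(activities, dtype=float)
        if times.ndim != 1 or times.shape != activities.shape:
            raise InvalidParameterError("WholeBloodCurve: times/activities shape mismatch")
        if times.size < 2:
            raise InvalidParameterError("WholeBloodCurve: need at least 2 samples")
        if not np.all(np.diff(times) > 0):
            raise InvalidParameterError("WholeBloodCurve: times must be strictly increasing")
        if not np.all(np.isfinite(activities)) or np.any(activities < 0):
            raise InvalidParameterError("WholeBloodCurve: activities must be finite and >= 0")
        self.times = times
        self.activities = activities

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.times, self.activities, left=0.0, right=self.activities[-1])

    def scaled(self, factor: float) -> "WholeBloodCurve":
        return WholeBloodCurve(self.times, self.activities * factor)


def feng_aif(p: FengParams, t) -> np.ndarray:
    """Evaluate the bolus input model.

    ``C_P(t) = (a1*t - a2 - a3) e^{-lam1 t} + a2 e^{-lam2 t} + a3 e^{-lam3 t}``.
    The early negative lobe of the first term is not clipped: the functional
    form guarantees ``C_P(0) = 0`` and fitting bounds keep the curve physical.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("feng_aif: t must be >= 0")
    return (
        (p.a1 * t - p.a2 - p.a3) * np.exp(-p.lam1 * t)
        + p.a2 * np.exp(-p.lam2 * t)
        + p.a3 * np.exp(-p.lam3 * t)
    )


def hill_fraction(p: HillParams, t) -> np.ndarray:
    """Parent fraction ``f(t) = 1 - (1 - a) t^b / (c + t^b)``.

    Monotonically non-increasing from 1 at t=0 toward the asymptote ``a``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("hill_fraction: t must be >= 0")
    tb = np.power(t, p.b)
    return 1.0 - (1.0 - p.a) * tb / (p.c + tb)


def ratio_line(p: RatioParams, t) -> np.ndarray:
    """Plasma/whole-blood ratio ``d*t + e``; must stay positive on the grid."""
    t = np.asarray(t, dtype=float)
    r = p.d * t + p.e
    if np.any(r <= 0):
        raise InvalidParameterError(
            "ratio_line: d*t + e must be > 0 over the requested grid "
            f"(min value {r.min():.4g})"
        )
    return r


def constrained_parent_aif(wb: WholeBloodCurve, h: HillParams, r: RatioParams, t) -> np.ndarray:
    """Parent AIF as the product ``C_WB(t) * f_Hill(t) * C_ratio(t)``."""
    t = np.asarray(t, dtype=float)
    return wb(t) * hill_fraction(h, t) * ratio_line(r, t)


def _feng_jacobian(p: FengParams, t: np.ndarray) -> np.ndarray:
    e1 = np.exp(-p.lam1 * t)
    e2 = np.exp(-p.lam2 * t)
    e3 = np.exp(-p.lam3 * t)
    cols = [
        t * e1,                                   # d/da1
        e2 - e1,                                  # d/da2
        e3 - e1,                                  # d/da3
        -t * (p.a1 * t - p.a2 - p.a3) * e1,       # d/dlam1
        -t * p.a2 * e2,                           # d/dlam2
        -t * p.a3 * e3,                           # d/dlam3
    ]
    return np.column_stack(cols)


def _hill_jacobian(p: HillParams, t: np.ndarray) -> np.ndarray:
    tb = np.power(t, p.b)
    denom = p.c + tb
    d_a = tb / denom
    # t^b * log t -> 0 as t -> 0+ for b > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tb_logt = np.where(t > 0, tb * np.log(np.where(t > 0, t, 1.0)), 0.0)
    d_b = -(1.0 - p.a) * p.c * tb_logt / denom**2
    d_c = (1.0 - p.a) * tb / denom**2
    return np.column_stack([d_a, d_b, d_c])


def aif_jacobian(model_id: str, params, t, wb: WholeBloodCurve | None = None) -> np.ndarray:
    """Analytic Jacobian of an AIF model w.r.t. its parameters.

    Parameters
    ----------
    model_id
        ``"feng"`` (columns a1, a2, a3, lam1, lam2, lam3) or ``"constrained"``
        (columns a, b, c, d, e; requires ``wb`` and ``params=(HillParams,
        RatioParams)``).
    """
    t = np.asarray(t, dtype=float)
    if model_id == "feng":
        if not isinstance(params, FengParams):
            raise InvalidParameterError("aif_jacobian: feng model expects FengParams")
        return _feng_jacobian(params, t)
    if model_id == "constrained":
        try:
            h, r = params
        except (TypeError, ValueError) as exc:
            raise InvalidParameterError(
                "aif_jacobian: constrained model expects (HillParams, RatioParams)"
            ) from exc
        if wb is None:
            raise InvalidParameterError("aif_jacobian: constrained model requires wb")
        wb_t = wb(t)
        f = hill_fraction(h, t)
        ratio = ratio_line(r, t)
        jh = _hill_jacobian(h, t)  # d f / d(a,b,c)
        cols = [
            wb_t * ratio * jh[:, 0],
            wb_t * ratio * jh[:, 1],
            wb_t * ratio * jh[:, 2],
            wb_t * f * t,   # d/dd
            wb_t * f,       # d/de
        ]
        return np.column_stack(cols)
    raise InvalidParameterError(f"aif_jacobian: unknown model id {model_id!r}")
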