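"""Gold-standard metabolite correction from arterial blood samples.

Fits the Hill parent fraction to measured metabolite fractions, fits the
plasma/whole-blood ratio line, and assembles the metabolite-corrected parent
AIF as the product of the interpolated whole-blood curve with both fits,
optionally after a rigid time shift compensating the artery-to-brain delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .aif_models import HillParams, RatioParams, WholeBloodCurve, hill_fraction, ratio_line
from .exceptions import DegenerateFitError, InvalidParameterError

__all__ = [
    "BloodSampleSet",
    "SampleBasedAif",
    "fit_hill_to_samples",
    "fit_ratio_to_samples",
    "sample_based_aif",
    "curve_auc",
    "PEAK_WINDOW",
    "TAIL_WINDOW",
]

#: default peak/tail AUC windows (min); the 3-min split is a convention
PEAK_WINDOW = (0.0, 3.0)
TAIL_WINDOW = (3.0, 90.0)


@dataclass
class BloodSampleSet:
    """Arterial samples: whole-blood/plasma counts plus parent-fraction assays."""

    times: np.ndarray
    wholeblood: np.ndarray
    plasma: np.ndarray
    pf_times: np.ndarray
    pf_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wholeblood = np.asarray(self.wholeblood, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        self.pf_times = np.asarray(self.pf_times, dtype=float)
        self.pf_values = np.asarray(self.pf_values, dtype=float)
        if not (self.times.shape == self.wholeblood.shape == self.plasma.shape):
            raise InvalidParameterError("BloodSampleSet: sample array shape mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("BloodSampleSet: times must be strictly increasing")
        if np.any(self.wholeblood < 0) or np.any(self.plasma < 0):
            raise InvalidParameterError("BloodSampleSet: counts must be >= 0")
        if self.pf_times.shape != self.pf_values.shape:
            raise InvalidParameterError("BloodSampleSet: parent-fraction shape mismatch")
        if np.any(self.pf_values < 0) or np.any(self.pf_values > 1):
            raise InvalidParameterError("BloodSampleSet: parent fractions must be in [0, 1]")


def fit_hill_to_samples(times, fractions, x0: tuple | None = None):
    """Bounded least-squares Hill fit to measured parent fractions.

    Returns ``(HillParams, residuals)``.  Requires >= 3 samples; a constant
    fraction profile (no observable metabolism) is rejected as degenerate.
    """
    times = np.asarray(times, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if times.size < 3:
        raise InvalidParameterError("fit_hill_to_samples: need >= 3 samples for 3 parameters")
    if np.allclose(fractions, fractions[0]):
        raise DegenerateFitError(
            "fit_hill_to_samples: all fractions identical; Hill parameters unidentifiable"
        )

    lo = np.array([0.0, 1e-3, 1e-6])
    hi = np.array([1.0, 10.0, 1e4])

    def residuals(x):
        tb = np.power(times, x[1])
        return (1.0 - (1.0 - x[0]) * tb / (x[2] + tb)) - fractions

    a0 = float(np.clip(fractions.min(), 0.0, 1.0))
    if x0 is not None:
        starts = [np.clip(np.asarray(x0, dtype=float), lo + 1e-12, hi)]
    else:
        t_mid = float(np.median(times))
        starts = [
            np.clip(np.array([a0, b0, t_mid**b0]), lo + 1e-12, hi)
            for b0 in (0.5, 1.5, 3.0)
        ]
    best = None
    for s in starts:
        sol = least_squares(residuals, s, bounds=(lo, hi), method="trf", ftol=1e-15, xtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    params = HillParams(*best.x)
    return params, residuals(best.x)


def fit_ratio_to_samples(times, plasma, wholeblood) -> RatioParams:
    """Ordinary least-squares line through plasma/whole-blood ratios vs time."""
    times = np.asarray(times, dtype=float)
    plasma = np.asarray(plasma, dtype=float)
    wholeblood = np.asarray(wholeblood, dtype=float)
    if times.size < 2:
        raise InvalidParameterError("fit_ratio_to_samples: need >= 2 samples")
    if np.any(wholeblood <= 0):
        raise InvalidParameterError("fit_ratio_to_samples: whole-blood activity must be > 0")
    ratios = plasma / wholeblood
    d, e = np.polyfit(times, ratios, 1)
    return RatioParams(float(d), float(e))


class SampleBasedAif:
    """Metabolite-corrected parent AIF assembled from arterial samples.

    ``C_P(t) = C_WB(t) * f_Hill(t) * C_ratio(t)`` with the whole-blood curve
    linearly interpolated between (time-shifted) samples and the Hill/ratio
    models fitted to the (time-shifted) assays.
    """

    def __init__(self, wb: WholeBloodCurve, hill: HillParams, ratio: RatioParams) -> None:
        self.wb = wb
        self.hill = hill
        self.ratio = ratio

    @property
    def t_end(self) -> float:
        return self.wb.t_end

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.wb(t) * hill_fraction(self.hill, t) * ratio_line(self.ratio, t)


def sample_based_aif(samples: BloodSampleSet, delay_shift: float = 0.0) -> SampleBasedAif:
    """Build the gold-standard parent AIF from a blood sample set.

    ``delay_shift`` (min) is added to every sample time — negative values
    advance the blood timeline to match the first PET frame.
    """
    times = samples.times + delay_shift
    if times[-1] <= 0:
        raise InvalidParameterError(
            "sample_based_aif: delay shift moved all samples out of the analysis window"
        )
    keep = times >= 0
    if keep.sum() < 2:
        raise InvalidParameterError("sample_based_aif: fewer than 2 samples after shift")
    wb = WholeBloodCurve(times[keep], samples.wholeblood[keep])
    hill, _ = fit_hill_to_samples(np.maximum(samples.pf_times + delay_shift, 0.0), samples.pf_values)
    # the ratio is undefined where whole blood is zero (pre-bolus samples)
    usable = keep & (samples.wholeblood > 0)
    if usable.sum() < 2:
        raise InvalidParameterError("sample_based_aif: need >= 2 samples with whole blood > 0")
    ratio = fit_ratio_to_samples(times[usable], samples.plasma[usable], samples.wholeblood[usable])
    return SampleBasedAif(wb, hill, ratio)


def curve_auc(values, times, window: tuple[float, float]) -> float:
    """Trapezoid area under a sampled curve over ``window = (t0, t1)``."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t0, t1 = window
    if t1 <= t0:
        raise InvalidParameterError(f"curve_auc: empty window {window}")
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise InvalidParameterError(f"curve_auc: window {window} outside sampled domain")
    inside = (times > t0) & (times < t1)
    tt = np.concatenate([[t0], times[inside], [t1]])
    vv = np.interp(tt, times, values)
    return float(np.trapezoid(vv, tt))
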