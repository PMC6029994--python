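"""Synthetic-study generator.

Emulates the acquisition structure of a bolus-injection receptor study: a
bolus-shaped true parent AIF, a whole-blood curve derived from it by
inverting the parent-fraction x ratio product (so the constrained AIF model
is exactly well-specified), four regional TACs with low / moderate / high
binding on the 35-frame 90-min schedule, frame-duration-weighted Gaussian
noise, arterial samples, and test-retest cohorts with between-subject
parameter jitter.

All kinetic profile values and noise levels are design choices recorded
here, calibrated for plausibility rather than taken from any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .aif_models import (
    FengParams,
    HillParams,
    RatioParams,
    WholeBloodCurve,
    constrained_parent_aif,
    feng_aif,
    hill_fraction,
    ratio_line,
)
from .blood import BloodSampleSet
from .exceptions import InvalidParameterError
from .kinetics import FrameSchedule, KineticParams, RegionTAC, model_tac
from .sime import SimeProblem

__all__ = [
    "StudyTruth",
    "SyntheticStudy",
    "REGIONS",
    "NOISE_LEVELS",
    "METABOLITE_SAMPLE_TIMES",
    "generate_truth",
    "generate_study",
    "generate_cohort",
    "add_frame_noise",
    "noise_sigma",
    "perturb_wb",
]

REGIONS = ("cerebellum", "parietal", "hippocampus", "striatum")

#: metabolite assay times (min)
METABOLITE_SAMPLE_TIMES = np.array([3.5, 10.0, 17.5, 32.5, 55.0, 85.0])

#: noise scale factors for sigma = level * sqrt(max(E, floor) / frame_duration)
NOISE_LEVELS = {"none": 0.0, "low": 0.05, "mid": 0.1, "high": 0.25}

#: variance floor (kBq/mL) so near-zero frames still carry noise
NOISE_FLOOR = 1.0

_DEFAULT_FENG = FengParams(a1=300.0, a2=30.0, a3=15.0, lam1=1.2, lam2=0.3, lam3=0.01)
_DEFAULT_HILL = HillParams(a=0.25, b=1.6, c=25.0)
_DEFAULT_RATIO = RatioParams(d=0.0015, e=1.08)

#: target binding potentials relative to cerebellum (low/moderate/high design)
_BP_TARGETS = {"parietal": 0.42, "hippocampus": 0.90, "striatum": 3.5}


def _default_kinetics() -> dict[str, KineticParams]:
    """Regional rate constants: k3 is solved so BP_ND hits the design targets."""
    cer = KineticParams(0.15, 0.10, 0.02, 0.06)
    v_nd = (cer.k1 / cer.k2) * (1.0 + cer.k3 / cer.k4)
    base = {
        "parietal": (0.16, 0.11, 0.05),
        "hippocampus": (0.14, 0.09, 0.05),
        "striatum": (0.17, 0.12, 0.04),
    }
    out = {"cerebellum": cer}
    for region, (k1, k2, k4) in base.items():
        v_t = v_nd * (1.0 + _BP_TARGETS[region])
        k3 = k4 * (v_t * k2 / k1 - 1.0)
        out[region] = KineticParams(k1, k2, k3, k4)
    return out


@dataclass(frozen=True)
class StudyTruth:
    """Ground-truth parameter set of one synthetic subject."""

    feng: FengParams
    hill: HillParams
    ratio: RatioParams
    kinetics: dict[str, KineticParams]
    noise_level: str = "none"
    seed: int = 0

    def v_t(self, region: str) -> float:
        kp = self.kinetics[region]
        return (kp.k1 / kp.k2) * (1.0 + kp.k3 / kp.k4)

    def bp_nd(self, region: str, reference: str = "cerebellum") -> float:
        v_nd = self.v_t(reference)
        return (self.v_t(region) - v_nd) / v_nd


@dataclass
class SyntheticStudy:
    """One simulated acquisition, regenerable bit-for-bit from (truth, seed)."""

    truth: StudyTruth
    schedule: FrameSchedule
    wb: WholeBloodCurve
    samples: BloodSampleSet
    tacs: list[RegionTAC]
    noiseless: list[RegionTAC]

    def problem(self, mode: str) -> SimeProblem:
        wb = self.wb if mode == "constrained" else None
        return SimeProblem(tacs=self.tacs, mode=mode, wb=wb)


def generate_truth(profile: str = "default", seed: int = 0) -> StudyTruth:
    """Deterministic ground truth for a named profile.

    ``default`` gives a low/moderate/high binding layout with BP_ND of 0.42,
    0.9 and 3.5 relative to cerebellum by construction; ``flat`` assigns the
    cerebellum parameters to all four regions (all BP_ND = 0).
    """
    if profile == "default":
        return StudyTruth(_DEFAULT_FENG, _DEFAULT_HILL, _DEFAULT_RATIO, _default_kinetics(), seed=seed)
    if profile == "flat":
        cer = _default_kinetics()["cerebellum"]
        return StudyTruth(
            _DEFAULT_FENG, _DEFAULT_HILL, _DEFAULT_RATIO,
            {r: cer for r in REGIONS}, seed=seed,
        )
    raise InvalidParameterError(f"generate_truth: unknown profile {profile!r}")


def blood_sampling_grid(t_end: float = 90.0) -> np.ndarray:
    """Blood sampling times: 2-s spacing around the bolus, coarsening later.

    Denser than typical early arterial sampling so that linear interpolation
    of the whole-blood curve stays within 1% of the generating curve even at
    the earliest frame mid-times.
    """
    early = np.arange(0.0, 3.0, 2.0 / 60.0)
    mid = np.arange(3.0, 10.0, 0.25)
    late = np.arange(10.0, t_end + 1e-9, 0.5)
    return np.concatenate([early, mid, late])


def noise_sigma(values: np.ndarray, sched: FrameSchedule, level: str) -> np.ndarray:
    """Frame noise SD: ``level * sqrt(max(E, floor) / frame_duration)``."""
    scale = NOISE_LEVELS[level]
    return scale * np.sqrt(np.maximum(values, NOISE_FLOOR) / sched.durations)


def add_frame_noise(
    values: np.ndarray, sched: FrameSchedule, level: str, rng: np.random.Generator
) -> np.ndarray:
    sigma = noise_sigma(values, sched, level)
    return values + rng.normal(0.0, 1.0, size=values.shape) * sigma


def generate_study(
    truth: StudyTruth,
    noise: str | None = None,
    seed: int | None = None,
    schedule: FrameSchedule | None = None,
    fine_step: float = 0.01,
    pf_noise_sd: float = 0.0,
) -> SyntheticStudy:
    """Simulate one acquisition from a ground truth.

    The whole-blood curve is constructed as ``C_P / (f_Hill * C_ratio)`` on
    the blood sampling grid, so the product model reproduces the generating
    parent AIF exactly at the sample times.  TACs are forward-modelled from
    the emitted whole-blood curve (the same object a fitter sees), then
    perturbed with frame-duration-weighted Gaussian noise.
    """
    noise = truth.noise_level if noise is None else noise
    if noise not in NOISE_LEVELS:
        raise InvalidParameterError(f"generate_study: unknown noise level {noise!r}")
    seed = truth.seed if seed is None else seed
    sched = schedule or FrameSchedule.default()

    grid = blood_sampling_grid(sched.t_end)
    denom = hill_fraction(truth.hill, grid) * ratio_line(truth.ratio, grid)
    if np.any(denom <= 0):
        raise InvalidParameterError("generate_study: f_Hill * C_ratio must be > 0")
    cp_grid = feng_aif(truth.feng, grid)
    wb = WholeBloodCurve(grid, np.maximum(cp_grid / denom, 0.0))

    def parent(t):
        return constrained_parent_aif(wb, truth.hill, truth.ratio, t)

    rng = np.random.default_rng(seed)
    noiseless: list[RegionTAC] = []
    tacs: list[RegionTAC] = []
    for region in REGIONS:
        clean = model_tac(parent, wb, truth.kinetics[region], sched, step=fine_step, region=region)
        noiseless.append(clean)
        noisy = add_frame_noise(clean.values, sched, noise, rng)
        tacs.append(RegionTAC(region, sched, noisy))

    pf = hill_fraction(truth.hill, METABOLITE_SAMPLE_TIMES)
    if pf_noise_sd > 0:
        pf = np.clip(pf + rng.normal(0.0, pf_noise_sd, pf.shape), 0.0, 1.0)
    samples = BloodSampleSet(
        times=grid,
        wholeblood=wb.activities,
        plasma=wb.activities * ratio_line(truth.ratio, grid),
        pf_times=METABOLITE_SAMPLE_TIMES,
        pf_values=pf,
    )
    return SyntheticStudy(truth, sched, wb, samples, tacs, noiseless)


def generate_cohort(
    n_subjects: int,
    test_retest: bool = False,
    profile: str = "default",
    noise: str = "mid",
    seed: int = 0,
    jitter_cv: float = 0.15,
    **study_kwargs,
) -> list[SyntheticStudy]:
    """Simulate a cohort with log-normal between-subject parameter jitter.

    Per subject, the four rate constants of every region and the bolus
    amplitudes are scaled by log-normal factors with the given CV.  With
    ``test_retest`` each subject contributes two studies sharing one truth
    but with independent noise realisations (ordered test, retest, test, ...).
    """
    if n_subjects < 1:
        raise InvalidParameterError("generate_cohort: n_subjects must be >= 1")
    base = generate_truth(profile, seed)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + jitter_cv**2))
    studies: list[SyntheticStudy] = []
    for _ in range(n_subjects):
        amp = float(rng.lognormal(0.0, sigma))
        feng = FengParams(
            base.feng.a1 * amp, base.feng.a2 * amp, base.feng.a3 * amp,
            base.feng.lam1, base.feng.lam2, base.feng.lam3,
        )
        kin = {}
        for region, kp in base.kinetics.items():
            factors = rng.lognormal(0.0, sigma, size=4)
            kin[region] = KineticParams(
                kp.k1 * factors[0], kp.k2 * factors[1],
                kp.k3 * factors[2], kp.k4 * factors[3], kp.vb,
            )
        truth = StudyTruth(feng, base.hill, base.ratio, kin, noise_level=noise)
        n_scans = 2 if test_retest else 1
        for _scan in range(n_scans):
            scan_seed = int(rng.integers(0, 2**31 - 1))
            studies.append(
                generate_study(replace(truth, seed=scan_seed), noise=noise, **study_kwargs)
            )
    return studies


def perturb_wb(
    wb: WholeBloodCurve,
    kind: str = "uniform",
    factor: float = 0.9,
    t_split: float = 3.0,
) -> WholeBloodCurve:
    """Apply a multiplicative bias to a whole-blood curve.

    ``uniform`` scales the whole curve; ``peak`` scales only samples before
    ``t_split`` — emulating an image-derived curve that underestimates the
    bolus peak.
    """
    if factor <= 0:
        raise InvalidParameterError(f"perturb_wb: factor must be > 0, got {factor}")
    if kind == "uniform":
        return wb.scaled(factor)
    if kind == "peak":
        scale = np.where(wb.times < t_split, factor, 1.0)
        return WholeBloodCurve(wb.times, wb.activities * scale)
    raise InvalidParameterError(f"perturb_wb: unknown bias kind {kind!r}")
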