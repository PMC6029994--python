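"""Simultaneous estimation (SIME) of the arterial input function.

Two variants of the joint fit are implemented:

* ``original`` — the parent AIF is the six-parameter bolus model
  (:class:`~simekit.aif_models.FengParams`); no blood measurement is used and
  the parent curve also stands in for the whole-blood term, giving a
  ``4m + 6`` parameter problem for ``m`` regions.
* ``constrained`` — the parent AIF is the product of a *measured* whole-blood
  curve with a Hill parent fraction and a straight-line plasma/whole-blood
  ratio, giving ``4m + 5`` parameters.

The joint cost is the uniformly weighted sum of squared frame residuals over
all regions.  It is minimised with bounded trust-region nonlinear least
squares and a seeded multistart, after which each region is refit
individually against the frozen AIF (second stage) and macroparameters are
derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.optimize import least_squares

from . import kinetics
from .aif_models import FengParams, HillParams, RatioParams, WholeBloodCurve
from .exceptions import InvalidParameterError, SimekitError
from .kinetics import FrameSchedule, KineticParams, RegionTAC

__all__ = [
    "FitConfig",
    "SimeProblem",
    "SimeResult",
    "RefitResult",
    "sime_cost",
    "fit_sime",
    "refit_individual",
    "reconstruct_aif",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
]

logger = logging.getLogger(__name__)

MODES = ("original", "constrained")

FENG_NAMES = ("a1", "a2", "a3", "lam1", "lam2", "lam3")
CONSTRAINED_NAMES = ("a", "b", "c", "d", "e")
KINETIC_NAMES = ("k1", "k2", "k3", "k4")

# Bounds are a design choice (physiologic ranges); the lambda windows are
# disjoint so the bolus-model rate ordering lam1 > lam2 > lam3 always holds.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": (1e-4, 2.0),
    "k2": (1e-4, 2.0),
    "k3": (1e-4, 2.0),
    "k4": (1e-4, 2.0),
    "a": (0.0, 1.0),
    "b": (1e-3, 10.0),
    "c": (1e-6, 1e4),
    "d": (-0.02, 0.02),
    "e": (1e-6, 3.0),
    "a1": (1.0, 5e3),
    "a2": (0.0, 500.0),
    "a3": (0.0, 500.0),
    "lam1": (0.502, 10.0),
    "lam2": (0.02, 0.5),
    "lam3": (1e-4, 0.0199),
}

DEFAULT_INIT: dict[str, float] = {
    "k1": 0.1,
    "k2": 0.1,
    "k3": 0.05,
    "k4": 0.05,
    "a": 0.3,
    "b": 1.5,
    "c": 20.0,
    "d": 0.0,
    "e": 1.0,
    "a1": 100.0,
    "a2": 20.0,
    "a3": 10.0,
    "lam1": 2.0,
    "lam2": 0.2,
    "lam3": 0.005,
}

#: coarse grids searched to seed the AIF parameters when no init is given
_GRID_INIT = {
    "constrained": {"a": (0.1, 0.3, 0.6), "b": (1.0, 2.0), "c": (10.0, 50.0)},
    "original": {"a1": (50.0, 200.0, 800.0), "lam1": (1.0, 3.0)},
}


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings; all defaults are recorded here for provenance."""

    multistarts: int = 5
    seed: int = 0
    fine_step: float = kinetics.DEFAULT_FINE_STEP
    t_end: float = 90.0
    vb: float = kinetics.DEFAULT_VB
    bounds: dict = field(default_factory=dict)
    init: dict = field(default_factory=dict)
    grid_init: bool = True
    max_nfev: int | None = None
    ftol: float = 1e-10
    xtol: float = 1e-10

    def bound(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, DEFAULT_BOUNDS[name]))

    def initial(self, name: str) -> float:
        return float(self.init.get(name, DEFAULT_INIT[name]))

    def with_overrides(self, **kwargs) -> "FitConfig":
        return replace(self, **kwargs)


@dataclass
class SimeProblem:
    """A joint estimation problem over ``m >= 2`` regions sharing one schedule."""

    tacs: list[RegionTAC]
    mode: str
    wb: WholeBloodCurve | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InvalidParameterError(f"SimeProblem: unknown mode {self.mode!r}")
        if len(self.tacs) < 2:
            raise InvalidParameterError("SimeProblem: need at least 2 regions")
        sched = self.tacs[0].schedule
        for tac in self.tacs[1:]:
            if tac.schedule != sched:
                raise InvalidParameterError("SimeProblem: all TACs must share one schedule")
        if self.mode == "constrained":
            if self.wb is None:
                raise InvalidParameterError("SimeProblem: constrained mode requires a whole-blood curve")
            if self.wb.t_end < sched.t_end - 1e-9:
                raise InvalidParameterError(
                    "SimeProblem: schedule extends past the whole-blood domain"
                )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.tacs), sched.n_frames):
                raise InvalidParameterError("SimeProblem: weights shape mismatch")
            if np.any(w < 0):
                raise InvalidParameterError("SimeProblem: weights must be >= 0")
            self.weights = w

    @property
    def schedule(self) -> FrameSchedule:
        return self.tacs[0].schedule

    @property
    def m(self) -> int:
        return len(self.tacs)

    @property
    def aif_names(self) -> tuple[str, ...]:
        return FENG_NAMES if self.mode == "original" else CONSTRAINED_NAMES

    @property
    def n_params(self) -> int:
        return len(self.aif_names) + 4 * self.m

    def theta_names(self) -> list[str]:
        names = list(self.aif_names)
        for tac in self.tacs:
            names.extend(f"{tac.region}.{k}" for k in KINETIC_NAMES)
        return names


class _JointModel:
    """Precomputed grids and measured data for fast residual evaluation.

    The hot path works on raw parameter vectors (no dataclass validation):
    bound constraints keep the optimiser inside the valid region, and the
    typed parameter objects are only constructed for the final result.
    """

    def __init__(self, problem: SimeProblem, cfg: FitConfig) -> None:
        self.problem = problem
        self.mode = problem.mode
        sched = problem.schedule
        if sched.t_end > cfg.t_end + 1e-9:
            sched_fit = sched.truncated(cfg.t_end)
        else:
            sched_fit = sched
        self.sched = sched_fit
        keep = slice(0, sched_fit.n_frames)
        self.t = kinetics.fine_grid(sched_fit.t_end, cfg.fine_step)
        self.step = self.t[1] - self.t[0]
        self.measured = np.stack([tac.values[keep] for tac in problem.tacs])
        if problem.weights is None:
            self.sqrtw = np.ones_like(self.measured)
        else:
            self.sqrtw = np.sqrt(problem.weights[:, keep])
        self.vb = cfg.vb
        self.wb_vals = problem.wb(self.t) if problem.wb is not None else None
        self.n_aif = len(problem.aif_names)
        self.nfft = next_fast_len(2 * self.t.size - 1)

    def _conv(self, cp_f: np.ndarray, x: np.ndarray, cp0: float, cp: np.ndarray) -> np.ndarray:
        """Trapezoid-corrected convolution with a cached rFFT of the input."""
        raw = irfft(cp_f * rfft(x, self.nfft), self.nfft)[: self.t.size]
        return self.step * (raw - 0.5 * cp0 * x - 0.5 * x[0] * cp)

    def parent_values(self, theta_aif: np.ndarray) -> np.ndarray:
        t = self.t
        if self.mode == "original":
            a1, a2, a3, l1, l2, l3 = theta_aif
            return (
                (a1 * t - a2 - a3) * np.exp(-l1 * t)
                + a2 * np.exp(-l2 * t)
                + a3 * np.exp(-l3 * t)
            )
        a, b, c, d, e = theta_aif
        tb = np.power(t, b)
        frac = 1.0 - (1.0 - a) * tb / (c + tb)
        return self.wb_vals * frac * (d * t + e)

    def _impulse(self, k: np.ndarray) -> np.ndarray:
        """Raw impulse response (no validation; bounds keep parameters legal)."""
        k1, k2, k3, k4 = k
        s = k2 + k3 + k4
        disc = s * s - 4.0 * k2 * k4
        if disc < 1e-12:
            alpha = s / 2.0
            return k1 * np.exp(-alpha * self.t) * (1.0 + (k3 + k4 - alpha) * self.t)
        sq = np.sqrt(disc)
        a1, a2 = (s - sq) / 2.0, (s + sq) / 2.0
        return (k1 / (a2 - a1)) * (
            (k3 + k4 - a1) * np.exp(-a1 * self.t) + (a2 - k3 - k4) * np.exp(-a2 * self.t)
        )

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        cp = self.parent_values(theta[: self.n_aif])
        cp_f = rfft(cp, self.nfft)
        wbv = cp if self.mode == "original" else self.wb_vals
        out = np.empty_like(self.measured)
        for i in range(self.measured.shape[0]):
            k = theta[self.n_aif + 4 * i : self.n_aif + 4 * (i + 1)]
            h = self._impulse(k)
            conv = self._conv(cp_f, h, cp[0], cp)
            e_t = (1.0 - self.vb) * conv + self.vb * wbv
            out[i] = kinetics.frame_average(e_t, self.t, self.sched) - self.measured[i]
        return (self.sqrtw * out).ravel()

    def parent_jacobian(self, theta_aif: np.ndarray) -> np.ndarray:
        """(n_t, n_aif) partials of the parent curve w.r.t. the AIF parameters."""
        from .aif_models import _feng_jacobian, _hill_jacobian

        if self.mode == "original":
            return _feng_jacobian(FengParams(*theta_aif), self.t)
        a, b, c, d, e = theta_aif
        jh = _hill_jacobian(HillParams(max(a, 0.0), b, c), self.t)
        tb = np.power(self.t, b)
        frac = 1.0 - (1.0 - a) * tb / (c + tb)
        ratio = d * self.t + e
        wr = self.wb_vals * ratio
        return np.column_stack(
            [
                wr * jh[:, 0],
                wr * jh[:, 1],
                wr * jh[:, 2],
                self.wb_vals * frac * self.t,
                self.wb_vals * frac,
            ]
        )

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Analytic residual Jacobian.

        AIF columns use the closed-form parent partials convolved with each
        region's impulse response; k1 exploits linearity of h in k1; k2..k4
        use central differences of the (cheap, analytic) impulse response
        only — the convolution and frame averaging stay exact.
        """
        n_par = theta.size
        m, n = self.measured.shape
        cp = self.parent_values(theta[: self.n_aif])
        cp_f = rfft(cp, self.nfft)
        pj = self.parent_jacobian(theta[: self.n_aif])
        pj_f = [rfft(pj[:, j], self.nfft) for j in range(self.n_aif)]
        jac = np.zeros((m, n, n_par))
        for i in range(m):
            k = theta[self.n_aif + 4 * i : self.n_aif + 4 * (i + 1)].copy()
            h = self._impulse(k)
            h_f = rfft(h, self.nfft)
            conv = self._conv(cp_f, h, cp[0], cp)
            for j in range(self.n_aif):
                col = pj[:, j]
                raw = irfft(pj_f[j] * h_f, self.nfft)[: self.t.size]
                dconv = self.step * (raw - 0.5 * col[0] * h - 0.5 * h[0] * col)
                de = (1.0 - self.vb) * dconv
                if self.mode == "original":
                    de = de + self.vb * col
                jac[i, :, j] = kinetics.frame_average(de, self.t, self.sched)
            # k1: h is exactly proportional to k1
            jac[i, :, self.n_aif + 4 * i] = kinetics.frame_average(
                (1.0 - self.vb) * conv / k[0], self.t, self.sched
            )
            for j in range(1, 4):
                delta = 1e-6 * max(abs(k[j]), 1e-3)
                kp, km = k.copy(), k.copy()
                kp[j] += delta
                km[j] = max(km[j] - delta, 0.0)
                dh = (self._impulse(kp) - self._impulse(km)) / (kp[j] - km[j])
                dconv = self._conv(cp_f, dh, cp[0], cp)
                jac[i, :, self.n_aif + 4 * i + j] = kinetics.frame_average(
                    (1.0 - self.vb) * dconv, self.t, self.sched
                )
            jac[i] *= self.sqrtw[i][:, None]
        return jac.reshape(m * n, n_par)


def sime_cost(problem: SimeProblem, theta, config: FitConfig | None = None) -> float:
    """Joint weighted sum-of-squares cost for a full parameter vector."""
    cfg = config or FitConfig()
    theta = np.asarray(theta, dtype=float)
    if theta.size != problem.n_params:
        raise InvalidParameterError(
            f"sime_cost: expected {problem.n_params} parameters "
            f"({len(problem.aif_names)} AIF + 4x{problem.m}), got {theta.size}"
        )
    res = _JointModel(problem, cfg).residuals(theta)
    return float(np.dot(res, res))


def _bounds_vectors(problem: SimeProblem, cfg: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in problem.aif_names:
        b = cfg.bound(name)
        lo.append(b[0])
        hi.append(b[1])
    for _ in range(problem.m):
        for name in KINETIC_NAMES:
            b = cfg.bound(name)
            lo.append(b[0])
            hi.append(b[1])
    return np.array(lo), np.array(hi)


def _initial_theta(problem: SimeProblem, cfg: FitConfig, model: _JointModel) -> np.ndarray:
    theta = np.empty(problem.n_params)
    for i, name in enumerate(problem.aif_names):
        theta[i] = cfg.initial(name)
    n_aif = len(problem.aif_names)
    for i, tac in enumerate(problem.tacs):
        for j, name in enumerate(KINETIC_NAMES):
            # per-region overrides ("<region>.k1") take precedence
            key = f"{tac.region}.{name}"
            theta[n_aif + 4 * i + j] = float(cfg.init.get(key, cfg.initial(name)))
    if cfg.grid_init:
        grid = _GRID_INIT[problem.mode]
        # only search parameters the user did not pin explicitly
        free = [n for n in grid if n not in cfg.init]
        if free:
            best = theta.copy()
            best_cost = np.inf
            idx = {n: problem.aif_names.index(n) for n in free}
            combos = [()]
            for n in free:
                combos = [c + (v,) for c in combos for v in grid[n]]
            for combo in combos:
                cand = theta.copy()
                for n, v in zip(free, combo):
                    cand[idx[n]] = v
                r = model.residuals(cand)
                cost = float(np.dot(r, r))
                if cost < best_cost:
                    best_cost = cost
                    best = cand
            theta = best
    return theta


def _perturb(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative x[0.5, 2] jitter; additive for sign-spanning parameters."""
    out = theta.copy()
    for i in range(theta.size):
        if lo[i] < 0 < hi[i]:
            out[i] = theta[i] + rng.uniform(0.25 * lo[i], 0.25 * hi[i])
        else:
            out[i] = theta[i] * np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
    span = hi - lo
    return np.clip(out, lo + 1e-12 * np.maximum(span, 1.0), hi)


@dataclass
class RefitResult:
    """Outcome of the second-stage single-region fit."""

    params: KineticParams
    cost: float
    success: bool
    message: str
    nfev: int
    at_lower_bound: list[str] = field(default_factory=list)


@dataclass
class SimeResult:
    """Full outcome of a SIME fit."""

    mode: str
    regions: list[str]
    aif_params: dict[str, float]
    first_stage: dict[str, KineticParams]
    refined: dict[str, KineticParams]
    v_t: dict[str, float]
    bp_nd: dict[str, float]
    reference_region: str
    cost: float
    success: bool
    message: str
    nfev: int
    n_starts: int
    best_start: int
    start_costs: list[float]
    seed: int
    aif_times: np.ndarray
    aif_values: np.ndarray
    wb: WholeBloodCurve | None = None
    refit_diagnostics: dict[str, RefitResult] = field(default_factory=dict)

    @property
    def feng(self) -> FengParams:
        if self.mode != "original":
            raise SimekitError("feng params only defined for original mode")
        return FengParams(**{k: self.aif_params[k] for k in FENG_NAMES})

    @property
    def hill(self) -> HillParams:
        if self.mode != "constrained":
            raise SimekitError("hill params only defined for constrained mode")
        return HillParams(self.aif_params["a"], self.aif_params["b"], self.aif_params["c"])

    @property
    def ratio(self) -> RatioParams:
        if self.mode != "constrained":
            raise SimekitError("ratio params only defined for constrained mode")
        return RatioParams(self.aif_params["d"], self.aif_params["e"])


def _parent_callable(mode: str, aif: dict[str, float], wb: WholeBloodCurve | None) -> Callable:
    """Dense-grid evaluator of the fitted AIF (raw formulas, no re-validation)."""
    if mode == "original":
        a1, a2, a3, l1, l2, l3 = (aif[k] for k in FENG_NAMES)

        def parent(t):
            t = np.asarray(t, dtype=float)
            return (
                (a1 * t - a2 - a3) * np.exp(-l1 * t)
                + a2 * np.exp(-l2 * t)
                + a3 * np.exp(-l3 * t)
            )

        return parent
    a, b, c, d, e = (aif[k] for k in CONSTRAINED_NAMES)

    def parent(t):
        t = np.asarray(t, dtype=float)
        tb = np.power(t, b)
        return wb(t) * (1.0 - (1.0 - a) * tb / (c + tb)) * (d * t + e)

    return parent


def refit_individual(
    tac: RegionTAC,
    parent: Callable[[np.ndarray], np.ndarray],
    wb: Callable[[np.ndarray], np.ndarray],
    config: FitConfig | None = None,
) -> RefitResult:
    """Fit the four rate constants of one region against a fixed AIF.

    ``wb`` is the whole-blood term of the forward model; original-mode callers
    pass the parent curve itself.
    """
    cfg = config or FitConfig()
    sched = tac.schedule
    if sched.t_end > cfg.t_end + 1e-9:
        sched = sched.truncated(cfg.t_end)
    measured = tac.values[: sched.n_frames]
    t = kinetics.fine_grid(sched.t_end, cfg.fine_step)
    step = t[1] - t[0]
    cp = np.asarray(parent(t), dtype=float)
    wbv = np.asarray(wb(t), dtype=float)

    def residuals(x):
        kp = KineticParams(x[0], x[1], x[2], x[3], cfg.vb)
        h = kinetics.impulse_response(kp, t)
        conv = kinetics.convolve_input(cp, h, step)
        e_t = (1.0 - cfg.vb) * conv + cfg.vb * wbv
        return kinetics.frame_average(e_t, t, sched) - measured

    lo = np.array([cfg.bound(n)[0] for n in KINETIC_NAMES])
    hi = np.array([cfg.bound(n)[1] for n in KINETIC_NAMES])
    x0 = np.clip(np.array([cfg.initial(n) for n in KINETIC_NAMES]), lo, hi)
    sol = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        ftol=cfg.ftol, xtol=cfg.xtol, max_nfev=cfg.max_nfev,
    )
    at_lb = [
        name for name, v, b in zip(KINETIC_NAMES, sol.x, lo)
        if v <= b * (1 + 1e-6) + 1e-12
    ]
    return RefitResult(
        params=KineticParams(*sol.x, vb=cfg.vb),
        cost=float(2.0 * sol.cost),
        success=bool(sol.status > 0),
        message=str(sol.message),
        nfev=int(sol.nfev),
        at_lower_bound=at_lb,
    )


def fit_sime(problem: SimeProblem, config: FitConfig | None = None) -> SimeResult:
    """Run the full SIME pipeline: joint fit, multistart, refit, macroparameters.

    Deterministic given ``(problem, config)``: multistart perturbations are
    drawn from ``config.seed`` and ties are broken by start index.
    """
    cfg = config or FitConfig()
    model = _JointModel(problem, cfg)
    lo, hi = _bounds_vectors(problem, cfg)
    theta0 = _initial_theta(problem, cfg, model)
    rng = np.random.default_rng(cfg.seed)

    starts = [theta0]
    for _ in range(max(cfg.multistarts, 1) - 1):
        starts.append(_perturb(theta0, lo, hi, rng))

    best = None
    best_cost = np.inf
    best_idx = -1
    start_costs: list[float] = []
    total_nfev = 0
    for s, x0 in enumerate(starts):
        sol = least_squares(
            model.residuals, x0, jac=model.jacobian, bounds=(lo, hi), method="trf",
            x_scale="jac", ftol=cfg.ftol, xtol=cfg.xtol, max_nfev=cfg.max_nfev,
        )
        cost = float(2.0 * sol.cost)
        start_costs.append(cost)
        total_nfev += int(sol.nfev)
        logger.info("sime start %d/%d: cost=%.6g status=%d", s + 1, len(starts), cost, sol.status)
        if cost < best_cost:
            best, best_cost, best_idx = sol, cost, s

    success = bool(best is not None and best.status > 0)
    message = str(best.message) if best is not None else "no optimiser run completed"
    theta = best.x

    n_aif = len(problem.aif_names)
    aif_params = {name: float(v) for name, v in zip(problem.aif_names, theta[:n_aif])}
    first_stage: dict[str, KineticParams] = {}
    for i, tac in enumerate(problem.tacs):
        k = theta[n_aif + 4 * i : n_aif + 4 * (i + 1)]
        first_stage[tac.region] = KineticParams(*k, vb=cfg.vb)

    parent = _parent_callable(problem.mode, aif_params, problem.wb)
    wb_term = parent if problem.mode == "original" else problem.wb

    refined: dict[str, KineticParams] = {}
    diagnostics: dict[str, RefitResult] = {}
    for tac in problem.tacs:
        rf = refit_individual(tac, parent, wb_term, cfg)
        refined[tac.region] = rf.params
        diagnostics[tac.region] = rf

    v_t = {r: kinetics.volume_of_distribution(kp) for r, kp in refined.items()}
    regions = [tac.region for tac in problem.tacs]
    ref_region = "cerebellum" if "cerebellum" in regions else regions[0]
    v_nd = v_t[ref_region]
    bp_nd = {r: kinetics.binding_potential(v, v_nd) for r, v in v_t.items()}

    aif_t = kinetics.fine_grid(model.sched.t_end, 0.1)
    return SimeResult(
        mode=problem.mode,
        regions=regions,
        aif_params=aif_params,
        first_stage=first_stage,
        refined=refined,
        v_t=v_t,
        bp_nd=bp_nd,
        reference_region=ref_region,
        cost=best_cost,
        success=success,
        message=message,
        nfev=total_nfev,
        n_starts=len(starts),
        best_start=best_idx,
        start_costs=start_costs,
        seed=cfg.seed,
        aif_times=aif_t,
        aif_values=np.asarray(parent(aif_t), dtype=float),
        wb=problem.wb,
        refit_diagnostics=diagnostics,
    )


def reconstruct_aif(result: SimeResult, t) -> np.ndarray:
    """Evaluate the fitted parent AIF on an arbitrary grid."""
    if not result.success:
        raise SimekitError("reconstruct_aif: result did not converge")
    parent = _parent_callable(result.mode, result.aif_params, result.wb)
    return np.asarray(parent(np.asarray(t, dtype=float)), dtype=float)
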