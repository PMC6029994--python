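"""File formats, run configuration, and the end-to-end pipeline.

Formats (all plain text):

* TACs       — CSV ``region,frame_start_min,frame_duration_min,activity_kBq_ml``
* blood      — CSV ``time_min,activity_kBq_ml``
* metabolite — CSV ``time_min,parent_fraction``
* samples    — CSV ``time_min,plasma_kBq_ml,wholeblood_kBq_ml``
* results    — JSON; config — YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aif_models import WholeBloodCurve
from .blood import BloodSampleSet, sample_based_aif
from .exceptions import InvalidParameterError, ScheduleError, SimekitError
from .kinetics import FrameSchedule, KineticParams, RegionTAC, volume_of_distribution
from .metrics import percent_error
from .sime import FitConfig, SimeResult, fit_sime, refit_individual
from .synthetic import generate_study, generate_truth

__all__ = [
    "RunConfig",
    "read_tacs",
    "write_tacs",
    "read_blood_curve",
    "write_blood_curve",
    "read_parent_fractions",
    "write_parent_fractions",
    "read_plasma_samples",
    "write_plasma_samples",
    "read_sample_set",
    "write_result",
    "read_result",
    "config_hash",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TAC_COLUMNS = ["region", "frame_start_min", "frame_duration_min", "activity_kBq_ml"]
BLOOD_COLUMNS = ["time_min", "activity_kBq_ml"]
PF_COLUMNS = ["time_min", "parent_fraction"]
SAMPLE_COLUMNS = ["time_min", "plasma_kBq_ml", "wholeblood_kBq_ml"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")


def read_tacs(path) -> list[RegionTAC]:
    """Read regional TACs, validating the shared schedule."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TAC_COLUMNS, path)
    for col in TAC_COLUMNS[1:]:
        if not np.issubdtype(df[col].dtype, np.number):
            raise InvalidParameterError(f"{path}: non-numeric values in column {col!r}")
    tacs = []
    schedule = None
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("frame_start_min")
        try:
            sched = FrameSchedule(
                grp["frame_start_min"].to_numpy(), grp["frame_duration_min"].to_numpy()
            )
        except ScheduleError as exc:
            raise ScheduleError(f"{path}: region {region!r}: {exc}") from exc
        if schedule is None:
            schedule = sched
        elif sched != schedule:
            raise ScheduleError(f"{path}: region {region!r} uses a different schedule")
        tacs.append(RegionTAC(str(region), sched, grp["activity_kBq_ml"].to_numpy()))
    if not tacs:
        raise InvalidParameterError(f"{path}: no TAC rows found")
    return tacs


def write_tacs(tacs: list[RegionTAC], path) -> None:
    rows = []
    for tac in tacs:
        for s, d, v in zip(tac.schedule.starts, tac.schedule.durations, tac.values):
            rows.append((tac.region, repr(float(s)), repr(float(d)), repr(float(v))))
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(path, index=False)


def read_blood_curve(path) -> WholeBloodCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, BLOOD_COLUMNS, path)
    return WholeBloodCurve(df["time_min"].to_numpy(), df["activity_kBq_ml"].to_numpy())


def write_blood_curve(wb: WholeBloodCurve, path) -> None:
    pd.DataFrame(
        {"time_min": [repr(float(t)) for t in wb.times],
         "activity_kBq_ml": [repr(float(v)) for v in wb.activities]}
    ).to_csv(path, index=False)


def read_parent_fractions(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PF_COLUMNS, path)
    return df["time_min"].to_numpy(dtype=float), df["parent_fraction"].to_numpy(dtype=float)


def write_parent_fractions(times, fractions, path) -> None:
    pd.DataFrame(
        {"time_min": [repr(float(t)) for t in np.asarray(times)],
         "parent_fraction": [repr(float(v)) for v in np.asarray(fractions)]}
    ).to_csv(path, index=False)


def read_plasma_samples(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SAMPLE_COLUMNS, path)
    return (
        df["time_min"].to_numpy(dtype=float),
        df["plasma_kBq_ml"].to_numpy(dtype=float),
        df["wholeblood_kBq_ml"].to_numpy(dtype=float),
    )


def write_plasma_samples(times, plasma, wholeblood, path) -> None:
    pd.DataFrame(
        {"time_min": [repr(float(t)) for t in np.asarray(times)],
         "plasma_kBq_ml": [repr(float(v)) for v in np.asarray(plasma)],
         "wholeblood_kBq_ml": [repr(float(v)) for v in np.asarray(wholeblood)]}
    ).to_csv(path, index=False)


def read_sample_set(samples_path, metabolites_path) -> BloodSampleSet:
    times, plasma, wholeblood = read_plasma_samples(samples_path)
    pf_times, pf_values = read_parent_fractions(metabolites_path)
    return BloodSampleSet(times, wholeblood, plasma, pf_times, pf_values)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    mode: str = "constrained"  # original | constrained | both
    fine_step: float = 0.01
    multistarts: int = 5
    seed: int = 0
    t_end: float = 90.0
    vb: float = 0.05
    bounds: dict = field(default_factory=dict)
    init: dict = field(default_factory=dict)
    noise: str = "mid"
    profile: str = "default"
    simulate: bool = True
    tacs_path: str | None = None
    blood_path: str | None = None
    out_dir: str = "simekit_out"

    def fit_config(self) -> FitConfig:
        bounds = {k: tuple(v) for k, v in self.bounds.items()}
        return FitConfig(
            multistarts=self.multistarts, seed=self.seed, fine_step=self.fine_step,
            t_end=self.t_end, vb=self.vb, bounds=bounds, init=dict(self.init),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def config_hash(config) -> str:
    """Stable hash of a configuration (dataclass or dict)."""
    data = asdict(config) if not isinstance(config, dict) else config
    blob = json.dumps(data, sort_keys=True, default=repr).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _kp_dict(kp: KineticParams) -> dict:
    return {"k1": kp.k1, "k2": kp.k2, "k3": kp.k3, "k4": kp.k4, "vb": kp.vb}


def result_to_dict(result: SimeResult, cfg_hash: str | None = None) -> dict:
    return {
        "mode": result.mode,
        "regions": result.regions,
        "aif_params": result.aif_params,
        "first_stage": {r: _kp_dict(kp) for r, kp in result.first_stage.items()},
        "refined": {r: _kp_dict(kp) for r, kp in result.refined.items()},
        "v_t": result.v_t,
        "bp_nd": result.bp_nd,
        "reference_region": result.reference_region,
        "cost": result.cost,
        "success": result.success,
        "message": result.message,
        "nfev": result.nfev,
        "n_starts": result.n_starts,
        "best_start": result.best_start,
        "start_costs": result.start_costs,
        "seed": result.seed,
        "config_hash": cfg_hash,
        "aif_times": [float(v) for v in result.aif_times],
        "aif_values": [float(v) for v in result.aif_values],
    }


def write_result(result: SimeResult, path, cfg_hash: str | None = None) -> None:
    """Write a fit result as deterministic JSON (sorted keys, full precision)."""
    with open(path, "w") as fh:
        json.dump(result_to_dict(result, cfg_hash), fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_study(study, out_dir) -> None:
    """Write a synthetic study as tacs.csv, wb.csv, pf.csv, samples.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tacs(study.tacs, out / "tacs.csv")
    write_blood_curve(study.wb, out / "wb.csv")
    write_parent_fractions(study.samples.pf_times, study.samples.pf_values, out / "pf.csv")
    write_plasma_samples(
        study.samples.times, study.samples.plasma, study.samples.wholeblood, out / "samples.csv"
    )
    truth = study.truth
    payload = {
        "feng": dict(zip(("a1", "a2", "a3", "lam1", "lam2", "lam3"), truth.feng.as_array().tolist())),
        "hill": dict(zip(("a", "b", "c"), truth.hill.as_array().tolist())),
        "ratio": dict(zip(("d", "e"), truth.ratio.as_array().tolist())),
        "kinetics": {r: _kp_dict(kp) for r, kp in truth.kinetics.items()},
        "v_t": {r: truth.v_t(r) for r in truth.kinetics},
        "noise_level": truth.noise_level,
        "seed": truth.seed,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) -> fit -> refit -> macroparameters -> error report.

    Returns a summary dict (also written to ``<out_dir>/report.json``).
    Any stage failure raises with a stage-tagged message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config)
    report: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}
    fit_cfg = config.fit_config()

    t0 = time.perf_counter()
    truth = None
    if config.simulate:
        truth = generate_truth(config.profile, config.seed)
        study = generate_study(truth, noise=config.noise, seed=config.seed, fine_step=config.fine_step)
        write_study(study, out)
        tacs, wb = study.tacs, study.wb
    else:
        if config.tacs_path is None:
            raise SimekitError("[stage: input] tacs_path required when simulate=false")
        tacs = read_tacs(config.tacs_path)
        wb = read_blood_curve(config.blood_path) if config.blood_path else None
    report["stages"]["input"] = {"seconds": time.perf_counter() - t0, "n_regions": len(tacs)}

    modes = ["original", "constrained"] if config.mode == "both" else [config.mode]
    from .sime import SimeProblem  # local import to avoid cycle at module load

    report["fits"] = {}
    for mode in modes:
        t0 = time.perf_counter()
        if mode == "constrained" and wb is None:
            raise SimekitError("[stage: fit] constrained mode requires a whole-blood curve (blood_path)")
        problem = SimeProblem(tacs=tacs, mode=mode, wb=wb if mode == "constrained" else None)
        result = fit_sime(problem, fit_cfg)
        logger.info("pipeline fit mode=%s cost=%.6g success=%s", mode, result.cost, result.success)
        write_result(result, out / f"result_{mode}.json", cfg_hash)
        entry = {
            "seconds": time.perf_counter() - t0,
            "cost": result.cost,
            "success": result.success,
            "v_t": result.v_t,
            "bp_nd": result.bp_nd,
        }
        if truth is not None:
            entry["v_t_percent_error"] = {
                r: percent_error(result.v_t[r], truth.v_t(r)) for r in result.v_t
            }
        report["fits"][mode] = entry

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return report


def refit_with_sample_aif(
    tacs: list[RegionTAC],
    samples: BloodSampleSet,
    delay_shift: float = 0.0,
    config: FitConfig | None = None,
) -> dict[str, float]:
    """Gold-standard path: V_T per region from the sample-based AIF."""
    aif = sample_based_aif(samples, delay_shift)
    wb = WholeBloodCurve(samples.times + delay_shift, samples.wholeblood)
    out = {}
    for tac in tacs:
        rf = refit_individual(tac, aif, wb, config)
        out[tac.region] = volume_of_distribution(rf.params)
    return out
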