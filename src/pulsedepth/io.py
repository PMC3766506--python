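"""File formats and run configuration.

CSV dialect everywhere: comma-separated, '.' decimal, header row, UTF-8,
no index column.  Times are seconds from recording start, pressures mmHg,
motor positions integer pulses.  Every recording set carries a JSON sidecar
with the method, subject, seed, per-step target/APP/position and the full
configuration, so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acquisition import (
    AcquisitionResult,
    MotorConfig,
    ProtocolConfig,
    StepRecording,
    SweepTrace,
)

__all__ = [
    "RunConfig",
    "save_result",
    "load_result",
    "save_sweep",
    "load_sweep",
    "config_hash",
]


@dataclass
class RunConfig:
    seed: int = 0
    motor: MotorConfig = field(default_factory=MotorConfig)
    proto: ProtocolConfig = field(default_factory=ProtocolConfig)
    noise_sd: float = 0.0
    out_dir: str = "."
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proto"]["fixed_step_pressures"] = list(d["proto"]["fixed_step_pressures"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "motor" in d:
            d["motor"] = MotorConfig(**d["motor"])
        if "proto" in d:
            p = dict(d["proto"])
            if "fixed_step_pressures" in p:
                p["fixed_step_pressures"] = tuple(p["fixed_step_pressures"])
            d["proto"] = ProtocolConfig(**p)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_result(result: AcquisitionResult, cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write one CSV per step plus a JSON sidecar (and the sweep CSV when
    present); returns the sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{result.subject_id}_{result.method}"
    steps_meta = []
    for rec in result.recordings:
        csv_path = out / f"{stem}_step{rec.step_index}.csv"
        pd.DataFrame(
            {"time_s": np.round(rec.times, 9), "pressure_mmHg": rec.samples}
        ).to_csv(csv_path, index=False, float_format="%.17g")
        steps_meta.append(
            {
                "step_index": rec.step_index,
                "target_pressure_mmHg": rec.target_pressure,
                "app_mmHg": rec.app,
                "motor_position_pulses": int(rec.motor_position),
                "t0_s": rec.t0,
                "sampling_rate_hz": rec.sampling_rate,
                "within_tolerance": bool(rec.within_tolerance),
                "csv": csv_path.name,
            }
        )
    sweep_name = None
    if result.sweep is not None:
        sweep_name = f"{stem}_sweep.csv"
        save_sweep(result.sweep, out / sweep_name)
    sidecar = {
        "method": result.method,
        "subject_id": result.subject_id,
        "seed": result.seed,
        "partial": bool(result.partial),
        "config_hash": config_hash(cfg),
        "config": cfg.to_dict(),
        "steps": steps_meta,
        "sweep_csv": sweep_name,
    }
    sidecar_path = out / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return sidecar_path


def load_result(sidecar_path: str | Path) -> AcquisitionResult:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    recs = []
    for s in meta["steps"]:
        df = pd.read_csv(sidecar_path.parent / s["csv"], float_precision="round_trip")
        recs.append(
            StepRecording(
                step_index=s["step_index"],
                target_pressure=s["target_pressure_mmHg"],
                app=s["app_mmHg"],
                motor_position=s["motor_position_pulses"],
                t0=s["t0_s"],
                sampling_rate=s["sampling_rate_hz"],
                samples=df["pressure_mmHg"].to_numpy(),
                within_tolerance=s["within_tolerance"],
            )
        )
    sweep = None
    if meta.get("sweep_csv"):
        sweep = load_sweep(sidecar_path.parent / meta["sweep_csv"])
    return AcquisitionResult(
        method=meta["method"],
        subject_id=meta["subject_id"],
        recordings=recs,
        sweep=sweep,
        partial=meta["partial"],
        seed=meta["seed"],
    )


def save_sweep(sweep: SweepTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": np.round(sweep.times, 9),
            "pressure_mmHg": sweep.pressures,
            "motor_position_pulses": sweep.motor_positions.astype(int),
            "phase": sweep.phases,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def load_sweep(path: str | Path) -> SweepTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "pressure_mmHg", "motor_position_pulses", "phase"}
    if not required.issubset(df.columns):
        raise ValueError(f"corrupt sweep CSV {path}: missing {required - set(df.columns)}")
    return SweepTrace(
        times=df["time_s"].to_numpy(float),
        pressures=df["pressure_mmHg"].to_numpy(float),
        motor_positions=df["motor_position_pulses"].to_numpy(int),
        phases=df["phase"].to_numpy(str),
    )
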