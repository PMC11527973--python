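"""Plain-text interchange formats for sensorgram runs and fit results.

A run is a CSV of ``time_s,response_RU,curve_id`` (all curves stacked)
plus a companion YAML/JSON config carrying per-curve concentration,
injection-schedule segments, schedule type and surface metadata.  Vendor
export formats are proprietary and deliberately out of scope.  Times are
stored relative to curve start (t=0 at the first sample); machine-
readable results are JSON, tables are CSV.  Every output embeds a hash of
the config that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import InjectionSchedule, InjectionSegment, Sensorgram

__all__ = [
    "RunConfig",
    "SchemaError",
    "DataError",
    "read_run",
    "write_run",
    "config_hash",
]

CSV_COLUMNS = ["time_s", "response_RU", "curve_id"]


class SchemaError(ValueError):
    """Config/CSV structure violates the interchange schema."""


class DataError(ValueError):
    """Well-formed file with invalid data (e.g. non-monotone time)."""


@dataclass
class RunConfig:
    """Fit/simulation options as read from a run config file."""

    seed: int
    model_orders: tuple[int, ...] = (1, 2, 3)
    n_starts: int = 32
    chi2_ratio_threshold: float = 2.0
    runs_alpha: float = 0.05
    fit_bulk_ri: bool = False
    preset: str | None = None
    sigma_RU: float = 0.5
    output_dir: str = "."

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        raw = _load_structured(path)
        opts = raw.get("options", raw)
        if "seed" not in opts:
            raise SchemaError("run config must declare a seed")
        known = {f for f in RunConfig.__dataclass_fields__}
        kwargs = {k: v for k, v in opts.items() if k in known}
        if "model_orders" in kwargs:
            kwargs["model_orders"] = tuple(kwargs["model_orders"])
        return RunConfig(**kwargs)


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Stable short hash identifying a config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _schedule_to_dict(schedule: InjectionSchedule) -> dict:
    return {
        "schedule_type": schedule.schedule_type,
        "segments": [
            {
                "kind": s.kind,
                "start_s": s.start_s,
                "end_s": s.end_s,
                "concentration_M": s.concentration_M,
            }
            for s in schedule.segments
        ],
    }


def _schedule_from_dict(d: dict) -> InjectionSchedule:
    try:
        segs = tuple(
            InjectionSegment(
                kind=s["kind"],
                start_s=float(s["start_s"]),
                end_s=float(s["end_s"]),
                concentration_M=float(s.get("concentration_M", 0.0)),
            )
            for s in d["segments"]
        )
        return InjectionSchedule(segs, d["schedule_type"])
    except KeyError as exc:
        raise SchemaError(f"schedule entry missing field {exc}") from exc


def write_run(
    curves: list[Sensorgram],
    csv_path: str | Path,
    config_path: str | Path,
    extra_config: dict | None = None,
) -> None:
    """Write all curves to one CSV and their metadata to a config file."""
    frames = [
        pd.DataFrame(
            {
                "time_s": c.time_s,
                "response_RU": c.response_RU,
                "curve_id": c.curve_id,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    config = {
        "curves": {
            c.curve_id: {
                "concentration_M": c.concentration_M,
                "sampling_rate_hz": c.sampling_rate_hz,
                "schedule": _schedule_to_dict(c.schedule),
            }
            for c in curves
        }
    }
    if extra_config:
        config.update(extra_config)
    config["config_hash"] = config_hash(
        {k: v for k, v in config.items() if k != "config_hash"}
    )
    config_path = Path(config_path)
    with open(config_path, "w") as fh:
        if config_path.suffix.lower() == ".json":
            json.dump(config, fh, indent=2)
        else:
            yaml.safe_dump(config, fh, sort_keys=False)


def read_run(csv_path: str | Path, config_path: str | Path) -> list[Sensorgram]:
    """Read a run CSV plus config into typed curves with schedules attached.

    Raises :class:`SchemaError` for curves missing from the config and
    :class:`DataError` for non-monotone or duplicated timestamps (naming
    the offending curve)."""
    df = pd.read_csv(csv_path)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"CSV missing required columns {missing_cols}")
    bad = df[df[["time_s", "response_RU"]].isna().any(axis=1)]
    if len(bad):
        raise DataError(
            f"malformed rows (NaN values) at CSV lines "
            f"{[int(i) + 2 for i in bad.index[:10]]}"
        )
    config = _load_structured(config_path)
    curve_meta = config.get("curves", {})
    curves = []
    for curve_id, group in df.groupby("curve_id", sort=False):
        if curve_id not in curve_meta:
            raise SchemaError(f"curve {curve_id!r} absent from run config")
        meta = curve_meta[curve_id]
        t = group["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(
                f"curve {curve_id!r}: time_s not strictly increasing "
                "(duplicated or out-of-order timestamps)"
            )
        curves.append(
            Sensorgram(
                time_s=t,
                response_RU=group["response_RU"].to_numpy(dtype=float),
                schedule=_schedule_from_dict(meta["schedule"]),
                curve_id=str(curve_id),
                concentration_M=meta.get("concentration_M"),
                sampling_rate_hz=meta.get("sampling_rate_hz"),
            )
        )
    for curve_id in curve_meta:
        if curve_id not in set(df["curve_id"].astype(str)):
            raise SchemaError(f"config references absent curve {curve_id!r}")
    return curves
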