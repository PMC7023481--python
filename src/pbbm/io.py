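"""Readers, writers, configuration and run manifests.

One unit convention everywhere, enforced at the boundary by column names:
times in hours (``time_h``), amounts in ug, volumes in mL
(``volume_ml``), concentrations in ug/mL (``conc_ug_per_ml``).  All
tables are plain CSV; configs and manifests are JSON.  Validation errors
carry the offending row number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .acat import CompartmentSchedule
from .estimation import ConcentrationDataset
from .gis import SubjectPhysiology
from .physchem import AcidSolubilityProfile

__all__ = [
    "ValidationError",
    "read_concentration_csv",
    "write_concentration_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "read_physiology_csv",
    "write_physiology_csv",
    "read_config",
    "RunManifest",
    "write_manifest",
]


class ValidationError(ValueError):
    """Schema violation with the file location that caused it."""


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")


def _check_nonnegative(df: pd.DataFrame, column: str, path) -> None:
    bad = df.index[df[column] < 0]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise ValidationError(f"{path}: negative {column} at row {bad[0] + 2}")


def read_concentration_csv(path, dose_ug: float) -> ConcentrationDataset:
    """Read a tidy (subject, region, time_h, conc_ug_per_ml) table."""
    df = pd.read_csv(path)
    _require_columns(df, {"subject", "region", "time_h", "conc_ug_per_ml"}, path)
    _check_nonnegative(df, "time_h", path)
    _check_nonnegative(df, "conc_ug_per_ml", path)
    return ConcentrationDataset(records=df, dose_ug=dose_ug)


def write_concentration_csv(dataset: ConcentrationDataset, path) -> None:
    dataset.records.to_csv(path, index=False)


def read_schedule_csv(path) -> dict[str, CompartmentSchedule]:
    """Read per-compartment volume/pH/transit schedules (the ".cat" analog).

    Columns: compartment, time_h, volume_ml, ph, transit_time_h; one row
    per (compartment, time stamp), single stamp = static compartment.
    """
    df = pd.read_csv(path)
    _require_columns(df, {"compartment", "time_h", "volume_ml", "ph", "transit_time_h"}, path)
    _check_nonnegative(df, "time_h", path)
    out = {}
    for name, grp in df.groupby("compartment", sort=False):
        if np.any(np.diff(grp["time_h"].to_numpy()) <= 0):
            row = grp.index[1] + 2
            raise ValidationError(f"{path}: unsorted times for {name!r} near row {row}")
        if (grp["volume_ml"] <= 0).any():
            row = grp.index[grp["volume_ml"] <= 0][0] + 2
            raise ValidationError(f"{path}: non-positive volume at row {row}")
        out[name] = CompartmentSchedule(
            name=name,
            times_h=grp["time_h"].to_numpy(float),
            volumes_ml=grp["volume_ml"].to_numpy(float),
            phs=grp["ph"].to_numpy(float),
            transit_time_h=float(grp["transit_time_h"].iloc[0]),
        )
    return out


def write_schedule_csv(schedules: dict[str, CompartmentSchedule], path) -> None:
    rows = []
    for sch in schedules.values():
        for t, v, p in zip(sch.times_h, sch.volumes_ml, sch.phs):
            rows.append({"compartment": sch.name, "time_h": t, "volume_ml": v,
                         "ph": p, "transit_time_h": sch.transit_time_h})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_physiology_csv(scalars_path, ph_path) -> dict[str, SubjectPhysiology]:
    """Read per-subject physiology: a scalar table
    (subject, tmmc_h, v1_ml, v2_ml, kel_per_h, v3_ml) and a pH table
    (subject, region, time_h, ph)."""
    scalars = pd.read_csv(scalars_path)
    _require_columns(scalars, {"subject", "tmmc_h", "v1_ml", "v2_ml", "kel_per_h", "v3_ml"},
                     scalars_path)
    ph = pd.read_csv(ph_path)
    _require_columns(ph, {"subject", "region", "time_h", "ph"}, ph_path)
    out = {}
    for _, row in scalars.iterrows():
        sid = row["subject"]
        series = {}
        for region in ("duodenum", "jejunum"):
            sub = ph[(ph["subject"] == sid) & (ph["region"] == region)].sort_values("time_h")
            if sub.empty:
                raise ValidationError(f"{ph_path}: no {region} pH rows for subject {sid!r}")
            series[region] = sub[["time_h", "ph"]].to_numpy(float)
        out[sid] = SubjectPhysiology(
            tmmc_h=float(row["tmmc_h"]),
            ph_duodenum=series["duodenum"],
            ph_jejunum=series["jejunum"],
            v1_ml=float(row["v1_ml"]),
            v2_ml=float(row["v2_ml"]),
            kel_per_h=float(row["kel_per_h"]),
            v3_ml=float(row["v3_ml"]),
            subject_id=str(sid),
        )
    return out


def write_physiology_csv(physiologies: dict[str, SubjectPhysiology],
                         scalars_path, ph_path) -> None:
    scalar_rows, ph_rows = [], []
    for sid, phys in physiologies.items():
        scalar_rows.append({"subject": sid, "tmmc_h": phys.tmmc_h, "v1_ml": phys.v1_ml,
                            "v2_ml": phys.v2_ml, "kel_per_h": phys.kel_per_h,
                            "v3_ml": phys.v3_ml})
        for region, series in (("duodenum", phys.ph_duodenum), ("jejunum", phys.ph_jejunum)):
            for t, p in series:
                ph_rows.append({"subject": sid, "region": region, "time_h": t, "ph": p})
    pd.DataFrame(scalar_rows).to_csv(scalars_path, index=False)
    pd.DataFrame(ph_rows).to_csv(ph_path, index=False)


def read_config(path) -> dict:
    """Read a JSON run config; a ``solubility`` key with fields
    ``s0_ug_per_ml``, ``pka``, optional ``cap`` / ``anchor {pH,
    s_ug_per_ml}`` becomes an :class:`AcidSolubilityProfile`."""
    with open(path) as fh:
        cfg = json.load(fh)
    if "solubility" in cfg:
        s = cfg["solubility"]
        anchor = s.get("anchor") or {}
        cfg["solubility"] = AcidSolubilityProfile(
            s0_ug_per_ml=s["s0_ug_per_ml"],
            pka=s["pka"],
            cap=s.get("cap"),
            reference_ph=anchor.get("pH"),
            reference_solubility_ug_per_ml=anchor.get("s_ug_per_ml"),
        )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically on the same
    platform: the command, config hash, seed, input checksums, package
    version and timestamp."""

    command: str
    seed: int | None
    config_hash: str | None
    inputs: dict[str, str]
    package_version: str
    timestamp_utc: str

    @classmethod
    def create(cls, command: str, seed: int | None = None,
               config: dict | None = None, input_paths=()) -> "RunManifest":
        try:
            pkg_version = version("pbbm")
        except PackageNotFoundError:
            pkg_version = "unknown"
        cfg_hash = None
        if config is not None:
            blob = json.dumps(config, sort_keys=True, default=str).encode()
            cfg_hash = hashlib.sha256(blob).hexdigest()
        inputs = {str(p): _sha256(Path(p)) for p in input_paths}
        return cls(command=command, seed=seed, config_hash=cfg_hash, inputs=inputs,
                   package_version=pkg_version,
                   timestamp_utc=datetime.now(timezone.utc).isoformat())


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
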