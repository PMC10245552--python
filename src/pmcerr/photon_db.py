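"""Persistent per-photon database: detected-photon records plus run metadata.

The simulator stores one row per detected photon — detector id, weight,
collision count, path length and the number of survived Russian-Roulette
events — together with metadata describing the run (photons launched, medium,
detector geometry, RR policy, seed).  Untallied photons are represented only
through their count: for a given detector the perturbed weight of every
untallied photon is zero, so population statistics need nothing beyond
``N_U = N - N_T``.

On-disk format is a UTF-8 CSV (17 significant digits, LF line endings) plus
a JSON metadata sidecar ``<prefix>.meta.json``, so databases produced by
other transport engines can be ingested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .optics import OpticalProperties

__all__ = [
    "PhotonRecord",
    "DatabaseMeta",
    "PhotonDatabase",
    "records_from_arrays",
    "write_database",
    "read_database",
    "tallied_subset",
]

RECORD_COLUMNS = ["photon_id", "detector_id", "weight", "n_collisions", "path_length_mm", "n_rr"]

#: absolute tolerance on the CAW/RR log-weight identity checked at read time
_IDENTITY_ATOL = 1e-9


class PhotonRecord(NamedTuple):
    """One detected photon."""

    photon_id: int
    detector_id: str
    weight: float
    n_collisions: int
    path_length_mm: float
    n_rr: int


@dataclass(frozen=True)
class DatabaseMeta:
    n_launched: int
    medium: OpticalProperties
    detectors: tuple  # of transport.Detector
    rr: Optional[object]  # transport.RRPolicy or None
    seed: int
    max_collisions: int = 1_000_000
    n_outside: Optional[float] = None  # None: index-matched boundary
    engine_version: str = "pmcerr-0.1.0"


@dataclass
class PhotonDatabase:
    meta: DatabaseMeta
    records: pd.DataFrame
    diagnostics: dict

    @property
    def n_launched(self) -> int:
        return self.meta.n_launched

    def detector_ids(self) -> list[str]:
        return [d.id for d in self.meta.detectors]

    def equals(self, other: "PhotonDatabase") -> bool:
        return (
            self.meta == other.meta
            and self.records.reset_index(drop=True).equals(other.records.reset_index(drop=True))
        )


def records_from_arrays(**columns) -> pd.DataFrame:
    """Assemble a record table from per-column arrays (see ``RECORD_COLUMNS``)."""
    df = pd.DataFrame({c: columns[c] for c in RECORD_COLUMNS})
    df["photon_id"] = df["photon_id"].astype(np.int64)
    df["detector_id"] = df["detector_id"].astype(str)
    df["weight"] = df["weight"].astype(np.float64)
    df["n_collisions"] = df["n_collisions"].astype(np.int64)
    df["path_length_mm"] = df["path_length_mm"].astype(np.float64)
    df["n_rr"] = df["n_rr"].astype(np.int64)
    return df


def validate_records(records: pd.DataFrame, meta: DatabaseMeta) -> None:
    """Check the per-record invariants; raise ``ValueError`` naming the first offender.

    Invariants: positive weight, at least one collision (a collimated photon
    cannot reach the surface unscattered), positive path length, and the
    CAW/RR weight identity ``ln W = -mua * L + n_rr * ln(1/p)``.
    """
    if records.empty:
        return

    def _fail(mask: np.ndarray, what: str) -> None:
        if mask.any():
            pid = int(records["photon_id"].to_numpy()[mask][0])
            raise ValueError(f"invalid record (photon_id={pid}): {what}")

    w = records["weight"].to_numpy()
    j = records["n_collisions"].to_numpy()
    length = records["path_length_mm"].to_numpy()
    nrr = records["n_rr"].to_numpy()
    _fail(~(w > 0.0), "weight must be > 0")
    _fail(j < 1, "n_collisions must be >= 1")
    _fail(~(length > 0.0), "path_length_mm must be > 0")
    _fail(nrr < 0, "n_rr must be >= 0")
    if meta.rr is None:
        _fail(nrr > 0, "n_rr > 0 in a database without an RR policy")
        resid = np.abs(np.log(w) + meta.medium.mua * length)
    else:
        resid = np.abs(np.log(w) + meta.medium.mua * length - nrr * math.log(1.0 / meta.rr.p))
    _fail(resid >= _IDENTITY_ATOL, "weight violates the CAW/RR identity")

    known = {d.id for d in meta.detectors}
    unknown = set(records["detector_id"]) - known
    if unknown:
        raise ValueError(f"records reference unknown detectors: {sorted(unknown)}")


def _meta_to_json(meta: DatabaseMeta, diagnostics: dict) -> dict:
    med = meta.medium
    return {
        "n_launched": meta.n_launched,
        "mua": med.mua,
        "mus": med.mus,
        "g": med.g,
        "n": med.n,
        "detectors": [
            {"id": d.id, "rho_min": d.rho_min, "rho_max": d.rho_max} for d in meta.detectors
        ],
        "rr": None if meta.rr is None else {"w_thr": meta.rr.w_thr, "p": meta.rr.p},
        "seed": meta.seed,
        "max_collisions": meta.max_collisions,
        "n_outside": meta.n_outside,
        "engine_version": meta.engine_version,
        "diagnostics": diagnostics,
    }


def _meta_from_json(payload: dict) -> tuple[DatabaseMeta, dict]:
    # Imported here: transport depends on this module for database assembly.
    from .transport import Detector, RRPolicy

    medium = OpticalProperties(
        mua=payload["mua"], mus=payload["mus"], g=payload["g"], n=payload["n"]
    )
    detectors = tuple(
        Detector(d["id"], d["rho_min"], d["rho_max"]) for d in payload["detectors"]
    )
    rr = None if payload["rr"] is None else RRPolicy(payload["rr"]["w_thr"], payload["rr"]["p"])
    meta = DatabaseMeta(
        n_launched=payload["n_launched"],
        medium=medium,
        detectors=detectors,
        rr=rr,
        seed=payload["seed"],
        max_collisions=payload.get("max_collisions", 1_000_000),
        n_outside=payload.get("n_outside"),
        engine_version=payload.get("engine_version", "unknown"),
    )
    return meta, payload.get("diagnostics", {})


def write_database(db: PhotonDatabase, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` and ``<prefix>.meta.json``; returns both paths."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".meta.json")
    try:
        db.records.to_csv(
            csv_path, index=False, float_format="%.17g", lineterminator="\n", encoding="utf-8"
        )
        meta_path.write_text(
            json.dumps(_meta_to_json(db.meta, db.diagnostics), indent=1) + "\n", encoding="utf-8"
        )
    except OSError as exc:
        raise OSError(f"cannot write photon database at prefix {prefix}: {exc}") from exc
    return csv_path, meta_path


def read_database(path_prefix: str | Path) -> PhotonDatabase:
    """Read a database written by :func:`write_database`, validating every record."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    meta_path = prefix.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    if not csv_path.exists():
        raise FileNotFoundError(f"missing record file {csv_path}")
    meta, diagnostics = _meta_from_json(json.loads(meta_path.read_text(encoding="utf-8")))
    records = pd.read_csv(csv_path, dtype={"detector_id": str}, float_precision="round_trip")
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"{csv_path} lacks required columns: {sorted(missing)}")
    records = records_from_arrays(**{c: records[c].to_numpy() for c in RECORD_COLUMNS})
    if len(records) > meta.n_launched:
        raise ValueError("database holds more records than photons launched")
    validate_records(records, meta)
    return PhotonDatabase(meta=meta, records=records, diagnostics=diagnostics)


def tallied_subset(db: PhotonDatabase, detector_id: str) -> tuple[pd.DataFrame, int, int]:
    """Records tallied at ``detector_id`` together with the counts ``(N_T, N_U)``.

    ``N_T + N_U = N`` always: every launched photon either deposits weight at
    this detector or contributes zero.
    """
    if detector_id not in db.detector_ids():
        raise KeyError(f"unknown detector {detector_id!r}; have {db.detector_ids()}")
    sub = db.records[db.records["detector_id"] == detector_id]
    n_t = len(sub)
    return sub, n_t, db.n_launched - n_t
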