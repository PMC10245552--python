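"""Shared fixtures: simulated photon databases at the canonical study conditions.

The expensive reference simulations are session-scoped so every test reuses
the same databases.  Seeds are fixed constants; nothing here depends on wall
time or the environment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pmcerr import (
    DatabaseMeta,
    PhotonDatabase,
    RRPolicy,
    SimulationConfig,
    from_ratio,
    run_simulation,
)
from pmcerr.photon_db import records_from_arrays
from pmcerr.transport import DISTAL, PROXIMAL

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

SEED = 20260921


@pytest.fixture(scope="session")
def db_r5_norr_small():
    """Ratio-5 medium, no RR, 200k photons: the workhorse unit-test database."""
    return run_simulation(
        SimulationConfig(n_photons=200_000, medium=from_ratio(5), seed=SEED)
    )


@pytest.fixture(scope="session")
def db_r5_rr_small():
    """Ratio-5 medium with Russian Roulette, 200k photons."""
    return run_simulation(
        SimulationConfig(n_photons=200_000, medium=from_ratio(5), rr=RRPolicy(), seed=SEED + 1)
    )


@pytest.fixture(scope="session")
def db_r5_norr_2e6():
    """Full-size (2M photon) ratio-5 reference simulation without RR."""
    return run_simulation(
        SimulationConfig(n_photons=2_000_000, medium=from_ratio(5), seed=SEED + 2)
    )


@pytest.fixture(scope="session")
def db_r100_norr_2e6():
    """Full-size (2M photon) ratio-100 reference simulation without RR."""
    return run_simulation(
        SimulationConfig(n_photons=2_000_000, medium=from_ratio(100), seed=SEED + 3)
    )


@pytest.fixture(scope="session")
def rr_dbs_2e6():
    """RR reference simulations (2M photons) for all five canonical media."""
    out = {}
    for k, ratio in enumerate((5, 10, 20, 50, 100)):
        out[ratio] = run_simulation(
            SimulationConfig(
                n_photons=2_000_000, medium=from_ratio(ratio), rr=RRPolicy(), seed=SEED + 10 + k
            )
        )
    return out


def build_synthetic_db(
    weights_by_detector: dict[str, np.ndarray],
    n_launched: int,
    medium=None,
    j_by_detector: dict[str, np.ndarray] | None = None,
    length_by_detector: dict[str, np.ndarray] | None = None,
) -> PhotonDatabase:
    """Hand-built database for oracle tests (synthetic: rows need not satisfy
    the CAW identity, so it bypasses read-time validation by construction)."""
    medium = medium if medium is not None else from_ratio(5)
    frames = []
    pid = 0
    for det, w in weights_by_detector.items():
        w = np.asarray(w, dtype=float)
        n = len(w)
        j = (
            j_by_detector[det]
            if j_by_detector is not None
            else np.arange(1, n + 1, dtype=np.int64)
        )
        length = (
            length_by_detector[det]
            if length_by_detector is not None
            else np.linspace(0.5, 5.0, n)
        )
        frames.append(
            records_from_arrays(
                photon_id=np.arange(pid, pid + n, dtype=np.int64),
                detector_id=np.array([det] * n, dtype=object),
                weight=w,
                n_collisions=np.asarray(j, dtype=np.int64),
                path_length_mm=np.asarray(length, dtype=float),
                n_rr=np.zeros(n, dtype=np.int64),
            )
        )
        pid += n
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else records_from_arrays(
            photon_id=np.array([], dtype=np.int64),
            detector_id=np.array([], dtype=object),
            weight=np.array([], dtype=float),
            n_collisions=np.array([], dtype=np.int64),
            path_length_mm=np.array([], dtype=float),
            n_rr=np.array([], dtype=np.int64),
        )
    )
    meta = DatabaseMeta(
        n_launched=n_launched,
        medium=medium,
        detectors=(PROXIMAL, DISTAL),
        rr=None,
        seed=0,
    )
    return PhotonDatabase(meta=meta, records=records, diagnostics={})
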