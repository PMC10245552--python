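"""Experiment driver: media x detectors x perturbations x (RR on/off) sweeps.

Reproduces the package's canonical study design — five media spanning
reduced-scattering-to-absorption ratios of 5 to 100 (all with ``g = 0.8``,
``n = 1.4``, ``lstar = 1 mm``), a proximal annular detector at
``rho in [0, 0.2) mm`` and a distal one at ``rho in [3, 3.2) mm``, and
scattering perturbations on a grid of fractional changes — and emits:

* a sweep table with, per (medium, detector, eps_s): the rigorous
  degradation degree ``dbar_p`` (ratio of perturbed to reference relative
  error), the rigorous ``sigma_WP``, the moment-propagated ``sigma_WP_est``
  and their relative discrepancy ``delta``, with optional delete-one-block
  jackknife standard errors on ``delta`` and ``dbar_p``;
* moment tables of the normalized variance, correlation and skewness of
  {ln W_R, j, L} per detector (the scale-free diagnostics that explain when
  the moment propagation works);
* fixed-bin histogram summaries of W_R, j and L per detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .estimator import (
    MomentSummary,
    compute_moments,
    estimate_error,
)
from .optics import OpticalProperties, Perturbation, from_ratio
from .photon_db import PhotonDatabase, tallied_subset
from .pmc import population_variance_direct
from .transport import DISTAL, PROXIMAL, Detector, RRPolicy, SimulationConfig, run_simulation

__all__ = [
    "StudyPlan",
    "StudyResult",
    "default_media",
    "run_study",
    "summarize_rr_impact",
    "histogram_summary",
    "sweep_detector",
]

DEFAULT_RATIOS = (5.0, 10.0, 20.0, 50.0, 100.0)


def default_media() -> tuple[OpticalProperties, ...]:
    """The five canonical media, parameterized by ``musp/mua`` at ``lstar = 1 mm``."""
    return tuple(from_ratio(r) for r in DEFAULT_RATIOS)


def default_eps_grid() -> tuple[float, ...]:
    """Scattering perturbations from -20% to +20% in 5% steps."""
    return tuple(np.round(np.arange(-0.20, 0.2001, 0.05), 10))


@dataclass(frozen=True)
class StudyPlan:
    media: tuple[OpticalProperties, ...] = field(default_factory=default_media)
    detectors: tuple[Detector, ...] = (PROXIMAL, DISTAL)
    eps_grid: tuple[float, ...] = field(default_factory=default_eps_grid)
    rr: str = "on"  # "on" | "off" | "both"
    rr_policy: RRPolicy = RRPolicy(w_thr=1e-3, p=0.1)
    n_photons: int = 2_000_000
    seed: int = 0
    max_collisions: int = 1_000_000
    jackknife_blocks: int = 20

    def __post_init__(self) -> None:
        if not self.media:
            raise ValueError("plan needs at least one medium")
        if self.rr not in ("on", "off", "both"):
            raise ValueError(f"rr must be 'on', 'off' or 'both', got {self.rr!r}")
        if any(not -1.0 < e for e in self.eps_grid):
            raise ValueError("eps grid entries must exceed -1")

    def rr_flags(self) -> tuple[bool, ...]:
        return {"on": (True,), "off": (False,), "both": (False, True)}[self.rr]


@dataclass
class StudyResult:
    plan: StudyPlan
    sweep: pd.DataFrame
    moments: pd.DataFrame
    histograms: pd.DataFrame
    databases: dict
    moment_summaries: dict


def _run_seed(base_seed: int, k: int) -> int:
    """Deterministic per-run seed below 2**31."""
    return (base_seed * 1_000_003 + 7_919 * k + 1) % 2_147_483_647


# ---------------------------------------------------------------------------
# Per-detector sweep with jackknife resampling
# ---------------------------------------------------------------------------


@dataclass
class _SubsetStats:
    """Precomputed per-subset quantities reused across the eps grid."""

    lnw: np.ndarray
    j: np.ndarray
    length: np.ndarray
    n_total: int
    moments: MomentSummary
    w_bar_r: float
    sigma_wr: float


def _subset_stats(records: pd.DataFrame, mask, n_total: int, medium: OpticalProperties,
                  detector_id: str) -> _SubsetStats:
    sub = records if mask is None else records[mask]
    m = compute_moments(
        sub, n_total, detector_id=detector_id,
        medium_key=(medium.mua, medium.mus, medium.g, medium.n),
    )
    w = sub["weight"].to_numpy(dtype=np.float64)
    w_bar_r, var_wr = population_variance_direct(w, n_total)
    return _SubsetStats(
        lnw=np.log(w),
        j=sub["n_collisions"].to_numpy(dtype=np.float64),
        length=sub["path_length_mm"].to_numpy(dtype=np.float64),
        n_total=n_total,
        moments=m,
        w_bar_r=w_bar_r,
        sigma_wr=float(np.sqrt(var_wr)),
    )


def _eval_point(stats: _SubsetStats, medium: OpticalProperties, eps_s: float) -> tuple[float, float, float, float]:
    """(dbar_p, sigma_wp, sigma_est, delta) for one subset and one perturbation."""
    pert = Perturbation(eps_s=eps_s)
    a = pert.log_scattering_ratio(medium)
    b = pert.delta_mut(medium)
    wp = np.exp(stats.lnw + a * stats.j - b * stats.length)
    w_bar_p, var_wp = population_variance_direct(wp, stats.n_total)
    sigma_wp = float(np.sqrt(var_wp))
    dbar = (sigma_wp / w_bar_p) / (stats.sigma_wr / stats.w_bar_r)
    est = estimate_error(stats.moments, pert, sigma_wp_true=sigma_wp)
    return dbar, sigma_wp, est.sigma_wp_est, est.delta


def _jackknife_se(values: np.ndarray) -> float:
    b = len(values)
    mean = values.mean()
    return float(np.sqrt((b - 1) / b * ((values - mean) ** 2).sum()))


def sweep_detector(
    db: PhotonDatabase,
    detector_id: str,
    eps_grid,
    jackknife_blocks: int = 20,
) -> pd.DataFrame:
    """Sweep one detector of one database over a grid of scattering perturbations.

    Returns one row per eps with the rigorous and estimated uncertainties and,
    when ``jackknife_blocks > 0``, delete-one-block jackknife standard errors
    computed over photon-index blocks (``photon_id mod B``); deleting a block
    removes its launched photons from both the tallied records and the total
    count, so each leave-out replicate is itself a consistent population.
    """
    medium = db.meta.medium
    records, n_t, _ = tallied_subset(db, detector_id)
    if n_t < 2:
        raise ValueError(f"detector {detector_id!r} tallied {n_t} photons; sweep undefined")
    n = db.n_launched
    full = _subset_stats(records, None, n, medium, detector_id)

    replicates: list[_SubsetStats] = []
    if jackknife_blocks > 1:
        pid_block = records["photon_id"].to_numpy() % jackknife_blocks
        for blk in range(jackknife_blocks):
            launched_in_block = n // jackknife_blocks + (1 if blk < n % jackknife_blocks else 0)
            replicates.append(
                _subset_stats(records, pid_block != blk, n - launched_in_block, medium, detector_id)
            )

    rows = []
    for eps in eps_grid:
        dbar, sigma_wp, sigma_est, delta = _eval_point(full, medium, eps)
        if replicates:
            reps = np.array([_eval_point(r, medium, eps) for r in replicates])
            dbar_se = _jackknife_se(reps[:, 0])
            delta_se = _jackknife_se(reps[:, 3])
        else:
            dbar_se = np.nan
            delta_se = np.nan
        rows.append(
            {
                "ratio": medium.ratio,
                "detector_id": detector_id,
                "rr": db.meta.rr is not None,
                "eps_s": eps,
                "n_tallied": n_t,
                "dbar_p": dbar,
                "sigma_wp": sigma_wp,
                "sigma_wp_est": sigma_est,
                "delta": delta,
                "dbar_p_se": dbar_se,
                "delta_se": delta_se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Moment tables and histogram summaries
# ---------------------------------------------------------------------------


def moment_table(m: MomentSummary, ratio: float, rr: bool) -> pd.DataFrame:
    """Scale-free moment diagnostics of one detector, in tabular long form."""
    rows = []
    names = {"lnw": "log(WR)", "j": "j", "L": "L"}
    for x in ("lnw", "j", "L"):
        rows.append(
            {
                "ratio": ratio,
                "detector_id": m.detector_id,
                "rr": rr,
                "name": names[x],
                "norm_var": m.normalized_var(x),
                "corr": np.nan,
                "skew": m.skew[x],
            }
        )
    for x, y in (("lnw", "j"), ("lnw", "L"), ("j", "L")):
        rows.append(
            {
                "ratio": ratio,
                "detector_id": m.detector_id,
                "rr": rr,
                "name": f"{names[x]}, {names[y]}",
                "norm_var": np.nan,
                "corr": m.corr(x, y),
                "skew": np.nan,
            }
        )
    return pd.DataFrame(rows)


def histogram_summary(records: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Fixed-bin count histograms of W_R (log-spaced bins), j and L (linear bins)."""
    out = []
    w = records["weight"].to_numpy(dtype=np.float64)
    edges_w = np.geomspace(w.min(), w.max() * (1 + 1e-12), n_bins + 1)
    specs = [
        ("W", w, edges_w),
        ("j", records["n_collisions"].to_numpy(dtype=np.float64), None),
        ("L", records["path_length_mm"].to_numpy(dtype=np.float64), None),
    ]
    for name, values, edges in specs:
        if edges is None:
            edges = np.linspace(values.min(), values.max() * (1 + 1e-12), n_bins + 1)
        counts, edges = np.histogram(values, bins=edges)
        out.append(
            pd.DataFrame(
                {
                    "variable": name,
                    "bin_lo": edges[:-1],
                    "bin_hi": edges[1:],
                    "count": counts,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def summarize_rr_impact(moments_no_rr: MomentSummary, moments_rr: MomentSummary) -> pd.DataFrame:
    """Per-variable reduction ratios (RR over no-RR) of the scale-free moments.

    Both summaries must describe the same medium, detector and launched-photon
    count.  Ratios below 1 mean RR reduced the metric; rows with a ratio
    above 1 are flagged.
    """
    for attr in ("detector_id", "medium_key", "n"):
        if getattr(moments_no_rr, attr) != getattr(moments_rr, attr):
            raise ValueError(f"mismatched provenance: {attr} differs between summaries")
    rows = []
    for x in ("lnw", "j", "L"):
        rows.append(
            {
                "name": x,
                "metric": "norm_var",
                "ratio": moments_rr.normalized_var(x) / moments_no_rr.normalized_var(x),
            }
        )
        rows.append(
            {
                "name": x,
                "metric": "abs_skew",
                "ratio": abs(moments_rr.skew[x]) / abs(moments_no_rr.skew[x]),
            }
        )
    for x, y in (("lnw", "j"), ("lnw", "L"), ("j", "L")):
        rows.append(
            {
                "name": f"{x},{y}",
                "metric": "abs_corr",
                "ratio": abs(moments_rr.corr(x, y)) / abs(moments_no_rr.corr(x, y)),
            }
        )
    df = pd.DataFrame(rows)
    df["reduced"] = df["ratio"] < 1.0
    return df


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def run_study(plan: StudyPlan) -> StudyResult:
    """Run the full study plan: simulate each medium (per RR setting) and sweep it.

    Any sub-step failure is re-raised with the (ratio, detector, rr)
    coordinate attached, so a long batch points at the offending cell.
    """
    sweeps = []
    moment_rows = []
    hist_rows = []
    databases: dict[tuple[float, bool], PhotonDatabase] = {}
    moment_summaries: dict[tuple[float, str, bool], MomentSummary] = {}

    k = 0
    for medium in plan.media:
        for rr_on in plan.rr_flags():
            config = SimulationConfig(
                n_photons=plan.n_photons,
                medium=medium,
                detectors=plan.detectors,
                rr=plan.rr_policy if rr_on else None,
                seed=_run_seed(plan.seed, k),
                max_collisions=plan.max_collisions,
            )
            k += 1
            db = run_simulation(config)
            databases[(medium.ratio, rr_on)] = db
            for det in plan.detectors:
                coord = f"(ratio={medium.ratio:g}, detector={det.id}, rr={rr_on})"
                try:
                    records, n_t, _ = tallied_subset(db, det.id)
                    m = compute_moments(
                        records,
                        db.n_launched,
                        detector_id=det.id,
                        medium_key=(medium.mua, medium.mus, medium.g, medium.n),
                    )
                    moment_summaries[(medium.ratio, det.id, rr_on)] = m
                    moment_rows.append(moment_table(m, medium.ratio, rr_on))
                    hist = histogram_summary(records)
                    hist.insert(0, "ratio", medium.ratio)
                    hist.insert(1, "detector_id", det.id)
                    hist.insert(2, "rr", rr_on)
                    hist_rows.append(hist)
                    sweeps.append(
                        sweep_detector(db, det.id, plan.eps_grid, plan.jackknife_blocks)
                    )
                except Exception as exc:
                    raise RuntimeError(f"study failed at {coord}: {exc}") from exc

    return StudyResult(
        plan=plan,
        sweep=pd.concat(sweeps, ignore_index=True),
        moments=pd.concat(moment_rows, ignore_index=True),
        histograms=pd.concat(hist_rows, ignore_index=True),
        databases=databases,
        moment_summaries=moment_summaries,
    )
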