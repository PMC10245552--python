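"""CAW photon random-walk engine for a homogeneous semi-infinite medium.

Geometry and conventions
------------------------
The medium occupies the half-space ``z > 0``; photons are launched at the
origin just inside the surface, travelling along +z with unit weight.
Inter-collision distances are drawn from an exponential with rate ``mus``
(collisions are pure scattering events) and absorption enters only through
the continuous weight factor ``exp(-mua * L)`` accumulated along the total
path length ``L`` — continuous absorption weighting (CAW).  This makes the
photon weight an exact deterministic function of its trajectory:

    W = exp(-mua * L) * p ** (-n_rr)

where ``n_rr`` counts survived Russian-Roulette events with survival
probability ``p``.  Scattering deflections use the Henyey–Greenstein phase
function with azimuthal symmetry.

In the canonical study configuration the boundary is index-matched
(``n_outside = None``): every photon exits, and is tallied, at its first
surface crossing, which keeps the detected weight an exact function of the
path length.  When an external index is configured, a surface crossing is
resolved probabilistically with the unpolarized Fresnel reflectance at the
internal incidence angle (full exit or full internal reflection, never
weight splitting); an internal reflection mirrors the z-direction,
accumulates path in ``L`` and does not count as a collision.

Russian Roulette is checked after each collision: once the weight falls
below the policy threshold the photon survives with probability ``p``
(weight amplified by ``1/p``) or is terminated.  Photons whose CAW weight
underflows double precision (``mua * L > 745``) can no longer contribute to
any tally and are terminated; they are counted in the database diagnostics,
as are photons stopped by the collision-count safety cap.

Randomness comes from one SplitMix64 stream per photon, seeded by mixing the
simulation seed with the photon index, so databases are reproducible and
independent of photon execution order.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .optics import OpticalProperties
from .photon_db import DatabaseMeta, PhotonDatabase, records_from_arrays

__all__ = [
    "Detector",
    "RRPolicy",
    "SimulationConfig",
    "PROXIMAL",
    "DISTAL",
    "sample_free_path",
    "sample_scatter_cos",
    "fresnel_reflectance",
    "apply_russian_roulette",
    "run_simulation",
]

#: ln of the smallest positive normal double times a safety margin; a CAW
#: weight below exp(-745) is exactly 0.0 in float64 and can never be tallied.
_LN_UNDERFLOW = -745.0


@dataclass(frozen=True)
class Detector:
    """Annular surface detector on z = 0; membership is half-open [rho_min, rho_max)."""

    id: str
    rho_min: float
    rho_max: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_min < self.rho_max:
            raise ValueError(f"need 0 <= rho_min < rho_max, got [{self.rho_min}, {self.rho_max})")


PROXIMAL = Detector("proximal", 0.0, 0.2)
DISTAL = Detector("distal", 3.0, 3.2)


@dataclass(frozen=True)
class RRPolicy:
    """Russian-Roulette policy: play once the weight drops below ``w_thr``; survive with ``p``."""

    w_thr: float = 1e-3
    p: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.w_thr < 1.0:
            raise ValueError(f"w_thr must lie in (0, 1), got {self.w_thr}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must lie in (0, 1], got {self.p}")


@dataclass(frozen=True)
class SimulationConfig:
    n_photons: int
    medium: OpticalProperties
    detectors: tuple[Detector, ...] = (PROXIMAL, DISTAL)
    rr: Optional[RRPolicy] = None
    seed: int = 0
    max_collisions: int = 1_000_000
    #: refractive index of the medium above the surface; None means matched to
    #: the tissue index, so every first surface crossing exits and is tallied.
    n_outside: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.max_collisions < 1:
            raise ValueError("max_collisions must be >= 1")
        dets = sorted(self.detectors, key=lambda d: d.rho_min)
        for a, b in zip(dets, dets[1:]):
            if b.rho_min < a.rho_max:
                raise ValueError(f"detectors {a.id!r} and {b.id!r} overlap")


# ---------------------------------------------------------------------------
# Scalar sampling contracts (unit-testable building blocks; the simulation
# kernel inlines the same formulas for speed).
# ---------------------------------------------------------------------------


def sample_free_path(mus: float, u: float) -> float:
    """Exponential free path ``-ln(u) / mus`` for a uniform(0, 1] variate ``u``."""
    if not mus > 0.0:
        raise ValueError(f"mus must be > 0, got {mus}")
    if not 0.0 < u <= 1.0:
        raise ValueError(f"u must lie in (0, 1], got {u}")
    return -math.log(u) / mus


def sample_scatter_cos(g: float, u: float) -> float:
    """Henyey–Greenstein deflection cosine via the inverse CDF.

    For ``g = 0`` the phase function is isotropic and ``cos = 2u - 1``.
    """
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must lie in [0, 1), got {g}")
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return min(1.0, max(-1.0, cos_t))


def fresnel_reflectance(n_in: float, n_out: float, cos_inc: float) -> float:
    """Unpolarized Fresnel reflectance (mean of s and p) at a planar interface.

    ``cos_inc`` is the cosine of the incidence angle on the ``n_in`` side.
    Beyond the critical angle (``n_in > n_out``) the reflectance is 1.
    """
    if not (n_in >= 1.0 and n_out >= 1.0):
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= cos_inc <= 1.0:
        raise ValueError(f"cos_inc must lie in [0, 1], got {cos_inc}")
    sin_t2 = (n_in / n_out) ** 2 * (1.0 - cos_inc * cos_inc)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_inc - n_out * cos_t) / (n_in * cos_inc + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_inc) / (n_in * cos_t + n_out * cos_inc)
    return 0.5 * (rs * rs + rp * rp)


def apply_russian_roulette(weight: float, policy: RRPolicy, u: float) -> Optional[float]:
    """One fair Roulette round: return ``weight / p`` if ``u < p``, else ``None`` (terminated).

    Counting a terminated photon as zero weight, the expected returned weight
    equals the input weight, so the game is unbiased.  Calling this with a
    weight at or above the policy threshold is a contract violation.
    """
    if not 0.0 < weight < policy.w_thr:
        raise ValueError(f"RR requires 0 < weight < w_thr={policy.w_thr}, got {weight}")
    if u < policy.p:
        return weight / policy.p
    return None


# ---------------------------------------------------------------------------
# SplitMix64 counter-based RNG (one independent stream per photon).
# ---------------------------------------------------------------------------

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_TO_UNIT = 1.0 / 9007199254740992.0  # 2 ** -53


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _next_unit(state):
    """Advance one SplitMix64 step; return (state, uniform in [0, 1))."""
    state = state + _GOLDEN
    return state, float(_mix64(state) >> np.uint64(11)) * _TO_UNIT


@njit(cache=True, fastmath=True)
def _simulate_kernel(
    n_photons,
    mua,
    mus,
    g,
    n_rel,
    rr_enabled,
    w_thr,
    p_surv,
    max_coll,
    seed,
    det_lo,
    det_hi,
):
    # Output buffers: a photon exits (and can be tallied) at most once.
    cap = n_photons
    out_id = np.empty(cap, dtype=np.int64)
    out_det = np.empty(cap, dtype=np.int64)
    out_j = np.empty(cap, dtype=np.int64)
    out_len = np.empty(cap, dtype=np.float64)
    out_nrr = np.empty(cap, dtype=np.int64)
    n_out = 0

    n_capped = 0
    n_underflow = 0
    n_rr_survived = 0
    n_rr_killed = 0

    ln_wthr = math.log(w_thr) if rr_enabled else 0.0
    ln_inv_p = -math.log(p_surv) if rr_enabled else 0.0
    n_det = det_lo.shape[0]
    base = _mix64(np.uint64(seed) ^ np.uint64(0xD1B54A32D192ED03))

    for i in range(n_photons):
        state = _mix64(base ^ (np.uint64(i) * _GOLDEN))
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        j = 0
        nrr = 0

        while True:
            state, u = _next_unit(state)
            s = -math.log(1.0 - u) / mus  # 1-u lies in (0, 1]

            if uz < 0.0 and s * (-uz) >= z:
                # Segment reaches the surface before the next collision.
                s_b = z / (-uz)
                x += s_b * ux
                y += s_b * uy
                z = 0.0
                path += s_b
                reflected = False
                if n_rel != 1.0:
                    cos_i = -uz
                    refl = 1.0
                    sin_t2 = (n_rel * n_rel) * (1.0 - cos_i * cos_i)
                    if sin_t2 < 1.0:
                        cos_t = math.sqrt(1.0 - sin_t2)
                        rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
                        rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
                        refl = 0.5 * (rs * rs + rp * rp)
                    state, u2 = _next_unit(state)
                    reflected = u2 < refl
                if not reflected:
                    # Exit: tally if the exit radius falls in a detector annulus.
                    r = math.sqrt(x * x + y * y)
                    for d in range(n_det):
                        if det_lo[d] <= r < det_hi[d]:
                            out_id[n_out] = i
                            out_det[n_out] = d
                            out_j[n_out] = j
                            out_len[n_out] = path
                            out_nrr[n_out] = nrr
                            n_out += 1
                            break
                    break
                # Internal reflection: mirror z-direction, finish the step.
                uz = -uz
                s -= s_b

            x += s * ux
            y += s * uy
            z += s * uz
            path += s
            j += 1

            ln_w = -mua * path + nrr * ln_inv_p
            if ln_w < _LN_UNDERFLOW:
                n_underflow += 1
                break
            if rr_enabled and ln_w < ln_wthr:
                state, u3 = _next_unit(state)
                if u3 < p_surv:
                    nrr += 1
                    n_rr_survived += 1
                else:
                    n_rr_killed += 1
                    break
            if j >= max_coll:
                n_capped += 1
                break

            # Henyey–Greenstein deflection, uniform azimuth.
            state, u4 = _next_unit(state)
            if g > 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u4)
                cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cos_t > 1.0:
                    cos_t = 1.0
                elif cos_t < -1.0:
                    cos_t = -1.0
            else:
                cos_t = 2.0 * u4 - 1.0
            sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            # Uniform azimuth without trig: rejection-sample a point in the
            # unit disk and use the double-angle identities.
            while True:
                state, ua = _next_unit(state)
                state, ub = _next_unit(state)
                va = 2.0 * ua - 1.0
                vb = 2.0 * ub - 1.0
                r2 = va * va + vb * vb
                if 0.0 < r2 <= 1.0:
                    break
            cos_p = (va * va - vb * vb) / r2
            sin_p = 2.0 * va * vb / r2
            if abs(uz) > 0.99999:
                ux = sin_t * cos_p
                uy = sin_t * sin_p
                uz = cos_t if uz > 0.0 else -cos_t
            else:
                denom = math.sqrt(1.0 - uz * uz)
                ux_new = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
                uy_new = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
                uz_new = -sin_t * cos_p * denom + uz * cos_t
                ux = ux_new
                uy = uy_new
                uz = uz_new

    return (
        out_id[:n_out].copy(),
        out_det[:n_out].copy(),
        out_j[:n_out].copy(),
        out_len[:n_out].copy(),
        out_nrr[:n_out].copy(),
        n_capped,
        n_underflow,
        n_rr_survived,
        n_rr_killed,
    )


def run_simulation(config: SimulationConfig) -> PhotonDatabase:
    """Simulate ``config.n_photons`` independent photons and return the per-photon database.

    Each detected photon contributes one record (detector id, weight, collision
    count, path length, Roulette-survival count).  The weight is evaluated from
    the CAW identity ``W = exp(-mua * L) * p**(-n_rr)``, which the stored
    trajectory quantities determine exactly.
    """
    med = config.medium
    rr = config.rr
    det_lo = np.array([d.rho_min for d in config.detectors], dtype=np.float64)
    det_hi = np.array([d.rho_max for d in config.detectors], dtype=np.float64)

    t0 = time.perf_counter()
    (ids, det_idx, j, path, nrr, n_capped, n_underflow, n_rr_survived, n_rr_killed) = _simulate_kernel(
        config.n_photons,
        med.mua,
        med.mus,
        med.g,
        1.0 if config.n_outside is None else med.n / config.n_outside,
        rr is not None,
        rr.w_thr if rr is not None else 1e-3,
        rr.p if rr is not None else 0.1,
        config.max_collisions,
        config.seed,
        det_lo,
        det_hi,
    )
    elapsed = time.perf_counter() - t0

    if rr is not None:
        weight = np.exp(-med.mua * path) * rr.p ** (-nrr.astype(np.float64))
    else:
        weight = np.exp(-med.mua * path)
    det_ids = np.array([d.id for d in config.detectors], dtype=object)
    records = records_from_arrays(
        photon_id=ids,
        detector_id=det_ids[det_idx] if len(ids) else np.array([], dtype=object),
        weight=weight,
        n_collisions=j,
        path_length_mm=path,
        n_rr=nrr,
    )
    meta = DatabaseMeta(
        n_launched=config.n_photons,
        medium=med,
        detectors=config.detectors,
        rr=rr,
        seed=config.seed,
        max_collisions=config.max_collisions,
        n_outside=config.n_outside,
    )
    diagnostics = {
        "terminated_by_cap": int(n_capped),
        "terminated_by_underflow": int(n_underflow),
        "rr_survivals": int(n_rr_survived),
        "rr_terminations": int(n_rr_killed),
        "wall_time_s": float(elapsed),
    }
    return PhotonDatabase(meta=meta, records=records, diagnostics=diagnostics)
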