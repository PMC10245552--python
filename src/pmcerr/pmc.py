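"""Perturbation Monte Carlo reweighting and rigorous perturbed-population statistics.

A reference simulation stores, for every photon tallied at a detector, its
weight ``W_R``, collision count ``j`` and path length ``L``.  For a global
change of the optical coefficients the detected weight under the perturbed
medium is obtained without re-simulation:

    W_P = W_R * (mus_P / mus_R) ** j * exp(-(mut_P - mut_R) * L)

evaluated in log space, ``ln W_P = ln W_R + j * a - b * L`` with
``a = ln(mus_P / mus_R)`` and ``b = mut_P - mut_R``, to avoid overflow at
large collision counts.  Untallied photons carry perturbed weight zero for
this detector, so the full-population mean and variance over all ``N``
launched photons follow from the tallied records and the counts alone.

All variances here use the population (1/N) normalization, matching the
estimator definitions used throughout the package; with millions of photons
the distinction from the unbiased (1/(N-1)) form is immaterial, but
definitional consistency makes the decomposition identities exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import OpticalProperties, Perturbation
from .photon_db import PhotonDatabase, PhotonRecord, tallied_subset

__all__ = [
    "PMCResult",
    "perturb_weight",
    "perturbed_log_weights",
    "population_variance_direct",
    "population_variance_decomposed",
    "perturbed_population_stats",
    "degradation_degree",
]

#: relative agreement demanded between the direct population variance and its
#: tallied/untallied decomposition — both are exact algebra, so only rounding
#: separates them
_DECOMPOSITION_RTOL = 1e-12


@dataclass(frozen=True)
class PMCResult:
    """Perturbed-weight population statistics for one detector and perturbation.

    ``w_bar_p`` and ``var_wp`` are mean and variance over all ``N`` launched
    photons (untallied photons counted as zero weight); ``w_bar_pt`` and
    ``var_wpt`` are restricted to the ``n_tallied`` detected photons.
    ``phi_bar = w_bar_p - w_bar_pt`` is the mean offset between the two
    populations and ``rel_error = sqrt(var_wp) / w_bar_p`` the relative
    error of the detector estimate.
    """

    detector_id: str
    perturbation: Perturbation
    n_launched: int
    n_tallied: int
    w_bar_p: float
    w_bar_pt: float
    phi_bar: float
    var_wp: float
    var_wpt: float

    @property
    def rel_error(self) -> float:
        return float(np.sqrt(self.var_wp) / self.w_bar_p)


def perturb_weight(record: PhotonRecord, ref: OpticalProperties, pert: Perturbation) -> float:
    """Perturbed weight of a single detected photon (log-space evaluation)."""
    a = pert.log_scattering_ratio(ref)
    b = pert.delta_mut(ref)
    ln_wp = np.log(record.weight) + record.n_collisions * a - b * record.path_length_mm
    wp = float(np.exp(ln_wp))
    if not np.isfinite(wp):
        raise OverflowError(
            f"perturbed weight overflows for photon_id={record.photon_id} (ln W_P={ln_wp})"
        )
    return wp


def perturbed_log_weights(
    records, ref: OpticalProperties, pert: Perturbation
) -> np.ndarray:
    """Vectorized ``ln W_P`` for a table of tallied records."""
    a = pert.log_scattering_ratio(ref)
    b = pert.delta_mut(ref)
    return (
        np.log(records["weight"].to_numpy())
        + records["n_collisions"].to_numpy() * a
        - b * records["path_length_mm"].to_numpy()
    )


def population_variance_direct(wp: np.ndarray, n_total: int) -> tuple[float, float]:
    """Mean and variance over the full population of ``n_total`` photons.

    ``wp`` holds the weights of the tallied photons; the remaining
    ``n_total - len(wp)`` photons have weight zero and enter the sums without
    being materialized.
    """
    n_t = len(wp)
    w_bar_p = float(wp.sum()) / n_total
    var = (float(((wp - w_bar_p) ** 2).sum()) + (n_total - n_t) * w_bar_p**2) / n_total
    return w_bar_p, var


def population_variance_decomposed(wp: np.ndarray, n_total: int) -> float:
    """Tallied/untallied decomposition of the full-population variance.

    ``var = (1/N) * [N_T * (var_T + phi_bar**2) + N_U * w_bar_p**2]`` with
    ``phi_bar = w_bar_p - w_bar_pt`` — algebraically identical to the direct
    population variance, but assembled from sub-population statistics.
    """
    n_t = len(wp)
    n_u = n_total - n_t
    w_bar_pt = float(wp.mean())
    var_t = float(((wp - w_bar_pt) ** 2).mean())
    w_bar_p = n_t / n_total * w_bar_pt
    phi_bar = w_bar_p - w_bar_pt
    return (n_t * (var_t + phi_bar**2) + n_u * w_bar_p**2) / n_total


def perturbed_population_stats(
    db: PhotonDatabase, detector_id: str, pert: Perturbation
) -> PMCResult:
    """Rigorous perturbed-weight statistics for one detector.

    Reweights every tallied record, then computes the full-population variance
    by both the direct sum and the tallied/untallied decomposition and asserts
    their agreement (a permanent internal consistency check on the bookkeeping
    of untallied photons).
    """
    records, n_t, _n_u = tallied_subset(db, detector_id)
    if n_t == 0:
        raise ValueError(
            f"detector {detector_id!r} tallied no photons; perturbed statistics undefined"
        )
    n = db.n_launched
    wp = np.exp(perturbed_log_weights(records, db.meta.medium, pert))
    if not np.all(np.isfinite(wp)):
        bad = records["photon_id"].to_numpy()[~np.isfinite(wp)][0]
        raise OverflowError(f"perturbed weight overflows for photon_id={int(bad)}")

    w_bar_pt = float(wp.mean())
    var_wpt = float(((wp - w_bar_pt) ** 2).mean())
    w_bar_p, var_direct = population_variance_direct(wp, n)
    var_decomposed = population_variance_decomposed(wp, n)
    if abs(var_decomposed - var_direct) > _DECOMPOSITION_RTOL * max(var_direct, 1e-300):
        raise AssertionError(
            f"variance decomposition disagrees with the direct sum: "
            f"{var_decomposed!r} vs {var_direct!r}"
        )
    return PMCResult(
        detector_id=detector_id,
        perturbation=pert,
        n_launched=n,
        n_tallied=n_t,
        w_bar_p=w_bar_p,
        w_bar_pt=w_bar_pt,
        phi_bar=w_bar_p - w_bar_pt,
        var_wp=var_direct,
        var_wpt=var_wpt,
    )


def degradation_degree(ref_stats: PMCResult, pmc: PMCResult) -> float:
    """Ratio of the perturbed to the reference relative error (>= 0; 1 at zero perturbation).

    Both results must come from the same database and detector; the reference
    statistics are the ``eps = 0`` evaluation.
    """
    if ref_stats.detector_id != pmc.detector_id or ref_stats.n_launched != pmc.n_launched:
        raise ValueError("degradation degree requires results from the same database and detector")
    if ref_stats.w_bar_p == 0.0 or pmc.w_bar_p == 0.0:
        raise ZeroDivisionError("degradation degree undefined for a zero mean weight")
    return pmc.rel_error / ref_stats.rel_error
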