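"""A-priori estimation of the pMC relative error from reference-simulation moments.

The rigorous route to the variance of a perturbed-weight population requires
reweighting every tallied photon for every perturbation of interest.  This
module implements the alternative: characterize the reference database once
through the low-order moments of the detected-photon variables

    x in {ln W_R, j, L}

— per-variable mean, variance and skewness plus the pairwise covariances,
all with population (1/N_T) normalization — and propagate those moments
through the log-linear reweighting transform

    ln W_P = ln W_R + j * a - b * L,      a = ln(mus_P/mus_R),  b = mut_P - mut_R

to predict the variance of ``ln W_P`` for any perturbation without touching
the records again.  The propagation template carries first-order variance
terms, covariance cross terms and third-order skewness terms with second
derivatives; for the log-linear transform the second derivatives vanish, so
the skewness terms contribute exactly zero and the propagated variance is
exact (the template is kept generic so nonlinear transforms remain
expressible).  The remaining approximations are the delta-method
back-transformation ``var(W_PT) ~= W_bar**2 * var(ln W_PT)`` and the use of
reference means in place of perturbed means throughout the full-population
assembly.

The quality of the final estimate ``sigma_WP_est`` is reported by the
relative discrepancy ``delta = (sigma_est - sigma_true) / sigma_true``
against the rigorously computed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .optics import Perturbation
from .photon_db import PhotonDatabase, tallied_subset

__all__ = [
    "VARIABLES",
    "MomentSummary",
    "ErrorEstimate",
    "TransformDerivatives",
    "compute_moments",
    "moments_for_detector",
    "propagate_variance",
    "propagate_log_variance",
    "back_transform_variance",
    "estimate_full_variance",
    "estimator_discrepancy",
    "estimate_error",
]

VARIABLES = ("lnw", "j", "L")


@dataclass(frozen=True)
class MomentSummary:
    """Population moments of {ln W_R, j, L} over one detector's tallied photons.

    ``mean``, ``var``, ``skew`` and ``third_moment`` (= skew * sd**3) are
    keyed by variable name; ``cov`` by unordered variable pair (stored under
    both orders, with ``cov[(x, x)] = var[x]``).  ``w_bar_rt`` is the mean
    tallied reference weight and ``w_bar_r = (N_T / N) * w_bar_rt`` the mean
    over the full launched population with untallied photons counted as zero.
    """

    n: int
    n_tallied: int
    mean: Mapping[str, float]
    var: Mapping[str, float]
    skew: Mapping[str, float]
    cov: Mapping[tuple[str, str], float]
    w_bar_rt: float
    detector_id: Optional[str] = None
    medium_key: Optional[tuple] = None

    @property
    def n_untallied(self) -> int:
        return self.n - self.n_tallied

    @property
    def w_bar_r(self) -> float:
        return self.n_tallied / self.n * self.w_bar_rt

    def sd(self, x: str) -> float:
        return float(np.sqrt(self.var[x]))

    def third_moment(self, x: str) -> float:
        return self.skew[x] * self.sd(x) ** 3

    def corr(self, x: str, y: str) -> float:
        return self.cov[(x, y)] / (self.sd(x) * self.sd(y))

    def normalized_var(self, x: str) -> float:
        """Variance normalized by the squared mean, the scale-free tabulation."""
        return self.var[x] / self.mean[x] ** 2


@dataclass(frozen=True)
class ErrorEstimate:
    """Moment-propagated pMC uncertainty for one detector and perturbation."""

    detector_id: Optional[str]
    perturbation: Perturbation
    var_ln_wpt: float
    var_wpt_est: float
    var_wp_est: float
    sigma_wp_est: float
    rel_error_est: float
    delta: Optional[float] = None


@dataclass(frozen=True)
class TransformDerivatives:
    """First and second derivatives of a scalar transform of {lnw, j, L} at the means."""

    grad: Mapping[str, float]
    hess_diag: Mapping[str, float]


def compute_moments(records, n_launched: int, detector_id: Optional[str] = None,
                    medium_key: Optional[tuple] = None) -> MomentSummary:
    """Two-pass population moments of {ln W_R, j, L} over a record table.

    Requires at least two records; every stored weight must be positive so the
    logarithm is defined.
    """
    n_t = len(records)
    if n_t < 2:
        raise ValueError(f"need at least 2 records to form moments, got {n_t}")
    w = records["weight"].to_numpy(dtype=np.float64)
    if not np.all(w > 0.0):
        raise ValueError("records contain non-positive weights")
    data = {
        "lnw": np.log(w),
        "j": records["n_collisions"].to_numpy(dtype=np.float64),
        "L": records["path_length_mm"].to_numpy(dtype=np.float64),
    }
    mean = {x: float(v.mean()) for x, v in data.items()}
    centered = {x: v - mean[x] for x, v in data.items()}
    var = {x: float((c**2).mean()) for x, c in centered.items()}
    skew = {}
    for x, c in centered.items():
        sd = np.sqrt(var[x])
        skew[x] = float(((c / sd) ** 3).mean()) if sd > 0.0 else 0.0
    cov: dict[tuple[str, str], float] = {}
    for i, x in enumerate(VARIABLES):
        for y in VARIABLES[i:]:
            c = float((centered[x] * centered[y]).mean()) if x != y else var[x]
            cov[(x, y)] = c
            cov[(y, x)] = c
    return MomentSummary(
        n=n_launched,
        n_tallied=n_t,
        mean=mean,
        var=var,
        skew=skew,
        cov=cov,
        w_bar_rt=float(w.mean()),
        detector_id=detector_id,
        medium_key=medium_key,
    )


def moments_for_detector(db: PhotonDatabase, detector_id: str) -> MomentSummary:
    """Moment summary of one detector's tallied records in a photon database."""
    records, _n_t, _n_u = tallied_subset(db, detector_id)
    med = db.meta.medium
    return compute_moments(
        records,
        db.n_launched,
        detector_id=detector_id,
        medium_key=(med.mua, med.mus, med.g, med.n),
    )


def propagate_variance(m: MomentSummary, deriv: TransformDerivatives) -> float:
    """Nine-term moment propagation of ``var(f(lnw, j, L))``.

    Sums the first-order variance terms ``f_x**2 * var_x``, the covariance
    cross terms ``2 * f_x * f_y * cov_xy`` and the skewness terms
    ``f_x * f_xx * skew_x * sd_x**3``.  The derivatives are supplied by the
    caller, so nonlinear transforms are expressible; for a linear transform
    the skewness terms vanish identically.
    """
    total = 0.0
    for x in VARIABLES:
        total += deriv.grad[x] ** 2 * m.var[x]
    for i, x in enumerate(VARIABLES):
        for y in VARIABLES[i + 1 :]:
            total += 2.0 * deriv.grad[x] * deriv.grad[y] * m.cov[(x, y)]
    for x in VARIABLES:
        total += deriv.grad[x] * deriv.hess_diag[x] * m.third_moment(x)
    return total


def log_transform_derivatives(a: float, b: float) -> TransformDerivatives:
    """Derivatives of ``ln W_P = lnw + a * j - b * L`` (linear: zero second derivatives)."""
    return TransformDerivatives(
        grad={"lnw": 1.0, "j": a, "L": -b},
        hess_diag={"lnw": 0.0, "j": 0.0, "L": 0.0},
    )


def propagate_log_variance(m: MomentSummary, pert: Perturbation, *, a: Optional[float] = None,
                           b: Optional[float] = None) -> float:
    """Variance of ``ln W_P`` over the tallied photons, from reference moments alone.

    ``a`` and ``b`` default to the perturbation's log-linear slopes against the
    reference medium recorded alongside the moments; passing them explicitly
    supports moment summaries built without medium context.
    """
    if a is None:
        a = float(np.log1p(pert.eps_s))
    if b is None:
        if m.medium_key is None:
            raise ValueError("moment summary carries no medium; pass b explicitly")
        mua, mus = m.medium_key[0], m.medium_key[1]
        b = mus * pert.eps_s + mua * pert.eps_a
    var = propagate_variance(m, log_transform_derivatives(a, b))
    if var < 0.0:
        raise AssertionError(f"propagated log-variance is negative ({var}); moment misuse")
    return var


def back_transform_variance(var_ln_wpt: float, m: MomentSummary) -> float:
    """Delta-method back-transformation ``var(W_PT) ~= W_bar_RT**2 * var(ln W_PT)``.

    Uses the reference tallied mean in place of the (unknown) perturbed mean.
    """
    if var_ln_wpt < 0.0:
        raise ValueError("var_ln_wpt must be >= 0")
    return m.w_bar_rt**2 * var_ln_wpt


def estimate_full_variance(m: MomentSummary, var_wpt_est: float) -> float:
    """Full-population sigma estimate assembled from the tallied-variance estimate.

    ``var_WP ~= (1/N) [N_T (var_WPT_est + phi_bar**2) + N_U * w_bar**2]`` with
    the reference means substituted for the perturbed ones
    (``phi_bar = w_bar_r - w_bar_rt``); returns the square root.
    """
    if m.n_tallied == 0:
        raise ValueError("no tallied photons; full-population variance undefined")
    phi_bar = m.w_bar_r - m.w_bar_rt
    var = (m.n_tallied * (var_wpt_est + phi_bar**2) + m.n_untallied * m.w_bar_r**2) / m.n
    return float(np.sqrt(var))


def estimator_discrepancy(sigma_wp_est: float, sigma_wp_true: float) -> float:
    """Relative discrepancy ``(sigma_est - sigma_true) / sigma_true`` of the estimate."""
    if not sigma_wp_true > 0.0:
        raise ValueError("sigma_wp_true must be > 0")
    return (sigma_wp_est - sigma_wp_true) / sigma_wp_true


def estimate_error(
    m: MomentSummary,
    pert: Perturbation,
    sigma_wp_true: Optional[float] = None,
) -> ErrorEstimate:
    """Run the full estimation pipeline for one perturbation.

    Propagates the reference moments to ``var(ln W_PT)``, back-transforms to a
    tallied-weight variance, assembles the full-population sigma and, when the
    rigorous ``sigma_wp_true`` is supplied, attaches the discrepancy ``delta``.
    """
    var_ln = propagate_log_variance(m, pert)
    var_wpt = back_transform_variance(var_ln, m)
    sigma = estimate_full_variance(m, var_wpt)
    delta = None if sigma_wp_true is None else estimator_discrepancy(sigma, sigma_wp_true)
    return ErrorEstimate(
        detector_id=m.detector_id,
        perturbation=pert,
        var_ln_wpt=var_ln,
        var_wpt_est=var_wpt,
        var_wp_est=sigma**2,
        sigma_wp_est=sigma,
        rel_error_est=sigma / m.w_bar_r,
        delta=delta,
    )
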