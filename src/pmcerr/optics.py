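"""Optical-property model for homogeneous turbid media.

A medium is described by its absorption coefficient ``mua``, scattering
coefficient ``mus`` (both per mm), single-scattering anisotropy ``g`` (the
mean cosine of the single-scattering deflection angle) and refractive index
``n``.  Derived quantities — the total interaction coefficient
``mut = mua + mus``, reduced scattering coefficient ``musp = mus * (1 - g)``,
transport mean free path ``lstar = 1 / (mua + musp)`` and single-scattering
albedo ``mus / mut`` — are always computed from the stored primaries so the
defining identities cannot drift.

Media are often specified in the diffuse-optics literature by the pair
``(musp / mua, lstar)`` rather than by ``(mua, mus)`` directly;
:func:`from_ratio` performs that conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalProperties",
    "Perturbation",
    "from_ratio",
    "apply_perturbation",
    "rr_threshold_pathlength",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous-medium optical properties.

    Parameters
    ----------
    mua : float
        Absorption coefficient, per mm.  Non-negative.
    mus : float
        Scattering coefficient, per mm.  Strictly positive.
    g : float
        Single-scattering anisotropy, ``0 <= g < 1``.
    n : float
        Refractive index, ``n >= 1``.
    """

    mua: float
    mus: float
    g: float = 0.8
    n: float = 1.4

    def __post_init__(self) -> None:
        if not self.mua >= 0.0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if not self.mus > 0.0:
            raise ValueError(f"mus must be > 0, got {self.mus}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must lie in [0, 1), got {self.g}")
        if not self.n >= 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mut(self) -> float:
        """Total interaction coefficient ``mua + mus``, per mm."""
        return self.mua + self.mus

    @property
    def musp(self) -> float:
        """Reduced scattering coefficient ``mus * (1 - g)``, per mm."""
        return self.mus * (1.0 - self.g)

    @property
    def lstar(self) -> float:
        """Transport mean free path ``1 / (mua + musp)``, mm."""
        return 1.0 / (self.mua + self.musp)

    @property
    def albedo(self) -> float:
        """Single-scattering albedo ``mus / mut``."""
        return self.mus / self.mut

    @property
    def ratio(self) -> float:
        """Reduced-scattering-to-absorption ratio ``musp / mua``."""
        return self.musp / self.mua


def from_ratio(ratio: float, lstar: float = 1.0, g: float = 0.8, n: float = 1.4) -> OpticalProperties:
    """Build optical properties from ``(musp/mua, lstar)``.

    Inverts the pair of identities ``lstar = 1 / (mua + musp)`` and
    ``ratio = musp / mua``:

    * ``mua  = 1 / (lstar * (1 + ratio))``
    * ``musp = ratio * mua``
    * ``mus  = musp / (1 - g)``

    Parameters
    ----------
    ratio : float
        Reduced-scattering-to-absorption ratio ``musp / mua``; positive.
    lstar : float
        Transport mean free path in mm; positive.
    g, n : float
        Anisotropy and refractive index, stored unchanged.
    """
    if not ratio > 0.0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    if not lstar > 0.0:
        raise ValueError(f"lstar must be > 0, got {lstar}")
    if not 0.0 <= g < 1.0:
        raise ValueError(f"g must lie in [0, 1), got {g}")
    mua = 1.0 / (lstar * (1.0 + ratio))
    musp = ratio * mua
    return OpticalProperties(mua=mua, mus=musp / (1.0 - g), g=g, n=n)


@dataclass(frozen=True)
class Perturbation:
    """Fractional, medium-wide change of the scattering and/or absorption coefficient.

    ``eps_s = 0.10`` means the perturbed medium has ``mus_P = 1.10 * mus_R``.
    Both fractions must exceed -1 (coefficients stay positive / non-negative).
    """

    eps_s: float = 0.0
    eps_a: float = 0.0

    def __post_init__(self) -> None:
        if not self.eps_s > -1.0:
            raise ValueError(f"eps_s must be > -1, got {self.eps_s}")
        if not self.eps_a > -1.0:
            raise ValueError(f"eps_a must be > -1, got {self.eps_a}")

    @property
    def is_identity(self) -> bool:
        return self.eps_s == 0.0 and self.eps_a == 0.0

    def log_scattering_ratio(self, ref: OpticalProperties) -> float:
        """``ln(mus_P / mus_R) = ln(1 + eps_s)`` — the per-collision log-weight slope."""
        del ref  # independent of the reference magnitude, kept for symmetry with delta_mut
        return math.log1p(self.eps_s)

    def delta_mut(self, ref: OpticalProperties) -> float:
        """``mut_P - mut_R`` (per mm) — the per-unit-path log-weight slope."""
        return ref.mus * self.eps_s + ref.mua * self.eps_a


def apply_perturbation(ref: OpticalProperties, pert: Perturbation) -> OpticalProperties:
    """Return the perturbed medium: ``mus`` scaled by ``1+eps_s``, ``mua`` by ``1+eps_a``.

    ``g`` and ``n`` are unchanged; the perturbation applies to the whole medium.
    """
    return OpticalProperties(
        mua=ref.mua * (1.0 + pert.eps_a),
        mus=ref.mus * (1.0 + pert.eps_s),
        g=ref.g,
        n=ref.n,
    )


def rr_threshold_pathlength(props: OpticalProperties, w_thr: float) -> float:
    """Path length (mm) at which a unit-launch-weight CAW photon reaches weight ``w_thr``.

    Under continuous absorption weighting the photon weight is
    ``exp(-mua * L)``, so the threshold is crossed at ``L = ln(1/w_thr) / mua``.
    For an absorption-free medium the threshold is never reached and ``inf``
    is returned.
    """
    if not 0.0 < w_thr <= 1.0:
        raise ValueError(f"w_thr must lie in (0, 1], got {w_thr}")
    if props.mua == 0.0:
        return math.inf
    return math.log(1.0 / w_thr) / props.mua
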