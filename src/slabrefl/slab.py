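"""Specular reflectivity of a layered interface via the Abeles optical matrix.

The interface is described as a ``Stack``: a semi-infinite fronting medium
(the silicon wafer the beam travels through), an ordered list of uniform
slabs, and a semi-infinite backing medium (the solvent).  For each momentum
transfer Q the perpendicular wavevector in medium *i* is

    k_i = sqrt(Q²/4 − 4π(ρ_i − ρ_fronting))        (complex branch, Im k ≥ 0)

Fresnel coefficients between adjacent media are damped by Névot–Croce
roughness factors exp(−2 k_i k_{i+1} σ²) and combined through the 2×2
characteristic-matrix product; R = |r|², normalised so total reflection
plateaus at exactly 1.

Instrumental resolution is modelled as a Gaussian in Q with constant dQ/Q,
which makes the kernel a fixed-width Gaussian in ln Q; smearing is performed
by convolution on an oversampled logarithmic grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from . import constants as c

__all__ = [
    "Slab",
    "Stack",
    "ReflectivityCurve",
    "BeamGeometry",
    "q_from_angle",
    "thickness_from_fringe_spacing",
    "abeles_reflectivity",
    "smear_resolution",
    "smeared_reflectivity",
    "sld_profile",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class Slab:
    """One uniform layer: thickness τ [Å], SLD ρ [Å⁻²], and the Gaussian
    width σ [Å] of the interface between this slab and the preceding medium."""

    thickness: float
    sld: float
    roughness: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError(f"thickness must be >= 0, got {self.thickness}")
        if self.roughness < 0:
            raise ValueError(f"roughness must be >= 0, got {self.roughness}")


@dataclass
class Stack:
    """Fronting medium, ordered slabs (fronting → backing), backing medium.

    ``backing_roughness`` is the width of the final slab/backing interface.
    Slab order follows the beam: silicon first, solvent last.
    """

    fronting_sld: float
    slabs: list[Slab] = field(default_factory=list)
    backing_sld: float = c.SLD_D2O
    backing_roughness: float = 0.0

    def __post_init__(self) -> None:
        if self.backing_roughness < 0:
            raise ValueError("backing_roughness must be >= 0")
        self.validate_roughness(warn=True)

    def validate_roughness(self, warn: bool = False) -> list[str]:
        """Flag roughnesses larger than either adjacent slab thickness.

        The erf-blended profile is only a faithful picture of the model when
        σ is small compared with the layers it separates; violations are
        reported as warnings, not errors.
        """
        msgs = []
        thicknesses = [s.thickness for s in self.slabs]
        sigmas = [s.roughness for s in self.slabs] + [self.backing_roughness]
        for i, sigma in enumerate(sigmas):
            neighbours = []
            if 0 <= i - 1 < len(thicknesses):
                neighbours.append(thicknesses[i - 1])
            if i < len(thicknesses):
                neighbours.append(thicknesses[i])
            if neighbours and sigma > min(n for n in neighbours):
                msgs.append(
                    f"interface {i}: roughness {sigma:g} Å exceeds an adjacent "
                    f"slab thickness (profile validity suspect)"
                )
        if warn:
            for m in msgs:
                warnings.warn(m, stacklevel=3)
        return msgs

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(slds, thicknesses, interface roughnesses) including both media."""
        slds = np.array(
            [self.fronting_sld] + [s.sld for s in self.slabs] + [self.backing_sld]
        )
        thick = np.array([0.0] + [s.thickness for s in self.slabs] + [0.0])
        rough = np.array([s.roughness for s in self.slabs] + [self.backing_roughness])
        return slds, thick, rough


@dataclass
class ReflectivityCurve:
    """A measured or computed reflectivity curve on a strictly increasing
    positive Q grid, with optional 1σ uncertainties dr and resolution widths
    dq (FWHM in Q)."""

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray | None = None
    dq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if self.r.shape != self.q.shape:
            raise ValueError("r must have the same shape as q")
        if np.any(self.q <= 0):
            raise ValueError("q values must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.r < 0):
            raise ValueError("reflectivity must be non-negative")
        for attr in ("dr", "dq"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.q.shape:
                    raise ValueError(f"{attr} must have the same shape as q")
                setattr(self, attr, v)

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class BeamGeometry:
    """Grazing angle θ [degrees] and neutron wavelength λ [Å]."""

    theta: float
    wavelength: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 90.0:
            raise ValueError(f"theta must lie in (0, 90) degrees, got {self.theta}")
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")


def q_from_angle(geometry: BeamGeometry) -> float:
    """Momentum transfer Q = 4π sin(θ)/λ, Å⁻¹."""
    return 4.0 * math.pi * math.sin(math.radians(geometry.theta)) / geometry.wavelength


def thickness_from_fringe_spacing(delta_q: float) -> float:
    """Film thickness d = 2π/ΔQ from the Kiessig-fringe spacing ΔQ."""
    if delta_q <= 0:
        raise ValueError(f"fringe spacing must be > 0, got {delta_q}")
    return 2.0 * math.pi / delta_q


def _abeles_r(q: np.ndarray, slds, thick, rough) -> np.ndarray:
    """|r|² for the stack arrays, vectorised over Q."""
    q = np.asarray(q, dtype=float)
    qsq4 = (q / 2.0) ** 2
    # perpendicular wavevector in each medium, relative to the fronting
    k = np.sqrt(qsq4[None, :] - 4.0 * np.pi * (slds[:, None] - slds[0]) + 0j)

    # interface 0 (fronting | first medium below)
    r01 = (k[0] - k[1]) / (k[0] + k[1]) * np.exp(-2.0 * k[0] * k[1] * rough[0] ** 2)
    m00, m01 = np.ones_like(r01), r01.copy()
    m10, m11 = r01.copy(), np.ones_like(r01)

    # the common factor exp(i beta_i) of each characteristic matrix cancels
    # in r = m10/m00, so matrices are applied in the cheaper factored form
    # [[1, r], [r p, p]] with p = exp(-2 i beta_i)
    for i in range(1, len(slds) - 1):
        rij = (k[i] - k[i + 1]) / (k[i] + k[i + 1]) * np.exp(
            -2.0 * k[i] * k[i + 1] * rough[i] ** 2
        )
        p = np.exp(-2j * k[i] * thick[i])
        rp = rij * p
        m00, m01, m10, m11 = (
            m00 + m01 * rp,
            m00 * rij + m01 * p,
            m10 + m11 * rp,
            m10 * rij + m11 * p,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.abs(m10 / m00) ** 2
    # total reflection plateaus at exactly 1; tiny overshoot from roughness
    # factors below the critical edge is clipped
    return np.clip(refl, 0.0, 1.0)


def abeles_reflectivity(stack: Stack, q: np.ndarray) -> ReflectivityCurve:
    """Unsmeared specular reflectivity R(Q) of the stack."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q values must be strictly positive")
    slds, thick, rough = stack._arrays()
    return ReflectivityCurve(q=q, r=_abeles_r(q, slds, thick, rough))


# ---------------------------------------------------------------------------
# Resolution smearing
# ---------------------------------------------------------------------------

def _gauss_kernel(step: float, sigma: float) -> np.ndarray:
    half = int(math.ceil(c.SMEAR_TRUNCATION_SIGMA * sigma / step))
    x = np.arange(-half, half + 1) * step
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def _smear_ln_grid(qmin, qmax, dq_over_q):
    """Uniform ln-Q evaluation grid padded beyond the kernel support."""
    sigma_ln = math.log1p(dq_over_q)
    pad = (c.SMEAR_TRUNCATION_SIGMA + 0.5) * sigma_ln
    step = sigma_ln / 6.0
    lo, hi = math.log(qmin) - pad, math.log(qmax) + pad
    n = int(math.ceil((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n), sigma_ln


def smeared_reflectivity(
    stack: Stack, q: np.ndarray, dq_over_q: float = c.DEFAULT_DQ_OVER_Q
) -> ReflectivityCurve:
    """Reflectivity convolved with a Gaussian of σ_Q = dq_over_q · Q.

    The model is evaluated exactly on an oversampled logarithmic grid (where
    the constant-dQ/Q kernel has fixed width) and convolved there, so data-grid
    spacing does not limit the smearing accuracy.
    """
    if dq_over_q < 0:
        raise ValueError(f"dq_over_q must be >= 0, got {dq_over_q}")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if dq_over_q == 0:
        return abeles_reflectivity(stack, q)
    lnq_f, sigma_ln = _smear_ln_grid(q.min(), q.max(), dq_over_q)
    fine = abeles_reflectivity(stack, np.exp(lnq_f))
    kernel = _gauss_kernel(lnq_f[1] - lnq_f[0], sigma_ln)
    r_sm = np.convolve(fine.r, kernel, mode="same")
    return ReflectivityCurve(q=q, r=np.interp(np.log(q), lnq_f, r_sm))


def smear_resolution(
    curve: ReflectivityCurve, dq_over_q: float = c.DEFAULT_DQ_OVER_Q
) -> ReflectivityCurve:
    """Smear an already-sampled curve with a constant-dQ/Q Gaussian.

    For model curves prefer :func:`smeared_reflectivity`, which re-evaluates
    the model on a fine grid instead of interpolating.  Endpoints are padded
    with edge values; dq_over_q = 0 returns the curve unchanged.
    """
    if dq_over_q < 0:
        raise ValueError(f"dq_over_q must be >= 0, got {dq_over_q}")
    if dq_over_q == 0:
        return curve
    lnq_f, sigma_ln = _smear_ln_grid(curve.q.min(), curve.q.max(), dq_over_q)
    r_fine = np.interp(lnq_f, np.log(curve.q), curve.r)
    kernel = _gauss_kernel(lnq_f[1] - lnq_f[0], sigma_ln)
    r_sm = np.convolve(r_fine, kernel, mode="same")
    return ReflectivityCurve(
        q=curve.q,
        r=np.interp(np.log(curve.q), lnq_f, r_sm),
        dr=curve.dr,
        dq=curve.dq,
    )


def fwhm_dq(q: np.ndarray, dq_over_q: float) -> np.ndarray:
    """FWHM resolution column for a constant-dQ/Q Gaussian (σ → FWHM)."""
    return _FWHM_PER_SIGMA * dq_over_q * np.asarray(q, dtype=float)


# ---------------------------------------------------------------------------
# SLD depth profile
# ---------------------------------------------------------------------------

def sld_profile(stack: Stack, z: np.ndarray) -> np.ndarray:
    """SLD versus depth, erf-blended at each interface by its roughness.

    z = 0 at the fronting/first-slab boundary, increasing toward the backing;
    z → −∞ gives the fronting SLD, z → +∞ the backing SLD.
    """
    z = np.asarray(z, dtype=float)
    slds, thick, rough = stack._arrays()
    z_if = np.concatenate(([0.0], np.cumsum(thick[1:-1])))
    profile = np.full_like(z, slds[0], dtype=float)
    for i, (z0, sigma) in enumerate(zip(z_if, rough)):
        step = slds[i + 1] - slds[i]
        if sigma == 0:
            profile += step * (z >= z0)
        else:
            profile += step * 0.5 * (1.0 + erf((z - z0) / (sigma * math.sqrt(2.0))))
    return profile
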