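"""Independent reference implementations used only to check the package.

These deliberately use a different algorithmic route than the library:
reflectivity via the Parratt recursion (bottom-up) instead of the Abeles
matrix product (top-down), plus a micro-slicing route for rough interfaces
and a bisection route for the contrast match point.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def parratt_reflectivity(q, fronting_sld, slds, thicknesses, roughnesses, backing_sld):
    """|r|² by the Parratt recursion with Névot–Croce damped interfaces.

    ``roughnesses[i]`` is the width of the interface *above* medium i+1,
    matching the package's convention (slab roughness on its fronting side,
    the last entry being the slab/backing interface).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    rho = np.array([fronting_sld] + list(slds) + [backing_sld])
    d = np.array([0.0] + list(thicknesses) + [0.0])
    sig = np.asarray(roughnesses, dtype=float)
    assert sig.size == rho.size - 1
    k = np.sqrt((q / 2.0) ** 2 - 4.0 * np.pi * (rho[:, None] - rho[0]) + 0j)

    r_tot = np.zeros_like(q, dtype=complex)
    for j in range(rho.size - 2, -1, -1):
        rj = (k[j] - k[j + 1]) / (k[j] + k[j + 1]) * np.exp(
            -2.0 * k[j] * k[j + 1] * sig[j] ** 2
        )
        phase = np.exp(2j * k[j + 1] * d[j + 1])
        r_tot = (rj + r_tot * phase) / (1.0 + rj * r_tot * phase)
    return np.minimum(np.abs(r_tot) ** 2, 1.0)


def microsliced_reflectivity(
    q, fronting_sld, slds, thicknesses, roughnesses, backing_sld, dz=0.25, pad_sigmas=6.0
):
    """Reflectivity of the erf-blended profile cut into thin zero-roughness
    slices, run through the Parratt recursion.  Converges to the Névot–Croce
    result when every roughness is small against its neighbouring layers."""
    rho = np.array([fronting_sld] + list(slds) + [backing_sld])
    d = np.array(list(thicknesses))
    z_if = np.concatenate(([0.0], np.cumsum(d)))
    sig = np.asarray(roughnesses, dtype=float)
    pad = pad_sigmas * max(sig.max(), 1.0)
    z = np.arange(-pad, z_if[-1] + pad, dz)
    zc = z + dz / 2.0
    profile = np.full_like(zc, rho[0])
    for i, (z0, s) in enumerate(zip(z_if, sig)):
        step = rho[i + 1] - rho[i]
        if s == 0:
            profile += step * (zc >= z0)
        else:
            profile += step * 0.5 * (1.0 + erf((zc - z0) / (s * np.sqrt(2.0))))
    return parratt_reflectivity(
        q,
        profile[0],
        list(profile[1:-1]),
        [dz] * (profile.size - 2),
        [0.0] * (profile.size - 1),
        profile[-1],
    )


def bisect_match_point(target, sld_d2o=6.36e-6, sld_h2o=-0.56e-6, tol=1e-15):
    """D2O fraction matching ``target`` by plain bisection on the mixing rule."""
    lo, hi = 0.0, 1.0
    f = lambda x: x * sld_d2o + (1 - x) * sld_h2o - target
    assert f(lo) <= 0 <= f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
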