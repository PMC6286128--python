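"""Closed-form algebra of isotropic 2D Gaussians.

The multiplicative gain-field model treats a measured pRF as the pointwise
product of a stimulus-driven Gaussian and a Gaussian attentional gain field.
Products and quotients of isotropic Gaussians are again isotropic Gaussians,
so both the forward model (product) and the inversion used to recover the
stimulus drive (division) have exact closed forms, collected here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gaussian_product", "gaussian_divide"]


def gaussian_product(g1, g2):
    """Pointwise product of two isotropic 2D Gaussians.

    Parameters
    ----------
    g1, g2 : tuple
        ``((x, y), sigma)`` — center in dva and standard deviation in dva.

    Returns
    -------
    center : ndarray, shape (2,)
        Precision-weighted mean of the two centers.
    sigma : float
        ``1/sigma**2 = 1/sigma1**2 + 1/sigma2**2``.
    scale : float
        Peak height of the product when both factors have unit peak:
        ``exp(-|c1-c2|**2 / (2*(sigma1**2 + sigma2**2)))``.
    """
    (c1, s1), (c2, s2) = g1, g2
    if s1 <= 0 or s2 <= 0:
        raise ValueError("Gaussian sigmas must be positive")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    p1, p2 = 1.0 / s1**2, 1.0 / s2**2
    sigma = 1.0 / np.sqrt(p1 + p2)
    center = (c1 * p1 + c2 * p2) / (p1 + p2)
    d2 = float(np.sum((c1 - c2) ** 2))
    scale = float(np.exp(-d2 / (2.0 * (s1**2 + s2**2))))
    return center, float(sigma), scale


def gaussian_divide(g_num, g_den):
    """Deconvolve one isotropic Gaussian factor out of another.

    Inverse of :func:`gaussian_product`: given the product ``g_num`` and one
    factor ``g_den``, recover the other factor. Requires the product to be
    narrower than the known factor (``sigma_num < sigma_den``), otherwise the
    quotient is not a proper Gaussian.

    Returns ``(center, sigma)`` of the recovered factor.
    """
    (cn, sn), (cd, sd) = g_num, g_den
    if sn <= 0 or sd <= 0:
        raise ValueError("Gaussian sigmas must be positive")
    if sn >= sd:
        raise ValueError(
            f"division undefined: numerator sigma {sn:.4f} >= denominator sigma {sd:.4f}"
        )
    cn = np.asarray(cn, dtype=float)
    cd = np.asarray(cd, dtype=float)
    p_out = 1.0 / sn**2 - 1.0 / sd**2
    sigma = 1.0 / np.sqrt(p_out)
    # precision-weighted mean relation solved for the unknown factor's center
    center = (cn / sn**2 - cd / sd**2) / p_out
    return center, float(sigma)
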