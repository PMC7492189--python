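"""Steerable second-derivative-of-Gaussian ridge filter.

A neurite is a bright curvilinear ridge: along its tangent the intensity
is flat, across it the second derivative is strongly negative.  The
classic G2 steerable basis lets the directional second derivative at any
angle be synthesized from three separable convolutions:

    R(theta) = cos^2(theta) * G_rr + 2 cos(theta) sin(theta) * G_rc
               + sin^2(theta) * G_cc

where the subscripts denote Gaussian-derivative filtering along the
(row, col) axes.  The ridge strength at a pixel is the maximum of
``-R(theta)`` over an orientation bank, and the ridge *tangent* is the
orientation perpendicular to the maximizing theta.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["steerable_ridge"]


def steerable_ridge(
    image: np.ndarray, sigma: float = 1.5, n_orientations: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge strength and tangent orientation per pixel.

    Returns ``(strength, tangent)`` where ``strength`` is
    ``max_theta(-R(theta))`` (positive on bright ridges of width ~2*sigma)
    and ``tangent`` is the ridge direction in radians, in ``[0, pi)``
    (orientation is defined modulo pi).
    """
    img = np.asarray(image, dtype=float)
    g_rr = gaussian_filter(img, sigma, order=(2, 0))
    g_cc = gaussian_filter(img, sigma, order=(0, 2))
    g_rc = gaussian_filter(img, sigma, order=(1, 1))

    thetas = np.linspace(0.0, np.pi, n_orientations, endpoint=False)
    best = np.full(img.shape, -np.inf)
    best_theta = np.zeros(img.shape)
    for theta in thetas:
        ct, st = np.cos(theta), np.sin(theta)
        # second derivative along the direction (cos, sin) in (row, col)
        resp = -(ct * ct * g_rr + 2 * ct * st * g_rc + st * st * g_cc)
        mask = resp > best
        best[mask] = resp[mask]
        best_theta[mask] = theta
    tangent = np.mod(best_theta + np.pi / 2, np.pi)
    return best, tangent
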