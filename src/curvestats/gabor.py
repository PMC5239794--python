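"""Gabor micro-pattern rendering.

The elementary stimulus unit is the product of a circular Gaussian envelope
and an oriented sinusoidal carrier,

    G(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x' / lambda + psi)

with (x', y') the coordinate frame rotated by the element orientation. At
the raster scale used throughout the package (64 px/deg) the defaults
sigma = 4 px and lambda = 8 px give a carrier peak spatial frequency of
8 cycles per degree of visual angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaborParams", "render_gabor", "PX_PER_DEG"]

#: raster scale: 64 px per degree of visual angle (8 px = 0.125 deg)
PX_PER_DEG = 64.0


@dataclass(frozen=True)
class GaborParams:
    """Carrier/envelope parameters of a Gabor micro-pattern.

    Parameters
    ----------
    sigma_px : float
        Standard deviation of the Gaussian envelope, pixels.
    lambda_px : float
        Period of the sinusoidal carrier, pixels.
    aspect_gamma : float
        Envelope aspect ratio; 1 gives a circular envelope.
    phase_psi : float
        Carrier phase in radians; 0 is even-symmetric (bright-centred).
    px_per_deg : float
        Raster scale, pixels per degree of visual angle.
    """

    sigma_px: float = 4.0
    lambda_px: float = 8.0
    aspect_gamma: float = 1.0
    phase_psi: float = 0.0
    px_per_deg: float = PX_PER_DEG

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError(f"sigma_px must be positive, got {self.sigma_px}")
        if self.lambda_px <= 0:
            raise ValueError(f"lambda_px must be positive, got {self.lambda_px}")
        if self.px_per_deg <= 0:
            raise ValueError(f"px_per_deg must be positive, got {self.px_per_deg}")

    @property
    def carrier_cpd(self) -> float:
        """Carrier peak spatial frequency in cycles per degree."""
        return self.px_per_deg / self.lambda_px


def gabor_value(p: GaborParams, orientation_deg: float, x, y):
    """Evaluate the Gabor analytically at offsets (x, y) px from its centre.

    ``x`` increases along image columns and ``y`` along rows; the
    orientation is measured from the x-axis toward the y-axis.
    """
    th = np.deg2rad(orientation_deg)
    xp = x * np.cos(th) + y * np.sin(th)
    yp = -x * np.sin(th) + y * np.cos(th)
    envelope = np.exp(-(xp**2 + (p.aspect_gamma**2) * yp**2) / (2.0 * p.sigma_px**2))
    carrier = np.cos(2.0 * np.pi * xp / p.lambda_px + p.phase_psi)
    return envelope * carrier


def render_gabor(p: GaborParams, orientation_deg: float, patch_size_px: int) -> np.ndarray:
    """Render a Gabor patch on a centred pixel grid.

    Returns a float array in [-1, 1] of shape (patch_size_px, patch_size_px).
    The patch must be large enough to contain the envelope
    (``patch_size_px >= 6 * sigma_px``).
    """
    if patch_size_px < 6 * p.sigma_px:
        raise ValueError(
            f"patch_size_px={patch_size_px} too small for sigma_px={p.sigma_px} "
            f"(need >= {6 * p.sigma_px})"
        )
    c = (patch_size_px - 1) / 2.0
    yy, xx = np.mgrid[0:patch_size_px, 0:patch_size_px].astype(float)
    return gabor_value(p, orientation_deg, xx - c, yy - c)
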