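"""Angle bookkeeping helpers.

Orientations of edge elements are axial quantities: an element oriented at
10 deg is indistinguishable from one at 190 deg. All public functions work
in degrees. The convention throughout the package is counter-clockwise from
the horizontal image axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap180", "wrap90", "orientation_mod180", "ang_diff_axial"]


def wrap180(angle_deg):
    """Wrap an angle to the interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def wrap90(angle_deg):
    """Wrap an angle to (-90, 90], the natural range for axial differences."""
    a = np.asarray(angle_deg, dtype=float)
    out = -((-a + 90.0) % 180.0 - 90.0)
    return out if out.ndim else float(out)


def orientation_mod180(angle_deg):
    """Reduce an orientation to [0, 180)."""
    a = np.asarray(angle_deg, dtype=float)
    out = a % 180.0
    return out if out.ndim else float(out)


def ang_diff_axial(a_deg, b_deg):
    """Signed axial difference a - b, wrapped to (-90, 90]."""
    return wrap90(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))
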