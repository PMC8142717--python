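"""Angle conventions shared across the package.

Color values live on a 360-degree wheel. Files and user-facing tables
store degrees; internal math uses radians. Signed angular errors are
wrapped to the half-open interval (-180, 180], with the tie at -180
mapped to +180.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "wrap_rad", "to_circle_deg"]


def wrap_deg(angles):
    """Wrap angles in degrees to (-180, 180].

    Idempotent; ties at exactly -180 map to +180.
    """
    a = np.asarray(angles, dtype=float)
    # Python-style modulo with a negative divisor yields (-360, 0],
    # which shifts to exactly (-180, 180].
    wrapped = np.mod(a - 180.0, -360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_rad(angles):
    """Wrap angles in radians to (-pi, pi]."""
    a = np.asarray(angles, dtype=float)
    wrapped = np.mod(a - np.pi, -2.0 * np.pi) + np.pi
    return wrapped if wrapped.ndim else float(wrapped)


def to_circle_deg(angles):
    """Map angles in degrees onto [0, 360), the color-wheel convention."""
    a = np.mod(np.asarray(angles, dtype=float), 360.0)
    return a if a.ndim else float(a)
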