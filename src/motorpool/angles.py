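"""Degree/radian helpers with one canonical wrap convention.

All user-facing angles in the package are degrees reduced to (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_degrees"]


def wrap_degrees(deg):
    """Reduce angle(s) in degrees to the interval (-180, 180]."""
    arr = np.asarray(deg, dtype=float)
    wrapped = ((arr + 180.0) % 360.0) - 180.0
    # the half-open convention keeps 180 (not -180) as the representative
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(deg) or arr.ndim == 0:
        return float(wrapped)
    return wrapped
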