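"""Axial (orientation, mod 180) circular statistics.

Junction and cell-axis orientations are axial quantities: 10 degrees and
190 degrees are the same orientation, and after folding across both image
axes every orientation lives in [0, 90] relative to the mediolateral axis.
Means and dispersions are computed on the doubled angles, the standard
treatment for axial data: R * exp(2i * theta_bar) = mean(exp(2i * theta_k)).
"""

from __future__ import annotations

import numpy as np

__all__ = ["axial_mean_resultant", "axial_mean_deg"]


def axial_mean_resultant(angles_deg: np.ndarray) -> tuple[float, float]:
    """Mean orientation and mean resultant length of axial angles.

    Parameters
    ----------
    angles_deg : array of orientations in degrees (interpreted mod 180).

    Returns
    -------
    (mean_deg, R) : mean orientation folded into [0, 90] and the mean
        resultant length of the doubled angles, R in [0, 1].  R = 1 iff all
        orientations coincide mod 180; antipodal axial pairs (0, 90) cancel
        to R = 0.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("axial mean of empty sample is undefined")
    z = np.exp(2j * np.deg2rad(a))
    m = z.mean()
    r = float(np.abs(m))
    mean = float(np.rad2deg(np.angle(m)) / 2.0) % 180.0
    # fold into [0, 90]: orientations are already measured off the ML axis
    if mean > 90.0:
        mean = 180.0 - mean
    return mean, r


def axial_mean_deg(angles_deg: np.ndarray) -> float:
    """Mean orientation only (see :func:`axial_mean_resultant`)."""
    return axial_mean_resultant(angles_deg)[0]
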