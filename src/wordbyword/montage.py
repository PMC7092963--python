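"""The 24-channel wireless cap montage and electrode geometry.

Recording channels of the dyadic setup (international 10/20), recorded
against an FCz online reference with AFz ground; positions are taken
from the standard 10/20 template and projected onto the unit sphere for
topography synthesis and spherical-spline interpolation.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

CHANNELS = (
    "Fp1", "Fp2", "F7", "Fz", "F8", "FC1", "FC2",
    "C3", "Cz", "C4", "T7", "T8", "TP9", "TP10",
    "CP5", "CP1", "CPz", "CP2", "CP6", "P3", "Pz", "P4", "O1", "O2",
)

MASTOIDS = ("TP9", "TP10")
MIDLINE = ("Fz", "Cz", "CPz", "Pz")

QUADRANTS = {
    "left_anterior": ("Fp1", "FC1", "F7", "C3"),
    "left_posterior": ("CP1", "CP5", "P3", "O1"),
    "right_anterior": ("Fp2", "F8", "FC2", "C4"),
    "right_posterior": ("CP2", "CP6", "P4", "O2"),
}


@lru_cache(maxsize=4)
def unit_positions(extra: tuple[str, ...] = ("Fpz", "Oz")) -> dict[str, np.ndarray]:
    """Unit-sphere electrode positions for the montage (+ helper sites)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = mne.channels.make_standard_montage("standard_1020")
    pos = m.get_positions()["ch_pos"]
    out = {}
    for name in CHANNELS + tuple(extra):
        p = np.asarray(pos[name], dtype=float)
        out[name] = p / np.linalg.norm(p)
    return out


def position_matrix(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    pos = unit_positions()
    return np.array([pos[c] for c in channels])


def gaussian_topography(
    center: str, spread: float = 0.5, channels: tuple[str, ...] = CHANNELS
) -> np.ndarray:
    """Smooth scalp weighting peaking (weight 1) at ``center``.

    ``spread`` is the Gaussian width in unit-sphere chord distance.
    """
    pos = unit_positions()
    c = pos[center]
    w = np.array(
        [np.exp(-np.sum((pos[ch] - c) ** 2) / (2 * spread**2)) for ch in channels]
    )
    return w / w.max()
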