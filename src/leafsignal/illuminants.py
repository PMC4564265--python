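"""Illuminant spectra on arbitrary wavelength grids, in relative quanta.

Quantum catches weight reflectance by the illuminant's photon flux, so
energy-based tables are converted to quanta by multiplying by wavelength.
The default illuminant is flat (equal quanta at every wavelength): the
minimal assumption when the true field illumination is unknown, and
irrelevant to within-study comparisons of catch ratios up to a fixed
reweighting.  CIE standard daylight D65 is available as the natural-daylight
alternative.
"""

from __future__ import annotations

import numpy as np

__all__ = ["flat_illuminant", "d65_illuminant", "get_illuminant"]

# CIE standard illuminant D65, relative spectral power (energy units),
# 300-700 nm at 10 nm steps, normalised to 100 at 560 nm.
_D65_WL = np.arange(300.0, 701.0, 10.0)
_D65_POWER = np.array([
    0.0341, 3.2945, 20.236, 37.0535, 39.9488, 44.9117, 46.6383, 52.0891,
    49.9755, 54.6482, 82.7549, 91.486, 93.4318, 86.6823, 104.865, 117.008,
    117.812, 114.861, 115.923, 108.811, 109.354, 107.802, 104.790, 107.689,
    104.405, 104.046, 100.0, 96.3342, 95.788, 88.6856, 90.0062, 89.5991,
    87.6987, 83.2886, 83.6992, 80.0268, 80.2146, 82.2778, 78.2842, 69.7213,
    71.6091,
])


def flat_illuminant(grid: np.ndarray) -> np.ndarray:
    """Equal-quanta illuminant: 1 at every wavelength."""
    return np.ones(np.asarray(grid, dtype=float).shape)


def d65_illuminant(grid: np.ndarray) -> np.ndarray:
    """CIE D65 daylight converted to relative quanta on ``grid``.

    Energy is interpolated from the 10-nm CIE table, multiplied by wavelength
    (photon flux is proportional to power times wavelength) and peak-normalised.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < _D65_WL[0] or grid.max() > _D65_WL[-1]:
        raise ValueError("D65 table covers 300-700 nm; requested grid extends beyond it")
    energy = np.interp(grid, _D65_WL, _D65_POWER)
    quanta = energy * grid
    return quanta / quanta.max()


def get_illuminant(name_or_curve, grid: np.ndarray) -> np.ndarray:
    """Resolve ``"flat"``, ``"d65"`` or an explicit curve to an array on ``grid``."""
    if isinstance(name_or_curve, str):
        key = name_or_curve.lower()
        if key == "flat":
            return flat_illuminant(grid)
        if key == "d65":
            return d65_illuminant(grid)
        raise ValueError(f"unknown illuminant {name_or_curve!r}; use 'flat' or 'd65'")
    curve = np.asarray(name_or_curve, dtype=float)
    if curve.shape != np.asarray(grid).shape:
        raise ValueError("explicit illuminant curve must match the wavelength grid")
    if np.any(curve <= 0):
        raise ValueError("illuminant must be strictly positive on the grid")
    return curve
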