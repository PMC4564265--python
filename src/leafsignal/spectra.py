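"""Reflectance-spectrum container and preprocessing.

Leaf reflectance is measured 300-700 nm with a fibre spectrometer against a
barium sulphate white standard.  Reflectance is unitless (sample counts
relative to the standard) and may exceed 1 for specular leaf surfaces, so no
upper clamp is applied anywhere in this module.

Preprocessing steps offered here:

* white/dark normalisation of raw counts,
* linear resampling onto a shared wavelength grid,
* least-squares smoothing with a piecewise-cubic regression spline
  (30 equal sections by default),
* normalisation to the chlorophyll reflectance peak near 550 nm,

all of which preserve the `Spectrum` container so stages compose freely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_lsq_spline

__all__ = [
    "CANONICAL_GRID",
    "Spectrum",
    "SpectrumParseError",
    "read_spectra",
    "write_spectra",
    "normalize_to_white",
    "resample",
    "smooth_piecewise_cubic",
    "normalize_to_peak",
]

#: 1-nm measurement grid, 300-700 nm inclusive.
CANONICAL_GRID: np.ndarray = np.arange(300.0, 701.0)


class SpectrumParseError(ValueError):
    """Raised when a spectra file contains malformed content."""


@dataclass(frozen=True)
class Spectrum:
    """One reflectance spectrum with sample metadata.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    reflectance
        Non-negative reflectance relative to a white standard; values above 1
        are permitted.
    sample_id
        Opaque sample label.
    survey
        Optional survey label (e.g. ``"first"`` / ``"second"``).
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    sample_id: str = ""
    survey: str | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or r.ndim != 1 or wl.size != r.size:
            raise ValueError("wavelengths and reflectance must be 1-D and the same length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError(f"wavelengths must be strictly increasing (sample {self.sample_id!r})")
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise ValueError(f"reflectance must be finite and >= 0 (sample {self.sample_id!r})")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", r)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def with_reflectance(self, reflectance: np.ndarray) -> "Spectrum":
        return replace(self, reflectance=np.asarray(reflectance, dtype=float))


def _numeric_column(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header row, one for 1-based numbering.
        raise SpectrumParseError(
            f"{path}: non-numeric value {df[col].iloc[idx]!r} in column {col!r} at line {idx + 2}"
        )
    return vals


def read_spectra(path: str | Path, dialect: str = "wide") -> list[Spectrum]:
    """Read reflectance spectra from a CSV file.

    ``wide`` dialect: first column ``wavelength_nm``, then one column per
    sample.  ``long`` dialect: columns ``sample_id, wavelength_nm,
    reflectance``.  Rows with missing reflectance are dropped (a warning
    reports the count); wavelengths are returned sorted ascending.
    """
    path = Path(path)
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    n_dropped = 0
    spectra: list[Spectrum] = []
    if dialect == "wide":
        wl_col = df.columns[0]
        wl = _numeric_column(df, wl_col, str(path))
        if wl.isna().any():
            idx = int(np.flatnonzero(wl.isna().to_numpy())[0])
            raise SpectrumParseError(f"{path}: missing wavelength at line {idx + 2}")
        for col in df.columns[1:]:
            r = _numeric_column(df, col, str(path))
            keep = r.notna()
            n_dropped += int((~keep).sum())
            sub = pd.DataFrame({"wl": wl[keep], "r": r[keep]}).sort_values("wl")
            if sub["wl"].duplicated().any():
                dup = sub["wl"][sub["wl"].duplicated()].iloc[0]
                raise SpectrumParseError(
                    f"{path}: duplicate wavelength {dup} nm for sample {col!r}"
                )
            spectra.append(Spectrum(sub["wl"].to_numpy(), sub["r"].to_numpy(), sample_id=str(col)))
    else:
        required = {"sample_id", "wavelength_nm", "reflectance"}
        if not required.issubset(df.columns):
            raise SpectrumParseError(
                f"{path}: long dialect needs columns {sorted(required)}, got {list(df.columns)}"
            )
        wl = _numeric_column(df, "wavelength_nm", str(path))
        r = _numeric_column(df, "reflectance", str(path))
        work = pd.DataFrame({"sample_id": df["sample_id"], "wl": wl, "r": r})
        for sid, sub in work.groupby("sample_id", sort=True):
            keep = sub["r"].notna()
            n_dropped += int((~keep).sum())
            sub = sub[keep].sort_values("wl")
            if sub["wl"].duplicated().any():
                dup = sub["wl"][sub["wl"].duplicated()].iloc[0]
                raise SpectrumParseError(
                    f"{path}: duplicate wavelength {dup} nm for sample {sid!r}"
                )
            spectra.append(Spectrum(sub["wl"].to_numpy(), sub["r"].to_numpy(), sample_id=str(sid)))
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} rows with missing reflectance", stacklevel=2)
    return spectra


def write_spectra(path: str | Path, spectra: Sequence[Spectrum], dialect: str = "wide") -> None:
    """Write spectra to CSV in the wide or long dialect."""
    if dialect == "wide":
        grids = {tuple(s.wavelengths_nm) for s in spectra}
        if len(grids) != 1:
            raise ValueError("wide dialect requires all spectra on a common grid")
        out = pd.DataFrame({"wavelength_nm": spectra[0].wavelengths_nm})
        for s in spectra:
            out[s.sample_id] = s.reflectance
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "wavelength_nm": s.wavelengths_nm,
                    "reflectance": s.reflectance,
                }
            )
            for s in spectra
        ]
        out = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, index=False)


def normalize_to_white(raw: Spectrum, white: Spectrum, dark: Spectrum | None = None) -> Spectrum:
    """Convert raw counts to reflectance: ``(raw - dark) / (white - dark)``.

    ``dark`` defaults to zero counts.  All three spectra must share a
    wavelength grid; the white standard must exceed the dark reading at every
    wavelength.  Negative values from noisy raw counts below dark are floored
    at 0.
    """
    if not np.array_equal(raw.wavelengths_nm, white.wavelengths_nm):
        raise ValueError("raw and white spectra are on different wavelength grids")
    d = np.zeros(len(raw)) if dark is None else dark.reflectance
    if dark is not None and not np.array_equal(raw.wavelengths_nm, dark.wavelengths_nm):
        raise ValueError("raw and dark spectra are on different wavelength grids")
    denom = white.reflectance - d
    bad = denom <= 0
    if bad.any():
        wl_bad = raw.wavelengths_nm[bad]
        raise ValueError(
            "white standard does not exceed dark reading at wavelengths (nm): "
            + ", ".join(f"{w:g}" for w in wl_bad[:10])
            + ("..." if wl_bad.size > 10 else "")
        )
    refl = np.clip((raw.reflectance - d) / denom, 0.0, None)
    return raw.with_reflectance(refl)


def resample(s: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.range_nm
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] nm extends beyond the measured "
            f"range [{lo:g}, {hi:g}] nm; extrapolation is not supported"
        )
    refl = np.interp(grid, s.wavelengths_nm, s.reflectance)
    return Spectrum(grid, refl, sample_id=s.sample_id, survey=s.survey)


def smooth_piecewise_cubic(
    s: Spectrum,
    n_sections: int = 30,
    fit_range_nm: tuple[float, float] = (300.0, 800.0),
) -> Spectrum:
    """Least-squares piecewise-cubic smoothing of a reflectance spectrum.

    A cubic regression spline with knots at the ``n_sections + 1`` equally
    spaced section boundaries (C2-continuous at the interior knots) is fitted
    by minimising the total squared deviation, and evaluated back on the input
    grid restricted to the fit range.  When the data do not cover
    ``fit_range_nm`` the sections span the available range instead (with a
    warning).  Because a single global cubic lies inside the spline space, the
    fitted residual sum of squares can never exceed that of the best global
    cubic over the same range.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    lo = max(fit_range_nm[0], s.range_nm[0])
    hi = min(fit_range_nm[1], s.range_nm[1])
    if (lo, hi) != tuple(map(float, fit_range_nm)):
        warnings.warn(
            f"data cover {s.range_nm[0]:g}-{s.range_nm[1]:g} nm; fitting the "
            f"{n_sections} sections over {lo:g}-{hi:g} nm instead of "
            f"{fit_range_nm[0]:g}-{fit_range_nm[1]:g} nm",
            stacklevel=2,
        )
    mask = (s.wavelengths_nm >= lo) & (s.wavelengths_nm <= hi)
    x = s.wavelengths_nm[mask]
    y = s.reflectance[mask]
    n_min = 4 * n_sections
    if x.size < n_min:
        raise ValueError(
            f"need at least {n_min} points in the fit range for {n_sections} sections, got {x.size}"
        )
    boundaries = np.linspace(lo, hi, n_sections + 1)
    t = np.r_[[lo] * 4, boundaries[1:-1], [hi] * 4]
    spline = make_lsq_spline(x, y, t, k=3)
    fitted = np.clip(spline(x), 0.0, None)
    return Spectrum(x, fitted, sample_id=s.sample_id, survey=s.survey)


def normalize_to_peak(s: Spectrum, anchor_nm: float = 550.0, window_nm: float = 30.0) -> Spectrum:
    """Scale reflectance so the maximum within ``anchor_nm +/- window_nm`` is 1.

    The anchor window targets the chlorophyll reflectance peak near 550 nm,
    making spectra of different overall intensity comparable by shape.
    """
    lo, hi = s.range_nm
    if anchor_nm - window_nm < lo or anchor_nm + window_nm > hi:
        raise ValueError(
            f"anchor window {anchor_nm:g}+/-{window_nm:g} nm not inside spectrum range [{lo:g}, {hi:g}]"
        )
    mask = np.abs(s.wavelengths_nm - anchor_nm) <= window_nm
    peak = float(s.reflectance[mask].max())
    if peak <= 0:
        raise ValueError("spectrum is zero throughout the anchor window; cannot normalise")
    return s.with_reflectance(s.reflectance / peak)
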