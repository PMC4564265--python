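"""Photoreceptor sensitivity curves, quantum catches and opponency ratios.

Spectral sensitivities are generated from a single peak wavelength with the
Govardovskii A1 visual-pigment nomogram (alpha band only), the field-standard
curve-from-peak construction when full physiological curves are unavailable.

Two herbivore eye models are provided:

* ``pieris`` — *Pieris rapae* (small white butterfly): UV, blue, green plus
  the two long-wavelength receptors characteristic of pierids, pale red
  (620 nm) and deep red (640 nm).  The UV/B/G peaks (360/450/563 nm) are
  configuration defaults sourced from pierid eye-physiology literature and
  can be overridden.
* ``aphid`` — *Brevicoryne brassicae* (cabbage aphid), using *Myzus persicae*
  peaks: UV 325, B 460, G 530 nm.

Colour is summarised per leaf by opponency-channel catch ratios (B:G, and for
the butterfly PR:G and DR:G) and by brightness, the green-receptor catch used
as the achromatic channel.  No receptor adaptation (von Kries) scaling is
applied: raw catch ratios are the published colour metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .illuminants import get_illuminant
from .spectra import CANONICAL_GRID, Spectrum

__all__ = [
    "Receptor",
    "ReceptorSet",
    "QuantumCatchProfile",
    "visual_pigment_template",
    "build_receptor_set",
    "quantum_catch",
    "catch_profile",
    "SPECIES_LAMBDA_MAX",
]

# Default peak sensitivities (nm).  Aphid and pieris PR/DR peaks are measured
# values for the modelled species; pieris UV/B/G are externally sourced
# pierid defaults and overridable.
SPECIES_LAMBDA_MAX: dict[str, dict[str, float]] = {
    "aphid": {"UV": 325.0, "B": 460.0, "G": 530.0},
    "pieris": {"UV": 360.0, "B": 450.0, "G": 563.0, "PR": 620.0, "DR": 640.0},
}

# Govardovskii et al. A1 alpha-band template constants.
_GOV_A = 69.7
_GOV_B = 28.0
_GOV_b = 0.922
_GOV_C = -14.9
_GOV_c = 1.104
_GOV_D = 0.674


def visual_pigment_template(lambda_max_nm: float, grid: np.ndarray | Sequence[float]) -> np.ndarray:
    """A1 visual-pigment alpha-band sensitivity for a pigment peaking at ``lambda_max_nm``.

    Evaluates the Govardovskii nomogram at ``x = lambda_max / lambda`` and
    peak-normalises.  Valid for peaks in 300-700 nm.
    """
    if not 300.0 <= lambda_max_nm <= 700.0:
        raise ValueError(f"lambda_max {lambda_max_nm} nm outside the supported range 300-700 nm")
    grid = np.asarray(grid, dtype=float)
    x = lambda_max_nm / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    sens = 1.0 / (
        np.exp(_GOV_A * (a - x))
        + np.exp(_GOV_B * (_GOV_b - x))
        + np.exp(_GOV_C * (_GOV_c - x))
        + _GOV_D
    )
    return sens / sens.max()


@dataclass(frozen=True)
class Receptor:
    """A named photoreceptor class with its peak-normalised sensitivity curve."""

    name: str
    lambda_max_nm: float
    sensitivity: np.ndarray
    grid: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivity, dtype=float)
        g = np.asarray(self.grid, dtype=float)
        if np.any(s < 0):
            raise ValueError("sensitivity must be non-negative")
        if abs(s.max() - 1.0) > 1e-9:
            raise ValueError("sensitivity must be peak-normalised to 1")
        peak_wl = g[int(np.argmax(s))]
        if abs(peak_wl - self.lambda_max_nm) > 1.0:
            raise ValueError(
                f"sensitivity peaks at {peak_wl:g} nm, not within 1 nm of lambda_max {self.lambda_max_nm:g}"
            )
        object.__setattr__(self, "sensitivity", s)
        object.__setattr__(self, "grid", g)


@dataclass(frozen=True)
class ReceptorSet:
    """An ordered set of receptors for one species plus the shared illuminant."""

    species: str
    receptors: tuple[Receptor, ...]
    illuminant: np.ndarray
    grid: np.ndarray

    def __post_init__(self) -> None:
        names = [r.name for r in self.receptors]
        if len(set(names)) != len(names):
            raise ValueError("receptor names must be unique")
        if np.any(np.asarray(self.illuminant) <= 0):
            raise ValueError("illuminant must be strictly positive on the grid")

    def __getitem__(self, name: str) -> Receptor:
        for r in self.receptors:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.receptors)


@dataclass(frozen=True)
class QuantumCatchProfile:
    """Per-receptor quantum catches and derived colour metrics for one leaf.

    ``bg_ratio`` is the blue:green catch ratio; for the butterfly model
    ``prg_ratio`` and ``drg_ratio`` are the pale-red:green and deep-red:green
    ratios.  ``brightness`` is the green-receptor catch (achromatic channel).
    """

    sample_id: str
    catches: dict[str, float]
    bg_ratio: float
    brightness: float
    prg_ratio: float | None = None
    drg_ratio: float | None = None


def build_receptor_set(
    species: str,
    overrides: Mapping[str, float] | None = None,
    illuminant: str | np.ndarray = "flat",
    grid: np.ndarray | None = None,
) -> ReceptorSet:
    """Construct the receptor set for ``species`` ('aphid' or 'pieris').

    ``overrides`` maps receptor names to replacement peak wavelengths;
    naming a receptor the species lacks is an error.  ``illuminant`` is
    ``"flat"`` (default), ``"d65"`` or an explicit curve on the grid.
    """
    if species not in SPECIES_LAMBDA_MAX:
        raise ValueError(f"unknown species {species!r}; known: {sorted(SPECIES_LAMBDA_MAX)}")
    peaks = dict(SPECIES_LAMBDA_MAX[species])
    if overrides:
        for name, lam in overrides.items():
            if name not in peaks:
                raise ValueError(f"species {species!r} has no receptor {name!r}")
            peaks[name] = float(lam)
    g = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    receptors = tuple(
        Receptor(name, lam, visual_pigment_template(lam, g), g) for name, lam in peaks.items()
    )
    ill = get_illuminant(illuminant, g)
    return ReceptorSet(species=species, receptors=receptors, illuminant=ill, grid=g)


def quantum_catch(s: Spectrum, r: Receptor, illuminant: np.ndarray) -> float:
    """Trapezoidal quantum catch: integral of reflectance x illuminant x sensitivity."""
    if not np.array_equal(s.wavelengths_nm, r.grid):
        raise ValueError("spectrum and receptor are on different wavelength grids; resample first")
    ill = np.asarray(illuminant, dtype=float)
    if ill.shape != s.wavelengths_nm.shape:
        raise ValueError("illuminant does not match the wavelength grid")
    return float(np.trapezoid(s.reflectance * ill * r.sensitivity, s.wavelengths_nm))


def catch_profile(s: Spectrum, rs: ReceptorSet) -> QuantumCatchProfile:
    """Quantum catches plus opponency ratios and brightness for one spectrum."""
    catches = {r.name: quantum_catch(s, r, rs.illuminant) for r in rs.receptors}
    g = catches.get("G", 0.0)
    if g <= 0:
        raise ValueError(
            f"green-receptor catch is {g:g} for sample {s.sample_id!r}; opponency ratios undefined"
        )
    return QuantumCatchProfile(
        sample_id=s.sample_id,
        catches=catches,
        bg_ratio=catches["B"] / g,
        brightness=g,
        prg_ratio=catches["PR"] / g if "PR" in catches else None,
        drg_ratio=catches["DR"] / g if "DR" in catches else None,
    )


def catch_profiles(spectra: Sequence[Spectrum], rs: ReceptorSet) -> list[QuantumCatchProfile]:
    """Vectorised convenience: profiles for many spectra sharing the set's grid."""
    return [catch_profile(s, rs) for s in spectra]
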