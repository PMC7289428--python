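"""Hexagon colour space model for trichromatic hymenopteran vision.

A floral reflectance spectrum I(λ) is turned into a colour locus in four
steps:

1. photon capture  P_i = R_i ∫ S_i(λ) I(λ) D(λ) dλ  for each receptor i,
2. von Kries adaptation  R_i = 1 / ∫ S_i(λ) I_B(λ) D(λ) dλ,  which forces
   the adapting background I_B to P_i = 1 in every receptor,
3. receptor excitation  E = P / (P + 1)  (hyperbolic transduction),
4. hexagon coordinates  x = sin 60°·(E_G − E_UV),  y = E_B − ½(E_G + E_UV).

Integrals are Riemann sums on the 10 nm model grid over 300–650 nm.
Hue is the counter-clockwise angle with the BLUE vertex (0, 1) at 90°;
chromatic contrast is Euclidean distance from the hexagon centre, where
the background itself always lands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spectra import (
    ReceptorSet,
    SpectralFunction,
    hymenopteran_receptors,
    make_illuminant,
    make_leaf_background,
)

__all__ = [
    "SECTOR_NAMES",
    "ACHROMATIC_EPS",
    "ColourLocus",
    "von_kries_coefficient",
    "photon_capture",
    "excitation",
    "hexagon_coords",
    "hue_and_contrast",
    "classify_sector",
    "spectrum_to_locus",
    "default_viewing_context",
]

#: The six 60° hue sectors, in counter-clockwise order from hue 0°.
SECTOR_NAMES = ("BG", "B", "UB", "U", "UG", "G")

#: Contrast below which hue (and sector) are undefined.
ACHROMATIC_EPS = 1e-9

_SIN60 = math.sin(math.radians(60.0))


@dataclass(frozen=True)
class ColourLocus:
    """A point in the bee colour hexagon.

    Attributes
    ----------
    e_uv, e_b, e_g :
        Receptor excitations in [0, 1).
    x, y :
        Cartesian hexagon coordinates.
    hue_deg :
        Counter-clockwise hue angle in [0°, 360°), with the BLUE vertex
        at 90°; ``None`` at the achromatic centre.
    contrast :
        Chromatic contrast (Euclidean distance from the centre).
    sector :
        One of B, BG, G, UG, U, UB; ``None`` at the achromatic centre.
    """

    e_uv: float
    e_b: float
    e_g: float
    x: float
    y: float
    hue_deg: float | None
    contrast: float
    sector: str | None


def _align(*fns: SpectralFunction) -> tuple[list[np.ndarray], float]:
    """Resample onto the first function's grid; return values and Δλ.

    The receptor sensitivity is passed first, so its grid (normally the
    10 nm model grid) defines the quadrature nodes of the Riemann sum.
    The grid must be uniformly spaced.
    """
    grid = fns[0].wavelengths_nm
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0]):
        raise ValueError("integration grid must be uniformly spaced")
    return [f.resample(grid).values for f in fns], float(steps[0])


def von_kries_coefficient(
    sensitivity: SpectralFunction,
    background: SpectralFunction,
    illuminant: SpectralFunction,
) -> float:
    """Adaptation coefficient R_i = 1 / ∫ S_i(λ) I_B(λ) D(λ) dλ.

    Normalizes the receptor to the light reflected from the adapting
    background so that the background itself gives unit photon capture.
    """
    (s, bg, d), dlam = _align(sensitivity, background, illuminant)
    integral = float((s * bg * d).sum() * dlam)
    if integral <= 0.0:
        raise ValueError("degenerate background: zero photon capture integral")
    return 1.0 / integral


def photon_capture(
    sensitivity: SpectralFunction,
    stimulus: SpectralFunction,
    illuminant: SpectralFunction,
    von_kries: float,
) -> float:
    """Relative photon capture P_i = R_i ∫ S_i(λ) I(λ) D(λ) dλ (≥ 0)."""
    (s, stim, d), dlam = _align(sensitivity, stimulus, illuminant)
    return von_kries * float((s * stim * d).sum() * dlam)


def excitation(p: float) -> float:
    """Receptor excitation E = P/(P+1): monotone, E(0)=0, E(1)=0.5."""
    if p < 0:
        raise ValueError(f"photon capture must be non-negative, got {p}")
    return p / (p + 1.0)


def hexagon_coords(e_uv: float, e_b: float, e_g: float) -> tuple[float, float]:
    """Cartesian hexagon coordinates of an excitation triple.

    x = sin 60°·(E_G − E_UV) and y = E_B − ½(E_G + E_UV), so the adapting
    background (all E = 0.5) maps to the centre (0, 0).
    """
    x = _SIN60 * (e_g - e_uv)
    y = e_b - 0.5 * (e_g + e_uv)
    return x, y


def hue_and_contrast(x: float, y: float) -> tuple[float | None, float]:
    """Polar form of a hexagon locus.

    Contrast is √(x²+y²).  Hue is measured counter-clockwise with the
    BLUE vertex (0, 1) at 90°; below the achromatic threshold it is
    returned as ``None`` rather than an arbitrary angle.
    """
    contrast = math.hypot(x, y)
    if contrast < ACHROMATIC_EPS:
        return None, contrast
    hue = math.degrees(math.atan2(y, x)) % 360.0
    return hue, contrast


def classify_sector(hue_deg: float | None) -> str:
    """Map a hue angle to one of the six 60° colour categories.

    BG = [0°, 60°), B = [60°, 120°), UB = [120°, 180°), U = [180°, 240°),
    UG = [240°, 300°), G = [300°, 360°); a boundary hue belongs to the
    counter-clockwise (upper) sector.
    """
    if hue_deg is None:
        raise ValueError("hue undefined at the achromatic centre")
    h = hue_deg % 360.0
    return SECTOR_NAMES[int(h // 60.0)]


@dataclass(frozen=True)
class ViewingContext:
    """Background, illuminant and receptor set, with precomputed R_i."""

    background: SpectralFunction
    illuminant: SpectralFunction
    receptors: ReceptorSet

    @property
    def von_kries(self) -> dict[str, float]:
        return {
            name: von_kries_coefficient(s, self.background, self.illuminant)
            for name, s in self.receptors.as_dict().items()
        }


def default_viewing_context() -> ViewingContext:
    """Green-leaf background, D65 daylight, generic bee receptors."""
    return ViewingContext(
        background=make_leaf_background(),
        illuminant=make_illuminant(),
        receptors=hymenopteran_receptors(),
    )


def locus_from_excitations(e_uv: float, e_b: float, e_g: float) -> ColourLocus:
    """Build a full colour locus from an excitation triple."""
    x, y = hexagon_coords(e_uv, e_b, e_g)
    hue, contrast = hue_and_contrast(x, y)
    sector = classify_sector(hue) if hue is not None else None
    return ColourLocus(e_uv, e_b, e_g, x, y, hue, contrast, sector)


def spectrum_to_locus(
    stimulus: SpectralFunction,
    background: SpectralFunction | None = None,
    illuminant: SpectralFunction | None = None,
    receptors: ReceptorSet | None = None,
) -> ColourLocus:
    """Run the full pipeline: reflectance spectrum → hexagon colour locus.

    Deterministic; defaults to the green-leaf background, D65 daylight
    and the generic trichromatic bee receptor set.
    """
    background = make_leaf_background() if background is None else background
    illuminant = make_illuminant() if illuminant is None else illuminant
    receptors = hymenopteran_receptors() if receptors is None else receptors

    excitations = {}
    for name, s in receptors.as_dict().items():
        r = von_kries_coefficient(s, background, illuminant)
        p = photon_capture(s, stimulus, illuminant, r)
        excitations[name] = excitation(p)
    return locus_from_excitations(
        excitations["UV"], excitations["B"], excitations["G"]
    )
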