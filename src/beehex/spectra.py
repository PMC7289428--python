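"""Tabulated spectral functions and standard spectra for the bee vision model.

Everything in the colour model is a function of wavelength sampled on a
common grid: floral reflectance I(λ), background reflectance I_B(λ),
illumination D(λ) and photoreceptor sensitivities S_i(λ).  The model grid
is 300–650 nm in 10 nm steps; finer measurement grids are resampled by
linear interpolation and data beyond 650 nm is truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MODEL_GRID",
    "SpectralFunction",
    "ReceptorSet",
    "a1_template",
    "average_spectra",
    "make_illuminant",
    "make_leaf_background",
    "hymenopteran_receptors",
]

#: The 36-point wavelength grid (nm) on which the colour model integrates.
MODEL_GRID: np.ndarray = np.arange(300, 651, 10, dtype=float)


@dataclass(frozen=True)
class SpectralFunction:
    """A non-negative function of wavelength tabulated on an increasing grid.

    Parameters
    ----------
    wavelengths_nm :
        Strictly increasing wavelengths in nanometres.
    values :
        Non-negative samples: reflectance as a fraction (typically in
        [0, ~1.1]), sensitivity in [0, 1], or relative photon flux.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.shape != w.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if w.size < 2:
            raise ValueError("need at least two samples")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(w)) or np.any(~np.isfinite(v)):
            raise ValueError("NaN/inf in spectral data")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    def resample(self, grid: np.ndarray | None = None) -> "SpectralFunction":
        """Linear-interpolate onto ``grid`` (default: the 10 nm model grid).

        Lossless when the function is already tabulated on ``grid``.
        Wavelengths outside the tabulated range raise, except that the grid
        is allowed to clip the tabulated range (truncation at 650 nm of
        spectra measured to 700 nm is the normal case).
        """
        grid = MODEL_GRID if grid is None else np.asarray(grid, dtype=float)
        if np.array_equal(grid, self.wavelengths_nm):
            return self
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] nm extends beyond the tabulated "
                f"range [{lo}, {hi}] nm"
            )
        return SpectralFunction(grid, np.interp(grid, self.wavelengths_nm, self.values))

    def on_model_grid(self) -> "SpectralFunction":
        return self.resample(MODEL_GRID)

    def __call__(self, wavelength_nm: float) -> float:
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.values))


@dataclass(frozen=True)
class ReceptorSet:
    """The three hymenopteran photoreceptor sensitivities (UV, B, G).

    Each sensitivity peaks at 1.0 within ±5 nm of its nominal λmax
    (350, 440 and 540 nm for the generic trichromatic bee).
    """

    uv: SpectralFunction
    b: SpectralFunction
    g: SpectralFunction
    nominal_peaks: tuple[float, float, float] = (350.0, 440.0, 540.0)

    def __post_init__(self) -> None:
        for s, nominal in zip((self.uv, self.b, self.g), self.nominal_peaks):
            peak_wl = s.wavelengths_nm[int(np.argmax(s.values))]
            if abs(peak_wl - nominal) > 5.0:
                raise ValueError(
                    f"receptor peak at {peak_wl} nm, expected {nominal}±5 nm"
                )
            if not np.isclose(s.values.max(), 1.0):
                raise ValueError("receptor sensitivity must be peak-normalized to 1")
            if np.any(s.values > 1.0 + 1e-12):
                raise ValueError("sensitivity values must lie in [0, 1]")

    def as_dict(self) -> dict[str, SpectralFunction]:
        return {"UV": self.uv, "B": self.b, "G": self.g}


def a1_template(
    lambda_max: float,
    grid: np.ndarray | None = None,
    *,
    beta_band: bool = False,
) -> SpectralFunction:
    """Vitamin-A1 visual pigment absorbance template (Govardovskii et al. 2000).

    The alpha band is

        S(λ) = 1 / (exp[A(a − x)] + exp[B(b − x)] + exp[C(c − x)] + D),

    with x = λmax/λ, A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922,
    c = 1.104 and a = 0.8795 + 0.0459·exp(−(λmax − 300)²/11940).  An
    optional beta (cis) band adds a Gaussian in the UV.  The result is
    re-normalized so the maximum on ``grid`` equals 1.

    Parameters
    ----------
    lambda_max :
        Peak wavelength of the alpha band, 300–600 nm.
    grid :
        Output wavelength grid; defaults to the 10 nm model grid.
    beta_band :
        Include the beta band (off by default).
    """
    if not 300.0 <= lambda_max <= 600.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside [300, 600]")
    grid = MODEL_GRID if grid is None else np.asarray(grid, dtype=float)
    lam = grid
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    alpha = 1.0 / (
        np.exp(A * (a - x)) + np.exp(B * (0.922 - x)) + np.exp(C * (1.104 - x)) + D
    )
    s = alpha
    if beta_band:
        lam_beta = 189.0 + 0.315 * lambda_max
        bw = -40.5 + 0.195 * lambda_max
        s = alpha + 0.26 * np.exp(-(((lam - lam_beta) / bw) ** 2))
    s = s / s.max()
    return SpectralFunction(grid, s)


def hymenopteran_receptors(
    grid: np.ndarray | None = None, *, beta_band: bool = False
) -> ReceptorSet:
    """Generic trichromatic bee receptor set (λmax = 350, 440, 540 nm)."""
    return ReceptorSet(
        uv=a1_template(350.0, grid, beta_band=beta_band),
        b=a1_template(440.0, grid, beta_band=beta_band),
        g=a1_template(540.0, grid, beta_band=beta_band),
    )


def average_spectra(spectra: list[SpectralFunction]) -> SpectralFunction:
    """Pointwise mean of spectra (per-species averaging of flower spectra).

    All spectra are resampled onto the first spectrum's grid clipped to the
    common range before averaging.
    """
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    if len(spectra) == 1:
        return spectra[0]
    lo = max(s.wavelengths_nm[0] for s in spectra)
    hi = min(s.wavelengths_nm[-1] for s in spectra)
    if hi <= lo:
        raise ValueError("spectra have no common wavelength range")
    base = spectra[0].wavelengths_nm
    grid = base[(base >= lo - 1e-9) & (base <= hi + 1e-9)]
    if grid.size < 2:
        raise ValueError("common wavelength range too narrow to resample")
    stacked = np.vstack([s.resample(grid).values for s in spectra])
    return SpectralFunction(grid, stacked.mean(axis=0))


# CIE standard illuminant D65 relative spectral power, 300-650 nm at 10 nm.
_D65_POWER = np.array([
    0.0341, 3.2945, 20.2360, 37.0535, 39.9488, 44.9117, 46.6383, 52.0891,
    49.9755, 54.6482, 82.7549, 91.4860, 93.4318, 86.6823, 104.8650, 117.0080,
    117.8120, 114.8610, 115.9230, 108.8110, 109.3540, 107.8020, 104.7900,
    107.6890, 104.4050, 104.0460, 100.0000, 96.3342, 95.7880, 88.6856,
    90.0062, 89.5991, 87.6987, 83.2886, 83.6992, 80.0268,
])


def make_illuminant() -> SpectralFunction:
    """Open-sky daylight (D65, 6500 K) as relative photon flux.

    The CIE D65 relative power table is converted to photon flux by
    multiplying by λ (photon energy ∝ 1/λ); absolute scale is irrelevant
    because von Kries adaptation cancels any constant factor.
    """
    flux = _D65_POWER * MODEL_GRID
    return SpectralFunction(MODEL_GRID, flux / flux.max())


def make_leaf_background(
    *,
    uv_floor: float = 0.035,
    green_peak: float = 0.12,
    peak_nm: float = 550.0,
    peak_width_nm: float
    = 45.0,
) -> SpectralFunction:
    """Parametric green-leaf reflectance used as the adapting background.

    Emulates an averaged eucalypt leaf: a few percent reflectance across
    the UV and blue, a chlorophyll-gap bump near 550 nm, staying well
    below 0.6 everywhere and strictly positive (so von Kries coefficients
    are always defined).
    """
    lam = MODEL_GRID
    bump = green_peak * np.exp(-(((lam - peak_nm) / peak_width_nm) ** 2))
    vals = uv_floor + bump
    return SpectralFunction(lam, vals)
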