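"""Parametric wavy epidermal profiles with analytically known rugosity.

A profile is a graph-like function y(x) over a section of length L (default
30 mm, the 3 cm excision).  The sinusoid is the canonical choice because its
arc length has an independent adaptive-quadrature oracle and a closed-form
small-slope limit RI -> 100 * pi^2 a^2 / lambda^2; a multi-harmonic composite
is provided for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from ..contour import Contour
from ..errors import InvalidParameterError, RenderError
from ..imaging import CalibratedImage

__all__ = [
    "WaveProfile",
    "CompositeProfile",
    "generate_contour",
    "true_ri_quadrature",
    "render_section_image",
]


def _check_finite(**params: float) -> None:
    for name, value in params.items():
        if not np.all(np.isfinite(value)):
            raise InvalidParameterError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class WaveProfile:
    """Sinusoidal epidermal profile: y = A sin(2 pi x / lambda + phase) + noise."""

    amplitude_mm: float
    wavelength_mm: float
    phase_rad: float = 0.0
    section_length_mm: float = 30.0
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(
            amplitude_mm=self.amplitude_mm,
            wavelength_mm=self.wavelength_mm,
            phase_rad=self.phase_rad,
            section_length_mm=self.section_length_mm,
            noise_sd_mm=self.noise_sd_mm,
        )
        if self.section_length_mm <= 0:
            raise InvalidParameterError("section_length_mm must be positive")
        if self.wavelength_mm <= 0:
            raise InvalidParameterError("wavelength_mm must be positive")
        if self.amplitude_mm < 0:
            raise InvalidParameterError("amplitude_mm must be non-negative")
        if self.amplitude_mm >= self.wavelength_mm:
            raise InvalidParameterError(
                "amplitude_mm must be smaller than wavelength_mm (graph-like profile)"
            )
        if self.noise_sd_mm < 0:
            raise InvalidParameterError("noise_sd_mm must be non-negative")

    def height(self, x: np.ndarray) -> np.ndarray:
        k = 2.0 * np.pi / self.wavelength_mm
        return self.amplitude_mm * np.sin(k * np.asarray(x, float) + self.phase_rad)

    def slope(self, x: np.ndarray) -> np.ndarray:
        k = 2.0 * np.pi / self.wavelength_mm
        return self.amplitude_mm * k * np.cos(k * np.asarray(x, float) + self.phase_rad)

    @property
    def min_wavelength_mm(self) -> float:
        return self.wavelength_mm


@dataclass(frozen=True)
class CompositeProfile:
    """Sum of sinusoidal harmonics; used to stress-test arc-length measurement."""

    amplitudes_mm: tuple[float, ...]
    wavelengths_mm: tuple[float, ...]
    phases_rad: tuple[float, ...] = ()
    section_length_mm: float = 30.0
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes_mm)
        wls = tuple(float(w) for w in self.wavelengths_mm)
        phases = tuple(float(p) for p in self.phases_rad) or (0.0,) * len(amps)
        if not (len(amps) == len(wls) == len(phases)):
            raise InvalidParameterError("amplitudes, wavelengths and phases must align")
        _check_finite(
            amplitudes_mm=np.array(amps),
            wavelengths_mm=np.array(wls),
            phases_rad=np.array(phases),
            section_length_mm=self.section_length_mm,
            noise_sd_mm=self.noise_sd_mm,
        )
        if any(a < 0 for a in amps) or any(w <= 0 for w in wls):
            raise InvalidParameterError("need amplitudes >= 0 and wavelengths > 0")
        if self.noise_sd_mm < 0:
            raise InvalidParameterError("noise_sd_mm must be non-negative")
        object.__setattr__(self, "amplitudes_mm", amps)
        object.__setattr__(self, "wavelengths_mm", wls)
        object.__setattr__(self, "phases_rad", phases)

    def height(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.zeros_like(x)
        for a, w, p in zip(self.amplitudes_mm, self.wavelengths_mm, self.phases_rad):
            y += a * np.sin(2.0 * np.pi * x / w + p)
        return y

    def slope(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        dy = np.zeros_like(x)
        for a, w, p in zip(self.amplitudes_mm, self.wavelengths_mm, self.phases_rad):
            k = 2.0 * np.pi / w
            dy += a * k * np.cos(k * x + p)
        return dy

    @property
    def min_wavelength_mm(self) -> float:
        return min(self.wavelengths_mm)


def generate_contour(profile, spacing_mm: float) -> Contour:
    """Sample a profile into an ordered polyline with exact endpoints.

    x runs from 0 to the section length at the given spacing (the last point
    is placed at the section length exactly); Gaussian noise of the profile's
    ``noise_sd_mm`` is added to y only, keeping the contour graph-like.
    """
    if not np.isfinite(spacing_mm) or spacing_mm <= 0:
        raise InvalidParameterError("spacing_mm must be positive")
    if spacing_mm > profile.min_wavelength_mm / 4.0:
        raise InvalidParameterError(
            f"spacing {spacing_mm} mm undersamples the profile; need "
            f"<= wavelength/4 = {profile.min_wavelength_mm / 4.0:.6g} mm"
        )
    length = profile.section_length_mm
    x = np.arange(0.0, length, spacing_mm)
    if length - x[-1] < spacing_mm * 1e-9:
        x[-1] = length
    else:
        x = np.append(x, length)
    y = profile.height(x)
    if profile.noise_sd_mm > 0:
        rng = np.random.default_rng(profile.seed)
        y = y + rng.normal(0.0, profile.noise_sd_mm, size=x.size)
    return Contour.from_points(x, y)


def true_ri_quadrature(profile) -> float:
    """RI (%) of a noise-free profile by adaptive quadrature of the arc length.

    Computes ``100 * (integral of sqrt(1 + y'(x)^2) - L) / L`` to a relative
    tolerance of 1e-9.  This is the independent oracle against which all
    polyline-based measurements are validated.
    """
    if profile.noise_sd_mm != 0:
        raise InvalidParameterError("quadrature oracle only supports noise-free profiles")
    length = profile.section_length_mm

    def integrand(x: float) -> float:
        return float(np.sqrt(1.0 + profile.slope(x) ** 2))

    # one quadrature call per wavelength keeps the adaptive rule honest on
    # strongly oscillatory profiles
    n_chunks = max(1, int(np.ceil(length / profile.min_wavelength_mm)))
    edges = np.linspace(0.0, length, n_chunks + 1)
    arc = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-11, limit=200)
        arc += val
    return 100.0 * (arc - length) / length


def render_section_image(
    contour: Contour,
    px_per_mm: float,
    band_height_mm: float = 5.0,
    margin_mm: float = 1.0,
) -> CalibratedImage:
    """Rasterise a contour as a filled binary tissue band.

    The upper boundary of the band is the contour; tissue extends
    ``band_height_mm`` below it.  Pixel centres sit on the grid
    ``(j / px_per_mm, y_top - r / px_per_mm)`` with row 0 at the top, so a
    traced boundary can be mapped back to physical coordinates without a
    half-grid offset in x.  Foreground (``True``) is tissue.
    """
    if not np.isfinite(px_per_mm) or px_per_mm < 10:
        raise InvalidParameterError("px_per_mm must be >= 10 for a usable render")
    if not np.isfinite(band_height_mm) or band_height_mm <= 0:
        raise InvalidParameterError("band_height_mm must be positive")
    xs = contour.x
    ys = contour.y
    # graph-likeness: x must not double back, and duplicate x (to pixel
    # precision) must not carry conflicting heights
    if np.any(np.diff(xs) < 0):
        raise RenderError("contour x doubles back; not graph-like")
    dup = np.diff(xs) == 0
    if np.any(dup & (np.abs(np.diff(ys)) > 0.5 / px_per_mm)):
        raise RenderError("contour is not graph-like on the pixel grid (duplicate x)")
    n_cols = int(round((xs[-1] - xs[0]) * px_per_mm)) + 1
    if n_cols < 2:
        raise InvalidParameterError("contour too short for this resolution")
    xc = xs[0] + np.arange(n_cols) / px_per_mm
    yc = np.interp(xc, xs, ys)
    y_top = float(yc.max() + margin_mm)  # background margin above the epidermis
    y_bot = float(yc.min() - band_height_mm)
    n_rows = int(np.ceil((y_top - y_bot) * px_per_mm)) + 1
    rows = np.arange(n_rows)
    y_rows = y_top - rows / px_per_mm  # physical y of each row's pixel centre
    above = y_rows[:, None] <= yc[None, :]  # at or below the contour
    below = y_rows[:, None] >= (yc[None, :] - band_height_mm)
    mask = above & below
    return CalibratedImage(mask, px_per_mm)
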