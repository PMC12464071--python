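"""Gabor stimulus model with task-irrelevant phase or contrast randomization.

A Gabor grating is a sinusoidal luminance carrier under a circular Gaussian
envelope.  The luminance map is

    L(x, y) = L_bg * (1 + c * exp(-(x^2+y^2)/(2 sigma^2))
                        * cos(2 pi f (x cos th + y sin th) + phi))

with contrast ``c`` (nominal carrier contrast), spatial frequency ``f`` in
cycles/deg, envelope SD ``sigma`` in degrees of visual angle (dva), carrier
orientation ``th`` and spatial phase ``phi``.  Orientation follows the
convention 0 deg = vertical carrier stripes, increasing clockwise; phase is
measured at the envelope center, so at phi = 0 the carrier peak coincides with
the envelope peak.

On each trial exactly one task-irrelevant dimension is resampled: either the
spatial phase (uniform on [0, 180) deg at fixed contrast) or the contrast
(uniform on a sub-interval of [0, 1] at fixed phase).  Because the Gaussian
envelope attenuates the nearest carrier trough, the measured Michelson
contrast of a rendered patch is strictly below the nominal carrier contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GaborSpec",
    "RandomizationScheme",
    "render_gabor",
    "sample_trial_stimulus",
    "michelson_contrast",
]


@dataclass(frozen=True)
class GaborSpec:
    """Full parameterization of one Gabor grating.

    Defaults are the experiment's stimulus constants: 2 dva aperture,
    2.5 cpd carrier, 0.28 dva envelope SD, 45 deg reference orientation,
    45% nominal contrast on a 52.42 cd/m^2 background.
    """

    size_deg: float = 2.0
    sf_cpd: float = 2.5
    sigma_deg: float = 0.28
    orientation_deg: float = 45.0
    phase_deg: float = 0.0
    contrast: float = 0.45
    background_lum: float = 52.42

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")
        if self.sf_cpd <= 0:
            raise ValueError("sf_cpd must be positive")
        if self.background_lum < 0:
            raise ValueError("background_lum must be nonnegative")
        # orientation is a direction of stripes: identified modulo 180 deg
        ori = float(self.orientation_deg) % 180.0
        phase = float(self.phase_deg) % 360.0
        object.__setattr__(self, "orientation_deg", ori if ori < 180.0 else 0.0)
        object.__setattr__(self, "phase_deg", phase if phase < 360.0 else 0.0)


@dataclass(frozen=True)
class RandomizationScheme:
    """Which task-irrelevant dimension varies from trial to trial.

    ``kind='phase'``: phase uniform on ``phase_range_deg`` (half-open),
    contrast clamped to ``fixed_contrast``.  ``kind='contrast'``: contrast
    uniform on ``contrast_range``, phase clamped to ``fixed_phase_deg``.
    """

    kind: str = "phase"
    phase_range_deg: tuple[float, float] = (0.0, 180.0)
    contrast_range: tuple[float, float] = (0.33, 0.66)
    fixed_phase_deg: float = 0.0
    fixed_contrast: float = 0.45

    def __post_init__(self) -> None:
        if self.kind not in ("phase", "contrast"):
            raise ValueError(f"kind must be 'phase' or 'contrast', got {self.kind!r}")
        lo, hi = self.phase_range_deg
        if not (0.0 <= lo < hi <= 360.0):
            raise ValueError(f"invalid phase_range_deg {self.phase_range_deg}")
        lo, hi = self.contrast_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid contrast_range {self.contrast_range}")
        if not 0.0 <= self.fixed_contrast <= 1.0:
            raise ValueError("fixed_contrast out of [0, 1]")


def render_gabor(
    spec: GaborSpec, pixels_per_deg: float, field_deg: float
) -> np.ndarray:
    """Render ``spec`` to a 2-D luminance map in cd/m^2.

    The grid is square with an odd number of samples so the envelope center
    falls exactly on a pixel.  ``pixels_per_deg`` must be at least four times
    the carrier frequency (twice Nyquist) and ``field_deg`` must cover the
    aperture.  Luminance is clipped at zero; no display gamma is modeled.
    """
    if pixels_per_deg <= 0 or field_deg <= 0:
        raise ValueError("pixels_per_deg and field_deg must be positive")
    if pixels_per_deg < 4.0 * spec.sf_cpd:
        raise ValueError(
            f"pixels_per_deg={pixels_per_deg} aliases a {spec.sf_cpd} cpd carrier; "
            f"need at least {4.0 * spec.sf_cpd}"
        )
    if field_deg < spec.size_deg:
        raise ValueError(
            f"field_deg={field_deg} does not cover the {spec.size_deg} dva aperture"
        )
    n = int(round(field_deg * pixels_per_deg))
    if n % 2 == 0:
        n += 1
    coords = (np.arange(n) - n // 2) / pixels_per_deg
    x, y = np.meshgrid(coords, coords)
    theta = np.deg2rad(spec.orientation_deg)
    phi = np.deg2rad(spec.phase_deg)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * spec.sigma_deg**2))
    carrier = np.cos(
        2.0 * np.pi * spec.sf_cpd * (x * np.cos(theta) + y * np.sin(theta)) + phi
    )
    lum = spec.background_lum * (1.0 + spec.contrast * envelope * carrier)
    return np.maximum(lum, 0.0)


def sample_trial_stimulus(
    scheme: RandomizationScheme, base: GaborSpec, rng: np.random.Generator
) -> GaborSpec:
    """Draw one trial's stimulus spec under ``scheme``, reproducibly via ``rng``."""
    if scheme.kind == "phase":
        lo, hi = scheme.phase_range_deg
        return replace(
            base,
            phase_deg=float(rng.uniform(lo, hi)),
            contrast=scheme.fixed_contrast,
        )
    lo, hi = scheme.contrast_range
    return replace(
        base,
        phase_deg=scheme.fixed_phase_deg,
        contrast=float(rng.uniform(lo, hi)),
    )


def michelson_contrast(lum_map: np.ndarray) -> float:
    """Michelson contrast (Lmax - Lmin) / (Lmax + Lmin) of a luminance map."""
    arr = np.asarray(lum_map, dtype=float)
    if arr.size == 0:
        raise ValueError("empty luminance map")
    lo = float(arr.min())
    hi = float(arr.max())
    if lo < 0:
        raise ValueError("luminance map must be nonnegative")
    if hi + lo == 0:
        raise ValueError("all-zero luminance map has undefined contrast")
    return (hi - lo) / (hi + lo)
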