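"""Pink-noise stereograms with sinusoidal disparity corrugations.

The psychophysical stimuli are 1/f (pink) noise fields carrying an oblique
(45 or 135 degree) sinusoidal disparity corrugation, windowed to an annulus
of the visual field with 1-degree raised-cosine edges.  A stereo pair is
rendered by resampling the same noise carrier horizontally by +/- half the
local disparity in the two eyes, which keeps the cyclopean geometry centered
and introduces no monocular (compression/expansion) artifact detectable in
the amplitude spectrum.

Geometry is specified in degrees of visual angle and converted to pixels via
``pixels_per_degree``; the default 23.857 px/deg reproduces a 0.311-mm dot
pitch display viewed at 45 cm (small-angle approximation), on which a
21-degree field radius spans ~501 pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "StimulusSpec",
    "StereoPair",
    "pink_noise",
    "corrugation_map",
    "annular_window",
    "render_stereo",
    "make_stimulus",
    "DEFAULT_PIXELS_PER_DEGREE",
]

#: 0.311 mm dot pitch at 45 cm: atan(0.311/450) per pixel -> ~23.86 px/deg.
DEFAULT_PIXELS_PER_DEGREE = 23.857

#: Disparities beyond this magnitude (degrees) are rejected as unphysical.
MAX_DISPARITY_DEG = 2.0

MID_GRAY = 0.5

#: The six corrugation frequencies (cycles/degree) of the standard protocol.
PROTOCOL_FREQUENCIES = (0.04, 0.09, 0.18, 0.35, 0.71, 1.41)


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one corrugated pink-noise stereogram.

    Frequencies are in cycles/degree, disparities in arcmin, angles and
    eccentricities in degrees.  ``tilt`` is the orientation of the
    corrugation stripes (45 or 135); the sinusoid runs along the orthogonal
    axis.  ``phase`` is the corrugation phase in radians (cosine convention,
    so mirror-symmetric stimuli for the two tilts share a phase origin).
    """

    corrugation_frequency: float
    peak_to_trough_disparity: float
    tilt: float = 45.0
    annulus_inner: float = 0.0
    annulus_outer: float = 21.0
    edge_width: float = 1.0
    field_radius: float = 21.0
    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE
    rng_seed: int = 0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.corrugation_frequency <= 0:
            raise ValueError("corrugation frequency must be positive")
        if self.peak_to_trough_disparity < 0:
            raise ValueError("peak-to-trough disparity must be >= 0")
        if not (0.0 <= self.annulus_inner < self.annulus_outer
                <= self.field_radius):
            raise ValueError(
                "need 0 <= annulus_inner < annulus_outer <= field_radius")

    @property
    def size(self) -> int:
        """Image side length in pixels (even)."""
        return 2 * int(round(self.field_radius * self.pixels_per_degree))


@dataclass(frozen=True)
class StereoPair:
    """A rendered stereogram with its ground-truth disparity map (arcmin)."""

    left: np.ndarray
    right: np.ndarray
    ground_truth_disparity: np.ndarray
    spec: StimulusSpec


def pink_noise(size: int, seed: int, mid_gray: float = MID_GRAY) -> np.ndarray:
    """A 1/f-amplitude noise image in [0, 1] with mean exactly ``mid_gray``.

    Random phases come from a seeded generator; the amplitude spectrum is
    shaped radially as 1/f with the DC term removed, the field standardized
    to zero mean and unit variance and then affinely mapped into [0, 1]
    around mid-gray (scaled by the extreme value, so no clipping occurs).
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    fx = np.fft.fftfreq(size)[None, :]
    fy = np.fft.fftfreq(size)[:, None]
    f = np.hypot(fx, fy)
    shaping = np.zeros_like(f)
    nonzero = f > 0
    shaping[nonzero] = 1.0 / f[nonzero]
    z = np.fft.ifft2(np.fft.fft2(white) * shaping).real
    z -= z.mean()
    z /= z.std()
    scale = (1.0 - mid_gray) / np.abs(z).max()
    return mid_gray + scale * z


def annular_window(spec: StimulusSpec) -> np.ndarray:
    """Annular window with raised-cosine edges, 1 in the flat zone, 0 outside.

    The cosinusoidal ramps of width ``edge_width`` lie inside the stated
    annulus bounds, so the window support is exactly
    ``[annulus_inner, annulus_outer]`` degrees (no inner ramp for a disk).
    The profile is C1 across the ramps.
    """
    rho = _eccentricity_grid(spec)
    e = spec.edge_width
    w = np.zeros_like(rho)
    inner, outer = spec.annulus_inner, spec.annulus_outer
    flat_lo = inner + e if inner > 0 else 0.0
    flat_hi = outer - e
    w[(rho >= flat_lo) & (rho <= flat_hi)] = 1.0
    if inner > 0:
        ramp = (rho >= inner) & (rho < flat_lo)
        w[ramp] = 0.5 * (1.0 - np.cos(np.pi * (rho[ramp] - inner) / e))
    ramp = (rho > flat_hi) & (rho <= outer)
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (rho[ramp] - flat_hi) / e))
    return w


def _degree_grids(spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.size
    coords = (np.arange(n) - (n - 1) / 2.0) / spec.pixels_per_degree
    x = coords[None, :]
    y = -coords[:, None]  # y upward
    return x, y


def _eccentricity_grid(spec: StimulusSpec) -> np.ndarray:
    x, y = _degree_grids(spec)
    return np.hypot(x, y)


def corrugation_map(spec: StimulusSpec) -> np.ndarray:
    """Windowed sinusoidal disparity corrugation in arcmin.

    A cosine of amplitude ``peak_to_trough/2`` with wave vector orthogonal to
    the tilt direction, multiplied by the annular window.  Warns (does not
    fail) when the annulus holds less than half a corrugation cycle -- the
    same geometric limit that makes central vision insensitive to the lowest
    corrugation frequencies.
    """
    span = spec.annulus_outer - spec.annulus_inner
    if spec.corrugation_frequency * span < 0.5:
        warnings.warn(
            f"annulus spans only {spec.corrugation_frequency * span:.2f} "
            "cycles (< 0.5) of the disparity corrugation", stacklevel=2)
    x, y = _degree_grids(spec)
    beta = np.deg2rad(spec.tilt - 90.0)  # wave-vector direction
    carrier = np.cos(
        2.0 * np.pi * spec.corrugation_frequency
        * (x * np.cos(beta) + y * np.sin(beta)) + spec.phase)
    amp = spec.peak_to_trough_disparity / 2.0
    return amp * carrier * annular_window(spec)


def render_stereo(noise: np.ndarray, disparity_map: np.ndarray,
                  spec: StimulusSpec) -> StereoPair:
    """Render a stereo pair by symmetric half-shifts of the noise carrier.

    Disparity ``d`` (arcmin, positive = crossed/near) places a feature at
    ``x + d/2`` in the left eye and ``x - d/2`` in the right eye, realized
    with cubic horizontal resampling.  The noise carrier is confined to the
    stimulus annulus (mid-gray outside), matching dichoptic presentation on
    a uniform gray background.
    """
    noise = np.asarray(noise, dtype=float)
    disparity_map = np.asarray(disparity_map, dtype=float)
    if noise.shape != disparity_map.shape:
        raise ValueError("noise and disparity map shapes differ")
    max_d = np.abs(disparity_map).max() / 60.0
    if max_d > MAX_DISPARITY_DEG:
        raise ValueError(
            f"|disparity| up to {max_d:.2f} deg exceeds the "
            f"{MAX_DISPARITY_DEG}-deg sanity bound")

    window = annular_window(spec)
    carrier = MID_GRAY + window * (noise - MID_GRAY)

    d_px = disparity_map * spec.pixels_per_degree / 60.0
    rows, cols = np.indices(noise.shape, dtype=float)
    left = ndimage.map_coordinates(carrier, [rows, cols - d_px / 2.0],
                                   order=3, mode="reflect")
    right = ndimage.map_coordinates(carrier, [rows, cols + d_px / 2.0],
                                    order=3, mode="reflect")
    return StereoPair(left=left, right=right,
                      ground_truth_disparity=disparity_map, spec=spec)


def make_stimulus(spec: StimulusSpec) -> StereoPair:
    """Generate the full stimulus for a spec: noise, corrugation, rendering."""
    noise = pink_noise(spec.size, spec.rng_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sub-cycle annuli are a valid probe
        dmap = corrugation_map(spec)
    return render_stereo(noise, dmap, spec)
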