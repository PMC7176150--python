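"""Cortical population model of binocular disparity: V1 binocular energy,
MT pooling, and linear population decoding of vector disparity.

The processing chain, applied to the log-polar (cortical) representations of
a stereo pair:

1. **V1 binocular simple cells** -- phase-shift model.  Left/right receptive
   fields are complex Gabors sharing a center but differing in phase by
   ``delta_psi``; the preferred cortical disparity of a channel is
   ``d = delta_psi / (2*pi*fs)`` with ``fs`` the radial peak frequency in
   cycles/cortical-pixel.  A binocular simple cell response is the sum of
   the two monocular convolutions; its quadrature partner uses the
   imaginary parts.
2. **Complex cells** -- binocular energy, the sum of squared quadrature
   responses, invariant to the absolute stimulus phase.
3. **Divisive normalization** -- a power-law nonlinearity (exponent 0.5)
   divided by the pooled response over orientations plus a small floor,
   which removes local-contrast confounds.  Uniform neural noise (a fixed
   fraction of the local average activity) is injected after
   normalization.
4. **MT cells** -- Gaussian spatial pooling of V1 afferents (wrap-around
   along the sector axis, since the cortex is topologically an annulus),
   cosine orientation weighting ``w_phi(theta) = cos(phi - theta)``, and an
   exponential output nonlinearity ``exp(lambda * s)``.  Two tuning
   directions (phi = 0, pi/2) suffice to encode the full disparity vector.
5. **Decoding** -- the disparity components are linear combinations of MT
   activity over the preferred-disparity channels,
   ``d_xi(p) = sum_i d_i * E_MT(p, 0, d_i)`` (and phi = pi/2 for d_eta).
   Because the exponential MT gain is not calibrated in absolute terms, a
   normalized (population-average) variant is available for magnitude
   recovery; the unnormalized printed form is scale-free and is what the
   tilt decision consumes.

Decoded cortical disparity is mapped back to retinal coordinates through
the inverse mapping's local Jacobian: a cortical displacement at node
``(xi, eta)`` corresponds to a retinal displacement scaled by
``rho0 * a**xi * ln(a)`` (radially) and ``rho0 * a**xi / q``
(tangentially), rotated by the polar angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage, signal

from .retino_cortical import (
    CorticalImage,
    MappingParams,
    cartesian_polar_grids,
    solve_rings,
    to_cortical,
    to_retinal,
)
from .stimulus import StereoPair

__all__ = [
    "GaborSpec",
    "V1PopulationSpec",
    "MTPopulationSpec",
    "PopulationResponse",
    "DisparityField",
    "gabor_kernel",
    "gabor_bank",
    "gabor_sigma_from_bandwidth",
    "gabor_bandwidth_from_sigma",
    "simple_cells",
    "complex_energy",
    "normalize_v1",
    "mt_response",
    "population_response",
    "annular_masks",
    "pool_annuli",
    "decode",
    "decoder_gain",
    "retinal_disparity_field",
    "tilt_decision",
    "disparity_range_arcmin",
    "make_model_mapping",
    "ModelObserver",
    "make_observer",
    "MODEL_VARIANTS",
    "REFERENCE_PIXELS_PER_DEGREE",
]

_TWO_PI = 2.0 * math.pi

#: Display resolution at which the reference geometry (rho0 = 9 px,
#: rho_max ~ 501 px for a 21-deg field) is expressed.
REFERENCE_PIXELS_PER_DEGREE = 501.0 / 21.0

#: Blind-spot radius of the reference geometry, in degrees.
RHO0_DEG = 9.0 / REFERENCE_PIXELS_PER_DEGREE

DEFAULT_CR = 6.4

MODEL_VARIANTS = ("LP", "LP2S", "noLP", "noLP2S")


# --------------------------------------------------------------------------
# Gabor receptive fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborSpec:
    """One cortical Gabor receptive field.

    ``theta`` is the carrier (wave-vector) direction in radians, ``sigma``
    the envelope scale in cortical pixels, ``fs`` the radial peak frequency
    in cycles/cortical-pixel, ``psi`` the carrier phase in radians.
    """

    theta: float
    sigma: float
    fs: float
    psi: float = 0.0


def gabor_sigma_from_bandwidth(fs: float, bandwidth_octaves: float) -> float:
    """Envelope sigma from the one-standard-deviation spectral cutoff.

    With the cutoff at one SD of the (Gaussian) amplitude spectrum, a
    filter of bandwidth ``B`` octaves satisfies
    ``sigma = (2**B + 1) / ((2**B - 1) * 2*pi*fs)``.
    """
    b = 2.0 ** bandwidth_octaves
    return (b + 1.0) / ((b - 1.0) * _TWO_PI * fs)


def gabor_bandwidth_from_sigma(fs: float, sigma: float) -> float:
    """Octave bandwidth implied by an envelope sigma (inverse relation)."""
    c = _TWO_PI * fs * sigma
    if c <= 1.0:
        raise ValueError("sigma too small for a band-pass filter at fs")
    return math.log2((c + 1.0) / (c - 1.0))


def gabor_kernel(spec: GaborSpec, support: int | None = None) -> np.ndarray:
    """Complex, zero-mean, unit-energy Gabor kernel on the cortical grid.

    The first axis is the ring (xi) direction, the second the sector (eta)
    direction.  Real and imaginary parts form a quadrature pair.  The DC
    response is removed by subtracting a scaled copy of the envelope, then
    the kernel is normalized to unit L2 energy.
    """
    if spec.sigma <= 0 or spec.fs <= 0:
        raise ValueError("sigma and fs must be positive")
    min_support = int(2 * math.ceil(3.0 * spec.sigma) + 1)
    if support is None:
        support = min_support
    elif support < min_support:
        import warnings

        warnings.warn(
            f"support {support} is below 6*sigma+1 = {min_support}; the "
            "kernel will be truncated", stacklevel=2)
    half = support // 2
    xi = np.arange(-half, half + 1, dtype=float)[:, None]
    eta = np.arange(-half, half + 1, dtype=float)[None, :]
    envelope = np.exp(-(xi**2 + eta**2) / (2.0 * spec.sigma**2))
    carrier = np.exp(1j * (_TWO_PI * spec.fs
                           * (math.cos(spec.theta) * xi
                              + math.sin(spec.theta) * eta)
                           + spec.psi))
    g = envelope * carrier
    g = g - envelope * (g.sum() / envelope.sum())  # exact zero DC
    return g / np.sqrt(np.sum(np.abs(g) ** 2))


def gabor_bank(specs) -> list[np.ndarray]:
    """Kernels for a list of :class:`GaborSpec`."""
    return [gabor_kernel(s) for s in specs]


# --------------------------------------------------------------------------
# Population specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class V1PopulationSpec:
    """V1 binocular-energy population parameters (defaults: full model).

    ``disparity_range`` is the maximum preferred cortical disparity D in
    cortical pixels; the K channels are symmetric,
    ``{-D, -D/2, 0, +D/2, +D}`` for K = 5, with binocular phase differences
    ``delta_psi = 2*pi*fs*d``.
    """

    n_orientations: int = 12
    n_channels: int = 5
    disparity_range: float = 1.52
    fs: float = 0.13
    sigma: float = 5.12
    exponent: float = 0.5
    epsilon: float = 1e-6
    noise_frac: float = 0.34

    def __post_init__(self) -> None:
        if self.n_channels % 2 == 0:
            raise ValueError("n_channels must be odd so that d = 0 is "
                             "represented")

    @property
    def thetas(self) -> np.ndarray:
        """Carrier directions, N samples over [0, 2*pi)."""
        return _TWO_PI * np.arange(self.n_orientations) / self.n_orientations

    @property
    def disparities(self) -> np.ndarray:
        """Preferred cortical disparities of the K channels (pixels)."""
        return np.linspace(-self.disparity_range, self.disparity_range,
                           self.n_channels)

    @property
    def delta_psis(self) -> np.ndarray:
        """Binocular phase differences of the K channels (radians)."""
        return _TWO_PI * self.fs * self.disparities

    @property
    def channel_spacing(self) -> float:
        return 2.0 * self.disparity_range / (self.n_channels - 1)


@dataclass(frozen=True)
class MTPopulationSpec:
    """MT pooling/readout parameters (defaults: full model)."""

    sigma_pool: float = 3.66
    lambda_gain: float = 0.65
    noise_frac: float = 0.18
    phis: tuple[float, ...] = (0.0, math.pi / 2.0)


@dataclass(frozen=True)
class PopulationResponse:
    """V1 and MT activity stacks over the cortical grid.

    ``v1`` has shape (K, N, R, S): disparity channel x orientation x grid.
    ``mt`` has shape (K, P, R, S): disparity channel x direction x grid.
    """

    v1: np.ndarray
    mt: np.ndarray
    mapping: MappingParams


@dataclass(frozen=True)
class DisparityField:
    """Decoded vector disparity in cortical and retinal coordinates.

    ``d_xi``/``d_eta`` are cortical components in cortical pixels (shape
    R x S); ``retinal_dx``/``retinal_dy`` are Cartesian components in
    arcmin (shape Nr x Nc), zero inside the blind spot and beyond the
    field radius.
    """

    d_xi: np.ndarray
    d_eta: np.ndarray
    retinal_dx: np.ndarray
    retinal_dy: np.ndarray
    mapping: MappingParams


# --------------------------------------------------------------------------
# V1 stage
# --------------------------------------------------------------------------

def _pad_cortical(values: np.ndarray, pad_xi: int, pad_eta: int
                  ) -> np.ndarray:
    """Mirror along rings, wrap along sectors (annular cortical topology)."""
    out = np.pad(values, ((pad_xi, pad_xi), (0, 0)), mode="reflect")
    return np.pad(out, ((0, 0), (pad_eta, pad_eta)), mode="wrap")


def _conv_bank(values: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Convolve one cortical image with a stack of kernels -> (n, R, S)."""
    kh, kw = kernels.shape[-2:]
    padded = _pad_cortical(values, kh // 2, kw // 2)
    return signal.fftconvolve(padded[None, :, :], kernels,
                              mode="valid", axes=(1, 2))


@lru_cache(maxsize=16)
def _monocular_kernels(v1: V1PopulationSpec) -> np.ndarray:
    """Zero-phase complex Gabors for all N orientations, stacked."""
    return np.stack([
        gabor_kernel(GaborSpec(theta=t, sigma=v1.sigma, fs=v1.fs))
        for t in v1.thetas
    ])


def simple_cells(left: CorticalImage, right: CorticalImage,
                 v1spec: V1PopulationSpec,
                 gabors: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Binocular simple-cell responses R and their quadrature partners R_q.

    Output shape (K, N, R, S).  The left/right receptive fields carry
    phases ``+delta_psi/2`` and ``-delta_psi/2``; since a Gabor phase
    offset factors out of the convolution, each eye is convolved once per
    orientation and the K phase-difference channels are formed by complex
    rotation.  Convolution mirrors along rings and wraps along sectors.
    """
    if left.mapping != right.mapping:
        raise ValueError("left/right cortical images use different mappings")
    kernels = _monocular_kernels(v1spec) if gabors is None else gabors
    c_left = _conv_bank(left.values, kernels)
    c_right = _conv_bank(right.values, kernels)
    half = v1spec.delta_psis[:, None, None, None] / 2.0
    binoc = (np.exp(1j * half) * c_left[None]
             + np.exp(-1j * half) * c_right[None])
    return binoc.real, binoc.imag


def complex_energy(resp: np.ndarray, resp_q: np.ndarray) -> np.ndarray:
    """Binocular energy of a quadrature pair, ``R**2 + R_q**2``."""
    if resp.shape != resp_q.shape:
        raise ValueError("quadrature responses must share a shape")
    return resp**2 + resp_q**2


def _add_activity_noise(activity: np.ndarray, frac: float,
                        rng: np.random.Generator,
                        axes: tuple[int, ...]) -> np.ndarray:
    """Zero-mean uniform noise, half-width = frac * local mean activity.

    The local average is taken over the tuning axes at each cortical
    location; activity is clipped at zero so rates stay nonnegative.
    """
    if frac <= 0.0:
        return activity
    half = frac * activity.mean(axis=axes, keepdims=True)
    noise = rng.uniform(-1.0, 1.0, size=activity.shape) * half
    return np.clip(activity + noise, 0.0, None)


def normalize_v1(energy: np.ndarray, v1spec: V1PopulationSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Divisive normalization of complex-cell energy across orientations.

    ``E_V1 = E**0.5 / (sum_theta E**0.5 + eps)``, applied per disparity
    channel and location; optional uniform neural noise follows.
    """
    e_pow = np.power(np.clip(energy, 0.0, None), v1spec.exponent)
    denom = e_pow.sum(axis=1, keepdims=True) + v1spec.epsilon
    e_v1 = e_pow / denom
    if rng is not None:
        e_v1 = _add_activity_noise(e_v1, v1spec.noise_frac, rng,
                                   axes=(0, 1))
    return e_v1


# --------------------------------------------------------------------------
# MT stage
# --------------------------------------------------------------------------

def mt_response(e_v1: np.ndarray, v1spec: V1PopulationSpec,
                mtspec: MTPopulationSpec,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """MT population response, shape (K, P, R, S).

    Gaussian spatial pooling of V1 afferents (reflect along rings, wrap
    along sectors), cosine orientation weighting, exponential output
    nonlinearity, optional uniform noise.
    """
    pooled = ndimage.gaussian_filter(
        e_v1, sigma=(0.0, 0.0, mtspec.sigma_pool, mtspec.sigma_pool),
        mode=("constant", "constant", "reflect", "wrap"))
    phis = np.asarray(mtspec.phis)
    weights = np.cos(phis[:, None] - v1spec.thetas[None, :])  # (P, N)
    s = mtspec.lambda_gain * np.einsum("pn,knrs->kprs", weights, pooled)
    e_mt = np.exp(s)
    if rng is not None:
        # Noise scales with the local average *driven* activity, i.e. the
        # modulation above the spontaneous rate F(0) = 1: unstimulated
        # regions of the visual field then exhibit no activity and no
        # noise, matching the localized responses to annular stimuli.
        half = mtspec.noise_frac * np.abs(e_mt - 1.0).mean(
            axis=(0, 1), keepdims=True)
        noise = rng.uniform(-1.0, 1.0, size=e_mt.shape) * half
        e_mt = np.clip(e_mt + noise, 0.0, None)
    return e_mt


def annular_masks(mapping: MappingParams, pixels_per_degree: float,
                  bounds_deg: tuple[float, ...] = (3.0, 9.0, 21.0)
                  ) -> list[np.ndarray]:
    """Boolean cortical masks for the foveal/mid/far annular regions.

    Ring centers at eccentricity ``rho0 * a**(u+1/2)`` are binned by the
    region bounds (degrees); the masks partition the full grid.
    """
    m = mapping
    u = np.arange(m.R, dtype=float)
    rho = m.rho0 * m.a ** (u + 0.5)
    edges_px = [0.0] + [b * pixels_per_degree for b in bounds_deg[:-1]]
    edges_px.append(np.inf)
    masks = []
    for lo, hi in zip(edges_px[:-1], edges_px[1:]):
        ring_sel = (rho >= lo) & (rho < hi)
        masks.append(np.repeat(ring_sel[:, None], m.S, axis=1))
    return masks


def pool_annuli(regional_responses, masks) -> np.ndarray:
    """Combine per-region MT responses into a full-field response.

    ``regional_responses`` is a sequence of identically shaped activity
    arrays (trailing dims R x S), one per region; ``masks`` the matching
    boolean cortical masks, which must be disjoint.  The combined response
    is the sum of the masked regional responses, so a full-field stimulus
    processed per region and recombined equals the unmasked computation.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(regional_responses) != len(masks):
        raise ValueError("one mask per regional response required")
    overlap = np.zeros_like(masks[0], dtype=int)
    for m in masks:
        overlap += m
    if np.any(overlap > 1):
        raise ValueError("region masks must be disjoint")
    out = np.zeros_like(np.asarray(regional_responses[0], dtype=float))
    for resp, m in zip(regional_responses, masks):
        out += np.asarray(resp, dtype=float) * m
    return out


# --------------------------------------------------------------------------
# Decoding
# --------------------------------------------------------------------------

def decode(e_mt: np.ndarray, v1spec: V1PopulationSpec,
           normalize: bool = False,
           gain: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Linear population decoding of the cortical disparity components.

    ``d_xi(p) = sum_i d_i * E_MT(p, phi=0, d_i)`` and likewise ``d_eta``
    with phi = pi/2.  The raw linear form is exactly homogeneous
    (``decode(alpha*E) = alpha*decode(E)``) but carries an arbitrary
    population gain; it is what the scale-free tilt decision consumes.
    For absolute magnitudes, divide by the calibrated population gain
    (see :func:`decoder_gain`) via ``gain``.  ``normalize=True`` instead
    divides by the summed population activity (a population-average
    read-out).
    """
    d = v1spec.disparities
    num_xi = np.einsum("k,krs->rs", d, e_mt[:, 0])
    num_eta = np.einsum("k,krs->rs", d, e_mt[:, 1])
    if normalize:
        den_xi = e_mt[:, 0].sum(axis=0) + 1e-12
        den_eta = e_mt[:, 1].sum(axis=0) + 1e-12
        return num_xi / den_xi, num_eta / den_eta
    return num_xi / gain, num_eta / gain


@lru_cache(maxsize=8)
def decoder_gain(v1spec: V1PopulationSpec, mtspec: MTPopulationSpec,
                 seed: int = 0) -> float:
    """Population gain of the linear MT read-out, from self-calibration.

    The raw linear decoder is proportional to the stimulus disparity but
    its slope depends on the population's tuning-curve modulation depth.
    The gain is measured once per population spec by probing the noiseless
    V1->MT stack with textured images carrying known uniform sub-range
    shifts and regressing the median decoded value on the true shift
    (through the origin).  Decoded maps divided by this gain are in
    cortical pixels.
    """
    from scipy import ndimage as _ndi

    rng = np.random.default_rng(seed)
    h, w = 96, 128
    shifts = (0.4 * v1spec.disparity_range, 0.8 * v1spec.disparity_range)
    num = den = 0.0
    for _ in range(2):
        base = _ndi.gaussian_filter(rng.standard_normal((h + 16, w)), 1.0)
        rows = np.arange(h, dtype=float) + 8.0
        cols = np.arange(w, dtype=float)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        for shift in shifts:
            left = _ndi.map_coordinates(base, [rr - shift / 2, cc], order=3)
            right = _ndi.map_coordinates(base, [rr + shift / 2, cc], order=3)
            resp, resp_q = simple_cells(_PlainImage(left),
                                        _PlainImage(right), v1spec)
            e_v1 = normalize_v1(complex_energy(resp, resp_q), v1spec)
            e_mt = mt_response(e_v1, v1spec, mtspec)
            dxi, _ = decode(e_mt, v1spec)
            med = float(np.median(dxi[12:-12, 12:-12]))
            num += med * shift
            den += shift * shift
    return num / den


def retinal_disparity_field(d_xi: np.ndarray, d_eta: np.ndarray,
                            mapping: MappingParams,
                            pixels_per_degree: float) -> DisparityField:
    """Back-map cortical disparity components to a retinal field (arcmin).

    Each cortical component is interpolated to the retinal plane with the
    inverse mapping, then rotated and scaled by the local inverse-mapping
    Jacobian: radial scale ``rho * ln(a)``, tangential scale ``rho / q``.
    """
    m = mapping
    interp_xi = to_retinal(d_xi, m, fill=0.0)
    interp_eta = to_retinal(d_eta, m, fill=0.0)
    rho, theta = cartesian_polar_grids(m)
    inside = (rho >= m.rho0) & (rho <= m.rho_max)
    ln_a = math.log(m.a)
    radial = rho * ln_a * interp_xi
    tangential = (rho / m.q) * interp_eta
    dx_px = radial * np.cos(theta) - tangential * np.sin(theta)
    dy_px = radial * np.sin(theta) + tangential * np.cos(theta)
    arcmin_per_px = 60.0 / pixels_per_degree
    dx = np.where(inside, dx_px * arcmin_per_px, 0.0)
    dy = np.where(inside, dy_px * arcmin_per_px, 0.0)
    return DisparityField(d_xi=d_xi, d_eta=d_eta, retinal_dx=dx,
                          retinal_dy=dy, mapping=m)


def tilt_evidence(disparity_map: np.ndarray, frequency_cpd: float,
                  pixels_per_degree: float,
                  aperture_deg: float) -> float:
    """Signed, background-normalized tilt evidence from one disparity map.

    Compares the Fourier power of the mean-subtracted map in small
    neighbourhoods of the two candidate corrugation wave vectors (at
    -45 deg for a 45-deg tilt, +45 deg for 135), normalized by the mean
    power of the surrounding frequency ring.  Positive values favour the
    45-deg tilt.  Spectral components that do not complete one full cycle
    across ``aperture_deg`` are discarded: a modulation slower than the
    aperture is indistinguishable from a uniform disparity pedestal and
    carries no tilt information, so an aperture smaller than the
    corrugation period yields zero evidence.  The ring normalization puts
    evidence from populations with different noise backgrounds on a
    common (roughly inverse-variance) scale, which is what lets evidence
    from several visual-field regions be summed near-optimally.
    """
    arr = np.asarray(disparity_map, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("disparity map must be finite")
    cutoff = 1.0 / aperture_deg
    if frequency_cpd < cutoff:
        return 0.0
    nr, nc = arr.shape
    power = np.abs(np.fft.fft2(arr - arr.mean())) ** 2
    fx = np.fft.fftfreq(nc)[None, :] * pixels_per_degree
    fy = -np.fft.fftfreq(nr)[:, None] * pixels_per_degree  # y upward
    radius = np.hypot(fx * np.ones((nr, 1)), fy * np.ones((1, nc)))
    resolvable = radius >= cutoff
    sigma_bin = 1.5 * pixels_per_degree / nc  # ~1.5 bins, in c/deg
    energies = {}
    for tilt, wave_angle in ((45.0, -math.pi / 4), (135.0, math.pi / 4)):
        kx = frequency_cpd * math.cos(wave_angle)
        ky = frequency_cpd * math.sin(wave_angle)
        e = 0.0
        for sx, sy in ((kx, ky), (-kx, -ky)):
            w = np.exp(-((fx - sx) ** 2 + (fy - sy) ** 2)
                       / (2.0 * sigma_bin**2))
            e += float((power * w * resolvable).sum())
        energies[tilt] = e
    ring = (resolvable & (radius >= frequency_cpd / math.sqrt(2.0))
            & (radius <= frequency_cpd * math.sqrt(2.0)))
    background = float(power[ring].mean()) if np.any(ring) else 0.0
    if background <= 0.0:
        return 0.0
    return (energies[45.0] - energies[135.0]) / background


def tilt_decision(disparity_map: np.ndarray, rng: np.random.Generator,
                  frequency_cpd: float | None = None,
                  pixels_per_degree: float | None = None,
                  aperture_deg: float | None = None) -> float:
    """Classify a corrugation's tilt (45 vs 135 deg) from its spectrum.

    The decision reads the position of the dominant peak of the Fourier
    magnitude of the mean-subtracted retinal disparity map.  In the 2AFC
    task the corrugation frequency and the stimulated aperture are known
    (conditions are blocked), so only two peak positions are consistent
    with the stimulus: the oblique wave vectors at -45 deg (a 45-deg
    tilt; with y upward its components satisfy fx*fy < 0) and at +45 deg
    (a 135-deg tilt, fx*fy > 0).  The decision compares the spectral
    power in small neighbourhoods of the two candidate (conjugate-pair)
    positions.

    Spectral components that do not complete at least one full cycle
    across the stimulated aperture are discarded first: a disparity
    modulation slower than the aperture is indistinguishable from a
    uniform disparity pedestal, which carries no tilt information.  This
    is what makes the lowest corrugation frequencies invisible to the
    small central field -- the foveal region simply cannot contain a
    full cycle -- while the same frequencies remain visible across the
    large peripheral annulus.

    Without a task frequency the rule falls back to the dominant oblique
    quadrant asymmetry across ~1-cycle radial bands (axis-aligned bins,
    which carry the radially symmetric window/mapping structure common
    to both tilts, are always excluded).  Ties and all-zero maps produce
    a seeded random guess, modelling guessing behaviour.
    """
    arr = np.asarray(disparity_map, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("disparity map must be finite")
    if frequency_cpd is not None:
        if pixels_per_degree is None or aperture_deg is None:
            raise ValueError("pixels_per_degree and aperture_deg are "
                             "required with frequency_cpd")
        evidence = tilt_evidence(arr, frequency_cpd, pixels_per_degree,
                                 aperture_deg)
        if evidence == 0.0:
            return float(rng.choice((45.0, 135.0)))
        return 45.0 if evidence > 0.0 else 135.0

    nr, nc = arr.shape
    power = np.abs(np.fft.fft2(arr - arr.mean())) ** 2
    fx = np.fft.fftfreq(nc)[None, :]
    fy = -np.fft.fftfreq(nr)[:, None]  # y axis points upward
    on_axis = (np.abs(fx) < 0.75 / nc) | (np.abs(fy) < 0.75 / nr)
    quadrant = np.where(on_axis, 0.0, np.sign(fx * fy))
    radius = np.hypot(fx * np.ones((nr, 1)), fy * np.ones((1, nc)))
    band = (radius * max(nr, nc)).astype(int)
    pos = np.bincount(band.ravel(), weights=(power * (quadrant > 0)).ravel())
    neg = np.bincount(band.ravel(), weights=(power * (quadrant < 0)).ravel())
    nbins = np.bincount(band.ravel(), weights=(quadrant != 0).ravel() * 1.0)
    total = pos + neg
    z = np.zeros_like(total)
    ok = total > 0
    z[ok] = (pos[ok] - neg[ok]) / total[ok] * np.sqrt(nbins[ok])
    best = int(np.argmax(np.abs(z)))
    if z[best] == 0.0:
        return float(rng.choice((45.0, 135.0)))
    return 135.0 if z[best] > 0 else 45.0


def population_response(left: CorticalImage, right: CorticalImage,
                        v1spec: V1PopulationSpec | None = None,
                        mtspec: MTPopulationSpec | None = None,
                        rng: np.random.Generator | None = None
                        ) -> PopulationResponse:
    """Run the V1 and MT stages on a cortical pair and return both stacks."""
    v1spec = v1spec if v1spec is not None else V1PopulationSpec()
    mtspec = mtspec if mtspec is not None else MTPopulationSpec()
    resp, resp_q = simple_cells(left, right, v1spec)
    e_v1 = normalize_v1(complex_energy(resp, resp_q), v1spec, rng)
    e_mt = mt_response(e_v1, v1spec, mtspec, rng)
    return PopulationResponse(v1=e_v1, mt=e_mt, mapping=left.mapping)


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def make_model_mapping(pixels_per_degree: float,
                       field_radius_deg: float = 21.0,
                       rho0_deg: float = RHO0_DEG,
                       cr: float = DEFAULT_CR) -> MappingParams:
    """Log-polar mapping realizing the reference geometry at any resolution.

    The geometry is fixed in degrees (blind-spot radius, field radius,
    compression ratio); the ring count is solved from the CR constraint, so
    lower-resolution instances are geometrically self-similar scale models
    of the full-resolution one (same cortical-pixel parameters).
    """
    rho_max = round(field_radius_deg * pixels_per_degree)
    rho0 = rho0_deg * pixels_per_degree
    return solve_rings(rho_max, rho0, cr)


def disparity_range_arcmin(mapping: MappingParams, d_cortical: float,
                           field_radius_deg: float = 21.0
                           ) -> tuple[float, float]:
    """Retinal disparity range (arcmin) at the foveal edge and periphery.

    A preferred cortical disparity ``d`` (cortical pixels) corresponds to a
    retinal displacement ``d * rho * ln(a)`` Cartesian pixels at
    eccentricity ``rho``; evaluated at ``rho0`` (foveal edge) and
    ``rho_max`` (periphery) and converted through the field radius.
    """
    m = mapping
    arcmin_per_px = field_radius_deg * 60.0 / m.rho_max
    ln_a = math.log(m.a)
    return (d_cortical * m.rho0 * ln_a * arcmin_per_px,
            d_cortical * m.rho_max * ln_a * arcmin_per_px)


# --------------------------------------------------------------------------
# Full observer pipelines (model variants)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelResponse:
    """Output of one model pass: decoded fields and the tilt decision."""

    field: DisparityField | None
    retinal_dx: np.ndarray
    retinal_dy: np.ndarray
    decision: float


class ModelObserver:
    """The foveated disparity pipeline run end-to-end as an observer.

    Variants:

    * ``LP`` (default) -- log-polar front end, single scale.
    * ``LP2S`` -- log-polar front end with a two-level cortical pyramid;
      decoded fields are merged coarse-to-fine by averaging.
    * ``noLP`` -- the log-polar stage replaced by uniform downsampling at a
      factor of sqrt(CR) (matching the pixel-count compression).
    * ``noLP2S`` -- uniform sampling with a two-level pyramid.
    """

    def __init__(self, pixels_per_degree: float,
                 field_radius_deg: float = 21.0,
                 mapping: MappingParams | None = None,
                 v1: V1PopulationSpec | None = None,
                 mt: MTPopulationSpec | None = None,
                 variant: str = "LP",
                 n_scales: int | None = None,
                 cr: float = DEFAULT_CR,
                 noisy: bool = True):
        if variant not in MODEL_VARIANTS:
            raise ValueError(
                f"unknown variant {variant!r}; choose from {MODEL_VARIANTS}")
        self.pixels_per_degree = float(pixels_per_degree)
        self.field_radius_deg = float(field_radius_deg)
        self.variant = variant
        self.n_scales = n_scales if n_scales is not None else (
            2 if variant.endswith("2S") else 1)
        self.v1 = v1 if v1 is not None else V1PopulationSpec()
        self.mt = mt if mt is not None else MTPopulationSpec()
        self.noisy = noisy
        self.cr = float(cr)
        if variant.startswith("noLP"):
            self.mapping = None
            self.downsample = math.sqrt(self.cr)
        else:
            self.mapping = mapping if mapping is not None else (
                make_model_mapping(pixels_per_degree, field_radius_deg,
                                   cr=cr))
            self.downsample = None

    # -- internals ---------------------------------------------------------

    def _stack(self, left: np.ndarray, right: np.ndarray,
               mapping_like, rng) -> tuple[np.ndarray, np.ndarray]:
        """V1+MT+decode on one (cortical or uniform) image pair."""
        if isinstance(mapping_like, MappingParams):
            lc = CorticalImage(left, mapping_like)
            rc = CorticalImage(right, mapping_like)
        else:
            lc = _PlainImage(left)
            rc = _PlainImage(right)
        resp, resp_q = simple_cells(lc, rc, self.v1)
        energy = complex_energy(resp, resp_q)
        e_v1 = normalize_v1(energy, self.v1, rng if self.noisy else None)
        e_mt = mt_response(e_v1, self.v1, self.mt,
                           rng if self.noisy else None)
        return decode(e_mt, self.v1)

    def respond(self, pair: StereoPair,
                rng: np.random.Generator) -> ModelResponse:
        """Process a stereo pair and return fields plus the tilt decision."""
        if self.mapping is not None:
            return self._respond_lp(pair, rng)
        return self._respond_uniform(pair, rng)

    def _respond_lp(self, pair, rng) -> ModelResponse:
        m = self.mapping
        left = to_cortical(pair.left, m).values
        right = to_cortical(pair.right, m).values
        fields = []
        for level in range(self.n_scales):
            f = 0.5 ** level
            if level == 0:
                lv, rv = left, right
            else:
                lv = ndimage.zoom(left, f, order=1, grid_mode=True,
                                  mode="grid-mirror")
                rv = ndimage.zoom(right, f, order=1, grid_mode=True,
                                  mode="grid-mirror")
            lvl_map = m if level == 0 else None
            dxi, deta = self._stack(lv, rv, lvl_map, rng)
            if level > 0:
                dxi = ndimage.zoom(dxi / f, left.shape[0] / dxi.shape[0],
                                   order=1) [:m.R, :m.S]
                deta = ndimage.zoom(deta / f, left.shape[0] / deta.shape[0],
                                    order=1)[:m.R, :m.S]
                dxi = _match_shape(dxi, (m.R, m.S))
                deta = _match_shape(deta, (m.R, m.S))
            fields.append((dxi, deta))
        d_xi = np.mean([f[0] for f in fields], axis=0)
        d_eta = np.mean([f[1] for f in fields], axis=0)
        fld = retinal_disparity_field(d_xi, d_eta, m,
                                      self.pixels_per_degree)

        # Cue combination across the visual field: the foveal, mid- and
        # far-peripheral MT populations are distinct; each contributes
        # background-normalized tilt evidence from its own annulus, and
        # the decision sums the evidence -- a near-optimal
        # (inverse-variance-weighted) combination.  A population only
        # contributes within its representable band: corrugations slower
        # than its aperture (one cycle across 2*outer) or finer than its
        # V1 passband at its best (innermost) eccentricity carry no
        # information for it, only noise.  The masks partition the
        # cortex, so the summed regional fields equal the full map.
        freq = pair.spec.corrugation_frequency
        masks = annular_masks(m, self.pixels_per_degree)
        ln_a = math.log(m.a)
        passband_hi = self.v1.fs + 1.0 / (_TWO_PI * self.v1.sigma)
        evidence = 0.0
        for mask, inner_deg, outer_deg in zip(masks, (0.0, 3.0, 9.0),
                                              (3.0, 9.0, 21.0)):
            rho_inner = max(inner_deg * self.pixels_per_degree, m.rho0)
            f_hi = (passband_hi * self.pixels_per_degree
                    / (rho_inner * ln_a))
            if freq > f_hi:
                continue
            sub = retinal_disparity_field(d_xi * mask, d_eta * mask, m,
                                          self.pixels_per_degree)
            evidence += tilt_evidence(sub.retinal_dx, freq,
                                      self.pixels_per_degree,
                                      aperture_deg=2.0 * outer_deg)
        if evidence == 0.0:
            decision = float(rng.choice((45.0, 135.0)))
        else:
            decision = 45.0 if evidence > 0.0 else 135.0
        return ModelResponse(field=fld, retinal_dx=fld.retinal_dx,
                             retinal_dy=fld.retinal_dy, decision=decision)

    def _respond_uniform(self, pair, rng) -> ModelResponse:
        factor = self.downsample
        left = ndimage.zoom(pair.left, 1.0 / factor, order=1)
        right = ndimage.zoom(pair.right, 1.0 / factor, order=1)
        fields = []
        for level in range(self.n_scales):
            f = 0.5 ** level
            if level == 0:
                lv, rv = left, right
            else:
                lv = ndimage.zoom(left, f, order=1)
                rv = ndimage.zoom(right, f, order=1)
            # decode's components follow array axes: first = rows
            # (y downward), second = columns (x rightward)
            d_row, d_col = self._stack(lv, rv, None, rng)
            if level > 0:
                d_row = _match_shape(
                    ndimage.zoom(d_row / f, left.shape[0] / d_row.shape[0],
                                 order=1), left.shape)
                d_col = _match_shape(
                    ndimage.zoom(d_col / f, left.shape[0] / d_col.shape[0],
                                 order=1), left.shape)
            fields.append((d_row, d_col))
        d_row = np.mean([f[0] for f in fields], axis=0)
        d_col = np.mean([f[1] for f in fields], axis=0)
        arcmin_per_sample = 60.0 * factor / self.pixels_per_degree
        retinal_dx = d_col * arcmin_per_sample
        retinal_dy = -d_row * arcmin_per_sample
        decision = tilt_decision(
            retinal_dx, rng,
            frequency_cpd=pair.spec.corrugation_frequency,
            pixels_per_degree=self.pixels_per_degree / factor,
            aperture_deg=2.0 * pair.spec.annulus_outer)
        return ModelResponse(field=None, retinal_dx=retinal_dx,
                             retinal_dy=retinal_dy, decision=decision)


class _PlainImage:
    """Duck-typed stand-in for CorticalImage in the uniform (noLP) variant."""

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)
        self.mapping = None


def _match_shape(arr: np.ndarray, shape) -> np.ndarray:
    out = arr
    pad = [(0, max(0, s - o)) for s, o in zip(shape, out.shape)]
    if any(p[1] for p in pad):
        out = np.pad(out, pad, mode="edge")
    return out[tuple(slice(0, s) for s in shape)]


def make_observer(variant: str = "LP", pixels_per_degree: float = 6.0,
                  field_radius_deg: float = 21.0,
                  cr: float = DEFAULT_CR,
                  rf_scale: float = 1.0,
                  noise_scale: float = 1.0,
                  **kwargs) -> ModelObserver:
    """Factory for model variants with sweep-friendly overrides.

    ``cr`` rebuilds the log-polar geometry at a different compression
    ratio; ``rf_scale`` scales the cortical receptive-field size (Gabor
    sigma up, peak frequency down, preserving octave bandwidth, which also
    rescales the preferred-disparity range, as the phase-shift limit is
    set by fs); ``noise_scale`` multiplies both neural noise fractions.
    """
    aliases = {"LP": "LP", "LP+scales": "LP2S", "LP2S": "LP2S",
               "noLP": "noLP", "noLP/2S": "noLP2S", "noLP2S": "noLP2S"}
    if variant not in aliases:
        raise ValueError(f"unknown variant {variant!r}")
    v1 = kwargs.pop("v1", V1PopulationSpec())
    mt = kwargs.pop("mt", MTPopulationSpec())
    if rf_scale != 1.0:
        v1 = replace(v1, sigma=v1.sigma * rf_scale, fs=v1.fs / rf_scale,
                     disparity_range=v1.disparity_range * rf_scale)
    if noise_scale != 1.0:
        v1 = replace(v1, noise_frac=v1.noise_frac * noise_scale)
        mt = replace(mt, noise_frac=mt.noise_frac * noise_scale)
    return ModelObserver(pixels_per_degree=pixels_per_degree,
                         field_radius_deg=field_radius_deg,
                         variant=aliases[variant], v1=v1, mt=mt, cr=cr,
                         **kwargs)
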