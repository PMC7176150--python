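"""Discrete log-polar retino-cortical mapping (central blind-spot model).

The projection from retina to primary visual cortex is space-variant: the
fovea is over-represented and resolution falls off roughly logarithmically
with eccentricity.  This module implements the *central blind-spot* log-polar
model of that projection,

    xi  = log_a(rho / rho0),        eta = q * theta,

where ``(rho, theta)`` are retinal polar coordinates, ``rho0`` is the radius
of a small central disk that is discarded to avoid the log singularity,
``a`` controls the non-linearity of the mapping and ``q = S / (2*pi)`` sets
the angular resolution.  Discretizing ``(xi, eta)`` on an ``R x S``
(rings x sectors) grid yields the *cortical image*.  Each cortical node has a
circular Gaussian receptive field in the retinal plane whose size grows
linearly with eccentricity, so a uniform filtering operation on the cortex
corresponds to a space-variant, multi-scale operation on the retina.

Key derived quantities:

* compression ratio ``CR = (Nc * Nr) / (R * S)`` -- the Cartesian-to-cortical
  pixel-count ratio, a proxy for the strength of cortical magnification;
* maximum receptive-field size ``Wmax = rho0 * a**R * (1 - 1/a)`` -- the
  retinal scale at which the periphery is processed;
* foveal fraction ``chi = (1 - log_a(rho0*(a-1))) / R`` -- the fraction of
  cortical rings that over-sample the retina (log-polar pixels smaller than
  Cartesian pixels).

Sectors are tied to rings by the isotropy rule: the local circular sampling
interval ``(2*pi/S) * rho0 * a**(u-1)`` must equal the radial interval
``rho0 * a**(u-1) * (a-1)``, hence ``S = round(2*pi / (a - 1))``, which makes
the log-polar pixel aspect ratio as close to 1 as possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, sparse

__all__ = [
    "MappingParams",
    "CorticalImage",
    "ReceptiveFieldTable",
    "make_mapping",
    "mapping_from_geometry",
    "isotropy_sectors",
    "solve_rings",
    "solve_field_radius",
    "to_cortical",
    "to_retinal",
    "rf_table",
    "node_centers",
    "cartesian_polar_grids",
]

_TWO_PI = 2.0 * math.pi

#: Minimum Gaussian receptive-field sigma (Cartesian pixels) in the
#: oversampled fovea, where the nominal log-polar pixel width drops below
#: one Cartesian pixel.
MIN_RF_SIGMA = 0.5

#: Receptive fields are truncated at this many standard deviations.
RF_TRUNCATE = 3.0


class InvalidGeometryError(ValueError):
    """Raised when log-polar mapping parameters are geometrically impossible."""


@dataclass(frozen=True)
class MappingParams:
    """Full parameterization of a discrete log-polar grid.

    Attributes
    ----------
    R, S : int
        Ring and sector counts of the cortical image.
    rho0 : float
        Blind-spot radius in Cartesian pixels.
    rho_max : float
        Field radius in Cartesian pixels (``0.5 * min(Nc, Nr)``).
    a : float
        Radial growth base, ``a = (rho_max / rho0)**(1/R)``.
    q : float
        Angular resolution, ``S / (2*pi)``.
    Nc, Nr : float
        Cartesian image width and height in pixels.
    CR : float
        Compression ratio ``Nc*Nr / (R*S)``.
    Wmax : float
        Maximum receptive-field size, ``rho0 * a**R * (1 - 1/a)``.
    chi : float
        Fraction of cortical rings representing the (oversampled) fovea.
    """

    R: int
    S: int
    rho0: float
    rho_max: float
    a: float
    q: float
    Nc: float
    Nr: float
    CR: float
    Wmax: float
    chi: float

    def __post_init__(self) -> None:
        if self.R < 2 or self.S < 2:
            raise ValueError("ring and sector counts must be >= 2")
        if not (0.0 < self.rho0 < self.rho_max):
            raise InvalidGeometryError(
                f"need 0 < rho0 < rho_max, got rho0={self.rho0}, "
                f"rho_max={self.rho_max}"
            )


def isotropy_sectors(a: float) -> int:
    """Sector count that equates circular and radial sampling intervals."""
    if a <= 1.0:
        raise InvalidGeometryError("growth base a must exceed 1")
    return int(round(_TWO_PI / (a - 1.0)))


def _finish_mapping(Nc: float, Nr: float, R: int, rho0: float,
                    rho_max: float, S: int | None) -> MappingParams:
    a = (rho_max / rho0) ** (1.0 / R)
    if S is None:
        S = isotropy_sectors(a)
    q = S / _TWO_PI
    cr = (Nc * Nr) / (R * S)
    wmax = rho0 * a**R * (1.0 - 1.0 / a)
    # chi: ring index where the local log-polar pixel width reaches one
    # Cartesian pixel, from Wmax(u) = rho0 * a**u * (1 - 1/a) = 1.
    chi = (1.0 - math.log(rho0 * (a - 1.0)) / math.log(a)) / R
    return MappingParams(R=int(R), S=int(S), rho0=float(rho0),
                         rho_max=float(rho_max), a=float(a), q=float(q),
                         Nc=float(Nc), Nr=float(Nr), CR=float(cr),
                         Wmax=float(wmax), chi=float(chi))


def make_mapping(Nc: int, Nr: int, R: int, rho0: float,
                 S: int | None = None) -> MappingParams:
    """Construct a consistent log-polar mapping for an ``Nc x Nr`` image.

    ``rho_max = 0.5 * min(Nc, Nr)`` (exact value, also on odd dimensions);
    ``S`` defaults to the isotropy rule.
    """
    for name, n in (("Nc", Nc), ("Nr", Nr), ("R", R)):
        if int(n) != n or n <= 0:
            raise ValueError(f"{name} must be a positive integer, got {n!r}")
    if Nc < 2 or Nr < 2 or R < 2:
        raise ValueError("need Nc, Nr >= 2 and R >= 2")
    rho_max = 0.5 * min(Nc, Nr)
    if not (0.0 < rho0 < rho_max):
        raise InvalidGeometryError(
            f"need 0 < rho0 < rho_max={rho_max}, got rho0={rho0}")
    return _finish_mapping(float(Nc), float(Nr), int(R), float(rho0),
                           rho_max, S)


def mapping_from_geometry(rho_max: float, rho0: float, R: int,
                          S: int | None = None) -> MappingParams:
    """Mapping for a square field of radius ``rho_max`` (``Nc = Nr = 2*rho_max``).

    Accepts non-integer ``rho_max``; useful for analytic work where the field
    radius is derived from a compression-ratio constraint.
    """
    if not (0.0 < rho0 < rho_max):
        raise InvalidGeometryError(
            f"need 0 < rho0 < rho_max, got rho0={rho0}, rho_max={rho_max}")
    return _finish_mapping(2.0 * rho_max, 2.0 * rho_max, int(R),
                           float(rho0), float(rho_max), S)


def solve_rings(rho_max: float, rho0: float, cr: float) -> MappingParams:
    """Find the ring count whose isotropic mapping best matches a target CR.

    Solves ``CR = 4*rho_max**2 / (R * S(R))`` over integer ``R`` with ``S``
    given by the isotropy rule, for a square field of radius ``rho_max``.
    """
    # continuous seed: S ~ 2*pi*R / ln(rho_max/rho0)
    lnr = math.log(rho_max / rho0)
    r_seed = math.sqrt(4.0 * rho_max**2 * lnr / (cr * _TWO_PI))
    best = None
    for R in range(max(2, int(r_seed) - 4), int(r_seed) + 6):
        m = mapping_from_geometry(rho_max, rho0, R)
        err = abs(m.CR - cr)
        if best is None or err < best[0]:
            best = (err, m)
    return best[1]


def solve_field_radius(R: int, rho0: float, cr: float) -> float:
    """Field radius consistent with (R, rho0, CR) on a square image.

    Solves ``CR = 4*rho_max**2 * (a-1) / (2*pi*R)`` with
    ``a = (rho_max/rho0)**(1/R)`` (continuous sector count) for ``rho_max``.
    """

    def f(log_rho_max: float) -> float:
        rho_max = math.exp(log_rho_max)
        a = (rho_max / rho0) ** (1.0 / R)
        s = _TWO_PI / (a - 1.0)
        return 4.0 * rho_max**2 / (R * s) - cr

    lo, hi = math.log(rho0 * 1.01), math.log(rho0 * 1e4)
    return math.exp(optimize.brentq(f, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class CorticalImage:
    """A 2-D activity array on the R x S cortical grid.

    The first axis indexes rings ``u`` (eccentricity), the second sectors
    ``v`` (polar angle); the sector axis is periodic.
    """

    values: np.ndarray
    mapping: MappingParams

    def __post_init__(self) -> None:
        expected = (self.mapping.R, self.mapping.S)
        if self.values.shape != expected:
            raise ValueError(
                f"cortical image shape {self.values.shape} does not match "
                f"mapping grid {expected}")


@dataclass(frozen=True)
class ReceptiveFieldTable:
    """Per-node receptive-field centers and Gaussian radii (Cartesian px).

    ``x`` and ``y`` use a centered frame (origin at image center, y upward);
    ``sigma`` is the Gaussian standard deviation, half the local log-polar
    pixel width, floored at :data:`MIN_RF_SIGMA` in the oversampled fovea.
    All arrays have shape ``(R, S)``.
    """

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    mapping: MappingParams


def node_centers(mapping: MappingParams) -> tuple[np.ndarray, np.ndarray]:
    """Receptive-field centers ``(x, y)`` obtained by inverting the mapping.

    Node ``(u, v)`` sits at ring center ``rho = rho0 * a**(u + 1/2)`` and
    sector center ``theta = (v + 1/2) / q``.
    """
    m = mapping
    u = np.arange(m.R, dtype=float)[:, None]
    v = np.arange(m.S, dtype=float)[None, :]
    rho = m.rho0 * m.a ** (u + 0.5)
    theta = (v + 0.5) / m.q
    return rho * np.cos(theta), rho * np.sin(theta)


def rf_table(mapping: MappingParams) -> ReceptiveFieldTable:
    """Receptive-field table of the mapping (one entry per cortical node)."""
    m = mapping
    x, y = node_centers(m)
    u = np.arange(m.R, dtype=float)[:, None]
    sigma = np.maximum(MIN_RF_SIGMA, m.rho0 * m.a**u * (m.a - 1.0) / 2.0)
    sigma = np.broadcast_to(sigma, (m.R, m.S)).copy()
    return ReceptiveFieldTable(x=x, y=y, sigma=sigma, mapping=m)


def cartesian_polar_grids(mapping: MappingParams
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel polar coordinates ``(rho, theta)`` of the Cartesian image.

    Origin at the image center; x rightward, y upward;
    ``theta = atan2(y, x) mod 2*pi``.
    """
    m = mapping
    nr, nc = int(round(m.Nr)), int(round(m.Nc))
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    x = cols - (nc - 1) / 2.0
    y = (nr - 1) / 2.0 - rows
    rho = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), _TWO_PI)
    return rho, theta


def _node_centers_array_coords(mapping: MappingParams
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Node centers as (row, col) float indices into the Cartesian array."""
    m = mapping
    nr, nc = int(round(m.Nr)), int(round(m.Nc))
    x, y = node_centers(m)
    col = x + (nc - 1) / 2.0
    row = (nr - 1) / 2.0 - y
    return row, col


@lru_cache(maxsize=8)
def _forward_operator(mapping: MappingParams) -> sparse.csr_matrix:
    """Sparse (R*S) x (Nr*Nc) Gaussian receptive-field averaging operator.

    Row ``u*S + v`` holds the normalized Gaussian weights of node ``(u, v)``
    over Cartesian pixels, truncated at RF_TRUNCATE sigma; pixels inside the
    blind spot carry zero weight.
    """
    m = mapping
    nr, nc = int(round(m.Nr)), int(round(m.Nc))
    rho_pix, _ = cartesian_polar_grids(m)
    blind = rho_pix < m.rho0
    crow, ccol = _node_centers_array_coords(m)
    tab = rf_table(m)

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    col_index = np.arange(nr * nc).reshape(nr, nc)

    for u in range(m.R):
        sig = float(tab.sigma[u, 0])
        hw = max(1, int(math.ceil(RF_TRUNCATE * sig)))
        inv2s2 = 1.0 / (2.0 * sig * sig)
        for v in range(m.S):
            cr, cc = crow[u, v], ccol[u, v]
            r0 = max(0, int(math.floor(cr)) - hw)
            r1 = min(nr, int(math.ceil(cr)) + hw + 1)
            c0 = max(0, int(math.floor(cc)) - hw)
            c1 = min(nc, int(math.ceil(cc)) + hw + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            dr = np.arange(r0, r1, dtype=float)[:, None] - cr
            dc = np.arange(c0, c1, dtype=float)[None, :] - cc
            w = np.exp(-(dr * dr + dc * dc) * inv2s2)
            w[blind[r0:r1, c0:c1]] = 0.0
            total = w.sum()
            if total <= 0.0:
                continue
            w = (w / total).ravel()
            keep = w > 0.0
            vals_out.append(w[keep])
            cols_out.append(col_index[r0:r1, c0:c1].ravel()[keep])
            rows_out.append(np.full(int(keep.sum()), u * m.S + v))

    mat = sparse.coo_matrix(
        (np.concatenate(vals_out),
         (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(m.R * m.S, nr * nc))
    return mat.tocsr()


def to_cortical(image: np.ndarray, mapping: MappingParams) -> CorticalImage:
    """Forward (retina -> cortex) transform of a grayscale image.

    Each cortical node's value is the Gaussian-receptive-field-weighted
    average of Cartesian pixels around its center; pixels inside the blind
    spot (``rho < rho0``) contribute to no node.
    """
    m = mapping
    nr, nc = int(round(m.Nr)), int(round(m.Nc))
    image = np.asarray(image, dtype=float)
    if image.shape != (nr, nc):
        raise ValueError(
            f"image shape {image.shape} does not match mapping "
            f"({nr}, {nc})")
    flat = _forward_operator(m) @ image.ravel()
    return CorticalImage(values=flat.reshape(m.R, m.S), mapping=m)


@lru_cache(maxsize=8)
def _backward_operator(mapping: MappingParams
                       ) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Bilinear (Nr*Nc) x (R*S) interpolation operator and its outside mask.

    Interpolation is bilinear in ``(xi, eta)`` with circular wrap along the
    sector axis and clamping along the ring axis.  Pixels in the blind spot
    or beyond ``rho_max`` are flagged in the mask and receive a fill value.
    """
    m = mapping
    nr, nc = int(round(m.Nr)), int(round(m.Nc))
    rho, theta = cartesian_polar_grids(m)
    outside = (rho < m.rho0) | (rho > m.rho_max)
    valid = ~outside

    xi = np.zeros_like(rho)
    xi[valid] = np.log(rho[valid] / m.rho0) / math.log(m.a)
    eta = m.q * theta

    t = np.clip(xi - 0.5, 0.0, m.R - 1.0)
    u0 = np.clip(np.floor(t).astype(int), 0, m.R - 1)
    u1 = np.minimum(u0 + 1, m.R - 1)
    fu = t - u0

    s = eta - 0.5
    v0 = np.floor(s).astype(int) % m.S
    v1 = (v0 + 1) % m.S
    fv = np.mod(s, 1.0)

    pix = np.flatnonzero(valid.ravel())
    u0f, u1f = u0.ravel()[pix], u1.ravel()[pix]
    v0f, v1f = v0.ravel()[pix], v1.ravel()[pix]
    fuf, fvf = fu.ravel()[pix], fv.ravel()[pix]

    rows = np.concatenate([pix] * 4)
    cols = np.concatenate([u0f * m.S + v0f, u0f * m.S + v1f,
                           u1f * m.S + v0f, u1f * m.S + v1f])
    vals = np.concatenate([(1 - fuf) * (1 - fvf), (1 - fuf) * fvf,
                           fuf * (1 - fvf), fuf * fvf])
    mat = sparse.coo_matrix((vals, (rows, cols)),
                            shape=(nr * nc, m.R * m.S)).tocsr()
    return mat, outside


def to_retinal(cortical: CorticalImage | np.ndarray,
               mapping: MappingParams | None = None,
               fill: float | None = None) -> np.ndarray:
    """Backward (cortex -> retina) transform.

    Returns an ``Nr x Nc`` Cartesian array; the blind spot and the region
    beyond ``rho_max`` are filled with ``fill`` (default: the mean cortical
    activity).  Used for visualization and for mapping decoded disparity
    components back to retinal coordinates.
    """
    if isinstance(cortical, CorticalImage):
        values, m = cortical.values, cortical.mapping
    else:
        if mapping is None:
            raise ValueError("mapping required when passing a bare array")
        values, m = np.asarray(cortical, dtype=float), mapping
        if values.shape != (m.R, m.S):
            raise ValueError(
                f"cortical shape {values.shape} != ({m.R}, {m.S})")
    nr, nc = int(round(m.Nr)), int(round(m.Nc))
    mat, outside = _backward_operator(m)
    out = (mat @ values.ravel()).reshape(nr, nc)
    out[outside] = float(np.mean(values)) if fill is None else float(fill)
    return out
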