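"""Polar resampling of the segmented myocardium.

Each segmented ring is resampled onto a uniform (radius-fraction x angle)
grid whose origin sits at the mask's centre of mass.  Because every image
uses its *own* mask centroid, a global translation of the heart moves the
origin with it and the polar image is unchanged — registration happens
implicitly, with no intensity-based alignment step.

Conventions (fixed here, used by both directions of the transform):
  * angle 0° along the +x image axis (increasing column), increasing
    counter-clockwise in (row, col) array space, 1° spacing, 360 rays;
  * radial sample m of C spans endo (m=0) to epi (m=C-1) inclusive, where
    the endo/epi radii are the mask's half-level crossings pulled half a
    pixel inward (so bilinear image samples at the endpoints do not average
    in blood-pool or background intensities across the discrete edge);
  * all subpixel sampling is bilinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PolarImage",
    "CartesianT1Map",
    "center_of_mass",
    "ray_boundaries",
    "to_polar",
    "from_polar",
    "DEFAULT_C",
    "DEFAULT_N_RAYS",
]

DEFAULT_C = 20        # samples per ray; exceeds the max wall thickness (15 px)
DEFAULT_N_RAYS = 360


@dataclass
class PolarImage:
    """Myocardium intensities on the polar grid, shape (C, n_rays).

    ``endo_radius``/``epi_radius`` are the mask's half-level crossings (the
    anatomical boundaries, used for wall thickness); ``sample_endo`` /
    ``sample_epi`` are the half-pixel-inset radii the C samples actually
    span, shared by the forward and inverse transforms.
    """

    values: np.ndarray        # float (C, n_rays)
    origin: tuple[float, float]
    endo_radius: np.ndarray   # float (n_rays,), px; NaN on invalid rays
    epi_radius: np.ndarray    # float (n_rays,), px
    valid_rays: np.ndarray    # bool (n_rays,)
    sample_endo: np.ndarray | None = None
    sample_epi: np.ndarray | None = None

    def __post_init__(self):
        if self.sample_endo is None:
            self.sample_endo = self.endo_radius
        if self.sample_epi is None:
            self.sample_epi = self.epi_radius

    @property
    def C(self) -> int:
        return self.values.shape[0]

    @property
    def n_rays(self) -> int:
        return self.values.shape[1]


@dataclass
class CartesianT1Map:
    """Per-pixel T1 (ms) on the reference image grid."""

    values: np.ndarray        # float (H, W); NaN outside support
    support: np.ndarray       # bool (H, W)
    reference_ti: float | None = None


def center_of_mass(mask: np.ndarray) -> tuple[float, float]:
    """Unweighted centroid (row, col) of the foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("center of mass of an empty mask is undefined")
    cy, cx = ndimage.center_of_mass(mask)
    return float(cy), float(cx)


def _ray_profile(mask_f: np.ndarray, origin, angle_rad: float,
                 r_max: float, step: float = 0.25):
    """Bilinear mask values sampled along one ray; returns (radii, values)."""
    radii = np.arange(0.0, r_max, step)
    oy, ox = origin
    rows = oy + radii * np.sin(angle_rad)
    cols = ox + radii * np.cos(angle_rad)
    vals = ndimage.map_coordinates(mask_f, [rows, cols], order=1,
                                   mode="constant", cval=0.0)
    return radii, vals


def ray_boundaries(mask: np.ndarray, origin, angle_deg: float,
                   step: float = 0.25):
    """Endo/epi radii where the ray at ``angle_deg`` crosses the myocardium.

    The innermost contiguous foreground run is taken (the myocardium is the
    ring nearest the cavity; specks or outer structures farther out are
    ignored).  Returns ``(endo_radius, epi_radius)`` or ``None`` if the ray
    never crosses the mask.
    """
    mask_f = np.asarray(mask, dtype=float)
    h, w = mask_f.shape
    r_max = float(np.hypot(h, w))
    radii, vals = _ray_profile(mask_f, origin, np.deg2rad(angle_deg), r_max, step)
    inside = vals >= 0.5
    if not inside.any():
        return None
    # first contiguous run of inside samples
    idx = np.flatnonzero(inside)
    run_end = idx[0]
    for j in idx:
        if j - run_end > 1:
            break
        run_end = j
    endo = _subpixel_crossing(radii, vals, idx[0], -1)
    epi = _subpixel_crossing(radii, vals, run_end, +1)
    return endo, epi


def _subpixel_crossing(radii, vals, i, direction):
    """Linear-interpolated radius of the 0.5 level next to sample ``i``.

    ``direction`` -1 looks at the sample before i (entering the mask),
    +1 at the sample after (leaving it).
    """
    j = i + direction
    if j < 0 or j >= len(vals) or vals[j] >= 0.5:
        return float(radii[i])
    v_in, v_out = vals[i], vals[j]
    t = (v_in - 0.5) / (v_in - v_out)       # fraction towards the outside
    return float(radii[i] + direction * t * abs(radii[j] - radii[i]))


def _inset(endo: float, epi: float, margin: float = 0.5):
    """Pull both boundaries inward, at most a quarter of the wall each."""
    d = min(margin, (epi - endo) / 4.0)
    return endo + d, epi - d


def _all_ray_boundaries(mask: np.ndarray, origin, n_rays: int, step: float = 0.25):
    """Vectorized ray_boundaries over all rays."""
    mask_f = np.asarray(mask, dtype=float)
    h, w = mask_f.shape
    r_max = float(np.hypot(h, w)) / 2.0 + 2.0
    radii = np.arange(0.0, r_max, step)
    angles = np.deg2rad(np.arange(n_rays) * (360.0 / n_rays))
    oy, ox = origin
    rows = oy + radii[None, :] * np.sin(angles)[:, None]   # (n_rays, n_r)
    cols = ox + radii[None, :] * np.cos(angles)[:, None]
    vals = ndimage.map_coordinates(mask_f, [rows.ravel(), cols.ravel()],
                                   order=1, mode="constant", cval=0.0)
    inside_vals = vals.reshape(n_rays, -1)
    inside = inside_vals >= 0.5

    endo = np.full(n_rays, np.nan)
    epi = np.full(n_rays, np.nan)
    valid = np.zeros(n_rays, dtype=bool)
    for i in range(n_rays):
        idx = np.flatnonzero(inside[i])
        if idx.size == 0:
            continue
        # end of first contiguous run
        breaks = np.flatnonzero(np.diff(idx) > 1)
        last = idx[breaks[0]] if breaks.size else idx[-1]
        endo[i] = _subpixel_crossing(radii, inside_vals[i], idx[0], -1)
        epi[i] = _subpixel_crossing(radii, inside_vals[i], last, +1)
        valid[i] = True
    return endo, epi, valid


def to_polar(image: np.ndarray, mask: np.ndarray, C: int = DEFAULT_C,
             n_rays: int = DEFAULT_N_RAYS,
             origin: tuple[float, float] | None = None) -> PolarImage:
    """Resample the segmented myocardium onto a C x n_rays polar grid.

    For each ray with a myocardium crossing, C intensities are sampled
    uniformly in radius between the endo and epi boundaries (both endpoints
    included), bilinearly interpolated from ``image``.  Rays without a
    crossing are flagged invalid and carry NaN.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot polar-transform an empty mask")
    if origin is None:
        origin = center_of_mass(mask)
    endo, epi, valid = _all_ray_boundaries(mask, origin, n_rays)
    s_endo = np.full_like(endo, np.nan)
    s_epi = np.full_like(epi, np.nan)
    if valid.any():
        ins = np.array([_inset(e, p) for e, p in zip(endo[valid], epi[valid])])
        s_endo[valid] = ins[:, 0]
        s_epi[valid] = ins[:, 1]

    values = np.full((C, n_rays), np.nan)
    if valid.any():
        frac = np.linspace(0.0, 1.0, C)                       # (C,)
        r = s_endo[valid][None, :] \
            + frac[:, None] * (s_epi[valid] - s_endo[valid])[None, :]
        ang = np.deg2rad(np.flatnonzero(valid) * (360.0 / n_rays))
        oy, ox = origin
        rows = oy + r * np.sin(ang)[None, :]
        cols = ox + r * np.cos(ang)[None, :]
        vals = ndimage.map_coordinates(image, [rows.ravel(), cols.ravel()],
                                       order=1, mode="constant", cval=0.0)
        values[:, valid] = vals.reshape(C, -1)

    return PolarImage(values=values, origin=origin, endo_radius=endo,
                      epi_radius=epi, valid_rays=valid,
                      sample_endo=s_endo, sample_epi=s_epi)


def from_polar(polar_values: np.ndarray, geometry: PolarImage,
               reference_mask: np.ndarray,
               reference_ti: float | None = None) -> CartesianT1Map:
    """Inverse polar transform onto the reference mask's grid.

    Each foreground pixel of ``reference_mask`` is converted to (angle,
    radius) about the geometry's origin, its radial position normalized by
    that angle's endo/epi boundaries, and the value bilinearly interpolated
    from ``polar_values`` with angular wrap-around.  Pixels mapping to
    invalid rays (or radially outside the ring) are excluded from support.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("empty reference mask")
    C, n_rays = polar_values.shape
    oy, ox = geometry.origin
    ys, xs = np.nonzero(reference_mask)
    dy = ys - oy
    dx = xs - ox
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    rad = np.hypot(dy, dx)

    ray_pos = ang / (360.0 / n_rays)                # fractional ray index
    i0 = np.floor(ray_pos).astype(int) % n_rays
    i1 = (i0 + 1) % n_rays
    w1 = ray_pos - np.floor(ray_pos)

    # sampling boundaries interpolated over angle (wrapped)
    endo = geometry.sample_endo
    epi = geometry.sample_epi
    ok = geometry.valid_rays[i0] & geometry.valid_rays[i1]
    e0, e1 = endo[i0], endo[i1]
    p0, p1 = epi[i0], epi[i1]
    endo_i = (1 - w1) * e0 + w1 * e1
    epi_i = (1 - w1) * p0 + w1 * p1
    thick = epi_i - endo_i
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (rad - endo_i) / np.where(thick > 0, thick, np.nan)
    # pixels radially outside the sampled band would extrapolate: excluded
    ok &= np.isfinite(frac) & (frac >= -0.02) & (frac <= 1.02)
    frac = np.clip(frac, 0.0, 1.0)

    m = frac * (C - 1)
    m0 = np.floor(m).astype(int)
    m1 = np.minimum(m0 + 1, C - 1)
    wm = m - m0

    def gather(mi, ri):
        return polar_values[np.clip(mi, 0, C - 1), ri]

    v = ((1 - wm) * (1 - w1) * gather(m0, i0)
         + (1 - wm) * w1 * gather(m0, i1)
         + wm * (1 - w1) * gather(m1, i0)
         + wm * w1 * gather(m1, i1))
    ok &= np.isfinite(v)

    out = np.full(reference_mask.shape, np.nan)
    support = np.zeros(reference_mask.shape, dtype=bool)
    out[ys[ok], xs[ok]] = v[ok]
    support[ys[ok], xs[ok]] = True
    return CartesianT1Map(values=out, support=support, reference_ti=reference_ti)
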