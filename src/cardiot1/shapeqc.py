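"""Segmentation post-processing and shape quality control.

A plausible short-axis myocardium is a single annulus: Euler number 0
(one object, one hole) and low eccentricity.  Raw segmentations are first
area-filtered, then assessed; improper masks are refined by affinely aligning
the longest-inversion-time mask (the most reliable one, thanks to its high
myocardium-to-blood contrast) onto them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage import measure
from skimage.transform import SimilarityTransform, warp

__all__ = [
    "ShapeVerdict",
    "RefinementResult",
    "area_filter",
    "euler_number",
    "eccentricity",
    "assess_shape",
    "refine",
    "DEFAULT_ECCENTRICITY_MAX",
    "DEFAULT_AREA_MIN_MM2",
    "DEFAULT_PIXEL_SPACING",
]

DEFAULT_ECCENTRICITY_MAX = 0.65
DEFAULT_AREA_MIN_MM2 = 500.0      # 5 cm^2
DEFAULT_PIXEL_SPACING = 2.1       # mm, used when metadata is absent


@dataclass(frozen=True)
class ShapeVerdict:
    euler: int | None
    eccentricity: float | None
    proper: bool
    reason: str  # "ok" | "bad_euler" | "bad_eccentricity" | "empty"


@dataclass
class RefinementResult:
    mask: np.ndarray | None
    translation: tuple[float, float]   # (dy, dx) px
    rotation: float                    # degrees
    scale: float
    overlap: float                     # Dice of refined mask vs the raw mask
    applied: bool


def area_filter(mask: np.ndarray, pixel_spacing: float = DEFAULT_PIXEL_SPACING,
                area_min_mm2: float = DEFAULT_AREA_MIN_MM2) -> np.ndarray:
    """Drop connected components with physical area below 5 cm², then keep
    only the largest survivor.  May return an empty mask."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())[1:]  # px per component
    areas_mm2 = counts * pixel_spacing ** 2
    keep = np.flatnonzero(areas_mm2 >= area_min_mm2) + 1
    if keep.size == 0:
        return np.zeros_like(mask)
    largest = keep[np.argmax(counts[keep - 1])]
    return labels == largest


def euler_number(mask: np.ndarray) -> int:
    """Connected components minus holes, 8-connected foreground
    (4-connected holes by duality).  0 for an annulus, 1 for a disk."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    return int(measure.euler_number(mask, connectivity=2))


def eccentricity(mask: np.ndarray) -> float:
    """Eccentricity of the ellipse with the same normalized second central
    moments as the foreground: 0 for a circle, 1 for a line segment."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("eccentricity of an empty mask is undefined")
    # All foreground pixels as one region, regardless of connectivity.
    props = measure.regionprops(mask.astype(np.uint8))[0]
    return float(props.eccentricity)


def assess_shape(mask: np.ndarray,
                 eccentricity_max: float = DEFAULT_ECCENTRICITY_MAX) -> ShapeVerdict:
    """Anatomical-plausibility verdict: proper iff non-empty, Euler number 0
    and eccentricity within bound."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return ShapeVerdict(euler=None, eccentricity=None, proper=False, reason="empty")
    eu = euler_number(mask)
    ecc = eccentricity(mask)
    if eu != 0:
        return ShapeVerdict(euler=eu, eccentricity=ecc, proper=False, reason="bad_euler")
    if ecc > eccentricity_max:
        return ShapeVerdict(euler=eu, eccentricity=ecc, proper=False,
                            reason="bad_eccentricity")
    return ShapeVerdict(euler=eu, eccentricity=ecc, proper=True, reason="ok")


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    if s == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / s


def _transform_mask(mask: np.ndarray, rotation_deg: float, scale: float,
                    dy: float = 0.0, dx: float = 0.0) -> np.ndarray:
    """Rotate/scale about the mask centroid, then translate."""
    cy, cx = ndimage.center_of_mass(mask)
    # skimage transforms use (x, y) order
    t = (SimilarityTransform(translation=(-cx, -cy))
         + SimilarityTransform(rotation=np.deg2rad(rotation_deg), scale=scale)
         + SimilarityTransform(translation=(cx + dx, cy + dy)))
    out = warp(mask.astype(float), t.inverse, order=1, preserve_range=True)
    return out >= 0.5


def refine(mask_k: np.ndarray, mask_inf: np.ndarray,
           max_shift: int = 10, rot_range: float = 15.0, rot_step: float = 3.0,
           scale_range: tuple[float, float] = (0.9, 1.1), scale_step: float = 0.05,
           eccentricity_max: float = DEFAULT_ECCENTRICITY_MAX) -> RefinementResult:
    """Refine an improper mask by affine-aligning the longest-TI mask onto it.

    Searches translation (±``max_shift`` px), rotation (±``rot_range``°) and
    isotropic scale over a coarse grid, maximizing Dice overlap with
    ``mask_k``; the identity is always a candidate, so the result never
    underperforms the untransformed ``mask_inf``.  If ``mask_inf`` is itself
    improper no refinement is possible and the caller must exclude the image
    (``applied=False``).

    Translation is searched exhaustively per (rotation, scale) via FFT
    cross-correlation: the correlation of two binary images at a shift is
    exactly their intersection area there.
    """
    mask_k = np.asarray(mask_k, dtype=bool)
    mask_inf = np.asarray(mask_inf, dtype=bool)
    if not mask_inf.any() or not assess_shape(mask_inf, eccentricity_max).proper:
        return RefinementResult(mask=None, translation=(0.0, 0.0), rotation=0.0,
                                scale=1.0, overlap=0.0, applied=False)

    nk = float(mask_k.sum())
    fk = mask_k.astype(float)

    def search(rotations, scales, shift_budget):
        best = (-1.0, 0.0, 0.0, (0, 0))   # dice, rot, scale, (dy, dx)
        for rot in rotations:
            for sc in scales:
                cand = _transform_mask(mask_inf, rot, sc)
                corr = fftconvolve(fk, cand[::-1, ::-1].astype(float),
                                   mode="same")
                h, w = corr.shape
                cy0, cx0 = h // 2, w // 2
                win = corr[cy0 - shift_budget: cy0 + shift_budget + 1,
                           cx0 - shift_budget: cx0 + shift_budget + 1]
                inter = np.round(win)
                dice_win = 2.0 * inter / max(nk + cand.sum(), 1)
                idx = np.unravel_index(np.argmax(dice_win), dice_win.shape)
                d = float(dice_win[idx])
                if d > best[0]:
                    dy = idx[0] - shift_budget
                    dx = idx[1] - shift_budget
                    best = (d, float(rot), float(sc), (int(dy), int(dx)))
        return best

    coarse_rot = np.arange(-rot_range, rot_range + rot_step / 2, rot_step)
    coarse_sc = np.arange(scale_range[0], scale_range[1] + scale_step / 2,
                          scale_step)
    best = search(coarse_rot, coarse_sc, max_shift)
    # local refinement between coarse grid nodes
    fine_rot = best[1] + np.linspace(-rot_step / 2, rot_step / 2, 5)
    fine_sc = np.clip(best[2] + np.linspace(-scale_step / 2, scale_step / 2, 5),
                      scale_range[0], scale_range[1])
    fine = search(fine_rot, np.unique(fine_sc), max_shift)
    if fine[0] > best[0]:
        best = fine

    # identity candidate guards against grid artefacts
    d_id = _dice(mask_k, mask_inf)
    if d_id >= best[0]:
        best = (d_id, 0.0, 1.0, (0, 0))

    d, rot, sc, (dy, dx) = best
    refined = (mask_inf if (rot == 0 and sc == 1 and dy == 0 and dx == 0)
               else _transform_mask(mask_inf, rot, sc, dy, dx))
    return RefinementResult(mask=refined, translation=(float(dy), float(dx)),
                            rotation=rot, scale=sc,
                            overlap=_dice(mask_k, refined), applied=True)


def segmentation_successful(verdict: ShapeVerdict) -> bool:
    """An image's segmentation counts as successful iff a proper-shaped mask
    resulted, whether or not refinement was applied."""
    return verdict.proper
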