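"""End-to-end orchestration of the T1-mapping workflow.

Per slice: normalize → segment → area filter → shape assessment →
refine-or-exclude → polar transform → pixel-wise fitting (≥ 8 images) →
inverse transform onto the shortest-TI reference → prune → summarize.
Slices that fail reconstruction are reported, never fatal; a patient fails
only when no slice reconstructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import math

import numpy as np

from . import shapeqc, polar, t1fit
from .io import T1wStack
from .polar import CartesianT1Map
from .t1fit import SliceRejected, T1Summary

__all__ = [
    "RunConfig",
    "StudyLayout",
    "TruthMaskSegmenter",
    "PatientResult",
    "SliceResult",
    "process_slice",
    "run_patient",
]


@dataclass
class RunConfig:
    """Pipeline constants; defaults are the published protocol values."""

    C: int = 20
    n_rays: int = 360
    min_images: int = 8
    accept_range: tuple[float, float] = (850.0, 1500.0)
    eccentricity_max: float = 0.65
    area_min_mm2: float = 500.0        # 5 cm^2
    prune_fraction: float = 1.0 / 3.0
    pixel_spacing: float = 2.1         # mm fallback
    max_invalid_rays: int = 90         # slice flagged unreliable beyond this
    seed: int = 0

    def config_hash(self) -> str:
        d = asdict(self)
        d["accept_range"] = list(d["accept_range"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyLayout:
    """Locations of one patient's data on disk (five slices expected)."""

    patient_id: str
    stack_paths: list[str]
    fmt: str = "nifti"
    mask_dir: str | None = None


class TruthMaskSegmenter:
    """Segmenter stub that returns provided ground-truth masks.

    Decouples pipeline validation from network training quality: any object
    with ``predict(image) -> bool mask`` plugs into :func:`process_slice`,
    this one ignores the image and replays known masks in order.
    """

    def __init__(self, masks: list[np.ndarray]):
        self._masks = [np.asarray(m, dtype=bool) for m in masks]
        self._i = 0

    def predict(self, image: np.ndarray) -> np.ndarray:
        m = self._masks[self._i % len(self._masks)]
        self._i += 1
        return m

    def reset(self) -> None:
        self._i = 0


@dataclass
class SliceResult:
    reconstructed: bool
    t1_map: CartesianT1Map | None
    pruned_mask: np.ndarray | None
    qc: list[dict]
    reason: str = ""
    unreliable: bool = False


@dataclass
class PatientResult:
    patient_id: str
    slices: list[SliceResult]
    summary: T1Summary | None
    failed: bool
    provenance: dict = field(default_factory=dict)


def _qc_record(ti, verdict, refined, excluded):
    return {
        "ti": None if math.isinf(ti) else ti,
        "euler": verdict.euler,
        "eccentricity": verdict.eccentricity,
        "proper": verdict.proper,
        "refined": refined,
        "excluded": excluded,
    }


def process_slice(stack: T1wStack, segmenter, config: RunConfig) -> SliceResult:
    """Run one slice through segmentation, QC, polar fitting and pruning."""
    stack = stack.sorted_by_ti()
    spacing = stack.pixel_spacing or config.pixel_spacing
    K = stack.images.shape[0]

    raw = [np.asarray(segmenter.predict(stack.images[k]), dtype=bool)
           for k in range(K)]
    filtered = [shapeqc.area_filter(m, spacing, config.area_min_mm2)
                for m in raw]
    verdicts = [shapeqc.assess_shape(m, config.eccentricity_max)
                for m in filtered]

    # reference for refinement: the longest (infinite) TI image
    inf_idx = int(np.argmax([1 if math.isinf(t) else 0 for t in stack.tis])) \
        if any(math.isinf(t) for t in stack.tis) else K - 1
    mask_inf = filtered[inf_idx]
    inf_proper = verdicts[inf_idx].proper

    final_masks: list[np.ndarray | None] = []
    qc = []
    for k in range(K):
        v = verdicts[k]
        refined = False
        excluded = False
        mask = filtered[k]
        if not v.proper:
            # an empty segmentation leaves nothing to align the reference
            # to; refinement would just copy the longest-TI mask verbatim
            if v.reason == "empty":
                excluded = True
            elif inf_proper and k != inf_idx:
                res = shapeqc.refine(mask, mask_inf,
                                     eccentricity_max=config.eccentricity_max)
                if res.applied:
                    re_v = shapeqc.assess_shape(res.mask, config.eccentricity_max)
                    if re_v.proper:
                        mask, v, refined = res.mask, re_v, True
                    else:
                        excluded = True
                else:
                    excluded = True
            else:
                excluded = True
        final_masks.append(None if excluded else mask)
        qc.append(_qc_record(stack.tis[k], v, refined, excluded))

    kept = [(k, m) for k, m in enumerate(final_masks) if m is not None]
    if len(kept) < config.min_images:
        return SliceResult(reconstructed=False, t1_map=None, pruned_mask=None,
                           qc=qc, reason=f"only {len(kept)} successfully "
                           f"segmented images (need {config.min_images})")

    polars, tis_kept = [], []
    for k, m in kept:
        p = polar.to_polar(stack.images[k], m, C=config.C, n_rays=config.n_rays)
        polars.append(p)
        tis_kept.append(stack.tis[k])
    unreliable = any((~p.valid_rays).sum() > config.max_invalid_rays
                     for p in polars)

    try:
        pmap = t1fit.reconstruct_map(polars, tis_kept,
                                     min_images=config.min_images)
    except SliceRejected as e:
        return SliceResult(reconstructed=False, t1_map=None, pruned_mask=None,
                           qc=qc, reason=str(e), unreliable=unreliable)

    # inverse transform onto the shortest-TI reference image's mask
    finite = [i for i, (k, _) in enumerate(kept)
              if not math.isinf(stack.tis[kept[i][0]])]
    ref_i = min(finite, key=lambda i: stack.tis[kept[i][0]]) if finite else 0
    ref_mask = kept[ref_i][1]
    ref_geom = polars[ref_i]
    cart = polar.from_polar(pmap.values, ref_geom, ref_mask,
                            reference_ti=stack.tis[kept[ref_i][0]])

    wall = t1fit.mean_wall_thickness(ref_geom)
    pruned = t1fit.prune_mask(ref_mask, wall, config.prune_fraction)
    return SliceResult(reconstructed=True, t1_map=cart, pruned_mask=pruned,
                       qc=qc, unreliable=unreliable)


def run_patient(stacks: list[T1wStack], segmenter, config: RunConfig,
                patient_id: str = "anon") -> PatientResult:
    """Process every slice of one patient and summarize global/regional T1.

    ``stacks`` are in-memory slice stacks (use :mod:`cardiot1.io` readers to
    build them from a :class:`StudyLayout`).  Inputs are never mutated.
    """
    results = [process_slice(s, segmenter, config) for s in stacks]
    ok = [r for r in results if r.reconstructed]
    provenance = {"config_hash": config.config_hash(),
                  "n_slices": len(stacks),
                  "n_reconstructed": len(ok)}
    if not ok:
        return PatientResult(patient_id=patient_id, slices=results,
                             summary=None, failed=True, provenance=provenance)
    try:
        summary = t1fit.summarize_t1([r.t1_map for r in ok],
                                     [r.pruned_mask for r in ok],
                                     accept_range=config.accept_range)
    except ValueError:
        return PatientResult(patient_id=patient_id, slices=results,
                             summary=None, failed=True, provenance=provenance)
    return PatientResult(patient_id=patient_id, slices=results,
                         summary=summary, failed=False, provenance=provenance)
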