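"""Pooled-healthy-reference pneumothorax detection on tidal images.

A case's tidal image is normalized to unit sum, compared pixelwise against
the pooled mean/SD of healthy controls, and the resulting
ventilation-deficit z-map is thresholded; the largest sufficiently large
connected component is flagged and localized to a lung segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "HealthyReference",
    "DetectionResult",
    "SD_FLOOR",
    "Z_THRESHOLD_DEFAULT",
    "MIN_AREA_DEFAULT",
    "build_reference",
    "deviation_map",
    "detect_ptx",
    "localize_segment",
]

SD_FLOOR = 1e-6
#: Relative SD floor: pixels with SD below this fraction of the median
#: in-mask SD are floored, so near-deterministic pixels (mask edge, heart
#: shadow) cannot dominate the z-map.
SD_FLOOR_FRAC_DEFAULT = 0.5
Z_THRESHOLD_DEFAULT = 2.5
MIN_AREA_DEFAULT = 8

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class HealthyReference:
    """Pixelwise mean/SD of unit-sum-normalized healthy tidal images."""

    mean_image: np.ndarray
    sd_image: np.ndarray
    mask: np.ndarray
    n_subjects: int
    normalization: str = "unit-sum"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a reference needs at least 2 subjects")
        if np.any(self.sd_image < 0):
            raise ValueError("sd_image must be nonnegative")


@dataclass(frozen=True)
class DetectionResult:
    is_positive: bool
    deviation_map: np.ndarray  # z-score image, ventilation deficit positive
    region_mask: np.ndarray
    segment_id: Optional[int]
    score: float  # max z within the flagged region (nan if negative)
    area_pixels: int

    def to_dict(self) -> Dict:
        return {
            "is_positive": bool(self.is_positive),
            "segment_id": None if self.segment_id is None else int(self.segment_id),
            "score": None if np.isnan(self.score) else float(self.score),
            "area_pixels": int(self.area_pixels),
        }


def _normalize(tidal: np.ndarray, mask: np.ndarray) -> np.ndarray:
    total = tidal[mask].sum()
    if total <= 0:
        raise ValueError("tidal image must have positive total over the mask")
    out = np.zeros_like(tidal, dtype=float)
    out[mask] = tidal[mask] / total
    return out


def build_reference(
    tidal_images: Sequence[np.ndarray],
    mask: np.ndarray,
    sd_floor_frac: float = SD_FLOOR_FRAC_DEFAULT,
) -> HealthyReference:
    """Pool unit-sum-normalized healthy tidal images into a pixelwise
    mean/SD reference.

    SD is floored at ``max(SD_FLOOR, sd_floor_frac * median in-mask SD)``.
    """
    if len(tidal_images) < 2:
        raise ValueError("need at least 2 healthy cases")
    normed = np.stack([_normalize(t, mask) for t in tidal_images])
    mean = normed.mean(axis=0)
    sd = normed.std(axis=0, ddof=1)
    floor = max(SD_FLOOR, sd_floor_frac * float(np.median(sd[mask])))
    sd[mask] = np.maximum(sd[mask], floor)
    sd[~mask] = 0.0
    mean[~mask] = 0.0
    return HealthyReference(mean_image=mean, sd_image=sd, mask=mask, n_subjects=len(tidal_images))


def deviation_map(tidal: np.ndarray, reference: HealthyReference) -> np.ndarray:
    """Ventilation-deficit z-map: (healthy mean - normalized tidal) / SD."""
    normed = _normalize(tidal, reference.mask)
    z = np.zeros_like(normed)
    m = reference.mask
    z[m] = (reference.mean_image[m] - normed[m]) / reference.sd_image[m]
    return z


def detect_ptx(
    tidal: np.ndarray,
    reference: HealthyReference,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    min_area_pixels: int = MIN_AREA_DEFAULT,
    segment_labels: Optional[np.ndarray] = None,
) -> DetectionResult:
    """Threshold the deviation map and report the largest connected
    suspicious region (8-connectivity), if any survives the area gate."""
    if z_threshold <= 0 or min_area_pixels <= 0:
        raise ValueError("thresholds must be > 0")
    z = deviation_map(tidal, reference)
    hot = (z > z_threshold) & reference.mask
    lab, n = ndimage.label(hot, structure=_EIGHT_CONN)
    best_mask = np.zeros_like(hot)
    best_area = 0
    for comp in range(1, n + 1):
        m = lab == comp
        area = int(m.sum())
        if area >= min_area_pixels and area > best_area:
            best_area = area
            best_mask = m
    if best_area == 0:
        return DetectionResult(
            is_positive=False,
            deviation_map=z,
            region_mask=np.zeros_like(hot),
            segment_id=None,
            score=float("nan"),
            area_pixels=0,
        )
    seg = None
    if segment_labels is not None:
        seg = localize_segment(best_mask, segment_labels)
    return DetectionResult(
        is_positive=True,
        deviation_map=z,
        region_mask=best_mask,
        segment_id=seg,
        score=float(z[best_mask].max()),
        area_pixels=best_area,
    )


def localize_segment(region_mask: np.ndarray, segment_labels: np.ndarray) -> int:
    """Segment with the largest overlap with the region; ties go to the lower
    id; regions with no lung overlap map to the nearest segment by centroid."""
    if not region_mask.any():
        raise ValueError("region is empty")
    overlap = segment_labels[region_mask]
    overlap = overlap[overlap > 0]
    if overlap.size:
        counts = np.bincount(overlap)
        return int(counts.argmax())  # argmax returns the lowest index on ties
    centroid = np.argwhere(region_mask).mean(axis=0)
    best, best_d = 0, np.inf
    for seg in np.unique(segment_labels[segment_labels > 0]):
        c = np.argwhere(segment_labels == seg).mean(axis=0)
        d = float(np.hypot(*(c - centroid)))
        if d < best_d:
            best, best_d = int(seg), d
    if best == 0:
        raise ValueError("segment map has no lung labels")
    return best
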