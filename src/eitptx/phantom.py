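"""Synthetic pig-thorax conductivity phantoms with pleural air lesions.

Coordinate convention (used throughout the package): arrays are indexed
``[row, col]``; row 0 is ventral, the image is viewed from caudal, and the
animal's right side is on the image left (low column indices).

The phantom is a 2D elliptical cross-section with two lung fields, a
ventromedial accessory lobe, and a ventral-medial heart.  Lesions are
low-conductivity air pockets placed against the pleural (outer) lung
boundary; their craniocaudal (out-of-plane) extent enters the 2D plane only
through a partial-volume weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "ThoraxPhantom",
    "PTXLesion",
    "RelevanceLabel",
    "DynamicsConfig",
    "CaseTruth",
    "ConductivitySeries",
    "LesionFitError",
    "build_phantom",
    "segment_map",
    "segment_adjacency",
    "place_lesion",
    "classify_relevance",
    "partial_volume_weight",
    "conductivity_series",
    "case_truth",
    "ANTERIOR_SEGMENTS",
    "ACCESSORY_SEGMENT",
]

#: Segments lying in the ventral half of the thorax; 6 is the accessory lobe.
ANTERIOR_SEGMENTS = frozenset({2, 3, 5, 6})
ACCESSORY_SEGMENT = 6


class LesionFitError(ValueError):
    """Raised when a requested lesion does not fit its host segment."""


@dataclass(frozen=True)
class ThoraxPhantom:
    grid_shape: Tuple[int, int]
    pixel_size: float  # cm per pixel
    body_mask: np.ndarray
    lung_masks: Dict[str, np.ndarray]  # keys: right, left, accessory
    heart_mask: np.ndarray
    sternovertebral_distance: float  # cm, ventral-dorsal extent of body_mask
    background_conductivity: float
    lung_conductivity_expiration: float
    heart_conductivity: float

    @property
    def lung_mask(self) -> np.ndarray:
        """Union of all lung regions."""
        out = np.zeros(self.grid_shape, dtype=bool)
        for m in self.lung_masks.values():
            out |= m
        return out

    @property
    def body_center(self) -> Tuple[float, float]:
        rr, cc = np.nonzero(self.body_mask)
        return float(rr.mean()), float(cc.mean())


@dataclass(frozen=True)
class RelevanceLabel:
    is_trans20: bool
    is_cc3: bool

    @property
    def is_transcc(self) -> bool:
        return self.is_trans20 and self.is_cc3

    @property
    def is_relevant(self) -> bool:
        return self.is_trans20 or self.is_cc3


@dataclass(frozen=True)
class PTXLesion:
    segment_id: int
    center: Tuple[float, float]  # (row, col) in grid coordinates
    transversal_diameter: float  # cm, measured max in-plane diameter
    craniocaudal_extent: float  # cm
    in_plane_mask: np.ndarray
    conductivity: float = 0.10  # S/m, effective in-slab value of the air pocket

    def __post_init__(self) -> None:
        if not 1 <= self.segment_id <= 10:
            raise ValueError(f"segment_id must be in 1..10, got {self.segment_id}")
        if self.transversal_diameter <= 0:
            raise ValueError("transversal_diameter must be > 0")
        if self.craniocaudal_extent < 0:
            raise ValueError("craniocaudal_extent must be >= 0")


@dataclass(frozen=True)
class DynamicsConfig:
    frame_rate: float = 50.0  # Hz
    duration: float = 180.0  # s
    respiratory_rate: float = 20.0  # breaths/min
    tidal_modulation: float = 0.3  # fractional lung conductivity swing
    heart_rate: float = 90.0  # beats/min
    spike_enabled: bool = False
    spike_magnitude: float = 1.0  # fractional transient conductivity rise
    lesion_ventilation_fraction: float = 0.0
    lesion_phase_lag: float = 0.0  # radians
    noise_sd_frac: float = 0.01  # Gaussian SD as fraction of background
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not 0.0 <= self.lesion_ventilation_fraction <= 1.0:
            raise ValueError("lesion_ventilation_fraction must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


@dataclass(frozen=True)
class CaseTruth:
    lesions: List[PTXLesion]
    labels: List[RelevanceLabel]
    largest_relevant_segment: Optional[int]
    quadrant_labels: Set[str]
    heart_contact: bool


@dataclass(frozen=True)
class ConductivitySeries:
    fields: np.ndarray  # (n_frames, H, W)
    frame_rate: float
    spike_frames: List[int]  # onset frame of each injected cardiac transient
    seed: int


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center_rc, semi_rc) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center_rc[0]) / semi_rc[0]) ** 2 + (
        (cc - center_rc[1]) / semi_rc[1]
    ) ** 2 <= 1.0


# Organ layout in normalized body coordinates: u along columns, v along rows,
# both in [-1, 1] over the body ellipse; v < 0 is ventral.
_ORGANS = {
    "heart": {"center": (-0.28, 0.0), "semi": (0.26, 0.30)},
    "right": {"center": (0.12, -0.42), "semi": (0.52, 0.40)},
    "left": {"center": (0.12, 0.42), "semi": (0.52, 0.40)},
    "accessory": {"center": (-0.55, 0.05), "semi": (0.18, 0.22)},
}


def build_phantom(
    grid_shape: Tuple[int, int] | int = (64, 64),
    pixel_size: float = 0.5,
    body_axes_px: Tuple[float, float] = (56.0, 44.0),
    background_conductivity: float = 0.30,
    lung_conductivity_expiration: float = 0.15,
    heart_conductivity: float = 0.50,
    seed: int = 0,
) -> ThoraxPhantom:
    """Build a deterministic thorax phantom.

    ``body_axes_px`` is (full transverse width, full ventral-dorsal height) of
    the body ellipse in pixels; the sternovertebral distance is the realized
    ventral-dorsal extent of the rasterized body mask times ``pixel_size``.
    ``seed`` is accepted for interface symmetry; the geometry is deterministic.
    """
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape, grid_shape)
    if grid_shape[0] < 32 or grid_shape[1] < 32:
        raise ValueError("grid_shape must be >= 32 per axis")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    for name, v in (
        ("background_conductivity", background_conductivity),
        ("lung_conductivity_expiration", lung_conductivity_expiration),
        ("heart_conductivity", heart_conductivity),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    w_px, h_px = body_axes_px
    if w_px <= 0 or h_px <= 0:
        raise ValueError("body axes must be positive")
    if w_px > grid_shape[1] or h_px > grid_shape[0]:
        raise ValueError("body ellipse does not fit the grid")

    center = ((grid_shape[0] - 1) / 2.0, (grid_shape[1] - 1) / 2.0)
    semi = (h_px / 2.0, w_px / 2.0)  # (row, col) semi-axes
    body = _ellipse_mask(grid_shape, center, semi)

    def organ(name: str) -> np.ndarray:
        spec = _ORGANS[name]
        c = (center[0] + spec["center"][0] * semi[0], center[1] + spec["center"][1] * semi[1])
        s = (spec["semi"][0] * semi[0], spec["semi"][1] * semi[1])
        return _ellipse_mask(grid_shape, c, s) & body

    heart = organ("heart")
    right = organ("right") & ~heart
    left = organ("left") & ~heart & ~right
    accessory = organ("accessory") & ~heart & ~right & ~left

    rows = np.nonzero(body.any(axis=1))[0]
    sv = float((rows[-1] - rows[0] + 1) * pixel_size)

    return ThoraxPhantom(
        grid_shape=grid_shape,
        pixel_size=pixel_size,
        body_mask=body,
        lung_masks={"right": right, "left": left, "accessory": accessory},
        heart_mask=heart,
        sternovertebral_distance=sv,
        background_conductivity=background_conductivity,
        lung_conductivity_expiration=lung_conductivity_expiration,
        heart_conductivity=heart_conductivity,
    )


def segment_map(phantom: ThoraxPhantom) -> np.ndarray:
    """Label lung pixels with segments 1-10 (0 = non-lung).

    Schematic layout: the accessory lobe is segment 6; the ventral halves of
    the right/left lungs carry segments {2, 3} and {5}; the dorsal halves are
    split into column thirds carrying {1, 4, 10} (right) and {8, 7, 9} (left,
    medial to lateral).  Anterior segments {2, 3, 5, 6} lie strictly in the
    ventral half of the grid.
    """
    labels = np.zeros(phantom.grid_shape, dtype=np.int32)
    cy, _ = phantom.body_center
    rr, cc = np.mgrid[0 : phantom.grid_shape[0], 0 : phantom.grid_shape[1]]
    ventral = rr < cy

    labels[phantom.lung_masks["accessory"]] = ACCESSORY_SEGMENT

    def split_thirds(mask: np.ndarray, ids: Sequence[int]) -> None:
        cols = np.nonzero(mask)[1]
        lo, hi = cols.min(), cols.max()
        t1 = lo + (hi - lo + 1) / 3.0
        t2 = lo + 2.0 * (hi - lo + 1) / 3.0
        labels[mask & (cc < t1)] = ids[0]
        labels[mask & (cc >= t1) & (cc < t2)] = ids[1]
        labels[mask & (cc >= t2)] = ids[2]

    right = phantom.lung_masks["right"]
    rv = right & ventral
    if rv.any():
        cols = np.nonzero(rv)[1]
        mid = (cols.min() + cols.max() + 1) / 2.0
        labels[rv & (cc < mid)] = 2  # lateral (image left = animal right)
        labels[rv & (cc >= mid)] = 3  # medial
    split_thirds(right & ~ventral, (1, 4, 10))  # lateral, mid, medial

    left = phantom.lung_masks["left"]
    labels[left & ventral] = 5
    split_thirds(left & ~ventral, (8, 7, 9))  # medial, mid, lateral

    return labels


def segment_adjacency(labels: np.ndarray) -> Dict[int, Set[int]]:
    """Pairs of neighbouring segments.

    Every pixel of the grid is assigned its nearest segment (Euclidean
    distance transform), so segments separated only by a thin non-lung gap
    (e.g. the heart between the accessory lobe and the ventral lung fields)
    still count as neighbours.
    """
    present = np.unique(labels[labels > 0])
    filled = labels.copy()
    if (labels == 0).any() and len(present) > 0:
        _, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
        filled = labels[ir, ic]
    adj: Dict[int, Set[int]] = {int(s): set() for s in present}
    H, W = filled.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = filled[max(0, -dr) : H - max(0, dr), max(0, -dc) : W - max(0, dc)]
        b = filled[max(0, dr) : H - max(0, -dr), max(0, dc) : W - max(0, -dc)]
        pairs = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[pairs].ravel(), b[pairs].ravel()):
            adj[int(x)].add(int(y))
            adj[int(y)].add(int(x))
    return adj


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def _max_pairwise_diameter_px(mask: np.ndarray) -> float:
    """Maximum Euclidean distance between pixel centers of a mask (pixels)."""
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 0:
        return 0.0
    if len(pts) == 1:
        return 0.0
    # Boundary pixels suffice for the diameter.
    eroded = ndimage.binary_erosion(mask)
    bpts = np.argwhere(mask & ~eroded).astype(float)
    if len(bpts) >= 2:
        pts = bpts
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _pleural_boundary(phantom: ThoraxPhantom, seg_mask: np.ndarray) -> np.ndarray:
    """(k, 2) array of segment pixels adjacent to extra-pulmonary body tissue
    lying radially outward (pleural side)."""
    lung = phantom.lung_mask
    outside = phantom.body_mask & ~lung & ~phantom.heart_mask
    cy, cx = phantom.body_center
    pts = []
    rr, cc = np.nonzero(seg_mask)
    H, W = seg_mask.shape
    for r, c in zip(rr, cc):
        r0 = (r - cy) ** 2 + (c - cx) ** 2
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < H and 0 <= nc < W and outside[nr, nc]:
                if (nr - cy) ** 2 + (nc - cx) ** 2 >= r0:
                    pts.append((r, c))
                    break
    if not pts:  # fall back to any lung-exterior boundary
        for r, c in zip(rr, cc):
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < H and 0 <= nc < W and not lung[nr, nc]:
                    pts.append((r, c))
                    break
    return np.array(pts, dtype=float)


def place_lesion(
    phantom: ThoraxPhantom,
    segment_id: int,
    trans_frac: float,
    cc_cm: float,
    seed: int = 0,
    conductivity: float = 0.10,
) -> PTXLesion:
    """Place a pleural air lesion in a segment.

    The lesion is a disc anchored at the segment's pleural boundary, clipped
    to the body interior; its realized maximum in-plane diameter equals
    ``trans_frac * sternovertebral_distance`` to within one pixel.
    """
    if trans_frac <= 0:
        raise ValueError("trans_frac must be > 0")
    if cc_cm < 0:
        raise ValueError("cc_cm must be >= 0")
    labels = segment_map(phantom)
    seg_mask = labels == segment_id
    if not seg_mask.any():
        raise ValueError(f"segment {segment_id} is empty on this phantom")

    sv = phantom.sternovertebral_distance
    d_px = trans_frac * sv / phantom.pixel_size
    radius = (d_px + 1.0) / 2.0

    boundary = _pleural_boundary(phantom, seg_mask)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(boundary))
    cy, cx = phantom.body_center
    interior = ndimage.binary_erosion(phantom.body_mask)
    rr, cc = np.mgrid[0 : phantom.grid_shape[0], 0 : phantom.grid_shape[1]]

    for idx in order:
        anchor = boundary[idx]
        vec = np.array([cy, cx]) - anchor
        nv = np.linalg.norm(vec)
        u = vec / nv if nv > 0 else np.array([0.0, 0.0])
        center = anchor + u * max(radius - 1.0, 0.0)
        disc = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2
        mask = disc & interior
        if not mask.any():
            continue
        measured = _max_pairwise_diameter_px(mask)
        if abs(measured - d_px) <= 1.0:
            return PTXLesion(
                segment_id=segment_id,
                center=(float(center[0]), float(center[1])),
                transversal_diameter=float(measured * phantom.pixel_size),
                craniocaudal_extent=float(cc_cm),
                in_plane_mask=mask,
                conductivity=conductivity,
            )
    raise LesionFitError(
        f"lesion does not fit: trans_frac={trans_frac} "
        f"({d_px:.1f} px) in segment {segment_id}"
    )


def classify_relevance(lesion: PTXLesion, sternovertebral_distance: float) -> RelevanceLabel:
    """Strict-inequality relevance rules on the two lesion diameters."""
    if sternovertebral_distance <= 0:
        raise ValueError("sternovertebral_distance must be > 0")
    return RelevanceLabel(
        is_trans20=lesion.transversal_diameter > 0.20 * sternovertebral_distance,
        is_cc3=lesion.craniocaudal_extent > 3.0,
    )


def partial_volume_weight(cc_cm: float, slab_halfwidth_cm: float = 3.0) -> float:
    """In-plane contrast attenuation of a lesion of craniocaudal size cc_cm.

    Linear ramp saturating once the lesion spans the full analysis slab
    (2 * slab_halfwidth_cm).
    """
    if cc_cm < 0:
        raise ValueError("cc_cm must be >= 0")
    if slab_halfwidth_cm <= 0:
        raise ValueError("slab_halfwidth_cm must be > 0")
    return min(1.0, cc_cm / (2.0 * slab_halfwidth_cm))


# ---------------------------------------------------------------------------
# Truth and dynamics
# ---------------------------------------------------------------------------

def _quadrant_of(r: float, c: float, cy: float, cx: float) -> str:
    v = "ventral" if r < cy else "dorsal"
    side = "right" if c < cx else "left"  # animal's right = image left
    return f"{v}-{side}"


def _lesion_heart_contact(phantom: ThoraxPhantom, lesion: PTXLesion) -> bool:
    grown = ndimage.binary_dilation(lesion.in_plane_mask, iterations=2)
    return bool((grown & ndimage.binary_dilation(phantom.heart_mask)).any())


def case_truth(phantom: ThoraxPhantom, lesions: Sequence[PTXLesion]) -> CaseTruth:
    """Ground-truth record for a simulated case."""
    labels = [classify_relevance(l, phantom.sternovertebral_distance) for l in lesions]
    cy, cx = phantom.body_center
    quadrants: Set[str] = set()
    for les in lesions:
        rr, cc = np.nonzero(les.in_plane_mask)
        for r, c in zip(rr, cc):
            quadrants.add(_quadrant_of(r, c, cy, cx))
    largest: Optional[int] = None
    best = -1.0
    for les, lab in zip(lesions, labels):
        if lab.is_relevant and les.transversal_diameter > best:
            best = les.transversal_diameter
            largest = les.segment_id
    contact = any(_lesion_heart_contact(phantom, l) for l in lesions)
    return CaseTruth(
        lesions=list(lesions),
        labels=labels,
        largest_relevant_segment=largest,
        quadrant_labels=quadrants,
        heart_contact=contact,
    )


def _spike_path_mask(phantom: ThoraxPhantom) -> np.ndarray:
    """Corridor between the heart's ventral edge and the ventral chest wall."""
    hrr, hcc = np.nonzero(phantom.heart_mask)
    c_lo = np.percentile(hcc, 25)
    c_hi = np.percentile(hcc, 75)
    # Ventral edge row of the heart per column.
    path = np.zeros(phantom.grid_shape, dtype=bool)
    for c in range(int(math.floor(c_lo)), int(math.ceil(c_hi)) + 1):
        col_heart = hrr[hcc == c]
        if len(col_heart) == 0:
            continue
        top = col_heart.min()
        body_rows = np.nonzero(phantom.body_mask[:, c])[0]
        if len(body_rows) == 0:
            continue
        path[body_rows.min() : top, c] = True
    return path & phantom.body_mask


def conductivity_series(
    phantom: ThoraxPhantom,
    lesions: Sequence[PTXLesion],
    dynamics: DynamicsConfig,
) -> ConductivitySeries:
    """Time-resolved conductivity fields with tidal, lesion, and cardiac dynamics.

    Lung conductivity oscillates between its expiration value and
    ``(1 - tidal_modulation)`` times it at the respiratory rate.  Lesion
    pixels mix underlying tissue and air with weight ``partial_volume_weight``;
    gas movement inside the lesion follows the tidal phase shifted by
    ``lesion_phase_lag`` and scaled by ``lesion_ventilation_fraction``.
    Cardiac transients (conductivity rises on the heart-chest-wall corridor,
    2 frames each) are injected once per cardiac cycle when ``spike_enabled``
    and a lesion contacts the heart.
    """
    dyn = dynamics
    if dyn.spike_enabled and len(lesions) == 0:
        raise ValueError("spike injection requires at least one lesion (heart contact)")

    truth = case_truth(phantom, lesions)
    inject_spikes = dyn.spike_enabled and truth.heart_contact

    n = dyn.n_frames
    H, W = phantom.grid_shape
    body = phantom.body_mask
    lung = phantom.lung_mask
    heart = phantom.heart_mask

    t = np.arange(n) / dyn.frame_rate
    f_resp = dyn.respiratory_rate / 60.0
    s = 0.5 * (1.0 - np.cos(2.0 * np.pi * f_resp * t))  # 0 at expiration

    sigma_lung = phantom.lung_conductivity_expiration * (1.0 - dyn.tidal_modulation * s)

    base = np.zeros((H, W))
    base[body] = phantom.background_conductivity
    base[heart] = phantom.heart_conductivity

    fields = np.repeat(base[None, :, :], n, axis=0)
    fields[:, lung] = sigma_lung[:, None]

    # Lesions: tissue/air mixture per partial-volume weight.
    s_lag = 0.5 * (1.0 - np.cos(2.0 * np.pi * f_resp * t - dyn.lesion_phase_lag))
    for les in lesions:
        w = partial_volume_weight(les.craniocaudal_extent)
        gas = les.conductivity + (
            dyn.lesion_ventilation_fraction
            * dyn.tidal_modulation
            * phantom.lung_conductivity_expiration
            * (1.0 - s_lag)
        )
        mask = les.in_plane_mask
        tissue = fields[:, mask]  # (n, k) underlying tissue dynamics
        fields[:, mask] = (1.0 - w) * tissue + w * gas[:, None]

    spike_frames: List[int] = []
    if inject_spikes:
        path = _spike_path_mask(phantom)
        beat_period = 60.0 / dyn.heart_rate
        n_beats = int(math.floor((dyn.duration - 1e-9) / beat_period)) + 1
        bump = dyn.spike_magnitude * phantom.background_conductivity
        for b in range(n_beats):
            f0 = int(round(b * beat_period * dyn.frame_rate))
            if f0 >= n:
                break
            f1 = min(f0 + 2, n)
            fields[f0:f1][:, path] += bump
            spike_frames.append(f0)

    rng = np.random.default_rng(dyn.seed)
    if dyn.noise_sd_frac > 0:
        noise = rng.normal(
            0.0, dyn.noise_sd_frac * phantom.background_conductivity, size=(n, int(body.sum()))
        )
        fields[:, body] = np.maximum(fields[:, body] + noise, 1e-3)

    return ConductivitySeries(
        fields=fields, frame_rate=dyn.frame_rate, spike_frames=spike_frames, seed=dyn.seed
    )
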