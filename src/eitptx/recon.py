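"""Linearized time-difference EIT reconstruction and waveform utilities.

Images live on a 32x32 grid with an inscribed circular mask; the elliptical
body cross-section is mapped onto the unit disk (normalized body
coordinates), matching the circular display convention of 16-electrode EIT
systems.  Orientation follows the package convention: row 0 ventral, animal's
right on image left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import signal

from .forward import ElectrodeBelt, ForwardSolver, N_MEASUREMENTS, drive_pairs, measurement_pairs

__all__ = [
    "RECON_SHAPE",
    "ROIWaveform",
    "BreathSegmentation",
    "ReconOperator",
    "circular_mask",
    "quadrant_masks",
    "jacobian",
    "build_recon_operator",
    "project_to_recon_grid",
    "project_labels",
    "reconstruct_difference",
    "reconstruct_series",
    "detect_breaths",
    "tidal_image",
    "mean_tidal_image",
    "quadrant_waveforms",
    "phase_map",
]

RECON_SHAPE = (32, 32)

ROI_NAMES = ("global", "ventral-right", "ventral-left", "dorsal-right", "dorsal-left")


@dataclass(frozen=True)
class ROIWaveform:
    roi_name: str
    samples: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        if self.roi_name not in ROI_NAMES:
            raise ValueError(f"unknown ROI {self.roi_name!r}")


@dataclass(frozen=True)
class BreathSegmentation:
    """(end_expiration_frame, end_inspiration_frame) pairs, strictly increasing."""

    breaths: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        flat = [i for pair in self.breaths for i in pair]
        if any(b <= a for a, b in zip(flat, flat[1:])):
            raise ValueError("breath indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.breaths)

    def __iter__(self):
        return iter(self.breaths)


def circular_mask(shape: Tuple[int, int] = RECON_SHAPE) -> np.ndarray:
    """Inscribed circular reconstruction mask."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r = min(H, W) / 2.0
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2


def quadrant_masks(shape: Tuple[int, int] = RECON_SHAPE) -> Dict[str, np.ndarray]:
    """Quadrants of the circular mask. Ventral = rows above center; the
    animal's right is the image left (low columns)."""
    mask = circular_mask(shape)
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    ventral = rr < H / 2.0
    right = cc < W / 2.0
    return {
        "ventral-right": mask & ventral & right,
        "ventral-left": mask & ventral & ~right,
        "dorsal-right": mask & ~ventral & right,
        "dorsal-left": mask & ~ventral & ~right,
    }


# ---------------------------------------------------------------------------
# Jacobian and reconstruction operator
# ---------------------------------------------------------------------------

def jacobian(
    sigma_ref: np.ndarray, body_mask: np.ndarray, belt: ElectrodeBelt
) -> Tuple[np.ndarray, ForwardSolver]:
    """Sensitivity matrix J (208 x n_mask_pixels) of the adjacent-drive frame
    with respect to pixel conductivities, by the adjoint method.

    Measurement lead fields coincide with the drive fields (adjacent pairs),
    so 16 forward solves suffice.  The derivative accounts exactly for the
    harmonic-mean edge conductances of the finite-difference scheme.
    """
    fs = ForwardSolver(body_mask, belt)
    fac = fs.factorize(sigma_ref)
    U = fac.drive_potentials()  # (16, n_pix)
    sig = np.asarray(sigma_ref, dtype=float)[fs.mask]
    i, j = fs.edges[:, 0], fs.edges[:, 1]
    si, sj = sig[i], sig[j]
    dg_dsi = 2.0 * sj**2 / (si + sj) ** 2
    dg_dsj = 2.0 * si**2 / (si + sj) ** 2

    dU = U[:, i] - U[:, j]  # (16, n_edges) potential drops per edge
    J = np.zeros((N_MEASUREMENTS, fs.n_pix))
    row = 0
    for d in range(16):
        for m, _ in measurement_pairs(d):
            ce = dU[d] * dU[m]  # (n_edges,)
            np.add.at(J[row], i, -ce * dg_dsi)
            np.add.at(J[row], j, -ce * dg_dsj)
            row += 1
    return J, fs


@dataclass(frozen=True)
class ReconOperator:
    """Precomputed one-step Tikhonov reconstructor onto the 32x32 mask."""

    R: np.ndarray  # (n_recon_pixels, 208)
    recon_index: np.ndarray  # 32x32 int map, -1 outside mask
    mask: np.ndarray  # 32x32 circular mask
    fwd_to_recon: np.ndarray  # forward-mask pixel -> recon pixel index
    lam: float

    @property
    def n_pixels(self) -> int:
        return self.R.shape[0]


def _fwd_to_recon_map(body_mask: np.ndarray, shape=RECON_SHAPE) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each forward-grid body pixel to a recon pixel via normalized body
    coordinates (ellipse -> inscribed disk)."""
    mask32 = circular_mask(shape)
    idx32 = -np.ones(shape, dtype=int)
    idx32[mask32] = np.arange(int(mask32.sum()))

    rr, cc = np.nonzero(body_mask)
    rows = np.nonzero(body_mask.any(axis=1))[0]
    cols = np.nonzero(body_mask.any(axis=0))[0]
    cy = (rows[0] + rows[-1]) / 2.0
    cx = (cols[0] + cols[-1]) / 2.0
    b = (rows[-1] - rows[0]) / 2.0 or 1.0
    a = (cols[-1] - cols[0]) / 2.0 or 1.0
    v = (rr - cy) / b  # in [-1, 1], negative = ventral
    u = (cc - cx) / a
    H, W = shape
    r32 = np.clip(np.round((H - 1) / 2.0 + v * (H / 2.0 - 1)), 0, H - 1).astype(int)
    c32 = np.clip(np.round((W - 1) / 2.0 + u * (W / 2.0 - 1)), 0, W - 1).astype(int)
    fwd_to_recon = idx32[r32, c32]
    # Normalized coords map strictly inside the inscribed circle, but guard:
    assert np.all(fwd_to_recon >= 0), "forward pixel mapped outside recon mask"
    return fwd_to_recon, idx32, mask32


def build_recon_operator(
    sigma_ref: np.ndarray,
    body_mask: np.ndarray,
    belt: ElectrodeBelt,
    lam_rel: float = 0.03,
) -> ReconOperator:
    """One-step Tikhonov operator R = (J'J + lam^2 I)^-1 J' on the recon grid.

    ``lam = lam_rel * ||J||_2``; the relative weight was fixed once by an
    L-curve sweep on the healthy fixture and frozen here.
    """
    if lam_rel <= 0:
        raise ValueError("lam_rel must be > 0")
    J, _ = jacobian(sigma_ref, body_mask, belt)
    fwd_to_recon, idx32, mask32 = _fwd_to_recon_map(body_mask)
    n32 = int(mask32.sum())
    J32 = np.zeros((N_MEASUREMENTS, n32))
    np.add.at(J32.T, fwd_to_recon, J.T)
    lam = lam_rel * np.linalg.norm(J32, 2)
    JtJ = J32.T @ J32
    JtJ[np.diag_indices_from(JtJ)] += lam**2
    R = np.linalg.solve(JtJ, J32.T)
    return ReconOperator(R=R, recon_index=idx32, mask=mask32, fwd_to_recon=fwd_to_recon, lam=lam)


def project_to_recon_grid(field: np.ndarray, body_mask: np.ndarray) -> np.ndarray:
    """Average a forward-grid field over the recon pixels (diagnostics)."""
    fwd_to_recon, idx32, mask32 = _fwd_to_recon_map(body_mask)
    n32 = int(mask32.sum())
    sums = np.zeros(n32)
    counts = np.zeros(n32)
    np.add.at(sums, fwd_to_recon, field[body_mask])
    np.add.at(counts, fwd_to_recon, 1.0)
    out = np.zeros(RECON_SHAPE)
    out[mask32] = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out


def project_labels(labels: np.ndarray, body_mask: np.ndarray) -> np.ndarray:
    """Project an integer label map (e.g. lung segments) onto the recon grid
    by majority vote per recon pixel (0 = background loses ties to any lung)."""
    fwd_to_recon, idx32, mask32 = _fwd_to_recon_map(body_mask)
    n32 = int(mask32.sum())
    lab = labels[body_mask]
    max_lab = int(lab.max()) if lab.size else 0
    counts = np.zeros((n32, max_lab + 1))
    np.add.at(counts, (fwd_to_recon, lab), 1.0)
    counts[:, 0] *= 0.5  # prefer lung labels at mixed pixels
    out32 = np.zeros(RECON_SHAPE, dtype=np.int32)
    out32[mask32] = counts.argmax(axis=1)
    return out32


def reconstruct_difference(
    frame: np.ndarray, reference_frame: np.ndarray, op: ReconOperator
) -> np.ndarray:
    """Reconstruct one relative-impedance difference image.

    Solves J x ~= (reference - frame); ventilation increase (conductivity
    drop) comes out positive.  Exactly zero outside the circular mask.
    """
    frame = np.asarray(frame, dtype=float)
    reference_frame = np.asarray(reference_frame, dtype=float)
    if frame.shape != (N_MEASUREMENTS,) or reference_frame.shape != (N_MEASUREMENTS,):
        raise ValueError("frames must be length-208 vectors")
    x = op.R @ (reference_frame - frame)
    img = np.zeros(RECON_SHAPE)
    img[op.mask] = x
    return img


def reconstruct_series(
    frames: np.ndarray, reference_frame: np.ndarray, op: ReconOperator
) -> np.ndarray:
    """Reconstruct a (T, 32, 32) image stack."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[1] != N_MEASUREMENTS:
        raise ValueError("frames must have shape (T, 208)")
    X = (np.asarray(reference_frame, dtype=float)[None, :] - frames) @ op.R.T
    out = np.zeros((frames.shape[0],) + RECON_SHAPE)
    out[:, op.mask] = X
    return out


# ---------------------------------------------------------------------------
# Waveforms, breaths, tidal images
# ---------------------------------------------------------------------------

def quadrant_waveforms(images: np.ndarray, frame_rate: float) -> Dict[str, ROIWaveform]:
    """Per-frame sums over the circular mask (global) and its four quadrants."""
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] == 0:
        raise ValueError("images must be a nonempty (T, H, W) stack")
    quads = quadrant_masks(images.shape[1:])
    out: Dict[str, ROIWaveform] = {}
    total = np.zeros(images.shape[0])
    for name, m in quads.items():
        s = images[:, m].sum(axis=1)
        out[name] = ROIWaveform(roi_name=name, samples=s, frame_rate=frame_rate)
        total += s
    out["global"] = ROIWaveform(roi_name="global", samples=total, frame_rate=frame_rate)
    return out


def detect_breaths(global_waveform: ROIWaveform, min_prominence: float = 0.25) -> BreathSegmentation:
    """Segment breaths: troughs are end-expiration, following peaks
    end-inspiration.  Prominence threshold is ``min_prominence`` times the
    robust signal swing (5th-95th percentile range); a constant signal yields
    an empty segmentation."""
    x = np.asarray(global_waveform.samples, dtype=float)
    if len(x) < 2 * global_waveform.frame_rate:
        raise ValueError("need at least 2 s of signal")
    swing = np.percentile(x, 95) - np.percentile(x, 5)
    if swing <= 0:
        return BreathSegmentation(breaths=[])
    prom = min_prominence * swing
    troughs, _ = signal.find_peaks(-x, prominence=prom)
    peaks, _ = signal.find_peaks(x, prominence=prom)
    breaths: List[Tuple[int, int]] = []
    last = -1
    for trough in troughs:
        if trough <= last:
            continue
        nxt = peaks[peaks > trough]
        if len(nxt) == 0:
            break
        breaths.append((int(trough), int(nxt[0])))
        last = int(nxt[0])
    return BreathSegmentation(breaths=breaths)


def tidal_image(images: np.ndarray, breath: Tuple[int, int]) -> np.ndarray:
    """Differential image end-inspiration minus end-expiration for one breath."""
    end_exp, end_insp = breath
    T = images.shape[0]
    if not (0 <= end_exp < T and 0 <= end_insp < T):
        raise IndexError("breath indices out of range")
    return images[end_insp] - images[end_exp]


def mean_tidal_image(images: np.ndarray, seg: BreathSegmentation) -> np.ndarray:
    """Breath-averaged tidal image."""
    if len(seg) == 0:
        raise ValueError("no breaths to average")
    return np.mean([tidal_image(images, b) for b in seg], axis=0)


def phase_map(
    images: np.ndarray,
    global_waveform: ROIWaveform,
    amplitude_floor: float = 0.05,
) -> np.ndarray:
    """Per-pixel phase lag (radians) at the respiratory frequency relative to
    the global waveform, via cross-spectral phase.  Pixels whose amplitude at
    the respiratory bin is below ``amplitude_floor`` times the maximum are NaN.
    """
    x = np.asarray(global_waveform.samples, dtype=float)
    images = np.asarray(images, dtype=float)
    n = len(x)
    if images.shape[0] != n:
        raise ValueError("images and waveform must have the same length")
    X = np.fft.rfft(x - x.mean())
    mag = np.abs(X)
    mag[0] = 0.0
    k = int(np.argmax(mag))
    if k == 0 or mag[k] <= 0:
        raise ValueError("no respiratory spectral peak found")
    P = np.fft.rfft(images - images.mean(axis=0), axis=0)[k]
    amp = np.abs(P)
    out = np.full(images.shape[1:], np.nan)
    defined = amp >= amplitude_floor * amp.max()
    # Positive lag = pixel lags the global signal.
    out[defined] = -np.angle(P[defined] * np.conj(X[k]))
    return out
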