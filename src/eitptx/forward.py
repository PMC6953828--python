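"""Finite-difference EIT forward model: 16-electrode adjacent drive on a
masked pixel grid.

The conduction equation div(sigma grad u) = 0 with no-flux boundary
conditions is discretized with 5-point finite differences on the body mask;
edge conductances are harmonic means of the two adjacent pixel
conductivities.  Electrodes are point electrodes at continuous positions just
inside the boundary; current injection and voltage pickup use bilinear
weights over the surrounding grid nodes, which keeps the effective electrode
geometry independent of grid resolution.  Drive current is normalized to 1
(the physical 5 mA / 50 kHz excitation is metadata only); measurements are
dimensionless transfer impedances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

__all__ = [
    "ElectrodeBelt",
    "VoltageFrame",
    "ForwardSolver",
    "SolverError",
    "build_belt",
    "drive_pairs",
    "measurement_pairs",
    "solve_forward",
    "acquire_frame",
    "acquire_series",
    "N_ELECTRODES",
    "N_MEASUREMENTS",
]

N_ELECTRODES = 16
#: 16 adjacent drives x 13 adjacent measurement pairs not touching the drive.
N_MEASUREMENTS = 208


class SolverError(RuntimeError):
    """Raised when the forward solve fails or is ill-posed."""


@dataclass(frozen=True)
class ElectrodeBelt:
    """Point electrodes on the body boundary.

    ``angles`` are placements in radians counterclockwise from the ventral
    midline (0 = ventral, pi = dorsal, increasing toward the image right);
    ``points`` are the continuous (row, col) positions just inside the
    boundary; ``pixels`` the nearest pixel coordinates.
    """

    angles: np.ndarray
    points: np.ndarray  # (16, 2) float
    pixels: np.ndarray  # (16, 2) int

    def __post_init__(self) -> None:
        if len(self.angles) != N_ELECTRODES:
            raise ValueError("belt must carry exactly 16 electrodes")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("electrode angles must be strictly increasing")
        if len(np.unique(self.pixels, axis=0)) != N_ELECTRODES:
            raise ValueError("electrode pixels must be distinct")

    @property
    def n_electrodes(self) -> int:
        return N_ELECTRODES


@dataclass(frozen=True)
class VoltageFrame:
    """One acquisition frame: 208 differential boundary voltages.

    Ordering is drive-major: for drive pair (k, k+1), measurement pairs
    (m, m+1) are listed counterclockwise for m not in {k-1, k, k+1} (mod 16).
    """

    measurements: np.ndarray
    drive_index: np.ndarray
    measure_index: np.ndarray

    def __post_init__(self) -> None:
        if len(self.measurements) != N_MEASUREMENTS:
            raise ValueError("a frame holds exactly 208 measurements")


#: Electrodes sit at this fraction of the body semi-axes, slightly inside the
#: rasterized boundary so their bilinear support stays within the mask.
_ELECTRODE_RADIAL_FRACTION = 0.94


def build_belt(body_mask: np.ndarray, n_electrodes: int = N_ELECTRODES) -> ElectrodeBelt:
    """Place electrodes equiangular on the body boundary, counterclockwise
    from the ventral midline (ventral -> image right -> dorsal -> image left).
    """
    if n_electrodes != N_ELECTRODES:
        raise ValueError("only 16-electrode belts are supported")
    rows = np.nonzero(body_mask.any(axis=1))[0]
    cols = np.nonzero(body_mask.any(axis=0))[0]
    cy = (rows[0] + rows[-1]) / 2.0
    cx = (cols[0] + cols[-1]) / 2.0
    b = (rows[-1] - rows[0]) / 2.0
    a = (cols[-1] - cols[0]) / 2.0
    angles = 2 * np.pi * np.arange(n_electrodes) / n_electrodes
    # Row decreases toward ventral (row 0); column increases to image right.
    pr = cy - _ELECTRODE_RADIAL_FRACTION * b * np.cos(angles)
    pc = cx + _ELECTRODE_RADIAL_FRACTION * a * np.sin(angles)
    points = np.stack([pr, pc], axis=1)
    return ElectrodeBelt(angles=angles, points=points, pixels=np.round(points).astype(int))


def drive_pairs() -> List[Tuple[int, int]]:
    """Adjacent drive pairs (k, k+1 mod 16)."""
    return [(k, (k + 1) % N_ELECTRODES) for k in range(N_ELECTRODES)]


def measurement_pairs(drive: int) -> List[Tuple[int, int]]:
    """The 13 adjacent measurement pairs for a drive pair (k, k+1): pairs
    (m, m+1) with m not in {k-1, k, k+1} (mod 16), m ascending."""
    excluded = {(drive - 1) % N_ELECTRODES, drive, (drive + 1) % N_ELECTRODES}
    return [(m, (m + 1) % N_ELECTRODES) for m in range(N_ELECTRODES) if m not in excluded]


class ForwardSolver:
    """Forward solves on a fixed mask/belt; conductivity varies per call."""

    def __init__(self, body_mask: np.ndarray, belt: ElectrodeBelt):
        self.mask = body_mask.astype(bool)
        self.belt = belt
        self.n_pix = int(self.mask.sum())
        self.index = -np.ones(self.mask.shape, dtype=int)
        self.index[self.mask] = np.arange(self.n_pix)
        self.pixel_coords = np.argwhere(self.mask)
        # Edges between 4-adjacent in-mask pixels.
        edges = []
        H, W = self.mask.shape
        for dr, dc in ((0, 1), (1, 0)):
            a = self.mask[: H - dr, : W - dc]
            b = self.mask[dr:, dc:]
            rr, cc = np.nonzero(a & b)
            i = self.index[rr, cc]
            j = self.index[rr + dr, cc + dc]
            edges.append(np.stack([i, j], axis=1))
        self.edges = np.concatenate(edges, axis=0)
        # Bilinear electrode weights (16, n_pix), rows sum to 1.
        self.W = self._electrode_weights(belt.points)
        # Gauge node: in-mask pixel farthest from every electrode support.
        support = np.unique(np.nonzero(self.W)[1])
        dist = np.full(self.n_pix, np.inf)
        for s in support:
            d = ((self.pixel_coords - self.pixel_coords[s]) ** 2).sum(axis=1)
            dist = np.minimum(dist, d)
        self.ground = int(np.argmax(dist))

    def _electrode_weights(self, points: np.ndarray) -> np.ndarray:
        H, W = self.mask.shape
        out = np.zeros((len(points), self.n_pix))
        for k, (r, c) in enumerate(points):
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            fr, fc = r - r0, c - c0
            for dr, dc, w in (
                (0, 0, (1 - fr) * (1 - fc)),
                (0, 1, (1 - fr) * fc),
                (1, 0, fr * (1 - fc)),
                (1, 1, fr * fc),
            ):
                rr, cc = r0 + dr, c0 + dc
                if 0 <= rr < H and 0 <= cc < W and self.mask[rr, cc] and w > 0:
                    out[k, self.index[rr, cc]] = w
            total = out[k].sum()
            if total <= 0:
                raise ValueError(f"electrode {k} has no in-mask support")
            out[k] /= total
        return out

    def _system(self, sigma: np.ndarray) -> csc_matrix:
        sig = np.asarray(sigma, dtype=float)[self.mask]
        if np.any(sig <= 0):
            raise SolverError("conductivity must be strictly positive on the body mask")
        i, j = self.edges[:, 0], self.edges[:, 1]
        si, sj = sig[i], sig[j]
        g = 2.0 * si * sj / (si + sj)
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-g, -g, g, g])
        return csc_matrix((vals, (rows, cols)), shape=(self.n_pix, self.n_pix))

    def factorize(self, sigma: np.ndarray) -> "FactorizedField":
        """Factorize the system for one conductivity field (reused across
        drives).  The pure-Neumann system is singular; one interior node away
        from the electrodes is grounded."""
        A = self._system(sigma)
        keep = np.ones(self.n_pix, dtype=bool)
        keep[self.ground] = False
        try:
            lu = splu(A[keep][:, keep].tocsc())
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise SolverError(f"forward system factorization failed: {exc}") from exc
        return FactorizedField(self, A, lu, keep)


@dataclass
class FactorizedField:
    solver: ForwardSolver
    A: csc_matrix
    lu: object
    keep: np.ndarray

    def solve_current(self, b: np.ndarray) -> np.ndarray:
        """Nodal potentials for a current pattern b (must sum to zero)."""
        u = np.zeros(self.solver.n_pix)
        u[self.keep] = self.lu.solve(b[self.keep])
        res = np.linalg.norm(self.A @ u - b) / np.linalg.norm(b)
        if res > 1e-8:
            raise SolverError(f"forward solve residual {res:.2e} exceeds tolerance")
        return u

    def solve_pair(self, src: int, sink: int) -> np.ndarray:
        """Nodal potentials for unit current in at electrode src, out at sink."""
        b = self.solver.W[src] - self.solver.W[sink]
        return self.solve_current(b)

    def drive_potentials(self) -> np.ndarray:
        """(16, n_pix) nodal potentials per adjacent drive pair, each with
        zero-mean gauge over the 16 electrode potentials."""
        W = self.solver.W
        out = np.empty((N_ELECTRODES, self.solver.n_pix))
        for k, (p, q) in enumerate(drive_pairs()):
            u = self.solve_pair(p, q)
            out[k] = u - (W @ u).mean()
        return out


def solve_forward(
    sigma: np.ndarray,
    body_mask: np.ndarray,
    belt: ElectrodeBelt,
    drive_pair: Tuple[int, int],
    solver: ForwardSolver | None = None,
) -> np.ndarray:
    """Potentials at the 16 electrodes (zero-mean gauge) for unit current
    injected at drive_pair[0] and withdrawn at drive_pair[1]."""
    p, q = drive_pair
    if p == q:
        raise ValueError("drive electrodes must be distinct")
    fs = solver or ForwardSolver(body_mask, belt)
    fac = fs.factorize(sigma)
    u_el = fs.W @ fac.solve_pair(p, q)
    return u_el - u_el.mean()


def acquire_frame(
    sigma: np.ndarray,
    body_mask: np.ndarray,
    belt: ElectrodeBelt,
    solver: ForwardSolver | None = None,
) -> VoltageFrame:
    """Acquire one 208-measurement frame (adjacent drive, adjacent measure)."""
    fs = solver or ForwardSolver(body_mask, belt)
    fac = fs.factorize(sigma)
    U = fac.drive_potentials()
    U_el = U @ fs.W.T  # (16 drives, 16 electrode potentials)
    meas = np.empty(N_MEASUREMENTS)
    didx = np.empty(N_MEASUREMENTS, dtype=int)
    midx = np.empty(N_MEASUREMENTS, dtype=int)
    pos = 0
    for k in range(N_ELECTRODES):
        for m, m1 in measurement_pairs(k):
            meas[pos] = U_el[k, m] - U_el[k, m1]
            didx[pos] = k
            midx[pos] = m
            pos += 1
    return VoltageFrame(measurements=meas, drive_index=didx, measure_index=midx)


def acquire_series(
    fields: Iterable[np.ndarray] | np.ndarray,
    body_mask: np.ndarray,
    belt: ElectrodeBelt,
) -> np.ndarray:
    """Acquire a (T, 208) voltage series, one frame per conductivity field."""
    fields = np.asarray(fields) if not isinstance(fields, np.ndarray) else fields
    if fields.ndim != 3 or fields.shape[0] == 0:
        raise ValueError("fields must be a nonempty (T, H, W) series")
    fs = ForwardSolver(body_mask, belt)
    out = np.empty((fields.shape[0], N_MEASUREMENTS))
    for t in range(fields.shape[0]):
        out[t] = acquire_frame(fields[t], body_mask, belt, solver=fs).measurements
    return out
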