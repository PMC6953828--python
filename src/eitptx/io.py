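"""Serialization: HDF5 recordings, JSON truth/reference/detection, CSV
waveforms, and a simple ``key = value`` config format."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd

from .detect import DetectionResult, HealthyReference
from .phantom import CaseTruth, ConductivitySeries, PTXLesion
from .recon import ROIWaveform

__all__ = [
    "rle_encode",
    "rle_decode",
    "save_recording",
    "load_recording",
    "save_truth",
    "load_truth_dict",
    "save_reference",
    "load_reference",
    "save_detection",
    "save_waveforms_csv",
    "load_waveforms_csv",
    "read_config",
    "save_image_pgm",
]

PathLike = Union[str, Path]


def rle_encode(mask: np.ndarray) -> Dict:
    """Run-length encode a boolean/integer map (row-major runs of values)."""
    flat = np.asarray(mask).ravel(order="C")
    if flat.size == 0:
        return {"shape": list(mask.shape), "values": [], "lengths": [], "dtype": str(mask.dtype)}
    change = np.nonzero(np.diff(flat) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    return {
        "shape": list(mask.shape),
        "values": [int(v) for v in flat[starts]],
        "lengths": [int(e - s) for s, e in zip(starts, ends)],
        "dtype": str(np.asarray(mask).dtype),
    }


def rle_decode(obj: Dict) -> np.ndarray:
    flat = np.repeat(np.array(obj["values"]), np.array(obj["lengths"], dtype=int))
    return flat.reshape(obj["shape"]).astype(obj.get("dtype", "int64"))


def save_recording(
    path: PathLike,
    voltage_frames: np.ndarray,
    frame_rate: float,
    seed: int,
    conductivity_fields: Optional[np.ndarray] = None,
) -> None:
    """Write a recording: dataset ``frames`` (T x 208) plus optional
    ``conductivity`` stack; frame_rate/seed/electrode layout as attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=np.asarray(voltage_frames, dtype=float))
        d.attrs["electrode_layout"] = "16-adjacent-drive; drive-major, 13 adjacent pairs"
        f.attrs["frame_rate"] = float(frame_rate)
        f.attrs["seed"] = int(seed)
        if conductivity_fields is not None:
            f.create_dataset(
                "conductivity", data=np.asarray(conductivity_fields, dtype=np.float32)
            )


def load_recording(path: PathLike) -> Tuple[np.ndarray, float, Optional[np.ndarray]]:
    with h5py.File(path, "r") as f:
        frames = f["frames"][...]
        frame_rate = float(f.attrs["frame_rate"])
        cond = f["conductivity"][...] if "conductivity" in f else None
    return frames, frame_rate, cond


def _lesion_to_dict(lesion: PTXLesion) -> Dict:
    return {
        "segment_id": lesion.segment_id,
        "center": list(lesion.center),
        "transversal_diameter_cm": lesion.transversal_diameter,
        "craniocaudal_extent_cm": lesion.craniocaudal_extent,
        "conductivity": lesion.conductivity,
        "in_plane_mask": rle_encode(lesion.in_plane_mask.astype(np.uint8)),
    }


def save_truth(path: PathLike, truth: CaseTruth, spike_frames: Sequence[int] = ()) -> None:
    obj = {
        "lesions": [_lesion_to_dict(l) for l in truth.lesions],
        "relevance": [
            {
                "is_trans20": lab.is_trans20,
                "is_cc3": lab.is_cc3,
                "is_transcc": lab.is_transcc,
                "is_relevant": lab.is_relevant,
            }
            for lab in truth.labels
        ],
        "largest_relevant_segment": truth.largest_relevant_segment,
        "quadrant_labels": sorted(truth.quadrant_labels),
        "heart_contact": truth.heart_contact,
        "spike_frames": [int(i) for i in spike_frames],
    }
    Path(path).write_text(json.dumps(obj, indent=2))


def load_truth_dict(path: PathLike) -> Dict:
    return json.loads(Path(path).read_text())


def save_reference(path: PathLike, reference: HealthyReference) -> None:
    obj = {
        "n_subjects": reference.n_subjects,
        "normalization": reference.normalization,
        "shape": list(reference.mean_image.shape),
        "mask": rle_encode(reference.mask.astype(np.uint8)),
        "mean_image": reference.mean_image.ravel().tolist(),
        "sd_image": reference.sd_image.ravel().tolist(),
    }
    Path(path).write_text(json.dumps(obj))


def load_reference(path: PathLike) -> HealthyReference:
    obj = json.loads(Path(path).read_text())
    shape = tuple(obj["shape"])
    return HealthyReference(
        mean_image=np.array(obj["mean_image"]).reshape(shape),
        sd_image=np.array(obj["sd_image"]).reshape(shape),
        mask=rle_decode(obj["mask"]).astype(bool),
        n_subjects=int(obj["n_subjects"]),
        normalization=obj["normalization"],
    )


def save_detection(path: PathLike, result: DetectionResult) -> None:
    obj = result.to_dict()
    obj["region_mask"] = rle_encode(result.region_mask.astype(np.uint8))
    Path(path).write_text(json.dumps(obj, indent=2))


def save_waveforms_csv(path: PathLike, waveforms: Dict[str, ROIWaveform]) -> None:
    """Columns: frame, global, vr, vl, dr, dl."""
    cols = {
        "global": "global",
        "ventral-right": "vr",
        "ventral-left": "vl",
        "dorsal-right": "dr",
        "dorsal-left": "dl",
    }
    n = len(waveforms["global"].samples)
    data = {"frame": np.arange(n)}
    for name, short in cols.items():
        data[short] = waveforms[name].samples
    df = pd.DataFrame(data)
    df.attrs["frame_rate"] = waveforms["global"].frame_rate
    with open(path, "w") as f:
        f.write(f"# frame_rate={waveforms['global'].frame_rate}\n")
        df.to_csv(f, index=False)


def load_waveforms_csv(path: PathLike) -> Tuple[pd.DataFrame, float]:
    with open(path) as f:
        header = f.readline().strip()
        frame_rate = float(header.split("=", 1)[1]) if header.startswith("#") else 50.0
        df = pd.read_csv(f) if header.startswith("#") else None
    if df is None:
        df = pd.read_csv(path)
    return df, frame_rate


def read_config(path: PathLike) -> Dict[str, str]:
    """Parse a ``key = value`` text config; '#' starts a comment."""
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def save_image_pgm(path: PathLike, image: np.ndarray, overlay: Optional[np.ndarray] = None) -> None:
    """Write a grayscale portable image (plain PGM / PPM with overlay).

    With ``overlay`` the output is a plain PPM where overlay pixels are marked
    in the red channel (the marked-region export of a detection)."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
    gray = np.round(scaled * 255).astype(int)
    H, W = gray.shape
    if overlay is None:
        lines = [f"P2\n{W} {H}\n255"]
        for row in gray:
            lines.append(" ".join(str(v) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")
        return
    lines = [f"P3\n{W} {H}\n255"]
    ov = np.asarray(overlay, dtype=bool)
    for r in range(H):
        vals = []
        for c in range(W):
            g = gray[r, c]
            if ov[r, c]:
                vals.extend([255, g // 2, g // 2])
            else:
                vals.extend([g, g, g])
        lines.append(" ".join(str(v) for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")
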