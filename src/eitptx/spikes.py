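"""Spike-potential analysis of impedance waveforms.

Operationalization of "spike-like patterns": remove the respiratory component
with a moving median over one respiratory period, flag residual excursions
beyond k * MAD, merge flags within a refractory window into single events,
and compare the event rate with the heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .recon import ROIWaveform

__all__ = [
    "SpikeEvent",
    "SpikeAnalysis",
    "detect_spikes",
    "spike_rate",
    "cardiac_match",
    "analyze_waveform",
    "K_MAD_DEFAULT",
    "REFRACTORY_S_DEFAULT",
]

K_MAD_DEFAULT = 4.0
REFRACTORY_S_DEFAULT = 0.25
#: Median smoothing window (s): longer than a spike transient, much shorter
#: than a breath, so the smoothed signal tracks respiration but not spikes.
SMOOTH_WINDOW_S_DEFAULT = 0.4


@dataclass(frozen=True)
class SpikeEvent:
    frame_index: int
    amplitude: float  # |residual| at the event extremum
    polarity: str  # "drop" or "rise"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.polarity not in ("drop", "rise"):
            raise ValueError("polarity must be 'drop' or 'rise'")


@dataclass(frozen=True)
class SpikeAnalysis:
    events: List[SpikeEvent]
    rate_per_min: float
    dominant_interval_s: Optional[float]  # median inter-event interval
    cardiac_match: Optional[bool]  # None when < 3 events or no heart rate given
    heart_rate_used: Optional[float]


def detect_spikes(
    waveform: ROIWaveform,
    k_mad: float = K_MAD_DEFAULT,
    refractory_s: float = REFRACTORY_S_DEFAULT,
    smooth_window_s: float = SMOOTH_WINDOW_S_DEFAULT,
) -> List[SpikeEvent]:
    """Detect transient excursions against the respiratory baseline.

    The baseline is a short moving median (``smooth_window_s``) that follows
    the respiratory waveform but suppresses spike transients; the residual
    signal - baseline therefore isolates spikes.  Residual samples with
    |residual| > k_mad * MAD are merged within ``refractory_s`` into one
    event at the residual extremum.
    """
    x = np.asarray(waveform.samples, dtype=float)
    fr = waveform.frame_rate
    if len(x) < 10 * fr:
        raise ValueError("need at least 10 s of signal")
    period = max(int(round(smooth_window_s * fr)), 3)
    if period % 2 == 0:
        period += 1
    baseline = ndimage.median_filter(x, size=period, mode="nearest")
    resid = x - baseline
    # The moving median reproduces the center sample wherever the window is
    # monotone, leaving exact zeros; scale the threshold on the nonzero
    # residuals (still robust: spikes are a minority of those).
    nz = resid[resid != 0.0]
    if nz.size == 0:
        return []
    mad = float(np.median(np.abs(nz - np.median(nz))))
    if mad <= 0:
        mad = float(np.median(np.abs(nz)))
    if mad <= 0:
        return []
    thresh = k_mad * mad
    flagged = np.abs(resid) > thresh
    if not flagged.any():
        return []
    gap = max(int(round(refractory_s * fr)), 1)
    idx = np.nonzero(flagged)[0]
    events: List[SpikeEvent] = []
    start = idx[0]
    prev = idx[0]
    groups = []
    for i in idx[1:]:
        if i - prev > gap:
            groups.append((start, prev))
            start = i
        prev = i
    groups.append((start, prev))
    for lo, hi in groups:
        seg = resid[lo : hi + 1]
        off = int(np.argmax(np.abs(seg)))
        peak = seg[off]
        events.append(
            SpikeEvent(
                frame_index=int(lo + off),
                amplitude=float(abs(peak)),
                polarity="drop" if peak < 0 else "rise",
            )
        )
    return events


def spike_rate(events: List[SpikeEvent], frame_rate: float, duration: float):
    """Event rate per minute and the median inter-event interval (seconds)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rate = 60.0 * len(events) / duration
    if len(events) >= 2:
        frames = np.array(sorted(e.frame_index for e in events))
        interval = float(np.median(np.diff(frames)) / frame_rate)
    else:
        interval = None
    return rate, interval


def cardiac_match(
    analysis: SpikeAnalysis, heart_rate: float, tolerance_frac: float = 0.1
) -> bool:
    """True iff the spike rate matches the heart rate within tolerance and at
    least 3 events were seen."""
    if heart_rate <= 0:
        raise ValueError("heart_rate must be > 0")
    if len(analysis.events) < 3:
        return False
    return abs(analysis.rate_per_min - heart_rate) <= tolerance_frac * heart_rate


def analyze_waveform(
    waveform: ROIWaveform,
    heart_rate: Optional[float] = None,
    k_mad: float = K_MAD_DEFAULT,
    refractory_s: float = REFRACTORY_S_DEFAULT,
    smooth_window_s: float = SMOOTH_WINDOW_S_DEFAULT,
    tolerance_frac: float = 0.1,
) -> SpikeAnalysis:
    """Full spike analysis of one ROI waveform."""
    events = detect_spikes(
        waveform, k_mad=k_mad, refractory_s=refractory_s, smooth_window_s=smooth_window_s
    )
    duration = len(waveform.samples) / waveform.frame_rate
    rate, interval = spike_rate(events, waveform.frame_rate, duration)
    analysis = SpikeAnalysis(
        events=events,
        rate_per_min=rate,
        dominant_interval_s=interval,
        cardiac_match=None,
        heart_rate_used=heart_rate,
    )
    if heart_rate is not None and len(events) >= 3:
        analysis = SpikeAnalysis(
            events=events,
            rate_per_min=rate,
            dominant_interval_s=interval,
            cardiac_match=cardiac_match(analysis, heart_rate, tolerance_frac),
            heart_rate_used=heart_rate,
        )
    return analysis
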