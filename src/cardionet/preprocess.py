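"""Detrending, standardization and time-domain markers for beat series.

Slow non-stationarities (thermoregulatory and humoral drifts) sit below the
frequency band of interest for short-term variability, so each column is
high-pass filtered with a zero-phase filter before any causality analysis.
The cutoff is specified in Hz and translated to cycles/beat through the
subject's mean beat duration, which is the only dimensionally consistent
reading for beat-indexed (not time-resampled) series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .series import BeatSeries

FILTER_ORDER = 4
DEFAULT_CUTOFF_HZ = 0.0156


def highpass_detrend(series: BeatSeries, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> BeatSeries:
    """Zero-phase high-pass filter each column, then remove its mean.

    An order-4 Butterworth high-pass at normalized cutoff
    ``cutoff_hz * mean_beat_duration_s`` cycles/beat is applied forward and
    backward (``filtfilt``) with reflective edge padding.
    """
    cutoff = cutoff_hz * series.mean_beat_duration_s  # cycles per beat
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= 0.5:
        raise ValueError(
            f"normalized cutoff {cutoff:.4g} cycles/beat is at or above the "
            "Nyquist frequency (0.5)"
        )
    b, a = signal.butter(FILTER_ORDER, cutoff, btype="highpass", fs=1.0)
    padlen = min(3 * FILTER_ORDER * 2, series.n_beats - 1)
    out = signal.filtfilt(b, a, series.values, axis=0, padtype="even", padlen=padlen)
    out = out - out.mean(axis=0, keepdims=True)
    return series.with_values(out)


def standardize(series: BeatSeries, mode: str = "unit_variance") -> BeatSeries:
    """Center each column (both modes); scale to unit SD for ``unit_variance``.

    Sample SD uses denominator N-1.  A constant column cannot be scaled and
    is rejected with its label.
    """
    if mode not in ("zero_mean", "unit_variance"):
        raise ValueError(f"unknown mode {mode!r}")
    x = series.values
    out = x - x.mean(axis=0, keepdims=True)
    if mode == "unit_variance":
        sd = x.std(axis=0, ddof=1)
        bad = [n for n, s in zip(series.nodes, sd) if s == 0]
        if bad:
            raise ValueError(f"constant column(s) cannot be standardized: {bad}")
        out = out / sd
    return series.with_values(out)


@dataclass(frozen=True)
class TimeDomainMarkers:
    """Per-node mean and sample SD of a raw (unfiltered) series."""

    subject_id: str
    condition: str
    mean: dict[str, float]
    sd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "condition": self.condition,
                "node": list(self.mean),
                "mean": list(self.mean.values()),
                "sd": list(self.sd.values()),
            }
        )


def time_domain_markers(series: BeatSeries | pd.DataFrame) -> TimeDomainMarkers:
    """Arithmetic mean and sample SD (denominator N-1) per node."""
    if isinstance(series, pd.DataFrame):
        data, sid, cond = series, "S00", "REST"
    else:
        data, sid, cond = series.data, series.subject_id, series.condition
    return TimeDomainMarkers(
        subject_id=sid,
        condition=cond,
        mean={n: float(data[n].mean()) for n in data.columns},
        sd={n: float(data[n].std(ddof=1)) for n in data.columns},
    )


def markers_table(cohort) -> pd.DataFrame:
    """Tidy marker table (subject, condition, node, mean, sd) for a cohort."""
    frames = [time_domain_markers(s).to_frame() for pair in cohort for s in pair]
    return pd.concat(frames, ignore_index=True)
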