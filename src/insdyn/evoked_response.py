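"""N1-P2 peak detection and RMS dose-response feature extraction.

The evoked magnitude is the RMS of the (high-pass filtered) LFP from stimulus
onset through the P2 sample. Peaks qualify when their z-score against the
per-trial baseline distribution reaches |z| >= 2, searched inside the
onset .. train-end + 150 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .core_data import AnalysisWindows, TrialRecording, compute_windows

PEAK_Z = 2.0


@dataclass
class N1P2Feature:
    n1_time: float
    p2_time: float
    n1_z: float
    p2_z: float
    rms: float
    valid: bool
    reason: str = ""
    animal: int = 0
    electrode: int = 0
    trial: int = 0
    energy_mj: float = float("nan")
    isi_ms: float = float("nan")


def _invalid(trial: TrialRecording, reason: str) -> N1P2Feature:
    return N1P2Feature(
        n1_time=float("nan"),
        p2_time=float("nan"),
        n1_z=float("nan"),
        p2_z=float("nan"),
        rms=float("nan"),
        valid=False,
        reason=reason,
        animal=trial.animal,
        electrode=trial.electrode,
        trial=trial.trial,
        energy_mj=trial.stimulus.energy_mj,
        isi_ms=trial.stimulus.isi_ms,
    )


def detect_n1p2(trial: TrialRecording, windows: AnalysisWindows | None = None) -> N1P2Feature:
    """First qualifying local minimum (N1), then next qualifying maximum (P2)."""
    if windows is None:
        windows = compute_windows(trial.stimulus)
    rate = trial.sampling_rate
    x = np.asarray(trial.lfp, dtype=float)
    base = x[windows.slice_for("baseline", rate)]
    if base.size < 2 or base.std(ddof=0) == 0:
        return _invalid(trial, "zero-variance baseline")
    mu, sd = base.mean(), base.std(ddof=0)
    sl = windows.slice_for("n1p2_search", rate)
    seg = x[sl]
    z = (seg - mu) / sd
    minima = argrelextrema(seg, np.less_equal, order=2)[0]
    minima = minima[(minima > 0) & (minima < seg.size - 1)]
    n1_candidates = minima[z[minima] <= -PEAK_Z]
    if n1_candidates.size == 0:
        return _invalid(trial, "no qualifying N1")
    n1 = int(n1_candidates[0])
    maxima = argrelextrema(seg, np.greater_equal, order=2)[0]
    maxima = maxima[(maxima > n1) & (maxima < seg.size - 1)]
    p2_candidates = maxima[z[maxima] >= PEAK_Z]
    if p2_candidates.size == 0:
        return _invalid(trial, "no qualifying P2")
    p2 = int(p2_candidates[0])
    feat = N1P2Feature(
        n1_time=(sl.start + n1) / rate,
        p2_time=(sl.start + p2) / rate,
        n1_z=float(z[n1]),
        p2_z=float(z[p2]),
        rms=float("nan"),
        valid=True,
        animal=trial.animal,
        electrode=trial.electrode,
        trial=trial.trial,
        energy_mj=trial.stimulus.energy_mj,
        isi_ms=trial.stimulus.isi_ms,
    )
    feat.rms = rms_n1p2(trial, feat, windows)
    return feat


def rms_n1p2(
    trial: TrialRecording, feature: N1P2Feature, windows: AnalysisWindows | None = None
) -> float:
    """RMS from the stimulus-onset sample through the P2 sample (inclusive)."""
    if not feature.valid:
        return float("nan")
    if windows is None:
        windows = compute_windows(trial.stimulus)
    rate = trial.sampling_rate
    start = windows.slice_for("onset", rate).start
    stop = int(round(feature.p2_time * rate))
    span = np.asarray(trial.lfp[start : stop + 1], dtype=float)
    return float(np.sqrt(np.mean(span**2)))


def dose_response_table(trialset, highpassed: bool = True) -> pd.DataFrame:
    """One row per valid trial: group keys, stimulus, and per-trial N1-P2 RMS."""
    rows = []
    for trial in trialset:
        feat = detect_n1p2(trial)
        rows.append(
            {
                "animal": trial.animal,
                "electrode": trial.electrode,
                "trial": trial.trial,
                "energy_mJ": trial.stimulus.energy_mj,
                "isi_ms": trial.stimulus.isi_ms,
                "rms": feat.rms,
                "valid": feat.valid,
            }
        )
    df = pd.DataFrame(rows)
    return df[df["valid"]].reset_index(drop=True)
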