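"""Spike-field coherence from trial-averaged cross/auto spectra.

SFC(f) = |mean_j S_ny,j(f)| / ( sqrt(mean_j S_nn,j(f)) * sqrt(mean_j S_yy,j(f)) )

with per-trial Hann-tapered periodograms of the binarized spike indicator
(mean-removed) against the LFP. Cauchy-Schwarz bounds SFC to [0, 1]; with a
single trial the ratio is identically 1 wherever defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .core_data import TrialRecording, compute_windows
from .spectral_bands import BANDS


@dataclass
class SFCSpectrum:
    freqs: np.ndarray
    sfc: np.ndarray  # NaN where auto-spectra vanish
    n_trials: int
    unit: int = -1
    electrode: int = -1
    animal: int = -1
    energy_mj: float = float("nan")


def binarize_spikes(spike_times: np.ndarray, rate: float, n_samples: int, offset_s: float = 0.0) -> np.ndarray:
    """0/1 indicator of spike occupancy on the LFP sample grid."""
    out = np.zeros(n_samples)
    idx = np.floor((np.asarray(spike_times, dtype=float) - offset_s) * rate).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samples)]
    out[idx] = 1.0
    return out


def compute_sfc(
    spike_segments: list[np.ndarray],
    lfp_segments: list[np.ndarray],
    rate: float,
    min_trials: int = 1,
) -> SFCSpectrum:
    """SFC spectrum from per-trial binarized spike and LFP window segments."""
    if len(spike_segments) != len(lfp_segments):
        raise ValueError("spike and LFP trial counts differ")
    n_trials = len(spike_segments)
    if n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} trials")
    n = len(lfp_segments[0])
    w = get_window("hann", n)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    s_ny = np.zeros(freqs.size, dtype=complex)
    s_nn = np.zeros(freqs.size)
    s_yy = np.zeros(freqs.size)
    for sp, y in zip(spike_segments, lfp_segments):
        sp = np.asarray(sp, dtype=float)
        y = np.asarray(y, dtype=float)
        if sp.size != n or y.size != n:
            raise ValueError("all segments must share one window length")
        xn = np.fft.rfft((sp - sp.mean()) * w)
        xy = np.fft.rfft((y - y.mean()) * w)
        s_ny += xn * np.conj(xy)
        s_nn += np.abs(xn) ** 2
        s_yy += np.abs(xy) ** 2
    s_ny /= n_trials
    s_nn /= n_trials
    s_yy /= n_trials
    denom = np.sqrt(s_nn) * np.sqrt(s_yy)
    with np.errstate(invalid="ignore", divide="ignore"):
        sfc = np.where(denom > 0, np.abs(s_ny) / denom, np.nan)
    return SFCSpectrum(freqs=freqs, sfc=sfc, n_trials=n_trials)


def sfc_for_unit(
    trials: list[TrialRecording], unit: int, window: str = "onset", min_trials: int = 5
) -> SFCSpectrum:
    """SFC over the chosen analysis window for one unit across trials."""
    if len(trials) < min_trials:
        raise ValueError(f"need >= {min_trials} trials")
    rate = trials[0].sampling_rate
    win = compute_windows(trials[0].stimulus)
    sl = win.slice_for(window, rate)
    t0 = sl.start / rate
    n = sl.stop - sl.start
    spike_segs, lfp_segs = [], []
    total_spikes = 0
    for tr in trials:
        times = tr.spikes.get(unit, np.array([]))
        seg_times = times[(times >= t0) & (times < sl.stop / rate)]
        total_spikes += seg_times.size
        spike_segs.append(binarize_spikes(seg_times, rate, n, offset_s=t0))
        lfp_segs.append(np.asarray(tr.lfp[sl], dtype=float))
    spec = compute_sfc(spike_segs, lfp_segs, rate, min_trials=min_trials)
    spec.unit = unit
    spec.electrode = trials[0].electrode
    spec.animal = trials[0].animal
    spec.energy_mj = trials[0].stimulus.energy_mj
    if total_spikes == 0:
        spec.sfc = np.full_like(spec.sfc, np.nan)
    return spec


def band_sfc(spectrum: SFCSpectrum, band: str | tuple[float, float]) -> float:
    """Mean SFC over the band's frequency bins (NaN bins ignored)."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) outside the frequency grid")
    vals = spectrum.sfc[mask]
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def sfc_table(trialset, bands: dict | None = None, window: str = "onset", min_trials: int = 5):
    """Band-averaged SFC per (unit, channel, energy) across the trial set."""
    import pandas as pd

    bands = bands or BANDS
    groups: dict[tuple, list] = {}
    for tr in trialset:
        for unit in tr.spikes:
            key = (tr.animal, tr.electrode, unit, tr.stimulus.energy_mj, tr.stimulus.isi_ms)
            groups.setdefault(key, []).append(tr)
    rows = []
    for (animal, electrode, unit, e, isi), trials in sorted(groups.items()):
        if len(trials) < min_trials:
            continue
        spec = sfc_for_unit(trials, unit, window=window, min_trials=min_trials)
        for bname in bands:
            rows.append(
                {
                    "animal": animal,
                    "electrode": electrode,
                    "unit": unit,
                    "energy_mJ": e,
                    "isi_ms": isi,
                    "band": bname,
                    "sfc": band_sfc(spec, bname),
                    "n_trials": len(trials),
                }
            )
    return pd.DataFrame(rows)
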