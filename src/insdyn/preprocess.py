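"""Rate conversion, drift filtering, PSTH construction, and responsiveness tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_data import AnalysisWindows, TrialRecording

ANALYSIS_RATE_HZ = 1526.0
#: z >= 2 * 1.96 on the PSTH marks a unit as responsive
RESPONSIVE_Z = 3.92


def _decimation_stages(factor: int) -> list[int]:
    """Split a decimation factor into stages of at most 8 (scipy guidance)."""
    stages = []
    while factor > 8:
        for s in (4, 5, 6, 7, 8, 3, 2):
            if factor % s == 0:
                stages.append(s)
                factor //= s
                break
        else:
            raise ValueError(f"cannot factor decimation {factor} into stages <= 8")
    stages.append(factor)
    return stages


def downsample_lfp(trial: TrialRecording, target_rate: float = ANALYSIS_RATE_HZ) -> TrialRecording:
    """Anti-aliased decimation to the analysis rate.

    The nominal target (e.g. 1526 Hz from 24414.0625 Hz) is accepted when it is
    within 0.5% of original_rate / round(original_rate / target); the output is
    labelled with the nominal target rate.
    """
    orig = trial.sampling_rate
    if target_rate > orig:
        raise ValueError(f"cannot upsample {orig} Hz to {target_rate} Hz")
    if target_rate == orig:
        return trial
    factor = round(orig / target_rate)
    if factor < 2 or abs(orig / factor - target_rate) / target_rate > 0.005:
        raise ValueError(f"{orig} Hz is not an integer decimation of {target_rate} Hz")
    x = np.asarray(trial.lfp, dtype=float)
    for stage in _decimation_stages(factor):
        # 8th-order Chebyshev-I anti-alias stage; 0.01 dB ripple keeps the
        # passband flat enough that zero-phase (squared-response) application
        # preserves in-band amplitudes to well under 1%
        aa = signal.dlti(*signal.cheby1(8, 0.01, 0.8 / stage))
        x = signal.decimate(x, stage, ftype=aa, zero_phase=True)
    expected = round(trial.stimulus.trial_length_s * target_rate)
    if x.size > expected:
        x = x[:expected]
    elif x.size < expected:
        x = np.pad(x, (0, expected - x.size), mode="edge")
    return TrialRecording(
        lfp=x,
        sampling_rate=target_rate,
        spikes=trial.spikes,
        stimulus=trial.stimulus,
        animal=trial.animal,
        electrode=trial.electrode,
        trial=trial.trial,
    )


def cheby2_highpass_sos(cutoff_hz: float, rate: float, order: int = 4, rs_db: float = 40.0):
    """Chebyshev type-II high-pass sections (stopband edge at the cutoff)."""
    if cutoff_hz >= rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    return signal.cheby2(order, rs_db, cutoff_hz, btype="highpass", fs=rate, output="sos")


def highpass_drift(trial: TrialRecording, cutoff_hz: float = 10.0) -> TrialRecording:
    """Zero-phase Chebyshev-II high-pass to remove slow baseline drift."""
    sos = cheby2_highpass_sos(cutoff_hz, trial.sampling_rate)
    x = np.asarray(trial.lfp, dtype=float)
    y = signal.sosfiltfilt(sos, x - x.mean())  # mean removal: Cheb-II DC gain is -rs, not 0
    return TrialRecording(
        lfp=y,
        sampling_rate=trial.sampling_rate,
        spikes=trial.spikes,
        stimulus=trial.stimulus,
        animal=trial.animal,
        electrode=trial.electrode,
        trial=trial.trial,
    )


@dataclass
class PSTH:
    bin_edges: np.ndarray  # (n_bins + 1,) seconds
    rates: np.ndarray  # (n_bins,) Hz
    spontaneous_mean: float
    spontaneous_sd: float
    n_trials: int

    def __post_init__(self) -> None:
        if np.any(self.rates < -1e-12):
            raise ValueError("PSTH rates must be nonnegative")


def build_psth(
    spike_lists: list[np.ndarray],
    windows: AnalysisWindows,
    bin_width_s: float = 0.010,
    trial_length_s: float | None = None,
) -> PSTH:
    """Trial-pooled PSTH; spontaneous stats come from per-trial baseline rates.

    ``spike_lists`` holds one array of spike times per trial; rate per bin is
    count / (n_trials * bin_width).
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width must be > 0")
    n_trials = len(spike_lists)
    if n_trials == 0:
        raise ValueError("need at least one trial")
    if trial_length_s is None:
        trial_length_s = windows.offset[1]
    n_bins = int(np.ceil(trial_length_s / bin_width_s))
    edges = np.arange(n_bins + 1) * bin_width_s
    counts = np.zeros(n_bins)
    base_rates = np.empty(n_trials)
    b0, b1 = windows.baseline
    base_dur = b1 - b0
    for i, spikes in enumerate(spike_lists):
        s = np.asarray(spikes, dtype=float)
        counts += np.histogram(s, bins=edges)[0]
        base_rates[i] = np.count_nonzero((s >= b0) & (s < b1)) / base_dur if base_dur > 0 else 0.0
    rates = counts / (n_trials * bin_width_s)
    return PSTH(
        bin_edges=edges,
        rates=rates,
        spontaneous_mean=float(base_rates.mean()),
        spontaneous_sd=float(base_rates.std(ddof=0)),
        n_trials=n_trials,
    )


@dataclass
class ResponsivenessVerdict:
    responsive: bool
    max_z: float
    threshold: float
    note: str = ""


def classify_responsive(
    psth: PSTH, windows: AnalysisWindows, threshold: float = RESPONSIVE_Z
) -> ResponsivenessVerdict:
    """Responsive iff max PSTH z-score over onset-window bins >= threshold.

    z = (bin rate - spontaneous mean) / spontaneous SD. A zero spontaneous SD
    with any evoked spikes yields an explicit 'undefined z' verdict rather than
    an exception.
    """
    centers = (psth.bin_edges[:-1] + psth.bin_edges[1:]) / 2
    t0, t1 = windows.onset
    mask = (centers >= t0) & (centers < t1)
    stim_rates = psth.rates[mask]
    if stim_rates.size == 0:
        return ResponsivenessVerdict(False, float("nan"), threshold, note="no stimulus bins")
    if psth.spontaneous_sd == 0:
        evoked = stim_rates.max() > psth.spontaneous_mean
        return ResponsivenessVerdict(
            bool(evoked),
            float("inf") if evoked else 0.0,
            threshold,
            note="undefined z; responsive by nonzero evoked count" if evoked else "undefined z",
        )
    z = (stim_rates - psth.spontaneous_mean) / psth.spontaneous_sd
    max_z = float(z.max())
    return ResponsivenessVerdict(max_z >= threshold, max_z, threshold)
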