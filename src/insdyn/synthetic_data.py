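"""Synthetic TrialSets and diagnostic time series with known ground truth.

All generators are pure functions of (config, seed): regenerating with the same
configuration yields bit-identical output. The evoked dose-response obeys
``ln(RMS) = b0 + bE*ln(E) + bISI*ln(ISI) + bX*ln(E)*ln(ISI) + N(0, sigma)``
so regressions fitted downstream can be checked against the generating
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.special import i0

from .core_data import StimulusTrain, TrialRecording, TrialSet, compute_windows

BAND_NAMES = ("theta", "alpha", "beta", "gamma_low", "gamma_high")
BAND_CENTERS = {"theta": 6.0, "alpha": 10.5, "beta": 21.0, "gamma_low": 55.0, "gamma_high": 140.0}
BAND_EDGES = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma_low": (30.0, 80.0),
    "gamma_high": (80.0, 200.0),
}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_trials_per_condition: int = 30
    energy_grid_mj: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0)
    isi_grid_ms: tuple[float, ...] = (5.0,)
    n_pulses: int = 5
    pulse_width_ms: float = 10.0
    prestim_s: float = 0.2
    trial_length_s: float = 1.0
    sampling_rate: float = 1526.0
    n_animals: int = 2
    n_electrodes_per_animal: int = 2
    # dose-response law on ln(N1-P2 template RMS)
    beta0: float = 3.0
    beta_energy: float = 0.087
    beta_isi: float = 0.065
    beta_interaction: float = 0.0
    noise_sigma: float = 0.1
    # evoked template shape (s, relative to stimulus onset)
    n1_latency_s: float = 0.025
    p2_latency_s: float = 0.070
    lobe_width_s: float = 0.012
    # band entrainment: stimulus-gated oscillation amplitude = gain * ln(1 + E)
    band_gains: dict[str, float] = field(
        default_factory=lambda: {"theta": 0.0, "alpha": 0.0, "beta": 2.0, "gamma_low": 3.0, "gamma_high": 1.5}
    )
    isi_component_gain: float = 2.0
    # 1/f background
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    # spiking
    spike_baseline_hz: float = 5.0
    spike_gain_hz_per_mj: float = 20.0
    kappa: float = 0.0
    lock_band: str = "gamma_low"
    units_per_electrode: int = 1


def _rng(seed: int, stream: int = 0) -> np.ndarray.__class__:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _gamma_lobe(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Gamma-density-shaped lobe peaking at ``peak`` with scale ``width``."""
    k = max((peak / width) ** 2, 1.001)
    theta = peak / k
    tt = np.clip(t, 0.0, None)
    shape = tt ** (k - 1) * np.exp(-tt / theta)
    m = shape.max()
    return shape / m if m > 0 else shape


def n1p2_template(cfg: GeneratorConfig, n_samples: int, onset_idx: int) -> np.ndarray:
    """Unit-RMS evoked template: negative N1 lobe followed by positive P2 lobe."""
    t = (np.arange(n_samples) - onset_idx) / cfg.sampling_rate
    w = -_gamma_lobe(t, cfg.n1_latency_s, cfg.lobe_width_s) + 0.8 * _gamma_lobe(
        t, cfg.p2_latency_s, cfg.lobe_width_s * 1.6
    )
    active = np.sqrt(np.mean(w[onset_idx:] ** 2))
    return w / (active if active > 0 else 1.0)


def one_over_f_noise(rng, n: int, rate: float, exponent: float, amplitude: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD ∝ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping, n)
    sd = shaped.std()
    return amplitude * shaped / (sd if sd > 0 else 1.0)


def gen_lfp_trialset(cfg: GeneratorConfig) -> TrialSet:
    """Generate per-trial LFPs with evoked template, band entrainment, ISI-locked
    component and 1/f background (deterministic given cfg.seed)."""
    rate = cfg.sampling_rate
    n_samples = round(cfg.trial_length_s * rate)
    trials: list[TrialRecording] = []
    channel_list = [
        (a, e) for a in range(cfg.n_animals) for e in range(cfg.n_electrodes_per_animal)
    ]
    cond_list = [(E, isi) for E in cfg.energy_grid_mj for isi in cfg.isi_grid_ms]
    trial_counter = {ch: 0 for ch in channel_list}
    for ci, (E, isi) in enumerate(cond_list):
        stim = StimulusTrain(
            energy_mj=E,
            isi_ms=isi,
            n_pulses=cfg.n_pulses,
            pulse_width_ms=cfg.pulse_width_ms,
            prestim_s=cfg.prestim_s,
            trial_length_s=cfg.trial_length_s,
        )
        onset_idx = round(cfg.prestim_s * rate)
        template = n1p2_template(cfg, n_samples, onset_idx)
        t = np.arange(n_samples) / rate
        train_gate = (t >= stim.prestim_s) & (t < stim.prestim_s + stim.train_duration_s + 0.1)
        # ISI-rate component at the pulse repetition rate 1/(width+isi)
        f_pulse = 1000.0 / (cfg.pulse_width_ms + isi)
        for ch_i, (animal, electrode) in enumerate(channel_list):
            rng = _rng(cfg.seed, stream=1 + ci * 1000 + ch_i)
            for _ in range(cfg.n_trials_per_condition):
                x = one_over_f_noise(rng, n_samples, rate, cfg.noise_exponent, cfg.noise_amplitude)
                if E > 0:
                    ln_rms = (
                        cfg.beta0
                        + cfg.beta_energy * np.log(E)
                        + cfg.beta_isi * np.log(isi)
                        + cfg.beta_interaction * np.log(E) * np.log(isi)
                        + (cfg.noise_sigma * rng.standard_normal() if cfg.noise_sigma > 0 else 0.0)
                    )
                    x = x + np.exp(ln_rms) * template
                    for band, gain in cfg.band_gains.items():
                        if gain <= 0:
                            continue
                        amp = gain * np.log1p(E)
                        phase = rng.uniform(0, 2 * np.pi)
                        x = x + amp * train_gate * np.sin(
                            2 * np.pi * BAND_CENTERS[band] * t + phase
                        )
                    if cfg.isi_component_gain > 0 and f_pulse < rate / 2:
                        amp = cfg.isi_component_gain * np.log1p(E)
                        x = x + amp * train_gate * np.sin(2 * np.pi * f_pulse * t)
                trials.append(
                    TrialRecording(
                        lfp=x.astype("<f4"),
                        sampling_rate=rate,
                        spikes={},
                        stimulus=stim,
                        animal=animal,
                        electrode=electrode,
                        trial=trial_counter[(animal, electrode)],
                    )
                )
                trial_counter[(animal, electrode)] += 1
    manifest = {"generator": asdict(cfg), "seed": cfg.seed}
    manifest["generator"]["energy_grid_mj"] = list(cfg.energy_grid_mj)
    manifest["generator"]["isi_grid_ms"] = list(cfg.isi_grid_ms)
    return TrialSet(trials=trials, manifest=manifest)


def band_phase(lfp: np.ndarray, rate: float, band: str) -> np.ndarray:
    """Instantaneous phase of a band-limited component (Hilbert transform)."""
    lo, hi = BAND_EDGES[band]
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return np.angle(hilbert(sosfiltfilt(sos, np.asarray(lfp, dtype=float))))


def gen_spike_trains(cfg: GeneratorConfig, trialset: TrialSet) -> TrialSet:
    """Attach spikes from an inhomogeneous point process phase-locked to the LFP.

    Rate is ``lambda0 + gain*E`` inside the onset window, modulated by a
    von Mises factor ``exp(kappa*cos(phi - mu))/I0(kappa)`` on the phase of the
    configured band (mean 1 under uniform phase, so kappa=0 leaves the rate
    unchanged and spiking independent of the LFP).
    """
    rate = trialset.sampling_rate
    out: list[TrialRecording] = []
    for i, tr in enumerate(trialset):
        rng = _rng(cfg.seed, stream=10_000_000 + i)
        win = compute_windows(tr.stimulus)
        t = tr.times
        lam = np.full(t.size, cfg.spike_baseline_hz, dtype=float)
        on = (t >= win.onset[0]) & (t < win.onset[1])
        lam[on] += cfg.spike_gain_hz_per_mj * tr.stimulus.energy_mj
        if cfg.kappa > 0:
            phi = band_phase(tr.lfp, rate, cfg.lock_band)
            lam = lam * np.exp(cfg.kappa * np.cos(phi)) / i0(cfg.kappa)
        spikes: dict[int, np.ndarray] = {}
        for unit in range(cfg.units_per_electrode):
            p = np.clip(lam / rate, 0.0, 1.0)
            fire = rng.random(t.size) < p
            times = t[fire] + rng.uniform(0, 1.0 / rate, fire.sum())
            times = times[times <= tr.stimulus.trial_length_s]
            spikes[unit] = np.sort(times)
        out.append(
            TrialRecording(
                lfp=tr.lfp,
                sampling_rate=rate,
                spikes=spikes,
                stimulus=tr.stimulus,
                animal=tr.animal,
                electrode=tr.electrode,
                trial=tr.trial,
            )
        )
    return TrialSet(trials=out, manifest=dict(trialset.manifest))


def gen_dynamics_series(kind: str, n: int, params: dict | None = None, seed: int = 0) -> np.ndarray:
    """Calibration series for the 0-1 chaos test.

    kinds: ``sine`` (amplitude 1), ``logistic`` (x_{k+1} = r x_k (1-x_k),
    1000-sample burn-in discarded), ``ar1`` (Gaussian AR(1)), ``constant``.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    params = dict(params or {})
    rng = _rng(seed, stream=77)
    if kind == "sine":
        f = params.get("freq_hz", 5.0)
        rate = params.get("rate_hz", 1526.0)
        return np.sin(2 * np.pi * f * np.arange(n) / rate)
    if kind == "logistic":
        r = params.get("r", 4.0)
        x0 = params.get("x0", 0.2)
        if not (0.0 < x0 < 1.0):
            raise ValueError("logistic x0 must lie in (0, 1)")
        burn = params.get("burn_in", 1000)
        x = x0
        for _ in range(burn):
            x = r * x * (1 - x)
        out = np.empty(n)
        for i in range(n):
            x = r * x * (1 - x)
            out[i] = x
        return out
    if kind == "ar1":
        phi = params.get("phi", 0.5)
        sigma = params.get("sigma", 1.0)
        eps = rng.standard_normal(n + 100) * sigma
        out = np.empty(n + 100)
        out[0] = eps[0]
        for i in range(1, n + 100):
            out[i] = phi * out[i - 1] + eps[i]
        return out[100:]
    if kind == "constant":
        return np.full(n, params.get("level", 1.0))
    raise ValueError(f"unknown kind {kind!r}")


def gen_regime_features(
    n_points: int = 300,
    seed: int = 7,
    mi_split: float = 0.4,
    separation: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(MI bits, K) feature pairs from a two-cluster mixture with ground truth.

    Cluster 0: low-information (MI < 0.4) responses with K near 1.
    Cluster 1: high-information (MI > 0.4) responses with bimodal K (low & high).
    Returns ``(points, labels)`` where points has shape (n_points, 2) = (MI, K).
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    rng = _rng(seed, stream=42)
    n0 = n_points // 2
    n1 = n_points - n0
    mi0 = np.clip(rng.normal(0.12, 0.06, n0), 0.0, mi_split - 0.02)
    k0 = np.clip(rng.normal(0.92, 0.05, n0), 0.0, 1.0)
    mi1 = np.clip(rng.normal(0.4 + 0.6 * separation, 0.25, n1), mi_split + 0.02, None)
    half = n1 // 2
    k_lo = np.clip(rng.normal(0.40, 0.13, half), 0.0, 1.0)
    k_hi = np.clip(rng.normal(0.65, 0.13, n1 - half), 0.0, 1.0)
    k1 = np.concatenate([k_lo, k_hi])
    pts = np.column_stack(
        [np.concatenate([mi0, mi1]), np.concatenate([k0, k1])]
    )
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    perm = rng.permutation(n_points)
    return pts[perm], labels[perm]
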