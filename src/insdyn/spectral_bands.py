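"""Wavelet band decomposition, band power, dB change, and band correlations.

The time-frequency transform is an FFT-implemented analytic Morlet CWT
(center frequency omega0 = 6 rad, 12 voices per octave). The returned density
S(f, t) is normalized so that ``2 * integral(S df)`` over a band containing a
sinusoid recovers the sinusoid's time-domain power A^2/2, matching the
band-power definition ``P_f = 2 * int S_f df`` (frequency-folding factor 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.stats import pearsonr

from .core_data import AnalysisWindows

OMEGA0 = 6.0
VOICES_PER_OCTAVE = 12

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma_low": (30.0, 80.0),
    "gamma_high": (80.0, 200.0),
}


def default_freq_grid(f_lo: float = 4.0, f_hi: float = 200.0) -> np.ndarray:
    """Log-spaced grid, 12 voices per octave, inclusive of both edges."""
    n_oct = np.log2(f_hi / f_lo)
    n = int(np.ceil(n_oct * VOICES_PER_OCTAVE)) + 1
    grid = f_lo * 2 ** (np.arange(n) / VOICES_PER_OCTAVE)
    if grid[-1] < f_hi:
        grid = np.append(grid, f_hi)
    grid[-1] = min(grid[-1], f_hi)
    return grid


@dataclass
class CWTResult:
    freqs: np.ndarray  # (n_f,)
    power: np.ndarray  # (n_f, n_t) density S(f, t)
    rate: float
    coi_s: np.ndarray  # (n_f,) cone-of-influence half-width in seconds

    def window_mean(self, t0: float, t1: float, exclude_coi: bool = True) -> np.ndarray:
        """Time-averaged density over [t0, t1) per frequency, COI-excluded."""
        n = self.power.shape[1]
        t = np.arange(n) / self.rate
        duration = n / self.rate
        out = np.empty(self.freqs.size)
        for i in range(self.freqs.size):
            mask = (t >= t0) & (t < t1)
            if exclude_coi:
                mask &= (t >= self.coi_s[i]) & (t <= duration - self.coi_s[i])
            out[i] = self.power[i, mask].mean() if mask.any() else np.nan
        return out


def cwt_decompose(lfp: np.ndarray, rate: float, freq_grid: np.ndarray | None = None) -> CWTResult:
    """Analytic Morlet power density over a log-spaced frequency grid."""
    x = np.asarray(lfp, dtype=float)
    if freq_grid is None:
        freq_grid = default_freq_grid()
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid <= 0) or np.any(freq_grid >= rate / 2):
        raise ValueError("frequency grid must lie inside (0, Nyquist)")
    n = x.size
    # pad to reduce wrap-around of the low-frequency wavelets
    n_fft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.fft(x, n_fft)
    omega = 2 * np.pi * np.fft.fftfreq(n_fft, 1.0 / rate)
    pos = omega > 0
    power = np.empty((freq_grid.size, n))
    for i, f in enumerate(freq_grid):
        s = OMEGA0 / (2 * np.pi * f)  # scale in seconds
        H = np.zeros(n_fft)
        H[pos] = np.sqrt(2.0) * np.exp(-0.5 * (s * omega[pos] - OMEGA0) ** 2)
        w = np.fft.ifft(X * H)[:n]
        power[i] = (np.abs(w) ** 2) * OMEGA0 / (2 * np.sqrt(np.pi) * f)
    coi = np.sqrt(2.0) * OMEGA0 / (2 * np.pi * freq_grid)
    return CWTResult(freqs=freq_grid, power=power, rate=rate, coi_s=coi)


def band_power(
    mean_density: np.ndarray, freqs: np.ndarray, band: str | tuple[float, float]
) -> float:
    """P_f = 2 * Simpson integral of the time-averaged density over the band.

    The exact band edges are included as integration nodes (density linearly
    interpolated) so that band power covers [f_lo, f_hi] rather than only the
    grid points that happen to fall inside.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    freqs = np.asarray(freqs, dtype=float)
    dens = np.asarray(mean_density, dtype=float)
    lo_c = max(lo, freqs[0])
    hi_c = min(hi, freqs[-1])
    if hi_c <= lo_c:
        raise ValueError(f"band ({lo}, {hi}) not covered by frequency grid")
    interior = (freqs > lo_c) & (freqs < hi_c)
    f_in = np.concatenate([[lo_c], freqs[interior], [hi_c]])
    s_in = np.concatenate(
        [[np.interp(lo_c, freqs, dens)], dens[interior], [np.interp(hi_c, freqs, dens)]]
    )
    if f_in.size < 3:
        warnings.warn("fewer than 3 grid points in band; falling back to trapezoid")
        return float(2.0 * np.trapezoid(s_in, f_in))
    return float(2.0 * simpson(s_in, x=f_in))


def db_change(p_f: float, mu_b: float) -> float:
    """Stimulus-induced change from baseline: 10*log10(P_f / mu_b)."""
    if mu_b <= 0:
        return float("nan")
    return float(10.0 * np.log10(p_f / mu_b))


def band_power_table(trialset, bands: dict | None = None, exclude_coi: bool = True) -> pd.DataFrame:
    """Per-trial, per-band powers and dB change for onset and offset windows.

    Expects LFPs at the analysis rate with only the hardware-style high-pass
    applied (no 10 Hz filter).
    """
    from .core_data import compute_windows

    bands = bands or BANDS
    rows = []
    for trial in trialset:
        win = compute_windows(trial.stimulus)
        res = cwt_decompose(trial.lfp, trial.sampling_rate)
        base = res.window_mean(*win.baseline, exclude_coi=exclude_coi)
        for wname in ("onset", "offset"):
            t0, t1 = getattr(win, wname)
            mean_d = res.window_mean(t0, t1, exclude_coi=exclude_coi)
            for bname in bands:
                good = ~np.isnan(mean_d) & ~np.isnan(base)
                lo, hi = BANDS[bname]
                bmask = (res.freqs >= lo) & (res.freqs <= hi) & good
                if bmask.sum() < 2:
                    continue
                p = band_power(np.where(good, mean_d, 0.0), res.freqs, bname)
                mu = band_power(np.where(good, base, 0.0), res.freqs, bname)
                rows.append(
                    {
                        "animal": trial.animal,
                        "electrode": trial.electrode,
                        "trial": trial.trial,
                        "energy_mJ": trial.stimulus.energy_mj,
                        "isi_ms": trial.stimulus.isi_ms,
                        "window": wname,
                        "band": bname,
                        "power": p,
                        "baseline_power": mu,
                        "db_change": db_change(p, mu),
                    }
                )
    return pd.DataFrame(rows)


def shuffle_pearson(
    x: np.ndarray, y: np.ndarray, n_shuffle: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Pearson R with a permutation two-sided p: Pr(|R_shuffled| >= |R|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = pearsonr(x, y).statistic
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = 0
    for _ in range(n_shuffle):
        perm = rng.permutation(x.size)
        r_s = (xc[perm] * yc).sum() / denom
        if abs(r_s) >= abs(r) - 1e-15:
            count += 1
    p = (count + 1) / (n_shuffle + 1)
    return float(r), float(p)


def band_correlations(
    table: pd.DataFrame,
    pair: tuple[str, str],
    window: str = "onset",
    energy_bin_width: float = 0.5,
    n_shuffle: int = 1000,
    seed: int = 0,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson R between two bands' powers within 500 uJ energy bins."""
    b1, b2 = pair
    sub = table[table["window"] == window]
    t1 = sub[sub["band"] == b1].set_index(["animal", "electrode", "trial", "energy_mJ", "isi_ms"])
    t2 = sub[sub["band"] == b2].set_index(["animal", "electrode", "trial", "energy_mJ", "isi_ms"])
    joined = t1[["power"]].join(t2[["power"]], lsuffix="_1", rsuffix="_2", how="inner").reset_index()
    joined["energy_bin"] = np.floor(joined["energy_mJ"] / energy_bin_width) * energy_bin_width
    rows = []
    for i, (bin_lo, grp) in enumerate(joined.groupby("energy_bin")):
        if len(grp) < min_pairs:
            continue
        r, p = shuffle_pearson(
            grp["power_1"].to_numpy(), grp["power_2"].to_numpy(), n_shuffle, seed + i
        )
        rows.append(
            {
                "energy_bin_lo": float(bin_lo),
                "band_1": b1,
                "band_2": b2,
                "window": window,
                "r": r,
                "p": p,
                "n": len(grp),
                "significant": p < 0.05,
            }
        )
    return pd.DataFrame(rows)
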