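"""Temporal modulation transfer functions at the stimulus ISI frequency.

Power is evaluated exactly at the ISI frequency with Bluestein's algorithm
(chirp z-transform) on Hann-tapered windows, with power-spectrum (not density)
scaling: a tone of amplitude A contributes A^2/2 regardless of window length,
so the unequal baseline/stimulation windows are directly comparable.
tMTF = 10*log10(P_s / P_B); |tMTF| >= 3 dB (a power doubling) marks
significant modulation. ISI frequencies at or above 763 Hz violate the
analysis Nyquist criterion and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import czt, get_window

from .core_data import StimulusTrain, compute_windows

NYQUIST_LIMIT_HZ = 763.0
SIGNIFICANCE_DB = 3.0

DEFAULT_ISI_FREQS_HZ = (10.0, 20.0, 40.0, 100.0, 200.0)
DEFAULT_ENERGY_BIN_EDGES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, np.inf)


def isi_frequency(stim: StimulusTrain, convention: str = "isi") -> float:
    """Stimulus repetition frequency: 1/ISI, or 1/(width+ISI) if requested."""
    if convention == "isi":
        return 1000.0 / stim.isi_ms
    if convention == "pulse_period":
        return 1000.0 / (stim.pulse_width_ms + stim.isi_ms)
    raise ValueError(f"unknown convention {convention!r}")


def power_at_frequency(x: np.ndarray, rate: float, f: float, window: str = "hann") -> float:
    """One-sided tone power at exactly ``f`` via the chirp z-transform.

    Spectrum scaling (2*|X/sum(w)|^2): a sinusoid of amplitude A at ``f``
    returns A^2/2 independent of window length.
    """
    if f >= NYQUIST_LIMIT_HZ or f >= rate / 2:
        raise ValueError(f"f={f} Hz violates the Nyquist criterion")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * rate / f:
        raise ValueError(f"window too short: need >= 2 cycles of {f} Hz")
    w = get_window(window, n)
    xw = (x - x.mean()) * w
    # single-point Bluestein evaluation of the DFT at frequency f
    a = np.exp(2j * np.pi * f / rate)
    X = czt(xw, m=1, a=a)[0]
    return float(2.0 * np.abs(X) ** 2 / np.sum(w) ** 2)


@dataclass
class TMTFResult:
    f_isi: float
    p_stim: float
    p_base: float
    tmtf_db: float
    significant: str  # 'increase' | 'decrease' | 'none' | 'undefined' | 'nyquist'
    energy_mj: float = float("nan")
    isi_ms: float = float("nan")


def classify_tmtf(tmtf_db: float) -> str:
    if np.isnan(tmtf_db):
        return "undefined"
    if tmtf_db >= SIGNIFICANCE_DB:
        return "increase"
    if tmtf_db <= -SIGNIFICANCE_DB:
        return "decrease"
    return "none"


def compute_tmtf(
    lfp: np.ndarray,
    rate: float,
    stim: StimulusTrain,
    f_isi: float | None = None,
    convention: str = "isi",
) -> TMTFResult:
    """tMTF for one response: baseline = 200 ms prestimulus, stimulation =
    train duration + 100 ms."""
    if f_isi is None:
        f_isi = isi_frequency(stim, convention)
    win = compute_windows(stim)
    if f_isi >= NYQUIST_LIMIT_HZ:
        return TMTFResult(f_isi, float("nan"), float("nan"), float("nan"), "nyquist",
                          stim.energy_mj, stim.isi_ms)
    x = np.asarray(lfp, dtype=float)
    sb = win.slice_for("baseline", rate)
    ss = win.slice_for("onset", rate)
    p_b = power_at_frequency(x[sb], rate, f_isi)
    p_s = power_at_frequency(x[ss], rate, f_isi)
    if p_b <= 0:
        return TMTFResult(f_isi, p_s, p_b, float("nan"), "undefined",
                          stim.energy_mj, stim.isi_ms)
    db = float(10.0 * np.log10(p_s / p_b))
    return TMTFResult(f_isi, p_s, p_b, db, classify_tmtf(db), stim.energy_mj, stim.isi_ms)


def tmtf_table(trialset, convention: str = "isi") -> pd.DataFrame:
    """One tMTF per (channel, condition) computed on the trial-mean LFP."""
    groups: dict[tuple, list] = {}
    for t in trialset:
        key = (t.animal, t.electrode, t.stimulus.energy_mj, t.stimulus.isi_ms)
        groups.setdefault(key, []).append(t)
    rows = []
    for (animal, electrode, e, isi), trials in sorted(groups.items()):
        mean_lfp = np.mean([np.asarray(t.lfp, dtype=float) for t in trials], axis=0)
        res = compute_tmtf(mean_lfp, trials[0].sampling_rate, trials[0].stimulus,
                           convention=convention)
        rows.append(
            {
                "animal": animal,
                "electrode": electrode,
                "energy_mJ": e,
                "isi_ms": isi,
                "f_isi_hz": res.f_isi,
                "p_stim": res.p_stim,
                "p_base": res.p_base,
                "tmtf_db": res.tmtf_db,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def tmtf_proportions(
    results: pd.DataFrame,
    energy_bin_edges: tuple = DEFAULT_ENERGY_BIN_EDGES,
    isi_freqs: tuple = DEFAULT_ISI_FREQS_HZ,
) -> pd.DataFrame:
    """% of responses above (+3 dB) and below (-3 dB) per (energy bin, f_isi).

    Empty cells are reported with NaN percentages (printed as N/A).
    """
    if results.empty:
        raise ValueError("no tMTF results to aggregate")
    edges = np.asarray(energy_bin_edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        for f in isi_freqs:
            cell = results[
                (results["energy_mJ"] >= lo)
                & (results["energy_mJ"] < hi)
                & (np.isclose(results["f_isi_hz"], f))
                & (results["significant"] != "nyquist")
            ]
            n = len(cell)
            rows.append(
                {
                    "energy_bin": f"{lo:g}-{hi:g} mJ" if np.isfinite(hi) else f">{lo:g} mJ",
                    "f_isi_hz": f,
                    "pct_increase": 100.0 * (cell["significant"] == "increase").mean() if n else float("nan"),
                    "pct_decrease": 100.0 * (cell["significant"] == "decrease").mean() if n else float("nan"),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
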