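"""Domain types, trial/window arithmetic, and on-disk I/O for trial-epoched recordings.

Time convention: seconds, trial-relative, 0 = trial start. Sample indices are
0-based; all windows are half-open ``[start, end)``. Window-to-sample conversion
uses exact rational arithmetic so that boundaries are reproducible at any
sampling rate.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1

#: default laser pulse width (ms) when a dataset does not record it
DEFAULT_PULSE_WIDTH_MS = 10.0


class InvalidStimulusError(ValueError):
    """Stimulus train parameters violate their physical bounds."""


class SchemaError(ValueError):
    """On-disk manifest is missing required fields or malformed."""


@dataclass(frozen=True)
class StimulusTrain:
    """Laser pulse-train parameters for one trial.

    ``isi`` is the offset-to-onset gap between successive pulses (ms).
    """

    energy_mj: float
    isi_ms: float
    n_pulses: int = 5
    pulse_width_ms: float = DEFAULT_PULSE_WIDTH_MS
    prestim_s: float = 0.2
    trial_length_s: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.energy_mj <= 4.5):
            raise InvalidStimulusError(f"energy_mj={self.energy_mj} outside [0, 4.5]")
        if not (0.2 <= self.isi_ms <= 100.0):
            raise InvalidStimulusError(f"isi_ms={self.isi_ms} outside [0.2, 100]")
        if self.n_pulses < 1:
            raise InvalidStimulusError("n_pulses must be >= 1")
        if not (0.1 <= self.pulse_width_ms <= 100.0):
            raise InvalidStimulusError(f"pulse_width_ms={self.pulse_width_ms} outside [0.1, 100]")
        if self.prestim_s < 0 or self.trial_length_s <= 0:
            raise InvalidStimulusError("prestim/trial_length must be nonnegative/positive")
        if self.prestim_s + self.train_duration_s > self.trial_length_s:
            raise InvalidStimulusError(
                "stimulus train extends past trial end: "
                f"prestim {self.prestim_s} s + train {self.train_duration_s} s "
                f"> trial {self.trial_length_s} s"
            )

    @property
    def train_duration_s(self) -> float:
        ms = self.n_pulses * self.pulse_width_ms + (self.n_pulses - 1) * self.isi_ms
        return ms / 1000.0

    def pulse_onsets_s(self) -> np.ndarray:
        """Trial-relative onset time of each laser pulse."""
        period = (self.pulse_width_ms + self.isi_ms) / 1000.0
        return self.prestim_s + period * np.arange(self.n_pulses)


@dataclass(frozen=True)
class AnalysisWindows:
    """Half-open analysis windows (s) derived from a stimulus train."""

    baseline: tuple[float, float]
    onset: tuple[float, float]
    offset: tuple[float, float]
    n1p2_search: tuple[float, float]

    def slice_for(self, name: str, rate: float) -> slice:
        """Sample slice for a window, exact via rational arithmetic."""
        t0, t1 = getattr(self, name)
        return slice(sample_index(t0, rate), sample_index(t1, rate))


def sample_index(t: float, rate: float) -> int:
    """0-based index of the first sample at or after time ``t`` (exact)."""
    frac = Fraction(t).limit_denominator(10**9) * Fraction(rate).limit_denominator(10**9)
    num, den = frac.numerator, frac.denominator
    return -((-num) // den)  # ceil for exact half-open boundaries


def compute_windows(stim: StimulusTrain, onset_pad_s: float = 0.1, n1p2_pad_s: float = 0.15) -> AnalysisWindows:
    """Baseline / onset / offset / N1-P2-search windows for one stimulus.

    Onset runs from stimulus onset through train end + 100 ms; offset runs from
    onset end to the end of the trial; the N1-P2 search is constrained to
    150 ms after the train end.
    """
    t_on = stim.prestim_s
    t_train_end = t_on + stim.train_duration_s
    onset_end = min(t_train_end + onset_pad_s, stim.trial_length_s)
    search_end = min(t_train_end + n1p2_pad_s, stim.trial_length_s)
    return AnalysisWindows(
        baseline=(0.0, t_on),
        onset=(t_on, onset_end),
        offset=(onset_end, stim.trial_length_s),
        n1p2_search=(t_on, search_end),
    )


@dataclass
class TrialRecording:
    """One trial: LFP waveform, per-unit spike times, and its stimulus.

    LFP samples are stored as little-endian float32 (the on-disk precision) so
    that save/load round-trips are bit-exact.
    """

    lfp: np.ndarray
    sampling_rate: float
    spikes: dict[int, np.ndarray]
    stimulus: StimulusTrain
    animal: int = 0
    electrode: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype="<f4")
        expected = round(self.stimulus.trial_length_s * self.sampling_rate)
        if self.lfp.shape != (expected,):
            raise ValueError(
                f"lfp length {self.lfp.shape} != round(trial_length*rate) = {expected}"
            )
        clean = {}
        for unit, times in self.spikes.items():
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.stimulus.trial_length_s):
                raise ValueError(f"unit {unit} spike times outside [0, trial_length]")
            clean[int(unit)] = t
        self.spikes = clean

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.animal, self.electrode, self.trial)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.lfp.size) / self.sampling_rate


@dataclass
class TrialSet:
    """Collection of trials plus study-level metadata."""

    trials: list[TrialRecording]
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [t.key for t in self.trials]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (animal, electrode, trial) keys in TrialSet")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate

    def channels(self) -> list[tuple[int, int]]:
        return sorted({(t.animal, t.electrode) for t in self.trials})

    def by_channel(self, animal: int, electrode: int) -> list[TrialRecording]:
        return [t for t in self.trials if (t.animal, t.electrode) == (animal, electrode)]


_REQUIRED_MANIFEST = ("schema_version", "sampling_rate", "trial_length_s", "prestim_s", "trials")


def save_trialset(ts: TrialSet, path: str | Path) -> Path:
    """Write a TrialSet as manifest.json + per-channel LFP matrix + spike CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rate = ts.sampling_rate
    trial_rows = []
    for ch_i, (animal, electrode) in enumerate(ts.channels()):
        trials = ts.by_channel(animal, electrode)
        mat = np.stack([t.lfp for t in trials]).astype("<f4")
        np.save(path / f"lfp_a{animal}_e{electrode}.npy", mat)
        with open(path / f"spikes_a{animal}_e{electrode}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial", "unit", "time_s"])
            for t in trials:
                for unit, times in sorted(t.spikes.items()):
                    for s in times:
                        w.writerow([t.trial, unit, format(float(s), ".17g")])
        for t in trials:
            st = t.stimulus
            trial_rows.append(
                {
                    "animal": animal,
                    "electrode": electrode,
                    "trial": t.trial,
                    "energy_mJ": st.energy_mj,
                    "isi_ms": st.isi_ms,
                    "n_pulses": st.n_pulses,
                    "pulse_width_ms": st.pulse_width_ms,
                    "units": sorted(t.spikes),
                }
            )
    first = ts.trials[0].stimulus
    manifest = dict(ts.manifest)
    manifest.update(
        schema_version=SCHEMA_VERSION,
        sampling_rate=rate,
        trial_length_s=first.trial_length_s,
        prestim_s=first.prestim_s,
        trials=trial_rows,
    )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    missing = [k for k in _REQUIRED_MANIFEST if k not in manifest]
    if missing:
        raise SchemaError(f"manifest missing fields: {missing}")
    rate = manifest["sampling_rate"]
    trial_len = manifest["trial_length_s"]
    prestim = manifest["prestim_s"]

    by_channel: dict[tuple[int, int], list[dict]] = {}
    for row in manifest["trials"]:
        by_channel.setdefault((row["animal"], row["electrode"]), []).append(row)

    trials: list[TrialRecording] = []
    for (animal, electrode), rows in sorted(by_channel.items()):
        mat = np.load(path / f"lfp_a{animal}_e{electrode}.npy")
        spikes_by_trial: dict[int, dict[int, list[float]]] = {}
        with open(path / f"spikes_a{animal}_e{electrode}.csv", newline="") as fh:
            for rec in csv.DictReader(fh):
                spikes_by_trial.setdefault(int(rec["trial"]), {}).setdefault(
                    int(rec["unit"]), []
                ).append(float(rec["time_s"]))
        for i, row in enumerate(sorted(rows, key=lambda r: r["trial"])):
            stim = StimulusTrain(
                energy_mj=row["energy_mJ"],
                isi_ms=row["isi_ms"],
                n_pulses=row["n_pulses"],
                pulse_width_ms=row["pulse_width_ms"],
                prestim_s=prestim,
                trial_length_s=trial_len,
            )
            got = spikes_by_trial.get(row["trial"], {})
            spikes = {u: np.asarray(got.get(u, []), dtype=float) for u in row.get("units", got)}
            trials.append(
                TrialRecording(
                    lfp=mat[i],
                    sampling_rate=rate,
                    spikes=spikes,
                    stimulus=stim,
                    animal=animal,
                    electrode=electrode,
                    trial=row["trial"],
                )
            )
    meta = {k: v for k, v in manifest.items() if k != "trials"}
    return TrialSet(trials=trials, manifest=meta)
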