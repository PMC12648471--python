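"""End-to-end orchestration: simulate -> preprocess -> evoked -> spectral ->
tmtf -> nonlinear -> sfc -> bayes, with per-stage seeds, CSV outputs, and a
JSON summary. Deterministic given the global seed; disabling one stage never
alters another stage's outputs (per-stage seeds are derived as seed + stage
index, independent of which stages run)."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes_models, evoked_response, nonlinear_dynamics, spectral_bands, spike_field, tmtf
from .core_data import TrialSet, compute_windows, load_trialset, save_trialset
from .preprocess import downsample_lfp, highpass_drift
from .synthetic_data import GeneratorConfig, gen_lfp_trialset, gen_spike_trains

log = logging.getLogger("insdyn")

STAGES = ("simulate", "preprocess", "evoked", "spectral", "tmtf", "nonlinear", "sfc", "bayes")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "input_dir": None,
    "simulate": {},
    "preprocess": {"target_rate": 1526.0, "highpass_hz": 10.0},
    "nonlinear": {"n_c": 100},
    "bayes": {"chains": 4, "draws": 2000, "warmup": 1000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def stage_seed(config: dict, stage: str) -> int:
    return int(config["seed"]) + STAGES.index(stage)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_csv(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    df.to_csv(out_dir / name, index=False, float_format="%.10g")


def run_pipeline(config: dict, out_dir: str | Path, trialset: TrialSet | None = None) -> dict:
    """Run the enabled stages and write the report bundle to ``out_dir``.

    Returns a summary dict (also written as summary.json).
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(config, indent=1, default=str))
    stages = list(config["stages"])
    summary: dict = {"stages": {}, "seed": config["seed"]}

    def record(stage: str, **info):
        summary["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    ts = trialset
    if "simulate" in stages:
        try:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", stage_seed(config, "simulate"))
            cfg = GeneratorConfig(**sim_kwargs)
            ts = gen_lfp_trialset(cfg)
            ts = gen_spike_trains(cfg, ts)
            record("simulate", n_trials=len(ts), n_channels=len(ts.channels()))
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", e) from e
    elif ts is None and config.get("input_dir"):
        ts = load_trialset(config["input_dir"])
    if ts is None:
        raise StageError("simulate", ValueError("no input TrialSet and simulate disabled"))

    if "preprocess" in stages:
        try:
            pp = config["preprocess"]
            trials = []
            for tr in ts:
                if tr.sampling_rate > pp["target_rate"]:
                    tr = downsample_lfp(tr, pp["target_rate"])
                trials.append(tr)
            ts = TrialSet(trials=trials, manifest=dict(ts.manifest))
            record("preprocess", n_trials=len(ts), rate=ts.sampling_rate)
        except Exception as e:  # noqa: BLE001
            raise StageError("preprocess", e) from e

    hp = None
    if {"evoked", "nonlinear", "bayes"} & set(stages):
        cutoff = config["preprocess"]["highpass_hz"]
        hp = TrialSet(
            trials=[highpass_drift(tr, cutoff) for tr in ts], manifest=dict(ts.manifest)
        )

    dose = None
    if "evoked" in stages:
        try:
            dose = evoked_response.dose_response_table(hp)
            _write_csv(dose, out_dir, "dose_response.csv")
            record("evoked", n_valid=len(dose))
        except Exception as e:  # noqa: BLE001
            raise StageError("evoked", e) from e

    band_table = None
    if "spectral" in stages:
        try:
            band_table = spectral_bands.band_power_table(ts)
            _write_csv(band_table, out_dir, "band_power.csv")
            corr = pd.concat(
                [
                    spectral_bands.band_correlations(
                        band_table, pair, seed=stage_seed(config, "spectral")
                    )
                    for pair in (("beta", "gamma_low"), ("beta", "gamma_high"), ("gamma_low", "gamma_high"))
                ],
                ignore_index=True,
            )
            _write_csv(corr, out_dir, "band_correlations.csv")
            record("spectral", n_rows=len(band_table))
        except Exception as e:  # noqa: BLE001
            raise StageError("spectral", e) from e

    if "tmtf" in stages:
        try:
            tm = tmtf.tmtf_table(ts)
            _write_csv(tm, out_dir, "tmtf.csv")
            _write_csv(tmtf.tmtf_proportions(tm), out_dir, "tmtf_proportions.csv")
            record("tmtf", n_responses=len(tm))
        except Exception as e:  # noqa: BLE001
            raise StageError("tmtf", e) from e

    if "nonlinear" in stages:
        try:
            nl_seed = stage_seed(config, "nonlinear")
            ccfg = nonlinear_dynamics.ChaosConfig(
                n_c=config["nonlinear"]["n_c"], seed=nl_seed
            )
            rows = []
            groups: dict[tuple, list] = {}
            for tr in hp:
                key = (tr.animal, tr.electrode, tr.stimulus.energy_mj, tr.stimulus.isi_ms)
                groups.setdefault(key, []).append(tr)
            for (animal, electrode, e, isi), trs in sorted(groups.items()):
                win = compute_windows(trs[0].stimulus)
                sl = slice(
                    win.slice_for("onset", trs[0].sampling_rate).start,
                    win.slice_for("offset", trs[0].sampling_rate).stop,
                )
                x = np.mean([np.asarray(t.lfp[sl], dtype=float) for t in trs], axis=0)
                verdict = nonlinear_dynamics.stochasticity_gate(x, seed=nl_seed)
                res = nonlinear_dynamics.chaos01(x, ccfg)
                rows.append(
                    {"animal": animal, "electrode": electrode, "energy_mJ": e,
                     "isi_ms": isi, "Kc": res.kc, "stochasticity": verdict}
                )
            chaos_df = pd.DataFrame(rows)
            _write_csv(chaos_df, out_dir, "chaos.csv")
            mi_summary = {}
            if dose is not None and dose["energy_mJ"].nunique() >= 2:
                mi = nonlinear_dynamics.estimate_mi(
                    dose["rms"].to_numpy(), dose["energy_mJ"].to_numpy(), seed=nl_seed
                )
                mi_summary = {"mi_bits": mi.i_corrected, "mi_raw_bits": mi.i_raw}
            record("nonlinear", n_series=len(chaos_df), **mi_summary)
        except Exception as e:  # noqa: BLE001
            raise StageError("nonlinear", e) from e

    sfc_df = None
    if "sfc" in stages:
        try:
            sfc_df = spike_field.sfc_table(ts)
            _write_csv(sfc_df, out_dir, "sfc.csv")
            record("sfc", n_rows=len(sfc_df))
        except Exception as e:  # noqa: BLE001
            raise StageError("sfc", e) from e

    if "bayes" in stages:
        try:
            bs = config["bayes"]
            settings = bayes_models.SamplerSettings(
                chains=bs["chains"], draws=bs["draws"], warmup=bs["warmup"],
                seed=stage_seed(config, "bayes"),
            )
            results = []
            if dose is not None and len(dose) >= 10:
                spec = bayes_models.RegressionSpec(settings=settings)
                summ = bayes_models.fit_hlr(dose, spec)
                df = summ.to_frame()
                df.insert(0, "model", "lfp_rms_hlr")
                results.append(df)
            if dose is not None and len(dose) >= 10 and any(tr.spikes for tr in ts):
                rate_rows = []
                for tr in ts:
                    win = compute_windows(tr.stimulus)
                    t0 = win.onset[0]
                    t1 = min(t0 + tr.stimulus.train_duration_s + 0.05, tr.stimulus.trial_length_s)
                    n_spk = sum(
                        int(np.count_nonzero((sp >= t0) & (sp < t1))) for sp in tr.spikes.values()
                    )
                    rate_rows.append(
                        {"animal": tr.animal, "electrode": tr.electrode, "trial": tr.trial,
                         "spike_rate": n_spk / (t1 - t0)}
                    )
                joined = dose.merge(pd.DataFrame(rate_rows), on=["animal", "electrode", "trial"])
                joined = joined[joined["spike_rate"] > 0]
                if len(joined) >= 10:
                    summ = bayes_models.fit_spike_lfp_lr(joined, settings=settings)
                    df = summ.to_frame()
                    df.insert(0, "model", "spike_lfp_lr")
                    results.append(df)
            if sfc_df is not None and not sfc_df.empty:
                for band in sfc_df["band"].unique():
                    sub = sfc_df[(sfc_df["band"] == band) & (sfc_df["energy_mJ"] > 0)]
                    agg = sub.groupby("energy_mJ", as_index=False)["sfc"].mean().dropna()
                    if len(agg) < 8:
                        continue
                    knot = bayes_models.find_knot(agg["energy_mJ"].to_numpy(), agg["sfc"].to_numpy())
                    if knot is None:
                        names = ["intercept", "beta_energy"]
                        X = np.column_stack(
                            [np.ones(len(sub)), np.log(sub["energy_mJ"].to_numpy())]
                        )
                        samples = bayes_models.gibbs_linear(
                            X, sub["sfc"].to_numpy(dtype=float), names, s=settings
                        )
                        summ = bayes_models.summarize_posterior(samples, error_name="sigma")
                    else:
                        summ = bayes_models.fit_spline_sfc(sub, knot, settings=settings)
                    df = summ.to_frame()
                    df.insert(0, "model", f"sfc_{band}" + (f"_knot{knot:g}" if knot else ""))
                    results.append(df)
            if results:
                _write_csv(pd.concat(results, ignore_index=True), out_dir, "regressions.csv")
            record("bayes", n_models=len(results))
        except Exception as e:  # noqa: BLE001
            raise StageError("bayes", e) from e

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
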