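"""Session pipeline: simulate -> analyze -> report.

``run_pipeline`` executes the analysis stages in dependency order over a
session bundle (loaded from disk or freshly simulated), producing a
machine-readable, schema-versioned session report that is byte-identical
under a fixed seed.  A single top-level seed fans out to per-stage child
seeds by fixed derivation, so individual stages are reproducible in
isolation.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np

from . import burst, choiceprob, coupling, layers, xcorr
from .io import Session, TrialEvents, read_session
from .synth import ForwardModelParams, simulate_session, simulate_stim_session

__all__ = [
    "SCHEMA_VERSION",
    "DEFAULT_CONFIG",
    "behavioral_summary",
    "run_pipeline",
    "report_to_json",
]

SCHEMA_VERSION = 1

ALL_STAGES = ("burst", "cp", "coupling", "xcorr", "layers", "stim")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "bundle": None,  # path to a session bundle; None -> simulate
    "simulate": {
        "n_oddballs": 40,
        "hit_rate": 0.75,
        "fa_rate": 0.02,
        "mode": "spike_driven",
        "params": {},  # ForwardModelParams overrides
    },
    "stages": list(ALL_STAGES),
    "n_perm": 1000,
    "cp_alpha": 0.01,
    "xcorr_alpha": 0.01,
    "coupling_p": 1e-3,
    "stim": {"n_pulses": 100},
}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def behavioral_summary(events: TrialEvents) -> dict:
    """Hit rate (hits / oddballs) and false-alarm rate (responded
    standards / standards)."""
    n_odd = int(events.is_oddball.sum())
    if n_odd == 0:
        raise ValueError("behavioral summary undefined without oddball trials")
    n_std = int((~events.is_oddball).sum())
    hit_rate = float(events.is_hit.sum() / n_odd)
    fa_rate = float(events.is_false_alarm.sum() / n_std) if n_std else 0.0
    return {
        "n_oddballs": n_odd,
        "n_standards": n_std,
        "hit_rate": hit_rate,
        "false_alarm_rate": fa_rate,
    }


def _merge_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _f(x) -> float:
    return float(np.round(float(x), 10))


def _fl(xs) -> list:
    return [_f(x) for x in np.asarray(xs).ravel()]


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(config: dict | str | Path | None = None,
                 session: Session | None = None) -> dict:
    """Run the requested stages over a session and return the report.

    ``config`` may be a dict, a path to a JSON config file, or ``None``
    for defaults.  A pre-built ``session`` overrides bundle/simulation.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    cfg = _merge_config(config)
    seed_root = np.random.SeedSequence(cfg["seed"])
    s_sim, s_cp, s_xc, s_stim = seed_root.spawn(4)
    n_perm = int(cfg["n_perm"])

    params = ForwardModelParams(**cfg["simulate"]["params"])
    if session is None:
        if cfg["bundle"]:
            session = read_session(cfg["bundle"])
        else:
            sim = cfg["simulate"]
            session = simulate_session(
                params, n_oddballs=sim["n_oddballs"], hit_rate=sim["hit_rate"],
                fa_rate=sim["fa_rate"], mode=sim["mode"], seed=s_sim,
            )

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg["seed"],
        "config": cfg,
        "behavioral": behavioral_summary(session.events),
        "n_units": len(session.spikes),
    }
    stages = cfg["stages"]
    trials = session.events
    rec = session.continuous

    metrics = []
    bursting_units = []
    pop_amp = None

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as e:
            raise StageError(f"stage {name!r} failed: {e}") from e
        _log(f"[bferp] stage {name}: {time.perf_counter() - t0:.2f} s")

    # ---- burst: classification + population amplitude (other stages
    # depend on it, so it always runs first when any stage needs it)
    def stage_burst():
        nonlocal metrics, bursting_units, pop_amp
        metrics = [burst.bursting_index(u, trials) for u in session.spikes]
        bursting_ids = {m.unit_id for m in metrics if m.is_bursting}
        bursting_units = [u for u in session.spikes
                          if u.unit_id in bursting_ids]
        if bursting_units:
            pop_amp = burst.population_bursting_amplitude(
                bursting_units, trials)
        report["burst"] = {
            "n_bursting": len(bursting_units),
            "cutoff": burst.BURSTING_INDEX_CUTOFF,
            "units": [
                {
                    "unit_id": m.unit_id,
                    "window_rate_hz": _f(m.window_rate_hz),
                    "session_mean_hz": _f(m.session_mean_hz),
                    "bursting_index": _f(m.bursting_index),
                    "is_bursting": m.is_bursting,
                }
                for m in metrics
            ],
        }

    run_stage("burst", stage_burst)

    if "cp" in stages:
        def stage_cp():
            out = {}
            onsets_hit = trials.onset_s[trials.is_hit]
            onsets_miss = trials.onset_s[trials.is_miss]
            onsets_odd = trials.onset_s[trials.is_oddball]
            onsets_std = trials.onset_s[~trials.is_oddball]
            contrasts = {}
            if onsets_miss.size:
                contrasts["hit_vs_miss"] = (onsets_hit, onsets_miss)
            contrasts["oddball_vs_standard"] = (onsets_odd, onsets_std)
            children = s_cp.spawn(2 * len(contrasts))
            k = 0
            for label in ("FrEEG", "CtrlEEG"):
                if label not in rec.labels:
                    continue
                out[label] = {}
                for cname, (oa, ob) in contrasts.items():
                    series = choiceprob.choice_probability_series(
                        rec, label, oa, ob, n_perm=n_perm,
                        alpha=cfg["cp_alpha"], seed=children[k])
                    k += 1
                    entry = {
                        "lag_s": _fl(series.lag_s),
                        "auc": _fl(series.auc),
                    }
                    if n_perm:
                        entry["p_two_sided"] = _fl(series.p_two_sided)
                        entry["significant"] = [
                            bool(x) for x in series.significant]
                        entry["n_significant_lags"] = int(
                            series.significant.sum())
                    out[label][cname] = entry
            report["cp"] = out

        run_stage("cp", stage_cp)

    if "coupling" in stages and bursting_units:
        def stage_coupling():
            rows = []
            hit_mask = trials.is_hit
            for u in session.spikes:
                counts, amps = coupling.trial_pairs(u, rec, "FrEEG", trials)
                try:
                    res = coupling.amplitude_correlation(
                        counts, amps, unit_id=u.unit_id,
                        significance_p=cfg["coupling_p"])
                except ValueError:
                    continue
                q = coupling.quintile_scaling(pop_amp, counts, amps, hit_mask)
                rows.append({
                    "unit_id": u.unit_id,
                    "r": _f(res.r),
                    "p": _f(res.p),
                    "significant": res.significant,
                    "quintiles_bf_pct": _fl(q[:, 0]),
                    "quintiles_signal_pct": _fl(q[:, 1]),
                })
            n_burst_sig = sum(
                1 for row in rows if row["significant"]
                and any(m.unit_id == row["unit_id"] and m.is_bursting
                        for m in metrics))
            report["coupling"] = {
                "units": rows,
                "n_bursting_significant": n_burst_sig,
            }

        run_stage("coupling", stage_coupling)

    if "xcorr" in stages and bursting_units:
        def stage_xcorr():
            keep = xcorr.select_trials(pop_amp, trials.is_hit)
            onsets = trials.onset_s[keep]
            children = s_xc.spawn(len(bursting_units))
            results = []
            for u, child in zip(bursting_units, children):
                results.append(xcorr.cross_correlate_unit(
                    u, rec, "FrEEG", onsets, n_perm=n_perm,
                    alpha=cfg["xcorr_alpha"], seed=child))
            rows = []
            for res in results:
                row = {
                    "unit_id": res.unit_id,
                    "best_lag_ms": res.best_lag_ms,
                    "max_r": _f(res.max_r),
                }
                if n_perm:
                    row["significant"] = res.significant_anywhere
                rows.append(row)
            entry = {
                "n_trials_selected": int(keep.sum()),
                "lags_ms": [int(x) for x in xcorr.DEFAULT_LAGS_MS],
                "units": rows,
            }
            if n_perm and any(r.significant_anywhere for r in results):
                entry["mean_significant_r"] = _fl(
                    xcorr.average_significant_xcorr(results))
            try:
                entry["delay_correlations"] = {
                    k: {"r": _f(v[0]), "p": _f(v[1])}
                    for k, v in xcorr.delay_metric_correlations(
                        results, metrics).items()
                }
            except ValueError:
                pass
            report["xcorr"] = entry

        run_stage("xcorr", stage_xcorr)

    if "layers" in stages and bursting_units and "laminar_lfp" in rec.roles:
        def stage_layers():
            odd = trials.is_oddball
            pp = burst.population_psth(
                bursting_units, trials.onset_s[odd], smoothing_sigma_ms=10.0)
            peak_ms = layers.burst_peak_time(pp)
            prof_odd = layers.extract_layer_profile(
                rec, trials.onset_s[odd], peak_ms)
            prof_std = layers.extract_layer_profile(
                rec, trials.onset_s[~odd], peak_ms)
            sim = layers.cosine_similarity(prof_odd, prof_std)
            prof_all = layers.extract_layer_profile(
                rec, trials.onset_s, peak_ms)
            entry = {
                "burst_peak_ms": _f(peak_ms),
                "profile_oddball": _fl(prof_odd.values),
                "profile_standard": _fl(prof_std.values),
                "profile_overall_normalized": _fl(
                    layers.normalize_profile(prof_all).values),
                "similarity_oddball_standard": _f(sim),
            }
            if n_perm:
                entry["similarity_p"] = _f(layers.profile_permutation_p(
                    prof_odd, prof_std, n_perm=n_perm,
                    seed=s_stim.spawn(1)[0]))
            report["layers"] = entry

        run_stage("layers", stage_layers)

    if "stim" in stages and "layers" in report:
        def stage_stim():
            children = s_stim.spawn(3)
            stim_ev, stim_rec = simulate_stim_session(
                params, n_pulses=int(cfg["stim"]["n_pulses"]),
                seed=children[1])
            prof_all = np.asarray(report["layers"]["profile_overall_normalized"])
            ref = layers.LayerProfile(
                prof_all, window_ms=(0, 60), n_trials=1, normalized=True)
            series = layers.stim_similarity_series(
                stim_rec, stim_ev, ref, n_perm=n_perm if n_perm else 1000,
                seed=children[2])
            entry = {
                "n_pulses": len(stim_ev),
                "t_ms": _fl(series.t_ms),
                "s_norm": _fl(series.s_norm),
                "onset_ms": (None if series.onset_ms is None
                             else _f(series.onset_ms)),
            }
            if n_perm:
                entry["band_lower"] = _fl(series.band_lower)
                entry["band_upper"] = _fl(series.band_upper)
            report["stim"] = entry

        run_stage("stim", stage_stim)

    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialisation (sorted keys; byte-identical under a
    fixed seed)."""
    return json.dumps(report, sort_keys=True, indent=1)
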