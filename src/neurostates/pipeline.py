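"""Stage orchestration: simulate -> segment -> spectral -> granger -> cfc -> report.

Each stage reads only upstream artifacts from the output directory and
writes its own files; the report stage assembles everything read-only.
Every artifact records the config hash and seed, so reruns with the same
config are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfc as cfc_mod
from . import granger as gc_mod
from . import segmentation as seg
from . import spectral as spec
from . import synth
from .config import RunConfig
from .errors import DependencyError

log = logging.getLogger("neurostates")

STAGES = ("simulate", "segment", "spectral", "granger", "cfc", "report")


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config_hash(config), "seed": config.seed}


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' requires {path.name} from stage '{stage}'"
        )
    return path


def stage_simulate(config: RunConfig, out: Path) -> None:
    params = seg.example_params()
    states = synth.simulate_state_sequence(params, config.n_steps, seed=config.seed)
    states.step_duration = config.symbol_step
    acl, dlc = synth.simulate_sensors(states, synth.default_sensor_profile(), seed=config.seed)
    synth.write_sensor_csv(out / "sensors.csv", acl, dlc, states)
    profile = synth.LfpProfile()
    lfp = synth.simulate_lfp(states, profile, fs=config.fs, seed=config.seed)
    synth.write_lfp(out / "lfp", lfp, config.fs, profile.channels)
    (out / "simulate.json").write_text(
        json.dumps({**_stamp(config), "n_steps": config.n_steps}, indent=2)
    )


def stage_segment(config: RunConfig, out: Path) -> None:
    src = _require(out / "sensors.csv", "simulate", "segment")
    df = pd.read_csv(src)
    symbols = seg.symbolize(
        df["acl"].to_numpy(), df["dlc"].to_numpy(), step_duration=config.symbol_step
    )
    params = seg.fit_hmm(
        symbols,
        n_states=config.hmm["n_states"],
        n_restarts=config.hmm["n_restarts"],
        seed=config.seed,
        tol=config.hmm["tol"],
        max_iter=config.hmm["max_iter"],
    )
    params = seg.canonicalize_states(params)
    path = seg.viterbi(symbols, params)
    payload = {**_stamp(config), **params.to_dict()}
    (out / "hmm_params.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame({"step": np.arange(len(path)), "state": path.states}).to_csv(
        out / "states.csv", index=False
    )
    dwell = seg.dwell_times(path, config.symbol_step)
    if "true_state" in df.columns:
        mat, _ = seg.overlap_matrix(path, df["true_state"].to_numpy())
        np.savetxt(out / "overlap.tsv", mat, delimiter="\t", fmt="%.6f")
    (out / "segment.json").write_text(
        json.dumps({**_stamp(config), "dwell_times_s": dwell}, indent=2)
    )


def _load_states_per_sample(config: RunConfig, out: Path, n_samples: int):
    path = _require(out / "states.csv", "segment", "spectral/granger/cfc")
    states = pd.read_csv(path)["state"].to_numpy()
    per = int(round(config.symbol_step * config.fs))
    full = np.repeat(states, per)
    return full[:n_samples]


def stage_spectral(config: RunConfig, out: Path) -> None:
    _require(out / "lfp.json", "simulate", "spectral")
    lfp, fs, channels = synth.read_lfp(out / "lfp")
    epoched = spec.epoch_signal(lfp, fs, config.epoch_length)
    table = spec.band_power_table(epoched, {k: tuple(v) for k, v in config.bands.items()})
    rows = []
    for band, powers in table.items():
        for ch_i, ch in enumerate(channels):
            for ep in range(powers.shape[0]):
                rows.append((ep, ch, band, powers[ep, ch_i]))
    pd.DataFrame(rows, columns=["epoch", "channel", "band", "power"]).to_csv(
        out / "band_power.tsv", sep="\t", index=False
    )
    damp = spec.delta_amplitude(lfp, fs, config.epoch_length)
    pd.DataFrame(damp, columns=list(channels)).to_csv(out / "delta_amplitude.csv", index=False)
    mask, thr = spec.high_delta_epochs(damp[:, 0])
    (out / "spectral.json").write_text(
        json.dumps(
            {**_stamp(config), "high_delta_threshold_mV": thr,
             "n_high_delta_epochs": int(mask.sum())},
            indent=2,
        )
    )


def stage_granger(config: RunConfig, out: Path) -> None:
    _require(out / "lfp.json", "simulate", "granger")
    lfp, fs, channels = synth.read_lfp(out / "lfp")
    states = _load_states_per_sample(config, out, lfp.shape[0])
    bands = {k: tuple(v) for k, v in config.bands.items()}
    rows = []
    for state in np.unique(states):
        sel = states == state
        epoched = spec.epoch_signal(lfp[sel], fs, config.epoch_length)
        p = gc_mod.select_order(
            epoched.data, fs, max_order_ms=config.granger["max_order_ms"]
        )
        results = gc_mod.gc_all_directions(
            epoched.data, p, fs, channel_names=list(channels),
            conditional=config.granger["conditional"], bands=bands,
        )
        gc_mod.gc_significance(results, Q=config.granger["Q"])
        for r in results:
            for band, val in r.band_means.items():
                rows.append(
                    (r.source, r.target, band, val, r.F_time, r.p_value,
                     r.q_value, int(state))
                )
    pd.DataFrame(
        rows,
        columns=["source", "target", "band", "gc", "F_time", "p", "q", "state"],
    ).to_csv(out / "granger.tsv", sep="\t", index=False)
    (out / "granger.json").write_text(json.dumps(_stamp(config), indent=2))


def stage_cfc(config: RunConfig, out: Path) -> None:
    _require(out / "lfp.json", "simulate", "cfc")
    lfp, fs, channels = synth.read_lfp(out / "lfp")
    states = _load_states_per_sample(config, out, lfp.shape[0])
    rows = []
    for ch_i, ch in enumerate(channels):
        vecs = cfc_mod.cfc_by_state(
            lfp[: states.size, ch_i],
            states,
            fs,
            low_band=tuple(config.cfc["low_band"]),
            high_band=tuple(config.cfc["high_band"]),
            weight=config.cfc["weight"],
        )
        for state, v in sorted(vecs.items()):
            rows.append((state, ch, v.strength, v.angle, v.n_samples, v.reliable))
    pd.DataFrame(
        rows,
        columns=["state", "channel", "strength", "angle_rad", "n_samples", "reliable"],
    ).to_csv(out / "cfc.csv", index=False)
    (out / "cfc.json").write_text(json.dumps(_stamp(config), indent=2))


def stage_report(config: RunConfig, out: Path) -> None:
    report = {**_stamp(config), "stages": {}}
    artifacts = {
        "simulate": "simulate.json",
        "segment": "segment.json",
        "spectral": "spectral.json",
        "granger": "granger.json",
        "cfc": "cfc.json",
    }
    for stage, fname in artifacts.items():
        p = out / fname
        if p.exists():
            report["stages"][stage] = json.loads(p.read_text())
    hp = out / "hmm_params.json"
    if hp.exists():
        report["hmm_params"] = json.loads(hp.read_text())
    ov = out / "overlap.tsv"
    if ov.exists():
        report["overlap_matrix"] = np.loadtxt(ov, delimiter="\t").tolist()
    for fname, key in (
        ("band_power.tsv", "band_power_file"),
        ("granger.tsv", "granger_file"),
        ("cfc.csv", "cfc_file"),
    ):
        if (out / fname).exists():
            report[key] = fname
    (out / "report.json").write_text(json.dumps(report, indent=2))


_STAGE_FN = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "spectral": stage_spectral,
    "granger": stage_granger,
    "cfc": stage_cfc,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=STAGES, out_dir=None) -> Path:
    """Run the requested stages in dependency order; returns the out dir."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        t0 = time.perf_counter()
        log.info("stage %s ...", stage)
        _STAGE_FN[stage](config, out)
        log.info("stage %s done in %.2f s", stage, time.perf_counter() - t0)
    return out
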