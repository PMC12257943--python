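"""End-to-end simulate -> extract -> summarize -> metrics runs.

A run executes every applicable stage in dependency order on a simulated
trial (or on files named in the config), collects warnings, and writes
stage outputs plus a machine-readable manifest with input digests so a
rerun under the same seed and config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardiac as cardiac_mod
from . import hypoxia as hypoxia_mod
from . import synthetic
from .io_units import RespirometerConfig
from .mo2 import correct_background, fit_mo2_windows
from .summary import summarize_trial
from .tolerance import extract_loe_endpoint

__all__ = ["run_pipeline", "analyze_trial"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_trial(
    truth: synthetic.TrialTruth,
    config: RespirometerConfig | None = None,
    protocol: synthetic.CycleProtocol | None = None,
) -> dict:
    """Simulate one full trial set and run every analysis stage on it.

    Returns a dict of stage results keyed by stage name, with the truth
    attached for parameter-recovery checks.
    """
    config = config or synthetic.default_config(temp_c=truth.accl_temp_c)
    protocol = protocol or synthetic.CycleProtocol()
    trace, blank, _ = synthetic.simulate_irap_trial(config, truth, protocol)
    series = fit_mo2_windows(trace, config)
    blank_series = fit_mo2_windows(blank, config)
    corrected = correct_background(series, blank_series)
    metab = summarize_trial(corrected, mass_kg=config.M_f)

    hyp_trace = synthetic.simulate_hypoxia_phase(
        config, truth, protocol=protocol, start_time_s=trace.time_s[-1] + 1.0
    )
    hyp_series = fit_mo2_windows(hyp_trace, config)
    pcrit = hypoxia_mod.estimate_pcrit(hyp_series, metab.smr, temp_c=truth.accl_temp_c)

    ramp = synthetic.simulate_tolerance_ramp("thermal", truth)
    ctmax = extract_loe_endpoint(ramp)
    hyp_ramp = synthetic.simulate_tolerance_ramp("hypoxia", truth)
    loehyp = extract_loe_endpoint(hyp_ramp)

    beats = synthetic.simulate_cardiac_trial(truth)
    t_arr, curve = cardiac_mod.detect_arrhythmia(beats)
    heart = cardiac_mod.summarize_cardiac(curve, t_arr)

    return {
        "truth": truth,
        "config": config,
        "series": corrected,
        "metabolic": metab,
        "pcrit": pcrit,
        "ctmax": ctmax,
        "loehyp": loehyp,
        "cardiac": heart,
        "heart_curve": curve,
    }


def run_pipeline(config_path: str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the default simulate-then-analyze scenario described by a config.

    The JSON config may carry ``truth`` (TrialTruth fields), ``chamber``
    (RespirometerConfig fields) and ``protocol`` overrides.  Outputs:
    ``mo2.csv``, ``summary.csv``, ``pcrit.json``, ``tolerance.csv``,
    ``cardiac.csv`` and ``manifest.json``.  Raises on any stage failure.
    """
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config_path.exists():
        raise FileNotFoundError(f"config file {config_path} not found")
    cfg = json.loads(config_path.read_text())

    truth_kwargs = dict(cfg.get("truth", {}))
    if seed is not None:
        truth_kwargs["seed"] = seed
    truth = synthetic.TrialTruth(**truth_kwargs)
    chamber = (
        RespirometerConfig(**cfg["chamber"])
        if "chamber" in cfg
        else synthetic.default_config(temp_c=truth.accl_temp_c)
    )
    protocol = synthetic.CycleProtocol(**cfg.get("protocol", {}))

    collected: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        res = analyze_trial(truth, chamber, protocol)
        collected = [str(w.message) for w in wlist]

    res["series"].to_frame().to_csv(out / "mo2.csv", index=False)
    m = res["metabolic"]
    pd.DataFrame([asdict(m)]).to_csv(out / "summary.csv", index=False)
    (out / "pcrit.json").write_text(json.dumps(asdict(res["pcrit"]), indent=2))
    pd.DataFrame([asdict(res["ctmax"]), asdict(res["loehyp"])]).to_csv(
        out / "tolerance.csv", index=False
    )
    res["heart_curve"].to_frame().to_csv(out / "cardiac.csv", index=False)

    manifest = {
        "software": {"irapkit": _pkg_version("irapkit")},
        "seed": truth.seed,
        "config_snapshot": cfg,
        "truth": json.loads(truth.model_dump_json()),
        "warnings": collected,
        "outputs": {
            p.name: _digest(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json"
        },
        "results": {
            "smr": m.smr,
            "mmr": m.mmr,
            "aas": m.aas,
            "epoc": m.epoc,
            "n_smr_values": m.n_smr_values,
            "pcrit": res["pcrit"].pcrit,
            "pcrit_valid": res["pcrit"].valid,
            "ctmax": res["ctmax"].endpoint_value,
            "tsm": res["ctmax"].tsm,
            "loehyp": res["loehyp"].endpoint_value,
            "loehyp_kpa": res["loehyp"].endpoint_kpa,
            "t_peak": res["cardiac"].t_peak_c,
            "t_arr": res["cardiac"].t_arr_c,
            "peak_fhmax": res["cardiac"].peak_fhmax_bpm,
            "delta_fhmax": res["cardiac"].delta_fhmax_bpm,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
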