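"""End-to-end orchestration: generate -> decompose -> indicators -> statistics.

A run is fully determined by its configuration and master seed: the same
RunConfig writes byte-identical results.  Stages can be skipped by pointing
the run at an existing directory of signal CSVs (analyze-only mode).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import signal_io
from .indicators import compute_indicators
from .injury import attach_external_mps, compute_hic
from .synthetic import (DEFAULT_HEAD, DEFAULT_VELOCITIES, MATERIALS,
                        POSITION_FACTORS, SIZES, ImpactScenario,
                        LumpedHeadModel, generate_matrix, simulate_impact)
from .stats import factor_test_matrix, fit_matrix, normalize_responses
from .wpt import wp_decompose

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    out_dir: str = "headwave_run"
    fs: float = 5000.0
    levels: int = 9
    hic_window: float = 0.015
    master_seed: int = 0
    duration: float = 0.2
    snr_db: float | None = None
    normalization: str = "minmax"
    unit: str = "m_per_s2"
    positions: tuple = tuple(POSITION_FACTORS)
    materials: tuple = tuple(MATERIALS)
    velocities: tuple = DEFAULT_VELOCITIES
    sizes: tuple = tuple(SIZES)
    signals_dir: str | None = None   # analyze-only mode when set
    mps_file: str | None = None
    write_spectra: bool = True

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def analyze_signal(signal, levels: int = 9, hic_window: float = 0.015) -> dict:
    """Spectrum, frequency-domain indicators and HIC for one signal."""
    spectrum = wp_decompose(signal, levels=levels)
    ind = compute_indicators(spectrum)
    hic = compute_hic(signal, max_window=hic_window)
    row = ind.to_row(signal.label)
    row["hic"] = hic.value
    return {"spectrum": spectrum, "row": row}


def compute_results(scenarios: list[ImpactScenario], levels: int = 9,
                    hic_window: float = 0.015,
                    head: LumpedHeadModel = DEFAULT_HEAD) -> pd.DataFrame:
    """Simulate every scenario and assemble the factorial results table."""
    rows = []
    for sc in scenarios:
        signal = simulate_impact(sc, head=head)
        out = analyze_signal(signal, levels=levels, hic_window=hic_window)
        row = {"scenario_id": sc.scenario_id, "position": sc.position,
               "material": sc.material.name, "velocity": sc.velocity,
               "size": sc.size}
        row.update({k: v for k, v in out["row"].items() if k != "signal_label"})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and write the run directory.

    Layout: ``signals/`` (one CSV per scenario), ``spectra/``,
    ``indicators.csv``, ``results.csv``, ``stats/`` (factor-test matrix,
    fit summaries, normalized responses) and ``run_log.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.signals_dir is None:
        scenarios = generate_matrix(
            master_seed=config.master_seed, positions=config.positions,
            materials=config.materials, velocities=config.velocities,
            sizes=config.sizes, fs=config.fs, duration=config.duration,
            snr_db=config.snr_db)
        sig_dir = out / "signals"
        signals = []
        for sc in scenarios:
            sig = simulate_impact(sc)
            if config.unit != sig.unit:
                sig = signal_io.convert_units(sig, config.unit)
            signal_io.write_signal(sig, sig_dir / f"{sc.scenario_id}.csv")
            signals.append((sig, {"position": sc.position,
                                  "material": sc.material.name,
                                  "velocity": sc.velocity, "size": sc.size}))
        timings["generate"] = time.perf_counter() - t0
    else:
        sig_dir = Path(config.signals_dir)
        signals = []
        for path in sorted(sig_dir.glob("*.csv")):
            sig = signal_io.load_signal(path, unit=config.unit)
            signals.append((sig, _parse_scenario_id(path.stem)))
        if not signals:
            raise ValueError(f"no signal CSVs found in {sig_dir}")
        timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rows = []
    spec_dir = out / "spectra"
    for sig, sc in signals:
        try:
            res = analyze_signal(sig, levels=config.levels, hic_window=config.hic_window)
        except Exception as exc:
            raise RuntimeError(f"analysis failed for scenario {sig.label!r}: {exc}") from exc
        if config.write_spectra:
            spec_dir.mkdir(parents=True, exist_ok=True)
            res["spectrum"].write(spec_dir / f"{sig.label}.csv")
        row = {"scenario_id": sig.label}
        if sc is not None:
            row.update(position=sc["position"], material=sc["material"],
                       velocity=sc["velocity"], size=sc["size"])
        row.update({k: v for k, v in res["row"].items() if k != "signal_label"})
        rows.append(row)
    results = pd.DataFrame(rows)
    ind_cols = ["scenario_id", "e_max", "band_index", "f_low_hz", "f_high_hz", "proportion"]
    results[ind_cols].to_csv(out / "indicators.csv", index=False, float_format=FLOAT_FMT)
    if config.mps_file is not None:
        results = attach_external_mps(results, config.mps_file)
    results.to_csv(out / "results.csv", index=False, float_format=FLOAT_FMT)
    timings["analyze"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats_dir = out / "stats"
    factor_cols = [c for c in ("position", "material", "velocity", "size")
                   if c in results.columns and results[c].nunique() >= 2]
    have_factors = bool(factor_cols)
    if have_factors:
        stats_dir.mkdir(parents=True, exist_ok=True)
        responses = [c for c in ("e_max", "band_index", "proportion", "hic", "mps")
                     if c in results.columns and results[c].notna().all()
                     and results[c].nunique() > 1]
        tests = factor_test_matrix(results, factors=factor_cols, responses=responses)
        tests.to_csv(stats_dir / "factor_tests.csv", index=False, float_format=FLOAT_FMT)
        fits = fit_matrix(results, ["e_max", "band_index", "proportion"], "hic")
        fits.to_csv(stats_dir / "fit_summaries.csv", index=False, float_format=FLOAT_FMT)
        norm_cols = [c for c in responses if results[c].nunique() > 1]
        normalized = normalize_responses(results, columns=norm_cols,
                                         method=config.normalization)
        normalized.to_csv(stats_dir / "normalized.csv", index=False, float_format=FLOAT_FMT)
    timings["stats"] = time.perf_counter() - t0

    log = {"config": asdict(config), "seed": config.master_seed,
           "n_signals": len(signals), "factor_stats": have_factors,
           "timings_s": {k: round(v, 3) for k, v in timings.items()}}
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out


def _parse_scenario_id(stem: str) -> dict | None:
    """Recover factor levels from a ``position_material_size_velocity`` file name."""
    parts = stem.split("_")
    if len(parts) != 4:
        return None
    pos, mat, size, vel = parts
    if pos not in POSITION_FACTORS or mat not in MATERIALS or size not in SIZES:
        return None
    try:
        return {"position": pos, "material": mat, "size": size, "velocity": float(vel)}
    except ValueError:
        return None
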