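"""File formats and configuration: trace tables, feature tables, posteriors.

Trace tables are delimited text in long format with the columns
``condition, cell_id, allele_id, frame, time_min, intensity_rna`` (header
required, UTF-8).  Configuration files are flat YAML with every default
overridable.  All writers use deterministic row order so identical runs
produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .promoter_sim import (
    KineticParams,
    Protocol,
    PromoterModelSpec,
    SignalProfile,
    TraceDataset,
    build_topology,
)
from .synthetic_data import NoiseModel

__all__ = [
    "TRACE_COLUMNS",
    "DEFAULT_CONFIG",
    "write_traces",
    "read_traces",
    "read_all_traces",
    "load_config",
    "model_from_config",
    "protocol_from_config",
    "noise_from_config",
    "write_feature_tables",
    "write_posterior",
    "write_run_log",
]

TRACE_COLUMNS = ["condition", "cell_id", "allele_id", "frame", "time_min", "intensity_rna"]


def _dataset_frame(ds: TraceDataset) -> pd.DataFrame:
    n_frames = ds.n_frames
    rows = {
        "condition": np.repeat(ds.condition or "default", ds.n_traces * n_frames),
        "cell_id": np.repeat(ds.cell_ids, n_frames),
        "allele_id": np.repeat(ds.allele_ids, n_frames),
        "frame": np.tile(np.arange(n_frames), ds.n_traces),
        "time_min": np.tile(ds.times, ds.n_traces),
        "intensity_rna": ds.intensity.ravel(),
    }
    return pd.DataFrame(rows)


def write_traces(datasets, path) -> Path:
    """Write one dataset or a list of datasets as a long-format trace table.

    Rows are ordered by (condition, cell, allele, frame) so repeated writes
    of the same data are byte-identical.
    """
    if isinstance(datasets, TraceDataset):
        datasets = [datasets]
    frames = [_dataset_frame(d) for d in datasets]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    df = df.sort_values(
        ["condition", "cell_id", "allele_id", "frame"], kind="mergesort"
    ).reset_index(drop=True)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
    return path


def _dataset_from_frame(df: pd.DataFrame, condition: str, protocol: Protocol | None) -> TraceDataset:
    groups = []
    times_ref = None
    for (cell, allele), g in df.groupby(["cell_id", "allele_id"], sort=True):
        g = g.sort_values("frame")
        if g["frame"].duplicated().any():
            raise ValueError(
                f"duplicate (cell, allele, frame) record for cell {cell}, allele {allele}"
            )
        t = g["time_min"].to_numpy(dtype=float)
        if len(t) >= 3:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"non-uniform time grid for cell {cell}, allele {allele}")
        if times_ref is None:
            times_ref = t
        elif len(t) != len(times_ref) or not np.allclose(t, times_ref):
            raise ValueError("traces have inconsistent time grids")
        groups.append((int(cell), int(allele), g["intensity_rna"].to_numpy(dtype=float)))
    intensity = np.vstack([v for _, _, v in groups])
    cell_ids = np.array([c for c, _, _ in groups])
    allele_ids = np.array([a for _, a, _ in groups])
    if protocol is None:
        dt = float(times_ref[1] - times_ref[0])
        protocol = Protocol(frame_interval_min=dt, n_frames=len(times_ref))
    return TraceDataset(
        intensity=intensity, times=times_ref, cell_ids=cell_ids,
        allele_ids=allele_ids, condition=condition, protocol=protocol,
    )


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table {path} is missing columns: {', '.join(missing)}")
    return df


def read_traces(path, condition: str | None = None, protocol: Protocol | None = None) -> TraceDataset:
    """Read a single-condition trace table (or select one condition)."""
    df = _read_table(path)
    conditions = sorted(df["condition"].astype(str).unique())
    if condition is None:
        if len(conditions) > 1:
            raise ValueError(
                f"file holds several conditions ({', '.join(conditions)}); pass condition="
            )
        condition = conditions[0]
    sub = df[df["condition"].astype(str) == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not present in {path}")
    return _dataset_from_frame(sub, condition, protocol)


def read_all_traces(path, protocol: Protocol | None = None) -> dict:
    """Read a trace table into one TraceDataset per condition."""
    df = _read_table(path)
    return {
        str(cond): _dataset_from_frame(g, str(cond), protocol)
        for cond, g in df.groupby("condition", sort=True)
    }


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "topology": "1-1-5",
    "t_on_min": 0.56,
    "t_off_min": 50.0,
    "burst_size": 7.9,
    "cv_ext_k_init": 0.35,
    "cv_ext_k_elong": 0.35,
    "cv_ext_k_on": 0.0,
    "cv_ext_k_off": 0.0,
    "delay_min": 0.0,
    "ramp_min": 2.0,
    "residence_min": 30.0,
    "background_mean": 0.0,
    "background_sd": 1.5,
    "n_cells": 60,
    "alleles_per_cell": 1,
    "frame_interval_min": 3.0,
    "n_frames": 250,
    "protocol": "steady_state",
    "equilibration_min": 80.0,
    "stimulus_min": 51.0,
    "seed": 0,
    # inference settings
    "n_particles": 2000,
    "keep_frac": 0.2,
    "n_cells_per_sim": 0,  # 0 = match the data
    "max_iterations": 15,
    "model_jump_prob": 0.05,
    "local_param": "t_off",
    "lag1_threshold": 0.2,
    "max_lag": 50,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the defaults, rejecting unknown keys."""
    cfg = dict(DEFAULT_CONFIG)
    loaded = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
    for source in (loaded, overrides or {}):
        for key, value in source.items():
            if key not in DEFAULT_CONFIG:
                raise ValueError(f"unknown configuration key {key!r}")
            cfg[key] = value
    build_topology(cfg["topology"])  # validate early
    if cfg["protocol"] not in ("steady_state", "induction"):
        raise ValueError(f"unknown protocol {cfg['protocol']!r}")
    return cfg


def model_from_config(cfg: dict) -> PromoterModelSpec:
    topo = build_topology(cfg["topology"])
    cv = {}
    for name in topo.resampled:
        cv[name] = float(cfg.get(f"cv_ext_{name}", 0.0))
    params = KineticParams(
        t_on=float(cfg["t_on_min"]),
        t_off=float(cfg["t_off_min"]),
        burst_size=float(cfg["burst_size"]),
        cv_ext=cv,
    )
    profile = SignalProfile(
        delay=float(cfg["delay_min"]), ramp=float(cfg["ramp_min"]),
        residence=float(cfg["residence_min"]),
    )
    return PromoterModelSpec(topo, params, profile)


def protocol_from_config(cfg: dict) -> Protocol:
    return Protocol(
        kind=cfg["protocol"],
        frame_interval_min=float(cfg["frame_interval_min"]),
        n_frames=int(cfg["n_frames"]),
        equilibration_min=float(cfg["equilibration_min"]),
        stimulus_min=float(cfg["stimulus_min"]),
    )


def noise_from_config(cfg: dict) -> NoiseModel:
    return NoiseModel(
        background_mean=float(cfg["background_mean"]),
        background_sd=float(cfg["background_sd"]),
    )


# ---------------------------------------------------------------------------
# result tables


def write_feature_tables(dataset: TraceDataset, out_dir, profile=None, lag1_threshold=0.2,
                         background: float = 0.0) -> tuple[Path, Path]:
    """Write per-cell and per-burst feature tables for a dataset."""
    from .promoter_sim import DEFAULT_PROFILE
    from .trace_features import (
        autocorrelation, classify_responder, extract_bursts, response_time,
        total_rna_output,
    )

    profile = profile or DEFAULT_PROFILE
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_rows, burst_rows = [], []
    induction = dataset.protocol.kind == "induction"
    stim = dataset.protocol.stimulus_min if induction else 0.0
    for trace in dataset.traces():
        acf = autocorrelation(trace)
        resp = response_time(trace, stimulus_min=stim) if induction else None
        cell_rows.append(
            {
                "cell_id": trace.cell_id,
                "allele_id": trace.allele_id,
                "sigma_rna": total_rna_output(trace, profile, background),
                "acf_half_life_min": acf.half_life,
                "acf_lag1": acf.lag1,
                "responder": classify_responder(acf, lag1_threshold),
                "response_time_min": np.nan if resp is None else resp,
            }
        )
        ann = extract_bursts(trace)
        for kind, intervals in (("on", ann.on_intervals), ("off", ann.off_intervals)):
            for j, (s, e) in enumerate(intervals):
                row = {
                    "cell_id": trace.cell_id,
                    "allele_id": trace.allele_id,
                    "kind": kind,
                    "start_min": s,
                    "duration_min": e - s,
                    "burst_size_rna": ann.burst_sizes[j] if kind == "on" else np.nan,
                    "init_rate_rna_per_min": ann.initiation_rates[j] if kind == "on" else np.nan,
                }
                burst_rows.append(row)
    cells = out_dir / "features_cells.csv"
    bursts = out_dir / "features_bursts.csv"
    pd.DataFrame(cell_rows).to_csv(cells, index=False, float_format="%.6g")
    pd.DataFrame(burst_rows).to_csv(bursts, index=False, float_format="%.6g")
    return cells, bursts


def write_posterior(posterior, path) -> Path:
    """One row per particle: model code, parameters, distance(s)."""
    path = Path(path)
    posterior.to_frame().to_csv(path, index=False, float_format="%.6g")
    return path


def write_run_log(path, seed: int, config: dict | None = None, extra: dict | None = None) -> Path:
    from . import __version__

    path = Path(path)
    lines = [f"burstabc {__version__}", f"seed: {seed}"]
    for source in (config or {}, extra or {}):
        for k in sorted(source):
            lines.append(f"{k}: {source[k]}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
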