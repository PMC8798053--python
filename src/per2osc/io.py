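"""Plain-text I/O: CSV time series, YAML configs, fit-result tables.

All series travel as CSV with a header — ``time_h,value`` (optionally a
``valid`` 0/1 column) for binned signals, ``time_h,state`` with states
W/N/R for hypnograms.  Times are decimal hours from recording start.
Round-trips are lossless to float precision.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BinnedSignal, EpochSeries, STATES
from .oscillator import OscillatorParams
from .protocols import Protocol
from .synth import SynthConfig


def save_signal(signal: BinnedSignal, path: str | Path) -> None:
    df = pd.DataFrame({"time_h": signal.times_h, "value": signal.values})
    if not signal.valid.all():
        df["valid"] = signal.valid.astype(int)
    df.to_csv(path, index=False, float_format="%.12g")


def save_hypnogram(epochs: EpochSeries, path: str | Path) -> None:
    pd.DataFrame({"time_h": epochs.times_h, "state": epochs.states}) \
        .to_csv(path, index=False, float_format="%.12g")


def _infer_bin_width(time_h: np.ndarray, path: str | Path) -> float:
    diffs = np.diff(time_h)
    if diffs.size == 0:
        raise ValueError(f"{path}: need at least two rows to infer bin width")
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 2
        raise ValueError(f"{path}: non-monotone time at data row {row}")
    return float(np.median(diffs))


def load_signal(path: str | Path, units: str = "") -> BinnedSignal:
    """Load a binned signal; gaps in the time grid become invalid bins."""
    df = pd.read_csv(path)
    for col in ("time_h", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_h"].to_numpy(dtype=float)
    width = _infer_bin_width(t, path)
    n = round((t[-1] - t[0]) / width) + 1
    idx = np.round((t - t[0]) / width).astype(int)
    if not np.allclose(t, t[0] + idx * width, atol=width * 1e-6):
        raise ValueError(f"{path}: times do not sit on a regular grid")
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    values[idx] = df["value"].to_numpy(dtype=float)
    if "valid" in df.columns:
        valid[idx] = df["valid"].to_numpy(dtype=int).astype(bool)
    else:
        valid[idx] = True
    return BinnedSignal(start_time=float(t[0]), bin_width=width,
                        values=values, valid=valid, units=units)


def load_hypnogram(path: str | Path) -> EpochSeries:
    df = pd.read_csv(path)
    for col in ("time_h", "state"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_h"].to_numpy(dtype=float)
    states = df["state"].astype(str).to_numpy()
    bad = ~np.isin(states, STATES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(
            f"{path}: unknown state code {states[bad][0]!r} at data row {row}"
        )
    epoch_len_s = _infer_bin_width(t, path) * 3600.0
    return EpochSeries(start_time=float(t[0]), epoch_len=epoch_len_s,
                       states=states)


# ---------------------------------------------------------------------------
# Structured configs


def save_experiment_config(path: str | Path, config: SynthConfig,
                           params: OscillatorParams,
                           protocol: Protocol) -> None:
    """Sidecar file recording the ground truth of a synthetic experiment."""
    doc = {
        "synth": dataclasses.asdict(config),
        "oscillator": dataclasses.asdict(params),
        "protocol": {
            "name": protocol.name,
            "sd_intervals": [list(iv) for iv in protocol.sd_intervals],
            "baseline": list(protocol.baseline) if protocol.baseline else None,
            "intervention": (list(protocol.intervention)
                             if protocol.intervention else None),
            "recovery": list(protocol.recovery) if protocol.recovery else None,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def load_experiment_config(path: str | Path
                           ) -> tuple[SynthConfig, OscillatorParams, Protocol]:
    doc = yaml.safe_load(Path(path).read_text())
    _check_keys(doc, {"synth", "oscillator", "protocol"}, "config")
    synth_fields = {f.name for f in dataclasses.fields(SynthConfig)}
    osc_fields = {f.name for f in dataclasses.fields(OscillatorParams)}
    _check_keys(doc["synth"], synth_fields, "synth")
    _check_keys(doc["oscillator"], osc_fields, "oscillator")
    proto = doc["protocol"]
    _check_keys(proto, {"name", "sd_intervals", "baseline", "intervention",
                        "recovery"}, "protocol")
    protocol = Protocol(
        name=proto["name"],
        sd_intervals=tuple(tuple(iv) for iv in proto["sd_intervals"]),
        baseline=tuple(proto["baseline"]) if proto["baseline"] else None,
        intervention=(tuple(proto["intervention"])
                      if proto["intervention"] else None),
        recovery=tuple(proto["recovery"]) if proto["recovery"] else None,
    )
    return (SynthConfig(**doc["synth"]), OscillatorParams(**doc["oscillator"]),
            protocol)


def fit_results_table(fits: list) -> pd.DataFrame:
    """One row per fitted variant: parameters, RSS, BIC, Bayes factor."""
    return pd.DataFrame([f.summary_row() for f in fits])
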