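"""File I/O, configuration, and synthetic-fixture generation.

Oscilloscope recordings travel as CSV in a PicoScope-like dialect: one
name row (optionally followed by a units row), a time column in
seconds, and one column per channel.  Trial logs are plain CSV with one
row per staircase trial.  Analysis results are written as JSON reports
carrying a config echo and provenance (input hash, seed, package
version) so every run is reproducible from its report alone.

:func:`synth_recording` turns a current-command profile into a
synthetic two-electrode recording through the circuit model; it is the
fixture generator used throughout the test-suite and the acceptance
pipeline, emulating what the bench setup measures (mid-supply electrode
offsets, additive noise, boost-converter ripple, a calibratable DC
offset error, and rail clipping).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .circuit import EhcsModel, LoadCondition, RippleSpec, simulate_device
from .characterize import DualChannelRecording
from .errors import ConfigError, DataFormatError
from .stimulus import SampledTrace


@dataclass(frozen=True)
class ScopeCsvDialect:
    """Column layout of a scope CSV export."""

    time_column: str = "Time"
    channel_columns: tuple = ("Channel A", "Channel B")
    dac_column: Optional[str] = None
    units_row_present: bool = True
    delimiter: str = ","
    jitter_tolerance: float = 1e-6  # relative timestamp jitter allowed


def read_scope_csv(
    path, dialect: ScopeCsvDialect = ScopeCsvDialect()
) -> DualChannelRecording:
    """Read a dual-channel scope CSV into a recording.

    The sample rate is inferred from the median timestamp spacing;
    non-uniform timestamps (relative jitter beyond the dialect's
    tolerance) and non-monotone time axes are rejected.
    """
    path = Path(path)
    skiprows = [1] if dialect.units_row_present else None
    df = pd.read_csv(path, sep=dialect.delimiter, skiprows=skiprows)
    required = [dialect.time_column, *dialect.channel_columns]
    if dialect.dac_column:
        required.append(dialect.dac_column)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path.name}: missing column(s) {missing}; found {list(df.columns)}"
        )
    t = df[dialect.time_column].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataFormatError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataFormatError(f"{path.name}: time axis not strictly increasing")
    dt_med = float(np.median(dt))
    if np.max(np.abs(dt - dt_med)) > dialect.jitter_tolerance * dt_med:
        raise DataFormatError(
            f"{path.name}: non-uniform sampling (jitter beyond "
            f"{dialect.jitter_tolerance:g} relative)"
        )
    chan_a = df[dialect.channel_columns[0]].to_numpy(dtype=float)
    chan_b = df[dialect.channel_columns[1]].to_numpy(dtype=float)
    dac = (
        df[dialect.dac_column].to_numpy(dtype=float) if dialect.dac_column else None
    )
    return DualChannelRecording(
        sample_rate_Hz=1.0 / dt_med,
        chanA_V=chan_a,
        chanB_V=chan_b,
        dac_V=dac,
        meta={"source": str(path)},
    )


def write_scope_csv(
    recording: DualChannelRecording, path, dialect: ScopeCsvDialect = ScopeCsvDialect()
) -> Path:
    """Write a recording in the scope CSV dialect (inverse of the reader)."""
    path = Path(path)
    cols = {dialect.time_column: recording.times_s}
    cols[dialect.channel_columns[0]] = recording.chanA_V
    cols[dialect.channel_columns[1]] = recording.chanB_V
    dac_col = dialect.dac_column
    if recording.dac_V is not None:
        dac_col = dac_col or "DAC"
        cols[dac_col] = recording.dac_V
    with open(path, "w", newline="") as fh:
        fh.write(dialect.delimiter.join(cols.keys()) + "\n")
        if dialect.units_row_present:
            units = ["(s)"] + ["(V)"] * (len(cols) - 1)
            fh.write(dialect.delimiter.join(units) + "\n")
        arr = np.column_stack(list(cols.values()))
        np.savetxt(fh, arr, delimiter=dialect.delimiter, fmt="%.12g")
    return path


def write_waveform_csv(trace: SampledTrace, path) -> Path:
    """Two-column waveform export: ``time_s,current_mA`` (or voltage_V)."""
    path = Path(path)
    unit = "current_mA" if trace.units == "mA" else "voltage_V"
    with open(path, "w", newline="") as fh:
        fh.write(f"time_s,{unit}\n")
        np.savetxt(
            fh,
            np.column_stack([trace.times_s, trace.values]),
            delimiter=",",
            fmt="%.12g",
        )
    return path


TRIAL_LOG_COLUMNS = [
    "participant", "trial", "polarity", "intensity_mA", "response",
    "correct", "reversal",
]

#: Maps alternative column names in third-party trial logs onto ours.
DEFAULT_TRIAL_COLUMN_MAP: dict = {}


def write_trial_log(records, path) -> Path:
    """Write staircase trial records as CSV (one header row)."""
    rows = [
        {
            "participant": r.participant_id,
            "trial": r.trial_index,
            "polarity": r.polarity,
            "intensity_mA": r.intensity_mA,
            "response": r.response,
            "correct": int(r.correct),
            "reversal": int(r.reversal),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_trial_log(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Read a trial-log CSV, renaming columns via ``column_map`` if given."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"trial log missing column(s) {missing}")
    df["correct"] = df["correct"].astype(bool)
    df["reversal"] = df["reversal"].astype(bool)
    return df


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "as_dict"):
        return _to_jsonable(obj.as_dict())
    if hasattr(obj, "__dataclass_fields__"):
        return _to_jsonable(asdict(obj))
    return obj


def input_hash(path) -> str:
    """SHA-256 of an input file, recorded in reports for provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    results: dict,
    path,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
    inputs: Sequence = (),
) -> Path:
    """Write a JSON analysis report with config echo and provenance."""
    doc = {
        "gvstim_version": __version__,
        "config": _to_jsonable(config or {}),
        "seed": seed,
        "inputs": {str(p): input_hash(p) for p in inputs},
        "results": _to_jsonable(results),
    }
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def synth_recording(
    profile: SampledTrace,
    load_ohm: float,
    noise_sd_V: float = 0.0,
    ripple_amplitude_V: float = 0.0,
    ripple_freq_Hz: float = 100_000.0,
    offset_error_mA: float = 0.0,
    seed: int = 0,
    model: Optional[EhcsModel] = None,
) -> DualChannelRecording:
    """Synthesize a two-electrode recording for a current-command profile.

    ``profile`` is in milliamps; it is mapped to DAC volts through the
    control law and pushed through :func:`gvstim.circuit.simulate_device`
    with the requested noise, ripple and DC offset error.  Over a
    plateau the differential mean equals
    ``(profile + offset_error) * load`` up to the noise.
    """
    from dataclasses import replace as _replace

    model = model or EhcsModel()
    if offset_error_mA:
        model = _replace(model, offset_mA=offset_error_mA)
    volts = model.vref_V * (profile.values + model.full_scale_mA) / model.full_scale_mA
    command = SampledTrace(
        profile.sample_rate_Hz, volts, t0_s=profile.t0_s, units="V"
    )
    ripple = RippleSpec(ripple_amplitude_V, ripple_freq_Hz)
    rec = simulate_device(
        model,
        LoadCondition(load_ohm),
        command,
        noise_sd_V=noise_sd_V,
        ripple=ripple,
        seed=seed,
    )
    rec.meta.update({"i_profile": "mA", "load_ohm": load_ohm, "seed": seed})
    return rec


def load_config(path) -> dict:
    """Load a TOML or YAML run-configuration file into a plain dict."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            return yaml.safe_load(fh) or {}
    raise ConfigError(f"unsupported config format: {path.suffix!r}")
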