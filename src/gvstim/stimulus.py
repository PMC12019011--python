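"""Stimulation command-signal generation and DAC mappings.

The stimulator delivers a ramp--hold--ramp current profile: a raised
sine-like ascent over ``S`` milliseconds, a constant hold of amplitude
``A`` milliamps for ``D`` milliseconds, and a mirrored descent, so the
full span is ``2S + D``.  The smooth ramps avoid the tingling and
burning sensations caused by abrupt current steps.

This module also provides the linear mappings between DAC codes, DAC
voltages and output current, frequency-sweep and band-limited-noise
command signals for dynamic characterization, and the hard safety clamp
(default |I| <= 4 mA, the accepted limit for low-intensity transcranial
electrical stimulation).

Units at the API surface are milliamps and milliseconds; sampled traces
carry their rate in Hz and start time in seconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DomainError, NyquistError, SafetyError

logger = logging.getLogger(__name__)

#: Default current safety limit in milliamps (low-intensity tES guideline).
SAFETY_LIMIT_MA = 4.0


@dataclass(frozen=True)
class StimulusSpec:
    """Ramp-hold-ramp stimulus: amplitude ``A``, slope ``S``, duration ``D``.

    Parameters
    ----------
    amplitude_mA : float
        Hold-state current ``A`` in milliamps, signed (polarity encodes
        tilt direction).  Must satisfy ``|A| <= safety_limit_mA``.
    slope_ms : float
        Ramp length ``S`` in milliseconds (each of ascent and descent).
    duration_ms : float
        Hold length ``D`` in milliseconds.
    safety_limit_mA : float
        Amplitude bound; override only deliberately.
    """

    amplitude_mA: float
    slope_ms: float
    duration_ms: float
    safety_limit_mA: float = SAFETY_LIMIT_MA

    def __post_init__(self) -> None:
        if abs(self.amplitude_mA) > self.safety_limit_mA:
            raise SafetyError(
                f"|amplitude| = {abs(self.amplitude_mA)} mA exceeds the "
                f"{self.safety_limit_mA} mA safety limit"
            )
        if self.slope_ms < 0 or self.duration_ms < 0:
            raise ConfigError("slope_ms and duration_ms must be >= 0")
        if self.slope_ms == 0:
            logger.warning(
                "slope_ms = 0: degenerate ramp, waveform is an instantaneous step"
            )

    @property
    def span_ms(self) -> float:
        """Total waveform span ``2S + D`` in milliseconds."""
        return 2.0 * self.slope_ms + self.duration_ms


@dataclass(frozen=True)
class DacConfig:
    """An n-bit DAC driving the current source.

    ``full_scale_mA`` is the single-side maximum output current ``N``:
    codes map linearly onto ``[-N, +N]`` milliamps, and DAC voltage
    ``Vref`` (half the maximum DAC output) maps to 0 mA.
    """

    bits: int = 12
    full_scale_mA: float = 4.0
    vref_V: float = 2.65

    def __post_init__(self) -> None:
        if not (8 <= self.bits <= 16):
            raise ConfigError(f"bits must be in [8, 16], got {self.bits}")
        if self.full_scale_mA <= 0:
            raise ConfigError("full_scale_mA must be > 0")
        if self.vref_V <= 0:
            raise ConfigError("vref_V must be > 0")

    @property
    def max_code(self) -> int:
        return 2**self.bits - 1

    @property
    def lsb_mA(self) -> float:
        """Current step per DAC code: ``2N / (2^n - 1)``."""
        return 2.0 * self.full_scale_mA / self.max_code


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled signal with declared units (``mA`` or ``V``)."""

    sample_rate_Hz: float
    values: np.ndarray
    t0_s: float = 0.0
    units: str = "mA"

    def __post_init__(self) -> None:
        if self.sample_rate_Hz <= 0:
            raise ConfigError("sample_rate_Hz must be > 0")
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("trace values must all be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0_s + np.arange(len(self.values)) / self.sample_rate_Hz


def waveform_value(spec: StimulusSpec, t_ms: float) -> float:
    """Evaluate the ramp-hold-ramp waveform at time ``t_ms``.

    Piecewise: ``A*sin(pi/2 * t/S)`` on the ascent (``0 <= t < S``),
    ``A`` on the hold (``S <= t < S+D``), and the mirrored
    ``A*sin(pi/2 - pi/2 * (t-(S+D))/S)`` on the descent, reaching 0 at
    ``t = 2S + D``.  Continuous at both junctions.

    Raises
    ------
    DomainError
        If ``t_ms`` lies outside ``[0, 2S+D]``.
    """
    a, s, d = spec.amplitude_mA, spec.slope_ms, spec.duration_ms
    span = spec.span_ms
    if not (0.0 <= t_ms <= span):
        raise DomainError(f"t = {t_ms} ms outside waveform span [0, {span}] ms")
    if s == 0.0:
        # degenerate ramp: instantaneous step to the hold level
        return a if t_ms <= d else 0.0
    if t_ms < s:
        return a * math.sin(math.pi / 2.0 * t_ms / s)
    if t_ms < s + d:
        return a
    return a * math.sin(math.pi / 2.0 - math.pi / 2.0 * (t_ms - (s + d)) / s)


def generate_waveform(spec: StimulusSpec, sample_rate_Hz: float) -> SampledTrace:
    """Sample the ramp-hold-ramp waveform over ``[0, 2S+D]`` inclusive.

    The first sample is 0 and hold-state samples equal ``A`` exactly.
    """
    if sample_rate_Hz <= 0:
        raise ConfigError("sample_rate_Hz must be > 0")
    span_s = spec.span_ms / 1000.0
    n = int(math.floor(span_s * sample_rate_Hz)) + 1
    t_ms = np.arange(n) / sample_rate_Hz * 1000.0
    values = np.array([waveform_value(spec, t) for t in t_ms])
    return SampledTrace(sample_rate_Hz, values, units="mA")


def code_to_current(cfg: DacConfig, code: int) -> float:
    """Map a DAC input code onto output current in milliamps.

    ``Iout = 2N/(2^n - 1) * Dn - N``: code 0 gives ``-N``, full code
    gives ``+N``.
    """
    if not (0 <= code <= cfg.max_code):
        raise DomainError(f"code {code} outside [0, {cfg.max_code}]")
    return cfg.lsb_mA * code - cfg.full_scale_mA


def current_to_code(cfg: DacConfig, current_mA: float) -> int:
    """Nearest DAC code for a target current; ties round half away from zero.

    Round-trip error through :func:`code_to_current` is at most half an
    LSB, ``N/(2^n - 1)`` mA.

    Raises
    ------
    SafetyError
        If ``|current_mA|`` exceeds the DAC full scale ``N``.
    """
    n_fs = cfg.full_scale_mA
    if abs(current_mA) > n_fs:
        raise SafetyError(
            f"|{current_mA}| mA exceeds DAC full scale {n_fs} mA"
        )
    exact = (current_mA + n_fs) / cfg.lsb_mA
    # round half away from zero (exact is always >= 0 here)
    code = int(math.floor(exact + 0.5))
    return min(code, cfg.max_code)


def voltage_to_current(cfg: DacConfig, vdac_V: float) -> float:
    """Map DAC output voltage onto current: ``Iout = N*VDAC/Vref - N`` (mA).

    ``VDAC = Vref`` (the mid-scale reference) gives 0 mA; ``VDAC = 2*Vref``
    gives ``+N``.
    """
    if vdac_V < 0:
        raise DomainError(f"VDAC = {vdac_V} V must be >= 0")
    return cfg.full_scale_mA * vdac_V / cfg.vref_V - cfg.full_scale_mA


def current_to_voltage(cfg: DacConfig, current_mA: float) -> float:
    """Inverse of :func:`voltage_to_current`: command voltage for a current."""
    return cfg.vref_V * (current_mA + cfg.full_scale_mA) / cfg.full_scale_mA


@dataclass(frozen=True)
class SweepSegment:
    """One constant-frequency stretch of a sweep (half-open sample range)."""

    freq_Hz: float
    start: int
    stop: int


def sweep_segment_bounds(
    freqs_Hz: "list[float]",
    repeats: int,
    sample_rate_Hz: float,
    cycles_per_repeat: int = 1,
) -> "list[SweepSegment]":
    """Sample-index boundaries of the segments :func:`sine_sweep` emits.

    Each repeat of frequency ``f`` spans ``round(cycles * fs / f)``
    samples (an integer number of cycles).
    """
    segments: list[SweepSegment] = []
    pos = 0
    for f in freqs_Hz:
        n_seg = int(round(cycles_per_repeat * sample_rate_Hz / f))
        for _ in range(repeats):
            segments.append(SweepSegment(f, pos, pos + n_seg))
            pos += n_seg
    return segments


def sine_sweep(
    freqs_Hz: "list[float]",
    amplitude_mA: float,
    repeats: int = 3,
    sample_rate_Hz: float = 2560.0,
    steps_per_cycle: int = 128,
    cycles_per_repeat: int = 1,
) -> SampledTrace:
    """Concatenated constant-amplitude sine segments for frequency sweeps.

    Emulates a DAC stepping through ``steps_per_cycle`` levels per cycle
    (zero-order hold), the way the stimulator's function generator
    produces smooth sines.  Each repeat contains an integer number of
    cycles, so every segment has zero mean.

    Raises
    ------
    NyquistError
        If ``sample_rate_Hz < 2 * max(freqs_Hz)``.
    """
    if not freqs_Hz:
        raise ConfigError("freqs_Hz must be non-empty")
    if steps_per_cycle < 2:
        raise ConfigError("steps_per_cycle must be >= 2")
    if repeats < 1 or cycles_per_repeat < 1:
        raise ConfigError("repeats and cycles_per_repeat must be >= 1")
    fmax = max(freqs_Hz)
    if sample_rate_Hz < 2.0 * fmax:
        raise NyquistError(
            f"sample rate {sample_rate_Hz} S/s below Nyquist 2*{fmax} Hz"
        )
    if abs(amplitude_mA) > SAFETY_LIMIT_MA:
        raise SafetyError(f"sweep amplitude {amplitude_mA} mA exceeds safety limit")
    chunks = []
    for seg in sweep_segment_bounds(freqs_Hz, repeats, sample_rate_Hz, cycles_per_repeat):
        n = seg.stop - seg.start
        phase = seg.freq_Hz * np.arange(n) / sample_rate_Hz  # in cycles
        stepped = np.floor(phase * steps_per_cycle) / steps_per_cycle
        chunk = amplitude_mA * np.sin(2.0 * np.pi * stepped)
        # rounding the segment length to whole samples leaves a residual
        # DC component of order amplitude/n; remove it so every segment
        # is exactly zero-mean
        if n > 0:
            chunk -= chunk.mean()
        chunks.append(chunk)
    return SampledTrace(sample_rate_Hz, np.concatenate(chunks), units="mA")


def zero_mean_noise(
    bandwidth_Hz: float,
    amplitude_mA: float,
    duration_s: float,
    sample_rate_Hz: float,
    seed: int,
) -> SampledTrace:
    """Band-limited zero-mean noise, the command signal for noisy stimulation.

    Synthesized in the frequency domain: unit magnitude with uniformly
    random phase on every bin up to ``bandwidth_Hz``, zero above, inverse
    transformed, mean-removed and rescaled so the peak equals
    ``amplitude_mA``.  The construction is exactly band-limited and
    reproducible per seed.
    """
    if bandwidth_Hz > sample_rate_Hz / 2.0:
        raise NyquistError(
            f"bandwidth {bandwidth_Hz} Hz exceeds Nyquist {sample_rate_Hz / 2} Hz"
        )
    if bandwidth_Hz <= 0 or duration_s <= 0:
        raise ConfigError("bandwidth_Hz and duration_s must be > 0")
    if abs(amplitude_mA) > SAFETY_LIMIT_MA:
        raise SafetyError(f"noise amplitude {amplitude_mA} mA exceeds safety limit")
    n = int(round(duration_s * sample_rate_Hz))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_Hz)
    spectrum = np.zeros(len(freqs), dtype=complex)
    in_band = (freqs > 0) & (freqs <= bandwidth_Hz)
    phases = rng.uniform(0.0, 2.0 * np.pi, int(in_band.sum()))
    spectrum[in_band] = np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    peak = np.max(np.abs(x))
    if peak > 0 and amplitude_mA != 0:
        x *= amplitude_mA / peak
    else:
        x = np.zeros(n)
    return SampledTrace(sample_rate_Hz, x, units="mA")


def enforce_current_limit(
    trace: SampledTrace, limit_mA: float = SAFETY_LIMIT_MA, policy: str = "raise"
) -> SampledTrace:
    """Enforce the current safety limit on a trace.

    ``policy="raise"`` (default) raises :class:`SafetyError` naming the
    first offending sample; ``policy="clip"`` returns a hard-clipped copy.
    A compliant trace is returned unchanged.
    """
    if limit_mA <= 0:
        raise ConfigError("limit_mA must be > 0")
    if policy not in ("raise", "clip"):
        raise ConfigError(f"unknown policy {policy!r}")
    over = np.abs(trace.values) > limit_mA
    if not over.any():
        return trace
    if policy == "raise":
        idx = int(np.argmax(over))
        raise SafetyError(
            f"sample {idx} ({trace.values[idx]:.4g} mA) exceeds the "
            f"{limit_mA} mA limit"
        )
    return replace(trace, values=np.clip(trace.values, -limit_mA, limit_mA))
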