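"""Hardware-evaluation pipelines: precision/stability and frequency response.

Two analyses quantify how faithfully the current source delivers its
command:

**Precision & stability (P&ST).**  Dual-channel oscilloscope recordings
of the electrode voltages (50 kS/s by default) are low-pass filtered
with a zero-phase Butterworth filter (order 5, 10 kHz cutoff), the
holding-state segments are located by a voltage threshold, and per
segment the peak-to-peak, RMS and SD of the differential voltage are
computed.  The current uncertainty is ``sigma_I = SD / R`` (Ohm's law on
the known test load) and the error rate is ``100 * sigma_I / |I_set|``.

**Frequency response analysis (FRA).**  A sine sweep (1-20 Hz) is
driven through the device; DC offsets are removed (median of an initial
window), the traces are FIR-decimated, and per nominal frequency the
gain ``20*log10(|V_out|/|V_cmd|)`` and phase difference are read off
the FFT at the command's dominant bin.  Channel A should sit at 0 deg
and channel B at 180 deg, since the electrodes swing in anti-phase.
The analytic expectation for the single-electrode gain is
``20*log10((N/Vref_fra)/2 * R)`` with transconductance ``N`` mA per
``Vref_fra`` volts, halved because each electrode carries half the
differential voltage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .circuit import EhcsModel, LoadCondition
from .errors import ConfigError, DomainError, InsufficientDataError
from .stimulus import SampledTrace


@dataclass
class DualChannelRecording:
    """Uniformly sampled two-electrode voltage trace, optional DAC command."""

    sample_rate_Hz: float
    chanA_V: np.ndarray
    chanB_V: np.ndarray
    dac_V: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chanA_V = np.asarray(self.chanA_V, dtype=float)
        self.chanB_V = np.asarray(self.chanB_V, dtype=float)
        if self.dac_V is not None:
            self.dac_V = np.asarray(self.dac_V, dtype=float)
        if self.sample_rate_Hz <= 0:
            raise ConfigError("sample_rate_Hz must be > 0")
        lens = {len(self.chanA_V), len(self.chanB_V)}
        if self.dac_V is not None:
            lens.add(len(self.dac_V))
        if len(lens) != 1:
            raise ConfigError("all channels must have equal length")
        for arr in (self.chanA_V, self.chanB_V, self.dac_V):
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ConfigError("channel values must be finite")

    def __len__(self) -> int:
        return len(self.chanA_V)

    @property
    def differential_V(self) -> np.ndarray:
        """Channel A minus channel B: the load voltage."""
        return self.chanA_V - self.chanB_V

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_Hz


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design target: order ``N``, cutoff ``fc``.

    The normalized cutoff is ``wc = 2*fc/fs`` and the magnitude target
    ``|H| = 1/sqrt(1 + (wd/wc)^(2N))``; the digital filter is designed
    by bilinear transform with pre-warping so the half-power point lands
    exactly at ``fc``.
    """

    order: int = 5
    cutoff_Hz: float = 10_000.0
    sample_rate_Hz: float = 50_000.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigError("order must be >= 1")
        if not (0.0 < self.cutoff_Hz < self.sample_rate_Hz / 2.0):
            raise ConfigError(
                f"cutoff {self.cutoff_Hz} Hz must lie in (0, fs/2)"
            )

    @property
    def omega_c(self) -> float:
        """Normalized cutoff ``2*fc/fs`` (1 = Nyquist)."""
        return 2.0 * self.cutoff_Hz / self.sample_rate_Hz

    def sos(self) -> np.ndarray:
        return signal.butter(
            self.order, self.cutoff_Hz, fs=self.sample_rate_Hz, output="sos"
        )


@dataclass(frozen=True)
class HoldingSegment:
    """Half-open sample range ``[start, stop)`` of one holding state."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ConfigError("segment must satisfy 0 <= start < stop")

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class PstMetrics:
    """Precision-and-stability summary for one holding segment.

    Voltage metrics are computed on the differential signal; per-channel
    SDs are also carried since single-electrode stability is of interest
    too.  ``sigma_I = SD/R`` (mA) and ``error_rate = 100*sigma_I/|I_set|``.
    """

    peak_peak_V: float
    rms_V: float
    sd_V: float
    sd_chanA_V: float
    sd_chanB_V: float
    sigma_I_mA: float
    error_rate_pct: Optional[float]
    i_measured_mA: float
    i_set_mA: float
    load_ohm: float

    def as_dict(self) -> dict:
        return {
            "peak_peak_V": self.peak_peak_V,
            "rms_V": self.rms_V,
            "sd_V": self.sd_V,
            "sd_chanA_V": self.sd_chanA_V,
            "sd_chanB_V": self.sd_chanB_V,
            "sigma_I_mA": self.sigma_I_mA,
            "error_rate_pct": self.error_rate_pct,
            "i_measured_mA": self.i_measured_mA,
            "i_set_mA": self.i_set_mA,
            "load_ohm": self.load_ohm,
        }


@dataclass(frozen=True)
class BodeResult:
    """Gain/phase versus frequency for both electrode channels."""

    freqs_Hz: np.ndarray
    gainA_dB: np.ndarray
    gainB_dB: np.ndarray
    phaseA_deg: np.ndarray
    phaseB_deg: np.ndarray
    expected_gain_dB: Optional[float] = None
    resolved: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        d = {
            "freqs_Hz": list(map(float, self.freqs_Hz)),
            "gainA_dB": list(map(float, self.gainA_dB)),
            "gainB_dB": list(map(float, self.gainB_dB)),
            "phaseA_deg": list(map(float, self.phaseA_deg)),
            "phaseB_deg": list(map(float, self.phaseB_deg)),
            "expected_gain_dB": self.expected_gain_dB,
        }
        if self.resolved is not None:
            d["resolved"] = list(map(bool, self.resolved))
        return d


def butterworth_magnitude(spec: FilterSpec, omega_d: float) -> float:
    """Analytic Butterworth magnitude ``1/sqrt(1 + (wd/wc)^(2N))``."""
    return 1.0 / math.sqrt(1.0 + (omega_d / spec.omega_c) ** (2 * spec.order))


def lowpass_zero_phase(
    recording: DualChannelRecording, spec: FilterSpec
) -> DualChannelRecording:
    """Zero-phase (forward-backward) Butterworth low-pass on both channels.

    Forward-backward application cancels the phase response, so
    symmetric inputs stay symmetric; the effective magnitude response is
    the square of the single-pass response.  The DAC channel, if
    present, is passed through untouched (it is the command, not a
    measurement).
    """
    if spec.sample_rate_Hz != recording.sample_rate_Hz:
        spec = replace(spec, sample_rate_Hz=recording.sample_rate_Hz)
    sos = spec.sos()
    padlen = 3 * (2 * spec.order + 1)
    if len(recording) <= padlen:
        raise DomainError(
            f"recording length {len(recording)} too short for filter "
            f"warm-up ({padlen} samples)"
        )
    return DualChannelRecording(
        sample_rate_Hz=recording.sample_rate_Hz,
        chanA_V=signal.sosfiltfilt(sos, recording.chanA_V),
        chanB_V=signal.sosfiltfilt(sos, recording.chanB_V),
        dac_V=None if recording.dac_V is None else recording.dac_V.copy(),
        meta=dict(recording.meta),
    )


def segment_holding_states(
    recording: DualChannelRecording,
    threshold_fraction: float = 0.9,
    guard_fraction: float = 0.05,
    min_duration_s: float = 0.05,
) -> "list[HoldingSegment]":
    """Locate holding-state segments of the differential voltage.

    The plateau level is estimated as the median of ``|v_diff|`` over
    samples above half its maximum; maximal runs with
    ``|v_diff| >= threshold_fraction * plateau`` are kept, trimmed by
    ``guard_fraction`` of their length at each edge, and runs shorter
    than ``min_duration_s`` are discarded.  Returns an empty list when
    nothing crosses the threshold (e.g. an idle recording).
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ConfigError("threshold_fraction must be in (0, 1]")
    if not (0.0 <= guard_fraction < 0.5):
        raise ConfigError("guard_fraction must be in [0, 0.5)")
    v = np.abs(recording.differential_V)
    vmax = v.max() if len(v) else 0.0
    if vmax <= 0.0:
        return []
    plateau = np.median(v[v >= 0.5 * vmax])
    mask = v >= threshold_fraction * plateau
    if not mask.any():
        return []
    # maximal runs of True
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [len(mask)]))
    segments: list[HoldingSegment] = []
    min_len = int(round(min_duration_s * recording.sample_rate_Hz))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if not mask[lo]:
            continue
        run = hi - lo
        guard = int(round(guard_fraction * run))
        s, e = lo + guard, hi - guard
        if e - s >= max(min_len, 1):
            segments.append(HoldingSegment(int(s), int(e)))
    return segments


def pst_metrics(
    recording: DualChannelRecording,
    segment: HoldingSegment,
    load_ohm: float,
    i_set_mA: float,
) -> PstMetrics:
    """Precision-and-stability metrics over one holding segment.

    ``i_measured`` is the mean differential voltage over the segment
    divided by the load (Ohm's law); ``sigma_I`` the differential SD over
    the load; ``error_rate`` compares the uncertainty with the commanded
    current and is ``None`` when ``i_set_mA`` is 0.
    """
    if load_ohm <= 0:
        raise ConfigError("load_ohm must be > 0")
    if segment.stop > len(recording):
        raise DomainError("segment extends past the recording")
    sl = slice(segment.start, segment.stop)
    v = recording.differential_V[sl]
    sd = float(np.std(v))
    sigma_i = sd / load_ohm * 1000.0
    return PstMetrics(
        peak_peak_V=float(v.max() - v.min()),
        rms_V=float(np.sqrt(np.mean(v**2))),
        sd_V=sd,
        sd_chanA_V=float(np.std(recording.chanA_V[sl])),
        sd_chanB_V=float(np.std(recording.chanB_V[sl])),
        sigma_I_mA=sigma_i,
        error_rate_pct=None if i_set_mA == 0 else 100.0 * sigma_i / abs(i_set_mA),
        i_measured_mA=float(np.mean(v)) / load_ohm * 1000.0,
        i_set_mA=i_set_mA,
        load_ohm=load_ohm,
    )


def remove_dc_offset(
    recording: DualChannelRecording, initial_window_s: float
) -> DualChannelRecording:
    """Subtract each channel's median over the initial window.

    Removes the mid-supply electrode offset (and the DAC's mid-scale
    reference when a command channel is present) before spectral
    analysis.  Idempotent for constant offsets.
    """
    n = int(round(initial_window_s * recording.sample_rate_Hz))
    if n < 1 or n > len(recording):
        raise DomainError(
            f"initial window of {n} samples invalid for recording of "
            f"length {len(recording)}"
        )
    dac = recording.dac_V
    return DualChannelRecording(
        sample_rate_Hz=recording.sample_rate_Hz,
        chanA_V=recording.chanA_V - np.median(recording.chanA_V[:n]),
        chanB_V=recording.chanB_V - np.median(recording.chanB_V[:n]),
        dac_V=None if dac is None else dac - np.median(dac[:n]),
        meta=dict(recording.meta),
    )


def _decimate_channel(x: np.ndarray, factor: int, numtaps: int = 31) -> np.ndarray:
    """Anti-alias FIR (Hamming windowed-sinc) then keep every factor-th sample.

    Cutoff 0.8 of the new Nyquist; applied forward-backward so the group
    delay is zero and no sample-index compensation is needed.
    """
    if factor == 1:
        return x.copy()
    taps = signal.firwin(numtaps, 0.8 / factor, window="hamming")
    filtered = signal.filtfilt(taps, [1.0], x)
    return filtered[::factor]


def decimate(recording: DualChannelRecording, factor: int) -> DualChannelRecording:
    """FIR-decimate all channels by an integer factor (new rate fs/factor)."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ConfigError(f"factor must be a positive integer, got {factor!r}")
    dac = recording.dac_V
    return DualChannelRecording(
        sample_rate_Hz=recording.sample_rate_Hz / factor,
        chanA_V=_decimate_channel(recording.chanA_V, factor),
        chanB_V=_decimate_channel(recording.chanB_V, factor),
        dac_V=None if dac is None else _decimate_channel(dac, factor),
        meta=dict(recording.meta),
    )


@dataclass(frozen=True)
class FraSettings:
    """Knobs for the FFT gain/phase extraction.

    ``segments`` optionally restricts the analysis of each nominal
    frequency to a half-open sample range (at the recording's current
    rate); with ``None`` the full trace is transformed once.  The search
    window around each nominal frequency defaults to +/-0.5 Hz, and a
    command bin is flagged unresolved when its magnitude is below
    ``noise_floor_ratio`` times the command spectrum's maximum.
    ``smooth_Hz`` > 0 applies a moving average over the per-frequency
    results with a window of ``max(1, round(smooth_Hz/df))`` points.
    """

    search_window_Hz: float = 0.5
    noise_floor_ratio: float = 1e-3
    smooth_Hz: float = 0.0
    segments: Optional[Sequence[tuple]] = None


def _spectral_peak(
    spectrum: np.ndarray, freqs: np.ndarray, f0: float, window_Hz: float
) -> int:
    lo = np.searchsorted(freqs, f0 - window_Hz)
    hi = np.searchsorted(freqs, f0 + window_Hz, side="right")
    if hi <= lo:
        return -1
    return lo + int(np.argmax(np.abs(spectrum[lo:hi])))


def fra_gain_phase(
    command: SampledTrace,
    recording: DualChannelRecording,
    freqs_Hz: Sequence[float],
    settings: FraSettings = FraSettings(),
    expected_gain_dB: Optional[float] = None,
) -> BodeResult:
    """FFT gain and phase of both electrode channels against the command.

    For each nominal frequency, the command's dominant bin within the
    search window anchors the measurement; gain is
    ``20*log10(|X_out|/|X_cmd|)`` at that bin, and phase is the wrapped
    difference of the bin phases.  Offsets must have been removed first
    (see :func:`remove_dc_offset`).  Frequencies whose command bin falls
    below the noise floor are flagged unresolved (NaN results).
    """
    if command.sample_rate_Hz != recording.sample_rate_Hz:
        raise ConfigError("command and recording sample rates differ")
    if len(command) != len(recording):
        raise ConfigError("command and recording lengths differ")
    freqs_Hz = np.asarray(list(freqs_Hz), dtype=float)
    if settings.segments is None:
        seg_for = {f: (0, len(command)) for f in freqs_Hz}
    else:
        seg_for = {}
        for entry in settings.segments:
            f, lo, hi = entry
            seg_for.setdefault(float(f), (int(lo), int(hi)))
        missing = [f for f in freqs_Hz if f not in seg_for]
        if missing:
            raise ConfigError(f"no segment provided for frequencies {missing}")

    n_f = len(freqs_Hz)
    gain_a = np.full(n_f, np.nan)
    gain_b = np.full(n_f, np.nan)
    phase_a = np.full(n_f, np.nan)
    phase_b = np.full(n_f, np.nan)
    resolved = np.zeros(n_f, dtype=bool)
    fft_cache: dict = {}
    for i, f0 in enumerate(freqs_Hz):
        lo, hi = seg_for[float(f0)]
        key = (lo, hi)
        if key not in fft_cache:
            n = hi - lo
            bin_freqs = np.fft.rfftfreq(n, d=1.0 / command.sample_rate_Hz)
            fft_cache[key] = (
                bin_freqs,
                np.fft.rfft(command.values[lo:hi]),
                np.fft.rfft(recording.chanA_V[lo:hi]),
                np.fft.rfft(recording.chanB_V[lo:hi]),
            )
        bin_freqs, x_cmd, x_a, x_b = fft_cache[key]
        k = _spectral_peak(x_cmd, bin_freqs, f0, settings.search_window_Hz)
        if k < 0:
            continue
        mag_cmd = np.abs(x_cmd[k])
        if mag_cmd < settings.noise_floor_ratio * np.abs(x_cmd[1:]).max():
            continue
        resolved[i] = True
        gain_a[i] = 20.0 * np.log10(np.abs(x_a[k]) / mag_cmd)
        gain_b[i] = 20.0 * np.log10(np.abs(x_b[k]) / mag_cmd)
        phase_a[i] = wrap_phase_deg(np.degrees(np.angle(x_a[k]) - np.angle(x_cmd[k])))
        phase_b[i] = wrap_phase_deg(np.degrees(np.angle(x_b[k]) - np.angle(x_cmd[k])))

    if settings.smooth_Hz > 0 and n_f > 1:
        df = float(np.median(np.diff(np.sort(freqs_Hz)))) or 1.0
        w = max(1, int(round(settings.smooth_Hz / df)))
        if w > 1:
            kernel = np.ones(w) / w
            for arr in (gain_a, gain_b, phase_a, phase_b):
                valid = ~np.isnan(arr)
                if valid.sum() >= w:
                    arr[valid] = np.convolve(arr[valid], kernel, mode="same")
    return BodeResult(
        freqs_Hz=freqs_Hz,
        gainA_dB=gain_a,
        gainB_dB=gain_b,
        phaseA_deg=phase_a,
        phaseB_deg=phase_b,
        expected_gain_dB=expected_gain_dB,
        resolved=resolved,
    )


def wrap_phase_deg(phi: float) -> float:
    """Wrap a phase in degrees to the interval (-180, 180]."""
    wrapped = (phi + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


def expected_gain(model: EhcsModel, load: LoadCondition) -> float:
    """Analytic single-electrode FRA gain in dB for a resistive load.

    The device converts command volts to ``N/Vref_fra`` milliamps per
    volt; the load converts that to volts and each electrode carries
    half the differential swing, so the voltage gain from command to a
    single electrode is ``(N/Vref_fra)/2 * R`` (with N in amps).
    """
    transconductance_A_per_V = model.full_scale_mA * 1e-3 / model.vref_fra_V
    ratio = transconductance_A_per_V / 2.0 * load.resistance_ohm
    return 20.0 * math.log10(ratio)
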