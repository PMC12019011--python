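"""Model of the enhanced Howland current source (EHCS) stimulator.

The stimulator converts a differential input voltage into a
load-independent output current through an op-amp difference stage with
a buffered sense resistor.  With the bridge resistor ratios balanced,
``R1/R2 = R3/R4 = k``, the load current is

    iL = (u_in+ - u_in-) / (k * R0)

so the transconductance is ``1/(k*R0)`` and is independent of the load
up to the output-swing (compliance) limit.  The module covers:

* the compliance-voltage budget that sizes the supply,
* the boost-converter DC set-point from its feedback divider,
* exact nodal analysis of the (possibly unbalanced) bridge, used for
  Monte-Carlo resistor-tolerance studies of the zero-input offset,
* offset calibration (a measured DC error subtracted in firmware), and
* a full device simulation producing synthetic two-electrode
  oscilloscope recordings for the characterization pipelines.

Electrode convention: the two electrodes sit at mid-supply and swing
symmetrically, each carrying half the differential load voltage
(channel A in phase with the command, channel B in anti-phase), and
hard-clip ``swing_margin_V`` away from the rails.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import CalibrationError, ConfigError, DomainError
from .stimulus import SampledTrace

#: Nominal bridge ratio from the bill of materials (49.9 kOhm / 10 kOhm).
DEFAULT_RATIO_K = 4.99


def _derived_r0(ratio_k: float, vref_V: float, full_scale_mA: float) -> float:
    """Sense resistance making the transconductance exactly N/Vref (mA/V)."""
    return vref_V / (ratio_k * full_scale_mA * 1e-3)


@dataclass(frozen=True)
class EhcsModel:
    """Small-signal model of the enhanced Howland current source.

    Parameters
    ----------
    ratio_k : float
        Bridge resistor ratio ``k = R1/R2 = R3/R4``.
    r0_ohm : float, optional
        Sense resistance ``R0``.  Defaults to ``Vref/(k*N)`` so that the
        DAC-voltage-to-current mapping ``Iout = N*VDAC/Vref - N`` holds
        exactly (about 132.8 Ohm for the nominal build, close to the
        130 Ohm the bill of materials implies).
    vref_V : float
        Control reference voltage (half the maximum DAC output, 2.65 V).
    full_scale_mA : float
        Single-side maximum output current ``N``.
    supply_V, swing_margin_V : float
        Boost-converter output and per-rail output-swing margin of the
        op-amps; electrode voltages are confined to
        ``[margin, supply - margin]``.
    offset_mA : float
        Residual zero-input output current (resistor-mismatch error),
        removable via :func:`apply_offset_calibration`.
    vref_fra_V : float
        Command-offset constant used by the frequency-response gain
        convention (2.6 V); kept separate from ``vref_V`` deliberately.
    """

    ratio_k: float = DEFAULT_RATIO_K
    r0_ohm: Optional[float] = None
    vref_V: float = 2.65
    full_scale_mA: float = 4.0
    supply_V: float = 24.6
    swing_margin_V: float = 3.0
    offset_mA: float = 0.0
    vref_fra_V: float = 2.6

    def __post_init__(self) -> None:
        if self.ratio_k <= 0:
            raise ConfigError("ratio_k must be > 0")
        if self.r0_ohm is None:
            object.__setattr__(
                self,
                "r0_ohm",
                _derived_r0(self.ratio_k, self.vref_V, self.full_scale_mA),
            )
        if self.r0_ohm <= 0:
            raise ConfigError("r0_ohm must be > 0")
        if self.supply_V <= 2.0 * self.swing_margin_V:
            raise ConfigError("supply_V must exceed 2*swing_margin_V")

    @property
    def transconductance_mA_per_V(self) -> float:
        """Output current per differential input volt, ``1/(k*R0)`` in mA/V."""
        return 1000.0 / (self.ratio_k * self.r0_ohm)

    @property
    def mid_supply_V(self) -> float:
        return self.supply_V / 2.0


@dataclass(frozen=True)
class BoostConfig:
    """Feedback divider of the MT3608 boost converter (R9, R11, R12)."""

    r9_ohm: float = 20_000.0
    r11_ohm: float = 20_000.0
    r12_ohm: float = 1_000.0

    def __post_init__(self) -> None:
        if self.r12_ohm <= 0:
            raise ConfigError("r12_ohm must be > 0")
        if self.r9_ohm < 0 or self.r11_ohm < 0:
            raise ConfigError("r9_ohm and r11_ohm must be >= 0")


@dataclass(frozen=True)
class ComplianceSpec:
    """Inputs to the compliance-voltage budget (currents in mA, R in Ohm)."""

    imax_mA: float = 4.0
    rmax_ohm: float = 5_000.0
    rsense_ohm: float = 0.0
    headroom_V: float = 0.0

    def __post_init__(self) -> None:
        if min(self.imax_mA, self.rmax_ohm, self.rsense_ohm, self.headroom_V) < 0:
            raise ConfigError("compliance parameters must be >= 0")


@dataclass(frozen=True)
class LoadCondition:
    """A resistive test load standing in for tissue impedance."""

    resistance_ohm: float

    def __post_init__(self) -> None:
        if self.resistance_ohm <= 0:
            raise ConfigError("resistance_ohm must be > 0")


def boost_output_voltage(cfg: BoostConfig) -> float:
    """Boost-converter DC set-point ``Vout = 0.6 * (1 + (R9+R11)/R12)`` volts."""
    return 0.6 * (1.0 + (cfg.r9_ohm + cfg.r11_ohm) / cfg.r12_ohm)


def required_voltage(spec: ComplianceSpec) -> float:
    """Compliance budget ``Imax*(Rmax + Rsense) + Vheadroom`` in volts."""
    return spec.imax_mA * 1e-3 * (spec.rmax_ohm + spec.rsense_ohm) + spec.headroom_V


def ehcs_current(model: EhcsModel, u_plus_V: float, u_minus_V: float) -> float:
    """Ideal balanced-bridge output current in milliamps.

    ``iL = (u+ - u-)/(k*R0) + offset``; load-independent up to the
    saturation limit.
    """
    return (
        (u_plus_V - u_minus_V) * model.transconductance_mA_per_V + model.offset_mA
    )


def saturation_limit(model: EhcsModel, load: LoadCondition) -> float:
    """Largest unclipped |current| in mA for a given load.

    Under the symmetric-drive convention each electrode swings half the
    differential load voltage around mid-supply, so clipping starts when
    ``|I| * R/2 = supply/2 - margin``.
    """
    headroom_V = model.mid_supply_V - model.swing_margin_V
    if headroom_V <= 0:
        return 0.0
    return headroom_V / (load.resistance_ohm / 2.0) * 1000.0


def nodal_howland_solve(
    r1_ohm: float,
    r2_ohm: float,
    r3_ohm: float,
    r4_ohm: float,
    r0_ohm: float,
    u_plus_V: float,
    u_minus_V: float,
    load_ohm: float,
) -> float:
    """Exact load current of the (possibly unbalanced) bridge, in mA.

    Ideal-op-amp nodal analysis of the enhanced Howland topology:
    ``u-`` enters through R1 with feedback R2 from the difference-stage
    output, ``u+`` enters through R3 with R4 returned (via the buffer)
    to the load node, and R0 senses the output.  When
    ``R1/R2 = R3/R4`` this reduces to ``iL = (u+ - u-)/(k*R0)``; any
    mismatch makes the output load-dependent and adds a zero-input
    offset, which is what resistor tolerance does to a real board.

    Unknowns: the shared op-amp input voltage ``Va``, the stage output
    ``Vo`` and the load-top voltage ``VL``; the buffer means R4 draws no
    current from the load node, so ``iL = (Vo - VL)/R0 = VL/RL``.
    """
    for name, r in (("r1", r1_ohm), ("r2", r2_ohm), ("r3", r3_ohm),
                    ("r4", r4_ohm), ("r0", r0_ohm), ("load", load_ohm)):
        if r <= 0:
            raise DomainError(f"{name} must be > 0, got {r}")
    # unknowns x = [Va, Vo, VL]
    a = np.array(
        [
            # KCL at inverting node: (u- - Va)/R1 + (Vo - Va)/R2 = 0
            [-(1.0 / r1_ohm + 1.0 / r2_ohm), 1.0 / r2_ohm, 0.0],
            # KCL at non-inverting node: (u+ - Va)/R3 + (VL - Va)/R4 = 0
            [-(1.0 / r3_ohm + 1.0 / r4_ohm), 0.0, 1.0 / r4_ohm],
            # load node: (Vo - VL)/R0 = VL/RL
            [0.0, 1.0 / r0_ohm, -(1.0 / r0_ohm + 1.0 / load_ohm)],
        ]
    )
    b = np.array([-u_minus_V / r1_ohm, -u_plus_V / r3_ohm, 0.0])
    try:
        va, vo, vl = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise DomainError(f"singular nodal system: {exc}") from exc
    return (vo - vl) / r0_ohm * 1000.0


@dataclass(frozen=True)
class ToleranceStats:
    """Zero-input offset-current statistics from a tolerance Monte Carlo."""

    mean_mA: float
    sd_mA: float
    p95_abs_mA: float
    n_draws: int
    tolerance_fraction: float


def tolerance_monte_carlo(
    model: EhcsModel,
    tolerance_fraction: float,
    n_draws: int,
    load: LoadCondition,
    seed: int,
) -> ToleranceStats:
    """Monte-Carlo study of the zero-input offset due to resistor tolerance.

    Each draw perturbs R1..R4 and R0 independently and uniformly within
    ``+/- tolerance_fraction`` (a tolerance is a guaranteed bound, not a
    dispersion, hence uniform) and records the zero-command output
    current from the exact nodal solve with both inputs at the common
    reference ``Vref``.  Sub-1% tolerance parts keep the offset at the
    few-hundredths-of-a-milliamp level seen on real boards.
    """
    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    if tolerance_fraction < 0:
        raise ConfigError("tolerance_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    # nominal bridge realizing ratio k with the BOM-like 10 kOhm low side
    r2 = r4 = 10_000.0
    r1 = r3 = model.ratio_k * r2
    nominal = np.array([r1, r2, r3, r4, model.r0_ohm])
    u_cm = model.vref_V
    offsets = np.empty(n_draws)
    for i in range(n_draws):
        pert = nominal * (1.0 + rng.uniform(-tolerance_fraction, tolerance_fraction, 5))
        offsets[i] = nodal_howland_solve(
            pert[0], pert[1], pert[2], pert[3], pert[4],
            u_cm, u_cm, load.resistance_ohm,
        )
    return ToleranceStats(
        mean_mA=float(offsets.mean()),
        sd_mA=float(offsets.std(ddof=1)) if n_draws > 1 else 0.0,
        p95_abs_mA=float(np.quantile(np.abs(offsets), 0.95)),
        n_draws=n_draws,
        tolerance_fraction=tolerance_fraction,
    )


def apply_offset_calibration(model: EhcsModel, measured_offset_mA: float) -> EhcsModel:
    """Subtract a measured zero-input error from the model's offset.

    Mirrors the firmware calibration step: measure the output with zero
    command, then store the error so it is subtracted from every command.
    Repeatable; calibrating with the true offset zeroes the output.

    Raises
    ------
    CalibrationError
        If ``|measured_offset_mA| >= 1``; an error that large suggests a
        hardware fault rather than resistor mismatch.
    """
    if abs(measured_offset_mA) >= 1.0:
        raise CalibrationError(
            f"measured offset {measured_offset_mA} mA outside the plausible "
            "(-1, 1) mA range; check the hardware"
        )
    return replace(model, offset_mA=model.offset_mA - measured_offset_mA)


@dataclass(frozen=True)
class RippleSpec:
    """Narrowband supply ripple injected into simulated recordings."""

    amplitude_V: float = 0.0
    freq_Hz: float = 100_000.0


def simulate_device(
    model: EhcsModel,
    load: LoadCondition,
    command: SampledTrace,
    noise_sd_V: float = 0.0,
    ripple: Optional[RippleSpec] = None,
    seed: int = 0,
):
    """Simulate electrode voltages for a DAC command trace.

    ``command`` holds DAC voltages in ``[0, 2*Vref]``.  The output
    current follows ``Iout = N*VDAC/Vref - N + offset``; each electrode
    sits at mid-supply and carries half the differential load voltage
    (channel A in phase, channel B in anti-phase), plus independent
    white measurement noise of ``noise_sd_V`` and optional narrowband
    ripple, hard-clipped at the swing limits.

    Returns
    -------
    DualChannelRecording
        With the command copied into ``dac_V`` and load/units metadata.
    """
    from .characterize import DualChannelRecording  # local import, no cycle at import time

    vdac = command.values
    if vdac.min() < 0 or vdac.max() > 2.0 * model.vref_V:
        raise DomainError(
            f"command range [{vdac.min():.3g}, {vdac.max():.3g}] V outside "
            f"[0, {2 * model.vref_V}] V"
        )
    i_mA = (
        model.full_scale_mA * vdac / model.vref_V
        - model.full_scale_mA
        + model.offset_mA
    )
    v_diff = i_mA * 1e-3 * load.resistance_ohm
    mid = model.mid_supply_V
    rng = np.random.default_rng(seed)
    n = len(vdac)
    chan_a = mid + v_diff / 2.0 + rng.normal(0.0, noise_sd_V, n)
    chan_b = mid - v_diff / 2.0 + rng.normal(0.0, noise_sd_V, n)
    if ripple is not None and ripple.amplitude_V != 0.0:
        t = np.arange(n) / command.sample_rate_Hz
        for chan in (chan_a, chan_b):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            chan += ripple.amplitude_V * np.sin(2.0 * np.pi * ripple.freq_Hz * t + phase)
    lo, hi = model.swing_margin_V, model.supply_V - model.swing_margin_V
    np.clip(chan_a, lo, hi, out=chan_a)
    np.clip(chan_b, lo, hi, out=chan_b)
    return DualChannelRecording(
        sample_rate_Hz=command.sample_rate_Hz,
        chanA_V=chan_a,
        chanB_V=chan_b,
        dac_V=vdac.copy(),
        meta={"load_ohm": load.resistance_ohm},
    )
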