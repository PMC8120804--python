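"""Stimulation protocols and LED-plate programs.

Pulse trains alternate dark (signaling, level 1) pulses with light-induced
off intervals (level 0); all trains used for signal-integration experiments
keep the summed dark time fixed (6 h by default) while the inter-pulse
interval is varied, i.e. pulse-frequency modulation between duty cycles of
100% (continuous) and 25%.  Plate programs encode per-well intensity values
at a fixed refresh interval; calibration scales every well of the 96-well LED
plate to the dimmest well after confirming PWM linearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import HOUR, MINUTE, StimulusProfile

__all__ = [
    "PulseProtocol",
    "PlateCalibration",
    "build_pulse_train",
    "duty_cycle",
    "calibrate_plate",
    "randomize_layout",
    "WELL_IDS",
    "write_plate_program",
    "read_plate_program",
]

WELL_IDS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]
DEFAULT_DUTY_CYCLES = (1.0, 0.8, 0.67, 0.5, 0.33, 0.25)


@dataclass(frozen=True)
class PulseProtocol:
    """A pulse-frequency-modulated stimulation protocol (times in minutes)."""

    pulse_duration: float
    interval: float
    n_pulses: int
    total_signal: float
    horizon: float  # minutes

    @property
    def duty_cycle(self) -> float:
        return self.pulse_duration / (self.pulse_duration + self.interval)


@dataclass(frozen=True)
class PlateCalibration:
    slopes: pd.Series  # intensity per PWM unit, per well
    offsets: pd.Series
    scale_factors: pd.Series  # <= 1, relative to the dimmest well
    uniformity_se: float  # % SEM of calibrated max outputs
    nonlinear_wells: tuple[str, ...]  # wells failing the linearity check


def build_pulse_train(
    pulse_duration: float,
    interval: float,
    total_signal: float = 360.0,
    horizon: float = 24 * 60.0,
) -> tuple[StimulusProfile, PulseProtocol]:
    """Alternating dark/light stimulus starting with a dark pulse at t = 0.

    Arguments are in minutes; the returned :class:`StimulusProfile` is in
    seconds.  ``total_signal`` must divide evenly into pulses and the train
    (including all but the trailing interval) must fit the horizon.
    """
    if pulse_duration <= 0 or interval < 0:
        raise ValueError("pulse_duration must be > 0 and interval >= 0")
    n_float = total_signal / pulse_duration
    n_pulses = int(round(n_float))
    if abs(n_float - n_pulses) > 1e-9 or n_pulses < 1:
        raise ValueError(f"total_signal {total_signal} min is not divisible by pulse_duration {pulse_duration} min")
    train_span = n_pulses * pulse_duration + (n_pulses - 1) * interval
    if train_span > horizon + 1e-9:
        max_interval = (horizon - total_signal) / (n_pulses - 1) if n_pulses > 1 else np.inf
        raise ValueError(
            f"train of {train_span:.0f} min exceeds the {horizon:.0f}-min horizon; "
            f"maximum interval for this pulse length is {max_interval:.1f} min"
        )
    segments = []
    t = 0.0
    for _ in range(n_pulses):
        segments.append((t * MINUTE, (t + pulse_duration) * MINUTE, 1.0))
        t += pulse_duration + interval
    profile = StimulusProfile(tuple(segments), horizon * MINUTE)
    proto = PulseProtocol(pulse_duration, interval, n_pulses, total_signal, horizon)
    return profile, proto


def duty_cycle(protocol: PulseProtocol) -> float:
    """Fraction of a pulse period spent signaling; 1.0 for a continuous pulse."""
    return protocol.duty_cycle


def interval_for_duty_cycle(pulse_duration: float, duty: float) -> float:
    """Light interval giving the requested duty cycle for a pulse length."""
    if not 0.0 < duty <= 1.0:
        raise ValueError("duty cycle must lie in (0, 1]")
    return pulse_duration * (1.0 - duty) / duty


def calibrate_plate(measurements: pd.DataFrame, r2_threshold: float = 0.98) -> PlateCalibration:
    """Per-well linear PWM calibration, scaled to the dimmest well.

    ``measurements`` has columns (well, pwm, intensity) with >= 3 PWM levels
    per well.  Wells whose intensity/PWM relationship has R^2 below
    ``r2_threshold`` are flagged as non-linear and excluded from scaling.
    The uniformity SE is the SEM of the calibrated maximum outputs as a
    percentage of their mean.
    """
    for col in ("well", "pwm", "intensity"):
        if col not in measurements.columns:
            raise KeyError(f"measurements table missing column {col!r}")
    slopes, offsets, bad = {}, {}, []
    for well, grp in measurements.groupby("well"):
        if grp["pwm"].nunique() < 3:
            raise ValueError(f"well {well}: need >= 3 PWM levels")
        x = grp["pwm"].to_numpy(dtype=float)
        y = grp["intensity"].to_numpy(dtype=float)
        slope, icept = np.polyfit(x, y, 1)
        pred = slope * x + icept
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if slope <= 0 or r2 < r2_threshold:
            bad.append(well)
            continue
        slopes[well], offsets[well] = float(slope), float(icept)
    if not slopes:
        raise ValueError("no well passed the linearity check")
    slopes = pd.Series(slopes, name="slope").sort_index()
    offsets = pd.Series(offsets, name="offset").sort_index()
    max_pwm = float(measurements["pwm"].max())
    max_out = slopes * max_pwm + offsets
    dimmest = float(max_out.min())
    scale = dimmest / max_out
    # residual non-uniformity judged on the *measured* top-PWM intensities
    # after scaling, not on the fitted values (which are equal by construction)
    top = measurements[measurements["pwm"] == max_pwm].groupby("well")["intensity"].mean()
    calibrated = top.reindex(scale.index) * scale
    uniformity = float(calibrated.std(ddof=1) / np.sqrt(len(calibrated)) / calibrated.mean() * 100.0)
    return PlateCalibration(
        slopes=slopes,
        offsets=offsets,
        scale_factors=scale.rename("scale"),
        uniformity_se=uniformity,
        nonlinear_wells=tuple(sorted(bad)),
    )


def randomize_layout(
    protocol_names: list[str],
    seed: int,
    control_names: tuple[str, ...] = ("constant_dark", "constant_light", "continuous_6h"),
    control_duplicates: int = 2,
) -> pd.Series:
    """Seeded random assignment of protocols (plus duplicated controls) to wells.

    Returns a Series mapping well ID -> protocol name; unused wells are
    omitted.  More protocols than wells is an error.
    """
    entries = list(protocol_names) + [name for name in control_names for _ in range(control_duplicates)]
    if len(entries) > len(WELL_IDS):
        raise ValueError(f"{len(entries)} protocols exceed the 96 available wells")
    rng = np.random.default_rng(seed)
    wells = rng.permutation(WELL_IDS)[: len(entries)]
    return pd.Series(dict(zip(wells, entries)), name="protocol").sort_index()


def write_plate_program(
    path,
    profiles: dict[str, StimulusProfile],
    layout: pd.Series,
    refresh_interval: float = 10.0,
    max_intensity: float = 255.0,
) -> pd.DataFrame:
    """Encode well illumination programs as a CSV (rows = wells, columns =
    time steps at the refresh interval).

    Illumination is the complement of signaling: a well's LED is on
    (``max_intensity``) whenever its protocol's stimulus level is 0.
    """
    horizon = max(p.horizon for p in profiles.values())
    steps = np.arange(0.0, horizon, refresh_interval)
    rows = {}
    for well, name in layout.items():
        profile = profiles[name]
        level = profile.level(np.minimum(steps, profile.horizon - 1e-9))
        rows[well] = np.round((1.0 - level) * max_intensity, 6)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[f"t{int(s)}" for s in steps])
    table.index.name = "well"
    table.to_csv(path)
    return table


def read_plate_program(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="well")
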