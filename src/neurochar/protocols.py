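"""Stimulus protocol construction.

Current-clamp waveforms used to characterize neuron models (square, long
square, ramp, pink noise, short square, short square triple — the kinds in
the Allen Cell Types stimulus set) and the current series used by the
variable-timestep complexity benchmark.

Conventions: time in milliseconds, current in nanoamps, voltage in
millivolts.  All stimulus intervals are half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusWaveform",
    "ComplexityCurrentSeries",
    "build_protocol",
    "complexity_current_series",
    "PROTOCOL_KINDS",
]

PROTOCOL_KINDS = (
    "square",
    "long_square",
    "ramp",
    "pink_noise",
    "short_square",
    "short_square_triple",
)

#: Default width of brief ("short square") pulses, ms.
DEFAULT_SHORT_PULSE_MS = 3.0


class ProtocolError(ValueError):
    """Invalid protocol kind or parameters."""


@dataclass(frozen=True, eq=False)
class StimulusWaveform:
    """A fully sampled current-clamp stimulus.

    Attributes
    ----------
    kind : str
        One of :data:`PROTOCOL_KINDS`.
    onset_ms, duration_ms : float
        Stimulus window; the waveform is nonzero only on
        ``[onset, onset + duration)``.
    amplitude_na : float
        Pulse amplitude (nA).  For ramps this is the rheobase reference
        (the ramp reaches ``slope * rheobase`` nA after 1 s); for pink
        noise it is the target RMS amplitude.
    dt_ms : float
        Sampling interval.
    t, current : numpy.ndarray
        Sample times (ms) and current values (nA).
    """

    kind: str
    onset_ms: float
    duration_ms: float
    amplitude_na: float
    dt_ms: float
    total_ms: float
    t: np.ndarray = field(repr=False)
    current: np.ndarray = field(repr=False)
    slope_rheo_per_s: float | None = None
    rheobase_na: float | None = None
    pulse_frequency_hz: float | None = None
    pulse_width_ms: float | None = None
    seed: int | None = None

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms

    @property
    def n_samples(self) -> int:
        return self.t.size

    def to_table(self):
        """Two-column (time, current) array suitable for delimited export."""
        return np.column_stack([self.t, self.current])


def _time_grid(total_ms: float, dt_ms: float) -> np.ndarray:
    n = int(round(total_ms / dt_ms))
    return np.arange(n) * dt_ms


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f amplitude spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def build_protocol(
    kind: str,
    *,
    onset_ms: float = 1000.0,
    duration_ms: float | None = None,
    amplitude_na: float = 0.0,
    dt_ms: float = 0.025,
    total_ms: float | None = None,
    slope_rheo_per_s: float | None = None,
    rheobase_na: float | None = None,
    pulse_frequency_hz: float | None = None,
    pulse_width_ms: float = DEFAULT_SHORT_PULSE_MS,
    seed: int | None = None,
) -> StimulusWaveform:
    """Construct a sampled stimulus waveform of the requested kind.

    Parameters follow the conventions of the characterization protocol:
    the default square pulse is 1 s long after a 1 s delay.  Ramps rise at
    ``slope_rheo_per_s`` rheobase units per second, i.e. the current at
    time ``t`` ms after onset is ``slope * rheobase * t / 1000`` nA.
    Triple pulses are three ``pulse_width_ms`` pulses whose onsets are
    spaced ``1000 / pulse_frequency_hz`` ms apart.

    Raises
    ------
    ProtocolError
        For an unknown kind, a missing required parameter, or a
        non-positive duration/sampling interval.
    """
    if kind not in PROTOCOL_KINDS:
        raise ProtocolError(f"unknown protocol kind: {kind!r}")
    if dt_ms <= 0:
        raise ProtocolError("sampling interval must be positive")
    if onset_ms < 0:
        raise ProtocolError("onset must be non-negative")

    if duration_ms is None:
        duration_ms = {
            "square": 1000.0,
            "long_square": 2000.0,
            "ramp": 3000.0,
            "pink_noise": 3000.0,
            "short_square": pulse_width_ms,
            "short_square_triple": None,
        }[kind]

    if kind == "short_square_triple":
        if pulse_frequency_hz is None or pulse_frequency_hz <= 0:
            raise ProtocolError("short_square_triple requires a positive pulse_frequency_hz")
        spacing = 1000.0 / pulse_frequency_hz
        duration_ms = 2 * spacing + pulse_width_ms

    if duration_ms is None or duration_ms <= 0:
        raise ProtocolError("duration must be positive")

    if total_ms is None:
        total_ms = onset_ms + duration_ms + 1000.0
    t = _time_grid(total_ms, dt_ms)
    current = np.zeros_like(t)
    in_window = (t >= onset_ms) & (t < onset_ms + duration_ms)

    if kind in ("square", "long_square", "short_square"):
        current[in_window] = amplitude_na
    elif kind == "ramp":
        if slope_rheo_per_s is None or rheobase_na is None:
            raise ProtocolError("ramp requires slope_rheo_per_s and rheobase_na")
        current[in_window] = (
            slope_rheo_per_s * rheobase_na * (t[in_window] - onset_ms) / 1000.0
        )
    elif kind == "pink_noise":
        rng = np.random.default_rng(seed)
        current[in_window] = amplitude_na * _pink_noise(int(in_window.sum()), rng)
    elif kind == "short_square_triple":
        spacing = 1000.0 / pulse_frequency_hz
        for k in range(3):
            start = onset_ms + k * spacing
            pulse = (t >= start) & (t < start + pulse_width_ms)
            current[pulse] = amplitude_na

    return StimulusWaveform(
        kind=kind,
        onset_ms=onset_ms,
        duration_ms=float(duration_ms),
        amplitude_na=amplitude_na,
        dt_ms=dt_ms,
        total_ms=float(total_ms),
        t=t,
        current=current,
        slope_rheo_per_s=slope_rheo_per_s,
        rheobase_na=rheobase_na,
        pulse_frequency_hz=pulse_frequency_hz,
        pulse_width_ms=pulse_width_ms if kind.startswith("short_square") else None,
        seed=seed,
    )


@dataclass(frozen=True)
class ComplexityCurrentSeries:
    """The 13-current series of the variable-timestep complexity benchmark.

    Amplitudes are 0 nA, the largest known sub-rheobase current, and 11
    evenly spaced currents spanning ``[rheobase, 1.5 * rheobase]``
    inclusive, sorted ascending.
    """

    amplitudes: np.ndarray
    rheobase_na: float
    sub_rheobase_na: float

    def __len__(self) -> int:
        return self.amplitudes.size

    @property
    def supra_threshold(self) -> np.ndarray:
        """The 11 evenly spaced currents at and above rheobase."""
        return self.amplitudes[2:]


def complexity_current_series(
    rheobase_na: float, sub_rheobase_na: float = 0.0
) -> ComplexityCurrentSeries:
    """Build the benchmark current series for a model with known rheobase.

    Raises
    ------
    ValueError
        If rheobase is non-positive (the benchmark does not apply to
        intrinsically spiking models) or the sub-rheobase bracket is
        invalid.
    """
    if rheobase_na <= 0:
        raise ValueError(
            "non-positive rheobase: complexity protocol requires a positive "
            "rheobase current (intrinsically spiking model?)"
        )
    if not 0 <= sub_rheobase_na < rheobase_na:
        raise ValueError("sub-rheobase current must lie in [0, rheobase)")
    supra = np.linspace(rheobase_na, 1.5 * rheobase_na, 11)
    amplitudes = np.concatenate([[0.0, sub_rheobase_na], supra])
    return ComplexityCurrentSeries(
        amplitudes=amplitudes,
        rheobase_na=rheobase_na,
        sub_rheobase_na=sub_rheobase_na,
    )
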