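"""Membrane-potential trace container and delimited-text IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .protocols import StimulusWaveform

__all__ = ["VoltageTrace", "write_trace", "read_trace"]


@dataclass(frozen=True, eq=False)
class VoltageTrace:
    """A uniformly sampled membrane potential paired with its stimulus.

    Attributes
    ----------
    t : numpy.ndarray
        Sample times, ms.
    v : numpy.ndarray
        Membrane potential, mV.
    dt_ms : float
        Sampling interval, ms.
    stimulus : StimulusWaveform or None
        The current waveform that elicited the trace, when known.
    """

    t: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    dt_ms: float
    stimulus: StimulusWaveform | None = None

    def __post_init__(self):
        if self.t.size == 0:
            raise ValueError("empty trace")
        if self.t.size != self.v.size:
            raise ValueError("time and voltage arrays differ in length")

    @property
    def n_samples(self) -> int:
        return self.t.size


def write_trace(trace: VoltageTrace, path: str | Path) -> None:
    """Write a trace as two-column delimited text (time_ms, voltage_mv)."""
    data = np.column_stack([trace.t, trace.v])
    np.savetxt(path, data, delimiter="\t", header="time_ms\tvoltage_mv", comments="")


def read_trace(path: str | Path) -> VoltageTrace:
    """Read a two-column delimited trace written by :func:`write_trace`."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"not a two-column trace file: {path}")
    t, v = data[:, 0], data[:, 1]
    if t.size < 2:
        raise ValueError("trace must contain at least two samples")
    dt = float(t[1] - t[0])
    return VoltageTrace(t=t, v=v, dt_ms=dt)
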