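"""Electrophysiology feature extraction.

Computes the 42-property characterization of a neuron model from its
current-clamp responses: 38 Druckmann-style action-potential and
spike-train properties measured at 1.5x and 3.0x rheobase square
injections, plus four added properties (resting AP count, time to first
ramp spike, and the pass-above / pass-below inflection frequencies of a
bi-sigmoidal "hat" fit to triple-pulse AP counts).

Spike detection uses an upward voltage-threshold crossing (default 0 mV)
with a derivative-based fallback for abstract models whose resting
potential already sits at or above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocols import build_protocol
from .traces import VoltageTrace

__all__ = [
    "SpikeTrain",
    "detect_spikes",
    "RheobaseResult",
    "find_rheobase",
    "NoRheobaseError",
    "compute_features",
    "compute_feature_matrix",
    "fit_hat_curve",
    "FEATURE_NAMES",
    "DRUCKMANN_FEATURES",
    "ADDED_FEATURES",
    "TRAIN_PROPERTY_NAMES",
]

# -- canonical feature names -------------------------------------------------

#: The 19 per-response AP / spike-train properties, measured at each of the
#: two square stimulus strengths (1.5x and 3.0x rheobase) -> 38 properties.
TRAIN_PROPERTY_NAMES = (
    "delay_first_ap_ms",
    "delay_second_ap_ms",
    "ap1_amplitude_mv",
    "ap1_halfwidth_ms",
    "ap1_ahp_depth_mv",
    "ap2_amplitude_mv",
    "ap2_halfwidth_ms",
    "ap2_ahp_depth_mv",
    "ap_amplitude_change_pct",
    "ap_halfwidth_change_pct",
    "ap_ahp_change_pct",
    "ap_count",
    "mean_firing_rate_hz",
    "mean_isi_ms",
    "median_isi_ms",
    "isi_cv",
    "initial_accommodation_pct",
    "steady_state_accommodation_pct",
    "accommodation_rate_pct_per_isi",
)

DRUCKMANN_FEATURES = tuple(
    f"{name}_{mult}" for mult in ("15x", "30x") for name in TRAIN_PROPERTY_NAMES
)

ADDED_FEATURES = (
    "resting_ap_count",
    "time_to_first_ramp_spike_ms",
    "freq_filter_pass_above_hz",
    "freq_filter_pass_below_hz",
)

#: All 42 features, in canonical order.
FEATURE_NAMES = DRUCKMANN_FEATURES + ADDED_FEATURES

#: Triple-pulse frequencies (Hz) probed for the frequency-filter fit.
TRIPLE_FREQUENCIES_HZ = tuple(
    int(round(f)) for f in np.geomspace(29.0, 143.0, 8)
)


# -- spike detection ---------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times with the stimulus window they were evoked in."""

    spike_times: np.ndarray
    stimulus_onset_ms: float
    stimulus_offset_ms: float

    def __post_init__(self):
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


def detect_spikes(
    trace: VoltageTrace,
    threshold_mv: float = 0.0,
    dvdt_threshold_mv_per_ms: float = 20.0,
    refractory_ms: float = 1.0,
) -> SpikeTrain:
    """Detect action potentials in a uniformly sampled trace.

    One event is reported per upward crossing of ``threshold_mv``, with
    crossings closer than ``refractory_ms`` merged into one.  If the trace
    rests at or above the voltage threshold (abstract-model case) a
    derivative criterion (``dV/dt >= dvdt_threshold_mv_per_ms``) is used
    instead.
    """
    v = trace.v
    if v.size == 0:
        raise ValueError("empty trace")
    resting = float(np.median(v[: max(1, v.size // 20)]))
    if resting < threshold_mv:
        above = v >= threshold_mv
        onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        if above[0]:
            onsets = np.concatenate([[0], onsets])
    else:
        dvdt = np.diff(v) / trace.dt_ms
        above = dvdt >= dvdt_threshold_mv_per_ms
        onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        if above.size and above[0]:
            onsets = np.concatenate([[0], onsets])
    times = trace.t[onsets]
    if times.size:
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= refractory_ms:
                keep.append(i)
        times = times[keep]
    stim = trace.stimulus
    onset = stim.onset_ms if stim is not None else float(trace.t[0])
    offset = stim.offset_ms if stim is not None else float(trace.t[-1])
    return SpikeTrain(
        spike_times=times, stimulus_onset_ms=onset, stimulus_offset_ms=offset
    )


# -- rheobase ----------------------------------------------------------------


class NoRheobaseError(RuntimeError):
    """The model never spiked up to the configured maximum current."""


@dataclass(frozen=True)
class RheobaseResult:
    """Outcome of the rheobase search.

    ``non_positive`` marks intrinsically spiking models (spikes at 0 nA);
    for those ``rheobase_na`` is set to 0 and has no further meaning.
    ``sub_rheobase_na`` is the largest current probed that did not elicit
    a spike (the lower bisection bracket at termination).
    """

    rheobase_na: float
    sub_rheobase_na: float
    non_positive: bool = False


def _square_response(model, amplitude_na, dt_ms=0.025):
    stim = build_protocol(
        "square", onset_ms=1000.0, duration_ms=1000.0,
        amplitude_na=amplitude_na, dt_ms=dt_ms, total_ms=2200.0,
    )
    return model.response(stim)


def _spikes_at(model, amplitude_na, detect_kwargs, dt_ms=0.025) -> int:
    trace = _square_response(model, amplitude_na, dt_ms)
    return detect_spikes(trace, **detect_kwargs).n_spikes


def find_rheobase(
    model,
    max_current_na: float = 10.0,
    rel_tol: float = 0.01,
    max_iter: int = 30,
    start_current_na: float = 0.05,
    dt_ms: float = 0.025,
    **detect_kwargs,
) -> RheobaseResult:
    """Bracketed bisection for the smallest square current that elicits a
    spike during a 1 s injection after a 1 s delay.

    The model must expose ``response(stimulus) -> VoltageTrace``.

    Raises
    ------
    NoRheobaseError
        If no current up to ``max_current_na`` elicits a spike.
    """
    if _spikes_at(model, 0.0, detect_kwargs, dt_ms) > 0:
        return RheobaseResult(0.0, 0.0, non_positive=True)
    lo, hi = 0.0, start_current_na
    while _spikes_at(model, hi, detect_kwargs, dt_ms) == 0:
        lo = hi
        hi *= 2.0
        if hi > max_current_na:
            raise NoRheobaseError(
                f"no rheobase <= max current ({max_current_na} nA)"
            )
    for _ in range(max_iter):
        if (hi - lo) / hi <= rel_tol:
            break
        mid = 0.5 * (lo + hi)
        if _spikes_at(model, mid, detect_kwargs, dt_ms) > 0:
            hi = mid
        else:
            lo = mid
    return RheobaseResult(rheobase_na=hi, sub_rheobase_na=lo)


# -- per-response spike-train properties ------------------------------------


def _ap_shape(trace: VoltageTrace, t_spike: float, t_next: float | None, resting: float):
    """Amplitude, half-width and AHP depth of one AP from the raw trace."""
    dt = trace.dt_ms
    i0 = int(np.searchsorted(trace.t, t_spike - 0.5 * dt))
    i1 = int(np.searchsorted(trace.t, t_next - 0.5 * dt)) if t_next is not None else min(
        trace.v.size, i0 + int(20.0 / dt)
    )
    window = trace.v[i0:i1]
    if window.size == 0:
        return np.nan, np.nan, np.nan
    peak = float(window.max())
    amplitude = peak - resting
    half_level = resting + 0.5 * amplitude
    halfwidth = float(np.count_nonzero(window >= half_level) * dt)
    ahp = resting - float(window.min())
    return amplitude, halfwidth, max(ahp, 0.0)


def _pct_change(a: float, b: float) -> float:
    return 100.0 * (b - a) / abs(a) if np.isfinite(a) and a != 0 else np.nan


def spike_train_properties(trace: VoltageTrace, spikes: SpikeTrain) -> dict[str, float]:
    """The 19 per-response properties; uncomputable entries are NaN."""
    out = {name: np.nan for name in TRAIN_PROPERTY_NAMES}
    st = spikes.spike_times
    onset, offset = spikes.stimulus_onset_ms, spikes.stimulus_offset_ms
    resting = float(np.median(trace.v[: max(1, trace.v.size // 20)]))
    out["ap_count"] = float(st.size)
    if st.size == 0:
        return out
    out["delay_first_ap_ms"] = float(st[0] - onset)
    a1, w1, ahp1 = _ap_shape(trace, st[0], st[1] if st.size > 1 else None, resting)
    out["ap1_amplitude_mv"] = a1
    out["ap1_halfwidth_ms"] = w1
    out["ap1_ahp_depth_mv"] = ahp1
    duration_s = (offset - onset) / 1000.0
    if duration_s > 0:
        out["mean_firing_rate_hz"] = st.size / duration_s
    if st.size < 2:
        return out
    out["delay_second_ap_ms"] = float(st[1] - onset)
    a2, w2, ahp2 = _ap_shape(trace, st[1], st[2] if st.size > 2 else None, resting)
    out["ap2_amplitude_mv"] = a2
    out["ap2_halfwidth_ms"] = w2
    out["ap2_ahp_depth_mv"] = ahp2
    out["ap_amplitude_change_pct"] = _pct_change(a1, a2)
    out["ap_halfwidth_change_pct"] = _pct_change(w1, w2)
    out["ap_ahp_change_pct"] = _pct_change(ahp1, ahp2)
    isis = np.diff(st)
    out["mean_isi_ms"] = float(np.mean(isis))
    out["median_isi_ms"] = float(np.median(isis))
    if np.mean(isis) > 0:
        out["isi_cv"] = float(np.std(isis) / np.mean(isis))
    first = isis[0]
    if first > 0:
        if isis.size >= 2:
            out["initial_accommodation_pct"] = 100.0 * (isis[1] - first) / first
        # steady state: ISIs that start within the last quarter of the stimulus
        late_start = offset - 0.25 * (offset - onset)
        late = isis[st[:-1] >= late_start]
        if late.size == 0:
            late = isis[-1:]
        out["steady_state_accommodation_pct"] = float(
            100.0 * (np.mean(late) - first) / first
        )
    if isis.size >= 2 and np.all(isis > 0):
        # per-ISI multiplicative drift from a log-linear fit
        slope = np.polyfit(np.arange(isis.size), np.log(isis), 1)[0]
        out["accommodation_rate_pct_per_isi"] = float(100.0 * (np.exp(slope) - 1.0))
    return out


# -- frequency-filter ("hat") fit -------------------------------------------


def _hat(f, base, amp, f_lo, f_hi, s_lo, s_hi):
    return base + amp / (1 + np.exp(-(f - f_lo) / s_lo)) / (1 + np.exp((f - f_hi) / s_hi))


def fit_hat_curve(
    freqs_hz: np.ndarray, ap_counts: np.ndarray
) -> tuple[float, float]:
    """Fit a bi-sigmoidal "hat" to AP counts vs triple-pulse frequency.

    Returns the two inflection frequencies ``(pass_above_hz,
    pass_below_hz)``: the response rises above its floor past the first and
    falls off past the second.  Returns NaNs when the profile carries no
    band structure (flat counts) or the fit fails.
    """
    freqs = np.asarray(freqs_hz, float)
    counts = np.asarray(ap_counts, float)
    if freqs.size < 4 or np.ptp(counts) == 0:
        return np.nan, np.nan
    base0 = float(counts.min())
    amp0 = float(np.ptp(counts))
    in_band = freqs[counts > base0 + 0.5 * amp0]
    if in_band.size == 0:
        return np.nan, np.nan
    p0 = [base0, amp0, in_band.min(), in_band.max(), 2.0, 2.0]
    lo = [0.0, 0.0, freqs.min() / 2, freqs.min() / 2, 0.1, 0.1]
    hi = [counts.max(), 2 * amp0, freqs.max() * 2, freqs.max() * 2, 50.0, 50.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _hat, freqs, counts, p0=p0, bounds=(lo, hi), maxfev=20000
            )
    except (RuntimeError, ValueError):
        return np.nan, np.nan
    _, _, f_lo, f_hi, _, _ = popt
    if f_hi < f_lo:
        f_lo, f_hi = f_hi, f_lo
    return float(f_lo), float(f_hi)


# -- the 42-feature vector ---------------------------------------------------


def compute_features(
    model,
    dt_ms: float = 0.025,
    triple_frequencies_hz: tuple = TRIPLE_FREQUENCIES_HZ,
    max_current_na: float = 10.0,
    **detect_kwargs,
) -> pd.Series:
    """Compute the 42-feature characterization of one stimulable model.

    The model must expose ``response(stimulus) -> VoltageTrace``.
    Properties that cannot be computed (too few spikes, non-positive
    rheobase, failed fits) are NaN — flagged missing, never silently zero.
    """
    feats = pd.Series(np.nan, index=list(FEATURE_NAMES), dtype=float)

    # resting behavior (no stimulation)
    rest_stim = build_protocol(
        "square", onset_ms=0.0, duration_ms=1000.0, amplitude_na=0.0,
        dt_ms=dt_ms, total_ms=1000.0,
    )
    rest_trace = model.response(rest_stim)
    rest_spikes = detect_spikes(rest_trace, **detect_kwargs)
    feats["resting_ap_count"] = float(rest_spikes.n_spikes)

    try:
        rheo = find_rheobase(
            model, max_current_na=max_current_na, dt_ms=dt_ms, **detect_kwargs
        )
    except NoRheobaseError:
        return feats
    if rheo.non_positive:
        return feats

    for mult, tag in ((1.5, "15x"), (3.0, "30x")):
        stim = build_protocol(
            "square", onset_ms=1000.0, duration_ms=1000.0,
            amplitude_na=mult * rheo.rheobase_na, dt_ms=dt_ms, total_ms=2500.0,
        )
        trace = model.response(stim)
        spikes = detect_spikes(trace, **detect_kwargs)
        for name, value in spike_train_properties(trace, spikes).items():
            feats[f"{name}_{tag}"] = value

    # ramp at 1 rheobase per second
    ramp = build_protocol(
        "ramp", onset_ms=0.0, duration_ms=3000.0, dt_ms=dt_ms,
        slope_rheo_per_s=1.0, rheobase_na=rheo.rheobase_na, total_ms=3000.0,
    )
    ramp_spikes = detect_spikes(model.response(ramp), **detect_kwargs)
    if ramp_spikes.n_spikes > 0:
        feats["time_to_first_ramp_spike_ms"] = float(
            ramp_spikes.spike_times[0] - ramp.onset_ms
        )

    # frequency filtering from triple-pulse responses
    counts = []
    for f in triple_frequencies_hz:
        stim = build_protocol(
            "short_square_triple", onset_ms=100.0, amplitude_na=1.5 * rheo.rheobase_na,
            dt_ms=dt_ms, pulse_frequency_hz=float(f),
        )
        counts.append(detect_spikes(model.response(stim), **detect_kwargs).n_spikes)
    f_lo, f_hi = fit_hat_curve(np.asarray(triple_frequencies_hz), np.asarray(counts))
    feats["freq_filter_pass_above_hz"] = f_lo
    feats["freq_filter_pass_below_hz"] = f_hi
    return feats


def compute_feature_matrix(models: dict, **kwargs) -> pd.DataFrame:
    """Feature vectors for a collection of models, one row per model id."""
    rows = {mid: compute_features(m, **kwargs) for mid, m in models.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
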