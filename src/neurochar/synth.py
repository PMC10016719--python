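"""Synthetic data generation with known ground truth.

Everything the characterization pipeline would normally obtain from a
model database is emulated here: spiking voltage responses with planted
rheobase/latency/ISI structure, "baseline + per-AP" integration-step-count
tables, ion-channel voltage-clamp responses with family-specific first-order
kinetics, NeuroML-subset conductance-density documents, and planted Gaussian
feature matrices for the clustering stages.

Spike generation is phenomenological: stylized action-potential waveforms
are inserted into a passive trace at analytically computed times, so the
planted parameters are recoverable exactly.  Seeds are explicit everywhere;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree
from scipy.signal import lfilter

from .protocols import ComplexityCurrentSeries, StimulusWaveform
from .traces import VoltageTrace

__all__ = [
    "SyntheticNeuronSpec",
    "SyntheticNeuron",
    "generate_voltage_response",
    "StepCountSpec",
    "generate_step_count_table",
    "ChannelFamilySpec",
    "CHANNEL_FAMILIES",
    "VoltageClampProtocol",
    "default_clamp_protocols",
    "generate_channel_response_set",
    "generate_channel_family_specs",
    "generate_cell_conductance_files",
    "generate_planted_feature_matrix",
    "generate_planted_hierarchy",
]


# ---------------------------------------------------------------------------
# Synthetic neurons
# ---------------------------------------------------------------------------

#: Stimulus strength at which the planted delay/ISI hold exactly, as a
#: multiple of rheobase (the reference stimulus of the characterization).
REFERENCE_RHEOBASE_MULTIPLE = 1.5


@dataclass(frozen=True)
class SyntheticNeuronSpec:
    """Ground-truth parameters of a phenomenological spiking neuron.

    At a square stimulus of ``REFERENCE_RHEOBASE_MULTIPLE * rheobase`` the
    first spike occurs ``delay_ms`` after onset and inter-spike intervals
    follow ``isi_base_ms * accommodation_rate**k``.  At other
    supra-threshold amplitudes both delay and ISI scale inversely with the
    stimulus strength (a monotone rule: stronger drive, earlier and faster
    spiking).
    """

    rheobase_na: float = 0.5
    delay_ms: float = 50.0
    isi_base_ms: float = 20.0
    accommodation_rate: float = 1.0
    ap_amplitude_mv: float = 100.0
    ap_width_ms: float = 1.0
    ahp_depth_mv: float = 8.0
    resting_mv: float = -70.0
    intrinsic_spiking: bool = False
    noise_sd_mv: float = 0.0
    freq_pass_lo_hz: float = 0.0
    freq_pass_hi_hz: float = float("inf")
    seed: int = 0

    def __post_init__(self):
        if self.isi_base_ms <= 0:
            raise ValueError("isi_base_ms must be positive")
        if self.ap_width_ms <= 0:
            raise ValueError("ap_width_ms must be positive")


#: Passive depolarization per injected nA (input-resistance proxy), mV/nA.
PASSIVE_MV_PER_NA = 10.0
#: Membrane time constant of the passive response filter, ms.
PASSIVE_TAU_MS = 10.0
#: Latency from a brief supra-threshold pulse to its spike, ms.
SHORT_PULSE_LATENCY_MS = 1.0


class SyntheticNeuron:
    """A stimulable response source wrapping a :class:`SyntheticNeuronSpec`.

    Implements the protocol expected by the feature-extraction and
    complexity stages: ``response(stimulus) -> VoltageTrace`` plus
    ``spike_times(stimulus)`` exposing the planted ground truth.
    """

    def __init__(self, spec: SyntheticNeuronSpec):
        self.spec = spec

    # -- ground-truth spike schedule ------------------------------------
    def _isi_train(self, start_ms: float, end_ms: float, isi0_ms: float) -> list[float]:
        times, t, isi, k = [], start_ms, isi0_ms, 0
        r = self.spec.accommodation_rate
        while t < end_ms and len(times) < 10000:
            times.append(t)
            isi = isi0_ms * r**k
            t += isi
            k += 1
        return times

    def spike_times(self, stim: StimulusWaveform) -> np.ndarray:
        """Planted spike times (ms) for the given stimulus."""
        s = self.spec
        out: list[float] = []
        if s.intrinsic_spiking:
            out = self._isi_train(s.delay_ms, stim.total_ms, s.isi_base_ms)
            return np.asarray(out)
        if s.rheobase_na <= 0:
            return np.asarray(out)

        amp = stim.amplitude_na
        if stim.kind in ("square", "long_square"):
            if amp >= s.rheobase_na * (1 - 1e-12):
                strength = amp / (REFERENCE_RHEOBASE_MULTIPLE * s.rheobase_na)
                delay = s.delay_ms / strength
                isi0 = s.isi_base_ms / strength
                out = self._isi_train(stim.onset_ms + delay, stim.offset_ms, isi0)
        elif stim.kind == "short_square":
            if amp >= s.rheobase_na:
                out = [stim.onset_ms + SHORT_PULSE_LATENCY_MS]
        elif stim.kind == "short_square_triple":
            if amp >= s.rheobase_na:
                f = stim.pulse_frequency_hz
                spacing = 1000.0 / f
                out = [stim.onset_ms + SHORT_PULSE_LATENCY_MS]
                if s.freq_pass_lo_hz <= f <= s.freq_pass_hi_hz:
                    out += [
                        stim.onset_ms + k * spacing + SHORT_PULSE_LATENCY_MS
                        for k in (1, 2)
                    ]
        elif stim.kind == "ramp":
            slope = stim.slope_rheo_per_s or 0.0
            rheo_ref = stim.rheobase_na if stim.rheobase_na is not None else s.rheobase_na
            if slope > 0 and rheo_ref > 0:
                # first spike when the ramp current reaches rheobase
                t_first = stim.onset_ms + 1000.0 * s.rheobase_na / (slope * rheo_ref)
                if t_first < stim.offset_ms:
                    out = self._isi_train(t_first, stim.offset_ms, s.isi_base_ms)
        elif stim.kind == "pink_noise":
            refractory = max(s.isi_base_ms, 6 * s.ap_width_ms)
            above = stim.current >= s.rheobase_na
            last = -np.inf
            for i in np.flatnonzero(above[1:] & ~above[:-1]):
                t = stim.t[i + 1]
                if t - last >= refractory:
                    out.append(t)
                    last = t
        return np.asarray(out)

    # -- trace rendering -------------------------------------------------
    def _ap_template(self, dt_ms: float) -> np.ndarray:
        """Stylized AP, relative to rest: instantaneous rise to the peak,
        linear decay over two half-widths, then an after-hyperpolarization."""
        s = self.spec
        w = s.ap_width_ms
        knots_t = np.array([0.0, 2 * w, 3 * w, 5 * w])
        knots_v = np.array([s.ap_amplitude_mv, 0.0, -s.ahp_depth_mv, 0.0])
        tt = np.arange(0.0, knots_t[-1] + dt_ms, dt_ms)
        return np.interp(tt, knots_t, knots_v)

    def response(self, stim: StimulusWaveform) -> VoltageTrace:
        """Render the voltage response to a sampled stimulus."""
        if stim.t.size == 0:
            raise ValueError("unsampled stimulus")
        s = self.spec
        dt = stim.dt_ms
        rng = np.random.default_rng(s.seed)

        # passive response: first-order low-pass of the injected current
        alpha = dt / (PASSIVE_TAU_MS + dt)
        drive = PASSIVE_MV_PER_NA * stim.current
        passive = lfilter([alpha], [1.0, -(1.0 - alpha)], drive)
        # keep sub-threshold: never let the passive deflection reach 0 mV
        if s.resting_mv < 0:
            passive = np.minimum(passive, -0.5 * s.resting_mv)

        v = s.resting_mv + passive
        if s.noise_sd_mv > 0:
            v = v + rng.normal(0.0, s.noise_sd_mv, size=v.size)

        tpl = self._ap_template(dt)
        n = v.size
        for t_spike in self.spike_times(stim):
            i0 = int(round(t_spike / dt))
            if i0 >= n:
                continue
            i1 = min(n, i0 + tpl.size)
            v[i0:i1] = s.resting_mv + tpl[: i1 - i0]
        return VoltageTrace(t=stim.t.copy(), v=v, dt_ms=dt, stimulus=stim)


def generate_voltage_response(
    spec: SyntheticNeuronSpec, stimulus: StimulusWaveform
) -> VoltageTrace:
    """Convenience wrapper: render one response from a spec."""
    return SyntheticNeuron(spec).response(stimulus)


# ---------------------------------------------------------------------------
# Step-count tables (variable-timestep benchmark input)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepCountSpec:
    """Ground truth for the linear steps-vs-APs model.

    ``steps = steps_base_true + steps_ap_true * APs``; with
    ``counting_noise="poisson"`` that value is the Poisson mean of the
    reported count.
    """

    steps_base_true: float = 1000.0
    steps_ap_true: float = 200.0
    counting_noise: str = "none"  # {"none", "poisson"}
    seed: int = 0

    def __post_init__(self):
        if self.steps_base_true <= 0:
            raise ValueError("steps_base_true must be positive")
        if self.steps_ap_true < 0:
            raise ValueError("steps_ap_true must be non-negative")
        if self.counting_noise not in ("none", "poisson"):
            raise ValueError(f"unknown counting_noise: {self.counting_noise!r}")


def generate_step_count_table(
    spec: StepCountSpec,
    series: ComplexityCurrentSeries,
    ap_counts: list[int] | np.ndarray,
) -> pd.DataFrame:
    """Simulated (current, AP count, total steps) benchmark table.

    One row per amplitude of the complexity current series; ``ap_counts``
    must give the number of action potentials elicited at each amplitude.
    """
    ap_counts = np.asarray(ap_counts)
    if ap_counts.size != len(series):
        raise ValueError(
            f"ap_counts length {ap_counts.size} != series length {len(series)}"
        )
    mean = spec.steps_base_true + spec.steps_ap_true * ap_counts
    if spec.counting_noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        steps = rng.poisson(mean)
    else:
        steps = np.round(mean).astype(int)
    return pd.DataFrame(
        {
            "current_na": series.amplitudes,
            "ap_count": ap_counts.astype(int),
            "total_steps": steps,
        }
    )


# ---------------------------------------------------------------------------
# Channel voltage-clamp responses
# ---------------------------------------------------------------------------

CHANNEL_FAMILIES = ("Kv", "Nav", "Cav", "KCa", "Ih")

CLAMP_PROTOCOL_KINDS = ("activation", "deactivation", "inactivation")


@dataclass(frozen=True)
class ChannelFamilySpec:
    """First-order gating kinetics of one synthetic channel model.

    Conductance follows ``g = m * h`` with sigmoidal steady states and
    voltage-independent time constants; ``h`` is present only when the
    inactivation fields are set.  ``activation_slope_mv`` may be negative
    (hyperpolarization-activated families such as Ih).
    """

    family: str
    activation_v_half: float
    activation_tau_ms: float
    activation_slope_mv: float = 5.0
    inactivation_v_half: float | None = None
    inactivation_tau_ms: float | None = None
    inactivation_slope_mv: float = 5.0
    reversal_mv: float = -85.0
    model_id: str = ""

    def __post_init__(self):
        if self.family not in CHANNEL_FAMILIES:
            raise ValueError(f"unknown channel family: {self.family!r}")
        if self.activation_tau_ms <= 0:
            raise ValueError("activation_tau_ms must be positive")
        if self.inactivation_tau_ms is not None and self.inactivation_tau_ms <= 0:
            raise ValueError("inactivation_tau_ms must be positive")

    @property
    def has_inactivation(self) -> bool:
        return self.inactivation_v_half is not None


@dataclass(frozen=True)
class VoltageClampProtocol:
    """A family of piecewise-constant voltage-clamp sweeps.

    ``segments`` is a list of (duration_ms, voltage) pairs where a voltage
    of ``None`` marks the segment stepped across ``step_voltages``.
    """

    kind: str
    step_voltages: tuple[float, ...]
    segments: tuple[tuple[float, float | None], ...]
    dt_ms: float = 0.2


def default_clamp_protocols() -> dict[str, VoltageClampProtocol]:
    """Activation / deactivation / inactivation protocols in the style of
    the uniform channel-comparison stimulus set."""
    return {
        "activation": VoltageClampProtocol(
            kind="activation",
            step_voltages=tuple(np.arange(-80.0, 51.0, 10.0)),
            segments=((20.0, -80.0), (100.0, None), (40.0, -80.0)),
        ),
        "deactivation": VoltageClampProtocol(
            kind="deactivation",
            step_voltages=tuple(np.arange(-120.0, 1.0, 10.0)),
            segments=((20.0, -80.0), (20.0, 40.0), (100.0, None)),
        ),
        "inactivation": VoltageClampProtocol(
            kind="inactivation",
            step_voltages=tuple(np.arange(-100.0, 21.0, 10.0)),
            segments=((20.0, -80.0), (100.0, None), (50.0, 40.0)),
        ),
    }


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _gate_series(
    t: np.ndarray, v: np.ndarray, v_half: float, slope: float, tau: float, x0: float
) -> np.ndarray:
    """Exact first-order gating solution for a piecewise-constant voltage."""
    x = np.empty_like(t)
    seg_start = 0
    cur = x0
    for i in range(1, t.size + 1):
        if i == t.size or v[i] != v[seg_start]:
            vv = v[seg_start]
            x_inf = _sigmoid((vv - v_half) / slope)
            tt = t[seg_start:i] - t[seg_start]
            x[seg_start:i] = x_inf + (cur - x_inf) * np.exp(-tt / tau)
            if i < t.size:
                # carry the gate value across the segment boundary
                cur = x_inf + (cur - x_inf) * np.exp(-(t[i] - t[seg_start]) / tau)
                seg_start = i
    return x


def _sweep_voltage(proto: VoltageClampProtocol, step_v: float) -> tuple[np.ndarray, np.ndarray]:
    total = sum(d for d, _ in proto.segments)
    t = np.arange(0.0, total, proto.dt_ms)
    v = np.empty_like(t)
    t0 = 0.0
    for dur, vv in proto.segments:
        seg = (t >= t0) & (t < t0 + dur)
        v[seg] = step_v if vv is None else vv
        t0 += dur
    return t, v


@dataclass(frozen=True, eq=False)
class ChannelResponseSet:
    """All voltage-clamp sweeps of one channel model, keyed by protocol."""

    model_id: str
    family: str
    sweeps: dict = field(repr=False)
    # sweeps: {protocol_kind: [ {voltage, t, v, conductance, current}, ... ]}


def simulate_channel_response(
    spec: ChannelFamilySpec, protocols: dict[str, VoltageClampProtocol]
) -> ChannelResponseSet:
    """Closed-form gating simulation of one channel under all protocols."""
    missing = [k for k in CLAMP_PROTOCOL_KINDS if k not in protocols]
    if missing:
        raise ValueError(f"missing protocol kind(s): {missing}")
    sweeps: dict[str, list[dict]] = {}
    for kind, proto in protocols.items():
        rows = []
        for step_v in proto.step_voltages:
            t, v = _sweep_voltage(proto, step_v)
            hold = v[0]
            m0 = float(_sigmoid((hold - spec.activation_v_half) / spec.activation_slope_mv))
            m = _gate_series(
                t, v, spec.activation_v_half, spec.activation_slope_mv,
                spec.activation_tau_ms, m0,
            )
            if spec.has_inactivation:
                h0 = float(
                    _sigmoid(-(hold - spec.inactivation_v_half) / spec.inactivation_slope_mv)
                )
                h = _gate_series(
                    t, v, spec.inactivation_v_half, -spec.inactivation_slope_mv,
                    spec.inactivation_tau_ms, h0,
                )
            else:
                h = np.ones_like(m)
            g = m * h
            i = g * (v - spec.reversal_mv)
            rows.append(
                {"voltage": float(step_v), "t": t, "v": v, "conductance": g, "current": i}
            )
        sweeps[kind] = rows
    return ChannelResponseSet(model_id=spec.model_id, family=spec.family, sweeps=sweeps)


def generate_channel_response_set(
    specs: list[ChannelFamilySpec],
    protocols: dict[str, VoltageClampProtocol] | None = None,
) -> list[ChannelResponseSet]:
    """Simulate all channel specs under the shared clamp protocols."""
    if protocols is None:
        protocols = default_clamp_protocols()
    return [simulate_channel_response(s, protocols) for s in specs]


_FAMILY_PRESETS: dict[str, ChannelFamilySpec] = {
    "Kv": ChannelFamilySpec("Kv", -20.0, 5.0, 5.0, None, None, 5.0, -85.0),
    "Nav": ChannelFamilySpec("Nav", -35.0, 0.5, 5.0, -60.0, 2.0, 5.0, 50.0),
    "Cav": ChannelFamilySpec("Cav", -25.0, 2.0, 5.0, -45.0, 40.0, 5.0, 120.0),
    "KCa": ChannelFamilySpec("KCa", -10.0, 20.0, 5.0, None, None, 5.0, -85.0),
    "Ih": ChannelFamilySpec("Ih", -80.0, 50.0, -8.0, None, None, 5.0, -30.0),
}


def generate_channel_family_specs(
    family: str,
    n: int,
    seed: int = 0,
    v_half_jitter_mv: float = 2.0,
    tau_jitter_frac: float = 0.1,
    base: ChannelFamilySpec | None = None,
) -> list[ChannelFamilySpec]:
    """Jittered channel specs around a family preset (or a given archetype)."""
    if base is None:
        base = _FAMILY_PRESETS[family]
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n):
        tau_a = base.activation_tau_ms * float(
            np.exp(rng.normal(0, tau_jitter_frac))
        )
        kwargs = dict(
            activation_v_half=base.activation_v_half + float(rng.normal(0, v_half_jitter_mv)),
            activation_tau_ms=tau_a,
            model_id=f"{family.lower()}_{seed}_{k}",
        )
        if base.has_inactivation:
            kwargs["inactivation_v_half"] = base.inactivation_v_half + float(
                rng.normal(0, v_half_jitter_mv)
            )
            kwargs["inactivation_tau_ms"] = base.inactivation_tau_ms * float(
                np.exp(rng.normal(0, tau_jitter_frac))
            )
        specs.append(replace(base, **kwargs))
    return specs


def generate_channel_archetype_set(
    family: str,
    seed: int = 0,
    sizes: tuple[int, ...] = (15, 9, 6),
    v_half_jitter_mv: float = 0.5,
    tau_jitter_frac: float = 0.03,
) -> tuple[list[ChannelFamilySpec], np.ndarray]:
    """Jittered channel specs drawn from distinct kinetic archetypes of one
    family, with unequal archetype sizes (as in real model populations,
    where a few sub-types dominate and others are rare).

    The archetypes differ in gating structure — the family preset, a
    fast-activating steeply gated variant with rapid inactivation, and a
    slow shallow-slope variant with slow inactivation.  Returns the specs
    and the true archetype labels.
    """
    base = _FAMILY_PRESETS[family]
    fast = replace(
        base,
        activation_v_half=base.activation_v_half - 25.0,
        activation_tau_ms=max(base.activation_tau_ms * 0.2, 0.2),
        activation_slope_mv=np.sign(base.activation_slope_mv) * 3.0,
        inactivation_v_half=base.activation_v_half - 50.0,
        inactivation_tau_ms=5.0,
    )
    slow = replace(
        base,
        activation_v_half=base.activation_v_half + 10.0,
        activation_tau_ms=base.activation_tau_ms * 5.0,
        activation_slope_mv=np.sign(base.activation_slope_mv) * 15.0,
        inactivation_v_half=base.activation_v_half - 20.0,
        inactivation_tau_ms=80.0,
    )
    archetypes = (base, fast, slow)
    specs: list[ChannelFamilySpec] = []
    labels: list[int] = []
    for i, (arch, n) in enumerate(zip(archetypes, sizes)):
        specs.extend(
            generate_channel_family_specs(
                family, n, seed=seed * 1000 + i, base=arch,
                v_half_jitter_mv=v_half_jitter_mv,
                tau_jitter_frac=tau_jitter_frac,
            )
        )
        labels.extend([i] * n)
    return specs, np.asarray(labels)


# ---------------------------------------------------------------------------
# NeuroML-subset conductance-density documents
# ---------------------------------------------------------------------------

NEUROML_NS = "http://www.neuroml.org/schema/neuroml2"


def generate_cell_conductance_files(
    cells: int,
    channel_ids: list[str],
    density_law: dict | None = None,
    seed: int = 0,
) -> dict[str, bytes]:
    """NeuroML-subset XML documents with somatic (and optionally dendritic)
    channel-density elements.

    ``density_law`` keys (all optional): ``median_mS_per_cm2`` (log-normal
    median, default 5.0), ``sigma`` (log-sd, default 1.0),
    ``presence_prob`` (probability a channel appears in a cell at all,
    default 0.8), ``dendritic_prob`` (probability of an additional
    dendritic entry, default 0.3).  Channels that are absent are genuinely
    absent from the document.  Output is deterministic for a fixed seed.
    """
    law = {
        "median_mS_per_cm2": 5.0,
        "sigma": 1.0,
        "presence_prob": 0.8,
        "dendritic_prob": 0.3,
    }
    law.update(density_law or {})
    if law["median_mS_per_cm2"] < 0 or law["sigma"] < 0:
        raise ValueError("density parameters must be non-negative")
    rng = np.random.default_rng(seed)
    docs: dict[str, bytes] = {}
    for c in range(cells):
        cell_id = f"cell_{c:04d}"
        root = etree.Element("neuroml", nsmap={None: NEUROML_NS}, id=f"doc_{cell_id}")
        cell = etree.SubElement(root, "cell", id=cell_id)
        biophys = etree.SubElement(cell, "biophysicalProperties", id="biophys")
        membrane = etree.SubElement(biophys, "membraneProperties")
        for ch in channel_ids:
            if rng.random() > law["presence_prob"]:
                continue
            dens_ms_cm2 = law["median_mS_per_cm2"] * float(
                np.exp(rng.normal(0, law["sigma"]))
            )
            # alternate units to exercise the parser's conversions
            if rng.random() < 0.5:
                value, units = dens_ms_cm2 / 1000.0, "S_per_cm2"
            else:
                value, units = dens_ms_cm2, "mS_per_cm2"
            etree.SubElement(
                membrane,
                "channelDensity",
                id=f"{ch}_soma",
                ionChannel=ch,
                condDensity=f"{value:.9g} {units}",
                segmentGroup="soma_group",
            )
            if rng.random() < law["dendritic_prob"]:
                dval = dens_ms_cm2 * float(rng.uniform(0.05, 0.5))
                etree.SubElement(
                    membrane,
                    "channelDensity",
                    id=f"{ch}_dend",
                    ionChannel=ch,
                    condDensity=f"{dval:.9g} mS_per_cm2",
                    segmentGroup="dendrite_group",
                )
        docs[cell_id] = etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    return docs


# ---------------------------------------------------------------------------
# Planted feature matrices for the clustering stages
# ---------------------------------------------------------------------------


def generate_planted_feature_matrix(
    k: int,
    n_per_cluster: int,
    separation: float,
    seed: int = 0,
    n_features: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs with pairwise center distance ``separation`` (in
    within-cluster standard deviations; within-cluster sd is 1).

    Returns the (n, n_features) matrix and integer labels.
    """
    if k < 1 or n_per_cluster < 1:
        raise ValueError("k and n_per_cluster must be >= 1")
    if n_features < k:
        n_features = k
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, n_features))
    for i in range(k):
        centers[i, i] = separation / np.sqrt(2.0)
    labels = np.repeat(np.arange(k), n_per_cluster)
    x = centers[labels] + rng.standard_normal((labels.size, n_features))
    return x, labels


def _hexagon(radius: float) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def generate_planted_hierarchy(
    separation: float = 8.0,
    n_leaf: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A three-level 4 -> 2 -> 6 planted cluster hierarchy.

    Each level lives in its own feature block at a scale roughly an order
    of magnitude below the previous one, and the branch that is recursed
    into is tight in the dimensions of its parent level.  This mirrors how
    nested structure hides from a variance-thresholded PCA at the parent
    level and is revealed when the PCA is refit within the subset.
    ``separation`` is the center spacing in units of the within-cluster sd
    at each level.

    Returns the (n, 12) matrix and a DataFrame with columns
    ``level1``/``level2``/``level3`` (-1 where a level does not apply).
    """
    rng = np.random.default_rng(seed)
    # per-level within-cluster sds: level scales
    s1, s2, s3 = 1.0, 0.2, 0.012
    tight1, tight2 = 0.002, 0.01
    n3 = 6 * n_leaf                  # level-3 parent (level-2 cluster 0)
    n2b = 2 * n_leaf                 # level-2 cluster 1
    n_parent = n3 + n2b              # level-1 cluster 0 (largest)
    n_other = 2 * n_leaf             # each remaining level-1 cluster
    n = n_parent + 3 * n_other

    x = np.zeros((n, 12))
    l1 = np.concatenate([np.zeros(n_parent, int), np.repeat([1, 2, 3], n_other)])
    l2 = np.full(n, -1)
    l2[:n3] = 0
    l2[n3:n_parent] = 1
    l3 = np.full(n, -1)
    l3[:n3] = np.repeat(np.arange(6), n_leaf)

    # level 1: tetrahedron in dims 0-2, edge length = separation * s1
    tetra = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
    ) * (separation * s1 / (2 * np.sqrt(2)))
    x[:, 0:3] = tetra[l1]
    sd1 = np.where(l1 == 0, tight1, s1)[:, None]
    x[:, 0:3] += rng.standard_normal((n, 3)) * sd1

    # level 2: split of cluster 0 along dim 3, size-balanced offsets so the
    # parent's mean stays at the tetrahedron vertex (no leakage into level 1)
    d2 = separation * s2
    off0 = -d2 * n2b / n_parent
    off1 = d2 * n3 / n_parent
    x[l2 == 0, 3] += off0
    x[l2 == 1, 3] += off1
    sd2 = np.full(n, 0.02)
    sd2[l2 == 0] = tight2
    sd2[l2 == 1] = s2
    x[:, 3] += rng.standard_normal(n) * sd2
    # sibling cluster is anisotropic (wider along dim 4) so the within-branch
    # PCA keeps a second component and density clustering stays 2-D
    sd2b = sd2.copy()
    sd2b[l2 == 1] = 2 * s2
    x[:, 4] += rng.standard_normal(n) * sd2b

    # level 3: hexagon in dims 5-6 within level-2 cluster 0
    hexc = _hexagon(separation * s3)
    x[l3 >= 0, 5:7] += hexc[l3[l3 >= 0]]
    sd3 = np.where(l3 >= 0, s3, tight2)
    x[:, 5:7] += rng.standard_normal((n, 2)) * sd3[:, None]

    # inert trailing dims
    x[:, 7:] = rng.standard_normal((n, 5)) * 1e-3

    labels = pd.DataFrame({"level1": l1, "level2": l2, "level3": l3})
    return x, labels
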