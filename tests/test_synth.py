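import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from neurochar.ephys import detect_spikes
from neurochar.ncd import parse_somatic_densities
from neurochar.protocols import build_protocol, complexity_current_series
from neurochar.synth import (
    ChannelFamilySpec,
    StepCountSpec,
    SyntheticNeuron,
    SyntheticNeuronSpec,
    generate_cell_conductance_files,
    generate_channel_family_specs,
    generate_channel_response_set,
    generate_planted_feature_matrix,
    generate_planted_hierarchy,
    generate_step_count_table,
    generate_voltage_response,
    simulate_channel_response,
)


class TestVoltageResponses:
    def test_planted_spike_times_at_reference_stimulus(self, basic_neuron):
        stim = build_protocol(
            "square", onset_ms=1000, duration_ms=1000, amplitude_na=0.75
        )
        times = basic_neuron.spike_times(stim)
        assert np.allclose(times[:4], [1050, 1070, 1090, 1110])

    def test_intrinsic_spiker_fires_without_stimulation(self):
        spec = SyntheticNeuronSpec(intrinsic_spiking=True, delay_ms=100)
        stim = build_protocol(
            "square", onset_ms=0, duration_ms=1000, amplitude_na=0.0, total_ms=1000
        )
        trace = generate_voltage_response(spec, stim)
        assert detect_spikes(trace).n_spikes >= 1

    def test_same_seed_gives_identical_trace(self, basic_spec):
        spec = SyntheticNeuronSpec(
            rheobase_na=0.5, delay_ms=50, isi_base_ms=20, noise_sd_mv=1.5, seed=3
        )
        stim = build_protocol("square", amplitude_na=0.75)
        a = generate_voltage_response(spec, stim)
        b = generate_voltage_response(spec, stim)
        assert np.array_equal(a.v, b.v)

    def test_unsampled_stimulus_is_rejected(self, basic_neuron):
        stim = build_protocol("square", amplitude_na=0.5)
        object.__setattr__(stim, "t", np.array([]))
        object.__setattr__(stim, "current", np.array([]))
        with pytest.raises(ValueError, match="unsampled"):
            basic_neuron.response(stim)

    def test_detected_delay_and_isi_match_planted_values(self, basic_neuron):
        """Ground-truth recoverability: delay within one sample and median
        ISI exact on a noise-free trace."""
        stim = build_protocol(
            "square", onset_ms=1000, duration_ms=1000, amplitude_na=0.75, dt_ms=0.025
        )
        trace = basic_neuron.response(stim)
        spikes = detect_spikes(trace)
        assert abs(spikes.spike_times[0] - 1050.0) <= stim.dt_ms
        assert np.median(spikes.isis) == pytest.approx(20.0, abs=1e-9)


class TestStepCountTables:
    def test_noise_free_table_is_exactly_linear(self):
        series = complexity_current_series(1.0, 0.9)
        spec = StepCountSpec(1000.0, 200.0)
        aps = np.arange(13)
        table = generate_step_count_table(spec, series, aps)
        assert np.array_equal(table["total_steps"], 1000 + 200 * aps)
        # residuals of an exact linear fit are all zero
        coef = np.polyfit(table["ap_count"], table["total_steps"], 1)
        resid = table["total_steps"] - np.polyval(coef, table["ap_count"])
        assert np.allclose(resid, 0, atol=1e-8)

    def test_zero_slope_gives_constant_rows(self):
        series = complexity_current_series(1.0)
        table = generate_step_count_table(
            StepCountSpec(1000.0, 0.0), series, np.arange(13)
        )
        assert (table["total_steps"] == 1000).all()

    def test_poisson_table_is_deterministic_for_fixed_seed(self):
        series = complexity_current_series(1.0)
        spec = StepCountSpec(1000.0, 200.0, counting_noise="poisson", seed=5)
        a = generate_step_count_table(spec, series, np.arange(13))
        b = generate_step_count_table(spec, series, np.arange(13))
        pd.testing.assert_frame_equal(a, b)

    def test_length_mismatch_is_rejected(self):
        series = complexity_current_series(1.0)
        with pytest.raises(ValueError, match="length"):
            generate_step_count_table(StepCountSpec(), series, [0, 1, 2])


class TestChannelResponses:
    def test_closed_channel_has_zero_conductance(self, clamp_protocols):
        # a channel whose activation midpoint is far above every protocol
        # voltage stays shut throughout
        spec = ChannelFamilySpec("Kv", activation_v_half=120.0, activation_tau_ms=5.0)
        resp = simulate_channel_response(spec, clamp_protocols)
        for sweeps in resp.sweeps.values():
            for sweep in sweeps:
                assert sweep["conductance"].max() < 1e-4

    def test_identical_specs_give_identical_responses(self, clamp_protocols):
        spec = ChannelFamilySpec("Nav", -35.0, 0.5, 5.0, -60.0, 2.0, 5.0, 50.0)
        a = simulate_channel_response(spec, clamp_protocols)
        b = simulate_channel_response(spec, clamp_protocols)
        for kind in a.sweeps:
            for sa, sb in zip(a.sweeps[kind], b.sweeps[kind]):
                assert np.array_equal(sa["current"], sb["current"])

    def test_within_family_responses_more_similar_than_between(self, clamp_protocols):
        from neurochar.chancluster import condense_responses

        kv = generate_channel_family_specs("Kv", 10, seed=1)
        nav = generate_channel_family_specs("Nav", 10, seed=2)
        responses = generate_channel_response_set(kv + nav, clamp_protocols)
        x = np.hstack(
            [
                condense_responses(responses, kind, grid_points=64).to_numpy()
                for kind in clamp_protocols
            ]
        )
        labels = np.array([0] * 10 + [1] * 10)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(20, dtype=bool)
        assert d[same & off_diag].mean() < d[~same].mean()

    def test_missing_protocol_is_rejected(self, clamp_protocols):
        spec = ChannelFamilySpec("Kv", -20.0, 5.0)
        partial = {k: v for k, v in clamp_protocols.items() if k != "inactivation"}
        with pytest.raises(ValueError, match="missing protocol"):
            simulate_channel_response(spec, partial)


class TestConductanceFiles:
    def test_somatic_density_round_trips_through_parser(self):
        docs = generate_cell_conductance_files(3, ["kv_a", "nav_b"], seed=0)
        for doc in docs.values():
            row = parse_somatic_densities(doc, ["kv_a", "nav_b"])
            assert (row >= 0).all()

    def test_absent_channel_parses_to_zero(self):
        docs = generate_cell_conductance_files(
            1, ["kv_a"], {"presence_prob": 1.0}, seed=0
        )
        row = parse_somatic_densities(docs["cell_0000"], ["kv_a", "ghost"])
        assert row["ghost"] == 0.0
        assert row["kv_a"] > 0.0

    def test_documents_are_byte_identical_for_fixed_seed(self):
        a = generate_cell_conductance_files(2, ["kv_a"], seed=9)
        b = generate_cell_conductance_files(2, ["kv_a"], seed=9)
        assert a == b

    def test_negative_density_parameter_is_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_conductance_files(1, ["kv_a"], {"median_mS_per_cm2": -1})


class TestPlantedMatrices:
    def test_single_cluster_has_uniform_labels(self):
        _, labels = generate_planted_feature_matrix(1, 20, 5.0, seed=0)
        assert np.unique(labels).size == 1

    def test_well_separated_blobs_are_exactly_recoverable(self):
        x, labels = generate_planted_feature_matrix(3, 50, 10.0, seed=0)
        found = KMeans(3, n_init=10, random_state=0).fit_predict(x)
        assert adjusted_rand_score(labels, found) == 1.0

    def test_matrix_is_deterministic_for_fixed_seed(self):
        a, _ = generate_planted_feature_matrix(2, 10, 8.0, seed=4)
        b, _ = generate_planted_feature_matrix(2, 10, 8.0, seed=4)
        assert np.array_equal(a, b)

    def test_hierarchy_has_planted_4_2_6_structure(self):
        x, labels = generate_planted_hierarchy(seed=0)
        assert labels["level1"].nunique() == 4
        assert labels.loc[labels["level2"] >= 0, "level2"].nunique() == 2
        assert labels.loc[labels["level3"] >= 0, "level3"].nunique() == 6
        # the recursed branch is the largest cluster at each level
        assert labels["level1"].value_counts().idxmax() == 0
        assert x.shape[0] == len(labels)
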