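import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from neurochar.chancluster import (
    cluster_channels,
    compute_family_scores,
    condense_responses,
    cut_tree_adaptive,
)
from neurochar.synth import (
    ChannelFamilySpec,
    ChannelResponseSet,
    VoltageClampProtocol,
    generate_channel_archetype_set,
    generate_channel_family_specs,
    generate_channel_response_set,
    simulate_channel_response,
)


def _zero_response(model_id, protocols):
    sweeps = {}
    for kind, proto in protocols.items():
        rows = []
        for v in proto.step_voltages:
            t = np.arange(0.0, 100.0, proto.dt_ms)
            rows.append(
                {"voltage": float(v), "t": t, "v": np.full_like(t, v),
                 "conductance": np.zeros_like(t), "current": np.zeros_like(t)}
            )
        sweeps[kind] = rows
    return ChannelResponseSet(model_id=model_id, family="Kv", sweeps=sweeps)


class TestCondenseResponses:
    def test_all_zero_response_condenses_to_zero_row(self, clamp_protocols):
        row = condense_responses(
            [_zero_response("z", clamp_protocols)], "activation", grid_points=32
        )
        assert (row.to_numpy() == 0).all()

    def test_identical_models_give_identical_rows(self, clamp_protocols):
        spec = ChannelFamilySpec("Kv", -20.0, 5.0, model_id="a")
        resp = [
            simulate_channel_response(spec, clamp_protocols),
            simulate_channel_response(spec, clamp_protocols),
        ]
        rows = condense_responses(resp, "activation", grid_points=64)
        assert np.array_equal(rows.iloc[0].to_numpy(), rows.iloc[1].to_numpy())

    def test_condensed_row_is_sampling_rate_invariant(self):
        # the same slow channel recorded at twice the rate condenses to the
        # same row up to interpolation error
        spec = ChannelFamilySpec("Kv", -20.0, 20.0, model_id="a")
        protos_coarse = {
            k: VoltageClampProtocol(v.kind, v.step_voltages, v.segments, dt_ms=0.2)
            for k, v in _default().items()
        }
        protos_fine = {
            k: VoltageClampProtocol(v.kind, v.step_voltages, v.segments, dt_ms=0.1)
            for k, v in _default().items()
        }
        a = condense_responses(
            [simulate_channel_response(spec, protos_coarse)], "activation", 128
        )
        b = condense_responses(
            [simulate_channel_response(spec, protos_fine)], "activation", 128
        )
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-3)

    def test_inconsistent_voltage_steps_rejected(self, clamp_protocols):
        spec = ChannelFamilySpec("Kv", -20.0, 5.0, model_id="a")
        good = simulate_channel_response(spec, clamp_protocols)
        altered = {
            k: VoltageClampProtocol(v.kind, v.step_voltages[:-1], v.segments)
            for k, v in clamp_protocols.items()
        }
        bad = simulate_channel_response(
            ChannelFamilySpec("Kv", -25.0, 5.0, model_id="b"), altered
        )
        with pytest.raises(ValueError, match="inconsistent"):
            condense_responses([good, bad], "activation")


def _default():
    from neurochar.synth import default_clamp_protocols

    return default_clamp_protocols()


class TestFamilyScores:
    def test_score_vector_is_three_dimensional(self, clamp_protocols):
        specs = generate_channel_family_specs("Kv", 6, seed=0)
        resp = generate_channel_response_set(specs, clamp_protocols)
        condensed = {
            k: condense_responses(resp, k, grid_points=64) for k in clamp_protocols
        }
        scores = compute_family_scores(condensed)
        assert scores.shape == (6, 3)
        assert set(scores.columns) == {"activation", "deactivation", "inactivation"}

    def test_identical_models_get_identical_scores(self, clamp_protocols):
        spec = ChannelFamilySpec("Kv", -20.0, 5.0, model_id="a")
        others = generate_channel_family_specs("Kv", 4, seed=1)
        resp = generate_channel_response_set([spec, spec] + others, clamp_protocols)
        condensed = {
            k: condense_responses(resp, k, grid_points=64) for k in clamp_protocols
        }
        scores = compute_family_scores(condensed)
        assert np.allclose(scores.iloc[0].to_numpy(), scores.iloc[1].to_numpy())

    def test_own_family_scores_higher_than_foreign_response(self, clamp_protocols):
        kv = generate_channel_family_specs("Kv", 8, seed=0)
        nav = generate_channel_family_specs("Nav", 8, seed=1)
        resp_kv = generate_channel_response_set(kv, clamp_protocols)
        resp_nav = generate_channel_response_set(nav, clamp_protocols)
        fit = {k: condense_responses(resp_kv, k, grid_points=64) for k in clamp_protocols}
        foreign = {
            k: condense_responses(resp_nav, k, grid_points=64) for k in clamp_protocols
        }
        own = compute_family_scores(fit)
        other = compute_family_scores(foreign, reference=fit)
        assert own.mean().mean() > other.mean().mean()

    def test_missing_protocol_rejected(self, clamp_protocols):
        specs = generate_channel_family_specs("Kv", 4, seed=0)
        resp = generate_channel_response_set(specs, clamp_protocols)
        condensed = {"activation": condense_responses(resp, "activation", 32)}
        with pytest.raises(ValueError, match="missing"):
            compute_family_scores(condensed)


class TestAdaptiveCut:
    def test_two_planted_groups_cut_into_two(self, rng):
        scores = pd.DataFrame(
            np.vstack(
                [rng.normal(0, 0.5, (20, 3)), rng.normal(20, 0.5, (15, 3))]
            )
        )
        cs = cluster_channels(scores)
        truth = [0] * 20 + [1] * 15
        assert cs.n_clusters == 2
        assert adjusted_rand_score(truth, cs.labels.to_numpy()) == 1.0

    def test_extreme_outlier_may_be_a_singleton(self, rng):
        scores = pd.DataFrame(
            np.vstack([rng.normal(0, 0.3, (20, 3)), [[500.0, 500.0, 500.0]]])
        )
        cs = cluster_channels(scores)
        counts = cs.labels.value_counts()
        assert counts.min() == 1  # the outlier stands alone

    def test_all_identical_scores_are_one_cluster(self):
        scores = pd.DataFrame(np.ones((10, 3)))
        cs = cluster_channels(scores)
        assert cs.n_clusters == 1

    def test_labels_permute_consistently_with_input_order(self, rng):
        scores = pd.DataFrame(
            np.vstack(
                [rng.normal(0, 0.5, (12, 3)), rng.normal(15, 0.5, (9, 3))]
            ),
            index=[f"m{i}" for i in range(21)],
        )
        perm = rng.permutation(21)
        cs1 = cluster_channels(scores)
        cs2 = cluster_channels(scores.iloc[perm])
        aligned = cs2.labels.loc[scores.index]
        assert adjusted_rand_score(cs1.labels.to_numpy(), aligned.to_numpy()) == 1.0

    def test_empty_linkage_is_single_cluster(self):
        assert np.array_equal(cut_tree_adaptive(np.empty((0, 4)), 1), [0])


class TestArchetypeRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_kinetic_archetypes_recovered(self, seed, clamp_protocols):
        specs, truth = generate_channel_archetype_set("Kv", seed=seed)
        background = []
        for j, fam in enumerate(["Nav", "Cav", "KCa", "Ih"]):
            background += generate_channel_family_specs(fam, 8, seed=seed * 100 + j)
        resp = generate_channel_response_set(specs + background, clamp_protocols)
        pooled = {
            k: condense_responses(resp, k, grid_points=128) for k in clamp_protocols
        }
        ids = [s.model_id for s in specs]
        condensed = {k: pooled[k].loc[ids] for k in clamp_protocols}
        scores = compute_family_scores(condensed, reference=pooled)
        cs = cluster_channels(scores, family="Kv")
        assert adjusted_rand_score(truth, cs.labels.to_numpy()) >= 0.8
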