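import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurochar.ncd import (
    NeuroMLParseError,
    build_conductance_table,
    integrate_cluster_density,
    normalize_densities,
    parse_somatic_densities,
    summarize_ncd,
    zscore_outlier_mask,
)

NML = """<?xml version="1.0" encoding="UTF-8"?>
<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="doc">
  <cell id="c1">
    <biophysicalProperties id="bp">
      <membraneProperties>
        <channelDensity id="d1" ionChannel="kv_a" condDensity="0.12 S_per_cm2"
                        segmentGroup="soma_group"/>
        <channelDensity id="d2" ionChannel="nav_b" condDensity="30 mS_per_cm2"
                        segmentGroup="soma_group"/>
        <channelDensity id="d3" ionChannel="cav_c" condDensity="5 mS_per_cm2"
                        segmentGroup="apical_dendrite"/>
      </membraneProperties>
    </biophysicalProperties>
  </cell>
</neuroml>
"""


class TestParser:
    def test_units_converted_to_ms_per_cm2(self):
        row = parse_somatic_densities(NML, ["kv_a", "nav_b"])
        assert row["kv_a"] == pytest.approx(120.0)
        assert row["nav_b"] == pytest.approx(30.0)

    def test_absent_channel_is_exactly_zero(self):
        row = parse_somatic_densities(NML, ["kv_a", "missing"])
        assert row["missing"] == 0.0

    def test_dendrite_only_channel_is_zero_in_somatic_table(self):
        row = parse_somatic_densities(NML, ["cav_c"])
        assert row["cav_c"] == 0.0

    def test_malformed_xml_rejected(self):
        with pytest.raises(NeuroMLParseError, match="malformed"):
            parse_somatic_densities("<neuroml><cell>", ["kv_a"])

    def test_unknown_units_rejected(self):
        doc = NML.replace("S_per_cm2", "furlongs")
        with pytest.raises(NeuroMLParseError, match="units"):
            parse_somatic_densities(doc, ["kv_a"])


class TestNormalize:
    def test_column_scaled_by_its_maximum(self):
        table = pd.DataFrame({"k": [2.0, 4.0, 8.0]})
        assert np.allclose(normalize_densities(table)["k"], [0.25, 0.5, 1.0])

    def test_all_zero_column_stays_zero(self):
        table = pd.DataFrame({"k": [0.0, 0.0], "n": [1.0, 2.0]})
        out = normalize_densities(table)
        assert (out["k"] == 0).all()

    def test_every_scaled_column_max_is_zero_or_one(self, rng):
        for _ in range(10):
            table = pd.DataFrame(rng.uniform(0, 50, size=(6, 4)))
            table.iloc[:, 0] = 0.0
            maxes = normalize_densities(table).max()
            assert set(np.round(maxes, 12)) <= {0.0, 1.0}

    def test_correlation_structure_preserved_under_scaling(self, rng):
        """Column-wise positive scaling leaves between-cell correlations of
        the density profiles unchanged."""
        table = pd.DataFrame(rng.uniform(1, 50, size=(5, 6)))
        scaled = normalize_densities(table)
        for i in range(4):
            r_raw = stats.pearsonr(table.iloc[i] / table.max(), scaled.iloc[i])[0]
            assert r_raw == pytest.approx(1.0)

    def test_negative_densities_rejected(self):
        with pytest.raises(ValueError):
            normalize_densities(pd.DataFrame({"k": [-1.0, 2.0]}))


class TestIntegrate:
    def test_co_clustered_channels_sum(self):
        scaled = pd.DataFrame({"a": [0.5], "b": [0.25], "c": [0.9]}, index=["cell"])
        ncd = integrate_cluster_density(scaled, {"a": "K1", "b": "K1", "c": "K2"})
        assert ncd.loc["cell", "K1"] == pytest.approx(0.75)
        assert ncd.loc["cell", "K2"] == pytest.approx(0.9)

    def test_singleton_cluster_passes_value_through(self):
        scaled = pd.DataFrame({"a": [0.4, 0.1]}, index=["c1", "c2"])
        ncd = integrate_cluster_density(scaled, {"a": "solo"})
        assert np.allclose(ncd["solo"], [0.4, 0.1])

    def test_zero_density_cell_has_zero_ncd_row(self):
        scaled = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["c"])
        ncd = integrate_cluster_density(scaled, {"a": "x", "b": "x"})
        assert (ncd.loc["c"] == 0).all()

    def test_unlabeled_channel_rejected(self):
        scaled = pd.DataFrame({"a": [0.5], "b": [0.2]})
        with pytest.raises(ValueError, match="unlabeled"):
            integrate_cluster_density(scaled, {"a": "x"})

    def test_ncd_is_monotone_in_raw_density(self, rng):
        raw = pd.DataFrame(rng.uniform(0, 10, size=(5, 3)), columns=list("abc"))
        bumped = raw.copy()
        bumped.iloc[2, 0] += 5.0
        clusters = {"a": "k", "b": "k", "c": "k"}
        ncd0 = integrate_cluster_density(normalize_densities(raw), clusters)
        ncd1 = integrate_cluster_density(normalize_densities(bumped), clusters)
        assert ncd1.iloc[2, 0] >= ncd0.iloc[2, 0]


class TestSummaries:
    def test_zero_variance_cluster_has_degenerate_interval(self):
        ncd = pd.DataFrame({"K1": [0.3, 0.3, 0.3]}, index=["a", "b", "c"])
        clusters = pd.Series(["RS", "RS", "RS"], index=["a", "b", "c"])
        out = summarize_ncd(ncd, clusters, n_boot=500, seed=0)
        row = out.iloc[0]
        assert row["mean_ncd"] == pytest.approx(0.3)
        assert row["ci_low"] == pytest.approx(0.3)
        assert row["ci_high"] == pytest.approx(0.3)

    def test_interval_contains_the_sample_mean(self, rng):
        ncd = pd.DataFrame({"K1": rng.uniform(0, 1, 40)})
        clusters = pd.Series(["RS"] * 40, index=ncd.index)
        out = summarize_ncd(ncd, clusters, n_boot=2000, seed=1)
        row = out.iloc[0]
        assert row["ci_low"] <= row["mean_ncd"] <= row["ci_high"]

    def test_ci_halfwidth_agrees_with_independent_bootstrap(self, rng):
        """Cross-check the percentile interval against scipy's independent
        bootstrap implementation on Bernoulli NCDs."""
        values = rng.binomial(1, 0.5, size=50).astype(float)
        ncd = pd.DataFrame({"K1": values})
        clusters = pd.Series(["RS"] * 50, index=ncd.index)
        out = summarize_ncd(ncd, clusters, n_boot=10_000, seed=2)
        ours = (out.iloc[0]["ci_high"] - out.iloc[0]["ci_low"]) / 2
        res = stats.bootstrap(
            (values,), np.mean, n_resamples=10_000, method="percentile",
            random_state=np.random.default_rng(3),
        )
        theirs = (res.confidence_interval.high - res.confidence_interval.low) / 2
        assert ours == pytest.approx(theirs, rel=0.2)

    def test_unlabeled_cell_rejected(self):
        ncd = pd.DataFrame({"K1": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            summarize_ncd(ncd, pd.Series({"a": "RS"}), n_boot=200, seed=0)

    def test_small_n_boot_rejected(self):
        ncd = pd.DataFrame({"K1": [0.1]}, index=["a"])
        with pytest.raises(ValueError):
            summarize_ncd(ncd, pd.Series({"a": "RS"}), n_boot=10, seed=0)


class TestOutlierMask:
    def test_mask_flags_only_extreme_rows(self, rng):
        x = pd.DataFrame(rng.normal(0, 1, size=(200, 3)))
        x.iloc[0] = [50.0, 0.0, 0.0]
        mask = zscore_outlier_mask(x, z_max=3.0)
        assert not mask.iloc[0]
        assert mask.iloc[1:].mean() > 0.9


class TestEndToEnd:
    def test_generated_documents_flow_through_to_ncd(self):
        from neurochar.synth import generate_cell_conductance_files

        channels = ["kv_a", "kv_b", "nav_a"]
        docs = generate_cell_conductance_files(
            6, channels, {"presence_prob": 0.9}, seed=4
        )
        table = build_conductance_table(docs, channels)
        assert table.shape == (6, 3)
        ncd = integrate_cluster_density(
            normalize_densities(table), {"kv_a": "K", "kv_b": "K", "nav_a": "Na"}
        )
        assert (ncd.to_numpy() >= 0).all()
        assert ncd.columns.tolist() == ["K", "Na"]
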