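"""End-to-end pipeline orchestration.

Runs the characterization stages in dependency order over synthetic
inputs — synth -> features -> complexity -> cluster-cells ->
cluster-channels -> ncd -> report — exchanging delimited-text artifacts in
a single output directory and emitting one JSON run manifest per run
(config snapshot, seeds, artifact hashes, timestamps).  Reruns with the
same config and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellcluster import run_nested_clustering
from .chancluster import cluster_channels, compute_family_scores, condense_responses
from .complexity import complexity_report, fit_step_model
from .ephys import FEATURE_NAMES, compute_features
from .ncd import build_conductance_table, integrate_cluster_density, normalize_densities, summarize_ncd
from .protocols import build_protocol, complexity_current_series
from .synth import (
    ChannelFamilySpec,
    StepCountSpec,
    SyntheticNeuron,
    SyntheticNeuronSpec,
    _FAMILY_PRESETS,
    default_clamp_protocols,
    generate_cell_conductance_files,
    generate_channel_archetype_set,
    generate_channel_family_specs,
    generate_channel_response_set,
    generate_step_count_table,
)
from .transforms import prepare_feature_matrix

__all__ = ["run_pipeline", "load_config", "validate_config", "ConfigError", "STAGES"]

STAGES = (
    "synth",
    "features",
    "complexity",
    "cluster-cells",
    "cluster-channels",
    "ncd",
    "report",
)

_STAGE_INPUTS = {
    "synth": (),
    "features": ("neuron_specs.csv",),
    "complexity": ("step_counts.csv",),
    "cluster-cells": ("features.csv",),
    "cluster-channels": ("channel_specs.csv",),
    "ncd": ("channel_clusters.csv", "cell_clusters.csv"),
    "report": (),
}

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": list(STAGES),
    "cells": {"n": 40, "trace_dt_ms": 0.05},
    "complexity": {"runtime_step_s": 1e-5, "target_rate_hz": 10.0},
    "clustering": {"variance_threshold": 0.95, "min_cluster_size": 10},
    "channels": {
        "families": ["Kv", "Nav"],
        "n_per_family": 8,
        "grid_points": 128,
        "variance_threshold": 0.99,
    },
    "ncd": {"n_boot": 2000},
}


class ConfigError(ValueError):
    """Configuration fails schema validation."""


class MissingArtifactError(FileNotFoundError):
    """A stage's upstream artifact is absent from the output directory."""


def validate_config(config: dict) -> dict:
    """Merge with defaults and check types/ranges; returns the full config."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in merged:
            raise ConfigError(f"unknown config section: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            unknown = set(value) - set(merged[key])
            if unknown:
                raise ConfigError(f"unknown key(s) in {key!r}: {sorted(unknown)}")
            merged[key].update(value)
        else:
            merged[key] = value
    if not isinstance(merged["seed"], int) or merged["seed"] < 0:
        raise ConfigError("seed must be a non-negative integer")
    bad = [s for s in merged["stages"] if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s): {bad}")
    if merged["cells"]["n"] < 1:
        raise ConfigError("cells.n must be >= 1")
    if merged["complexity"]["runtime_step_s"] <= 0:
        raise ConfigError("complexity.runtime_step_s must be positive")
    for fam in merged["channels"]["families"]:
        if fam not in _FAMILY_PRESETS:
            raise ConfigError(f"unknown channel family: {fam!r}")
    return merged


def load_config(path: str | Path) -> dict:
    """Read and validate a YAML/JSON config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw or {})


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


# Behavioral archetypes the synthetic population is drawn from: regular,
# delayed-regular, fast, and bursting/accommodating spiking patterns.
_CELL_ARCHETYPES = (
    {"delay_ms": 30.0, "isi_base_ms": 25.0, "accommodation_rate": 1.03},
    {"delay_ms": 120.0, "isi_base_ms": 25.0, "accommodation_rate": 1.0},
    {"delay_ms": 10.0, "isi_base_ms": 8.0, "accommodation_rate": 1.0},
    {"delay_ms": 12.0, "isi_base_ms": 40.0, "accommodation_rate": 1.12},
)


def _sample_neuron_specs(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        arch = _CELL_ARCHETYPES[i % len(_CELL_ARCHETYPES)]
        rows.append(
            {
                "model_id": f"cell_{i:04d}",
                "archetype": i % len(_CELL_ARCHETYPES),
                "rheobase_na": float(rng.uniform(0.2, 0.8)),
                "delay_ms": float(arch["delay_ms"] * np.exp(rng.normal(0, 0.15))),
                "isi_base_ms": float(arch["isi_base_ms"] * np.exp(rng.normal(0, 0.1))),
                "accommodation_rate": float(
                    arch["accommodation_rate"] + rng.normal(0, 0.005)
                ),
                "ap_amplitude_mv": float(rng.uniform(80.0, 110.0)),
                "ap_width_ms": float(rng.uniform(0.5, 2.0)),
                "resting_mv": float(rng.uniform(-75.0, -60.0)),
                "freq_pass_lo_hz": float(rng.uniform(20.0, 50.0)),
                "freq_pass_hi_hz": float(rng.uniform(80.0, 160.0)),
                "steps_base_true": float(rng.uniform(500.0, 5000.0)),
                "steps_ap_true": float(rng.uniform(50.0, 500.0)),
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
    return pd.DataFrame(rows).set_index("model_id")


def _neuron_from_row(row: pd.Series) -> SyntheticNeuron:
    return SyntheticNeuron(
        SyntheticNeuronSpec(
            rheobase_na=row["rheobase_na"],
            delay_ms=row["delay_ms"],
            isi_base_ms=row["isi_base_ms"],
            accommodation_rate=row["accommodation_rate"],
            ap_amplitude_mv=row["ap_amplitude_mv"],
            ap_width_ms=row["ap_width_ms"],
            resting_mv=row["resting_mv"],
            freq_pass_lo_hz=row["freq_pass_lo_hz"],
            freq_pass_hi_hz=row["freq_pass_hi_hz"],
            seed=int(row["seed"]),
        )
    )


def _channel_spec_table(config: dict, seed: int) -> pd.DataFrame:
    rows = []
    for f_i, family in enumerate(config["channels"]["families"]):
        n = config["channels"]["n_per_family"]
        sizes = (n - 2 * (n // 4), n // 4, n // 4) if n >= 4 else (n,)
        specs, _ = generate_channel_archetype_set(
            family, seed=seed + 17 * f_i, sizes=sizes
        )
        for s in specs:
            rows.append(
                {
                    "model_id": s.model_id,
                    "family": s.family,
                    "activation_v_half": s.activation_v_half,
                    "activation_tau_ms": s.activation_tau_ms,
                    "activation_slope_mv": s.activation_slope_mv,
                    "inactivation_v_half": s.inactivation_v_half,
                    "inactivation_tau_ms": s.inactivation_tau_ms,
                    "inactivation_slope_mv": s.inactivation_slope_mv,
                    "reversal_mv": s.reversal_mv,
                }
            )
    return pd.DataFrame(rows).set_index("model_id")


def _spec_from_channel_row(mid: str, row: pd.Series) -> ChannelFamilySpec:
    inact_v = row["inactivation_v_half"]
    inact_v = None if pd.isna(inact_v) else float(inact_v)
    inact_tau = row["inactivation_tau_ms"]
    inact_tau = None if pd.isna(inact_tau) else float(inact_tau)
    return ChannelFamilySpec(
        family=row["family"],
        activation_v_half=float(row["activation_v_half"]),
        activation_tau_ms=float(row["activation_tau_ms"]),
        activation_slope_mv=float(row["activation_slope_mv"]),
        inactivation_v_half=inact_v,
        inactivation_tau_ms=inact_tau,
        inactivation_slope_mv=float(row["inactivation_slope_mv"]),
        reversal_mv=float(row["reversal_mv"]),
        model_id=mid,
    )


def _stage_synth(config, outdir: Path):
    seed = config["seed"]
    specs = _sample_neuron_specs(config["cells"]["n"], seed)
    specs.to_csv(outdir / "neuron_specs.csv")

    # step-count benchmark tables, one block per cell
    blocks = []
    for mid, row in specs.iterrows():
        neuron = _neuron_from_row(row)
        series = complexity_current_series(row["rheobase_na"], row["rheobase_na"] * 0.9)
        counts = [
            len(
                neuron.spike_times(
                    build_protocol(
                        "square", onset_ms=1000.0, duration_ms=1000.0,
                        amplitude_na=a, dt_ms=1.0, total_ms=2200.0,
                    )
                )
            )
            for a in series.amplitudes
        ]
        table = generate_step_count_table(
            StepCountSpec(
                steps_base_true=row["steps_base_true"],
                steps_ap_true=row["steps_ap_true"],
                counting_noise="poisson",
                seed=int(row["seed"]) % 2**31,
            ),
            series,
            counts,
        )
        table.insert(0, "model_id", mid)
        blocks.append(table)
    pd.concat(blocks, ignore_index=True).to_csv(outdir / "step_counts.csv", index=False)

    # channel specs + conductance documents referencing them
    chan = _channel_spec_table(config, seed)
    chan.to_csv(outdir / "channel_specs.csv")
    docs = generate_cell_conductance_files(
        config["cells"]["n"], list(chan.index), seed=seed + 101
    )
    xml_dir = outdir / "cells_xml"
    xml_dir.mkdir(exist_ok=True)
    for cell_id, doc in docs.items():
        (xml_dir / f"{cell_id}.nml").write_bytes(doc)
    return ["neuron_specs.csv", "step_counts.csv", "channel_specs.csv", "cells_xml"]


def _stage_features(config, outdir: Path):
    specs = pd.read_csv(outdir / "neuron_specs.csv", index_col=0)
    dt = config["cells"]["trace_dt_ms"]
    rows = {
        mid: compute_features(_neuron_from_row(row), dt_ms=dt)
        for mid, row in specs.iterrows()
    }
    feats = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    feats.to_csv(outdir / "features.csv")
    return ["features.csv"]


def _stage_complexity(config, outdir: Path):
    tables = pd.read_csv(outdir / "step_counts.csv")
    fits = {
        mid: fit_step_model(grp[["ap_count", "total_steps"]])
        for mid, grp in tables.groupby("model_id")
    }
    reference = config["complexity"].get("reference") or sorted(fits)[0]
    report = complexity_report(
        fits,
        config["complexity"]["runtime_step_s"],
        reference,
        config["complexity"]["target_rate_hz"],
    )
    report.to_csv(outdir / "complexity.csv")
    return ["complexity.csv"]


def _stage_cluster_cells(config, outdir: Path):
    feats = pd.read_csv(outdir / "features.csv", index_col=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepared = prepare_feature_matrix(feats)
    tree = run_nested_clustering(
        prepared,
        variance_threshold=config["clustering"]["variance_threshold"],
        min_cluster_size=config["clustering"]["min_cluster_size"],
        seed=config["seed"],
    )
    tree.assignments.to_csv(outdir / "cell_clusters.csv")
    loadings = pd.DataFrame(
        tree.levels[0].pca.component_loadings, columns=feats.columns
    )
    loadings.to_csv(outdir / "pca_loadings.csv", index=False)
    return ["cell_clusters.csv", "pca_loadings.csv"]


def _stage_cluster_channels(config, outdir: Path):
    chan = pd.read_csv(outdir / "channel_specs.csv", index_col=0)
    protocols = default_clamp_protocols()
    grid = config["channels"]["grid_points"]
    # the per-protocol PCA models are learned over the whole channel
    # population; each family is scored under them
    all_specs = [_spec_from_channel_row(mid, row) for mid, row in chan.iterrows()]
    all_responses = generate_channel_response_set(all_specs, protocols)
    pooled = {
        kind: condense_responses(all_responses, kind, grid_points=grid)
        for kind in protocols
    }
    all_scores, all_labels = [], []
    for family, grp in chan.groupby("family", sort=True):
        condensed = {
            kind: pooled[kind].loc[list(grp.index)] for kind in protocols
        }
        scores = compute_family_scores(
            condensed, config["channels"]["variance_threshold"], reference=pooled
        )
        clusters = cluster_channels(scores, family=family)
        scores.insert(0, "family", family)
        all_scores.append(scores)
        labels = clusters.labels.rename("cluster").to_frame()
        labels.insert(0, "family", family)
        labels["cluster"] = [f"{family}:{c}" for c in clusters.labels]
        all_labels.append(labels)
    pd.concat(all_scores).to_csv(outdir / "channel_scores.csv")
    pd.concat(all_labels).to_csv(outdir / "channel_clusters.csv")
    return ["channel_scores.csv", "channel_clusters.csv"]


def _stage_ncd(config, outdir: Path):
    labels = pd.read_csv(outdir / "channel_clusters.csv", index_col=0)
    xml_dir = outdir / "cells_xml"
    docs = {p.stem: p for p in sorted(xml_dir.glob("*.nml"))}
    table = build_conductance_table(docs, list(labels.index))
    scaled = normalize_densities(table)
    ncd = integrate_cluster_density(scaled, labels["cluster"])
    ncd.to_csv(outdir / "ncd.csv")
    cell_clusters = pd.read_csv(outdir / "cell_clusters.csv", index_col=0)["final"]
    common = ncd.index.intersection(cell_clusters.index)
    summary = summarize_ncd(
        ncd.loc[common],
        cell_clusters.loc[common],
        n_boot=config["ncd"]["n_boot"],
        seed=config["seed"] + 7,
    )
    summary.to_csv(outdir / "ncd_summary.csv", index=False)
    return ["ncd.csv", "ncd_summary.csv"]


def _stage_report(config, outdir: Path):
    report = {}
    if (outdir / "complexity.csv").exists():
        comp = pd.read_csv(outdir / "complexity.csv", index_col=0)
        report["complexity"] = {
            "n_models": int(len(comp)),
            "omega_hh_min": float(comp["omega_hh"].min()),
            "omega_hh_max": float(comp["omega_hh"].max()),
        }
    if (outdir / "cell_clusters.csv").exists():
        cc = pd.read_csv(outdir / "cell_clusters.csv", index_col=0)
        report["cell_clusters"] = {
            "level1": int(cc["level1"].nunique()),
            "final_leaves": int(cc["final"].nunique()),
        }
    if (outdir / "channel_clusters.csv").exists():
        ch = pd.read_csv(outdir / "channel_clusters.csv", index_col=0)
        report["channel_clusters"] = {
            "n_subtypes": int(ch["cluster"].nunique()),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return ["report.json"]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "features": _stage_features,
    "complexity": _stage_complexity,
    "cluster-cells": _stage_cluster_cells,
    "cluster-channels": _stage_cluster_channels,
    "ncd": _stage_ncd,
    "report": _stage_report,
}


def _hash_path(path: Path) -> str:
    if path.is_dir():
        h = hashlib.sha256()
        for p in sorted(path.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
        return h.hexdigest()
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the requested stages in dependency order and write the manifest.

    ``config`` is a validated mapping or a path to a YAML/JSON file.
    Returns the run manifest.

    Raises
    ------
    MissingArtifactError
        When a requested stage's upstream artifact is absent (e.g. ncd
        requested without channel clusters).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    requested = [s for s in STAGES if s in config["stages"]]
    manifest = {
        "package_version": __version__,
        "config": config,
        "seed": config["seed"],
        "stages": {},
        "started_unix": time.time(),
    }
    artifacts: list[str] = []
    for stage in requested:
        for needed in _STAGE_INPUTS[stage]:
            if not (outdir / needed).exists():
                raise MissingArtifactError(
                    f"stage {stage!r}: missing upstream artifact {needed!r}"
                )
        t0 = time.time()
        produced = _STAGE_FUNCS[stage](config, outdir)
        manifest["stages"][stage] = {
            "outputs": produced,
            "seconds": round(time.time() - t0, 3),
        }
        artifacts.extend(produced)
    manifest["artifact_sha256"] = {
        name: _hash_path(outdir / name) for name in artifacts
    }
    manifest["finished_unix"] = time.time()
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
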