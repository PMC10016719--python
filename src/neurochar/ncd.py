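"""Normalized channel densities (NCD).

Somatic conductance densities are read from NeuroML-subset cell documents
(channel-density elements only), expressed in mS/cm^2, assembled into a
cells x channels matrix (absent channel -> exactly 0), scaled column-wise
by each channel's maximum across cells, and summed over the channels of
each discovered channel cluster to give one non-negative NCD per cell per
channel cluster.  Per-cell-cluster means carry percentile-bootstrap 95%
confidence intervals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "parse_somatic_densities",
    "build_conductance_table",
    "normalize_densities",
    "integrate_cluster_density",
    "summarize_ncd",
    "zscore_outlier_mask",
    "NeuroMLParseError",
]

#: A density element is "somatic" when its segment group name contains one
#: of these substrings (case-insensitive); an absent segmentGroup attribute
#: means the density applies everywhere, including the soma.
DEFAULT_SOMA_GROUP_SUBSTRINGS = ("soma",)

_UNIT_TO_MS_PER_CM2 = {
    "mS_per_cm2": 1.0,
    "S_per_cm2": 1000.0,
    "S_per_m2": 0.1,
    "mS_per_m2": 1e-4,
}


class NeuroMLParseError(ValueError):
    """Malformed NeuroML-subset document or unparseable density value."""


def _density_to_ms_per_cm2(text: str) -> float:
    parts = text.split()
    if len(parts) != 2:
        raise NeuroMLParseError(f"unparseable condDensity value: {text!r}")
    value, units = parts
    if units not in _UNIT_TO_MS_PER_CM2:
        raise NeuroMLParseError(f"unknown conductance-density units: {units!r}")
    try:
        return float(value) * _UNIT_TO_MS_PER_CM2[units]
    except ValueError as exc:
        raise NeuroMLParseError(f"unparseable condDensity value: {text!r}") from exc


def parse_somatic_densities(
    document: bytes | str | Path,
    channel_ids: list[str],
    soma_group_substrings: tuple[str, ...] = DEFAULT_SOMA_GROUP_SUBSTRINGS,
) -> pd.Series:
    """Somatic conductance densities (mS/cm^2) of one cell document.

    ``document`` may be XML bytes/text or a path.  Channels in
    ``channel_ids`` that are absent from the file map to exactly 0;
    densities attributed to non-somatic segment groups are ignored.
    Multiple somatic entries for the same channel are averaged
    (area-unweighted).
    """
    try:
        if isinstance(document, (bytes, bytearray)):
            root = etree.fromstring(bytes(document))
        elif isinstance(document, str) and document.lstrip().startswith("<"):
            root = etree.fromstring(document.encode())
        else:
            root = etree.parse(str(document)).getroot()
    except etree.XMLSyntaxError as exc:
        raise NeuroMLParseError(f"malformed XML: {exc}") from exc

    values: dict[str, list[float]] = {ch: [] for ch in channel_ids}
    # namespace-agnostic match on the element's local name
    for el in root.iter():
        if etree.QName(el).localname != "channelDensity":
            continue
        channel = el.get("ionChannel")
        if channel not in values:
            continue
        group = el.get("segmentGroup")
        if group is not None and not any(
            s.lower() in group.lower() for s in soma_group_substrings
        ):
            continue
        dens = el.get("condDensity")
        if dens is None:
            raise NeuroMLParseError(
                f"channelDensity for {channel!r} lacks condDensity"
            )
        values[channel].append(_density_to_ms_per_cm2(dens))
    return pd.Series(
        {ch: (float(np.mean(v)) if v else 0.0) for ch, v in values.items()},
        name="mS_per_cm2",
    )


def build_conductance_table(
    documents: dict[str, bytes | str | Path],
    channel_ids: list[str],
    **kwargs,
) -> pd.DataFrame:
    """Cells x channels conductance-density matrix (mS/cm^2)."""
    rows = {
        cell: parse_somatic_densities(doc, channel_ids, **kwargs)
        for cell, doc in documents.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(channel_ids)]


def normalize_densities(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel column by its maximum across cells.

    All-zero columns are left as zeros.  Column-wise positive scaling
    preserves the correlation structure across cells.
    """
    values = table.to_numpy(float)
    if (values < 0).any():
        raise ValueError("conductance densities must be non-negative")
    colmax = values.max(axis=0)
    scale = np.where(colmax > 0, colmax, 1.0)
    return pd.DataFrame(values / scale, index=table.index, columns=table.columns)


def integrate_cluster_density(
    scaled: pd.DataFrame, channel_clusters: dict[str, object] | pd.Series
) -> pd.DataFrame:
    """Sum scaled densities over each channel cluster: the NCD matrix.

    ``channel_clusters`` maps every channel column to its cluster label.
    """
    mapping = dict(channel_clusters) if not isinstance(channel_clusters, dict) else channel_clusters
    unlabeled = [c for c in scaled.columns if c not in mapping]
    if unlabeled:
        raise ValueError(f"unlabeled channel(s): {unlabeled}")
    return scaled.T.groupby(scaled.columns.map(mapping)).sum().T


def summarize_ncd(
    ncd: pd.DataFrame,
    cell_clusters: pd.Series | dict,
    n_boot: int = 10_000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Mean NCD per (cell cluster, channel cluster) with percentile
    bootstrap confidence intervals, resampling cells with replacement.

    All cluster members enter the summary (no outlier exclusion).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    clusters = pd.Series(cell_clusters)
    missing = ncd.index.difference(clusters.index)
    if len(missing):
        raise ValueError(f"cells without a cluster label: {list(missing)}")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    for cc in pd.unique(clusters.loc[ncd.index]):
        members = ncd.loc[clusters.loc[ncd.index] == cc]
        if members.empty:
            raise ValueError(f"empty cell cluster: {cc!r}")
        values = members.to_numpy(float)
        n = values.shape[0]
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = values[idx].mean(axis=1)  # (n_boot, n_channel_clusters)
        mean = values.mean(axis=0)
        lo = np.percentile(boot_means, lo_q, axis=0)
        hi = np.percentile(boot_means, hi_q, axis=0)
        for j, chc in enumerate(ncd.columns):
            rows.append(
                {
                    "cell_cluster": cc,
                    "channel_cluster": chc,
                    "mean_ncd": mean[j],
                    "ci_low": lo[j],
                    "ci_high": hi[j],
                    "n_cells": n,
                }
            )
    return pd.DataFrame(rows)


def zscore_outlier_mask(features: pd.DataFrame, z_max: float = 3.0) -> pd.Series:
    """Rows within ``|Z| < z_max`` on every column — a visualization
    filter only; summary statistics always use all models."""
    values = features.to_numpy(float)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (values - values.mean(axis=0)) / sd
    return pd.Series((np.abs(z) < z_max).all(axis=1), index=features.index)
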