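"""Channel-model response condensation, PCA-likelihood scoring, and
within-family clustering.

Voltage-clamp sweeps are condensed into one fixed-length vector per model
per protocol (fixed-grid resampling of each step's current trace,
concatenation across steps, per-model amplitude normalization).  For each
protocol a probabilistic PCA retaining 99% of variance is fitted to the
family's condensed matrix, and every model is scored by its log-likelihood
under each protocol's model — a 3-vector per channel.  The score matrix is
reduced by a second PCA (99%) and clustered by Ward-linkage agglomerative
clustering with an adaptive dendrogram cut that allows singleton clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ward
from sklearn.decomposition import PCA

from .synth import CLAMP_PROTOCOL_KINDS, ChannelResponseSet

__all__ = [
    "condense_responses",
    "compute_family_scores",
    "cut_tree_adaptive",
    "ChannelClusterSet",
    "cluster_channels",
]

#: Resampling grid length per voltage step.
DEFAULT_GRID_POINTS = 512


def condense_responses(
    responses: list[ChannelResponseSet],
    protocol: str,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> pd.DataFrame:
    """One fixed-length row per model for the given protocol.

    Each voltage step's current trace is linearly resampled onto a uniform
    grid of ``grid_points`` samples, the steps are concatenated, and the
    row is normalized by its maximum absolute current (shape, not
    amplitude, carries the kinetics).  Deterministic.

    Raises
    ------
    ValueError
        If models were recorded with inconsistent voltage steps.
    """
    if not responses:
        raise ValueError("no responses")
    ref_steps = [s["voltage"] for s in responses[0].sweeps[protocol]]
    rows, ids = [], []
    for resp in responses:
        if protocol not in resp.sweeps:
            raise ValueError(f"model {resp.model_id}: missing protocol {protocol!r}")
        sweeps = resp.sweeps[protocol]
        steps = [s["voltage"] for s in sweeps]
        if steps != ref_steps:
            raise ValueError(
                f"model {resp.model_id}: inconsistent voltage steps for {protocol!r}"
            )
        parts = []
        for sweep in sweeps:
            t = sweep["t"]
            grid = np.linspace(t[0], t[-1], grid_points)
            parts.append(np.interp(grid, t, sweep["current"]))
        row = np.concatenate(parts)
        peak = np.abs(row).max()
        if peak > 0:
            row = row / peak
        rows.append(row)
        ids.append(resp.model_id)
    return pd.DataFrame(np.vstack(rows), index=ids)


def compute_family_scores(
    condensed: dict[str, pd.DataFrame],
    variance_threshold: float = 0.99,
    reference: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-model log-likelihood under each protocol's fitted PCA model.

    ``condensed`` maps protocol kind -> condensed matrix for one channel
    family (identical model order across protocols).  When ``reference``
    is given (per-protocol condensed matrices pooled over the whole
    channel population), each protocol's probabilistic PCA is fitted on
    the pooled matrix and the family's models are scored under it;
    otherwise the fit uses the family's own matrix.  The likelihood is
    the probabilistic-PCA marginal, with residual variance estimated from
    the discarded components.  Returns an (n_models, 3) DataFrame with one
    column per protocol.
    """
    missing = [k for k in CLAMP_PROTOCOL_KINDS if k not in condensed]
    if missing:
        raise ValueError(f"missing protocol(s): {missing}")
    index = condensed[CLAMP_PROTOCOL_KINDS[0]].index
    if len(index) < 2:
        raise ValueError("need at least 2 channel models")
    scores = {}
    for kind in CLAMP_PROTOCOL_KINDS:
        x = condensed[kind].to_numpy(float)
        fit_on = x if reference is None else reference[kind].to_numpy(float)
        pca = PCA(n_components=variance_threshold, svd_solver="full")
        pca.fit(fit_on)
        scores[kind] = pca.score_samples(x)
    return pd.DataFrame(scores, index=index)


def cut_tree_adaptive(
    linkage: np.ndarray,
    n_leaves: int,
    gap_ratio: float = 2.0,
    height_floor_frac: float = 0.05,
) -> np.ndarray:
    """Adaptive top-down dendrogram cut with singletons allowed.

    Starting from the root, a merge is split when its height exceeds
    ``gap_ratio`` times the larger internal height of its two subtrees
    (leaves count as height 0) and is non-negligible relative to the root
    height (``height_floor_frac``).  This keeps clusters that merge
    smoothly intact, severs well-separated groups, and lets an isolated
    model fall out as a singleton.
    """
    labels = np.zeros(n_leaves, dtype=int)
    if linkage.shape[0] == 0:
        return labels
    heights = {i: 0.0 for i in range(n_leaves)}
    children = {}
    for k, (a, b, h, _cnt) in enumerate(linkage):
        node = n_leaves + k
        heights[node] = float(h)
        children[node] = (int(a), int(b))
    root = n_leaves + linkage.shape[0] - 1
    floor = height_floor_frac * heights[root]

    def leaves_of(node):
        stack, out = [node], []
        while stack:
            m = stack.pop()
            if m < n_leaves:
                out.append(m)
            else:
                stack.extend(children[m])
        return out

    clusters: list[list[int]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n_leaves:
            clusters.append([node])
            continue
        a, b = children[node]
        h = heights[node]
        internal = max(heights[a], heights[b])
        if h > floor and h > gap_ratio * internal:
            stack.extend([a, b])
        else:
            clusters.append(leaves_of(node))
    # canonical labels: by order of each cluster's smallest leaf index
    clusters.sort(key=min)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


@dataclass(frozen=True, eq=False)
class ChannelClusterSet:
    """Clustering of one channel family's score matrix."""

    family: str
    labels: pd.Series            # model id -> cluster label
    linkage: np.ndarray = field(repr=False)
    gap_ratio: float = 2.0
    height_floor_frac: float = 0.05

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def linkage_as_nested_lists(self):
        """The dendrogram as nested [left, right, height] lists (leaves are
        model ids), a plain serialization for export."""
        n = self.labels.size
        ids = list(self.labels.index)
        nodes: dict[int, object] = {i: ids[i] for i in range(n)}
        for k, (a, b, h, _c) in enumerate(self.linkage):
            nodes[n + k] = [nodes[int(a)], nodes[int(b)], float(h)]
        return nodes[n + self.linkage.shape[0] - 1]


def cluster_channels(
    scores: pd.DataFrame,
    family: str = "",
    variance_threshold: float = 0.99,
    gap_ratio: float = 2.0,
    height_floor_frac: float = 0.05,
) -> ChannelClusterSet:
    """PCA (99%) on the family score matrix, Ward linkage, adaptive cut.

    All-identical score matrices degenerate to a single cluster.  Labels
    are canonicalized by first occurrence, so permuting the input rows
    permutes the labels consistently.
    """
    x = scores.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 channel models")
    if np.allclose(x, x[0]):
        labels = pd.Series(0, index=scores.index)
        return ChannelClusterSet(family, labels, np.empty((0, 4)))
    _, reduced = _pca_scores(x, variance_threshold)
    linkage = ward(reduced)
    raw = cut_tree_adaptive(linkage, x.shape[0], gap_ratio, height_floor_frac)
    labels = pd.Series(raw, index=scores.index)
    return ChannelClusterSet(family, labels, linkage, gap_ratio, height_floor_frac)


def _pca_scores(x: np.ndarray, variance_threshold: float):
    pca = PCA(n_components=variance_threshold, svd_solver="full")
    return pca, pca.fit_transform(x)
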