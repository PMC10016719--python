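"""Feature-matrix preparation: missing-value filling, bi-symmetric log,
z-scoring.

The pipeline order is fill -> bilog -> z-score; the clustering stages
expect a complete, transformed, standardized matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "bilog_transform",
    "DEFAULT_BILOG_C",
    "fill_missing",
    "standardize",
    "prepare_feature_matrix",
    "FillPolicyError",
]

#: Default scale constant of the bi-symmetric log.  With C = 1/ln(10) the
#: transform has unit slope at the origin.
DEFAULT_BILOG_C = 1.0 / np.log(10.0)


def bilog_transform(x, c: float = DEFAULT_BILOG_C):
    """Bi-symmetric log: ``sign(x) * log10(1 + |x| / C)``.

    Odd, strictly increasing and smooth through zero; compresses large
    magnitudes of either sign logarithmically without exaggerating values
    between -1 and 1.  Total on the reals.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log10(1.0 + np.abs(x) / c)


class FillPolicyError(ValueError):
    """A feature with missing entries has no usable fill policy."""


def fill_missing(
    matrix: pd.DataFrame, policies: dict[str, str] | None = None,
    default_policy: str = "mean",
) -> pd.DataFrame:
    """Replace missing feature values by the feature's declared policy.

    ``policies`` maps feature name -> one of ``min`` / ``max`` / ``mean``,
    interpreted across models (column-wise).  Features without an entry
    use ``default_policy``.

    Raises
    ------
    FillPolicyError
        For an unknown policy name, or when a column is entirely missing
        (its mean/min/max is undefined).
    """
    policies = policies or {}
    out = matrix.copy()
    for col in out.columns:
        if not out[col].isna().any():
            continue
        policy = policies.get(col, default_policy)
        series = out[col]
        if series.isna().all():
            raise FillPolicyError(
                f"feature {col!r}: all values missing, {policy} undefined"
            )
        if policy == "mean":
            fill = series.mean()
        elif policy == "min":
            fill = series.min()
        elif policy == "max":
            fill = series.max()
        else:
            raise FillPolicyError(f"feature {col!r}: unknown fill policy {policy!r}")
        out[col] = series.fillna(fill)
    return out


def standardize(matrix: pd.DataFrame | np.ndarray):
    """Column-wise z-scores (mean 0, sd 1, population sd).

    Zero-variance columns are mapped to 0 with a warning.
    """
    values = np.asarray(matrix, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance column(s) mapped to 0 during "
            "standardization",
            stacklevel=2,
        )
    sd_safe = np.where(zero, 1.0, sd)
    z = (values - mean) / sd_safe
    z[:, zero] = 0.0
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


def prepare_feature_matrix(
    matrix: pd.DataFrame,
    fill_policies: dict[str, str] | None = None,
    bilog_c: float = DEFAULT_BILOG_C,
    bilog_features: list[str] | None = None,
) -> pd.DataFrame:
    """The full preparation pipeline: fill -> bilog -> z-score.

    ``bilog_features`` restricts the log compression to a subset of
    columns; by default every feature is transformed.
    """
    filled = fill_missing(matrix, fill_policies)
    cols = list(filled.columns) if bilog_features is None else bilog_features
    transformed = filled.copy()
    for col in cols:
        transformed[col] = bilog_transform(filled[col].to_numpy(), bilog_c)
    return standardize(transformed)
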