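"""Variable-timestep computational complexity.

A variable-step integrator (e.g. CVODE) uses a baseline number of steps
per simulated second plus extra steps for every action potential, so the
total step count is modeled as ``steps = steps_base + steps_ap * APs`` and
fitted by ordinary least squares over a series of square current
injections.  Absolute complexity is the wall-clock time to simulate 1 s at
a target firing rate:

    omega_abs = (steps_base + steps_ap * target_rate) * runtime_step

and relative complexity is the ratio of a model's omega_abs to that of a
reference model (conventionally the Hodgkin-Huxley model, whose relative
complexity is 1 HH by definition).  ``runtime_step`` — the mean wall-clock
seconds per integration step — is a measured input, so the pipeline stays
hardware-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StepModelFit",
    "ComplexityEstimate",
    "fit_step_model",
    "absolute_complexity",
    "relative_complexity",
    "complexity_report",
    "DEFAULT_TARGET_RATE_HZ",
]

#: Assumed target firing rate (APs per simulated second).
DEFAULT_TARGET_RATE_HZ = 10.0


@dataclass(frozen=True)
class StepModelFit:
    """OLS fit of total integration steps versus AP count."""

    steps_base: float   # intercept: baseline steps per simulated second
    steps_ap: float     # slope: extra steps per action potential
    fit_r2: float
    n_points: int


@dataclass(frozen=True)
class ComplexityEstimate:
    """Absolute (seconds) and reference-relative (HH) complexity."""

    steps_base: float
    steps_ap: float
    runtime_step_s: float
    target_rate_hz: float
    omega_abs_s: float
    omega_hh: float | None = None


def fit_step_model(pairs) -> StepModelFit:
    """Fit ``steps = steps_base + steps_ap * APs`` by least squares.

    ``pairs`` is an iterable of (AP count, total steps) rows, or a
    DataFrame with ``ap_count`` and ``total_steps`` columns.  A negative
    fitted slope is clamped to 0 with a warning.

    Raises
    ------
    ValueError
        If fewer than 2 rows or all AP counts are identical (slope
        unidentifiable).
    """
    if isinstance(pairs, pd.DataFrame):
        aps = pairs["ap_count"].to_numpy(float)
        steps = pairs["total_steps"].to_numpy(float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be rows of (AP count, total steps)")
        aps, steps = arr[:, 0], arr[:, 1]
    if aps.size < 2:
        raise ValueError("need at least 2 points to fit the step model")
    if np.unique(aps).size < 2:
        raise ValueError("slope unidentifiable: all AP counts identical")
    slope, intercept = np.polyfit(aps, steps, 1)
    if slope < 0:
        warnings.warn("negative steps/AP slope clamped to 0", stacklevel=2)
        slope = 0.0
        intercept = float(np.mean(steps))
    pred = intercept + slope * aps
    ss_res = float(np.sum((steps - pred) ** 2))
    ss_tot = float(np.sum((steps - np.mean(steps)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StepModelFit(
        steps_base=float(intercept), steps_ap=float(slope),
        fit_r2=r2, n_points=int(aps.size),
    )


def absolute_complexity(
    fit: StepModelFit,
    runtime_step_s: float,
    target_rate_hz: float = DEFAULT_TARGET_RATE_HZ,
) -> ComplexityEstimate:
    """Seconds of wall-clock time to simulate 1 s at the target AP rate."""
    if runtime_step_s <= 0:
        raise ValueError("runtime_step must be positive")
    omega = (fit.steps_base + fit.steps_ap * target_rate_hz) * runtime_step_s
    return ComplexityEstimate(
        steps_base=fit.steps_base, steps_ap=fit.steps_ap,
        runtime_step_s=runtime_step_s, target_rate_hz=target_rate_hz,
        omega_abs_s=omega,
    )


def relative_complexity(
    target: ComplexityEstimate, reference: ComplexityEstimate
) -> float:
    """Complexity of ``target`` in reference units (HH): the ratio of the
    two absolute complexities.  The reference against itself is exactly 1.
    """
    if reference.omega_abs_s <= 0:
        raise ValueError("reference omega_abs must be positive")
    return target.omega_abs_s / reference.omega_abs_s


def complexity_report(
    fits: dict[str, StepModelFit],
    runtime_steps_s: dict[str, float] | float,
    reference_id: str,
    target_rate_hz: float = DEFAULT_TARGET_RATE_HZ,
) -> pd.DataFrame:
    """Per-model complexity table relative to one reference model.

    ``runtime_steps_s`` may be a single shared measurement or a per-model
    mapping.  Columns: steps_base, steps_ap, fit_r2, omega_abs_s, omega_hh.
    """
    if reference_id not in fits:
        raise KeyError(f"reference model {reference_id!r} not among fits")

    def rts(mid):
        return runtime_steps_s if np.isscalar(runtime_steps_s) else runtime_steps_s[mid]

    estimates = {
        mid: absolute_complexity(fit, rts(mid), target_rate_hz)
        for mid, fit in fits.items()
    }
    ref = estimates[reference_id]
    rows = {
        mid: {
            "steps_base": est.steps_base,
            "steps_ap": est.steps_ap,
            "fit_r2": fits[mid].fit_r2,
            "omega_abs_s": est.omega_abs_s,
            "omega_hh": relative_complexity(est, ref),
        }
        for mid, est in estimates.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
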