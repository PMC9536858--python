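"""Threshold-linear decomposition of inhibition into divisive and subtractive parts.

Responses of a neuron under control conditions are ordered from largest to
smallest, the light-condition responses are permuted by that same control
ordering (never re-sorted independently), and both vectors are normalized to
the largest control response. An ordinary least-squares line of the
inhibited responses against the control responses then summarizes the
effect: the slope captures the proportional (divisive) component and the
intercept the subtractive component. Slope 1 with intercept 0 means no
effect; a purely divisive suppression changes only the slope, a purely
subtractive one shifts the intercept with slope 1.

The population-mean scope averages the normalized, ordered response vectors
across neurons first and fits the averaged tuning curve, which is the
headline analysis for both taste profiles and mouth-light frequency series.
Because those points are ordered and averaged, the attached p-values are
descriptive rather than strictly inferential; they are reported with that
caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ValidationError

__all__ = ["GainFit", "tuning_curve_assembly", "threshold_linear_fit"]


@dataclass
class GainFit:
    scope: str  # "per_neuron" | "population_mean"
    control: np.ndarray  # normalized, ordered nonincreasing, max = 1
    light: np.ndarray  # matched ordering
    slope: float
    intercept: float
    r_squared: float
    p_slope_ne_1: float
    p_intercept_ne_0: float
    n_points: int


def tuning_curve_assembly(
    control: dict[str, float],
    light: dict[str, float],
    order: tuple[str, ...] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Order both conditions by the CONTROL response magnitudes.

    ``order`` supplies the tie-break (panel order); ties are resolved to the
    earlier panel position and the chosen ordering is returned so it can be
    recorded. Raises on mismatched stimulus sets.
    """
    if set(control) != set(light):
        raise ValidationError(
            f"mismatched stimulus sets: {sorted(set(control) ^ set(light))}"
        )
    labels = list(order) if order is not None else sorted(control)
    missing = set(control) - set(labels)
    if missing:
        raise ValidationError(f"stimuli absent from tie-break order: {sorted(missing)}")
    labels = [s for s in labels if s in control]
    # stable sort: equal control responses keep panel order
    ranked = sorted(labels, key=lambda s: -control[s])
    c = np.array([control[s] for s in ranked], dtype=float)
    l = np.array([light[s] for s in ranked], dtype=float)
    return ranked, c, l


def _normalize_ordered(control: np.ndarray, light: np.ndarray):
    control = np.asarray(control, dtype=float)
    light = np.asarray(light, dtype=float)
    if control.shape != light.shape or control.ndim != 1:
        raise ValidationError("control and light responses must be matched 1-D vectors")
    order = np.argsort(-control, kind="stable")
    control, light = control[order], light[order]
    peak = control[0]
    if peak <= 0:
        raise ValidationError("maximum control response must be > 0")
    return control / peak, light / peak


def threshold_linear_fit(control, light, scope: str = "per_neuron") -> GainFit:
    """OLS of normalized inhibited responses on normalized control responses.

    ``per_neuron``: ``control`` and ``light`` are matched 1-D response
    vectors for a single neuron. ``population_mean``: they are sequences of
    such vectors (one per neuron, equal length); each neuron is normalized
    and ordered individually, then the vectors are averaged pointwise before
    fitting. Needs >= 3 matched points. The fit is invariant to the common
    normalization constant by construction.
    """
    if scope == "per_neuron":
        c, l = _normalize_ordered(control, light)
    elif scope == "population_mean":
        pairs = [_normalize_ordered(ci, li) for ci, li in zip(control, light, strict=True)]
        lengths = {p[0].size for p in pairs}
        if len(lengths) != 1:
            raise ValidationError("population_mean requires equal-length response vectors")
        c = np.mean([p[0] for p in pairs], axis=0)
        l = np.mean([p[1] for p in pairs], axis=0)
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    if c.size < 3:
        raise ValidationError("threshold-linear fit needs >= 3 matched response pairs")
    res = stats.linregress(c, l)
    df = c.size - 2

    def t_pvalue(estimate: float, null: float, se: float) -> float:
        if se == 0 or math.isnan(se):
            return 0.0 if not np.isclose(estimate, null) else 1.0
        t = (estimate - null) / se
        return float(2 * stats.t.sf(abs(t), df))

    return GainFit(
        scope=scope,
        control=c,
        light=l,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope_ne_1=t_pvalue(res.slope, 1.0, res.stderr),
        p_intercept_ne_0=t_pvalue(res.intercept, 0.0, res.intercept_stderr),
        n_points=int(c.size),
    )
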