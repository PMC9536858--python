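"""Brief-access lick quantification and concentration-response fitting.

Licking in 5-s access trials is standardized per mouse and session by the
modal interlick interval (ILI): the standardized lick ratio (SLR) divides
the observed lick count by the maximum count the animal's own rhythm would
allow, which compensates for drug- or time-related changes in lick rate.
For the aversive stimulus, responses are instead expressed relative to the
session's mean water lick count. Concentration-response curves are fit with
the four-parameter logistic

    Y = Min + (Max - Min) / (1 + 10 ** ((LogEC50 - X) * HillSlope))

where X is log10(concentration); fitting uses multi-start nonlinear least
squares and reports a convergence flag instead of raising when no start
converges (some stimuli genuinely cannot be fit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import ttest_rel

from .core import LickSession, ValidationError

__all__ = [
    "LickMetrics",
    "LogisticFit",
    "modal_ili",
    "standardized_lick_ratio",
    "water_ratio",
    "fit_logistic",
    "logistic4",
    "lick_metrics",
    "bonferroni_paired",
]


def modal_ili(
    session: LickSession,
    band_ms: tuple[float, float] = (50.0, 250.0),
    bin_ms: float = 5.0,
    min_ilis: int = 100,
) -> float:
    """Modal interlick interval (ms) for one mouse and session.

    ILIs are pooled across trials, restricted to the within-burst band
    (excluding pauses and double-cranks), histogrammed at ``bin_ms``
    resolution, and the mode is the center of the tallest bin; ties break
    toward the smaller ILI.
    """
    ilis = np.concatenate([t.ilis for t in session.trials]) * 1000.0 if session.trials else np.array([])
    ilis = ilis[(ilis >= band_ms[0]) & (ilis <= band_ms[1])]
    if ilis.size < min_ilis:
        raise ValidationError(
            f"session {session.session_id}: only {ilis.size} in-band ILIs "
            f"(need >= {min_ilis})"
        )
    edges = np.arange(band_ms[0], band_ms[1] + bin_ms, bin_ms)
    counts, _ = np.histogram(ilis, bins=edges)
    mode_bin = int(np.argmax(counts))  # argmax takes the first (smallest) on ties
    return float(edges[mode_bin] + bin_ms / 2.0)


def standardized_lick_ratio(
    n_licks: int, access_dur_s: float, modal_ili_ms: float
) -> float:
    """Licks divided by the maximum possible at the modal ILI."""
    if modal_ili_ms <= 0:
        raise ValidationError("modal ILI must be > 0")
    max_licks = access_dur_s / (modal_ili_ms / 1000.0)
    return n_licks / max_licks


def water_ratio(quinine_licks, water_licks) -> float:
    """Mean licks at one quinine concentration over the session water mean.

    NaN (flagged by the caller) when no water licks occurred.
    """
    water_licks = np.asarray(water_licks, dtype=float)
    if water_licks.size == 0:
        raise ValidationError("water ratio needs >= 1 water trial")
    wmean = float(np.mean(water_licks))
    if wmean == 0:
        return float("nan")
    return float(np.mean(np.asarray(quinine_licks, dtype=float)) / wmean)


def lick_metrics(
    sessions: list[LickSession],
    measure: str = "slr",
    water_stimulus: str = "WATER",
    min_trials_per_stim: int = 2,
    **modal_kwargs,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-session, per-concentration lick metrics.

    ``measure`` is "slr" (standardized lick ratio; also reports the modal
    ILI used) or "water_ratio". Sessions in which the mouse sampled any
    stimulus on fewer than ``min_trials_per_stim`` trials are excluded; the
    second return value logs the exclusions.
    """
    rows, excluded = [], []
    for s in sessions:
        n_by_stim: dict[str, int] = {}
        for t in s.trials:
            n_by_stim[t.stimulus] = n_by_stim.get(t.stimulus, 0) + 1
        if any(n < min_trials_per_stim for n in n_by_stim.values()):
            excluded.append(
                f"{s.mouse_id}/{s.session_id}: fewer than {min_trials_per_stim} "
                "trials for some stimulus"
            )
            continue
        if measure == "slr":
            ili = modal_ili(s, **modal_kwargs)
        elif measure == "water_ratio":
            wlicks = [t.n_licks for t in s.trials if t.stimulus == water_stimulus]
            if not wlicks:
                excluded.append(f"{s.mouse_id}/{s.session_id}: no water trials")
                continue
        else:
            raise ValidationError(f"unknown measure {measure!r}")
        for stim in s.stimuli:
            if measure == "water_ratio" and stim == water_stimulus:
                continue
            concs = sorted({t.concentration for t in s.trials_for(stim)})
            for conc in concs:
                trials = s.trials_for(stim, conc)
                licks = [t.n_licks for t in trials]
                if measure == "slr":
                    vals = [
                        standardized_lick_ratio(t.n_licks, t.access_duration, ili)
                        for t in trials
                    ]
                    value = float(np.mean(vals))
                else:
                    value = water_ratio(licks, wlicks)
                    if math.isnan(value):
                        warnings.warn(
                            f"{s.mouse_id}/{s.session_id}: zero water licks; "
                            "water ratio undefined"
                        )
                rows.append(
                    {
                        "mouse_id": s.mouse_id,
                        "session_id": s.session_id,
                        "drug": s.drug,
                        "stimulus": stim,
                        "concentration": conc,
                        "n_trials": len(trials),
                        "mean_licks": float(np.mean(licks)),
                        "modal_ili_ms": ili if measure == "slr" else float("nan"),
                        measure: value,
                    }
                )
    cols = [
        "mouse_id", "session_id", "drug", "stimulus", "concentration",
        "n_trials", "mean_licks", "modal_ili_ms", measure,
    ]
    return pd.DataFrame(rows, columns=cols), excluded


def logistic4(x, minimum, maximum, log_ec50, hill):
    """Four-parameter concentration-response logistic; x = log10(conc)."""
    return minimum + (maximum - minimum) / (1.0 + 10.0 ** ((log_ec50 - x) * hill))


@dataclass
class LogisticFit:
    minimum: float
    maximum: float
    log_ec50: float
    hill_slope: float
    converged: bool
    residual_ss: float

    @property
    def ec50(self) -> float:
        return 10.0**self.log_ec50

    def predict(self, concentrations) -> np.ndarray:
        x = np.log10(np.asarray(concentrations, dtype=float))
        return logistic4(x, self.minimum, self.maximum, self.log_ec50, self.hill_slope)


def fit_logistic(
    concentrations,
    responses,
    n_logec50_starts: int = 4,
    hill_starts=(0.5, 1.0, 2.0, -0.5, -1.0, -2.0),
    maxfev: int = 2000,
) -> LogisticFit:
    """Multi-start nonlinear least-squares fit of the logistic equation.

    Min/Max start from the data extremes, LogEC50 starts span the tested
    concentration range, and Hill slopes of both signs are tried so that a
    monotone-decreasing series converges as readily as an increasing one.
    On total failure returns ``converged=False`` rather than raising.
    """
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(conc).size < 4:
        raise ValidationError("logistic fit needs >= 4 distinct concentrations")
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive (X is log10)")
    x = np.log10(conc)
    lo, hi = float(y.min()), float(y.max())
    grid = np.linspace(x.min(), x.max(), n_logec50_starts)
    best = None
    for le in grid:
        for h in hill_starts:
            p0 = (lo, hi, le, h)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(logistic4, x, y, p0=p0, maxfev=maxfev)
            except (RuntimeError, TypeError, ValueError):
                continue
            ss = float(np.sum((logistic4(x, *popt) - y) ** 2))
            if not np.all(np.isfinite(popt)):
                continue
            if best is None or ss < best[1]:
                best = (popt, ss)
    if best is None:
        return LogisticFit(
            minimum=float("nan"), maximum=float("nan"), log_ec50=float("nan"),
            hill_slope=float("nan"), converged=False, residual_ss=float("nan"),
        )
    (mn, mx, le, h), ss = best
    if mn > mx:  # canonical orientation: Min <= Max, sign absorbed by Hill
        mn, mx, h = mx, mn, -h
    return LogisticFit(
        minimum=float(mn), maximum=float(mx), log_ec50=float(le),
        hill_slope=float(h), converged=True, residual_ss=ss,
    )


def bonferroni_paired(
    table: pd.DataFrame,
    value: str,
    within: str = "concentration",
    between: str = "drug",
    subject: str = "mouse_id",
) -> pd.DataFrame:
    """Bonferroni-adjusted paired t tests at each concentration.

    Orchestration around standard paired tests (the inferential layer is
    delegated); the adjustment multiplies each raw p by the number of
    comparisons, capped at 1.
    """
    levels = sorted(table[within].unique())
    groups = sorted(table[between].unique())
    if len(groups) != 2:
        raise ValidationError("paired comparison needs exactly 2 groups")
    rows = []
    for lev in levels:
        sub = table[table[within] == lev]
        wide = sub.pivot_table(index=subject, columns=between, values=value)
        wide = wide.dropna()
        if len(wide) < 2:
            continue
        t, p = ttest_rel(wide[groups[0]], wide[groups[1]])
        rows.append({within: lev, "n": len(wide), "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out
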