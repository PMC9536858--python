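"""Trial-aligned net responses, the response criterion, and multiunit AUC.

A net taste response is the spike count during the stimulus window minus the
count during the matched prestimulus rinse window, averaged across trials.
The prestimulus baseline is computed separately for control trials and trials
with concurrent brain-light stimulation, because activating the inhibitory
network often lowers the spontaneous rate. A response is deemed significant
when the net evoked rate is at least ``rate_threshold`` (default 1 Hz, i.e.
10 spikes per 10-s window) AND at least ``sd_multiplier`` (default 2.5) times
the across-trial SD of the baseline counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import PulseTrain, SpikeTrain, StimulusPanel, TasteTrial, ValidationError

__all__ = [
    "NetResponse",
    "ResponseProfile",
    "CriterionError",
    "net_response",
    "lightm_net_response",
    "apply_criterion",
    "compute_profile",
    "multiunit_auc",
    "normalize_to_max",
]


class CriterionError(ValueError):
    """The response criterion could not be evaluated."""


@dataclass
class NetResponse:
    """Mean net response of one unit to one stimulus under one condition.

    Units are spikes per analysis window (10 s for taste, 2 s for
    mouth-light). ``baseline_sd`` is the sample SD of the per-trial baseline
    counts and is NaN when only a single trial was run. ``significant`` is
    ``None`` until the criterion has been evaluated. ``manual_override``
    marks a response admitted by hand despite failing the criterion (the
    procedure allows documented exceptions, e.g. a delayed bitter response);
    it is never set automatically.
    """

    unit_id: str
    stimulus: str
    light_condition: str
    net: float
    n_trials: int
    window_s: float
    baseline_mean: float
    baseline_sd: float
    significant: bool | None = None
    manual_override: bool = False

    @property
    def net_rate_hz(self) -> float:
        return self.net / self.window_s

    @property
    def sd_defined(self) -> bool:
        return not math.isnan(self.baseline_sd)


def _counts(spikes: SpikeTrain, trials: list[TasteTrial], span=None):
    stim = np.empty(len(trials))
    pre = np.empty(len(trials))
    for i, tr in enumerate(trials):
        if span is not None:
            lo, hi = span
            for name, (w0, w1) in (("stimulus", tr.stim_window), ("prestim", tr.prestim_window)):
                if w0 < lo - 1e-9 or w1 > hi + 1e-9:
                    raise ValidationError(
                        f"trial {tr.trial_id}: {name} window [{w0}, {w1}) outside "
                        f"recording span [{lo}, {hi})"
                    )
        stim[i] = spikes.count_between(*tr.stim_window)
        pre[i] = spikes.count_between(*tr.prestim_window)
    return stim, pre


def net_response(
    spikes: SpikeTrain,
    trials: list[TasteTrial],
    recording_span: tuple[float, float] | None = None,
) -> NetResponse:
    """Net response for one unit x stimulus x light condition.

    All trials must share stimulus and light condition. If
    ``recording_span`` is given, a trial whose window falls outside it is an
    error (naming the trial).
    """
    if not trials:
        raise ValidationError("net_response requires at least one trial")
    stimuli = {t.stimulus for t in trials}
    conds = {t.light_condition for t in trials}
    if len(stimuli) != 1 or len(conds) != 1:
        raise ValidationError(
            "trials passed to net_response must share stimulus and light condition"
        )
    durs = {t.stimulus_duration for t in trials}
    if len(durs) != 1:
        raise ValidationError("trials must share stimulus duration")
    stim, pre = _counts(spikes, trials, recording_span)
    net = float(np.mean(stim - pre))
    sd = float(np.std(pre, ddof=1)) if len(trials) >= 2 else float("nan")
    return NetResponse(
        unit_id=spikes.unit_id,
        stimulus=stimuli.pop(),
        light_condition=conds.pop(),
        net=net,
        n_trials=len(trials),
        window_s=durs.pop(),
        baseline_mean=float(np.mean(pre)),
        baseline_sd=sd,
    )


def lightm_net_response(
    spikes: SpikeTrain,
    trains: list[PulseTrain],
    window_s: float = 2.0,
) -> NetResponse:
    """Net mouth-light response against an equal-length spontaneous window.

    The artificial-saliva rinse does not flow during mouth-light trains, so
    the baseline is the unstimulated period of the same length immediately
    preceding each train. Repeated trains at the same nominal frequency and
    light condition count as trials.
    """
    if not trains:
        raise ValidationError("lightm_net_response requires at least one train")
    freqs = {t.nominal_frequency for t in trains}
    conds = {t.light_condition for t in trains}
    if len(freqs) != 1 or len(conds) != 1:
        raise ValidationError("trains must share nominal frequency and light condition")
    stim = np.empty(len(trains))
    pre = np.empty(len(trains))
    for i, tr in enumerate(trains):
        if tr.target != "mouth":
            raise ValidationError(f"train {tr.train_id} is not a mouth train")
        t0 = tr.pulse_onsets[0]
        stim[i] = spikes.count_between(t0, t0 + window_s)
        pre[i] = spikes.count_between(t0 - window_s, t0)
    sd = float(np.std(pre, ddof=1)) if len(trains) >= 2 else float("nan")
    return NetResponse(
        unit_id=spikes.unit_id,
        stimulus=f"light_m_{freqs.pop():g}Hz",
        light_condition=conds.pop(),
        net=float(np.mean(stim - pre)),
        n_trials=len(trains),
        window_s=window_s,
        baseline_mean=float(np.mean(pre)),
        baseline_sd=sd,
    )


def apply_criterion(
    net: NetResponse,
    rate_threshold_hz: float = 1.0,
    sd_multiplier: float = 2.5,
    fallback_sd: float | None = None,
) -> bool:
    """Joint response criterion; sets and returns ``net.significant``.

    A single-trial response has no across-trial SD; evaluating it without an
    explicit ``fallback_sd`` raises rather than silently passing.
    """
    sd = net.baseline_sd
    if math.isnan(sd):
        if fallback_sd is None:
            raise CriterionError(
                f"{net.unit_id}/{net.stimulus}: baseline SD undefined (n=1) and no "
                "fallback SD configured"
            )
        sd = fallback_sd
    passed = (net.net >= rate_threshold_hz * net.window_s) and (
        net.net >= sd_multiplier * sd
    )
    net.significant = bool(passed)
    return net.significant


@dataclass
class ResponseProfile:
    """Per-stimulus net responses of one unit for each light condition."""

    unit_id: str
    panel: StimulusPanel
    responses: dict[tuple[str, str], NetResponse] = field(default_factory=dict)
    spontaneous_rate: float = float("nan")

    def get(self, stimulus: str, condition: str) -> NetResponse | None:
        return self.responses.get((stimulus, condition))

    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({c for (_, c) in self.responses}))

    def vector(self, condition: str, stimuli=None) -> np.ndarray:
        """Net responses in panel order; missing stimuli are NaN."""
        stimuli = tuple(stimuli) if stimuli is not None else self.panel.labels
        out = np.full(len(stimuli), np.nan)
        for i, s in enumerate(stimuli):
            r = self.responses.get((s, condition))
            if r is not None:
                out[i] = r.net
        return out

    def best_stimulus(self, condition: str) -> str:
        """Stimulus with the maximum net response; ties break by panel order."""
        best, best_net = None, -np.inf
        for s in self.panel.labels:
            r = self.responses.get((s, condition))
            if r is not None and r.net > best_net:
                best, best_net = s, r.net
        if best is None:
            raise ValidationError(f"{self.unit_id}: no responses for {condition!r}")
        return best

    def n_significant(self, condition: str) -> int:
        return sum(
            1
            for (s, c), r in self.responses.items()
            if c == condition and (r.significant or r.manual_override)
        )


def compute_profile(
    spikes: SpikeTrain,
    trials: list[TasteTrial],
    panel: StimulusPanel,
    rate_threshold_hz: float = 1.0,
    sd_multiplier: float = 2.5,
    fallback_sd: float | None = None,
) -> ResponseProfile:
    """Net responses and significance flags for every stimulus x condition.

    The spontaneous rate is estimated from the control-condition prestimulus
    windows (spikes per second).
    """
    unknown = {t.stimulus for t in trials} - set(panel.labels)
    if unknown:
        raise ValidationError(f"{spikes.unit_id}: trials use unknown stimuli {sorted(unknown)}")
    profile = ResponseProfile(unit_id=spikes.unit_id, panel=panel)
    groups: dict[tuple[str, str], list[TasteTrial]] = {}
    for t in trials:
        groups.setdefault((t.stimulus, t.light_condition), []).append(t)
    for key, grp in groups.items():
        nr = net_response(spikes, grp)
        apply_criterion(nr, rate_threshold_hz, sd_multiplier, fallback_sd)
        profile.responses[key] = nr
    ctrl_pre = [
        (spikes.count_between(*t.prestim_window), t.prestim_duration)
        for t in trials
        if t.light_condition == "control"
    ]
    if ctrl_pre:
        counts, durs = zip(*ctrl_pre)
        profile.spontaneous_rate = float(np.sum(counts) / np.sum(durs))
    return profile


def multiunit_auc(
    activity,
    stim_window: tuple[float, float],
    baseline_window: tuple[float, float],
    tau: float = 0.1,
    bin_s: float = 0.01,
    binned: bool = False,
) -> float:
    """Baseline-adjusted area under a leaky-integrated activity trace.

    ``activity`` is a spike-time array (binned internally at ``bin_s``), or,
    with ``binned=True``, a pre-binned count trace starting at t = 0 with bin
    width ``bin_s``. Counts are passed through a first-order exponential
    integrator with time constant ``tau`` and the area under the integrated
    trace is summed over each window; the result is AUC(stim) minus
    AUC(baseline) scaled to the stimulus-window length. Linear in the input
    counts.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    s0, s1 = stim_window
    b0, b1 = baseline_window
    if s1 <= s0 or b1 <= b0:
        raise ValidationError("windows must have positive duration")
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 1:
        raise ValidationError("activity must be one-dimensional")
    t_end = max(s1, b1)
    n_bins = int(np.ceil(t_end / bin_s)) + 1
    if binned:
        counts = activity
        if counts.size < n_bins:
            raise ValidationError("binned trace does not cover both windows")
    else:
        counts = np.bincount(
            np.minimum((activity / bin_s).astype(int), n_bins - 1), minlength=n_bins
        ).astype(float)
    decay = math.exp(-bin_s / tau)
    # first-order IIR: y[i] = decay * y[i-1] + c[i]
    integ = lfilter([1.0], [1.0, -decay], counts)
    times = np.arange(counts.size) * bin_s

    def window_auc(w0, w1):
        sel = (times >= w0) & (times < w1)
        return float(np.sum(integ[sel]) * bin_s)

    stim_auc = window_auc(s0, s1)
    base_auc = window_auc(b0, b1) * (s1 - s0) / (b1 - b0)
    return stim_auc - base_auc


def normalize_to_max(responses) -> np.ndarray:
    """Normalize a group of responses to its maximum (maps the max to 1.0)."""
    arr = np.asarray(responses, dtype=float)
    peak = np.nanmax(arr)
    if peak <= 0:
        raise ValidationError("maximum response must be positive for normalization")
    return arr / peak
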