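"""Synthetic spike-train and lick-session generator with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised and parameter recovery verified
without recorded data:

* baseline and taste-evoked firing are piecewise-homogeneous Poisson;
* three neuron classes: non-GABA taste cells (G-TASTE), GABA taste cells
  (G+TASTE) firing at a fraction (default 0.37) of G-TASTE rates, and GABA
  cells unresponsive to oral stimuli (G+UNR) with near-zero spontaneous
  activity;
* ChR2-expressing units follow each brain-light pulse independently with a
  per-pulse probability, spiking at a normally distributed latency
  (defaults 5.9 ms mean, 0.72 ms SD, 0.96 follow);
* activating the GABA network multiplies evoked rates by a gain g in [0, 1]
  and optionally subtracts an offset (rates clamp at zero with a warning),
  with the spontaneous rate suppressed separately;
* mouth-light trains entrain spikes with a frequency-dependent follow
  probability that rises, saturates near 10-20 Hz, and declines;
* lick trains are rhythmic at a per-mouse modal interlick interval, with
  per-trial counts following a logistic concentration-response.

Determinism: one master seed; each unit/mouse draws from its own derived
substream, so adding a neuron does not perturb the others, and identical
(specs, seed) give byte-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .behavior import logistic4
from .core import (
    LickSession,
    LickTrial,
    PulseTrain,
    SpikeTrain,
    StimulusPanel,
    TasteTrial,
    ValidationError,
)

__all__ = [
    "NeuronSpec",
    "LickSpec",
    "GroundTruth",
    "SessionResult",
    "standard_plan",
    "simulate_session",
    "simulate_optotag_block",
    "simulate_lightm_series",
    "simulate_lick_study",
    "default_mouth_follow",
    "gminus_taste",
    "gplus_taste",
    "gplus_unr",
    "default_population",
    "sucrose_lick_spec",
]

CELL_CLASSES = ("G_minus_taste", "G_plus_taste", "G_plus_unr")

# Chemosensitive templates: relative evoked rates over (SUC, MSGai, NaCl,
# CIT, BIT), one per cluster reported for non-GABA taste cells.
PROFILE_TEMPLATES = {
    "SWEET_UMAMI": (1.0, 0.8, 0.15, 0.1, 0.05),
    "NA": (0.1, 0.3, 1.0, 0.25, 0.05),
    "EG": (0.1, 0.8, 0.9, 1.0, 0.1),
    "BIT": (0.05, 0.05, 0.1, 0.15, 1.0),
}
# Cluster mix among G-TASTE cells, proportional to reported cluster sizes.
PROFILE_MIX = {"SWEET_UMAMI": 24, "NA": 14, "EG": 13, "BIT": 3}


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one simulated unit."""

    unit_id: str
    cell_class: str
    spontaneous_rate: float
    evoked_rate: dict[str, float]
    chr2: bool
    tag_latency_mean_ms: float = 5.9
    tag_jitter_sd_ms: float = 0.72
    follow_prob: float = 0.96
    inhibition_gain: float = 1.0  # multiplicative g on evoked rate under light_br
    inhibition_offset_hz: float = 0.0  # subtractive beta under light_br
    spont_gain: float | None = None  # defaults to inhibition_gain

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(f"{self.unit_id}: unknown cell class {self.cell_class!r}")
        if self.spontaneous_rate < 0 or any(v < 0 for v in self.evoked_rate.values()):
            raise ValidationError(f"{self.unit_id}: rates must be >= 0")
        if not 0.0 <= self.inhibition_gain <= 1.0:
            raise ValidationError(f"{self.unit_id}: inhibition_gain must be in [0, 1]")
        if not 0.0 <= self.follow_prob <= 1.0:
            raise ValidationError(f"{self.unit_id}: follow_prob must be in [0, 1]")
        if self.cell_class == "G_plus_unr" and any(
            v != 0 for v in self.evoked_rate.values()
        ):
            raise ValidationError(f"{self.unit_id}: G_plus_unr must have zero evoked rates")

    @property
    def effective_spont_gain(self) -> float:
        return self.inhibition_gain if self.spont_gain is None else self.spont_gain


def gminus_taste(unit_id, evoked, spont=1.2, g=0.5, beta=0.0, **kw) -> NeuronSpec:
    """Non-GABA taste cell: no ChR2, suppressed under brain light."""
    return NeuronSpec(
        unit_id=unit_id, cell_class="G_minus_taste", spontaneous_rate=spont,
        evoked_rate=dict(evoked), chr2=False, follow_prob=0.0,
        inhibition_gain=g, inhibition_offset_hz=beta, **kw,
    )


def gplus_taste(unit_id, evoked, spont=0.5, **kw) -> NeuronSpec:
    """GABA taste cell: ChR2-tagged, weaker taste responses."""
    return NeuronSpec(
        unit_id=unit_id, cell_class="G_plus_taste", spontaneous_rate=spont,
        evoked_rate=dict(evoked), chr2=True, **kw,
    )


def gplus_unr(unit_id, spont=0.05, **kw) -> NeuronSpec:
    """GABA cell unresponsive to oral stimuli; often silent at rest."""
    return NeuronSpec(
        unit_id=unit_id, cell_class="G_plus_unr", spontaneous_rate=spont,
        evoked_rate={}, chr2=True, **kw,
    )


def default_population(
    panel: StimulusPanel,
    n_gminus: int = 54,
    n_gplus_taste: int = 12,
    n_gplus_unr: int = 19,
    best_rate_hz: float = 5.0,
    best_rate_cv: float = 0.4,
    gplus_scale: float = 0.37,
    g: float = 0.5,
    beta: float = 0.0,
    seed: int = 0,
) -> list[NeuronSpec]:
    """A population with the calibration defaults of the study conditions.

    G-TASTE cells draw a best evoked rate around ``best_rate_hz`` (lognormal
    with the given CV) on a chemosensitive template sampled from the
    reported cluster mix; G+TASTE cells use the same templates scaled by
    ``gplus_scale`` (their mean responses run ~37% of G-TASTE). Spontaneous
    rates default to ~1.2 Hz for G-TASTE (the rinse-period firing scale),
    lower for GABA classes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    names = list(PROFILE_MIX)
    weights = np.array([PROFILE_MIX[n] for n in names], dtype=float)
    weights /= weights.sum()
    sigma = np.sqrt(np.log(1 + best_rate_cv**2))
    mu = np.log(best_rate_hz) - sigma**2 / 2

    def draw_profile(scale=1.0):
        template = PROFILE_TEMPLATES[rng.choice(names, p=weights)]
        best = rng.lognormal(mu, sigma) * scale
        jitter = rng.uniform(0.85, 1.15, size=len(template))
        return {s: best * t * j for s, t, j in zip(panel.labels, template, jitter)}

    specs: list[NeuronSpec] = []
    for i in range(n_gminus):
        specs.append(gminus_taste(f"gm{i:03d}", draw_profile(), g=g, beta=beta))
    for i in range(n_gplus_taste):
        specs.append(gplus_taste(f"gt{i:03d}", draw_profile(gplus_scale)))
    for i in range(n_gplus_unr):
        specs.append(gplus_unr(f"gu{i:03d}"))
    return specs


@dataclass
class GroundTruth:
    """Full parameter record; sufficient to regenerate a dataset exactly."""

    seed: int
    neurons: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(seed=obj["seed"], neurons=obj["neurons"], extras=obj.get("extras", {}))


@dataclass
class SessionResult:
    spikes: dict[str, SpikeTrain]
    trials: dict[str, list[TasteTrial]]
    pulses: list[PulseTrain]
    ground_truth: GroundTruth


def standard_plan(
    panel: StimulusPanel,
    n_reps: int = 2,
    light_conditions=("control", "light_br"),
) -> list[tuple[str, str]]:
    """Replication plan: every stimulus x light condition, n_reps times."""
    return [
        (s, cond)
        for s in panel.labels
        for cond in light_conditions
        for _ in range(n_reps)
    ]


def _unit_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _poisson_times(rng, rate: float, t0: float, dur: float) -> np.ndarray:
    if rate <= 0 or dur <= 0:
        return np.empty(0)
    n = rng.poisson(rate * dur)
    return t0 + np.sort(rng.random(n)) * dur


def _locked_spikes(rng, onsets, follow_prob, latency_ms, jitter_ms) -> np.ndarray:
    hit = rng.random(len(onsets)) < follow_prob
    lat = rng.normal(latency_ms, jitter_ms, size=len(onsets)) / 1000.0
    return (np.asarray(onsets) + np.maximum(lat, 0.0))[hit]


def _finalize(unit_id: str, segments: list[np.ndarray], refractory_s: float) -> SpikeTrain:
    if segments:
        ts = np.sort(np.concatenate(segments))
    else:
        ts = np.empty(0)
    if refractory_s > 0 and ts.size > 1:
        keep = [0]
        last = ts[0]
        for i in range(1, ts.size):
            if ts[i] - last >= refractory_s:
                keep.append(i)
                last = ts[i]
        ts = ts[keep]
    return SpikeTrain(unit_id, ts)


def _suppressed_evoked(spec: NeuronSpec, stimulus: str) -> float:
    evoked = spec.evoked_rate.get(stimulus, 0.0)
    rate = spec.inhibition_gain * evoked - spec.inhibition_offset_hz
    if rate < 0:
        warnings.warn(
            f"{spec.unit_id}/{stimulus}: suppressed evoked rate clamped at 0",
            stacklevel=2,
        )
        rate = 0.0
    return rate


def simulate_session(
    neuron_specs: list[NeuronSpec],
    panel: StimulusPanel,
    trial_plan: list[tuple[str, str]],
    seed: int,
    prestim_s: float = 10.0,
    stim_s: float = 10.0,
    iti_s: float = 5.0,
    light_pulse_hz: float = 10.0,
    pulse_width_s: float = 0.005,
    light_covers_prestim: bool = True,
    refractory_s: float = 0.001,
) -> SessionResult:
    """Simulate taste trials for each unit recorded on its own timeline.

    Each trial is a prestimulus rinse window followed by the stimulus
    window. Under brain light the evoked rate becomes
    max(0, g * evoked - beta) and the spontaneous rate is multiplied by the
    (separately configurable) spontaneous gain; light spans the prestimulus
    window too by default, since light-condition baselines are measured
    separately. ChR2 units additionally follow each brain pulse with their
    per-pulse probability. Identical inputs give identical output.
    """
    unknown = {s for s, _ in trial_plan} - set(panel.labels)
    if unknown:
        raise ValidationError(f"trial plan uses unknown stimuli {sorted(unknown)}")
    spikes: dict[str, SpikeTrain] = {}
    trials: dict[str, list[TasteTrial]] = {}
    pulses: list[PulseTrain] = []
    for k, spec in enumerate(neuron_specs):
        rng = _unit_rng(seed, k)
        segs: list[np.ndarray] = []
        unit_trials: list[TasteTrial] = []
        t = iti_s
        for j, (stim, cond) in enumerate(trial_plan):
            light = cond == "light_br"
            pre0, stim0 = t, t + prestim_s
            sg = spec.effective_spont_gain
            pre_rate = spec.spontaneous_rate * (sg if light and light_covers_prestim else 1.0)
            evoked = (
                _suppressed_evoked(spec, stim)
                if light
                else spec.evoked_rate.get(stim, 0.0)
            )
            stim_rate = spec.spontaneous_rate * (sg if light else 1.0) + evoked
            segs.append(_poisson_times(rng, pre_rate, pre0, prestim_s))
            segs.append(_poisson_times(rng, stim_rate, stim0, stim_s))
            segs.append(_poisson_times(rng, spec.spontaneous_rate, stim0 + stim_s, iti_s))
            if light:
                span0 = pre0 if light_covers_prestim else stim0
                onsets = np.arange(span0, stim0 + stim_s - 1e-9, 1.0 / light_pulse_hz)
                pulses.append(
                    PulseTrain(
                        train_id=f"{spec.unit_id}_br{j:03d}",
                        unit_id=spec.unit_id,
                        pulse_onsets=onsets,
                        nominal_frequency=light_pulse_hz,
                        target="brain",
                        pulse_width=pulse_width_s,
                        light_condition="light_br",
                    )
                )
                if spec.chr2:
                    segs.append(
                        _locked_spikes(
                            rng, onsets, spec.follow_prob,
                            spec.tag_latency_mean_ms, spec.tag_jitter_sd_ms,
                        )
                    )
            unit_trials.append(
                TasteTrial(
                    trial_id=f"{spec.unit_id}_t{j:03d}",
                    stimulus=stim,
                    stimulus_onset=stim0,
                    stimulus_duration=stim_s,
                    prestim_onset=pre0,
                    prestim_duration=prestim_s,
                    light_condition=cond,
                )
            )
            t = stim0 + stim_s + iti_s
        spikes[spec.unit_id] = _finalize(spec.unit_id, segs, refractory_s)
        trials[spec.unit_id] = unit_trials
    gt = GroundTruth(
        seed=seed,
        neurons=[asdict(s) for s in neuron_specs],
        extras={
            "trial_plan": trial_plan,
            "prestim_s": prestim_s,
            "stim_s": stim_s,
            "light_pulse_hz": light_pulse_hz,
            "light_covers_prestim": light_covers_prestim,
        },
    )
    return SessionResult(spikes=spikes, trials=trials, pulses=pulses, ground_truth=gt)


def simulate_optotag_block(
    spec: NeuronSpec,
    seed: int,
    frequencies=(1.0, 4.0, 10.0, 20.0, 50.0),
    n_pulses: int = 20,
    gap_s: float = 2.0,
    pulse_width_s: float = 0.005,
    refractory_s: float = 0.001,
    stream_key: int = 0,
    t_start: float = 0.0,
) -> tuple[SpikeTrain, list[PulseTrain]]:
    """Brain-light pulse series (20 pulses per frequency) for tagging.

    ChR2 units follow pulses with their per-pulse probability at their
    configured latency and jitter; non-ChR2 units only show (possibly
    suppressed) spontaneous activity during the trains.
    """
    if not len(frequencies):
        raise ValidationError("frequencies must be non-empty")
    rng = _unit_rng(seed, 7, stream_key)
    segs: list[np.ndarray] = []
    trains: list[PulseTrain] = []
    t = t_start + gap_s
    for i, hz in enumerate(frequencies):
        dur = n_pulses / hz
        onsets = t + np.arange(n_pulses) / hz
        trains.append(
            PulseTrain(
                train_id=f"{spec.unit_id}_tag{i:02d}",
                unit_id=spec.unit_id,
                pulse_onsets=onsets,
                nominal_frequency=float(hz),
                target="brain",
                pulse_width=pulse_width_s,
                light_condition="control",
            )
        )
        base = spec.spontaneous_rate * (1.0 if spec.chr2 else spec.effective_spont_gain)
        segs.append(_poisson_times(rng, base, t, dur))
        if spec.chr2:
            segs.append(
                _locked_spikes(
                    rng, onsets, spec.follow_prob,
                    spec.tag_latency_mean_ms, spec.tag_jitter_sd_ms,
                )
            )
        segs.append(_poisson_times(rng, spec.spontaneous_rate, t + dur, gap_s))
        t += dur + gap_s
    return _finalize(spec.unit_id, segs, refractory_s), trains


def default_mouth_follow(freq_hz: float, p_max: float = 0.85, f_half: float = 25.0, power: float = 2.0) -> float:
    """Per-pulse follow probability for mouth light as a function of frequency.

    Entrained counts (freq x duration x p) rise with frequency, saturate
    near 10-20 Hz and decline above, matching the shape of graded
    taste-bud photostimulation responses.
    """
    return p_max / (1.0 + (freq_hz / f_half) ** power)


def simulate_lightm_series(
    spec: NeuronSpec,
    seed: int,
    frequencies=(2.0, 5.0, 10.0, 20.0, 50.0),
    duration_s: float = 2.0,
    conditions=("control", "light_br"),
    follow_curve=default_mouth_follow,
    latency_ms: float = 8.0,
    jitter_ms: float = 1.5,
    gap_s: float = 4.0,
    pulse_width_s: float = 0.005,
    refractory_s: float = 0.001,
) -> tuple[SpikeTrain, list[PulseTrain]]:
    """Mouth-light frequency series for one unit, per light condition.

    Each 2-s train entrains spikes with probability follow_curve(freq),
    scaled by the inhibition gain (minus the subtractive offset expressed
    as an equivalent per-pulse probability) under brain light. Baseline
    gaps before each train support the spontaneous comparison window.
    """
    if not len(frequencies):
        raise ValidationError("frequencies must be non-empty")
    rng = _unit_rng(seed, 11)
    segs: list[np.ndarray] = []
    trains: list[PulseTrain] = []
    t = gap_s
    i = 0
    for cond in conditions:
        light = cond == "light_br"
        for hz in frequencies:
            n = max(int(np.floor(duration_s * hz)), 1)
            onsets = t + np.arange(n) / hz
            trains.append(
                PulseTrain(
                    train_id=f"{spec.unit_id}_m{i:02d}",
                    unit_id=spec.unit_id,
                    pulse_onsets=onsets,
                    nominal_frequency=float(hz),
                    target="mouth",
                    pulse_width=pulse_width_s,
                    light_condition=cond,
                )
            )
            p = follow_curve(hz)
            spont = spec.spontaneous_rate
            if light:
                p = max(0.0, spec.inhibition_gain * p - spec.inhibition_offset_hz / max(hz, 1e-9))
                spont = spont * spec.effective_spont_gain
            segs.append(_locked_spikes(rng, onsets, p, latency_ms, jitter_ms))
            segs.append(_poisson_times(rng, spont, t, duration_s))
            segs.append(_poisson_times(rng, spec.spontaneous_rate, t + duration_s, gap_s))
            t += duration_s + gap_s
            i += 1
    return _finalize(spec.unit_id, segs, refractory_s), trains


@dataclass
class LickSpec:
    """Ground-truth licking parameters for one simulated mouse."""

    mouse_id: str
    logistic_params: dict[str, tuple[float, float, float, float]]  # drug -> (Min, Max, LogEC50, Hill)
    modal_ili_ms: float = 115.5
    ili_sd_ms: float = 12.0
    slr_sigma: float = 0.05
    water_slr: float = 0.95
    pause_prob: float = 0.0
    pause_range_ms: tuple[float, float] = (300.0, 1000.0)

    def __post_init__(self) -> None:
        if self.modal_ili_ms <= 0:
            raise ValidationError(f"{self.mouse_id}: modal ILI must be > 0")
        for drug, (mn, mx, _, _) in self.logistic_params.items():
            if mn > mx:
                raise ValidationError(f"{self.mouse_id}/{drug}: Min must be <= Max")


def sucrose_lick_spec(
    mouse_id: str,
    cno_log_shift: float | None = None,
    minimum: float = 0.05,
    maximum: float = 0.95,
    saline_ec50: float = 228.0,
    cno_ec50: float = 252.0,
    hill: float = 1.5,
    **kw,
) -> LickSpec:
    """Sucrose-like spec; EC50 defaults 228 mM (saline) and 252 mM (CNO).

    ``cno_log_shift`` overrides the CNO curve as saline LogEC50 plus a
    fixed log10 shift.
    """
    log_sal = np.log10(saline_ec50)
    log_cno = log_sal + cno_log_shift if cno_log_shift is not None else np.log10(cno_ec50)
    return LickSpec(
        mouse_id=mouse_id,
        logistic_params={
            "saline": (minimum, maximum, float(log_sal), hill),
            "CNO": (minimum, maximum, float(log_cno), hill),
        },
        **kw,
    )


def _lick_times(rng, spec: LickSpec, n_licks: int) -> np.ndarray:
    if n_licks <= 0:
        return np.empty(0)
    ilis = rng.normal(spec.modal_ili_ms, spec.ili_sd_ms, size=n_licks - 1)
    ilis = np.maximum(ilis, 50.0 + 1e-6)  # truncate below the burst floor
    if spec.pause_prob > 0:
        pause = rng.random(ilis.size) < spec.pause_prob
        ilis[pause] = rng.uniform(*spec.pause_range_ms, size=int(pause.sum()))
    return np.concatenate([[0.0], np.cumsum(ilis) / 1000.0])


def simulate_lick_study(
    lick_specs: list[LickSpec],
    stimulus: str,
    concentrations,
    conc_units: str,
    seed: int,
    n_trials: int = 2,
    n_sessions_per_drug: int = 2,
    access_dur_s: float = 5.0,
    include_water: bool = False,
    n_water_trials: int = 2,
    drugs=("saline", "CNO"),
) -> tuple[list[LickSession], GroundTruth]:
    """Brief-access study: each stimulus tested per drug in repeat sessions.

    Per trial the target standardized lick ratio is the mouse's logistic
    evaluated at log10(concentration) plus Gaussian noise (sd
    ``slr_sigma``), clipped to [0, 1.05]; the lick count is the target
    times the maximum licks the modal ILI allows in the access window, and
    timestamps are rhythmic at that ILI. Water trials (for the
    water-relative measure of aversive stimuli) use the ``water_slr``
    target.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ValidationError("concentrations must be non-empty")
    sessions: list[LickSession] = []
    for mi, spec in enumerate(lick_specs):
        for di, drug in enumerate(drugs):
            if drug not in spec.logistic_params:
                raise ValidationError(f"{spec.mouse_id}: no logistic params for {drug!r}")
            params = spec.logistic_params[drug]
            for rep in range(n_sessions_per_drug):
                rng = _unit_rng(seed, mi, di, rep)
                trials: list[LickTrial] = []
                ti = 0
                for conc in concentrations:
                    for _ in range(n_trials):
                        target = logistic4(np.log10(conc), *params)
                        slr = float(np.clip(target + rng.normal(0, spec.slr_sigma), 0.0, 1.05))
                        n = int(round(slr * access_dur_s / (spec.modal_ili_ms / 1000.0)))
                        trials.append(
                            LickTrial(
                                trial_id=f"{spec.mouse_id}_{drug}{rep}_{ti:03d}",
                                stimulus=stimulus,
                                concentration=float(conc),
                                conc_units=conc_units,
                                lick_times=_lick_times(rng, spec, n),
                                access_duration=access_dur_s,
                            )
                        )
                        ti += 1
                if include_water:
                    for _ in range(n_water_trials):
                        slr = float(np.clip(spec.water_slr + rng.normal(0, spec.slr_sigma), 0.0, 1.05))
                        n = int(round(slr * access_dur_s / (spec.modal_ili_ms / 1000.0)))
                        trials.append(
                            LickTrial(
                                trial_id=f"{spec.mouse_id}_{drug}{rep}_{ti:03d}",
                                stimulus="WATER",
                                concentration=0.0,
                                conc_units="n/a",
                                lick_times=_lick_times(rng, spec, n),
                                access_duration=access_dur_s,
                            )
                        )
                        ti += 1
                sessions.append(
                    LickSession(
                        mouse_id=spec.mouse_id,
                        session_id=f"{spec.mouse_id}_{drug}{rep}",
                        drug=drug,
                        trials=trials,
                    )
                )
    gt = GroundTruth(
        seed=seed,
        neurons=[],
        extras={
            "lick_specs": [asdict(s) for s in lick_specs],
            "stimulus": stimulus,
            "concentrations": [float(c) for c in concentrations],
            "n_trials": n_trials,
            "n_sessions_per_drug": n_sessions_per_drug,
        },
    )
    return sessions, gt
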