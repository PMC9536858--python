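"""Domain containers for spike, trial, pulse and lick data.

All times are seconds from the start of the recording session, stored as
plain floats; there is no wall-clock handling. Containers validate their
invariants on construction and raise :class:`ValidationError` on violation,
so any object that exists is well formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "LIGHT_CONDITIONS",
    "SpikeTrain",
    "TasteTrial",
    "PulseTrain",
    "StimulusPanel",
    "LickTrial",
    "LickSession",
]

LIGHT_CONDITIONS = ("control", "light_br")
PULSE_TARGETS = ("brain", "mouth")


class ValidationError(ValueError):
    """A container invariant was violated."""


def _as_time_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if arr.size and arr.min() < 0:
        raise ValidationError(f"{name} contains negative times")
    return arr


@dataclass
class SpikeTrain:
    """Action-potential timestamps of one unit for one session."""

    unit_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = _as_time_array(self.timestamps, f"{self.unit_id} timestamps")
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            raise ValidationError(f"{self.unit_id} timestamps are not sorted")
        self.timestamps = ts

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def count_between(self, t0: float, t1: float) -> int:
        """Number of spikes in the half-open window [t0, t1)."""
        lo, hi = np.searchsorted(self.timestamps, [t0, t1], side="left")
        return int(hi - lo)

    def rate_between(self, t0: float, t1: float) -> float:
        if t1 <= t0:
            raise ValidationError("window must have positive duration")
        return self.count_between(t0, t1) / (t1 - t0)


@dataclass
class TasteTrial:
    """One taste delivery with its matched prestimulus rinse window.

    The prestimulus window (artificial-saliva rinse) is carried explicitly
    rather than derived from inter-trial timing, so irregular intervals
    between stimulations need no reconstruction.
    """

    trial_id: str
    stimulus: str
    stimulus_onset: float
    stimulus_duration: float = 10.0
    prestim_onset: float = None  # type: ignore[assignment]
    prestim_duration: float = 10.0
    light_condition: str = "control"

    def __post_init__(self) -> None:
        if self.prestim_onset is None:
            self.prestim_onset = self.stimulus_onset - self.prestim_duration
        if self.stimulus_duration <= 0 or self.prestim_duration <= 0:
            raise ValidationError(f"trial {self.trial_id}: durations must be > 0")
        if self.prestim_onset < 0 or self.stimulus_onset < 0:
            raise ValidationError(f"trial {self.trial_id}: negative onset")
        if self.prestim_onset + self.prestim_duration > self.stimulus_onset + 1e-9:
            raise ValidationError(
                f"trial {self.trial_id}: prestimulus window ends after stimulus onset"
            )
        if self.light_condition not in LIGHT_CONDITIONS:
            raise ValidationError(
                f"trial {self.trial_id}: unknown light_condition "
                f"{self.light_condition!r}"
            )

    @property
    def stim_window(self) -> tuple[float, float]:
        return (self.stimulus_onset, self.stimulus_onset + self.stimulus_duration)

    @property
    def prestim_window(self) -> tuple[float, float]:
        return (self.prestim_onset, self.prestim_onset + self.prestim_duration)


@dataclass
class PulseTrain:
    """A train of light pulses delivered to the brain or the mouth."""

    train_id: str
    unit_id: str
    pulse_onsets: np.ndarray
    nominal_frequency: float
    target: str = "brain"
    pulse_width: float = 0.005
    light_condition: str = "control"

    def __post_init__(self) -> None:
        onsets = _as_time_array(self.pulse_onsets, f"{self.train_id} pulse_onsets")
        if onsets.size == 0:
            raise ValidationError(f"train {self.train_id}: no pulses")
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValidationError(
                f"train {self.train_id}: onsets not strictly increasing"
            )
        if self.pulse_width <= 0:
            raise ValidationError(f"train {self.train_id}: pulse_width must be > 0")
        if self.target not in PULSE_TARGETS:
            raise ValidationError(f"train {self.train_id}: unknown target {self.target!r}")
        if self.light_condition not in LIGHT_CONDITIONS:
            raise ValidationError(
                f"train {self.train_id}: unknown light_condition "
                f"{self.light_condition!r}"
            )
        self.pulse_onsets = onsets

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_onsets.size)

    @property
    def empirical_rate(self) -> float:
        """Mean pulse rate implied by the onsets (Hz)."""
        if self.n_pulses < 2:
            return float("nan")
        span = self.pulse_onsets[-1] - self.pulse_onsets[0]
        return (self.n_pulses - 1) / span


@dataclass
class StimulusPanel:
    """Ordered stimulus labels with concentrations and exclusion flags.

    ``excluded_from_ns`` marks stimuli omitted from the noise:signal ratio
    (the umami cocktail, whose multiple effective constituents make a
    sideband interpretation inappropriate).
    """

    labels: tuple[str, ...]
    concentrations: dict[str, str] = field(default_factory=dict)
    excluded_from_ns: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(self.labels) < 2:
            raise ValidationError("panel needs at least 2 stimuli")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("panel labels must be unique")
        self.excluded_from_ns = frozenset(self.excluded_from_ns)
        unknown = self.excluded_from_ns - set(self.labels)
        if unknown:
            raise ValidationError(f"excluded_from_ns not in panel: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def ns_labels(self) -> tuple[str, ...]:
        return tuple(s for s in self.labels if s not in self.excluded_from_ns)

    def order_index(self, label: str) -> int:
        return self.labels.index(label)

    @classmethod
    def set_a(cls) -> "StimulusPanel":
        """Mid-high concentration panel (five standard taste qualities)."""
        return cls(
            labels=("SUC", "MSGai", "NaCl", "CIT", "BIT"),
            concentrations={
                "SUC": "600 mM sucrose",
                "MSGai": "600 mM MSG + 2.5 mM IMP + 100 uM amiloride",
                "NaCl": "300 mM NaCl",
                "CIT": "30 mM citric acid",
                "BIT": "0.01 mM cycloheximide + 2.7 mM quinine",
            },
            excluded_from_ns=frozenset({"MSGai"}),
        )

    @classmethod
    def set_b(cls) -> "StimulusPanel":
        """Mid-range concentration panel."""
        return cls(
            labels=("SUC", "MSGai", "NaCl", "CIT", "BIT"),
            concentrations={
                "SUC": "300 mM sucrose",
                "MSGai": "600 mM MSG + 2.5 mM IMP + 100 uM amiloride",
                "NaCl": "100 mM NaCl",
                "CIT": "10 mM citric acid",
                "BIT": "0.01 mM cycloheximide",
            },
            excluded_from_ns=frozenset({"MSGai"}),
        )


@dataclass
class LickTrial:
    trial_id: str
    stimulus: str
    concentration: float
    conc_units: str
    lick_times: np.ndarray
    access_duration: float = 5.0

    def __post_init__(self) -> None:
        ts = _as_time_array(self.lick_times, f"{self.trial_id} lick_times")
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            raise ValidationError(f"trial {self.trial_id}: lick times not sorted")
        if self.access_duration <= 0:
            raise ValidationError(f"trial {self.trial_id}: access_duration must be > 0")
        self.lick_times = ts

    @property
    def n_licks(self) -> int:
        return int(self.lick_times.size)

    @property
    def ilis(self) -> np.ndarray:
        """Interlick intervals in seconds."""
        return np.diff(self.lick_times)


DRUGS = ("saline", "CNO")


@dataclass
class LickSession:
    """Brief-access licking session for one mouse under one drug state."""

    mouse_id: str
    session_id: str
    drug: str
    trials: list[LickTrial]

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValidationError(
                f"session {self.session_id}: unknown drug {self.drug!r}"
            )

    def trials_for(self, stimulus: str, concentration: float | None = None):
        out = [t for t in self.trials if t.stimulus == stimulus]
        if concentration is not None:
            out = [t for t in out if np.isclose(t.concentration, concentration)]
        return out

    @property
    def stimuli(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.trials:
            if t.stimulus not in seen:
                seen.append(t.stimulus)
        return tuple(seen)
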