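"""Readers and writers for the delimited-text data formats.

Schemas (one header row, comma separated):

* ``spikes.csv``:  unit_id, t_seconds
* ``trials.csv``:  trial_id, unit_id, stimulus, stim_onset_s, stim_dur_s,
  prestim_onset_s, prestim_dur_s, light_condition
* ``pulses.csv``:  train_id, unit_id, target, light_condition, nominal_hz,
  pulse_width_s, onset_s  (one row per pulse)
* ``licks.csv``:   mouse_id, session_id, drug, trial_id, stimulus,
  concentration, conc_units, access_dur_s, lick_t_s  (one row per lick; a
  trial with zero licks is a single row with an empty lick_t_s field)
* ``panel.json``:  sidecar with labels, concentrations, NS-exclusions.

Every reader validates through the :mod:`gustnet.core` constructors, so a
successfully loaded object satisfies all container invariants, and
``read(write(x))`` reproduces ``x`` up to row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    LickSession,
    LickTrial,
    PulseTrain,
    SpikeTrain,
    StimulusPanel,
    TasteTrial,
)

__all__ = [
    "ParseError",
    "read_spikes",
    "write_spikes",
    "read_trials",
    "write_trials",
    "read_pulses",
    "write_pulses",
    "read_licks",
    "write_licks",
    "read_responses",
    "write_responses",
    "read_panel",
    "write_panel",
]


class ParseError(ValueError):
    """A file could not be parsed into valid domain objects."""


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path, allow_blank: bool = False) -> pd.Series:
    raw = df[col].astype(str).str.strip()
    # detect malformed entries first (with line numbers), then convert with
    # numpy's exact parser — pandas' fast to_numeric path can lose ULPs
    probe = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = probe.isna() & (raw != "" if allow_blank else True)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
    return raw.replace("", "nan").astype(float)


def read_spikes(path) -> dict[str, SpikeTrain]:
    """Load spike timestamp tables, one :class:`SpikeTrain` per unit."""
    df = _read_csv(path, ["unit_id", "t_seconds"])
    if df.empty:
        return {}
    t = _numeric(df, "t_seconds", path)
    neg = t < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ParseError(f"{path}: negative spike time at line {line}")
    out: dict[str, SpikeTrain] = {}
    for unit_id, sub in df.assign(t=t).groupby("unit_id", sort=True):
        out[unit_id] = SpikeTrain(unit_id, np.sort(sub["t"].to_numpy()))
    return out


def write_spikes(spikes: dict[str, SpikeTrain], path) -> None:
    rows = [
        {"unit_id": uid, "t_seconds": t}
        for uid in sorted(spikes)
        for t in spikes[uid].timestamps
    ]
    pd.DataFrame(rows, columns=["unit_id", "t_seconds"]).to_csv(path, index=False)


_TRIAL_COLS = [
    "trial_id",
    "unit_id",
    "stimulus",
    "stim_onset_s",
    "stim_dur_s",
    "prestim_onset_s",
    "prestim_dur_s",
    "light_condition",
]


def read_trials(path) -> dict[str, list[TasteTrial]]:
    """Load taste trials grouped by unit_id."""
    df = _read_csv(path, _TRIAL_COLS)
    if df.empty:
        return {}
    for col in ["stim_onset_s", "stim_dur_s", "prestim_onset_s", "prestim_dur_s"]:
        df[col] = _numeric(df, col, path)
    out: dict[str, list[TasteTrial]] = {}
    for i, row in df.iterrows():
        try:
            trial = TasteTrial(
                trial_id=row["trial_id"],
                stimulus=row["stimulus"],
                stimulus_onset=row["stim_onset_s"],
                stimulus_duration=row["stim_dur_s"],
                prestim_onset=row["prestim_onset_s"],
                prestim_duration=row["prestim_dur_s"],
                light_condition=row["light_condition"],
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {int(i) + 2}: {exc}") from exc
        out.setdefault(row["unit_id"], []).append(trial)
    return out


def write_trials(trials: dict[str, list[TasteTrial]], path) -> None:
    rows = []
    for uid in sorted(trials):
        for t in trials[uid]:
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "unit_id": uid,
                    "stimulus": t.stimulus,
                    "stim_onset_s": t.stimulus_onset,
                    "stim_dur_s": t.stimulus_duration,
                    "prestim_onset_s": t.prestim_onset,
                    "prestim_dur_s": t.prestim_duration,
                    "light_condition": t.light_condition,
                }
            )
    pd.DataFrame(rows, columns=_TRIAL_COLS).to_csv(path, index=False)


_PULSE_COLS = [
    "train_id",
    "unit_id",
    "target",
    "light_condition",
    "nominal_hz",
    "pulse_width_s",
    "onset_s",
]


def read_pulses(path) -> list[PulseTrain]:
    df = _read_csv(path, _PULSE_COLS)
    if df.empty:
        return []
    df["nominal_hz"] = _numeric(df, "nominal_hz", path)
    df["pulse_width_s"] = _numeric(df, "pulse_width_s", path)
    df["onset_s"] = _numeric(df, "onset_s", path)
    trains: list[PulseTrain] = []
    for train_id, sub in df.groupby("train_id", sort=True):
        for col in ["unit_id", "target", "light_condition"]:
            if sub[col].nunique() != 1:
                raise ParseError(f"{path}: train {train_id}: inconsistent {col}")
        first = sub.iloc[0]
        try:
            trains.append(
                PulseTrain(
                    train_id=train_id,
                    unit_id=first["unit_id"],
                    pulse_onsets=np.sort(sub["onset_s"].to_numpy()),
                    nominal_frequency=first["nominal_hz"],
                    target=first["target"],
                    pulse_width=first["pulse_width_s"],
                    light_condition=first["light_condition"],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: train {train_id}: {exc}") from exc
    return trains


def write_pulses(trains: list[PulseTrain], path) -> None:
    rows = []
    for tr in sorted(trains, key=lambda t: t.train_id):
        for onset in tr.pulse_onsets:
            rows.append(
                {
                    "train_id": tr.train_id,
                    "unit_id": tr.unit_id,
                    "target": tr.target,
                    "light_condition": tr.light_condition,
                    "nominal_hz": tr.nominal_frequency,
                    "pulse_width_s": tr.pulse_width,
                    "onset_s": onset,
                }
            )
    pd.DataFrame(rows, columns=_PULSE_COLS).to_csv(path, index=False)


_LICK_COLS = [
    "mouse_id",
    "session_id",
    "drug",
    "trial_id",
    "stimulus",
    "concentration",
    "conc_units",
    "access_dur_s",
    "lick_t_s",
]


def read_licks(path) -> list[LickSession]:
    df = _read_csv(path, _LICK_COLS)
    if df.empty:
        return []
    df["concentration"] = _numeric(df, "concentration", path)
    df["access_dur_s"] = _numeric(df, "access_dur_s", path)
    df["lick_t_s"] = _numeric(df, "lick_t_s", path, allow_blank=True)
    sessions: list[LickSession] = []
    for (mouse, sess), sub in df.groupby(["mouse_id", "session_id"], sort=True):
        if sub["drug"].nunique() != 1:
            raise ParseError(f"{path}: session {sess}: inconsistent drug")
        trials = []
        for trial_id, tsub in sub.groupby("trial_id", sort=True):
            first = tsub.iloc[0]
            licks = tsub["lick_t_s"].dropna().to_numpy()
            try:
                trials.append(
                    LickTrial(
                        trial_id=trial_id,
                        stimulus=first["stimulus"],
                        concentration=first["concentration"],
                        conc_units=first["conc_units"],
                        lick_times=np.sort(licks),
                        access_duration=first["access_dur_s"],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: trial {trial_id}: {exc}") from exc
        try:
            sessions.append(
                LickSession(mouse_id=mouse, session_id=sess, drug=first["drug"], trials=trials)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: session {sess}: {exc}") from exc
    return sessions


def write_licks(sessions: list[LickSession], path) -> None:
    rows = []
    for s in sorted(sessions, key=lambda s: (s.mouse_id, s.session_id)):
        for t in sorted(s.trials, key=lambda t: t.trial_id):
            base = {
                "mouse_id": s.mouse_id,
                "session_id": s.session_id,
                "drug": s.drug,
                "trial_id": t.trial_id,
                "stimulus": t.stimulus,
                "concentration": t.concentration,
                "conc_units": t.conc_units,
                "access_dur_s": t.access_duration,
            }
            if t.n_licks == 0:
                rows.append({**base, "lick_t_s": ""})
            else:
                for lt in t.lick_times:
                    rows.append({**base, "lick_t_s": lt})
    pd.DataFrame(rows, columns=_LICK_COLS).to_csv(path, index=False)


_RESPONSE_COLS = [
    "unit_id",
    "stimulus",
    "light_condition",
    "net_spikes",
    "n_trials",
    "window_s",
    "baseline_mean",
    "baseline_sd",
    "significant",
    "manual_override",
    "spontaneous_rate_hz",
]


def write_responses(profiles, path) -> None:
    """Persist response profiles as one row per unit x stimulus x condition."""
    rows = []
    for p in sorted(profiles, key=lambda p: p.unit_id):
        for (stim, cond) in sorted(p.responses):
            r = p.responses[(stim, cond)]
            rows.append(
                {
                    "unit_id": p.unit_id,
                    "stimulus": stim,
                    "light_condition": cond,
                    "net_spikes": r.net,
                    "n_trials": r.n_trials,
                    "window_s": r.window_s,
                    "baseline_mean": r.baseline_mean,
                    "baseline_sd": r.baseline_sd,
                    "significant": "" if r.significant is None else str(bool(r.significant)),
                    "manual_override": str(bool(r.manual_override)),
                    "spontaneous_rate_hz": p.spontaneous_rate,
                }
            )
    pd.DataFrame(rows, columns=_RESPONSE_COLS).to_csv(path, index=False)


def read_responses(path, panel: StimulusPanel):
    """Rebuild :class:`~gustnet.responses.ResponseProfile` objects from CSV."""
    from .responses import NetResponse, ResponseProfile

    df = _read_csv(path, _RESPONSE_COLS)
    profiles: dict[str, ResponseProfile] = {}
    if df.empty:
        return []
    for col in ["net_spikes", "n_trials", "window_s", "baseline_mean", "spontaneous_rate_hz"]:
        df[col] = _numeric(df, col, path)
    df["baseline_sd"] = _numeric(df, "baseline_sd", path, allow_blank=True)
    for _, row in df.iterrows():
        uid = row["unit_id"]
        prof = profiles.get(uid)
        if prof is None:
            prof = ResponseProfile(
                unit_id=uid, panel=panel, spontaneous_rate=row["spontaneous_rate_hz"]
            )
            profiles[uid] = prof
        sig_raw = str(row["significant"]).strip()
        nr = NetResponse(
            unit_id=uid,
            stimulus=row["stimulus"],
            light_condition=row["light_condition"],
            net=row["net_spikes"],
            n_trials=int(row["n_trials"]),
            window_s=row["window_s"],
            baseline_mean=row["baseline_mean"],
            baseline_sd=float(row["baseline_sd"]),
            significant=None if sig_raw == "" else sig_raw == "True",
            manual_override=str(row["manual_override"]).strip() == "True",
        )
        prof.responses[(nr.stimulus, nr.light_condition)] = nr
    return list(profiles.values())


def read_panel(path) -> StimulusPanel:
    with open(path) as fh:
        obj = json.load(fh)
    return StimulusPanel(
        labels=tuple(obj["labels"]),
        concentrations=obj.get("concentrations", {}),
        excluded_from_ns=frozenset(obj.get("excluded_from_ns", [])),
    )


def write_panel(panel: StimulusPanel, path) -> None:
    obj = {
        "labels": list(panel.labels),
        "concentrations": dict(panel.concentrations),
        "excluded_from_ns": sorted(panel.excluded_from_ns),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
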