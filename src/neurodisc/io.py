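"""Session data model and on-disk layout.

A recording session is stored as one directory of UTF-8 tab-delimited text
tables, mirroring the flat tabular exports of Kilosort/Phy-style pipelines
while staying human readable:

``trials.tsv``
    One row per trial: ``trial_id  t_onset  freq  level  category  task
    tone_dur  outcome  lick_count  first_lick_latency``.
``licks.tsv``
    One column ``t_s`` of lick-event times.
``spikes.tsv``
    Columns ``unit_id  t_s``; all units interleaved, times ascending per unit.
``units.tsv``
    Columns ``unit_id  depth_um  region  layer  quality``.
``meta.json``
    Session-level key/value pairs (group label, protocol name, notes).

All times are seconds relative to the session start, written as decimal text
with nine digits after the point; there is no sample-index representation
anywhere in the package.  Analysis windows are half-open ``[start, end)``
relative to tone onset (onset = 0 s).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "Session",
    "load_session",
    "save_session",
    "validate_session",
    "SessionFormatError",
    "REGIONS",
    "LAYERS",
    "OUTCOMES",
    "CATEGORIES",
    "TASKS",
    "TRIAL_COLUMNS",
    "EASY_FREQS_HZ",
    "HARD_FREQS_HZ",
    "PROBE_FREQS_HZ",
]

#: Closed vocabulary of anatomical region labels (auditory cortical fields
#: pooled as ACx in the analysis; anything else maps to "other").
REGIONS = ("AUDd", "AUDp", "AUDv", "TEa", "other")
LAYERS = ("L5/6", "other")
OUTCOMES = ("hit", "miss", "fa", "cr", "probe", "unclassified")
CATEGORIES = ("go", "nogo", "probe")
TASKS = ("easy", "hard", "probe")

#: Go/No-Go tone pairs of the discrimination protocol.  The easy pair spans
#: exactly one octave around the 10 kHz category boundary; the hard pair
#: spans 0.25 octaves (10 kHz * 2**(+-0.125)).
EASY_FREQS_HZ = (7070.0, 14140.0)
HARD_FREQS_HZ = (9170.0, 10905.1)
#: Unreinforced probe tones interleaved between the boundary and the
#: learned tones.
PROBE_FREQS_HZ = (8490.0, 9567.0, 10000.0, 10440.0, 11890.0)

TRIAL_COLUMNS = [
    "trial_id",
    "t_onset",
    "freq",
    "level",
    "category",
    "task",
    "tone_dur",
    "outcome",
    "lick_count",
    "first_lick_latency",
]

_FLOAT_FMT = "%.9f"


class SessionFormatError(ValueError):
    """Raised when a session directory or Session violates the layout contract."""


@dataclass
class Unit:
    """A single sorted unit.

    Parameters
    ----------
    unit_id : str
        Opaque identifier, unique within the session.
    spike_times : numpy.ndarray
        Spike times in seconds, sorted ascending, no NaN.
    depth_um : float
        Recording depth in micrometers.
    region : str
        One of :data:`REGIONS`.
    layer : str
        One of :data:`LAYERS`.
    quality : str
        Sorter/curation quality label (carried through, not interpreted).
    """

    unit_id: str
    spike_times: np.ndarray
    depth_um: float = 0.0
    region: str = "AUDp"
    layer: str = "L5/6"
    quality: str = "good"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def __eq__(self, other: object) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, Unit):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.depth_um == other.depth_um
            and self.region == other.region
            and self.layer == other.layer
            and self.quality == other.quality
            and len(self.spike_times) == len(other.spike_times)
            and np.allclose(self.spike_times, other.spike_times, rtol=0.0, atol=1e-9)
        )


@dataclass
class Session:
    """One behavioral/recording session with a common time base in seconds."""

    trials: pd.DataFrame
    licks: np.ndarray
    units: list[Unit] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.licks = np.asarray(self.licks, dtype=float)

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def copy(self) -> "Session":
        return Session(
            trials=self.trials.copy(),
            licks=self.licks.copy(),
            units=[replace(u, spike_times=u.spike_times.copy()) for u in self.units],
            meta=dict(self.meta),
        )


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{name}: missing columns {missing}")


def validate_session(session: Session) -> list[str]:
    """Check a :class:`Session` against its invariants.

    Returns a list of human-readable violation messages naming the offending
    trial or unit; an empty list means the session is valid.  Never mutates
    the input and is deterministic (repeated calls give identical reports).
    """
    report: list[str] = []
    trials = session.trials

    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        report.append(f"trials: missing columns {missing}")
        return report

    onsets = trials["t_onset"].to_numpy(dtype=float)
    if len(onsets):
        if not np.all(np.isfinite(onsets)) or np.any(onsets < 0):
            report.append("trials: non-finite or negative t_onset")
        if np.any(np.diff(onsets) <= 0):
            i = int(np.flatnonzero(np.diff(onsets) <= 0)[0])
            report.append(
                f"trials: t_onset not strictly increasing at trial_id="
                f"{trials['trial_id'].iloc[i + 1]}"
            )
    for _, row in trials.iterrows():
        tid = row["trial_id"]
        if not (row["freq"] > 0):
            report.append(f"trials: trial_id={tid} has non-positive freq")
        if not (0 <= row["level"] <= 120):
            report.append(f"trials: trial_id={tid} level outside [0, 120] dB SPL")
        if not (row["tone_dur"] > 0):
            report.append(f"trials: trial_id={tid} has non-positive tone_dur")
        if row["category"] not in CATEGORIES:
            report.append(f"trials: trial_id={tid} unknown category {row['category']!r}")
        if row["task"] not in TASKS:
            report.append(f"trials: trial_id={tid} unknown task {row['task']!r}")
        if row["outcome"] not in OUTCOMES:
            report.append(f"trials: trial_id={tid} unknown outcome {row['outcome']!r}")

    licks = np.asarray(session.licks, dtype=float)
    if licks.size and (not np.all(np.isfinite(licks)) or np.any(licks < 0)):
        report.append("licks: non-finite or negative lick time")

    seen: set[str] = set()
    for u in session.units:
        if u.unit_id in seen:
            report.append(f"units: duplicate unit_id {u.unit_id!r}")
        seen.add(u.unit_id)
        st = np.asarray(u.spike_times, dtype=float)
        if st.size:
            if np.any(~np.isfinite(st)):
                i = int(np.flatnonzero(~np.isfinite(st))[0])
                report.append(f"unit {u.unit_id!r}: non-finite spike time at index {i}")
            elif np.any(st < 0):
                i = int(np.flatnonzero(st < 0)[0])
                report.append(f"unit {u.unit_id!r}: negative spike time at index {i}")
            if np.any(np.diff(st) < 0):
                i = int(np.flatnonzero(np.diff(st) < 0)[0])
                report.append(f"unit {u.unit_id!r}: spike times not sorted at index {i + 1}")
        if u.region not in REGIONS:
            report.append(f"unit {u.unit_id!r}: unknown region {u.region!r}")
        if u.layer not in LAYERS:
            report.append(f"unit {u.unit_id!r}: unknown layer {u.layer!r}")
    return report


def save_session(session: Session, dir_path: str | Path) -> Path:
    """Write a Session to ``dir_path`` in the documented TSV layout.

    Writing is deterministic: saving the same Session twice produces
    byte-identical files.  Returns the directory path.
    """
    violations = validate_session(session)
    if violations:
        raise SessionFormatError("cannot save invalid session: " + "; ".join(violations))
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)

    trials = session.trials[TRIAL_COLUMNS].copy()
    trials.to_csv(out / "trials.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    pd.DataFrame({"t_s": np.asarray(session.licks, dtype=float)}).to_csv(
        out / "licks.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    spike_frames = [
        pd.DataFrame({"unit_id": u.unit_id, "t_s": np.asarray(u.spike_times, dtype=float)})
        for u in session.units
    ]
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame({"unit_id": pd.Series(dtype=str), "t_s": pd.Series(dtype=float)})
    )
    spikes.to_csv(out / "spikes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    units = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "depth_um": [u.depth_um for u in session.units],
            "region": [u.region for u in session.units],
            "layer": [u.layer for u in session.units],
            "quality": [u.quality for u in session.units],
        }
    )
    units.to_csv(out / "units.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(session.meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def load_session(dir_path: str | Path, protocol: str | None = None) -> Session:
    """Load and validate a session directory written by :func:`save_session`.

    Parameters
    ----------
    dir_path : path
        Directory containing ``trials.tsv``, ``licks.tsv``, ``spikes.tsv``,
        ``units.tsv`` (``meta.json`` optional).
    protocol : str, optional
        If ``"standard"``, additionally checks that learned-task tone
        frequencies match the protocol pairs within 1 Hz.

    Raises
    ------
    SessionFormatError
        Missing files, non-monotonic trial onsets, or spikes referencing an
        unknown unit are fatal.  Unknown region labels are mapped to
        ``"other"`` with a warning entry in ``session.meta["load_warnings"]``.
    """
    d = Path(dir_path)
    for fname in ("trials.tsv", "licks.tsv", "spikes.tsv", "units.tsv"):
        if not (d / fname).exists():
            raise SessionFormatError(f"missing required file: {d / fname}")

    trials = pd.read_csv(d / "trials.tsv", sep="\t")
    _check_columns(trials, TRIAL_COLUMNS, "trials.tsv")
    trials = trials[TRIAL_COLUMNS]
    trials["trial_id"] = trials["trial_id"].astype(int)
    trials["lick_count"] = trials["lick_count"].astype(int)
    for col in ("t_onset", "freq", "level", "tone_dur", "first_lick_latency"):
        trials[col] = trials[col].astype(float)

    onsets = trials["t_onset"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        raise SessionFormatError("trials.tsv: t_onset must be strictly increasing")

    licks_df = pd.read_csv(d / "licks.tsv", sep="\t")
    _check_columns(licks_df, ["t_s"], "licks.tsv")
    licks = licks_df["t_s"].to_numpy(dtype=float)

    units_df = pd.read_csv(d / "units.tsv", sep="\t")
    _check_columns(units_df, ["unit_id", "depth_um", "region", "layer", "quality"], "units.tsv")

    spikes = pd.read_csv(d / "spikes.tsv", sep="\t")
    _check_columns(spikes, ["unit_id", "t_s"], "spikes.tsv")

    warnings: list[str] = []
    known_ids = set(units_df["unit_id"].astype(str))
    if len(spikes):
        spike_ids = set(spikes["unit_id"].astype(str))
        orphans = spike_ids - known_ids
        if orphans:
            raise SessionFormatError(
                f"spikes.tsv references unit_id(s) absent from units.tsv: {sorted(orphans)}"
            )

    by_unit = (
        {str(k): g["t_s"].to_numpy(dtype=float) for k, g in spikes.groupby("unit_id")}
        if len(spikes)
        else {}
    )
    units: list[Unit] = []
    for _, row in units_df.iterrows():
        region = str(row["region"])
        if region not in REGIONS:
            warnings.append(f"unit {row['unit_id']!r}: unknown region {region!r} mapped to 'other'")
            region = "other"
        layer = str(row["layer"])
        if layer not in LAYERS:
            warnings.append(f"unit {row['unit_id']!r}: unknown layer {layer!r} mapped to 'other'")
            layer = "other"
        st = np.sort(by_unit.get(str(row["unit_id"]), np.empty(0)))
        units.append(
            Unit(
                unit_id=str(row["unit_id"]),
                spike_times=st,
                depth_um=float(row["depth_um"]),
                region=region,
                layer=layer,
                quality=str(row["quality"]),
            )
        )

    meta: dict = {}
    if (d / "meta.json").exists():
        with open(d / "meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
    if warnings:
        meta = dict(meta)
        meta["load_warnings"] = warnings

    session = Session(trials=trials, licks=licks, units=units, meta=meta)
    violations = validate_session(session)
    if violations:
        raise SessionFormatError("invalid session: " + "; ".join(violations))

    if protocol == "standard":
        _check_protocol_freqs(trials)
    return session


def _check_protocol_freqs(trials: pd.DataFrame, tol_hz: float = 1.0) -> None:
    for task, pair in (("easy", EASY_FREQS_HZ), ("hard", HARD_FREQS_HZ)):
        freqs = trials.loc[trials["task"] == task, "freq"].to_numpy(dtype=float)
        for f in np.unique(freqs):
            if not any(math.isclose(f, p, abs_tol=tol_hz) for p in pair):
                raise SessionFormatError(
                    f"protocol 'standard': {task}-task frequency {f} Hz not within "
                    f"{tol_hz} Hz of the protocol pair {pair}"
                )
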