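"""Session data model, validation, and bundle readers/writers.

A *session bundle* is a directory holding one recording session of the
auditory oddball task:

* ``events.tsv``      — trial event table (tone onsets, types, outcomes)
* ``spikes.tsv``      — long-format per-unit spike timestamps
* ``continuous.bin``  — little-endian float32 samples, channel-major
* ``continuous.json`` — sidecar with sampling rate, channel labels/roles,
  laminar depth order, and units
* ``stim.tsv``        — optional electrical-stimulation pulse table

Timestamps are stored as decimal text with microsecond precision so that
bundles are language-neutral and round-trip bit-exactly.  All analysis
windows throughout the package are half-open ``[a, b)`` in time: a sample
or spike at time ``t`` belongs to the bin whose left edge is ``<= t``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SessionValidationError",
    "SessionLoadError",
    "TrialEvents",
    "SpikeTrain",
    "ContinuousRecording",
    "StimEvents",
    "Session",
    "read_session",
    "write_session",
    "ms_to_s",
]

#: Roles a continuous channel may take.
CHANNEL_ROLES = ("frontal_eeg", "control_eeg", "laminar_lfp")

TONES = ("oddball", "standard")
OUTCOMES = ("hit", "miss", "none")

#: Minimum spacing of consecutive tone onsets (the task presents a tone
#: every 2 s); a small tolerance absorbs decimal-text rounding.
MIN_ONSET_GAP_S = 2.0 - 1e-9


class SessionValidationError(ValueError):
    """An invariant of a session data type is violated."""


class SessionLoadError(OSError):
    """A bundle file is missing or cannot be parsed."""


def ms_to_s(x_ms: float) -> float:
    """Convert milliseconds to seconds (the single, central conversion)."""
    return x_ms / 1000.0


def _round_us(x: np.ndarray) -> np.ndarray:
    """Quantize timestamps to the microsecond grid used by the text format."""
    return np.round(np.asarray(x, dtype=float), 6)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialEvents:
    """Tone onsets, types, and behavioral outcomes — the temporal backbone.

    ``outcome`` is ``hit``/``miss`` for oddball tones and ``none`` for
    standards; a standard with a recorded ``response_time_s`` is a false
    alarm.  ``response_time_s`` is NaN when there was no response.
    """

    trial_id: np.ndarray
    onset_s: np.ndarray
    tone: np.ndarray
    outcome: np.ndarray
    response_time_s: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "trial_id", np.asarray(self.trial_id, dtype=int))
        object.__setattr__(self, "onset_s", np.asarray(self.onset_s, dtype=float))
        object.__setattr__(self, "tone", np.asarray(self.tone, dtype=object))
        object.__setattr__(self, "outcome", np.asarray(self.outcome, dtype=object))
        object.__setattr__(
            self, "response_time_s", np.asarray(self.response_time_s, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        n = len(self.onset_s)
        for name in ("trial_id", "tone", "outcome", "response_time_s"):
            if len(getattr(self, name)) != n:
                raise SessionValidationError(
                    f"TrialEvents field lengths differ: {name} has "
                    f"{len(getattr(self, name))}, onset_s has {n}"
                )
        if n and np.any(np.diff(self.onset_s) <= 0):
            raise SessionValidationError("onsets not ascending")
        if n and np.any(np.diff(self.onset_s) < MIN_ONSET_GAP_S):
            raise SessionValidationError(
                "consecutive onsets closer than 2 s (task presents one tone per 2 s)"
            )
        bad_tone = set(self.tone) - set(TONES)
        if bad_tone:
            raise SessionValidationError(f"unknown tone labels: {sorted(bad_tone)}")
        bad_out = set(self.outcome) - set(OUTCOMES)
        if bad_out:
            raise SessionValidationError(f"unknown outcome labels: {sorted(bad_out)}")
        is_odd = self.tone == "oddball"
        if np.any((self.outcome == "none") & is_odd):
            raise SessionValidationError(
                "outcome 'none' on an oddball tone (oddballs are hit or miss)"
            )
        if np.any(np.isin(self.outcome, ("hit", "miss")) & ~is_odd):
            raise SessionValidationError(
                "hit/miss outcome on a standard tone (standards are outcome 'none')"
            )
        # between consecutive oddballs there must be 2..6 standards
        odd_pos = np.flatnonzero(is_odd)
        gaps = np.diff(odd_pos) - 1
        if gaps.size and (gaps.min() < 2 or gaps.max() > 6):
            raise SessionValidationError(
                "count of standards between consecutive oddballs outside {2..6} "
                f"(found {sorted(set(gaps) - set(range(2, 7)))})"
            )

    # -- convenience views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.onset_s)

    @property
    def is_oddball(self) -> np.ndarray:
        return self.tone == "oddball"

    @property
    def is_hit(self) -> np.ndarray:
        return self.outcome == "hit"

    @property
    def is_miss(self) -> np.ndarray:
        return self.outcome == "miss"

    @property
    def is_false_alarm(self) -> np.ndarray:
        return (self.tone == "standard") & np.isfinite(self.response_time_s)

    def subset(self, mask: np.ndarray) -> "TrialEvents":
        """Row subset; re-validation of the oddball-gap invariant is skipped
        because arbitrary subsets (e.g. only hits) legitimately break it."""
        ev = object.__new__(TrialEvents)
        for name in ("trial_id", "onset_s", "tone", "outcome", "response_time_s"):
            object.__setattr__(ev, name, getattr(self, name)[mask])
        return ev


@dataclass(frozen=True)
class SpikeTrain:
    """One sorted unit's spike timestamps plus the recorded session span."""

    unit_id: str
    spikes_s: np.ndarray
    session_span_s: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "spikes_s", np.asarray(self.spikes_s, dtype=float))
        object.__setattr__(
            self,
            "session_span_s",
            (float(self.session_span_s[0]), float(self.session_span_s[1])),
        )
        self.validate()

    def validate(self) -> None:
        t0, t1 = self.session_span_s
        if not t1 > t0:
            raise SessionValidationError(
                f"session span length must be > 0 (got [{t0}, {t1}])"
            )
        s = self.spikes_s
        if s.size and np.any(np.diff(s) < 0):
            raise SessionValidationError(f"unit {self.unit_id}: spikes not sorted")
        if s.size and (s[0] < t0 or s[-1] > t1):
            raise SessionValidationError(
                f"unit {self.unit_id}: spikes outside session span"
            )

    def __len__(self) -> int:
        return len(self.spikes_s)

    @property
    def span_length_s(self) -> float:
        return self.session_span_s[1] - self.session_span_s[0]

    @property
    def mean_rate_hz(self) -> float:
        """Average firing rate over the entire session span."""
        return len(self.spikes_s) / self.span_length_s

    def count_in_window(self, start_s: float, stop_s: float) -> int:
        """Spike count in the half-open window [start_s, stop_s)."""
        return int(
            np.searchsorted(self.spikes_s, stop_s, side="left")
            - np.searchsorted(self.spikes_s, start_s, side="left")
        )


@dataclass(frozen=True)
class ContinuousRecording:
    """Uniformly sampled multichannel signal (EEG and/or laminar LFP).

    ``samples`` is channels x time in microvolts.  ``depth_rank`` holds, for
    each channel, its laminar depth order (1 = most superficial, 32 =
    deepest) or ``None`` for non-laminar channels.
    """

    fs_hz: float
    labels: tuple[str, ...]
    roles: tuple[str, ...]
    depth_rank: tuple
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "depth_rank", tuple(self.depth_rank))
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float32)
        )
        self.validate()

    def validate(self) -> None:
        if self.fs_hz not in (1000.0, 2000.0, 1000, 2000):
            raise SessionValidationError(
                f"sampling rate must be 1000 or 2000 Hz (got {self.fs_hz})"
            )
        n_ch = len(self.labels)
        if len(self.roles) != n_ch or len(self.depth_rank) != n_ch:
            raise SessionValidationError("channel metadata lengths differ")
        bad = set(self.roles) - set(CHANNEL_ROLES)
        if bad:
            raise SessionValidationError(f"unknown channel roles: {sorted(bad)}")
        if self.samples.ndim != 2 or self.samples.shape[0] != n_ch:
            raise SessionValidationError(
                f"samples must be (n_channels, n_time); got {self.samples.shape} "
                f"for {n_ch} channels"
            )
        lam = [i for i, r in enumerate(self.roles) if r == "laminar_lfp"]
        if lam:
            if len(lam) != 32:
                raise SessionValidationError(
                    f"laminar probe must have exactly 32 channels (got {len(lam)})"
                )
            ranks = sorted(self.depth_rank[i] for i in lam)
            if ranks != list(range(1, 33)):
                raise SessionValidationError(
                    "laminar depth_rank must be a permutation of 1..32"
                )
        for i, r in enumerate(self.roles):
            if r != "laminar_lfp" and self.depth_rank[i] is not None:
                raise SessionValidationError(
                    f"non-laminar channel {self.labels[i]} carries a depth_rank"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def t_end_s(self) -> float:
        return self.t0_s + self.duration_s

    def channel(self, label: str) -> np.ndarray:
        """Single channel trace by label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.samples[idx]

    def by_role(self, role: str) -> np.ndarray:
        """All channels with the given role, in stored order."""
        idx = [i for i, r in enumerate(self.roles) if r == role]
        if not idx:
            raise KeyError(f"no channel with role {role!r}")
        return self.samples[idx]

    def laminar_by_depth(self) -> np.ndarray:
        """The 32 laminar channels as a (32, n_time) array ordered by
        depth_rank (row 0 = most superficial)."""
        lam = [(self.depth_rank[i], i) for i, r in enumerate(self.roles)
               if r == "laminar_lfp"]
        if not lam:
            raise KeyError("recording has no laminar channels")
        order = [i for _, i in sorted(lam)]
        return self.samples[order]

    def sample_index(self, t_s: float) -> int:
        """Index of the sample bin containing time ``t_s`` (half-open bins)."""
        return int(math.floor((t_s - self.t0_s) * self.fs_hz + 1e-9))

    def window_slice(self, start_s: float, stop_s: float) -> slice:
        """Sample slice covering the half-open time window [start_s, stop_s)."""
        i0 = self.sample_index(start_s)
        i1 = self.sample_index(stop_s)
        if i0 < 0 or i1 > self.n_samples:
            raise SessionValidationError(
                f"window [{start_s}, {stop_s}) s outside recorded span "
                f"[{self.t0_s}, {self.t_end_s}) s"
            )
        return slice(i0, i1)


@dataclass(frozen=True)
class StimEvents:
    """Electrical-stimulation pulse times (one pulse every 2 s, no tones)."""

    pulse_times_s: np.ndarray
    current_per_electrode_ua: float

    def __post_init__(self):
        object.__setattr__(
            self, "pulse_times_s", np.asarray(self.pulse_times_s, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        p = self.pulse_times_s
        if p.size > 1:
            ipi = np.diff(p)
            if np.any(ipi <= 0):
                raise SessionValidationError("pulse times not ascending")
            if np.any(np.abs(ipi - 2.0) > 0.1):
                raise SessionValidationError(
                    "inter-pulse interval must be ~2 s "
                    f"(found intervals in [{ipi.min():.3f}, {ipi.max():.3f}] s)"
                )

    def __len__(self) -> int:
        return len(self.pulse_times_s)


@dataclass
class Session:
    """One session bundle held in memory."""

    events: TrialEvents
    spikes: list
    continuous: ContinuousRecording
    stim: StimEvents | None = None


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

_EVENT_COLS = ["trial_id", "onset_s", "tone", "outcome", "response_time_s"]
_TS_FMT = "%.6f"  # microsecond-precision decimal text


def write_session(session: Session, bundle_path: str | Path) -> None:
    """Write a session bundle (events/spikes/continuous[/stim]) to a directory."""
    path = Path(bundle_path)
    path.mkdir(parents=True, exist_ok=True)
    ev = session.events
    df = pd.DataFrame(
        {
            "trial_id": ev.trial_id,
            "onset_s": [_TS_FMT % t for t in ev.onset_s],
            "tone": ev.tone,
            "outcome": ev.outcome,
            "response_time_s": [
                "" if not np.isfinite(t) else _TS_FMT % t for t in ev.response_time_s
            ],
        }
    )
    df.to_csv(path / "events.tsv", sep="\t", index=False)

    rows = []
    for st in session.spikes:
        for t in st.spikes_s:
            rows.append((st.unit_id, _TS_FMT % t))
        if len(st) == 0:  # keep empty units visible via a sentinel-free format:
            rows.append((st.unit_id, ""))
    pd.DataFrame(rows, columns=["unit_id", "spike_s"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False
    )

    rec = session.continuous
    rec.samples.astype("<f4").tofile(path / "continuous.bin")
    meta = {
        "fs_hz": float(rec.fs_hz),
        "t0_s": float(rec.t0_s),
        "n_samples": int(rec.n_samples),
        "units": "uV",
        "channels": [
            {"label": lbl, "role": role, "depth_rank": rank}
            for lbl, role, rank in zip(rec.labels, rec.roles, rec.depth_rank)
        ],
        "session_span_s": list(session.spikes[0].session_span_s)
        if session.spikes
        else [rec.t0_s, rec.t_end_s],
    }
    (path / "continuous.json").write_text(json.dumps(meta, indent=1))

    if session.stim is not None:
        pd.DataFrame(
            {
                "pulse_s": [_TS_FMT % t for t in session.stim.pulse_times_s],
                "current_uA": session.stim.current_per_electrode_ua,
            }
        ).to_csv(path / "stim.tsv", sep="\t", index=False)


def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionLoadError(f"bundle file missing: {path}")
    return path


def read_session(bundle_path: str | Path) -> Session:
    """Read and validate a session bundle directory.

    Raises :class:`SessionLoadError` for missing/unparseable files and
    :class:`SessionValidationError` (naming the invariant) for invalid data.
    """
    path = Path(bundle_path)
    if not path.is_dir():
        raise SessionLoadError(f"bundle directory not found: {path}")

    try:
        edf = pd.read_csv(_require(path / "events.tsv"), sep="\t")
    except (pd.errors.ParserError, ValueError) as e:
        raise SessionLoadError(f"{path/'events.tsv'}: {e}") from e
    missing = set(_EVENT_COLS) - set(edf.columns)
    if missing:
        raise SessionLoadError(
            f"{path/'events.tsv'}: missing columns {sorted(missing)}"
        )
    try:
        events = TrialEvents(
            trial_id=edf["trial_id"].to_numpy(),
            onset_s=edf["onset_s"].to_numpy(dtype=float),
            tone=edf["tone"].to_numpy(dtype=object),
            outcome=edf["outcome"].to_numpy(dtype=object),
            response_time_s=pd.to_numeric(
                edf["response_time_s"], errors="coerce"
            ).to_numpy(dtype=float),
        )
    except SessionValidationError as e:
        raise SessionValidationError(f"{path/'events.tsv'}: {e}") from e

    meta_path = _require(path / "continuous.json")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:
        raise SessionLoadError(f"{meta_path}: {e}") from e
    n_ch = len(meta["channels"])
    raw = np.fromfile(_require(path / "continuous.bin"), dtype="<f4")
    if n_ch and raw.size % n_ch:
        raise SessionLoadError(
            f"{path/'continuous.bin'}: {raw.size} samples not divisible by "
            f"{n_ch} channels"
        )
    try:
        continuous = ContinuousRecording(
            fs_hz=meta["fs_hz"],
            labels=[c["label"] for c in meta["channels"]],
            roles=[c["role"] for c in meta["channels"]],
            depth_rank=[c["depth_rank"] for c in meta["channels"]],
            samples=raw.reshape(n_ch, -1),
            t0_s=meta.get("t0_s", 0.0),
        )
    except SessionValidationError as e:
        raise SessionValidationError(f"{meta_path}: {e}") from e

    span = tuple(meta.get("session_span_s", (continuous.t0_s, continuous.t_end_s)))
    sdf = pd.read_csv(_require(path / "spikes.tsv"), sep="\t")
    spikes = []
    for unit_id, grp in sdf.groupby("unit_id", sort=False):
        t = pd.to_numeric(grp["spike_s"], errors="coerce").dropna().to_numpy(float)
        try:
            spikes.append(SpikeTrain(str(unit_id), t, span))
        except SessionValidationError as e:
            raise SessionValidationError(f"{path/'spikes.tsv'}: {e}") from e

    stim = None
    stim_path = path / "stim.tsv"
    if stim_path.exists():
        tdf = pd.read_csv(stim_path, sep="\t")
        try:
            stim = StimEvents(
                pulse_times_s=tdf["pulse_s"].to_numpy(dtype=float),
                current_per_electrode_ua=float(tdf["current_uA"].iloc[0])
                if len(tdf)
                else 0.0,
            )
        except SessionValidationError as e:
            raise SessionValidationError(f"{stim_path}: {e}") from e
        if len(events) and len(stim):
            d = np.abs(events.onset_s[:, None] - stim.pulse_times_s[None, :])
            if d.min() < 0.5:
                raise SessionValidationError(
                    "stimulation pulses co-occur with tone events"
                )

    return Session(events=events, spikes=spikes, continuous=continuous, stim=stim)
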