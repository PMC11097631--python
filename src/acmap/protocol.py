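"""Stimulus protocols shared by all analysis stages.

A protocol is an ordered table of sound events.  Each event carries the
sound identity and class, the pure-tone frequency and sound pressure
level where applicable, the onset frame of the presentation and the
repetition index.  The same table drives trial extraction for tuning,
running exclusion and ensemble cell-vector construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The pure-tone grid: 17 frequencies, 4-64 kHz in quarter-octave steps.
PT_FREQS_KHZ = 4.0 * 2.0 ** (np.arange(17) / 4.0)

#: Sound pressure levels used for frequency response areas (dB SPL).
PT_SPLS_DB = np.array([30.0, 40.0, 50.0, 60.0, 70.0])

#: Widefield tone set (kHz), one tone per octave.
WIDEFIELD_FREQS_KHZ = np.array([4.0, 8.0, 16.0, 32.0, 64.0])

#: Reference frequency for the octave axis.
F_REF_KHZ = 4.0

EVENT_COLUMNS = [
    "sound_id",
    "sound_class",
    "frequency_khz",
    "spl_db",
    "onset_frame",
    "repetition",
    "duration_s",
]


def to_octaves(freq_khz):
    """Map frequency in kHz onto the octave axis log2(f / 4 kHz)."""
    return np.log2(np.asarray(freq_khz, dtype=float) / F_REF_KHZ)


def from_octaves(oct_pos):
    """Inverse of :func:`to_octaves`."""
    return F_REF_KHZ * 2.0 ** np.asarray(oct_pos, dtype=float)


@dataclass
class StimulusProtocol:
    """Ordered sound events plus the pure-tone grid they were drawn from.

    Parameters
    ----------
    events : pandas.DataFrame
        One row per presentation with columns ``sound_id``,
        ``sound_class`` (``"PT"``, ``"AM"`` or ``"complex"``),
        ``frequency_khz`` (NaN for complex sounds), ``spl_db``,
        ``onset_frame``, ``repetition`` and ``duration_s``.
    frame_rate : float
        Imaging frame rate in Hz the onset frames refer to.
    """

    events: pd.DataFrame
    frame_rate: float = 29.76
    pt_freqs_khz: np.ndarray = field(default_factory=lambda: PT_FREQS_KHZ.copy())
    pt_spls_db: np.ndarray = field(default_factory=lambda: PT_SPLS_DB.copy())

    def __post_init__(self):
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"protocol events missing columns: {missing}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dup = self.events.duplicated(subset=["sound_id", "spl_db", "repetition"])
        if dup.any():
            raise ValueError(
                "each (sound, SPL, repetition) may appear only once; "
                f"{int(dup.sum())} duplicates found"
            )

    # -- accessors -----------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_frames(self) -> int:
        """Number of frames needed to contain every event window."""
        ev = self.events
        ends = ev["onset_frame"] + np.ceil(ev["duration_s"] * self.frame_rate)
        return int(ends.max()) + int(self.frame_rate)  # a second of tail

    @property
    def sound_ids(self) -> list:
        return list(pd.unique(self.events["sound_id"]))

    @property
    def n_repetitions(self) -> int:
        return int(self.events["repetition"].max()) + 1

    def pt_events(self) -> pd.DataFrame:
        return self.events[self.events["sound_class"] == "PT"]

    def events_for(self, sound_id) -> pd.DataFrame:
        return self.events[self.events["sound_id"] == sound_id]

    def stim_frames(self, row) -> np.ndarray:
        """Frames covered by one event, onset to offset (inclusive start)."""
        n = max(1, int(round(row["duration_s"] * self.frame_rate)))
        start = int(row["onset_frame"])
        return np.arange(start, start + n)

    def to_json(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "pt_freqs_khz": self.pt_freqs_khz.tolist(),
            "pt_spls_db": self.pt_spls_db.tolist(),
            "events": self.events.to_dict(orient="list"),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "StimulusProtocol":
        return cls(
            events=pd.DataFrame(payload["events"]),
            frame_rate=float(payload["frame_rate"]),
            pt_freqs_khz=np.asarray(payload["pt_freqs_khz"], dtype=float),
            pt_spls_db=np.asarray(payload["pt_spls_db"], dtype=float),
        )


def pt_grid_protocol(
    n_repetitions: int = 10,
    frame_rate: float = 29.76,
    tone_s: float = 0.25,
    gap_s: float = 1.0,
    spls_db=PT_SPLS_DB,
    freqs_khz=PT_FREQS_KHZ,
    shuffle_within_repetition: bool = False,
    rng=None,
) -> StimulusProtocol:
    """Build the full pure-tone grid protocol (frequencies x SPLs x reps).

    Tones are presented back to back with ``gap_s`` of silence after each
    ``tone_s`` presentation.  Within a repetition every grid cell occurs
    exactly once; ``shuffle_within_repetition`` randomises the order as in
    the experiments, otherwise the order is the deterministic grid order.
    """
    freqs_khz = np.asarray(freqs_khz, dtype=float)
    spls_db = np.asarray(spls_db, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    step = tone_s + gap_s
    rows = []
    frame = int(frame_rate)  # leave one second of lead-in
    for rep in range(n_repetitions):
        cells = [(f, s) for f in freqs_khz for s in spls_db]
        if shuffle_within_repetition:
            order = rng.permutation(len(cells))
            cells = [cells[i] for i in order]
        for f, s in cells:
            rows.append(
                {
                    "sound_id": f"PT_{f:.2f}kHz_{s:.0f}dB",
                    "sound_class": "PT",
                    "frequency_khz": f,
                    "spl_db": s,
                    "onset_frame": frame,
                    "repetition": rep,
                    "duration_s": tone_s,
                }
            )
            frame += int(round(step * frame_rate))
    return StimulusProtocol(
        events=pd.DataFrame(rows),
        frame_rate=frame_rate,
        pt_freqs_khz=freqs_khz,
        pt_spls_db=spls_db,
    )


def ensemble_protocol(
    n_pt: int = 17,
    n_am: int = 34,
    n_complex: int = 13,
    n_repetitions: int = 10,
    frame_rate: float = 29.76,
    tone_s: float = 0.25,
    gap_s: float = 1.0,
) -> StimulusProtocol:
    """Protocol for the ensemble analyses: PTs, AM tones and complex sounds.

    PT and AM events reuse the 17-tone carrier grid at 70 dB SPL; complex
    sounds have no frequency attached.  Durations follow the presentation
    scheme (0.25 s tones, ~1 s complex sounds).
    """
    rows = []
    frame = int(frame_rate)
    step = int(round((tone_s + gap_s) * frame_rate))
    sounds = []
    for i in range(n_pt):
        f = PT_FREQS_KHZ[i % 17]
        sounds.append((f"PT_{i:02d}", "PT", f, 70.0, tone_s))
    for i in range(n_am):
        f = PT_FREQS_KHZ[i % 17]
        sounds.append((f"AM_{i:02d}", "AM", f, 70.0, tone_s))
    for i in range(n_complex):
        sounds.append((f"CPLX_{i:02d}", "complex", np.nan, 70.0, 1.0))
    for rep in range(n_repetitions):
        for sid, cls, f, spl, dur in sounds:
            rows.append(
                {
                    "sound_id": sid,
                    "sound_class": cls,
                    "frequency_khz": f,
                    "spl_db": spl,
                    "onset_frame": frame,
                    "repetition": rep,
                    "duration_s": dur,
                }
            )
            frame += step
    return StimulusProtocol(events=pd.DataFrame(rows), frame_rate=frame_rate)


def widefield_protocol(
    n_repetitions: int = 16,
    frame_rate: float = 10.0,
    tone_s: float = 0.5,
    pause_s: float = 5.0,
    freqs_khz=WIDEFIELD_FREQS_KHZ,
) -> StimulusProtocol:
    """Widefield tone schedule: 5 tones x 16 repetitions at 10 Hz."""
    freqs_khz = np.asarray(freqs_khz, dtype=float)
    rows = []
    frame = int(round(3.0 * frame_rate))  # lead-in covering the baseline
    step = int(round((tone_s + pause_s) * frame_rate))
    for rep in range(n_repetitions):
        for f in freqs_khz:
            rows.append(
                {
                    "sound_id": f"WF_{f:.0f}kHz",
                    "sound_class": "PT",
                    "frequency_khz": f,
                    "spl_db": 70.0,
                    "onset_frame": frame,
                    "repetition": rep,
                    "duration_s": tone_s,
                }
            )
            frame += step
    return StimulusProtocol(
        events=pd.DataFrame(rows),
        frame_rate=frame_rate,
        pt_freqs_khz=freqs_khz,
        pt_spls_db=np.array([70.0]),
    )
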