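"""Neuron-level preprocessing: PSNR filtering, running exclusion and the
amplitude-rescaling control.

The pipeline starts from motion-corrected, deconvolved recordings (raw
ROI trace, neuropil trace, spike-probability trace); everything upstream
of that is external.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _wavelet
from .protocol import StimulusProtocol

logger = logging.getLogger(__name__)

PSNR_THRESHOLD_DB = 36.0
RUN_SPEED_THRESHOLD = 1.0  # cm/s
MIN_CLEAN_REPETITIONS = 5
RESCALE_FACTOR = 0.86


@dataclass
class NeuronRecording:
    """One imaged neuron's traces and FOV-local metadata.

    Traces are sampled per frame at ``frame_rate``; the spike-probability
    trace is the deconvolved (nonnegative) activity used by most
    downstream analyses.
    """

    neuron_id: str
    raw_trace: np.ndarray
    neuropil_trace: np.ndarray
    spike_prob_trace: np.ndarray
    position: tuple  # (x, y) um, FOV-local
    fov_id: str = "fov0"
    depth: float = 200.0
    frame_rate: float = 29.76

    def __post_init__(self):
        self.raw_trace = np.asarray(self.raw_trace, dtype=float)
        self.neuropil_trace = np.asarray(self.neuropil_trace, dtype=float)
        self.spike_prob_trace = np.asarray(self.spike_prob_trace, dtype=float)
        lengths = {
            self.raw_trace.size,
            self.neuropil_trace.size,
            self.spike_prob_trace.size,
        }
        if len(lengths - {0}) > 1:
            raise ValueError(
                f"neuron {self.neuron_id}: traces have mismatched lengths {lengths}"
            )
        if self.spike_prob_trace.size and np.nanmin(self.spike_prob_trace) < 0:
            raise ValueError(f"neuron {self.neuron_id}: spike probabilities < 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.raw_trace.size


@dataclass
class RepetitionMask:
    """Clean/contaminated flags per (sound, repetition) plus FOV validity."""

    table: pd.DataFrame  # columns: sound_id, repetition, clean
    fov_valid: bool
    min_clean: int = MIN_CLEAN_REPETITIONS

    def is_clean(self, sound_id, repetition) -> bool:
        sel = self.table[
            (self.table["sound_id"] == sound_id)
            & (self.table["repetition"] == repetition)
        ]
        if sel.empty:
            raise KeyError(f"no event ({sound_id}, rep {repetition}) in mask")
        return bool(sel["clean"].all())

    def clean_repetitions(self, sound_id) -> np.ndarray:
        sel = self.table[self.table["sound_id"] == sound_id]
        return np.sort(sel.loc[sel["clean"], "repetition"].to_numpy())

    @classmethod
    def all_clean(cls, protocol: StimulusProtocol) -> "RepetitionMask":
        tab = protocol.events[["sound_id", "repetition"]].copy()
        tab["clean"] = True
        return cls(table=tab, fov_valid=True)

    def to_json(self) -> dict:
        return {
            "fov_valid": bool(self.fov_valid),
            "min_clean": int(self.min_clean),
            "table": self.table.to_dict(orient="list"),
        }


def compute_psnr(rec: NeuronRecording, ddof: int = 0) -> float:
    """Peak signal-to-noise ratio of a trace in decibels.

    ``20 * log10(max(F_raw - F_n) / sigma_n)`` where ``sigma_n`` is the
    standard deviation of the whole neuropil trace.  Degenerate inputs
    (zero neuropil variance, or a ROI trace never exceeding the
    neuropil) return ``-inf`` so the neuron is excluded by any finite
    threshold.
    """
    if rec.raw_trace.size == 0:
        raise ValueError("empty trace")
    sigma_n = float(np.std(rec.neuropil_trace, ddof=ddof))
    if sigma_n == 0.0 or not np.isfinite(sigma_n):
        warnings.warn(
            f"neuron {rec.neuron_id}: neuropil trace has zero/non-finite sd; "
            "PSNR undefined, neuron flagged for exclusion",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    peak = float(np.max(rec.raw_trace - rec.neuropil_trace))
    if peak <= 0:
        return -np.inf
    return 20.0 * np.log10(peak / sigma_n)


def filter_neurons(recs, threshold_db: float = PSNR_THRESHOLD_DB):
    """Retain neurons whose PSNR is at or above ``threshold_db``.

    Only strictly sub-threshold neurons are removed, so a neuron sitting
    exactly at the threshold is kept.
    """
    recs = list(recs)
    if not recs:
        warnings.warn("filter_neurons: empty input", RuntimeWarning, stacklevel=2)
        return []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kept = [rec for rec in recs if compute_psnr(rec) >= threshold_db]
    logger.info("PSNR filter: retained %d / %d neurons", len(kept), len(recs))
    return kept


def exclude_running(
    protocol: StimulusProtocol,
    speed: np.ndarray,
    threshold: float = RUN_SPEED_THRESHOLD,
    min_clean: int = MIN_CLEAN_REPETITIONS,
) -> RepetitionMask:
    """Flag repetitions during which the animal ran.

    A repetition of a sound is contaminated when the running speed
    exceeds ``threshold`` (strictly) during any frame of that sound's
    stimulation window.  The FOV is marked invalid when any sound ends
    up with fewer than ``min_clean`` clean repetitions.
    """
    speed = np.asarray(speed, dtype=float)
    ev = protocol.events
    last_needed = int(
        (ev["onset_frame"] + np.ceil(ev["duration_s"] * protocol.frame_rate)).max()
    )
    if speed.size < last_needed:
        raise ValueError(
            f"speed trace ({speed.size} frames) shorter than protocol "
            f"({last_needed} frames needed)"
        )
    rows = []
    for _, row in ev.iterrows():
        frames = protocol.stim_frames(row)
        contaminated = bool(np.any(speed[frames] > threshold))
        rows.append(
            {
                "sound_id": row["sound_id"],
                "repetition": int(row["repetition"]),
                "clean": not contaminated,
            }
        )
    table = pd.DataFrame(rows)
    counts = table.groupby("sound_id")["clean"].sum()
    fov_valid = bool((counts >= min_clean).all())
    if not fov_valid:
        logger.info(
            "FOV invalid: %d sounds have < %d clean repetitions",
            int((counts < min_clean).sum()),
            min_clean,
        )
    return RepetitionMask(table=table, fov_valid=fov_valid, min_clean=min_clean)


def rescale_trace(
    trace: np.ndarray, factor: float = RESCALE_FACTOR, level: int | None = None
) -> np.ndarray:
    """Scale the denoised component of a trace, keeping its noise intact.

    The trace is wavelet-denoised; the denoised part is multiplied by
    ``factor`` and the residual (trace minus denoised) is added back
    unchanged, so the noise floor of the output matches the input.
    """
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    denoised = _wavelet.denoise(trace, level=level)
    residual = trace - denoised
    return factor * denoised + residual


def rescale_recording(
    rec: NeuronRecording, factor: float = RESCALE_FACTOR
) -> NeuronRecording:
    """Apply :func:`rescale_trace` to the ROI and neuropil traces."""
    return replace(
        rec,
        raw_trace=rescale_trace(rec.raw_trace, factor),
        neuropil_trace=rescale_trace(rec.neuropil_trace, factor),
    )
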