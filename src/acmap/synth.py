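"""Synthetic datasets with planted ground truth.

Every downstream stage is testable by parameter recovery: populations
with a planted tonotopic gradient and tuning classes, trial responses
from planted Gaussian tuning, raw/neuropil/spike-probability traces with
known transient amplitudes, widefield movies with a planted reversal,
and two-session ensemble data with controlled representational drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .ensembles import CellVectorSet
from .preprocess import NeuronRecording
from .protocol import (
    StimulusProtocol,
    from_octaves,
    to_octaves,
    widefield_protocol,
)

CLASSES = ("single", "double", "irregular")


@dataclass
class SynthConfig:
    """Knobs for all synthetic generators; see field names for units."""

    n_neurons: int = 200
    fov_extent_um: float = 820.0
    gradient_axis: tuple = (1.0, 0.0)
    gradient_rate_oct_per_um: float = 4.0 / 820.0
    scatter_sd_oct: float = 0.3
    class_fractions: tuple = (0.25, 0.05, 0.70)  # single, double, irregular
    response_gain: float = 1.0
    trial_noise_sd: float = 0.1
    n_repetitions: int = 10
    frame_rate: float = 29.76
    n_ensembles: int = 3
    drift_fraction: float = 0.0
    rng_seed: int = 0
    # trace generation
    transient_amp: float = 50.0
    transient_tau_s: float = 0.5
    raw_noise_sd: float = 0.2
    neuropil_noise_sd: float = 1.0
    neuropil_baseline: float = 0.0
    neuropil_slow_amp: float = 0.0
    run_prob: float = 0.0
    run_speed_cm_s: float = 3.0
    # widefield generation
    wf_size: int = 128
    wf_hub: tuple | None = None  # (x, y) px; None = frame centre
    wf_crest_frac: float = 0.23  # reversal crest radius / frame size
    wf_extent_frac: float = 0.39  # responsive radius / frame size
    wf_amp_percent: float = 8.0  # peak dF/F response (%)
    wf_tuning_sd_oct: float = 0.6
    wf_noise_sd: float = 0.0  # imaging noise (raw counts)
    wf_drift_amp: float = 0.0  # slow baseline drift (raw counts)
    wf_baseline: float = 1000.0
    wf_n_repetitions: int = 16
    wf_pause_s: float = 3.0  # >= 2 s prestimulus baseline required
    # two-session ensemble data
    n_sounds: int = 15
    n_unassigned_sounds: int = 0
    session_noise_sd: float = 0.0
    loading_sd: float = 0.2

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"config field {f.name} is not finite")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        fracs = np.asarray(self.class_fractions, dtype=float)
        if fracs.size != 3 or np.any(fracs < 0) or abs(fracs.sum() - 1) > 1e-9:
            raise ValueError("class_fractions must be 3 nonnegative values summing to 1")
        for name in ("scatter_sd_oct", "trial_noise_sd", "raw_noise_sd",
                     "neuropil_noise_sd", "session_noise_sd", "wf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValueError("drift_fraction must be in [0, 1]")
        axis = np.asarray(self.gradient_axis, dtype=float)
        if axis.shape != (2,) or np.linalg.norm(axis) == 0:
            raise ValueError("gradient_axis must be a nonzero 2-vector")


@dataclass
class GroundTruth:
    """Planted truth records for one synthetic dataset."""

    # population truth (per neuron)
    classes: np.ndarray | None = None
    bf_khz: np.ndarray | None = None
    bf_oct: np.ndarray | None = None
    gauss_params: pd.DataFrame | None = None  # A1,B1,C1,A2,B2,C2,D
    positions_um: np.ndarray | None = None
    # widefield truth (per pixel)
    wf_bf_khz: np.ndarray | None = None  # planted tone-level BF
    wf_bf_oct_field: np.ndarray | None = None  # continuous octave field
    wf_responsive: np.ndarray | None = None
    wf_hub: tuple | None = None
    wf_crest_radius_px: float | None = None
    wf_margin_px: float | None = None
    # ensemble truth
    sound_ensemble: np.ndarray | None = None  # per sound: ensemble id or -1
    loadings_session1: np.ndarray | None = None  # (N, K)
    loadings_session2: np.ndarray | None = None
    drifted: np.ndarray | None = None  # (N,) bool


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(config: SynthConfig):
    """Neuron stubs (positions + metadata) and planted tuning truth.

    Positions are uniform in the FOV; the true BF is the projection of
    the position onto the gradient axis (octaves) plus Gaussian scatter,
    clipped to the 4-64 kHz range.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_neurons
    pos = rng.uniform(0.0, config.fov_extent_um, size=(n, 2))
    axis = np.asarray(config.gradient_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = pos @ axis
    bf_oct = (
        2.0
        + (proj - config.fov_extent_um / 2.0) * config.gradient_rate_oct_per_um
        + rng.normal(0.0, config.scatter_sd_oct, size=n)
    )
    bf_oct = np.clip(bf_oct, 0.0, 4.0)
    bf_khz = from_octaves(bf_oct)
    classes = rng.choice(
        np.array(CLASSES), size=n, p=np.asarray(config.class_fractions, float)
    )
    g = config.response_gain
    a1 = g * rng.uniform(0.8, 1.2, size=n)
    c1 = rng.uniform(0.3, 0.6, size=n)
    d = g * rng.uniform(0.0, 0.05, size=n)
    b1 = bf_oct.copy()
    a2 = np.full(n, np.nan)
    b2 = np.full(n, np.nan)
    c2 = np.full(n, np.nan)
    for i in range(n):
        if classes[i] == "double":
            sep = rng.uniform(1.5, 2.5)
            cand = b1[i] + sep if b1[i] + sep <= 4.0 else b1[i] - sep
            b2[i] = np.clip(cand, 0.0, 4.0)
            a2[i] = a1[i] * rng.uniform(0.5, 0.9)
            c2[i] = rng.uniform(0.3, 0.6)
        elif classes[i] == "irregular":
            a1[i] = 0.0
    params = pd.DataFrame(
        {"A1": a1, "B1": b1, "C1": c1, "A2": a2, "B2": b2, "C2": c2, "D": d}
    )
    recordings = [
        NeuronRecording(
            neuron_id=f"n{i:05d}",
            raw_trace=np.empty(0),
            neuropil_trace=np.empty(0),
            spike_prob_trace=np.empty(0),
            position=(float(pos[i, 0]), float(pos[i, 1])),
            fov_id="fov0",
            frame_rate=config.frame_rate,
        )
        for i in range(n)
    ]
    truth = GroundTruth(
        classes=classes,
        bf_khz=bf_khz,
        bf_oct=bf_oct,
        gauss_params=params,
        positions_um=pos,
    )
    return recordings, truth


# ---------------------------------------------------------------------------
# trial responses
# ---------------------------------------------------------------------------

def spl_gain(spl_db) -> np.ndarray:
    """Monotone saturating gain, 0.4 at 30 dB SPL rising to 1.0 at 70 dB."""
    spl = np.asarray(spl_db, dtype=float)
    return 0.4 + 0.6 * np.tanh((spl - 30.0) / 30.0) / np.tanh(40.0 / 30.0)


def planted_mean_response(truth: GroundTruth, x_oct, spl_db) -> np.ndarray:
    """Noiseless per-neuron mean response at octave position(s) x."""
    p = truth.gauss_params
    x = np.atleast_1d(np.asarray(x_oct, dtype=float))[None, :]
    a1 = p["A1"].to_numpy()[:, None]
    b1 = p["B1"].to_numpy()[:, None]
    c1 = p["C1"].to_numpy()[:, None]
    gauss = a1 * np.exp(-(((x - b1) / c1) ** 2))
    a2 = p["A2"].to_numpy()[:, None]
    has2 = np.isfinite(a2)
    if has2.any():
        b2 = p["B2"].to_numpy()[:, None]
        c2 = p["C2"].to_numpy()[:, None]
        with np.errstate(invalid="ignore"):
            g2 = np.where(has2, a2 * np.exp(-(((x - b2) / c2) ** 2)), 0.0)
        gauss = gauss + np.nan_to_num(g2)
    return gauss * spl_gain(spl_db) + p["D"].to_numpy()[:, None]


def generate_trial_responses(
    truth: GroundTruth, protocol: StimulusProtocol, config: SynthConfig
) -> pd.DataFrame:
    """Per (neuron, PT event) mean post-onset responses.

    Response = planted tuning at the tone's octave position x SPL gain
    + offset + i.i.d. Gaussian noise, rectified at 0.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    ev = protocol.pt_events().reset_index(drop=True)
    freqs = ev["frequency_khz"].to_numpy(dtype=float)
    if np.any(freqs < 4.0 - 1e-9) or np.any(freqs > 64.0 + 1e-9):
        raise ValueError("tone frequency outside the planted 4-64 kHz axis")
    x = to_octaves(freqs)
    means = np.empty((config.n_neurons, len(ev)))
    for j in range(len(ev)):
        means[:, j] = planted_mean_response(truth, x[j], ev.loc[j, "spl_db"])[:, 0]
    noise = rng.normal(0.0, config.trial_noise_sd, size=means.shape)
    resp = np.maximum(means + noise, 0.0)
    n, m = resp.shape
    out = pd.DataFrame(
        {
            "neuron_id": np.repeat([f"n{i:05d}" for i in range(n)], m),
            "sound_id": np.tile(ev["sound_id"].to_numpy(), n),
            "frequency_khz": np.tile(freqs, n),
            "spl_db": np.tile(ev["spl_db"].to_numpy(dtype=float), n),
            "repetition": np.tile(ev["repetition"].to_numpy(dtype=int), n),
            "response": resp.ravel(),
        }
    )
    return out


def responses_to_grid(
    responses: pd.DataFrame, protocol: StimulusProtocol
) -> np.ndarray:
    """Pivot a trial-response table into (neuron, freq, spl, rep) array."""
    freqs = protocol.pt_freqs_khz
    spls = protocol.pt_spls_db
    n_rep = protocol.n_repetitions
    neuron_ids = sorted(responses["neuron_id"].unique())
    fi = {round(f, 6): i for i, f in enumerate(freqs)}
    si = {round(s, 6): j for j, s in enumerate(spls)}
    ni = {nid: k for k, nid in enumerate(neuron_ids)}
    grid = np.full((len(neuron_ids), freqs.size, spls.size, n_rep), np.nan)
    idx_n = responses["neuron_id"].map(ni).to_numpy()
    idx_f = responses["frequency_khz"].round(6).map(fi).to_numpy()
    idx_s = responses["spl_db"].round(6).map(si).to_numpy()
    idx_r = responses["repetition"].to_numpy(dtype=int)
    grid[idx_n, idx_f, idx_s, idx_r] = responses["response"].to_numpy()
    return grid


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def generate_traces(
    truth: GroundTruth, protocol: StimulusProtocol, config: SynthConfig
):
    """Raw/neuropil/spike-probability traces per neuron plus a speed trace.

    raw = 0.7 * neuropil + transients (exponential decay at event times,
    amplitude following the planted tuning, peak = ``transient_amp``)
    + white noise; neuropil = baseline + optional slow wave + white
    noise; the speed trace alternates rest and run bouts.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    n_frames = protocol.n_frames
    fr = protocol.frame_rate
    t = np.arange(n_frames) / fr
    ev = protocol.pt_events().reset_index(drop=True)
    x = to_octaves(ev["frequency_khz"].to_numpy(dtype=float))
    # normalized planted response per neuron/event (peak 1 at the BF)
    mean_resp = np.stack(
        [
            planted_mean_response(truth, x[j], ev.loc[j, "spl_db"])[:, 0]
            for j in range(len(ev))
        ],
        axis=1,
    )  # (n, n_events)
    peak = mean_resp.max(axis=1, keepdims=True)
    peak[peak <= 0] = 1.0
    norm_resp = np.clip(mean_resp / peak, 0.0, None)
    kernel = np.exp(-np.arange(0, int(5 * config.transient_tau_s * fr)) /
                    (config.transient_tau_s * fr))
    onsets = ev["onset_frame"].to_numpy(dtype=int)
    recordings = []
    for i in range(config.n_neurons):
        neuropil = (
            config.neuropil_baseline
            + config.neuropil_slow_amp * np.sin(2 * np.pi * t / 60.0)
            + rng.normal(0.0, config.neuropil_noise_sd, size=n_frames)
        )
        transients = np.zeros(n_frames)
        spike_prob = np.zeros(n_frames)
        for j, onset in enumerate(onsets):
            amp = config.transient_amp * norm_resp[i, j]
            if amp <= 0 or onset >= n_frames:
                continue
            seg = kernel[: n_frames - onset]
            transients[onset : onset + seg.size] += amp * seg
            spike_prob[onset] += norm_resp[i, j]
        raw = (
            0.7 * neuropil
            + transients
            + rng.normal(0.0, config.raw_noise_sd, size=n_frames)
        )
        recordings.append(
            NeuronRecording(
                neuron_id=f"n{i:05d}",
                raw_trace=raw,
                neuropil_trace=neuropil,
                spike_prob_trace=spike_prob,
                position=tuple(truth.positions_um[i])
                if truth.positions_um is not None
                else (0.0, 0.0),
                frame_rate=fr,
            )
        )
    # rest/run bouts in 1 s blocks
    speed = np.zeros(n_frames)
    block = max(1, int(round(fr)))
    for start in range(0, n_frames, block):
        if rng.uniform() < config.run_prob:
            speed[start : start + block] = config.run_speed_cm_s * rng.uniform(
                0.8, 1.2
            )
    return recordings, speed


# ---------------------------------------------------------------------------
# widefield
# ---------------------------------------------------------------------------

def _wf_response_amplitudes(config: SynthConfig, bf_oct_field, tone_octs):
    """Noiseless response amplitude (%) per tone at every pixel."""
    d = bf_oct_field[None, :, :] - tone_octs[:, None, None]
    return config.wf_amp_percent * np.exp(
        -(d**2) / (2.0 * config.wf_tuning_sd_oct**2)
    )


def generate_widefield_movie(config: SynthConfig):
    """Widefield movie with a planted low-frequency hub and reversal.

    The octave field rises linearly from the hub to a crest (the planted
    reversal ring) and falls beyond it; pixels outside the responsive
    radius never respond, leaving an unresponsive margin before the
    frame edge.  Returns ``(movie, protocol, truth)``.
    """
    size = config.wf_size
    if size < 64:
        raise ValueError("widefield frame must be at least 64 x 64")
    hub = config.wf_hub if config.wf_hub is not None else (size / 2.0, size / 2.0)
    if not (0 <= hub[0] < size and 0 <= hub[1] < size):
        raise ValueError(f"hub {hub} outside the {size} x {size} frame")
    rng = np.random.default_rng(config.rng_seed + 3)
    protocol = widefield_protocol(
        n_repetitions=config.wf_n_repetitions, pause_s=config.wf_pause_s
    )
    tone_freqs = protocol.pt_freqs_khz
    tone_octs = to_octaves(tone_freqs)

    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - hub[0], yy - hub[1])
    crest = config.wf_crest_frac * size
    extent = config.wf_extent_frac * size
    margin = size / 2.0 - extent
    rising = np.clip(r / crest, 0.0, 1.0) * 4.0
    falling = np.clip((r - crest) / max(extent - crest, 1.0), 0.0, 1.0) * 3.0
    bf_oct_field = rising - falling
    responsive = r <= extent

    # tones sit at integer octaves, so the planted per-pixel tuning is
    # anchored to the nearest tone; this keeps a clear amplitude margin
    # between the best and runner-up tone at every pixel
    quantized_oct = np.round(bf_oct_field)
    amps = _wf_response_amplitudes(config, quantized_oct, tone_octs)
    amps[:, ~responsive] = 0.0
    wf_bf = np.where(responsive, from_octaves(quantized_oct), np.nan)

    t_frames = protocol.n_frames
    fr = protocol.frame_rate
    movie = np.full((t_frames, size, size), config.wf_baseline, dtype=np.float32)
    if config.wf_drift_amp > 0:
        drift = config.wf_drift_amp * np.sin(
            2 * np.pi * np.arange(t_frames) / (60.0 * fr)
        )
        movie += drift[:, None, None].astype(np.float32)
    # response time course: sustained over the tone, brief decay after
    shape = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.6, 0.3], dtype=np.float32)
    tone_idx = {round(f, 6): i for i, f in enumerate(tone_freqs)}
    for _, row in protocol.events.iterrows():
        onset = int(row["onset_frame"])
        ti = tone_idx[round(row["frequency_khz"], 6)]
        bump = (config.wf_baseline / 100.0) * amps[ti]
        for k, s in enumerate(shape):
            if onset + k < t_frames:
                movie[onset + k] += (s * bump).astype(np.float32)
    if config.wf_noise_sd > 0:
        movie += rng.normal(0.0, config.wf_noise_sd, size=movie.shape).astype(
            np.float32
        )
    truth = GroundTruth(
        wf_bf_khz=wf_bf,
        wf_bf_oct_field=bf_oct_field,
        wf_responsive=responsive,
        wf_hub=tuple(hub),
        wf_crest_radius_px=float(crest),
        wf_margin_px=float(margin),
    )
    return movie, protocol, truth


# ---------------------------------------------------------------------------
# two sessions
# ---------------------------------------------------------------------------

def _draw_loadings(rng, n_neurons, n_ensembles, loading_sd):
    assign = rng.integers(0, n_ensembles, size=n_neurons)
    load = np.zeros((n_neurons, n_ensembles))
    load[np.arange(n_neurons), assign] = np.abs(
        rng.normal(1.0, loading_sd, size=n_neurons)
    )
    return load


def generate_two_sessions(config: SynthConfig, ensemble_sizes=None):
    """Two-session ensemble data with controlled drift.

    Each sound belongs to one of ``n_ensembles`` latent ensembles (or to
    none); a neuron's response to a sound is its loading on the sound's
    ensemble plus noise.  In session 2 the loadings of a
    ``drift_fraction`` of neurons are redrawn independently.
    """
    k = config.n_ensembles
    s = config.n_sounds
    if k > s:
        raise ValueError("more ensembles than sounds")
    rng = np.random.default_rng(config.rng_seed + 4)
    n = config.n_neurons
    n_assigned = s - config.n_unassigned_sounds
    if ensemble_sizes is not None:
        if sum(ensemble_sizes) != n_assigned or len(ensemble_sizes) != k:
            raise ValueError("ensemble_sizes inconsistent with config")
        sound_ens = np.concatenate(
            [np.full(sz, i) for i, sz in enumerate(ensemble_sizes)]
            + [np.full(config.n_unassigned_sounds, -1)]
        )
    else:
        sound_ens = np.concatenate(
            [np.arange(n_assigned) % k, np.full(config.n_unassigned_sounds, -1)]
        )
    load1 = _draw_loadings(rng, n, k, config.loading_sd)
    load2 = load1.copy()
    n_drift = int(round(config.drift_fraction * n))
    drifted = np.zeros(n, dtype=bool)
    if n_drift:
        idx = rng.choice(n, size=n_drift, replace=False)
        drifted[idx] = True
        redraw = _draw_loadings(rng, n_drift, k, config.loading_sd)
        load2[idx] = redraw

    def _session(load, rng_s):
        vals = np.empty((s, config.n_repetitions, n))
        for si in range(s):
            base = load[:, sound_ens[si]] if sound_ens[si] >= 0 else np.zeros(n)
            noise = rng_s.normal(
                0.0, config.session_noise_sd, size=(config.n_repetitions, n)
            )
            vals[si] = np.maximum(base[None, :] + noise, 0.0)
        sound_ids = [f"S{si:02d}" for si in range(s)]
        return CellVectorSet(values=vals, sound_ids=sound_ids)

    sess1 = _session(load1, np.random.default_rng(config.rng_seed + 5))
    sess2 = _session(load2, np.random.default_rng(config.rng_seed + 6))
    truth = GroundTruth(
        sound_ensemble=sound_ens,
        loadings_session1=load1,
        loadings_session2=load2,
        drifted=drifted,
    )
    return sess1, sess2, truth
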