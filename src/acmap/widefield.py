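"""Widefield best-frequency mapping and subfield parcellation.

Pixelwise dF/F against a sliding polynomial baseline, z-scored evoked
response detection, best-frequency maps with FOV merging, radial-vector
reversal detection from low-frequency hubs, and a boundary rule based on
runs of unresponsive pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .protocol import to_octaves

BASELINE_WINDOW_S = 15.0
BASELINE_DEGREE = 3
PRESTIM_S = 2.0
POST_WINDOW_S = 0.75
Z_THRESHOLD = 2.0
MIN_EVOKED_REPS = 4
N_RADIAL_VECTORS = 1440
RADIAL_HALFWIDTH_DEG = 1.0
SMOOTH_WINDOW = 10
BOUNDARY_RUN = 10


# ---------------------------------------------------------------------------
# dF/F
# ---------------------------------------------------------------------------

def preprocess_movie(
    movie: np.ndarray,
    frame_rate: float = 10.0,
    window_s: float = BASELINE_WINDOW_S,
    degree: int = BASELINE_DEGREE,
):
    """Pixelwise percent dF/F against a sliding polynomial baseline.

    The baseline F0 is the centered degree-3 polynomial fit within a
    ``window_s`` sliding window (a Savitzky-Golay filter; edge windows
    are handled by fitting the polynomial to the clipped window).
    Returns ``(dff, valid)`` where ``valid`` flags pixels whose baseline
    stayed positive throughout.
    """
    movie = np.asarray(movie, dtype=float)
    t = movie.shape[0]
    win = int(round(window_s * frame_rate))
    if win % 2 == 0:
        win += 1
    if t <= win:
        raise ValueError(
            f"movie too short ({t} frames) for a {window_s} s baseline window"
        )
    f0 = signal.savgol_filter(movie, win, degree, axis=0, mode="interp")
    valid = np.all(f0 > 0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (movie - f0) / f0 * 100.0
    dff[:, ~valid] = np.nan
    return dff, valid


# ---------------------------------------------------------------------------
# evoked responses
# ---------------------------------------------------------------------------

def evoked_amplitude(
    dff: np.ndarray,
    onsets: np.ndarray,
    frame_rate: float = 10.0,
    prestim_s: float = PRESTIM_S,
    post_s: float = POST_WINDOW_S,
    z_threshold: float = Z_THRESHOLD,
):
    """Per-event response amplitude and evoked flag for every pixel.

    For each onset the baseline mean/sd come from the ``prestim_s``
    pre-onset frames; the response is the maximum of the ``post_s``
    post-onset window after averaging each frame with its two
    neighbours, taken relative to the baseline mean.  Evoked requires a
    z-score strictly above ``z_threshold``.

    ``dff`` is (T, ...); returns arrays shaped (n_events, ...).
    """
    dff = np.asarray(dff, dtype=float)
    onsets = np.asarray(onsets, dtype=int)
    pre_n = int(round(prestim_s * frame_rate))
    post_n = int(round(post_s * frame_rate))
    spatial = dff.shape[1:]
    amps = np.full((onsets.size,) + spatial, np.nan)
    evoked = np.zeros((onsets.size,) + spatial, dtype=bool)
    # 3-frame neighbour average along time
    kernel_avg = np.empty_like(dff)
    kernel_avg[1:-1] = (dff[:-2] + dff[1:-1] + dff[2:]) / 3.0
    kernel_avg[0] = (dff[0] + dff[1]) / 2.0
    kernel_avg[-1] = (dff[-2] + dff[-1]) / 2.0
    n_skipped = 0
    for k, onset in enumerate(onsets):
        if onset - pre_n < 0 or onset + post_n > dff.shape[0]:
            raise ValueError(
                f"event at frame {onset} lacks a full {prestim_s} s baseline "
                "or response window"
            )
        base = dff[onset - pre_n : onset]
        mu = base.mean(axis=0)
        sd = base.std(axis=0)
        resp = kernel_avg[onset : onset + post_n].max(axis=0)
        amp = resp - mu
        with np.errstate(divide="ignore", invalid="ignore"):
            z = amp / sd
        ok = sd > 0
        n_skipped += int(np.sum(~ok & np.isfinite(mu)))
        amps[k] = np.where(ok, amp, np.nan)
        evoked[k] = ok & (z > z_threshold)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} pixel-repetitions with zero baseline sd skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return amps, evoked


# ---------------------------------------------------------------------------
# best-frequency maps
# ---------------------------------------------------------------------------

@dataclass
class PixelBFMap:
    """Per-pixel best frequency, response amplitude and responsive mask."""

    bf_khz: np.ndarray  # (H, W), NaN where not responsive
    amplitude: np.ndarray  # (H, W) mean evoked amplitude of the BF tone
    responsive: np.ndarray  # (H, W) bool
    fov_id: str = "wf0"

    def __post_init__(self):
        if np.any(np.isfinite(self.bf_khz) & ~self.responsive):
            raise ValueError("BF defined at non-responsive pixels")


def pixel_bf(
    amps: np.ndarray,
    evoked: np.ndarray,
    freqs_khz: np.ndarray,
    min_evoked: int = MIN_EVOKED_REPS,
    fov_id: str = "wf0",
) -> PixelBFMap:
    """Best frequency per pixel from per-repetition evoked amplitudes.

    ``amps``/``evoked`` are (n_tones, n_reps, H, W).  A tone qualifies at
    a pixel when it was evoked in at least ``min_evoked`` repetitions;
    its amplitude is the mean over the evoked repetitions only.  The BF
    is the qualifying tone with the highest mean amplitude (ties toward
    the lower frequency); pixels with no qualifying tone are
    non-responsive.
    """
    amps = np.asarray(amps, dtype=float)
    evoked = np.asarray(evoked, dtype=bool)
    freqs_khz = np.asarray(freqs_khz, dtype=float)
    n_tones = amps.shape[0]
    counts = evoked.sum(axis=1)  # (n_tones, H, W)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        masked = np.where(evoked, amps, np.nan)
        tone_amp = np.nanmean(masked, axis=1)
    qualify = counts >= min_evoked
    tone_amp = np.where(qualify, tone_amp, -np.inf)
    responsive = qualify.any(axis=0)
    order = np.argsort(freqs_khz)  # scan low to high so ties pick lower
    best_idx = np.zeros(responsive.shape, dtype=int)
    best_amp = np.full(responsive.shape, -np.inf)
    for i in order:
        better = tone_amp[i] > best_amp
        best_idx = np.where(better, i, best_idx)
        best_amp = np.where(better, tone_amp[i], best_amp)
    bf = np.where(responsive, freqs_khz[best_idx], np.nan)
    amplitude = np.where(responsive, best_amp, np.nan)
    return PixelBFMap(
        bf_khz=bf, amplitude=amplitude, responsive=responsive, fov_id=fov_id
    )


def merge_fov_maps(maps) -> PixelBFMap:
    """Merge per-FOV BF maps registered to one shared pixel grid.

    Amplitudes are first normalized within each FOV to its maximum;
    where FOVs overlap, the BF with the higher normalized amplitude
    wins.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to merge")
    shape = maps[0].bf_khz.shape
    if any(m.bf_khz.shape != shape for m in maps):
        raise ValueError("maps are not registered to a shared pixel grid")
    best_norm = np.full(shape, -np.inf)
    bf = np.full(shape, np.nan)
    responsive = np.zeros(shape, dtype=bool)
    for m in maps:
        peak = np.nanmax(m.amplitude) if np.any(m.responsive) else np.nan
        norm = m.amplitude / peak if peak and peak > 0 else m.amplitude
        take = m.responsive & ~np.isnan(norm) & (norm > best_norm)
        bf[take] = m.bf_khz[take]
        best_norm[take] = norm[take]
        responsive |= m.responsive
    amplitude = np.where(responsive, best_norm, np.nan)
    return PixelBFMap(
        bf_khz=bf, amplitude=amplitude, responsive=responsive, fov_id="merged"
    )


# ---------------------------------------------------------------------------
# hubs, reversals, boundary, parcellation
# ---------------------------------------------------------------------------

def detect_hubs(
    bf_map: PixelBFMap,
    quantile: float = 0.2,
    median_size: int = 3,
    min_area: int = 25,
):
    """Centroids of connected low-frequency regions (lowest-BF quantile)."""
    bf_oct = to_octaves(bf_map.bf_khz)
    filled = np.where(bf_map.responsive, bf_oct, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = ndimage.generic_filter(filled, np.nanmedian, size=median_size)
    vals = filled[np.isfinite(filled)]
    if vals.size == 0:
        return []
    thr = np.quantile(vals, quantile)
    low = bf_map.responsive & (med <= thr)
    lab, n = ndimage.label(low)
    hubs = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(lab == i)
        if ys.size < min_area:
            continue
        hubs.append((float(xs.mean()), float(ys.mean())))
    return hubs


@dataclass
class ParcellationResult:
    """Reversal points per radial direction, boundary points, labels."""

    hubs: list
    angles_deg: np.ndarray
    reversal_radii: np.ndarray  # (n_hubs, n_angles), NaN = none
    reversal_points: np.ndarray  # (n_hubs, n_angles, 2) (x, y)
    boundary_radii: np.ndarray
    boundary_points: np.ndarray
    label_map: np.ndarray | None = None  # (H, W) strings
    border_polylines: dict = field(default_factory=dict)


def _gauss3(r, p):
    a1, m1, s1, a2, m2, s2, a3, m3, s3, d = p
    return (
        a1 * np.exp(-(((r - m1) / s1) ** 2))
        + a2 * np.exp(-(((r - m2) / s2) ** 2))
        + a3 * np.exp(-(((r - m3) / s3) ** 2))
        + d
    )


def _fit_radial_profile(r, y, mode: str):
    """Fit/smooth a radial BF profile; returns values on the same grid."""
    if mode == "smooth":
        return ndimage.gaussian_filter1d(y, sigma=3.0, mode="nearest")
    if mode != "gauss3":
        raise ValueError(f"unknown radial fit mode {mode!r}")
    rmax = r[-1] if r.size else 1.0
    amp = max(y.max() - y.min(), 1e-9)
    p0 = np.array(
        [
            amp, r[np.argmax(y)], rmax / 4,
            amp / 2, rmax / 3, rmax / 4,
            amp / 2, 2 * rmax / 3, rmax / 4,
            y.min(),
        ]
    )
    lo = np.array([0, 0, 1, 0, 0, 1, 0, 0, 1, -np.inf])
    hi = np.array(
        [np.inf, rmax, rmax, np.inf, rmax, rmax, np.inf, rmax, rmax, np.inf]
    )
    try:
        res = optimize.least_squares(
            lambda p: _gauss3(r, p) - y,
            x0=np.clip(p0, lo, hi),
            bounds=(lo, hi),
            max_nfev=200,
        )
        fitted = _gauss3(r, res.x)
        if np.all(np.isfinite(fitted)):
            return fitted
    except (ValueError, RuntimeError):
        pass
    return ndimage.gaussian_filter1d(y, sigma=3.0, mode="nearest")


def _first_local_max(y: np.ndarray, tol: float = 1e-9):
    """Index of the first interior local maximum, or None."""
    for i in range(1, y.size - 1):
        if y[i] > y[i - 1] + tol and y[i] >= y[i + 1] - tol:
            # require an eventual drop to rule out plateau edges
            j = i
            while j + 1 < y.size and abs(y[j + 1] - y[i]) <= tol:
                j += 1
            if j + 1 < y.size and y[j + 1] < y[i] - tol:
                return i
    return None


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if y.size < window:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    out = np.convolve(ypad, kernel, mode="same")[pad : pad + y.size]
    return out


def find_reversals_and_boundary(
    bf_map: PixelBFMap,
    hubs,
    n_angles: int = N_RADIAL_VECTORS,
    halfwidth_deg: float = RADIAL_HALFWIDTH_DEG,
    smooth_window: int = SMOOTH_WINDOW,
    fit_mode: str = "gauss3",
    boundary_run: int = BOUNDARY_RUN,
    min_samples: int = 10,
) -> ParcellationResult:
    """Scan radial vectors from each hub for tonotopic reversal points.

    For each of ``n_angles`` directions the BF (octave scale) is averaged
    over sub-rays within +-``halfwidth_deg``, smoothed with a
    ``smooth_window``-sample moving average, fitted (three-Gaussian sum
    by default), and the first interior local maximum marks the reversal
    radius.  Independently, the first run of ``boundary_run`` radially
    consecutive unresponsive samples marks the edge of the responsive
    territory.
    """
    hubs = list(hubs)
    if not hubs:
        raise ValueError("at least one hub center is required")
    h, w = bf_map.bf_khz.shape
    for hx, hy in hubs:
        if not (0 <= hx < w and 0 <= hy < h):
            raise ValueError(f"hub ({hx}, {hy}) lies outside the frame")
    bf_oct = to_octaves(bf_map.bf_khz)
    angles = np.arange(n_angles) * (360.0 / n_angles)
    sub = np.linspace(-halfwidth_deg, halfwidth_deg, 9)
    rev_r = np.full((len(hubs), n_angles), np.nan)
    rev_p = np.full((len(hubs), n_angles, 2), np.nan)
    bnd_r = np.full((len(hubs), n_angles), np.nan)
    bnd_p = np.full((len(hubs), n_angles, 2), np.nan)
    for hi_, (hx, hy) in enumerate(hubs):
        rmax = int(np.ceil(np.hypot(h, w)))
        radii = np.arange(1, rmax + 1, dtype=float)
        for ai, ang in enumerate(angles):
            theta = np.deg2rad(ang + sub)  # (9,)
            xs = hx + radii[:, None] * np.cos(theta)[None, :]
            ys = hy + radii[:, None] * np.sin(theta)[None, :]
            xi = np.round(xs).astype(int)
            yi = np.round(ys).astype(int)
            inside = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            vals = np.full(xi.shape, np.nan)
            resp = np.zeros(xi.shape, dtype=bool)
            vals[inside] = bf_oct[yi[inside], xi[inside]]
            resp[inside] = bf_map.responsive[yi[inside], xi[inside]]
            in_frame = inside.any(axis=1)
            n_in = int(in_frame.sum())
            if n_in == 0:
                continue
            resp_any = resp.any(axis=1)[:n_in]
            # boundary: first run of `boundary_run` unresponsive samples
            run = 0
            for k in range(n_in):
                run = 0 if resp_any[k] else run + 1
                if run >= boundary_run:
                    r_end = radii[k - boundary_run + 1]
                    bnd_r[hi_, ai] = r_end
                    bnd_p[hi_, ai] = (
                        hx + r_end * np.cos(np.deg2rad(ang)),
                        hy + r_end * np.sin(np.deg2rad(ang)),
                    )
                    break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                profile = np.nanmean(vals, axis=1)
            valid = np.isfinite(profile)
            if valid.sum() < max(min_samples, smooth_window):
                continue
            r_valid = radii[valid]
            y_valid = profile[valid]
            stop = np.nonzero(np.diff(r_valid) > boundary_run)[0]
            if stop.size:  # do not scan past large unresponsive gaps
                r_valid = r_valid[: stop[0] + 1]
                y_valid = y_valid[: stop[0] + 1]
            if r_valid.size < max(min_samples, smooth_window):
                continue
            smoothed = _moving_average(y_valid, smooth_window)
            fitted = _fit_radial_profile(r_valid, smoothed, fit_mode)
            idx = _first_local_max(fitted)
            if idx is None:
                continue
            r_rev = r_valid[idx]
            rev_r[hi_, ai] = r_rev
            rev_p[hi_, ai] = (
                hx + r_rev * np.cos(np.deg2rad(ang)),
                hy + r_rev * np.sin(np.deg2rad(ang)),
            )
    return ParcellationResult(
        hubs=hubs,
        angles_deg=angles,
        reversal_radii=rev_r,
        reversal_points=rev_p,
        boundary_radii=bnd_r,
        boundary_points=bnd_p,
    )


def _polygon_mask(shape, polygon):
    from skimage.draw import polygon as draw_polygon

    poly = np.asarray(polygon, dtype=float)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def parcellate(
    bf_map: PixelBFMap,
    result: ParcellationResult,
    mode: str = "auto",
    borders: dict | None = None,
) -> ParcellationResult:
    """Assign subfield labels to the responsive territory.

    ``import`` mode applies externally supplied closed border polygons
    (``{label: [(x, y), ...]}``), replacing the manual drawing step.
    ``auto`` mode connects the reversal points of the first hub into a
    closed border and labels regions relative to the hub (inside the
    reversal border -> A1; outside, anterior of the hub -> AAF, else
    A2).  The auto assignment is an explicit heuristic approximation and
    is marked as such in the result.
    """
    shape = bf_map.bf_khz.shape
    labels = np.full(shape, "none", dtype=object)
    polylines = {}
    if mode == "import":
        if not borders:
            raise ValueError("import mode requires border polygons")
        for name, poly in borders.items():
            poly = np.asarray(poly, dtype=float)
            if poly.shape[0] < 3 or not np.allclose(poly[0], poly[-1]):
                raise ValueError(
                    f"border {name!r} is open (first and last vertex differ)"
                )
            labels[_polygon_mask(shape, poly[:-1])] = name
            polylines[name] = poly.tolist()
    elif mode == "auto":
        pts = result.reversal_points[0]
        good = np.isfinite(pts[:, 0])
        if good.sum() < 3:
            labels[bf_map.responsive] = "unassigned"
        else:
            poly = pts[good]
            hub = result.hubs[0]
            inside = _polygon_mask(shape, poly)
            labels[bf_map.responsive & inside] = "A1"
            ys, xs = np.nonzero(bf_map.responsive & ~inside)
            anterior = xs >= hub[0]
            labels[ys[anterior], xs[anterior]] = "AAF"
            labels[ys[~anterior], xs[~anterior]] = "A2"
            polylines["reversal_border"] = np.vstack([poly, poly[:1]]).tolist()
            polylines["note"] = "auto parcellation heuristic"
    else:
        raise ValueError(f"unknown parcellation mode {mode!r}")
    result.label_map = labels
    result.border_polylines = polylines
    return result
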