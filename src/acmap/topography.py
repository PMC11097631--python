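"""Global neuron maps and local tonotopic heterogeneity.

The heterogeneity statistic is the interquartile range of best
frequencies (octave scale) over all single-peak neurons within a 100 um
radius of each neuron; neighborhoods with fewer than five members yield
no value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .protocol import to_octaves

IQR_RADIUS_UM = 100.0
IQR_MIN_NEIGHBORS = 5

#: Named frequency bands (kHz); the grid tones between 17 and 24 kHz
#: belong to no named band and are reported under "other".
DEFAULT_BANDS = {
    "low": (4.0, 6.0, "left"),     # [4, 6)
    "mid": (6.0, 17.0, "both"),    # [6, 17]
    "high": (24.0, 64.0, "both"),  # [24, 64]
}


def to_global(neurons: pd.DataFrame, fov_offsets: dict) -> pd.DataFrame:
    """Convert FOV-local positions into a global coordinate system.

    ``neurons`` needs columns ``neuron_id``, ``fov_id``, ``x_um``,
    ``y_um`` (FOV-local) and any payload columns (``bf_khz``,
    ``tuning_class``, ``subfield`` ...).  Offsets are per-FOV (dx, dy)
    in micrometres; within-FOV pairwise distances are preserved exactly.
    """
    missing = set(neurons["fov_id"]) - set(fov_offsets)
    if missing:
        raise KeyError(f"no global offset for FOV(s): {sorted(missing)}")
    if neurons["neuron_id"].duplicated().any():
        dups = neurons.loc[neurons["neuron_id"].duplicated(), "neuron_id"]
        raise ValueError(f"duplicated neuron ids: {sorted(set(dups))[:5]}")
    out = neurons.copy()
    dx = out["fov_id"].map(lambda f: fov_offsets[f][0]).astype(float)
    dy = out["fov_id"].map(lambda f: fov_offsets[f][1]).astype(float)
    out["x_um"] = out["x_um"].astype(float) + dx
    out["y_um"] = out["y_um"].astype(float) + dy
    if "bf_khz" in out.columns and "bf_oct" not in out.columns:
        out["bf_oct"] = to_octaves(out["bf_khz"])
    return out


def local_bf_iqr(
    neuron_map: pd.DataFrame,
    radius_um: float = IQR_RADIUS_UM,
    min_n: int = IQR_MIN_NEIGHBORS,
    scale: str = "octave",
) -> pd.Series:
    """Per-neuron IQR of best frequencies within ``radius_um``.

    Only single-peak neurons enter, both as centers and as neighbors
    (the neuron itself included).  Quartiles use linear interpolation
    between order statistics.  Returns a Series indexed like the
    single-peak subset, NaN where fewer than ``min_n`` neurons fall in
    the neighborhood.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    single = neuron_map[neuron_map["tuning_class"] == "single"]
    if single.empty:
        return pd.Series(dtype=float, name="bf_iqr")
    xy = single[["x_um", "y_um"]].to_numpy(dtype=float)
    if scale == "octave":
        bf = (
            single["bf_oct"].to_numpy(dtype=float)
            if "bf_oct" in single
            else to_octaves(single["bf_khz"].to_numpy(dtype=float))
        )
    elif scale == "khz":
        bf = single["bf_khz"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(xy, r=radius_um)
    out = np.full(len(single), np.nan)
    for i, nbrs in enumerate(neighbor_lists):
        if len(nbrs) < min_n:
            continue
        vals = bf[nbrs]
        q1, q3 = np.percentile(vals, [25.0, 75.0])  # linear interpolation
        out[i] = q3 - q1
    return pd.Series(out, index=single.index, name="bf_iqr")


def _in_band(bf_khz: np.ndarray, lo: float, hi: float, closed: str) -> np.ndarray:
    if closed == "left":
        return (bf_khz >= lo) & (bf_khz < hi)
    if closed == "both":
        return (bf_khz >= lo) & (bf_khz <= hi)
    raise ValueError(closed)


def bf_distribution(neuron_map: pd.DataFrame, bands: dict | None = None) -> dict:
    """Fractions of single-peak neurons per frequency band per subfield.

    Bands are ``{name: (lo_khz, hi_khz, closed)}``; overlapping bands are
    rejected.  Neurons falling in no band count toward ``"other"``.
    Subfields with no single-peak neurons are reported as None.
    """
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    edges = sorted((lo, hi) for lo, hi, _ in bands.values())
    for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
        if lo2 < hi1:
            raise ValueError("bands overlap")
    single = neuron_map[neuron_map["tuning_class"] == "single"]
    result = {}
    for subfield, grp in single.groupby("subfield"):
        bf = grp["bf_khz"].to_numpy(dtype=float)
        if bf.size == 0:
            result[str(subfield)] = None
            continue
        fracs = {}
        assigned = np.zeros(bf.size, dtype=bool)
        for name, (lo, hi, closed) in bands.items():
            in_b = _in_band(bf, lo, hi, closed)
            fracs[name] = float(in_b.mean())
            assigned |= in_b
        fracs["other"] = float((~assigned).mean())
        fracs["n"] = int(bf.size)
        result[str(subfield)] = fracs
    for subfield in neuron_map["subfield"].unique():
        result.setdefault(str(subfield), None)
    return result
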