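"""Sound-ensemble analysis: population cell vectors, sound-by-sound
correlation matrices with reliability diagonals, UPGMA + hybrid dynamic
tree cut clustering, and cross-session stability metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._treecut import cutree_hybrid
from .preprocess import RepetitionMask
from .protocol import StimulusProtocol

WINDOW_DEFAULT_S = 0.4
WINDOW_COMPLEX_S = 0.55
DEEP_SPLIT = 2.5
MIN_CLUSTER_SIZE = 2
UNCLUSTERED = "unclustered"


@dataclass
class CellVectorSet:
    """Population activity tensor indexed (sound, repetition, neuron).

    NaN planes mark repetitions that were contaminated or absent.
    """

    values: np.ndarray  # (S, R, N)
    sound_ids: list
    window_s: float = WINDOW_DEFAULT_S

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cell-vector tensor must be (sound, rep, neuron)")
        if len(self.sound_ids) != self.values.shape[0]:
            raise ValueError("sound_ids length mismatch")

    @property
    def n_sounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[2]

    def rep_present(self) -> np.ndarray:
        """(S, R) boolean: repetition has data."""
        return ~np.all(np.isnan(self.values), axis=2)


def build_cell_vectors(
    spike_probs: np.ndarray,
    protocol: StimulusProtocol,
    mask: RepetitionMask | None = None,
    window_s: float = WINDOW_DEFAULT_S,
    sound_ids: list | None = None,
) -> CellVectorSet:
    """Average each neuron's spike probability over the response window.

    ``spike_probs`` is (n_neurons, n_frames).  The window spans
    ``floor(window_s * frame_rate)`` frames from the onset frame
    inclusive.  Contaminated repetitions are dropped (NaN); an invalid
    FOV mask is refused outright.
    """
    spike_probs = np.atleast_2d(np.asarray(spike_probs, dtype=float))
    if mask is not None and not mask.fov_valid:
        raise ValueError(
            "FOV is invalid (fewer than the minimum clean repetitions for "
            "at least one sound); refusing to build cell vectors"
        )
    if sound_ids is None:
        sound_ids = protocol.sound_ids
    n_rep = protocol.n_repetitions
    n_neurons = spike_probs.shape[0]
    nw = int(np.floor(window_s * protocol.frame_rate))
    if nw < 1:
        raise ValueError("window shorter than one frame")
    values = np.full((len(sound_ids), n_rep, n_neurons), np.nan)
    sidx = {s: i for i, s in enumerate(sound_ids)}
    for _, row in protocol.events.iterrows():
        i = sidx.get(row["sound_id"])
        if i is None:
            continue
        rep = int(row["repetition"])
        if mask is not None and not mask.is_clean(row["sound_id"], rep):
            continue
        onset = int(row["onset_frame"])
        if onset + nw > spike_probs.shape[1]:
            continue
        values[i, rep] = spike_probs[:, onset : onset + nw].mean(axis=1)
    return CellVectorSet(values=values, sound_ids=list(sound_ids), window_s=window_s)


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class SoundCorrelation:
    """Sound x sound mean Pearson matrix; diagonal = reliability."""

    matrix: np.ndarray
    sound_ids: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(
            self.matrix, self.matrix.T, equal_nan=True, atol=1e-12
        ):
            raise ValueError("correlation matrix must be symmetric")


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    du, dv = u - u.mean(), v - v.mean()
    su, sv = np.sqrt((du**2).sum()), np.sqrt((dv**2).sum())
    if su == 0 or sv == 0:
        return np.nan
    return float((du * dv).sum() / (su * sv))


def sound_correlation(vectors: CellVectorSet) -> SoundCorrelation:
    """Mean Pearson correlation over repetition pairs, per sound pair.

    Off-diagonal (a, b) averages r over all pairs of repetitions (one
    from each sound); the diagonal averages distinct repetition pairs of
    the same sound (response reliability).  Zero-variance vectors are
    excluded pairwise with a warning.
    """
    vals = vectors.values
    s, r, n = vals.shape
    if n < 3:
        raise ValueError("need at least 3 neurons")
    present = vectors.rep_present()
    if present.sum(axis=1).min() < 2:
        raise ValueError("every sound needs at least 2 repetitions")
    flat = vals.reshape(s * r, n)
    ok = ~np.all(np.isnan(flat), axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(flat, axis=1)
    degenerate = ok & (sd == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance cell vectors excluded",
            RuntimeWarning,
            stacklevel=2,
        )
        ok &= sd > 0
    if not ok.any():
        raise ValueError("all cell vectors have zero variance")
    # full (S*R) x (S*R) correlation, then average blocks
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cmat = np.corrcoef(flat[ok])
    full = np.full((s * r, s * r), np.nan)
    oki = np.nonzero(ok)[0]
    full[np.ix_(oki, oki)] = cmat
    full = full.reshape(s, r, s, r)
    out = np.full((s, s), np.nan)
    for a in range(s):
        for b in range(a, s):
            block = full[a, :, b, :]
            if a == b:
                iu = np.triu_indices(r, k=1)
                vals_ab = block[iu]
            else:
                vals_ab = block.ravel()
            vals_ab = vals_ab[~np.isnan(vals_ab)]
            if vals_ab.size:
                out[a, b] = out[b, a] = vals_ab.mean()
    return SoundCorrelation(matrix=out, sound_ids=list(vectors.sound_ids))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Cluster labels per sound plus summary metrics."""

    labels: dict  # sound_id -> int cluster label or UNCLUSTERED
    metrics: dict = field(default_factory=dict)

    def members(self, label) -> set:
        return {s for s, l in self.labels.items() if l == label}

    @property
    def cluster_labels(self) -> list:
        return sorted({l for l in self.labels.values() if l != UNCLUSTERED})


def cluster_metrics(corr: SoundCorrelation, labels: dict) -> dict:
    """Within/between-cluster correlation, reliability and coverage."""
    ids = corr.sound_ids
    mat = corr.matrix
    lab = np.array([labels[s] for s in ids], dtype=object)
    clustered = lab != UNCLUSTERED
    cluster_set = sorted({l for l in lab if l != UNCLUSTERED})
    within, between, reliability = [], [], []
    for a in range(len(ids)):
        if clustered[a]:
            reliability.append(mat[a, a])
        for b in range(a + 1, len(ids)):
            if not (clustered[a] and clustered[b]):
                continue
            if lab[a] == lab[b]:
                within.append(mat[a, b])
            else:
                between.append(mat[a, b])
    def _mean(x):
        return float(np.mean(x)) if len(x) else np.nan
    return {
        "n_clusters": len(cluster_set),
        "sounds_per_cluster": {
            str(l): int(np.sum(lab == l)) for l in cluster_set
        },
        "fraction_clustered": float(np.mean(clustered)) if len(ids) else np.nan,
        "within_cluster_correlation": _mean(within),
        "between_cluster_correlation": _mean(between),
        "within_cluster_reliability": _mean(reliability),
    }


def cluster_sounds(
    corr: SoundCorrelation,
    deep_split: float = DEEP_SPLIT,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    cut_height: float | None = None,
) -> ClusterResult:
    """UPGMA dendrogram on 1 - r distances, cut with the hybrid method.

    The diagonal (reliability) does not enter the distances.  Sounds the
    cut leaves out are labeled ``"unclustered"``.
    """
    ids = corr.sound_ids
    s = len(ids)
    if s < 3:
        raise ValueError("need at least 3 sounds to build a tree")
    mat = corr.matrix
    if not np.all(np.isfinite(mat[~np.eye(s, dtype=bool)])):
        raise ValueError("correlation matrix has non-finite off-diagonals")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = cutree_hybrid(
        link,
        dist,
        deep_split=deep_split,
        min_cluster_size=min_cluster_size,
        cut_height=cut_height,
    )
    labels = {
        sid: (UNCLUSTERED if raw[i] == 0 else int(raw[i]))
        for i, sid in enumerate(ids)
    }
    return ClusterResult(labels=labels, metrics=cluster_metrics(corr, labels))


# ---------------------------------------------------------------------------
# cross-session stability
# ---------------------------------------------------------------------------

def cross_week_cluster_similarity(
    week1: ClusterResult,
    week2: ClusterResult,
    mode: str = "fraction_shared",
) -> float:
    """Mean fraction of each week-1 cluster shared with its best week-2
    counterpart.

    For every week-1 cluster A the week-2 cluster B maximising the
    overlap is the counterpart; the score contributed is |A & B| / |A|
    (or Jaccard with ``mode="jaccard"``).  Ties go to the smaller, then
    lowest-labeled, week-2 cluster.
    """
    if set(week1.labels) != set(week2.labels):
        raise ValueError("cluster results cover different sound sets")
    w1_clusters = week1.cluster_labels
    w2_clusters = week2.cluster_labels
    if not w1_clusters:
        warnings.warn("week 1 has no clusters", RuntimeWarning, stacklevel=2)
        return 0.0
    if not w2_clusters:
        warnings.warn("week 2 has no clusters", RuntimeWarning, stacklevel=2)
        return 0.0
    scores = []
    for la in w1_clusters:
        a = week1.members(la)
        best = 0.0
        best_key = None
        for lb in w2_clusters:
            b = week2.members(lb)
            inter = len(a & b)
            score = (
                inter / len(a)
                if mode == "fraction_shared"
                else inter / max(len(a | b), 1)
            )
            key = (-score, len(b), lb)
            if best_key is None or key < best_key:
                best_key = key
                best = score
        scores.append(best)
    return float(np.mean(scores))


def cross_week_neuron_correlation(
    week1: CellVectorSet,
    week2: CellVectorSet,
    matched_idx1: np.ndarray | None = None,
    matched_idx2: np.ndarray | None = None,
) -> float:
    """Mean Pearson r between matched-neuron cell vectors across weeks.

    For each sound and repetition index present in both sessions, the
    two population vectors (restricted to matched neurons) are
    correlated; the mean over sounds and repetitions is returned.
    """
    if week1.sound_ids != week2.sound_ids:
        raise ValueError("sessions cover different sound sets")
    v1, v2 = week1.values, week2.values
    if matched_idx1 is not None:
        v1 = v1[:, :, np.asarray(matched_idx1)]
    if matched_idx2 is not None:
        v2 = v2[:, :, np.asarray(matched_idx2)]
    if v1.shape[2] != v2.shape[2]:
        raise ValueError("matched neuron sets differ in size")
    if v1.shape[2] < 3:
        raise ValueError("need at least 3 matched neurons")
    n_rep = min(v1.shape[1], v2.shape[1])
    rs = []
    for s in range(v1.shape[0]):
        for r in range(n_rep):
            u, v = v1[s, r], v2[s, r]
            if np.any(np.isnan(u)) or np.any(np.isnan(v)):
                continue
            rv = _pearson(u, v)
            if not np.isnan(rv):
                rs.append(rv)
    if not rs:
        return np.nan
    return float(np.mean(rs))
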