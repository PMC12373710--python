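"""EEG microstate segmentation.

The segmentation pipeline follows the classical topographic-clustering recipe,
with one deliberate twist: clustering is *polarity sensitive*.  Global field
power (GFP) peaks are extracted per epoch, pooled across trials and subjects,
cleaned of outlier maps, and clustered with plain k-means into eight clusters.
The eight centers are then paired into four canonical classes (A-D) by
matching each center with its near-negation, so every class has an explicit
"+" and "-" prototype.  Back-fitting supports both the conventional
polarity-invariant 4-state labeling (absolute spatial correlation) and the
polarity-aware 8-state labeling (signed correlation), followed by iterative
rejection of segments shorter than a temporal-smoothing window (30 ms by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

#: Polarity-aware state order; also the deterministic tie-break order
#: (A < B < C < D, "+" before "-").
STATES_8: tuple[str, ...] = ("A+", "A-", "B+", "B-", "C+", "C-", "D+", "D-")
#: Polarity-invariant state order.
STATES_4: tuple[str, ...] = ("A", "B", "C", "D")

MODE_4 = "polarity_invariant_4"
MODE_8 = "polarity_aware_8"


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PrototypeSet:
    """A set of K cluster-center topographies, optionally labeled and paired.

    ``maps`` is (K, C) with rows in the order of ``labels`` when labeled.  A
    fully labeled polarity-aware set has K = 8 rows ordered as ``STATES_8``
    and ``pairing`` mapping each class letter to its (+, -) row indices.
    """

    maps: np.ndarray
    channel_names: tuple[str, ...]
    labels: tuple[str, ...] | None = None
    pairing: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "maps", np.asarray(self.maps, dtype=float))
        if self.maps.ndim != 2:
            raise ValueError("maps must be a (K, C) array")
        if self.labels is not None and len(self.labels) != self.maps.shape[0]:
            raise ValueError("labels length must match number of maps")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    def map_for(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("prototype set is unlabeled")
        return self.maps[self.labels.index(label)]

    def class_maps(self) -> np.ndarray:
        """(4, C) array of the "+" prototype of each class, in A..D order."""
        return np.stack([self.map_for(c + "+") for c in STATES_4])


@dataclass
class LabelSequence:
    """Per-sample microstate labels for one epoch (or a slice of one).

    ``labels`` holds indices into ``states``; ``segments`` is the run-length
    view (state index, start sample, length), recomputed on demand so the two
    can never disagree.
    """

    labels: np.ndarray
    fs: float
    mode: str = MODE_8
    states: tuple[str, ...] = STATES_8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.mode not in (MODE_4, MODE_8):
            raise ValueError(f"unknown mode: {self.mode!r}")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        return run_lengths(self.labels)

    @property
    def n_segments(self) -> int:
        if self.labels.size == 0:
            return 0
        return int(1 + np.count_nonzero(np.diff(self.labels)))


def run_lengths(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode an integer sequence as (value, start, length) triples."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# GFP and peak maps


def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: per-sample population SD across channels.

    ``data`` is (C, n); returns a length-n nonnegative series.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("GFP needs at least two channels")
    return data.std(axis=0, ddof=0)


def gfp_peaks(series: np.ndarray) -> np.ndarray:
    """Indices of local GFP maxima: strict rise then non-rise.

    A sample i is a peak iff series[i-1] < series[i] >= series[i+1]; a plateau
    is attributed to its first sample and endpoints are never peaks.
    """
    g = np.asarray(series, dtype=float)
    if g.size < 3:
        raise ValueError("series too short for peak detection")
    inner = np.arange(1, g.size - 1)
    mask = (g[inner - 1] < g[inner]) & (g[inner] >= g[inner + 1])
    return inner[mask]


def remove_outlier_maps(
    maps: np.ndarray, cutoff: float = 3.0
) -> tuple[np.ndarray, int]:
    """Drop maps whose L2 norm is a robust-z outlier.

    Robust z uses |x - median| / (1.4826 * MAD); maps with z > ``cutoff`` are
    discarded.  Returns (surviving maps, number removed).  The scale gets a
    tiny relative floor so ulp-level jitter in otherwise identical norms does
    not masquerade as spread.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 10:
        raise ValueError("need at least 10 maps for outlier screening")
    norms = np.linalg.norm(maps, axis=1)
    med = np.median(norms)
    mad = np.median(np.abs(norms - med))
    scale = max(1.4826 * mad, 1e-9 * max(1.0, abs(med)))
    keep = np.abs(norms - med) / scale <= cutoff
    if keep.sum() < 2:
        raise ValueError("outlier screening left fewer than 2 maps")
    return maps[keep], int((~keep).sum())


# ---------------------------------------------------------------------------
# spatial correlation (the back-fitting similarity)


def spatial_correlation(x: np.ndarray, a: np.ndarray) -> float:
    """Cosine similarity between two maps, without mean-centering.

    Equals the Pearson correlation when both maps are average-referenced
    (zero channel mean), which is the state of all maps in this pipeline.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if x.shape != a.shape:
        raise ValueError("maps must have equal length")
    nx = np.linalg.norm(x)
    na = np.linalg.norm(a)
    if nx == 0.0 or na == 0.0:
        raise ValueError("spatial correlation undefined for a zero map")
    return float(x @ a / (nx * na))


def _corr_matrix(maps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """(K, n) matrix of cosine similarities between maps and data columns.

    Zero-norm data columns get similarity 0 to every map (they carry no
    topography; the tie-break then assigns the first state).
    """
    maps = np.asarray(maps, dtype=float)
    data = np.asarray(data, dtype=float)
    mnorm = np.linalg.norm(maps, axis=1, keepdims=True)
    dnorm = np.linalg.norm(data, axis=0, keepdims=True)
    safe = np.where(dnorm == 0.0, 1.0, dnorm)
    return (maps / mnorm) @ (data / safe)


# ---------------------------------------------------------------------------
# clustering and class assignment


def cluster_maps(
    maps: np.ndarray,
    k: int = 8,
    n_restarts: int = 50,
    seed: int = 0,
    channel_names: tuple[str, ...] | None = None,
) -> PrototypeSet:
    """Polarity-sensitive k-means over topographic maps.

    Runs standard k-means with ``n_restarts`` random initialisations and
    keeps the solution with the lowest within-cluster sum of squares; the
    returned centers are renormalised to unit norm.  The result is unlabeled:
    polarity pairing and canonical class assignment come next.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < k:
        raise ValueError(f"need at least k={k} maps, got {maps.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**32))
    km.fit(maps)
    centers = km.cluster_centers_
    norms = np.linalg.norm(centers, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("k-means produced a zero center")
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(maps.shape[1]))
    return PrototypeSet(maps=centers / norms, channel_names=tuple(channel_names))


def pair_polarity(centers: PrototypeSet) -> PrototypeSet:
    """Greedily pair the 8 centers into 4 opposite-polarity classes.

    Pairs are matched most-negative-correlation first, so each class joins a
    center with its (approximate) negation.  Emits a warning when a matched
    pair correlates above -0.5, i.e. when the polarity structure is weak.
    """
    if centers.n_maps != 8:
        raise ValueError("polarity pairing expects exactly 8 centers")
    maps = centers.maps
    corr = np.array(
        [[spatial_correlation(maps[i], maps[j]) for j in range(8)] for i in range(8)]
    )
    unmatched = set(range(8))
    pairs: list[tuple[int, int]] = []
    while unmatched:
        best = None
        for i in sorted(unmatched):
            for j in sorted(unmatched):
                if j <= i:
                    continue
                if best is None or corr[i, j] < corr[best]:
                    best = (i, j)
        pairs.append(best)
        unmatched -= set(best)
    for i, j in pairs:
        if corr[i, j] > -0.5:
            warnings.warn(
                f"weak polarity structure: centers {i},{j} correlate {corr[i, j]:.2f}",
                stacklevel=2,
            )
    pairing = {f"pair{p}": (i, j) for p, (i, j) in enumerate(pairs)}
    return replace(centers, pairing=pairing)


def assign_canonical_labels(
    paired: PrototypeSet, templates: PrototypeSet
) -> PrototypeSet:
    """Assign the four paired classes to the canonical A-D classes.

    Uses the Hungarian algorithm to maximize total absolute spatial
    correlation between each pair's members and the canonical class
    templates; within a class the member positively correlated with the
    template becomes "+".  Returns a fully labeled set with rows reordered to
    ``STATES_8``.
    """
    if paired.pairing is None or len(paired.pairing) != 4:
        raise ValueError("expected a polarity-paired set of 4 classes")
    tmaps = (
        templates.class_maps()
        if templates.labels and set(STATES_8) <= set(templates.labels)
        else templates.maps
    )
    if tmaps.shape[0] != 4:
        raise ValueError("expected 4 canonical templates")
    pairs = list(paired.pairing.values())
    score = np.zeros((4, 4))
    for p, (i, j) in enumerate(pairs):
        for t in range(4):
            ci = spatial_correlation(paired.maps[i], tmaps[t])
            cj = spatial_correlation(paired.maps[j], tmaps[t])
            score[p, t] = (abs(ci) + abs(cj)) / 2.0
    rows, cols = linear_sum_assignment(-score)
    if np.any(score[rows, cols] < 0.3):
        warnings.warn("ambiguous canonical class assignment (|corr| < 0.3)", stacklevel=2)
    ordered = np.zeros((8, len(paired.channel_names)))
    pairing: dict[str, tuple[int, int]] = {}
    for p, t in zip(rows, cols):
        i, j = pairs[p]
        cls = STATES_4[t]
        ci = spatial_correlation(paired.maps[i], tmaps[t])
        cj = spatial_correlation(paired.maps[j], tmaps[t])
        pos, neg = (i, j) if ci >= cj else (j, i)
        ip = STATES_8.index(cls + "+")
        ordered[ip] = paired.maps[pos]
        ordered[ip + 1] = paired.maps[neg]
        pairing[cls] = (ip, ip + 1)
    return PrototypeSet(
        maps=ordered,
        channel_names=paired.channel_names,
        labels=STATES_8,
        pairing=pairing,
    )


# ---------------------------------------------------------------------------
# back-fitting and temporal smoothing


def _similarity(data: np.ndarray, prototypes: PrototypeSet, mode: str) -> np.ndarray:
    """Per-state similarity used for both back-fitting and smoothing."""
    if prototypes.labels != STATES_8:
        raise ValueError("back-fitting requires a fully labeled 8-state prototype set")
    if mode == MODE_8:
        return _corr_matrix(prototypes.maps, data)
    if mode == MODE_4:
        return np.abs(_corr_matrix(prototypes.class_maps(), data))
    raise ValueError(f"unknown mode: {mode!r}")


def backfit(data: np.ndarray, prototypes: PrototypeSet, mode: str, fs: float) -> LabelSequence:
    """Label every sample with its most similar prototype.

    Polarity-invariant mode takes the argmax of |corr| over the four class
    maps; polarity-aware mode the argmax of the signed correlation over all
    eight.  Ties resolve to the lowest state index (A < B < C < D, "+"
    before "-"), which argmax-over-first-occurrence provides.
    """
    sim = _similarity(np.asarray(data, dtype=float), prototypes, mode)
    labels = sim.argmax(axis=0)
    states = STATES_8 if mode == MODE_8 else STATES_4
    return LabelSequence(labels=labels, fs=fs, mode=mode, states=states)


def smooth_labels(
    seq: LabelSequence,
    data: np.ndarray,
    prototypes: PrototypeSet,
    window: float = 0.03,
) -> LabelSequence:
    """Reject label segments shorter than the smoothing window.

    Iteratively removes the shortest interior segment below ``window``
    seconds: its samples are split contiguously between the two neighbouring
    segments at the cut point that maximizes total spatial-correlation
    similarity, so each sample ends up with whichever neighbour state fits it
    better while segments stay contiguous.  Edge segments are exempt.  The
    segment count strictly decreases each iteration, so termination is
    guaranteed, and afterwards every interior segment spans at least the
    window.
    """
    w = int(round(window * seq.fs))
    if w < 2:
        raise ValueError("smoothing window must span at least 2 samples")
    sim = _similarity(np.asarray(data, dtype=float), prototypes, seq.mode)
    labels = seq.labels.copy()
    while True:
        segs = run_lengths(labels)
        short = [
            (length, start, k)
            for k, (_, start, length) in enumerate(segs)
            if 0 < k < len(segs) - 1 and length < w
        ]
        if not short:
            break
        length, start, k = min(short)
        prev_state = segs[k - 1][0]
        next_state = segs[k + 1][0]
        sl = slice(start, start + length)
        gain = sim[prev_state, sl] - sim[next_state, sl]
        # cut in [0, length]: samples before the cut join the previous
        # segment, the rest the next; pick the similarity-maximizing cut
        cum = np.concatenate(([0.0], np.cumsum(gain)))
        cut = int(np.argmax(cum))
        labels[start : start + cut] = prev_state
        labels[start + cut : start + length] = next_state
    return LabelSequence(labels=labels, fs=seq.fs, mode=seq.mode, states=seq.states)
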