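"""Microstate segmentation: GFP, peak topographies, polarity-invariant
modified k-means, cross-validation model selection, canonical A-D labelling,
and full-record backfitting.

Global field power at sample t is the spatial standard deviation of the
average-referenced map,

    GFP(t) = sqrt( sum_i (v_i(t) - vbar(t))^2 / n ).

Maps at GFP local maxima (highest signal-to-noise topographies) are clustered
with a k-means variant that treats a map and its negation as the same class:
map x is assigned to the template m_k maximising (x . m_k)^2, and templates
update to the dominant eigenvector of the within-class scatter sum x x^T.
The objective is the global explained variance (GEV)

    GEV = sum_t (x_t . m_{L(t)})^2 / sum_t ||x_t||^2,

which with average-referenced maps and unit-norm templates equals the
GFP^2-weighted mean squared spatial correlation; it is non-decreasing across
iterations.  The number of classes is chosen by the predictive-residual
cross-validation criterion

    CV(K) = sigma^2 * ((C - 1) / (C - 1 - K))^2,
    sigma^2 = sum_t (x_t . x_t - (x_t . m_{L(t)})^2) / (N (C - 1)),

with C channels and N peak maps.  The fitted maps are matched to canonical
references (A left-right diagonal, B its mirror, C anterior-posterior, D
fronto-central) by a one-to-one assignment maximising total |spatial
correlation|, and every sample of the full recording is then backfit to the
class with the largest absolute spatial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import ConditionEpoch

_FLAT_EPS = 1e-12


@dataclass
class GFPSeries:
    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class MicrostateModel:
    maps: np.ndarray            # K x n_channels, unit-norm, average-referenced
    labels: list[str]
    gev: float
    cv_value: float = float("nan")
    fit_meta: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.maps.shape[0]


@dataclass
class Segmentation:
    labels_per_sample: np.ndarray
    srate: float
    K: int
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels_per_sample = np.asarray(self.labels_per_sample, dtype=np.int64)
        if not self.class_names:
            self.class_names = [f"M{i + 1}" for i in range(self.K)]

    @property
    def n_samples(self) -> int:
        return len(self.labels_per_sample)

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        """Maximal runs as (label, start, end), half-open, partitioning the epoch."""
        lab = self.labels_per_sample
        if len(lab) == 0:
            return []
        change = np.flatnonzero(np.diff(lab)) + 1
        bounds = np.concatenate([[0], change, [len(lab)]])
        return [(int(lab[s]), int(s), int(e)) for s, e in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# GFP
# ---------------------------------------------------------------------------

def gfp(epoch: ConditionEpoch | np.ndarray) -> GFPSeries:
    """Global field power per sample (spatial SD of the average-referenced map)."""
    data = epoch.data if isinstance(epoch, ConditionEpoch) else np.asarray(epoch)
    if data.shape[0] < 2:
        raise ValueError("GFP needs >= 2 channels")
    centered = data - data.mean(axis=0, keepdims=True)
    return GFPSeries(values=np.sqrt(np.mean(centered**2, axis=0)))


def find_gfp_peaks(series: GFPSeries, min_distance_samples: int = 0) -> np.ndarray:
    """Strict local maxima of the GFP curve.

    A plateau counts once, at its first sample.  With a minimum distance,
    peaks are kept greedily from largest to smallest.
    """
    v = np.asarray(series.values, dtype=float)
    if len(v) < 3:
        raise ValueError("series too short to have interior maxima")
    peaks = []
    i = 1
    while i < len(v) - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < len(v) and v[j + 1] == v[i]:
                j += 1
            if j < len(v) - 1 and v[j + 1] < v[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    peaks = np.asarray(peaks, dtype=int)
    if min_distance_samples > 0 and len(peaks):
        order = peaks[np.argsort(-v[peaks], kind="stable")]
        kept: list[int] = []
        for p in order:
            if all(abs(p - q) >= min_distance_samples for q in kept):
                kept.append(int(p))
        peaks = np.array(sorted(kept), dtype=int)
    series.peak_indices = peaks
    return peaks


def extract_peak_maps(epoch: ConditionEpoch, min_distance_samples: int = 0) -> np.ndarray:
    """Average-referenced topographies at GFP peaks: (n_peaks, n_channels)."""
    series = gfp(epoch)
    peaks = find_gfp_peaks(series, min_distance_samples)
    maps = epoch.data[:, peaks].T
    return maps - maps.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------

def _gev(X: np.ndarray, maps: np.ndarray, assign: np.ndarray, total: float) -> float:
    proj = np.einsum("ij,ij->i", X, maps[assign])
    return float(np.sum(proj**2) / total)


def _dominant_eigvec(scatter: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(scatter)
    vec = v[:, -1]
    # deterministic sign: largest-magnitude entry positive
    k = np.argmax(np.abs(vec))
    return vec * np.sign(vec[k]) if vec[k] != 0 else vec


def modified_kmeans(
    peak_maps: np.ndarray,
    K: int,
    restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | np.random.Generator = 0,
) -> MicrostateModel:
    """Polarity-invariant modified k-means over GFP-peak topographies.

    Maps are average-referenced; templates are unit-norm dominant
    eigenvectors.  Returns the best of ``restarts`` random initialisations
    (templates seeded from peaks sampled without replacement) by GEV.
    """
    X = np.asarray(peak_maps, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    n, n_ch = X.shape
    if n < K:
        raise ValueError(f"K={K} exceeds the {n} available peak maps")
    if n < 10 * K:
        raise ValueError(f"need >= 10*K={10 * K} peak maps, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = float(np.sum(X**2))
    if total <= 0:
        raise ValueError("all peak maps are flat")

    best: tuple[float, np.ndarray, np.ndarray, dict] | None = None
    for r in range(restarts):
        idx = rng.choice(n, size=K, replace=False)
        maps = X[idx].copy()
        norms = np.linalg.norm(maps, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        maps /= norms
        prev_gev = -np.inf
        gev_trace: list[float] = []
        for it in range(max_iter):
            proj = X @ maps.T                       # n x K
            assign = np.argmax(proj**2, axis=1)
            for k in range(K):
                members = assign == k
                if not members.any():
                    # re-seed an empty cluster from the worst-fit map
                    fit = np.max(proj**2, axis=1) / np.maximum(
                        np.sum(X**2, axis=1), _FLAT_EPS)
                    w = int(np.argmin(fit))
                    assign[w] = k
                    members = assign == k
                Xk = X[members]
                maps[k] = _dominant_eigvec(Xk.T @ Xk)
            cur = _gev(X, maps, np.argmax((X @ maps.T) ** 2, axis=1), total)
            gev_trace.append(cur)
            if cur - prev_gev < tol * max(abs(prev_gev), 1e-30) and it > 0:
                break
            prev_gev = cur
        assign = np.argmax((X @ maps.T) ** 2, axis=1)
        cur = _gev(X, maps, assign, total)
        if best is None or cur > best[0]:
            best = (cur, maps.copy(), assign,
                    {"restart": r, "iterations": it + 1, "gev_trace": gev_trace})
    gev_val, maps, assign, meta = best
    meta.update({"restarts": restarts, "n_peak_maps": n})
    labels = [f"M{i + 1}" for i in range(K)]
    return MicrostateModel(maps=maps, labels=labels, gev=gev_val, fit_meta=meta)


def cross_validation_criterion(peak_maps: np.ndarray, model: MicrostateModel) -> float:
    """Predictive-residual CV criterion; lower is better."""
    X = np.asarray(peak_maps, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    C = X.shape[1]
    K = model.K
    if C - 1 <= K:
        raise ValueError(f"CV undefined: channels-1 ({C - 1}) <= K ({K})")
    proj = X @ model.maps.T
    best = np.max(proj**2, axis=1)
    resid = np.sum(X**2, axis=1) - best
    sigma2 = float(np.sum(resid)) / (X.shape[0] * (C - 1))
    return sigma2 * ((C - 1) / (C - 1 - K)) ** 2


def select_cluster_number(
    peak_maps: np.ndarray,
    k_range: tuple[int, int] = (4, 8),
    restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | np.random.Generator = 0,
) -> tuple[int, list[dict]]:
    """Fit each K in the inclusive range, return (argmin-CV K, per-K table).

    Ties go to the smallest K.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = []
    for K in range(k_range[0], k_range[1] + 1):
        model = modified_kmeans(peak_maps, K, restarts, max_iter, tol, rng)
        cv = cross_validation_criterion(peak_maps, model)
        model.cv_value = cv
        table.append({"K": K, "cv": cv, "gev": model.gev, "model": model})
    best = min(table, key=lambda row: row["cv"])
    return best["K"], table


# ---------------------------------------------------------------------------
# Canonical labelling
# ---------------------------------------------------------------------------

def assign_canonical_labels(
    model: MicrostateModel, canonical: np.ndarray,
    canonical_names: tuple[str, ...] = ("A", "B", "C", "D"),
) -> MicrostateModel:
    """Reorder/relabel a K=4 model against canonical references.

    One-to-one assignment maximising total absolute spatial correlation
    (Hungarian method); non-4 models keep generic M1..MK labels.
    """
    if model.K != 4 or np.asarray(canonical).shape[0] != 4:
        return model
    can = np.asarray(canonical, dtype=float)
    can = can - can.mean(axis=1, keepdims=True)
    can = can / np.linalg.norm(can, axis=1, keepdims=True)
    corr = np.abs(model.maps @ can.T)
    rows, cols = linear_sum_assignment(-corr)
    order = rows[np.argsort(cols)]
    return MicrostateModel(
        maps=model.maps[order], labels=list(canonical_names),
        gev=model.gev, cv_value=model.cv_value,
        fit_meta={**model.fit_meta, "canonical_match": corr[order, range(4)].tolist()},
    )


# ---------------------------------------------------------------------------
# Backfitting
# ---------------------------------------------------------------------------

def backfit(
    epoch: ConditionEpoch,
    model: MicrostateModel,
    smoothing_min_samples: int = 0,
) -> Segmentation:
    """Label every sample with the class of largest |spatial correlation|.

    Ties go to the previous sample's label (else the lowest class index);
    flat samples inherit the previous label, and leading flat samples take
    the first non-flat label.  With smoothing, runs shorter than the minimum
    are absorbed into the neighbouring class with higher mean correlation.
    """
    X = epoch.data.T - epoch.data.T.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    corr = np.abs(X @ model.maps.T) / np.maximum(norms, _FLAT_EPS)[:, None]
    n = X.shape[0]
    labels = np.argmax(corr, axis=1).astype(np.int64)
    flat = norms < _FLAT_EPS

    # tie-break toward the incumbent label
    best = corr[np.arange(n), labels]
    for t in range(1, n):
        if flat[t]:
            labels[t] = labels[t - 1]
        elif corr[t, labels[t - 1]] == best[t]:
            labels[t] = labels[t - 1]
    if flat[0] and not flat.all():
        labels[: np.argmin(flat)] = labels[np.argmin(flat)]

    if smoothing_min_samples > 0:
        labels = _absorb_short_runs(labels, corr, smoothing_min_samples)
    return Segmentation(labels, epoch.srate, model.K, list(model.labels))


def _absorb_short_runs(labels: np.ndarray, corr: np.ndarray, min_len: int) -> np.ndarray:
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        seg = Segmentation(labels, 1.0, corr.shape[1]).segments
        for i, (lab, s, e) in enumerate(seg):
            if e - s >= min_len or len(seg) == 1:
                continue
            cands = []
            if i > 0:
                cands.append(seg[i - 1][0])
            if i < len(seg) - 1:
                cands.append(seg[i + 1][0])
            new = max(cands, key=lambda c: corr[s:e, c].mean())
            labels[s:e] = new
            changed = True
            break
    return labels
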