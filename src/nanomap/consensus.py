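"""Consensus-map construction from pools of single-molecule maps.

Molecules are scored pairwise on their channel-1 label patterns, clustered by
agglomerative hierarchical clustering on the resulting Euclidean distance
matrix, oriented consistently within each cluster, and reduced to a per-clone
two-color consensus: label-position histograms with Gaussian peak fits.
Channel 1 defines the clustering frame; other channels are overlaid in the
same frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import cluster as _scicluster
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform

from ._defaults import section
from .errors import ClusteringError, ValidationError
from .molsim import MoleculeMap

_D = section("consensus")


@dataclass(frozen=True)
class ConsensusParams:
    bin_width_bp: float = _D["bin_width_bp"]
    hist_bin_bp: float = _D["hist_bin_bp"]
    resolution_bp: float = _D["resolution_bp"]
    support_threshold: float = _D["support_threshold"]
    max_peak_sd_bp: float = _D["max_peak_sd_bp"]
    min_support: int = _D["min_support"]
    cut_height: float | None = _D["cut_height"]
    linkage: str = _D["linkage"]


@dataclass
class Peak:
    position_bp: float
    sd_bp: float
    support: int


@dataclass
class ConsensusMap:
    map_id: str
    length_bp: float
    peaks: dict[int, list[Peak]] = field(default_factory=dict)
    n_molecules: int = 1

    def validate(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"{self.map_id}: non-positive length")
        for ch, pk in self.peaks.items():
            for a, b in zip(pk, pk[1:]):
                if b.position_bp <= a.position_bp:
                    raise ValidationError(f"{self.map_id}: channel {ch} peaks not increasing")
            for p in pk:
                if p.support > self.n_molecules:
                    raise ValidationError(f"{self.map_id}: support exceeds n_molecules")

    @property
    def channels(self) -> list[int]:
        return sorted(self.peaks)

    def positions(self, channel: int) -> np.ndarray:
        return np.asarray([p.position_bp for p in self.peaks.get(channel, ())])


@dataclass
class ClusterResult:
    assignments: dict[str, int]
    orientations: dict[str, str]  # 'forward' | 'flipped', relative to cluster's first member
    distance_matrix: np.ndarray
    unusable: set[str] = field(default_factory=set)  # zero-label or tiny-cluster molecules

    def members(self, label: int) -> list[str]:
        return [m for m, c in self.assignments.items() if c == label]

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.assignments.values()))


def _raster(mol: MoleculeMap, n_bins: int, channel: int = 1) -> np.ndarray:
    """Length-normalized, Gaussian-smoothed bin-occupancy vector."""
    v = np.zeros(n_bins)
    pos = mol.labels.get(channel, np.empty(0))
    if len(pos):
        idx = np.clip((np.asarray(pos) / mol.length_bp * n_bins).astype(int), 0, n_bins - 1)
        np.add.at(v, idx, 1.0)
    return gaussian_filter1d(v, sigma=1.0, mode="constant")


def pairwise_distance(
    molecules: list[MoleculeMap],
    bin_width_bp: float | None = None,
    channel: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Euclidean distances between molecule label fingerprints.

    Returns ``(D, O, usable)``: the symmetric distance matrix, the matrix of
    minimizing relative orientations (+1 forward, -1 flipped), and a boolean
    mask marking molecules that carry at least one channel-``channel`` label.
    Unusable molecules get infinite distance to everything.
    """
    if len(molecules) < 2:
        raise ValidationError("need at least 2 molecules")
    bw = float(bin_width_bp if bin_width_bp is not None else ConsensusParams().bin_width_bp)
    if bw <= 0:
        raise ValidationError("bin_width_bp must be > 0")
    med_len = float(np.median([m.length_bp for m in molecules]))
    n_bins = max(4, int(round(med_len / bw)))

    usable = np.array([len(m.labels.get(channel, ())) > 0 for m in molecules])
    vecs = np.stack([_raster(m, n_bins, channel) for m in molecules])
    n = len(molecules)
    D = np.full((n, n), np.inf)
    O = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(D, 0.0)

    fwd = vecs[usable]
    rev = fwd[:, ::-1]
    idx = np.flatnonzero(usable)
    d_f = np.linalg.norm(fwd[:, None, :] - fwd[None, :, :], axis=2)
    d_r = np.linalg.norm(fwd[:, None, :] - rev[None, :, :], axis=2)
    for a, ia in enumerate(idx):
        for b, ib in enumerate(idx):
            if d_r[a, b] < d_f[a, b]:
                D[ia, ib] = d_r[a, b]
                O[ia, ib] = -1
            else:
                D[ia, ib] = d_f[a, b]
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(O, 1)
    return D, O, usable


def _default_cut_height(sub: np.ndarray) -> float:
    """Data-driven tree-cut height.

    Two-means split of the pairwise distances: when the split is well
    separated (multiple clones in the pool) the cut sits at the midpoint of
    the two distance modes; when the distances are unimodal (a single-clone
    pool) the cut is placed above the largest distance so everything merges.
    """
    n = sub.shape[0]
    d = sub[np.triu_indices(n, k=1)]
    d = d[np.isfinite(d)]
    if len(d) == 0:
        return 1.0
    lo, hi = float(d.min()), float(d.max())
    if hi - lo < 1e-12:
        return hi + 1.0
    thr = 0.5 * (lo + hi)
    for _ in range(50):
        a = d[d <= thr]
        b = d[d > thr]
        if len(a) == 0 or len(b) == 0:
            break
        new = 0.5 * (a.mean() + b.mean())
        if abs(new - thr) < 1e-9:
            break
        thr = new
    a = d[d <= thr]
    b = d[d > thr]
    min_frac = 0.05 * len(d)
    if len(a) < max(2, min_frac) or len(b) < max(2, min_frac):
        return hi + 1.0
    spread = max(np.sqrt(0.5 * (a.var() + b.var())), 1e-9)
    if (b.mean() - a.mean()) > 3.5 * spread:
        return float(thr)
    return hi + 1.0


def cluster_molecules(
    distance_matrix: np.ndarray,
    orientations: np.ndarray,
    molecule_ids: list[str] | None = None,
    linkage: str | None = None,
    cut_height: float | None = None,
    min_support: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering of the pairwise distance matrix.

    The tree is cut at ``cut_height`` (default 0.6 x median finite pairwise
    distance). Clusters smaller than ``min_support`` are flagged unusable.
    Orientations are propagated from each cluster's first member via the
    recorded pairwise orientation.
    """
    p = ConsensusParams()
    linkage = linkage or p.linkage
    min_support = min_support if min_support is not None else p.min_support
    n = distance_matrix.shape[0]
    ids = molecule_ids or [str(i) for i in range(n)]

    finite = np.isfinite(distance_matrix).all(axis=1)
    if not finite.any() or finite.sum() < 1:
        raise ClusteringError("no usable molecules")
    idx = np.flatnonzero(finite)
    sub = distance_matrix[np.ix_(idx, idx)]

    if cut_height is None:
        cut_height = _default_cut_height(sub)

    if len(idx) == 1:
        labels = np.array([1])
    else:
        Z = _scicluster.hierarchy.linkage(squareform(sub, checks=False), method=linkage)
        labels = _scicluster.hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    assignments: dict[str, int] = {}
    orient: dict[str, str] = {}
    unusable = {ids[i] for i in range(n) if not finite[i]}
    for local, i in enumerate(idx):
        assignments[ids[i]] = int(labels[local])

    for c in sorted(set(labels)):
        members = [idx[k] for k in range(len(idx)) if labels[k] == c]
        if len(members) < min_support:
            unusable.update(ids[i] for i in members)
        # consistent within-cluster orientation: leading eigenvector sign of the
        # pairwise orientation matrix, anchored so the first member is forward
        sub_o = orientations[np.ix_(members, members)].astype(float)
        if len(members) > 2:
            w, v = np.linalg.eigh(sub_o)
            lead = v[:, np.argmax(w)]
            signs = np.where(lead >= 0, 1, -1)
        else:
            signs = sub_o[0]
        if signs[0] < 0:
            signs = -signs
        for s, i in zip(signs, members):
            orient[ids[i]] = "forward" if s >= 0 else "flipped"

    return ClusterResult(assignments, orient, distance_matrix, unusable)


def orient_molecules(
    molecules: list[MoleculeMap], orientations: dict[str, str]
) -> list[MoleculeMap]:
    """Flip molecules marked 'flipped' into the common cluster frame."""
    out = []
    for m in molecules:
        o = orientations.get(m.molecule_id, "forward")
        out.append(m.flipped() if o == "flipped" else m)
    return out


def refine_orientations(
    molecules: list[MoleculeMap],
    orientations: dict[str, str],
    bin_width_bp: float | None = None,
    n_iter: int = 2,
    channel: int = 1,
) -> dict[str, str]:
    """Polish per-molecule orientations against the pooled cluster raster.

    Pairwise orientation votes leave a few percent of molecules mirrored;
    re-orienting each molecule against the mean occupancy vector of the whole
    cluster is a much stronger signal.
    """
    bw = float(bin_width_bp if bin_width_bp is not None else ConsensusParams().bin_width_bp)
    med_len = float(np.median([m.length_bp for m in molecules]))
    n_bins = max(4, int(round(med_len / bw)))
    vecs = {m.molecule_id: _raster(m, n_bins, channel) for m in molecules}
    orient = dict(orientations)
    for _ in range(n_iter):
        mean = np.zeros(n_bins)
        for m in molecules:
            v = vecs[m.molecule_id]
            mean += v[::-1] if orient.get(m.molecule_id) == "flipped" else v
        mean /= max(len(molecules), 1)
        changed = 0
        for m in molecules:
            v = vecs[m.molecule_id]
            d_f = np.linalg.norm(v - mean)
            d_r = np.linalg.norm(v[::-1] - mean)
            new = "forward" if d_f <= d_r else "flipped"
            if new != orient.get(m.molecule_id, "forward"):
                changed += 1
            orient[m.molecule_id] = new
        if changed == 0:
            break
    return orient


def _gauss(x, a, mu, sd):
    return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _fit_peak(
    pool: np.ndarray,
    counts: np.ndarray,
    centers: np.ndarray,
    k: int,
    hist_bin: float,
    max_sd: float,
) -> tuple[float, float] | None:
    """Gaussian least-squares fit around histogram bin ``k``.

    Returns (mean, sd) or None when the neighborhood is not a discrete peak
    (fitted or moment sd beyond ``max_sd``). Degenerate neighborhoods fall
    back to the label centroid.
    """
    lo, hi = centers[k] - 2.5 * hist_bin, centers[k] + 2.5 * hist_bin
    local = pool[(pool >= lo) & (pool <= hi)]
    if len(local) == 0:
        return None
    if np.ptp(local) == 0:  # noiseless spike: exact position, degenerate sd
        return float(local[0]), 0.0
    w0, w1 = max(k - 2, 0), min(k + 3, len(counts))
    x = centers[w0:w1]
    y = counts[w0:w1].astype(float)
    mu0 = float(np.mean(local))
    sd0 = float(np.std(local))
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss,
                x,
                y,
                p0=(max(y.max(), 1.0), mu0, max(sd0, hist_bin / 4)),
                bounds=([0.0, x[0] - hist_bin, 1e-6],
                        [np.inf, x[-1] + hist_bin, 10 * max_sd]),
                maxfev=2000,
            )
        mu, sd = float(popt[1]), float(abs(popt[2]))
    except Exception:
        mu, sd = mu0, sd0  # fall back to the histogram-peak centroid
    if sd > max_sd or not np.isfinite(mu):
        return None
    return mu, sd


def build_consensus(
    cluster: list[MoleculeMap],
    hist_bin_bp: float | None = None,
    resolution_bp: float | None = None,
    params: ConsensusParams | None = None,
    map_id: str = "consensus",
) -> ConsensusMap:
    """Reduce an oriented molecule cluster to a two-color consensus map.

    Per channel: pool label positions, histogram them, take local maxima with
    enough molecule support as peak candidates, least-squares-fit a Gaussian
    to each candidate's neighborhood, and merge fitted peaks closer than the
    optical resolution by support-weighted averaging. Candidates whose fitted
    width exceeds ``max_peak_sd_bp`` are rejected: such label pools do not
    cluster into discrete peaks (the tandem-repeat signature) and are left to
    the high-density detector. Consensus length is the median molecule length.
    """
    p = params or ConsensusParams()
    hist_bin = float(hist_bin_bp if hist_bin_bp is not None else p.hist_bin_bp)
    resolution = float(resolution_bp if resolution_bp is not None else p.resolution_bp)
    if not cluster:
        raise ValidationError("empty cluster")
    n_mol = len(cluster)
    length = float(np.median([m.length_bp for m in cluster]))
    # molecules are full-length clones: rescaling each to the median length
    # removes per-molecule stretch variation before pooling
    cluster = [
        MoleculeMap(
            m.molecule_id,
            length,
            {ch: pos * (length / m.length_bp) for ch, pos in m.labels.items()},
            m.truth,
        )
        for m in cluster
    ]
    n_bins = max(1, int(math.ceil(length / hist_bin)))
    edges = np.arange(n_bins + 1) * hist_bin
    centers = (edges[:-1] + edges[1:]) / 2.0
    support_halfwin = max(resolution, 2 * hist_bin)

    channels = sorted({ch for m in cluster for ch in m.labels})
    peaks: dict[int, list[Peak]] = {}
    for ch in channels:
        pools = [np.asarray(m.labels.get(ch, np.empty(0)), dtype=float) for m in cluster]
        pool = np.concatenate(pools) if pools else np.empty(0)
        if len(pool) == 0:
            peaks[ch] = []
            continue
        counts, _ = np.histogram(np.clip(pool, 0, edges[-1] - 1e-9), bins=edges)
        smooth = gaussian_filter1d(counts.astype(float), sigma=1.0, mode="constant")
        cand: list[int] = []
        for k in range(n_bins):
            left = smooth[k - 1] if k > 0 else -1.0
            right = smooth[k + 1] if k < n_bins - 1 else -1.0
            if smooth[k] <= 0 or smooth[k] < left or smooth[k] <= right:
                continue
            neigh = counts[max(k - 1, 0) : k + 2].sum()
            if neigh >= p.support_threshold * n_mol:
                cand.append(k)

        fitted: list[Peak] = []
        for k in cand:
            fit = _fit_peak(pool, counts, centers, k, hist_bin, p.max_peak_sd_bp)
            if fit is None:
                continue
            mu, sd = fit
            support = sum(
                1 for lp in pools if len(lp) and np.min(np.abs(lp - mu)) <= support_halfwin
            )
            if support >= max(1, int(round(p.support_threshold * n_mol))):
                fitted.append(Peak(mu, sd, min(support, n_mol)))

        fitted.sort(key=lambda q: q.position_bp)
        merged: list[Peak] = []
        for q in fitted:
            if merged and q.position_bp - merged[-1].position_bp < resolution:
                a = merged[-1]
                w = a.support + q.support
                merged[-1] = Peak(
                    (a.position_bp * a.support + q.position_bp * q.support) / w,
                    (a.sd_bp * a.support + q.sd_bp * q.support) / w,
                    min(max(a.support, q.support), n_mol),
                )
            else:
                merged.append(q)
        # identical fitted positions can survive as duplicates; drop them
        dedup: list[Peak] = []
        for q in merged:
            if dedup and q.position_bp <= dedup[-1].position_bp:
                continue
            dedup.append(q)
        peaks[ch] = dedup

    cm = ConsensusMap(map_id=map_id, length_bp=length, peaks=peaks, n_molecules=n_mol)
    cm.validate()
    return cm
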