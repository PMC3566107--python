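"""Ordered two-color map alignment and region-map assembly.

`align_maps` is a dynamic program over the position-ordered union of both
label channels: matches are only allowed between labels of the same channel,
and the matching must be jointly monotone in position. A matched interval pair
pays a chi-square sizing penalty with variance linear in interval length
(standard ordered-map alignment practice); skipped labels pay flat penalties.
`merge_consensus` tiles per-clone consensus maps into a region genome map via
all-pairs overlap alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._defaults import section
from .consensus import ConsensusMap, Peak
from .errors import AlignmentError, ValidationError

_D = section("alignment")

@dataclass(frozen=True)
class AlignParams:
    match_bonus: float = _D["match_bonus"]
    miss_penalty: float = _D["miss_penalty"]
    false_penalty: float = _D["false_penalty"]
    sd_scale: float = _D["sd_scale"]
    sd_base_bp: float = _D["sd_base_bp"]
    penalty_cap: float = _D["penalty_cap"]
    min_score: float = _D["min_score"]
    min_labels: int = _D["min_labels"]
    max_skip: int = _D["max_skip"]

    def with_(self, **kw) -> "AlignParams":
        return replace(self, **kw)


@dataclass
class MapAlignment:
    query_id: str
    ref_id: str
    orientation: str  # 'forward' | 'flipped'
    matches: list[tuple[int, int, int]]  # (ref_idx, qry_idx original frame, channel)
    score: float
    offset_bp: float
    unmatched_ref: dict[int, list[int]]
    unmatched_query: dict[int, list[int]]
    aligned_ref_span: tuple[float, float]
    accepted: bool
    mode: str = "fit"
    # positions parallel to `matches`: (ref_pos, qry_pos original, qry_pos oriented)
    match_positions: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def n_matches(self) -> int:
        return len(self.matches)


def labels_of(map_) -> tuple[np.ndarray, np.ndarray]:
    """(positions, channels) of any map type, sorted by (position, channel)."""
    pairs: list[tuple[float, int]] = []
    if hasattr(map_, "peaks"):
        for ch, pks in map_.peaks.items():
            pairs.extend((p.position_bp, ch) for p in pks)
    else:
        for ch, pos in map_.labels.items():
            pairs.extend((float(p), ch) for p in pos)
    pairs.sort()
    if not pairs:
        return np.empty(0), np.empty(0, dtype=int)
    pos, ch = zip(*pairs)
    return np.asarray(pos, dtype=float), np.asarray(ch, dtype=int)


def interval_penalty(dr: float, dq: float, params: AlignParams) -> float:
    """Sizing penalty for a matched interval pair of lengths dr (ref) and dq (query)."""
    var = params.sd_scale * (dr + dq) / 2.0 + params.sd_base_bp**2
    return min(params.penalty_cap, (dr - dq) ** 2 / (2.0 * var))


def score_matching(
    ref_labels: tuple[np.ndarray, np.ndarray],
    qry_labels: tuple[np.ndarray, np.ndarray],
    matching: list[tuple[int, int]],
    mode: str,
    params: AlignParams,
) -> float:
    """Score an explicit monotone matching with the aligner's scoring function.

    ``matching`` is an ordered list of (ref_idx, qry_idx); channels must agree
    pairwise. This is the single source of truth for the score that the DP in
    :func:`align_maps` optimizes.
    """
    rpos, rch = ref_labels
    qpos, qch = qry_labels
    if not matching:
        return -np.inf
    score = 0.0
    prev = None
    for i, j in matching:
        if rch[i] != qch[j]:
            raise ValidationError("channel mismatch in matching")
        score += params.match_bonus
        if prev is not None:
            pi, pj = prev
            if i <= pi or j <= pj:
                raise ValidationError("matching not monotone")
            dr = rpos[i] - rpos[pi]
            dq = qpos[j] - qpos[pj]
            score -= interval_penalty(dr, dq, params)
            score -= params.miss_penalty * (i - pi - 1)
            score -= params.false_penalty * (j - pj - 1)
        prev = (i, j)
    if mode == "fit":
        j0 = matching[0][1]
        jk = matching[-1][1]
        score -= params.false_penalty * (j0 + (len(qpos) - 1 - jk))
    return score


def _dp_orient(rpos, rch, qpos, qch, mode: str, params: AlignParams):
    """Best-scoring monotone matching for one query orientation.

    Transitions from within the ``max_skip`` index window use the exact
    interval penalty. Longer reference skips (e.g. across a large assembly
    gap) are allowed through a "long jump" transition that charges the full
    penalty cap plus the per-label skip costs; since the exact penalty of a
    genuinely long, size-discordant interval is capped anyway, this is exact
    wherever it matters and conservative elsewhere.
    """
    n, m = len(rpos), len(qpos)
    K = max(params.max_skip, 1)
    mb, miss, fp = params.match_bonus, params.miss_penalty, params.false_penalty
    cap = params.penalty_cap
    S = np.full((n, m), -np.inf)
    C = np.zeros((n, m), dtype=int)
    BP = np.full((n, m, 2), -1, dtype=int)
    start_cost = fp * np.arange(m) if mode == "fit" else np.zeros(m)
    # per-column running max of S[i', j] + miss*(i'+1) over processed rows
    R = np.full(m, -np.inf)
    RA = np.full(m, -1, dtype=int)

    for i in range(n):
        for j in np.flatnonzero(qch == rch[i]):
            best = mb - start_cost[j]
            cnt, bi, bj = 1, -1, -1
            i0 = max(0, i - K)
            j0 = max(0, j - K)
            if i > 0 and j > 0:
                sub = S[i0:i, j0:j]
                if np.isfinite(sub).any():
                    dr = rpos[i] - rpos[i0:i]
                    dq = qpos[j] - qpos[j0:j]
                    var = params.sd_scale * (dr[:, None] + dq[None, :]) / 2.0 + params.sd_base_bp**2
                    pen = np.minimum(cap, (dr[:, None] - dq[None, :]) ** 2 / (2.0 * var))
                    skip = (
                        miss * (i - np.arange(i0, i) - 1)[:, None]
                        + fp * (j - np.arange(j0, j) - 1)[None, :]
                    )
                    cand = sub + mb - pen - skip
                    k = int(np.argmax(cand))
                    ci, cj = divmod(k, cand.shape[1])
                    cbest = cand[ci, cj]
                    ccnt = C[i0 + ci, j0 + cj] + 1
                    if cbest > best + 1e-12 or (abs(cbest - best) <= 1e-12 and ccnt > cnt):
                        best, cnt, bi, bj = cbest, ccnt, i0 + ci, j0 + cj
                for j2 in range(j0, j):
                    if np.isfinite(R[j2]):
                        cand_lj = R[j2] - miss * i + mb - cap - fp * (j - j2 - 1)
                        if cand_lj > best + 1e-12:
                            best, cnt, bi, bj = cand_lj, C[RA[j2], j2] + 1, RA[j2], j2
            S[i, j] = best
            C[i, j] = cnt
            BP[i, j] = (bi, bj)
        upd = S[i, :] + miss * (i + 1)
        better = upd > R
        R[better] = upd[better]
        RA[better] = i

    end_cost = params.false_penalty * (m - 1 - np.arange(m)) if mode == "fit" else np.zeros(m)
    totals = S - end_cost[None, :]
    if not np.isfinite(totals).any():
        return None
    flat = np.argmax(totals)
    # deterministic tie-break: score, then match count, then end-offset magnitude
    best_val = totals.flat[flat]
    ties = np.argwhere(np.abs(totals - best_val) <= 1e-12)
    if len(ties) > 1:
        def key(ij):
            i, j = ij
            return (-C[i, j], abs(rpos[i] - qpos[j]), i, j)
        ties = sorted(map(tuple, ties), key=key)
        ei, ej = ties[0]
    else:
        ei, ej = divmod(flat, m)
    path = []
    i, j = int(ei), int(ej)
    while i >= 0:
        path.append((i, j))
        i, j = int(BP[i, j, 0]), int(BP[i, j, 1])
    path.reverse()
    return float(best_val), path


def align_maps(query, ref, mode: str = "fit", params: AlignParams | None = None) -> MapAlignment:
    """Align ``query`` to ``ref``; tries both orientations, returns the best.

    mode='fit' anchors the whole query inside the reference (free reference
    ends, penalized unmatched query labels); mode='overlap' leaves all ends
    free (dovetail). An unacceptable alignment (score < min_score or too few
    matched labels) is returned with ``accepted=False`` carrying the best
    rejected score, never raised.
    """
    if mode not in ("fit", "overlap"):
        raise ValidationError(f"unknown mode {mode!r}")
    params = params or AlignParams()
    rpos, rch = labels_of(ref)
    qpos, qch = labels_of(query)
    qid = getattr(query, "map_id", "query")
    rid = getattr(ref, "map_id", "ref")
    qlen = float(getattr(query, "length_bp", qpos[-1] if len(qpos) else 0.0))

    def empty(score=-np.inf):
        return MapAlignment(qid, rid, "forward", [], float(score), 0.0,
                            _bychannel(rpos, rch, set()), _bychannel(qpos, qch, set()),
                            (0.0, 0.0), False, mode)

    if len(rpos) == 0 or len(qpos) == 0 or not (set(rch) & set(qch)):
        return empty()

    best = None
    for orientation in ("forward", "flipped"):
        if orientation == "forward":
            opos, och = qpos, qch
        else:
            opos = (qlen - qpos)[::-1].copy()
            och = qch[::-1].copy()
        res = _dp_orient(rpos, rch, opos, och, mode, params)
        if res is None:
            continue
        score, path = res
        if best is None or score > best[0] + 1e-12 or (
            abs(score - best[0]) <= 1e-12 and len(path) > len(best[1])
        ):
            best = (score, path, orientation, opos)

    if best is None:
        return empty()
    score, path, orientation, opos = best
    m = len(qpos)

    matches = []
    match_positions = []
    offs = []
    for i, j in path:
        jo = j if orientation == "forward" else m - 1 - j
        matches.append((int(i), int(jo), int(rch[i])))
        match_positions.append((float(rpos[i]), float(qpos[jo]), float(opos[j])))
        offs.append(rpos[i] - opos[j])
    offset = float(np.median(offs))
    matched_r = {i for i, _, _ in matches}
    matched_q = {jo for _, jo, _ in matches}
    span = (float(rpos[path[0][0]]), float(rpos[path[-1][0]]))
    accepted = score >= params.min_score and len(matches) >= params.min_labels
    return MapAlignment(
        qid, rid, orientation, matches, float(score), offset,
        _bychannel(rpos, rch, matched_r), _bychannel(qpos, qch, matched_q),
        span, accepted, mode, match_positions,
    )


def _bychannel(pos, ch, matched: set[int]) -> dict[int, list[int]]:
    """Unmatched combined indices re-expressed as per-channel index lists."""
    out: dict[int, list[int]] = {}
    counters: dict[int, int] = {}
    for k in range(len(pos)):
        c = int(ch[k])
        within = counters.get(c, 0)
        counters[c] = within + 1
        if k not in matched:
            out.setdefault(c, []).append(within)
    return out


@dataclass
class GenomeMap:
    """A merged region map: consensus plus the clone tiling that produced it."""

    consensus: ConsensusMap
    tiling: list[tuple[str, float, float, str]]  # (clone_id, start, end, orientation)
    breaks: list[float] = field(default_factory=list)

    @property
    def map_id(self) -> str:
        return self.consensus.map_id

    @property
    def length_bp(self) -> float:
        return self.consensus.length_bp

    @property
    def peaks(self):
        return self.consensus.peaks

    @property
    def n_molecules(self) -> int:
        return self.consensus.n_molecules


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.p[ra] = rb
        return True


def merge_consensus(
    clone_maps: list[ConsensusMap],
    params: AlignParams | None = None,
    resolution_bp: float = 1000.0,
    consistency_tol_bp: float = 5000.0,
    map_id: str = "genome_map",
    overlap_min_score: float = 25.0,
    overlap_min_labels: int = 6,
) -> GenomeMap:
    """Tile per-clone consensus maps into one region genome map.

    All-pairs overlap alignments form a graph; a maximum-weight spanning
    forest fixes each clone's orientation and offset; matched peaks are merged
    by support-weighted averaging. Clones with no acceptable overlap start a
    new segment, and a break is recorded at the junction. Strong overlaps that
    contradict the spanning-tree layout raise an AlignmentError naming the
    inconsistent clone triple.
    """
    if not clone_maps:
        raise ValidationError("need at least one clone map")
    params = params or AlignParams()
    # overlaps between short map pairs are easy to fake; demand more evidence
    # than the generic alignment acceptance does
    params = params.with_(
        min_score=max(params.min_score, overlap_min_score),
        min_labels=max(params.min_labels, overlap_min_labels),
    )
    n = len(clone_maps)

    edges = []  # (score, i, j, orient_sign, beta) with x_i = beta + sign * x_j
    alns: dict[tuple[int, int], MapAlignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_maps(clone_maps[j], clone_maps[i], mode="overlap", params=params)
            if not aln.accepted:
                continue
            alns[(i, j)] = aln
            Lj = clone_maps[j].length_bp
            if aln.orientation == "forward":
                edges.append((aln.score, i, j, 1, aln.offset_bp))
            else:
                edges.append((aln.score, i, j, -1, aln.offset_bp + Lj))

    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    uf = _UnionFind(n)
    tree_edges = []
    extra_edges = []
    for score, i, j, sign, beta in edges:
        if uf.union(i, j):
            tree_edges.append((i, j, sign, beta, score))
        else:
            extra_edges.append((i, j, sign, beta, score))

    # BFS over the spanning forest to assign per-clone affine transforms
    # X = t + o * x  (o in {+1,-1})
    t = np.zeros(n)
    o = np.ones(n, dtype=int)
    placed = np.zeros(n, dtype=bool)
    adj: dict[int, list[tuple[int, int, float, bool]]] = {i: [] for i in range(n)}
    for i, j, sign, beta, _ in tree_edges:
        adj[i].append((j, sign, beta, True))   # x_i = beta + sign * x_j
        adj[j].append((i, sign, beta, False))
    components: list[list[int]] = []
    for root in range(n):
        if placed[root]:
            continue
        comp = [root]
        placed[root] = True
        queue = [root]
        while queue:
            a = queue.pop()
            for b, sign, beta, fwd in adj[a]:
                if placed[b]:
                    continue
                if fwd:  # x_a = beta + sign * x_b  ->  G_b = G_a o edge
                    o[b] = o[a] * sign
                    t[b] = t[a] + o[a] * beta
                else:    # x_b = beta + sign * x_a  ->  invert
                    o[b] = o[a] * sign
                    t[b] = t[a] - o[a] * sign * beta
                placed[b] = True
                comp.append(b)
                queue.append(b)
        components.append(sorted(comp))

    # consistency check on non-tree edges
    tree_scores = [e[4] for e in tree_edges] or [0.0]
    strong = 0.5 * float(np.median(tree_scores))
    for i, j, sign, beta, score in extra_edges:
        pred_o = o[i] * sign
        pred_t = t[i] + o[i] * beta
        if (pred_o != o[j] or abs(pred_t - t[j]) > consistency_tol_bp):
            if score >= strong:
                raise AlignmentError(
                    f"contradictory overlaps among clones "
                    f"({clone_maps[i].map_id}, {clone_maps[j].map_id}) and the "
                    f"spanning-tree path joining them (offset disagreement "
                    f"{abs(pred_t - t[j]):.0f} bp)"
                )
            # weak spurious overlap: ignore

    components.sort(key=lambda c: c[0])

    # lay segments end to end, recording a break at each junction
    tiling = []
    breaks: list[float] = []
    global_shift = 0.0
    seg_offsets = {}
    for seg_idx, comp in enumerate(components):
        starts = []
        ends = []
        for c in comp:
            L = clone_maps[c].length_bp
            a, b = t[c] + 0.0 * o[c], t[c] + o[c] * L
            starts.append(min(a, b))
            ends.append(max(a, b))
        seg_min = min(starts)
        seg_max = max(ends)
        if seg_idx > 0:
            breaks.append(global_shift)
        for c in comp:
            seg_offsets[c] = global_shift - seg_min
        global_shift += seg_max - seg_min

    total_len = global_shift
    for c in range(n):
        L = clone_maps[c].length_bp
        a = t[c] + seg_offsets[c]
        b = t[c] + o[c] * L + seg_offsets[c]
        tiling.append(
            (clone_maps[c].map_id, min(a, b), max(a, b), "forward" if o[c] == 1 else "flipped")
        )

    channels = sorted({ch for cm in clone_maps for ch in cm.peaks})
    merged_peaks: dict[int, list[Peak]] = {}
    for ch in channels:
        items = []
        for c, cm in enumerate(clone_maps):
            for p in cm.peaks.get(ch, ()):
                X = t[c] + o[c] * p.position_bp + seg_offsets[c]
                items.append((X, p.sd_bp, p.support))
        items.sort()
        out: list[Peak] = []
        group: list[tuple[float, float, int]] = []
        def flush():
            if not group:
                return
            w = sum(g[2] for g in group)
            pos = sum(g[0] * g[2] for g in group) / w
            sd = sum(g[1] * g[2] for g in group) / w
            out.append(Peak(pos, sd, max(g[2] for g in group)))
        for it in items:
            if group and it[0] - group[-1][0] < resolution_bp:
                group.append(it)
            else:
                flush()
                group = [it]
        flush()
        dedup: list[Peak] = []
        for q in out:
            if dedup and q.position_bp <= dedup[-1].position_bp:
                continue
            dedup.append(q)
        merged_peaks[ch] = dedup

    n_mol = sum(cm.n_molecules for cm in clone_maps)
    cons = ConsensusMap(map_id=map_id, length_bp=max(total_len, 1.0),
                        peaks=merged_peaks, n_molecules=n_mol)
    cons.validate()
    tiling.sort(key=lambda r: (r[1], r[0]))
    return GenomeMap(consensus=cons, tiling=tiling, breaks=breaks)
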