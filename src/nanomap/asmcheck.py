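"""Assembly validation against a genome map.

Classifies map-vs-sequence disagreements into the four discrepancy classes
(extra sequence, missing sequence, interval mismatch, high-density region),
anchors unplaced scaffolds into genome-map gaps, and computes completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._defaults import section
from .consensus import ConsensusMap
from .errors import ValidationError
from .mapalign import AlignParams, MapAlignment, align_maps
from .molsim import MoleculeMap, merge_close_labels
from .motifmap import ReferenceMap

_D = section("asmcheck")

EXTRA_SEQUENCE = "EXTRA_SEQUENCE"
MISSING_SEQUENCE = "MISSING_SEQUENCE"
INTERVAL_MISMATCH = "INTERVAL_MISMATCH"
HIGH_DENSITY_REGION = "HIGH_DENSITY_REGION"
UNALIGNED_END = "UNALIGNED_END"

KINDS = (EXTRA_SEQUENCE, MISSING_SEQUENCE, INTERVAL_MISMATCH, HIGH_DENSITY_REGION, UNALIGNED_END)


@dataclass(frozen=True)
class AsmParams:
    tol_bp: float | None = _D["tol_bp"]
    min_gap_labels: int = _D["min_gap_labels"]
    merge_bridge_bp: float = _D["merge_bridge_bp"]
    condense_bp: float = _D["condense_bp"]
    window_bp: float = _D["window_bp"]
    repeat_bin_bp: float = _D["repeat_bin_bp"]
    density_threshold: float = _D["density_threshold"]
    min_mol_count: float = _D["min_mol_count"]
    exclusions: tuple[tuple[float, float], ...] = ()
    align: AlignParams = AlignParams()

    def with_(self, **kw) -> "AsmParams":
        return replace(self, **kw)

    def effective_tol(self, pooled_sd: float = 0.0) -> float:
        if self.tol_bp is not None:
            return float(self.tol_bp)
        return max(1500.0, 3.0 * pooled_sd)


@dataclass
class Discrepancy:
    kind: str
    query_id: str | None
    ref_interval: tuple[float, float] | None
    query_interval: tuple[float, float] | None
    size_estimate_bp: float  # signed: + means sequence surplus in the assembly
    evidence: dict = field(default_factory=dict)


@dataclass
class CompletenessReport:
    aligned_ref_bp: float
    total_ref_bp: float
    fraction: float
    excluded_intervals: list[tuple[float, float, str]] = field(default_factory=list)


def _condensed_query(scaffold: ReferenceMap, condense_bp: float):
    """Condense in-silico labels below optical resolution before aligning."""
    labels = {}
    for ch, pos in scaffold.labels.items():
        merged, _ = merge_close_labels(np.asarray(pos, dtype=float), condense_bp)
        labels[ch] = merged
    cq = MoleculeMap(scaffold.map_id, float(max(scaffold.length_bp, 1)), labels)
    cq.map_id = scaffold.map_id  # duck-type as a map for align_maps
    cq.gaps = list(scaffold.gaps)
    return cq


def _union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[list[float]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(intervals, holes):
    """Set difference of two sorted disjoint interval lists."""
    out = []
    for s, e in intervals:
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, min(hs, e)))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _clip_len(intervals, lo, hi) -> float:
    return sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in intervals)


def _pooled_peak_sd(genome_map) -> float:
    sds = [p.sd_bp for pks in genome_map.peaks.values() for p in pks]
    return float(np.median(sds)) if sds else 0.0


def compare_assembly(
    assembly_maps,
    genome_map,
    params: AsmParams | None = None,
) -> tuple[list[Discrepancy], CompletenessReport, list[MapAlignment]]:
    """Fit-align each assembly scaffold map to the genome map and classify.

    Walking consecutive matched label pairs of each accepted alignment:

    * extra query labels between matched flanks with query span exceeding the
      reference span beyond tolerance -> EXTRA_SEQUENCE;
    * query surplus beyond tolerance with no extra label but a scaffold gap
      (N run) inside the interval -> EXTRA_SEQUENCE (length-only case, a
      scaffolding join); deficit across a scaffold gap -> MISSING_SEQUENCE;
    * extra reference labels / length deficit beyond tolerance ->
      MISSING_SEQUENCE (an assembly gap, sized by the genome-map flank span);
    * length disagreement beyond tolerance inside one contig with no extra
      labels -> INTERVAL_MISMATCH.

    Genome-map regions carrying labels but covered by no accepted alignment
    are also MISSING_SEQUENCE. Completeness is the aligned fraction of the
    genome map after user-supplied exclusions.
    """
    params = params or AsmParams()
    if isinstance(assembly_maps, ReferenceMap):
        assembly_maps = [assembly_maps]
    gm_channels = set(genome_map.peaks)
    for sc in assembly_maps:
        if not (set(sc.labels) & gm_channels):
            raise ValidationError(
                f"scaffold {sc.map_id} shares no label channel with the genome map"
            )
    tol = params.effective_tol(_pooled_peak_sd(genome_map))
    gpos, _gch = _genome_positions(genome_map)

    discrepancies: list[Discrepancy] = []
    alignments: list[MapAlignment] = []
    covered: list[tuple[float, float]] = []

    for sc in assembly_maps:
        query = _condensed_query(sc, params.condense_bp)
        aln = align_maps(query, genome_map, mode="fit", params=params.align)
        alignments.append(aln)
        if not aln.accepted:
            if sum(len(v) for v in sc.labels.values()) > 0:
                discrepancies.append(
                    Discrepancy(
                        EXTRA_SEQUENCE, sc.map_id, None, (0.0, float(sc.length_bp)),
                        float(sc.length_bp),
                        {"reason": "scaffold aligned nowhere on the genome map",
                         "best_rejected_score": aln.score},
                    )
                )
            continue
        # covered span extends past the outermost matched labels by the query
        # overhang (the aligned sequence continues beyond its last label)
        o_first = aln.match_positions[0][2]
        o_last = aln.match_positions[-1][2]
        qlen = float(query.length_bp)
        covered.append(
            (max(0.0, aln.aligned_ref_span[0] - o_first),
             min(float(genome_map.length_bp), aln.aligned_ref_span[1] + (qlen - o_last)))
        )
        discrepancies.extend(_walk_alignment(sc, query, aln, tol, params, gpos))

    # regions where the assembly lacks sequence do not count as covered, even
    # when the surrounding alignment bridges them
    deficits: list[tuple[float, float]] = []
    for d in discrepancies:
        if d.ref_interval is None:
            continue
        if d.kind == MISSING_SEQUENCE:
            deficits.append(d.ref_interval)
        elif d.kind == INTERVAL_MISMATCH and d.size_estimate_bp < -tol:
            s, e = d.ref_interval
            mid = 0.5 * (s + e)
            half = min(abs(d.size_estimate_bp), e - s) / 2.0
            deficits.append((mid - half, mid + half))
    covered = _subtract(_union(covered), _union(deficits))
    # genome-map segments with labels but no alignment cover
    uncovered = _complement(covered, genome_map.length_bp)
    already = [d.ref_interval for d in discrepancies
               if d.kind == MISSING_SEQUENCE and d.ref_interval]
    for s, e in uncovered:
        if any(hs < e and he > s for hs, he in already):
            continue
        n_lab = int(np.sum((gpos >= s) & (gpos < e)))
        if n_lab >= params.min_gap_labels and (e - s) > tol:
            discrepancies.append(
                Discrepancy(
                    MISSING_SEQUENCE, None, (s, e), None, -(e - s),
                    {"ref_labels": n_lab, "reason": "no accepted alignment covers this region"},
                )
            )

    total = float(genome_map.length_bp)
    excl = _union([(max(0.0, s), min(total, e)) for s, e in params.exclusions])
    excl_len = sum(e - s for s, e in excl)
    aligned = sum(e - s for s, e in covered) - sum(
        _clip_len(covered, s, e) for s, e in excl
    )
    denom = max(total - excl_len, 1e-9)
    report = CompletenessReport(
        aligned_ref_bp=aligned,
        total_ref_bp=total,
        fraction=min(1.0, aligned / denom),
        excluded_intervals=[(s, e, "user-supplied exclusion") for s, e in excl],
    )
    return discrepancies, report, alignments


def _genome_positions(genome_map):
    pos, ch = [], []
    for c, pks in genome_map.peaks.items():
        pos.extend(p.position_bp for p in pks)
        ch.extend([c] * len(pks))
    order = np.argsort(pos) if pos else []
    return (
        np.asarray(pos, dtype=float)[order] if len(pos) else np.empty(0),
        np.asarray(ch, dtype=int)[order] if len(pos) else np.empty(0, dtype=int),
    )


def _walk_alignment(
    scaffold: ReferenceMap,
    query,
    aln: MapAlignment,
    tol: float,
    params: AsmParams,
    gpos: np.ndarray,
) -> list[Discrepancy]:
    out: list[Discrepancy] = []
    qpos_all, _ = _map_label_arrays(query)
    qlen = float(query.length_bp)
    opos_all = np.sort(qlen - qpos_all) if aln.orientation == "flipped" else qpos_all
    mp = aln.match_positions
    gaps = list(getattr(query, "gaps", []) or [])

    def q_orig_interval(o1, o2):
        """Oriented query interval back to original scaffold coordinates."""
        if aln.orientation == "forward":
            return (o1, o2)
        return (qlen - o2, qlen - o1)

    # classify every flank-to-flank interval, then merge adjacent same-kind
    # events: a gap crossing can be split by a stray in-gap match
    records = []
    for a, b in zip(mp, mp[1:]):
        r1, _, o1 = a
        r2, _, o2 = b
        dr = r2 - r1
        dq = o2 - o1
        delta = dq - dr  # + = assembly surplus
        # consecutive matched pairs bound an interval with no matched label
        # inside it, so every interior label is unmatched by construction
        extra_q = int(np.sum((opos_all > o1 + 1e-6) & (opos_all < o2 - 1e-6)))
        extra_r = int(np.sum((gpos > r1 + 1e-6) & (gpos < r2 - 1e-6)))
        qint = q_orig_interval(o1, o2)
        has_gap = any(s < qint[1] and e > qint[0] for s, e in gaps)
        if extra_q > 0 and delta > tol:
            kind = EXTRA_SEQUENCE
        elif extra_r > 0 and -delta > tol:
            kind = MISSING_SEQUENCE
        elif abs(delta) > tol:
            kind = (EXTRA_SEQUENCE if delta > 0 else MISSING_SEQUENCE) if has_gap \
                else INTERVAL_MISMATCH
        else:
            kind = None
        records.append(
            {"kind": kind, "r1": r1, "r2": r2, "qint": qint, "delta": delta,
             "extra_q": extra_q, "extra_r": extra_r, "has_gap": has_gap}
        )

    k = 0
    bridge = params.merge_bridge_bp
    while k < len(records):
        rec = records[k]
        if rec["kind"] is None:
            k += 1
            continue
        kind = rec["kind"]
        end = k
        if kind in (EXTRA_SEQUENCE, MISSING_SEQUENCE):
            j = k + 1
            while j < len(records):
                nxt = records[j]
                if nxt["kind"] == kind:
                    end = j
                    j += 1
                elif nxt["kind"] is None and (nxt["r2"] - nxt["r1"]) <= bridge:
                    j += 1  # short clean stretch between two halves of one event
                else:
                    break
        group = records[k:end + 1]
        delta = sum(g["delta"] for g in group)
        qlo = min(min(g["qint"]) for g in group)
        qhi = max(max(g["qint"]) for g in group)
        ev = {
            "flank_ref_bp": (group[0]["r1"], group[-1]["r2"]),
            "flank_query_bp": (qlo, qhi),
            "extra_query_labels": sum(g["extra_q"] for g in group),
            "extra_ref_labels": sum(g["extra_r"] for g in group),
            "scaffold_gap_in_interval": any(g["has_gap"] for g in group),
            "n_intervals": len(group),
        }
        out.append(
            Discrepancy(kind, scaffold.map_id, (group[0]["r1"], group[-1]["r2"]),
                        (qlo, qhi), delta, ev)
        )
        k = end + 1

    # unaligned scaffold ends carrying labels over a sizable span
    if mp:
        o_first = mp[0][2]
        o_last = mp[-1][2]
        lead = [p for p in opos_all if p < o_first - 1e-6]
        trail = [p for p in opos_all if p > o_last + 1e-6]
        for side, pts, ref_pt in (("left", lead, aln.aligned_ref_span[0]),
                                  ("right", trail, aln.aligned_ref_span[1])):
            if len(pts) >= params.min_gap_labels and (max(pts) - min(pts)) > tol:
                qint = q_orig_interval(min(pts), max(pts))
                out.append(
                    Discrepancy(
                        UNALIGNED_END, scaffold.map_id, (ref_pt, ref_pt), qint,
                        max(pts) - min(pts),
                        {"side": side, "n_labels": len(pts)},
                    )
                )
    return out


def _map_label_arrays(map_):
    from .mapalign import labels_of

    return labels_of(map_)


def _complement(intervals: list[tuple[float, float]], length: float):
    out = []
    prev = 0.0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


@dataclass
class Placement:
    scaffold_id: str
    gap_index: int
    status: str  # 'placed' | 'ambiguous' | 'unanchorable' | 'conflict'
    ref_start_bp: float | None = None
    orientation: str | None = None
    score: float = float("-inf")
    residual_gap_bp: float | None = None


def anchor_scaffolds(
    unplaced: list[ReferenceMap],
    genome_map,
    gaps: list[tuple[float, float]],
    params: AsmParams | None = None,
    flank_margin_bp: float = 20000.0,
    min_margin: float = 5.0,
) -> list[Placement]:
    """Place unplaced scaffolds into genome-map gaps by fit alignment.

    Each scaffold is aligned against each gap extended by a flank margin; a
    placement is accepted when it is the unique best for that gap by a score
    margin of at least ``min_margin``. Two scaffolds claiming the same gap
    with indistinguishable scores are both reported ambiguous. Accepted
    placements must not overlap; conflicts keep the higher score.
    """
    params = params or AsmParams()
    placements: list[Placement] = []
    candidates: dict[int, list[tuple[float, ReferenceMap, MapAlignment, float]]] = {}

    for sc in unplaced:
        if sum(len(v) for v in sc.labels.values()) == 0:
            placements.append(Placement(sc.map_id, -1, "unanchorable"))
            continue
        for gi, (gs, ge) in enumerate(gaps):
            lo = max(0.0, gs - flank_margin_bp)
            hi = min(float(genome_map.length_bp), ge + flank_margin_bp)
            sub = _submap(genome_map, lo, hi)
            query = _condensed_query(sc, params.condense_bp)
            aln = align_maps(query, sub, mode="fit", params=params.align)
            if aln.accepted:
                candidates.setdefault(gi, []).append((aln.score, sc, aln, lo))

    taken: list[tuple[float, float]] = []
    for gi in sorted(candidates):
        cands = sorted(candidates[gi], key=lambda c: -c[0])
        if len(cands) > 1 and cands[0][0] - cands[1][0] < min_margin:
            for score, sc, aln, lo in cands[:2]:
                placements.append(Placement(sc.map_id, gi, "ambiguous", score=score))
            continue
        score, sc, aln, lo = cands[0]
        start = lo + aln.offset_bp
        end = start + sc.length_bp
        if any(s < end and e > start for s, e in taken):
            placements.append(Placement(sc.map_id, gi, "conflict", score=score))
            continue
        taken.append((start, end))
        gs, ge = gaps[gi]
        placements.append(
            Placement(
                sc.map_id, gi, "placed",
                ref_start_bp=float(start),
                orientation=aln.orientation,
                score=score,
                residual_gap_bp=float((ge - gs) - sc.length_bp),
            )
        )
    return placements


def _submap(genome_map, lo: float, hi: float) -> ConsensusMap:
    from .consensus import Peak

    peaks = {
        ch: [Peak(p.position_bp - lo, p.sd_bp, p.support)
             for p in pks if lo <= p.position_bp < hi]
        for ch, pks in genome_map.peaks.items()
    }
    return ConsensusMap(
        map_id=f"{genome_map.map_id}:{lo:.0f}-{hi:.0f}",
        length_bp=hi - lo,
        peaks=peaks,
        n_molecules=genome_map.n_molecules,
    )


def detect_label_repeats(
    molecules: list[MoleculeMap],
    consensus: ConsensusMap,
    window_bp: float | None = None,
    density_threshold: float | None = None,
    params: AsmParams | None = None,
    channel: int = 1,
    unit_length_bp: float | None = None,
) -> list[Discrepancy]:
    """Flag windows whose per-molecule label density the consensus peaks cannot
    explain: the tandem-repeat (satellite) signature of label runs too dense
    for the optical resolution.

    Windows where the mean per-molecule label count exceeds the consensus peak
    count by ``density_threshold`` (and an absolute floor) are merged into
    regions; region bounds are trimmed to the bins that actually carry label
    density. Copy number is estimated as region length / unit length when a
    repeat-unit length is given.
    """
    params = params or AsmParams()
    window = float(window_bp if window_bp is not None else params.window_bp)
    thr = float(density_threshold if density_threshold is not None else params.density_threshold)
    if not molecules:
        raise ValidationError("no molecules")
    med_len = float(np.median([m.length_bp for m in molecules]))
    if not (0.75 * consensus.length_bp <= med_len <= 1.25 * consensus.length_bp):
        raise ValidationError("molecules are not scaled/oriented to the consensus frame")
    _check_orientation(molecules, consensus, channel)

    L = float(consensus.length_bp)
    bin_bp = float(params.repeat_bin_bp)
    n_bins = max(1, int(np.ceil(L / bin_bp)))
    edges = np.arange(n_bins + 1) * bin_bp
    n_mol = len(molecules)

    mol_counts = np.zeros(n_bins)
    for m in molecules:
        pos = np.asarray(m.labels.get(channel, ()), dtype=float)
        if len(pos):
            pos = pos * (L / m.length_bp)  # remove per-molecule stretch variation
            c, _ = np.histogram(np.clip(pos, 0, edges[-1] - 1e-9), bins=edges)
            mol_counts += c
    mol_density = mol_counts / n_mol  # mean labels per molecule per bin

    peak_pos = consensus.positions(channel)
    peak_counts, _ = np.histogram(
        np.clip(peak_pos, 0, edges[-1] - 1e-9) if len(peak_pos) else peak_pos, bins=edges
    )

    w_bins = max(1, int(round(window / bin_bp)))
    kernel = np.ones(w_bins)
    M = np.convolve(mol_density, kernel, mode="same")
    P = np.convolve(peak_counts.astype(float), kernel, mode="same")
    flagged = (M >= thr * P) & (M >= params.min_mol_count)

    regions = []
    in_run = False
    start = 0
    for k in range(n_bins):
        if flagged[k] and not in_run:
            in_run, start = True, k
        elif not flagged[k] and in_run:
            regions.append((start, k))
            in_run = False
    if in_run:
        regions.append((start, n_bins))

    out: list[Discrepancy] = []
    floor = 0.15  # per-molecule labels per bin marking true repeat core
    for k0, k1 in regions:
        lo = max(0, k0 - w_bins)
        hi = min(n_bins, k1 + w_bins)
        core = np.flatnonzero(mol_density[lo:hi] >= floor)
        if len(core) == 0:
            continue
        c0, c1 = lo + core[0], lo + core[-1] + 1
        length = (c1 - c0) * bin_bp
        if length < window / 2:
            continue
        ev = {
            "channel": channel,
            "mean_molecule_labels_per_window": float(M[(c0 + c1) // 2]),
            "consensus_peaks_in_window": float(P[(c0 + c1) // 2]),
        }
        if unit_length_bp:
            ev["estimated_copies"] = round(length / unit_length_bp)
            ev["unit_length_bp"] = unit_length_bp
        out.append(
            Discrepancy(
                HIGH_DENSITY_REGION, None, (c0 * bin_bp, c1 * bin_bp), None, length, ev
            )
        )
    return out


def _check_orientation(molecules, consensus, channel):
    """Cheap majority-vote check that molecules lie in the consensus frame."""
    peak_pos = consensus.positions(channel)
    if len(peak_pos) < 2:
        return
    votes_flipped = votes = 0
    tol = 1000.0
    for m in molecules:
        pos = np.asarray(m.labels.get(channel, ()), dtype=float)
        if len(pos) < 2:
            continue
        # fraction of labels explained by a nearby peak; robust against dense
        # label runs that the consensus deliberately left peak-free
        fwd = np.mean(np.min(np.abs(pos[:, None] - peak_pos[None, :]), axis=1) <= tol)
        mirrored = m.length_bp - pos
        flp = np.mean(np.min(np.abs(mirrored[:, None] - peak_pos[None, :]), axis=1) <= tol)
        if flp > fwd + 0.1:
            votes_flipped += 1
        votes += 1
    if votes and votes_flipped / votes > 0.6:
        raise ValidationError("molecules appear mirror-oriented relative to the consensus")
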