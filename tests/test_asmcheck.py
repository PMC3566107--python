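import numpy as np
import pytest

from nanomap.asmcheck import (
    EXTRA_SEQUENCE,
    HIGH_DENSITY_REGION,
    INTERVAL_MISMATCH,
    MISSING_SEQUENCE,
    AsmParams,
    anchor_scaffolds,
    compare_assembly,
    detect_label_repeats,
)
from nanomap.consensus import (
    ConsensusMap,
    Peak,
    build_consensus,
    cluster_molecules,
    orient_molecules,
    pairwise_distance,
    refine_orientations,
)
from nanomap.errors import ValidationError
from nanomap.molsim import SimulationParams, simulate_molecules
from nanomap.motifmap import ReferenceMap

from conftest import spaced_sites


def as_consensus(ref: ReferenceMap, sd=80.0, support=20, mid=None) -> ConsensusMap:
    return ConsensusMap(
        mid or ref.map_id, float(ref.length_bp),
        {ch: [Peak(float(p), sd, support) for p in pos] for ch, pos in ref.labels.items()},
        n_molecules=support,
    )


def irregular_ref(rng, length=400_000, n1=70, n2=45, map_id="truth"):
    return ReferenceMap(
        map_id, length,
        {1: spaced_sites(rng, length, n1), 2: spaced_sites(rng, length, n2)},
    )


class TestCompareAssembly:
    def test_identical_maps_no_discrepancies_full_coverage(self, rng):
        truth = irregular_ref(rng)
        gm = as_consensus(truth, mid="gm")
        disc, report, alns = compare_assembly(truth, gm)
        assert disc == []
        assert report.fraction == pytest.approx(1.0)
        assert alns[0].accepted

    def test_fig5_style_interval_mismatch(self):
        left = [5_000, 12_000, 19_000, 26_000]
        rightq = [26_000 + 20_763 + d for d in (0, 7_000, 14_000, 21_000)]
        rightr = [26_000 + 17_700 + d for d in (0, 7_000, 14_000, 21_000)]
        asm = ReferenceMap("asm", rightq[-1] + 5_000, {1: rightq, 2: left})
        gm = ConsensusMap(
            "gm", float(rightr[-1] + 5_000),
            {1: [Peak(float(p), 100.0, 20) for p in rightr],
             2: [Peak(float(p), 100.0, 20) for p in left]},
            20,
        )
        disc, _, _ = compare_assembly(asm, gm)
        assert len(disc) == 1
        d = disc[0]
        assert d.kind == INTERVAL_MISMATCH
        assert d.size_estimate_bp == pytest.approx(3_063, abs=1)
        assert round(d.size_estimate_bp / 1000) == 3

    def test_planted_events_recovered(self, rng):
        truth = irregular_ref(rng)
        gm = as_consensus(truth, mid="gm")
        L = truth.length_bp

        # corrupt the in-silico assembly map directly (coordinates edits)
        def shift(positions, frm, by):
            return [p + by if p >= frm else p for p in positions]

        ch1 = list(truth.labels[1])
        ch2 = list(truth.labels[2])
        # planted 1: EXTRA contig at 100k: +9 kb carrying 4 foreign ch1 labels
        # planted 2: INTERVAL expansion +3 kb at 200k, no labels
        # planted 3: MISSING 50 kb at 300k (deleted, 100 bp N stub)
        events = []
        ins1, ins1_len = 100_000, 9_000
        ins2, ins2_len = 200_000, 3_000
        del3, del3_len = 300_000, 50_000

        # apply from right to left
        keep1 = [p for p in ch1 if not (del3 <= p < del3 + del3_len)]
        keep2 = [p for p in ch2 if not (del3 <= p < del3 + del3_len)]
        ch1 = shift(keep1, del3, -del3_len + 100)
        ch2 = shift(keep2, del3, -del3_len + 100)
        ch1 = shift(ch1, ins2, ins2_len)
        ch2 = shift(ch2, ins2, ins2_len)
        ch1 = shift(ch1, ins1, ins1_len)
        ch2 = shift(ch2, ins1, ins1_len)
        extra_labels = [ins1 + 2_000, ins1 + 4_000, ins1 + 5_500, ins1 + 7_000]
        ch1 = sorted(ch1 + extra_labels)
        new_len = L + ins1_len + ins2_len - del3_len + 100
        asm = ReferenceMap("asm", new_len, {1: ch1, 2: ch2},
                           gaps=[(ins1, ins1 + 10), (ins1 + ins1_len - 10, ins1 + ins1_len),
                                 (ins1 + ins2_len + del3 - del3_len + 90 + ins1_len - 0, 0)][0:2])
        # gap marker for the deletion stub
        stub_start = del3 + ins1_len + ins2_len
        asm = ReferenceMap("asm", new_len, {1: ch1, 2: ch2},
                           gaps=sorted([(ins1, ins1 + 10), (ins1 + ins1_len - 10, ins1 + ins1_len),
                                        (stub_start, stub_start + 100)]))

        disc, report, _ = compare_assembly(asm, gm)
        kinds = {}
        for d in disc:
            kinds.setdefault(d.kind, []).append(d)
        assert set(kinds) == {EXTRA_SEQUENCE, INTERVAL_MISMATCH, MISSING_SEQUENCE}
        assert kinds[EXTRA_SEQUENCE][0].size_estimate_bp == pytest.approx(ins1_len, abs=1_000)
        assert kinds[INTERVAL_MISMATCH][0].size_estimate_bp == pytest.approx(ins2_len, abs=1_000)
        assert kinds[MISSING_SEQUENCE][0].size_estimate_bp == pytest.approx(
            -(del3_len - 100), abs=1_000
        )
        # sum of |size| within 10% of planted total
        total = sum(abs(d.size_estimate_bp) for ds in kinds.values() for d in ds)
        planted = ins1_len + ins2_len + (del3_len - 100)
        assert abs(total - planted) / planted < 0.10
        assert report.fraction < 1.0

    def test_extra_and_missing_swap_under_role_exchange(self, rng):
        truth = irregular_ref(rng, length=200_000, n1=35, n2=20)
        # assembly with a 10-kb insertion carrying 3 labels at 90k
        ch1 = [p + 10_000 if p >= 90_000 else p for p in truth.labels[1]]
        ch1 = sorted(ch1 + [92_000, 95_000, 98_000])
        ch2 = [p + 10_000 if p >= 90_000 else p for p in truth.labels[2]]
        asm = ReferenceMap("asm", 210_000, {1: ch1, 2: ch2})

        disc_fwd, _, _ = compare_assembly(asm, as_consensus(truth, mid="gm"))
        kinds_fwd = {d.kind for d in disc_fwd}
        assert EXTRA_SEQUENCE in kinds_fwd

        disc_swp, _, _ = compare_assembly(truth, as_consensus(asm, mid="gm2"))
        kinds_swp = {d.kind for d in disc_swp}
        assert MISSING_SEQUENCE in kinds_swp
        assert EXTRA_SEQUENCE not in kinds_swp

    def test_channel_mismatch_rejected(self):
        asm = ReferenceMap("a", 50_000, {3: [10_000, 30_000]})
        gm = ConsensusMap("g", 50_000.0, {1: [Peak(10_000.0, 50.0, 10)]}, 10)
        with pytest.raises(ValidationError, match="channel"):
            compare_assembly(asm, gm)

    def test_completeness_excludes_user_intervals(self, rng):
        truth = irregular_ref(rng, length=200_000, n1=35, n2=20)
        gm = as_consensus(truth, mid="gm")
        p = AsmParams(exclusions=((150_000.0, 200_000.0),))
        _, rep, _ = compare_assembly(truth, gm, p)
        assert rep.total_ref_bp == pytest.approx(200_000)
        assert rep.fraction == pytest.approx(1.0)
        assert rep.excluded_intervals[0][:2] == (150_000.0, 200_000.0)


class TestAnchorScaffolds:
    def _genome_with_gap(self, rng):
        truth = irregular_ref(rng, length=400_000, n1=70, n2=45)
        gm = as_consensus(truth, mid="gm")
        gap = (150_000.0, 235_000.0)  # 85-kb gap, as a MISSING call would report
        scaffold = truth.slice(150_000, 235_000, map_id="unplaced")
        return truth, gm, gap, scaffold

    def test_85kb_gap_scaffold_placed_zero_residual(self, rng):
        _, gm, gap, scaffold = self._genome_with_gap(rng)
        placements = anchor_scaffolds([scaffold], gm, [gap])
        placed = [p for p in placements if p.status == "placed"]
        assert len(placed) == 1
        assert placed[0].ref_start_bp == pytest.approx(150_000, abs=500)
        assert placed[0].residual_gap_bp == pytest.approx(0.0, abs=500)

    def test_zero_label_scaffold_unanchorable(self, rng):
        _, gm, gap, _ = self._genome_with_gap(rng)
        empty = ReferenceMap("empty", 20_000, {1: [], 2: []})
        placements = anchor_scaffolds([empty], gm, [gap])
        assert placements[0].status == "unanchorable"

    def test_shuffled_scaffolds_restored(self, rng):
        truth = irregular_ref(rng, length=500_000, n1=90, n2=55)
        gm = as_consensus(truth, mid="gm")
        bounds = [(50_000, 120_000), (140_000, 200_000), (230_000, 300_000),
                  (330_000, 390_000), (410_000, 480_000)]
        scaffolds = [truth.slice(s, e, map_id=f"s{k}") for k, (s, e) in enumerate(bounds)]
        order = [3, 0, 4, 2, 1]  # shuffled presentation
        placements = anchor_scaffolds(
            [scaffolds[k] for k in order], gm, [(float(s), float(e)) for s, e in bounds]
        )
        placed = {p.scaffold_id: p for p in placements if p.status == "placed"}
        assert len(placed) == 5
        for k, (s, e) in enumerate(bounds):
            p = placed[f"s{k}"]
            assert p.ref_start_bp == pytest.approx(s, abs=500)
            assert p.orientation == "forward"


class TestDetectLabelRepeats:
    def _clone_with_arrays(self, arrays, L=120_000, seed=5, coverage=60):
        # deliberately asymmetric so mirror orientation is detectable
        normal = [4_000, 9_000, 17_000, 23_000, 35_000, 96_000, 111_000]
        sites = list(normal)
        for start, n_copies, unit in arrays:
            sites += [start + unit * i for i in range(n_copies)]
        ref = ReferenceMap("c", L, {1: sorted(sites), 2: [20_000, 60_000, 98_000]})
        mols = simulate_molecules(ref, SimulationParams(coverage_per_clone=coverage, seed=seed))
        D, O, _ = pairwise_distance(mols)
        cr = cluster_molecules(D, O, [m.molecule_id for m in mols])
        ori = refine_orientations(mols, cr.orientations)
        oriented = orient_molecules(mols, ori)
        cm = build_consensus(oriented, map_id="c")
        return oriented, cm

    def test_14_copy_array_detected_with_copy_number(self):
        oriented, cm = self._clone_with_arrays([(50_000, 14, 670)])
        det = detect_label_repeats(oriented, cm, unit_length_bp=670)
        assert len(det) == 1
        d = det[0]
        assert d.kind == HIGH_DENSITY_REGION
        assert abs(d.evidence["estimated_copies"] - 14) <= 2
        assert d.size_estimate_bp == pytest.approx(14 * 670, abs=1_500)

    def test_uniform_low_density_no_regions(self):
        oriented, cm = self._clone_with_arrays([])
        assert detect_label_repeats(oriented, cm) == []

    def test_two_arrays_9_8kb_and_8kb(self):
        # arrays separated by >= 20 kb; truth lengths 9.8 kb and 8.0 kb
        arrays = [(45_000, 14, 700), (80_000, 10, 800)]
        oriented, cm = self._clone_with_arrays(arrays, seed=6)
        det = detect_label_repeats(oriented, cm)
        assert len(det) == 2
        lengths = sorted(d.size_estimate_bp for d in det)
        # consensus frame may be mirrored; compare lengths only
        assert lengths[0] == pytest.approx(8_000, abs=1_500)
        assert lengths[1] == pytest.approx(9_800, abs=1_500)

    def test_unoriented_molecules_rejected(self):
        oriented, cm = self._clone_with_arrays([(50_000, 14, 670)])
        mirrored = [m.flipped() for m in oriented]
        with pytest.raises(ValidationError):
            detect_label_repeats(mirrored, cm)
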