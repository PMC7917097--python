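"""Viterbi block inference, parental-phase assignment and founder labeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from founderhap.datamodel import (
    MISSING,
    FounderAssignment,
    MarkerMap,
    Pedigree,
    PhasedGenotypes,
)
from founderhap.trace import (
    TraceConfig,
    assign_parental_phases,
    coverage_stat,
    haplotyping_accuracy,
    trace_founder_haplotypes,
    viterbi_blocks,
)

from helpers import viterbi_bruteforce


class TestViterbi:
    def test_exact_match_gives_zero_penalty_single_state(self):
        p1 = np.array([0, 1, 0, 1, 1], dtype=np.int8)
        p2 = 1 - p1
        path = viterbi_blocks(p1, p1, p2)
        assert path.penalty == 0.0
        assert (path.states == 0).all()
        assert len(path.breakpoints) == 0

    def test_single_crossover_beats_mismatch_run(self):
        # 24 markers, parents differ everywhere, child follows p1 then p2:
        # one crossover (penalty 10) beats staying (penalty 12)
        m = 24
        rng = np.random.default_rng(0)
        p1 = rng.integers(0, 2, m).astype(np.int8)
        p2 = (1 - p1).astype(np.int8)
        h = np.concatenate([p1[:12], p2[12:]])
        path = viterbi_blocks(h, p1, p2)
        assert path.penalty == 10.0
        assert list(path.breakpoints) == [12]
        # the same configuration at oracle-checkable size (16 markers, 8+8)
        h16, q1, q2 = h[4:20], p1[4:20], p2[4:20]
        assert viterbi_blocks(h16, q1, q2).penalty == viterbi_bruteforce(h16, q1, q2)

    def test_short_interior_segment_absorbed_as_mismatches(self):
        # 4 interior markers from the other phase: 4 mismatches (penalty 4)
        # beat a switch-and-return (>= 20)
        m = 20
        rng = np.random.default_rng(1)
        p1 = rng.integers(0, 2, m).astype(np.int8)
        p2 = (1 - p1).astype(np.int8)
        h = p1.copy()
        h[8:12] = p2[8:12]
        path = viterbi_blocks(h, p1, p2)
        assert path.penalty == 4.0
        assert (path.states == 0).all()
        assert viterbi_bruteforce(h[2:18], p1[2:18], p2[2:18]) == 4.0

    def test_empty_chromosome(self):
        path = viterbi_blocks(np.empty(0, np.int8), np.empty(0, np.int8), np.empty(0, np.int8))
        assert path.penalty == 0.0 and len(path.states) == 0

    def test_penalty_equals_recomputed_path_cost(self, rng):
        cfg = TraceConfig(mismatch_penalty=1.0, crossover_penalty=10.0)
        for _ in range(50):
            m = int(rng.integers(1, 30))
            p1 = rng.integers(0, 2, m).astype(np.int8)
            p2 = rng.integers(0, 2, m).astype(np.int8)
            h = rng.integers(0, 2, m).astype(np.int8)
            h[rng.random(m) < 0.1] = MISSING
            path = viterbi_blocks(h, p1, p2, cfg)
            p = np.stack([p1, p2], axis=1)
            emitted = p[np.arange(m), path.states]
            mism = int(((h != MISSING) & (emitted != MISSING) & (h != emitted)).sum())
            assert path.penalty == mism * 1.0 + len(path.breakpoints) * 10.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_minimum(self, data):
        m = data.draw(st.integers(1, 12))
        bits = st.lists(st.integers(-1, 1), min_size=m, max_size=m)
        h = np.array(data.draw(bits), dtype=np.int8)
        p1 = np.array(data.draw(bits), dtype=np.int8)
        p2 = np.array(data.draw(bits), dtype=np.int8)
        mp = data.draw(st.sampled_from([0.5, 1.0, 2.0]))
        cp = data.draw(st.sampled_from([1.0, 3.0, 10.0]))
        cfg = TraceConfig(mismatch_penalty=mp, crossover_penalty=cp)
        assert viterbi_blocks(h, p1, p2, cfg).penalty == pytest.approx(
            viterbi_bruteforce(h, p1, p2, mp, cp)
        )

    def test_raising_crossover_penalty_never_adds_crossovers(self, rng):
        for _ in range(100):
            m = int(rng.integers(5, 60))
            p1 = rng.integers(0, 2, m).astype(np.int8)
            p2 = rng.integers(0, 2, m).astype(np.int8)
            h = rng.integers(0, 2, m).astype(np.int8)
            previous = None
            for cp in (1.0, 5.0, 10.0, 25.0):
                k = len(viterbi_blocks(h, p1, p2, TraceConfig(crossover_penalty=cp)).breakpoints)
                if previous is not None:
                    assert k <= previous
                previous = k


def _phased(individuals, alleles, n_markers=None, chroms=1):
    n_markers = n_markers or alleles.shape[1]
    per = n_markers // chroms
    mm = MarkerMap(
        [f"m{i}" for i in range(n_markers)],
        [str(1 + i // per) for i in range(n_markers)],
        [(i % per) + 1 for i in range(n_markers)],
    )
    return PhasedGenotypes(individuals, mm, alleles)


class TestAssignParentalPhases:
    def test_opposite_homozygous_parents(self):
        m = 20
        alleles = np.zeros((1, m, 2), dtype=np.int8)
        alleles[0, :, 1] = 1
        child = _phased(["kid"], alleles)
        mo = np.zeros(m, dtype=np.int8)
        fa = np.full(m, 2, dtype=np.int8)
        out = assign_parental_phases(child, mo, fa, individual="kid")
        assert out.slot_of["1"] == {"maternal": 0, "paternal": 1}

    def test_identical_parents_tie_unassigned(self, rng):
        m = 30
        alleles = rng.integers(0, 2, (1, m, 2)).astype(np.int8)
        child = _phased(["kid"], alleles)
        par = rng.integers(0, 3, m).astype(np.int8)
        out = assign_parental_phases(child, par, par.copy(), individual="kid")
        assert out.slot_of["1"] == {"maternal": None, "paternal": None}

    def test_too_few_informative_markers_unassigned(self, rng):
        m = 5  # below the default minimum of 10
        alleles = rng.integers(0, 2, (1, m, 2)).astype(np.int8)
        child = _phased(["kid"], alleles)
        out = assign_parental_phases(
            child, np.zeros(m, np.int8), np.full(m, 2, np.int8), individual="kid"
        )
        assert out.slot_of["1"] == {"maternal": None, "paternal": None}

    def test_simulated_trios_agree_with_truth(self, noisy_truth):
        # truth convention: slot 0 maternal, slot 1 paternal
        res = trace_founder_haplotypes(noisy_truth.pedigree, noisy_truth.phased)
        total = correct = 0
        for ind, a in res.phase_assignments.items():
            for chrom, slots in a.slot_of.items():
                total += 1
                correct += slots == {"maternal": 0, "paternal": 1}
        assert total > 0
        assert correct / total >= 0.99


class TestFounderLabels:
    def test_founders_keep_fixed_labels(self, small_truth):
        res = trace_founder_haplotypes(small_truth.pedigree, small_truth.phased)
        for fid in small_truth.pedigree.founder_ids:
            l1, l2 = small_truth.pedigree.founder_labels(fid)
            r = res.assignment.row(fid)
            assert (res.assignment.labels[r, :, 0] == l1).all()
            assert (res.assignment.labels[r, :, 1] == l2).all()

    def test_f1_labels_form_parent_mosaics(self, small_truth):
        res = trace_founder_haplotypes(small_truth.pedigree, small_truth.phased)
        ped = small_truth.pedigree
        for ind in ped.ids:
            if not ind.startswith("G1"):
                continue
            r = res.assignment.row(ind)
            mo_labels = set(ped.founder_labels(ped.mother_of(ind)))
            fa_labels = set(ped.founder_labels(ped.father_of(ind)))
            assert set(np.unique(res.assignment.labels[r, :, 0])) <= mo_labels
            assert set(np.unique(res.assignment.labels[r, :, 1])) <= fa_labels

    def test_label_allele_inconsistencies_are_exactly_path_mismatches(self, small_truth):
        # labeling never edits alleles; a label can imply a different allele
        # only where the chosen minimum-penalty path itself paid an emission
        # mismatch, so the two counts must agree exactly (and stay rare on
        # error-free data)
        res = trace_founder_haplotypes(small_truth.pedigree, small_truth.phased)
        ped = small_truth.pedigree
        mk = small_truth.phased.markers
        alle = small_truth.phased.alleles
        lab = res.assignment.labels
        n_inconsistent = n_mismatch = n_entries = 0
        for (ind, side, chrom), path in res.paths.items():
            sl = mk.chrom_slice(chrom)
            slot = res.phase_assignments[ind].slot_of[chrom][side]
            pr = small_truth.phased.row(ped.mother_of(ind) if side == "maternal" else ped.father_of(ind))
            r = small_truth.phased.row(ind)
            t = np.arange(sl.stop - sl.start)
            parent_allele = alle[pr, sl, :][t, path.states]
            parent_label = lab[pr, sl, :][t, path.states]
            h = alle[r, sl, slot]
            mism = (h != MISSING) & (parent_allele != MISSING) & (h != parent_allele)
            n_mismatch += int(mism.sum())
            child_label = lab[r, sl, slot]
            founder_labeled = child_label <= 14
            implied = parent_allele
            n_inconsistent += int(((h != implied) & founder_labeled).sum())
            n_entries += len(t)
        assert n_inconsistent == n_mismatch
        # paths still explain the vast majority of alleles on error-free data
        assert n_mismatch / n_entries < 0.1

    def test_blocks_table_is_consistent(self, small_truth):
        res = trace_founder_haplotypes(small_truth.pedigree, small_truth.phased)
        blocks = res.blocks_table()
        assert (blocks["end_marker"] > blocks["start_marker"]).all()
        assert set(blocks["parent_phase_state"].unique()) <= {1, 2}


class TestCoverage:
    def test_founder_only_subset_is_one(self, small_truth):
        res = trace_founder_haplotypes(small_truth.pedigree, small_truth.phased)
        assert coverage_stat(res.assignment, small_truth.pedigree.founder_ids) == 1.0

    def test_all_raw_codes_is_zero(self):
        mm = MarkerMap(["m1", "m2"], ["1", "1"], [1, 2])
        labels = np.full((2, 2, 2), 15, dtype=np.int16)
        fa = FounderAssignment(["a", "b"], mm, labels, 7)
        assert coverage_stat(fa, ["a", "b"]) == 0.0

    def test_empty_subset_rejected(self, small_truth):
        res = trace_founder_haplotypes(small_truth.pedigree, small_truth.phased)
        with pytest.raises(ValueError, match="empty"):
            coverage_stat(res.assignment, [])


class TestHaplotypingAccuracy:
    def test_identity_is_one(self, small_truth):
        fa = small_truth.assignment
        assert haplotyping_accuracy(fa, fa) == 1.0

    def test_slot_swap_is_one(self, small_truth):
        fa = small_truth.assignment
        swapped = FounderAssignment(
            list(fa.individuals), fa.markers, fa.labels[:, :, ::-1].copy(), fa.n_founders
        )
        assert haplotyping_accuracy(swapped, fa) == 1.0

    def test_random_labels_score_near_one_in_fourteen(self, rng):
        n, m = 250, 200  # 100,000 entries
        mm = MarkerMap([f"m{i}" for i in range(m)], ["1"] * m, range(1, m + 1))
        inds = [f"I{i}" for i in range(n)]
        ref = FounderAssignment(
            inds, mm, rng.integers(1, 15, (n, m, 2)).astype(np.int16), 7
        )
        est = FounderAssignment(
            inds, mm, rng.integers(1, 15, (n, m, 2)).astype(np.int16), 7
        )
        acc = haplotyping_accuracy(est, ref)
        # 1/14 plus the small upward bias of the alignment maximization
        assert acc == pytest.approx(1 / 14, abs=0.012)

    def test_shape_mismatch_rejected(self, small_truth):
        fa = small_truth.assignment
        mm = MarkerMap(["m1"], ["1"], [1])
        other = FounderAssignment(["x"], mm, np.ones((1, 1, 2), dtype=np.int16), 7)
        with pytest.raises(ValueError, match="shape"):
            haplotyping_accuracy(fa, other)
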