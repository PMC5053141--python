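"""Sequence alignment, superposition and homologue ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from lorefine.homology import (AlignmentError, GeometryError,
                               HomologueAssessment, align_sequences,
                               assess_homologue, filter_homologues,
                               flexible_score, rank_homologues, superpose)
from lorefine.synthetic import (make_hinge_bent, make_homologue,
                                make_ideal_helix, make_random_walk_chain)
from oracles import grid_search_rmsd


class TestAlignSequences:
    def test_identical_sequences(self):
        a = align_sequences("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY")
        assert a.identity == pytest.approx(100.0)
        assert a.coverage == pytest.approx(100.0)
        assert len(a.pairs) == 20

    def test_five_substitutions_give_75_percent_identity(self):
        target = "ACDEFGHIKLMNPQRSTVWY"
        ref = "ACDEFWWWWWMNPQRSTVWY"  # 5 substitutions
        a = align_sequences(target, ref)
        assert a.identity == pytest.approx(75.0)
        assert a.coverage == pytest.approx(100.0)

    def test_half_length_reference_gives_50_percent_coverage(self):
        target = "ACDEFGHIKLMNPQRSTVWY"
        a = align_sequences(target, target[:10])
        assert a.coverage == pytest.approx(50.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_sequences("", "ACDE")

    def test_pairs_strictly_increasing(self):
        a = align_sequences("ACDEFGHIKL", "ACDFGHIKL")
        diffs = np.diff(np.array(a.pairs), axis=0)
        assert (diffs > 0).all()


class TestSuperpose:
    def test_identical_sets_have_zero_rmsd(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        sup = superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, 0.0, 0.0])
        sup = superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.apply(moved), pts, atol=1e-9)

    def test_single_displaced_point_matches_grid_oracle(self):
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0]])
        moved = pts.copy()
        moved[3] += [0.0, 0.0, 0.4]
        sup = superpose(pts, moved)
        assert sup.rmsd == pytest.approx(grid_search_rmsd(pts, moved),
                                         abs=1e-3)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_random_sets_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        a = rng.normal(scale=3.0, size=(n, 3))
        b = a + rng.normal(scale=0.5, size=(n, 3))
        assert superpose(a, b).rmsd == pytest.approx(
            grid_search_rmsd(a, b), abs=1e-3)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(GeometryError):
            superpose(line, line)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rmsd_invariant_under_random_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=2.0, size=(7, 3))
        b = rng.normal(scale=2.0, size=(7, 3))
        base = superpose(a, b).rmsd
        rot = Rotation.random(random_state=np.random.RandomState(seed))
        moved = b @ rot.as_matrix().T + rng.normal(scale=10.0, size=3)
        assert superpose(a, moved).rmsd == pytest.approx(base, abs=1e-6)


class TestFlexibleScore:
    def test_identical_chains_score_zero(self, helix24):
        chain = helix24.chains[0]
        assert flexible_score(chain, chain) == pytest.approx(0.0, abs=1e-9)

    def test_hinge_bend_keeps_local_score_low(self, helix24):
        bent = make_hinge_bent(helix24, 12, 30)
        a = assess_homologue(helix24.chains[0], bent.chains[0])
        assert a.global_rmsd > 1.0
        assert a.flexible_score < a.global_rmsd / 2

    def test_hinge_windows_match_independent_per_window_fit(self, helix24):
        # implementation (SVD Kabsch) vs scipy align_vectors per window
        bent = make_hinge_bent(helix24, 12, 30)
        t_res = helix24.chains[0].polymer_residues
        r_res = bent.chains[0].polymer_residues
        names = ("N", "CA", "C", "O")
        scores = []
        for start in range(len(t_res) - 9 + 1):
            ta = np.array([t_res[i].atom(n).xyz
                           for i in range(start, start + 9) for n in names])
            ra = np.array([r_res[i].atom(n).xyz
                           for i in range(start, start + 9) for n in names])
            a0, b0 = ta - ta.mean(0), ra - ra.mean(0)
            _, rssd = Rotation.align_vectors(a0, b0)
            scores.append(rssd / np.sqrt(len(a0)))
        expected = float(np.mean(scores))
        assert flexible_score(helix24.chains[0], bent.chains[0]) == \
            pytest.approx(expected, abs=1e-6)

    def test_short_alignment_falls_back_to_single_fragment(self):
        target = make_ideal_helix(6)
        ref = make_homologue(target, 100, 0.2, seed=9)
        names = ("N", "CA", "C", "O")
        ta = np.array([r.atom(n).xyz
                       for r in target.chains[0].residues for n in names])
        ra = np.array([r.atom(n).xyz
                       for r in ref.chains[0].residues for n in names])
        expected = superpose(ta, ra).rmsd
        assert flexible_score(target.chains[0], ref.chains[0]) == \
            pytest.approx(expected, abs=1e-9)


class TestAssessAndRank:
    def test_self_assessment_is_perfect(self, helix12):
        a = assess_homologue(helix12.chains[0], helix12.chains[0])
        assert a.identity == pytest.approx(100.0)
        assert a.global_rmsd == pytest.approx(0.0, abs=1e-9)
        assert a.flexible_score == pytest.approx(0.0, abs=1e-9)
        assert a.rank_score == pytest.approx(0.0, abs=1e-9)

    def test_perturbed_copy_rmsd_matches_independent_fit(self, helix24):
        hom = make_homologue(helix24, 100, 0.3, seed=11)
        a = assess_homologue(helix24.chains[0], hom.chains[0])
        assert 0.2 <= a.global_rmsd <= 0.5
        ca_t = np.array([r.atom("CA").xyz
                         for r in helix24.chains[0].residues])
        ca_r = np.array([r.atom("CA").xyz for r in hom.chains[0].residues])
        a0, b0 = ca_t - ca_t.mean(0), ca_r - ca_r.mean(0)
        _, rssd = Rotation.align_vectors(a0, b0)
        assert a.global_rmsd == pytest.approx(rssd / np.sqrt(len(a0)),
                                              abs=1e-9)

    def test_unrelated_chain_assessed_with_low_identity(self, helix24):
        decoy = make_random_walk_chain(24, seed=5)
        a = assess_homologue(helix24.chains[0], decoy.chains[0])
        assert a.identity < 30.0

    def test_filter_boundary_values_retained(self):
        def mk(identity, coverage=100.0):
            return HomologueAssessment("h", "A", identity, coverage, 1.0, 0.5)

        kept = filter_homologues([mk(70), mk(74.9), mk(75), mk(80)])
        assert [a.identity for a in kept] == [75, 80]
        assert filter_homologues([mk(90, coverage=60)]) == []
        assert filter_homologues([]) == []

    def test_rank_by_sum_of_scores(self):
        a = HomologueAssessment("a", "A", 90, 100, 0.5, 0.2)  # sum 0.7
        b = HomologueAssessment("b", "A", 90, 100, 0.4, 0.4)  # sum 0.8
        assert [x.structure_id for x in rank_homologues([b, a])] == ["a", "b"]
        assert rank_homologues([a]) == [a]

    def test_rank_tie_broken_by_identity_then_order(self):
        a = HomologueAssessment("a", "A", 90, 100, 0.5, 0.2)
        b = HomologueAssessment("b", "A", 95, 100, 0.3, 0.4)
        assert [x.structure_id for x in rank_homologues([a, b])] == ["b", "a"]

    def test_most_different_order_reverses_on_global_rmsd(self):
        a = HomologueAssessment("a", "A", 90, 100, 0.2, 0.0)
        b = HomologueAssessment("b", "A", 90, 100, 1.5, 0.0)
        assert [x.structure_id
                for x in rank_homologues([a, b], most_different=True)] == \
            ["b", "a"]

    @given(st.permutations(range(4)))
    @settings(max_examples=20, deadline=None)
    def test_ranking_is_permutation_invariant(self, order):
        pool = [HomologueAssessment(f"h{i}", "A", 80 + i, 100,
                                    0.3 * (i + 1), 0.1) for i in range(4)]
        shuffled = [pool[i] for i in order]
        assert [a.structure_id for a in rank_homologues(shuffled)] == \
            [a.structure_id for a in rank_homologues(pool)]
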