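"""Homologue assessment and ranking for reference-structure selection.

A candidate reference chain is compared with the target chain in three
steps: global sequence alignment (identity and coverage), whole-chain
rigid superposition of matched CA atoms (global r.m.s.d.) and a
fragment-based flexible score — the mean backbone r.m.s.d. over sliding
nine-residue windows, which stays small under domain motion because
each window is superposed independently.  Homologues are ranked by the
sum of global r.m.s.d. and flexible score; the reverse order (largest
global r.m.s.d. first) selects the "most different" homologues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model_io import Chain

__all__ = [
    "SeqAlignment",
    "Superposition",
    "HomologueAssessment",
    "AlignmentError",
    "GeometryError",
    "align_sequences",
    "superpose",
    "flexible_score",
    "residue_pairing",
    "atom_pairing",
    "assess_homologue",
    "filter_homologues",
    "rank_homologues",
    "FRAGMENT_LENGTH",
    "MIN_FRAGMENT_FALLBACK",
]

FRAGMENT_LENGTH = 9
MIN_FRAGMENT_FALLBACK = 5

BACKBONE = ("N", "CA", "C", "O")


class AlignmentError(ValueError):
    """Sequences or chains cannot be aligned/assessed."""


class GeometryError(ValueError):
    """Superposition input is degenerate."""


@dataclass(frozen=True)
class SeqAlignment:
    """Residue-index pairing between target and reference sequences.

    ``pairs`` holds (target_index, reference_index) tuples, strictly
    increasing in both coordinates.  ``identity`` is the percentage of
    aligned positions with identical residues; ``coverage`` the
    percentage of target residues that are aligned.
    """

    pairs: tuple[tuple[int, int], ...]
    identity: float
    coverage: float

    def __post_init__(self):
        for (t0, r0), (t1, r1) in zip(self.pairs, self.pairs[1:]):
            if not (t1 > t0 and r1 > r0):
                raise ValueError("aligned pairs must be strictly increasing")


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid-body fit: x_fitted = rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class HomologueAssessment:
    """Per reference chain: similarity metrics and the combined rank score."""

    structure_id: str
    chain_id: str
    identity: float
    coverage: float
    global_rmsd: float
    flexible_score: float
    alignment: SeqAlignment | None = field(default=None, compare=False,
                                           repr=False)

    @property
    def rank_score(self) -> float:
        """Sum of global r.m.s.d. and flexible score (Å); lower is better."""
        return self.global_rmsd + self.flexible_score


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -10.0
_aligner.extend_gap_score = -0.5


def align_sequences(target_seq: str, ref_seq: str) -> SeqAlignment:
    """Global alignment (BLOSUM62, affine gaps 10/0.5) of two sequences."""
    if not target_seq or not ref_seq:
        raise AlignmentError("cannot align an empty sequence")
    aln = _aligner.align(target_seq, ref_seq)[0]
    pairs: list[tuple[int, int]] = []
    identical = 0
    for (t0, t1), (r0, r1) in zip(*aln.aligned):
        for dt in range(t1 - t0):
            ti, ri = t0 + dt, r0 + dt
            pairs.append((ti, ri))
            if target_seq[ti] == ref_seq[ri]:
                identical += 1
    n_aligned = len(pairs)
    identity = 100.0 * identical / n_aligned if n_aligned else 0.0
    coverage = 100.0 * n_aligned / len(target_seq)
    return SeqAlignment(tuple(pairs), identity, coverage)


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of b onto a (Kabsch, SVD).

    Proper rotation is enforced (determinant +1); the returned r.m.s.d.
    is the minimized value over the matched points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError("inputs must be matched (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 matched points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # degenerate (collinear) sets leave the rotation underdetermined
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a0) ** 2, axis=1))))
    trans = ca - rot @ cb
    return Superposition(rot, trans, rmsd)


def residue_pairing(target_chain: Chain, ref_chain: Chain,
                    alignment: SeqAlignment | None = None):
    """(target Residue, reference Residue) pairs from a sequence alignment."""
    if alignment is None:
        alignment = align_sequences(target_chain.sequence, ref_chain.sequence)
    tres = target_chain.polymer_residues
    rres = ref_chain.polymer_residues
    return [(tres[ti], rres[ri]) for ti, ri in alignment.pairs]


def atom_pairing(target_chain: Chain, ref_chain: Chain,
                 alignment: SeqAlignment | None = None):
    """Matched (target Atom, reference Atom) pairs by name within aligned
    residues; hydrogens excluded."""
    pairs = []
    for tr, rr in residue_pairing(target_chain, ref_chain, alignment):
        for ta in tr.atoms:
            if ta.is_hydrogen:
                continue
            ra = rr.atom(ta.name)
            if ra is not None and not ra.is_hydrogen:
                pairs.append((ta, ra))
    return pairs


def _contiguous_runs(pairs):
    """Split aligned residue-index pairs into runs consecutive in both."""
    runs, current = [], []
    for p in pairs:
        if current and not (p[0] == current[-1][0] + 1
                            and p[1] == current[-1][1] + 1):
            runs.append(current)
            current = []
        current.append(p)
    if current:
        runs.append(current)
    return runs


def flexible_score(target_chain: Chain, ref_chain: Chain,
                   pairing: SeqAlignment | None = None,
                   fragment_length: int = FRAGMENT_LENGTH) -> float:
    """Mean backbone r.m.s.d. over sliding windows of aligned residues.

    Windows (stride 1) must be contiguous in both chains and contain all
    four backbone atoms in every residue.  If fewer than
    ``fragment_length`` residues are contiguously aligned, the longest
    run is scored as a single fragment provided it spans at least
    5 residues; otherwise the score is undefined.
    """
    if pairing is None:
        pairing = align_sequences(target_chain.sequence, ref_chain.sequence)
    tres = target_chain.polymer_residues
    rres = ref_chain.polymer_residues

    def window_coords(run, start, length):
        ta, ra = [], []
        for ti, ri in run[start:start + length]:
            for name in BACKBONE:
                t_atom, r_atom = tres[ti].atom(name), rres[ri].atom(name)
                if t_atom is None or r_atom is None:
                    return None
                ta.append(t_atom.xyz)
                ra.append(r_atom.xyz)
        return np.array(ta), np.array(ra)

    runs = _contiguous_runs(pairing.pairs)
    scores = []
    for run in runs:
        for start in range(len(run) - fragment_length + 1):
            coords = window_coords(run, start, fragment_length)
            if coords is not None:
                scores.append(superpose(coords[0], coords[1]).rmsd)
    if scores:
        return float(np.mean(scores))
    longest = max(runs, key=len) if runs else []
    if len(longest) >= MIN_FRAGMENT_FALLBACK:
        coords = window_coords(longest, 0, len(longest))
        if coords is not None:
            return superpose(coords[0], coords[1]).rmsd
    raise AlignmentError(
        f"fewer than {MIN_FRAGMENT_FALLBACK} contiguously aligned residues; "
        "flexible score undefined")


def assess_homologue(target_chain: Chain, ref_chain: Chain,
                     structure_id: str = "") -> HomologueAssessment:
    """Full assessment: alignment, CA-based global r.m.s.d., flexible score."""
    alignment = align_sequences(target_chain.sequence, ref_chain.sequence)
    if not alignment.pairs:
        raise AlignmentError("no aligned residues between chains")
    tres = target_chain.polymer_residues
    rres = ref_chain.polymer_residues
    ta, ra = [], []
    for ti, ri in alignment.pairs:
        t_atom, r_atom = tres[ti].atom("CA"), rres[ri].atom("CA")
        if t_atom is not None and r_atom is not None:
            ta.append(t_atom.xyz)
            ra.append(r_atom.xyz)
    if len(ta) < 3:
        raise AlignmentError("fewer than 3 matched CA atoms")
    sup = superpose(np.array(ta), np.array(ra))
    flex = flexible_score(target_chain, ref_chain, alignment)
    return HomologueAssessment(
        structure_id=structure_id,
        chain_id=ref_chain.id,
        identity=alignment.identity,
        coverage=alignment.coverage,
        global_rmsd=sup.rmsd,
        flexible_score=flex,
        alignment=alignment,
    )


def filter_homologues(assessments, min_identity: float = 75.0,
                      min_coverage: float = 75.0):
    """Keep homologues with identity and coverage at or above the cutoffs.

    Chains below 75 % sequence identity or covering less than 75 % of
    the target chain are rejected; boundary values are retained.
    """
    return [a for a in assessments
            if a.identity >= min_identity and a.coverage >= min_coverage]


def rank_homologues(assessments, most_different: bool = False):
    """Order homologues best-first by rank score (global + flexible r.m.s.d.).

    Ties break toward higher sequence identity, then input order.  With
    ``most_different=True`` the order is by descending global r.m.s.d.,
    selecting the homologues conformationally farthest from the target.
    """
    indexed = list(enumerate(assessments))
    if most_different:
        key = lambda ia: (-ia[1].global_rmsd, -ia[1].identity, ia[0])
    else:
        key = lambda ia: (ia[1].rank_score, -ia[1].identity, ia[0])
    return [a for _, a in sorted(indexed, key=key)]
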