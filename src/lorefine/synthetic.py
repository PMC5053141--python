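"""Synthetic polypeptide generators used as fixtures and benchmarks.

Backbones are built from ideal internal coordinates (bond lengths,
angles, torsions) with the NeRF chain-extension construction, so an
"ideal helix" here really has helical hydrogen-bond geometry and an
extended strand has none.  Side chains stop at CB: every computation in
the package uses backbone + CB only, which keeps fixtures small.

Mutations change residue names only and never move coordinates, so
sequence identity and conformational distance vary independently.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import Atom, Chain, Residue, Structure, STANDARD_AA

__all__ = [
    "make_ideal_helix",
    "make_ideal_strand",
    "make_chain_from_torsions",
    "make_antiparallel_pair",
    "make_homologue",
    "make_hinge_bent",
    "make_random_walk_chain",
    "BenchmarkCase",
    "make_benchmark_case",
]

# Engh & Huber-style ideal backbone internal coordinates (Å, degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_C_CA_CB = 120.8, 111.1
_T_CB_IMPROPER = 122.6  # N-C-CA-CB improper torsion

HELIX_PHI_PSI = (-57.8, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c given internal coordinates (NeRF)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_chain_from_torsions(n: int, phi: float, psi: float,
                             chain_id: str = "A",
                             structure_id: str = "synthetic") -> Structure:
    """Poly-Ala chain of ``n`` residues with uniform (phi, psi), omega 180.

    Atoms per residue: N, CA, C, O, CB.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [N[0] + np.array([_B_N_CA, 0.0, 0.0])]
    # first C at the ideal N-CA-C angle in the xy-plane
    ang = math.radians(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        Ni = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CAi = _nerf(CA[i - 1], C[i - 1], Ni, _B_N_CA, _A_C_N_CA, 180.0)
        Ci = _nerf(C[i - 1], Ni, CAi, _B_CA_C, _A_N_CA_C, phi)
        N.append(Ni)
        CA.append(CAi)
        C.append(Ci)
    residues = []
    for i in range(n):
        # carbonyl O sits opposite the next amide N: dihedral N-CA-C-O = psi+180
        O = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        CB = _nerf(N[i], C[i], CA[i], _B_CA_CB, _A_C_CA_CB, _T_CB_IMPROPER)
        coords = {"N": N[i], "CA": CA[i], "C": C[i], "O": O, "CB": CB}
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
        atoms = [Atom(name, elements[name], tuple(map(float, xyz)),
                      "ALA", i + 1, "", chain_id)
                 for name, xyz in coords.items()]
        residues.append(Residue("ALA", i + 1, "", chain_id, atoms))
    return Structure(structure_id, [Chain(chain_id, residues)])


def make_ideal_helix(n: int, chain_id: str = "A",
                     structure_id: str = "helix") -> Structure:
    """Ideal poly-Ala α-helix (rise ≈ 1.5 Å, ≈ 100°/residue)."""
    return make_chain_from_torsions(n, *HELIX_PHI_PSI, chain_id=chain_id,
                                    structure_id=structure_id)


def make_ideal_strand(n: int, chain_id: str = "A",
                      structure_id: str = "strand") -> Structure:
    """Extended β-strand-like poly-Ala chain (no internal hydrogen bonds)."""
    return make_chain_from_torsions(n, *STRAND_PHI_PSI, chain_id=chain_id,
                                    structure_id=structure_id)


def make_antiparallel_pair(n: int, structure_id: str = "sheet") -> Structure:
    """Two strands placed at sheet-like inter-strand hydrogen-bond geometry.

    The second chain is a 180°-flipped copy translated so that a
    carbonyl oxygen of the first strand sits 2.9 Å from one of its amide
    nitrogens, along that nitrogen's inferred N-H direction — an ideal
    inter-strand hydrogen bond.
    """
    if n < 4:
        raise ValueError("need at least 4 residues per strand")
    a = make_ideal_strand(n, chain_id="A", structure_id=structure_id)
    chain_a = a.chains[0]
    flipped = _transform_structure(
        make_ideal_strand(n, chain_id="B", structure_id="tmp"),
        Rotation.from_euler("x", 180, degrees=True).as_matrix(),
        np.zeros(3))
    mid = n // 2
    o_pos = chain_a.residues[mid].atom("O").xyz
    chain_b = flipped.chains[0]
    res_b, prev_b = chain_b.residues[mid], chain_b.residues[mid - 1]
    n_pos, ca_pos = res_b.atom("N").xyz, res_b.atom("CA").xyz
    c_prev = prev_b.atom("C").xyz
    u1 = n_pos - c_prev
    u2 = n_pos - ca_pos
    h_dir = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
    h_dir /= np.linalg.norm(h_dir)
    shift = o_pos - (n_pos + 2.9 * h_dir)
    shifted = _transform_structure(flipped, np.eye(3), shift)
    return Structure(structure_id, [chain_a, shifted.chains[0]])


def _transform_structure(structure: Structure, rot: np.ndarray,
                         trans: np.ndarray,
                         center: np.ndarray | None = None) -> Structure:
    center = np.zeros(3) if center is None else center
    atoms = structure.atoms(include_hydrogens=True)
    coords = np.array([a.xyz for a in atoms])
    coords = (coords - center) @ rot.T + center + trans
    return structure.copy_with_coords(coords, atoms)


def make_random_walk_chain(n: int, seed: int = 0, chain_id: str = "A",
                           structure_id: str = "randomwalk") -> Structure:
    """Chain with random torsions and random sequence — an unrelated decoy."""
    rng = np.random.default_rng(seed)
    phi = float(rng.uniform(-180, 180))
    psi = float(rng.uniform(-180, 180))
    st = make_chain_from_torsions(n, phi, psi, chain_id=chain_id,
                                  structure_id=structure_id)
    names = [code for code in STANDARD_AA if code not in ("ALA", "GLY")]
    for res in st.chains[0].residues:
        new_name = names[int(rng.integers(len(names)))]
        res.name = new_name
        res.atoms = [replace(a, residue_name=new_name) for a in res.atoms]
    return st


def make_homologue(structure: Structure, identity: float, noise: float,
                   seed: int, structure_id: str | None = None) -> Structure:
    """Point-mutated, coordinate-perturbed copy at a requested identity.

    Mutates ``ceil((1 - identity/100) * n)`` residues (names only; never
    to Gly, so the CB atom set stays consistent) and adds i.i.d.
    Gaussian noise of standard deviation ``noise`` Å to every coordinate.
    """
    if not 0 < identity <= 100:
        raise ValueError("identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    atoms = structure.atoms(include_hydrogens=True)
    coords = np.array([a.xyz for a in atoms])
    if noise > 0:
        coords = coords + rng.normal(0.0, noise, size=coords.shape)
    out = structure.copy_with_coords(coords, atoms)
    out.id = structure_id or f"{structure.id}_hom"
    candidates = [code for code in STANDARD_AA if code != "GLY"]
    for chain in out.polymer_chains:
        poly = chain.polymer_residues
        n_mut = math.ceil((1.0 - identity / 100.0) * len(poly))
        idx = rng.choice(len(poly), size=n_mut, replace=False)
        for i in idx:
            res = poly[int(i)]
            options = [c for c in candidates if c != res.name]
            new_name = options[int(rng.integers(len(options)))]
            res.name = new_name
            res.atoms = [replace(a, residue_name=new_name) for a in res.atoms]
    return out


def make_hinge_bent(structure: Structure, hinge_residue: int,
                    angle: float, structure_id: str | None = None) -> Structure:
    """Rotate the C-terminal half rigidly about an axis through the hinge CA.

    The axis is perpendicular to the chain's principal direction, so a
    bend of tens of degrees produces a large global displacement while
    every 9-residue window away from the hinge stays internally rigid.
    """
    chain = structure.polymer_chains[0]
    poly = chain.polymer_residues
    positions = {r.seq: k for k, r in enumerate(poly)}
    if hinge_residue not in positions:
        raise ValueError(f"no residue numbered {hinge_residue}")
    k = positions[hinge_residue]
    if k == 0 or k == len(poly) - 1:
        raise ValueError("hinge must be strictly interior")
    ca = np.array([r.atom("CA").xyz for r in poly])
    center = ca[k]
    # axis from the stationary N-terminal half, so successive bends at
    # the same hinge share the axis and compose exactly
    fixed = ca[:k + 1]
    _, _, vt = np.linalg.svd(fixed - fixed.mean(axis=0))
    principal = vt[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, principal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    axis = np.cross(principal, ref)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    moving = {r.key for r in poly[k + 1:]}
    atoms = structure.atoms(include_hydrogens=True)
    coords = np.array([a.xyz for a in atoms])
    for j, a in enumerate(atoms):
        if (a.chain_id, a.residue_seq, a.icode) in moving:
            coords[j] = (coords[j] - center) @ rot.T + center
    out = structure.copy_with_coords(coords, atoms)
    out.id = structure_id or f"{structure.id}_bent"
    return out


@dataclass
class BenchmarkCase:
    """A desk-scale refinement case with known ground truth.

    ``target`` is a heavily perturbed copy of ``truth`` (the
    "low-resolution model"); homologues span sequence identities
    75–95 % plus one below-threshold decoy, with conformational
    distance from the truth increasing as identity drops.
    ``best_homologue`` names the homologue nearest the ground truth.
    """

    truth: Structure
    target: Structure
    homologues: dict[str, Structure]
    best_homologue: str
    rejected_homologues: tuple[str, ...]
    seed: int


#: (identity %, conformational noise σ Å) per generated homologue, best first.
BENCHMARK_HOMOLOGUE_SPECS = (
    ("hom_a", 95.0, 0.05),
    ("hom_b", 90.0, 0.15),
    ("hom_c", 85.0, 0.30),
    ("hom_d", 78.0, 0.50),
    ("hom_e", 70.0, 0.80),
)


def make_benchmark_case(seed: int, n_residues: int = 30,
                        target_noise: float = 0.5) -> BenchmarkCase:
    """Generate a ground truth, a noisy target and a graded homologue set."""
    rng = np.random.default_rng(seed)
    truth = make_ideal_helix(n_residues, structure_id="truth")
    target = make_homologue(truth, 100.0, target_noise,
                            seed=int(rng.integers(2 ** 31)),
                            structure_id="target")
    homologues = {}
    for name, identity, sigma in BENCHMARK_HOMOLOGUE_SPECS:
        homologues[name] = make_homologue(
            truth, identity, sigma, seed=int(rng.integers(2 ** 31)),
            structure_id=name)
    return BenchmarkCase(
        truth=truth,
        target=target,
        homologues=homologues,
        best_homologue="hom_a",
        rejected_homologues=("hom_e",),
        seed=seed,
    )
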