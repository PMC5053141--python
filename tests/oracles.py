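"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: superposition is
done by rotation-grid search (refined locally), restraint enumeration by
plain O(n^2) loops with a from-scratch bond graph, and hydrogen bonds by
an all-pairs scan.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_search_rmsd(coords_a, coords_b, coarse_step=12.0, fine_step=1.0):
    """Best-fit rmsd via hierarchical rotation-grid search.

    Optimal translation is centroid matching for any rotation, so only
    rotations are searched: a coarse Euler grid, a 1°-step local grid
    around the coarse optimum, then a local numerical refinement.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def rmsd_for(rotations):
        rotated = np.einsum("rij,nj->rni", rotations, b0)
        return np.sqrt(((rotated - a0) ** 2).sum(axis=(1, 2)) / len(a0))

    def grid(center, half_width, step):
        axis = np.arange(-half_width, half_width + step / 2, step)
        ez, ey, ex = np.meshgrid(axis, axis, axis, indexing="ij")
        angles = np.stack([ez.ravel(), ey.ravel(), ex.ravel()], axis=1)
        return center + angles

    coarse = grid(np.zeros(3), 180.0, coarse_step)
    vals = rmsd_for(Rotation.from_euler("zyx", coarse,
                                        degrees=True).as_matrix())
    best = coarse[np.argmin(vals)]
    fine = grid(best, coarse_step, fine_step)
    vals = rmsd_for(Rotation.from_euler("zyx", fine, degrees=True).as_matrix())
    best = fine[np.argmin(vals)]

    def objective(angles):
        rot = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return float(np.sqrt(((b0 @ rot.T - a0) ** 2).sum() / len(a0)))

    res = minimize(objective, best, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12})
    return min(float(res.fun), float(vals.min()))


def oracle_bond_paths(structure, max_path):
    """Atom pairs within ``max_path`` covalent bonds, from a from-scratch
    bond list (distance rule within residues + peptide C-N links)."""
    atoms = structure.atoms()
    index = {a.key: i for i, a in enumerate(atoms)}
    edges = set()
    for chain in structure.chains:
        for res in chain.residues:
            heavy = [a for a in res.atoms if not a.is_hydrogen]
            for i, a in enumerate(heavy):
                for b in heavy[i + 1:]:
                    limit = 2.1 if "S" in (a.element, b.element) else 1.85
                    if np.linalg.norm(a.xyz - b.xyz) <= limit:
                        edges.add((index[a.key], index[b.key]))
        poly = chain.polymer_residues
        for r1, r2 in zip(poly, poly[1:]):
            c, n = r1.atom("C"), r2.atom("N")
            if c is not None and n is not None and \
                    np.linalg.norm(c.xyz - n.xyz) <= 1.8:
                edges.add((index[c.key], index[n.key]))
    adj = {i: set() for i in range(len(atoms))}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    close = set()
    for start in range(len(atoms)):
        seen, frontier = {start}, {start}
        for _ in range(max_path):
            frontier = {n for f in frontier for n in adj[f]} - seen
            seen |= frontier
        for other in seen - {start}:
            close.add(frozenset((atoms[start].key, atoms[other].key)))
    return close


def oracle_homologue_pairs(target, ref, pairing, cutoff=4.2, min_path=4):
    """Expected homologue restraints: {frozenset(target keys): distance}."""
    close = oracle_bond_paths(target, min_path - 1)
    expected = {}
    for i in range(len(pairing)):
        for j in range(i + 1, len(pairing)):
            ta, ra = pairing[i]
            tb, rb = pairing[j]
            if ta.key == tb.key:
                continue
            d = float(np.linalg.norm(ra.xyz - rb.xyz))
            pair = frozenset((ta.key, tb.key))
            if d <= cutoff and pair not in close:
                expected[pair] = d
    return expected


def oracle_jelly_pairs(structure, cutoff=4.2, min_path=4):
    """Expected jelly self-restraints: {frozenset(keys): current distance}."""
    close = oracle_bond_paths(structure, min_path - 1)
    atoms = structure.atoms()
    expected = {}
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = float(np.linalg.norm(atoms[i].xyz - atoms[j].xyz))
            pair = frozenset((atoms[i].key, atoms[j].key))
            if d <= cutoff and pair not in close:
                expected[pair] = d
    return expected


def oracle_hbonds(structure, dist_max=3.5, min_sep=2, min_angle=90.0,
                  min_nho=120.0):
    """All-pairs backbone hydrogen-bond scan (same criteria, independent
    implementation; one bond per donor, closest acceptor wins)."""
    residues = []
    for chain in structure.polymer_chains:
        poly = chain.polymer_residues
        for pos, res in enumerate(poly):
            prev = poly[pos - 1] if pos > 0 else None
            residues.append((chain.id, pos, res, prev))
    bonds = set()
    for cn, pn, rn, prev in residues:
        n, ca = rn.atom("N"), rn.atom("CA")
        if n is None:
            continue
        h = None
        if ca is not None and prev is not None and \
                prev.atom("C") is not None:
            u1 = n.xyz - prev.atom("C").xyz
            u2 = n.xyz - ca.xyz
            hd = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            h = n.xyz + hd / np.linalg.norm(hd)
        best = None
        for co, po, ro, _ in residues:
            o, c = ro.atom("O"), ro.atom("C")
            if o is None or c is None:
                continue
            if cn == co and abs(pn - po) < min_sep:
                continue
            d = float(np.linalg.norm(n.xyz - o.xyz))
            if d > dist_max:
                continue

            def ang(v1, v2):
                cosv = np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
                return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))

            if ang(c.xyz - o.xyz, n.xyz - o.xyz) < min_angle:
                continue
            if h is not None and ang(n.xyz - h, o.xyz - h) < min_nho:
                continue
            if best is None or d < best[0]:
                best = (d, o)
        if best is not None:
            bonds.add((n.key, best[1].key))
    return bonds


def oracle_protocol_count(n_homologues, k_max=3):
    """Subset-dedup enumeration count: distinct top/distant/all subsets
    plus the two homologue-free protocols."""
    ids = list(range(n_homologues))
    subsets = set()
    for k in range(1, min(k_max, n_homologues) + 1):
        subsets.add(frozenset(ids[:k]))            # top-k
        subsets.add(frozenset(ids[::-1][:k]))      # most-different-k
    if ids:
        subsets.add(frozenset(ids))
    return len(subsets) + 2


def ca_rmsd(structure_a, structure_b):
    """Superposed CA rmsd via an independent route (scipy align_vectors)."""
    ca_a = np.array([r.atom("CA").xyz
                     for c in structure_a.polymer_chains
                     for r in c.polymer_residues])
    ca_b = np.array([r.atom("CA").xyz
                     for c in structure_b.polymer_chains
                     for r in c.polymer_residues])
    a0 = ca_a - ca_a.mean(axis=0)
    b0 = ca_b - ca_b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd / np.sqrt(len(a0)))
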