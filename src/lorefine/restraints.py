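"""External-restraint generation and REFMAC-style keyword serialization.

Three restraint flavours are produced:

* homologue restraints — interatomic distances observed in a reference
  structure become objective values for the matched atom pairs of the
  target (neighbour search within 4.2 Å, covalently bonded and
  geometry-covered 1-2/1-3 pairs excluded);
* hydrogen-bond restraints — backbone N···O pairs detected in the
  target itself, restrained to the standard 2.8 Å bond length;
* jelly-body-style self-restraints — every non-bonded pair within the
  neighbour cutoff restrained to its current distance with a tight
  sigma, regularizing refinement without preferring any new
  conformation.

When several reference structures restrain the same atom pair, the
alternatives share a group id so a downstream minimizer can pick, each
cycle, the alternative closest to the current interatomic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Atom, Structure

__all__ = [
    "RestraintConfig",
    "Restraint",
    "RestraintSet",
    "covalent_neighbourhoods",
    "generate_homologue_restraints",
    "detect_mainchain_hbonds",
    "generate_hbond_restraints",
    "generate_jelly_restraints",
    "write_refmac_external",
    "read_refmac_external",
    "RestraintParseError",
]

AtomKey = tuple[str, int, str, str]


class RestraintParseError(ValueError):
    """Malformed external-restraint keyword line."""


@dataclass(frozen=True)
class RestraintConfig:
    """Generation parameters (all distances in Å).

    ``min_bond_path`` excludes pairs separated by fewer covalent bonds
    — 1-2 and 1-3 (and by default 1-4) relationships are already
    maintained by standard geometry restraints.
    """

    neighbour_cutoff: float = 4.2
    hbond_target: float = 2.8
    sigma_homologue: float = 0.1
    sigma_hbond: float = 0.1
    sigma_jelly: float = 0.02
    min_bond_path: int = 4
    hbond_distance_max: float = 3.5
    hbond_min_separation: int = 2
    hbond_min_angle: float = 90.0
    hbond_min_nho_angle: float = 120.0

    def __post_init__(self):
        for name in ("neighbour_cutoff", "hbond_target", "sigma_homologue",
                     "sigma_hbond", "sigma_jelly"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Restraint:
    """A single interatomic-distance restraint between two target atoms."""

    atom_1: AtomKey
    atom_2: AtomKey
    target_distance: float
    sigma: float
    group_id: int
    source: str

    def __post_init__(self):
        if self.atom_1 == self.atom_2:
            raise ValueError("restraint endpoints must differ")
        if self.target_distance <= 0 or self.sigma <= 0:
            raise ValueError("distance and sigma must be positive")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.atom_1, self.atom_2))


@dataclass
class RestraintSet:
    restraints: list[Restraint] = field(default_factory=list)
    config: RestraintConfig = field(default_factory=RestraintConfig)
    target_id: str = ""

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def by_group(self) -> dict[int, list[Restraint]]:
        groups: dict[int, list[Restraint]] = {}
        for r in self.restraints:
            groups.setdefault(r.group_id, []).append(r)
        return groups

    def merged_with(self, other: "RestraintSet") -> "RestraintSet":
        """Concatenate two sets, renumbering the other's groups."""
        offset = max((r.group_id for r in self.restraints), default=-1) + 1
        moved = [Restraint(r.atom_1, r.atom_2, r.target_distance, r.sigma,
                           r.group_id + offset, r.source) for r in other]
        return RestraintSet(self.restraints + moved, self.config,
                            self.target_id or other.target_id)


_GENERIC_BOND_MAX = 1.85
_SULFUR_BOND_MAX = 2.1
_PEPTIDE_BOND_MAX = 1.8


def _bonded(a: Atom, b: Atom) -> bool:
    cutoff = _SULFUR_BOND_MAX if "S" in (a.element, b.element) \
        else _GENERIC_BOND_MAX
    return float(np.linalg.norm(a.xyz - b.xyz)) <= cutoff


def _bond_graph(structure: Structure) -> dict[AtomKey, set[AtomKey]]:
    """Covalent bonds: intra-residue by distance heuristic, plus the
    peptide C(i)-N(i+1) link between consecutive polymer residues."""
    adj: dict[AtomKey, set[AtomKey]] = {}

    def link(a: Atom, b: Atom):
        adj.setdefault(a.key, set()).add(b.key)
        adj.setdefault(b.key, set()).add(a.key)

    for chain in structure.chains:
        for res in chain.residues:
            heavy = [a for a in res.atoms if not a.is_hydrogen]
            for i, a in enumerate(heavy):
                adj.setdefault(a.key, set())
                for b in heavy[i + 1:]:
                    if _bonded(a, b):
                        link(a, b)
        poly = chain.polymer_residues
        for r1, r2 in zip(poly, poly[1:]):
            c, n = r1.atom("C"), r2.atom("N")
            if c is not None and n is not None and \
                    np.linalg.norm(c.xyz - n.xyz) <= _PEPTIDE_BOND_MAX:
                link(c, n)
    return adj


def covalent_neighbourhoods(structure: Structure,
                            max_path: int) -> dict[AtomKey, set[AtomKey]]:
    """For each atom, the set of atoms within ``max_path`` covalent bonds."""
    adj = _bond_graph(structure)
    near: dict[AtomKey, set[AtomKey]] = {}
    for start in adj:
        seen = {start}
        frontier = {start}
        for _ in range(max_path):
            frontier = {n for f in frontier for n in adj.get(f, ())} - seen
            seen |= frontier
        seen.discard(start)
        near[start] = seen
    return near


def _excluded_pairs(structure: Structure, config: RestraintConfig):
    """Unordered atom-key pairs separated by < min_bond_path bonds."""
    near = covalent_neighbourhoods(structure, config.min_bond_path - 1)
    excluded = set()
    for a, neighbours in near.items():
        for b in neighbours:
            excluded.add(frozenset((a, b)))
    return excluded


def generate_homologue_restraints(
        target: Structure,
        refs: list[tuple[Structure, list[tuple[Atom, Atom]]]],
        config: RestraintConfig = RestraintConfig()) -> RestraintSet:
    """Distance restraints from one or more reference structures.

    ``refs`` pairs each reference structure with its (target atom,
    reference atom) matching.  For every matched pair of atoms whose
    distance in the *reference* is within the neighbour cutoff and whose
    covalent bond path in the target is at least ``min_bond_path``, a
    restraint with the reference distance as objective is emitted.
    Restraints from different references for the same target atom pair
    share a group id (alternatives).
    """
    excluded = _excluded_pairs(target, config)
    group_of: dict[frozenset, int] = {}
    restraints: list[Restraint] = []
    for ref_structure, pairing in refs:
        if not pairing:
            continue
        t_atoms = [t for t, _ in pairing]
        r_coords = np.array([r.xyz for _, r in pairing])
        tree = cKDTree(r_coords)
        for i, j in sorted(tree.query_pairs(config.neighbour_cutoff)):
            ta, tb = t_atoms[i], t_atoms[j]
            if ta.key == tb.key:
                continue
            pair = frozenset((ta.key, tb.key))
            if pair in excluded:
                continue
            d = float(np.linalg.norm(r_coords[i] - r_coords[j]))
            if pair not in group_of:
                group_of[pair] = len(group_of)
            restraints.append(Restraint(
                min(ta.key, tb.key), max(ta.key, tb.key), d,
                config.sigma_homologue, group_of[pair], ref_structure.id))
    return RestraintSet(restraints, config, target.id)


def detect_mainchain_hbonds(structure: Structure,
                            config: RestraintConfig = RestraintConfig()
                            ) -> list[tuple[Atom, Atom]]:
    """Backbone N(donor)···O(acceptor) pairs with hydrogen-bond geometry.

    Criteria: N···O distance within ``hbond_distance_max`` (3.5 Å),
    sequence separation of at least ``hbond_min_separation`` residues
    when donor and acceptor share a chain, a C=O···N angle of at least
    ``hbond_min_angle`` (90°), and — where the amide hydrogen can be
    inferred from the preceding residue — an N-H···O angle of at least
    ``hbond_min_nho_angle`` (120°).  Each amide donor carries a single
    hydrogen, so at most one bond (the closest qualifying acceptor) is
    kept per donor; in an ideal α-helix this yields exactly the
    N(i+4)→O(i) pattern.
    """
    donors, acceptors = [], []
    index_of: dict[tuple, int] = {}
    for chain in structure.polymer_chains:
        poly = chain.polymer_residues
        for pos, res in enumerate(poly):
            index_of[res.key] = pos
            n, o, c = res.atom("N"), res.atom("O"), res.atom("C")
            if n is not None:
                h_pos = None
                ca = res.atom("CA")
                prev_c = poly[pos - 1].atom("C") if pos > 0 else None
                if ca is not None and prev_c is not None:
                    # amide H along the bisector opposite C(i-1) and CA
                    u1 = n.xyz - prev_c.xyz
                    u2 = n.xyz - ca.xyz
                    h_dir = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
                    h_pos = n.xyz + h_dir / np.linalg.norm(h_dir)
                donors.append((n, h_pos))
            if o is not None and c is not None:
                acceptors.append((o, c))

    def angle_deg(v1, v2):
        cosang = float(np.dot(v1, v2)
                       / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    bonds = []
    for n_atom, h_pos in donors:
        best = None
        for o_atom, c_atom in acceptors:
            if n_atom.chain_id == o_atom.chain_id:
                sep = abs(index_of[(n_atom.chain_id, n_atom.residue_seq,
                                    n_atom.icode)]
                          - index_of[(o_atom.chain_id, o_atom.residue_seq,
                                      o_atom.icode)])
                if sep < config.hbond_min_separation:
                    continue
            d = float(np.linalg.norm(n_atom.xyz - o_atom.xyz))
            if d > config.hbond_distance_max:
                continue
            if angle_deg(c_atom.xyz - o_atom.xyz, n_atom.xyz - o_atom.xyz) \
                    < config.hbond_min_angle:
                continue
            if h_pos is not None and \
                    angle_deg(n_atom.xyz - h_pos, o_atom.xyz - h_pos) \
                    < config.hbond_min_nho_angle:
                continue
            if best is None or d < best[0]:
                best = (d, o_atom)
        if best is not None:
            bonds.append((n_atom, best[1]))
    return bonds


def generate_hbond_restraints(structure: Structure,
                              config: RestraintConfig = RestraintConfig()
                              ) -> RestraintSet:
    """One restraint per detected backbone hydrogen bond, objective 2.8 Å."""
    restraints = []
    for gid, (n_atom, o_atom) in \
            enumerate(detect_mainchain_hbonds(structure, config)):
        restraints.append(Restraint(
            min(n_atom.key, o_atom.key), max(n_atom.key, o_atom.key),
            config.hbond_target, config.sigma_hbond, gid, "hbond"))
    return RestraintSet(restraints, config, structure.id)


def generate_jelly_restraints(structure: Structure,
                              config: RestraintConfig = RestraintConfig()
                              ) -> RestraintSet:
    """Self-restraints: every non-bonded pair within the cutoff is tied
    to its current distance (zero residual at the starting model)."""
    excluded = _excluded_pairs(structure, config)
    atoms = structure.atoms()
    coords = np.array([a.xyz for a in atoms])
    restraints = []
    if len(atoms) >= 2:
        tree = cKDTree(coords)
        gid = 0
        for i, j in sorted(tree.query_pairs(config.neighbour_cutoff)):
            pair = frozenset((atoms[i].key, atoms[j].key))
            if pair in excluded or atoms[i].key == atoms[j].key:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            restraints.append(Restraint(
                min(atoms[i].key, atoms[j].key),
                max(atoms[i].key, atoms[j].key),
                d, config.sigma_jelly, gid, "jelly"))
            gid += 1
    return RestraintSet(restraints, config, structure.id)


def _fmt_key(key: AtomKey) -> str:
    chain, seq, icode, name = key
    return (f"chain {chain} resi {seq} ins {icode or '.'} atom {name}")


def write_refmac_external(restraint_set: RestraintSet,
                          path: str | Path) -> None:
    """Serialize as REFMAC ``exte dist`` keyword lines.

    A trailing ``#`` comment carries provenance and alternative-group
    id; keyword parsers ignore it, and :func:`read_refmac_external` uses
    it to reconstruct the full restraint set.
    """
    lines = []
    for r in restraint_set:
        lines.append(
            f"exte dist first {_fmt_key(r.atom_1)} "
            f"second {_fmt_key(r.atom_2)} "
            f"value {r.target_distance:.3f} sigma {r.sigma:.3f} type 0 "
            f"# source={r.source} group={r.group_id}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _parse_side(tokens: list[str], lineno: int) -> AtomKey:
    expect = ("chain", "resi", "ins", "atom")
    values = {}
    for kw in expect:
        if len(tokens) < 2 or tokens[0] != kw:
            raise RestraintParseError(
                f"line {lineno}: expected '{kw} <value>'")
        values[kw] = tokens[1]
        del tokens[:2]
    icode = "" if values["ins"] == "." else values["ins"]
    try:
        seq = int(values["resi"])
    except ValueError as exc:
        raise RestraintParseError(
            f"line {lineno}: bad residue number {values['resi']!r}") from exc
    return (values["chain"], seq, icode, values["atom"])


def read_refmac_external(path: str | Path) -> RestraintSet:
    """Parse an ``exte dist`` keyword file written by this package."""
    restraints = []
    pair_groups: dict[frozenset, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        meta = {}
        if "#" in line:
            line, _, comment = line.partition("#")
            for token in comment.split():
                if "=" in token:
                    k, _, v = token.partition("=")
                    meta[k] = v
        tokens = line.split()
        if tokens[:3] != ["exte", "dist", "first"]:
            raise RestraintParseError(
                f"line {lineno}: expected 'exte dist first ...'")
        del tokens[:3]
        atom_1 = _parse_side(tokens, lineno)
        if not tokens or tokens[0] != "second":
            raise RestraintParseError(f"line {lineno}: missing 'second'")
        del tokens[:1]
        atom_2 = _parse_side(tokens, lineno)
        fields = dict(zip(tokens[::2], tokens[1::2]))
        for required in ("value", "sigma"):
            if required not in fields:
                raise RestraintParseError(
                    f"line {lineno}: missing '{required}' token")
        if "group" in meta:
            gid = int(meta["group"])
        else:
            pair = frozenset((atom_1, atom_2))
            gid = pair_groups.setdefault(pair, len(pair_groups))
        restraints.append(Restraint(
            atom_1, atom_2, float(fields["value"]), float(fields["sigma"]),
            gid, meta.get("source", "external")))
    return RestraintSet(restraints)
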