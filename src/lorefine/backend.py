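"""Pluggable refinement backends and the built-in toy restrained minimizer.

A backend receives a model plus a restraint set and returns a refined
model with outcome statistics (r_work / r_free percentages and,
optionally, a geometry percentile).  Real crystallographic refinement
is outside this package; the contract lets one plug in an external
program, while the built-in :class:`ToyBackend` makes the whole
pipeline exercisable on synthetic structures.

The toy minimizer performs gradient descent on

    E = sum over groups of  min over alternatives  ((d - d_target) / sigma)^2

where, within each alternative group (the same atom pair restrained by
several reference structures), the alternative closest to the current
interatomic distance is active each cycle.

The toy backend's R statistics are NOT crystallographic R factors.
They are monotone transforms of distance residuals:

* the minimizer itself reports ``100 * s / (1 + s)`` with
  ``s = sqrt(E / N_groups)`` over its own restraint set;
* when the backend is given pseudo-observation data (a reference
  structure standing in for the diffraction experiment), r_work and
  r_free are the same transform computed against observed interatomic
  distances, split 90/10 into work and cross-validation pairs, which is
  what lets different protocols be ranked against common data.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_io import Structure, read_structure, write_structure
from .restraints import (RestraintConfig, RestraintSet,
                         generate_jelly_restraints, write_refmac_external)

__all__ = [
    "BackendRequest",
    "BackendResponse",
    "BackendError",
    "toy_refine",
    "ToyBackend",
    "CommandBackend",
    "residual_to_pseudo_r",
]

IDEAL_CA_CA = 3.80  # Å, consecutive residues
IDEAL_PEPTIDE_CN = 1.33  # Å


class BackendError(RuntimeError):
    """Refinement backend failed."""


@dataclass(frozen=True)
class BackendRequest:
    model: Structure
    restraints: RestraintSet
    cycles: int = 20
    twin: bool = False           # pass-through; toy backend ignores
    scaling: str = "standard"    # pass-through; toy backend ignores
    mr_mode: bool = False


@dataclass(frozen=True)
class BackendResponse:
    model: Structure
    r_work: float
    r_free: float
    mp_percentile: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.r_work) and np.isfinite(self.r_free)):
            raise ValueError("backend statistics must be finite")


def residual_to_pseudo_r(mean_sq_residual: float) -> float:
    """Map a mean squared normalized residual to a bounded percentage."""
    s = float(np.sqrt(mean_sq_residual))
    return 100.0 * s / (1.0 + s)


def _index_restraints(model: Structure, restraint_set: RestraintSet):
    """Vectorized view: atom indices, targets, sigmas, group segments."""
    atoms = model.atoms()
    pos_of = {a.key: i for i, a in enumerate(atoms)}
    rows = []
    for r in restraint_set:
        if r.atom_1 not in pos_of or r.atom_2 not in pos_of:
            raise BackendError(f"restraint references atom absent from "
                               f"model: {r.atom_1} / {r.atom_2}")
        rows.append((r.group_id, pos_of[r.atom_1], pos_of[r.atom_2],
                     r.target_distance, r.sigma))
    rows.sort()
    gid = np.array([r[0] for r in rows], dtype=int)
    i_idx = np.array([r[1] for r in rows], dtype=int)
    j_idx = np.array([r[2] for r in rows], dtype=int)
    targets = np.array([r[3] for r in rows])
    sigmas = np.array([r[4] for r in rows])
    seg_starts = np.flatnonzero(np.r_[True, np.diff(gid) != 0])
    seg_len = np.diff(np.r_[seg_starts, len(gid)])
    seg_id = np.repeat(np.arange(len(seg_starts)), seg_len)
    return atoms, i_idx, j_idx, targets, sigmas, seg_starts, seg_id


def _group_energy(coords, i_idx, j_idx, targets, sigmas, seg_starts, seg_id):
    """E and the per-restraint active mask (closest alternative per group)."""
    diff = coords[i_idx] - coords[j_idx]
    d = np.linalg.norm(diff, axis=1)
    misfit = np.abs(d - targets)
    seg_min = np.minimum.reduceat(misfit, seg_starts)
    candidates = np.flatnonzero(misfit <= seg_min[seg_id] + 1e-15)
    # first minimum per group wins (seg_id is sorted, so unique keeps it)
    _, first_idx = np.unique(seg_id[candidates], return_index=True)
    active = np.zeros(len(misfit), dtype=bool)
    active[candidates[first_idx]] = True
    res = (d - targets) / sigmas
    energy = float(np.sum(res[active] ** 2))
    return energy, active, d, diff


def toy_refine(model: Structure, restraint_set: RestraintSet,
               cycles: int = 20) -> tuple[Structure, float, float]:
    """Gradient-descent minimization of the restraint energy.

    Returns ``(refined model, final energy, pseudo-R)`` where pseudo-R
    is the bounded residual transform over the restraint groups.  The
    energy is non-increasing across cycles (backtracking line search).
    An empty restraint set returns the model unchanged.
    """
    if len(restraint_set) == 0:
        return model, 0.0, 0.0
    atoms, i_idx, j_idx, targets, sigmas, seg_starts, seg_id = \
        _index_restraints(model, restraint_set)
    coords = np.array([a.xyz for a in atoms])
    n_groups = len(seg_starts)
    step = 1e-4
    energy, active, d, diff = _group_energy(coords, i_idx, j_idx, targets,
                                            sigmas, seg_starts, seg_id)
    for _ in range(max(cycles, 0)):
        if energy <= 1e-18:
            break
        grad = np.zeros_like(coords)
        k = np.flatnonzero(active)
        safe_d = np.maximum(d[k], 1e-9)
        coef = 2.0 * (d[k] - targets[k]) / (sigmas[k] ** 2 * safe_d)
        contrib = coef[:, None] * diff[k]
        np.add.at(grad, i_idx[k], contrib)
        np.add.at(grad, j_idx[k], -contrib)
        improved = False
        for _ in range(40):
            trial = coords - step * grad
            e_new, a_new, d_new, diff_new = _group_energy(
                trial, i_idx, j_idx, targets, sigmas, seg_starts, seg_id)
            if e_new <= energy + 1e-12:
                coords, energy = trial, e_new
                active, d, diff = a_new, d_new, diff_new
                improved = True
                step *= 1.5
                break
            step *= 0.5
        if not improved:
            break
    refined = model.copy_with_coords(coords, atoms)
    pseudo_r = residual_to_pseudo_r(energy / n_groups)
    return refined, energy, pseudo_r


def _pseudo_geometry_percentile(model: Structure) -> float:
    """Geometry-quality proxy in [0, 100]: penalizes deviation of
    consecutive CA-CA and peptide C-N distances from ideal values."""
    devs = []
    for chain in model.polymer_chains:
        poly = chain.polymer_residues
        for r1, r2 in zip(poly, poly[1:]):
            ca1, ca2 = r1.atom("CA"), r2.atom("CA")
            if ca1 is not None and ca2 is not None:
                devs.append(np.linalg.norm(ca1.xyz - ca2.xyz) - IDEAL_CA_CA)
            c, n = r1.atom("C"), r2.atom("N")
            if c is not None and n is not None:
                devs.append(np.linalg.norm(c.xyz - n.xyz) - IDEAL_PEPTIDE_CN)
    if not devs:
        return 50.0
    rms = float(np.sqrt(np.mean(np.square(devs))))
    return 100.0 * float(np.exp(-5.0 * rms))


@dataclass
class ToyBackend:
    """Restraint-only minimizer with pseudo-observation statistics.

    ``data`` is a reference structure standing in for the experimental
    data (for synthetic benchmarks, the ground truth): its non-bonded
    interatomic distances within ``data_cutoff`` become the
    observations.  r_work / r_free are residual transforms of the
    current model against the work / free observation split (every
    tenth observation, by index, is held out as "free").  Without
    ``data``, statistics fall back to the minimizer's own restraint
    residual.  ``geometry=True`` additionally reports the
    backbone-regularity percentile so Q-score ranking is exercised.
    """

    data: Structure | None = None
    data_sigma: float = 0.5
    data_cutoff: float = 5.0
    geometry: bool = True
    _observations: RestraintSet | None = field(default=None, repr=False)

    def _data_observations(self) -> RestraintSet | None:
        if self.data is None:
            return None
        if self._observations is None:
            config = RestraintConfig(neighbour_cutoff=self.data_cutoff,
                                     sigma_jelly=self.data_sigma)
            self._observations = generate_jelly_restraints(self.data, config)
        return self._observations

    def _data_statistics(self, model: Structure) -> tuple[float, float] | None:
        obs = self._data_observations()
        if obs is None or len(obs) == 0:
            return None
        index = model.atom_index()
        work, free = [], []
        for k, r in enumerate(obs):
            a, b = index.get(r.atom_1), index.get(r.atom_2)
            if a is None or b is None:
                continue
            d = float(np.linalg.norm(a.xyz - b.xyz))
            res = ((d - r.target_distance) / r.sigma) ** 2
            (free if k % 10 == 0 else work).append(res)
        if not work or not free:
            return None
        return (residual_to_pseudo_r(float(np.mean(work))),
                residual_to_pseudo_r(float(np.mean(free))))

    def evaluate(self, model: Structure) -> BackendResponse:
        """Statistics of a model without refining it."""
        stats = self._data_statistics(model)
        if stats is None:
            stats = (0.0, 0.0)
        mp = _pseudo_geometry_percentile(model) if self.geometry else None
        return BackendResponse(model, stats[0], stats[1], mp)

    def refine(self, request: BackendRequest) -> BackendResponse:
        model, _, pseudo_r = toy_refine(request.model, request.restraints,
                                        request.cycles)
        stats = self._data_statistics(model)
        if stats is None:
            stats = (pseudo_r, pseudo_r)
        mp = _pseudo_geometry_percentile(model) if self.geometry else None
        return BackendResponse(model, stats[0], stats[1], mp)


@dataclass
class CommandBackend:
    """Run an external refinement program from a shell template.

    The template may use the placeholders ``{model_in}``,
    ``{restraints}``, ``{cycles}``, ``{model_out}`` and ``{stats}``.
    The command must write a PDB model to ``{model_out}`` and a JSON
    object with keys ``r_work``, ``r_free`` (and optionally
    ``mp_percentile``) to ``{stats}``.
    """

    template: str
    workdir: str | None = None

    def refine(self, request: BackendRequest) -> BackendResponse:
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            tmp = Path(tmp)
            model_in = tmp / "in.pdb"
            model_out = tmp / "out.pdb"
            restr = tmp / "external.txt"
            stats_path = tmp / "stats.json"
            write_structure(request.model, model_in)
            write_refmac_external(request.restraints, restr)
            cmd = self.template.format(
                model_in=model_in, model_out=model_out, restraints=restr,
                cycles=request.cycles, stats=stats_path)
            proc = subprocess.run(cmd, shell=True, capture_output=True,
                                  text=True)
            if proc.returncode != 0:
                raise BackendError(
                    f"backend command failed ({proc.returncode}): "
                    f"{proc.stderr.strip()[:500]}")
            if not model_out.exists() or not stats_path.exists():
                raise BackendError("backend command produced no output")
            stats = json.loads(stats_path.read_text())
            return BackendResponse(
                read_structure(model_out),
                float(stats["r_work"]), float(stats["r_free"]),
                (float(stats["mp_percentile"])
                 if stats.get("mp_percentile") is not None else None))

    def evaluate(self, model: Structure) -> BackendResponse:
        return self.refine(BackendRequest(model, RestraintSet(), cycles=0))
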