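"""Protocol enumeration, execution and selection.

Given a target model and a set of candidate homologues, the pipeline

1. assesses every homologue chain against every target chain, rejects
   those below the identity/coverage cutoffs (75 %/75 % by default) and
   ranks the survivors by the sum of global and local r.m.s.d.;
2. enumerates refinement protocols: external restraints from the one,
   two and three best-ranked homologues, from the one, two and three
   most different homologues (largest global r.m.s.d.), from all
   homologues, plus the two homologue-free protocols (hydrogen-bond
   restraints and jelly-body restraints).  Protocols whose homologue
   subsets coincide are deduplicated;
3. runs each protocol through the refinement backend — external-
   restraint stage followed by a jelly-body relaxation stage (the
   homologue-free jelly protocol is a single stage).  In
   molecular-replacement mode an extended jelly relaxation (100 cycles,
   200 when the starting R is high) is prepended;
4. ranks the outcomes by Q-score (or R_free when geometry percentiles
   are unavailable) and reports the best protocol.

Fragment-library (ERF) protocols are recognized identifiers but their
restraint generation is not implemented.  Remote homologue search is a
stub that is disabled by default.
"""

from __future__ import annotations

import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backend import BackendRequest, ToyBackend
from .homology import (HomologueAssessment, assess_homologue, atom_pairing,
                       filter_homologues, rank_homologues)
from .model_io import Structure, read_structure, write_structure
from .restraints import (RestraintConfig, RestraintSet,
                         generate_hbond_restraints,
                         generate_homologue_restraints,
                         generate_jelly_restraints)
from .scoring import (FallbackRequired, ProtocolResult, QScoreTable,
                      compute_q_scores, select_best_protocol,
                      write_results_csv)

__all__ = [
    "Protocol",
    "PipelineOptions",
    "PipelineReport",
    "PipelineError",
    "enumerate_protocols",
    "run_protocol",
    "run_pipeline",
    "save_protocol_file",
    "load_protocol_file",
    "remote_homologue_search",
]

_KIND_RE = re.compile(
    r"^(ERH_top\d+|ERH_distant\d+|ERH_all|ERB|JELLY|ERF(_\w+)?)$")

MR_CYCLES_LOW, MR_CYCLES_HIGH = 100, 200
MR_HIGH_R_THRESHOLD = 40.0  # % ; above this the longer relaxation is used


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class Protocol:
    """A named restraint + refinement recipe.

    External-restraint protocols (ERH/ERB) run two stages — the
    external-restraint round, then a jelly-body relaxation round; the
    jelly-only protocol runs a single stage.
    """

    kind: str
    homologue_ids: tuple[str, ...] = ()
    stages: tuple[str, ...] = ("external", "jelly")

    def __post_init__(self):
        if not _KIND_RE.match(self.kind):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "JELLY":
            if self.stages != ("jelly",):
                raise ValueError("JELLY protocol has exactly one stage")
        elif self.kind.startswith(("ERH", "ERB")):
            if self.stages != ("external", "jelly"):
                raise ValueError(
                    "external-restraint protocols have exactly two stages")
        if self.kind.startswith("ERF"):
            raise NotImplementedError(
                "fragment-library (ERF) restraint generation is not "
                "implemented; ERF kinds exist as identifiers only")


@dataclass
class PipelineOptions:
    min_identity: float = 75.0
    min_coverage: float = 75.0
    max_homologues: int = 3
    cycles: int = 20
    mr_mode: bool = False
    jobs: int = 1
    twin: bool = False
    scaling: str = "standard"
    restraint_config: RestraintConfig = field(default_factory=RestraintConfig)
    output_dir: Path | None = None
    protocol_file: Path | None = None
    remote_search: bool = False
    seed: int = 0


@dataclass
class PipelineReport:
    assessments: list[HomologueAssessment]
    retained: list[HomologueAssessment]
    protocols: list[Protocol]
    results: list[ProtocolResult]
    q_table: QScoreTable | None
    fallback_note: str | None
    best_protocol: str
    best_model: Structure
    protocol_file: Path | None = None

    @property
    def best_result(self) -> ProtocolResult:
        return next(r for r in self.results
                    if r.protocol_id == self.best_protocol)


def remote_homologue_search(sequence: str, enabled: bool = False):
    """Stub for BLAST-over-PDB homologue retrieval (off by default).

    Homologues are expected to be supplied locally; when disabled this
    returns an empty list without touching the network.
    """
    if not enabled:
        return []
    raise NotImplementedError(
        "remote homologue search is not implemented; supply homologue "
        "PDB files locally")


def enumerate_protocols(ranked_homologues: list[HomologueAssessment],
                        options: PipelineOptions | None = None
                        ) -> list[Protocol]:
    """Enumerate the protocol grid for the available homologues.

    With no homologues only the two homologue-free protocols (ERB,
    JELLY) are produced.  Otherwise top-K and most-different-K subsets
    (K up to ``max_homologues``) plus the all-homologue protocol are
    generated, deduplicated on unordered homologue-id sets.
    """
    options = options or PipelineOptions()
    best = rank_homologues(ranked_homologues)
    distant = rank_homologues(ranked_homologues, most_different=True)
    best_ids = [a.structure_id for a in best]
    distant_ids = [a.structure_id for a in distant]
    k_max = min(options.max_homologues, len(best_ids))
    candidates: list[Protocol] = []
    for k in range(1, k_max + 1):
        candidates.append(Protocol(f"ERH_top{k}", tuple(best_ids[:k])))
    for k in range(1, k_max + 1):
        candidates.append(Protocol(f"ERH_distant{k}",
                                   tuple(distant_ids[:k])))
    if best_ids:
        candidates.append(Protocol("ERH_all", tuple(best_ids)))
    protocols: list[Protocol] = []
    seen: set[frozenset] = set()
    for p in candidates:
        key = frozenset(p.homologue_ids)
        if key not in seen:
            seen.add(key)
            protocols.append(p)
    protocols.append(Protocol("ERB"))
    protocols.append(Protocol("JELLY", stages=("jelly",)))
    return protocols


def _external_restraints(protocol: Protocol, target: Structure,
                         homologue_data, hbond_chains,
                         config: RestraintConfig) -> RestraintSet:
    if protocol.kind == "ERB":
        return generate_hbond_restraints(target, config)
    refs = [homologue_data[hid] for hid in protocol.homologue_ids]
    restraints = generate_homologue_restraints(target, refs, config)
    if hbond_chains:
        hb = generate_hbond_restraints(target, config)
        hb = RestraintSet([r for r in hb if r.atom_1[0] in hbond_chains
                           and r.atom_2[0] in hbond_chains], config,
                          target.id)
        restraints = restraints.merged_with(hb)
    return restraints


def run_protocol(protocol: Protocol, target: Structure, backend,
                 options: PipelineOptions | None = None,
                 homologue_data: dict | None = None,
                 hbond_chains: set | None = None
                 ) -> tuple[ProtocolResult, Structure]:
    """Execute one protocol: optional MR relaxation, then its stages."""
    options = options or PipelineOptions()
    homologue_data = homologue_data or {}
    hbond_chains = hbond_chains or set()
    config = options.restraint_config
    model = target
    try:
        if options.mr_mode:
            start = backend.evaluate(model)
            mr_cycles = (MR_CYCLES_HIGH if start.r_free > MR_HIGH_R_THRESHOLD
                         else MR_CYCLES_LOW)
            response = backend.refine(BackendRequest(
                model, generate_jelly_restraints(model, config),
                cycles=mr_cycles, twin=options.twin,
                scaling=options.scaling, mr_mode=True))
            model = response.model
        response = None
        for stage in protocol.stages:
            if stage == "external":
                restraints = _external_restraints(
                    protocol, model, homologue_data, hbond_chains, config)
            else:
                restraints = generate_jelly_restraints(model, config)
            response = backend.refine(BackendRequest(
                model, restraints, cycles=options.cycles,
                twin=options.twin, scaling=options.scaling))
            model = response.model
        result = ProtocolResult(protocol.kind, response.r_work,
                                response.r_free, response.mp_percentile)
        return result, model
    except Exception as exc:  # protocol failure must not kill the pipeline
        return ProtocolResult(protocol.kind, float("nan"), float("nan"),
                              failed=True, error=str(exc)), target


def _load(obj) -> Structure:
    return obj if isinstance(obj, Structure) else read_structure(obj)


def run_pipeline(target, homologues=(), options: PipelineOptions | None = None,
                 backend=None) -> PipelineReport:
    """Assess homologues, enumerate and run protocols, pick the best.

    ``target`` and ``homologues`` may be paths or in-memory structures.
    Target chains for which no homologue survives filtering receive
    hydrogen-bond restraints within every external-restraint protocol.
    """
    options = options or PipelineOptions()
    backend = backend or ToyBackend()
    target_st = _load(target)
    homologue_sts = [_load(h) for h in homologues]

    # per-homologue assessment: best-matching chain per target chain
    assessments: list[HomologueAssessment] = []
    homologue_data: dict[str, tuple[Structure, list]] = {}
    covered_chains: dict[str, set[str]] = {}
    for hom in homologue_sts:
        per_chain: list[HomologueAssessment] = []
        pairing_all = []
        for t_chain in target_st.polymer_chains:
            chain_best = None
            for r_chain in hom.polymer_chains:
                try:
                    a = assess_homologue(t_chain, r_chain,
                                         structure_id=hom.id)
                except Exception:
                    continue
                if chain_best is None or a.rank_score < chain_best.rank_score:
                    chain_best = a
            if chain_best is None:
                continue
            per_chain.append(chain_best)
            if chain_best.identity >= options.min_identity and \
                    chain_best.coverage >= options.min_coverage:
                covered_chains.setdefault(hom.id, set()).add(t_chain.id)
                pairing_all.extend(atom_pairing(
                    t_chain, hom.chain(chain_best.chain_id),
                    chain_best.alignment))
        if not per_chain:
            continue
        # one summary assessment per homologue (mean over target chains)
        n = len(per_chain)
        summary = HomologueAssessment(
            structure_id=hom.id,
            chain_id=per_chain[0].chain_id,
            identity=sum(a.identity for a in per_chain) / n,
            coverage=sum(a.coverage for a in per_chain) / n,
            global_rmsd=sum(a.global_rmsd for a in per_chain) / n,
            flexible_score=sum(a.flexible_score for a in per_chain) / n,
        )
        assessments.append(summary)
        homologue_data[hom.id] = (hom, pairing_all)

    retained = filter_homologues(assessments, options.min_identity,
                                 options.min_coverage)
    retained_ids = {a.structure_id for a in retained}
    chains_with_hom = set()
    for hid in retained_ids:
        chains_with_hom |= covered_chains.get(hid, set())
    hbond_chains = {c.id for c in target_st.polymer_chains} - chains_with_hom

    if options.protocol_file is not None:
        protocols = [load_protocol_file(options.protocol_file,
                                        known_homologues=set(homologue_data))]
    else:
        protocols = enumerate_protocols(retained, options)

    data = {hid: homologue_data[hid] for hid in retained_ids
            if hid in homologue_data}

    def run_one(protocol: Protocol):
        return run_protocol(protocol, target_st, backend, options,
                            data, hbond_chains)

    if options.jobs > 1:
        with ThreadPoolExecutor(max_workers=options.jobs) as pool:
            outcomes = list(pool.map(run_one, protocols))
    else:
        outcomes = [run_one(p) for p in protocols]

    results = [res for res, _ in outcomes]
    models = {res.protocol_id: model for (res, model) in outcomes}
    live = [r for r in results if not r.failed]
    if not live:
        details = "; ".join(f"{r.protocol_id}: {r.error}" for r in results)
        raise PipelineError(f"all protocols failed ({details})")

    q_table, fallback_note = None, None
    try:
        q_table = compute_q_scores(live)
        best = select_best_protocol(live, geometry_available=True)
    except FallbackRequired as exc:
        fallback_note = str(exc)
        best = select_best_protocol(live, geometry_available=False)

    report = PipelineReport(
        assessments=assessments,
        retained=retained,
        protocols=protocols,
        results=results,
        q_table=q_table,
        fallback_note=fallback_note,
        best_protocol=best,
        best_model=models[best],
    )
    if options.output_dir is not None:
        out = Path(options.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results_csv(live, out / "results.csv")
        write_structure(report.best_model, out / "best_model.pdb")
        best_protocol = next(p for p in protocols if p.kind == best)
        report.protocol_file = out / "protocol.yaml"
        save_protocol_file(best_protocol, report.protocol_file,
                           options=options)
    return report


def save_protocol_file(protocol: Protocol, path,
                       options: PipelineOptions | None = None) -> None:
    """Persist a protocol so a later run can execute just that recipe."""
    payload = {
        "kind": protocol.kind,
        "homologues": list(protocol.homologue_ids),
        "stages": list(protocol.stages),
    }
    if options is not None:
        payload["cycles"] = options.cycles
        payload["mr_mode"] = options.mr_mode
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_protocol_file(path, known_homologues: set | None = None) -> Protocol:
    """Load a protocol file; validates kind and homologue ids."""
    try:
        payload = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise PipelineError(f"malformed protocol file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "kind" not in payload:
        raise PipelineError(f"malformed protocol file {path}: no 'kind'")
    kind = str(payload["kind"])
    homologue_ids = tuple(payload.get("homologues") or ())
    stages = tuple(payload.get("stages") or
                   (("jelly",) if kind == "JELLY" else ("external", "jelly")))
    if known_homologues is not None:
        unknown = set(homologue_ids) - known_homologues
        if unknown:
            raise PipelineError(
                f"protocol file names unknown homologue(s): "
                f"{sorted(unknown)}")
    try:
        return Protocol(kind, homologue_ids, stages)
    except ValueError as exc:
        raise PipelineError(str(exc)) from exc
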