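"""Protocol ranking by the Q-score.

Refinement protocols are compared on two axes: R_free (fit to data,
percent, lower is better) and the MolProbity score percentile (model
geometry, higher is better).  The Q-score folds the two into one
number by inflating each protocol's R_free in proportion to how far
its geometry falls short of the best geometry seen across protocols:

    q = R_free + c * (MP_max - MP)
    c = (R_free_max - R_free_min) / (MP_max - MP_min)

so the protocol(s) with the best geometry keep q = R_free, and c is
zero when all protocols have identical geometry percentiles (then q
degenerates to R_free).  The protocol with the lowest Q-score ranks
best; when geometry percentiles are unavailable, ranking falls back to
plain R_free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ProtocolResult",
    "QScoreTable",
    "FallbackRequired",
    "compute_q_scores",
    "select_best_protocol",
    "read_results_csv",
    "write_results_csv",
]


class FallbackRequired(ValueError):
    """Geometry percentiles missing; rank by R_free instead."""


@dataclass
class ProtocolResult:
    """Outcome statistics of one refinement protocol."""

    protocol_id: str
    r_work: float
    r_free: float
    mp_percentile: float | None = None
    model_path: str | None = None
    failed: bool = False
    error: str | None = None

    def __post_init__(self):
        if self.failed:
            return
        if not 0 <= self.r_free <= 100:
            raise ValueError("r_free must be a percentage in [0, 100]")
        if self.mp_percentile is not None and \
                not 0 <= self.mp_percentile <= 100:
            raise ValueError("mp_percentile must be in [0, 100]")


@dataclass
class QScoreTable:
    q: dict[str, float]
    c: float
    r_min: float
    r_max: float
    mp_min: float
    mp_max: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protocol": list(self.q), "q_score": list(self.q.values())}
        ).sort_values("q_score", ignore_index=True)


def compute_q_scores(results: list[ProtocolResult]) -> QScoreTable:
    """Q-scores for a set of protocol results.

    Raises :class:`FallbackRequired` if any result lacks a geometry
    percentile — the caller should then rank by R_free alone.
    """
    results = [r for r in results if not r.failed]
    if not results:
        raise ValueError("no successful protocol results")
    if any(r.mp_percentile is None for r in results):
        raise FallbackRequired("MolProbity percentile missing for some "
                               "protocols; rank by R_free")
    r_vals = [r.r_free for r in results]
    mp_vals = [r.mp_percentile for r in results]
    r_min, r_max = min(r_vals), max(r_vals)
    mp_min, mp_max = min(mp_vals), max(mp_vals)
    c = (r_max - r_min) / (mp_max - mp_min) if mp_max > mp_min else 0.0
    q = {r.protocol_id: r.r_free + c * (mp_max - r.mp_percentile)
         for r in results}
    return QScoreTable(q, c, r_min, r_max, mp_min, mp_max)


def select_best_protocol(results: list[ProtocolResult],
                         geometry_available: bool = True) -> str:
    """Best protocol id: argmin Q-score, or argmin R_free as fallback.

    Ties break toward lower R_free, then better (higher) geometry
    percentile, then input order.
    """
    live = [r for r in results if not r.failed]
    if not live:
        raise ValueError("cannot select from an empty result list")
    if geometry_available:
        try:
            table = compute_q_scores(live)
        except FallbackRequired:
            geometry_available = False
    if geometry_available:
        key = lambda ir: (round(table.q[ir[1].protocol_id], 9),
                          ir[1].r_free,
                          -(ir[1].mp_percentile or 0.0),
                          ir[0])
    else:
        key = lambda ir: (ir[1].r_free, ir[0])
    return min(enumerate(live), key=key)[1].protocol_id


def write_results_csv(results: list[ProtocolResult],
                      path: str | Path) -> None:
    rows = [{"protocol": r.protocol_id, "r_work": r.r_work,
             "r_free": r.r_free, "mp_percentile": r.mp_percentile}
            for r in results if not r.failed]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results_csv(path: str | Path) -> list[ProtocolResult]:
    """Load protocol results from a CSV with columns
    protocol, r_work, r_free[, mp_percentile]."""
    df = pd.read_csv(path)
    required = {"protocol", "r_work", "r_free"}
    if not required <= set(df.columns):
        raise ValueError(f"results CSV must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        mp = row.get("mp_percentile")
        mp = None if mp is None or pd.isna(mp) else float(mp)
        out.append(ProtocolResult(str(row["protocol"]), float(row["r_work"]),
                                  float(row["r_free"]), mp))
    return out
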