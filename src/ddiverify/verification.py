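"""Turn solved candidates into accepted complexes with explicit topology.

A candidate is accepted when three or more of its proteins are connected by
simultaneously feasible, DDI-mediated PPIs: the graph of active PPIs from
the optimal assignment is split into connected components, and every
component with at least ``min_size`` proteins becomes one verified complex
carrying its active PPI edges and the DDIs that mediate them. A connected
component of >= 3 proteins necessarily carries >= 2 active DDIs, so the
size rule subsumes the multiple-interaction requirement.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .binding import BindingSolution, DDIVariable, build_model, solve
from .clustering import CandidateComplex
from .io import DDICatalog, DomainAnnotation, InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 3


@dataclass(frozen=True)
class VerifiedComplex:
    """An accepted complex with its explicit PPI/DDI organization."""

    members: frozenset[str]
    ppis: frozenset[tuple[str, str]]
    ddis: frozenset[DDIVariable]
    objective: int  # solver objective of the source candidate
    source: str = ""
    complex_id: str = ""

    def __post_init__(self) -> None:
        endpoints = {p for e in self.ppis for p in e}
        if endpoints != self.members:
            raise ValueError("member set must equal the union of active PPI endpoints")
        if len(self.members) < 3:
            raise ValueError("verified complex needs >= 3 members")
        g = nx.Graph(self.ppis)
        if not nx.is_connected(g):
            raise ValueError("active-PPI graph must be connected")
        mediated = Counter(d.proteins for d in self.ddis)
        if set(mediated) != set(self.ppis) or any(c != 1 for c in mediated.values()):
            raise ValueError("every active PPI must be mediated by exactly one DDI")
        used: Counter = Counter()
        for d in self.ddis:
            used.update(d.endpoints)
        if any(c > 1 for c in used.values()):
            raise ValueError("a domain instance participates in more than one DDI")

    @property
    def size(self) -> int:
        return len(self.members)

    def sort_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def extract_verified(
    candidate: CandidateComplex,
    solution: BindingSolution,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[VerifiedComplex]:
    """Split the active-PPI graph into components and keep the large ones.

    A single candidate may yield zero, one, or several verified complexes.
    """
    if solution.model.members != candidate.members:
        raise ValueError("solution does not belong to this candidate's model")
    active_ppis = solution.active_ppis()
    if not active_ppis:
        return []
    g = nx.Graph(active_ppis)
    ddis_by_pair = {d.proteins: d for d in solution.active_ddis()}
    out: list[VerifiedComplex] = []
    for comp in nx.connected_components(g):
        if len(comp) < min_size:
            continue
        ppis = frozenset(e for e in active_ppis if e[0] in comp)
        out.append(
            VerifiedComplex(
                members=frozenset(comp),
                ppis=ppis,
                ddis=frozenset(ddis_by_pair[e] for e in ppis),
                objective=solution.objective,
                source=candidate.source,
            )
        )
    out.sort(key=VerifiedComplex.sort_key)
    return out


def verify_all(
    candidates: Sequence[CandidateComplex],
    network: InteractionNetwork,
    domains: DomainAnnotation,
    ddis: DDICatalog,
    min_size: int = DEFAULT_MIN_SIZE,
) -> tuple[list[VerifiedComplex], dict]:
    """Run build -> solve -> extract for every candidate and summarize.

    Verified complexes with identical member sets are deduplicated, keeping
    the record with the higher solver objective. The summary reports the
    candidate and complex counts, the reduction rate, and the verified size
    distribution. Candidates smaller than ``min_size`` are skipped (they can
    never produce an acceptable component).
    """
    kept: dict[frozenset[str], VerifiedComplex] = {}
    n_solved = 0
    n_failed = 0
    for cand in candidates:
        if cand.size < min_size:
            continue
        try:
            solution = solve(build_model(cand.members, network, domains, ddis, cand.source))
            n_solved += 1
        except Exception:  # pragma: no cover - per-candidate robustness
            logger.exception("candidate %s failed; skipping", sorted(cand.members))
            n_failed += 1
            continue
        for vc in extract_verified(cand, solution, min_size):
            prev = kept.get(vc.members)
            if prev is None or vc.objective > prev.objective:
                kept[vc.members] = vc

    verified = sorted(kept.values(), key=VerifiedComplex.sort_key)
    verified = [
        VerifiedComplex(
            vc.members, vc.ppis, vc.ddis, vc.objective, vc.source, complex_id=f"VC{i}"
        )
        for i, vc in enumerate(verified, start=1)
    ]
    n_cand = len(candidates)
    summary = {
        "n_candidates": n_cand,
        "n_candidates_eligible": sum(1 for c in candidates if c.size >= min_size),
        "n_solved": n_solved,
        "n_failed": n_failed,
        "n_verified": len(verified),
        "reduction_rate": (1 - len(verified) / n_cand) if n_cand else 0.0,
        "size_distribution": dict(sorted(Counter(vc.size for vc in verified).items())),
        "mean_size": (
            sum(vc.size for vc in verified) / len(verified) if verified else 0.0
        ),
    }
    return verified, summary


def format_summary(summary: dict) -> str:
    lines = [f"{k}\t{v}" for k, v in summary.items() if k != "size_distribution"]
    for size, count in summary.get("size_distribution", {}).items():
        lines.append(f"size_{size}\t{count}")
    return "\n".join(lines)
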