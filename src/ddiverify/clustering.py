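"""Step-1 candidate generation: dense regions of the PPI network.

Three sources of candidates are supported:

* :func:`mcl_cluster` — a deterministic Markov clustering (expansion by
  matrix squaring, entrywise inflation, column renormalization) run until
  convergence; clusters are read off attractor rows.
* :func:`cc_cluster` — seed-plus-neighborhood extraction around every
  protein whose local clustering coefficient clears a threshold.
* :func:`import_clusters` — consume cluster files produced by external
  tools (MCODE, command-line MCL, ...), one whitespace-separated cluster
  per line.

Candidates of any size are emitted; the verification stage skips those
below the minimum complex size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .io import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_INFLATION = 3.6  # granularity of Markov clustering
DEFAULT_CC_THRESHOLD = 0.4  # local clustering-coefficient cutoff

_PRUNE = 1e-5  # entries below this are zeroed each iteration
_CONVERGENCE = 1e-8  # max entrywise change declaring a steady state


@dataclass(frozen=True)
class CandidateComplex:
    """A protein set proposed by step 1, prior to verification."""

    members: frozenset[str]
    source: str  # mcl | cc | imported
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("candidate must have at least one member")

    @property
    def size(self) -> int:
        return len(self.members)

    def sort_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def mcl_cluster(
    network: InteractionNetwork,
    inflation: float = DEFAULT_INFLATION,
    max_iters: int = 200,
    prune_threshold: float = _PRUNE,
) -> list[CandidateComplex]:
    """Deterministic Markov clustering of the PPI network.

    The transition matrix starts from the adjacency matrix with unit
    self-loops, column-normalized. Each iteration squares the matrix
    (expansion), raises it entrywise to ``inflation`` and renormalizes
    columns (inflation), then prunes tiny entries. At the steady state,
    rows with mass on the diagonal are attractors; each attractor's row
    support is one cluster, attractors supporting each other are merged,
    and any protein claimed by several clusters is assigned to the
    lexicographically smallest one, so the output partitions the node set.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    if not network.proteins:
        raise ValueError("network is empty")

    nodes = sorted(network.proteins)
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b in network.edges:
        m[index[a], index[b]] = 1.0
        m[index[b], index[a]] = 1.0
    np.fill_diagonal(m, 1.0)  # self-loops stabilize odd-cycle oscillation
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iters):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < _CONVERGENCE:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iters)

    # attractors carry diagonal mass; merge attractor rows that overlap
    attractors = [i for i in range(n) if m[i, i] > 0]
    raw: list[set[int]] = []
    for i in attractors:
        support = set(np.nonzero(m[i])[0])
        support.add(i)
        merged = False
        for cluster in raw:
            if cluster & support:
                cluster |= support
                merged = True
                break
        if not merged:
            raw.append(support)
    # second pass in case late merges chained clusters together
    changed = True
    while changed:
        changed = False
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                if raw[i] & raw[j]:
                    raw[i] |= raw.pop(j)
                    changed = True
                    break
            if changed:
                break

    clusters = sorted((tuple(sorted(nodes[i] for i in c)) for c in raw))
    assigned: dict[str, tuple[str, ...]] = {}
    for c in clusters:  # lexicographically smallest cluster wins ties
        for p in c:
            assigned.setdefault(p, c)
    for p in nodes:  # nodes never reached by any attractor become singletons
        assigned.setdefault(p, (p,))

    final: dict[tuple[str, ...], set[str]] = {}
    for p, c in assigned.items():
        final.setdefault(c, set()).add(p)
    params = {"inflation": inflation}
    return [
        CandidateComplex(frozenset(members), "mcl", params)
        for _, members in sorted((tuple(sorted(v)), v) for v in final.values())
    ]


# ---------------------------------------------------------------------------
# clustering-coefficient extraction
# ---------------------------------------------------------------------------


def clustering_coefficient(network: InteractionNetwork, protein: str) -> float:
    """Local clustering coefficient; 0 for degree < 2."""
    if protein not in network.proteins:
        raise KeyError(f"unknown protein {protein!r}")
    return float(nx.clustering(network.to_networkx(), protein))


def cc_cluster(
    network: InteractionNetwork, threshold: float = DEFAULT_CC_THRESHOLD
) -> list[CandidateComplex]:
    """Seed-plus-neighborhood candidates around high-coefficient proteins.

    Every protein with degree >= 2 whose local clustering coefficient is at
    least ``threshold`` seeds one candidate consisting of itself and its
    neighbors; identical member sets are deduplicated and the output is
    sorted by member set.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    g = network.to_networkx()
    coeffs = nx.clustering(g)
    seen: set[frozenset[str]] = set()
    out: list[CandidateComplex] = []
    for v in g.nodes:
        if g.degree[v] >= 2 and coeffs[v] >= threshold:
            members = frozenset(g.neighbors(v)) | {v}
            if members not in seen:
                seen.add(members)
                out.append(CandidateComplex(members, "cc", {"threshold": threshold}))
    out.sort(key=CandidateComplex.sort_key)
    return out


# ---------------------------------------------------------------------------
# external cluster files
# ---------------------------------------------------------------------------


def import_clusters(path: str | Path, network: InteractionNetwork) -> list[CandidateComplex]:
    """Read one whitespace-separated cluster per line (MCL ``--abc`` dialect).

    Members absent from the network are dropped with a warning; lines left
    empty after filtering are skipped.
    """
    out: list[CandidateComplex] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            ids = line.split()
            known = [p for p in ids if p in network.proteins]
            dropped = set(ids) - set(known)
            if dropped:
                logger.warning(
                    "%s:%d: dropping %d member(s) not in network: %s",
                    path, lineno, len(dropped), ", ".join(sorted(dropped)),
                )
            if known:
                out.append(
                    CandidateComplex(frozenset(known), "imported", {"line": lineno})
                )
    return out


def write_clusters(candidates: list[CandidateComplex], path: str | Path) -> None:
    """Write candidates in the same one-cluster-per-line dialect."""
    with open(path, "wt", encoding="utf-8") as fh:
        for c in candidates:
            fh.write("\t".join(sorted(c.members)) + "\n")
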