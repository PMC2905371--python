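"""Synthetic benchmarks with planted ground truth.

The generator plants two kinds of cliques in a PPI network:

* **feasible complexes** — every clique pair is backed by its own dedicated
  domain-type pair, so each protein carries one fresh domain instance per
  partner and the whole clique can bind simultaneously. The feasibility
  witness (one DDI per clique edge, every instance used once) is built
  during generation and validated directly against the exclusivity and
  pair constraints — no solver is involved, so tests against the solver
  are not circular.
* **domain-starved decoys** — each clique member carries exactly one
  instance of a single promiscuous domain type, so exclusivity caps the
  number of simultaneously active PPIs at floor(size/2) and the decoy can
  never connect three proteins.

Background noise is an Erdős–Rényi layer of edges touching dedicated
background proteins, whose domains have no cataloged partner. The known
catalog lists exactly the planted feasible complexes, and GO gives every
planted complex one shared molecular-function term. Generation is a pure
function of the scenario seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from pathlib import Path

from .binding import BindingModel, BindingSolution, DDIVariable, build_model
from .io import (
    ComplexCatalog,
    DDICatalog,
    DomainAnnotation,
    DomainInstance,
    GOAnnotation,
    InteractionNetwork,
    canonical_pair,
    write_complex_catalog,
    write_ddi_catalog,
    write_domain_annotation,
    write_go_annotation,
    write_ppi_network,
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one planted benchmark.

    Defaults give a small but non-trivial study: ten feasible complexes of
    3-5 proteins, ten equally sized decoys, and a sparse random background.
    """

    n_true_complexes: int = 10
    size_range: tuple[int, int] = (3, 5)
    n_decoys: int = 10
    n_background: int = 50
    background_edge_p: float = 0.02
    decoy_mode: str = "single-domain"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_true_complexes, self.n_decoys, self.n_background) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.background_edge_p <= 1:
            raise ValueError("background_edge_p must be in [0,1]")
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError(f"size range must satisfy 3 <= lo <= hi, got {self.size_range}")
        if self.decoy_mode != "single-domain":
            raise ValueError(f"unknown decoy mode {self.decoy_mode!r}")


@dataclass(frozen=True)
class SyntheticData:
    """The five generated inputs plus the planted truth bookkeeping."""

    network: InteractionNetwork
    domains: DomainAnnotation
    ddis: DDICatalog
    known: ComplexCatalog
    go: GOAnnotation
    true_complexes: tuple[frozenset[str], ...]
    decoys: tuple[frozenset[str], ...]
    #: per true complex: the constructed witness assignment, one DDI per edge
    witnesses: tuple[tuple[DDIVariable, ...], ...]

    def as_inputs(self):
        return self.network, self.domains, self.ddis, self.known, self.go


def _validate_witness(members: frozenset[str], witness: tuple[DDIVariable, ...]) -> None:
    """Check the constructed assignment covers every clique pair exactly once
    while using each domain instance at most once."""
    pairs = {d.proteins for d in witness}
    expected = {
        canonical_pair(a, b)
        for a in members
        for b in members
        if a < b
    }
    if pairs != expected or len(witness) != len(expected):
        raise AssertionError("witness does not cover the clique pairs exactly once")
    seen: set[tuple[str, DomainInstance]] = set()
    for d in witness:
        for endpoint in d.endpoints:
            if endpoint in seen:
                raise AssertionError("witness reuses a domain instance")
            seen.add(endpoint)


def generate(scenario: SyntheticScenario) -> SyntheticData:
    """Generate the five pipeline inputs with planted ground truth."""
    rng = random.Random(scenario.seed)
    lo, hi = scenario.size_range

    edges: set[tuple[str, str]] = set()
    proteins: list[str] = []
    domain_counts: dict[str, dict[str, int]] = {}
    catalog: set[tuple[str, str]] = set()
    go_terms: dict[str, set[str]] = {}
    known_entries: list[tuple[str, frozenset[str]]] = []
    true_sets: list[frozenset[str]] = []
    decoy_sets: list[frozenset[str]] = []
    witnesses: list[tuple[DDIVariable, ...]] = []

    def add_protein(name: str) -> None:
        proteins.append(name)
        domain_counts.setdefault(name, {})
        go_terms.setdefault(name, set())

    # planted feasible complexes: one dedicated homotypic type per clique edge
    for i in range(scenario.n_true_complexes):
        size = rng.randint(lo, hi)
        members = [f"TC{i}_P{j}" for j in range(size)]
        for m in members:
            add_protein(m)
            go_terms[m].add(f"GO:{i + 1:07d}")  # shared function term
        witness: list[DDIVariable] = []
        for k, (a, b) in enumerate(
            (x, y) for xi, x in enumerate(members) for y in members[xi + 1 :]
        ):
            edges.add(canonical_pair(a, b))
            dtype = f"FT{i}_{k}"
            domain_counts[a][dtype] = 1
            domain_counts[b][dtype] = 1
            catalog.add((dtype, dtype))
            pa, pb = canonical_pair(a, b)
            witness.append(
                DDIVariable((pa, pb), DomainInstance(dtype, 1), DomainInstance(dtype, 1))
            )
        fs = frozenset(members)
        _validate_witness(fs, tuple(witness))
        true_sets.append(fs)
        witnesses.append(tuple(witness))
        known_entries.append((f"TRUE{i}", fs))

    # domain-starved decoys: one shared single-copy domain per clique
    for i in range(scenario.n_decoys):
        size = rng.randint(lo, hi)
        members = [f"DC{i}_P{j}" for j in range(size)]
        dtype = f"DT{i}"
        for m in members:
            add_protein(m)
            domain_counts[m][dtype] = 1
            go_terms[m].add(f"GO:{5000000 + rng.randrange(100):07d}")
        catalog.add((dtype, dtype))
        for xi, a in enumerate(members):
            for b in members[xi + 1 :]:
                edges.add(canonical_pair(a, b))
        decoy_sets.append(frozenset(members))

    # background proteins: domains with no cataloged partner, random GO
    for j in range(scenario.n_background):
        name = f"BG{j}"
        add_protein(name)
        domain_counts[name][f"BGDOM{rng.randrange(20)}"] = 1
        go_terms[name].add(f"GO:{5000000 + rng.randrange(100):07d}")

    # Erdős–Rényi noise over pairs touching at least one background protein
    background = [p for p in proteins if p.startswith("BG")]
    others = [p for p in proteins if not p.startswith("BG")]
    if scenario.background_edge_p > 0 and background:
        for xi, a in enumerate(background):
            for b in background[xi + 1 :]:
                if rng.random() < scenario.background_edge_p:
                    edges.add(canonical_pair(a, b))
            for b in others:
                if rng.random() < scenario.background_edge_p:
                    edges.add(canonical_pair(a, b))

    if not edges:
        raise ValueError("scenario generated an empty network; increase counts")

    network = InteractionNetwork.from_edges(edges, extra_proteins=proteins)
    data = SyntheticData(
        network=network,
        domains=DomainAnnotation.from_counts(domain_counts),
        ddis=DDICatalog.from_pairs(catalog),
        known=ComplexCatalog(tuple(known_entries)),
        go=GOAnnotation({g: frozenset(t) for g, t in go_terms.items() if t}),
        true_complexes=tuple(true_sets),
        decoys=tuple(decoy_sets),
        witnesses=tuple(witnesses),
    )
    # every planted complex must admit its full-clique assignment
    for members, witness in zip(data.true_complexes, data.witnesses):
        model = build_model(members, network, data.domains, data.ddis)
        index = {v: k for k, v in enumerate(model.ddi_vars)}
        values = [0] * model.n_ddi_vars
        for d in witness:
            values[index[d]] = 1
        BindingSolution(model, tuple(values)).validate()
    return data


def write_scenario(data: SyntheticData, out_dir: str | Path) -> dict[str, Path]:
    """Write the five inputs as TSVs into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out / "ppi.tsv",
        "domains": out / "domains.tsv",
        "ddis": out / "ddis.tsv",
        "known": out / "known_complexes.tsv",
        "go": out / "go.tsv",
    }
    write_ppi_network(data.network, paths["ppi"])
    write_domain_annotation(data.domains, paths["domains"])
    write_ddi_catalog(data.ddis, paths["ddis"])
    write_complex_catalog(data.known, paths["known"])
    write_go_annotation(data.go, paths["go"])
    return paths


# ---------------------------------------------------------------------------
# canonical worked examples
# ---------------------------------------------------------------------------


def worked_example() -> tuple[InteractionNetwork, DomainAnnotation, DDICatalog]:
    """Three proteins, two PPIs, four potential DDIs.

    p1 carries domains d1 and d4; p2 carries d2; p3 carries d3. Both
    p1-p2 and p1-p3 are potential PPIs, and the catalog allows d1-d2,
    d4-d2, d1-d3 and d4-d3, so each PPI can be mediated by either of p1's
    two domains. Both PPIs are simultaneously realizable (objective 2) by
    using d1 for one partner and d4 for the other.
    """
    network = InteractionNetwork.from_edges([("p1", "p2"), ("p1", "p3")])
    domains = DomainAnnotation.from_counts(
        {"p1": {"d1": 1, "d4": 1}, "p2": {"d2": 1}, "p3": {"d3": 1}}
    )
    catalog = DDICatalog.from_pairs([("d1", "d2"), ("d4", "d2"), ("d1", "d3"), ("d4", "d3")])
    return network, domains, catalog


def starved_triangle() -> tuple[InteractionNetwork, DomainAnnotation, DDICatalog]:
    """A triangle decoy: one promiscuous domain per protein.

    All three pairwise PPIs are potential and every domain pair is allowed,
    but exclusivity lets at most one DDI be active at a time (objective 1),
    so the triangle can never be verified.
    """
    network = InteractionNetwork.from_edges([("q1", "q2"), ("q1", "q3"), ("q2", "q3")])
    domains = DomainAnnotation.from_counts({"q1": {"e": 1}, "q2": {"e": 1}, "q3": {"e": 1}})
    catalog = DDICatalog.from_pairs([("e", "e")])
    return network, domains, catalog


def feasible_triangle() -> tuple[InteractionNetwork, DomainAnnotation, DDICatalog]:
    """A triangle where every protein has enough domains to bind both partners."""
    network = InteractionNetwork.from_edges([("q1", "q2"), ("q1", "q3"), ("q2", "q3")])
    domains = DomainAnnotation.from_counts(
        {"q1": {"e12": 1, "e13": 1}, "q2": {"e12": 1, "e23": 1}, "q3": {"e13": 1, "e23": 1}}
    )
    catalog = DDICatalog.from_pairs([("e12", "e12"), ("e13", "e13"), ("e23", "e23")])
    return network, domains, catalog
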