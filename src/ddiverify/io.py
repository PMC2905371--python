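"""Readers and writers for the tabular formats used throughout the pipeline.

All inputs are plain TSV with ``#``-prefixed comment lines and no quoting:

* **PPI network** — two protein identifiers per row, optional third column
  carrying the experiment-system label (BioGrid-style export).
* **Domain annotation** — protein id, domain-type id, optional copy count.
* **DDI catalog** — two domain-type ids per row, optional source label.
* **Known complexes** — complex id, comma-separated member list.
* **GO annotation** — gene id, GO term id, optional aspect column
  (only molecular-function rows are kept).

Identifiers are opaque, case-sensitive strings; no id mapping is performed.
Every reader canonicalizes its output (unordered pairs stored with the
lexicographically smaller id first, duplicates collapsed) and raises
:class:`FormatError` with the offending line number on malformed input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

logger = logging.getLogger(__name__)

#: GO term ids that mean "molecular function unknown"; proteins carrying one
#: of these are treated as uncharacterized.
UNKNOWN_FUNCTION_TERMS = frozenset({"GO:0003674", "GO:0005554"})

_GO_TERM_RE = re.compile(r"^GO:\d{7}$")

#: Aspect labels accepted as the molecular-function namespace.
_MF_ASPECTS = frozenset({"F", "MF", "molecular_function", "Function"})


class FormatError(ValueError):
    """Malformed input file; the message names the file and line number."""


class DomainInstance(NamedTuple):
    """One copy of a domain type within a protein."""

    domain_type: str
    copy: int  # 1-based copy index

    def __str__(self) -> str:  # "PF00001:2"
        return f"{self.domain_type}:{self.copy}"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) with the smaller id first."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionNetwork:
    """An undirected PPI network: the potential-interaction set Omega.

    ``edges`` holds canonically ordered pairs; self-loops are rejected and
    every endpoint must appear in ``proteins``.
    """

    proteins: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge ({a},{b}) not allowed")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"edge ({a},{b}) not canonically ordered")
            if a not in self.proteins or b not in self.proteins:
                raise ValueError(f"edge ({a},{b}) has endpoint outside protein set")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], extra_proteins: Iterable[str] = ()
    ) -> "InteractionNetwork":
        canon = {canonical_pair(a, b) for a, b in edges if a != b}
        proteins = {p for e in canon for p in e} | set(extra_proteins)
        return cls(frozenset(proteins), frozenset(canon))

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def neighbors(self, protein: str) -> set[str]:
        if protein not in self.proteins:
            raise KeyError(protein)
        out: set[str] = set()
        for a, b in self.edges:
            if a == protein:
                out.add(b)
            elif b == protein:
                out.add(a)
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.proteins))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class DomainAnnotation:
    """Map protein id -> tuple of domain instances.

    Copy indices for each (protein, domain-type) run 1..n with no gaps, so a
    protein carrying two copies of PF00001 holds (PF00001,1) and (PF00001,2).
    """

    instances: Mapping[str, tuple[DomainInstance, ...]]

    def __post_init__(self) -> None:
        for protein, insts in self.instances.items():
            if len(set(insts)) != len(insts):
                raise ValueError(f"duplicate domain instance on {protein}")
            counts: dict[str, list[int]] = {}
            for inst in insts:
                counts.setdefault(inst.domain_type, []).append(inst.copy)
            for dtype, copies in counts.items():
                if sorted(copies) != list(range(1, len(copies) + 1)):
                    raise ValueError(
                        f"copy indices for ({protein},{dtype}) are not 1..n: {sorted(copies)}"
                    )

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, int]]) -> "DomainAnnotation":
        """Build from {protein: {domain_type: copy_count}}."""
        out: dict[str, tuple[DomainInstance, ...]] = {}
        for protein in sorted(counts):
            insts = [
                DomainInstance(dtype, i)
                for dtype in sorted(counts[protein])
                for i in range(1, counts[protein][dtype] + 1)
            ]
            out[protein] = tuple(insts)
        return cls(out)

    def domains_of(self, protein: str) -> tuple[DomainInstance, ...]:
        return self.instances.get(protein, ())

    @property
    def proteins(self) -> set[str]:
        return set(self.instances)


@dataclass(frozen=True)
class DDICatalog:
    """The universe of allowed domain-type pairs (potential DDIs).

    Pairs are unordered and canonically stored; homotypic pairs (d, d) are
    allowed. ``sources`` optionally labels where each pair came from.
    """

    pairs: frozenset[tuple[str, str]]
    sources: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"DDI pair ({a},{b}) not canonically ordered")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DDICatalog":
        return cls(frozenset(canonical_pair(a, b) for a, b in pairs))

    def allows(self, type_a: str, type_b: str) -> bool:
        return canonical_pair(type_a, type_b) in self.pairs


@dataclass(frozen=True)
class ComplexCatalog:
    """Known complexes: (complex id, member protein set) records."""

    entries: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate complex ids in catalog")
        for cid, members in self.entries:
            if not members:
                raise ValueError(f"complex {cid} has no members")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self.entries)

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.entries]


@dataclass(frozen=True)
class GOAnnotation:
    """Gene id -> molecular-function GO term ids (flat, no ontology walk)."""

    terms: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, terms in self.terms.items():
            for t in terms:
                if not _GO_TERM_RE.match(t):
                    raise ValueError(f"invalid GO term id {t!r} on {gene}")

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.terms.get(gene, frozenset())

    def known_terms_of(self, gene: str) -> frozenset[str]:
        """Terms excluding the 'molecular function unknown' placeholders."""
        return self.terms_of(gene) - UNKNOWN_FUNCTION_TERMS

    def is_uncharacterized(self, gene: str) -> bool:
        """True when the gene carries an unknown-function placeholder term."""
        return bool(self.terms_of(gene) & UNKNOWN_FUNCTION_TERMS)


# ---------------------------------------------------------------------------
# low-level TSV scanning
# ---------------------------------------------------------------------------


def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _fail(path: str | Path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_ppi_network(
    path: str | Path, experiment_systems: set[str] | None = None
) -> InteractionNetwork:
    """Read a PPI edge list, dropping self-loops and collapsing duplicates.

    When ``experiment_systems`` is given, only rows whose third column is in
    the allowed set are kept (rows without a system column are dropped).
    An empty resulting network is a hard error.
    """
    edges: set[tuple[str, str]] = set()
    proteins: set[str] = set()
    n_loops = n_dups = n_filtered = 0
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            _fail(path, lineno, f"expected >=2 tab-separated columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            _fail(path, lineno, "empty protein identifier")
        if experiment_systems is not None:
            system = fields[2].strip() if len(fields) >= 3 else None
            if system not in experiment_systems:
                n_filtered += 1
                continue
        if a == b:
            n_loops += 1
            continue
        pair = canonical_pair(a, b)
        if pair in edges:
            n_dups += 1
            continue
        edges.add(pair)
        proteins.update(pair)
    logger.info(
        "read_ppi_network(%s): %d edges, %d proteins (%d self-loops, "
        "%d duplicates, %d system-filtered rows dropped)",
        path, len(edges), len(proteins), n_loops, n_dups, n_filtered,
    )
    if not edges:
        raise FormatError(f"{path}: no usable PPI rows after filtering")
    return InteractionNetwork(frozenset(proteins), frozenset(edges))


def read_domain_annotation(path: str | Path) -> DomainAnnotation:
    """Read (protein, domain-type[, count]) rows into copy-indexed instances.

    Repeated rows for the same (protein, domain-type) accumulate their
    counts. An empty file yields an empty annotation with a warning.
    """
    counts: dict[str, dict[str, int]] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            _fail(path, lineno, f"expected >=2 tab-separated columns, got {len(fields)}")
        protein, dtype = fields[0].strip(), fields[1].strip()
        if not protein or not dtype:
            _fail(path, lineno, "empty identifier")
        count = 1
        if len(fields) >= 3 and fields[2].strip():
            try:
                count = int(fields[2])
            except ValueError:
                _fail(path, lineno, f"count column is not an integer: {fields[2]!r}")
            if count < 1:
                _fail(path, lineno, f"count must be >= 1, got {count}")
        counts.setdefault(protein, {}).setdefault(dtype, 0)
        counts[protein][dtype] += count
    if not counts:
        logger.warning("read_domain_annotation(%s): empty annotation", path)
    return DomainAnnotation.from_counts(counts)


def read_ddi_catalog(path: str | Path) -> DDICatalog:
    """Read domain-type pair rows (optional third column = source label)."""
    pairs: set[tuple[str, str]] = set()
    sources: dict[tuple[str, str], str] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            _fail(path, lineno, f"expected >=2 tab-separated columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            _fail(path, lineno, "empty domain identifier")
        pair = canonical_pair(a, b)
        pairs.add(pair)
        if len(fields) >= 3 and fields[2].strip():
            sources[pair] = fields[2].strip()
    logger.info("read_ddi_catalog(%s): %d pairs", path, len(pairs))
    return DDICatalog(frozenset(pairs), sources)


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Read (complex id, comma-separated member list) rows."""
    entries: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            _fail(path, lineno, f"expected 2 tab-separated columns, got {len(fields)}")
        cid = fields[0].strip()
        members = frozenset(m.strip() for m in fields[1].split(",") if m.strip())
        if not cid:
            _fail(path, lineno, "empty complex id")
        if cid in seen:
            _fail(path, lineno, f"duplicate complex id {cid!r}")
        if not members:
            _fail(path, lineno, f"complex {cid!r} has no members")
        seen.add(cid)
        entries.append((cid, members))
    return ComplexCatalog(tuple(entries))


def read_go_annotation(path: str | Path) -> GOAnnotation:
    """Read (gene, GO term[, aspect]) rows, keeping molecular-function rows.

    Rows with no aspect column are assumed to be molecular-function terms.
    """
    terms: dict[str, set[str]] = {}
    n_dropped = 0
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            _fail(path, lineno, f"expected >=2 tab-separated columns, got {len(fields)}")
        gene, term = fields[0].strip(), fields[1].strip()
        if not _GO_TERM_RE.match(term):
            _fail(path, lineno, f"invalid GO term id {term!r}")
        if len(fields) >= 3 and fields[2].strip() and fields[2].strip() not in _MF_ASPECTS:
            n_dropped += 1
            continue
        terms.setdefault(gene, set()).add(term)
    logger.info(
        "read_go_annotation(%s): %d genes (%d non-MF rows dropped)",
        path, len(terms), n_dropped,
    )
    return GOAnnotation({g: frozenset(t) for g, t in terms.items()})


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_ppi_network(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
        # isolated proteins round-trip as degenerate self-referential comments
        isolated = network.proteins - {p for e in network.edges for p in e}
        for p in sorted(isolated):
            fh.write(f"# isolated\t{p}\n")


def write_domain_annotation(annotation: DomainAnnotation, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# protein\tdomain_type\tcount\n")
        for protein in sorted(annotation.instances):
            counts: dict[str, int] = {}
            for inst in annotation.instances[protein]:
                counts[inst.domain_type] = max(counts.get(inst.domain_type, 0), inst.copy)
            for dtype in sorted(counts):
                fh.write(f"{protein}\t{dtype}\t{counts[dtype]}\n")


def write_ddi_catalog(catalog: DDICatalog, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# domain_a\tdomain_b\tsource\n")
        for a, b in sorted(catalog.pairs):
            src = catalog.sources.get((a, b), "")
            fh.write(f"{a}\t{b}\t{src}\n" if src else f"{a}\t{b}\n")


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# complex_id\tmembers\n")
        for cid, members in catalog:
            fh.write(f"{cid}\t{','.join(sorted(members))}\n")


def write_go_annotation(annotation: GOAnnotation, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# gene\tgo_term\taspect\n")
        for gene in sorted(annotation.terms):
            for term in sorted(annotation.terms[gene]):
                fh.write(f"{gene}\t{term}\tF\n")


# ---------------------------------------------------------------------------
# verified-complex block format
# ---------------------------------------------------------------------------
# One block per complex:
#   >id  objective=<int>  source=<label>
#   M <protein>                      (one per member)
#   PPI <protein_a> <protein_b>
#   DDI <protein_a> <type:copy> <protein_b> <type:copy>


def write_verified_complexes(complexes: Sequence, path: str | Path) -> None:
    """Serialize verified complexes; round-trips through the companion reader."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# verified complexes\n")
        for i, vc in enumerate(complexes, start=1):
            fh.write(f">{vc.complex_id or f'VC{i}'}\tobjective={vc.objective}\tsource={vc.source}\n")
            for p in sorted(vc.members):
                fh.write(f"M\t{p}\n")
            for a, b in sorted(vc.ppis):
                fh.write(f"PPI\t{a}\t{b}\n")
            for ddi in sorted(vc.ddis):
                (a, b), ia, ib = ddi.proteins, ddi.instance_a, ddi.instance_b
                fh.write(f"DDI\t{a}\t{ia}\t{b}\t{ib}\n")


def _parse_instance(token: str, path: str | Path, lineno: int) -> DomainInstance:
    dtype, sep, copy = token.rpartition(":")
    if not sep or not copy.isdigit():
        _fail(path, lineno, f"bad domain instance token {token!r}")
    return DomainInstance(dtype, int(copy))


def read_verified_complexes(path: str | Path) -> list:
    """Read the block format written by :func:`write_verified_complexes`."""
    from .verification import VerifiedComplex
    from .binding import DDIVariable

    out: list[VerifiedComplex] = []
    header: tuple[str, int, str] | None = None
    members: set[str] = set()
    ppis: set[tuple[str, str]] = set()
    ddis: set[DDIVariable] = set()

    def flush() -> None:
        nonlocal header
        if header is None:
            return
        cid, objective, source = header
        out.append(
            VerifiedComplex(
                members=frozenset(members),
                ppis=frozenset(ppis),
                ddis=frozenset(ddis),
                objective=objective,
                source=source,
                complex_id=cid,
            )
        )
        header = None
        members.clear()
        ppis.clear()
        ddis.clear()

    for lineno, fields in _rows(path):
        tag = fields[0]
        if tag.startswith(">"):
            flush()
            cid = tag[1:]
            objective, source = 0, ""
            for f in fields[1:]:
                key, _, val = f.partition("=")
                if key == "objective":
                    objective = int(val)
                elif key == "source":
                    source = val
            header = (cid, objective, source)
        elif tag == "M":
            members.add(fields[1])
        elif tag == "PPI":
            ppis.add(canonical_pair(fields[1], fields[2]))
        elif tag == "DDI":
            a, ia, b, ib = fields[1], fields[2], fields[3], fields[4]
            ddis.add(
                DDIVariable.make(
                    a, _parse_instance(ia, path, lineno),
                    b, _parse_instance(ib, path, lineno),
                )
            )
        else:
            _fail(path, lineno, f"unknown record tag {tag!r}")
    flush()
    return out
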