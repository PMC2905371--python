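"""Per-candidate binary integer program over domain-domain interactions.

Given a candidate complex, the potential-PPI set Omega, per-protein domain
instances and a catalog of allowed domain-type pairs, the model decides which
DDIs can be simultaneously active under binding-interface exclusivity:

* one binary PPI variable ``P(i,j)`` per candidate pair present in Omega;
* one binary DDI variable ``D(i,j,k)`` per pair of domain instances — one in
  protein ``i``, one in protein ``j`` — whose types form a cataloged pair;
* a pair constraint ``P(i,j) = sum_k D(i,j,k)`` (because P is binary this
  also forbids two simultaneous DDIs across the same protein pair);
* an exclusivity constraint ``sum(D containing instance d) <= 1`` for every
  domain instance, encoding that one binding interface engages one partner
  at a time.

The objective maximizes the number of realized PPIs. ``solve`` uses an exact
0/1 solver (HiGHS via ``scipy.optimize.milp``); ``solve_bruteforce`` is the
independent enumeration oracle. Both apply the same deterministic tie-break:
among co-optimal solutions, the lexicographically smallest assignment over
DDI variables sorted by (protein pair, instance pair).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .io import (
    DDICatalog,
    DomainAnnotation,
    DomainInstance,
    InteractionNetwork,
    canonical_pair,
)


@dataclass(frozen=True, order=True)
class DDIVariable:
    """A potential DDI between one domain instance in each of two proteins.

    ``proteins`` is the canonical (sorted) protein pair; ``instance_a``
    belongs to ``proteins[0]`` and ``instance_b`` to ``proteins[1]``. The
    two proteins are always distinct: intra-protein binding is not modeled.
    """

    proteins: tuple[str, str]
    instance_a: DomainInstance
    instance_b: DomainInstance

    def __post_init__(self) -> None:
        if self.proteins[0] == self.proteins[1]:
            raise ValueError("DDI variable must span two distinct proteins")
        if self.proteins != canonical_pair(*self.proteins):
            raise ValueError("protein pair must be canonically ordered")

    @classmethod
    def make(
        cls, protein_a: str, instance_a: DomainInstance, protein_b: str, instance_b: DomainInstance
    ) -> "DDIVariable":
        if (protein_a, protein_b) == canonical_pair(protein_a, protein_b):
            return cls((protein_a, protein_b), instance_a, instance_b)
        return cls((protein_b, protein_a), instance_b, instance_a)

    @property
    def endpoints(self) -> tuple[tuple[str, DomainInstance], tuple[str, DomainInstance]]:
        return (self.proteins[0], self.instance_a), (self.proteins[1], self.instance_b)


@dataclass(frozen=True)
class BindingModel:
    """The assembled binary program for one candidate complex.

    ``ppi_pairs`` are the candidate pairs found in Omega; pairs without any
    cognate DDI variable have their P variable implicitly fixed to 0.
    ``ddi_vars`` is sorted by (protein pair, instance pair) — the order the
    tie-break rule refers to.
    """

    members: frozenset[str]
    ppi_pairs: tuple[tuple[str, str], ...]
    ddi_vars: tuple[DDIVariable, ...]
    source: str = ""

    @property
    def n_ddi_vars(self) -> int:
        return len(self.ddi_vars)

    @property
    def vars_by_pair(self) -> dict[tuple[str, str], list[int]]:
        out: dict[tuple[str, str], list[int]] = {pair: [] for pair in self.ppi_pairs}
        for k, var in enumerate(self.ddi_vars):
            out[var.proteins].append(k)
        return out

    @property
    def vars_by_instance(self) -> dict[tuple[str, DomainInstance], list[int]]:
        out: dict[tuple[str, DomainInstance], list[int]] = {}
        for k, var in enumerate(self.ddi_vars):
            for endpoint in var.endpoints:
                out.setdefault(endpoint, []).append(k)
        return out

    @property
    def exclusivity_constraints(self) -> dict[tuple[str, DomainInstance], list[int]]:
        """Non-redundant exclusivity constraints.

        An instance whose DDI variables all connect the same protein pair is
        already capped at one active DDI by the binary pair equality, so only
        instances shared across two or more pairs contribute a constraint of
        their own.
        """
        return {
            endpoint: ks
            for endpoint, ks in self.vars_by_instance.items()
            if len(ks) >= 2
            and len({self.ddi_vars[k].proteins for k in ks}) >= 2
        }

    def constraint_strings(self) -> list[str]:
        """Human-readable LP-style dump of objective and constraints."""
        lines = [
            "maximize  " + " + ".join(f"P({a},{b})" for a, b in self.ppi_pairs)
            if self.ppi_pairs
            else "maximize  0"
        ]
        by_pair = self.vars_by_pair
        for pair in self.ppi_pairs:
            ks = by_pair[pair]
            if ks:
                rhs = " + ".join(self._dname(k) for k in ks)
                lines.append(f"P({pair[0]},{pair[1]}) = {rhs}")
            else:
                lines.append(f"P({pair[0]},{pair[1]}) = 0")
        for (protein, inst), ks in sorted(self.exclusivity_constraints.items()):
            lhs = " + ".join(self._dname(k) for k in ks)
            lines.append(f"{lhs} <= 1    [exclusivity of {protein}/{inst}]")
        return lines

    def _dname(self, k: int) -> str:
        v = self.ddi_vars[k]
        return f"D({v.proteins[0]}/{v.instance_a},{v.proteins[1]}/{v.instance_b})"


@dataclass(frozen=True)
class BindingSolution:
    """An optimal 0/1 assignment for a :class:`BindingModel`.

    ``objective`` equals the number of realized PPIs, which under the pair
    equality also equals the number of active DDIs.
    """

    model: BindingModel
    ddi_values: tuple[int, ...]
    status: str = "optimal"

    @property
    def objective(self) -> int:
        return sum(self.ddi_values)

    def active_ddis(self) -> list[DDIVariable]:
        return [v for v, x in zip(self.model.ddi_vars, self.ddi_values) if x]

    def active_ppis(self) -> list[tuple[str, str]]:
        by_pair = self.model.vars_by_pair
        return [
            pair
            for pair in self.model.ppi_pairs
            if any(self.ddi_values[k] for k in by_pair[pair])
        ]

    def ppi_values(self) -> dict[tuple[str, str], int]:
        active = set(self.active_ppis())
        return {pair: int(pair in active) for pair in self.model.ppi_pairs}

    def validate(self) -> None:
        """Re-check every constraint directly from the assignment."""
        if any(x not in (0, 1) for x in self.ddi_values):
            raise AssertionError("non-binary DDI value")
        for pair, ks in self.model.vars_by_pair.items():
            if sum(self.ddi_values[k] for k in ks) > 1:
                raise AssertionError(f"pair constraint violated on {pair}")
        for endpoint, ks in self.model.vars_by_instance.items():
            if sum(self.ddi_values[k] for k in ks) > 1:
                raise AssertionError(f"exclusivity violated on {endpoint}")

    def summary(self) -> str:
        lines = [
            f"candidate members : {', '.join(sorted(self.model.members))}",
            f"potential PPIs    : {len(self.model.ppi_pairs)}",
            f"DDI variables     : {self.model.n_ddi_vars}",
            f"objective (PPIs)  : {self.objective}",
            f"status            : {self.status}",
        ]
        for v in self.active_ddis():
            lines.append(
                f"  active DDI {v.proteins[0]}/{v.instance_a} -- {v.proteins[1]}/{v.instance_b}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def build_model(
    candidate: Iterable[str],
    network: InteractionNetwork,
    domains: DomainAnnotation,
    ddis: DDICatalog,
    source: str = "",
) -> BindingModel:
    """Assemble the binary program for one candidate complex.

    P variables are created exactly for candidate pairs present in Omega;
    D variables enumerate all cross-protein instance combinations whose
    domain-type pair is cataloged.
    """
    members = frozenset(candidate)
    if len(members) < 2:
        raise ValueError(f"candidate must contain at least 2 proteins, got {len(members)}")
    missing = members - network.proteins
    if missing:
        raise ValueError(f"candidate members not in network: {sorted(missing)}")

    pairs = tuple(
        sorted(
            canonical_pair(a, b)
            for a, b in itertools.combinations(sorted(members), 2)
            if network.has_edge(a, b)
        )
    )
    ddi_vars: list[DDIVariable] = []
    for a, b in pairs:
        for inst_a in domains.domains_of(a):
            for inst_b in domains.domains_of(b):
                if ddis.allows(inst_a.domain_type, inst_b.domain_type):
                    ddi_vars.append(DDIVariable((a, b), inst_a, inst_b))
    return BindingModel(members, pairs, tuple(sorted(set(ddi_vars))), source=source)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _constraint_matrix(model: BindingModel) -> csr_matrix | None:
    """Rows = pair and exclusivity constraints, columns = DDI variables.

    Every row has right-hand side <= 1; rows with a single entry are
    redundant for 0/1 variables but kept for the oracle's feasibility check.
    """
    n = model.n_ddi_vars
    if n == 0:
        return None
    rows: list[int] = []
    cols: list[int] = []
    r = 0
    for ks in model.vars_by_pair.values():
        if ks:
            rows.extend([r] * len(ks))
            cols.extend(ks)
            r += 1
    for ks in model.vars_by_instance.values():
        rows.extend([r] * len(ks))
        cols.extend(ks)
        r += 1
    data = np.ones(len(rows), dtype=np.int8)
    return csr_matrix((data, (rows, cols)), shape=(r, n))


def solve_bruteforce(model: BindingModel, max_vars: int = 20) -> BindingSolution:
    """Exhaustive enumeration over all 2^n DDI assignments.

    Serves as the independent oracle for :func:`solve`; applies the same
    lexicographic tie-break (first DDI variable is the most significant bit,
    so the smallest feasible-and-optimal integer encodes the winner).
    """
    n = model.n_ddi_vars
    if n > max_vars:
        raise ValueError(
            f"{n} DDI variables exceed max_vars={max_vars}; use solve() instead"
        )
    if n == 0:
        return BindingSolution(model, ())

    A = _constraint_matrix(model).toarray().astype(np.int32)
    # bit j of the assignment index encodes DDI variable j, MSB-first
    shifts = np.arange(n - 1, -1, -1, dtype=np.uint32)
    best_obj = -1
    best_code = 0
    chunk = 1 << 16
    for start in range(0, 1 << n, chunk):
        codes = np.arange(start, min(start + chunk, 1 << n), dtype=np.uint32)
        bits = ((codes[:, None] >> shifts[None, :]) & 1).astype(np.int32)
        feasible = (bits @ A.T <= 1).all(axis=1)
        if not feasible.any():
            continue
        objs = bits.sum(axis=1)
        objs[~feasible] = -1
        i = int(objs.argmax())  # argmax returns the first (lex-smallest) max
        if objs[i] > best_obj:
            best_obj = int(objs[i])
            best_code = int(codes[i])
    values = tuple(int((best_code >> int(s)) & 1) for s in shifts)
    return BindingSolution(model, values)


def _milp_optimum(
    A: csr_matrix, n: int, fixed: Mapping[int, int]
) -> tuple[int, np.ndarray] | None:
    """Maximize sum(x) s.t. A x <= 1, x binary, with some entries fixed."""
    lb = np.zeros(n)
    ub = np.ones(n)
    for k, v in fixed.items():
        lb[k] = ub[k] = v
    res = milp(
        c=-np.ones(n),
        constraints=LinearConstraint(A, -np.inf, 1),
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
    )
    if not res.success:
        return None
    x = np.rint(res.x).astype(int)
    return int(x.sum()), x


def solve(model: BindingModel) -> BindingSolution:
    """Exact maximization via 0/1 integer programming (HiGHS backend).

    The program is never infeasible (all-zero is feasible). After finding
    the optimal objective, variables are fixed one by one in sorted order to
    return the lexicographically smallest co-optimal assignment, matching
    the enumeration oracle exactly.
    """
    n = model.n_ddi_vars
    if n == 0:
        return BindingSolution(model, ())
    A = _constraint_matrix(model)
    first = _milp_optimum(A, n, {})
    assert first is not None, "0/1 program with all-zero feasible point must solve"
    best_obj, x = first

    fixed: dict[int, int] = {}
    for k in range(n):
        if x[k] == 0:
            fixed[k] = 0  # current witness already has 0 here
            continue
        trial = _milp_optimum(A, n, {**fixed, k: 0})
        if trial is not None and trial[0] == best_obj:
            fixed[k] = 0
            x = trial[1]
        else:
            fixed[k] = 1
    values = tuple(fixed[k] for k in range(n))
    solution = BindingSolution(model, values)
    solution.validate()
    assert solution.objective == best_obj
    return solution
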