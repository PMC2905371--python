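import random

import pytest

import ddiverify as dv
from ddiverify.binding import DDIVariable

from conftest import random_model


class TestBuildModel:
    def test_worked_example_variable_counts(self, example_model):
        assert len(example_model.ppi_pairs) == 2
        assert example_model.n_ddi_vars == 4

    def test_worked_example_pair_constraints(self, example_model):
        by_pair = example_model.vars_by_pair
        # P(p1,p2) = sum of two DDI variables, likewise P(p1,p3)
        assert sorted(len(v) for v in by_pair.values()) == [2, 2]
        types_12 = {
            (example_model.ddi_vars[k].instance_a.domain_type,
             example_model.ddi_vars[k].instance_b.domain_type)
            for k in by_pair[("p1", "p2")]
        }
        assert types_12 == {("d1", "d2"), ("d4", "d2")}

    def test_worked_example_exclusivity_constraints(self, example_model):
        shared = example_model.exclusivity_constraints
        # d1 and d4 on p1 are shared across the two PPIs; d2 and d3 are
        # capped by their pair equalities and need no constraint of their own
        assert set(shared) == {
            ("p1", dv.DomainInstance("d1", 1)),
            ("p1", dv.DomainInstance("d4", 1)),
        }

    def test_pair_without_cognate_domains_has_no_vars(self):
        net = dv.InteractionNetwork.from_edges([("a", "b")])
        dom = dv.DomainAnnotation.from_counts({"a": {"x": 1}, "b": {"y": 1}})
        cat = dv.DDICatalog.from_pairs([("x", "x")])
        model = dv.build_model({"a", "b"}, net, dom, cat)
        assert model.ppi_pairs == (("a", "b"),)
        assert model.n_ddi_vars == 0

    def test_candidate_below_two_proteins_rejected(self, example_model):
        net, dom, cat = dv.worked_example()
        with pytest.raises(ValueError, match="at least 2"):
            dv.build_model({"p1"}, net, dom, cat)

    def test_ddi_variables_span_distinct_proteins(self):
        with pytest.raises(ValueError, match="distinct"):
            DDIVariable(("a", "a"), dv.DomainInstance("t", 1), dv.DomainInstance("t", 2))

    def test_homotypic_pair_uses_distinct_instances(self):
        # one instance on each protein of the same type: exactly one variable
        net = dv.InteractionNetwork.from_edges([("a", "b")])
        dom = dv.DomainAnnotation.from_counts({"a": {"t": 2}, "b": {"t": 1}})
        cat = dv.DDICatalog.from_pairs([("t", "t")])
        model = dv.build_model({"a", "b"}, net, dom, cat)
        assert model.n_ddi_vars == 2  # (t:1@a, t:1@b) and (t:2@a, t:1@b)


class TestSolve:
    def test_worked_example_objective_two(self, example_model):
        assert dv.solve(example_model).objective == 2

    def test_starved_triangle_objective_one(self):
        net, dom, cat = dv.starved_triangle()
        model = dv.build_model({"q1", "q2", "q3"}, net, dom, cat)
        assert model.n_ddi_vars == 3
        assert dv.solve(model).objective == 1

    def test_model_with_no_ddi_vars_gives_zero(self):
        net = dv.InteractionNetwork.from_edges([("a", "b")])
        dom = dv.DomainAnnotation.from_counts({})
        cat = dv.DDICatalog.from_pairs([])
        model = dv.build_model({"a", "b"}, net, dom, cat)
        assert dv.solve(model).objective == 0
        assert dv.solve_bruteforce(model).objective == 0

    def test_bruteforce_refuses_large_models(self, example_model):
        with pytest.raises(ValueError, match="solve"):
            dv.solve_bruteforce(example_model, max_vars=2)

    def test_oracle_equivalence_on_worked_example(self, example_model):
        exact = dv.solve(example_model)
        oracle = dv.solve_bruteforce(example_model)
        assert exact.objective == oracle.objective == 2
        assert exact.ddi_values == oracle.ddi_values

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_models(self, seed):
        model = random_model(random.Random(seed), max_ddi_vars=14)
        exact = dv.solve(model)
        oracle = dv.solve_bruteforce(model)
        assert exact.objective == oracle.objective
        assert exact.ddi_values == oracle.ddi_values

    @pytest.mark.parametrize("seed", range(10))
    def test_solution_invariants(self, seed):
        model = random_model(random.Random(100 + seed), max_ddi_vars=14)
        sol = dv.solve(model)
        sol.validate()  # exclusivity + pair constraints, outside the solver
        # P(i,j)=1 iff exactly one D(i,j,k)=1
        by_pair = model.vars_by_pair
        for pair, value in sol.ppi_values().items():
            active = sum(sol.ddi_values[k] for k in by_pair[pair])
            assert (value == 1) == (active == 1)
            assert active <= 1
        # objective bounds: pairs in Omega, and half the touched instances
        seen = {ep for v in model.ddi_vars for ep in v.endpoints}
        assert sol.objective <= len(model.ppi_pairs)
        assert sol.objective <= len(seen) // 2

    @pytest.mark.parametrize("seed", range(5))
    def test_catalog_monotonicity(self, seed):
        rng = random.Random(200 + seed)
        model = random_model(rng, max_ddi_vars=12)
        base = dv.solve(model).objective
        # enlarge the catalog to allow every type pair seen in the model
        types = sorted(
            {v.instance_a.domain_type for v in model.ddi_vars}
            | {v.instance_b.domain_type for v in model.ddi_vars}
            | {"extraT"}
        )
        full = dv.DDICatalog.from_pairs(
            [(a, b) for i, a in enumerate(types) for b in types[i:]]
        )
        # rebuild with identical members/edges/domains but a bigger catalog
        net = dv.InteractionNetwork.from_edges(model.ppi_pairs,
                                               extra_proteins=model.members)
        counts: dict[str, dict[str, int]] = {}
        for v in model.ddi_vars:
            for protein, inst in v.endpoints:
                counts.setdefault(protein, {})
                counts[protein][inst.domain_type] = max(
                    counts[protein].get(inst.domain_type, 0), inst.copy
                )
        dom = dv.DomainAnnotation.from_counts(counts)
        bigger = dv.build_model(model.members, net, dom, full)
        assert dv.solve(bigger).objective >= base

    def test_tie_break_is_lexicographically_smallest(self):
        # starved triangle has three co-optimal single-DDI solutions;
        # the lex-smallest assignment activates the last sorted variable
        net, dom, cat = dv.starved_triangle()
        model = dv.build_model({"q1", "q2", "q3"}, net, dom, cat)
        for sol in (dv.solve(model), dv.solve_bruteforce(model)):
            assert sol.ddi_values == (0, 0, 1)

    def test_lp_style_dump_mentions_all_constraints(self, example_model):
        text = "\n".join(example_model.constraint_strings())
        assert text.count("exclusivity") == 2
        assert "maximize" in text
        assert "P(p1,p2)" in text and "P(p1,p3)" in text
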