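# ddiverify

Protein-complex prediction that checks whether the proteins in a candidate
complex can actually bind **at the same time**.

Graph-clustering methods (MCL, MCODE, clustering-coefficient seeding)
propose complexes as densely connected regions of a protein-protein
interaction (PPI) network, but a dense cluster is not automatically a
complex: the member proteins must carry enough binding interfaces to hold
all of those interactions simultaneously. `ddiverify` verifies each
candidate at the domain level. Every PPI must be mediated by a
domain-domain interaction (DDI) between one domain instance in each
protein, and — because a binding interface is roughly one domain — each
domain instance may engage in **at most one** DDI at a time. Candidates in
which three or more proteins remain connected by simultaneously feasible,
DDI-mediated interactions are accepted, together with their explicit
PPI/DDI topology. The rest are filtered out as structurally impossible.

## The optimization at the core

For a candidate with proteins $p_1,\dots,p_m$, let $\Omega$ be the set of
experimentally supported PPIs and let $P_{i,j}\in\{0,1\}$ indicate that the
pair $(p_i,p_j)\in\Omega$ is realized. Let $D_{i,j,k}\in\{0,1\}$ indicate
that the $k$-th potential DDI between $p_i$ and $p_j$ (a pair of domain
instances whose types form a cataloged DDI) is active. The program is

$$\max \sum_{(i,j)\in\Omega} P_{i,j}$$

subject to, for every pair, $P_{i,j}=\sum_k D_{i,j,k}$ (a PPI happens
exactly when one of its candidate DDIs is active; the binary $P$ also
forbids two simultaneous DDIs across one pair), and for every domain
instance $d_\ell$, $\sum_{D\in D(d_\ell)} D \le 1$ (binding-interface
exclusivity). The program is solved exactly as a 0/1 integer program; an
exhaustive $2^n$ enumeration oracle with the same deterministic tie-break
is provided for cross-checking. Any connected component of the realized-PPI
graph with at least three proteins is a verified complex.

## Worked example

Three proteins: `p1` carries domains `d1` and `d4`, `p2` carries `d2`, `p3`
carries `d3`. Both `p1-p2` and `p1-p3` are potential PPIs, and the DDI
catalog allows `d1-d2`, `d4-d2`, `d1-d3`, `d4-d3` — four potential DDIs,
all competing for `p1`'s two domains.

```python
import ddiverify as dv

network, domains, catalog = dv.worked_example()
model = dv.build_model({"p1", "p2", "p3"}, network, domains, catalog)
print("\n".join(model.constraint_strings()))
solution = dv.solve(model)
print(solution.summary())
```

prints

```
maximize  P(p1,p2) + P(p1,p3)
P(p1,p2) = D(p1/d1:1,p2/d2:1) + D(p1/d4:1,p2/d2:1)
P(p1,p3) = D(p1/d1:1,p3/d3:1) + D(p1/d4:1,p3/d3:1)
D(p1/d1:1,p2/d2:1) + D(p1/d1:1,p3/d3:1) <= 1    [exclusivity of p1/d1:1]
D(p1/d4:1,p2/d2:1) + D(p1/d4:1,p3/d3:1) <= 1    [exclusivity of p1/d4:1]
candidate members : p1, p2, p3
potential PPIs    : 2
DDI variables     : 4
objective (PPIs)  : 2
status            : optimal
  active DDI p1/d4:1 -- p2/d2:1
  active DDI p1/d1:1 -- p3/d3:1
```

Both PPIs are simultaneously realizable (objective 2: `d1` binds one
partner, `d4` the other), so the candidate is verified as one 3-protein
complex. By contrast, a triangle in which each protein carries a single
promiscuous domain solves to objective 1 — any one DDI blocks the other
two — and is rejected.

## Command line

```sh
ddiverify simulate --out data --seed 1          # planted synthetic benchmark
ddiverify run --ppi data/ppi.tsv --domains data/domains.tsv \
    --ddis data/ddis.tsv --known data/known_complexes.tsv \
    --go data/go.tsv --method cc --out results
```

Subcommands `cluster`, `verify`, and `evaluate` run the stages
independently on the same TSV formats; chained stage outputs are
byte-identical with the full pipeline. Defaults: MCL inflation 3.6,
clustering-coefficient threshold 0.4, minimum complex size 3, overlap
threshold 0.25.

## Evaluation

Predictions are scored against a known-complex catalog with the Bader
overlap $V=|N_p\cap N_k|^2/(|N_p||N_k|)$, matched when $V>0.25$; precision
and recall count matched predictions and matched known complexes. The
package also computes the same-function ratio of within-complex protein
pairs from GO molecular-function terms, suggests functions for
uncharacterized proteins (terms GO:0003674/GO:0005554) from their complex
co-members, and accounts for the net false negatives attributable to the
exclusivity assumption.

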