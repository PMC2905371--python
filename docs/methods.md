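# Methods

## Model

A protein complex is modeled as a set of proteins whose pairwise physical
interactions are each mediated by one domain-domain interaction (DDI): a
pair of domain instances, one in each protein, whose domain types are known
to bind. Two assumptions drive the verification step:

1. a protein in a candidate can bind another member only if the pair is a
   potential PPI (observed experimentally) **and** some pair of their
   domain instances forms a cataloged DDI type pair;
2. each domain instance participates in at most one DDI at a time
   (binding-interface exclusivity). A domain is equated with one binding
   interface; real cases where a single domain binds several partners
   simultaneously are deliberately not modeled, which trades some false
   negatives for a tractable formulation.

Per candidate, a 0/1 integer program maximizes the number of realized PPIs
subject to a pair equality (`P = Σ D` over the pair's DDI variables; with
binary `P` this also caps each pair at one active DDI) and per-instance
exclusivity (`Σ D ≤ 1` over all variables touching an instance).
Exclusivity rows whose variables all belong to one protein pair are implied
by the pair equality; they are kept in the solver matrix (redundant rows
are harmless) but omitted from the human-readable constraint dump and not
counted as exclusivity constraints. A candidate is accepted when a
connected component of the realized-PPI graph has at least three proteins;
such a component necessarily contains at least two active DDIs. One
candidate may yield several verified complexes (all components above the
size cutoff are kept) or none.

Modeling choices where the formulation is open:

- **Homotypic DDIs** (type pair d–d) require two distinct instances; an
  instance cannot bind itself, and intra-protein DDIs are excluded —
  variables always span two distinct proteins.
- **Multiple optima.** The objective often has co-optimal solutions (the
  worked example has two symmetric ones). Both solvers return the
  lexicographically smallest assignment over DDI variables sorted by
  (protein pair, instance pair), purely for determinism; no biological
  meaning is attached to the choice.
- **Candidates are solved independently**; a protein shared by two
  candidates may use the same domain in both.
- **Deduplication** of verified complexes is keyed on the member set,
  keeping the record with the higher objective.
- **Domain multiplicity**: the annotation format carries an explicit copy
  count per (protein, domain type), defaulting to one copy; copies are
  expanded into instances indexed 1..n, each carrying its own exclusivity
  constraint.

## Solvers

`solve()` uses HiGHS through `scipy.optimize.milp`. After the optimum is
found, variables are fixed one at a time in sorted order (keeping a 0
whenever the optimum is still attainable) so the returned assignment is the
lexicographic minimum among co-optima. `solve_bruteforce()` enumerates all
2^n assignments (vectorized, chunked; refused above 20 variables) and is
the independent oracle: every solver result in the test suite is compared
against it on models small enough to enumerate, and feasibility is
re-checked directly from the assignment rather than trusted from the
solver. The program is never infeasible — the all-zero assignment always
satisfies every constraint — so `solve` always returns an optimal solution.

## Candidate generation

- **Markov clustering** (default inflation 3.6): column-stochastic
  transition matrix with unit self-loops; iterations alternate expansion
  (matrix squaring) and inflation (entrywise power, column renormalization)
  with pruning of entries below 1e-5, until the maximum entrywise change
  falls below 1e-8 or 200 iterations pass (then a warning and the current
  state are used). Clusters are the attractor-row supports; attractor
  systems are merged, and a node claimed by several clusters goes to the
  lexicographically smallest, so the output partitions the node set and
  never spans connected components. The implementation is dense; it is
  intended for networks up to a few thousand proteins, not for
  genome-scale matrices.
- **Clustering-coefficient seeding** (default threshold 0.4): every protein
  with degree ≥ 2 whose local clustering coefficient reaches the threshold
  seeds a candidate of itself plus its neighbors; identical member sets are
  deduplicated. The seed-plus-neighborhood rule is the simplest dense-region
  construction consistent with thresholding the coefficient; other
  extraction rules exist, so counts on real data are method-dependent.
- **Import**: one whitespace-separated cluster per line, so output of
  external tools (command-line MCL, MCODE) can be verified without
  re-implementing them.

Candidates below the minimum complex size (default 3) are carried through
clustering output but skipped by verification, since no component of theirs
can reach the acceptance size.

## Evaluation protocol

Matching uses the Bader overlap `V = |Np ∩ Nk|² / (|Np|·|Nk|)` with a
strict `V > 0.25` criterion. Precision = matched predictions / predictions;
recall = matched known complexes / known complexes; several predictions may
match one known complex. The same-function ratio counts within-complex
pairs sharing at least one molecular-function GO term id (flat comparison,
no ontology traversal) among pairs where both proteins have at least one
known term; unannotated proteins and proteins carrying only the
unknown-function placeholders GO:0003674/GO:0005554 are excluded from the
denominator — including them would conflate missing annotation with
functional disagreement. Function suggestions are emitted only for
complexes with exactly one uncharacterized protein whose remaining members
all share a common term. The false-negative report takes the known
complexes recovered by unverified candidates (β), counts those lost by
verification, subtracts complexes whose members have no cataloged DDI at
all (no verifier could keep them), and reports the remainder (α) and α/β —
the net cost of the exclusivity assumption.

## Synthetic benchmark

The generator plants ground truth so the whole pipeline is testable without
external downloads:

- **Feasible complexes** are cliques with one dedicated homotypic domain
  type per clique edge, carried by exactly the two endpoint proteins. The
  full-clique assignment (one DDI per edge, each instance used once) is
  constructed as a witness during generation and validated directly against
  the constraints, so planted feasibility never depends on the solver being
  correct.
- **Decoys** are cliques where every member carries a single instance of
  one shared promiscuous type; exclusivity caps active PPIs at ⌊size/2⌋,
  so no three proteins can stay connected and decoys are always rejected.
- **Background** proteins carry domains with no cataloged partner and
  acquire Erdős–Rényi noise edges (default p = 0.02 on pairs touching a
  background protein).

Defaults (10 feasible complexes and 10 decoys of 3–5 proteins, 50
background proteins) give a benchmark where clustering-coefficient
candidates include every planted clique plus decoys and noise
neighborhoods, verification removes exactly the structurally impossible
ones, and in the noise-free variant the verified output equals the planted
catalog (precision = recall = 1 at V > 0.25). Generation is a pure function
of one integer seed; the same seed yields byte-identical files.

What the benchmark does **not** emulate: scale-free degree distributions,
false-positive PPI rates concentrated on hubs, noisy or incomplete domain
annotation, and DDI catalogs with false entries. Passing it demonstrates
the combinatorial filter and the bookkeeping are correct, not that any
particular precision will be achieved on real interactome data, where
performance depends on the coverage and quality of the PPI and DDI sources.

## Numerical and degenerate-input choices

- Unordered pairs are stored lexicographically smaller-id-first; all
  outputs are sorted, so every run is deterministic (the only randomness in
  the package is the synthetic generator's seed).
- Brute-force enumeration orders assignments with the first sorted DDI
  variable as the most significant bit, making "first optimum found" and
  "lexicographically smallest optimum" coincide.
- Empty networks are a hard error for clustering; candidates smaller than
  two proteins are a hard error for model building; a model with zero DDI
  variables solves to objective 0; an evaluation with no predictions
  reports precision = recall = 0 with a warning; a same-function ratio with
  no eligible pair is reported as missing rather than 0.

## Problem sizes used in the checks

The randomized suites use candidates of 3–6 proteins with up to 20 DDI
variables (the enumeration oracle's limit) — 200 models for the
solver-vs-oracle comparison, 50 for monotonicity — and the synthetic
benchmark uses its default scenario (≈ 90 proteins). These sizes make every
result exhaustively checkable; the solver itself handles much larger
candidates, scaling with the per-candidate variable count rather than the
network size.
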