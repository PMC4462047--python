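# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `lipoflux`, and what the bundled tests do and do not
demonstrate about real data.

## Constraint-based model

A metabolic network is a stoichiometric matrix S (metabolites ×
reactions, declaration order, signed coefficients in mol/mol) with flux
bounds in mmol·gDW⁻¹·h⁻¹.  Exchange reactions are written as export
(`metabolite → ∅`), so uptake is negative flux and a medium specification
is a map of non-negative uptake magnitudes; applying a medium sets each
exchange lower bound to −uptake (0 for metabolites not in the medium) and
leaves export bounds untouched.  Gene–protein–reaction rules are boolean
expressions over gene ids (`and` = complex subunits, `or` = isozymes,
case-insensitive, parenthesized; no negation).  A reaction is disabled by
a deletion set iff its rule evaluates false with exactly those genes set
false — which makes deletion effects monotone in the deleted set.

### FBA

`fba` solves max/min c·v subject to S v = 0, bounds, and optional exact
pins via scipy's HiGHS simplex.  Pins model the growth condition: the
biomass reaction held at a minimal proliferation rate μ = 0.03 h⁻¹ while
a product exchange is maximized.  The pin is an equality by default (the
simulated condition is "growth at exactly the minimal rate"); screening
callers can pass any pin set they wish, so a ≥-style constraint is simply
a lower bound on the biomass reaction instead.  Infeasible and unbounded
LPs are reported as statuses, not exceptions, because both are legitimate
screen outcomes.

### Parsimonious reference

FBA optima are almost always degenerate, and MOMA's answer depends on
which wild-type optimum is used.  The reference is therefore made
reproducible: with the objective fixed at its optimum, Σ|v| is minimized
(fluxes split into non-negative forward/reverse parts; bound intervals
not containing zero are enforced with explicit inequality rows).  This
removes internal cycles (they add |v| without improving a fixed
objective) and in practice pins a unique, declaration-order-independent
reference.

### MOMA

A knockout is predicted as the feasible mutant flux vector closest to the
wild-type reference in squared Euclidean distance — the hypothesis being
that the perturbed metabolism initially stays near its previous operating
point rather than re-optimizing growth.  The quadratic distance is the
default and only implemented variant (a linear variant is reserved as a
config switch).  Pins remain in force for the mutant; a knockout that
cannot satisfy them is reported infeasible in its screen row.

The QP `min ½‖v − w‖² s.t. S v = 0, lb ≤ v ≤ ub` is solved by a primal
active-set method specialized to the identity Hessian: a feasibility LP
provides the start, each iteration projects w exactly onto the affine
subspace of the current working set (least-squares solve, tolerant of the
rank-deficient S), steps as far as inactive bounds allow, and at subspace
optima releases the bound with the most negative multiplier.  For a
strictly convex QP this terminates finitely and deterministically.  An
earlier interior-point formulation (scipy trust-constr plus polish) was
abandoned after it returned infeasible iterates on some knockouts; the
active-set method is both exact and faster at these problem sizes.  The
test suite cross-checks it against an independent SLSQP oracle run on a
rank-reduced (SVD) equality system, agreeing to ~1e−11 in flux norm on
the toy network and never being the worse of the two on 300 random
polytopes.

Tolerances: feasibility 1e−9 (‖S·v‖∞, scaled), optimality/oracle
agreement 1e−6 for LP objectives and 1e−5 for QP flux vectors, rates
below 1e−9 suppressed in cofactor reports, serialized floats at 9
significant digits.

### NADPH accounting

Two views are deliberately kept separate, since a count of "NADPH
reactions" can mean either:

* **structural** — anabolic if the net cofactor coefficient is positive
  in the feasible flux direction, catabolic if negative, with fully
  reversible reactions listed as ambiguous;
* **flux-carrying** — under one solved distribution, rate = coefficient ×
  flux per reaction; positive rates rank producers, negative consumers,
  ties broken by reaction id.  S v = 0 forces total production to equal
  total consumption, which the report exposes as `balance_gap`.

Cofactor identity is a parameter (default the cytosolic NADPH id), pooled
across compartments by default since per-compartment pool separation is a
model-specific question the data model supports but does not assume.

## Expression pattern analysis

FPKM values below the detection floor (default 0.05, the smallest
reliably detected non-zero abundance) are raised to the floor before any
logarithm or ratio, making "induced from zero" well defined: a gene
appearing at 113 FPKM from undetectable scores 113/0.05 = 2260-fold.
Fold changes against the reference sample (E, the last pre-exhaustion
point) are signed symmetric ratios: max(r, 1/r) with the sign of the
direction.  The fold-change spectrum bins differentially expressed genes
(max |fold| ≥ 5, the first bin edge; configurable) into left-closed bins
[5,10), [10,100), [100,1000), [1000,∞).

Regulation calls use the ratio of floored phase means (three post vs
three pre samples); up if ≥ 2, down if ≤ ½, else unchanged.  The
threshold 2 is a package choice — any threshold strictly between 1 and
the planted effect size recovers noise-free planted directions exactly,
which the suite verifies.  Concordance between two direction tables is
the fraction of shared genes with identical labels (with the discordant
genes listed); it is the documented stand-in for published cross-species
"similarity" percentages whose exact metric is not recoverable.

Sample clustering is average-linkage agglomeration on 1 − Pearson
correlation of floored log10 columns; constant samples are rejected by
name since their correlation is undefined.  Genesis-era software defaults
are not recoverable, so the metric/linkage pair is fixed and documented
rather than configurable.

The bundled 23-gene core (14 up, 9 down) spans glycolysis (PK, PCK up;
HK, ALDO, GAPDH, ENO down), the TCA cycle (PDH, OGDH, SUCLG up; ACO,
IDH, MDH down), acetyl-CoA supply (ACLY, ACS up), glycerolipid assembly
(ALDH, ADH, GPAT, DGAT, ACSL up; LIP down), β-oxidation gating (CRAT
down) and the PPP dehydrogenases (G6PD, PGD up).  Hexokinase is counted
once (EC 2.7.1.1 and EC 2.7.1.2 grouped under HK), which is what makes
the total 23.

## Synthetic data

### Toy core-carbon network

21 reactions, 16 metabolites; pathway blocks are lumped so brute-force
oracles (vertex enumeration, dense least squares) stay tractable while
the producer/consumer logic is preserved: glycolysis is one reaction
(G6P → 2 pyruvate), the oxidative PPP is G6PD then PGD (one NADPH each,
pentose skeleton returned to pyruvate by a lumped non-oxidative branch),
acetyl-CoA comes through the citrate shuttle (PC/CS/ACLY with a catalytic
oxaloacetate pool), malic enzyme closes a carbon-neutral
transhydrogenation cycle, and fatty-acid synthesis consumes a
configurable 2 NADPH per unit of exported arachidonic acid.  NADPH is
produced only by G6PD, PGD and ME.  A 6-phosphogluconate export keeps
G6PD a halved NADPH source when PGD is deleted (so single deletions give
intermediate phenotypes), while a G6PD deletion starves PGD of substrate.
ATP and redox balancing beyond NADP(H) are deliberately not modelled.

Default capacities: glucose uptake 10, ammonium 5, ME 2, other branches
effectively uncapped (1000); biomass draws 0.2 G6P + 0.3 pyruvate +
0.2 acetyl-CoA + 0.5 ammonium per unit flux and is pinned at μ = 0.03.
Under these defaults the AA-export optimum has the closed form derived in
`toy_wild_type_optimum` and equals 10.4865; with ME capacity 0 the double
G6PD+PGD deletion forces AA export to exactly 0, the toy's signature
outcome.

### Planted expression time courses

Six samples (A, B, E pre; K, L, M post at −12, −2, −0.5, +1, +12, +48 h).
Per-gene baselines are log10-normal (mean 1.5, sd 0.8 → typically tens of
FPKM, spanning the dynamic range of fungal transcriptomes).  Planted up
genes have post-phase mean = effect × pre-phase mean (default effect 8),
down genes the inverse, background genes are flat; every entry then gets
multiplicative log-normal noise exp(σ·z) with σ = 0.2 by default.  All
randomness flows through one `numpy` generator seeded explicitly.

What this emulates: magnitude scales, a clean two-phase switch, and
noise levels at which recovery is expected but not trivial.  What it does
not emulate: library-size artefacts, transcript-length biases, genuinely
time-graded (rather than step) responses, correlated noise between
samples, or the ~12,000-gene background of a real transcriptome.  Passing
recovery tests therefore certifies the pipeline's logic, not its
performance on real sequencing data; published global percentages (genes
expressed, fold-change bin occupancies) depend on the original reads and
alignment stack and are out of desk-scale reach.

## Known limitations

* The MOMA active-set solver is dense; it is sized for networks up to a
  few hundred reactions.  Genome-scale screens run (the machinery is
  format-agnostic) but are not performance-tuned.
* Only the quadratic MOMA distance is implemented; linear MOMA and ROOM
  are out of scope.
* Flux variability, dynamic FBA and thermodynamic constraints are
  non-goals, as are read alignment and FPKM quantification upstream of
  the expression matrix, and replicated differential-expression
  statistics (the six-sample design has no replicates).
* SBML support is Level 3 + FBC v2 (bounds, objective, gene
  associations); kinetic laws and annotations are ignored.
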