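# lipoflux

Constraint-based flux simulation and transcriptome pattern analysis of
NADPH-driven lipogenesis in oleaginous fungi.

## The problem

Oleaginous fungi such as *Mortierella alpina* switch from growth to lipid
accumulation when nitrogen runs out: protein synthesis stops, but glucose
keeps being assimilated and carbon is routed into fatty acids.  Every two
carbons added to a growing acyl chain cost two NADPH, so the question of
*which* reactions supply that reducing power — the malic enzyme (ME),
classically assumed to be the sole source, or the pentose phosphate
pathway dehydrogenases G6PD and PGD — is central to understanding and
engineering microbial lipid production.

`lipoflux` packages the two desk-scale analyses that address this
question:

1. **Constraint-based simulation.** Flux balance analysis (FBA), a
   parsimonious wild-type reference, MOMA knockout prediction and a
   deletion screen on a metabolic model, plus NADPH producer/consumer
   accounting of any solved flux state.
2. **Expression pattern analysis.** FPKM time courses over six samples
   spanning nitrogen exhaustion (A: −12 h, B: −2 h, E: −30 min pre;
   K: +1 h, L: +12 h, M: +48 h post) are processed with a detection floor,
   fold changes against reference sample E, fold-change spectra, up/down
   regulation calls per gene, concordance between species, and sample
   clustering.  A curated 23-gene regulation core (14 up, 9 down) covering
   glycolysis, TCA, precursor supply, glycerolipid assembly and the PPP is
   bundled.

Synthetic generators — a hand-solvable toy core-carbon network with NADPH
coupling, and a planted-signal FPKM simulator — make every stage testable
without any external data.

## The models

**FBA** solves the linear program

```
max  c·v   s.t.   S v = 0,   lb ≤ v ≤ ub,   v_p = μ  (pins)
```

where S is the stoichiometric matrix, v the flux vector
(mmol·gDW⁻¹·h⁻¹), c selects the objective reaction (here the arachidonic
acid exchange), and the biomass flux can be pinned at a minimal
proliferation rate (μ = 0.03 h⁻¹).  Because FBA optima are degenerate, the
wild-type reference **w** handed to MOMA is the parsimonious optimum:
objective fixed, Σ|v| minimized, which zeroes internal cycles.

**MOMA** predicts a knockout phenotype as the closest feasible point to
the wild-type operating state:

```
min ‖v − w‖²   s.t.   S v = 0,  lb ≤ v ≤ ub,  v_k = 0  ∀ k disabled
```

Gene deletions map to disabled reactions through boolean gene–protein–
reaction rules (AND = complex subunits, OR = isozymes).  The quadratic
program is solved by a primal active-set method with exact affine
projections; an independent least-squares oracle cross-checks it in the
test suite.

**NADPH accounting** evaluates, per reaction, rate = (cofactor
coefficient) × flux; positive rates are producers, negative consumers, and
steady state forces both totals to be equal.

## Worked example

```
$ lipoflux simulate --what network --out sim
$ lipoflux fba --model sim/toy_network.json --objective EX_aa \
      --pin BIOMASS=0.03 --parsimonious --out fba
objective EX_aa = 10.4865
```

10.4865 mmol·gDW⁻¹·h⁻¹ of arachidonic-acid export is the hand-derivable
wild-type optimum of the toy network (glucose uptake 10, ME capacity 2,
2 NADPH per AA unit, growth pinned at 0.03).  Ranking NADPH flux:

```
$ lipoflux nadph-report --model sim/toy_network.json --flux fba/flux.tsv --out nadph
production 20.973 = consumption 20.973 (gap 0.00e+00)
$ cat nadph/nadph_report.tsv
reaction  side      rate        share
G6PD      producer  9.4865      0.452319649
PGD       producer  9.4865      0.452319649
ME        producer  2           0.0953607019
FAS       consumer  20.973      1
```

The two PPP dehydrogenases supply ~90% of NADPH; fatty-acid synthesis
consumes all of it.  Knockouts (MOMA, against the parsimonious reference):

```
$ printf 'deletion\ngG6PD\ngPGD\ngG6PD,gPGD\ngME\n' > deletions.tsv
$ lipoflux moma-screen --model sim/toy_network.json --objective EX_aa \
      --pin BIOMASS=0.03 --deletions deletions.tsv --report EX_aa --out screen
$ cut -f1,5,6 screen/moma_screen.tsv
deletion     mutant_flux  percent_change
gG6PD        1            -90.4639298
gPGD         3.842397     -63.3586325
gG6PD,gPGD   1            -90.4639298
gME          9.88055204   -5.77836223
```

Deleting both PPP dehydrogenases leaves only the capacity-limited malic
enzyme (AA flux 1.0); deleting ME barely matters.  With ME capacity set
to zero, the double G6PD+PGD deletion drives AA export to exactly 0 — the
signature in-silico outcome this package reproduces.

The expression side:

```
$ lipoflux simulate --what expression --seed 1 --out expr
$ lipoflux transcriptome-patterns --fpkm expr/fpkm.tsv --phases expr/phases.tsv \
      --reference E --out patterns
$ python -c "import json; print(json.load(open('patterns/patterns_summary.json'))['core_concordance'])"
1.0
```

All 23 planted core directions are recovered from the noisy (σ = 0.2)
simulated time course.

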