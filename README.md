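# trihelix

Genetic-algorithm design of **heterotrimeric collagen-mimetic peptides**
(CMPs): sets of two (A₂B) or three (ABC) collagen-like strands that
self-assemble into a single target triple helix with a user-chosen
melting temperature and specificity.

## The problem

A collagen-like strand repeats the Xaa-Yaa-Gly triplet (Xaa often Pro,
Yaa often 4-hydroxyproline, written `O`). Mixing two distinct strands
can produce **8** triple-helical species — two homotrimers plus three
registers each of A₂B and AB₂ — and mixing three strands produces
**27**, because a triple helix is an *ordered* (leading, middle,
trailing) assignment under the canonical one-residue stagger. A usable
heterotrimer design must make one target assembly stable *and* leave
every competitor far behind. The margin is the **specificity**:

```
ΔTm = Tm(most stable assembly) − Tm(second most stable assembly)
```

## The model

Every assembly is scored with an additive melting-temperature model:

```
Tm = baseline(L)                                  length baseline
   + Σ propensity(residue, Xaa/Yaa role)          substitutions vs Pro/Hyp
   + Σ axial(Yaaₙ, Xaaₙ₊₁)  over adjacent strands  axial pairwise contacts
   + Σ lateral(Yaaₙ, Xaaₙ)  over adjacent strands  lateral pairwise contacts
   + frameshift(frame offset) + terminal(ends, capping)
```

All parameter *values* are data files (see `trihelix.scoring.load_parameters`);
the bundled tables are **synthetic**, version-tagged `synthetic-*`, and
exist to exercise the machinery — drop in a published parameter file for
real predictions.

The evolutionary search scores a population of candidate helix sets
(default 500), selects the two fittest as parents, and rebuilds the
population by Gly-anchored crossover (rate 0.6) and per-position
Xaa/Yaa mutation (rate 0.2) with elitism. Fitness:

```
F = 0.5·Tm + 0.5·ΔTm                       (plain design)
F = 0.4·ΔTm + 0.4·Tm + 0.2·(±50)           (motif-constrained design)
```

where the ±50 register term rewards the designated input-order register
being the most stable. Conserved motifs (e.g. the α2β1 integrin-binding
GFOGER) are masked out of both mutation and crossover, so their bytes
survive every generation.

## Worked example

Design an ABC heterotrimer of 27-mers carrying GFOGER on the trailing
strand, restricting substitutions to the well-studied Lys/Asp charge-pair
alphabet (Xaa ∈ {P, D}, Yaa ∈ {O, K}):

```
$ trihelix design --composition ABC --length 27 \
    --target-tm 30 --target-spec 10 --motif-c GFOGER \
    --exclude-xaa ACEFGHIKLMNQRSTVWYO --exclude-yaa ACDEFGHILMNPQRSTVWY \
    --seed 0 --population 100 --max-rounds 400 --out-dir demo

converged: Tm 30.4 °C, specificity 11.2 °C after 18 generations
  A: OGPKGPOGDOGDOGDOGPKGDOGPKGD
  B: KGPKGDKGPOGPOGDKGPKGDKGPOGD
  C: OGDKGDKGDKGFOGERGDOGDKGDOGP
```

The most stable of the 27 competing species is the `{ABC}` register at
30.4 °C, 11.2 °C above the best competitor (`{AAB}` at 19.2 °C), and the
GFOGER motif sits intact, frame-aligned, on the trailing strand. The run
writes three artifacts into `demo/`: `design.fasta` (the winning
strands), `report.json` (targets, seed, the full ranked competing-species
table with `<10.0` floor rendering), and `FitnessLandscape.csv`
(`Generation,TimeElapsed,FitnessScore,Tm,Spec` per generation). Exit
status is 0 on convergence and 3 when the round cap is hit.

Audit an existing peptide set (FASTA or one-sequence-per-line text):

```
$ trihelix audit peptides.fasta --params my_fitted.params
```

prints all k³ assemblies ranked by predicted Tm, the specificity, and
the best register.

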