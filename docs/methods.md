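# Methods

## Strand model

A strand is a string over the 20 canonical one-letter codes plus `O`
(4R-hydroxyproline) with glycine at every third position. The *frame
offset* ∈ {0, 1, 2} is the index of the first Gly; roles are a pure
function of position: phase 0 (mod 3, relative to the frame) is Gly,
phase 1 Xaa, phase 2 Yaa. Residues in a partial trailing triplet (after
the last Gly) still carry their Xaa/Yaa role and are scored like any
other substitution site; the test oracle assigns them to a virtual
trailing triplet. Validation is strict in both directions by default —
no missing on-frame Gly, no off-frame Gly — with a `permissive` escape
hatch for scoring exotic user strands. Strands are assumed N-acetylated
and C-amidated; uncapped termini are legal and penalized through the
terminal table rather than rejected.

Glycine is excluded from the Xaa/Yaa substitution alphabet by default
(`allow_gly_xy` overrides): designed sequences never break Gly
periodicity, and letting mutation propose G at Xaa/Yaa would only create
near-lethal candidates the search must then purge.

## Assemblies and contact geometry

An assembly is an ordered (leading, middle, trailing) triple; k strands
give k³ species, enumerated in lexicographic register order. All strands
of an assembly must share one length and one frame offset (the canonical
one-residue stagger keeps Gly at every helix cross-section only then).

Contacts follow the two standard geometries: axial pairs Yaa of triplet
n with Xaa of triplet n+1 on the adjacent strand; lateral pairs Yaa of
triplet n with Xaa of the same triplet n. Adjacency runs
leading→middle and middle→trailing. For the third pair the cycle closes
trailing→leading with the acceptor triplet index shifted by +1, because
the trailing strand sits one further triplet behind the leading strand
under the stagger. Published descriptions specify only the
adjacent-strand geometry, not the closure, so the convention is isolated
behind a single switch (`closure="cyclic"` default, `"open"` drops the
closing pair) and every scoring path honours it. Contacts are truncated
at sequence bounds, which is why a (POG)₇ homotrimer yields 7+6 contacts
on each unshifted pair but 6+5 on the shifted closing pair (37 total).

Non-canonical (frameshifted) staggers are not enumerated; the closure
switch is the only geometry knob exposed.

## Additive stability score

Tm = baseline(length) + substitution propensities (relative to Pro at
Xaa, Hyp at Yaa, both pinned to zero) + axial and lateral pairwise sums
+ a frameshift correction keyed on the shared frame offset + per-end
terminal corrections keyed on residue identity and capping state (with a
`*` residue wildcard). Missing pairwise entries count as zero — many
destabilizing combinations have never been parameterized — and additivity
of co-located pairwise interactions is an assumption of the model, not a
verified fact.

Parameter tables are versioned data files (INI-style sections, pairs
keyed `Y:X`). The bundled tables are synthetic: the `zeros` style is
baseline-only; the `toy-stabilizing` style has hand-set propensity
penalties (−1 to −9 °C, imino acids mild, bulky residues harsh) and a
few pairwise entries dominated by the Lys–Asp axial pair. The charged
residues' penalties are mild enough that a frame-aligned K–D axial pair
is net-stabilizing (−1.6 − 2.0 + 4.4 = +0.8 °C); without that property
the synthetic system would have no non-trivial design optimum and every
search exercise would collapse onto (POG)ₙ. No bundled value is a fitted
constant, so predicted temperatures under these tables are meaningful
only relative to each other; tests accordingly assert structure
(additivity, ranking, invariances), never absolute temperatures.

The `<10.0` display floor is applied at rendering only; ranking and
specificity arithmetic always use the unclamped values. In the bundled
reference tables the floored cells are never among the top two of a row,
so the stored floor value (10.0) cannot perturb a specificity.

Internally `specificity_report` scores all k³ assemblies by recombining
per-strand sums with per-ordered-pair contact sums (the model is
additive, so k strand scans and 2k² pair scans suffice); the
per-assembly walk in `predict_tm` is retained as the reference path and
the test suite asserts exact agreement between the two and against an
independent brute-force walker. Ties in Tm rank lexicographically by
register label for determinism.

## Evolutionary search

Defaults mirror the published protocol: population 500, crossover 0.6,
mutation 0.2, round cap 500 000, top-2 selection with earliest-index tie
breaks, elitism (both parents copied unchanged), fitness weights
(0.5, 0.5) plain and (0.4, 0.4, 0.2) with a ±50 register term in motif
mode. Choices the protocol leaves open were resolved as follows:

* **Mutation semantics** — an independent per-position event with
  probability equal to the mutation rate at every unmasked Xaa/Yaa site;
  the replacement is drawn uniformly from the allowed alphabet
  *excluding the current residue* (when possible), so the number of
  changed positions is exactly binomial and testable. Configurable
  exclusion lists zero the effective mutation rate of barred residues by
  removing them from the draw.
* **Crossover semantics** — one cut index, drawn uniformly from the
  positions just after each Gly, applied at the same index to every
  strand of the set (cutting strands at different points would scramble
  the register). Cuts interior to a conserved-motif mask are excluded
  from the draw; if parents' frames disagree or no legal cut exists the
  offspring is a copy of the first parent. Parent roles are assigned
  randomly per child.
* **Motif placement** — the first motif is centred (left flank
  `(L − m)//2`; flanks differ by one residue when the parity does not
  work out) and the global frame offset follows from the motif's
  internal Gly phase; additional motifs are nudged at most two positions
  off centre to land on the same frame, else the configuration is
  rejected. Motifs must contain at least one Gly with all Gly mutually
  spaced by multiples of three. In A₂B designs the leading and middle
  strands are the same peptide, so their motifs must coincide.
* **Stopping rule** — the search converges when the generation best
  meets both targets, its strand sequences are pairwise distinct, *and*
  its most stable assembly uses every peptide slot (a true ABC register
  for three-slot designs, both peptides for A₂B). The last clause is the
  operative reading of "registers differ": without it the gap-based
  fitness converges onto a degenerate solution — one clean strand whose
  homotrimer towers over deliberately ruined partners — which is
  numerically an excellent fitness maximum and chemically useless. The
  register term in motif mode pushes against the same attractor; in
  plain mode with heavily restricted alphabets the attractor can still
  dominate, which mirrors the practical need for either a motif/register
  constraint or a parameter set in which pairwise stabilization can pay
  for its propensity cost.
* **Restart** — off by default; when `restart_after` is set, a best
  fitness stagnant for that many generations triggers full population
  reinitialization. The globally best set is retained across restarts
  for the final result, so the recorded trace may dip but the answer
  never regresses. With restarts off the recorded best fitness is
  provably non-decreasing (elitism), and the suite checks it.

All randomness flows through a single seeded NumPy generator owned by
the run; identical configuration and seed reproduce the result
bit-for-bit. Per-generation records (generation, elapsed seconds, best
fitness, Tm, specificity, register) are exported as
`FitnessLandscape.csv` with the canonical header.

## Synthetic data and what the tests show

The random-peptide generator draws frames uniformly and Xaa/Yaa residues
uniformly from the allowed alphabets — it emulates the search's initial
population, not natural collagen statistics (no composition bias, no
positional correlation, no real thermal data). Consequently the test
suite demonstrates *mechanical* correctness: enumeration combinatorics,
scorer additivity against an independent walker, operator invariants
(motif conservation, Gly periodicity, exclusion compliance, elitism,
determinism), search optimality on an exhaustively enumerable space, and
the arithmetic of the bundled reference tables. It cannot, and does not
claim to, validate thermodynamic accuracy of any parameter set.

Problem sizes used by the suite and the acceptance script are package
choices: the optimality check uses a 256-state A₂B space (a 15-residue
frozen motif plus {P,D}×{O,K} flank alphabets) with population 30 and a
250-round budget over 50 seeds; the demonstration design run uses
population 100, a 600-round cap and the minimum published target ranges
(Tm ≥ 30 °C, ΔTm ≥ 10 °C), which converges in seconds under the
synthetic tables.

## Known limitations

* Parameter values shipped here are synthetic; real predictive use
  requires a fitted table in the documented schema.
* The additive model ignores interactions between co-located pairwise
  contacts and any concentration or kinetic effects; fitted versions of
  such models are known to overestimate target stability.
* Only canonical one-residue staggers are modelled; the trailing→leading
  closure convention is a documented choice behind a switch, not a
  measured geometry.
* The degenerate homotrimer-gap attractor of the plain fitness (above)
  means plain-mode searches may exhaust their round budget rather than
  converge under parameter sets where substitutions cannot pay for
  themselves; the round-cap path returns the best set found with a
  distinct exit status rather than failing.
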