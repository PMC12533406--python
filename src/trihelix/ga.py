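"""Evolutionary search for self-assembling heterotrimer sequences.

An *individual* is a helix set: two peptide slots for an A2B design or
three for an ABC design (slot ids "A", "B", "C"). Each generation the
whole population is scored, the two fittest sets become parents, and the
next population is rebuilt from them by Gly-anchored crossover and
per-position mutation, with both parents copied in unchanged (elitism).

Fitness without a motif::

    F = 0.5 * Tm + 0.5 * specificity

where Tm is the predicted melting temperature of the most stable
assembly of the set and specificity the gap to the runner-up. With a
conserved motif the weights become 0.4/0.4 plus a 0.2-weighted register
term of ±50 that rewards the designated input-order register (leading,
middle, trailing = slots in order) being the most stable — motif-bearing
designs must place the motif on the intended strand of the intended
register, not merely fold.

Motif residues are frozen: their positions are masked out of both the
mutation and the crossover-cut draws, so the motif bytes survive every
generation verbatim.

The search stops when the best set meets both targets with pairwise
distinct strand sequences *and* its most stable assembly uses every
peptide slot (the winning species is a genuine heterotrimer of the
requested kind, not a collapsed homotrimer of one clean strand), or
when the round cap is reached, in which case the best set found so
far is returned with a non-converged status. An optional stagnation
restart reinitializes the population when the best fitness has not
improved for a configured number of generations.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .peptides import (
    ALPHABET,
    MAX_LENGTH,
    MIN_LENGTH,
    ROLE_XAA,
    ROLE_YAA,
    CollagenPeptide,
    allowed_residues,
)
from .scoring import ScoringParameters, specificity_report

HelixSet = tuple[CollagenPeptide, ...]

#: Bounds enforced on user targets and motif length.
TM_RANGE = (30.0, 70.0)
SPEC_RANGE = (10.0, 35.0)
MOTIF_RANGE = (3, 15)

_SLOT_IDS = ("A", "B", "C")
_STAGNATION_EPS = 1e-9


@dataclass(frozen=True)
class MotifSpec:
    """Conserved motifs per strand of the target register.

    Each motif must be 3-15 residues, contain at least one Gly, and have
    all its Gly residues mutually spaced by multiples of three so that it
    can sit on the global Xaa-Yaa-Gly frame.
    """

    leading: Optional[str] = None
    middle: Optional[str] = None
    trailing: Optional[str] = None

    def __post_init__(self):
        if not any((self.leading, self.middle, self.trailing)):
            raise ConfigError("motif spec given but no strand carries a motif")
        for name in ("leading", "middle", "trailing"):
            seq = getattr(self, name)
            if seq is None:
                continue
            seq = seq.strip().upper()
            object.__setattr__(self, name, seq)
            lo, hi = MOTIF_RANGE
            if not lo <= len(seq) <= hi:
                raise ConfigError(
                    f"{name} motif length {len(seq)} outside [{lo},{hi}]"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise ConfigError(f"{name} motif has invalid residues {sorted(bad)}")
            gly = [i for i, ch in enumerate(seq) if ch == "G"]
            if not gly:
                raise ConfigError(
                    f"{name} motif {seq!r} has no Gly and cannot sit on the frame"
                )
            if any((g - gly[0]) % 3 for g in gly):
                raise ConfigError(
                    f"{name} motif {seq!r}: Gly spacing breaks the triplet frame"
                )

    def motif_phase(self, name: str) -> int:
        """Phase (mod 3) of the motif's internal Gly positions."""
        seq = getattr(self, name)
        return next(i for i, ch in enumerate(seq) if ch == "G") % 3


@dataclass
class GAConfig:
    """All evolution knobs.

    Defaults mirror the published protocol: population 500, crossover
    0.6, mutation 0.2, round cap 500000, ±50 register bonus, fitness
    weights (0.5, 0.5, 0) without a motif and (0.4, 0.4, 0.2) with one.
    """

    composition: str = "ABC"  # "A2B" | "ABC"
    peptide_length: int = 27
    target_tm: float = 35.0
    target_specificity: float = 10.0
    population_size: int = 500
    crossover_rate: float = 0.6
    mutation_rate: float = 0.2
    motif: Optional[MotifSpec] = None
    excluded: Mapping[str, Iterable[str]] = field(default_factory=dict)
    max_rounds: int = 500_000
    register_bonus: float = 50.0
    rng_seed: int = 0
    restart_after: Optional[int] = None
    allow_gly_xy: bool = False
    closure: str = "cyclic"
    log_every: int = 100

    def __post_init__(self):
        if self.composition not in ("A2B", "ABC"):
            raise ConfigError(
                f"composition must be 'A2B' or 'ABC', got {self.composition!r}"
            )
        if not MIN_LENGTH <= self.peptide_length <= MAX_LENGTH:
            raise ConfigError(
                f"peptide length {self.peptide_length} outside "
                f"[{MIN_LENGTH},{MAX_LENGTH}]"
            )
        if not TM_RANGE[0] <= self.target_tm <= TM_RANGE[1]:
            raise ConfigError(
                f"target Tm {self.target_tm} outside "
                f"[{TM_RANGE[0]:.0f},{TM_RANGE[1]:.0f}]"
            )
        if not SPEC_RANGE[0] <= self.target_specificity <= SPEC_RANGE[1]:
            raise ConfigError(
                f"target specificity {self.target_specificity} outside "
                f"[{SPEC_RANGE[0]:.0f},{SPEC_RANGE[1]:.0f}]"
            )
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} {rate} outside [0,1]")
        if self.population_size < 2:
            raise ConfigError("population size must be at least 2")
        # fail early on exhausted alphabets
        allowed_residues(ROLE_XAA, self.excluded, allow_gly=self.allow_gly_xy)
        allowed_residues(ROLE_YAA, self.excluded, allow_gly=self.allow_gly_xy)
        self._layout()  # motif placement must be feasible

    @property
    def n_slots(self) -> int:
        return 2 if self.composition == "A2B" else 3

    @property
    def weights(self) -> tuple[float, float, float]:
        """(specificity, Tm, register) fitness weights."""
        return (0.4, 0.4, 0.2) if self.motif is not None else (0.5, 0.5, 0.0)

    @property
    def designated_register(self) -> tuple[int, ...]:
        """Slot indices of the target register in input order."""
        return (0, 0, 1) if self.composition == "A2B" else (0, 1, 2)

    def slot_motifs(self) -> tuple[Optional[str], ...]:
        """Motif per peptide slot (A2B maps leading+middle to slot A)."""
        if self.motif is None:
            return (None,) * self.n_slots
        m = self.motif
        if self.composition == "ABC":
            return (m.leading, m.middle, m.trailing)
        if m.leading and m.middle and m.leading != m.middle:
            raise ConfigError(
                "A2B designs share one peptide on leading and middle strands; "
                "their motifs must be identical"
            )
        return (m.leading or m.middle, m.trailing)

    def _layout(self) -> tuple[Optional[int], tuple[Optional[tuple[int, int]], ...]]:
        """(frame offset or None, per-slot motif [start, end) masks).

        In motif mode the first motif is centred (left flank
        ``(L - len(motif)) // 2``) and the global frame offset follows
        from its internal Gly phase; further motifs are nudged by at most
        one position off centre to land on the same frame.
        """
        slot_motifs = self.slot_motifs()
        if all(m is None for m in slot_motifs):
            return None, (None,) * self.n_slots
        L = self.peptide_length
        frame: Optional[int] = None
        masks: list[Optional[tuple[int, int]]] = []
        for motif in slot_motifs:
            if motif is None:
                masks.append(None)
                continue
            if len(motif) > L:
                raise ConfigError(
                    f"motif {motif!r} longer than peptide length {L}"
                )
            phase = next(i for i, ch in enumerate(motif) if ch == "G") % 3
            start = (L - len(motif)) // 2
            if frame is None:
                frame = (start + phase) % 3
            else:
                for delta in (0, 1, -1, 2, -2):
                    s = start + delta
                    if 0 <= s and s + len(motif) <= L and (s + phase) % 3 == frame:
                        start = s
                        break
                else:
                    raise ConfigError(
                        f"motif {motif!r} cannot be frame-aligned within length {L}"
                    )
            masks.append((start, start + len(motif)))
        return frame, tuple(masks)

    @property
    def frame_offset(self) -> Optional[int]:
        """Fixed frame in motif mode; None means random per helix set."""
        return self._layout()[0]

    @property
    def motif_masks(self) -> tuple[Optional[tuple[int, int]], ...]:
        return self._layout()[1]


@dataclass(frozen=True)
class FitnessResult:
    score: float
    tm: float
    specificity: float
    best_register: tuple[int, ...]


@dataclass(frozen=True)
class GenerationRecord:
    """One row of the exported fitness landscape."""

    generation: int
    elapsed: float
    best_fitness: float
    best_tm: float
    best_specificity: float
    best_register: tuple[int, ...]


@dataclass(frozen=True)
class DesignResult:
    peptides: HelixSet
    fitness: float
    tm: float
    specificity: float
    best_register: tuple[int, ...]
    converged: bool
    status: str  # "converged" | "round-cap"
    generations: int
    trace: tuple[GenerationRecord, ...]


# ---------------------------------------------------------------------------
# Operators


def _fill_slot(
    config: GAConfig,
    slot: int,
    frame: int,
    rng: np.random.Generator,
) -> CollagenPeptide:
    """One random strand, with the slot's motif (if any) frozen in place."""
    motif = config.slot_motifs()[slot]
    mask = config.motif_masks[slot]
    xaa = allowed_residues(ROLE_XAA, config.excluded, allow_gly=config.allow_gly_xy)
    yaa = allowed_residues(ROLE_YAA, config.excluded, allow_gly=config.allow_gly_xy)
    chars: list[str] = []
    for i in range(config.peptide_length):
        if mask is not None and mask[0] <= i < mask[1]:
            chars.append(motif[i - mask[0]])
            continue
        phase = (i - frame) % 3
        if phase == 0:
            chars.append("G")
        elif phase == 1:
            chars.append(xaa[int(rng.integers(len(xaa)))])
        else:
            chars.append(yaa[int(rng.integers(len(yaa)))])
    return CollagenPeptide(
        id=_SLOT_IDS[slot], residues="".join(chars), frame_offset=frame
    )


def initialize_population(
    config: GAConfig, rng: np.random.Generator
) -> list[HelixSet]:
    """Random initial population of helix sets.

    Without a motif each set draws its own frame offset so the population
    represents all three frames; with a motif the frame is fixed by the
    motif placement and shared by the whole population.
    """
    fixed_frame = config.frame_offset
    population: list[HelixSet] = []
    for _ in range(config.population_size):
        frame = fixed_frame if fixed_frame is not None else int(rng.integers(3))
        population.append(
            tuple(_fill_slot(config, s, frame, rng) for s in range(config.n_slots))
        )
    return population


def fitness(
    helix_set: HelixSet, params: ScoringParameters, config: GAConfig
) -> FitnessResult:
    """Score one helix set; see the module docstring for the formula."""
    report = specificity_report(list(helix_set), params, closure=config.closure)
    tm = report.ranked[0][1].tm
    spec = report.specificity
    if not math.isfinite(spec):
        spec = 0.0  # lone-assembly sentinel never arises for 2-3 slots
    a, b, c = config.weights
    score = a * spec + b * tm
    if c:
        bonus = (
            config.register_bonus
            if report.best_register == config.designated_register
            else -config.register_bonus
        )
        score += c * bonus
    return FitnessResult(
        score=score, tm=tm, specificity=spec, best_register=report.best_register
    )


def select_parents(
    population: Sequence[HelixSet], scores: Sequence[float]
) -> tuple[int, int]:
    """Indices of the two best-scoring sets; ties go to the earliest index."""
    if len(population) < 2:
        raise ConfigError("selection needs a population of at least 2")
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return order[0], order[1]


def legal_cut_points(
    parent: HelixSet, masks: Sequence[Optional[tuple[int, int]]]
) -> list[int]:
    """Crossover cut indices: just after each Gly, outside motif regions.

    A cut at index ``c`` splices ``[:c]`` of one parent onto ``[c:]`` of
    the other on every strand simultaneously, preserving both the Gly
    frame and the register alignment. Cuts that would split a conserved
    motif are excluded from the draw.
    """
    L = len(parent[0].residues)
    f = parent[0].frame_offset
    cuts = []
    for g in range(f, L, 3):
        c = g + 1
        if not 0 < c < L:
            continue
        if any(m is not None and m[0] < c < m[1] for m in masks):
            continue
        cuts.append(c)
    return cuts


def crossover(
    parent1: HelixSet,
    parent2: HelixSet,
    rate: float,
    masks: Sequence[Optional[tuple[int, int]]],
    rng: np.random.Generator,
) -> HelixSet:
    """Single Gly-anchored cut applied at the same index on every strand.

    With probability ``1 - rate`` (or when the parents' frames disagree,
    or no legal cut exists) the offspring is a copy of ``parent1``.
    """
    if rng.random() >= rate:
        return parent1
    if (
        parent1[0].frame_offset != parent2[0].frame_offset
        or len(parent1[0].residues) != len(parent2[0].residues)
    ):
        return parent1
    cuts = legal_cut_points(parent1, masks)
    if not cuts:
        return parent1
    c = cuts[int(rng.integers(len(cuts)))]
    return tuple(
        replace(p1, residues=p1.residues[:c] + p2.residues[c:])
        for p1, p2 in zip(parent1, parent2)
    )


def mutate(
    helix_set: HelixSet,
    rate: float,
    excluded: Mapping[str, Iterable[str]],
    masks: Sequence[Optional[tuple[int, int]]],
    rng: np.random.Generator,
    *,
    allow_gly_xy: bool = False,
) -> HelixSet:
    """Independent per-position substitution at unmasked Xaa/Yaa sites.

    Each mutable position flips with probability ``rate`` to a uniform
    draw over its allowed alphabet excluding the current residue (so a
    mutation event always changes the sequence, and the event count is
    exactly binomial). Gly positions and motif regions never mutate.
    """
    alphabets = {
        ROLE_XAA: allowed_residues(ROLE_XAA, excluded, allow_gly=allow_gly_xy),
        ROLE_YAA: allowed_residues(ROLE_YAA, excluded, allow_gly=allow_gly_xy),
    }
    out = []
    for slot, peptide in enumerate(helix_set):
        mask = masks[slot] if slot < len(masks) else None
        f = peptide.frame_offset
        chars = list(peptide.residues)
        changed = False
        for i, ch in enumerate(chars):
            phase = (i - f) % 3
            if phase == 0:
                continue
            if mask is not None and mask[0] <= i < mask[1]:
                continue
            if rng.random() >= rate:
                continue
            allowed = alphabets[ROLE_XAA if phase == 1 else ROLE_YAA]
            choices = [r for r in allowed if r != ch] or list(allowed)
            chars[i] = choices[int(rng.integers(len(choices)))]
            changed = True
        out.append(replace(peptide, residues="".join(chars)) if changed else peptide)
    return tuple(out)


# ---------------------------------------------------------------------------
# The evolution loop


def _distinct_strands(helix_set: HelixSet) -> bool:
    seqs = [p.residues for p in helix_set]
    return len(set(seqs)) == len(seqs)


def run(
    config: GAConfig,
    params: ScoringParameters,
    *,
    progress: Optional[Callable[[GenerationRecord], None]] = None,
) -> DesignResult:
    """Evolve until the targets are met or the round cap is hit.

    Per generation: score everyone (memoized — offspring of the same two
    parents repeat often), pick the top two, record the best, test the
    stopping rule, then rebuild the population from the parents. With
    elitism and no restart the recorded best fitness is non-decreasing;
    a stagnation restart may dip the trace but the globally best set is
    retained for the final result. Hitting the round cap returns the best
    set found so far with ``status="round-cap"``, never an exception.
    """
    rng = np.random.default_rng(config.rng_seed)
    masks = config.motif_masks
    population = initialize_population(config, rng)

    memo: dict[tuple, FitnessResult] = {}

    def evaluate(helix_set: HelixSet) -> FitnessResult:
        key = tuple(p.residues for p in helix_set) + (helix_set[0].frame_offset,)
        result = memo.get(key)
        if result is None:
            result = fitness(helix_set, params, config)
            memo[key] = result
        return result

    t0 = time.perf_counter()
    trace: list[GenerationRecord] = []
    best_overall: Optional[tuple[FitnessResult, HelixSet]] = None
    generation = 0
    stagnant = 0
    last_best = -math.inf
    converged = False

    while True:
        results = [evaluate(ind) for ind in population]
        i1, i2 = select_parents(population, [r.score for r in results])
        best_ind, best_fit = population[i1], results[i1]
        if best_overall is None or best_fit.score > best_overall[0].score:
            best_overall = (best_fit, best_ind)

        record = GenerationRecord(
            generation=generation,
            elapsed=time.perf_counter() - t0,
            best_fitness=best_fit.score,
            best_tm=best_fit.tm,
            best_specificity=best_fit.specificity,
            best_register=best_fit.best_register,
        )
        trace.append(record)
        if progress is not None and generation % config.log_every == 0:
            progress(record)

        if (
            best_fit.tm >= config.target_tm
            and best_fit.specificity >= config.target_specificity
            and _distinct_strands(best_ind)
            and len(set(best_fit.best_register)) == config.n_slots
        ):
            converged = True
            best_overall = (best_fit, best_ind)
            break
        if generation >= config.max_rounds:
            break

        if best_fit.score > last_best + _STAGNATION_EPS:
            last_best = best_fit.score
            stagnant = 0
        else:
            stagnant += 1
        if config.restart_after is not None and stagnant >= config.restart_after:
            population = initialize_population(config, rng)
            stagnant = 0
            last_best = -math.inf
            generation += 1
            continue

        p1, p2 = population[i1], population[i2]
        new_population = [p1, p2]
        while len(new_population) < config.population_size:
            a, b = (p1, p2) if rng.random() < 0.5 else (p2, p1)
            child = crossover(a, b, config.crossover_rate, masks, rng)
            child = mutate(
                child,
                config.mutation_rate,
                config.excluded,
                masks,
                rng,
                allow_gly_xy=config.allow_gly_xy,
            )
            new_population.append(child)
        population = new_population
        generation += 1

    final_fit, final_ind = best_overall
    return DesignResult(
        peptides=final_ind,
        fitness=final_fit.score,
        tm=final_fit.tm,
        specificity=final_fit.specificity,
        best_register=final_fit.best_register,
        converged=converged,
        status="converged" if converged else "round-cap",
        generations=generation,
        trace=tuple(trace),
    )
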