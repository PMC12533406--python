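"""Bundled fixtures: synthetic scoring tables and reference Tm tables.

Two kinds of data live here.

*Synthetic parameter tables* exercise every term of the additive scorer
without claiming any fitted values. The "zeros" style carries only a
length baseline (every substitution scores zero), the "toy-stabilizing"
style adds hand-set propensity penalties and a handful of pairwise
interaction increments — most prominently the well-studied Lys–Asp
axial charge pair — at magnitudes plausible for collagen-mimetic
peptides. Both are version-tagged ``synthetic-*``; drop in a published
parameter file for real predictions.

*Reference Tm tables* hold the published predicted and CD-measured
melting temperatures of four designed heterotrimers (two plain ABC
designs and two carrying the GFOGER integrin-binding motif), used to
check specificity and deviation arithmetic. Values below the 10 °C
reporting floor are stored as an explicit floor marker with numeric
value 10.0; such cells are never among the top two of any row, so
specificity arithmetic is unaffected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .errors import ConfigError
from .peptides import ALPHABET
from .scoring import ScoringParameters

_BASELINE_SLOPE = 1.8  # °C per residue in the synthetic baseline
_BASELINE_21 = 36.0  # synthetic (POG)7-like anchor


def _full_propensity(reference: str, values: dict[str, float]) -> dict[str, float]:
    table = dict(values)
    table[reference] = 0.0
    for res in ALPHABET:
        table.setdefault(res, -6.0)
    return table


# Hand-set synthetic penalties: imino acids mild, bulky/branched residues
# harsh, charged residues mild so pairwise bonuses can pay for them.
_TOY_XAA = _full_propensity(
    "P",
    {
        "O": -1.2, "G": -9.0, "A": -5.2, "S": -5.6, "C": -7.4, "T": -6.8,
        "V": -8.2, "I": -8.6, "L": -7.8, "M": -7.0, "F": -6.6, "W": -8.4,
        "Y": -6.4, "H": -6.2, "K": -4.6, "R": -4.4, "Q": -4.2, "N": -6.8,
        "D": -2.0, "E": -2.4,
    },
)
_TOY_YAA = _full_propensity(
    "O",
    {
        "P": -3.6, "G": -9.0, "A": -5.8, "S": -5.4, "C": -7.6, "T": -6.4,
        "V": -8.0, "I": -8.8, "L": -8.0, "M": -7.2, "F": -7.0, "W": -8.6,
        "Y": -6.8, "H": -6.0, "K": -3.4, "R": -3.2, "Q": -4.8, "N": -5.6,
        "D": -6.4, "E": -6.2,
    },
)
_TOY_AXIAL = {
    ("K", "D"): 4.4, ("K", "E"): 3.6, ("R", "D"): 2.8, ("R", "E"): 2.4,
    ("K", "F"): 1.6, ("Q", "F"): 1.8,
    ("K", "K"): -2.0, ("D", "D"): -2.0, ("R", "R"): -1.8,
}
_TOY_LATERAL = {("K", "D"): 1.8, ("K", "E"): 1.2, ("R", "D"): 1.4}
_TOY_FRAMESHIFT = {"0": -1.2, "1": -2.0, "2": 0.0}  # Xaa-Yaa-Gly is canonical
_TOY_TERMINAL = {"nterm:*:uncapped": -5.0, "cterm:*:uncapped": -3.5}


def synthetic_baseline(lengths=range(21, 41)) -> dict[int, float]:
    """Linear synthetic length baseline (°C), anchored at 36 °C for 21-mers."""
    return {n: _BASELINE_21 + _BASELINE_SLOPE * (n - 21) for n in lengths}


def synthetic_parameter_table(
    style: str = "toy-stabilizing", rng_seed: Optional[int] = None
) -> ScoringParameters:
    """Deterministic synthetic :class:`ScoringParameters`.

    ``rng_seed`` is accepted for interface uniformity; the tables are
    constant, so any seed yields the identical object.
    """
    if style == "zeros":
        params = ScoringParameters(
            baseline_tm=synthetic_baseline(),
            xaa_propensity={res: 0.0 for res in ALPHABET},
            yaa_propensity={res: 0.0 for res in ALPHABET},
            version_tag="synthetic-zeros-1",
        )
    elif style == "toy-stabilizing":
        params = ScoringParameters(
            baseline_tm=synthetic_baseline(),
            xaa_propensity=dict(_TOY_XAA),
            yaa_propensity=dict(_TOY_YAA),
            axial_interaction=dict(_TOY_AXIAL),
            lateral_interaction=dict(_TOY_LATERAL),
            frameshift_correction=dict(_TOY_FRAMESHIFT),
            terminal_correction=dict(_TOY_TERMINAL),
            version_tag="synthetic-toy-1",
        )
    else:
        raise ConfigError(f"unknown synthetic table style {style!r}")
    params.validate()
    return params


def bundled_parameter_path() -> str:
    """Path of the packaged synthetic toy parameter file."""
    return str(resources.files("trihelix.data").joinpath("synthetic_toy.params"))


# ---------------------------------------------------------------------------
# Reference Tm tables


@dataclass(frozen=True)
class TableCell:
    """One melting temperature cell; ``floored`` marks a '<10.0' entry."""

    tm: float
    floored: bool = False
    register: Optional[str] = None

    @property
    def display(self) -> str:
        text = "<10.0" if self.floored else f"{self.tm:.1f}"
        return f"{text} {{{self.register}}}" if self.register else text


@dataclass(frozen=True)
class PrintedTmTable:
    """Per-design map of peptide-combination label → Tm cell."""

    source: str  # "predicted" | "experimental"
    rows: dict[str, dict[str, TableCell]] = field(default_factory=dict)
    specificities: dict[str, float] = field(default_factory=dict)


def _load_reference() -> dict:
    path = resources.files("trihelix.data").joinpath("reference_tm.json")
    return json.loads(path.read_text())


def reference_tm_table(which: str) -> PrintedTmTable:
    """Published Tm table for the four designed heterotrimers.

    ``which`` is ``"predicted"`` (scored by the fitted stability model the
    designs were optimized under) or ``"experimental"`` (CD melting).
    """
    data = _load_reference()
    if which not in ("predicted", "experimental"):
        raise ConfigError(f"which must be 'predicted' or 'experimental', got {which!r}")
    block = data[which]
    rows = {
        name: {
            label: TableCell(
                tm=cell["tm"],
                floored=cell.get("floor", False),
                register=cell.get("register"),
            )
            for label, cell in row.items()
        }
        for name, row in block["rows"].items()
    }
    return PrintedTmTable(
        source=which, rows=rows, specificities=dict(block["specificity"])
    )


def reference_tm_comparison() -> dict[str, dict[str, float]]:
    """Predicted vs experimental Tm of each target assembly, with deviation."""
    return _load_reference()["comparison"]


def specificity_from_row(row: dict[str, TableCell]) -> float:
    """Most-stable minus second-most-stable Tm over one table row."""
    values = sorted((cell.tm for cell in row.values()), reverse=True)
    if len(values) < 2:
        raise ConfigError("specificity needs at least two assemblies")
    return values[0] - values[1]


# ---------------------------------------------------------------------------
# Enumerable toy design space


@dataclass(frozen=True)
class ToyDesignSpace:
    """A tiny, exhaustively enumerable A2B design problem.

    A 15-residue frozen motif covers the middle of both 21-mer strands
    and the Xaa/Yaa alphabets are restricted to {P, D} and {O, K}, so
    only the four flank substitution sites per strand are searchable:
    256 candidate helix sets in total. Brute-force enumeration of this
    space provides the ground-truth optimum against which the
    evolutionary search is validated.
    """

    config: "GAConfig"
    free_positions: tuple[int, ...]
    options: tuple[tuple[str, ...], ...]

    def build(self, choices) -> tuple:
        """Helix set for one assignment of the free positions (A then B)."""
        from .peptides import CollagenPeptide

        per = len(self.free_positions)
        motif = self.config.slot_motifs()[0]
        start = self.config.motif_masks[0][0]
        sets = []
        for slot, name in enumerate("AB"):
            res = [None] * self.config.peptide_length
            for i in range(self.config.peptide_length):
                if start <= i < start + len(motif):
                    res[i] = motif[i - start]
                elif (i - self.config.frame_offset) % 3 == 0:
                    res[i] = "G"
            for pos, ch in zip(self.free_positions, choices[slot * per:][:per]):
                res[pos] = ch
            sets.append(
                CollagenPeptide(id=name, residues="".join(res), frame_offset=0)
            )
        return tuple(sets)

    def all_choices(self):
        import itertools

        return itertools.product(*(self.options * 2))


def toy_design_space(
    rng_seed: int = 0, population_size: int = 30, max_rounds: int = 250
) -> ToyDesignSpace:
    """Construct the standard 256-state toy problem (see ToyDesignSpace)."""
    from .ga import GAConfig, MotifSpec

    alphabet = set(ALPHABET)
    motif = "GPOGPOGPOGPOGPO"
    config = GAConfig(
        composition="A2B",
        peptide_length=21,
        population_size=population_size,
        # targets at the top of the allowed ranges are unattainable in
        # this space, so the search always spends its full round budget
        target_tm=70.0,
        target_specificity=35.0,
        excluded={"Xaa": alphabet - {"P", "D"}, "Yaa": alphabet - {"O", "K"}},
        motif=MotifSpec(leading=motif, trailing=motif),
        max_rounds=max_rounds,
        rng_seed=rng_seed,
    )
    return ToyDesignSpace(
        config=config,
        free_positions=(1, 2, 19, 20),
        options=(("P", "D"), ("O", "K"), ("P", "D"), ("O", "K")),
    )
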