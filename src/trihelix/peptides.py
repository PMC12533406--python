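"""Collagen-mimetic peptide strands: validation, position roles, generation, I/O.

A collagen-like strand repeats the obligatory Xaa-Yaa-Gly triplet. Residues
are drawn from the 20 canonical one-letter amino-acid codes plus ``O`` for
(4R)-4-hydroxyproline (Hyp). The *frame offset* records which position of
the first triplet carries glycine:

====== ================ =======================
offset first triplet    example
====== ================ =======================
0      Gly-Xaa-Yaa      ``GPOGPO...``
1      Yaa-Gly-Xaa      ``OGPOGP...``
2      Xaa-Yaa-Gly      ``POGPOG...`` (canonical notation)
====== ================ =======================

Strands are assumed N-terminally acetylated and C-terminally amidated
unless flagged otherwise; uncapped termini are penalized by the scoring
model, not rejected here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, ConfigError, FastaError, FrameError

#: 20 canonical residues plus "O" (4-hydroxyproline).
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYO")

#: Residues eligible at Xaa/Yaa positions by default. Glycine is reserved
#: for the obligatory Gly slots and is not proposed at Xaa/Yaa unless the
#: caller explicitly allows it.
XY_ALPHABET = tuple(sorted(ALPHABET - {"G"}))

#: Length bounds for generated strands (user-supplied strands for
#: scoring-only use may fall outside this window).
MIN_LENGTH = 21
MAX_LENGTH = 40

ROLE_GLY = "Gly"
ROLE_XAA = "Xaa"
ROLE_YAA = "Yaa"

# (index - frame_offset) mod 3 -> role. The Xaa two before a Gly and the
# Yaa one before it belong to that Gly's triplet.
_ROLE_BY_PHASE = {0: ROLE_GLY, 1: ROLE_XAA, 2: ROLE_YAA}


@dataclass(frozen=True)
class CollagenPeptide:
    """One validated strand.

    Instances are produced by :func:`validate_sequence` or the generator
    functions; the dataclass itself performs no checking so that hot GA
    loops can rebuild strands cheaply while maintaining the invariants by
    construction.
    """

    id: str
    residues: str
    frame_offset: int
    n_term_acetylated: bool = True
    c_term_amidated: bool = True

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def gly_positions(self) -> tuple[int, ...]:
        return tuple(range(self.frame_offset, len(self.residues), 3))


@dataclass(frozen=True)
class PositionRole:
    """Role (Xaa/Yaa/Gly) and owning triplet of one residue position."""

    role: str
    triplet_index: int


def role_of(peptide: CollagenPeptide, index: int) -> PositionRole:
    """Role of the residue at ``index``, fully determined by the frame.

    Triplet ``n`` owns the Gly at ``frame_offset + 3n`` together with the
    Xaa two positions before it and the Yaa one position before it.
    """
    if not 0 <= index < len(peptide.residues):
        raise IndexError(
            f"index {index} out of range for {len(peptide.residues)}-mer"
        )
    phase = (index - peptide.frame_offset) % 3
    triplet = (index - peptide.frame_offset + 2) // 3
    return PositionRole(_ROLE_BY_PHASE[phase], triplet)


def _check_alphabet(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise AlphabetError(f"invalid residue {ch!r} at position {i}")


def infer_frame(seq: str) -> int:
    """Frame offset implied by the Gly positions of ``seq``.

    A frame fits when every position congruent to it (mod 3) is Gly and no
    Gly occurs elsewhere. Sequences shorter than one full triplet are
    rejected rather than guessed.
    """
    if len(seq) < 3:
        raise FrameError("sequence shorter than one triplet; cannot infer frame")
    fits = [
        f
        for f in (0, 1, 2)
        if all((ch == "G") == ((i - f) % 3 == 0) for i, ch in enumerate(seq))
    ]
    if not fits:
        raise FrameError("glycine pattern fits no single Xaa-Yaa-Gly frame")
    if len(fits) > 1:  # only possible for pathological short inputs
        raise FrameError("glycine pattern is ambiguous between frames")
    return fits[0]


def validate_sequence(
    raw: str,
    frame_offset: Optional[int] = None,
    *,
    id: str = "pep",
    permissive: bool = False,
    n_term_acetylated: bool = True,
    c_term_amidated: bool = True,
) -> CollagenPeptide:
    """Validate ``raw`` into a :class:`CollagenPeptide`.

    Input is case-insensitive and stored uppercase. When ``frame_offset``
    is ``None`` it is inferred from the Gly positions. Strict validation
    (the default) requires Gly at every on-frame position and nowhere
    else; ``permissive=True`` relaxes both directions for scoring exotic
    user strands, which the designer itself never produces.
    """
    seq = raw.strip().upper()
    if not seq:
        raise AlphabetError("empty sequence")
    _check_alphabet(seq)
    if frame_offset is None:
        frame_offset = infer_frame(seq)
    elif frame_offset not in (0, 1, 2):
        raise FrameError(f"frame offset must be 0, 1 or 2, got {frame_offset}")
    if not permissive:
        for i, ch in enumerate(seq):
            on_frame = (i - frame_offset) % 3 == 0
            if on_frame and ch != "G":
                raise FrameError(
                    f"expected Gly at position {i} (frame {frame_offset}), found {ch!r}"
                )
            if not on_frame and ch == "G":
                raise FrameError(
                    f"off-frame Gly at position {i} (frame {frame_offset})"
                )
    return CollagenPeptide(
        id=id,
        residues=seq,
        frame_offset=frame_offset,
        n_term_acetylated=n_term_acetylated,
        c_term_amidated=c_term_amidated,
    )


def allowed_residues(
    role: str,
    excluded: Optional[Mapping[str, Iterable[str]]] = None,
    *,
    allow_gly: bool = False,
) -> tuple[str, ...]:
    """Sorted alphabet allowed at an Xaa or Yaa position.

    ``excluded`` maps role name ("Xaa"/"Yaa") to residues barred from that
    role. An exclusion set that empties the alphabet is a configuration
    error.
    """
    if role not in (ROLE_XAA, ROLE_YAA):
        raise ValueError(f"no substitution alphabet for role {role!r}")
    base = set(XY_ALPHABET) | ({"G"} if allow_gly else set())
    if excluded:
        barred = {r.upper() for r in excluded.get(role, ())}
        unknown = barred - ALPHABET
        if unknown:
            raise ConfigError(f"excluded residues not in alphabet: {sorted(unknown)}")
        base -= barred
    if not base:
        raise ConfigError(f"exclusions leave no allowed residue at {role}")
    return tuple(sorted(base))


def random_peptide(
    length: int,
    frame_offset: Optional[int] = None,
    excluded: Optional[Mapping[str, Iterable[str]]] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    id: str = "pep",
    allow_gly_xy: bool = False,
    relax_length: bool = False,
) -> CollagenPeptide:
    """Random Gly-periodic strand with uniform Xaa/Yaa draws.

    The frame offset is drawn uniformly from {0, 1, 2} when not given, so
    a population of random strands represents all three frames.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not relax_length and not MIN_LENGTH <= length <= MAX_LENGTH:
        raise ConfigError(
            f"length {length} outside [{MIN_LENGTH},{MAX_LENGTH}]"
        )
    if frame_offset is None:
        frame_offset = int(rng.integers(3))
    xaa = allowed_residues(ROLE_XAA, excluded, allow_gly=allow_gly_xy)
    yaa = allowed_residues(ROLE_YAA, excluded, allow_gly=allow_gly_xy)
    chars = []
    for i in range(length):
        phase = (i - frame_offset) % 3
        if phase == 0:
            chars.append("G")
        elif phase == 1:
            chars.append(xaa[int(rng.integers(len(xaa)))])
        else:
            chars.append(yaa[int(rng.integers(len(yaa)))])
    return CollagenPeptide(id=id, residues="".join(chars), frame_offset=frame_offset)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, *, permissive: bool = False) -> list[CollagenPeptide]:
    """Read strands from FASTA; ``O`` is accepted in sequence lines."""
    peptides = []
    for idx, record in enumerate(SeqIO.parse(str(path), "fasta")):
        try:
            peptides.append(
                validate_sequence(str(record.seq), id=record.id, permissive=permissive)
            )
        except (AlphabetError, FrameError) as exc:
            raise FastaError(f"record {idx} ({record.id!r}): {exc}") from exc
    return peptides


def write_fasta(peptides: Sequence[CollagenPeptide], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_plain(path: str | Path, *, permissive: bool = False) -> list[CollagenPeptide]:
    """Read one sequence per line, optionally ``id<TAB>sequence``."""
    peptides = []
    for idx, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            name, seq = line.split("\t", 1)
        else:
            name, seq = f"pep{len(peptides) + 1}", line
        try:
            peptides.append(validate_sequence(seq, id=name, permissive=permissive))
        except (AlphabetError, FrameError) as exc:
            raise FastaError(f"line {idx + 1}: {exc}") from exc
    return peptides
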