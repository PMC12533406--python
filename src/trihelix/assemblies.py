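"""Enumeration of triple-helical species and their interstrand contacts.

Mixing up to three distinct strands yields every ordered (leading, middle,
trailing) triple: 1 homotrimer for one peptide, 8 species for two (two
homotrimers plus three registers each of A2B and AB2), 27 for three.
Identity is the *ordered* triple — {ABB}, {BAB} and {BBA} are distinct
registers of the same composition.

Under the canonical one-residue stagger, interstrand pairwise contacts
come in two geometries:

* axial   — Yaa of triplet *n* on one strand with Xaa of triplet *n*\\ +1
  on the adjacent strand (roughly parallel to the helix axis);
* lateral — Yaa of triplet *n* with Xaa of the same triplet *n* on the
  neighbouring strand (roughly perpendicular).

Adjacency runs leading→middle and middle→trailing; closing the cycle,
the trailing strand sits one further triplet behind the leading strand,
so the trailing→leading pair is emitted with its acceptor triplet index
shifted by +1. The closure is isolated behind the ``closure`` switch
(``"cyclic"`` default, ``"open"`` drops the trailing→leading pair).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError, FrameError
from .peptides import CollagenPeptide

#: (donor strand, acceptor strand, extra triplet shift) per adjacency.
_PAIRS_CYCLIC = ((0, 1, 0), (1, 2, 0), (2, 0, 1))
_PAIRS_OPEN = ((0, 1, 0), (1, 2, 0))


@dataclass(frozen=True)
class HelixAssembly:
    """An ordered (leading, middle, trailing) triple of strands."""

    strands: tuple[CollagenPeptide, CollagenPeptide, CollagenPeptide]
    indices: tuple[int, int, int]  # positions in the input peptide list

    @property
    def register_ids(self) -> tuple[str, str, str]:
        return tuple(s.id for s in self.strands)

    @property
    def register_label(self) -> str:
        """Curly-brace register label, leading-middle-trailing order."""
        return "{" + "".join(self.register_ids) + "}"

    @property
    def composition_label(self) -> str:
        """Multiset label such as ``A3``, ``A2B``, ``ABC``."""
        counts = Counter(self.register_ids)
        return "".join(
            f"{name}{n}" if n > 1 else name for name, n in sorted(counts.items())
        )

    @property
    def length(self) -> int:
        return len(self.strands[0].residues)


@dataclass(frozen=True)
class Contact:
    """One axial or lateral Yaa→Xaa pairing between adjacent strands."""

    geometry: str  # "axial" | "lateral"
    yaa_residue: str
    xaa_residue: str
    donor_strand: int
    acceptor_strand: int
    donor_triplet: int
    acceptor_triplet: int
    yaa_index: int
    xaa_index: int


def enumerate_assemblies(
    peptides: Sequence[CollagenPeptide],
) -> list[HelixAssembly]:
    """All ``k**3`` ordered triples formable from ``k`` (1-3) peptides.

    Output order is deterministic: lexicographic by register label.
    Strands must share one length; every designed set does, and the
    contact geometry is only defined for equal-length strands.
    """
    if not peptides:
        raise ConfigError("no peptides given")
    if len(peptides) > 3:
        raise ConfigError(f"at most 3 distinct peptides supported, got {len(peptides)}")
    lengths = {len(p.residues) for p in peptides}
    if len(lengths) > 1:
        raise ConfigError(f"strands must share one length, got {sorted(lengths)}")
    out = [
        HelixAssembly(
            strands=(peptides[i], peptides[j], peptides[k]), indices=(i, j, k)
        )
        for i, j, k in itertools.product(range(len(peptides)), repeat=3)
    ]
    out.sort(key=lambda a: (a.register_ids, a.indices))
    return out


def pairwise_contacts(
    assembly: HelixAssembly, *, closure: str = "cyclic"
) -> list[Contact]:
    """Every in-bounds axial and lateral contact of ``assembly``.

    Requires all three strands to share one frame offset (the canonical
    stagger keeps Gly at every cross-section only for aligned frames).
    """
    if closure == "cyclic":
        pairs = _PAIRS_CYCLIC
    elif closure == "open":
        pairs = _PAIRS_OPEN
    else:
        raise ConfigError(f"closure must be 'cyclic' or 'open', got {closure!r}")
    strands = assembly.strands
    f = strands[0].frame_offset
    if any(s.frame_offset != f for s in strands):
        raise FrameError(
            "strand frames are not aligned: "
            + ", ".join(f"{s.id}={s.frame_offset}" for s in strands)
        )
    contacts: list[Contact] = []
    for donor, acceptor, shift in pairs:
        sd, sa = strands[donor], strands[acceptor]
        t = 0
        while True:
            iy = f + 3 * t - 1  # Yaa of triplet t
            if iy >= len(sd.residues):
                break
            if iy >= 0:
                for geometry, tshift in (("lateral", shift), ("axial", shift + 1)):
                    ta = t + tshift
                    ix = f + 3 * ta - 2  # Xaa of triplet ta
                    if 0 <= ix < len(sa.residues):
                        contacts.append(
                            Contact(
                                geometry=geometry,
                                yaa_residue=sd.residues[iy],
                                xaa_residue=sa.residues[ix],
                                donor_strand=donor,
                                acceptor_strand=acceptor,
                                donor_triplet=t,
                                acceptor_triplet=ta,
                                yaa_index=iy,
                                xaa_index=ix,
                            )
                        )
            t += 1
    return contacts


def assembly_record(assembly: HelixAssembly, *, closure: str = "cyclic") -> dict:
    """JSON-serializable debug record of one assembly and its contacts."""
    return {
        "register": assembly.register_label,
        "composition": assembly.composition_label,
        "strand_ids": list(assembly.register_ids),
        "contacts": [
            {
                "geometry": c.geometry,
                "pair": f"{c.yaa_residue}:{c.xaa_residue}",
                "strands": [c.donor_strand, c.acceptor_strand],
                "triplets": [c.donor_triplet, c.acceptor_triplet],
            }
            for c in pairwise_contacts(assembly, closure=closure)
        ],
    }
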