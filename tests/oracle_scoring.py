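"""Independent brute-force oracle for the additive stability model.

Re-derives every term of the predicted melting temperature from first
principles — triplet bookkeeping via the explicit Gly-position list and
contacts via an exhaustive double loop over residue index pairs with a
geometric predicate — sharing no walking code with the package scorer.
"""

from __future__ import annotations


def _gly_anchors(strand) -> list[int]:
    """Gly positions plus one virtual anchor past the end, so Xaa/Yaa
    residues of a partial trailing triplet still get a triplet number."""
    glys = [i for i in range(strand.frame_offset, len(strand.residues), 3)]
    return glys + [glys[-1] + 3]


def _yaa_sites(strand) -> dict[int, int]:
    """Map residue index -> triplet number for every Yaa in the strand."""
    L = len(strand.residues)
    return {g - 1: t for t, g in enumerate(_gly_anchors(strand)) if 0 <= g - 1 < L}


def _xaa_sites(strand) -> dict[int, int]:
    L = len(strand.residues)
    return {g - 2: t for t, g in enumerate(_gly_anchors(strand)) if 0 <= g - 2 < L}


def oracle_contacts(assembly, closure: str = "cyclic") -> list[tuple]:
    """(geometry, Yaa residue, Xaa residue, donor, acceptor) tuples."""
    adjacency = [(0, 1, 0), (1, 2, 0)]
    if closure == "cyclic":
        adjacency.append((2, 0, 1))
    found = []
    for d, a, shift in adjacency:
        donor, acceptor = assembly.strands[d], assembly.strands[a]
        for iy, ty in _yaa_sites(donor).items():
            for ix, tx in _xaa_sites(acceptor).items():
                if tx == ty + shift:
                    found.append(
                        ("lateral", donor.residues[iy], acceptor.residues[ix], d, a)
                    )
                elif tx == ty + shift + 1:
                    found.append(
                        ("axial", donor.residues[iy], acceptor.residues[ix], d, a)
                    )
    return found


def oracle_tm(assembly, params, closure: str = "cyclic") -> float:
    """Full additive Tm, summed position by position and contact by contact."""
    total = params.baseline_tm[len(assembly.strands[0].residues)]
    for strand in assembly.strands:
        for ix in _xaa_sites(strand):
            total += params.xaa_propensity[strand.residues[ix]]
        for iy in _yaa_sites(strand):
            total += params.yaa_propensity[strand.residues[iy]]
    for geometry, y, x, _, _ in oracle_contacts(assembly, closure):
        table = (
            params.axial_interaction
            if geometry == "axial"
            else params.lateral_interaction
        )
        total += table.get((y, x), 0.0)
    total += params.frameshift_correction.get(
        str(assembly.strands[0].frame_offset), 0.0
    )
    for strand in assembly.strands:
        for end, res, capped in (
            ("nterm", strand.residues[0], strand.n_term_acetylated),
            ("cterm", strand.residues[-1], strand.c_term_amidated),
        ):
            state = "capped" if capped else "uncapped"
            table = params.terminal_correction
            total += table.get(
                f"{end}:{res}:{state}", table.get(f"{end}:*:{state}", 0.0)
            )
    return total
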