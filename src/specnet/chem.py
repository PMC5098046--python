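"""Peptide mass arithmetic.

Monoisotopic residue masses, parsing of peptide strings carrying bracketless
signed mass offsets (e.g. ``"PEPT+15.995IDE"`` for an oxidation on T, or a
leading ``"+42.011PEPTIDE"`` for an N-terminal offset), and theoretical
fragment/prefix mass lists used throughout alignment, localization and
simulation.
"""

from __future__ import annotations

import re

import numpy as np

PROTON = 1.007276
H2O = 18.010565
NH3 = 17.026549
C13_SHIFT = 1.003355

#: Monoisotopic residue (not amino acid) masses, Da.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

_TOKEN = re.compile(r"([A-Z])|([+-]\d+(?:\.\d+)?)")


def parse_peptide(peptide: str) -> tuple[str, np.ndarray]:
    """Split a peptide string into its residue sequence and per-residue offsets.

    A signed number applies to the residue immediately preceding it; a
    leading signed number (N-terminal offset) is attached to the first
    residue. Returns ``(sequence, offsets)`` with ``offsets`` of the same
    length as ``sequence``.

    Raises ``ValueError`` on empty input, unknown residue letters, or
    malformed offset syntax.
    """
    if not peptide:
        raise ValueError("empty peptide string")
    seq: list[str] = []
    offs: list[float] = []
    nterm = 0.0
    pos = 0
    for m in _TOKEN.finditer(peptide):
        if m.start() != pos:
            raise ValueError(f"unparseable peptide {peptide!r} at position {pos}")
        pos = m.end()
        if m.group(1):
            aa = m.group(1)
            if aa not in RESIDUE_MASS:
                raise ValueError(f"unknown amino acid {aa!r} in {peptide!r}")
            seq.append(aa)
            offs.append(0.0)
        else:
            delta = float(m.group(2))
            if not np.isfinite(delta):
                raise ValueError(f"non-finite mass offset in {peptide!r}")
            if not seq:
                nterm += delta
            else:
                offs[-1] += delta
    if pos != len(peptide):
        raise ValueError(f"unparseable peptide {peptide!r} at position {pos}")
    if not seq:
        raise ValueError(f"peptide {peptide!r} contains no residues")
    offsets = np.asarray(offs, dtype=float)
    offsets[0] += nterm
    return "".join(seq), offsets


def format_peptide(seq: str, offsets: np.ndarray | None = None) -> str:
    """Inverse of :func:`parse_peptide` (offsets rendered to 5 decimals)."""
    if offsets is None:
        return seq
    out = []
    for aa, off in zip(seq, offsets):
        out.append(aa)
        if abs(off) > 1e-9:
            out.append(f"{off:+.5f}".rstrip("0").rstrip("."))
    return "".join(out)


def peptide_mass(seq: str, offsets: np.ndarray | None = None) -> float:
    """Neutral monoisotopic mass of a (possibly offset-carrying) peptide."""
    m = sum(RESIDUE_MASS[a] for a in seq) + H2O
    if offsets is not None:
        m += float(np.sum(offsets))
    return m


def prefix_masses(seq: str, offsets: np.ndarray | None = None) -> np.ndarray:
    """Cumulative residue masses at the L-1 internal bonds (N-terminal side)."""
    res = np.array([RESIDUE_MASS[a] for a in seq], dtype=float)
    if offsets is not None:
        res = res + offsets
    return np.cumsum(res)[:-1]


def theoretical_by_masses(seq: str, offsets: np.ndarray | None = None) -> np.ndarray:
    """Sorted singly charged b and y fragment masses of a peptide."""
    pm = prefix_masses(seq, offsets)
    total = peptide_mass(seq, offsets)
    b = pm + PROTON
    y = (total - H2O - pm) + H2O + PROTON
    return np.sort(np.concatenate([b, y]))
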