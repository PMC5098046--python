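"""Pairwise alignment of PRM spectra allowing at most one mass offset.

Two spectra whose precursor masses differ by delta are aligned under a
single-breakpoint model: prefix masses up to the breakpoint match directly,
prefix masses beyond it match after shifting by delta. This is exactly the
effect of one modification, mutation, or terminal truncation: every fragment
C-terminal of the event moves by delta in prefix-mass space. The alignment
maximizes the summed matched score on both sides (T1 + T2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Config
from .prm import PRMSpectrum


@dataclass
class AlignmentResult:
    """A scored spectrum pair.

    ``t1``/``t2`` are the summed scores of matched peaks on each side;
    ``breakpoint`` is the prefix mass at which matching switches from
    unshifted to shifted; ``matched_pairs`` holds (index in s1, index in
    s2, shifted) triples. ``p1``/``p2``/``pair_p`` are filled in by the
    alignment-significance stage.
    """

    id_1: str
    id_2: str
    delta_mass: float
    breakpoint: float
    t1: float
    t2: float
    matched_pairs: list[tuple[int, int, bool]] = field(default_factory=list)
    p1: float | None = None
    p2: float | None = None
    pair_p: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_1, self.id_2)


def _candidates(m1: np.ndarray, m2: np.ndarray, shift: float,
                tol: float) -> list[tuple[float, int, int]]:
    """(|mass error|, i, j) for every s1/s2 peak pair within tolerance."""
    shifted_m = m1 + shift
    lo = np.searchsorted(m2, shifted_m - tol, side="left")
    hi = np.searchsorted(m2, shifted_m + tol, side="right")
    out = []
    for i in range(m1.size):
        for j in range(lo[i], hi[i]):
            out.append((abs(shifted_m[i] - m2[j]), i, j))
    out.sort()
    return out


def align_pair(s1: PRMSpectrum, s2: PRMSpectrum,
               config: Config | None = None) -> AlignmentResult:
    """Align two PRM spectra allowing up to one mass offset.

    Scans every breakpoint b in {0} ∪ {prefix masses of s1} ∪ {M1}: peaks of
    s1 at mass <= b are matched unshifted, peaks above b are matched after
    shifting by delta = M2 - M1. Returns the breakpoint maximizing T1 + T2
    (ties to the smallest breakpoint). When |delta| is within the precursor
    grouping tolerance only the unshifted matching is used.

    Callers orient pairs so s1 is the lighter spectrum; |delta| must not
    exceed the configured maximum modification mass.
    """
    cfg = config or Config()
    if s1.n_peaks == 0 or s2.n_peaks == 0:
        raise ValueError(f"empty PRM spectrum in pair ({s1.spectrum_id}, "
                         f"{s2.spectrum_id})")
    delta = s2.precursor_mass - s1.precursor_mass
    if abs(delta) > cfg.max_mod_mass_da:
        raise ValueError(
            f"|delta| = {abs(delta):.3f} exceeds max_mod_mass_da "
            f"({cfg.max_mod_mass_da})")
    tol = cfg.fragment_tolerance_da
    m1, m2 = s1.masses, s2.masses

    unshifted_only = abs(delta) <= cfg.precursor_tolerance_da
    if unshifted_only:
        breakpoints: list[float] = [s1.precursor_mass]
    else:
        breakpoints = [0.0] + [float(x) for x in m1] + [s1.precursor_mass]

    cand_u = _candidates(m1, m2, 0.0, tol)
    cand_s = [] if unshifted_only else _candidates(m1, m2, delta, tol)

    best: AlignmentResult | None = None
    for b in breakpoints:
        # merge the two sorted candidate streams, honoring the breakpoint:
        # unshifted matches use s1 peaks at mass <= b, shifted ones above it
        used1 = np.zeros(m1.size, dtype=bool)
        used2 = np.zeros(m2.size, dtype=bool)
        pairs: list[tuple[int, int, bool]] = []
        iu = isft = 0
        while iu < len(cand_u) or isft < len(cand_s):
            take_u = (isft >= len(cand_s)
                      or (iu < len(cand_u) and cand_u[iu] <= cand_s[isft]))
            if take_u:
                _, i, j = cand_u[iu]
                iu += 1
                ok = m1[i] <= b
                shifted = False
            else:
                _, i, j = cand_s[isft]
                isft += 1
                ok = m1[i] > b
                shifted = True
            if ok and not used1[i] and not used2[j]:
                used1[i] = used2[j] = True
                pairs.append((i, j, shifted))
        t1 = float(s1.scores[used1].sum())
        t2 = float(s2.scores[used2].sum())
        if best is None or t1 + t2 > best.t1 + best.t2 + 1e-12:
            best = AlignmentResult(s1.spectrum_id, s2.spectrum_id, delta,
                                   b, t1, t2, pairs)
    assert best is not None
    best.matched_pairs.sort()
    return best
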