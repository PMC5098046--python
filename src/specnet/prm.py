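"""Conversion of MS/MS spectra into scored prefix-residue-mass (PRM) spectra.

Each observed fragment peak is interpreted as b- or y-type evidence for a
peptide-bond prefix mass; corroborating ion channels (neutral losses, doubly
charged ions, the +1 isotope) add evidence at the same prefix mass. Scores
are rank-based log-likelihood-style values and candidate masses whose total
score is non-positive are removed, so that true bond positions keep high
scores while unsupported interpretations and noise drop out.

The scorer is deliberately transparent and untrained; it is pluggable so a
trained fragmentation model can be substituted. The downstream alignment
p-value machinery only requires positive peak scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .chem import C13_SHIFT, H2O, NH3, PROTON
from .config import Config, log
from .spectra_io import Spectrum


@dataclass
class PRMSpectrum:
    """Scored prefix-residue-mass representation of one spectrum."""

    spectrum_id: str
    precursor_mass: float
    masses: np.ndarray   # strictly increasing, in (0, precursor_mass)
    scores: np.ndarray   # strictly positive

    @property
    def n_peaks(self) -> int:
        return int(self.masses.size)

    @property
    def total_score(self) -> float:
        return float(self.scores.sum())


def theoretical_prm(spectrum_id: str, precursor_mass: float,
                    prefix_masses: np.ndarray, score: float = 5.0) -> PRMSpectrum:
    """A noiseless PRM spectrum with uniform scores at given prefix masses."""
    pm = np.sort(np.asarray(prefix_masses, dtype=float))
    return PRMSpectrum(spectrum_id, precursor_mass, pm,
                       np.full(pm.size, float(score)))


# Expected observed fragment m/z for a candidate prefix mass p in a peptide of
# neutral mass M. y-type masses use the complementary suffix M - H2O - p.
_CHANNELS: dict[str, Callable[[float, float], float]] = {
    "b": lambda p, M: p + PROTON,
    "y": lambda p, M: (M - p) + PROTON,
    "b-H2O": lambda p, M: p + PROTON - H2O,
    "b-NH3": lambda p, M: p + PROTON - NH3,
    "y-H2O": lambda p, M: (M - p) + PROTON - H2O,
    "y-NH3": lambda p, M: (M - p) + PROTON - NH3,
    "b2": lambda p, M: (p + 2 * PROTON) / 2.0,
    "y2": lambda p, M: ((M - p) + 2 * PROTON) / 2.0,
    "b+iso": lambda p, M: p + PROTON + C13_SHIFT,
    "y+iso": lambda p, M: (M - p) + PROTON + C13_SHIFT,
}

_MAJOR = ("b", "y")


def _resolve_mirrors(masses: np.ndarray, scores: np.ndarray,
                     dual: np.ndarray, M: float,
                     tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Keep the better-supported of each complementary candidate pair.

    Interpreting one fragment peak as both b and y evidence places
    candidates at p and M - p; when only one of them is a real bond, the
    strictly lower-scoring candidate is dropped. The b/y channel-weight
    asymmetry makes the true interpretation score higher whenever y ions
    dominate b ions in intensity.

    Two *true* bonds whose prefix masses sum to ~M produce coincident b/y
    fragment peaks; such candidates carry two peaks in each primary-channel
    window (``dual``) and are never dropped, so real bonds are not lost to
    the competition.
    """
    if masses.size < 2:
        return masses, scores
    drop = np.zeros(masses.size, dtype=bool)
    mirror = M - masses
    lo = np.searchsorted(masses, mirror - tol, side="left")
    hi = np.searchsorted(masses, mirror + tol, side="right")
    for i in range(masses.size):
        if dual[i]:
            continue
        for j in range(lo[i], hi[i]):
            if j != i and scores[j] > scores[i] + 1e-9:
                drop[i] = True
                break
    return masses[~drop], scores[~drop]


def to_prm(spectrum: Spectrum, config: Config | None = None) -> PRMSpectrum:
    """Convert a spectrum into a scored PRM spectrum.

    Candidate prefix masses are the b- and y-interpretations of every
    observed peak. Each candidate is scored over all ion channels: a channel
    supported by a peak of intensity rank r among R peaks contributes
    ``weight * max(0, log(((R - r + 1)/R) / null_rate))``; an unsupported
    primary (b/y) channel subtracts ``major_miss_penalty``. Candidates with
    non-positive total score are dropped; the ``peak_cap`` highest-scoring
    survivors are kept, sorted by mass.
    """
    cfg = config or Config()
    M = spectrum.precursor_mass
    tol = cfg.fragment_tolerance_da
    min_res = 57.0  # glycine, lightest residue
    if M <= min_res:
        log.warning("%s: precursor mass %.2f too small for any residue",
                    spectrum.spectrum_id, M)
        return PRMSpectrum(spectrum.spectrum_id, M, np.empty(0), np.empty(0))
    if spectrum.n_peaks == 0:
        raise ValueError(f"{spectrum.spectrum_id}: spectrum has no peaks")

    mz = spectrum.mz
    R = spectrum.n_peaks
    # rank 1 = most intense; rank quantile (R - r + 1)/R in (0, 1]
    rank = np.empty(R, dtype=float)
    rank[np.argsort(-spectrum.intensity, kind="stable")] = np.arange(1, R + 1)
    quantile = (R - rank + 1.0) / R

    # candidate prefix masses from primary interpretations
    cand = np.concatenate([mz - PROTON, M - mz + PROTON])
    cand = cand[(cand > tol) & (cand < M - tol)]
    if cand.size == 0:
        return PRMSpectrum(spectrum.spectrum_id, M, np.empty(0), np.empty(0))
    cand = np.sort(cand)
    # merge candidates closer than the tolerance into clusters
    groups = np.concatenate([[0], np.cumsum(np.diff(cand) > tol)])
    centers = np.array([cand[groups == g].mean() for g in range(groups[-1] + 1)])

    masses, scores, dual = [], [], []
    for p in centers:
        total = 0.0
        major_counts = {}
        for name, fmz in _CHANNELS.items():
            w = cfg.channel_weights.get(name, 0.0)
            if w <= 0:
                continue
            expect = fmz(p, M)
            lo = np.searchsorted(mz, expect - tol, side="left")
            hi = np.searchsorted(mz, expect + tol, side="right")
            if name in _MAJOR:
                major_counts[name] = hi - lo
            if hi > lo:
                q = quantile[lo:hi].max()
                total += w * max(0.0, np.log(q / cfg.channel_null_rate))
            elif name in _MAJOR:
                total -= w * cfg.major_miss_penalty
        if total > 0:
            masses.append(p)
            scores.append(total)
            dual.append(min(major_counts.values()) >= 2)

    masses_a = np.asarray(masses)
    scores_a = np.asarray(scores)
    dual_a = np.asarray(dual, dtype=bool)
    masses_a, scores_a = _resolve_mirrors(masses_a, scores_a, dual_a, M, tol)
    if masses_a.size > cfg.peak_cap:
        # keep top-scoring peaks, ties to lower mass
        order = np.lexsort((masses_a, -scores_a))[: cfg.peak_cap]
        keep = np.sort(order)
        masses_a, scores_a = masses_a[keep], scores_a[keep]
    return PRMSpectrum(spectrum.spectrum_id, M, masses_a, scores_a)
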