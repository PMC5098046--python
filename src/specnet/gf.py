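"""Exact alignment-score null distributions by generating functions.

For a PRM spectrum S with N peaks, every possible alignment against S is a
subset of its peaks; a subset with m peaks occurs under the null with
probability theta^m (1-theta)^(N-m), where theta is the probability that a
random spectrum matches any given peak. The distribution of subset scores
over all 2^N subsets is computed exactly by dynamic programming on a
discretized score grid:

    D[i, t] = theta * D[i-1, t - score(i)] + (1 - theta) * D[i-1, t]

with D[0, 0] = 1. The p-value of an observed alignment score T against S is
the tail sum of the final row at T. A spectrum pair is accepted when both of
its per-side p-values clear the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .align import AlignmentResult, align_pair
from .config import Config
from .prm import PRMSpectrum


@dataclass
class ScoreHistogram:
    """Exact null distribution of alignment scores against one spectrum."""

    spectrum_id: str
    theta: float
    grid: float
    density: np.ndarray      # index t = score bin, density[t] = D[N, t]
    survival: np.ndarray     # survival[t] = sum_{u >= t} density[u]

    @property
    def max_score(self) -> float:
        return (self.density.size - 1) * self.grid


def discretize_scores(scores: np.ndarray, grid: float) -> np.ndarray:
    """Round peak scores to integer grid units; positive scores stay >= 1."""
    s = np.rint(np.asarray(scores, dtype=float) / grid).astype(np.int64)
    return np.maximum(s, 1)


def build_histogram(s: PRMSpectrum, theta: float | None = None,
                    config: Config | None = None) -> ScoreHistogram:
    """Exact score histogram of all 2^N alignments against ``s``."""
    cfg = config or Config()
    th = cfg.theta if theta is None else theta
    if not 0.0 < th < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {th}")
    grid = cfg.score_grid
    si = discretize_scores(s.scores, grid) if s.n_peaks else np.empty(0, np.int64)
    total = int(si.sum())
    D = np.zeros(total + 1)
    D[0] = 1.0
    for sc in si:
        nxt = (1.0 - th) * D
        nxt[sc:] += th * D[:-sc] if sc else th * D
        D = nxt
    surv = np.cumsum(D[::-1])[::-1]
    return ScoreHistogram(s.spectrum_id, th, grid, D, surv)


def p_value(h: ScoreHistogram, T: float) -> float:
    """Probability that a random alignment scores at least T.

    T is rounded down to its grid bin, so the p-value never understates.
    """
    if T < 0:
        raise ValueError(f"alignment score must be >= 0, got {T}")
    t = int(np.floor(T / h.grid + 1e-9))
    if t <= 0:
        return 1.0
    if t >= h.survival.size:
        return 0.0
    return float(h.survival[t])


class HistogramCache:
    """Memoizes per-spectrum histograms across an all-vs-all pass."""

    def __init__(self, config: Config | None = None,
                 theta: float | None = None) -> None:
        self.config = config or Config()
        self.theta = self.config.theta if theta is None else theta
        self._cache: dict[str, ScoreHistogram] = {}

    def get(self, s: PRMSpectrum) -> ScoreHistogram:
        h = self._cache.get(s.spectrum_id)
        if h is None:
            h = build_histogram(s, self.theta, self.config)
            self._cache[s.spectrum_id] = h
        return h


def score_pair(s1: PRMSpectrum, s2: PRMSpectrum, config: Config | None = None,
               cache: HistogramCache | None = None) -> AlignmentResult:
    """Align two PRM spectra and attach exact per-side p-values.

    ``pair_p`` is max(p1, p2): the pair is only as significant as its
    weaker side, mirroring the requirement that both p-values clear the
    cutoff.
    """
    cfg = config or Config()
    cache = cache or HistogramCache(cfg)
    res = align_pair(s1, s2, cfg)
    res.p1 = p_value(cache.get(s1), res.t1)
    res.p2 = p_value(cache.get(s2), res.t2)
    res.pair_p = max(res.p1, res.p2)
    return res


def accepted(res: AlignmentResult, config: Config | None = None) -> bool:
    cfg = config or Config()
    return res.pair_p is not None and res.pair_p < cfg.pair_p_cutoff


def estimate_theta(prm_spectra: list[PRMSpectrum], rng: np.random.Generator,
                   n_trials: int = 1000, config: Config | None = None) -> float:
    """Estimate the random peak-match probability theta from decoys.

    Random theoretical prefix-mass lists (peptide-like residue ladders) are
    matched against the observed PRM spectra at the fragment tolerance; the
    returned estimate is the fraction of decoy masses that land within
    tolerance of some PRM peak.
    """
    from .chem import RESIDUE_MASS

    cfg = config or Config()
    tol = cfg.fragment_tolerance_da
    residues = np.array(sorted(RESIDUE_MASS.values()))
    hits = 0
    total = 0
    spectra = [s for s in prm_spectra if s.n_peaks > 0]
    if not spectra:
        raise ValueError("no non-empty PRM spectra to estimate theta from")
    for _ in range(n_trials):
        s = spectra[rng.integers(len(spectra))]
        length = int(rng.integers(8, 26))
        seq_masses = rng.choice(residues, size=length)
        decoy = np.cumsum(seq_masses)[:-1]
        decoy = decoy[decoy < s.precursor_mass]
        if decoy.size == 0:
            continue
        lo = np.searchsorted(s.masses, decoy - tol, side="left")
        hi = np.searchsorted(s.masses, decoy + tol, side="right")
        hits += int((hi > lo).sum())
        total += decoy.size
    if total == 0:
        raise ValueError("decoy trials produced no comparable masses")
    return hits / total


def gaussian_p_value(s: PRMSpectrum, T: float,
                     config: Config | None = None) -> float:
    """Gaussian approximation of the alignment-score null (baseline only).

    Approximates the Bernoulli subset-score sum by a normal with matched
    mean and variance. Kept solely as the comparison baseline for the exact
    generating-function p-value; not a supported scoring path.
    """
    cfg = config or Config()
    th = cfg.theta
    mean = th * s.scores.sum()
    var = th * (1 - th) * (s.scores ** 2).sum()
    if var <= 0:
        return 1.0 if T <= mean else 0.0
    return float(norm.sf(T, loc=mean, scale=np.sqrt(var)))
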