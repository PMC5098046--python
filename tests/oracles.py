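"""Independent reference implementations used to check the fast paths.

Deliberately written as plain, slow Python: the score-histogram oracle
enumerates all 2^N peak subsets, and the alignment oracle scans every
breakpoint with a naive matching loop. They share no code with the package
internals they verify.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_histogram(int_scores: list[int], theta: float) -> dict[int, float]:
    """Exact alignment-score distribution by full subset enumeration."""
    n = len(int_scores)
    density: dict[int, float] = {}
    for mask in itertools.product([0, 1], repeat=n):
        m = sum(mask)
        t = sum(s for s, bit in zip(int_scores, mask) if bit)
        density[t] = density.get(t, 0.0) + theta ** m * (1 - theta) ** (n - m)
    return density


def brute_force_align(m1, s1, m2, s2, delta, precursor_mass_1, tol,
                      precursor_tol):
    """Best (T1, T2, breakpoint) by scanning every breakpoint naively.

    Matching at a fixed breakpoint: all (i, j) peak pairs within tolerance
    (unshifted for s1 masses <= b, shifted by delta above b) taken greedily
    in order of |mass error| with ties to lower (i, j), one use per peak.
    """
    m1 = list(map(float, m1))
    m2 = list(map(float, m2))
    if abs(delta) <= precursor_tol:
        breakpoints = [precursor_mass_1]
    else:
        breakpoints = [0.0] + m1 + [precursor_mass_1]
    best = None
    for b in breakpoints:
        cands = []
        for i, x in enumerate(m1):
            shifted = x > b
            target = x + delta if shifted else x
            for j, y in enumerate(m2):
                if abs(target - y) <= tol:
                    cands.append((abs(target - y), i, j, shifted))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        used_i: set[int] = set()
        used_j: set[int] = set()
        for _, i, j, shifted in cands:
            if i not in used_i and j not in used_j:
                used_i.add(i)
                used_j.add(j)
        t1 = sum(s1[i] for i in used_i)
        t2 = sum(s2[j] for j in used_j)
        if best is None or t1 + t2 > best[0] + best[1] + 1e-12:
            best = (t1, t2, b)
    return best


def random_prm(rng: np.random.Generator, n_peaks: int, mass_range=(100.0, 1500.0),
               score_range=(0.5, 8.0)):
    """A random PRM-like (masses, scores, precursor_mass) triple."""
    hi = rng.uniform(mass_range[1] * 0.7, mass_range[1])
    masses = np.sort(rng.uniform(mass_range[0], hi, size=n_peaks))
    # enforce strict increase
    masses += np.arange(n_peaks) * 1e-6
    scores = rng.uniform(*score_range, size=n_peaks)
    return masses, scores, hi + rng.uniform(50, 150)
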