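"""Annotation propagation with modification localization and FDR control.

Seed peptide-spectrum matches annotate their nodes at depth 0. Propagation
then grows the annotated set one node at a time, always crossing the
lowest-p edge from an annotated to an unannotated node (globally, in the
manner of Prim's algorithm), so every node receives its annotation from its
best incoming edge and multi-event variants are reached through
intermediate one-event neighbors rather than in a single ambiguous jump.
The edge's precursor mass difference is attached and localized on arrival.
An annotation reached through n edges is correct only if its seed and all n
edges are correct, so its FDR is

    FDR_n = 1 - (1 - a) * (1 - r)^n

with a the seed FDR and r the edge FDR. The run-level (aggregate) FDR is
the ID_k-weighted mean of FDR_k over propagation steps k >= 1, and waves
are admitted only while the aggregate stays within the configured budget.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (RESIDUE_MASS, format_peptide, parse_peptide,
                   prefix_masses)
from .config import Config, log
from .network import SpectralNetwork
from .prm import PRMSpectrum


@dataclass
class Annotation:
    """A peptide assignment on a node with provenance and running FDR."""

    spectrum_id: str
    peptide: str
    source: str                  # "seed" | "propagated"
    n_steps: int = 0
    via_edge: tuple[str, str] | None = None
    parent: str | None = None    # annotated neighbor the peptide came from
    step_fdr_value: float = 0.0
    site: int | None = None      # localized modification site (0-based)
    localization: str = ""       # identity|modified|truncated|unlocalized
    delta_mass: float = 0.0


@dataclass
class PropagationState:
    """Per-wave identification counts and the running aggregate FDR."""

    a: float
    r: float
    fdr_threshold: float
    id_k: list[int] = field(default_factory=list)   # id_k[k] = IDs at step k
    aggregate_fdr: float = 0.0

    def summary(self) -> pd.DataFrame:
        rows = [{"step": k, "n_ids": n, "step_fdr": step_fdr(self.a, self.r, k)}
                for k, n in enumerate(self.id_k)]
        return pd.DataFrame(rows)


def step_fdr(a: float, r: float, n: int) -> float:
    """FDR of an annotation propagated n steps from a seed with FDR a.

    The annotation is correct only when the seed and every traversed edge
    are correct: 1 - (1 - a)(1 - r)^n.
    """
    if not (0 <= a < 1 and 0 <= r < 1):
        raise ValueError("a and r must be in [0, 1)")
    if n < 0:
        raise ValueError("n must be >= 0")
    return 1.0 - (1.0 - a) * (1.0 - r) ** n


def aggregate_fdr(id_k: list[int], a: float, r: float) -> float:
    """ID_k-weighted mean of step FDRs over propagation steps k >= 1."""
    num = sum(n * step_fdr(a, r, k) for k, n in enumerate(id_k) if k >= 1)
    den = sum(n for k, n in enumerate(id_k) if k >= 1)
    return num / den if den else 0.0


def localize_mod(peptide: str, delta: float, target: PRMSpectrum | None,
                 config: Config | None = None
                 ) -> tuple[str, int | None, float, str]:
    """Place a mass difference on the propagated peptide.

    Every residue is tried as the modification site (the site shifts all
    prefix masses C-terminal of it by delta). A negative delta matching the
    mass of a prefix or suffix of the peptide within the precursor
    tolerance adds truncation candidates, including variants in which the
    retained boundary residue sheds its own modification (a truncated form
    of the unmodified peptide). Each candidate's theoretical prefix ladder
    is scored as the sum of target PRM peak scores matched within the
    fragment tolerance; the highest score wins, with ties going to a
    truncation over a modification and then to the N-terminal-most site.
    Returns ``(annotated_peptide, site, score, kind)`` with kind one of
    ``identity``, ``modified``, ``truncated``, ``unlocalized``.
    """
    cfg = config or Config()
    seq, offs = parse_peptide(peptide)
    L = len(seq)
    if abs(delta) > cfg.max_mod_mass_da:
        raise ValueError(f"|delta| = {abs(delta):.3f} exceeds max_mod_mass_da")
    if abs(delta) <= cfg.precursor_tolerance_da:
        return peptide, None, _ladder_score(seq, offs, target, cfg), "identity"

    # every interpretation of the delta is a candidate peptide; the one whose
    # theoretical prefix ladder best explains the target PRM spectrum wins
    candidates: list[tuple[str, np.ndarray, int | None, str]] = []
    for j in range(L):
        if RESIDUE_MASS[seq[j]] + offs[j] + delta <= 0:
            continue  # a residue cannot lose more than its own mass
        mod = np.array(offs, copy=True)
        mod[j] += delta
        candidates.append((seq, mod, j, "modified"))
    if delta < 0:
        res = np.array([RESIDUE_MASS[aa] for aa in seq]) + offs
        cum = np.concatenate([[0.0], np.cumsum(res)])
        ptol = cfg.precursor_tolerance_da
        for i in range(1, L):
            # prefix of i residues lost; optionally the retained boundary
            # residue also loses its modification
            if abs(-delta - cum[i]) <= ptol:
                candidates.append((seq[i:], offs[i:].copy(), None, "truncated"))
            if offs[i] and abs(-delta - (cum[i] + offs[i])) <= ptol:
                stripped = offs[i:].copy()
                stripped[0] = 0.0
                candidates.append((seq[i:], stripped, None, "truncated"))
            suffix_mass = cum[L] - cum[L - i]
            if abs(-delta - suffix_mass) <= ptol:
                candidates.append((seq[: L - i], offs[: L - i].copy(),
                                   None, "truncated"))
            if offs[L - i - 1] and abs(-delta - (suffix_mass + offs[L - i - 1])) <= ptol:
                stripped = offs[: L - i].copy()
                stripped[-1] = 0.0
                candidates.append((seq[: L - i], stripped, None, "truncated"))

    _PRIORITY = {"truncated": 0, "modified": 1}
    best = None
    best_key = None
    for cseq, coffs, site, kind in candidates:
        sc = _ladder_score(cseq, coffs, target, cfg)
        # higher score first; truncation beats an equal-scoring modification;
        # then N-terminal-most site for determinism
        key = (-sc, _PRIORITY[kind], site if site is not None else -1)
        if best_key is None or key < best_key:
            best, best_key = (cseq, coffs, site, kind, sc), key
    if best is None:
        out = np.array(offs, copy=True)
        out[0] += delta
        return format_peptide(seq, out), None, 0.0, "unlocalized"
    cseq, coffs, site, kind, sc = best
    if target is not None and kind == "modified" and sc <= 0:
        out = np.array(offs, copy=True)
        out[0] += delta
        return format_peptide(seq, out), None, 0.0, "unlocalized"
    return format_peptide(cseq, coffs), site, float(sc), kind


def _ladder_score(seq: str, offs: np.ndarray,
                  target: PRMSpectrum | None, cfg: Config) -> float:
    """Target PRM score explained by the candidate's prefix ladder.

    Sum of target peak scores matched within tolerance, minus a small
    penalty per theoretical ladder mass with no supporting peak — a
    candidate that merely *contains* the true ladder must not tie with the
    true ladder itself.
    """
    if target is None:
        return 0.0
    theo = prefix_masses(seq, offs)
    tol = cfg.fragment_tolerance_da
    lo = np.searchsorted(target.masses, theo - tol, side="left")
    hi = np.searchsorted(target.masses, theo + tol, side="right")
    hit = np.zeros(target.n_peaks, dtype=bool)
    for a, b in zip(lo, hi):
        hit[a:b] = True
    n_missed = int((hi == lo).sum())
    return float(target.scores[hit].sum()
                 - cfg.localization_miss_penalty * n_missed)


def propagate(network: SpectralNetwork, seeds: dict[str, str],
              a: float | None = None, r: float | None = None,
              fdr_threshold: float | None = None,
              prm_index: dict[str, PRMSpectrum] | None = None,
              config: Config | None = None
              ) -> tuple[dict[str, Annotation], PropagationState]:
    """Lowest-p-edge-first annotation propagation under an FDR budget.

    ``seeds`` maps node ids to peptide strings (depth-0 annotations).
    Annotated-to-unannotated edges are crossed in order of increasing pair
    p-value; each crossing annotates the receiving node at depth
    parent + 1. When ``prm_index`` is supplied, the propagated peptide has
    the edge's mass difference localized against the receiving node's PRM
    spectrum; otherwise the mass is attached N-terminally unlocalized.
    Propagation stops at the first annotation that would push the aggregate
    FDR over the threshold.
    """
    cfg = config or Config()
    a = cfg.seed_fdr if a is None else a
    r = cfg.edge_fdr if r is None else r
    threshold = cfg.aggregate_fdr_threshold if fdr_threshold is None else fdr_threshold

    annotations: dict[str, Annotation] = {}
    for sid, pep in sorted(seeds.items()):
        if sid not in network.nodes:
            log.warning("seed on unknown node %s skipped", sid)
            continue
        annotations[sid] = Annotation(sid, pep, "seed",
                                      step_fdr_value=step_fdr(a, r, 0))
    state = PropagationState(a=a, r=r, fdr_threshold=threshold,
                             id_k=[len(annotations)])
    if not annotations:
        return annotations, state

    adj = network.adjacency()
    heap: list[tuple[float, str, str, str]] = []

    def push_edges(src: str) -> None:
        for e in adj[src]:
            other = e.id_2 if e.id_1 == src else e.id_1
            if other not in annotations:
                p = e.pair_p if e.pair_p is not None else 1.0
                heapq.heappush(heap, (p, e.id_1, e.id_2, src))

    for sid in annotations:
        push_edges(sid)

    while heap:
        p, e1, e2, src = heapq.heappop(heap)
        node = e2 if e1 == src else e1
        if node in annotations:
            continue
        # the popped edge fixes *when* the node is annotated; the annotation
        # itself comes from whichever annotated neighbor's edge explains the
        # node's PRM spectrum best (ties broken by lowest pair p-value):
        # near-tied p-values cannot tell a one-event edge from a composite
        # substitution-plus-modification edge, but the localization score can
        target_prm = prm_index.get(node) if prm_index else None
        best = None
        best_key = None
        for e in adj[node]:
            u = e.id_2 if e.id_1 == node else e.id_1
            if u not in annotations:
                continue
            ep = e.pair_p if e.pair_p is not None else 1.0
            delta = (network.nodes[node].precursor_mass
                     - network.nodes[u].precursor_mass)
            if abs(delta) <= cfg.precursor_tolerance_da:
                pep, site, kind = annotations[u].peptide, None, "identity"
                sc = _ladder_score(*parse_peptide(pep), target_prm, cfg)
            else:
                pep, site, sc, kind = localize_mod(annotations[u].peptide,
                                                   delta, target_prm, cfg)
            key = (-sc, ep, e.id_1, e.id_2)
            if best_key is None or key < best_key:
                best = (u, e, pep, site, kind, delta)
                best_key = key
        assert best is not None
        src, edge, pep, site, kind, delta = best
        n = annotations[src].n_steps + 1
        would_be = list(state.id_k) + [0] * (n + 1 - len(state.id_k))
        would_be[n] += 1
        if aggregate_fdr(would_be, a, r) > threshold + 1e-12:
            log.info("propagation stopped: admitting %s at step %d would "
                     "raise the aggregate FDR to %.4f > %.4f", node, n,
                     aggregate_fdr(would_be, a, r), threshold)
            break
        annotations[node] = Annotation(
            spectrum_id=node, peptide=pep, source="propagated",
            n_steps=n, via_edge=(edge.id_1, edge.id_2), parent=src,
            step_fdr_value=step_fdr(a, r, n), site=site,
            localization=kind, delta_mass=delta)
        state.id_k = would_be
        push_edges(node)
    state.aggregate_fdr = aggregate_fdr(state.id_k, a, r)
    return annotations, state


def annotations_table(annotations: dict[str, Annotation],
                      network: SpectralNetwork | None = None) -> pd.DataFrame:
    rows = []
    for ann in sorted(annotations.values(), key=lambda x: x.spectrum_id):
        rows.append({
            "spectrum_id": ann.spectrum_id, "peptide": ann.peptide,
            "delta_mass": ann.delta_mass, "site": ann.site,
            "n_steps": ann.n_steps, "step_fdr": ann.step_fdr_value,
            "source": ann.source,
            "component": (network.component_of(ann.spectrum_id)
                          if network else ""),
        })
    return pd.DataFrame(rows, columns=["spectrum_id", "peptide", "delta_mass",
                                       "site", "n_steps", "step_fdr",
                                       "source", "component"])
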