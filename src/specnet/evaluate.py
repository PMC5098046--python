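"""Gold-standard pair labeling, edge-FDR estimation and network statistics.

A spectral pair whose two spectra carry known peptides is *true* when the
peptides are identical, one is a prefix/suffix of the other, or one is a
singly modified or singly mutated form of the other (offsets are compared
at the mass level; the site is ignored since tools may localize
differently). It is *ambiguous* when
the peptides share 12 or more consecutive residues or their theoretical
fragment ions overlap by more than 60%; ambiguous pairs enter neither the
numerator nor denominator of precision or FDR. Everything else is *false*.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chem import parse_peptide, prefix_masses, theoretical_by_masses
from .config import Config
from .network import SpectralNetwork
from .propagate import Annotation


def _longest_common_run(a: str, b: str) -> int:
    # O(len(a)*len(b)) suffix-table scan; peptides are short
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def fragment_ion_overlap(pep1: str, pep2: str,
                         config: Config | None = None) -> float:
    """Fraction of the smaller peptide's b/y ions matched by the other's.

    Singly charged b and y masses compared at the fragment tolerance; the
    denominator is the smaller ion set.
    """
    cfg = config or Config()
    s1, o1 = parse_peptide(pep1)
    s2, o2 = parse_peptide(pep2)
    ions1 = theoretical_by_masses(s1, o1)
    ions2 = theoretical_by_masses(s2, o2)
    if ions1.size > ions2.size:
        ions1, ions2 = ions2, ions1
    if ions1.size == 0:
        return 0.0
    tol = cfg.fragment_tolerance_da
    lo = np.searchsorted(ions2, ions1 - tol, side="left")
    hi = np.searchsorted(ions2, ions1 + tol, side="right")
    return float((hi > lo).sum()) / ions1.size


def label_pair(pep1: str, pep2: str, config: Config | None = None) -> str:
    """Classify a peptide pair as ``true``, ``ambiguous`` or ``false``."""
    cfg = config or Config()
    s1, o1 = parse_peptide(pep1)
    s2, o2 = parse_peptide(pep2)
    dmod = abs(float(o1.sum()) - float(o2.sum()))
    same_mods = dmod <= cfg.precursor_tolerance_da
    if s1 == s2:
        # identical, or a singly modified form (offset totals differ)
        return "true"
    if same_mods and (s1.startswith(s2) or s1.endswith(s2)
                      or s2.startswith(s1) or s2.endswith(s1)):
        return "true"
    if (same_mods and len(s1) == len(s2)
            and sum(a != b for a, b in zip(s1, s2)) == 1):
        return "true"  # singly mutated form (one substitution)
    if _longest_common_run(s1, s2) >= 12:
        return "ambiguous"
    if fragment_ion_overlap(pep1, pep2, cfg) > 0.60:
        return "ambiguous"
    return "false"


def is_variant_pair(pep1: str, pep2: str, config: Config | None = None) -> bool:
    """True pair whose peptides differ: prefix/suffix or singly modified."""
    cfg = config or Config()
    s1, o1 = parse_peptide(pep1)
    s2, o2 = parse_peptide(pep2)
    if label_pair(pep1, pep2, cfg) != "true":
        return False
    return s1 != s2 or abs(float(o1.sum()) - float(o2.sum())) > cfg.precursor_tolerance_da


def estimate_edge_fdr(labels: list[str]) -> float:
    """r = #false / (#false + #true); ambiguous labels are excluded."""
    n_true = sum(1 for l in labels if l == "true")
    n_false = sum(1 for l in labels if l == "false")
    if n_true + n_false == 0:
        raise ValueError("no true/false labels: cannot estimate edge FDR")
    return n_false / (n_false + n_true)


def precision_recall_curve(pairs, labels: dict[tuple[str, str], str],
                           variant_flags: dict[tuple[str, str], bool] | None = None
                           ) -> pd.DataFrame:
    """Precision and true-pair yield as the p cutoff sweeps the pair list.

    ``pairs`` are scored alignments with pair_p; only labeled, unambiguous
    edges enter the counts. When ``variant_flags`` is given, extra columns
    restrict the curve to variant pairs.
    """
    rows = []
    n_true = n_false = nv_true = nv_false = 0
    scored = sorted((e for e in pairs if e.key in labels
                     and labels[e.key] != "ambiguous"),
                    key=lambda e: (e.pair_p, e.id_1, e.id_2))
    for e in scored:
        lab = labels[e.key]
        if lab == "true":
            n_true += 1
        else:
            n_false += 1
        if variant_flags is not None and variant_flags.get(e.key, False):
            if lab == "true":
                nv_true += 1
            else:
                nv_false += 1
        row = {"pair_p": e.pair_p, "n_true": n_true, "n_false": n_false,
               "precision": n_true / (n_true + n_false)}
        if variant_flags is not None:
            row |= {"n_variant_true": nv_true,
                    "variant_precision": (nv_true / (nv_true + nv_false)
                                          if nv_true + nv_false else np.nan)}
        rows.append(row)
    return pd.DataFrame(rows)


def annotation_matches_truth(annotated: str, truth: str,
                             config: Config | None = None) -> bool:
    """Does an annotation (possibly with located offsets) match the truth?

    Compared at the fragment-mass level: equal precursor mass within the
    precursor tolerance and every prefix mass of one within the fragment
    tolerance of the other's. This accepts a substitution reported as a
    located mass offset at the correct position.
    """
    cfg = config or Config()
    s1, o1 = parse_peptide(annotated)
    s2, o2 = parse_peptide(truth)
    from .chem import peptide_mass
    if abs(peptide_mass(s1, o1) - peptide_mass(s2, o2)) > cfg.precursor_tolerance_da:
        return False
    pm1 = prefix_masses(s1, o1)
    pm2 = prefix_masses(s2, o2)
    if pm1.size != pm2.size:
        return False
    return bool(np.all(np.abs(pm1 - pm2) <= cfg.fragment_tolerance_da))


def delta_mass_histogram(network: SpectralNetwork,
                         interspecies_only: bool = True,
                         variant_only: bool = True) -> pd.Series:
    """Histogram of edge |delta masses| in 1 Da bins (bin = round(|delta|)).

    By default restricted to interspecies variant pairs (|delta| > 5 Da),
    where orthologous substitutions concentrate.
    """
    bins: dict[int, int] = {}
    for e in network.edges:
        if variant_only and abs(e.delta_mass) <= 5.0:
            continue
        if interspecies_only:
            sp1 = network.nodes[e.id_1].species_label
            sp2 = network.nodes[e.id_2].species_label
            if sp1 == sp2:
                continue
        b = int(round(abs(e.delta_mass)))
        bins[b] = bins.get(b, 0) + 1
    return pd.Series(bins, dtype=int).sort_index()


def network_summaries(network: SpectralNetwork,
                      annotations: dict[str, Annotation] | None = None,
                      config: Config | None = None
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Component-level table (species Venn class, variant flag, annotation
    coverage) plus the interspecies variant delta-mass histogram."""
    from .network import component_summary

    comp = component_summary(network, config)
    comp_ids = {i: network.component_of(i) for i in network.nodes}
    species_sets: dict[str, set[str]] = {}
    ann_counts: dict[str, int] = {}
    for i, cid in comp_ids.items():
        species_sets.setdefault(cid, set()).add(network.nodes[i].species_label)
        if annotations and i in annotations:
            ann_counts[cid] = ann_counts.get(cid, 0) + 1
    comp["species_class"] = [
        "+".join(sorted(species_sets[c])) for c in comp["component"]]
    comp["n_annotated"] = [ann_counts.get(c, 0) for c in comp["component"]]
    return comp, delta_mass_histogram(network)
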