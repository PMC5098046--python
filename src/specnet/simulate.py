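"""Synthetic multi-species MS/MS datasets with known ground truth.

Emulates the structure of a multi-species proteomics experiment on related
organisms: families of tryptic-like peptides whose orthologs differ by
single amino-acid substitutions (by default drawn from the +14 Da pair set
Asp/Glu, Gly/Ala, Ser/Thr, Asn/Gln, Asn/Lys, Thr/Asp, Val/Leu, Val/Ile),
plus modified and terminally truncated variants, uniform noise peaks, and a
configurable fraction of multiplexed (co-fragmented) spectra that bridge
unrelated families. Every spectrum's true peptide, family and planted
events are recorded, so each pipeline stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import (H2O, PROTON, format_peptide, parse_peptide,
                   peptide_mass, prefix_masses)
from .config import Config
from .spectra_io import Spectrum

#: Substitution pairs whose residue-mass differences are ~14 Da.
PLUS14_PAIRS: tuple[tuple[str, str], ...] = (
    ("D", "E"), ("G", "A"), ("S", "T"), ("N", "Q"),
    ("N", "K"), ("T", "D"), ("V", "L"), ("V", "I"),
)

_INTERNAL = "ACDEFGHILMNPQSTVWY"  # no K/R inside tryptic peptides


@dataclass
class SimConfig:
    n_species: int = 3
    n_families: int = 100
    peptide_length: tuple[int, int] = (8, 25)
    #: Probability that a non-reference species' ortholog carries one substitution.
    mutation_rate: float = 0.6
    substitution_pairs: tuple[tuple[str, str], ...] = PLUS14_PAIRS
    #: Probability of an additional modified-variant spectrum per species/family.
    modification_rate: float = 0.15
    modification_masses: tuple[float, ...] = (15.994915, 42.010565, 79.966331)
    #: Probability of an additional truncated-variant spectrum per species/family.
    truncation_rate: float = 0.08
    #: Noise peaks emitted per signal peak (uniform mass, low intensity).
    noise_peak_fraction: float = 0.5
    #: Fraction of spectra replaced by the peak union of two co-eluting peptides.
    multiplex_fraction: float = 0.07
    #: Precursor window within which co-fragmentation can occur, Da.
    isolation_window_da: float = 3.0
    charges: tuple[int, ...] = (2, 3)
    charge_weights: tuple[float, ...] = (0.7, 0.3)


@dataclass
class GroundTruth:
    """Per-spectrum truth and planted events for a generated dataset."""

    spectra: pd.DataFrame   # spectrum_id, species, family, peptide, kind, multiplexed, partner_family
    config: SimConfig

    def peptide_of(self, spectrum_id: str) -> str:
        return self._index()[spectrum_id]

    def _index(self) -> dict[str, str]:
        if not hasattr(self, "_pep_cache"):
            self._pep_cache = dict(zip(self.spectra["spectrum_id"],
                                       self.spectra["peptide"]))
        return self._pep_cache


def _random_peptide(rng: np.random.Generator, cfg: SimConfig) -> str:
    lo, hi = cfg.peptide_length
    length = int(rng.integers(lo, hi + 1))
    inner = rng.choice(list(_INTERNAL), size=length - 1)
    cterm = rng.choice(["K", "R"])
    return "".join(inner) + cterm


def _substitute(peptide: str, rng: np.random.Generator,
                cfg: SimConfig) -> str | None:
    """Apply one substitution from the pair table at a random eligible site."""
    pairs = list(cfg.substitution_pairs)
    sub_map: dict[str, list[str]] = {}
    for a, b in pairs:
        sub_map.setdefault(a, []).append(b)
        sub_map.setdefault(b, []).append(a)
    # internal positions only, to keep the tryptic terminus
    eligible = [i for i, aa in enumerate(peptide[:-1]) if aa in sub_map]
    if not eligible:
        return None
    i = int(rng.choice(eligible))
    repl = str(rng.choice(sub_map[peptide[i]]))
    return peptide[:i] + repl + peptide[i + 1:]


def spectrum_from_peptide(peptide: str, spectrum_id: str, species: str,
                          rng: np.random.Generator,
                          cfg: SimConfig | None = None,
                          charge: int | None = None,
                          noise_peak_fraction: float | None = None) -> Spectrum:
    """Theoretical b/y spectrum with rank-structured intensities and noise.

    Signal intensities decay exponentially in a randomly assigned rank;
    noise peaks are uniform in mass with intensities below the 20th
    percentile of the signal.
    """
    cfg = cfg or SimConfig()
    seq, offs = parse_peptide(peptide)
    M = peptide_mass(seq, offs)
    pm = prefix_masses(seq, offs)
    b = pm + PROTON
    y = (M - H2O - pm) + H2O + PROTON
    signal = np.concatenate([b, y])
    # y ions dominate b ions (tryptic CID); exponential decay in a random
    # within-series rank keeps intensities rank-structured but non-trivial
    b_int = 300.0 * np.power(0.9, rng.permutation(b.size))
    y_int = 1000.0 * np.power(0.97, rng.permutation(y.size))
    intensity = np.concatenate([b_int, y_int])
    intensity *= 1 + 0.03 * rng.standard_normal(signal.size)
    intensity = np.maximum(intensity, 1.0)
    nf = cfg.noise_peak_fraction if noise_peak_fraction is None else noise_peak_fraction
    n_noise = int(round(nf * signal.size))
    if n_noise > 0:
        floor = np.percentile(intensity, 20)
        noise_mz = rng.uniform(60.0, max(61.0, M - 10.0), size=n_noise)
        noise_int = rng.uniform(0.2 * floor, floor, size=n_noise)
        signal = np.concatenate([signal, noise_mz])
        intensity = np.concatenate([intensity, noise_int])
    if charge is None:
        charge = int(rng.choice(cfg.charges, p=np.asarray(cfg.charge_weights)
                                / sum(cfg.charge_weights)))
    mz = (M + charge * PROTON) / charge
    return Spectrum(spectrum_id=spectrum_id, precursor_mz=mz,
                    precursor_charge=charge, mz=signal, intensity=intensity,
                    source_file=f"{species}.mgf", species_label=species)


def _truncate(peptide: str, rng: np.random.Generator) -> str | None:
    seq, offs = parse_peptide(peptide)
    if len(seq) < 8:
        return None
    k = int(rng.integers(1, 3))
    if rng.random() < 0.5:
        return format_peptide(seq[k:], offs[k:])
    return format_peptide(seq[:-k], offs[:-k])


def generate_dataset(config: SimConfig | None = None,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[list[Spectrum], GroundTruth]:
    """Generate a multi-species dataset; fully reproducible from the seed."""
    cfg = config or SimConfig()
    if cfg.n_families < 1 or cfg.n_species < 1:
        raise ValueError("need at least one species and one family")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    species_names = [f"species{k + 1}" for k in range(cfg.n_species)]
    records: list[dict] = []
    plan: list[tuple[str, str, int, str]] = []  # (spectrum_id, peptide, family, kind) per species
    counters = {sp: 0 for sp in species_names}

    for fam in range(cfg.n_families):
        base = _random_peptide(rng, cfg)
        for k, sp in enumerate(species_names):
            ortholog = base
            if k > 0 and rng.random() < cfg.mutation_rate:
                mutated = _substitute(base, rng, cfg)
                if mutated is not None:
                    ortholog = mutated
            variants: list[tuple[str, str]] = [(ortholog, "base")]
            if rng.random() < cfg.modification_rate:
                seq, offs = parse_peptide(ortholog)
                j = int(rng.integers(0, len(seq)))
                mod = np.array(offs, copy=True)
                mod[j] += float(rng.choice(cfg.modification_masses))
                variants.append((format_peptide(seq, mod), "modified"))
            if rng.random() < cfg.truncation_rate:
                trunc = _truncate(ortholog, rng)
                if trunc is not None:
                    variants.append((trunc, "truncated"))
            for pep, kind in variants:
                sid = f"{sp}:{counters[sp]}"
                counters[sp] += 1
                plan.append((sid, pep, fam, kind))
                records.append({"spectrum_id": sid, "species": sp,
                                "family": fam, "peptide": pep, "kind": kind,
                                "multiplexed": False, "partner_family": -1})

    spectra = []
    for sid, pep, fam, kind in plan:
        sp = sid.split(":", 1)[0]
        spectra.append(spectrum_from_peptide(pep, sid, sp, rng, cfg))

    # multiplex a fraction of spectra with a co-eluting peptide from another family
    truth = pd.DataFrame.from_records(records)
    n_multi = int(round(cfg.multiplex_fraction * len(spectra)))
    if n_multi > 0 and len(spectra) > 1:
        masses = np.array([s.precursor_mass for s in spectra])
        fams = truth["family"].to_numpy()
        order = rng.permutation(len(spectra))
        done = 0
        for i in order:
            if done >= n_multi:
                break
            close = np.flatnonzero(
                (np.abs(masses - masses[i]) <= cfg.isolation_window_da)
                & (fams != fams[i]))
            if close.size == 0:
                continue
            j = int(rng.choice(close))
            s, partner = spectra[i], spectra[j]
            spectra[i] = Spectrum(
                spectrum_id=s.spectrum_id, precursor_mz=s.precursor_mz,
                precursor_charge=s.precursor_charge,
                mz=np.concatenate([s.mz, partner.mz]),
                intensity=np.concatenate([s.intensity, 0.6 * partner.intensity]),
                source_file=s.source_file, species_label=s.species_label)
            truth.loc[i, "multiplexed"] = True
            truth.loc[i, "partner_family"] = truth.loc[j, "family"]
            done += 1

    return spectra, GroundTruth(spectra=truth, config=cfg)


def truth_labels(gt: GroundTruth,
                 identified_fraction: dict[str, float] | float = 1.0,
                 seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Seed PSM table for a configurable identified fraction per species.

    A species mapped to fraction 0 contributes no seeds (the genome-free
    scenario). Multiplexed spectra are never used as seeds. Returns a
    DataFrame with spectrum_id and peptide columns.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows = []
    for sp, grp in gt.spectra.groupby("species", sort=True):
        frac = (identified_fraction.get(sp, 0.0)
                if isinstance(identified_fraction, dict) else identified_fraction)
        cand = grp[~grp["multiplexed"]]
        n = int(round(frac * len(cand)))
        if n == 0:
            continue
        chosen = cand.iloc[np.sort(rng.choice(len(cand), size=n, replace=False))]
        for _, r in chosen.iterrows():
            rows.append({"spectrum_id": r["spectrum_id"], "peptide": r["peptide"]})
    return pd.DataFrame(rows, columns=["spectrum_id", "peptide"])


def gold_labels(gt: GroundTruth, pairs,
                config: Config | None = None) -> dict[tuple[str, str], str]:
    """Gold-standard labels for scored pairs from the planted peptides."""
    from .evaluate import label_pair

    cfg = config or Config()
    peps = gt._index()
    return {e.key: label_pair(peps[e.id_1], peps[e.id_2], cfg) for e in pairs}


def planted_pair_is_bridge(gt: GroundTruth, id_1: str, id_2: str) -> bool:
    """Is this pair a planted-false edge (connects different families)?"""
    idx = dict(zip(gt.spectra["spectrum_id"], gt.spectra["family"]))
    return idx[id_1] != idx[id_2]


#: Disjoint modification-mass sets used to give the two bridged families
#: distinct precursor-mass inventories.
_BRIDGE_MODS_A = (15.994915, 42.01057, 79.96633, 28.0313, 14.01565,
                  57.02146, 100.01604, 119.00413, 156.10111)
_BRIDGE_MODS_B = (31.98983, 27.99491, 43.98983, 58.00548, 71.03711,
                  86.00037, 114.04293, 128.09496, 163.06333)


def generate_bridged_families(seed: int | np.random.Generator = 0,
                              n_bridges: int = 3,
                              noise_peak_fraction: float = 1.0
                              ) -> tuple[list[Spectrum], dict[str, str],
                                         set[str]]:
    """Two mass-saturated peptide families joined by multiplexed bridges.

    The worst case for network purity: two distinct peptides of identical
    precursor mass (sequence anagrams, i.e. co-eluting isobaric precursors)
    co-fragment, so the multiplexed spectra pair coherently with both
    families. Each family carries nine modified variants drawn from
    disjoint modification-mass sets, giving each family ten distinct
    precursor masses. Returns ``(spectra, family_of, bridge_ids)``; bridge
    spectra belong to family ``"A"`` and their pairs into family ``"B"``
    are the planted-false edges.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    body = list(rng.choice(list(_INTERNAL), size=15))
    pep_a = "".join(body) + "K"
    body_b = body.copy()
    rng.shuffle(body_b)
    pep_b = "".join(body_b) + "K"

    def family(name: str, pep: str, mods) -> list[Spectrum]:
        peptides = [pep]
        for m in mods:
            seq, offs = parse_peptide(pep)
            j = int(rng.integers(0, len(seq) - 1))
            shifted = offs.copy()
            shifted[j] += m
            peptides.append(format_peptide(seq, shifted))
        return [spectrum_from_peptide(p, f"{name}:{k}", name, rng,
                                      noise_peak_fraction=noise_peak_fraction)
                for k, p in enumerate(peptides)]

    fam_a = family("A", pep_a, _BRIDGE_MODS_A)
    fam_b = family("B", pep_b, _BRIDGE_MODS_B)
    spectra = fam_a + fam_b
    bridge_ids: set[str] = set()
    for k in range(n_bridges):
        a, b = fam_a[k], fam_b[k]
        sid = f"A:b{k}"
        spectra.append(Spectrum(
            spectrum_id=sid, precursor_mz=a.precursor_mz,
            precursor_charge=a.precursor_charge,
            mz=np.concatenate([a.mz, b.mz]),
            intensity=np.concatenate([a.intensity, b.intensity]),
            species_label="A"))
        bridge_ids.add(sid)
    family_of = {s.spectrum_id: s.species_label for s in spectra}
    return spectra, family_of, bridge_ids
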