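"""Reading and writing MS/MS peak lists and seed-identification tables.

MGF is the reference dialect (read/write through pyteomics); mzML is
supported behind the same reader contract. Seed PSM tables are TSV/CSV with
``spectrum_id`` and ``peptide`` columns and a table-level seed FDR supplied
either as a ``# seed_fdr=`` header comment or by the caller.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chem import PROTON, parse_peptide
from .config import log


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with precursor metadata.

    ``precursor_mass`` is the neutral (uncharged) precursor mass derived
    from m/z and charge: ``mz * z - z * proton``.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    source_file: str = ""
    species_label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.precursor_charge < 1:
            raise ValueError(f"{self.spectrum_id}: charge must be >= 1")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        keep = self.intensity > 0
        self.mz, self.intensity = self.mz[keep], self.intensity[keep]

    @property
    def precursor_mass(self) -> float:
        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class SeedPSM:
    spectrum_id: str
    peptide: str


def read_mgf(path: str, species_label: str | None = None) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects.

    Spectrum ids are ``<basename>:<scan-or-index>``; a missing CHARGE line
    defaults to 2+ with a logged warning; a missing PEPMASS is an error.
    """
    base = os.path.splitext(os.path.basename(path))[0]
    species = species_label if species_label is not None else base
    spectra: list[Spectrum] = []
    with _mgf.MGF(path, convert_arrays=1) as reader:
        for idx, block in enumerate(reader):
            params = block["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"{path}: block {idx} has no PEPMASS")
            mz = float(params["pepmass"][0])
            charge = params.get("charge")
            if charge:
                z = int(charge[0])
            else:
                log.warning("%s: block %d has no CHARGE, defaulting to 2+", path, idx)
                z = 2
            title = str(params.get("title", "")).strip()
            scan = title if title else str(idx)
            spectra.append(Spectrum(
                spectrum_id=f"{base}:{scan}",
                precursor_mz=mz,
                precursor_charge=z,
                mz=block["m/z array"],
                intensity=block["intensity array"],
                source_file=path,
                species_label=species,
            ))
    return spectra


def write_mgf(spectra: list[Spectrum], path: str) -> None:
    """Write spectra as MGF; masses to 5 decimals, intensities to 3."""
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": np.round(s.mz, 5),
            "intensity array": np.round(s.intensity, 3),
            "params": {
                "title": s.spectrum_id.split(":", 1)[-1],
                "pepmass": round(s.precursor_mz, 5),
                "charge": f"{s.precursor_charge}+",
            },
        })
    _mgf.write(entries, output=path, file_mode="w")


def read_mzml(path: str, species_label: str | None = None) -> list[Spectrum]:
    """Read MS2 scans from an mzML file under the same contract as read_mgf."""
    from pyteomics import mzml as _mzml

    base = os.path.splitext(os.path.basename(path))[0]
    species = species_label if species_label is not None else base
    spectra: list[Spectrum] = []
    with _mzml.MzML(path) as reader:
        for idx, scan in enumerate(reader):
            if scan.get("ms level") != 2:
                continue
            prec = scan["precursorList"]["precursor"][0]
            ion = prec["selectedIonList"]["selectedIon"][0]
            mz = float(ion["selected ion m/z"])
            z = int(ion.get("charge state", 2))
            spectra.append(Spectrum(
                spectrum_id=f"{base}:{scan.get('id', idx)}",
                precursor_mz=mz,
                precursor_charge=z,
                mz=scan["m/z array"],
                intensity=scan["intensity array"],
                source_file=path,
                species_label=species,
            ))
    return spectra


def read_seeds(path: str, seed_fdr: float | None = None
               ) -> tuple[list[SeedPSM], float]:
    """Read a seed PSM table; returns the rows and the table-level seed FDR.

    The FDR may appear as a ``# seed_fdr=<x>`` comment on the first line or
    be passed by the caller (caller wins). Duplicate spectrum_ids keep the
    first row. Unknown amino-acid characters raise with the row number.
    """
    header_fdr = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].replace(",", " ").split():
            if tok.startswith("seed_fdr="):
                header_fdr = float(tok.split("=", 1)[1])
    sep = "\t" if "\t" in first or first.startswith("#") else None
    df = pd.read_csv(path, sep=sep or r"[\t,]", comment="#", engine="python")
    if not {"spectrum_id", "peptide"} <= set(df.columns):
        raise ValueError(f"{path}: needs 'spectrum_id' and 'peptide' columns")
    fdr = seed_fdr if seed_fdr is not None else header_fdr
    if fdr is None:
        raise ValueError(f"{path}: seed FDR not in header; pass seed_fdr")
    seeds: list[SeedPSM] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = str(row["spectrum_id"])
        if sid in seen:
            log.warning("%s: duplicate spectrum_id %s at row %d dropped", path, sid, i)
            continue
        try:
            parse_peptide(str(row["peptide"]))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        seen.add(sid)
        seeds.append(SeedPSM(spectrum_id=sid, peptide=str(row["peptide"])))
    return seeds, float(fdr)


def write_seeds(seeds: list[SeedPSM], seed_fdr: float, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed_fdr={seed_fdr:g}\n")
        fh.write("spectrum_id\tpeptide\n")
        for s in seeds:
            fh.write(f"{s.spectrum_id}\t{s.peptide}\n")
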