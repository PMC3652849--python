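"""Readers and writers for the standard formats the engine touches.

Spectra come in as Mascot generic format (MGF) files or directories of
single-spectrum Sequest ``.dta`` files; protein databases as FASTA; scored
results go out as CSV tables. MGF and FASTA parsing is delegated to
pyteomics; the dta format (first line ``MH+ charge``, then ``m/z intensity``
pairs) is simple enough to read directly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import fasta as _pfasta
from pyteomics import mgf as _pmgf

from .constants import PROTON, STANDARD_AA

PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "modifications",
    "charge",
    "is_decoy",
    "S_frag",
    "S_consec",
    "S_by",
    "Sp",
    "rank",
]


@dataclass
class RawSpectrum:
    """One MS/MS scan: precursor m/z and charge plus (m/z, intensity) peaks.

    Peaks are stored as parallel numpy arrays sorted ascending by m/z.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.spectrum_id!r} has no peaks")
        if self.mz.size != self.intensity.size:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def neutral_mass(self) -> float:
        """Neutral precursor mass: mz*z - z*proton."""
        return self.precursor_mz * self.precursor_charge - self.precursor_charge * PROTON


@dataclass
class ProteinRecord:
    accession: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has empty sequence")


def read_mgf(path: str | os.PathLike, default_charges: tuple[int, ...] = (2, 3)) -> list[RawSpectrum]:
    """Read an MGF file into a list of :class:`RawSpectrum`.

    PEPMASS lines may carry an optional intensity token (ignored); unknown
    headers are ignored. Blocks without a CHARGE line are expanded into one
    spectrum per charge in ``default_charges`` (same spectrum id), so every
    plausible charge is searched.
    """
    out: list[RawSpectrum] = []
    with _pmgf.MGF(str(path), convert_arrays=1) as reader:
        for block_idx, entry in enumerate(reader):
            try:
                params = entry["params"]
                title = str(params.get("title", f"index={block_idx}"))
                pepmass = params["pepmass"]
                precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                mz = np.asarray(entry["m/z array"], dtype=float)
                inten = np.asarray(entry["intensity array"], dtype=float)
                charges = params.get("charge")
                if charges:
                    zs = [int(z) for z in charges]
                else:
                    zs = list(default_charges)
                for z in zs:
                    out.append(RawSpectrum(title, precursor_mz, z, mz, inten))
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed MGF block {block_idx} in {path}: {exc}") from exc
    return out


def write_mgf(spectra: list[RawSpectrum], path: str | os.PathLike) -> None:
    """Write spectra as MGF (one BEGIN/END IONS block each)."""
    entries = [
        {
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": f"{s.precursor_charge}+",
            },
        }
        for s in spectra
    ]
    _pmgf.write(entries, str(path), file_mode="w")


def read_dta(path: str | os.PathLike, spectrum_id: str | None = None) -> RawSpectrum:
    """Read one Sequest dta file.

    The first line holds the singly-protonated precursor mass (MH+) and the
    charge; the precursor m/z is reconstructed as ``(MH+ + (z-1)*proton)/z``.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"dta file {path} is empty")
    head = lines[0].split()
    if len(head) != 2:
        raise ValueError(f"dta file {path}: first line must be 'MH+ charge', got {lines[0]!r}")
    try:
        mh, z = float(head[0]), int(float(head[1]))
    except ValueError as exc:
        raise ValueError(f"dta file {path}: first line must be 'MH+ charge'") from exc
    mz, inten = [], []
    for ln in lines[1:]:
        parts = ln.split()
        mz.append(float(parts[0]))
        inten.append(float(parts[1]))
    precursor_mz = (mh + (z - 1) * PROTON) / z
    sid = spectrum_id if spectrum_id is not None else os.path.basename(str(path))
    return RawSpectrum(sid, precursor_mz, z, np.array(mz), np.array(inten))


def read_dta_dir(path: str | os.PathLike) -> list[RawSpectrum]:
    """Read every ``.dta`` file in a directory (sorted by filename)."""
    names = sorted(f for f in os.listdir(path) if f.lower().endswith(".dta"))
    return [read_dta(os.path.join(path, name)) for name in names]


def read_fasta(path: str | os.PathLike, skip_unknown: bool = True) -> list[ProteinRecord]:
    """Read a FASTA protein database.

    Sequences are uppercased; a trailing ``*`` terminator is stripped.
    Residue letters outside the 20 standard amino acids are dropped with a
    warning when ``skip_unknown``, otherwise rejected. Duplicate accessions
    are kept with disambiguated ids (``acc``, ``acc.2`` ...).
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for header, seq in _pfasta.FASTA(str(path)):
        accession = header.split()[0] if header.split() else header
        seq = seq.upper().replace("*", "").replace(" ", "")
        bad = set(seq) - STANDARD_AA
        if bad:
            if not skip_unknown:
                raise ValueError(f"protein {accession!r}: unknown residues {sorted(bad)}")
            warnings.warn(f"protein {accession!r}: dropping unknown residues {sorted(bad)}")
            seq = "".join(aa for aa in seq if aa in STANDARD_AA)
        n = seen.get(accession, 0) + 1
        seen[accession] = n
        if n > 1:
            warnings.warn(f"duplicate accession {accession!r}; keeping as {accession}.{n}")
            accession = f"{accession}.{n}"
        records.append(ProteinRecord(accession, seq))
    return records


def write_fasta(records: list[ProteinRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def psm_frame(psms) -> pd.DataFrame:
    """Flatten scored PSMs into the canonical result table."""
    rows = []
    for p in psms:
        rows.append(
            {
                "spectrum_id": p.spectrum_id,
                "peptide": p.peptide.sequence,
                "modifications": p.peptide.mod_string(),
                "charge": p.charge,
                "is_decoy": p.is_decoy,
                "S_frag": p.breakdown.S_frag,
                "S_consec": p.breakdown.S_consec,
                "S_by": p.breakdown.S_by,
                "Sp": p.breakdown.Sp,
                "rank": p.rank,
            }
        )
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def write_psm_table(psms, path: str | os.PathLike) -> None:
    """Write scored PSMs as CSV with the fixed column order."""
    psm_frame(psms).to_csv(path, index=False, float_format="%.6f")


def read_psm_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} missing columns: {missing}")
    return df
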