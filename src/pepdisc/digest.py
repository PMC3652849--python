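"""The searchable peptide space: tryptic digestion, modifications, decoys, mass lookup.

Digestion is fully tryptic: cleavage after K or R except when the next
residue is proline, with up to a configured number of missed cleavages.
Decoys are whole-protein sequence reversals appended to the target
database, so a search against the concatenated database supports
target-decoy FDR estimation downstream.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .config import SearchConfig
from .constants import peptide_mono_mass
from .io import ProteinRecord

DECOY_PREFIX = "REV_"


@dataclass(frozen=True)
class PeptideCandidate:
    """A (possibly modified) tryptic peptide with provenance.

    ``mod_deltas`` maps 0-based residue positions to mass deltas in Da;
    ``mono_mass`` is the neutral monoisotopic mass (residues + mods + water).
    """

    sequence: str
    mod_deltas: tuple[tuple[int, float], ...]
    mono_mass: float
    missed_cleavages: int
    protein_ids: tuple[str, ...]
    is_decoy: bool

    def __len__(self) -> int:
        return len(self.sequence)

    def mod_string(self) -> str:
        """Human-readable modification summary, e.g. ``C3+57.021464;M5+15.994915``."""
        return ";".join(f"{self.sequence[pos]}{pos + 1}{delta:+.6f}" for pos, delta in self.mod_deltas)

    def residue_masses(self) -> np.ndarray:
        """Per-position residue masses including modification deltas."""
        from .constants import RESIDUE_MASS

        masses = np.array([RESIDUE_MASS[aa] for aa in self.sequence])
        for pos, delta in self.mod_deltas:
            masses[pos] += delta
        return masses

    def key(self) -> tuple[str, tuple[tuple[int, float], ...], bool]:
        return (self.sequence, self.mod_deltas, self.is_decoy)


def cleavage_sites(sequence: str) -> list[int]:
    """Indices i such that trypsin cuts between sequence[i] and sequence[i+1]."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_protein(
    record: ProteinRecord,
    max_missed: int = 2,
    min_length: int = 1,
    max_length: int | None = None,
) -> list[PeptideCandidate]:
    """Emit every fully tryptic peptide with 0..max_missed missed cleavages."""
    seq = record.sequence
    sites = cleavage_sites(seq)
    # fragment boundaries: start indices of consecutive fully-cleaved fragments
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(seq)]
    peptides: list[PeptideCandidate] = []
    n = len(starts)
    for i in range(n):
        for missed in range(min(max_missed, n - 1 - i) + 1):
            pep = seq[starts[i] : ends[i + missed]]
            if len(pep) < min_length:
                continue
            if max_length is not None and len(pep) > max_length:
                continue
            peptides.append(
                PeptideCandidate(
                    sequence=pep,
                    mod_deltas=(),
                    mono_mass=peptide_mono_mass(pep),
                    missed_cleavages=missed,
                    protein_ids=(record.accession,),
                    is_decoy=record.is_decoy,
                )
            )
    return peptides


def generate_decoys(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Concatenated forward/reverse database: each protein plus its reversal."""
    decoys = [
        ProteinRecord(DECOY_PREFIX + rec.accession, rec.sequence[::-1], is_decoy=True)
        for rec in records
    ]
    return list(records) + decoys


def apply_modifications(
    peptide: PeptideCandidate,
    fixed_mods: dict[str, float],
    variable_mods: dict[str, float],
    max_variable_mods: int = 3,
) -> list[PeptideCandidate]:
    """Expand one peptide into its modification variants.

    Every residue carrying a fixed modification is modified in all variants;
    each subset of variably-modifiable positions up to ``max_variable_mods``
    yields one variant.
    """
    fixed = [(i, fixed_mods[aa]) for i, aa in enumerate(peptide.sequence) if aa in fixed_mods]
    var_positions = [
        (i, variable_mods[aa]) for i, aa in enumerate(peptide.sequence) if aa in variable_mods
    ]
    variants: list[PeptideCandidate] = []
    for k in range(min(len(var_positions), max_variable_mods) + 1):
        for subset in combinations(var_positions, k):
            mods = tuple(sorted(fixed + list(subset)))
            variants.append(
                PeptideCandidate(
                    sequence=peptide.sequence,
                    mod_deltas=mods,
                    mono_mass=peptide_mono_mass(peptide.sequence, mods),
                    missed_cleavages=peptide.missed_cleavages,
                    protein_ids=peptide.protein_ids,
                    is_decoy=peptide.is_decoy,
                )
            )
    return variants


class PeptideIndex:
    """Mass-sorted index over the modified target+decoy peptide space.

    Peptides identical in (sequence, modifications, decoy flag) are merged,
    accumulating protein provenance, then sorted by monoisotopic mass for
    binary-search precursor lookup.
    """

    def __init__(self, candidates: list[PeptideCandidate]):
        merged: dict[tuple, PeptideCandidate] = {}
        for cand in candidates:
            key = cand.key()
            if key in merged:
                prev = merged[key]
                merged[key] = PeptideCandidate(
                    sequence=prev.sequence,
                    mod_deltas=prev.mod_deltas,
                    mono_mass=prev.mono_mass,
                    missed_cleavages=min(prev.missed_cleavages, cand.missed_cleavages),
                    protein_ids=tuple(sorted(set(prev.protein_ids) | set(cand.protein_ids))),
                    is_decoy=prev.is_decoy,
                )
            else:
                merged[key] = cand
        self.candidates = sorted(merged.values(), key=lambda c: (c.mono_mass, c.sequence, c.mod_deltas))
        self._masses = [c.mono_mass for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)

    @classmethod
    def build(cls, records: list[ProteinRecord], config: SearchConfig) -> "PeptideIndex":
        """Digest and modify every protein (targets and decoys alike)."""
        cands: list[PeptideCandidate] = []
        for rec in records:
            for pep in digest_protein(rec, config.max_missed_cleavages, config.min_peptide_length):
                cands.extend(
                    apply_modifications(
                        pep, config.fixed_mods, config.variable_mods, config.max_variable_mods
                    )
                )
        return cls(cands)

    def lookup(self, neutral_mass: float, config: SearchConfig) -> list[PeptideCandidate]:
        """All candidates within the precursor tolerance of the query mass."""
        tol = config.precursor_window(neutral_mass)
        lo = bisect.bisect_left(self._masses, neutral_mass - tol)
        hi = bisect.bisect_right(self._masses, neutral_mass + tol)
        return self.candidates[lo:hi]


def candidate_lookup(
    neutral_mass: float, index: PeptideIndex, config: SearchConfig
) -> list[PeptideCandidate]:
    """Functional wrapper around :meth:`PeptideIndex.lookup`."""
    return index.lookup(neutral_mass, config)
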