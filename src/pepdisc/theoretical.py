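"""Theoretical fragment-ion spectra of candidate peptides.

For CID-style peptide-bond breakage the engine predicts b and y ions plus
their conditional neutral losses:

* ``b-H2O`` / ``y-H2O`` when the fragment contains S, T, E or D;
* ``b-NH3`` / ``y-NH3`` when the fragment contains R, K, Q or N;
* singly charged ions always; doubly charged ions only when the precursor
  charge is >= 2 and the fragment contains R, K or H.

Residue conditions are evaluated on the fragment's own residue span: the
prefix for b ions, the suffix for y ions. Modification deltas shift exactly
the ions whose span covers the modified position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import NH3, PROTON, WATER
from .digest import PeptideCandidate

SERIES = ("b", "y", "b-H2O", "y-H2O", "b-NH3", "y-NH3")
_S_B, _S_Y, _S_BH2O, _S_YH2O, _S_BNH3, _S_YNH3 = range(6)

_H2O_RESIDUES = frozenset("STED")
_NH3_RESIDUES = frozenset("RKQN")
_CHARGE2_RESIDUES = frozenset("RKH")


@dataclass(frozen=True)
class TheoreticalIon:
    series: str
    ordinal: int
    charge: int
    mz: float


class TheoreticalSpectrum:
    """Predicted fragment ions of one candidate peptide, as parallel arrays."""

    __slots__ = ("mz", "series_code", "ordinal", "charge", "_order")

    def __init__(self, mz, series_code, ordinal, charge):
        self.mz = np.asarray(mz, dtype=float)
        self.series_code = np.asarray(series_code, dtype=np.int8)
        self.ordinal = np.asarray(ordinal, dtype=np.int16)
        self.charge = np.asarray(charge, dtype=np.int8)
        self._order = np.argsort(self.mz, kind="stable")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def sorted_mz(self) -> np.ndarray:
        return self.mz[self._order]

    @property
    def sort_order(self) -> np.ndarray:
        return self._order

    @property
    def is_by(self) -> np.ndarray:
        """Mask of plain b/y ions (no neutral loss)."""
        return self.series_code < 2

    def ions(self) -> list[TheoreticalIon]:
        return [
            TheoreticalIon(SERIES[s], int(o), int(z), float(m))
            for s, o, z, m in zip(self.series_code, self.ordinal, self.charge, self.mz)
        ]

    def n_total(self) -> int:
        return len(self)

    def n_by(self) -> int:
        return int(np.count_nonzero(self.is_by))

    def n_consecutive_pairs(self) -> int:
        """Adjacent-ordinal pairs within each (series, charge) group."""
        pairs = 0
        present = {
            (int(s), int(z), int(o))
            for s, z, o in zip(self.series_code, self.charge, self.ordinal)
        }
        for s, z, o in present:
            if (s, z, o + 1) in present:
                pairs += 1
        return pairs


def fragment_ions(peptide: PeptideCandidate, precursor_charge: int) -> TheoreticalSpectrum:
    """Generate the theoretical fragment spectrum of ``peptide``."""
    seq = peptide.sequence
    L = len(seq)
    if L < 2:
        raise ValueError("peptide must have length >= 2 to fragment")

    res = peptide.residue_masses()
    prefix = np.cumsum(res)  # prefix[i-1] = neutral mass of b_i
    total = prefix[-1]

    mz, series, ordinal, charge = [], [], [], []

    def emit(series_code: int, ord_: int, neutral: float) -> None:
        mz.append(neutral + PROTON)
        series.append(series_code)
        ordinal.append(ord_)
        charge.append(1)

    def emit2(series_code: int, ord_: int, neutral: float) -> None:
        mz.append((neutral + 2 * PROTON) / 2)
        series.append(series_code)
        ordinal.append(ord_)
        charge.append(2)

    allow2 = precursor_charge >= 2
    # cumulative residue-content flags for prefixes and suffixes
    pre_h2o = pre_nh3 = pre_z2 = False
    suf_h2o = [False] * (L + 1)
    suf_nh3 = [False] * (L + 1)
    suf_z2 = [False] * (L + 1)
    for i in range(L - 1, -1, -1):
        suf_h2o[i] = suf_h2o[i + 1] or seq[i] in _H2O_RESIDUES
        suf_nh3[i] = suf_nh3[i + 1] or seq[i] in _NH3_RESIDUES
        suf_z2[i] = suf_z2[i + 1] or seq[i] in _CHARGE2_RESIDUES

    for i in range(1, L):
        aa = seq[i - 1]
        pre_h2o = pre_h2o or aa in _H2O_RESIDUES
        pre_nh3 = pre_nh3 or aa in _NH3_RESIDUES
        pre_z2 = pre_z2 or aa in _CHARGE2_RESIDUES

        b_neutral = prefix[i - 1]
        y_neutral = total - prefix[L - 1 - i] + WATER  # suffix of length i
        b2 = allow2 and pre_z2
        y2 = allow2 and suf_z2[L - i]

        emit(_S_B, i, b_neutral)
        emit(_S_Y, i, y_neutral)
        if b2:
            emit2(_S_B, i, b_neutral)
        if y2:
            emit2(_S_Y, i, y_neutral)
        if pre_h2o:
            emit(_S_BH2O, i, b_neutral - WATER)
            if b2:
                emit2(_S_BH2O, i, b_neutral - WATER)
        if suf_h2o[L - i]:
            emit(_S_YH2O, i, y_neutral - WATER)
            if y2:
                emit2(_S_YH2O, i, y_neutral - WATER)
        if pre_nh3:
            emit(_S_BNH3, i, b_neutral - NH3)
            if b2:
                emit2(_S_BNH3, i, b_neutral - NH3)
        if suf_nh3[L - i]:
            emit(_S_YNH3, i, y_neutral - NH3)
            if y2:
                emit2(_S_YNH3, i, y_neutral - NH3)

    return TheoreticalSpectrum(mz, series, ordinal, charge)
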