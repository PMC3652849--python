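"""Spectrum preprocessing: isotope filtering, binned peak selection, normalization.

A raw scan is reduced to the peak set the engine scores against:

1. isotope filtering — peaks 1±0.25 Da apart are treated as members of one
   isotope envelope and only the locally most intense member survives;
2. binned selection — the observed m/z range is split into 10 equal-width
   bins and the 20 most intense peaks per bin are kept (≤200 total);
3. normalization — kept intensities are divided by the largest kept
   intensity, so the base peak has normalized intensity exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RawSpectrum

ISOTOPE_WINDOW = (0.75, 1.25)  # Da; 1 ± 0.25
N_BINS = 10
PEAKS_PER_BIN = 20


@dataclass
class ProcessedSpectrum:
    """Selected, normalized peaks of one scan, ready for scoring."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity_raw: np.ndarray
    intensity_norm: np.ndarray
    bin_edges: np.ndarray  # 11 ascending Da values

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def filter_isotopes(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse isotope envelopes in a single ascending-m/z pass.

    A peak is dropped when it lies 0.75–1.25 Da above an already-retained
    peak and is not more intense than it; otherwise the earlier peak is
    dropped instead, so the most intense member of each chain survives.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    lo, hi = ISOTOPE_WINDOW
    kept: list[int] = []
    for i in range(mz.size):
        # all retained peaks sitting an isotope spacing below peak i
        window: list[int] = []
        j = len(kept) - 1
        while j >= 0 and mz[i] - mz[kept[j]] <= hi:
            if mz[i] - mz[kept[j]] >= lo:
                window.append(j)
            j -= 1
        if any(intensity[kept[j]] > intensity[i] for j in window):
            continue  # peak i is a lower-intensity isotope of a retained peak
        for j in sorted(window, reverse=True):
            kept.pop(j)  # earlier, weaker members of the envelope give way
        kept.append(i)
    idx = np.array(kept, dtype=int)
    return mz[idx], intensity[idx]


def select_peaks(spectrum: RawSpectrum) -> ProcessedSpectrum:
    """Isotope-filter, bin, select and normalize the peaks of one scan."""
    mz, inten = filter_isotopes(spectrum.mz, spectrum.intensity)
    if mz.size == 0:
        raise ValueError(f"spectrum {spectrum.spectrum_id!r}: no peaks after isotope filtering")

    lo, hi = float(mz[0]), float(mz[-1])
    if hi == lo:  # degenerate: all peaks at one m/z -> single bin
        edges = np.linspace(lo, lo + 1.0, N_BINS + 1)
        bins = np.zeros(mz.size, dtype=int)
    else:
        edges = np.linspace(lo, hi, N_BINS + 1)
        bins = np.minimum(((mz - lo) / (hi - lo) * N_BINS).astype(int), N_BINS - 1)

    keep: list[int] = []
    for b in range(N_BINS):
        members = np.nonzero(bins == b)[0]
        if members.size > PEAKS_PER_BIN:
            # top 20 by intensity; ties broken toward higher m/z
            order = sorted(members, key=lambda i: (-inten[i], -mz[i]))
            members = np.array(order[:PEAKS_PER_BIN])
        keep.extend(members.tolist())
    idx = np.array(sorted(keep), dtype=int)

    sel_mz, sel_int = mz[idx], inten[idx]
    norm = sel_int / sel_int.max()
    return ProcessedSpectrum(
        spectrum_id=spectrum.spectrum_id,
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        mz=sel_mz,
        intensity_raw=sel_int,
        intensity_norm=norm,
        bin_edges=edges,
    )
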