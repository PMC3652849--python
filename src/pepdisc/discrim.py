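"""The three discriminability signals behind the scoring function.

Peptide matching discriminability (PMD) is a property of each selected
peak: a peak matched by few of the spectrum's candidate peptides pins the
identification down more than a peak matched by many, regardless of its
intensity. Intensity and m/z-error discriminability are correct-to-random
match-count ratios, binned over normalized intensity and over fragment
mass error, estimated once from a training corpus and then looked up.

This module owns peak-ion matching, PMD computation, the binned lookup
tables (with the shipped defaults), and table re-training from a corpus of
correct and incorrect peptide-spectrum assignments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .digest import PeptideCandidate
from .preprocess import ProcessedSpectrum
from .theoretical import SERIES, TheoreticalSpectrum, fragment_ions

ROWS = ("b", "y", "s")
_ROW_INDEX = {"b": 0, "y": 1, "s": 2}
N_INTENSITY_BINS = 11  # 10 equal bins over [0,1) plus the 1.0 category
N_ERROR_BINS = 10  # 10 equal bins over [0,0.5]
_ERROR_RANGE = 0.5  # Da; the tolerance the tables were trained at
_BIN_EPS = 1e-9  # guards against float noise at bin boundaries


# ---------------------------------------------------------------------------
# peak-ion matching


@dataclass(frozen=True)
class Match:
    """One experimental peak assigned to one theoretical ion."""

    peak_index: int
    ion_index: int
    series: str
    ordinal: int
    charge: int
    mz_theo: float
    intensity_norm: float
    abs_error: float


def _as_theoretical(ions) -> TheoreticalSpectrum:
    if isinstance(ions, TheoreticalSpectrum):
        return ions
    ions = list(ions)
    return TheoreticalSpectrum(
        [i.mz for i in ions],
        [SERIES.index(i.series) for i in ions],
        [i.ordinal for i in ions],
        [i.charge for i in ions],
    )


def match_peaks(
    spectrum: ProcessedSpectrum, ions, fragment_tol: float
) -> list[Match]:
    """One-to-one assignment of experimental peaks to theoretical ions.

    Candidate (peak, ion) pairs within the fragment tolerance are assigned
    greedily by ascending |m/z error|, so each peak takes its closest
    available ion and each ion is used at most once.
    """
    theo = _as_theoretical(ions)
    if len(theo) == 0 or spectrum.n_peaks == 0:
        return []
    sorted_mz = theo.sorted_mz
    order = theo.sort_order
    pairs: list[tuple[float, float, float, int, int]] = []
    for pi in range(spectrum.n_peaks):
        pmz = spectrum.mz[pi]
        lo = int(np.searchsorted(sorted_mz, pmz - fragment_tol, side="left"))
        hi = int(np.searchsorted(sorted_mz, pmz + fragment_tol, side="right"))
        for pos in range(lo, hi):
            ii = int(order[pos])
            err = abs(pmz - theo.mz[ii])
            if err <= fragment_tol:
                pairs.append((err, pmz, theo.mz[ii], pi, ii))
    pairs.sort()
    peak_used = np.zeros(spectrum.n_peaks, dtype=bool)
    ion_used = np.zeros(len(theo), dtype=bool)
    matches: list[Match] = []
    for err, _pmz, _imz, pi, ii in pairs:
        if peak_used[pi] or ion_used[ii]:
            continue
        peak_used[pi] = True
        ion_used[ii] = True
        matches.append(
            Match(
                peak_index=pi,
                ion_index=ii,
                series=SERIES[theo.series_code[ii]],
                ordinal=int(theo.ordinal[ii]),
                charge=int(theo.charge[ii]),
                mz_theo=float(theo.mz[ii]),
                intensity_norm=float(spectrum.intensity_norm[pi]),
                abs_error=err,
            )
        )
    matches.sort(key=lambda m: m.peak_index)
    return matches


def peak_match_mask(
    spectrum: ProcessedSpectrum, theo: TheoreticalSpectrum, fragment_tol: float
) -> np.ndarray:
    """Boolean mask: does each selected peak lie within tolerance of any ion?"""
    sorted_mz = theo.sorted_mz
    if sorted_mz.size == 0:
        return np.zeros(spectrum.n_peaks, dtype=bool)
    pos = np.searchsorted(sorted_mz, spectrum.mz)
    left = np.clip(pos - 1, 0, sorted_mz.size - 1)
    right = np.clip(pos, 0, sorted_mz.size - 1)
    dist = np.minimum(
        np.abs(spectrum.mz - sorted_mz[left]), np.abs(spectrum.mz - sorted_mz[right])
    )
    return dist <= fragment_tol


def consecutive_pairs(matches: list[Match]) -> list[tuple[Match, Match]]:
    """Adjacent-ordinal match pairs within each (series, charge) group.

    N consecutively matched ions yield N-1 pairs (b1,b2,b3 -> b1-b2, b2-b3).
    """
    by_group: dict[tuple[str, int], dict[int, Match]] = {}
    for m in matches:
        by_group.setdefault((m.series, m.charge), {})[m.ordinal] = m
    pairs: list[tuple[Match, Match]] = []
    for group in by_group.values():
        for o in sorted(group):
            if o + 1 in group:
                pairs.append((group[o], group[o + 1]))
    return pairs


# ---------------------------------------------------------------------------
# PMD


@dataclass
class PMDMap:
    """Per-peak peptide matching discriminability over one candidate set.

    ``match_counts[i]`` is the number of candidate peptides that peak i
    matches (i.e. lies within the fragment tolerance of at least one of the
    candidate's theoretical ions). ``mean_matches`` averages the counts of
    the matched peaks only, and ``d[i]`` is the discriminability of peak i
    (NaN for peaks matching no candidate).
    """

    match_counts: np.ndarray
    mean_matches: float
    d: np.ndarray

    @property
    def is_empty(self) -> bool:
        return not np.any(self.match_counts > 0)

    def discriminability(self, peak_index: int) -> float:
        v = self.d[peak_index]
        if math.isnan(v):
            raise ValueError(f"peak {peak_index} matches no candidate; it has no PMD")
        return float(v)


def pmd_from_counts(match_counts: np.ndarray, form: str = "ratio") -> PMDMap:
    """Build a PMD map from per-peak candidate-match counts.

    The default "ratio" form sets D(m_i) = mean/M_i: a peak matching fewer
    candidates than average is more discriminative and scores above 1. The
    alternative "shifted" form uses mean - M_i + 1 clamped below at 0.1.
    """
    counts = np.asarray(match_counts, dtype=float)
    matched = counts > 0
    d = np.full(counts.shape, np.nan)
    if not matched.any():
        return PMDMap(counts.astype(int), 0.0, d)
    mean = float(counts[matched].mean())
    if form == "ratio":
        d[matched] = mean / counts[matched]
    elif form == "shifted":
        d[matched] = np.maximum(mean - counts[matched] + 1.0, 0.1)
    else:
        raise ValueError(f"unknown PMD form {form!r}")
    return PMDMap(counts.astype(int), mean, d)


def compute_pmd(
    spectrum: ProcessedSpectrum,
    candidates: list[PeptideCandidate],
    fragment_tol: float,
    form: str = "ratio",
    theoreticals: list[TheoreticalSpectrum] | None = None,
) -> PMDMap:
    """PMD of each selected peak over the spectrum's candidate set.

    A peak matches a candidate when it lies within the fragment tolerance
    of at least one of the candidate's theoretical ions. Targets and decoys
    both count — the candidate universe is whatever the precursor window
    returned from the concatenated database.
    """
    counts = np.zeros(spectrum.n_peaks, dtype=int)
    if theoreticals is None:
        theoreticals = [fragment_ions(c, spectrum.precursor_charge) for c in candidates]
    for theo in theoreticals:
        counts += peak_match_mask(spectrum, theo, fragment_tol)
    return pmd_from_counts(counts, form=form)


# ---------------------------------------------------------------------------
# binned discriminability tables


@dataclass
class DiscrimTables:
    """Binned intensity and m/z-error discriminability plus match probabilities.

    ``intensity`` is 3 rows (b, y, pooled s) x 11 bins over normalized
    intensity; ``mz_error`` is 3 rows x 10 bins over [0, 0.5] Da. The three
    probabilities are the random single-ion, consecutive-pair and plain-b/y
    match rates of an incorrect (decoy) assignment.
    """

    intensity: np.ndarray
    mz_error: np.ndarray
    p_frag: float = 0.1406
    p_consec: float = 0.0279
    p_by: float = 0.0706

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mz_error = np.asarray(self.mz_error, dtype=float)
        if self.intensity.shape != (3, N_INTENSITY_BINS):
            raise ValueError(f"intensity table must be 3x{N_INTENSITY_BINS}")
        if self.mz_error.shape != (3, N_ERROR_BINS):
            raise ValueError(f"mz_error table must be 3x{N_ERROR_BINS}")
        for p in (self.p_frag, self.p_consec, self.p_by):
            if not 0.0 < p < 1.0:
                raise ValueError("match probabilities must lie in (0,1)")

    def intensity_discriminability(self, intensity_norm: float, row: str) -> float:
        """Table lookup by normalized intensity; exactly 1.0 hits the base-peak bin."""
        if not 0.0 <= intensity_norm <= 1.0:
            raise ValueError(f"normalized intensity {intensity_norm} outside [0,1]")
        if intensity_norm == 1.0:
            b = N_INTENSITY_BINS - 1
        else:
            b = min(int(math.floor(intensity_norm * 10 + _BIN_EPS)), 9)
        return float(self.intensity[_ROW_INDEX[row], b])

    def mz_error_discriminability(self, abs_error: float, fragment_tol: float, row: str) -> float:
        """Table lookup by fragment m/z error, rescaled to the trained window.

        The tables were estimated at a 0.5 Da fragment tolerance; when the
        search runs at a different tolerance the error is rescaled
        proportionally (err * 0.5/tol) so bin semantics are preserved.
        """
        if abs_error < 0 or abs_error > fragment_tol:
            raise ValueError(f"|error| {abs_error} outside [0, tol={fragment_tol}]")
        scaled = _ERROR_RANGE * abs_error / fragment_tol
        width = _ERROR_RANGE / N_ERROR_BINS
        b = min(int(math.floor(scaled / width + _BIN_EPS)), N_ERROR_BINS - 1)
        return float(self.mz_error[_ROW_INDEX[row], b])

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("[intensity]\n")
            fh.write("row\t" + "\t".join(f"{i / 10:.1f}" for i in range(N_INTENSITY_BINS)) + "\n")
            for r, name in enumerate(ROWS):
                fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in self.intensity[r]) + "\n")
            fh.write("[mz_error]\n")
            fh.write("row\t" + "\t".join(f"{i * 0.05:.2f}" for i in range(N_ERROR_BINS)) + "\n")
            for r, name in enumerate(ROWS):
                fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in self.mz_error[r]) + "\n")
            fh.write("[constants]\n")
            fh.write(f"p_frag\t{self.p_frag:.6g}\n")
            fh.write(f"p_consec\t{self.p_consec:.6g}\n")
            fh.write(f"p_by\t{self.p_by:.6g}\n")

    @classmethod
    def load(cls, path) -> "DiscrimTables":
        with open(path) as fh:
            text = fh.read()
        return cls._parse(text)

    @classmethod
    def _parse(cls, text: str) -> "DiscrimTables":
        section = None
        intensity = {}
        mz_error = {}
        consts = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            parts = line.split("\t")
            if parts[0] == "row":
                continue
            if section == "intensity":
                intensity[parts[0]] = [float(x) for x in parts[1:]]
            elif section == "mz_error":
                mz_error[parts[0]] = [float(x) for x in parts[1:]]
            elif section == "constants":
                consts[parts[0]] = float(parts[1])
        return cls(
            intensity=np.array([intensity[r] for r in ROWS]),
            mz_error=np.array([mz_error[r] for r in ROWS]),
            p_frag=consts["p_frag"],
            p_consec=consts["p_consec"],
            p_by=consts["p_by"],
        )

    @classmethod
    def default(cls) -> "DiscrimTables":
        """The shipped default tables."""
        text = resources.files("pepdisc").joinpath("data/default_tables.tsv").read_text()
        return cls._parse(text)


# ---------------------------------------------------------------------------
# table training


def _intensity_bin(x: float) -> int:
    if x == 1.0:
        return N_INTENSITY_BINS - 1
    return min(int(math.floor(x * 10 + _BIN_EPS)), 9)


def _error_bin(err: float, tol: float) -> int:
    scaled = _ERROR_RANGE * err / tol
    width = _ERROR_RANGE / N_ERROR_BINS
    return min(int(math.floor(scaled / width + _BIN_EPS)), N_ERROR_BINS - 1)


def _accumulate(corpus, fragment_tol: float):
    """Bin counts and matching totals over one corpus of (spectrum, peptide)."""
    int_counts = np.zeros((3, N_INTENSITY_BINS))
    err_counts = np.zeros((3, N_ERROR_BINS))
    totals = {"matched": 0, "theo": 0, "pairs": 0, "theo_pairs": 0, "by": 0, "theo_by": 0}
    for spectrum, peptide in corpus:
        theo = fragment_ions(peptide, spectrum.precursor_charge)
        matches = match_peaks(spectrum, theo, fragment_tol)
        totals["theo"] += theo.n_total()
        totals["theo_pairs"] += theo.n_consecutive_pairs()
        totals["theo_by"] += theo.n_by()
        totals["matched"] += len(matches)
        totals["pairs"] += len(consecutive_pairs(matches))
        for m in matches:
            ib = _intensity_bin(m.intensity_norm)
            eb = _error_bin(m.abs_error, fragment_tol)
            int_counts[2, ib] += 1
            err_counts[2, eb] += 1
            if m.series == "b":
                int_counts[0, ib] += 1
                err_counts[0, eb] += 1
                totals["by"] += 1
            elif m.series == "y":
                int_counts[1, ib] += 1
                err_counts[1, eb] += 1
                totals["by"] += 1
    return int_counts, err_counts, totals


def _ratio(correct: np.ndarray, random: np.ndarray, pseudocount: float) -> np.ndarray:
    out = np.empty_like(correct)
    for idx in np.ndindex(correct.shape):
        c, r = correct[idx], random[idx]
        if c == 0 and r == 0:
            warnings.warn(f"empty bin {idx} in both corpora; discriminability set to 1.0")
            out[idx] = 1.0
        else:
            out[idx] = (c if c > 0 else pseudocount) / (r if r > 0 else pseudocount)
    return out


def train_tables(
    correct_psms,
    incorrect_psms,
    fragment_tol: float = 0.5,
    pseudocount: float = 1.0,
) -> DiscrimTables:
    """Estimate discriminability tables and match probabilities from a corpus.

    ``correct_psms`` and ``incorrect_psms`` are iterables of
    (ProcessedSpectrum, PeptideCandidate) pairs; the incorrect corpus is
    conventionally built by pairing each spectrum with the reversed
    sequence of its correct peptide. Table cells are correct/random
    matched-ion count ratios per bin; the three probabilities are the
    matched fractions of the incorrect corpus (single ions, consecutive
    pairs, plain b/y ions).
    """
    correct_psms = list(correct_psms)
    incorrect_psms = list(incorrect_psms)
    if not correct_psms or not incorrect_psms:
        raise ValueError("both training corpora must be non-empty")
    int_c, err_c, _ = _accumulate(correct_psms, fragment_tol)
    int_r, err_r, totals = _accumulate(incorrect_psms, fragment_tol)

    def frac(k: int, n: int) -> float:
        if n == 0 or k == 0:
            warnings.warn("degenerate random-match totals; falling back to pseudocount rate")
            return max(pseudocount, 1.0) / max(n, 1.0)
        return min(k / n, 1.0 - 1e-9)

    return DiscrimTables(
        intensity=_ratio(int_c, int_r, pseudocount),
        mz_error=_ratio(err_c, err_r, pseudocount),
        p_frag=frac(totals["matched"], totals["theo"]),
        p_consec=frac(totals["pairs"], totals["theo_pairs"]),
        p_by=frac(totals["by"], totals["theo_by"]),
    )
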