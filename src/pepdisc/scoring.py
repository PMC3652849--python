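"""Candidate scoring: three discriminability-weighted sub-scores and the overall Sp.

Each sub-score multiplies a discriminability weight sum by the binomial
significance of the observed match count:

    S = (Σ_j d_j) · (−log10 P(X ≥ k)),   X ~ Binomial(n, p)

* fragment term — every matched ion, pooled six-type table rows, random
  match probability p_frag;
* consecutive term — adjacent-ordinal match pairs within a series/charge,
  pair weight sqrt(d_l · d_m), probability p_consec;
* b/y term — plain b and y matches only, using the b- and y-specific table
  rows, probability p_by.

Sp is the plain sum of the three. A candidate with no matches scores 0 in
every term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .config import SearchConfig
from .digest import PeptideCandidate
from .discrim import (
    DiscrimTables,
    Match,
    PMDMap,
    compute_pmd,
    consecutive_pairs,
    match_peaks,
)
from .preprocess import ProcessedSpectrum
from .theoretical import TheoreticalSpectrum, fragment_ions

_TINY = 1e-300


@dataclass(frozen=True)
class ScoreBreakdown:
    S_frag: float
    S_consec: float
    S_by: float
    Sp: float
    k0: int
    n0: int
    k1: int
    n1: int
    k2: int
    n2: int


@dataclass
class PSM:
    """One scored spectrum-peptide match."""

    spectrum_id: str
    peptide: PeptideCandidate
    charge: int
    breakdown: ScoreBreakdown
    rank: int = 0

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    @property
    def score(self) -> float:
        return self.breakdown.Sp


def binom_tail(k: int, n: int, p: float) -> float:
    """Upper tail P(X >= k) for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(stats.binom.sf(k - 1, n, p))


def _neg_log10_tail(k: int, n: int, p: float) -> float:
    return -math.log10(max(binom_tail(k, n, p), _TINY))


def _pooled_weight(m: Match, pmd: PMDMap, tables: DiscrimTables, fragment_tol: float) -> float:
    return (
        pmd.discriminability(m.peak_index)
        * tables.intensity_discriminability(m.intensity_norm, "s")
        * tables.mz_error_discriminability(m.abs_error, fragment_tol, "s")
    )


def score_fragments(
    matches: list[Match],
    pmd: PMDMap,
    tables: DiscrimTables,
    n0: int,
    fragment_tol: float,
) -> tuple[float, int]:
    """Fragment-ion term over all matched ions (pooled table rows)."""
    k0 = len(matches)
    if k0 == 0:
        return 0.0, 0
    if k0 > n0:
        raise RuntimeError("matched more peaks than theoretical ions; matching contract violated")
    d_total = sum(_pooled_weight(m, pmd, tables, fragment_tol) for m in matches)
    return d_total * _neg_log10_tail(k0, n0, tables.p_frag), k0


def score_consecutive(
    matches: list[Match],
    pmd: PMDMap,
    tables: DiscrimTables,
    n1: int,
    fragment_tol: float,
) -> tuple[float, int]:
    """Consecutive-pair term: geometric-mean pair weights, pair-count significance."""
    pairs = consecutive_pairs(matches)
    k1 = len(pairs)
    if k1 == 0 or n1 == 0:
        return 0.0, k1
    d_total = sum(
        math.sqrt(
            _pooled_weight(a, pmd, tables, fragment_tol)
            * _pooled_weight(b, pmd, tables, fragment_tol)
        )
        for a, b in pairs
    )
    return d_total * _neg_log10_tail(k1, n1, tables.p_consec), k1


def score_by_ions(
    matches: list[Match],
    pmd: PMDMap,
    tables: DiscrimTables,
    n2: int,
    fragment_tol: float,
) -> tuple[float, int]:
    """Plain b/y term using the series-specific table rows."""
    by = [m for m in matches if m.series in ("b", "y")]
    k2 = len(by)
    if k2 == 0 or n2 == 0:
        return 0.0, k2
    d_total = sum(
        pmd.discriminability(m.peak_index)
        * tables.intensity_discriminability(m.intensity_norm, m.series)
        * tables.mz_error_discriminability(m.abs_error, fragment_tol, m.series)
        for m in by
    )
    return d_total * _neg_log10_tail(k2, n2, tables.p_by), k2


def score_candidate(
    spectrum: ProcessedSpectrum,
    matches: list[Match],
    theo: TheoreticalSpectrum,
    pmd: PMDMap,
    tables: DiscrimTables,
    fragment_tol: float,
) -> ScoreBreakdown:
    n0 = theo.n_total()
    n1 = theo.n_consecutive_pairs()
    n2 = theo.n_by()
    s0, k0 = score_fragments(matches, pmd, tables, n0, fragment_tol)
    s1, k1 = score_consecutive(matches, pmd, tables, n1, fragment_tol)
    s2, k2 = score_by_ions(matches, pmd, tables, n2, fragment_tol)
    return ScoreBreakdown(s0, s1, s2, s0 + s1 + s2, k0, n0, k1, n1, k2, n2)


def psm_sort_key(psm: PSM):
    """Deterministic ranking: Sp descending, then fewer mods, then sequence."""
    return (
        -psm.breakdown.Sp,
        len(psm.peptide.mod_deltas),
        psm.peptide.sequence,
        psm.is_decoy,
    )


def rank_candidates(
    spectrum: ProcessedSpectrum,
    candidates: list[PeptideCandidate],
    tables: DiscrimTables,
    config: SearchConfig,
) -> list[PSM]:
    """Score every candidate against the spectrum and rank by Sp.

    The PMD map is computed once over the whole candidate set (targets and
    decoys together); each candidate is then scored from its own one-to-one
    peak-ion assignment.
    """
    if not candidates:
        return []
    tol = config.fragment_tol
    theos = [fragment_ions(c, spectrum.precursor_charge) for c in candidates]
    pmd = compute_pmd(spectrum, candidates, tol, form=config.pmd_form, theoreticals=theos)
    psms: list[PSM] = []
    for cand, theo in zip(candidates, theos):
        if pmd.is_empty:
            matches: list[Match] = []
        else:
            matches = match_peaks(spectrum, theo, tol)
        breakdown = score_candidate(spectrum, matches, theo, pmd, tables, tol)
        psms.append(PSM(spectrum.spectrum_id, cand, spectrum.precursor_charge, breakdown))
    psms.sort(key=psm_sort_key)
    for rank, psm in enumerate(psms, start=1):
        psm.rank = rank
    return psms
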