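"""Independent brute-force oracles the implementation is checked against.

Each function here recomputes a quantity by direct enumeration, staying
deliberately naive and separate from the library's own code paths.
"""

from fractions import Fraction

import numpy as np


def tryptic_peptides_bruteforce(sequence: str, max_missed: int) -> set[tuple[str, int]]:
    """All fully tryptic (peptide, missed_cleavages) by substring enumeration."""
    n = len(sequence)
    sites = {i for i in range(n - 1) if sequence[i] in "KR" and sequence[i + 1] != "P"}
    boundaries = {-1} | sites | {n - 1}  # cut after index i
    out = set()
    for start in sorted(boundaries - {n - 1}):
        for end in sorted(b for b in boundaries if b > start):
            internal = [s for s in sites if start < s < end]
            if len(internal) <= max_missed:
                out.add((sequence[start + 1 : end + 1], len(internal)))
    return out


def select_peaks_bruteforce(mz, intensity, n_bins=10, per_bin=20):
    """Per-bin sort-and-take selection over already isotope-filtered peaks."""
    mz = np.asarray(mz, float)
    intensity = np.asarray(intensity, float)
    lo, hi = mz.min(), mz.max()
    if hi == lo:
        bins = np.zeros(mz.size, int)
    else:
        width = (hi - lo) / n_bins
        bins = np.minimum(((mz - lo) / width).astype(int), n_bins - 1)
    keep = []
    for b in range(n_bins):
        idx = [i for i in range(mz.size) if bins[i] == b]
        idx.sort(key=lambda i: (-intensity[i], -mz[i]))
        keep.extend(idx[:per_bin])
    keep.sort()
    return mz[keep], intensity[keep]


def pmd_bruteforce(peak_mz, candidate_ion_mzs, tol):
    """Triple loop over peaks x candidates x ions: per-peak match counts."""
    counts = []
    for pmz in peak_mz:
        c = 0
        for ions in candidate_ion_mzs:
            if any(abs(pmz - imz) <= tol for imz in ions):
                c += 1
        counts.append(c)
    return counts


def binom_tail_exact(k: int, n: int, p: float) -> float:
    """P(X >= k) by exhaustive summation with exact binomial coefficients."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    total = 0.0
    for j in range(k, n + 1):
        coeff = Fraction(1)
        for t in range(j):
            coeff = coeff * (n - t) / (t + 1)
        total += float(coeff) * p**j * (1 - p) ** (n - j)
    return total


def fdr_curve_bruteforce(target_scores, decoy_scores, level):
    """O(T*D) threshold scan: FDR at every distinct score plus the threshold."""
    scores = sorted(set(target_scores) | set(decoy_scores), reverse=True)
    curve = []
    for s in scores:
        t = sum(1 for x in target_scores if x >= s)
        d = sum(1 for x in decoy_scores if x >= s)
        fdr = d / t if t else float("inf")
        curve.append((s, t, d, fdr))
    feasible = [s for s, _, _, f in curve if f <= level]
    threshold = min(feasible) if feasible else float("inf")
    accepted = sorted((x for x in target_scores if x >= threshold), reverse=True)
    return curve, threshold, accepted
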