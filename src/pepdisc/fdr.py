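"""Target-decoy FDR estimation and thresholding at the PSM level.

Only each spectrum's rank-1 PSM with peptide length >= 6 participates. The
FDR at a score s is the plain ratio decoys_ge(s) / targets_ge(s) over PSMs
scoring at or above s (ties count as above); the chosen threshold is the
smallest score whose FDR is at or below the requested level, and the
accepted set is every target PSM at or above that threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import PSM


@dataclass
class FDRResult:
    """The score-sorted target/decoy curve, chosen threshold and accepted PSMs."""

    scores: np.ndarray  # distinct scores, descending
    targets_ge: np.ndarray
    decoys_ge: np.ndarray
    fdr: np.ndarray
    threshold: float  # inf when no score meets the level
    level: float
    accepted: list[PSM]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.scores,
                "targets": self.targets_ge,
                "decoys": self.decoys_ge,
                "fdr": self.fdr,
            }
        )


def _eligible(psms: list[PSM], min_length: int) -> list[PSM]:
    return [p for p in psms if p.rank == 1 and len(p.peptide) >= min_length]


def compute_fdr_curve(
    psms: list[PSM],
    level: float = 0.01,
    min_peptide_length: int = 6,
    monotonize: bool = False,
) -> FDRResult:
    """Estimate the target-decoy FDR curve and threshold it at ``level``.

    ``monotonize`` optionally replaces the raw ratio with its running
    minimum from the top of the score list (a q-value); off by default.
    """
    eligible = _eligible(psms, min_peptide_length)
    if not eligible:
        warnings.warn("no eligible PSMs (rank 1, length >= minimum); empty FDR result")
        return FDRResult(
            np.array([]), np.array([], int), np.array([], int), np.array([]),
            float("inf"), level, [],
        )
    scores = np.array([p.score for p in eligible])
    decoy = np.array([p.is_decoy for p in eligible])
    order = np.argsort(-scores, kind="stable")
    scores_sorted = scores[order]
    decoy_sorted = decoy[order]
    distinct, first_idx = np.unique(-scores_sorted, return_index=True)
    distinct = -distinct  # descending distinct scores
    cum_decoys = np.cumsum(decoy_sorted)
    cum_targets = np.cumsum(~decoy_sorted)
    # counts at-or-above each distinct score = cumulative count through its last occurrence
    last_idx = np.append(first_idx[1:], len(scores_sorted)) - 1
    targets_ge = cum_targets[last_idx]
    decoys_ge = cum_decoys[last_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(targets_ge > 0, decoys_ge / np.maximum(targets_ge, 1), np.inf)
        fdr = np.where((targets_ge == 0) & (decoys_ge == 0), 0.0, fdr)
    if monotonize:
        fdr = np.minimum.accumulate(fdr[::-1])[::-1]

    ok = np.nonzero(fdr <= level)[0]
    if ok.size == 0:
        warnings.warn(f"no score threshold achieves FDR <= {level}; nothing accepted")
        threshold = float("inf")
        accepted: list[PSM] = []
    else:
        threshold = float(distinct[ok].min())
        accepted = [p for p in eligible if not p.is_decoy and p.score >= threshold]
    return FDRResult(distinct, targets_ge, decoys_ge, fdr, threshold, level, accepted)


def compute_fdr(
    psms: list[PSM],
    level: float = 0.01,
    min_peptide_length: int = 6,
    monotonize: bool = False,
    per_charge: bool = False,
) -> FDRResult | dict[int, FDRResult]:
    """FDR thresholding, optionally stratified by precursor charge."""
    if not per_charge:
        return compute_fdr_curve(psms, level, min_peptide_length, monotonize)
    by_charge: dict[int, list[PSM]] = {}
    for p in psms:
        by_charge.setdefault(p.charge, []).append(p)
    return {
        z: compute_fdr_curve(group, level, min_peptide_length, monotonize)
        for z, group in sorted(by_charge.items())
    }


def unique_peptides(accepted: list[PSM]) -> tuple[int, list[tuple[str, str]]]:
    """Count accepted peptides unique by (sequence, modification set)."""
    keys = sorted({(p.peptide.sequence, p.peptide.mod_string()) for p in accepted})
    return len(keys), keys
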