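"""End-to-end search orchestration.

``run_search`` ties the pipeline together: decoy generation, digestion and
indexing, per-spectrum preprocessing and candidate lookup, PMD and
discriminability scoring, ranking, and PSM-level target-decoy FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import SearchConfig
from .digest import PeptideIndex, generate_decoys
from .discrim import DiscrimTables
from .fdr import FDRResult, compute_fdr_curve, unique_peptides
from .io import ProteinRecord, RawSpectrum
from .preprocess import select_peaks
from .scoring import PSM, psm_sort_key, rank_candidates

log = logging.getLogger("pepdisc")


@dataclass
class SearchResult:
    best_psms: list[PSM]  # one rank-1 PSM per spectrum id
    fdr: FDRResult
    stats: dict = field(default_factory=dict)

    @property
    def accepted(self) -> list[PSM]:
        return self.fdr.accepted


def run_search(
    spectra: list[RawSpectrum],
    records: list[ProteinRecord],
    config: SearchConfig | None = None,
    tables: DiscrimTables | None = None,
    index: PeptideIndex | None = None,
) -> SearchResult:
    """Search spectra against a protein database with target-decoy FDR control.

    ``records`` is the forward (target) database; reversed decoys are
    appended automatically. When one spectrum id appears with several
    precursor charges (chargeless MGF blocks expanded over a default charge
    list), only its best-scoring PSM across charges is kept.
    """
    config = config or SearchConfig()
    tables = tables or DiscrimTables.default()
    if index is None:
        database = generate_decoys(records)
        index = PeptideIndex.build(database, config)
        log.info("database: %d proteins (with decoys), %d indexed peptide variants",
                 len(database), len(index))

    best: dict[str, PSM] = {}
    n_candidates_total = 0
    n_scored = 0
    for spec in spectra:
        try:
            processed = select_peaks(spec)
        except ValueError as exc:
            log.warning("skipping spectrum %s: %s", spec.spectrum_id, exc)
            continue
        candidates = index.lookup(spec.neutral_mass(), config)
        n_candidates_total += len(candidates)
        psms = rank_candidates(processed, candidates, tables, config)
        n_scored += len(psms)
        if not psms:
            continue
        top = psms[0]
        prev = best.get(top.spectrum_id)
        if prev is None or psm_sort_key(top) < psm_sort_key(prev):
            best[top.spectrum_id] = top

    best_psms = list(best.values())
    for p in best_psms:
        p.rank = 1
    fdr = compute_fdr_curve(
        best_psms,
        level=config.fdr_level,
        min_peptide_length=config.fdr_min_peptide_length,
        monotonize=config.fdr_monotonize,
    ) if best_psms else compute_fdr_curve([], level=config.fdr_level)

    n_unique, _ = unique_peptides(fdr.accepted)
    stats = {
        "n_spectra": len(spectra),
        "n_spectra_scored": len(best_psms),
        "n_indexed_peptides": len(index),
        "mean_candidates_per_spectrum": n_candidates_total / max(len(spectra), 1),
        "n_psms_scored": n_scored,
        "fdr_threshold": fdr.threshold,
        "n_accepted_psms": len(fdr.accepted),
        "n_unique_peptides": n_unique,
    }
    log.info(
        "searched %d spectra; %d PSMs scored; Sp threshold %.3f at FDR %.3g; "
        "%d PSMs / %d unique peptides accepted",
        len(spectra), n_scored, fdr.threshold, config.fdr_level,
        len(fdr.accepted), n_unique,
    )
    return SearchResult(best_psms, fdr, stats)
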