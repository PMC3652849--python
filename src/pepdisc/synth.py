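"""Synthetic protein databases and MS/MS spectra with known ground truth.

The generator emulates the structure the scoring model exploits: fragment
peaks at the theoretical b/y (and conditional loss) m/z values with
Gaussian m/z jitter, y ions brighter than b ions on average, neutral-loss
peaks attenuated, multiplicative log-normal intensity noise, and uniform
random noise peaks. Every output is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CARBAMIDOMETHYL, PROTON, peptide_mono_mass
from .digest import PeptideCandidate, digest_protein
from .io import ProteinRecord, RawSpectrum, write_fasta, write_mgf
from .theoretical import fragment_ions

#: residue weights for random protein sequences; K/R slightly enriched so
#: tryptic peptides of length 6-30 are plentiful
_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")
_WEIGHTS = np.array([1.5 if aa in "KR" else 0.2 if aa in "CM" else 1.0 for aa in _ALPHABET])
_WEIGHTS = _WEIGHTS / _WEIGHTS.sum()

#: planted-peptide interior alphabet: no K/R (tryptic termini only), no P
#: (would complicate the cleavage flanks)
_INTERIOR = [aa for aa in _ALPHABET if aa not in "KRP"]
_INTERIOR_W = np.array([0.2 if aa in "CM" else 1.0 for aa in _INTERIOR])
_INTERIOR_W = _INTERIOR_W / _INTERIOR_W.sum()


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    n_proteins: int = 40
    protein_length: int = 240
    n_planted: int = 100
    planted_peptides: list[str] | None = None
    planted_length: tuple[int, int] = (8, 14)
    charge: int = 2
    #: fragment intensity model: arbitrary units, multiplicative log-normal noise
    b_base: float = 100.0
    y_base: float = 300.0
    loss_attenuation: float = 0.3
    intensity_sigma: float = 0.4
    #: m/z jitter of true fragment peaks, Da (default well inside tol/3 for 0.5 Da searches)
    jitter_sd: float = 0.05
    #: uniform-m/z noise peaks per spectrum
    n_noise_peaks: int = 10
    noise_intensity: tuple[float, float] = (5.0, 80.0)
    #: additional spectra containing only noise peaks
    n_noise_only: int = 0
    noise_only_peaks: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass
class Benchmark:
    records: list[ProteinRecord]
    spectra: list[RawSpectrum]
    truth: pd.DataFrame  # spectrum_id, peptide, charge


def make_candidate(sequence: str, is_decoy: bool = False) -> PeptideCandidate:
    """Peptide candidate with the fixed carbamidomethyl-C modification applied."""
    mods = tuple((i, CARBAMIDOMETHYL) for i, aa in enumerate(sequence) if aa == "C")
    return PeptideCandidate(
        sequence=sequence,
        mod_deltas=mods,
        mono_mass=peptide_mono_mass(sequence, mods),
        missed_cleavages=0,
        protein_ids=("synthetic",),
        is_decoy=is_decoy,
    )


def sample_planted_peptide(rng: np.random.Generator, length_range=(8, 14)) -> str:
    """A fully tryptic peptide: non-K/R/P interior, K or R at the C-terminus."""
    L = int(rng.integers(length_range[0], length_range[1] + 1))
    interior = rng.choice(_INTERIOR, size=L - 1, p=_INTERIOR_W)
    cterm = rng.choice(["K", "R"])
    return "".join(interior) + cterm


def generate_database(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[str]]:
    """Random protein records with planted tryptic peptides embedded verbatim.

    Each planted peptide is inserted between a K flank and a non-proline
    continuation, so full tryptic digestion recovers it exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.planted_peptides is not None:
        planted = list(config.planted_peptides)
    else:
        seen: set[str] = set()
        planted = []
        while len(planted) < config.n_planted:
            pep = sample_planted_peptide(rng, config.planted_length)
            if pep not in seen:
                seen.add(pep)
                planted.append(pep)

    by_protein: list[list[str]] = [[] for _ in range(config.n_proteins)]
    for j, pep in enumerate(planted):
        by_protein[j % config.n_proteins].append(pep)

    records: list[ProteinRecord] = []
    for p in range(config.n_proteins):
        seq = "".join(rng.choice(_ALPHABET, size=config.protein_length, p=_WEIGHTS))
        peps = by_protein[p]
        # interleave random chunks with K<peptide>A inserts so embeddings
        # never overlap each other
        cuts = sorted(int(c) for c in rng.integers(1, len(seq), size=len(peps)))
        parts = [seq[: cuts[0]] if cuts else seq]
        for i, pep in enumerate(peps):
            parts.append("K" + pep + "A")
            end = cuts[i + 1] if i + 1 < len(cuts) else len(seq)
            parts.append(seq[cuts[i] : end])
        records.append(ProteinRecord(f"SYN_{p:04d}", "".join(parts)))
    return records, planted


def simulate_spectrum(
    peptide: str | PeptideCandidate,
    charge: int,
    config: SynthConfig,
    rng: np.random.Generator,
    spectrum_id: str = "sim_0",
) -> RawSpectrum:
    """Simulate the MS/MS spectrum of a peptide under the intensity/jitter model."""
    cand = peptide if isinstance(peptide, PeptideCandidate) else make_candidate(peptide)
    if len(cand) < 6:
        raise ValueError("simulated peptides must have length >= 6")
    theo = fragment_ions(cand, charge)

    base = np.empty(len(theo))
    for i, code in enumerate(theo.series_code):
        series_base = config.b_base if code % 2 == 0 else config.y_base
        base[i] = series_base if code < 2 else series_base * config.loss_attenuation
    intensity = base * np.exp(rng.normal(0.0, config.intensity_sigma, size=len(theo)))
    mz = theo.mz + rng.normal(0.0, config.jitter_sd, size=len(theo))

    if config.n_noise_peaks > 0:
        lo, hi = float(theo.mz.min()) - 20.0, float(theo.mz.max()) + 20.0
        noise_mz = rng.uniform(lo, hi, size=config.n_noise_peaks)
        noise_int = rng.uniform(*config.noise_intensity, size=config.n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_int])

    precursor_mz = (cand.mono_mass + charge * PROTON) / charge
    return RawSpectrum(spectrum_id, precursor_mz, charge, mz, intensity)


def simulate_noise_spectrum(
    precursor_neutral_mass: float,
    charge: int,
    config: SynthConfig,
    rng: np.random.Generator,
    spectrum_id: str = "noise_0",
) -> RawSpectrum:
    """A spectrum of pure noise at a plausible precursor mass."""
    hi = max(precursor_neutral_mass, 400.0)
    mz = rng.uniform(150.0, hi, size=config.noise_only_peaks)
    intensity = rng.uniform(*config.noise_intensity, size=config.noise_only_peaks)
    precursor_mz = (precursor_neutral_mass + charge * PROTON) / charge
    return RawSpectrum(spectrum_id, precursor_mz, charge, mz, intensity)


def generate_benchmark(config: SynthConfig) -> Benchmark:
    """Database + spectra + truth table, all deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    records, planted = generate_database(config, rng)

    spectra: list[RawSpectrum] = []
    rows = []
    for j, pep in enumerate(planted):
        sid = f"synth_{j:04d}"
        spectra.append(simulate_spectrum(pep, config.charge, config, rng, sid))
        rows.append({"spectrum_id": sid, "peptide": pep, "charge": config.charge})

    if config.n_noise_only > 0:
        # plausible precursor masses: real tryptic peptide masses from the db
        masses = [
            p.mono_mass
            for rec in records
            for p in digest_protein(rec, max_missed=0, min_length=7, max_length=20)
        ]
        for j in range(config.n_noise_only):
            m = float(rng.choice(masses))
            sid = f"noise_{j:04d}"
            spectra.append(simulate_noise_spectrum(m, config.charge, config, rng, sid))

    truth = pd.DataFrame(rows, columns=["spectrum_id", "peptide", "charge"])
    return Benchmark(records, spectra, truth)


def write_benchmark(bench: Benchmark, fasta_path, mgf_path, truth_path) -> None:
    write_fasta(bench.records, fasta_path)
    write_mgf(bench.spectra, mgf_path)
    bench.truth.to_csv(truth_path, index=False)
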