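# Methods

This note documents the model behind pepdisc, the choices made where the
design was genuinely open, the synthetic data the tests rely on, and the
known limitations.

## Spectrum preprocessing

A raw scan is reduced to the scored peak set in three steps.

**Isotope filtering.** Peaks separated by 1 ± 0.25 Da are treated as members
of one isotope envelope. A single ascending-m/z pass compares each peak
against every already-retained peak within 1.25 Da below it: if any such peak
is more intense, the current peak is dropped; otherwise the weaker earlier
members give way, so the locally most intense member of each chain survives.
Comparing against *all* retained peaks in the window (not only the nearest)
matters when a non-isotope peak (< 0.75 Da away) sits between two members of
an envelope.

**Binned selection.** The observed m/z range [min, max] is split into 10
equal-width bins (last bin right-closed) and the 20 most intense peaks per
bin are kept, so at most 200 peaks are scored. Ties are broken toward higher
m/z for determinism. A degenerate spectrum whose peaks share one m/z value
collapses into a single bin. Because the bins are recomputed from the
observed range, re-running selection on its own output is not strictly
idempotent — dropping an extreme peak narrows the range and shifts the bins —
but repeated application shrinks monotonically to a stable fixpoint, which
the test suite verifies.

**Normalization.** Kept intensities are divided by the largest kept
intensity, so the base peak has normalized intensity exactly 1.0; the
intensity table has a dedicated category for it.

## Peptide space

Digestion is fully tryptic: cleavage after K or R except before proline, with
0–2 missed cleavages (default 2). Decoys are whole-protein reversals appended
to the target database; the search runs against the concatenation, so the
candidate window for each precursor returns targets and decoys together.
Modifications are carbamidomethyl-C (+57.021464 Da, fixed) and oxidized-M
(+15.994915 Da, variable, at most 3 per peptide — unbounded variable
modification would make the variant count explode combinatorially). All mass
arithmetic is monoisotopic (proton 1.007276 Da, water 18.010565 Da, ammonia
17.026549 Da, residue masses from the standard table). The precursor neutral
mass of a spectrum is m/z·z − z·proton; candidates are retrieved by binary
search on a mass-sorted index within the Da or ppm tolerance.

The length ≥ 6 filter is applied at FDR ranking, not at candidate generation:
short peptides may still compete for a spectrum (affecting PMD and ranking),
but they cannot enter the reported set.

## Theoretical spectra

Six series are predicted: b, y, b−H₂O, y−H₂O, b−NH₃, y−NH₃. Water loss
requires S/T/E/D and ammonia loss R/K/Q/N within the fragment's own residue
span (the prefix for b, the suffix for y). Singly charged fragments are
always generated; doubly charged fragments only when the precursor charge is
≥ 2 and the fragment contains R, K or H, and losses are emitted at both
charge states when both conditions hold. No a/c/x/z ions, immonium ions,
internal fragments or combined losses are generated.

## Discriminability

**PMD.** For each selected peak, *M_i* counts the candidates with at least
one theoretical ion within the fragment tolerance of the peak; *M̄* averages
the counts of matched peaks only (peaks matching no candidate can never
contribute to a score and are excluded). The discriminability is the ratio
*D = M̄ / M_i*. The ratio form was chosen because it makes rarer (more
discriminative) peaks score higher, normalizes the average matched peak to
exactly 1, and is scale-free in the candidate-set size; an alternative
shifted form (*M̄ − M_i + 1*, clamped below at 0.1) is available behind
`SearchConfig.pmd_form` for experimentation.

**Tables.** The shipped intensity table is 3 rows (b, y, pooled) × 11 bins
over normalized intensity; the m/z-error table is 3 × 10 bins over [0, 0.5]
Da. Lookups are left-closed/right-open except the final category; intensity
exactly 1.0 hits the base-peak bin, and an error equal to 0.5 joins the last
error bin (the table has no separate column for it). When a search runs at a
fragment tolerance other than the 0.5 Da the tables were estimated at (the
QTOF preset uses 0.2 Da), the error is rescaled proportionally
(err · 0.5/tol) so bin semantics are preserved.

**Training.** `train_tables` re-estimates everything from a corpus of
(spectrum, peptide) pairs judged correct, paired with the reversed sequences
as the incorrect corpus. Each cell is the correct/random matched-ion count
ratio in that bin; a zero denominator is replaced by a pseudocount (default
1.0), and a bin empty in both corpora becomes 1.0 with a warning. The three
random-match probabilities are the matched fractions of the incorrect corpus:
matched ions over theoretical ions (p_frag), matched adjacent pairs over
theoretical adjacent pairs (p_consec), and matched plain b/y ions over
theoretical b/y ions (p_by). Training uses the same one-to-one matching rules
as scoring.

## Scoring

Peak-ion matching is one-to-one: candidate pairs within the fragment
tolerance are assigned greedily by ascending |error|, so each peak takes its
closest available ion and no ion is used twice.

The three sub-scores share one functional form,
S = (Σ d_j) · (−log₁₀ P(X ≥ k)) with X ~ Binomial(n, p). The ingredients —
match count k, theoretical count n, the random-match probability p, and the
discriminability weights d_j — are the model's stated quantities; combining
them as a weight sum times a binomial tail significance is this package's
design choice. It is monotone in the match count at fixed n (adding a match
never lowers a sub-score), reduces to exactly 0 for an empty match set, and
is linear in the discriminability weights. The form is isolated in one module
so alternatives can be swapped. Consecutive-pair weights use the geometric
mean √(d_l·d_m), keeping pairs on the same scale as single matches. Plain b/y
matches intentionally contribute to both the fragment term (pooled rows) and
the b/y term (series-specific rows): the b/y signal is considered separately
on top of the overall match evidence. n₁ counts theoretically adjacent
ordinal pairs per series and charge; n₂ counts plain b/y ions at all emitted
charges.

Candidates are ranked by Sp descending; ties break toward fewer
modifications, then lexicographic sequence, so output is deterministic. The
absolute score scale of the original implementation is not reproduced — only
the ordering semantics matter for FDR control.

## FDR

Only each spectrum's best PSM with peptide length ≥ 6 participates. The FDR
at score s is the plain ratio decoys/targets counted at or above s (ties
inclusive, conservatively counting the tied decoy); the threshold is the
smallest score with FDR ≤ the requested level and the accepted set is every
target PSM at or above it. Per-charge stratification and q-value
monotonization exist as options, both off by default.

A property of the plain ratio worth knowing: in a run dominated by
high-scoring true PSMs, the ratio stays below 1% until roughly one decoy per
hundred targets, so the threshold can slide below the top decoy score and
admit about one junk PSM per hundred true ones. That is the nominal 1%
false-discovery budget, not a defect; runs containing signal-free spectra
will typically see those spectra absorb exactly that budget.

## Synthetic benchmark

The generator emulates what the scoring model exploits, with defaults chosen
once as realistic desk-scale conditions:

* database: 40 random proteins of 240 residues, K/R enriched (~14%) so
  tryptic peptides of length 6–30 are plentiful, C/M rare; 100 planted
  fully tryptic peptides (length 8–14, K/R C-terminus, no internal K/R/P)
  embedded between a K flank and a non-proline continuation;
* spectra: one charge-2 scan per planted peptide; fragment peaks at the
  theoretical m/z with Gaussian jitter (sd 0.05 Da, comfortably inside a
  0.5 Da tolerance), y-series base intensity 3× the b-series, neutral losses
  attenuated to 0.3×, multiplicative log-normal intensity noise (σ = 0.4),
  plus 10 uniform-m/z noise peaks per scan;
* optionally, signal-free spectra (60 noise peaks at a real tryptic
  precursor mass) to probe false acceptance.

Everything is a deterministic function of the seed; regeneration is
byte-identical. The generator does **not** simulate isotope envelopes,
chromatography, charge-state mixtures, co-fragmentation, or instrument-
specific intensity response — so passing recovery tests demonstrate the
engine's internal consistency and discrimination under the stated noise
model, not performance on real instrument data, and the shipped tables'
absolute values are not validated by synthetic recovery.

## Numerical choices

Binomial tails use the exact survival function (verified against exhaustive
summation to 1e−12 for n ≤ 30) and are floored at 1e−300 before the log. Bin
indices add a 1e−9 guard against floating-point boundary noise. MGF blocks
without a charge line are expanded over a configurable charge list (default
2, 3) and the best PSM across charges is kept per spectrum id. Spectra whose
peaks are all filtered away are skipped with a warning; an empty candidate
window yields no PSM for that spectrum.

## Known limitations

Semi-tryptic and non-specific searches, protein-terminal modifications,
precursor isotope-error windows, a/c/x/z ions, peptide- and protein-level
FDR, and posterior error probabilities are out of scope. The shipped tables
were estimated on ion-trap-style data at 0.5 Da fragment tolerance; the
proportional error rescaling for other tolerances preserves bin semantics
but not necessarily calibration.
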