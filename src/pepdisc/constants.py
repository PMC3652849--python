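"""Monoisotopic mass constants shared across the engine.

All arithmetic is monoisotopic: the fixed carbamidomethyl modification mass
(+57.021464 Da) only makes sense on that scale, so residue, water, ammonia
and proton masses are monoisotopic throughout.
"""

from pyteomics import mass as _pmass

PROTON = 1.007276
WATER = 18.010565
NH3 = 17.026549

#: Monoisotopic residue (amino-acid minus water) masses for the 20 standard letters.
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

#: Fixed modification: carbamidomethylation of cysteine.
CARBAMIDOMETHYL = 57.021464
#: Variable modification: oxidation of methionine.
OXIDATION = 15.994915

STANDARD_AA = frozenset(RESIDUE_MASS)


def peptide_mono_mass(sequence: str, mod_deltas=()) -> float:
    """Neutral monoisotopic mass of a peptide: residues + modifications + water."""
    m = WATER
    for aa in sequence:
        m += RESIDUE_MASS[aa]
    for _, delta in mod_deltas:
        m += delta
    return m
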