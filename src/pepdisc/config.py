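"""Search configuration and instrument presets.

The presets carry the precursor/fragment tolerances appropriate to each
instrument class: ion traps (LCQ_Deca, LTQ) use wide Da windows, FT and
Orbitrap instruments use 10 ppm precursor windows, QTOF uses tight Da
windows on both levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import CARBAMIDOMETHYL, OXIDATION


@dataclass(frozen=True)
class InstrumentPreset:
    name: str
    precursor_tol: float
    precursor_unit: str  # "Da" or "ppm"
    fragment_tol: float  # Da


INSTRUMENT_PRESETS: dict[str, InstrumentPreset] = {
    p.name: p
    for p in [
        InstrumentPreset("LCQ_Deca", 3.0, "Da", 0.5),
        InstrumentPreset("LTQ", 3.0, "Da", 0.5),
        InstrumentPreset("LTQ-FT", 10.0, "ppm", 0.5),
        InstrumentPreset("QTOF", 0.2, "Da", 0.2),
        InstrumentPreset("LTQ-Orbitrap", 10.0, "ppm", 0.5),
    ]
}


@dataclass
class SearchConfig:
    """All knobs of a database search.

    Defaults follow common practice for tryptic searches: full tryptic
    specificity with up to 2 missed cleavages, fixed carbamidomethyl-C,
    variable oxidized-M (at most 3 variable mods per peptide), and the LTQ
    tolerance preset.
    """

    precursor_tol: float = 3.0
    precursor_unit: str = "Da"  # "Da" or "ppm"
    fragment_tol: float = 0.5  # Da
    max_missed_cleavages: int = 2
    fixed_mods: dict[str, float] = field(default_factory=lambda: {"C": CARBAMIDOMETHYL})
    variable_mods: dict[str, float] = field(default_factory=lambda: {"M": OXIDATION})
    max_variable_mods: int = 3
    min_peptide_length: int = 1  # length >=6 is enforced at FDR ranking, not here
    fdr_min_peptide_length: int = 6
    fdr_level: float = 0.01
    default_charges: tuple[int, ...] = (2, 3)
    #: PMD functional form: "ratio" (mean/M_i) or "shifted" (mean - M_i + 1, floored at a minimum)
    pmd_form: str = "ratio"
    #: stratify the FDR computation by precursor charge (off: scores sorted globally)
    fdr_per_charge: bool = False
    #: monotonize the FDR curve into q-values (off: plain decoy/target ratio)
    fdr_monotonize: bool = False

    def __post_init__(self) -> None:
        if self.precursor_unit not in ("Da", "ppm"):
            raise ValueError("precursor_unit must be 'Da' or 'ppm'")
        if self.fragment_tol <= 0 or self.precursor_tol <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "SearchConfig":
        preset = INSTRUMENT_PRESETS[name]
        kwargs = dict(
            precursor_tol=preset.precursor_tol,
            precursor_unit=preset.precursor_unit,
            fragment_tol=preset.fragment_tol,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def precursor_window(self, neutral_mass: float) -> float:
        """Half-width of the precursor window in Da at the given mass."""
        if self.precursor_unit == "ppm":
            return neutral_mass * self.precursor_tol * 1e-6
        return self.precursor_tol
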