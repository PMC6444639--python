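"""Monoisotopic mass deltas for common plant metabolite decorations.

Deltas are computed from monoisotopic atomic masses (via :mod:`pyteomics.mass`)
for the net formula gained in each biotransformation, e.g. glycosylation adds a
hexose minus water, C6H10O5 = 162.05282 Da.  The shipped table covers the
decorations most often seen on plant specialized metabolites; it is a default,
fully replaceable by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics.mass import calculate_mass

from .model import ValidationError

# monoisotopic mass of a proton (H+); hydrogen atom minus the electron mass
PROTON_MASS = 1.00727646688


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a chemical formula in Da."""
    return float(calculate_mass(formula=formula))


#: net formula gained per biotransformation step
DEFAULT_DELTA_FORMULAS: dict[str, str] = {
    "glycosylation": "C6H10O5",     # hexose (e.g. glucose) minus water
    "rhamnosylation": "C6H10O4",    # deoxyhexose minus water
    "methylation": "CH2",
    "hydroxylation": "O",
    "acetylation": "C2H2O",
    "malonylation": "C3H2O3",
    "sinapoylation": "C11H10O4",    # sinapic acid minus water
}


@dataclass(frozen=True)
class BiotransformationTable:
    """Named positive mass deltas plus the matching tolerances.

    A pair of features matches an entry when their m/z difference agrees with
    the delta within ``max(tolerance_abs, tolerance_ppm * mean_mz * 1e-6)``.
    """

    entries: tuple[tuple[str, float], ...]
    tolerance_ppm: float = 10.0
    tolerance_abs: float = 0.005  # Da

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("biotransformation names must be unique")
        for name, delta in self.entries:
            if not delta > 0:
                raise ValidationError(f"delta for {name!r} must be > 0, got {delta}")
        if self.tolerance_ppm < 0 or self.tolerance_abs < 0:
            raise ValidationError("tolerances must be non-negative")

    def delta(self, name: str) -> float:
        for n, d in self.entries:
            if n == name:
                return d
        raise KeyError(name)

    def tolerance_at(self, mean_mz: float) -> float:
        return max(self.tolerance_abs, self.tolerance_ppm * mean_mz * 1e-6)


def default_biotransformations(
    tolerance_ppm: float = 10.0, tolerance_abs: float = 0.005
) -> BiotransformationTable:
    """The shipped decoration table, deltas computed from atomic masses."""
    entries = tuple(
        (name, formula_mass(formula)) for name, formula in DEFAULT_DELTA_FORMULAS.items()
    )
    return BiotransformationTable(entries, tolerance_ppm, tolerance_abs)
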