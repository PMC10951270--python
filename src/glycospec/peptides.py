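"""Peptide sequences, modifications and monoisotopic mass bookkeeping.

Amino-acid residue masses, water and proton masses come from pyteomics.
Modifications are carried as elemental-composition deltas over (H, C, N, O,
S, P) — the same six-element representation the spectrum predictor embeds —
plus the implied monoisotopic mass delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _pt_mass

__all__ = [
    "Modification",
    "PeptideSequence",
    "AMINO_ACIDS",
    "PROTON_MASS",
    "WATER_MASS",
    "residue_masses",
    "CARBAMIDOMETHYL",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PROTON_MASS = 1.007276466
WATER_MASS = _pt_mass.calculate_mass(formula="H2O")

_ELEMENTS = ("H", "C", "N", "O", "S", "P")

residue_masses = {aa: _pt_mass.std_aa_mass[aa] for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class Modification:
    """A fixed or variable PTM as an elemental delta over H,C,N,O,S,P."""

    name: str
    elements: tuple[int, int, int, int, int, int]  # H, C, N, O, S, P

    @property
    def mass(self) -> float:
        comp = {el: n for el, n in zip(_ELEMENTS, self.elements) if n}
        return _pt_mass.calculate_mass(composition=_pt_mass.Composition(comp))

    @classmethod
    def from_formula(cls, name: str, formula: str) -> "Modification":
        comp = _pt_mass.Composition(formula=formula)
        return cls(name, tuple(int(comp.get(el, 0)) for el in _ELEMENTS))


CARBAMIDOMETHYL = Modification.from_formula("Carbamidomethyl", "C2H3NO")


@dataclass
class PeptideSequence:
    """A peptide with one glycosylation site.

    ``modifications`` maps 0-based residue positions to :class:`Modification`;
    ``glycosite`` is the 0-based index of the glycosylated residue.
    """

    sequence: str
    glycosite: int
    modifications: dict[int, Modification] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown amino-acid code(s): {sorted(bad)}")
        if not 0 <= self.glycosite < len(self.sequence):
            raise ValueError("glycosite outside the sequence")
        for pos in self.modifications:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"modification position {pos} out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_mass(self, i: int) -> float:
        m = residue_masses[self.sequence[i]]
        if i in self.modifications:
            m += self.modifications[i].mass
        return m

    def neutral_mass(self) -> float:
        """Monoisotopic mass of the unglycosylated peptide."""
        return sum(self.residue_mass(i) for i in range(len(self))) + WATER_MASS

    def prefix_mass(self, n: int) -> float:
        """Sum of the first ``n`` residue masses (b-ion side, no termini)."""
        return sum(self.residue_mass(i) for i in range(n))

    def suffix_mass(self, n: int) -> float:
        """Sum of the last ``n`` residue masses (y-ion side, no termini)."""
        L = len(self)
        return sum(self.residue_mass(i) for i in range(L - n, L))

    def modified_string(self) -> str:
        out = []
        for i, aa in enumerate(self.sequence):
            out.append(aa)
            if i in self.modifications:
                out.append(f"[{self.modifications[i].name}]")
        return "".join(out)
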