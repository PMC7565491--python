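"""Monoisotopic mass arithmetic for peptides, modifications and disulfides.

Every downstream computation (peak pairing, digest-fragment matching, b/y-ion
ladders) reduces to sums over this module's residue-mass table, so the table is
hard-coded to five decimals and cross-checked against pyteomics in the test
suite.  Average masses are deliberately unsupported: MALDI reflector-mode data
is monoisotopic.

Conventions
-----------
* A *residue* mass is the mass of the amino acid minus water (the in-chain
  mass); the neutral peptide mass M adds one water per chain.
* ``[M+H]+`` adds one proton (1.00728 Da), the singly-protonated MALDI species.
* One disulfide bond removes two hydrogens from the reduced chain; reduction
  adds them back, and carbamidomethylation adds +57.02146 Da per free thiol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

__all__ = [
    "AMINO_ACIDS",
    "MONOISOTOPIC",
    "WATER",
    "PROTON",
    "HYDROGEN",
    "CAM_DELTA",
    "AlphabetError",
    "Modification",
    "CARBAMIDOMETHYL",
    "Peptide",
    "PeptideMass",
    "residue_mass",
    "peptide_mass",
    "reduction_alkylation_shift",
    "composition",
    "carbamidomethylated",
]

#: Monoisotopic in-chain residue masses (Da), standard IUPAC/Unimod values.
MONOISOTOPIC: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

AMINO_ACIDS = frozenset(MONOISOTOPIC)

WATER = 18.010565
PROTON = 1.007276
HYDROGEN = 1.007825
#: Carbamidomethylation of a free cysteine thiol by iodoacetamide.
CAM_DELTA = 57.02146


class AlphabetError(ValueError):
    """A sequence contains a character outside the 20-residue alphabet."""


def _validate(sequence: str) -> None:
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise AlphabetError(
            f"non-standard residue(s) {sorted(bad)} in sequence {sequence!r}"
        )


@dataclass(frozen=True)
class Modification:
    """A fixed-mass modification targeting one residue code or terminus."""

    name: str
    delta_mass: float
    target: str  # residue code, or "nterm"/"cterm"


CARBAMIDOMETHYL = Modification("carbamidomethyl", CAM_DELTA, "C")


@dataclass
class Peptide:
    """A linear peptide with per-position modifications and a disulfide count.

    Parameters
    ----------
    sequence:
        One-letter residue string.
    modifications:
        ``(position, Modification)`` pairs, 0-based positions.
    n_disulfides:
        Number of intramolecular disulfide bonds.  ``None`` defaults to
        ``n_Cys // 2``, the fully-oxidized state assumed for native CRPs;
        pass 0 explicitly for free-thiol peptides.
    """

    sequence: str
    modifications: list[tuple[int, Modification]] = field(default_factory=list)
    n_disulfides: int | None = None

    def __post_init__(self) -> None:
        _validate(self.sequence)
        n_cys = self.sequence.count("C")
        if self.n_disulfides is None:
            self.n_disulfides = n_cys // 2
        if self.n_disulfides < 0 or self.n_disulfides > n_cys // 2:
            raise ValueError(
                f"n_disulfides={self.n_disulfides} impossible for {n_cys} Cys"
            )
        for pos, mod in self.modifications:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"modification position {pos} outside sequence")
            if mod.target in AMINO_ACIDS and self.sequence[pos] != mod.target:
                raise ValueError(
                    f"{mod.name} targets {mod.target}, found "
                    f"{self.sequence[pos]} at position {pos}"
                )


class PeptideMass(NamedTuple):
    M: float
    MH: float


def residue_mass(code: str) -> float:
    """Monoisotopic in-chain mass of one residue (not the free amino acid)."""
    try:
        return MONOISOTOPIC[code]
    except KeyError:
        raise AlphabetError(f"unknown residue code {code!r}") from None


def peptide_mass(p: Peptide | str) -> PeptideMass:
    """Neutral monoisotopic mass M and singly-protonated [M+H]+ of a peptide.

    M = sum of residue masses + water + modification deltas - 2H per disulfide.
    A plain string is treated as an unmodified, disulfide-free peptide.
    """
    if isinstance(p, str):
        p = Peptide(p, n_disulfides=0)
    m = sum(MONOISOTOPIC[c] for c in p.sequence) + WATER
    m += sum(mod.delta_mass for _, mod in p.modifications)
    m -= p.n_disulfides * 2 * HYDROGEN
    return PeptideMass(M=m, MH=m + PROTON)


def reduction_alkylation_shift(n_cys: int, n_disulfides: int) -> float:
    """Mass shift from reducing ``n_disulfides`` bonds and alkylating all Cys.

    Reduction restores two hydrogens per disulfide; iodoacetamide then adds a
    carbamidomethyl group to every cysteine thiol.  For a fully-oxidized
    six-Cys / three-disulfide peptide this is the diagnostic ~348 Da shift.
    """
    if n_cys < 0 or n_disulfides < 0:
        raise ValueError("counts must be non-negative")
    if n_cys < 2 * n_disulfides:
        raise ValueError(f"{n_disulfides} disulfides need >= {2*n_disulfides} Cys")
    return n_disulfides * 2 * HYDROGEN + n_cys * CAM_DELTA


def composition(sequence: str) -> dict[str, int]:
    """Residue counts over the full 20-letter alphabet (zeros included)."""
    _validate(sequence)
    counts = {aa: 0 for aa in sorted(MONOISOTOPIC)}
    for c in sequence:
        counts[c] += 1
    return counts


def carbamidomethylated(sequence: str) -> Peptide:
    """The reduced, fully carbamidomethylated form of a sequence.

    All disulfides opened (count 0) and one CAM on every cysteine — the species
    actually observed after the reduction/alkylation step.
    """
    mods = [(i, CARBAMIDOMETHYL) for i, c in enumerate(sequence) if c == "C"]
    return Peptide(sequence, modifications=mods, n_disulfides=0)
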