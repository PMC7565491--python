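"""In-silico complete and partial proteolysis.

Cleavage rules are deliberately simple site sets.  Two conventions differ from
textbook defaults and are documented choices: the trypsin Lys/Arg-Pro block is
OFF by default (observed CRP fragments require cleavage at K-P junctions), and
chymotrypsin uses the high-specificity set plus leucine {F, Y, W, L} without a
proline block.  Fragment masses are computed on the carbamidomethylated
sequence, the species that is actually digested after reduction/alkylation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import carbamidomethylated, peptide_mass

__all__ = [
    "Enzyme",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "GLU_C",
    "get_enzyme",
    "DigestFragment",
    "cleavage_sites",
    "digest_complete",
    "digest_partial",
]

#: MALDI low-mass acquisition bound; fragments below are retained but flagged.
REPORTING_MH_THRESHOLD = 500.0


@dataclass(frozen=True)
class Enzyme:
    name: str
    cleave_after: frozenset[str]
    block_before_proline: bool = False


TRYPSIN = Enzyme("trypsin", frozenset("KR"))
CHYMOTRYPSIN = Enzyme("chymotrypsin", frozenset("FYWL"))
GLU_C = Enzyme("glu-c", frozenset("E"))

_ENZYMES = {e.name: e for e in (TRYPSIN, CHYMOTRYPSIN, GLU_C)}


def get_enzyme(name: str, proline_block: bool = False) -> Enzyme:
    try:
        base = _ENZYMES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown enzyme {name!r}; choose from {sorted(_ENZYMES)}") from None
    return Enzyme(base.name, base.cleave_after, proline_block)


@dataclass
class DigestFragment:
    """A parent subsequence bounded by cleavage sites or termini.

    Coordinates are 0-based half-open on the parent; ``theoretical_mh`` is the
    [M+H]+ of the carbamidomethylated fragment.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    theoretical_mh: float

    @property
    def below_reporting_threshold(self) -> bool:
        return self.theoretical_mh < REPORTING_MH_THRESHOLD


def cleavage_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based indices i such that the enzyme cuts after ``sequence[i]``.

    The last residue is never a site (there is nothing to cut off).
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] not in enzyme.cleave_after:
            continue
        if enzyme.block_before_proline and sequence[i + 1] == "P":
            continue
        sites.append(i)
    return sites


def _fragment(sequence: str, parent_id: str, start: int, end: int, missed: int,
              cam: bool) -> DigestFragment:
    sub = sequence[start:end]
    pep = carbamidomethylated(sub) if cam else sub
    return DigestFragment(parent_id, start, end, sub, missed, peptide_mass(pep).MH)


def digest_complete(
    sequence: str,
    enzyme: Enzyme,
    max_missed: int = 0,
    parent_id: str = "peptide",
    cam: bool = True,
) -> list[DigestFragment]:
    """All fragments bounded by sites/termini with at most ``max_missed``
    internal (missed) cleavage sites.  The 0-missed fragments tile the parent.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = cleavage_sites(sequence, enzyme)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            missed = j - i - 1
            out.append(_fragment(sequence, parent_id, bounds[i], bounds[j], missed, cam))
    return out


def digest_partial(
    sequence: str, enzyme: Enzyme, parent_id: str = "peptide", cam: bool = True
) -> list[DigestFragment]:
    """Every site/terminus-bounded substring: a partial digest leaves any
    subset of sites uncut, so any number of missed cleavages is allowed.
    """
    n_sites = len(cleavage_sites(sequence, enzyme))
    return digest_complete(sequence, enzyme, max_missed=n_sites,
                           parent_id=parent_id, cam=cam)
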