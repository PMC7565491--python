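"""Cysteine-loop annotation, P1 classification and sequence comparison.

Knottin-type cysteine-rich peptides are described by their Cys spacing
(prefix, five inter-Cys loops, suffix for the six-Cys family) and classified
functionally by the residue at the putative P1 position: squash trypsin
inhibitors carry Arg or Lys there, while the antimicrobial-like branch does
not.  P1 is taken as the second residue of loop 1, the offset shared by the
characterized squash inhibitors (MCoTI/EETI) and the citcol family.

Pairwise comparison follows the EMBOSS Needle protocol: global alignment with
affine gaps (BLOSUM62, open 10, extend 0.5, end gaps free), identity and
similarity expressed as percentages of the alignment length, similarity
counting residue pairs with a positive substitution score.  Trees are built
by neighbor joining on 1 - identity-fraction distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .chem import AMINO_ACIDS, AlphabetError

__all__ = [
    "CysPattern",
    "CrpClassification",
    "Connectivity",
    "AlignmentResult",
    "PatternError",
    "ClassificationError",
    "TopologyError",
    "loop_pattern",
    "classify_p1",
    "putative_connectivity",
    "needle_align",
    "frequency_matrix",
    "nj_tree",
    "ANTIMICROBIAL_LIKE",
    "TRYPSIN_INHIBITOR_LIKE",
]

ANTIMICROBIAL_LIKE = "antimicrobial_like"
TRYPSIN_INHIBITOR_LIKE = "trypsin_inhibitor_like"

#: Residues conferring trypsin inhibition when found at P1.
BASIC_P1 = frozenset("RK")


class PatternError(ValueError):
    """Sequence has too few cysteines for a loop decomposition."""


class ClassificationError(ValueError):
    """Loop 1 is too short to contain a P1 residue."""


class TopologyError(ValueError):
    """Connectivity is only defined for the six-cysteine ICK topology."""


@dataclass(frozen=True)
class CysPattern:
    """Decomposition of a sequence into prefix, inter-Cys loops and suffix."""

    prefix_len: int
    loops: tuple[int, ...]
    suffix_len: int
    cys_positions: tuple[int, ...]  # 0-based

    @property
    def n_cys(self) -> int:
        return len(self.loops) + 1

    def reconstruct_length(self) -> int:
        return self.prefix_len + self.n_cys + sum(self.loops) + self.suffix_len


@dataclass(frozen=True)
class CrpClassification:
    p1_residue: str
    label: str
    basis: str


@dataclass(frozen=True)
class Connectivity:
    """Disulfide pairing as Cys ordinals (1-based) with residue indices."""

    pairs: tuple[tuple[int, int], ...]
    residue_pairs: tuple[tuple[int, int], ...]  # 1-based residue positions


def loop_pattern(sequence: str) -> CysPattern:
    """Prefix / inter-Cys loop lengths / suffix of a Cys-containing sequence."""
    positions = tuple(i for i, c in enumerate(sequence) if c == "C")
    if len(positions) < 2:
        raise PatternError(f"need >=2 Cys, found {len(positions)}")
    loops = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)
    )
    return CysPattern(
        prefix_len=positions[0],
        loops=loops,
        suffix_len=len(sequence) - positions[-1] - 1,
        cys_positions=positions,
    )


def classify_p1(sequence: str, p1_offset: int = 1) -> CrpClassification:
    """Functional label from the P1 residue (position ``p1_offset`` of loop 1).

    Arg/Lys at P1 marks a trypsin-inhibitor-like peptide; anything else
    (Phe in the citcol family) is labelled antimicrobial-like.
    """
    pattern = loop_pattern(sequence)
    c1, c2 = pattern.cys_positions[0], pattern.cys_positions[1]
    loop1 = sequence[c1 + 1 : c2]
    if len(loop1) <= p1_offset:
        raise ClassificationError(
            f"loop 1 ({loop1!r}) too short for P1 at offset {p1_offset}"
        )
    p1 = loop1[p1_offset]
    label = TRYPSIN_INHIBITOR_LIKE if p1 in BASIC_P1 else ANTIMICROBIAL_LIKE
    return CrpClassification(
        p1_residue=p1,
        label=label,
        basis=f"P1 = loop-1 residue {p1_offset + 1} = {p1}; basic P1 => trypsin inhibitor",
    )


def putative_connectivity(pattern: CysPattern) -> Connectivity:
    """ICK connectivity C1-C4, C2-C5, C3-C6 for a six-cysteine pattern."""
    if pattern.n_cys != 6:
        raise TopologyError(f"ICK connectivity needs 6 Cys, got {pattern.n_cys}")
    ordinal_pairs = ((1, 4), (2, 5), (3, 6))
    residue_pairs = tuple(
        (pattern.cys_positions[a - 1] + 1, pattern.cys_positions[b - 1] + 1)
        for a, b in ordinal_pairs
    )
    return Connectivity(ordinal_pairs, residue_pairs)


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps_pct: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float,
             end_gaps_penalized: bool, local: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "local" if local else "global"
    # EMBOSS convention: a gap of length L costs open + L * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if not local and not end_gaps_penalized:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise AlphabetError(
            f"residue(s) {sorted(bad)} not covered by the substitution matrix"
        )


def needle_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_penalized: bool = False,
) -> AlignmentResult:
    """EMBOSS-Needle-style optimal global alignment of two sequences.

    The result is symmetric in its arguments: the pair is aligned in a
    canonical order internally, so ties in the traceback cannot make
    ``needle_align(a, b)`` and ``needle_align(b, a)`` disagree.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(a)
    _check_alphabet(b)
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    aligner = _aligner(matrix, gap_open, gap_extend, end_gaps_penalized, False)
    aln = aligner.align(x, y)[0]
    row_x, row_y = str(aln[0]), str(aln[1])
    if swapped:
        row_x, row_y = row_y, row_x
    subs = aligner.substitution_matrix
    length = len(row_x)
    identities = sum(p == q and p != "-" for p, q in zip(row_x, row_y))
    similars = sum(
        p != "-" and q != "-" and subs[p, q] > 0 for p, q in zip(row_x, row_y)
    )
    gaps = sum(p == "-" or q == "-" for p, q in zip(row_x, row_y))
    return AlignmentResult(
        aligned_a=row_x,
        aligned_b=row_y,
        score=float(aln.score),
        identity_pct=100.0 * identities / length,
        similarity_pct=100.0 * similars / length,
        gaps_pct=100.0 * gaps / length,
    )


def frequency_matrix(aligned_sequences: list[str]):
    """Per-column residue/gap frequencies of an alignment (columns sum to 1)."""
    import pandas as pd

    if not aligned_sequences:
        raise ValueError("no sequences")
    length = len(aligned_sequences[0])
    if any(len(s) != length for s in aligned_sequences):
        raise ValueError("aligned sequences must have equal gapped lengths")
    residues = sorted(AMINO_ACIDS) + ["-"]
    counts = np.zeros((length, len(residues)))
    index = {r: i for i, r in enumerate(residues)}
    for seq in aligned_sequences:
        for pos, ch in enumerate(seq):
            counts[pos, index[ch]] += 1
    freq = counts / len(aligned_sequences)
    return pd.DataFrame(freq, columns=residues)


def nj_tree(sequences: dict[str, str]) -> TreeNode:
    """Neighbor-joining tree on pairwise 1 - identity-fraction distances.

    A documented stand-in for a maximum-likelihood tree, adequate for
    recovering the antimicrobial vs. trypsin-inhibitor bipartition at desk
    scale.  Negative NJ branch lengths are clamped to zero.
    """
    names = list(sequences)
    if len(names) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = needle_align(sequences[names[i]], sequences[names[j]])
            d = 1.0 - res.identity_pct / 100.0
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids=names))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree
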