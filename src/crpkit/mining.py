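"""Six-frame translation and motif/alignment mining of nucleotide data.

A local stand-in for a tblastn-style search on user-supplied FASTA: translate
all six reading frames, scan for candidate segments matching the conserved
cysteine-spacing template, then rank candidates by Smith-Waterman score
against the query peptides with an ungapped Karlin-Altschul E-value estimate.

The E-values use the published ungapped BLOSUM62 parameters (lambda ~= 0.318,
K ~= 0.13) scaled by query and database lengths — adequate for thresholding a
local search, not a reproduction of NCBI BLAST statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Seq import Seq

from .annotation import CysPattern, _aligner, loop_pattern

__all__ = [
    "KARLIN_ALTSCHUL_LAMBDA",
    "KARLIN_ALTSCHUL_K",
    "DEFAULT_TEMPLATE",
    "MotifTemplate",
    "FrameTranslation",
    "MiningHit",
    "six_frame_translate",
    "scan_motif",
    "rank_hits",
    "mine",
]

KARLIN_ALTSCHUL_LAMBDA = 0.318
KARLIN_ALTSCHUL_K = 0.13

_NT_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class MotifTemplate:
    """(min, max) bounds on the prefix, the five loops, and the suffix.

    The default captures both branches of the six-Cys squash CRP family:
    loops 1-4 are fixed at 6/5/3/1 and loop 5, the branch-discriminating
    loop, spans 5-12 residues.
    """

    prefix: tuple[int, int] = (0, 5)
    loops: tuple[tuple[int, int], ...] = ((6, 6), (5, 5), (3, 3), (1, 1), (5, 12))
    suffix: tuple[int, int] = (0, 3)

    def __post_init__(self) -> None:
        for lo, hi in (self.prefix, *self.loops, self.suffix):
            if lo < 0 or hi < lo:
                raise ValueError(f"inconsistent template bound ({lo}, {hi})")


DEFAULT_TEMPLATE = MotifTemplate()


@dataclass(frozen=True)
class FrameTranslation:
    source_id: str
    frame: int  # +1..+3 forward, -1..-3 on the reverse complement
    offset: int  # nt skipped at the (strand-oriented) 5' end
    protein: str  # stops retained as '*'


@dataclass
class MiningHit:
    source_id: str
    frame: int
    start: int  # 0-based half-open protein coordinates within the frame
    end: int
    segment: str
    sw_score: float
    evalue: float
    query_id: str
    cys_pattern: CysPattern


def six_frame_translate(nt_sequence: str, source_id: str = "seq") -> list[FrameTranslation]:
    """Translate all six reading frames; N codons yield X, stops stay as '*'."""
    nt = nt_sequence.upper()
    bad = set(nt) - _NT_ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN character(s) {sorted(bad)} in nucleotide input")
    out = []
    rc = str(Seq(nt).reverse_complement())
    for strand, seq in ((1, nt), (-1, rc)):
        for off in range(3):
            trimmed = seq[off : off + 3 * ((len(seq) - off) // 3)]
            protein = str(Seq(trimmed).translate()) if trimmed else ""
            out.append(
                FrameTranslation(source_id, strand * (off + 1), off, protein)
            )
    return out


def scan_motif(
    protein: str, template: MotifTemplate = DEFAULT_TEMPLATE
) -> list[tuple[int, int, str]]:
    """Candidate (start, end, segment) windows matching the Cys template.

    A window is anchored on six consecutive cysteines whose spacings satisfy
    the loop bounds, extended by up to the prefix/suffix bounds without
    crossing a stop codon or a further cysteine, so each segment contains
    exactly six Cys and no stop.  Overlapping candidates are all reported.
    """
    cys = [i for i, c in enumerate(protein) if c == "C"]
    out = []
    for w in range(len(cys) - 5):
        group = cys[w : w + 6]
        gaps = [group[k + 1] - group[k] - 1 for k in range(5)]
        if any(not lo <= g <= hi for g, (lo, hi) in zip(gaps, template.loops)):
            continue
        if "*" in protein[group[0] : group[5] + 1]:
            continue
        # extend the prefix/suffix, stopping at '*', 'C' or the bounds
        start = group[0]
        for _ in range(template.prefix[1]):
            if start == 0 or protein[start - 1] in "*C":
                break
            start -= 1
        end = group[5] + 1
        for _ in range(template.suffix[1]):
            if end == len(protein) or protein[end] in "*C":
                break
            end += 1
        if group[0] - start < template.prefix[0]:
            continue
        if end - (group[5] + 1) < template.suffix[0]:
            continue
        out.append((start, end, protein[start:end]))
    return out


def _local_score(query: str, candidate: str) -> float:
    # ungapped local alignment: the best-scoring diagonal segment.  The
    # Karlin-Altschul parameters below are the ungapped BLOSUM62 ones, and
    # pairing them with gapped scores would overstate significance.
    aligner = _aligner("BLOSUM62", 1e6, 1e6, True, True)
    return float(aligner.score(query, candidate))


def karlin_altschul_evalue(
    score: float, query_len: int, database_len: int, lam: float | None = None
) -> float:
    """Expected chance hits of at least ``score``: E = K * m * n * exp(-lambda*S)."""
    if lam is None:
        lam = KARLIN_ALTSCHUL_LAMBDA
    return KARLIN_ALTSCHUL_K * query_len * database_len * math.exp(-lam * score)


@lru_cache(maxsize=64)
def composition_lambda(query: str) -> float:
    """Karlin-Altschul lambda for a null of the query's own composition.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with p taken from the query's
    residue frequencies.  Cysteine-rich queries score highly against any
    similarly biased segment, and the standard-background lambda (0.318)
    badly overstates the significance of such matches — composition-matched
    decoys (shuffles of the query) are only a fair null under this corrected
    parameter.
    """
    import numpy as np
    from Bio.Align import substitution_matrices
    from collections import Counter

    counts = Counter(query)
    letters = sorted(counts)
    p = np.array([counts[a] / len(query) for a in letters])
    subs = substitution_matrices.load("BLOSUM62")
    scores = np.array([[subs[a, b] for b in letters] for a in letters])
    lo, hi = 1e-4, 2.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if float(p @ np.exp(mid * scores) @ p) > 1.0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


def rank_hits(
    queries: dict[str, str],
    candidates: list[tuple[str, int, int, int, str]],
    evalue_cutoff: float = 0.001,
) -> list[MiningHit]:
    """Score candidate segments against the queries and filter by E-value.

    ``candidates`` holds (source_id, frame, start, end, segment) tuples; each
    is scored with ungapped local alignment (BLOSUM62) against every query,
    keeping the best.  E-values scale with the best query's length and the
    total candidate residue count, and hits are returned sorted by ascending
    E-value (ties by descending score).
    """
    if not queries:
        raise ValueError("need at least one query")
    if not candidates:
        return []
    database_len = sum(len(seg) for *_, seg in candidates)
    hits = []
    for source_id, frame, start, end, segment in candidates:
        best_score, best_query = max(
            ((_local_score(q, segment), name) for name, q in queries.items()),
            key=lambda t: t[0],
        )
        ev = karlin_altschul_evalue(
            best_score,
            len(queries[best_query]),
            database_len,
            lam=composition_lambda(queries[best_query]),
        )
        if ev <= evalue_cutoff:
            hits.append(
                MiningHit(
                    source_id, frame, start, end, segment,
                    best_score, ev, best_query, loop_pattern(segment),
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.sw_score))
    return hits


def hit_nt_span(hit: MiningHit, source_len: int) -> tuple[int, int]:
    """Map a hit's protein span back to 0-based half-open source coordinates
    (forward-strand orientation, for comparison with annotation/truth)."""
    off = abs(hit.frame) - 1
    start, end = off + 3 * hit.start, off + 3 * hit.end
    if hit.frame > 0:
        return start, end
    return source_len - end, source_len - start


def mine(
    nt_records: dict[str, str],
    queries: dict[str, str],
    template: MotifTemplate = DEFAULT_TEMPLATE,
    evalue_cutoff: float = 0.001,
) -> list[MiningHit]:
    """Full pipeline: six-frame translate, motif-scan, rank against queries."""
    candidates = []
    for source_id, nt in nt_records.items():
        for ft in six_frame_translate(nt, source_id):
            for start, end, segment in scan_motif(ft.protein, template):
                candidates.append((source_id, ft.frame, start, end, segment))
    return rank_hits(queries, candidates, evalue_cutoff)
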