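"""De novo sequencing: b/y ion ladders, spectrum interpretation, fragment
assembly and isobaric-residue resolution.

The interpreter walks a spectrum graph: peaks become nodes in b-ion space
(y ions are mirrored through the precursor via the complementarity identity
``b_i + y_{n-i} = MH + proton``), and directed edges connect nodes whose mass
difference matches a residue.  Cys is treated as the carbamidomethylated
160.031 Da pseudo-residue, since spectra are acquired after
reduction/alkylation.  Leucine/isoleucine are indistinguishable by mass and
are reported as the ambiguity code ``J``; lysine/glutamine differ by only
0.0364 Da and stay ambiguous at any realistic MALDI tolerance — both are
resolved downstream from enzyme-specific cleavage evidence.

Where a ladder junction is missing from both ion series, the interpreter
falls back to a two-residue composite gap (emitting every residue order),
so sequence candidates survive isolated ion dropout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .chem import (
    CAM_DELTA,
    MONOISOTOPIC,
    PROTON,
    WATER,
    Peptide,
    carbamidomethylated,
    peptide_mass,
)
from .digestion import Enzyme, digest_complete
from .peaks import PeakList

__all__ = [
    "IonSeries",
    "MsMsSpectrum",
    "SequenceCandidate",
    "Assembly",
    "AssemblyConflictError",
    "MassMismatchError",
    "by_ion_series",
    "interpret_spectrum",
    "assemble_fragments",
    "resolve_isobaric",
    "sequence_from_spectra",
]

#: K and Q differ by this much; below it they are mass-resolvable.
KQ_GAP = MONOISOTOPIC["K"] - MONOISOTOPIC["Q"]

# Distinct single-residue ladder gaps.  L/I collapse onto 'J'; Cys appears
# only in its carbamidomethylated form.
_GAP_MASSES: dict[str, float] = {
    aa: m for aa, m in MONOISOTOPIC.items() if aa not in ("I", "L", "C")
}
_GAP_MASSES["J"] = MONOISOTOPIC["L"]
_GAP_MASSES["C"] = MONOISOTOPIC["C"] + CAM_DELTA  # 160.03065

_MIN_GAP = min(_GAP_MASSES.values())
_MAX_GAP = max(_GAP_MASSES.values())

#: All unordered two-residue composite gaps, used when no single residue fits.
_PAIR_MASSES: list[tuple[float, str, str]] = sorted(
    (m1 + m2, a1, a2)
    for (a1, m1), (a2, m2) in itertools.combinations_with_replacement(
        sorted(_GAP_MASSES.items()), 2
    )
)


class AssemblyConflictError(ValueError):
    """No mutually consistent placement of the fragments exists."""


class MassMismatchError(ValueError):
    """Every consistent assembly misses the intact precursor mass."""


@dataclass
class IonSeries:
    """Singly-charged theoretical b (b1..b(n-1)) and y (y1..y(n-1)) series."""

    peptide: Peptide
    b: np.ndarray
    y: np.ndarray


def by_ion_series(p: Peptide | str) -> IonSeries:
    """Theoretical singly-protonated b- and y-ion ladders of a peptide."""
    if isinstance(p, str):
        p = Peptide(p, n_disulfides=0)
    n = len(p.sequence)
    if n < 2:
        raise ValueError("ion series need at least 2 residues")
    per_res = np.array([MONOISOTOPIC[c] for c in p.sequence])
    for pos, mod in p.modifications:
        per_res[pos] += mod.delta_mass
    cum = np.cumsum(per_res)
    b = cum[:-1] + PROTON
    y = (cum[-1] - cum[:-1])[::-1] + WATER + PROTON
    return IonSeries(p, b, y)


@dataclass
class MsMsSpectrum:
    """A fragment spectrum with a singly-protonated precursor mass."""

    precursor_mh: float
    peaks: PeakList

    def __post_init__(self) -> None:
        if isinstance(self.peaks, (list, tuple)):
            self.peaks = PeakList.from_pairs(self.peaks, label="msms")


@dataclass
class SequenceCandidate:
    """One spectrum interpretation.

    ``sequence`` uses ``J`` for Leu/Ile; ambiguous Lys/Gln positions are
    written ``K`` and listed in ``ambiguous_kq`` (0-based).  ``supported``
    marks which of the n-1 ladder junctions had an observed ion.
    """

    sequence: str
    ambiguous_kq: frozenset[int] = frozenset()
    ion_coverage: float = 1.0
    supported: tuple[bool, ...] = ()
    intensity: float = 0.0
    supporting_peaks: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


def _theoretical_mh_cam(sequence: str) -> float:
    concrete = sequence.replace("J", "L")
    return peptide_mass(carbamidomethylated(concrete)).MH


def _match_single(delta: float, tol: float) -> list[tuple[str, bool]]:
    """Residue labels matching a ladder gap; (label, kq_ambiguous)."""
    out = []
    k_hit = abs(delta - _GAP_MASSES["K"]) <= tol
    q_hit = abs(delta - _GAP_MASSES["Q"]) <= tol
    if k_hit and q_hit:
        out.append(("K", True))
    elif k_hit:
        out.append(("K", False))
    elif q_hit:
        out.append(("Q", False))
    for aa, m in _GAP_MASSES.items():
        if aa in ("K", "Q"):
            continue
        if abs(delta - m) <= tol:
            out.append((aa, False))
    return out


def _match_pair(delta: float, tol: float) -> list[tuple[str, str]]:
    out = []
    for m, a1, a2 in _PAIR_MASSES:
        if m < delta - tol:
            continue
        if m > delta + tol:
            break
        out.append((a1, a2))
        if a1 != a2:
            out.append((a2, a1))
    return out


def interpret_spectrum(
    s: MsMsSpectrum,
    tol: float = 0.05,
    max_candidates: int = 20,
    _max_expansions: int = 20000,
) -> list[SequenceCandidate]:
    """Candidate sequences explaining a spectrum's b/y ladders.

    Builds the mirrored spectrum graph and enumerates source-to-sink residue
    chains, ranked by ion coverage, then summed supporting intensity, then
    lexicographically.  Returns at most ``max_candidates``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(s.peaks) == 0:
        return []
    source = PROTON
    sink = s.precursor_mh - WATER
    raw: list[tuple[float, float]] = []
    for mz, inten in zip(s.peaks.mz, s.peaks.intensity):
        raw.append((float(mz), float(inten)))
        raw.append((s.precursor_mh + PROTON - float(mz), float(inten)))  # y mirror
    lo, hi = source + _MIN_GAP - tol, sink - _MIN_GAP + tol
    raw = [(m, i) for m, i in raw if lo <= m <= hi]
    raw.sort()
    # cluster coincident b/mirrored-y nodes; a junction seen in both series
    # collapses to one node supported by two peaks, which outranks the
    # spurious single-peak nodes that mirroring a b-ion creates
    nodes: list[list[float]] = []  # [mass, intensity, n_peaks]
    for m, i in raw:
        if nodes and m - nodes[-1][0] <= tol * 0.5:
            tot = nodes[-1][1] + i
            nodes[-1][0] = (nodes[-1][0] * nodes[-1][1] + m * i) / tot if tot else m
            nodes[-1][1] = tot
            nodes[-1][2] += 1
        else:
            nodes.append([m, i, 1])
    masses = [source] + [n[0] for n in nodes] + [sink]
    intens = [0.0] + [n[1] for n in nodes] + [0.0]
    npeaks = [0] + [int(n[2]) for n in nodes] + [0]
    n_nodes = len(masses)

    # adjacency with single-residue labels, composite only as fallback
    edges: list[list[tuple[int, str, bool]]] = [[] for _ in range(n_nodes)]
    for i in range(n_nodes - 1):
        for j in range(i + 1, n_nodes):
            d = masses[j] - masses[i]
            if d < _MIN_GAP - tol:
                continue
            if d > 2 * _MAX_GAP + tol:
                break
            for lab, amb in _match_single(d, tol):
                edges[i].append((j, lab, amb))
            if d > 2 * _MIN_GAP - tol:
                # composite two-residue gaps cover a junction lost from both
                # ion series; several pair sums collide with single residues
                # (G+G=N, G+V~R, A+D~W ...), so they are emitted alongside
                # any single match and rank below it on ion coverage
                for a1, a2 in _match_pair(d, tol):
                    edges[i].append((j, a1 + a2, False))

    results: dict[tuple[str, frozenset], SequenceCandidate] = {}
    budget = [_max_expansions]
    # antisymmetry: two distinct nodes whose masses sum to MH + proton are the
    # b- and y-space images of the same ion; a valid ladder never uses both
    comp_sum = s.precursor_mh + PROTON

    def dfs(node: int, seq: list[str], amb: list[int], support: list[bool],
            inten_sum: float, peaks_sum: int, used: list[float], comp_left: int):
        if budget[0] <= 0:
            return
        budget[0] -= 1
        if node == n_nodes - 1:
            sequence = "".join(seq)
            if len(sequence) == 0:
                return
            kq = frozenset(amb)
            supported = tuple(support[:-1])  # last entry is the sink, not a junction
            n_junc = len(sequence) - 1
            cov = (sum(supported) / n_junc) if n_junc else 1.0
            key = (sequence, kq)
            cand = SequenceCandidate(sequence, kq, cov, supported, inten_sum, peaks_sum)
            prev = results.get(key)
            if prev is None or (cand.ion_coverage, cand.supporting_peaks, cand.intensity) > (
                prev.ion_coverage,
                prev.supporting_peaks,
                prev.intensity,
            ):
                results[key] = cand
            return
        for j, lab, kq_amb in edges[node]:
            if len(lab) == 2 and comp_left <= 0:
                continue
            interior = 0 < j < n_nodes - 1
            if interior and any(abs(m + masses[j] - comp_sum) <= tol for m in used):
                continue
            base = sum(len(x) for x in seq)
            seq.append(lab)
            added = [base] if kq_amb else []
            if len(lab) == 2:
                # a composite gap fixes only the residue pair's total mass;
                # any K/Q it emits is as ambiguous as a single-residue gap
                added.extend(base + i for i, ch in enumerate(lab) if ch in "KQ")
                support.append(False)
            amb.extend(added)
            support.append(j < n_nodes - 1)
            if interior:
                used.append(masses[j])
            dfs(j, seq, amb, support, inten_sum + intens[j], peaks_sum + npeaks[j],
                used, comp_left - (len(lab) == 2))
            if interior:
                used.pop()
            support.pop()
            if len(lab) == 2:
                support.pop()
            if added:
                del amb[-len(added):]
            seq.pop()

    # iterative deepening over the composite-gap allowance: unconstrained
    # composite branching explodes the path space, yet most spectra need at
    # most one or two patched junctions
    for comp_allow in (1, 2, 3):
        results.clear()
        budget[0] = _max_expansions
        dfs(0, [], [], [], 0.0, 0, [], comp_allow)
        if results:
            break

    out = []
    for cand in results.values():
        theo = _theoretical_mh_cam(cand.sequence)
        if abs(theo - s.precursor_mh) > max(0.1, 3 * tol):
            continue
        out.append(cand)
    out.sort(
        key=lambda c: (-c.ion_coverage, -c.supporting_peaks, -c.intensity, c.sequence)
    )
    return out[:max_candidates]


# ---------------------------------------------------------------------------
# fragment assembly
# ---------------------------------------------------------------------------

# a consensus position: (letter, ambiguity) with ambiguity in {None,"LI","KQ"}
_Pos = tuple[str, str | None]


def _candidate_positions(c: SequenceCandidate | str) -> tuple[_Pos, ...]:
    if isinstance(c, str):
        return tuple(
            (ch if ch not in "IL" else ch, None) if ch != "J" else ("J", "LI")
            for ch in c
        )
    out = []
    for i, ch in enumerate(c.sequence):
        if ch == "J":
            out.append(("J", "LI"))
        elif i in c.ambiguous_kq:
            out.append(("K", "KQ"))
        else:
            out.append((ch, None))
    return tuple(out)


def _merge_pos(a: _Pos, b: _Pos) -> _Pos | None:
    if a == b:
        return a
    la, aa = a
    lb, ab = b
    if aa == "LI" and lb in ("L", "I") and ab is None:
        return b
    if ab == "LI" and la in ("L", "I") and aa is None:
        return a
    if aa == "KQ" and lb in ("K", "Q") and ab is None:
        return b
    if ab == "KQ" and la in ("K", "Q") and aa is None:
        return a
    return None


def _is_potential_site(pos: _Pos, enzyme: Enzyme) -> bool:
    letter, amb = pos
    if amb == "LI":
        return "L" in enzyme.cleave_after or "I" in enzyme.cleave_after
    if amb == "KQ":
        return "K" in enzyme.cleave_after or "Q" in enzyme.cleave_after
    return letter in enzyme.cleave_after


@dataclass
class Assembly:
    """A consistent layout of fragment candidates with its consensus."""

    placements: tuple[tuple[int, int], ...]  # (fragment index, offset)
    consensus: str  # J for unresolved Leu/Ile, K at unresolved Lys/Gln
    ambiguous_li: frozenset[int]
    ambiguous_kq: frozenset[int]
    ambiguous_order: bool
    consensus_mh: float  # native (disulfide-oxidized, unmodified) [M+H]+


def _native_mh(consensus: str) -> float:
    concrete = consensus.replace("J", "L")
    return peptide_mass(Peptide(concrete)).MH  # default n_disulfides = nCys//2


def assemble_fragments(
    candidates: list[tuple[SequenceCandidate | str, Enzyme]],
    intact_mh: float,
    tol: float = 0.7,
    _max_states: int = 50000,
) -> list[Assembly]:
    """All maximal-overlap orderings of fragments consistent with enzyme
    boundaries and the intact native mass.

    Every fragment must be placed; a placed fragment's N-terminus must either
    open the assembly or directly follow a (potential) cleavage residue of its
    own enzyme.  Overlapping fragments must agree at every shared position,
    with ``J`` and flagged ``K`` treated as L/I and K/Q wildcards.  Layouts
    whose consensus native [M+H]+ deviates from ``intact_mh`` by more than
    ``tol`` are rejected.  Multiple surviving layouts are all returned,
    flagged as order-ambiguous.
    """
    if not candidates:
        raise ValueError("no candidates to assemble")
    frags = [_candidate_positions(c) for c, _ in candidates]
    enzymes = [e for _, e in candidates]
    n = len(frags)

    def try_place(consensus: tuple[_Pos, ...], fi: int, offset: int):
        frag = frags[fi]
        merged = list(consensus)
        for k, p in enumerate(frag):
            at = offset + k
            if at < len(merged):
                m = _merge_pos(merged[at], p)
                if m is None:
                    return None
                merged[at] = m
            else:
                merged.append(p)
        if offset > 0 and not _is_potential_site(merged[offset - 1], enzymes[fi]):
            return None
        return tuple(merged)

    complete: dict[tuple, tuple] = {}
    seen: set = set()
    stack: list[tuple[frozenset, tuple[_Pos, ...], tuple]] = []
    for i in range(n):
        state = (frozenset([i]), frags[i], ((i, 0),))
        stack.append(state)
    states_used = 0
    while stack:
        placed, consensus, placements = stack.pop()
        key = (placed, consensus)
        if key in seen:
            continue
        seen.add(key)
        states_used += 1
        if states_used > _max_states:
            break
        if len(placed) == n:
            ckey = (consensus, frozenset(placements))
            complete.setdefault(ckey, placements)
            continue
        for fi in range(n):
            if fi in placed:
                continue
            for offset in range(len(consensus) + 1):
                # require overlap, or abutment at the current right edge
                if offset + len(frags[fi]) <= len(consensus) or offset <= len(consensus):
                    merged = try_place(consensus, fi, offset)
                    if merged is not None:
                        stack.append((placed | {fi}, merged, placements + ((fi, offset),)))

    if not complete:
        raise AssemblyConflictError("fragments cannot be placed consistently")

    assemblies = []
    best_miss = None
    for (consensus, _), placements in complete.items():
        letters = "".join(p[0] for p in consensus)
        mh = _native_mh(letters)
        miss = abs(mh - intact_mh)
        if best_miss is None or miss < best_miss:
            best_miss = miss
        if miss > tol:
            continue
        li = frozenset(i for i, p in enumerate(consensus) if p[1] == "LI")
        kq = frozenset(i for i, p in enumerate(consensus) if p[1] == "KQ")
        assemblies.append(
            Assembly(tuple(sorted(placements, key=lambda x: x[1])), letters, li, kq, False, mh)
        )
    if not assemblies:
        raise MassMismatchError(
            f"no assembly within {tol} Da of intact [M+H]+ {intact_mh} "
            f"(closest misses by {best_miss:.3f} Da)"
        )
    # dedupe identical consensus reached through different placement tuples
    uniq: dict[str, Assembly] = {}
    for a in assemblies:
        uniq.setdefault(a.consensus, a)
    assemblies = sorted(uniq.values(), key=lambda a: a.consensus)
    if len(assemblies) > 1:
        assemblies = [replace(a, ambiguous_order=True) for a in assemblies]
    return assemblies


# ---------------------------------------------------------------------------
# isobaric resolution
# ---------------------------------------------------------------------------


def _observed(mh: float, peaklist: PeakList, tol: float) -> bool:
    mz = peaklist.mz
    i = np.searchsorted(mz, mh)
    for j in (i - 1, i):
        if 0 <= j < mz.size and abs(mz[j] - mh) <= tol:
            return True
    return False


def _digest_score(seq: str, peaklists: list[tuple[Enzyme, PeakList]], tol: float) -> int:
    score = 0
    for enzyme, pl in peaklists:
        for frag in digest_complete(seq, enzyme, max_missed=0, cam=True):
            if _observed(frag.theoretical_mh, pl, tol):
                score += 1
            else:
                score -= 1
    return score


def _resolve_group(
    base_seq: list[str],
    positions: list[int],
    pair: tuple[str, str],  # (cleaving, non-cleaving): ("L","I") or ("K","Q")
    enzymes: list[tuple[Enzyme, PeakList]],
    tol: float,
    target_counts: tuple[int, int] | None,
    max_enumeration: int,
) -> dict[int, str]:
    """Assign one isobaric pair's flagged positions from digest evidence.

    Returns position -> letter for every position all top-scoring (and
    composition-consistent) assignments agree on.
    """
    cleave, keep = pair
    if 2 ** len(positions) <= max_enumeration:
        assignments = list(itertools.product(pair, repeat=len(positions)))
    else:  # greedy fallback: all-cleaving baseline plus single flips
        base = (cleave,) * len(positions)
        assignments = [base] + [
            base[:i] + (keep,) + base[i + 1 :] for i in range(len(positions))
        ]
    if target_counts is not None:
        fixed_cleave = sum(
            1 for i, ch in enumerate(base_seq) if ch == cleave and i not in positions
        )
        fixed_keep = sum(
            1 for i, ch in enumerate(base_seq) if ch == keep and i not in positions
        )
        want_cleave = target_counts[0] - fixed_cleave
        want_keep = target_counts[1] - fixed_keep
        filtered = [
            asg for asg in assignments
            if asg.count(cleave) == want_cleave and asg.count(keep) == want_keep
        ]
        if filtered:
            assignments = filtered

    scored: list[tuple[int, tuple[str, ...]]] = []
    for asg in assignments:
        seq = list(base_seq)
        for pos, letter in zip(positions, asg):
            seq[pos] = letter
        scored.append((_digest_score("".join(seq), enzymes, tol), asg))
    best = max(s for s, _ in scored)
    top = [asg for s, asg in scored if s == best]

    resolved: dict[int, str] = {}
    for idx, pos in enumerate(positions):
        letters = {asg[idx] for asg in top}
        if len(letters) > 1 and pos == len(base_seq) - 1:
            # terminal boundary convention: the C-terminus is always a
            # fragment boundary, attributed to the cleaving residue
            letters = {cleave}
        if len(letters) == 1:
            resolved[pos] = letters.pop()
    return resolved


def resolve_isobaric(
    a: Assembly,
    complete_digest_peaks: dict[Enzyme, PeakList],
    tol: float = 0.2,
    composition_counts: dict[str, int] | None = None,
    _max_enumeration: int = 4096,
) -> Assembly:
    """Resolve K/Q and L/I ambiguities from complete-digest evidence.

    Trypsin cleaves after Lys but not Gln, chymotrypsin after Leu but not
    Ile, so the complete-digest fragment set of the true sequence differs
    between the isobaric alternatives.  Assignments of the flagged positions
    are enumerated (the two pairs independently — K/Q only moves tryptic
    sites, L/I only chymotryptic ones); each predicted complete-digest
    fragment set is scored against the observed peak lists (+1 per predicted
    mass observed within ``tol``, -1 per predicted mass absent), and a
    position is fixed only if every top-scoring assignment agrees on it.
    An optional residue composition (from amino-acid analysis) further
    constrains the assignment sets.  Positions the evidence cannot decide
    stay flagged — except the C-terminal residue, which never bounds an
    internal cleavage site and is assigned by the terminal-boundary
    convention (the cleaving residue) when tied.  An empty evidence dict
    returns the assembly unchanged.
    """
    if not (a.ambiguous_li or a.ambiguous_kq) or not complete_digest_peaks:
        return a
    enzymes = list(complete_digest_peaks.items())

    # canonical working sequence: J -> L, flagged K/Q already written K
    base_seq = [("L" if ch == "J" else ch) for ch in a.consensus]
    new_seq = list(base_seq)
    li, kq = set(a.ambiguous_li), set(a.ambiguous_kq)
    for positions, pair in ((sorted(li), ("L", "I")), (sorted(kq), ("K", "Q"))):
        if not positions:
            continue
        relevant = [
            (e, pl) for e, pl in enzymes if set(pair) & set(e.cleave_after)
        ] or enzymes
        targets = None
        if composition_counts is not None:
            targets = (
                composition_counts.get(pair[0], 0),
                composition_counts.get(pair[1], 0),
            )
        resolved = _resolve_group(
            base_seq, positions, pair, relevant, tol, targets, _max_enumeration
        )
        for pos, letter in resolved.items():
            new_seq[pos] = letter
            li.discard(pos)
            kq.discard(pos)
    for pos in li:
        new_seq[pos] = "J"
    for pos in kq:
        new_seq[pos] = "K"
    letters_s = "".join(new_seq)
    return replace(
        a,
        consensus=letters_s,
        ambiguous_li=frozenset(li),
        ambiguous_kq=frozenset(kq),
        consensus_mh=_native_mh(letters_s),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _letters(positions: tuple[_Pos, ...]) -> str:
    return "".join(p[0] for p in positions)


def _best_merge(
    contig: tuple[_Pos, ...], frag: tuple[_Pos, ...], min_overlap: int
) -> tuple[tuple[_Pos, ...], int] | None:
    """Merge ``frag`` into ``contig`` at its maximal consistent overlap.

    Returns (merged contig, overlap used), or ``None`` when no placement
    reaches ``min_overlap`` or the maximal overlap is ambiguous (two
    placements of equal overlap yielding different consensi).
    """
    best: list[tuple[int, tuple[_Pos, ...]]] = []
    lo = -(len(frag) - min_overlap)
    hi = len(contig) - min_overlap
    for offset in range(lo, hi + 1):
        start = max(0, offset)
        end = min(len(contig), offset + len(frag))
        overlap = end - start
        if overlap < min_overlap:
            continue
        merged_mid = []
        ok = True
        for at in range(start, end):
            m = _merge_pos(contig[at], frag[at - offset])
            if m is None:
                ok = False
                break
            merged_mid.append(m)
        if not ok:
            continue
        left = frag[: -offset] if offset < 0 else contig[:start]
        right = (
            frag[len(contig) - offset :]
            if offset + len(frag) > len(contig)
            else contig[end:]
        )
        best.append((overlap, tuple(left) + tuple(merged_mid) + tuple(right)))
    if not best:
        return None
    best.sort(key=lambda t: -t[0])
    top = [m for ov, m in best if ov == best[0][0]]
    if len({m for m in top}) > 1:
        return None  # ambiguous placement; caller may retry later
    return top[0], best[0][0]


def _pooled_counts(letters: list[str] | str) -> dict[str, int]:
    """Residue counts with the isobaric pairs pooled (J = L+I, K = K+Q)."""
    from collections import Counter

    got = Counter(letters)
    pooled = {aa: got.get(aa, 0) for aa in _GAP_MASSES if aa not in ("J", "K", "Q")}
    pooled["J"] = got.get("J", 0) + got.get("L", 0) + got.get("I", 0)
    pooled["K"] = got.get("K", 0) + got.get("Q", 0)
    return pooled


def _pool_targets(counts: dict[str, int]) -> dict[str, int]:
    out = {aa: counts.get(aa, 0) for aa in _GAP_MASSES if aa not in ("J", "K", "Q")}
    out["J"] = counts.get("L", 0) + counts.get("I", 0)
    out["K"] = counts.get("K", 0) + counts.get("Q", 0)
    return out


def _matches_composition(contig: tuple[_Pos, ...], counts: dict[str, int]) -> bool:
    """Compare a contig's residue counts to a known composition, pooling the
    isobaric pairs (L+I, K+Q) that the contig may still leave ambiguous."""
    return _pooled_counts([p[0] for p in contig]) == _pool_targets(counts)


#: Mass-degenerate re-readings: one residue whose mass equals a residue pair
#: within the fragment tolerance (G+G = N, G+V ~ R, A+D ~ W, ...).  A ladder
#: junction lost from both ion series can silently merge two residues into
#: one such single; the known amino-acid composition exposes the error.
_SINGLE_TO_PAIRS: dict[str, list[tuple[str, str]]] = {}
for _x, _mx in _GAP_MASSES.items():
    for _m, _a, _b in _PAIR_MASSES:
        if abs(_m - _mx) <= 0.05:
            _SINGLE_TO_PAIRS.setdefault(_x, []).append((_a, _b))


def _pos_of_letter(ch: str) -> _Pos:
    if ch == "J":
        return ("J", "LI")
    if ch in ("K", "Q"):
        return ("K", "KQ")
    return (ch, None)


def _composition_repair(
    contig: tuple[_Pos, ...], counts: dict[str, int]
) -> list[tuple[_Pos, ...]]:
    """Single mass-neutral edits reconciling a contig with a known composition.

    Tries replacing one residue by a mass-equivalent pair (both orders) and
    one adjacent pair by its mass-equivalent single, returning every variant
    whose pooled counts then match.  The caller arbitrates survivors against
    the complete-digest evidence.
    """
    target = _pool_targets(counts)
    variants: list[tuple[_Pos, ...]] = []
    letters = [p[0] for p in contig]
    for i, ch in enumerate(letters):
        key = "K" if ch == "Q" else ch
        for a, b in _SINGLE_TO_PAIRS.get(key, ()):
            for pair in {(a, b), (b, a)}:
                new = letters[:i] + list(pair) + letters[i + 1 :]
                if _pooled_counts(new) == target:
                    variants.append(
                        contig[:i]
                        + (_pos_of_letter(pair[0]), _pos_of_letter(pair[1]))
                        + contig[i + 1 :]
                    )
    for i in range(len(letters) - 1):
        a = "K" if letters[i] == "Q" else letters[i]
        b = "K" if letters[i + 1] == "Q" else letters[i + 1]
        for single, pairs in _SINGLE_TO_PAIRS.items():
            if (a, b) in pairs or (b, a) in pairs:
                new = letters[:i] + [single] + letters[i + 2 :]
                if _pooled_counts(new) == target:
                    variants.append(
                        contig[:i] + (_pos_of_letter(single),) + contig[i + 2 :]
                    )
    # dedupe preserving order
    seen: set = set()
    out = []
    for v in variants:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def sequence_from_spectra(
    spectra: list[tuple[MsMsSpectrum, Enzyme]],
    intact_mh: float,
    complete_digest_peaks: dict[Enzyme, PeakList] | None = None,
    fragment_tol: float = 0.05,
    mass_tol: float = 0.7,
    composition_counts: dict[str, int] | None = None,
    min_overlap: int = 3,
    candidates_per_spectrum: int = 3,
    max_seeds: int = 12,
) -> Assembly | None:
    """Interpret, assemble and resolve a set of digest-fragment spectra.

    Each spectrum contributes its top interpretation candidates; contigs are
    grown greedily by maximal consistent overlap from several alternative
    seeds (partial digests make fragments highly redundant, so a chimeric or
    mis-read candidate is simply left unplaced in that attempt).  Contig
    hypotheses are filtered by the intact native mass and, when given, the
    residue composition, then arbitrated by how well their predicted
    complete-digest fragment masses match the observed complete-digest peak
    lists — the same evidence that resolves the isobaric residues.  Returns
    the winning resolved assembly, or ``None`` when no contig survives.
    """
    scored_lists: list[tuple[tuple[float, int], list[tuple[_Pos, ...]]]] = []
    for spec, _ in spectra:
        cands = interpret_spectrum(spec, tol=fragment_tol)
        uniq: list[tuple[_Pos, ...]] = []
        for c in cands:
            pos = _candidate_positions(c)
            if pos not in uniq:
                uniq.append(pos)
            if len(uniq) == candidates_per_spectrum:
                break
        if uniq:
            scored_lists.append(((cands[0].ion_coverage, len(uniq[0])), uniq))
    if not scored_lists:
        return None
    # confident (fully ion-covered, long) readings shape the contig first;
    # composite-patched or chimeric readings merge late, where conflicts
    # with the established consensus exclude them
    scored_lists.sort(key=lambda t: (-t[0][0], -t[0][1]))
    cand_lists = [cl for _, cl in scored_lists]

    seed_order = list(range(len(cand_lists)))
    contigs: dict[str, tuple[tuple[_Pos, ...], int]] = {}
    overlap_levels = [min_overlap] + ([2] if min_overlap > 2 else [])
    mass_cap = intact_mh + mass_tol

    def _within_cap(c: tuple[_Pos, ...]) -> bool:
        # the parent mass bounds every sub-assembly: an over-mass contig is a
        # mis-merge (typically a repeat-induced pileup), never a prefix of
        # the truth
        return _native_mh(_letters(c)) <= mass_cap

    def _corroborated(contig, remaining):
        """Apply every unambiguous merge, deep overlaps first; a spectrum
        whose candidate variants merge equally well but disagree (an
        unresolved transposition) is deferred until other spectra pin the
        region down."""
        n_applied = 0
        moved = True
        while moved:
            moved = False
            # exhaust confident (long-overlap) merges before falling back to
            # the minimum two-residue overlap a 0-missed boundary can leave
            for ov in overlap_levels:
                changed = True
                while changed:
                    changed = False
                    rest = []
                    for cl in remaining:
                        merges = []
                        for cand in cl:
                            m = _best_merge(contig, cand, ov)
                            if m is not None and _within_cap(m[0]):
                                merges.append(m)
                        if merges:
                            deepest = max(o for _, o in merges)
                            tops = [m for m, o in merges if o == deepest]
                            if all(t == tops[0] for t in tops[1:]):
                                contig = tops[0]
                                n_applied += 1
                                changed = moved = True
                                continue
                        rest.append(cl)
                    remaining = rest
                if moved and ov != overlap_levels[0]:
                    break  # a relaxed merge may unlock strict ones; restart
        return contig, remaining, n_applied

    min_ov = overlap_levels[-1]
    for seed_idx in seed_order[:max_seeds]:
        # grow from this seed; at every forced (uncorroborated) merge also
        # branch into the state where the questionable spectrum is dropped —
        # a deep overlap from a mis-read candidate must not be able to
        # poison every assembly path
        stack = [
            (cand_lists[seed_idx][0],
             [cl for i, cl in enumerate(cand_lists) if i != seed_idx],
             1, 3)
        ]
        while stack:
            contig, remaining, n_placed, budget = stack.pop()
            while True:
                contig, remaining, applied = _corroborated(contig, remaining)
                n_placed += applied
                forced = None
                for idx, cl in enumerate(remaining):
                    for rank, cand in enumerate(cl):
                        m = _best_merge(contig, cand, min_ov)
                        if m is not None and _within_cap(m[0]):
                            key = (m[1], -rank)
                            if forced is None or key > forced[0]:
                                forced = (key, idx, m[0])
                if forced is None:
                    break
                _, idx, merged = forced
                rest = remaining[:idx] + remaining[idx + 1 :]
                if budget > 0:
                    stack.append((contig, rest, n_placed, budget - 1))
                contig, remaining = merged, rest
                n_placed += 1
            letters = _letters(contig)
            if letters not in contigs or contigs[letters][1] < n_placed:
                contigs[letters] = (contig, n_placed)

    viable = []
    for letters in sorted(contigs):
        contig, n_placed = contigs[letters]
        mh = _native_mh(letters)
        if abs(mh - intact_mh) > mass_tol:
            continue
        if composition_counts is not None and not _matches_composition(
            contig, composition_counts
        ):
            # a lost junction can merge two residues into one isobaric
            # single (or split one into a pair); amino-acid analysis sees it
            for repaired in _composition_repair(contig, composition_counts):
                rl = _letters(repaired)
                rmh = _native_mh(rl)
                if abs(rmh - intact_mh) <= mass_tol:
                    viable.append((rl, repaired, rmh, n_placed))
            continue
        viable.append((letters, contig, mh, n_placed))
    if not viable:
        return None

    evidence = list(complete_digest_peaks.items()) if complete_digest_peaks else []
    top_letters = [_letters(cl[0]) for cl in cand_lists]

    def _supporters(contig_letters: str) -> int:
        # spectra whose best-ranked reading is a verbatim piece of the contig;
        # a junction mis-ordered in the contig repels every spectrum that
        # actually observed that junction
        return sum(1 for t in top_letters if t in contig_letters)

    # arbitration: complete-digest agreement first (it distinguishes isobaric
    # rearrangements that move cleavage sites), then spectrum support, then
    # how many spectra the contig absorbed during growth
    viable.sort(
        key=lambda t: (
            -_digest_score(t[0].replace("J", "L"), evidence, 0.2) if evidence else 0,
            -_supporters(t[0]),
            -t[3],
            t[0],
        )
    )
    letters, contig, mh, _ = viable[0]
    assembly = Assembly(
        placements=(),
        consensus=letters,
        ambiguous_li=frozenset(i for i, p in enumerate(contig) if p[1] == "LI"),
        ambiguous_kq=frozenset(i for i, p in enumerate(contig) if p[1] == "KQ"),
        ambiguous_order=False,
        consensus_mh=mh,
    )
    if complete_digest_peaks:
        assembly = resolve_isobaric(
            assembly, complete_digest_peaks, composition_counts=composition_counts
        )
    return assembly
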