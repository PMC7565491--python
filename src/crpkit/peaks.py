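"""Pairing of native vs. reduced/alkylated peak lists and cysteine counting.

A disulfide-rich peptide shifts by ~58.029 Da per cysteine upon reduction and
carbamidomethylation (one hydrogen from disulfide opening plus +57.021 from the
alkyl group).  Matching each native [M+H]+ signal to an alkylated signal whose
mass difference is an integer multiple of that shift therefore counts the
cysteines without any sequence knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import CAM_DELTA, HYDROGEN

__all__ = ["PER_CYS_SHIFT", "PeakList", "CysCountResult", "count_cys_from_shift", "pair_peaks"]

#: Per-cysteine mass shift for a disulfide-oxidized peptide (reduction + CAM).
PER_CYS_SHIFT = CAM_DELTA + HYDROGEN  # 58.029285


@dataclass
class PeakList:
    """Centroided (m/z, intensity) peaks, kept sorted and deduplicated."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = "native"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        # exact duplicates collapse to the more intense peak
        if self.mz.size:
            keep = np.ones(self.mz.size, dtype=bool)
            for i in range(1, self.mz.size):
                if self.mz[i] == self.mz[i - 1]:
                    j = i - 1
                    while j > 0 and not keep[j]:
                        j -= 1
                    if self.intensity[i] >= self.intensity[j]:
                        keep[j] = False
                    else:
                        keep[i] = False
            self.mz = self.mz[keep]
            self.intensity = self.intensity[keep]

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_pairs(cls, pairs, label: str = "native") -> "PeakList":
        pairs = list(pairs)
        mz = [p[0] for p in pairs]
        inten = [p[1] for p in pairs]
        return cls(np.array(mz, dtype=float), np.array(inten, dtype=float), label)


@dataclass
class CysCountResult:
    """One native/alkylated pairing with its inferred cysteine count."""

    native_mz: float
    alkylated_mz: float
    delta: float
    n_cys: int
    residual: float
    primary: bool = False


def count_cys_from_shift(
    delta: float, per_cys_shift: float = PER_CYS_SHIFT, tol: float = 0.3
) -> int | None:
    """Nearest integer cysteine count explaining a mass shift, or ``None``.

    Returns k with ``|delta - k * per_cys_shift| <= tol`` (k >= 0), else None.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    k = max(0, round(delta / per_cys_shift))
    if abs(delta - k * per_cys_shift) <= tol:
        return k
    return None


def pair_peaks(
    native: PeakList,
    alkylated: PeakList,
    per_cys_shift: float = PER_CYS_SHIFT,
    max_cys: int = 20,
    tol: float = 0.3,
) -> list[CysCountResult]:
    """Report every native/alkylated peak pair consistent with k alkylated Cys.

    For each native peak, every alkylated peak whose shift lies within ``tol``
    of ``k * per_cys_shift`` (1 <= k <= max_cys) is reported; the pair with the
    smallest residual per native peak is flagged ``primary``.  Ambiguous
    pairings are all retained, ranked by residual — nothing is silently
    dropped.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    results: list[CysCountResult] = []
    for nm in native.mz:
        candidates: list[CysCountResult] = []
        for am in alkylated.mz:
            delta = am - nm
            if delta <= 0:
                continue
            k = round(delta / per_cys_shift)
            if not 1 <= k <= max_cys:
                continue
            residual = delta - k * per_cys_shift
            if abs(residual) <= tol:
                candidates.append(
                    CysCountResult(float(nm), float(am), float(delta), int(k), float(residual))
                )
        if candidates:
            candidates.sort(key=lambda r: (abs(r.residual), r.alkylated_mz))
            candidates[0].primary = True
            results.extend(candidates)
    return results
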