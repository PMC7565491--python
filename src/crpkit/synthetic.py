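"""Seeded generators for every input class the pipeline consumes.

The generators emulate the structure of the real study inputs — MALDI peak
lists of native vs. reduced/alkylated extracts, partial-digest fragment
ladders with b/y MS/MS spectra, and nucleotide backgrounds with planted
CRP-coding segments — so that every stage is testable without instrument data
or database downloads.  All generators are pure functions of their parameters
and a seed.

What is deliberately not modelled: isotope envelopes, charge states beyond
1+, detector saturation, digestion kinetics.  Peak intensities are drawn
log-normal (a MALDI-like dynamic range); mass accuracy is a plain Gaussian
calibration jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import (
    MONOISOTOPIC,
    Peptide,
    carbamidomethylated,
    composition,
    peptide_mass,
    reduction_alkylation_shift,
)
from .denovo import MsMsSpectrum, by_ion_series
from .digestion import CHYMOTRYPSIN, TRYPSIN, Enzyme, digest_complete, digest_partial
from .peaks import PeakList

__all__ = [
    "CrpSpec",
    "SpectrumNoiseModel",
    "DenovoExperiment",
    "gen_crp",
    "mutate",
    "gen_precursor_genome",
    "sim_peaklists",
    "sim_msms",
    "simulate_denovo_experiment",
]

#: Residues eligible for loop/prefix/suffix positions (anything but Cys).
_NON_CYS = sorted(set(MONOISOTOPIC) - {"C"})
_AROMATIC = ("F", "Y", "W")
_BASIC = ("R", "K")

_CODONS: dict[str, list[str]] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            from Bio.Seq import Seq as _Seq

            _codon = _c1 + _c2 + _c3
            _aa = str(_Seq(_codon).translate())
            _CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class CrpSpec:
    """Shape of a generated cysteine-rich peptide.

    Defaults follow the six-Cys family template: loops 6/5/3/1/10 with a short
    prefix and suffix, and an aromatic P1 (the antimicrobial-like branch).
    """

    prefix_range: tuple[int, int] = (1, 5)
    loops: tuple[int, ...] = (6, 5, 3, 1, 10)
    suffix_range: tuple[int, int] = (1, 3)
    p1_policy: str = "aromatic"  # aromatic | basic | random

    def __post_init__(self) -> None:
        if self.p1_policy not in ("aromatic", "basic", "random"):
            raise ValueError(f"unknown P1 policy {self.p1_policy!r}")
        for lo, hi in (self.prefix_range, self.suffix_range):
            if lo < 0 or hi < lo:
                raise ValueError("inconsistent length range")
        if len(self.loops) != 5 or any(l < 2 for l in self.loops[:1]) or any(
            l < 0 for l in self.loops
        ):
            raise ValueError("need 5 loop lengths with loop 1 >= 2 (P1 must exist)")


@dataclass(frozen=True)
class SpectrumNoiseModel:
    """Calibration jitter, decoy peaks and ion dropout for simulated spectra."""

    jitter_sigma: float = 0.01  # Da, per-peak Gaussian calibration error
    n_noise_peaks: int = 5
    dropout: float = 0.1  # per-ion loss probability
    intensity_mu: float = 8.0  # log-normal location (median e^mu counts)
    intensity_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if self.jitter_sigma < 0 or self.n_noise_peaks < 0:
            raise ValueError("noise parameters must be non-negative")


DEFAULT_MSMS_NOISE = SpectrumNoiseModel()
DEFAULT_MS1_NOISE = SpectrumNoiseModel(jitter_sigma=0.05, n_noise_peaks=20, dropout=0.0)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_crp(spec: CrpSpec, n: int, seed: int | np.random.Generator = 0) -> list[tuple[str, str]]:
    """Generate ``n`` six-cysteine peptides satisfying ``spec``.

    Returns (name, sequence) pairs; names embed the seed policy for
    traceability.  Identical seeds yield identical output.
    """
    rng = _rng(seed)
    out = []
    for i in range(n):
        prefix_len = int(rng.integers(spec.prefix_range[0], spec.prefix_range[1] + 1))
        suffix_len = int(rng.integers(spec.suffix_range[0], spec.suffix_range[1] + 1))
        parts = ["".join(rng.choice(_NON_CYS, size=prefix_len))]
        for loop_idx, loop_len in enumerate(spec.loops):
            loop = list(rng.choice(_NON_CYS, size=loop_len))
            if loop_idx == 0:
                if spec.p1_policy == "aromatic":
                    loop[1] = str(rng.choice(_AROMATIC))
                elif spec.p1_policy == "basic":
                    loop[1] = str(rng.choice(_BASIC))
            parts.append("C" + "".join(loop))
        parts.append("C" + "".join(rng.choice(_NON_CYS, size=suffix_len)))
        out.append((f"crp_{spec.p1_policy}_{i + 1}", "".join(parts)))
    return out


def mutate(
    sequence: str,
    rate: float,
    seed: int | np.random.Generator = 0,
    preserve_cys: bool = True,
    preserve: tuple[int, ...] = (),
) -> str:
    """Point-substitute each position with probability ``rate``.

    Cysteines (and any explicitly preserved positions) are left untouched so
    the loop scaffold survives; substitutions never introduce a new Cys.
    """
    rng = _rng(seed)
    seq = list(sequence)
    for i, ch in enumerate(seq):
        if i in preserve or (preserve_cys and ch == "C"):
            continue
        if rng.random() < rate:
            seq[i] = str(rng.choice([aa for aa in _NON_CYS if aa != ch]))
    return "".join(seq)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(str(rng.choice(_CODONS[aa])) for aa in protein)


def gen_precursor_genome(
    crps: list[tuple[str, str]],
    background_nt: int = 50_000,
    seed: int | np.random.Generator = 0,
) -> tuple[str, pd.DataFrame]:
    """Random nucleotide background with CRPs reverse-translated and planted.

    Each peptide is back-translated with uniformly random synonymous codons
    and embedded at a random non-overlapping position on a random strand.
    Returns the genome string and a truth table with one row per insert:
    name, nt_start, nt_end (0-based half-open, genome coordinates), strand,
    frame (the six-frame-translation frame containing the peptide) and the
    protein sequence.
    """
    rng = _rng(seed)
    inserts = [(name, _reverse_translate(seq, rng), seq) for name, seq in crps]
    total = sum(len(nt) for _, nt, _ in inserts)
    if total > background_nt:
        raise ValueError(
            f"{total} nt of inserts do not fit a {background_nt} nt background"
        )
    genome = list(rng.choice(list("ACGT"), size=background_nt))
    # place left to right in disjoint random slots
    rows = []
    free = background_nt - total
    n_ins = len(inserts)
    cut_positions = sorted(rng.choice(free + 1, size=n_ins, replace=True)) if n_ins else []
    cursor = 0
    for (name, nt, protein), cut in zip(inserts, cut_positions):
        start = cut + cursor
        strand = int(rng.choice([1, -1]))
        placed = nt if strand == 1 else str(_Seq(nt).reverse_complement())
        genome[start : start + len(nt)] = list(placed)
        end = start + len(nt)
        if strand == 1:
            frame = start % 3 + 1
        else:
            frame = -((background_nt - end) % 3 + 1)
        rows.append(
            dict(name=name, nt_start=start, nt_end=end, strand=strand,
                 frame=frame, protein=protein)
        )
        cursor += len(nt)
    truth = pd.DataFrame(
        rows, columns=["name", "nt_start", "nt_end", "strand", "frame", "protein"]
    )
    return "".join(genome), truth


def _intensities(n: int, noise: SpectrumNoiseModel, rng: np.random.Generator) -> np.ndarray:
    return rng.lognormal(noise.intensity_mu, noise.intensity_sigma, size=n)


def sim_peaklists(
    peptides: list[Peptide | str],
    noise: SpectrumNoiseModel = DEFAULT_MS1_NOISE,
    seed: int | np.random.Generator = 0,
) -> tuple[PeakList, PeakList]:
    """Native and reduced/alkylated MALDI peak lists for a peptide panel.

    Each peptide contributes a native [M+H]+ peak and an alkylated peak
    shifted by its reduction+carbamidomethylation delta, both with independent
    calibration jitter; decoy peaks are sprinkled uniformly over the mass
    range of both lists.
    """
    rng = _rng(seed)
    peps = [Peptide(p) if isinstance(p, str) else p for p in peptides]
    native_mz, alk_mz = [], []
    for p in peps:
        m = peptide_mass(p).MH
        shift = reduction_alkylation_shift(p.sequence.count("C"), p.n_disulfides)
        native_mz.append(m + rng.normal(0, noise.jitter_sigma))
        alk_mz.append(m + shift + rng.normal(0, noise.jitter_sigma))
    lo, hi = (3500.0, 4600.0) if not native_mz else (
        min(native_mz) - 200.0, max(alk_mz) + 200.0
    )
    lists = []
    for mzs, label in ((native_mz, "native"), (alk_mz, "alkylated")):
        decoys = list(rng.uniform(lo, hi, size=noise.n_noise_peaks))
        all_mz = np.array(mzs + decoys)
        inten = _intensities(all_mz.size, noise, rng)
        lists.append(PeakList(all_mz, inten, label))
    return lists[0], lists[1]


def sim_msms(
    fragment: str,
    noise: SpectrumNoiseModel = DEFAULT_MSMS_NOISE,
    seed: int | np.random.Generator = 0,
) -> MsMsSpectrum:
    """Simulated b/y fragment spectrum of a carbamidomethylated peptide.

    Every b and y ion is emitted with probability 1 - dropout, jittered;
    decoy peaks fall uniformly between 100 Da and the precursor.  The
    precursor [M+H]+ is the exact theoretical value.
    """
    if len(fragment) < 2:
        raise ValueError("fragment must have at least 2 residues")
    rng = _rng(seed)
    pep = carbamidomethylated(fragment)
    series = by_ion_series(pep)
    precursor = peptide_mass(pep).MH
    mz = [
        float(ion) + rng.normal(0, noise.jitter_sigma)
        for ion in np.concatenate([series.b, series.y])
        if rng.random() >= noise.dropout
    ]
    mz += list(rng.uniform(100.0, precursor, size=noise.n_noise_peaks))
    inten = _intensities(len(mz), noise, rng)
    return MsMsSpectrum(precursor, PeakList(np.array(mz), inten, "msms"))


@dataclass
class DenovoExperiment:
    """Everything one simulated sequencing experiment produces."""

    true_sequence: str
    intact_mh: float
    spectra: list[tuple[MsMsSpectrum, Enzyme]]
    complete_digest_peaks: dict[Enzyme, PeakList]
    composition_counts: dict[str, int]


def simulate_denovo_experiment(
    sequence: str,
    noise: SpectrumNoiseModel = DEFAULT_MSMS_NOISE,
    seed: int | np.random.Generator = 0,
    enzymes: tuple[Enzyme, ...] = (TRYPSIN, CHYMOTRYPSIN),
    min_len: int = 4,
    max_len: int = 30,
    max_missed: int = 2,
) -> DenovoExperiment:
    """Simulate the full wet-lab sequencing workflow for one peptide.

    Partial digests with each enzyme yield fragments (filtered to the
    MS/MS-amenable length range and up to ``max_missed`` missed cleavages),
    each fragmented into a noisy b/y spectrum; complete digests yield the
    peak lists used for isobaric resolution; the residue composition stands
    in for the amino-acid-analysis confirmation step.
    """
    rng = _rng(seed)
    spectra: list[tuple[MsMsSpectrum, Enzyme]] = []
    complete: dict[Enzyme, PeakList] = {}
    for enzyme in enzymes:
        for frag in digest_partial(sequence, enzyme):
            if frag.missed_cleavages > max_missed:
                continue
            if not min_len <= len(frag.sequence) <= max_len:
                continue
            spectra.append((sim_msms(frag.sequence, noise, rng), enzyme))
        mhs = [
            f.theoretical_mh + rng.normal(0, noise.jitter_sigma)
            for f in digest_complete(sequence, enzyme, max_missed=0)
        ]
        complete[enzyme] = PeakList(
            np.array(mhs), np.ones(len(mhs)), f"complete-{enzyme.name}"
        )
    return DenovoExperiment(
        true_sequence=sequence,
        intact_mh=peptide_mass(Peptide(sequence)).MH,
        spectra=spectra,
        complete_digest_peaks=complete,
        composition_counts=composition(sequence),
    )
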