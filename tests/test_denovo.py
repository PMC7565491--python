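import numpy as np
import pytest

from crpkit.chem import PROTON, Peptide, carbamidomethylated, peptide_mass
from crpkit.denovo import (
    Assembly,
    AssemblyConflictError,
    MassMismatchError,
    MsMsSpectrum,
    assemble_fragments,
    by_ion_series,
    interpret_spectrum,
    resolve_isobaric,
    sequence_from_spectra,
)
from crpkit.digestion import CHYMOTRYPSIN, TRYPSIN
from crpkit.peaks import PeakList
from crpkit.synthetic import (
    SpectrumNoiseModel,
    sim_msms,
    simulate_denovo_experiment,
)

from conftest import CITCOL2

CLEAN = SpectrumNoiseModel(jitter_sigma=0.0, n_noise_peaks=0, dropout=0.0)


def canonical(seq: str) -> str:
    """The mass-level reading of a sequence: L/I -> J, Q indistinct from K."""
    return seq.replace("L", "J").replace("I", "J").replace("Q", "K")


class TestIonSeries:
    def test_dipeptide(self):
        s = by_ion_series("AG")
        assert s.b[0] == pytest.approx(72.044, abs=1e-3)
        assert s.y[0] == pytest.approx(76.039, abs=1e-3)

    def test_complementarity_identity(self):
        pep = carbamidomethylated("VCLFVGK")
        s = by_ion_series(pep)
        m = peptide_mass(pep).M
        for i in range(len(s.b)):
            assert s.b[i] + s.y[len(s.y) - 1 - i] == pytest.approx(m + 2 * PROTON, abs=1e-6)

    def test_cterm_lysine_y1(self):
        s = by_ion_series(carbamidomethylated("VCLFVGK"))
        assert s.y[0] == pytest.approx(147.113, abs=1e-3)

    def test_too_short(self):
        with pytest.raises(ValueError):
            by_ion_series("A")


class TestInterpretSpectrum:
    def test_complete_ladder_recovered(self):
        spec = sim_msms("VCLFVGK", CLEAN, 1)
        cands = interpret_spectrum(spec)
        top = cands[0]
        assert top.sequence == "VCJFVGK"
        assert top.ion_coverage == 1.0
        assert 6 in top.ambiguous_kq  # terminal K could be Q by mass alone

    def test_empty_spectrum(self):
        spec = MsMsSpectrum(500.0, PeakList.from_pairs([], "msms"))
        assert interpret_spectrum(spec) == []

    def test_missing_b_ion_recovered_from_complementary_y(self):
        pep = carbamidomethylated("VCLFVGK")
        series = by_ion_series(pep)
        mh = peptide_mass(pep).MH
        ions = list(series.b) + list(series.y)
        ions.remove(series.b[2])  # drop b3; y4 still pins the junction
        spec = MsMsSpectrum(mh, PeakList.from_pairs([(m, 1.0) for m in ions], "msms"))
        assert interpret_spectrum(spec)[0].sequence == "VCJFVGK"

    def test_invariant_to_intensity_scaling(self):
        spec = sim_msms("PLPLIDAGYCGFL", CLEAN, 3)
        scaled = MsMsSpectrum(
            spec.precursor_mh,
            PeakList(spec.peaks.mz.copy(), spec.peaks.intensity * 100.0, "msms"),
        )
        a = [c.sequence for c in interpret_spectrum(spec)]
        b = [c.sequence for c in interpret_spectrum(scaled)]
        assert a == b

    def test_invariant_to_chainless_noise_peaks(self):
        spec = sim_msms("VCLFVGK", CLEAN, 1)
        # noise peaks offset by half a dalton cannot join any residue chain
        noise = [(m + 0.5, 999.0) for m in spec.peaks.mz[:3]]
        noisy = MsMsSpectrum(
            spec.precursor_mh,
            PeakList.from_pairs(
                list(zip(spec.peaks.mz, spec.peaks.intensity)) + noise, "msms"
            ),
        )
        assert interpret_spectrum(noisy)[0].sequence == "VCJFVGK"


def _citcol2_candidates():
    frags = [
        ("VCLFVGK", TRYPSIN),
        ("PCWSDADCPSGCYCK", TRYPSIN),
        ("PLPLIDAGYCGFL", TRYPSIN),
        ("VGKPCWSDADCPSGCY", CHYMOTRYPSIN),
        ("CKPLPLIDAGYCGFL", CHYMOTRYPSIN),
    ]
    return [
        (interpret_spectrum(sim_msms(f, CLEAN, i))[0], e)
        for i, (f, e) in enumerate(frags)
    ]


class TestAssembleFragments:
    def test_citcol2_unique_consensus(self):
        assemblies = assemble_fragments(_citcol2_candidates(), 3734.1, tol=0.7)
        assert len(assemblies) == 1
        a = assemblies[0]
        assert a.consensus == canonical(CITCOL2)
        assert not a.ambiguous_order
        assert sorted(a.ambiguous_kq) == [6, 21]

    def test_single_fragment_is_itself(self):
        intact = peptide_mass(Peptide("VCLFVGK", n_disulfides=0)).MH
        [a] = assemble_fragments([("VCLFVGK", TRYPSIN)], intact, tol=0.7)
        assert a.consensus == "VCLFVGK"

    def test_disjoint_fragments_give_both_orders(self):
        intact = peptide_mass(Peptide("GGGKAAAR", n_disulfides=0)).MH
        assemblies = assemble_fragments(
            [("GGGK", TRYPSIN), ("AAAR", TRYPSIN)], intact, tol=0.7
        )
        assert len(assemblies) == 2
        assert all(a.ambiguous_order for a in assemblies)
        assert {a.consensus for a in assemblies} == {"GGGKAAAR", "AAARGGGK"}

    def test_mass_mismatch_raises(self):
        with pytest.raises(MassMismatchError):
            assemble_fragments([("VCLFVGK", TRYPSIN)], 5000.0, tol=0.7)

    def test_contradictory_fragments_raise(self):
        # same span, incompatible residues, and no enzyme boundary to abut at
        with pytest.raises((AssemblyConflictError, MassMismatchError)):
            assemble_fragments(
                [("AAAG", TRYPSIN), ("AAAW", TRYPSIN)], 500.0, tol=0.1
            )


class TestResolveIsobaric:
    def test_citcol2_fully_resolved(self):
        [a] = assemble_fragments(_citcol2_candidates(), 3734.1, tol=0.7)
        exp = simulate_denovo_experiment(CITCOL2, CLEAN, 0)
        r = resolve_isobaric(a, exp.complete_digest_peaks)
        assert r.consensus == CITCOL2
        assert not (r.ambiguous_li or r.ambiguous_kq)

    def test_lys_by_tryptic_boundary_evidence(self):
        [a] = assemble_fragments(_citcol2_candidates(), 3734.1, tol=0.7)
        assert {6, 21} <= a.ambiguous_kq  # flagged before resolution
        exp = simulate_denovo_experiment(CITCOL2, CLEAN, 0)
        r = resolve_isobaric(a, exp.complete_digest_peaks)
        assert r.consensus[6] == "K" and r.consensus[21] == "K"

    def test_ile_by_absent_chymotryptic_cleavage(self):
        [a] = assemble_fragments(_citcol2_candidates(), 3734.1, tol=0.7)
        exp = simulate_denovo_experiment(CITCOL2, CLEAN, 0)
        r = resolve_isobaric(a, exp.complete_digest_peaks)
        assert r.consensus[26] == "I"

    def test_no_flags_returned_unchanged(self):
        a = Assembly((), "GGGK", frozenset(), frozenset(), False, 0.0)
        assert resolve_isobaric(a, {}) is a

    def test_no_evidence_keeps_flags(self):
        [a] = assemble_fragments(_citcol2_candidates(), 3734.1, tol=0.7)
        r = resolve_isobaric(a, {})
        assert r.ambiguous_kq == a.ambiguous_kq


class TestSevenMerDropoutRecovery:
    def test_most_seven_mers_survive_twenty_percent_dropout(self):
        rng = np.random.default_rng(99)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        noise = SpectrumNoiseModel(jitter_sigma=0.01, n_noise_peaks=5, dropout=0.2)
        hits = 0
        n = 100
        for i in range(n):
            seq = "".join(rng.choice(alphabet, size=7))
            spec = sim_msms(seq, noise, seed=10_000 + i)
            cands = interpret_spectrum(spec)
            if any(c.sequence == canonical(seq) for c in cands):
                hits += 1
        assert hits >= 90


class TestSequenceFromSpectra:
    def test_citcol2_pipeline(self):
        exp = simulate_denovo_experiment(CITCOL2, CLEAN, 2)
        a = sequence_from_spectra(
            exp.spectra, exp.intact_mh, exp.complete_digest_peaks,
            composition_counts=exp.composition_counts,
        )
        assert a is not None and a.consensus == CITCOL2

    def test_no_spectra(self):
        assert sequence_from_spectra([], 1000.0) is None
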