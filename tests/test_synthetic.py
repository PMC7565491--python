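import numpy as np
import pytest

from crpkit.annotation import ANTIMICROBIAL_LIKE, TRYPSIN_INHIBITOR_LIKE, classify_p1, loop_pattern
from crpkit.denovo import sequence_from_spectra
from crpkit.mining import DEFAULT_TEMPLATE, hit_nt_span, mine
from crpkit.peaks import pair_peaks
from crpkit.synthetic import (
    CrpSpec,
    DEFAULT_MSMS_NOISE,
    SpectrumNoiseModel,
    gen_crp,
    gen_precursor_genome,
    mutate,
    sim_msms,
    sim_peaklists,
    simulate_denovo_experiment,
)

from conftest import CITCOL2


class TestGenCrp:
    def test_deterministic(self):
        a = gen_crp(CrpSpec(), 5, seed=42)
        b = gen_crp(CrpSpec(), 5, seed=42)
        assert a == b

    def test_zero(self):
        assert gen_crp(CrpSpec(), 0, seed=1) == []

    def test_aromatic_policy_gives_antimicrobial_labels(self):
        for _, seq in gen_crp(CrpSpec(p1_policy="aromatic"), 8, seed=2):
            assert seq.count("C") == 6
            assert classify_p1(seq).label == ANTIMICROBIAL_LIKE

    def test_basic_policy_gives_inhibitor_labels(self):
        for _, seq in gen_crp(CrpSpec(p1_policy="basic"), 8, seed=3):
            assert classify_p1(seq).label == TRYPSIN_INHIBITOR_LIKE

    def test_loops_match_spec(self):
        for _, seq in gen_crp(CrpSpec(loops=(6, 5, 3, 1, 10)), 4, seed=4):
            assert loop_pattern(seq).loops == (6, 5, 3, 1, 10)

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            CrpSpec(p1_policy="acidic")


class TestMutate:
    def test_rate_zero_identity(self):
        assert mutate(CITCOL2, 0.0, seed=1) == CITCOL2

    def test_cysteines_preserved(self):
        m = mutate(CITCOL2, 0.5, seed=1)
        assert [i for i, c in enumerate(m) if c == "C"] == [
            i for i, c in enumerate(CITCOL2) if c == "C"
        ]


class TestSimPeaklists:
    def test_noise_free_pair_exact(self):
        native, alk = sim_peaklists(
            [CITCOL2], SpectrumNoiseModel(jitter_sigma=0.0, n_noise_peaks=0, dropout=0.0),
            seed=0,
        )
        assert native.mz[0] == pytest.approx(3734.632, abs=1e-3)
        assert alk.mz[0] == pytest.approx(4082.808, abs=1e-3)

    def test_noisy_pairing_recovers_six_cys(self):
        native, alk = sim_peaklists(
            [CITCOL2], SpectrumNoiseModel(jitter_sigma=0.05, n_noise_peaks=20, dropout=0.0),
            seed=1,
        )
        primaries = [r for r in pair_peaks(native, alk, tol=0.3) if r.primary]
        assert any(r.n_cys == 6 and abs(r.native_mz - 3734.6) < 1 for r in primaries)

    def test_empty_panel_only_decoys(self):
        noise = SpectrumNoiseModel(jitter_sigma=0.0, n_noise_peaks=7, dropout=0.0)
        native, alk = sim_peaklists([], noise, seed=2)
        assert len(native) == 7 and len(alk) == 7

    def test_deterministic(self):
        a = sim_peaklists([CITCOL2], seed=9)
        b = sim_peaklists([CITCOL2], seed=9)
        assert np.array_equal(a[0].mz, b[0].mz)
        assert np.array_equal(a[1].mz, b[1].mz)


class TestSimMsms:
    def test_no_dropout_full_ladder(self):
        spec = sim_msms("VCLFVGK", SpectrumNoiseModel(0.0, 0, 0.0), seed=1)
        assert len(spec.peaks) == 12  # b1..b6 + y1..y6

    def test_full_dropout_only_decoys(self):
        spec = sim_msms("VCLFVGK", SpectrumNoiseModel(0.0, 3, 1.0), seed=1)
        assert len(spec.peaks) == 3

    def test_too_short(self):
        with pytest.raises(ValueError):
            sim_msms("A", seed=1)


class TestPrecursorGenome:
    def test_deterministic(self):
        crps = gen_crp(CrpSpec(), 3, seed=1)
        g1, t1 = gen_precursor_genome(crps, 10_000, seed=8)
        g2, t2 = gen_precursor_genome(crps, 10_000, seed=8)
        assert g1 == g2 and t1.equals(t2)

    def test_overcrowded_background(self):
        crps = gen_crp(CrpSpec(), 20, seed=1)
        with pytest.raises(ValueError):
            gen_precursor_genome(crps, 500, seed=0)

    def test_mining_recovers_planted_precursors(self):
        crps = gen_crp(CrpSpec(), 3, seed=6)
        genome, truth = gen_precursor_genome(crps, 12_000, seed=6)
        queries = {name: seq for name, seq in crps}
        hits = mine({"genome": genome}, queries, DEFAULT_TEMPLATE, 0.001)
        assert len(hits) == 3
        for _, row in truth.iterrows():
            matching = [
                h for h in hits
                if row.protein[row.protein.index("C"):] in h.segment
            ]
            assert matching, f"{row['name']} not recovered"
            span = hit_nt_span(matching[0], len(genome))
            # the scan may extend a few residues into flanking background
            assert span[0] <= row.nt_start + 3 and span[1] >= row.nt_end - 3

    def test_empty_plant_list_no_hits(self):
        genome, truth = gen_precursor_genome([], 6_000, seed=5)
        hits = mine({"genome": genome}, {"q": gen_crp(CrpSpec(), 1, seed=1)[0][1]},
                    DEFAULT_TEMPLATE, 0.001)
        assert truth.empty and hits == []


class TestFullPipelineRecovery:
    def test_recovery_rate_at_default_noise(self):
        """Simulated digests + spectra -> de novo -> resolution reproduces
        the planted sequence for at least 95% of generated peptides."""
        crps = gen_crp(CrpSpec(), 60, seed=7)
        ok = 0
        for i, (_, seq) in enumerate(crps):
            exp = simulate_denovo_experiment(seq, DEFAULT_MSMS_NOISE, seed=1000 + i)
            a = sequence_from_spectra(
                exp.spectra, exp.intact_mh, exp.complete_digest_peaks,
                composition_counts=exp.composition_counts,
            )
            if a is not None and a.consensus == seq:
                ok += 1
        assert ok >= 57  # >= 95% of 60

    def test_label_recovered_with_sequence(self):
        crps = gen_crp(CrpSpec(p1_policy="basic"), 5, seed=21)
        for i, (_, seq) in enumerate(crps):
            exp = simulate_denovo_experiment(seq, DEFAULT_MSMS_NOISE, seed=3000 + i)
            a = sequence_from_spectra(
                exp.spectra, exp.intact_mh, exp.complete_digest_peaks,
                composition_counts=exp.composition_counts,
            )
            if a is not None and a.consensus == seq:
                assert classify_p1(a.consensus).label == TRYPSIN_INHIBITOR_LIKE
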