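import dataclasses

import pytest

from psibridge import (
    DesignParams,
    Oligo,
    PsiSite,
    RoundtripParams,
    StopCause,
    TranscriptWithPsi,
    design_bridging_oligo,
    dna,
    generate_synthetic_transcript,
    infer_psi,
    reverse_complement,
    rna,
    roundtrip,
    simulate_pcr,
    simulate_rt,
    simulate_splint_ligation,
    validate_primer_layout,
)
from psibridge import reference
from psibridge.simulate import InferenceError, PrimerSiteError, SimulationError


@pytest.fixture
def toy_with_psi(toy_transcript):
    return TranscriptWithPsi("toy", toy_transcript, frozenset({7}))


@pytest.fixture
def toy_bridge(adaptor, toy_transcript, toy_psi):
    return design_bridging_oligo(
        adaptor, toy_transcript, toy_psi, DesignParams(10, 4)
    )


class TestReverseTranscription:
    def test_cmc_stop_at_psi(self, toy_with_psi, toy_rt_primer):
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, cmc_treated=True)
        assert cdna.dna.letters == "GGATGCTCCATGG"
        assert cdna.stop_cause is StopCause.PSI_ADDUCT
        assert cdna.junction_rna_position == 8

    def test_no_cmc_runs_off_5prime_end(self, toy_with_psi, toy_rt_primer):
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, cmc_treated=False)
        assert cdna.dna.letters == "GGATGCTCCATGGAAATCCC"
        assert cdna.stop_cause is StopCause.RUNOFF

    def test_blocking_oligo_read_through(self, toy_with_psi, toy_rt_primer):
        blocked = dataclasses.replace(toy_with_psi, blocking_ligated=True)
        cdna = simulate_rt(blocked, toy_rt_primer, cmc_treated=False)
        assert cdna.dna.letters == "GGATGCTCCATGGAAATCCCTGGGT"
        assert cdna.stop_cause is StopCause.RUNOFF

    def test_cdna_starts_with_primer(self, toy_with_psi, toy_rt_primer):
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, True)
        assert cdna.dna.letters.startswith(toy_rt_primer.core.letters)

    def test_primer_without_site_errors(self, toy_with_psi):
        with pytest.raises(PrimerSiteError, match="no exact site"):
            simulate_rt(toy_with_psi, Oligo("bad", dna("GGGGGGGG")), True)

    def test_ambiguous_primer_reports_candidates(self):
        t = TranscriptWithPsi("rep", rna("AAGGAUCCAAGGAUCCAA"), frozenset())
        with pytest.raises(PrimerSiteError, match="candidate"):
            simulate_rt(t, Oligo("rep", reverse_complement(dna("GGATCC"))),
                        True)

    def test_fragment_end_stop(self, toy_transcript, toy_rt_primer):
        t = TranscriptWithPsi("toy", toy_transcript, frozenset({7}),
                              fragments=(10,))
        # psi 7 is outside the primer's fragment [10, 20]
        cdna = simulate_rt(t, toy_rt_primer, cmc_treated=True)
        assert cdna.stop_cause is StopCause.FRAGMENT_END
        assert cdna.junction_rna_position == 10
        assert cdna.dna.letters == \
            reverse_complement(dna("ATGGAGCATCC")).letters

    def test_non_uridine_psi_rejected(self, toy_transcript):
        with pytest.raises(SimulationError, match="not a uridine"):
            TranscriptWithPsi("toy", toy_transcript, frozenset({1}))


class TestSplintLigation:
    def test_psi_stopped_cdna_ligates(self, toy_with_psi, toy_rt_primer,
                                      phosphorylated_adaptor, toy_bridge):
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, True)
        result = simulate_splint_ligation(
            cdna, phosphorylated_adaptor, toy_bridge, 10, 4
        )
        assert result.success
        assert result.product.letters == (
            "GGATGCTCCATGG" + phosphorylated_adaptor.core.letters
        )

    def test_unphosphorylated_adaptor_fails(self, toy_with_psi, adaptor,
                                            toy_rt_primer, toy_bridge):
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, True)
        result = simulate_splint_ligation(cdna, adaptor, toy_bridge, 10, 4)
        assert not result.success
        assert result.reason == "adaptor not 5'-phosphorylated"

    def test_runoff_cdna_mismatches(self, toy_with_psi, toy_rt_primer,
                                    phosphorylated_adaptor, toy_bridge):
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, False)
        result = simulate_splint_ligation(
            cdna, phosphorylated_adaptor, toy_bridge, 10, 4
        )
        assert not result.success
        assert result.reason == "cDNA-side mismatch"

    def test_wrong_adaptor_fails_adaptor_side(self, toy_with_psi,
                                              toy_rt_primer, toy_bridge):
        other = Oligo("other", dna("G" * 20)).with_phosphorylation()
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, True)
        result = simulate_splint_ligation(cdna, other, toy_bridge, 10, 4)
        assert result.reason == "adaptor-side mismatch"


class TestPCRAndInference:
    @pytest.fixture
    def ligated(self, toy_with_psi, toy_rt_primer, phosphorylated_adaptor,
                toy_bridge):
        cdna = simulate_rt(toy_with_psi, toy_rt_primer, True)
        return simulate_splint_ligation(
            cdna, phosphorylated_adaptor, toy_bridge, 10, 4
        ).product

    def test_outer_amplicon_spans_junction(self, ligated, toy_rt_primer):
        amp = simulate_pcr(ligated, reference.ADAPTOR_PRIMER, toy_rt_primer)
        assert amp is not None and amp.length == 57
        assert amp.sense.letters.endswith("CCATGGAGCATCC")
        assert amp.forward_site == (1, 23)
        assert amp.reverse_site == (50, 57)

    def test_absent_forward_primer_gives_none(self, ligated, toy_rt_primer):
        assert simulate_pcr(ligated, Oligo("x", dna("GGGGGGGGGG")),
                            toy_rt_primer) is None

    def test_nested_amplicon_is_substring_of_outer(self, ligated,
                                                   toy_rt_primer):
        outer = simulate_pcr(ligated, reference.ADAPTOR_PRIMER, toy_rt_primer)
        nested = simulate_pcr(
            reverse_complement(outer.sense), reference.ADAPTOR_NESTED_PRIMER,
            toy_rt_primer,
        )
        assert nested is not None
        assert nested.length < outer.length
        assert nested.sense.letters in outer.sense.letters

    def test_infer_psi_recovers_planted_site(self, ligated, toy_rt_primer,
                                             adaptor, toy_transcript):
        amp = simulate_pcr(ligated, reference.ADAPTOR_PRIMER, toy_rt_primer)
        assert infer_psi(amp, adaptor, toy_transcript) == 7

    def test_amplicon_without_adaptor_prefix_unmappable(self, adaptor,
                                                        toy_transcript):
        from psibridge.simulate import Amplicon
        amp = Amplicon(dna("AAAACCCCGGGG"), (1, 4), (9, 12))
        with pytest.raises(InferenceError, match="unmappable"):
            infer_psi(amp, adaptor, toy_transcript)

    def test_multi_mapping_segment_is_ambiguous(self, adaptor):
        from psibridge.simulate import Amplicon
        rc = reverse_complement(adaptor.core).letters
        amp = Amplicon(dna(rc + "AT"), (1, 10), (len(rc) - 3, len(rc) + 2))
        with pytest.raises(InferenceError, match="ambiguous"):
            infer_psi(amp, adaptor, rna("AUAUAUAU"))


class TestBlockingOligoProtection:
    def test_fragment_false_positive_without_blocker(self,
                                                     phosphorylated_adaptor):
        # transcript engineered so the fragment starting at 13 begins with
        # the same 4-nt context as the psi-7 site: an unblocked run-off
        # cDNA from the fragment end is indistinguishable from a Psi stop
        t_seq = rna("GGGAUUUCCAUGCCAUGGAGCAUCC")
        rt_primer = Oligo("rt", reverse_complement(dna("GAGCATCC")))
        bridge = design_bridging_oligo(
            phosphorylated_adaptor, t_seq, PsiSite("eng", 7),
            DesignParams(10, 4),
        )
        broken = TranscriptWithPsi("eng", t_seq, frozenset({7}),
                                   fragments=(13,))
        cdna = simulate_rt(broken, rt_primer, cmc_treated=True)
        assert cdna.stop_cause is StopCause.FRAGMENT_END
        result = simulate_splint_ligation(
            cdna, phosphorylated_adaptor, bridge, 10, 4
        )
        assert result.success  # the artefact the blocking oligo prevents

    def test_blocker_prevents_fragment_ligation(self, phosphorylated_adaptor):
        t_seq = rna("GGGAUUUCCAUGCCAUGGAGCAUCC")
        rt_primer = Oligo("rt", reverse_complement(dna("GAGCATCC")))
        bridge = design_bridging_oligo(
            phosphorylated_adaptor, t_seq, PsiSite("eng", 7),
            DesignParams(10, 4),
        )
        blocked = TranscriptWithPsi("eng", t_seq, frozenset({7}),
                                    fragments=(13,), blocking_ligated=True)
        cdna = simulate_rt(blocked, rt_primer, cmc_treated=True)
        assert cdna.dna.letters.endswith("TGGGT")  # read into the blocker
        result = simulate_splint_ligation(
            cdna, phosphorylated_adaptor, bridge, 10, 4
        )
        assert not result.success
        assert result.reason == "cDNA-side mismatch"

    def test_no_fragment_cdna_ligates_across_seeded_trials(
        self, phosphorylated_adaptor
    ):
        # breakpoint injected between psi and the RT window, blocker on
        ligations = 0
        for i in range(100):
            fixture = generate_synthetic_transcript(seed=7_000 + i)
            t = fixture.transcript
            psi = min(t.psis)
            bridge = design_bridging_oligo(
                phosphorylated_adaptor, t.rna, PsiSite(t.id, psi),
                DesignParams(10, 10),
            )
            breakpoint_ = min(psi + 5 + (i % 20),
                              fixture.rt_segment[0] - 1)
            broken = dataclasses.replace(
                t, fragments=(breakpoint_,), blocking_ligated=True
            )
            cdna = simulate_rt(broken, fixture.rt_primer, cmc_treated=True)
            assert cdna.stop_cause is not StopCause.PSI_ADDUCT
            if simulate_splint_ligation(
                cdna, phosphorylated_adaptor, bridge, 10, 10
            ).success:
                ligations += 1
        assert ligations == 0


class TestSyntheticGenerator:
    def test_deterministic_for_seed(self):
        a = generate_synthetic_transcript(200, 0.5, 3, seed=1)
        b = generate_synthetic_transcript(200, 0.5, 3, seed=1)
        assert a.transcript == b.transcript
        assert a.rt_primer == b.rt_primer

    def test_different_seeds_differ(self):
        a = generate_synthetic_transcript(seed=1)
        b = generate_synthetic_transcript(seed=2)
        assert a.transcript.rna != b.transcript.rna

    def test_psis_index_uridines_and_are_separated(self):
        fixture = generate_synthetic_transcript(300, 0.5, 4, seed=11)
        psis = sorted(fixture.transcript.psis)
        assert all(fixture.transcript.rna.base(p) == "U" for p in psis)
        assert all(b - a >= 5 for a, b in zip(psis, psis[1:]))

    def test_psis_clear_of_rt_window(self):
        fixture = generate_synthetic_transcript(200, 0.5, 3, seed=4, m=10)
        rt_start = fixture.rt_segment[0]
        assert all(p + 10 < rt_start for p in fixture.transcript.psis)

    def test_rt_primer_validates_in_layout(self):
        for seed in range(5):
            fixture = generate_synthetic_transcript(seed=seed)
            psi = PsiSite(fixture.transcript.id, min(fixture.transcript.psis))
            gene = [fixture.nested_primer] if fixture.nested_primer else []
            report = validate_primer_layout(
                fixture.transcript.rna, psi, fixture.rt_primer, gene
            )
            assert report.passed

    def test_too_short_rejected(self):
        with pytest.raises(SimulationError):
            generate_synthetic_transcript(length=20)

    def test_unsatisfiable_constraints_suggest_parameters(self):
        with pytest.raises(SimulationError, match="longer transcript"):
            generate_synthetic_transcript(length=60, gc_fraction=0.97,
                                          n_psi=6, seed=0)


class TestRoundtrip:
    def test_small_run_recovers_everything(self):
        report = roundtrip(seed=42, n_transcripts=20)
        assert report.n == 20
        assert report.n_recovered == 20
        assert report.n_minus_cmc_amplicons == 0
        assert report.failures == ()

    def test_multi_psi_transcripts(self):
        report = roundtrip(
            seed=3, n_transcripts=5,
            params=RoundtripParams(length=300, n_psi=3),
        )
        assert report.n == 15
        assert report.n_recovered == 15

    def test_short_splint_never_reports_wrong_position(self):
        # m=2 halves are unavoidably non-unique; every non-recovered site
        # must surface as an explicit failure, never a wrong inference
        # counted as recovered
        report = roundtrip(
            seed=9, n_transcripts=10,
            params=RoundtripParams(design=DesignParams(10, 2)),
        )
        assert report.n == 10
        assert report.n_recovered + len(report.failures) >= report.n
        for failure in report.failures:
            assert failure.stage in (
                "generate", "ligation", "pcr", "nested_pcr", "inference",
                "error",
            )

    def test_design_simulation_consistency_property(self,
                                                    phosphorylated_adaptor):
        # revcomp(rna_side) always equals the +CMC cDNA 3'-terminal m nt
        for seed in range(10):
            fixture = generate_synthetic_transcript(seed=100 + seed)
            t = fixture.transcript
            psi = min(t.psis)
            bridge = design_bridging_oligo(
                phosphorylated_adaptor, t.rna, PsiSite(t.id, psi),
                DesignParams(10, 10),
            )
            cdna = simulate_rt(t, fixture.rt_primer, True)
            assert cdna.dna.letters[-10:] == \
                reverse_complement(bridge.rna_side).letters

    def test_psi_specificity_across_sites(self, phosphorylated_adaptor):
        # a bridge designed for one psi rejects cDNAs stopped at another
        fixture = generate_synthetic_transcript(300, 0.5, 3, seed=77)
        t = fixture.transcript
        psis = sorted(t.psis)
        bridges = {
            p: design_bridging_oligo(
                phosphorylated_adaptor, t.rna, PsiSite(t.id, p),
                DesignParams(10, 10),
            )
            for p in psis
        }
        for stopped_at in psis:
            mono = dataclasses.replace(t, psis=frozenset({stopped_at}))
            cdna = simulate_rt(mono, fixture.rt_primer, True)
            for target, bridge in bridges.items():
                ok = simulate_splint_ligation(
                    cdna, phosphorylated_adaptor, bridge, 10, 10
                ).success
                assert ok == (target == stopped_at)
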