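"""Peak binning, allele inference rules, genotype assembly and QC."""

import itertools

import numpy as np
import pytest

import cherryplex as cp
from cherryplex.panel import DyeChannel

B, G, Y, R = DyeChannel.B, DyeChannel.G, DyeChannel.Y, DyeChannel.R


def run_of(*peaks, sample_id="t"):
    return cp.SampleRun(sample_id, [cp.Peak(ch, s, h) for ch, s, h in peaks])


def calls_of(run, panel):
    matches, _, _ = cp.bin_peaks(run, panel)
    return cp.infer_alleles(matches, panel)


def status_map(calls):
    return {c.allele: c.status for c in calls}


class TestBinPeaks:
    def test_nearest_bin_with_deviation(self, panel):
        run = run_of((B, 226.8, 900))
        matches, unassigned, ambiguous = cp.bin_peaks(run, panel)
        assert unassigned == [] and ambiguous == []
        (m,) = matches
        assert m.fragment.id == "B227"
        assert m.deviation == pytest.approx(-0.2)

    def test_one_nt_bins_resolved_at_default_tolerance(self, panel):
        """384.4 belongs to the S5' 384 bin, never the S5 385 bin."""
        matches, _, _ = cp.bin_peaks(run_of((B, 384.4, 500)), panel, 0.45)
        assert [m.fragment.id for m in matches] == ["B384"]

    def test_s5_s5p_mixture_two_matches(self, panel):
        matches, _, _ = cp.bin_peaks(
            run_of((B, 384.4, 500), (B, 385.1, 480)), panel)
        assert {m.fragment.id for m in matches} == {"B384", "B385"}

    def test_far_peak_unassigned(self, panel):
        _, unassigned, _ = cp.bin_peaks(run_of((B, 300.0, 500)), panel)
        assert len(unassigned) == 1

    def test_tallest_wins_shoulders_kept(self, panel):
        """A +1 nt double-peak artifact must not displace the main peak."""
        matches, _, _ = cp.bin_peaks(
            run_of((B, 227.0, 1000), (B, 227.3, 600)), panel)
        (m,) = matches
        assert m.peak.height == 1000
        assert [p.height for p in m.shoulders] == [600]

    @pytest.mark.parametrize("tol", [0.0, -1.0, 0.5, 2.0])
    def test_tolerance_precondition(self, panel, tol):
        with pytest.raises(ValueError, match="tolerance"):
            cp.bin_peaks(run_of((B, 227.0, 100)), panel, tol)

    def test_brute_force_oracle_equivalence(self, panel):
        rng = np.random.default_rng(42)
        channels = list(DyeChannel)
        bins = {ch: [(f.id, f.observed_size)
                     for f in panel.channel_fragments(ch)]
                for ch in channels}
        tol = panel.bin_tolerance_default
        peaks = [cp.Peak(channels[rng.integers(4)],
                         float(rng.uniform(50, 500)),
                         float(rng.uniform(10, 5000)))
                 for _ in range(1000)]
        run = cp.SampleRun("rand", peaks)
        matches, unassigned, ambiguous = cp.bin_peaks(run, panel)
        got = {}
        for m in matches:
            for p in [m.peak, *m.shoulders]:
                got[id(p)] = m.fragment.id
        for p in unassigned + ambiguous:
            got[id(p)] = None
        for p in peaks:
            within = [(abs(p.size - s), fid) for fid, s in bins[p.channel]
                      if abs(p.size - s) <= tol]
            expect = min(within)[1] if len(within) == 1 else None
            assert got[id(p)] == expect

    def test_determinism(self, panel, zero_noise):
        run = cp.simulate_run(("S1", "S4p"), ("MGSTwt",) * 2, zero_noise,
                              panel)
        c1 = cp.call_sample(run, panel)
        c2 = cp.call_sample(run, panel)
        assert c1.to_dict() == c2.to_dict()


class TestInferAlleles:
    def test_s3_both_fragments_confirmed(self, panel):
        calls = calls_of(run_of((B, 122.0, 800), (B, 227.0, 900)), panel)
        assert status_map(calls)["S3"] == "confirmed"
        assert "S3p" not in status_map(calls)

    def test_s3p_from_lone_227(self, panel):
        calls = calls_of(run_of((B, 227.0, 900)), panel)
        assert status_map(calls) == {"S3p": "candidate"}

    def test_s4p_confirmed(self, panel):
        calls = calls_of(run_of((B, 443.0, 700), (B, 177.0, 800)), panel)
        assert status_map(calls)["S4p"] == "confirmed"

    def test_s4_s4p_heterozygote(self, panel):
        calls = calls_of(
            run_of((B, 443.0, 700), (B, 177.0, 800), (B, 181.0, 750)), panel)
        sm = status_map(calls)
        assert sm["S4"] == "confirmed" and sm["S4p"] == "confirmed"

    def test_s1_without_confirmation_unconfirmed(self, panel):
        calls = calls_of(run_of((B, 373.0, 900)), panel)
        assert status_map(calls)["S1"] == "unconfirmed"

    def test_s5p_candidate(self, panel):
        calls = calls_of(run_of((B, 384.0, 600)), panel)
        assert status_map(calls)["S5p"] == "candidate"

    def test_s5_requires_sfb(self, panel):
        sm = status_map(calls_of(run_of((B, 385.0, 600), (B, 83.0, 700)),
                                 panel))
        assert sm["S5"] == "confirmed"
        sm = status_map(calls_of(run_of((B, 385.0, 600)), panel))
        assert sm["S5"] == "unconfirmed"

    def test_r_only_alleles(self, panel):
        sm = status_map(calls_of(run_of((R, 119.0, 500), (R, 172.0, 600)),
                                 panel))
        assert sm == {"S13": "confirmed", "S54": "confirmed"}

    def test_shared_r223_explained_by_confirmed_s6(self, panel):
        """S6's confirmation fragment must not conjure a spurious S24."""
        calls = calls_of(run_of((B, 435.0, 700), (R, 223.0, 650)), panel)
        assert status_map(calls) == {"S6": "confirmed"}

    def test_shared_r223_alone_is_ambiguous(self, panel):
        sm = status_map(calls_of(run_of((R, 223.0, 650)), panel))
        assert sm == {"S6": "ambiguous", "S24": "ambiguous"}

    def test_s24_via_provisional_bin(self, panel):
        sm = status_map(calls_of(run_of((B, 416.0, 700), (R, 223.0, 650)),
                                 panel))
        assert sm == {"S24": "confirmed"}

    def test_s22_vs_s24_separated(self, panel):
        sm = status_map(calls_of(
            run_of((B, 415.0, 700), (R, 258.0, 600),
                   (B, 416.0, 650), (R, 223.0, 550)), panel))
        assert sm["S22"] == "confirmed" and sm["S24"] == "confirmed"


HALKA = [(B, 373.0, 900), (R, 240.0, 850), (B, 177.0, 800),
         (B, 443.0, 700), (G, 140.0, 950), (Y, 118.0, 1000)]


class TestAssembleGenotype:
    def test_halka_worked_example(self, panel):
        call = cp.call_sample(run_of(*HALKA, sample_id="Halka"), panel)
        assert call.s_genotype == ("S1", "S4p")
        assert call.mgst_genotype == ("MGSTwt",)
        assert call.sc_interpretation == "self_compatible"
        assert call.qc == []

    def test_missing_control_flags_and_disables_dosage(self, panel):
        peaks = [p for p in HALKA if p[0] != Y]
        call = cp.call_sample(run_of(*peaks), panel)
        assert "NO_CONTROL" in call.qc_codes()
        assert call.s_genotype == ("S1", "S4p")
        assert call.dosage is None

    def test_lone_s3_invokes_dosage(self, panel, zero_noise):
        run = cp.simulate_run(("S3", "S3p"), ("MGSTwt",) * 2, zero_noise,
                              panel)
        call = cp.call_sample(run, panel)
        assert call.dosage is not None
        assert call.dosage.decision == "homozygous_sc"
        assert call.s_genotype == ("S3", "S3p")

    def test_lone_unresolvable_allele_pairs_with_placeholder(self, panel):
        call = cp.call_sample(
            run_of((B, 373.0, 900), (R, 240.0, 850), (Y, 118.0, 1000)),
            panel)
        assert call.s_genotype == ("S1", "S?")
        assert "ONE_S_ALLELE" in call.qc_codes()
        assert call.sc_interpretation == "undetermined"

    def test_mgstins_without_sc_allele_is_partial(self, panel, zero_noise):
        run = cp.simulate_run(("S1", "S2"), ("MGSTwt", "MGSTins"), zero_noise,
                              panel)
        call = cp.call_sample(run, panel)
        assert call.sc_interpretation == "partial_sc_associated"
        assert set(call.mgst_genotype) == {"MGSTwt", "MGSTins"}

    def test_three_alleles_flagged(self, panel, zero_noise):
        a = cp.simulate_run(("S1", "S2"), ("MGSTwt",) * 2, zero_noise, panel)
        b = cp.simulate_run(("S6", "S7"), ("MGSTwt",) * 2, zero_noise, panel)
        call = cp.call_sample(cp.SampleRun("mix", a.peaks + b.peaks), panel)
        assert "TOO_MANY_S_ALLELES" in call.qc_codes()

    def test_mgst_dosage_zygosity(self, panel, zero_noise):
        run = cp.simulate_run(("S1", "S2"), ("MGSTwt", "MGSTwt"), zero_noise,
                              panel)
        call = cp.call_sample(run, panel, mgst_dosage=True)
        assert call.mgst_genotype == ("MGSTwt", "MGSTwt")
        assert call.mgst_zygosity == "hom"


class TestQC:
    def test_clean_run_no_flags(self, panel, zero_noise):
        run = cp.simulate_run(("S1", "S9"), ("MGSTwt",) * 2, zero_noise,
                              panel)
        assert cp.call_sample(run, panel).qc == []

    def test_control_low(self, panel):
        peaks = [p for p in HALKA if p[0] != Y] + [(Y, 118.0, 40.0)]
        call = cp.call_sample(run_of(*peaks), panel, min_height=10,
                              control_floor=100)
        assert "CONTROL_LOW" in call.qc_codes()

    def test_stray_peak_flagged(self, panel):
        call = cp.call_sample(run_of(*HALKA, (B, 300.0, 500)), panel)
        assert "UNASSIGNED_PEAKS" in call.qc_codes()

    def test_noise_floor_suppresses_tiny_peaks(self, panel):
        call = cp.call_sample(run_of(*HALKA, (B, 300.0, 20)), panel,
                              min_height=50)
        assert "UNASSIGNED_PEAKS" not in call.qc_codes()

    def test_unconfirmed_flagged(self, panel):
        call = cp.call_sample(
            run_of((B, 373.0, 900), (B, 337.0, 800), (R, 302.0, 700),
                   (Y, 118.0, 1000)), panel)
        assert call.s_genotype == ("S1", "S2")
        assert "UNCONFIRMED_ALLELE" in call.qc_codes()

    def test_provisional_bin_flagged(self, panel, zero_noise):
        run = cp.simulate_run(("S10", "S1"), ("MGSTwt",) * 2, zero_noise,
                              panel)
        call = cp.call_sample(run, panel)
        assert "PROVISIONAL_BIN" in call.qc_codes()
        assert call.s_genotype == ("S1", "S10")

    def test_qc_checks_recompute(self, panel):
        run = run_of(*HALKA, (B, 300.0, 500))
        call = cp.call_sample(run, panel)
        flags = cp.qc_checks(run, call, panel)
        assert {f.code for f in flags} == call.qc_codes()


SUPPORTED = ["S1", "S2", "S3", "S3p", "S4", "S4p", "S5", "S5p", "S6", "S7",
             "S9", "S12", "S13", "S14/S23", "S16", "S21/S25", "S22", "S54"]


@pytest.mark.parametrize("pair", [
    ("S1", "S4p"), ("S3", "S3p"), ("S4", "S4p"), ("S5", "S5p"),
    ("S3p", "S5p"), ("S9", "S22"), ("S13", "S54"), ("S14/S23", "S21/S25"),
])
def test_zero_noise_round_trip_sampled_pairs(panel, zero_noise, pair):
    """Simulate -> call identity on representative pairs (the exhaustive
    153-pair sweep runs in the acceptance suite)."""
    for mgst in [("MGSTwt", "MGSTwt"), ("MGSTins", "MGSTdel")]:
        run = cp.simulate_run(pair, mgst, zero_noise, panel)
        call = cp.call_sample(run, panel)
        assert call.s_genotype == cp.order_pair(*pair)
        assert set(call.mgst_genotype) == set(mgst)
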