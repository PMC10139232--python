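"""Binding-site search, amplicon prediction, and the mismatch report."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from Bio.Seq import Seq

import cherryplex as cp
from cherryplex.panel import DyeChannel, PrimerSpec

CTTC = "CTTGTTCTTGCTTTTGCTTTCTTC"   # PaConsI-CTTC-F
GTTC = "CTTGTTCTTGGTTTTGCTTTCTTC"   # PaConsI-GTTC-F
R2 = "GCCATTGTTGCACAAATTGA"         # PaConsI-R2 (FAM)


def primer(name, seq, label=None):
    return PrimerSpec(name=name, sequence=seq, label=label,
                      final_concentration=0.2)


def template(seq, tid="tpl"):
    return cp.TemplateSeq(tid, seq)


def rc(s):
    return str(Seq(s).reverse_complement())


class TestFindBindingSites:
    def test_exact_forward_site(self):
        tpl = template("AAAA" + GTTC + "GGGG")
        sites = cp.find_binding_sites(primer("GTTC-F", GTTC), tpl)
        (s,) = [x for x in sites if x.strand == "forward"]
        assert (s.start, s.end, s.mismatches) == (4, 4 + len(GTTC), 0)

    def test_cttc_vs_gttc_site_one_mismatch_at_11(self):
        """The two primer variants differ at position 11 only."""
        tpl = template("AT" + GTTC + "CG")
        sites = cp.find_binding_sites(primer("CTTC-F", CTTC), tpl,
                                      max_mismatches=2, protect_3prime=3)
        fwd = [s for s in sites if s.strand == "forward"]
        assert len(fwd) == 1
        assert fwd[0].mismatches == 1
        assert fwd[0].mismatch_positions == (11,)

    def test_iupac_y_matches_c_and_t(self):
        p = primer("ExR", "GTATCATTGCCACYTTCCACG")
        for base in "CT":
            site_seq = p.sequence.replace("Y", base)
            sites = cp.find_binding_sites(p, template("AA" + site_seq + "AA"))
            assert any(s.strand == "forward" and s.mismatches == 0
                       for s in sites)

    def test_template_n_matches_nothing(self):
        tpl = template("AAAA" + GTTC[:10] + "N" + GTTC[11:] + "GGGG")
        sites = cp.find_binding_sites(primer("GTTC-F", GTTC), tpl,
                                      max_mismatches=0)
        assert sites == []

    def test_protected_3prime_window(self):
        """A mismatch in the 3'-terminal window kills the site even when the
        total count is within budget (the S5/S5' discrimination trick)."""
        mutated = GTTC[:-1] + ("A" if GTTC[-1] != "A" else "G")
        tpl = template("AAAA" + mutated + "GGGG")
        assert cp.find_binding_sites(primer("GTTC-F", GTTC), tpl,
                                     max_mismatches=2, protect_3prime=3) == []
        hits = cp.find_binding_sites(primer("GTTC-F", GTTC), tpl,
                                     max_mismatches=2, protect_3prime=0)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_reverse_strand_site(self):
        tpl = template("AAAA" + rc(R2) + "GGGG")
        sites = cp.find_binding_sites(primer("R2", R2), tpl)
        (s,) = sites
        assert s.strand == "reverse"
        assert (s.start, s.end) == (4, 4 + len(R2))

    def test_primer_longer_than_template(self):
        assert cp.find_binding_sites(primer("GTTC-F", GTTC),
                                     template("ACGT")) == []

    def test_naive_oracle_equivalence(self):
        """Bitmask scan agrees with a per-offset character comparison."""
        iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG",
                 "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
                 "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN"}

        def naive(pseq, tseq, maxmm, prot):
            out = []
            L = len(pseq)
            for variant, strand in ((pseq, "forward"), (rc(pseq), "reverse")):
                for off in range(len(tseq) - L + 1):
                    mm = [i for i in range(L)
                          if tseq[off + i] not in iupac[variant[i]]]
                    if strand == "forward":
                        pos = [i + 1 for i in mm]
                        protected = any(i >= L - prot for i in mm)
                    else:
                        pos = sorted(L - i for i in mm)
                        protected = any(i < prot for i in mm)
                    if len(mm) <= maxmm and not protected:
                        out.append((strand, off, off + L, len(mm),
                                    tuple(pos)))
            return sorted(out)

        rng = np.random.default_rng(5)
        primers = [primer("GTTC-F", GTTC), primer("CTTC-F", CTTC),
                   primer("ExR", "GTATCATTGCCACYTTCCACG")]
        for trial in range(8):
            tseq = "".join(rng.choice(list("ACGTN"), size=400,
                                      p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            # embed a real site sometimes
            if trial % 2 == 0:
                tseq = tseq[:100] + GTTC + tseq[100 + len(GTTC):]
            tpl = template(tseq, f"t{trial}")
            for p in primers:
                got = sorted((s.strand, s.start, s.end, s.mismatches,
                              s.mismatch_positions)
                             for s in cp.find_binding_sites(p, tpl, 2, 3))
                assert got == naive(p.sequence, tseq, 2, 3)

    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        """Reverse-complementing the template mirrors every site."""
        rng = np.random.default_rng(seed)
        tseq = "".join(rng.choice(list("ACGT"), size=120))
        tseq = tseq[:40] + GTTC + tseq[40 + len(GTTC):]
        p = primer("GTTC-F", GTTC)
        tpl = template(tseq)
        mirror = template(rc(tseq))
        n = len(tseq)
        fwd = {(s.start, s.end, s.strand, s.mismatches)
               for s in cp.find_binding_sites(p, tpl, 2, 3)}
        rev = {(n - s.end, n - s.start,
                "forward" if s.strand == "reverse" else "reverse",
                s.mismatches)
               for s in cp.find_binding_sites(p, mirror, 2, 3)}
        assert fwd == rev


class TestPredictAmplicons:
    def _template_343(self):
        """Forward CTTC site + spacer + reverse-complemented R2 site so the
        span is exactly 343 nt (the S2 expected length)."""
        spacer = "A" * (343 - len(CTTC) - len(R2))
        return template("GG" + CTTC + spacer + rc(R2) + "TT")

    def test_constructed_343_amplicon_channel_b(self):
        prs = [primer("CTTC-F", CTTC), primer("R2", R2, DyeChannel.B)]
        amps = cp.predict_amplicons(prs, self._template_343(), max_len=600)
        (a,) = amps
        assert a.length == 343
        assert a.channel == DyeChannel.B
        assert a.fwd.primer.name == "CTTC-F"

    def test_no_reverse_site_no_amplicons(self):
        tpl = template("GG" + CTTC + "A" * 50)
        prs = [primer("CTTC-F", CTTC), primer("R2", R2, DyeChannel.B)]
        assert cp.predict_amplicons(prs, tpl) == []

    def test_two_forward_sites_share_one_reverse(self):
        spacer = "C" * 30
        tpl = template(CTTC + spacer + CTTC + spacer + rc(R2))
        prs = [primer("CTTC-F", CTTC), primer("R2", R2, DyeChannel.B)]
        amps = cp.predict_amplicons(prs, tpl, max_len=500)
        assert len(amps) == 2
        assert amps[0].fwd.start < amps[1].fwd.start

    def test_max_len_excludes_long_products(self):
        amps = cp.predict_amplicons(
            [primer("CTTC-F", CTTC), primer("R2", R2, DyeChannel.B)],
            self._template_343(), max_len=300)
        assert amps == []

    def test_default_panel_multiplex_on_constructed_template(self, panel):
        amps = cp.predict_amplicons(panel.primers, self._template_343(),
                                    max_len=600)
        assert any(a.length == 343 and a.channel == DyeChannel.B
                   for a in amps)


class TestBindingReport:
    def test_diagonal_of_zeros_for_variant_primers(self, panel):
        variants = {
            "PaConsI-CTTC-F": CTTC,
            "PaConsI-GTTC-F": GTTC,
            "PaConsI-CTCC-F": "CTTGTTCTTGCTTTCGCTTTCTTC",
            "PaConsI-CTTT-F": "CTTGTTCTTGCTTTTGTTTTCTTC",
            "PaConsI-CGTC-F": "CTTGTTCTTGCTTGTGCTTTCTTC",
        }
        primers = [p for p in panel.primers if p.name in variants]
        templates = [template("AAAA" + seq + "GGGG", tid=name)
                     for name, seq in variants.items()]
        df = cp.binding_report(primers, templates, max_mismatches=0)
        for p in primers:
            row = df[(df.primer == p.name) & (df.template == p.name)]
            assert row.best_mismatches.item() == 0

    def test_no_site_flag(self):
        df = cp.binding_report([primer("GTTC-F", GTTC)],
                               [template("A" * 60, "empty")])
        assert df.no_site.item()

    def test_minus_strand_reported(self):
        df = cp.binding_report([primer("GTTC-F", GTTC)],
                               [template("TT" + rc(GTTC) + "AA", "minus")])
        assert df.strand.item() == "reverse"
        assert df.best_mismatches.item() == 0


def test_read_templates_fasta(tmp_path):
    fa = tmp_path / "t.fa"
    fa.write_text(">s1\nACGTACGT\n>s2\nGGGGCCCC\n")
    templates = cp.read_templates(fa)
    assert [t.id for t in templates] == ["s1", "s2"]
    assert templates[1].sequence == "GGGGCCCC"


def test_template_alphabet_checked():
    with pytest.raises(ValueError):
        cp.TemplateSeq("bad", "ACGU")
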