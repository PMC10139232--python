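"""Genotype calling from binned peaks.

The pipeline is: bin peaks to panel fragments (nearest same-channel bin
within tolerance), infer allele presence with the assay's interpretation
rules, then assemble a two-S-allele + MGST genotype with QC flags.

The interpretation rules mirror the assay design:

* S3 family: both the 227-nt S-RNase and 122-nt SFB fragments -> S3;
  the 227-nt fragment alone -> S3' (the SFB region is deleted in S3').
  Because a failed SFB amplification is indistinguishable from the S3'
  deletion, a lone 227-nt call is only ever a *candidate*.
* S4 family: 443-nt S-RNase with the 181-nt SFB fragment -> S4, with the
  177-nt fragment (4-nt SFB deletion) -> S4', with both -> S4 + S4'.
* S5 family: 385-nt S-RNase corroborated by the 83-nt wild-type SFB
  fragment -> S5; the 384-nt fragment alone -> S5' (the inactivating point
  mutation abolishes the SFB amplicon).
* S1, S2, S6, S7, S9, S12, S22, S24 require both their universal blue
  fragment and their red allele-specific confirmation fragment to be
  *confirmed*; one of the two alone yields *unconfirmed*.  S6 and S24 share
  one red confirmation bin (223 nt) and are separated by their blue
  fragments (435 nt vs the provisional 416-nt bin).
* S13 and S54 escape the universal primers and are called from their single
  red fragments.
* Remaining single-fragment alleles (S14/S23, S16, S21/S25 and the
  provisional bins) are *candidates*.

Exactly two S-alleles are expected per sample.  A lone S3, S3', S4' or S5'
triggers the quantitative dosage classification; any other lone allele is
paired with the ``S?`` placeholder and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from . import dosage as _dosage
from .panel import (
    DosageScenario,
    DyeChannel,
    FragmentDef,
    FragmentRole,
    Panel,
    allele_sort_key,
    display_allele,
    order_pair,
)
from .peaks_io import Peak, SampleRun


@dataclass
class FragmentMatch:
    """A peak assigned to a fragment bin."""

    peak: Peak
    fragment: FragmentDef
    deviation: float                      # peak size − bin observed size
    shoulders: list[Peak] = field(default_factory=list)


class BinningResult(NamedTuple):
    matches: list[FragmentMatch]
    unassigned: list[Peak]
    ambiguous: list[Peak]                 # within tolerance of two bins


@dataclass
class AlleleCall:
    allele: str
    status: str                           # confirmed|candidate|unconfirmed|ambiguous
    evidence: list[FragmentMatch] = field(default_factory=list)
    notes: str = ""


@dataclass(frozen=True)
class QCFlag:
    code: str
    detail: str = ""


@dataclass
class GenotypeCall:
    """The assembled per-sample result."""

    sample_id: str
    s_genotype: tuple[str, str]
    mgst_genotype: tuple[str, ...]
    mgst_zygosity: str                    # het|undetermined|hom|none
    sc_interpretation: str
    qc: list[QCFlag] = field(default_factory=list)
    dosage: Optional[_dosage.DosageDecision] = None
    allele_calls: list[AlleleCall] = field(default_factory=list)

    def qc_codes(self) -> set[str]:
        return {f.code for f in self.qc}

    def to_row(self) -> dict:
        """Flat TSV-friendly summary."""
        return {
            "sample": self.sample_id,
            "S_allele_1": display_allele(self.s_genotype[0]),
            "S_allele_2": display_allele(self.s_genotype[1]),
            "MGST": "/".join(self.mgst_genotype) if self.mgst_genotype else ".",
            "sc_interpretation": self.sc_interpretation,
            "flags": ";".join(sorted(self.qc_codes())) or ".",
        }

    def to_dict(self) -> dict:
        """Full evidence report (JSON-serializable)."""
        return {
            "sample": self.sample_id,
            "s_genotype": [display_allele(a) for a in self.s_genotype],
            "mgst_genotype": list(self.mgst_genotype),
            "mgst_zygosity": self.mgst_zygosity,
            "sc_interpretation": self.sc_interpretation,
            "qc": [{"code": f.code, "detail": f.detail} for f in self.qc],
            "dosage": None if self.dosage is None else {
                "scenario": self.dosage.scenario.value,
                "ratios": self.dosage.ratios,
                "z_homo": self.dosage.z_homo,
                "z_het": self.dosage.z_het,
                "decision": self.dosage.decision,
                "resolved_genotype": [
                    display_allele(a) for a in self.dosage.resolved_genotype
                ],
                "notes": self.dosage.notes,
            },
            "allele_calls": [
                {
                    "allele": display_allele(c.allele),
                    "status": c.status,
                    "fragments": [m.fragment.id for m in c.evidence],
                    "notes": c.notes,
                }
                for c in self.allele_calls
            ],
        }


# ---------------------------------------------------------------------------
# peak binning


def bin_peaks(run: SampleRun, panel: Panel,
              tolerance: Optional[float] = None) -> BinningResult:
    """Assign each peak to the nearest same-channel bin within tolerance.

    Peaks equidistant-or-within-tolerance of two bins are never guessed
    (the S5/S5' bins differ by 1 nt); they are returned as ambiguous.  When
    several peaks land in one bin the tallest wins and the rest are kept as
    shoulder peaks on the match (absorbing double-peak PCR artifacts).
    """
    tol = panel.bin_tolerance_default if tolerance is None else tolerance
    min_sep = panel.min_channel_separation()
    if not (0 < tol < min_sep / 2):
        raise ValueError(
            f"tolerance must be in (0, {min_sep / 2}) for this panel, "
            f"got {tol}"
        )

    by_bin: dict[str, list[Peak]] = {}
    unassigned: list[Peak] = []
    ambiguous: list[Peak] = []
    for peak in run.peaks:
        hits = [
            f for f in panel.channel_fragments(peak.channel)
            if abs(peak.size - f.observed_size) <= tol
        ]
        if not hits:
            unassigned.append(peak)
        elif len(hits) > 1:
            ambiguous.append(peak)
        else:
            by_bin.setdefault(hits[0].id, []).append(peak)

    matches: list[FragmentMatch] = []
    for fid, peaks in by_bin.items():
        frag = panel.fragment(fid)
        peaks = sorted(peaks, key=lambda p: (-p.height, p.size))
        matches.append(FragmentMatch(
            peak=peaks[0],
            fragment=frag,
            deviation=peaks[0].size - frag.observed_size,
            shoulders=peaks[1:],
        ))
    matches.sort(key=lambda m: (m.fragment.channel.value,
                                m.fragment.observed_size))
    return BinningResult(matches, unassigned, ambiguous)


# ---------------------------------------------------------------------------
# allele inference

# confirm-required alleles: (universal blue fragment, red confirmation)
_CONFIRM_PAIRS: dict[str, tuple[str, str]] = {
    "S1": ("B373", "R240"),
    "S2": ("B337", "R302"),
    "S6": ("B435", "R223"),
    "S7": ("B339", "R249"),
    "S9": ("B350", "R266"),
    "S12": ("B338", "R147"),
    "S22": ("B415", "R258"),
    "S24": ("B416", "R223"),
}

_R_ONLY = {"S13": "R119", "S54": "R172"}

_S3_NOTE = ("S3 with failed SFB amplification is indistinguishable from S3'; "
            "verify the primer mix with a known S3 control")


def infer_alleles(matches: list[FragmentMatch], panel: Panel) -> list[AlleleCall]:
    """Apply the assay's interpretation rules to one sample's matches."""
    present: dict[str, FragmentMatch] = {m.fragment.id: m for m in matches}

    def has(fid: str) -> bool:
        return fid in present

    def ev(*fids: str) -> list[FragmentMatch]:
        return [present[f] for f in fids if f in present]

    calls: list[AlleleCall] = []
    explained: set[str] = set()

    # (a) control and MGST bins are assigned directly
    if has(panel.control_fragment_id):
        calls.append(AlleleCall("PaveIF-1A", "confirmed",
                                ev(panel.control_fragment_id)))
        explained.add(panel.control_fragment_id)
    for frag in panel.channel_fragments(DyeChannel.G):
        if has(frag.id):
            calls.append(AlleleCall(frag.alleles[0], "confirmed", ev(frag.id)))
            explained.add(frag.id)

    # (b) S3 rule
    if has("B122") and has("B227"):
        calls.append(AlleleCall("S3", "confirmed", ev("B122", "B227")))
        explained.update({"B122", "B227"})
    elif has("B227"):
        calls.append(AlleleCall("S3p", "candidate", ev("B227"), notes=_S3_NOTE))
        explained.add("B227")
    elif has("B122"):
        calls.append(AlleleCall("S3", "unconfirmed", ev("B122"),
                                notes="227-nt S-RNase fragment missing"))
        explained.add("B122")

    # (c) S4 rule
    if has("B443"):
        if has("B181"):
            calls.append(AlleleCall("S4", "confirmed", ev("B181", "B443")))
            explained.update({"B181", "B443"})
        if has("B177"):
            calls.append(AlleleCall("S4p", "confirmed", ev("B177", "B443")))
            explained.update({"B177", "B443"})
        if not has("B181") and not has("B177"):
            calls.append(AlleleCall(
                "S4", "ambiguous", ev("B443"),
                notes="443-nt S-RNase without an SFB marker: S4 vs S4' "
                      "undetermined"))
            explained.add("B443")
    else:
        if has("B181"):
            calls.append(AlleleCall("S4", "unconfirmed", ev("B181"),
                                    notes="443-nt S-RNase fragment missing"))
            explained.add("B181")
        if has("B177"):
            calls.append(AlleleCall("S4p", "unconfirmed", ev("B177"),
                                    notes="443-nt S-RNase fragment missing"))
            explained.add("B177")

    # (d) S5 rule
    if has("B385"):
        if has("B83"):
            calls.append(AlleleCall("S5", "confirmed", ev("B83", "B385")))
            explained.update({"B83", "B385"})
        else:
            calls.append(AlleleCall("S5", "unconfirmed", ev("B385"),
                                    notes="83-nt SFB fragment missing"))
            explained.add("B385")
    elif has("B83"):
        calls.append(AlleleCall("S5", "unconfirmed", ev("B83"),
                                notes="385-nt S-RNase fragment missing"))
        explained.add("B83")
    if has("B384"):
        calls.append(AlleleCall("S5p", "candidate", ev("B384"),
                                notes="wild-type S5 SFB fragment absent, as "
                                      "expected for S5'"))
        explained.add("B384")

    # (e) confirm-required alleles: universal blue + specific red
    for allele, (b, r) in _CONFIRM_PAIRS.items():
        if has(b) and has(r):
            calls.append(AlleleCall(allele, "confirmed", ev(b, r)))
            explained.update({b, r})
        elif has(b):
            calls.append(AlleleCall(
                allele, "unconfirmed", ev(b),
                notes=f"specific confirmation fragment {r} missing"))
            explained.add(b)
    # red confirmation fragments without their blue partner
    for allele, (b, r) in _CONFIRM_PAIRS.items():
        if has(r) and not has(b) and r not in explained:
            shared = [a for a, (_, rr) in _CONFIRM_PAIRS.items() if rr == r]
            if len(shared) > 1:
                for a in shared:
                    calls.append(AlleleCall(
                        a, "ambiguous", ev(r),
                        notes=f"shared confirmation fragment {r} only; "
                              f"cannot separate {'/'.join(shared)}"))
            else:
                calls.append(AlleleCall(
                    allele, "unconfirmed", ev(r),
                    notes=f"universal fragment {b} missing"))
            explained.add(r)

    # (f) alleles escaping the universal primers: single red fragment
    for allele, r in _R_ONLY.items():
        if has(r):
            calls.append(AlleleCall(allele, "confirmed", ev(r)))
            explained.add(r)

    # (g) remaining single-fragment universal bins -> candidates
    for m in matches:
        frag = m.fragment
        if frag.id in explained or frag.role != FragmentRole.UNIVERSAL_SRNASE:
            continue
        note = "provisional bin (observed size never measured)" \
            if frag.provisional else ""
        for allele in frag.alleles:
            calls.append(AlleleCall(allele, "candidate", [m], notes=note))
        explained.add(frag.id)

    calls.sort(key=lambda c: allele_sort_key(c.allele))
    return calls


# ---------------------------------------------------------------------------
# genotype assembly + QC

_DOSAGE_TRIGGERS = {
    "S3": DosageScenario.S3_only,
    "S3p": DosageScenario.S3p_only,
    "S4p": DosageScenario.S4p_only,
    "S5p": DosageScenario.S5p_only,
}

_MGST_DIPLOID_RATIO = 1.12   # G140/Y118 in MGSTwt homozygotes (calibrated)


def _is_s_allele(label: str) -> bool:
    return label.startswith("S") and label != "S?"


def assemble_genotype(
    allele_calls: list[AlleleCall],
    run: SampleRun,
    panel: Panel,
    tolerance: Optional[float] = None,
    min_height: float = 50.0,
    control_floor: float = 100.0,
    z_cut: float = 3.0,
    mgst_dosage: bool = False,
) -> GenotypeCall:
    """Combine allele calls into the final genotype with QC flags."""
    binres = bin_peaks(_filtered(run, min_height), panel, tolerance)
    matched_ids = {m.fragment.id for m in binres.matches}

    s_calls = [
        c for c in allele_calls
        if _is_s_allele(c.allele) and not c.allele.startswith("MGST")
        and c.allele != "PaveIF-1A"
        and c.status in ("confirmed", "candidate", "unconfirmed")
    ]
    qc: list[QCFlag] = []
    decision: Optional[_dosage.DosageDecision] = None

    control_ok = panel.control_fragment_id in matched_ids
    control_match = next(
        (m for m in binres.matches
         if m.fragment.id == panel.control_fragment_id), None)
    if control_match is None:
        qc.append(QCFlag("NO_CONTROL",
                         "PaveIF-1A control fragment not detected; dosage "
                         "normalization disabled"))
    elif control_match.peak.height < control_floor:
        qc.append(QCFlag("CONTROL_LOW",
                         f"control height {control_match.peak.height:.0f} RFU "
                         f"below floor {control_floor:.0f}"))

    alleles = [c.allele for c in s_calls]
    if len(alleles) == 2:
        s_genotype = order_pair(*alleles)
    elif len(alleles) == 1:
        lone = alleles[0]
        scenario = _DOSAGE_TRIGGERS.get(lone)
        if scenario is not None and control_ok:
            decision = _dosage.classify_single_allele_case(
                run=_filtered(run, min_height), scenario=scenario,
                panel=panel, z_cut=z_cut, tolerance=tolerance)
            s_genotype = order_pair(*decision.resolved_genotype) \
                if "S?" not in decision.resolved_genotype \
                else decision.resolved_genotype
        else:
            s_genotype = (lone, "S?")
    elif len(alleles) == 0:
        s_genotype = ("S?", "S?")
    else:
        qc.append(QCFlag(
            "TOO_MANY_S_ALLELES",
            "detected: " + ", ".join(display_allele(a) for a in
                                     sorted(alleles, key=allele_sort_key))))
        ordered = sorted(alleles, key=allele_sort_key)
        s_genotype = (ordered[0], ordered[1])

    if "S?" in s_genotype:
        qc.append(QCFlag("ONE_S_ALLELE",
                         "second S-allele undetected; two are always expected"))

    # MGST genotype from the green channel
    mgst_present = sorted(
        {c.allele for c in allele_calls if c.allele.startswith("MGST")})
    if len(mgst_present) >= 2:
        mgst_genotype = tuple(mgst_present[:2])
        mgst_zygosity = "het"
        if len(mgst_present) > 2:
            qc.append(QCFlag("TOO_MANY_S_ALLELES",
                             "more than two MGST alleles detected"))
    elif len(mgst_present) == 1:
        allele = mgst_present[0]
        if mgst_dosage and control_ok:
            frag_id = next(
                f.id for f in panel.channel_fragments(DyeChannel.G)
                if allele in f.alleles)
            ratio = _dosage.peak_ratio(_filtered(run, min_height), frag_id,
                                       panel.control_fragment_id, panel,
                                       tolerance)
            if ratio > 0.75 * _MGST_DIPLOID_RATIO:
                mgst_genotype = (allele, allele)
                mgst_zygosity = "hom"
            else:
                mgst_genotype = (allele,)
                mgst_zygosity = "undetermined"
        else:
            mgst_genotype = (allele,)
            mgst_zygosity = "undetermined"
    else:
        mgst_genotype = ()
        mgst_zygosity = "none"

    # self-(in)compatibility interpretation
    sc_alleles = {"S3p", "S4p", "S5p"}
    if sc_alleles & set(s_genotype):
        sc = "self_compatible"
    elif "MGSTins" in mgst_genotype:
        sc = "partial_sc_associated"
    elif "S?" in s_genotype:
        sc = "undetermined"
    else:
        sc = "self_incompatible"

    # remaining QC
    for c in s_calls:
        if c.status == "unconfirmed":
            qc.append(QCFlag("UNCONFIRMED_ALLELE",
                             f"{display_allele(c.allele)}: {c.notes}"))
    for c in allele_calls:
        if any(m.fragment.provisional for m in c.evidence):
            qc.append(QCFlag("PROVISIONAL_BIN",
                             f"{display_allele(c.allele)} rests on a "
                             f"provisional bin"))
    stray = [p for p in binres.unassigned if p.height >= min_height]
    if stray:
        qc.append(QCFlag(
            "UNASSIGNED_PEAKS",
            "; ".join(f"{p.channel.value}:{p.size:.1f} ({p.height:.0f} RFU)"
                      for p in stray)))
    for p in binres.ambiguous:
        qc.append(QCFlag("AMBIGUOUS_BIN",
                         f"{p.channel.value}:{p.size:.2f} within tolerance of "
                         f"two bins; left unassigned"))

    return GenotypeCall(
        sample_id=run.sample_id,
        s_genotype=s_genotype,
        mgst_genotype=mgst_genotype,
        mgst_zygosity=mgst_zygosity,
        sc_interpretation=sc,
        qc=qc,
        dosage=decision,
        allele_calls=allele_calls,
    )


def qc_checks(run: SampleRun, genotype: GenotypeCall, panel: Panel,
              tolerance: Optional[float] = None, min_height: float = 50.0,
              control_floor: float = 100.0) -> list[QCFlag]:
    """Recompute the QC flags for an assembled genotype."""
    rebuilt = assemble_genotype(
        genotype.allele_calls, run, panel, tolerance=tolerance,
        min_height=min_height, control_floor=control_floor)
    return rebuilt.qc


def _filtered(run: SampleRun, min_height: float) -> SampleRun:
    if min_height <= 0:
        return run
    return SampleRun(run.sample_id,
                     [p for p in run.peaks if p.height >= min_height])


def call_sample(
    run: SampleRun,
    panel: Panel,
    tolerance: Optional[float] = None,
    min_height: float = 50.0,
    control_floor: float = 100.0,
    z_cut: float = 3.0,
    mgst_dosage: bool = False,
) -> GenotypeCall:
    """Full pipeline for one sample: bin, infer, assemble."""
    binres = bin_peaks(_filtered(run, min_height), panel, tolerance)
    calls = infer_alleles(binres.matches, panel)
    return assemble_genotype(
        calls, run, panel, tolerance=tolerance, min_height=min_height,
        control_floor=control_floor, z_cut=z_cut, mgst_dosage=mgst_dosage)
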