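"""Assay panel: primers, fragment bins, and dosage calibrations.

The panel describes a one-tube multiplex PCR assay for sweet cherry
(*Prunus avium*) self-(in)compatibility genotyping, read out by capillary
fragment analysis on four dye channels:

* blue (6-FAM) -- universal S-RNase intron-1 fragments plus the SFB
  fragments that separate self-compatible (SC) from self-incompatible (SI)
  S-alleles,
* green (VIC) -- MGST promoter alleles,
* yellow (NED) -- the diploid single-copy PaveIF-1A control fragment,
* red (PET) -- allele-specific S-RNase confirmation fragments.

Fragment bins are keyed by *observed* electrophoretic sizes (labeled
fragments run up to ~7 nt shorter than their sequence length); expected
sequence lengths are retained for in-silico PCR.  Alleles whose observed
size has never been measured carry a provisional bin derived from the
expected size minus a per-channel mobility offset and are flagged as such.

Allele labels are ASCII: the SC alleles S3', S4', S5' are written
``S3p``/``S4p``/``S5p`` internally; :data:`DISPLAY_NAMES` maps them to the
primed notation for rendering.  The indistinguishable pairs S14/S23 and
S21/S25 are single composite labels.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Optional, Sequence


class DyeChannel(str, Enum):
    """One of the four fluorescence detection channels."""

    B = "B"  # 6-FAM, blue
    G = "G"  # VIC, green
    Y = "Y"  # NED, yellow (rendered black in electropherograms)
    R = "R"  # PET, red

    @property
    def dye_name(self) -> str:
        return _DYE_NAMES[self]


_DYE_NAMES = {
    DyeChannel.B: "6-FAM",
    DyeChannel.G: "VIC",
    DyeChannel.Y: "NED",
    DyeChannel.R: "PET",
}

#: IUPAC nucleotide alphabet accepted in primer sequences.
IUPAC_ALPHABET = set("ACGTRYSWKMBDHVN")

#: render map for primed / display allele names
DISPLAY_NAMES = {
    "S3p": "S3′",
    "S4p": "S4′",
    "S5p": "S5′",
}


def display_allele(label: str) -> str:
    """Render an internal allele label using primed notation."""
    return DISPLAY_NAMES.get(label, label)


class FragmentRole(str, Enum):
    UNIVERSAL_SRNASE = "universal_sRNase"
    SFB_MARKER = "sfb_marker"
    SPECIFIC_CONFIRM = "specific_confirm"
    MGST = "mgst"
    CONTROL = "control"


@dataclass(frozen=True)
class PrimerSpec:
    """A single primer of the multiplex, with its fluorescent label (if any)."""

    name: str
    sequence: str
    label: Optional[DyeChannel] = None
    final_concentration: float = 0.0  # µM in the final reaction
    recognized_alleles: tuple[str, ...] = ()
    reference: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"primer {self.name}: non-IUPAC characters {sorted(bad)}"
            )
        if self.final_concentration <= 0:
            raise ValueError(f"primer {self.name}: concentration must be > 0")


@dataclass(frozen=True)
class FragmentDef:
    """A fragment bin on one dye channel.

    ``observed_size`` is the bin center used by the caller; for alleles never
    run on the instrument it is provisional (expected size minus the channel
    mobility offset) and ``provisional`` is set.
    """

    id: str
    channel: DyeChannel
    observed_size: float
    expected_size: float
    alleles: tuple[str, ...]
    role: FragmentRole
    confirmatory_for: Optional[str] = None
    expected_sizes: tuple[float, ...] = ()  # all printed variants, if several
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.observed_size <= 0 or self.expected_size <= 0:
            raise ValueError(f"fragment {self.id}: sizes must be > 0")
        if not self.alleles:
            raise ValueError(f"fragment {self.id}: alleles must be non-empty")
        if not self.expected_sizes:
            object.__setattr__(self, "expected_sizes", (self.expected_size,))


@dataclass(frozen=True)
class CalibrationRatio:
    """One calibrated peak-height ratio contrasting two genotype groups.

    ``mean_homo``/``sd_homo`` describe the group carrying two copies of the
    SC-associated target fragment, ``mean_het``/``sd_het`` the group carrying
    one copy plus an unrelated partner allele.  ``informative`` is False for
    ratios whose copy numbers do not differ between the groups (the assay
    stores them as internal consistency checks only).
    """

    numerator: str
    denominator: str
    mean_homo: float
    sd_homo: float
    mean_het: float
    sd_het: float
    informative: bool = True
    p_value: Optional[float] = None
    requires: Optional[str] = None  # e.g. "mgst_wt_homo"
    note: str = ""

    def __post_init__(self) -> None:
        if self.sd_homo <= 0 or self.sd_het <= 0:
            raise ValueError("calibration SDs must be > 0")


class DosageScenario(str, Enum):
    """Single-S-allele situations requiring quantitative resolution."""

    S3_only = "S3_only"
    S3p_only = "S3p_only"
    S4p_only = "S4p_only"
    S5p_only = "S5p_only"


@dataclass(frozen=True)
class DosageCalibration:
    """Calibrated ratio statistics for one dosage scenario."""

    scenario: DosageScenario
    trigger_allele: str              # allele whose lone detection triggers this
    homo_genotype: tuple[str, str]   # resolution when copy number says "two"
    het_partner: str                 # placeholder partner when it says "one"
    ratios: tuple[CalibrationRatio, ...]
    provisional: bool = False
    note: str = ""


@dataclass
class Panel:
    """The full assay definition."""

    primers: list[PrimerSpec]
    fragments: list[FragmentDef]
    control_fragment_id: str
    dye_offsets: dict[DyeChannel, tuple[float, float]]  # (point offset, window)
    calibrations: list[DosageCalibration]
    bin_tolerance_default: float = 0.45
    name: str = "default"

    # -- lookups -----------------------------------------------------------

    def fragment(self, fragment_id: str) -> FragmentDef:
        for f in self.fragments:
            if f.id == fragment_id:
                return f
        raise KeyError(f"unknown fragment id: {fragment_id}")

    @property
    def control_fragment(self) -> FragmentDef:
        return self.fragment(self.control_fragment_id)

    def allele_labels(self) -> list[str]:
        """All allele labels referenced by any fragment, in canonical order."""
        seen: set[str] = set()
        for f in self.fragments:
            seen.update(f.alleles)
        return sorted(seen, key=allele_sort_key)

    def s_allele_labels(self) -> list[str]:
        """S-allele labels only (no MGST alleles, no control)."""
        return [
            a
            for a in self.allele_labels()
            if not a.startswith("MGST") and a != "PaveIF-1A"
        ]

    def channel_fragments(self, channel: DyeChannel) -> list[FragmentDef]:
        return sorted(
            (f for f in self.fragments if f.channel == channel),
            key=lambda f: f.observed_size,
        )

    def calibration(self, scenario: DosageScenario) -> DosageCalibration:
        for c in self.calibrations:
            if c.scenario == scenario:
                return c
        raise KeyError(f"no calibration for scenario {scenario}")

    def min_channel_separation(self) -> float:
        """Smallest gap between two bins sharing a channel."""
        best = math.inf
        for ch in DyeChannel:
            sizes = sorted(f.observed_size for f in self.channel_fragments(ch))
            for a, b in zip(sizes, sizes[1:]):
                best = min(best, b - a)
        return best

    # -- serialization -----------------------------------------------------

    def to_json(self, indent: int = 2) -> str:
        def enc(obj):
            if isinstance(obj, Enum):
                return obj.value
            return obj

        doc = {
            "name": self.name,
            "bin_tolerance_default": self.bin_tolerance_default,
            "control_fragment_id": self.control_fragment_id,
            "dye_offsets": {ch.value: list(v) for ch, v in self.dye_offsets.items()},
            "primers": [
                {k: enc(v) for k, v in asdict(p).items()} for p in self.primers
            ],
            "fragments": [
                {k: enc(v) for k, v in asdict(f).items()} for f in self.fragments
            ],
            "calibrations": [
                {
                    "scenario": c.scenario.value,
                    "trigger_allele": c.trigger_allele,
                    "homo_genotype": list(c.homo_genotype),
                    "het_partner": c.het_partner,
                    "provisional": c.provisional,
                    "note": c.note,
                    "ratios": [asdict(r) for r in c.ratios],
                }
                for c in self.calibrations
            ],
        }
        return json.dumps(doc, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "Panel":
        doc = json.loads(text)
        primers = [
            PrimerSpec(
                name=p["name"],
                sequence=p["sequence"],
                label=DyeChannel(p["label"]) if p.get("label") else None,
                final_concentration=p["final_concentration"],
                recognized_alleles=tuple(p.get("recognized_alleles", ())),
                reference=p.get("reference", ""),
            )
            for p in doc["primers"]
        ]
        fragments = [
            FragmentDef(
                id=f["id"],
                channel=DyeChannel(f["channel"]),
                observed_size=f["observed_size"],
                expected_size=f["expected_size"],
                alleles=tuple(f["alleles"]),
                role=FragmentRole(f["role"]),
                confirmatory_for=f.get("confirmatory_for"),
                expected_sizes=tuple(f.get("expected_sizes", ())),
                provisional=f.get("provisional", False),
            )
            for f in doc["fragments"]
        ]
        calibrations = [
            DosageCalibration(
                scenario=DosageScenario(c["scenario"]),
                trigger_allele=c["trigger_allele"],
                homo_genotype=tuple(c["homo_genotype"]),
                het_partner=c["het_partner"],
                provisional=c.get("provisional", False),
                note=c.get("note", ""),
                ratios=tuple(CalibrationRatio(**r) for r in c["ratios"]),
            )
            for c in doc["calibrations"]
        ]
        return cls(
            primers=primers,
            fragments=fragments,
            control_fragment_id=doc["control_fragment_id"],
            dye_offsets={
                DyeChannel(k): tuple(v) for k, v in doc["dye_offsets"].items()
            },
            calibrations=calibrations,
            bin_tolerance_default=doc.get("bin_tolerance_default", 0.45),
            name=doc.get("name", "custom"),
        )


# ---------------------------------------------------------------------------
# canonical allele ordering


_ALLELE_RE = re.compile(r"^S(\d+)(p?)$")


def allele_sort_key(label: str):
    """Canonical sort key: numeric, primes after their base, composites by
    first member, MGST alleles and the control after all S-alleles, ``S?``
    last."""
    if label == "S?":
        return (2, 0, 0, "")
    if label.startswith("MGST") or label == "PaveIF-1A":
        return (1, 0, 0, label)
    first = label.split("/")[0]
    m = _ALLELE_RE.match(first)
    if m:
        return (0, int(m.group(1)), 1 if m.group(2) else 0, label)
    return (0, 10**6, 0, label)


def order_pair(a: str, b: str) -> tuple[str, str]:
    """Sort an S-allele pair into canonical order."""
    return tuple(sorted((a, b), key=allele_sort_key))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# operations


def fragments_for_allele(panel: Panel, allele: str) -> list[FragmentDef]:
    """Every bin indicating *allele*, in ascending observed size."""
    hits = [f for f in panel.fragments if allele in f.alleles]
    if not hits:
        raise KeyError(f"unknown allele label: {allele!r}")
    return sorted(hits, key=lambda f: f.observed_size)


def alleles_for_fragment(
    panel: Panel,
    channel: DyeChannel,
    size: float,
    tolerance: Optional[float] = None,
) -> set[str]:
    """Alleles of the unique bin within *tolerance* of *size* on *channel*.

    Returns the empty set when no bin is close enough; raises if two bins are
    (which cannot happen with the shipped panel and default tolerance).
    """
    if size <= 0:
        raise ValueError("size must be > 0")
    tol = panel.bin_tolerance_default if tolerance is None else tolerance
    hits = [
        f
        for f in panel.channel_fragments(channel)
        if abs(f.observed_size - size) <= tol
    ]
    if len(hits) > 1:
        raise ValueError(
            f"size {size} on channel {channel.value} falls within tolerance "
            f"of {len(hits)} bins: {[f.id for f in hits]}"
        )
    return set(hits[0].alleles) if hits else set()


def validate_panel(panel: Panel) -> list[str]:
    """Check all panel invariants; returns human-readable violations."""
    problems: list[str] = []

    # bin separation and tolerance
    min_sep = panel.min_channel_separation()
    for ch in DyeChannel:
        frs = panel.channel_fragments(ch)
        for a, b in zip(frs, frs[1:]):
            if b.observed_size - a.observed_size < 1.0:
                problems.append(
                    f"fragments {a.id} and {b.id}: observed sizes "
                    f"{a.observed_size} and {b.observed_size} are separated by "
                    f"< 1 nt on channel {ch.value}"
                )
    if math.isfinite(min_sep) and panel.bin_tolerance_default >= min_sep / 2:
        problems.append(
            f"bin_tolerance_default {panel.bin_tolerance_default} is not below "
            f"half the minimum within-channel separation ({min_sep / 2})"
        )

    # fragment sanity: observed vs expected (1 nt size-calling slack; the
    # shipped S54 bin runs 1 nt long of its sequence length)
    for f in panel.fragments:
        if f.observed_size > max(f.expected_sizes) + 1.0:
            problems.append(
                f"fragment {f.id}: observed size {f.observed_size} exceeds "
                f"expected {max(f.expected_sizes)} by more than 1 nt"
            )

    # control fragment exists
    try:
        panel.control_fragment
    except KeyError:
        problems.append(f"control fragment {panel.control_fragment_id} missing")

    # calibrations reference known fragments/alleles, directionality
    frag_ids = {f.id for f in panel.fragments}
    alleles = set(panel.allele_labels())
    for cal in panel.calibrations:
        for a in (cal.trigger_allele, *cal.homo_genotype):
            if a not in alleles:
                problems.append(
                    f"calibration {cal.scenario.value}: allele {a} not in panel"
                )
        for r in cal.ratios:
            for fid in (r.numerator, r.denominator):
                if fid not in frag_ids:
                    problems.append(
                        f"calibration {cal.scenario.value}: fragment {fid} "
                        f"not in panel"
                    )
            if r.informative:
                num_role = (
                    panel.fragment(r.numerator).role
                    if r.numerator in frag_ids
                    else None
                )
                if (
                    num_role in (FragmentRole.CONTROL, FragmentRole.MGST)
                    and r.mean_het <= r.mean_homo
                ):
                    problems.append(
                        f"calibration {cal.scenario.value} "
                        f"{r.numerator}/{r.denominator}: informative "
                        f"control-over-target ratio must have mean_het > "
                        f"mean_homo"
                    )

    # at most one label per primer is structural; count check
    labeled = [p for p in panel.primers if p.label is not None]
    if panel.name == "default" and len(labeled) != 8:
        problems.append(f"default panel must have 8 labeled primers, got {len(labeled)}")

    return problems


# ---------------------------------------------------------------------------
# the packaged default panel (assay constants)

_B = DyeChannel.B
_G = DyeChannel.G
_Y = DyeChannel.Y
_R = DyeChannel.R

_PRIMERS: list[tuple[str, str, Optional[DyeChannel], float, tuple[str, ...], str]] = [
    ("PaConsI-CTTC-F", "CTTGTTCTTGCTTTTGCTTTCTTC", None, 0.19,
     ("S1", "S2", "S5", "S6", "S7", "S12", "S14", "S16", "S23", "S25"), ""),
    ("PaConsI-GTTC-F", "CTTGTTCTTGGTTTTGCTTTCTTC", None, 0.33, ("S3", "S3p"), ""),
    ("PaConsI-CTCC-F", "CTTGTTCTTGCTTTCGCTTTCTTC", None, 0.18,
     ("S4", "S4p", "S5p", "S10"), ""),
    ("PaConsI-CTTT-F", "CTTGTTCTTGCTTTTGTTTTCTTC", None, 0.5, ("S22", "S24"), ""),
    ("PaConsI-CGTC-F", "CTTGTTCTTGCTTGTGCTTTCTTC", None, 0.22, ("S9",), ""),
    ("PaConsI-R2", "GCCATTGTTGCACAAATTGA", _B, 0.21, ("*",),
     "Sonneveld et al. 2006"),
    ("S-RNase-S1-In2-F", "TGGTCTCCCTAACATGACCC", None, 0.175, ("S1",), ""),
    ("S-RNase-S2-In2-F", "TGAACGAAATCTCAACTCATAAATC", None, 0.43, ("S2",), ""),
    ("S-RNase-S6+S24-In2-F", "TCATTTTGTTTTCCACCTACCC", None, 0.18, ("S6", "S24"), ""),
    ("S-RNase-S7-In2-F", "TCTGTCTGGTTGTTTTGCTGG", None, 0.17, ("S7",), ""),
    ("S-RNase-S9+S22-In2-F", "TCTAATAATGGATCTGCTCATCTAATT", None, 0.7,
     ("S9", "S22"), ""),
    ("S-RNase-S12-In2-F", "GCTAACCCTTACATTTTGACCC", None, 0.25, ("S12",), ""),
    ("S-RNase-S13-In2-F", "ATATGTCTGTCTATCTATCTGTTTTCTCA", None, 0.4, ("S13",), ""),
    ("S-RNases-Ex3-R", "GTATCATTGCCACYTTCCACG", _R, 0.24, ("*",), ""),
    ("PaSFB3-F", "CCACAATTTGAACGTCAGAAC", None, 0.28, ("S3",),
     "Sonneveld et al. 2005"),
    ("PaSFB3-short-R", "TCTGTGTTTTCTAAAGGATGGC", _B, 0.28, ("S3",), ""),
    ("PaSFB4+4'-F", "TCTAGCTTTTATTCTTGCGAGG", _B, 0.155, ("S4", "S4p"), ""),
    ("PaSFB4+4'-R", "GATCTCCTATGCCCCTAGAGAA", None, 0.155, ("S4", "S4p"), ""),
    ("PaSFB-S5-F", "GCTTGGACAAAATTGACTTGTG", None, 0.2, ("S5",), ""),
    ("PaSFB-S5+S5'-R", "GATCACAATCACCCAAAGGAGG", _B, 0.2, ("S5", "S5p"), ""),
    ("S-RNase-S54-F", "CTCTCTTTGGTCTTCTTCTTGTGC", _R, 0.17, ("S54",), ""),
    ("S-RNase-S54-R", "GCTTGCTGATTGTAAATAAACTGC", None, 0.17, ("S54",), ""),
    ("MGST-TE-in-F", "ATAAATGGGTCAGTGGTGGG", None, 0.105, ("MGSTins",), ""),
    ("MGST-TE-out-F", "AAAGCCTTCAAGTGGGAAAG", None, 0.105,
     ("MGSTwt", "MGSTdel"), ""),
    ("MGST-TE-out-R", "TTGCTTACAGGTCATTACTTACACG", _G, 0.105,
     ("MGSTwt", "MGSTdel", "MGSTins"), "Ono et al. 2018"),
    ("PaveIF-1A-F", "GCCCAAGTGCTTCGTATGCT", _Y, 0.05, ("PaveIF-1A",),
     "adapted from Prunus persica"),
    ("PaveIF-1A-R", "ATCACCGGCTGCAATCCA", None, 0.05, ("PaveIF-1A",),
     "adapted from Prunus persica"),
]

_U = FragmentRole.UNIVERSAL_SRNASE
_SFB = FragmentRole.SFB_MARKER
_SPC = FragmentRole.SPECIFIC_CONFIRM

# (id, channel, observed, expected-variants, alleles, role, confirmatory_for,
#  provisional)
_FRAGMENTS: list[tuple] = [
    # blue: SFB markers
    ("B83", _B, 83.0, (90.0,), ("S5",), _SFB, "S5", False),
    ("B122", _B, 122.0, (125.0,), ("S3",), _SFB, "S3", False),
    ("B177", _B, 177.0, (181.0,), ("S4p",), _SFB, "S4p", False),
    ("B181", _B, 181.0, (184.0,), ("S4",), _SFB, "S4", False),
    # blue: universal S-RNase intron-1 fragments
    ("B227", _B, 227.0, (233.0,), ("S3", "S3p"), _U, None, False),
    ("B323", _B, 323.0, (330.0,), ("S14/S23",), _U, None, False),
    ("B337", _B, 337.0, (343.0,), ("S2",), _U, None, False),
    ("B338", _B, 338.0, (344.0,), ("S12",), _U, None, False),
    ("B339", _B, 339.0, (340.0,), ("S7",), _U, None, False),
    ("B350", _B, 350.0, (355.0,), ("S9",), _U, None, False),
    ("B367", _B, 367.0, (374.0,), ("S21/S25",), _U, None, False),
    ("B373", _B, 373.0, (376.0, 379.0), ("S1",), _U, None, False),
    ("B384", _B, 384.0, (391.0,), ("S5p",), _U, None, False),
    ("B385", _B, 385.0, (392.0,), ("S5",), _U, None, False),
    ("B406", _B, 406.0, (412.0,), ("S16",), _U, None, False),
    ("B415", _B, 415.0, (421.0,), ("S22",), _U, None, False),
    ("B435", _B, 435.0, (442.0,), ("S6",), _U, None, False),
    ("B443", _B, 443.0, (450.0,), ("S4", "S4p"), _U, None, False),
    # blue: provisional bins (observed size never measured; expected − 5 nt)
    ("B203", _B, 203.0, (208.0,), ("S31",), _U, None, True),
    ("B304", _B, 304.0, (309.0,), ("S38",), _U, None, True),
    ("B333", _B, 333.0, (338.0,), ("S29",), _U, None, True),
    ("B358", _B, 358.0, (363.0,), ("S10",), _U, None, True),
    ("B362", _B, 362.0, (367.0,), ("S28",), _U, None, True),
    ("B372", _B, 372.0, (377.0,), ("S34",), _U, None, True),
    ("B379", _B, 379.0, (384.0,), ("S30",), _U, None, True),
    ("B416", _B, 416.0, (421.0,), ("S24",), _U, None, True),
    # red: allele-specific confirmation fragments
    ("R119", _R, 119.0, (121.0,), ("S13",), _SPC, None, False),
    ("R147", _R, 147.0, (148.0, 149.0), ("S12",), _SPC, "S12", False),
    ("R172", _R, 172.0, (171.0,), ("S54",), _SPC, None, False),
    # S6 and S24 share one confirmation amplicon (same primer pair, same
    # expected size 225); the bin therefore indicates either allele.
    ("R223", _R, 223.0, (225.0,), ("S6", "S24"), _SPC, None, False),
    ("R240", _R, 240.0, (240.0,), ("S1",), _SPC, "S1", False),
    ("R249", _R, 249.0, (250.0,), ("S7",), _SPC, "S7", False),
    ("R258", _R, 258.0, (253.0, 260.0), ("S22",), _SPC, "S22", False),
    ("R266", _R, 266.0, (266.0,), ("S9",), _SPC, "S9", False),
    ("R302", _R, 302.0, (303.0,), ("S2",), _SPC, "S2", False),
    # green: MGST promoter alleles
    ("G132", _G, 132.0, (137.0,), ("MGSTdel",), FragmentRole.MGST, None, False),
    ("G140", _G, 140.0, (145.0,), ("MGSTwt",), FragmentRole.MGST, None, False),
    ("G192", _G, 192.0, (197.0,), ("MGSTins",), FragmentRole.MGST, None, False),
    # yellow: diploid single-copy control
    ("Y118", _Y, 118.0, (120.0,), ("PaveIF-1A",), FragmentRole.CONTROL, None,
     False),
]

# Tables of calibrated peak-height ratios.  homo = two copies of the
# SC-associated target fragment, het = one copy plus an unrelated partner.
_CALIBRATIONS: list[DosageCalibration] = [
    DosageCalibration(
        scenario=DosageScenario.S3_only,
        trigger_allele="S3",
        homo_genotype=("S3", "S3p"),
        het_partner="S?",
        ratios=(
            CalibrationRatio("Y118", "B122", 1.75, 0.33, 1.65, 0.26,
                             informative=False, p_value=0.20,
                             note="SFB fragment is single-copy in both groups"),
            CalibrationRatio("Y118", "B227", 1.17, 0.21, 2.12, 0.25,
                             informative=True, p_value=2.08e-22),
            CalibrationRatio("B227", "B122", 1.50, 0.22, 0.78, 0.15,
                             informative=True, p_value=4.77e-19),
        ),
    ),
    DosageCalibration(
        scenario=DosageScenario.S3p_only,
        trigger_allele="S3p",
        homo_genotype=("S3p", "S3p"),
        het_partner="S?",
        ratios=(
            CalibrationRatio("Y118", "B227", 1.30, 0.16, 2.25, 0.22,
                             informative=True, p_value=3.48e-26),
            CalibrationRatio("G140", "Y118", 1.14, 0.14, 1.10, 0.13,
                             informative=False, p_value=0.28,
                             requires="mgst_wt_homo",
                             note="two diploid controls against each other"),
            CalibrationRatio("G140", "B227", 1.47, 0.16, 2.47, 0.27,
                             informative=True, p_value=6.19e-22,
                             requires="mgst_wt_homo"),
        ),
    ),
    DosageCalibration(
        scenario=DosageScenario.S4p_only,
        trigger_allele="S4p",
        homo_genotype=("S4p", "S4p"),
        het_partner="S?",
        ratios=(
            CalibrationRatio("Y118", "B177", 0.53, 0.06, 1.04, 0.13,
                             informative=True, p_value=7.44e-22),
            CalibrationRatio("Y118", "B443", 0.66, 0.08, 1.34, 0.13,
                             informative=True, p_value=2.76e-28),
            CalibrationRatio("B443", "B177", 0.81, 0.05, 0.78, 0.05,
                             informative=False, p_value=0.052,
                             note="both fragments track the same copy number"),
        ),
    ),
    DosageCalibration(
        scenario=DosageScenario.S5p_only,
        trigger_allele="S5p",
        homo_genotype=("S5p", "S5p"),
        het_partner="S?",
        provisional=True,
        note=("no calibration cohort exists for S5'; reuses the S3' "
              "control/S-RNase ratio shape on the 384-nt fragment"),
        ratios=(
            CalibrationRatio("Y118", "B384", 1.30, 0.16, 2.25, 0.22,
                             informative=True,
                             note="borrowed from the S3' calibration"),
        ),
    ),
]


def load_default_panel() -> Panel:
    """The packaged assay definition (27 primers, 4-channel fragment matrix,
    dosage calibrations)."""
    primers = [
        PrimerSpec(name=n, sequence=s, label=lab, final_concentration=c,
                   recognized_alleles=rec, reference=ref)
        for n, s, lab, c, rec, ref in _PRIMERS
    ]
    fragments = [
        FragmentDef(id=i, channel=ch, observed_size=obs, expected_size=exp[0],
                    expected_sizes=exp, alleles=alleles, role=role,
                    confirmatory_for=conf, provisional=prov)
        for i, ch, obs, exp, alleles, role, conf, prov in _FRAGMENTS
    ]
    return Panel(
        primers=primers,
        fragments=fragments,
        control_fragment_id="Y118",
        dye_offsets={_B: (5.0, 2.0), _G: (5.0, 2.0), _Y: (2.0, 2.0),
                     _R: (1.0, 2.0)},
        calibrations=list(_CALIBRATIONS),
        bin_tolerance_default=0.45,
        name="default",
    )
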