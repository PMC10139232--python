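"""In-silico multiplex PCR: degenerate primer binding-site search and
amplicon prediction.

Primers may contain IUPAC ambiguity codes (Y matches C or T, and so on);
templates are plain A/C/G/T/N sequences.  A template N matches nothing
except a primer N (conservative).  Binding sites are searched on both
strands with a mismatch budget, with a protected 3'-terminal window in
which no mismatch is tolerated (a 3' mismatch blocks extension — the
design trick that makes the S5-specific SFB primer ignore the S5' point
mutant).  Mismatch counting is the only amplification predictor; no
thermodynamics are modeled.

Coordinates are 0-based half-open on the forward strand; an amplicon's
length spans primer 5' end to primer 5' end, matching how expected
fragment sizes are derived from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .panel import DyeChannel, PrimerSpec

# base -> bitmask; template N gets its own bit so it only matches primer N
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 16}
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_PRIMER_MASK = {
    code: sum(_BITS[b] for b in bases) for code, bases in _IUPAC_SETS.items()
}


@dataclass(frozen=True)
class TemplateSeq:
    """A named template sequence (A/C/G/T/N)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"template {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"template {self.id}: invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site on a template.

    ``start``/``end`` are 0-based half-open on the forward strand;
    ``mismatch_positions`` are 1-based from the primer's 5' end.
    """

    primer: PrimerSpec
    template_id: str
    strand: str                # "forward" | "reverse"
    start: int
    end: int
    mismatches: int
    mismatch_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product."""

    fwd: BindingSite
    rev: BindingSite
    length: int
    channel: Optional[DyeChannel]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BITS[c] for c in seq.upper()], dtype=np.uint8)


def _site_scan(primer_codes: str, template_bits: np.ndarray) -> np.ndarray:
    """Mismatch matrix (n_offsets x primer_len), True where mismatched."""
    L = len(primer_codes)
    n = template_bits.size
    if L > n:
        return np.zeros((0, L), dtype=bool)
    mask = np.array([_PRIMER_MASK[c] for c in primer_codes.upper()],
                    dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(template_bits, L)
    return (windows & mask[None, :]) == 0


def find_binding_sites(
    primer: PrimerSpec,
    template: TemplateSeq,
    max_mismatches: int = 2,
    protect_3prime: int = 3,
) -> list[BindingSite]:
    """All annealing sites of *primer* on both strands of *template*.

    A site qualifies when its mismatch count is within *max_mismatches* and
    no mismatch falls in the *protect_3prime* 3'-terminal bases.
    """
    if max_mismatches < 0 or protect_3prime < 0:
        raise ValueError("max_mismatches and protect_3prime must be >= 0")
    seq = template.sequence.upper()
    L = len(primer.sequence)
    bits = _encode(seq)
    sites: list[BindingSite] = []

    # forward strand: primer read 5'->3' aligns left-to-right
    mm = _site_scan(primer.sequence, bits)
    counts = mm.sum(axis=1)
    prot = mm[:, L - protect_3prime:].any(axis=1) if protect_3prime else \
        np.zeros(mm.shape[0], dtype=bool)
    for off in np.nonzero((counts <= max_mismatches) & ~prot)[0]:
        pos = tuple(int(i) + 1 for i in np.nonzero(mm[off])[0])
        sites.append(BindingSite(primer, template.id, "forward",
                                 int(off), int(off) + L, int(counts[off]), pos))

    # reverse strand: scan with the primer's reverse complement; column k of
    # the scan corresponds to primer position L-k (1-based), and the primer
    # 3' end sits at the left edge of the forward-strand window
    rc = str(Seq(primer.sequence).reverse_complement())
    mm = _site_scan(rc, bits)
    counts = mm.sum(axis=1)
    prot = mm[:, :protect_3prime].any(axis=1) if protect_3prime else \
        np.zeros(mm.shape[0], dtype=bool)
    for off in np.nonzero((counts <= max_mismatches) & ~prot)[0]:
        pos = tuple(sorted(L - int(i) for i in np.nonzero(mm[off])[0]))
        sites.append(BindingSite(primer, template.id, "reverse",
                                 int(off), int(off) + L, int(counts[off]), pos))

    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    primers: Sequence[PrimerSpec],
    template: TemplateSeq,
    max_len: int = 1000,
    max_mismatches: int = 2,
    protect_3prime: int = 3,
) -> list[Amplicon]:
    """Every forward-site x downstream reverse-site pairing up to *max_len*.

    The product channel is the label of the single labeled primer of the
    pair (None when neither or both are labeled).
    """
    if max_len <= 0:
        raise ValueError("max_len must be > 0")
    fwd_sites: list[BindingSite] = []
    rev_sites: list[BindingSite] = []
    for primer in primers:
        for site in find_binding_sites(primer, template, max_mismatches,
                                       protect_3prime):
            (fwd_sites if site.strand == "forward" else rev_sites).append(site)

    amplicons: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.start < f.end:
                continue
            length = r.end - f.start
            if length > max_len:
                continue
            labels = [s.primer.label for s in (f, r) if s.primer.label]
            channel = labels[0] if len(labels) == 1 else None
            amplicons.append(Amplicon(f, r, length, channel))
    amplicons.sort(key=lambda a: (a.fwd.start, a.length))
    return amplicons


def binding_report(
    primers: Sequence[PrimerSpec],
    templates: Sequence[TemplateSeq],
    max_mismatches: int = 2,
    protect_3prime: int = 3,
) -> pd.DataFrame:
    """Best-site mismatch summary per (primer, template).

    Templates with no qualifying site are flagged (predicting amplification
    failure of that primer on that allele).  The mismatch threshold is an
    engineering choice, not a measured failure point.
    """
    rows = []
    for primer in primers:
        for tpl in templates:
            sites = find_binding_sites(primer, tpl, max_mismatches,
                                       protect_3prime)
            if sites:
                best = min(sites, key=lambda s: s.mismatches)
                rows.append({
                    "primer": primer.name,
                    "template": tpl.id,
                    "n_sites": len(sites),
                    "best_mismatches": best.mismatches,
                    "mismatch_positions": ",".join(
                        str(p) for p in best.mismatch_positions) or ".",
                    "strand": best.strand,
                    "no_site": False,
                })
            else:
                rows.append({
                    "primer": primer.name,
                    "template": tpl.id,
                    "n_sites": 0,
                    "best_mismatches": None,
                    "mismatch_positions": ".",
                    "strand": ".",
                    "no_site": True,
                })
    return pd.DataFrame(rows)


def read_templates(path) -> list[TemplateSeq]:
    """Load templates from a FASTA file."""
    from Bio import SeqIO

    return [TemplateSeq(rec.id, str(rec.seq)) for rec in
            SeqIO.parse(str(path), "fasta")]
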