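"""Copy-number interpretation of peak heights.

A diploid genome contributes two copies of the PaveIF-1A control fragment,
so after normalization to the control peak the height of an S-locus
fragment tracks its allele copy number.  This resolves the four otherwise
ambiguous single-S-allele situations: a lone S3 (S3S3' vs S3Sx), a lone S3'
(S3'S3' vs S3'Sx), a lone S4' (S4'S4' vs S4'Sy), and by extension a lone
S5'.  For each scenario the panel ships group statistics (mean ± SD of
calibrated ratios in homozygous-SC vs heterozygous cohorts); a sample is
assigned to the nearer group in SD units (z-score), combining several
ratios by root-mean-square, with |z| > z_cut on both hypotheses declared
indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .panel import (
    DosageCalibration,
    DosageScenario,
    DyeChannel,
    Panel,
    order_pair,
)
from .peaks_io import SampleRun


@dataclass
class DosageDecision:
    """Outcome of the copy-number classification for one sample."""

    scenario: DosageScenario
    ratios: list[tuple[str, float]]      # (ratio id "num/den", value)
    z_homo: float                        # combined RMS z vs homozygous-SC group
    z_het: float                         # combined RMS z vs heterozygous group
    decision: str                        # homozygous_sc | heterozygous | indeterminate
    resolved_genotype: tuple[str, str]
    provisional: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TestResult:
    """F-test on variances followed by the matching two-sample t-test."""

    f_stat: float
    f_p: float
    t_stat: float
    df: float
    t_p: float
    variant: str  # "pooled" | "welch"
    note: str = ""


def _peak_height(run: SampleRun, fragment_id: str, panel: Panel,
                 tolerance: Optional[float] = None) -> float:
    frag = panel.fragment(fragment_id)
    tol = panel.bin_tolerance_default if tolerance is None else tolerance
    candidates = [
        p for p in run.channel_peaks(frag.channel)
        if abs(p.size - frag.observed_size) <= tol
    ]
    if not candidates:
        raise ValueError(f"fragment {fragment_id} not matched in sample "
                         f"{run.sample_id}")
    return max(p.height for p in candidates)


def peak_ratio(run: SampleRun, numerator: str, denominator: str,
               panel: Panel, tolerance: Optional[float] = None) -> float:
    """Height of the numerator fragment's peak over the denominator's."""
    num = _peak_height(run, numerator, panel, tolerance)
    den = _peak_height(run, denominator, panel, tolerance)
    if den == 0:
        raise ValueError(f"fragment {denominator} has zero height in sample "
                         f"{run.sample_id}")
    return num / den


def _mgst_wt_homo(run: SampleRun, panel: Panel,
                  tolerance: Optional[float]) -> bool:
    """True when the green channel shows the MGSTwt bin and nothing else,
    i.e. the 140-nt peak can be treated as a second diploid control."""
    tol = panel.bin_tolerance_default if tolerance is None else tolerance
    green = panel.channel_fragments(DyeChannel.G)
    seen = set()
    for p in run.channel_peaks(DyeChannel.G):
        for f in green:
            if abs(p.size - f.observed_size) <= tol:
                seen.add(f.id)
    return seen == {"G140"}


def classify_single_allele_case(
    run: SampleRun,
    scenario: DosageScenario,
    panel: Panel,
    calibration: Optional[DosageCalibration] = None,
    z_cut: float = 3.0,
    tolerance: Optional[float] = None,
) -> DosageDecision:
    """Decide homozygous-SC vs heterozygous for a lone SC-informative allele.

    Requires the control fragment (normalization is impossible without it)
    and the scenario's target fragments.  Only informative calibrated ratios
    enter the decision; ratios involving the MGSTwt peak are used only when
    the sample is homozygous MGSTwt.
    """
    if calibration is None:
        calibration = panel.calibration(scenario)
    elif calibration.scenario != scenario:
        raise ValueError(
            f"calibration is for {calibration.scenario.value}, "
            f"not {scenario.value}"
        )
    try:
        _peak_height(run, panel.control_fragment_id, panel, tolerance)
    except ValueError as exc:
        raise ValueError(
            f"control fragment absent in sample {run.sample_id}: "
            f"normalization impossible"
        ) from exc

    notes: list[str] = []
    if calibration.provisional:
        notes.append("PROVISIONAL: " + (calibration.note or
                                        "calibration reused from another scenario"))
    mgst_ok = _mgst_wt_homo(run, panel, tolerance)

    values: list[tuple[str, float]] = []
    z_h: list[float] = []
    z_x: list[float] = []
    for r in calibration.ratios:
        if not r.informative:
            continue
        if r.requires == "mgst_wt_homo" and not mgst_ok:
            notes.append(
                f"ratio {r.numerator}/{r.denominator} skipped: sample is not "
                f"homozygous MGSTwt"
            )
            continue
        value = peak_ratio(run, r.numerator, r.denominator, panel, tolerance)
        values.append((f"{r.numerator}/{r.denominator}", value))
        z_h.append((value - r.mean_homo) / r.sd_homo)
        z_x.append((value - r.mean_het) / r.sd_het)
    if not values:
        raise ValueError(
            f"no informative calibrated ratio measurable for scenario "
            f"{scenario.value} in sample {run.sample_id}"
        )

    z_homo = float(np.sqrt(np.mean(np.square(z_h))))
    z_het = float(np.sqrt(np.mean(np.square(z_x))))

    if min(z_homo, z_het) > z_cut:
        decision = "indeterminate"
        resolved = (calibration.trigger_allele, "S?")
    elif z_homo < z_het:
        decision = "homozygous_sc"
        resolved = order_pair(*calibration.homo_genotype)
    elif z_het < z_homo:
        decision = "heterozygous"
        resolved = (calibration.trigger_allele, calibration.het_partner)
    else:  # exact tie: refuse to guess
        decision = "indeterminate"
        resolved = (calibration.trigger_allele, "S?")

    return DosageDecision(
        scenario=scenario,
        ratios=values,
        z_homo=z_homo,
        z_het=z_het,
        decision=decision,
        resolved_genotype=resolved,
        provisional=calibration.provisional,
        notes=notes,
    )


def f_then_t_test(group_a: Sequence[float], group_b: Sequence[float],
                  alpha_f: float = 0.05) -> TestResult:
    """Two-sided F-test of variance equality, then the matching t-test.

    Equal variances not rejected at *alpha_f* -> pooled-variance two-sample
    t-test; rejected -> Welch.  Zero variance in either group makes the
    F statistic undefined; Welch is used with a note (and the degenerate
    both-variances-zero case is resolved by comparing means directly).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")

    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    note = ""

    if va == 0.0 or vb == 0.0:
        f_stat, f_p = math.nan, math.nan
        variant = "welch"
        note = "zero variance: F-test undefined, falling back to Welch"
    else:
        f_stat = va / vb
        dist = stats.f(a.size - 1, b.size - 1)
        f_p = 2.0 * min(dist.cdf(f_stat), dist.sf(f_stat))
        f_p = min(f_p, 1.0)
        variant = "pooled" if f_p >= alpha_f else "welch"

    if va == 0.0 and vb == 0.0:
        # no within-group spread at all
        if float(np.mean(a)) == float(np.mean(b)):
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat = math.inf if float(np.mean(a)) > float(np.mean(b)) else -math.inf
            t_p = 0.0
        df = float(a.size + b.size - 2)
        return TestResult(f_stat, f_p, t_stat, df, t_p, variant, note)

    if variant == "pooled":
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
        df = float(a.size + b.size - 2)
    else:
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
        sa, sb = va / a.size, vb / b.size
        df = (sa + sb) ** 2 / (
            sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
        )
    return TestResult(float(f_stat), float(f_p), float(t_stat), float(df),
                      float(t_p), variant, note)
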