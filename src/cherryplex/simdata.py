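"""Synthetic peak-table generator.

Simulates the assay's observable — (channel, size, height) peaks — under
the copy-number height model the dosage analysis assumes: the expected
height of a fragment's peak is

    base_height x copies x efficiency,

where copies is the number of allele copies contributing the fragment (the
diploid control always contributes 2) and efficiency is the fragment's
relative amplification efficiency (control = 1).  Multiplicative lognormal
noise with E[factor] = 1 models run-to-run height variation (heights are
positive and ratios are the analysis currency); peak sizes get additive
Gaussian jitter.  Optional artifacts: per-fragment dropout and the +1-nt
"double peak" shadow seen with some polymerase master mixes, which the
caller's tallest-in-bin rule must absorb.

Per-fragment efficiencies can be fitted from the panel's dosage
calibration tables so that simulated cohorts reproduce the calibrated
group-mean ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .panel import (
    DosageCalibration,
    DyeChannel,
    Panel,
    fragments_for_allele,
)
from .peaks_io import Peak, SampleRun


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    cv is the per-peak multiplicative coefficient of variation; ratio-level
    relative SDs come out ~ cv * sqrt(2) for a ratio of two independent
    peaks.
    """

    base_height: float = 1000.0
    cv: float = 0.15
    size_sd: float = 0.15
    dropout_p: float = 0.0
    double_peak_p: float = 0.0
    double_peak_fraction: float = 0.6
    efficiencies: Optional[dict[str, float]] = None  # None -> calibrated fit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_height <= 0:
            raise ValueError("base_height must be > 0")
        for name in ("cv", "dropout_p", "double_peak_p"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.efficiencies is not None:
            if any(e <= 0 for e in self.efficiencies.values()):
                raise ValueError("efficiencies must be > 0")


def fragment_copies(
    s_genotype: Sequence[str],
    mgst_genotype: Sequence[str],
    panel: Panel,
) -> dict[str, int]:
    """Copy number per fragment id implied by a genotype.

    Each allele copy contributes one copy of each of its fragments (so a
    fragment shared by both alleles of the genotype gets 2); the control
    fragment always gets 2.  ``S?``/None placeholders contribute nothing.
    """
    copies: dict[str, int] = {}
    for allele in (*s_genotype, *mgst_genotype):
        if allele is None or allele == "S?":
            continue
        for frag in fragments_for_allele(panel, allele):
            copies[frag.id] = copies.get(frag.id, 0) + 1
    copies[panel.control_fragment_id] = 2
    return copies


def default_efficiencies(
    calibrations: Sequence[DosageCalibration],
    panel: Panel,
) -> dict[str, float]:
    """Least-squares fit of relative per-fragment efficiencies.

    Solves, in log space, for e_f (control fixed at 1) such that the
    predicted ratio (copies_num * e_num) / (copies_den * e_den) matches each
    calibration group mean.  Provisional calibrations (borrowed statistics)
    are excluded; their fragments inherit the efficiency of the fragment
    the statistics were borrowed from.  Fragments not constrained by any
    calibration get efficiency 1.
    """
    control = panel.control_fragment_id
    # MGST-involving calibrations were measured on MGSTwt homozygotes
    mgst_bg = ("MGSTwt", "MGSTwt")

    ids: list[str] = []
    for cal in calibrations:
        if cal.provisional:
            continue
        for r in cal.ratios:
            for fid in (r.numerator, r.denominator):
                if fid != control and fid not in ids:
                    ids.append(fid)
    if not ids:
        return {control: 1.0}
    index = {fid: i for i, fid in enumerate(ids)}

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for cal in calibrations:
        if cal.provisional:
            continue
        homo = fragment_copies(cal.homo_genotype, mgst_bg, panel)
        het = fragment_copies((cal.trigger_allele, None), mgst_bg, panel)
        for r in cal.ratios:
            for copies, mean in ((homo, r.mean_homo), (het, r.mean_het)):
                c_num = copies.get(r.numerator, 0)
                c_den = copies.get(r.denominator, 0)
                if c_num == 0 or c_den == 0:
                    continue
                row = np.zeros(len(ids))
                if r.numerator != control:
                    row[index[r.numerator]] = 1.0
                if r.denominator != control:
                    row[index[r.denominator]] = -1.0
                rows.append(row)
                rhs.append(math.log(mean) - math.log(c_num) + math.log(c_den))
    x, *_ = np.linalg.lstsq(np.vstack(rows), np.asarray(rhs), rcond=None)

    eff = {fid: 1.0 for fid in (f.id for f in panel.fragments)}
    for fid, i in index.items():
        eff[fid] = float(np.exp(x[i]))
    eff[control] = 1.0
    # provisional S5'-only scenario borrows the S3' S-RNase statistics
    if "B384" in eff and "B227" in index:
        eff["B384"] = eff["B227"]
    return eff


def calibration_group_efficiencies(
    calibration: DosageCalibration,
    group: str,
    panel: Panel,
) -> dict[str, float]:
    """Efficiencies fitted from one calibration cohort's group means.

    In a multiplex, per-copy amplification efficiency depends on the
    genotype composition (fragments of a partner allele compete for the
    shared universal primers), so the homozygous-SC and heterozygous
    cohorts of a calibration table carry distinct efficiency profiles.
    Fitting a group's own means (which are internally consistent) lets a
    simulated cohort reproduce that group's calibrated ratios; the shared
    fit of :func:`default_efficiencies` is the compromise across all
    tables.
    """
    if group not in ("homo", "het"):
        raise ValueError("group must be 'homo' or 'het'")
    control = panel.control_fragment_id
    mgst_bg = ("MGSTwt", "MGSTwt")
    if group == "homo":
        genotype = calibration.homo_genotype
    else:
        genotype = (calibration.trigger_allele, None)
    copies = fragment_copies(genotype, mgst_bg, panel)

    ids: list[str] = []
    for r in calibration.ratios:
        for fid in (r.numerator, r.denominator):
            if fid != control and fid not in ids:
                ids.append(fid)
    index = {fid: i for i, fid in enumerate(ids)}
    rows, rhs = [], []
    for r in calibration.ratios:
        if r.informative:
            mean = r.mean_homo if group == "homo" else r.mean_het
        else:
            # copy numbers are equal in both groups, so the printed group
            # difference is sampling noise; pool it (geometric mean) rather
            # than building it in as a true effect
            mean = math.sqrt(r.mean_homo * r.mean_het)
        c_num = copies.get(r.numerator, 0)
        c_den = copies.get(r.denominator, 0)
        if c_num == 0 or c_den == 0:
            continue
        row = np.zeros(len(ids))
        if r.numerator != control:
            row[index[r.numerator]] = 1.0
        if r.denominator != control:
            row[index[r.denominator]] = -1.0
        rows.append(row)
        rhs.append(math.log(mean) - math.log(c_num) + math.log(c_den))
    x, *_ = np.linalg.lstsq(np.vstack(rows), np.asarray(rhs), rcond=None)
    eff = {fid: 1.0 for fid in (f.id for f in panel.fragments)}
    for fid, i in index.items():
        eff[fid] = float(np.exp(x[i]))
    eff[control] = 1.0
    return eff


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unbiased multiplicative noise: E[factor] = 1 for any cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def simulate_run(
    s_genotype: Sequence[str],
    mgst_genotype: Sequence[str],
    params: SimParams,
    panel: Panel,
    sample_id: str = "sim",
) -> SampleRun:
    """One synthetic capillary run for a genotype; reproducible from seed."""
    eff = params.efficiencies
    if eff is None:
        eff = default_efficiencies(panel.calibrations, panel)

    copies = fragment_copies(s_genotype, mgst_genotype, panel)
    frag_ids = sorted(
        copies,
        key=lambda fid: (panel.fragment(fid).channel.value,
                         panel.fragment(fid).observed_size),
    )
    rng = np.random.default_rng(params.seed)
    noise = _lognormal_factors(rng, params.cv, len(frag_ids))
    size_jitter = (rng.normal(0.0, params.size_sd, len(frag_ids))
                   if params.size_sd > 0 else np.zeros(len(frag_ids)))
    drops = (rng.random(len(frag_ids)) < params.dropout_p
             if params.dropout_p > 0 else np.zeros(len(frag_ids), dtype=bool))
    doubles = (rng.random(len(frag_ids)) < params.double_peak_p
               if params.double_peak_p > 0
               else np.zeros(len(frag_ids), dtype=bool))

    peaks: list[Peak] = []
    for i, fid in enumerate(frag_ids):
        if drops[i]:
            continue
        frag = panel.fragment(fid)
        height = (params.base_height * copies[fid] * eff.get(fid, 1.0)
                  * noise[i])
        size = frag.observed_size + float(size_jitter[i])
        peaks.append(Peak(frag.channel, size, height))
        if doubles[i]:
            peaks.append(Peak(frag.channel, size + 1.0,
                              height * params.double_peak_fraction))
    return SampleRun(sample_id, peaks)


def simulate_cohort(
    group_spec: Sequence[tuple[Sequence[str], Sequence[str]]],
    n_per_group: int,
    params: SimParams,
    panel: Panel,
) -> list[SampleRun]:
    """n_per_group runs per (s_genotype, mgst_genotype) group; per-run seeds
    derive deterministically from params.seed and the group index."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    runs: list[SampleRun] = []
    for g, (s_geno, mgst_geno) in enumerate(group_spec):
        for i in range(n_per_group):
            seed = (params.seed * 1_000_003 + g * 10_007 + i) % (2**31 - 1)
            run_params = replace(params, seed=seed)
            runs.append(simulate_run(
                s_geno, mgst_geno, run_params, panel,
                sample_id=f"g{g}_s{i}"))
    return runs
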