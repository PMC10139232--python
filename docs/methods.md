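# Methods

## The assay model

`cherryplex` models a one-tube multiplex PCR for sweet cherry
self-(in)compatibility genotyping, read out on a four-dye capillary
analyzer. The observable is a peak list: (dye channel, fragment size in
nt, height in RFU). Sizes arrive pre-computed against a size standard; no
trace-level signal processing is modeled.

The panel partitions the readout into subsystems:

* Universal S-RNase intron-1 fragments (blue/6-FAM, from five forward
  primer variants sharing one FAM-labeled reverse primer) give most
  S-alleles a characteristic size between 83 and 443 nt.
* SFB-derived markers (blue) separate SC alleles from their SI
  counterparts: S3 carries a 122-nt SFB fragment deleted in S3′; S4′'s
  4-nt SFB deletion shifts 181 → 177 nt; the S5-specific SFB primer ends
  on the S5′ point mutation (plus a deliberate destabilizing mismatch near
  its 3′ end), so only S5 yields the 83-nt fragment.
* Red (PET) fragments confirm alleles whose universal fragments collide
  within ~1 nt (S1, S2, S6+S24, S7, S9+S22, S12) and carry the two alleles
  that escape the universal primers entirely (S13, S54).
* Green (VIC) is reserved for the three MGST promoter alleles; yellow
  (NED) for the diploid single-copy *PaveIF-1A* control.

Fragment bins use **observed** sizes. Labeled fragments migrate short of
their sequence length (blue roughly 1–7 nt, red −1–2 nt, green 5 nt,
yellow 2 nt in the shipped panel), so expected (sequence) lengths are kept
separately for in-silico work. Alleles whose observed size was never
measured (S10, S24's blue fragment, S28–S38) get provisional bins at
expected − channel offset (blue −5, red −1, green −5, yellow −2); calls
resting on them carry a `PROVISIONAL_BIN` flag. Validation allows observed
≤ max(expected) + 1 nt, since the S54 red bin runs 1 nt long of its
sequence length.

## Calling rules and their edge cases

Peaks below the noise floor (default 50 RFU, configurable) are ignored.
Each remaining peak goes to the nearest same-channel bin within the
tolerance (default 0.45 nt — below half the minimum 1-nt bin separation,
so a peak can never sit within tolerance of two bins in the shipped panel;
if a custom panel makes that possible the peak is left unassigned with an
`AMBIGUOUS_BIN` flag rather than guessed). Multiple peaks in one bin keep
the tallest as the match; the rest become shoulder peaks, which absorbs
the +1-nt double-peak artifact some polymerase master mixes produce.

Allele inference applies the subsystem rules in order (S3/S3′, S4/S4′,
S5/S5′ families; confirm-required alleles; red-only alleles; remaining
single-fragment bins). Notable choices:

* A lone 227-nt fragment is only ever a *candidate* S3′: a failed SFB
  amplification of true S3 would look identical, and only primer-mix
  pretesting excludes that.
* S6 and S24 share one red confirmation bin (223 nt; identical expected
  size, same primer pair). The bin is credited to whichever allele also
  shows its blue fragment; the 223-nt fragment alone yields ambiguous
  calls for both, and a confirmed S6 (or S24) fully explains the shared
  fragment so no spurious second allele is emitted.
* S4S4′ (181 + 177 + 443 nt) and S5S5′ (385 + 384 nt) heterozygotes are
  supported even though no such genotypes were available to calibrate the
  wet assay.
* Composite labels `S14/S23` and `S21/S25` are reported as such; their
  members differ only in intronic positions outside any assay fragment.

Exactly two S-alleles are expected. A lone S3/S3′/S4′/S5′ triggers dosage;
any other lone allele pairs with the placeholder `S?` and an
`ONE_S_ALLELE` flag. A genotype is interpreted self-compatible exactly
when it contains S3′, S4′ or S5′; otherwise `MGSTins` yields
`partial_sc_associated`, an `S?` yields `undetermined` (an SC partner
cannot be excluded), else self-incompatible.

MGST zygosity from a single green bin is reported as undetermined by
default; with `mgst_dosage=True` the MGST/control height ratio (diploid
calibration ≈ 1.12) upgrades it to a homozygote call.

## Dosage classification

For each scenario the panel stores calibrated ratio statistics
(mean ± SD for the two-copy and one-copy groups). Ratios flagged
non-informative (equal copy numbers in both groups: control/SFB in the S3
table, MGST/control in the S3′ table, 443/177 in the S4′ table) are
excluded from classification. Ratios involving the MGSTwt peak are used
only when the green channel shows MGSTwt alone (the peak is then diploid).
Per-ratio z-scores against each group are combined by root-mean-square
(simple and symmetric; inter-ratio correlation through the shared control
peak is ignored and accepted as a small approximation), the sample joins
the nearer group, and `|z| > z_cut` (default 3) on both hypotheses is
declared indeterminate. The S5′-only scenario has no calibration cohort;
it reuses the S3′ control/S-RNase statistics on the 384-nt fragment and
marks every decision provisional.

`f_then_t_test` mirrors the calibration statistics: a two-sided F-test of
variance equality at `alpha_f` = 0.05 selects pooled or Welch two-sample
t-tests. Zero variance in a group makes F undefined; the implementation
falls back to Welch with a note, and the all-degenerate case is resolved
by direct mean comparison.

## The simulator and what it does (not) show

`simulate_run` draws, per fragment implied by the genotype,

    height = base_height · copies · efficiency · LogNormal(−σ²/2, σ),
    size   = observed bin + Normal(0, size_sd),

with σ² = ln(1 + cv²) so the noise factor has unit mean (heights stay
unbiased). Defaults: base 1000 RFU, cv 0.15, size_sd 0.15 nt, no dropout,
no double peaks. The double-peak artifact, when enabled, adds a +1.0-nt
shadow at 60 % of the parent height.

Efficiencies default to `default_efficiencies`: a log-linear least-squares
fit of per-fragment relative efficiencies (control fixed at 1) to all
non-provisional calibration group means; every predicted mean lands within
~11 % of its calibrated value. The fit cannot do better, because the
calibration cohorts are mutually inconsistent under a shared-efficiency
copy-number model: the S3′ table's two-copy vs one-copy step is 1.73×
rather than 2×. `calibration_group_efficiencies` therefore fits one
cohort group at a time (each group's means are internally consistent to
< 2 %), which is the profile used for cohort simulations — defensible
because per-copy efficiency in a multiplex genuinely depends on genotype
composition (fragments of a partner allele compete for the shared
universal primers). For non-informative ratios the per-group fit pools the
two group means: their printed difference is sampling noise under the
model, not a real effect to build in.

Cohort studies in the test suite use n = 30 per group, cv = 0.10 (the
calibrated ratio relative SDs have median ≈ 0.14 and a ratio of two
independent lognormal peaks has relative SD ≈ cv·√2), and size_sd = 0.05
nt (replicate-run sizing precision; at 0.15 nt about 0.3 % of peaks fall
outside the 0.45-nt bin). Fixed seeds make all of this reproducible.

What the simulator does **not** emulate: baseline noise, pull-up between
dye channels, size-standard miscalibration, allele dropout correlated with
fragment length, stutter beyond the single +1-nt shadow, and any
systematic efficiency drift between instruments. Passing tests therefore
show that the interpretation logic and dosage arithmetic are correct under
the assay's own model, not that the assay tolerates every artifact of
real electropherograms.

## Numerical and design choices

* Bin tolerance 0.45 nt: must resolve the 1-nt S5/S5′ pair, and sits
  below the 0.5-nt ambiguity midpoint.
* Noise floor 50 RFU and control-height floor 100 RFU are conventions
  (the assay description gives none); both configurable.
* z_cut = 3: the calibration provides group statistics, not a per-sample
  decision rule; nearest-group-in-SD-units is this package's construction.
* In-silico defaults max_mismatches = 2, protect_3prime = 3, chosen so the
  S5-specific SFB primer (3′-terminal mismatch plus a destabilizing
  mismatch near the 3′ end on S5′) amplifies S5 but not S5′. No
  thermodynamics are modeled; the mismatch threshold at which a real
  multiplex fails is unknown, and reports say so in their header.
* Exhaustive correctness is checked over all 153 distinct pairs of the 18
  S-allele labels with observed bins × all 6 MGST genotypes at zero noise.
  Same-allele SI homozygote pairs are excluded by design: only SC-allele
  homozygosity is dosage-resolvable (an SI homozygote cannot arise from
  self-pollination in the field, and the assay has no second independent
  fragment to quantify against for most alleles).

## Known limitations

* S24 identification rests on a provisional blue bin 1 nt above S22's
  observed bin; real S24 material could plausibly land in the S22 bin, so
  S24 calls always carry the provisional warning.
* Dual expected lengths (S1 376/379, S12 148/149, S22 253/260) are stored
  without deciding which sub-variant maps to the single observed bin.
* The dosage classifier assumes exactly one diploid control; inter-run
  normalization and Bayesian height modeling are out of scope.
* The per-sample false-assignment probability of the dosage rule is not
  the same quantity as the calibration cohorts' t-test p-values; no
  per-sample error rate is claimed.
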