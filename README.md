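# cherryplex

Genotype calling for sweet cherry (*Prunus avium* L.) self-(in)compatibility
from one-tube multiplex PCR fragment analysis.

Sweet cherry is gametophytically self-incompatible: a pollen grain is
rejected when its S-allele matches either pistil S-allele of the S-locus
(S-RNase + SFB haploblock). Mutated, self-compatible (SC) S-alleles — S3′,
S4′, S5′, written `S3p`/`S4p`/`S5p` in code — and a transposon insertion in
the MGST promoter (`MGSTins`, associated with partial self-compatibility)
change that, and knowing a tree's S-genotype decides which cultivars can
pollinate each other and which seedlings a breeding program should keep.
`cherryplex` implements, as software, a capillary fragment-analysis assay
that reads all of this out of a single multiplexed PCR:

* **panel** — the assay definition: 27 primers (8 fluorescently labeled),
  the four-dye fragment interpretation matrix (blue 6-FAM: universal
  S-RNase intron-1 fragments + SC-discriminating SFB markers; green VIC:
  MGST promoter alleles; yellow NED: the diploid single-copy *PaveIF-1A*
  control; red PET: allele-specific confirmation fragments), and the
  peak-height dosage calibrations. Bins are keyed by *observed*
  electrophoretic sizes; fragments run up to ~7 nt short of their sequence
  length.
* **caller** — bins peaks to fragments (0.45 nt tolerance, enough to split
  the 1-nt S5/S5′ pair), applies the assay's confirmation rules, and
  assembles a two-S-allele + MGST genotype with QC flags.
* **dosage** — resolves a lone S3, S3′, S4′ or S5′: after normalization to
  the diploid control peak, the height of an S-locus fragment tracks its
  copy number, separating e.g. S3′S3′ (control/227-ratio ≈ 1.30 ± 0.16)
  from S3′Sx (≈ 2.25 ± 0.22). Samples are assigned to the nearer
  calibrated group in SD units; `f_then_t_test` reproduces the calibration
  statistics (F-test of variance equality, then pooled or Welch t-test).
* **insilico** — IUPAC-degenerate primer binding-site search (bitmask scan,
  both strands, protected 3′ window) and multiplex amplicon prediction on
  FASTA templates.
* **simdata** — a seeded generator of synthetic peak tables under the
  copy-number height model (height = base × copies × efficiency ×
  lognormal noise), with efficiencies fittable from the calibration
  tables.

## Worked example

```python
import io, cherryplex as cp

table = """sample,dye,size,height
Halka,B,373.0,950
Halka,R,240.1,870
Halka,B,177.0,820
Halka,B,443.1,700
Halka,G,140.0,940
Halka,Y,118.0,1010
"""

panel = cp.load_default_panel()
run, = cp.read_peak_table(io.StringIO(table))
call = cp.call_sample(run, panel)
print(call.to_row())
```

prints

```
{'sample': 'Halka', 'S_allele_1': 'S1', 'S_allele_2': 'S4′',
 'MGST': 'MGSTwt', 'sc_interpretation': 'self_compatible', 'flags': '.'}
```

The 373-nt blue + 240-nt red pair is S1; the 177-nt SFB marker (4-nt
deletion) with the 443-nt S-RNase fragment is S4′, a self-compatible
allele, so the sample is interpreted as self-compatible; the 118-nt
control confirms a clean run. The scripts in `examples/` walk through
calling, dosage resolution, in-silico PCR and cohort simulation, each
printing the numbers it computes.

The same pipeline is available from a shell:

```bash
cherryplex simulate --genotype S3p,S3p --seed 1 | cherryplex call -
cherryplex panel show
cherryplex insilico templates.fasta --report binding
```

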