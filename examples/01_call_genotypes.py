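"""Call S-allele + MGST genotypes from a peak table.

Builds a small peak table in memory (the 'Halka'-like profile: universal
S-RNase fragments for S1 and S4', the S1 red confirmation fragment, the
S4' SFB marker, the MGSTwt green bin and the PaveIF-1A control), then runs
the full caller.
"""

import io

import cherryplex as cp

PEAK_TABLE = """\
sample,dye,size,height
Halka,B,373.0,950
Halka,R,240.1,870
Halka,B,177.0,820
Halka,B,443.1,700
Halka,G,140.0,940
Halka,Y,118.0,1010
"""

panel = cp.load_default_panel()
runs = cp.read_peak_table(io.StringIO(PEAK_TABLE))

for run in runs:
    call = cp.call_sample(run, panel)
    row = call.to_row()
    print(f"sample {row['sample']}: "
          f"{row['S_allele_1']}{row['S_allele_2']}; MGST {row['MGST']}; "
          f"{row['sc_interpretation']}; flags: {row['flags']}")
    for ac in call.allele_calls:
        frags = ", ".join(m.fragment.id for m in ac.evidence)
        print(f"  {cp.display_allele(ac.allele):<10} {ac.status:<11} "
              f"via {frags}")

# The S-genotype S1S4' contains the self-compatible S4' allele (4-nt SFB
# deletion -> 177-nt marker instead of 181), so the cultivar can pollinate
# itself; the MGST wild-type promoter bin and the 118-nt diploid control
# confirm a clean run.
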