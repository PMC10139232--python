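"""In-silico multiplex PCR on a constructed template.

Builds a synthetic S2-like template: the PaConsI-CTTC-F forward site, a
spacer, and the reverse complement of the PaConsI-R2 site, spanning
exactly 343 nt (the S2 expected fragment length).  Predicts amplicons with
the full 27-primer panel and reports binding-site mismatches for the five
PaConsI forward variants.
"""

from Bio.Seq import Seq

import cherryplex as cp

panel = cp.load_default_panel()

cttc = next(p for p in panel.primers if p.name == "PaConsI-CTTC-F").sequence
r2 = next(p for p in panel.primers if p.name == "PaConsI-R2").sequence
spacer = "A" * (343 - len(cttc) - len(r2))
template = cp.TemplateSeq(
    "synthetic_S2_like",
    "GG" + cttc + spacer + str(Seq(r2).reverse_complement()) + "TT",
)

print("predicted amplicons:")
for amp in cp.predict_amplicons(panel.primers, template, max_len=600):
    ch = amp.channel.value if amp.channel else "unlabeled"
    print(f"  {amp.fwd.primer.name} + {amp.rev.primer.name}: "
          f"{amp.length} nt, channel {ch}")

variants = [p for p in panel.primers
            if p.name.startswith("PaConsI-") and p.name.endswith("-F")]
report = cp.binding_report(variants, [template], max_mismatches=3)
print("\nforward-variant binding (mismatches on this template):")
print(report[["primer", "best_mismatches", "mismatch_positions"]]
      .to_string(index=False))

# Only primer pairs with tolerable mismatches and an intact 3' end yield
# products; the 343-nt FAM-labeled amplicon is what fragment analysis would
# size (minus electrophoretic mobility) in the blue channel.
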