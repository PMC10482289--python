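"""Enumerate stop/start codons creatable by editing, and name sites.

From the tolerant native context, lists the minimal substitution sets that
let the C-to-U conversion create each of the three stop codons or a start
codon, then shows codon-consequence naming from a CDS anchor.
"""

from ppredit import NAD4_WINDOW, design_codon_edits, name_site

print("engineering the native context (reads ...uuCau... around the edit):")
for design in design_codon_edits(NAD4_WINDOW):
    subs = "|".join(str(s) for s in design.substitutions) or "(none needed)"
    print(f"  {design.category:>5} {design.codon}: {subs}")

print("\nnaming edits from a start-codon-anchored CDS:")
cds = "AUG" + "GCU" * 89 + "UCA" + "GCU" * 5 + "UAA"
print("  edit at CDS 272 (UCA -> UUA):", name_site("nad4", cds, 1, 272))
cds2 = "AUG" + "GCU" * 133 + "CAA" + "GCU" * 3 + "UAA"
print("  edit at CDS 403 (CAA -> UAA):", name_site("fdhE", cds2, 1, 403))
# The labels encode locus, position from the start codon's A, and the
# amino-acid consequence ('*' = stop).
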