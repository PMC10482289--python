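"""Parse mutation labels and check a protein/target compensation pair.

The repeat exchange S-4TN>TD switches the repeat facing position -7 from
an adenosine to a guanosine preference; the matching target exchange a-7g
restores the conceptual fit.  The script parses both labels, applies them
and prints the match counts before and after.
"""

from ppredit import (
    NAD4_WINDOW,
    PPR56,
    apply_ppr_mutation,
    apply_target_mutations,
    parse_protein_label,
    parse_target_label,
    score_window,
)

protein = parse_protein_label("PPR56|S-4TN>TD")
mutant_array = apply_ppr_mutation(PPR56, protein.mutations[0])
variant = parse_target_label("nad4eU272SL|a-7g")
mutant_target = apply_target_mutations(NAD4_WINDOW, variant)

for array, label_a in ((PPR56, "PPR56"), (mutant_array, str(protein))):
    for window, label_t in ((NAD4_WINDOW, "nad4eU272SL"), (mutant_target, str(variant))):
        r = score_window(array, window)
        print(f"{label_a:18} vs {label_t:18}: "
              f"{r.n_match}/{r.n_scored} matches")
# The mutant array loses the native -7 match and regains it on the
# adapted target; the wild-type array shows the mirror image.
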