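"""Scan a sequence for candidate targets, including pre-edited T states.

Embeds the native context in a toy transcript, converts the edited C to
its "pre-edited" T state (as a genome that no longer needs editing would
encode it), and shows that scanning with center_base="U" still finds the
position — the strategy used to spot candidate targets that exist as T in
related genomes.
"""

from ppredit import PPR56, scan_sequence
from ppredit.builtin import NAD4_WINDOW

flank5, flank3 = "AUUUAAAUGAGUCGAUCGA", "GGAUCCUUAAGG"
transcript = flank5 + NAD4_WINDOW.seq + flank3
c_position = len(flank5) + 17

print("genomic C state, scanning for editable cytidines:")
for hit in scan_sequence(PPR56, transcript, "C", min_matches=7):
    mark = "  <- native site" if hit.position == c_position else ""
    print(f"  pos {hit.position:3d}: {hit.report.n_match}/"
          f"{hit.report.n_scored} matches{mark}")

pre_edited = transcript[: c_position - 1] + "U" + transcript[c_position:]
print("pre-edited T state, scanning uridines:")
for hit in scan_sequence(PPR56, pre_edited, "U", min_matches=7):
    mark = "  <- same position" if hit.position == c_position else ""
    print(f"  pos {hit.position:3d}: {hit.report.n_match}/"
          f"{hit.report.n_scored} matches{mark}")
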