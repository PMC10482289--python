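"""Packaged PPR56 model and its two native mitochondrial target windows.

PPR56 is a C-to-U RNA editing factor from the moss *Physcomitrium patens*
with two native targets, nad4eU272SL and nad3eU230SL.  The repeat array
below lists the position 5 / position Last identities of each repeat; the
5/Last identities of the N-terminal L-14 repeat are not established and are
stored as unknown (neutral).  The E1/E2 position-34 residues are N and K.

The target windows cover offsets -16..+2 around the edited cytidine (offset
0).  Both share the local core u u C a u at -2..+2.  Under the default
recognition code both windows match at 7 of 9 P/S-class repeats; the
mismatches sit at offsets {-16, -9} for nad4 and {-16, -6} for nad3.
"""

from __future__ import annotations

from .ppr_code import PPRArray, TargetWindow

PPR56 = PPRArray.from_string(
    "PPR56",
    "L-14??,S-13NS,P-12NN,L-11MD,S-10TD,P-9TN,L-8VD,S-7TD,P-6ND,L-5LD,"
    "S-4TN,P2-3ND,L2-2VD,S2-1ND,E1:?N,E2:?K",
)

#: nad4eU272SL context, offsets -16..+2 (edited C at offset 0).
NAD4_WINDOW = TargetWindow("AUAGACGGUAUCUCUUCAU", start=-16)

#: nad3eU230SL context, offsets -16..+2.
NAD3_WINDOW = TargetWindow("UUGGAAGUCACCUUUUCAU", start=-16)

NATIVE_WINDOWS = {"nad4eU272SL": NAD4_WINDOW, "nad3eU230SL": NAD3_WINDOW}
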