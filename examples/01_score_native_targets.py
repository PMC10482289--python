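"""Score the two native PPR56 targets with the PPR-RNA recognition code.

Builds nothing: uses the packaged repeat array and the packaged
nad4eU272SL / nad3eU230SL context windows, applies the code position by
position and prints the verdicts.  Both targets match at 7 of the 9
code-following (P/S-class) repeats, but at different positions — the code
alone does not explain why the nad4 site is edited more efficiently.
"""

from ppredit import PPR56, score_window
from ppredit.builtin import NATIVE_WINDOWS

for name, window in NATIVE_WINDOWS.items():
    report = score_window(PPR56, window)
    print(f"{name}: {report.n_match}/{report.n_scored} P/S matches, "
          f"score {report.score}, mismatches at {report.mismatch_offsets}")
    for rec in report.records:
        if rec.verdict in ("match", "mismatch"):
            print(f"  {rec.motif.name:>6} ({rec.motif.pair}) vs "
                  f"{rec.observed} at {rec.offset:+d}: {rec.verdict}")
    print()
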