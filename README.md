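# ppredit

Tools for analyzing C-to-U RNA editing by PLS-type pentatricopeptide-repeat
(PPR) editing factors — the single-protein editing machines of early-branching
land plants such as the moss *Physcomitrium patens* — with a focus on the
kind of data produced when such a factor (e.g. PPR56) is expressed in a
heterologous host and edits both its native targets and many off-targets in
the host transcriptome.

The package is a library first: its public face is the importable API plus
the narrative scripts in `examples/`. A thin `ppredit` command-line wrapper
exposes the pipeline stages (`simulate`, `scan`, `call`, `profile`,
`mutate`, `run`) for shell use.

## What it computes

**PPR-RNA code matching.** A PLS-type repeat array binds one nucleotide per
repeat; the amino acids at repeat positions 5 and Last jointly encode the
preference T/S+N:A, T/S+D:G, N+D:U, N+S:C, N+N:pyrimidine (P/S-class
repeats only). Repeats are numbered backwards from the C-terminus and the
terminal repeat S2-1 faces target position −4, so a repeat with index *i*
faces offset *i* − 3 (E1 → −3, E2 → −2). The library scores
match/mismatch/neutral verdicts per position, scans sequences for candidate
sites (including "pre-edited" T states), finds the best alignment register
within ±k nucleotides (shift classification), and applies protein-side
mutations (`S-4TN>TD`, `E1:N34D`, truncations) to arrays.

**Nomenclature.** Parsers and formatters for the field's label grammars:
editing sites (`nad4eU272SL` = locus, position from the start-codon A,
codon change; `folDeU-5` = upstream of the start), target variants
(`nad4eU272SL|u-4g`, `|c0u` = pre-edited), and protein mutations
(`PPR56|S-7TD>TN|S-4TN>TD`). Plus codon-consequence naming from
GFF3/BED12-annotated references and enumeration of stop/start codons
creatable by editing.

**Off-target calling.** Downstream of external alignment + per-base variant
calling (tables ingested via column mapping), a site is called when it
shows a C→T (or G→A on the reverse strand) RNA–DNA difference that passes,
per dataset: (i) RNA coverage ≥ 30, (ii) transition purity (C+T or G+A)
> 99 %, (iii) DNA reference purity > 98 %, (iv) editing signal ≥ 1 %; and
is then supported by ≥ 2 datasets of the same protein while silent in
every control. The reported efficiency is the read-sum over supporting
datasets, Σ edited / Σ (edited + unedited). The Sanger quantifier
T/(T+C) is included for single-construct assays.

**Profiles.** Efficiency-weighted position frequency matrices of the called
sites' contexts with per-offset Shannon information content, after
optionally excluding sites whose best array alignment requires a shift.

**Synthetic experiments.** A seeded generator produces the full evidence
chain — reference, planted sites with known efficiencies, negative-binomial
coverage, sequencing error, replicate and control count tables, and decoys
that each violate exactly one filter criterion — so the whole pipeline is
testable end to end.

## Worked example

```
$ python examples/01_score_native_targets.py
nad4eU272SL: 7/9 P/S matches, score 5, mismatches at (-16, -9)
...
nad3eU230SL: 7/9 P/S matches, score 5, mismatches at (-16, -6)
```

Both native targets match 7 of the 9 code-following repeats — the code
alone does not rank them, which is exactly why off-target spectra and
context effects matter.

```
$ python examples/03_call_offtargets_synthetic.py
15000 treatment records -> 20 called sites
rejections: {'edit_signal': 7235, 'not_candidate': 7587, 'transition_purity': 74, ...}
replicate-rule failures: 16, control-excluded: 1

position strand  true_eff  called_eff  n_datasets
     202      +     0.020       0.023           3
     387      +     0.071       0.065           3
...
    3717      +     0.990       0.989           3
```

All 20 planted sites (efficiencies 0.02–0.99) are recovered, no decoy and
no background position is called, and the read-sum efficiencies track the
planted values within binomial sampling error. The other examples cover
retargeting mutations, weighted profiles, codon engineering and pre-edited
candidate scanning.

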