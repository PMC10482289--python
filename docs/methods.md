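# Methods

## The recognition model

A PLS-type PPR array is modeled as an ordered list of repeats, each with a
class (P, L, S, or the deviant C-terminal P2/L2/S2 variants, optionally
followed by the E1/E2 extension motifs) and the amino-acid identities at
repeat positions 5 and Last. Repeats are numbered backwards: the terminal
S2 repeat is S2-1 and is juxtaposed with target position −4, so an indexed
repeat faces offset `index − 3`; E1 and E2 face −3 and −2. Offsets are
relative to the edited cytidine (offset 0), negative = 5′.

The code table maps (aa5, aaLast) pairs to favored nucleotide sets:
T/S+N → {A}, T/S+D → {G}, N+D → {U}, N+S → {C}, N+N → {C, U}. Any pair
outside the table is neutral — it can never count as a mismatch. This
matters for L-class repeats (MD, VD, LD combinations) and for repeats with
unknown identities (the packaged PPR56 model stores the N-terminal L-14
identities as unknown).

**Scoring.** A repeat's verdict is *match* if the observed base is in its
preference set, *mismatch* if the set is non-empty and the base is not in
it, *neutral* otherwise; L-class repeats and E1/E2 are not scored unless
options enable them. The default score is `n_match − n_mismatch` over
P/S-class repeats. An option treats the E1 position-34 residue as a
PPR-like Last residue using the half-code N → amino {A, C}, D → keto
{G, U}; this is speculative and off by default. No tie-breaker is built in
for targets with equal match counts: both packaged native targets score
7/9, and the model deliberately does not rank them further.

**Shift classification.** `best_offset` slides the array by s ∈
[−k, +k] (default k = 2) and returns the shift maximizing the match count;
positive shift moves the array toward 3′ of the transcript, ties prefer 0
and then the negative shift. A site is "shifted" when the optimum is
non-zero. The shift window size is not canonical; k = 2 is a package
default and is configurable everywhere it is used.

**Scanning** enumerates every C (or U for pre-edited T-state searches, or
both) in a sequence, scores the upstream window, applies
`min_matches`/`max_mismatches` thresholds and optionally discards sites
with G at −1, which genuine editing sites avoid. Hits sort by descending
score, then ascending position. Scanning is strand-oriented; the CLI scans
the given sequence as provided.

## Nomenclature

Site labels are `locus + "eU" + position [+ codon change]`, with the
position counted 1-based from the A of the start codon and negative values
(no zero) for upstream sites; the codon change uses one-letter amino
acids with `*` for stop, computed with the standard genetic code (the
relevant codons translate identically under the bacterial table).
Target-variant segments are lower-case RNA with signed offsets relative to
the edited base (`u-4g`, `c0u`; `t` accepted for `u`); offset 0 denotes the
edited cytidine itself (the pre-edited state). Protein segments are domain
points (`DYW:G3A`, `E1:N34D`) and the 5/Last shorthand (`P-6ND>TD`).
Truncations have no printed grammar in the field; the package uses
`trunc:P-12` (remove everything N-terminal of and including P-12) as a
documented extension. Synonymous edits inside a CDS would be labeled with
the repeated amino acid (e.g. `eU123PP`) — an extension, since no printed
case exists. Sites outside any annotation fall back to the raw
`contig:position` form. Multi-exon CDS coordinates count spliced positions.

## The off-target caller

Input is one row per (dataset, contig, position) with plus-strand RNA base
counts and optional DNA counts; JACUSA-style exports map onto this schema
via a column mapping (including comma-packed A,C,G,T count columns). All
coordinates are 1-based and fully closed.

Orientation: reference C → forward candidate (edited = T reads, unedited =
C reads), reference G → reverse candidate (edited = A, unedited = G);
A/T references are not candidates. Criteria per dataset:

1. coverage ≥ 30 (default),
2. transition purity (edited + unedited)/coverage **strictly** > 0.99,
3. DNA reference purity strictly > 0.98 when DNA counts are present
   (assumed pure and flagged otherwise),
4. editing signal ≥ 0.01.

Strict vs. non-strict comparisons follow the wording of the thresholds
("more than 99 %" vs. "at least 30/1 %"). The signal is computed as
edited/(edited + unedited) by default — identical to the Sanger T/(T+C)
formula and within ≤ 1 % relative of edited/coverage given criterion 2; a
flag switches to the coverage denominator.

A site is called when it passes in ≥ 2 treatment datasets (filter first,
then intersect) and no control dataset shows signal ≥ 1 % at coverage
≥ 10 for the same oriented site. The control thresholds are package
defaults, exposed in `CallerParams`, since "absent from controls" is not a
quantified rule. Datasets of the same protein with different co-delivered
targets count as interchangeable replicates. Sites on opposite strands of
the same position are independent. Aggregate efficiency is the read sum
Σ edited / Σ (edited + unedited) over supporting datasets, equal to the
coverage-weighted mean of per-dataset fractions.

## Profiles

Weighted frequencies: freq(o, b) = Σᵢ wᵢ·[seqᵢ(o) = b] / Σᵢ wᵢ with N
excluded from both sums; weights are the aggregate efficiencies exactly as
computed (no rescaling), so the profile is invariant under weight scaling
and reduces to plain frequencies for equal weights. Information content is
the plain Shannon form 2 + Σ f log₂ f in bits, without small-sample
correction. The default window is −20…+5; the weighting interpretation
(frequencies weighted before stacking) is one of two readings of how
published logos weight by efficiency, and is the one implemented. Contexts
are strand-oriented (C at offset 0) and N-padded at contig edges.

## The synthetic generator

The generator emulates the per-site evidence structure of a bacterial
expression experiment, not reads: counts are drawn directly at each
position. Defaults (the study conditions of the test suite): 3 treatment
+ 1 control dataset, negative-binomial coverage with mean 200 and
dispersion 5 (RNA-seq-like overdispersion; no coverage distribution is
canonical), uniform substitution error 0.001 to the three other bases
(transitions not privileged, so the purity criterion is genuinely
exercised), DNA coverage 100 at error 5·10⁻⁴, and 20 planted sites with
efficiencies 0.02–0.99 whose first two carry the native nad4/nad3 contexts
and the rest are sampled to match the array with 0–2 mismatches. The
reference is 5 kb at GC 0.5 — a scale at which the expected number of
background positions fluctuating past all four criteria in ≥ 2 datasets is
far below one. Edited reads are Binomial(coverage, efficiency); reverse-
strand sites emit G→A evidence on the plus strand.

Decoys are constructed, not sampled, to violate exactly one rule each:
coverage forced to 29; a foreign base forced to 2 % of reads (purity
≤ 0.98); DNA reference fraction forced to exactly 0.98 (fails the strict
comparison); edited reads forced below 1 %; a site present in only one
treatment dataset; a site also planted in the control. All randomness
derives from one seed through per-dataset child streams; a fixed
configuration reproduces byte-identical output files.

Passing tests on this generator show the cascade's logic (thresholds,
replicate restriction, control exclusion, aggregation) is implemented
correctly and recovers planted truth under realistic noise. They do not
certify performance on real data, where alignment artifacts, strand
bias, correlated errors and coverage structure differ from the model.

## Numerical and design choices

- Windows must contain offset 0; missing offsets are reported
  `not_scored`, never fabricated.
- DNA input (T alphabet) is normalized to RNA internally; rendered output
  honors the input alphabet.
- Scan hits and calls sort deterministically (score/position; contig,
  position, strand), and tables are written with fixed column orders, so
  identical inputs give byte-identical outputs.
- Stop-codon designs place the edited U at the first codon position and
  only touch offsets +1/+2; the start design reads AUG across −1…+1.
  Designs are minimal substitution sets and are re-verifiable by applying
  them and translating.
- Efficiencies are fractions in (0, 1] internally; percentages appear only
  in rendered output.
- The pipeline (`run_pipeline`) is a pure function of (inputs, config,
  seed); any stage failure aborts with a stage-tagged error.

## Known limitations

- The recognition model is the established combinatorial code; no binding
  energies, no structural modeling, no learned extensions (SS/LL repeat
  classes are treated as neutral).
- The caller handles C→U (and its reverse-strand mirror) transitions only;
  no indels, no other RDD classes.
- Read-level simulation (FASTQ, alignment) is out of scope; the generator
  works at the count level the caller consumes.
- U-to-C "reverse" editing labels are not supported.
- Acceptance-scale problem sizes (5 kb reference, 4 datasets, 20 sites)
  are the package's test-suite defaults; they are chosen to make the
  statistical assertions sharp, not to emulate transcriptome scale.
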