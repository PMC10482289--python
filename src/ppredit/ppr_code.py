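"""PLS-type PPR arrays and the PPR-RNA recognition code.

Plant organelle C-to-U RNA editing factors carry an array of
pentatricopeptide repeats (PPRs) that binds the RNA upstream of the edited
cytidine, one repeat per nucleotide.  The amino acids at repeat positions 5
and "Last" jointly encode a nucleotide preference (the PPR-RNA code):
T/S+N favors A, T/S+D favors G, N+D favors U, N+S favors C and N+N favors a
pyrimidine.  The code applies to P- and S-type repeats only; L-type repeats
and the E1/E2 extension motifs carry no established preference.

Repeats are numbered backwards from the C-terminus: the terminal S2 repeat
is S2-1 and sits opposite target position -4 (four nucleotides upstream of
the edited cytidine), so an indexed repeat faces target offset ``index - 3``.
The E1 and E2 motifs face offsets -3 and -2.

This module models arrays and target windows, scores code matches, scans
sequences for candidate editing sites, finds the best array/target register
(shift detection) and applies protein-side mutations to arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
RNA_BASES = ("A", "C", "G", "U")
PLS_KINDS = ("P", "L", "S", "P2", "L2", "S2")
E_KINDS = ("E1", "E2")
#: P/S-class repeats are the ones the recognition code applies to.
CODE_SCORED_KINDS = frozenset({"P", "S", "P2", "S2"})
L_CLASS_KINDS = frozenset({"L", "L2"})

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (U complements to A)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Upper-case and convert T to U; validates the alphabet."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return out


class CodeTable:
    """Mapping from (aa5, aaLast) pairs to favored nucleotide sets.

    Pairs absent from the table are neutral and yield the empty set; they
    are never counted as mismatches.
    """

    def __init__(self, entries: Mapping[tuple[str, str], Iterable[str]]):
        self.entries: dict[tuple[str, str], frozenset[str]] = {
            (a5, aL): frozenset(normalize_rna("".join(nts)))
            for (a5, aL), nts in entries.items()
        }

    def preference(self, aa5: str | None, aaL: str | None) -> frozenset[str]:
        if aa5 is None or aaL is None:
            return frozenset()
        for aa in (aa5, aaL):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid amino-acid letter: {aa!r}")
        return self.entries.get((aa5, aaL), frozenset())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries


#: The canonical code: T/S+N:A, T/S+D:G, N+D:U, N+S:C, N+N:Y (pyrimidine).
DEFAULT_CODE = CodeTable(
    {
        ("T", "N"): "A",
        ("S", "N"): "A",
        ("T", "D"): "G",
        ("S", "D"): "G",
        ("N", "D"): "U",
        ("N", "S"): "C",
        ("N", "N"): "CU",
    }
)


def code_preference(
    aa5: str, aaL: str, table: CodeTable = DEFAULT_CODE
) -> frozenset[str]:
    """Favored nucleotides for a (position 5, position Last) amino-acid pair.

    The empty set means the pair is outside the code (neutral).
    """
    return table.preference(aa5, aaL)


@dataclass(frozen=True)
class PPRMotif:
    """One repeat of a PLS array.

    ``index`` is the backwards repeat number (-1 = C-terminal-most PLS
    repeat) and is ``None`` for the E1/E2 motifs.  ``aa5``/``aaL`` may be
    ``None`` when the identity is not known; unknown identities are neutral.
    """

    kind: str
    index: int | None = None
    aa5: str | None = None
    aaL: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in PLS_KINDS and self.kind not in E_KINDS:
            raise ValueError(f"unknown motif class {self.kind!r}")
        if self.kind in PLS_KINDS:
            if self.index is None or self.index >= 0:
                raise ValueError(f"{self.kind} motif requires a negative index")
        elif self.index is not None:
            raise ValueError(f"{self.kind} motif carries no index")
        for aa in (self.aa5, self.aaL):
            if aa is not None and aa not in AMINO_ACIDS:
                raise ValueError(f"invalid amino-acid letter: {aa!r}")

    @property
    def name(self) -> str:
        if self.index is None:
            return self.kind
        return f"{self.kind}{self.index}"

    @property
    def pair(self) -> str:
        return f"{self.aa5 or '?'}{self.aaL or '?'}"


@dataclass(frozen=True)
class PPRArray:
    """An ordered PLS-type repeat array, N- to C-terminal.

    Indexed repeats must increase strictly toward -1 and the array must end
    in S2-1, optionally followed by E1 and E2.
    """

    name: str
    motifs: tuple[PPRMotif, ...]

    def __post_init__(self) -> None:
        indexed = [m for m in self.motifs if m.index is not None]
        if not indexed:
            raise ValueError("array contains no indexed PLS motifs")
        indices = [m.index for m in indexed]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("motif indices must strictly increase toward -1")
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate motif index")
        terminal = indexed[-1]
        if terminal.kind != "S2" or terminal.index != -1:
            raise ValueError("array must end in the terminal S2-1 motif")
        tail = [m.kind for m in self.motifs if m.index is None]
        if tail not in ([], ["E1"], ["E1", "E2"]):
            raise ValueError("E motifs must follow the PLS array as E1[, E2]")
        if tail and self.motifs[-len(tail):][0].index is not None:
            raise ValueError("E motifs must come after all indexed motifs")

    def __iter__(self) -> Iterator[PPRMotif]:
        return iter(self.motifs)

    def motif(self, kind: str, index: int | None = None) -> PPRMotif:
        for m in self.motifs:
            if m.kind == kind and m.index == index:
                return m
        raise KeyError(f"no motif {kind}{index if index is not None else ''}")

    @property
    def indexed_motifs(self) -> tuple[PPRMotif, ...]:
        return tuple(m for m in self.motifs if m.index is not None)

    @property
    def span(self) -> tuple[int, int]:
        """(min, max) target offsets faced by the array incl. E motifs."""
        offsets = list(juxtapose(self).values())
        return min(offsets), max(offsets)

    def to_string(self) -> str:
        """Compact inline form, e.g. ``"L-14??,S-13NS,...,S2-1ND,E1:?N"``."""
        parts = []
        for m in self.motifs:
            if m.index is None:
                parts.append(f"{m.kind}:{m.pair}")
            else:
                parts.append(f"{m.kind}{m.index}{m.pair}")
        return ",".join(parts)

    @classmethod
    def from_string(cls, name: str, text: str) -> "PPRArray":
        motifs = []
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            if token.startswith(("E1:", "E2:")):
                kind, pair = token.split(":")
                motifs.append(PPRMotif(kind, None, _aa(pair[0]), _aa(pair[1])))
                continue
            # e.g. "S2-1ND", "P-12NN", "L-14??"
            minus = token.index("-")
            kind = token[:minus]
            rest = token[minus:]
            i = 1
            while i < len(rest) and rest[i].isdigit():
                i += 1
            index = int(rest[:i])
            pair = rest[i:]
            if len(pair) != 2:
                raise ValueError(f"malformed motif token {token!r}")
            motifs.append(PPRMotif(kind, index, _aa(pair[0]), _aa(pair[1])))
        return cls(name, tuple(motifs))


def _aa(ch: str) -> str | None:
    return None if ch in "?." else ch


def juxtapose(array: PPRArray) -> dict[PPRMotif, int]:
    """Map every motif to the target offset it faces.

    Indexed repeats face ``index - 3`` (S2-1 -> -4); E1 faces -3, E2 -2.
    """
    mapping: dict[PPRMotif, int] = {}
    for m in array.motifs:
        if m.index is not None:
            mapping[m] = m.index - 3
        else:
            mapping[m] = -3 if m.kind == "E1" else -2
    return mapping


@dataclass(frozen=True)
class TargetWindow:
    """A stretch of target sequence indexed by offset from the edited base.

    Offset 0 is the edited cytidine, negative offsets are 5' (upstream).
    Stores RNA alphabet internally; remembers whether the input used T so
    output can honor the source alphabet.
    """

    seq: str
    start: int
    dna_input: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper().replace("T", "U"))
        bad = set(self.seq) - set("ACGUN")
        if bad:
            raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
        if not (self.start <= 0 < self.start + len(self.seq)):
            raise ValueError("window must contain offset 0 (the edited base)")

    @classmethod
    def from_text(cls, seq: str, start: int) -> "TargetWindow":
        return cls(seq=seq, start=start, dna_input="T" in seq.upper())

    @property
    def end(self) -> int:
        """One past the last offset."""
        return self.start + len(self.seq)

    @property
    def offsets(self) -> range:
        return range(self.start, self.end)

    def __contains__(self, offset: int) -> bool:
        return self.start <= offset < self.end

    def __getitem__(self, offset: int) -> str:
        if offset not in self:
            raise KeyError(f"offset {offset} outside window {self.start}..{self.end - 1}")
        return self.seq[offset - self.start]

    def get(self, offset: int, default: str | None = None) -> str | None:
        return self[offset] if offset in self else default

    def with_base(self, offset: int, base: str) -> "TargetWindow":
        base = normalize_rna(base)
        if len(base) != 1:
            raise ValueError("one base at a time")
        i = offset - self.start
        if not 0 <= i < len(self.seq):
            raise KeyError(f"offset {offset} outside window")
        return replace(self, seq=self.seq[:i] + base + self.seq[i + 1:])

    def render(self) -> str:
        """The window sequence in the input alphabet (T if DNA input)."""
        return self.seq.replace("U", "T") if self.dna_input else self.seq


VERDICTS = ("match", "mismatch", "neutral", "not_scored")


@dataclass(frozen=True)
class PositionVerdict:
    offset: int
    motif: PPRMotif
    observed: str | None
    verdict: str


@dataclass(frozen=True)
class MatchReport:
    """Per-position code verdicts for one array/window alignment.

    ``n_match``/``n_mismatch``/``n_scored`` count P/S-class repeats only;
    ``score`` is ``n_match - n_mismatch``.
    """

    records: tuple[PositionVerdict, ...]
    n_match: int
    n_mismatch: int
    n_scored: int

    @property
    def score(self) -> int:
        return self.n_match - self.n_mismatch

    @property
    def mismatch_offsets(self) -> tuple[int, ...]:
        return tuple(r.offset for r in self.records if r.verdict == "mismatch")

    @property
    def match_offsets(self) -> tuple[int, ...]:
        return tuple(r.offset for r in self.records if r.verdict == "match")


@dataclass(frozen=True)
class ScoringOptions:
    """Knobs for code scoring.

    ``score_l`` applies the code table to L-class repeats too (off by
    default: the code is established for P/S-class repeats only).
    ``score_e1_last`` treats the E1 position-34 residue like a PPR "Last"
    residue, using the half-code N -> amino bases {A, C}, D -> keto {G, U}.
    """

    table: CodeTable = DEFAULT_CODE
    score_l: bool = False
    score_e1_last: bool = False
    shift: int = 0


_E1_LAST_HALF_CODE = {"N": frozenset("AC"), "D": frozenset("GU")}


def score_window(
    array: PPRArray,
    window: TargetWindow,
    options: ScoringOptions | None = None,
) -> MatchReport:
    """Apply the PPR-RNA code to a target window, one verdict per repeat.

    A repeat is a *match* if the observed base is in its preference set, a
    *mismatch* if the set is non-empty and the base is not in it, *neutral*
    if the set is empty, and *not_scored* if the repeat class is not scored
    or its offset lies outside the window.  Only P/S-class repeats enter the
    match/mismatch counts.
    """
    opts = options or ScoringOptions()
    records = []
    n_match = n_mismatch = n_scored = 0
    for motif, offset in juxtapose(array).items():
        obs = window.get(offset + opts.shift)
        scored_class = motif.kind in CODE_SCORED_KINDS or (
            opts.score_l and motif.kind in L_CLASS_KINDS
        )
        if motif.kind == "E1" and opts.score_e1_last:
            pref = _E1_LAST_HALF_CODE.get(motif.aaL or "", frozenset())
        elif scored_class:
            pref = opts.table.preference(motif.aa5, motif.aaL)
        else:
            pref = frozenset()
            records.append(PositionVerdict(offset, motif, obs, "not_scored"))
            continue
        if obs is None:
            records.append(PositionVerdict(offset, motif, None, "not_scored"))
            continue
        if not pref or obs == "N":
            verdict = "neutral"
        elif obs in pref:
            verdict = "match"
        else:
            verdict = "mismatch"
        records.append(PositionVerdict(offset, motif, obs, verdict))
        if motif.kind in CODE_SCORED_KINDS:
            n_scored += 1
            n_match += verdict == "match"
            n_mismatch += verdict == "mismatch"
    records.sort(key=lambda r: r.offset)
    return MatchReport(tuple(records), n_match, n_mismatch, n_scored)


@dataclass(frozen=True)
class ScanHit:
    """A candidate editing site found by :func:`scan_sequence`.

    ``position`` is 1-based in the scanned sequence.
    """

    position: int
    center_base: str
    report: MatchReport

    @property
    def score(self) -> int:
        return self.report.score


def scan_sequence(
    array: PPRArray,
    seq: str,
    center_base: str = "C",
    min_matches: int = 0,
    max_mismatches: int | None = None,
    forbid_g_minus1: bool = False,
    options: ScoringOptions | None = None,
) -> list[ScanHit]:
    """Scan a sequence for positions whose upstream context fits the array.

    ``center_base`` selects cytidines (``"C"``, genomically encoded
    candidate sites), uridines (``"U"``, pre-edited T-state candidates) or
    ``"both"``.  Hits must reach ``min_matches`` matches and stay within
    ``max_mismatches``; ``forbid_g_minus1`` drops sites with G immediately
    5' of the center, a base avoided at genuine editing sites.  Hits are
    sorted by descending score, ties by ascending position.
    """
    if center_base not in ("C", "U", "both"):
        raise ValueError("center_base must be 'C', 'U' or 'both'")
    if not seq:
        return []
    rna = normalize_rna(seq)
    wanted = {"C", "U"} if center_base == "both" else {center_base}
    lo, hi = array.span
    hits = []
    for i, base in enumerate(rna):
        if base not in wanted:
            continue
        if forbid_g_minus1 and i > 0 and rna[i - 1] == "G":
            continue
        # the window must cover the juxtaposed offsets and the center base
        start = max(min(lo, 0), -i)
        end = min(max(hi, 0), len(rna) - 1 - i)
        window = TargetWindow(rna[i + start: i + end + 1], start)
        report = score_window(array, window, options)
        if report.n_match < min_matches:
            continue
        if max_mismatches is not None and report.n_mismatch > max_mismatches:
            continue
        hits.append(ScanHit(i + 1, base, report))
    hits.sort(key=lambda h: (-h.score, h.position))
    return hits


def best_offset(
    array: PPRArray,
    window: TargetWindow,
    max_shift: int = 2,
    options: ScoringOptions | None = None,
) -> int:
    """Shift (in nucleotides) giving the most code matches.

    Positive shift slides the array toward 3' of the transcript (each
    repeat reads the base ``shift`` positions downstream of its canonical
    offset).  Ties prefer no shift, then the more negative shift.  0 means
    the canonical S2-1 at -4 register is already optimal.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    opts = options or ScoringOptions()
    best_s, best_n = 0, -1
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s > 0)):
        n = score_window(array, window, replace(opts, shift=s)).n_match
        if n > best_n:
            best_s, best_n = s, n
    return best_s


# ---------------------------------------------------------------------------
# Protein-side mutations applied to arrays


def apply_ppr_mutation(array: PPRArray, mutation) -> PPRArray:
    """Return a new array with one protein mutation applied.

    Accepts the mutation objects from :mod:`ppredit.nomenclature`:
    position 5/Last shorthand exchanges (``S-4TN>TD``), E-motif point
    mutations at position 34 (``E1:N34D``) and N-terminal truncations
    (``trunc:P-12``).  DYW-domain point mutations do not touch the repeat
    array and are rejected here.
    """
    kind = getattr(mutation, "kind", None)
    if kind == "ppr_5L":
        target = array.motif(mutation.motif_kind, mutation.motif_index)
        if target.pair != mutation.from_pair:
            raise ValueError(
                f"motif {target.name} carries {target.pair}, "
                f"not {mutation.from_pair}"
            )
        new = replace(target, aa5=mutation.to_pair[0], aaL=mutation.to_pair[1])
        motifs = tuple(new if m is target else m for m in array.motifs)
        return replace(array, motifs=motifs)
    if kind == "domain_point":
        if mutation.domain not in E_KINDS:
            raise ValueError(
                f"{mutation.domain} mutations do not address the PPR array"
            )
        if mutation.position != 34:
            raise ValueError("only position 34 (Last) of E motifs is modeled")
        target = array.motif(mutation.domain)
        if target.aaL != mutation.from_aa:
            raise ValueError(
                f"{mutation.domain} position 34 is {target.aaL}, "
                f"not {mutation.from_aa}"
            )
        new = replace(target, aaL=mutation.to_aa)
        motifs = tuple(new if m is target else m for m in array.motifs)
        return replace(array, motifs=motifs)
    if kind == "truncation":
        target = array.motif(mutation.motif_kind, mutation.motif_index)
        idx = array.motifs.index(target)
        remaining = array.motifs[idx + 1:]
        return replace(array, motifs=remaining)
    raise ValueError(f"unsupported mutation kind {kind!r}")


def apply_protein_mutations(array: PPRArray, mutations: Sequence) -> PPRArray:
    for mut in mutations:
        array = apply_ppr_mutation(array, mut)
    return array


# ---------------------------------------------------------------------------
# Tabular I/O for arrays

def write_array_tsv(array: PPRArray, path) -> None:
    """Write the motif table (columns: kind, index, aa5, aaL; '.' = unknown)."""
    with open(path, "w") as fh:
        fh.write("# PPR array: one motif per row, N- to C-terminal\n")
        fh.write("kind\tindex\taa5\taaL\n")
        for m in array.motifs:
            fh.write(
                f"{m.kind}\t{m.index if m.index is not None else '.'}"
                f"\t{m.aa5 or '.'}\t{m.aaL or '.'}\n"
            )


def read_array_tsv(path, name: str = "array") -> PPRArray:
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("kind\t"):
                continue
            kind, index, aa5, aaL = line.split("\t")
            motifs.append(
                PPRMotif(
                    kind,
                    None if index == "." else int(index),
                    _aa(aa5),
                    _aa(aaL),
                )
            )
    return PPRArray(name, tuple(motifs))
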