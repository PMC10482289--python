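"""Label grammars for editing sites, target variants and protein mutations.

Three plain-text grammars are implemented:

* **Editing-site labels** — locus + ``eU`` + transcript position (1-based
  from the A of the AUG start codon; negative = upstream of the start, no
  zero) + the codon change, e.g. ``nad4eU272SL`` (serine to leucine) or
  ``fdhEeU403Q*`` (glutamine to stop).  Sites outside a CDS carry no codon
  suffix (``folDeU-5``).
* **Target-variant labels** — a site label followed by pipe-separated
  lower-case substitutions at offsets relative to the edited base, e.g.
  ``nad4eU272SL|u-4g`` (U-to-G four nucleotides upstream) or ``...|c0u``
  (the edited cytidine itself replaced by uridine: the pre-edited state).
* **Protein-mutation labels** — factor name plus pipe-separated segments:
  domain points ``DYW:G3A`` / ``E1:N34D``, repeat 5/Last shorthand
  ``S-4TN>TD``, and N-terminal truncations ``trunc:P-12`` (an extension;
  removes all repeats up to and including the named one).

Site naming from annotation (GFF3/BED12) and enumeration of stop/start
codon designs creatable by C-to-U editing live here too.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .ppr_code import AMINO_ACIDS, PLS_KINDS, TargetWindow, normalize_rna


class LabelError(ValueError):
    """A label does not follow its grammar."""


# ---------------------------------------------------------------------------
# Protein mutations


@dataclass(frozen=True)
class DomainPointMutation:
    """Single amino-acid exchange inside a named domain (DYW, E1 or E2)."""

    domain: str
    position: int
    from_aa: str
    to_aa: str
    kind: str = "domain_point"

    def __str__(self) -> str:
        return f"{self.domain}:{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class Ppr5LMutation:
    """Exchange of the position 5/Last pair of one repeat (``S-4TN>TD``)."""

    motif_kind: str
    motif_index: int
    from_pair: str
    to_pair: str
    kind: str = "ppr_5L"

    def __str__(self) -> str:
        return f"{self.motif_kind}{self.motif_index}{self.from_pair}>{self.to_pair}"

    def inverse(self) -> "Ppr5LMutation":
        return Ppr5LMutation(
            self.motif_kind, self.motif_index, self.to_pair, self.from_pair
        )


@dataclass(frozen=True)
class TruncationMutation:
    """Removal of all repeats N-terminal of and including the named one."""

    motif_kind: str
    motif_index: int
    kind: str = "truncation"

    def __str__(self) -> str:
        return f"trunc:{self.motif_kind}{self.motif_index}"


ProteinMutation = DomainPointMutation | Ppr5LMutation | TruncationMutation


@dataclass(frozen=True)
class ProteinLabel:
    factor: str
    mutations: tuple[ProteinMutation, ...]

    def __str__(self) -> str:
        return format_protein_label(self)


_DOMAIN_RE = re.compile(r"^(DYW|E1|E2):([A-Z])(\d+)([A-Z])$")
_PPR5L_RE = re.compile(r"^(P2|L2|S2|P|L|S)(-\d+)([A-Z]{2})>([A-Z]{2})$")
_TRUNC_RE = re.compile(r"^trunc:(P2|L2|S2|P|L|S)(-\d+)$")


def _parse_mutation_segment(segment: str) -> ProteinMutation:
    if m := _DOMAIN_RE.match(segment):
        domain, from_aa, pos, to_aa = m.groups()
        for aa in (from_aa, to_aa):
            if aa not in AMINO_ACIDS:
                raise LabelError(f"invalid amino acid in segment {segment!r}")
        return DomainPointMutation(domain, int(pos), from_aa, to_aa)
    if m := _PPR5L_RE.match(segment):
        kind, index, from_pair, to_pair = m.groups()
        for pair in (from_pair, to_pair):
            if not set(pair) <= AMINO_ACIDS:
                raise LabelError(f"invalid amino acid in segment {segment!r}")
        return Ppr5LMutation(kind, int(index), from_pair, to_pair)
    if m := _TRUNC_RE.match(segment):
        return TruncationMutation(m.group(1), int(m.group(2)))
    raise LabelError(f"cannot parse protein-mutation segment {segment!r}")


def parse_protein_label(label: str) -> ProteinLabel:
    """Parse ``"PPR56|S-7TD>TN|S-4TN>TD"`` into factor + ordered mutations."""
    parts = label.split("|")
    factor = parts[0].strip()
    if not factor:
        raise LabelError("empty factor name")
    mutations = tuple(_parse_mutation_segment(seg.strip()) for seg in parts[1:])
    seen = set()
    for mut in mutations:
        key = (getattr(mut, "domain", None), getattr(mut, "motif_kind", None),
               getattr(mut, "motif_index", None), getattr(mut, "position", None))
        if key in seen:
            raise LabelError(f"chained mutations address {key} twice")
        seen.add(key)
    return ProteinLabel(factor, mutations)


def format_protein_label(label: ProteinLabel) -> str:
    return "|".join([label.factor, *(str(m) for m in label.mutations)])


# ---------------------------------------------------------------------------
# Editing-site labels


@dataclass(frozen=True)
class SiteLabel:
    """``nad4eU272SL``: locus, 1-based CDS position, codon change.

    ``position`` counts from the first nucleotide of the start codon;
    negative values are upstream of the start (there is no position 0).
    ``aa_from``/``aa_to`` are present only for sites inside an annotated
    CDS; stop is rendered ``*``.
    """

    locus: str
    position: int
    aa_from: str | None = None
    aa_to: str | None = None

    def __post_init__(self) -> None:
        if self.position == 0:
            raise LabelError("site positions are 1-based; 0 does not exist")
        if (self.aa_from is None) != (self.aa_to is None):
            raise LabelError("codon change requires both amino acids")
        if self.aa_from is not None and self.position < 0:
            raise LabelError("upstream sites carry no codon change")

    def __str__(self) -> str:
        suffix = f"{self.aa_from}{self.aa_to}" if self.aa_from else ""
        return f"{self.locus}eU{self.position}{suffix}"


_SITE_RE = re.compile(r"^(.+?)eU(-?\d+)([A-Z*]{2})?$")


def parse_site_label(label: str) -> SiteLabel:
    m = _SITE_RE.match(label.strip())
    if not m:
        raise LabelError(f"cannot parse site label {label!r} (missing 'eU'?)")
    locus, pos, change = m.groups()
    aa_from = aa_to = None
    if change:
        aa_from, aa_to = change[0], change[1]
        for aa in (aa_from, aa_to):
            if aa != "*" and aa not in AMINO_ACIDS:
                raise LabelError(f"invalid amino acid {aa!r} in {label!r}")
    return SiteLabel(locus, int(pos), aa_from, aa_to)


# ---------------------------------------------------------------------------
# Target variants


@dataclass(frozen=True)
class Substitution:
    """One nucleotide exchange at a signed offset from the edited base."""

    offset: int
    from_nt: str
    to_nt: str

    def __post_init__(self) -> None:
        for nt in (self.from_nt, self.to_nt):
            if nt not in "acgu":
                raise LabelError(f"substitution bases are lower-case RNA: {nt!r}")
        if self.from_nt == self.to_nt:
            raise LabelError("substitution must change the base")

    def __str__(self) -> str:
        sign = "+" if self.offset > 0 else ""
        return f"{self.from_nt}{sign}{self.offset}{self.to_nt}"

    def inverse(self) -> "Substitution":
        return Substitution(self.offset, self.to_nt, self.from_nt)


@dataclass(frozen=True)
class TargetVariant:
    base_site: SiteLabel
    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        offsets = [s.offset for s in self.substitutions]
        if len(set(offsets)) != len(offsets):
            raise LabelError("duplicate substitution offset")

    def __str__(self) -> str:
        return "|".join([str(self.base_site), *(str(s) for s in self.substitutions)])


_SUBST_RE = re.compile(r"^([acgut])([+-]?\d+)([acgut])$")


def parse_target_label(label: str) -> TargetVariant:
    """Parse ``"nad3eU230SL|u-16a|u-9g|c-6u"`` (``t`` accepted for ``u``)."""
    parts = label.strip().split("|")
    base = parse_site_label(parts[0])
    subs = []
    for seg in parts[1:]:
        m = _SUBST_RE.match(seg.strip())
        if not m:
            raise LabelError(f"cannot parse substitution segment {seg!r}")
        from_nt, offset, to_nt = m.groups()
        subs.append(
            Substitution(
                int(offset),
                from_nt.replace("t", "u"),
                to_nt.replace("t", "u"),
            )
        )
    return TargetVariant(base, tuple(subs))


def apply_target_mutations(
    window: TargetWindow, variant: TargetVariant | Sequence[Substitution]
) -> TargetWindow:
    """Install a variant's substitutions into a target window.

    Every substitution's *from* base must match the window (consistency
    check); the input window is left untouched.
    """
    subs = variant.substitutions if isinstance(variant, TargetVariant) else variant
    out = window
    for sub in subs:
        if sub.offset not in out:
            raise LabelError(f"offset {sub.offset} outside window")
        have = out[sub.offset]
        if have != sub.from_nt.upper():
            raise LabelError(
                f"window has {have} at offset {sub.offset}, "
                f"substitution expects {sub.from_nt.upper()}"
            )
        out = out.with_base(sub.offset, sub.to_nt)
    return out


# ---------------------------------------------------------------------------
# Naming sites from a CDS anchor


def name_site(
    locus: str,
    transcript: str,
    cds_start: int,
    edit_position: int,
    cds_end: int | None = None,
) -> SiteLabel:
    """Name a C-to-U edit from a start-codon-anchored transcript.

    ``transcript`` is the strand-oriented (coding) sequence; ``cds_start``
    and ``edit_position`` are 1-based coordinates within it, ``cds_start``
    pointing at the A of the start codon.  Positions upstream of the start
    get negative labels without a codon suffix.  The codon change uses the
    standard genetic code, stop rendered ``*``.
    """
    rna = normalize_rna(transcript)
    if not 1 <= edit_position <= len(rna):
        raise ValueError("edit position outside the transcript")
    if edit_position < cds_start:
        return SiteLabel(locus, edit_position - cds_start)
    pos = edit_position - cds_start + 1  # 1-based CDS coordinate
    if cds_end is None:
        cds_end = len(rna)
    if edit_position > cds_end:
        # downstream of the CDS: positive position, no codon change
        return SiteLabel(locus, pos)
    if rna[edit_position - 1] != "C":
        raise ValueError(
            f"edited base at CDS position {pos} is {rna[edit_position - 1]}, not C"
        )
    codon_index = math.ceil(pos / 3)
    codon_start = cds_start - 1 + 3 * (codon_index - 1)
    codon = rna[codon_start: codon_start + 3]
    if len(codon) < 3:
        return SiteLabel(locus, pos)
    within = pos - 1 - 3 * (codon_index - 1)
    edited = codon[:within] + "U" + codon[within + 1:]
    aa_from = str(Seq(codon).translate())
    aa_to = str(Seq(edited).translate())
    return SiteLabel(locus, pos, aa_from, aa_to)


# ---------------------------------------------------------------------------
# Codon engineering: stops and starts creatable by C-to-U editing


@dataclass(frozen=True)
class CodonDesign:
    """A minimal substitution set creating a stop or start codon by editing.

    ``codon`` is read after the C(0) -> U conversion; substitutions only
    touch offsets -1, +1 and +2, never the edited base itself.
    """

    category: str  # "stop" or "start"
    codon: str
    substitutions: tuple[Substitution, ...]


STOP_CODONS = ("UAA", "UAG", "UGA")


def design_codon_edits(window: TargetWindow) -> list[CodonDesign]:
    """Enumerate stop/start codons creatable by editing the central C.

    Stops place the edited U at the first codon position (frame 0,+1,+2);
    the start places it in the middle of AUG (frame -1,0,+1).  One design
    per achievable codon with the minimal substitutions required; an empty
    substitution set means the window already reads the codon after
    editing.
    """
    for off in (-1, 0, 1, 2):
        if off not in window:
            raise ValueError("window must span offsets -1..+2")
    if window[0] != "C":
        raise ValueError("no cytidine at offset 0")
    designs = []
    for stop in STOP_CODONS:
        subs = tuple(
            Substitution(off, window[off].lower(), stop[i].lower())
            for i, off in enumerate((0, 1, 2))
            if off != 0 and window[off] != stop[i]
        )
        designs.append(CodonDesign("stop", stop, subs))
    start_subs = tuple(
        Substitution(off, window[off].lower(), base)
        for off, base in ((-1, "a"), (1, "g"))
        if window[off] != base.upper()
    )
    designs.append(CodonDesign("start", "AUG", start_subs))
    return designs


# ---------------------------------------------------------------------------
# Annotation-backed naming (GFF3 / BED12)


@dataclass(frozen=True)
class CdsModel:
    """A spliced CDS: locus name, contig, strand and exon blocks.

    Blocks are 1-based inclusive (start, end) pairs in genomic order.
    """

    locus: str
    contig: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def cds_position(self, genomic_pos: int) -> int | None:
        """1-based spliced CDS coordinate of a genomic position, or None."""
        offset = 0
        blocks = self.blocks if self.strand == "+" else self.blocks[::-1]
        for start, end in blocks:
            if start <= genomic_pos <= end:
                if self.strand == "+":
                    return offset + genomic_pos - start + 1
                return offset + end - genomic_pos + 1
            offset += end - start + 1
        return None

    def upstream_offset(self, genomic_pos: int) -> int | None:
        """Negative offset if the position is 5' of the start codon."""
        if self.strand == "+":
            first = min(s for s, _ in self.blocks)
            if genomic_pos < first:
                return genomic_pos - first
        else:
            last = max(e for _, e in self.blocks)
            if genomic_pos > last:
                return last - genomic_pos
        return None

    def spliced_sequence(self, contig_seq: str) -> str:
        """Strand-oriented CDS sequence from a plus-strand contig string."""
        from .ppr_code import reverse_complement

        parts = [contig_seq[s - 1: e] for s, e in self.blocks]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


def read_cds_gff3(path) -> list[CdsModel]:
    """Read CDS models from GFF3, grouping CDS features by parent/ID.

    The locus name is taken from ``gene``, ``Name`` or ``Parent``/``ID``
    attributes, in that order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", []) or feat.attributes.get("ID", [])
        key = parents[0] if parents else f"{feat.seqid}:{feat.start}"
        groups.setdefault(key, []).append(feat)
    models = []
    for key, feats in groups.items():
        feats.sort(key=lambda f: f.start)
        first = feats[0]
        locus = (
            first.attributes.get("gene", [None])[0]
            or first.attributes.get("Name", [None])[0]
            or key
        )
        models.append(
            CdsModel(
                locus,
                first.seqid,
                first.strand,
                tuple((f.start, f.end) for f in feats),
            )
        )
    return models


def read_cds_bed12(path) -> list[CdsModel]:
    """Read CDS models from BED12 (thickStart/thickEnd delimit the CDS)."""
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise LabelError("BED12 requires 12 columns")
            contig, chrom_start, _, name, _, strand = f[0], int(f[1]), f[2], f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = []
            for size, rel in zip(sizes, starts):
                b_start = chrom_start + rel
                b_end = b_start + size
                s = max(b_start, thick_start)
                e = min(b_end, thick_end)
                if s < e:
                    blocks.append((s + 1, e))  # to 1-based inclusive
            if blocks:
                models.append(CdsModel(name, contig, strand, tuple(blocks)))
    return models


def name_site_from_annotation(
    contig: str,
    position: int,
    strand: str,
    models: Iterable[CdsModel],
    reference: dict[str, str],
    max_upstream: int = 200,
) -> str:
    """Label a genomic edit using CDS annotation; raw form if unannotated.

    Returns the ``locus eU position codon-change`` label when the site lies
    in a CDS on the matching strand, a negative-offset label when within
    ``max_upstream`` nucleotides 5' of a start codon, and the raw
    ``contig:position`` form otherwise.
    """
    candidates = [m for m in models if m.contig == contig and m.strand == strand]
    for model in candidates:
        cds_pos = model.cds_position(position)
        if cds_pos is not None:
            seq = model.spliced_sequence(reference[contig])
            return str(name_site(model.locus, seq, 1, cds_pos, cds_end=len(seq)))
    best = None
    for model in candidates:
        off = model.upstream_offset(position)
        if off is not None and -max_upstream <= off:
            if best is None or off > best[0]:
                best = (off, model.locus)
    if best is not None:
        return str(SiteLabel(best[1], best[0]))
    return f"{contig}:{position}"
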