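"""C-to-U off-target calling from per-site base-count tables.

The caller works downstream of external read alignment and per-base variant
calling (e.g. JACUSA exports): its input is one row per (dataset, contig,
position) with RNA base counts on the plus strand, optionally DNA base
counts.  A site is considered a candidate when the reference base is C
(forward edit, RNA reads T) or G (reverse-strand edit, RNA reads A) and
passes four per-dataset criteria:

(i)   RNA read coverage of at least 30,
(ii)  a clear transition signal in the RNA reads (C+T, or G+A, > 99%),
(iii) a clear DNA reference position (C, or G, > 98% of DNA reads),
(iv)  a C-to-U signal of at least 1%.

Sites must then pass in at least two datasets from expression of the same
protein and must be silent in every control dataset (wild-type or other
factors).  The final editing efficiency adds up reads over all supporting
("hitting") datasets: sum(edited) / sum(edited + unedited), i.e. the
coverage-weighted mean of per-dataset fractions.  The Sanger-trace
quantifier T/(T+C) is included for single-construct assays.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SiteCounts:
    """Per-dataset base-count evidence at one genomic position (plus strand)."""

    dataset_id: str
    contig: str
    position: int  # 1-based
    dna_ref: str
    rna_counts: tuple[int, int, int, int]  # A, C, G, T
    dna_counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.dna_ref not in BASES:
            raise ValueError(f"invalid reference base {self.dna_ref!r}")
        if any(c < 0 for c in self.rna_counts):
            raise ValueError("negative RNA count")
        if self.dna_counts is not None and any(c < 0 for c in self.dna_counts):
            raise ValueError("negative DNA count")

    @property
    def coverage(self) -> int:
        return sum(self.rna_counts)

    def rna(self, base: str) -> int:
        return self.rna_counts[BASES.index(base)]

    def dna(self, base: str) -> int:
        if self.dna_counts is None:
            raise ValueError("no DNA counts")
        return self.dna_counts[BASES.index(base)]


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the filter cascade.

    Purity criteria use strict ``>`` (as stated: "> 99%", "> 98%");
    coverage and edit signal use ``>=`` ("at least 30", "at least 1%").
    The control-exclusion knobs are not quantified in the source procedure
    ("not in wild-type") and are exposed here: a control dataset vetoes a
    site when it shows an edit fraction of at least ``min_control_frac`` at
    coverage ``min_control_coverage`` or more.
    """

    min_coverage: int = 30
    min_transition_purity: float = 0.99
    min_dna_purity: float = 0.98
    min_edit_frac: float = 0.01
    min_replicates: int = 2
    min_control_frac: float = 0.01
    min_control_coverage: int = 10
    #: compute the edit signal as edited/(edited+unedited) (default) or
    #: edited/coverage
    edit_frac_over_transition: bool = True

    def __post_init__(self) -> None:
        for frac in (
            self.min_transition_purity,
            self.min_dna_purity,
            self.min_edit_frac,
            self.min_control_frac,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.min_coverage < 1 or self.min_replicates < 1:
            raise ValueError("min_coverage and min_replicates must be >= 1")


@dataclass(frozen=True)
class DatasetSet:
    """Treatment replicates of one protein and the control datasets."""

    protein_label: str
    treatment: tuple[str, ...]
    control: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.treatment) & set(self.control):
            raise ValueError("treatment and control dataset ids overlap")


@dataclass(frozen=True)
class Orientation:
    strand: str  # '+' forward C->T edit, '-' reverse (G->A on plus strand)
    edited_reads: int
    unedited_reads: int
    transition_purity: float
    edit_frac: float


def orient(site: SiteCounts) -> Orientation | None:
    """Resolve strand and the edited/unedited read split, or not-a-candidate.

    Reference C: forward site, edited reads are T, purity (C+T)/coverage.
    Reference G: reverse site, edited reads are A, purity (G+A)/coverage.
    A/T references cannot host a C-to-U edit and return ``None``.
    """
    cov = site.coverage
    if cov == 0 or site.dna_ref in ("A", "T"):
        return None
    if site.dna_ref == "C":
        strand, edited, unedited = "+", site.rna("T"), site.rna("C")
    else:
        strand, edited, unedited = "-", site.rna("A"), site.rna("G")
    purity = (edited + unedited) / cov
    frac = edited / (edited + unedited) if edited + unedited else 0.0
    return Orientation(strand, edited, unedited, purity, frac)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the four per-dataset criteria for one site record."""

    orientation: Orientation | None
    coverage_ok: bool
    transition_ok: bool
    dna_ok: bool
    signal_ok: bool
    dna_assumed_pure: bool

    @property
    def passed(self) -> bool:
        return (
            self.orientation is not None
            and self.coverage_ok
            and self.transition_ok
            and self.dna_ok
            and self.signal_ok
        )

    @property
    def first_failure(self) -> str | None:
        if self.orientation is None:
            return "not_candidate"
        for name, ok in (
            ("coverage", self.coverage_ok),
            ("transition_purity", self.transition_ok),
            ("dna_purity", self.dna_ok),
            ("edit_signal", self.signal_ok),
        ):
            if not ok:
                return name
        return None


def passes_filters(site: SiteCounts, params: CallerParams) -> FilterVerdict:
    """Evaluate criteria (i)-(iv) independently for one site record."""
    ori = orient(site)
    if ori is None:
        return FilterVerdict(None, False, False, False, False, False)
    coverage_ok = site.coverage >= params.min_coverage
    transition_ok = ori.transition_purity > params.min_transition_purity
    dna_assumed = site.dna_counts is None or sum(site.dna_counts) == 0
    if dna_assumed:
        dna_ok = True
    else:
        ref_base = "C" if ori.strand == "+" else "G"
        dna_ok = site.dna(ref_base) / sum(site.dna_counts) > params.min_dna_purity
    if params.edit_frac_over_transition:
        signal = ori.edit_frac
    else:
        signal = ori.edited_reads / site.coverage
    signal_ok = signal >= params.min_edit_frac
    return FilterVerdict(ori, coverage_ok, transition_ok, dna_ok, signal_ok, dna_assumed)


@dataclass(frozen=True)
class OffTargetCall:
    """A replicate-supported C-to-U editing site."""

    contig: str
    position: int
    strand: str
    per_dataset: tuple[tuple[str, int, int], ...]  # (dataset, edited, unedited)
    aggregate_efficiency: float
    supporting_dataset_ids: tuple[str, ...]
    label: str | None = None
    shift_class: int | None = None

    @property
    def fractions(self) -> dict[str, float]:
        return {d: e / (e + u) for d, e, u in self.per_dataset if e + u}


@dataclass
class CallStats:
    """Per-filter rejection tallies accumulated during a calling run."""

    records: int = 0
    rejections: Counter = field(default_factory=Counter)
    candidate_sites: int = 0
    failed_replicate_rule: int = 0
    failed_control_rule: int = 0
    called: int = 0

    def as_dict(self) -> dict:
        return {
            "records": self.records,
            "rejections": dict(self.rejections),
            "candidate_sites": self.candidate_sites,
            "failed_replicate_rule": self.failed_replicate_rule,
            "failed_control_rule": self.failed_control_rule,
            "called": self.called,
        }


def aggregate_efficiency(evidence: Iterable[tuple[int, int]]) -> float:
    """Read-sum efficiency over supporting datasets.

    ``evidence`` holds (edited, unedited) pairs; the result is
    sum(edited)/sum(edited+unedited), i.e. the coverage-weighted mean of
    the per-dataset fractions.
    """
    edited = unedited = 0
    for e, u in evidence:
        edited += e
        unedited += u
    if edited + unedited == 0:
        raise ValueError("aggregate efficiency undefined without reads")
    return edited / (edited + unedited)


def quantify_peaks(peak_t: float, peak_c: float) -> float:
    """Sanger-trace editing fraction: T peak over (T + C) peaks."""
    if peak_t < 0 or peak_c < 0:
        raise ValueError("peak heights must be non-negative")
    if peak_t + peak_c == 0:
        raise ValueError("editing fraction undefined for two zero peaks")
    return peak_t / (peak_t + peak_c)


def call_offtargets(
    sets: DatasetSet,
    counts: Iterable[SiteCounts],
    params: CallerParams = CallerParams(),
    annotate=None,
    classify_shift=None,
) -> tuple[list[OffTargetCall], CallStats]:
    """Run the full cascade: per-dataset filters, replicate rule, controls.

    A site (contig, position, strand) is called iff it passes criteria
    (i)-(iv) in at least ``min_replicates`` treatment datasets and no
    control dataset shows an edit fraction >= ``min_control_frac`` at
    coverage >= ``min_control_coverage`` for the same oriented site.
    Aggregation uses the supporting treatment datasets only.  ``annotate``
    and ``classify_shift`` are optional callbacks ``(contig, position,
    strand) -> str | int`` attaching site labels and shift classes.
    Output is sorted by contig, position, strand.
    """
    treatment = set(sets.treatment)
    control = set(sets.control)
    if len(treatment) < params.min_replicates:
        raise ValueError(
            f"need at least {params.min_replicates} treatment datasets, "
            f"got {len(treatment)}"
        )
    stats = CallStats()
    supporting: dict[tuple[str, int, str], list[tuple[str, int, int]]] = {}
    vetoed: set[tuple[str, int, str]] = set()
    for site in counts:
        if site.dataset_id in treatment:
            stats.records += 1
            verdict = passes_filters(site, params)
            if not verdict.passed:
                stats.rejections[verdict.first_failure or "unknown"] += 1
                continue
            ori = verdict.orientation
            key = (site.contig, site.position, ori.strand)
            supporting.setdefault(key, []).append(
                (site.dataset_id, ori.edited_reads, ori.unedited_reads)
            )
        elif site.dataset_id in control:
            ori = orient(site)
            if (
                ori is not None
                and site.coverage >= params.min_control_coverage
                and ori.edit_frac >= params.min_control_frac
            ):
                vetoed.add((site.contig, site.position, ori.strand))
    calls = []
    for key in sorted(supporting):
        evidence = sorted(supporting[key])
        stats.candidate_sites += 1
        datasets = {d for d, _, _ in evidence}
        if len(datasets) < params.min_replicates:
            stats.failed_replicate_rule += 1
            continue
        if key in vetoed:
            stats.failed_control_rule += 1
            continue
        contig, position, strand = key
        eff = aggregate_efficiency((e, u) for _, e, u in evidence)
        calls.append(
            OffTargetCall(
                contig=contig,
                position=position,
                strand=strand,
                per_dataset=tuple(evidence),
                aggregate_efficiency=eff,
                supporting_dataset_ids=tuple(sorted(datasets)),
                label=annotate(contig, position, strand) if annotate else None,
                shift_class=(
                    classify_shift(contig, position, strand)
                    if classify_shift
                    else None
                ),
            )
        )
    stats.called = len(calls)
    logger.info(
        "called %d sites from %d records (%d candidates; %d below replicate "
        "rule, %d control-excluded)",
        stats.called,
        stats.records,
        stats.candidate_sites,
        stats.failed_replicate_rule,
        stats.failed_control_rule,
    )
    return calls, stats


# ---------------------------------------------------------------------------
# Tabular I/O

#: native column schema of per-site count tables
NATIVE_COLUMNS = ("contig", "pos", "ref", "A", "C", "G", "T", "dataset")
DNA_COLUMNS = ("dna_A", "dna_C", "dna_G", "dna_T")


def read_site_counts(
    path,
    column_map: Mapping[str, str] | None = None,
    dataset_id: str | None = None,
) -> list[SiteCounts]:
    """Read a per-site count TSV (native schema or mapped export).

    ``column_map`` renames foreign columns onto the native schema, e.g.
    ``{"contig": "#contig", "pos": "position", "rna_bases": "bases11"}``.
    A mapped ``rna_bases`` (and optionally ``dna_bases``) column holds
    comma-separated A,C,G,T counts as in JACUSA-style exports.  Rows with
    zero RNA coverage are dropped (logged).  ``dataset_id`` supplies the
    dataset for tables lacking a dataset column.
    """
    df = pd.read_csv(path, sep="\t", comment=None)
    if column_map:
        packed_rna = column_map.get("rna_bases")
        packed_dna = column_map.get("dna_bases")
        rename = {
            src: dst
            for dst, src in column_map.items()
            if dst not in ("rna_bases", "dna_bases")
        }
        df = df.rename(columns=rename)
        if packed_rna:
            split = df[packed_rna].astype(str).str.split(",", expand=True)
            df[["A", "C", "G", "T"]] = split.astype(int)
        if packed_dna:
            split = df[packed_dna].astype(str).str.split(",", expand=True)
            df[list(DNA_COLUMNS)] = split.astype(int)
    missing = {"contig", "pos", "ref", "A", "C", "G", "T"} - set(df.columns)
    if missing:
        raise ValueError(f"missing mandatory columns: {sorted(missing)}")
    if "dataset" not in df.columns:
        if dataset_id is None:
            raise ValueError("no dataset column and no dataset_id given")
        df["dataset"] = dataset_id
    has_dna = all(c in df.columns for c in DNA_COLUMNS)
    records = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rna = (int(row.A), int(row.C), int(row.G), int(row.T))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric count at line {i}") from exc
        if sum(rna) == 0:
            dropped += 1
            continue
        dna = None
        if has_dna:
            dna = tuple(int(getattr(row, c)) for c in DNA_COLUMNS)
        records.append(
            SiteCounts(
                dataset_id=str(row.dataset),
                contig=str(row.contig),
                position=int(row.pos),
                dna_ref=str(row.ref).upper(),
                rna_counts=rna,
                dna_counts=dna,
            )
        )
    if dropped:
        logger.info("dropped %d zero-coverage rows from %s", dropped, path)
    return records


def write_site_counts(records: Sequence[SiteCounts], path) -> None:
    """Write records in the native schema (1-based, fully closed coords)."""
    rows = []
    has_dna = any(r.dna_counts is not None for r in records)
    for r in records:
        row = {
            "contig": r.contig,
            "pos": r.position,
            "ref": r.dna_ref,
            "A": r.rna_counts[0],
            "C": r.rna_counts[1],
            "G": r.rna_counts[2],
            "T": r.rna_counts[3],
            "dataset": r.dataset_id,
        }
        if has_dna:
            dna = r.dna_counts or (0, 0, 0, 0)
            row.update(dict(zip(DNA_COLUMNS, dna)))
        rows.append(row)
    cols = list(NATIVE_COLUMNS) + (list(DNA_COLUMNS) if has_dna else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_calls(calls: Sequence[OffTargetCall], path) -> None:
    """Off-target table: 1-based positions, per-dataset fractions inline."""
    rows = []
    for c in calls:
        fracs = ";".join(
            f"{d}:{e}/{e + u}" for d, e, u in c.per_dataset
        )
        rows.append(
            {
                "contig": c.contig,
                "position": c.position,
                "strand": c.strand,
                "label": c.label or ".",
                "n_supporting": len(c.supporting_dataset_ids),
                "per_dataset": fracs,
                "aggregate_efficiency": f"{c.aggregate_efficiency:.6g}",
                "shift_class": "." if c.shift_class is None else c.shift_class,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "contig",
            "position",
            "strand",
            "label",
            "n_supporting",
            "per_dataset",
            "aggregate_efficiency",
            "shift_class",
        ],
    ).to_csv(path, sep="\t", index=False)
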