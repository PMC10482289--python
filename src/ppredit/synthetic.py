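"""Self-contained synthetic editing experiments.

Generates everything the pipeline consumes without external data: a random
reference with planted editing-site contexts (the native nad4/nad3 windows
or windows sampled to match the repeat array), per-dataset per-site RNA and
DNA base-count tables with binomial C-to-U editing at the planted
efficiencies, negative-binomial coverage, uniform sequencing error,
replicate treatment datasets, control datasets, decoy sites engineered to
fail exactly one filter criterion each, and noisy Sanger peak pairs.

All randomness flows from one seed through per-dataset child streams, so a
fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .builtin import NAD3_WINDOW, NAD4_WINDOW, PPR56
from .offtarget_caller import SiteCounts
from .ppr_code import (
    CODE_SCORED_KINDS,
    DEFAULT_CODE,
    PPRArray,
    TargetWindow,
    juxtapose,
    reverse_complement,
)

RNA = "ACGU"
DNA = "ACGT"

#: decoy kinds, one per filter criterion plus the two set-level rules
DECOY_KINDS = (
    "coverage",
    "transition_purity",
    "dna_purity",
    "edit_signal",
    "replicate",
    "control",
)


@dataclass(frozen=True)
class PlantedSite:
    """One planted editing site: context source, efficiency, decoy role."""

    name: str
    efficiency: float
    source: str = "sampled"  # "nad4", "nad3" or "sampled"
    mismatches: int = 0
    decoy: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        if self.source not in ("nad4", "nad3", "sampled"):
            raise ValueError(f"unknown context source {self.source!r}")
        if self.decoy is not None and self.decoy not in DECOY_KINDS:
            raise ValueError(f"unknown decoy kind {self.decoy!r}")


def default_planted_sites() -> tuple[PlantedSite, ...]:
    """20 true sites with efficiencies 0.02-0.99 plus one decoy per rule.

    The first two sites carry the native nad4/nad3 contexts; the rest are
    sampled to match the PPR56 array (a few with planted mismatches).
    """
    efficiencies = np.linspace(0.02, 0.99, 20)
    sites = []
    for i, eff in enumerate(efficiencies):
        if i == 0:
            src, mm = "nad4", 0
        elif i == 1:
            src, mm = "nad3", 0
        else:
            src, mm = "sampled", i % 3
        sites.append(PlantedSite(f"site{i + 1:02d}", round(float(eff), 4), src, mm))
    for kind in DECOY_KINDS:
        sites.append(
            PlantedSite(f"decoy_{kind}", 0.30, "sampled", 0, decoy=kind)
        )
    return tuple(sites)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    reference_length: int = 5000
    gc_content: float = 0.5
    n_treatment_datasets: int = 3
    n_control_datasets: int = 1
    coverage_mean: float = 200.0
    coverage_dispersion: float = 5.0
    error_rate: float = 0.001
    dna_coverage: int = 100
    dna_error_rate: float = 0.0005
    contig: str = "synth1"
    planted: tuple[PlantedSite, ...] = field(default_factory=default_planted_sites)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must lie in [0, 0.05]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("GC content must lie in (0, 1)")

    @property
    def treatment_ids(self) -> tuple[str, ...]:
        return tuple(f"treat{i + 1}" for i in range(self.n_treatment_datasets))

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(f"ctrl{i + 1}" for i in range(self.n_control_datasets))


@dataclass(frozen=True)
class GroundTruthSite:
    """Where a site was planted and what the caller should see."""

    name: str
    contig: str
    position: int  # 1-based, plus strand, the edited C (or G on minus)
    strand: str
    efficiency: float
    decoy: str | None
    context: str  # strand-oriented window sequence, edited base at index 16


def sample_matching_window(
    rng: np.random.Generator,
    array: PPRArray = PPR56,
    mismatches: int = 0,
) -> TargetWindow:
    """Draw a -16..+2 window matching the array's code preferences.

    P/S-class offsets read a base from the repeat's preference set except
    at ``mismatches`` randomly chosen scored offsets, which read a base
    outside it.  Unscored offsets are random, position -1 avoids G (as
    genuine editing sites do) and offset 0 is the edited C.
    """
    pref_by_offset = {}
    for motif, off in juxtapose(array).items():
        if motif.kind in CODE_SCORED_KINDS:
            pref = DEFAULT_CODE.preference(motif.aa5, motif.aaL)
            if pref:
                pref_by_offset[off] = pref
    scored = [o for o in sorted(pref_by_offset) if -16 <= o <= -1]
    mm_offsets = set(
        rng.choice(scored, size=min(mismatches, len(scored)), replace=False).tolist()
    )
    bases = []
    for off in range(-16, 3):
        if off == 0:
            bases.append("C")
        elif off in pref_by_offset:
            pool = pref_by_offset[off]
            if off in mm_offsets:
                pool = frozenset(RNA) - pool
            bases.append(str(rng.choice(sorted(pool))))
        elif off == -1:
            bases.append(str(rng.choice(["A", "C", "U"])))
        else:
            bases.append(str(rng.choice(list(RNA))))
    return TargetWindow("".join(bases), -16)


def make_reference(
    config: SimConfig,
) -> tuple[dict[str, str], list[GroundTruthSite]]:
    """Random background with planted contexts at recorded positions."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = list(rng.choice(list(DNA), size=config.reference_length, p=probs))
    contexts = []
    for site in config.planted:
        if site.source == "nad4":
            win = NAD4_WINDOW
        elif site.source == "nad3":
            win = NAD3_WINDOW
        else:
            win = sample_matching_window(rng, mismatches=site.mismatches)
        contexts.append(win)
    span = 19  # window length (-16..+2)
    gap = config.reference_length // (len(config.planted) + 1)
    if gap <= span + 2:
        raise ValueError("contexts longer than the reference allows")
    truth = []
    for i, (site, win) in enumerate(zip(config.planted, contexts)):
        strand = "+" if rng.random() < 0.5 else "-"
        p0 = gap * (i + 1)  # 0-based start of the planted block
        dna_ctx = win.seq.replace("U", "T")
        if strand == "+":
            block = dna_ctx
            edit_index = p0 + 16
        else:
            block = reverse_complement(dna_ctx)
            edit_index = p0 + (span - 1 - 16)
        seq[p0: p0 + span] = list(block)
        truth.append(
            GroundTruthSite(
                name=site.name,
                contig=config.contig,
                position=edit_index + 1,
                strand=strand,
                efficiency=site.efficiency,
                decoy=site.decoy,
                context=win.seq,
            )
        )
    return {config.contig: "".join(seq)}, truth


def _noisy_counts(
    rng: np.random.Generator,
    ref_base: str,
    coverage: int,
    error_rate: float,
    edited: int = 0,
    edited_base: str | None = None,
) -> tuple[int, int, int, int]:
    """A,C,G,T counts: ref reads minus edits, uniform errors to other bases."""
    counts = dict.fromkeys(DNA, 0)
    n_err = rng.binomial(coverage - edited, error_rate) if coverage > edited else 0
    others = [b for b in DNA if b != ref_base]
    if n_err:
        split = rng.multinomial(n_err, [1 / 3] * 3)
        for b, n in zip(others, split):
            counts[b] += int(n)
    counts[ref_base] += coverage - edited - n_err
    if edited:
        counts[edited_base] += edited
    return (counts["A"], counts["C"], counts["G"], counts["T"])


def _dna_counts(
    rng: np.random.Generator, ref_base: str, coverage: int, error_rate: float
) -> tuple[int, int, int, int]:
    return _noisy_counts(rng, ref_base, coverage, error_rate)


def simulate_counts(
    reference: Mapping[str, str],
    truth: Sequence[GroundTruthSite],
    config: SimConfig,
) -> list[SiteCounts]:
    """Per-dataset, per-position base-count records for all datasets.

    Planted sites gain Binomial(coverage, efficiency) edited reads in
    treatment datasets (T on plus-strand sites, A on minus-strand sites,
    always reported on the plus strand); elsewhere only error-rate noise.
    Decoys violate exactly their designated criterion.  DNA counts are
    emitted at every candidate (C/G) position.
    """
    contig = config.contig
    seq = reference[contig]
    n = len(seq)
    truth_by_pos = {t.position: t for t in truth}
    disp = config.coverage_dispersion
    p_nb = disp / (disp + config.coverage_mean)
    records: list[SiteCounts] = []
    all_ids = list(config.treatment_ids) + list(config.control_ids)
    for d_index, dataset in enumerate(all_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1, d_index])
        )
        is_treatment = dataset in config.treatment_ids
        coverages = rng.negative_binomial(disp, p_nb, size=n)
        for pos0 in range(n):
            ref_base = seq[pos0]
            cov = int(coverages[pos0])
            if cov == 0:
                continue
            site = truth_by_pos.get(pos0 + 1)
            edited = 0
            edited_base = None
            forced_rna = None
            dna = None
            if ref_base in "CG":
                dna = _dna_counts(
                    rng, ref_base, config.dna_coverage, config.dna_error_rate
                )
            if site is not None:
                active = is_treatment or site.decoy == "control"
                if site.decoy == "replicate" and dataset != all_ids[0]:
                    active = False
                if active:
                    edited_base = "T" if site.strand == "+" else "A"
                    if site.decoy == "coverage":
                        cov = 29  # one read short of the coverage criterion
                        edited = int(rng.binomial(cov, site.efficiency))
                    elif site.decoy == "edit_signal":
                        edited = int(0.005 * cov)  # < 1% of the reads, always
                    else:
                        edited = int(rng.binomial(cov, site.efficiency))
                    if site.decoy == "transition_purity":
                        # push C+T (or G+A) purity to <= 98% with a foreign base
                        bad = max(1, int(np.ceil(0.02 * cov)))
                        foreign = "G" if site.strand == "+" else "T"
                        edited = int(rng.binomial(cov - bad, site.efficiency))
                        base_counts = list(
                            _noisy_counts(
                                rng, ref_base, cov - bad, config.error_rate,
                                edited, edited_base,
                            )
                        )
                        base_counts[DNA.index(foreign)] += bad
                        forced_rna = tuple(base_counts)
                    if site.decoy == "dna_purity":
                        # exactly 98% reference reads: fails the strict > rule
                        alt = max(1, int(round(0.02 * config.dna_coverage)))
                        dna_counts = dict.fromkeys(DNA, 0)
                        dna_counts[ref_base] = config.dna_coverage - alt
                        other = "A" if ref_base != "A" else "C"
                        dna_counts[other] = alt
                        dna = (
                            dna_counts["A"],
                            dna_counts["C"],
                            dna_counts["G"],
                            dna_counts["T"],
                        )
            rna = forced_rna or _noisy_counts(
                rng, ref_base, cov, config.error_rate, edited, edited_base
            )
            records.append(
                SiteCounts(
                    dataset_id=dataset,
                    contig=contig,
                    position=pos0 + 1,
                    dna_ref=ref_base,
                    rna_counts=rna,
                    dna_counts=dna,
                )
            )
    return records


def simulate_sanger(
    true_efficiency: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Noisy (T, C) peak heights proportional to (e, 1 - e).

    Gaussian noise truncated at zero; with ``noise_sd=0`` the peaks
    quantify back to the exact efficiency.
    """
    if not 0.0 <= true_efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    noise_t = float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
    noise_c = float(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
    peak_t = max(0.0, true_efficiency + noise_t)
    peak_c = max(0.0, (1.0 - true_efficiency) + noise_c)
    return peak_t, peak_c


# ---------------------------------------------------------------------------
# File outputs


def write_fasta(reference: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_ground_truth(truth: Sequence[GroundTruthSite], path) -> None:
    pd.DataFrame(
        [
            {
                "name": t.name,
                "contig": t.contig,
                "position": t.position,
                "strand": t.strand,
                "efficiency": t.efficiency,
                "decoy": t.decoy or ".",
                "context": t.context,
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> list[GroundTruthSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        GroundTruthSite(
            name=row["name"],
            contig=row["contig"],
            position=int(row["position"]),
            strand=row["strand"],
            efficiency=float(row["efficiency"]),
            decoy=None if row["decoy"] == "." else row["decoy"],
            context=row["context"],
        )
        for _, row in df.iterrows()
    ]
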