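"""End-to-end orchestration: simulate -> call -> profile -> scan.

A run is a pure function of (inputs, configuration, seed): the same
configuration writes byte-identical outputs.  Each stage leaves its table
in the output directory and the run report summarizes counts per stage and
per-filter rejections.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import builtin
from .offtarget_caller import (
    CallerParams,
    DatasetSet,
    call_offtargets,
    read_site_counts,
    write_calls,
    write_site_counts,
)
from .ppr_code import PPRArray, best_offset, read_array_tsv, scan_sequence
from .profiles import build_profile, exclude_shifted, export_profile, extract_context
from .synthetic import (
    SimConfig,
    make_reference,
    read_fasta,
    simulate_counts,
    write_fasta,
    write_ground_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    reference: str | None = None  # FASTA; None -> simulate
    counts: str | None = None  # count TSV; None -> simulate
    array: str | None = None  # motif TSV; None -> packaged PPR56
    params: CallerParams = field(default_factory=CallerParams)
    sim: SimConfig = field(default_factory=SimConfig)
    profile_window: tuple[int, int] = (-20, 5)
    max_shift: int = 2
    scan_min_matches: int = 7

    def load_array(self) -> PPRArray:
        if self.array:
            return read_array_tsv(self.array, name=Path(self.array).stem)
        return builtin.PPR56


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON).

    Stages: (1) simulate or load reference + counts, (2) call off-targets
    with the filter cascade, (3) build the efficiency-weighted profile of
    unshifted calls, (4) scan the reference for candidate sites.  Any stage
    failure aborts with a stage-tagged error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    array = config.load_array()
    report: dict = {"seed": config.seed, "array": array.name}

    stage = "simulate"
    try:
        if config.reference and config.counts:
            reference = read_fasta(config.reference)
            records = read_site_counts(config.counts)
            treatment = sorted(
                {r.dataset_id for r in records if r.dataset_id.startswith("treat")}
            )
            control = sorted(
                {r.dataset_id for r in records if r.dataset_id.startswith("ctrl")}
            )
            report["simulated"] = False
        elif config.reference or config.counts:
            raise ValueError("reference and counts must be given together")
        else:
            sim = SimConfig(
                seed=config.seed,
                **{
                    k: v
                    for k, v in asdict(config.sim).items()
                    if k not in ("seed", "planted")
                },
                planted=config.sim.planted,
            )
            reference, truth = make_reference(sim)
            records = simulate_counts(reference, truth, sim)
            write_fasta(reference, out / "reference.fasta")
            write_ground_truth(truth, out / "ground_truth.tsv")
            write_site_counts(records, out / "site_counts.tsv")
            treatment, control = list(sim.treatment_ids), list(sim.control_ids)
            report["simulated"] = True
            report["planted_sites"] = sum(1 for t in truth if t.decoy is None)
            report["decoys"] = sum(1 for t in truth if t.decoy is not None)

        stage = "call"
        sets = DatasetSet("factor", tuple(treatment), tuple(control))

        def classify(contig: str, position: int, strand: str) -> int:
            ctx = extract_context(
                reference, contig, position, strand, config.profile_window
            )
            return best_offset(array, ctx, config.max_shift)

        calls, stats = call_offtargets(
            sets, records, config.params, classify_shift=classify
        )
        write_calls(calls, out / "offtargets.tsv")
        report["calling"] = stats.as_dict()
        if report.get("simulated"):
            truth_keys = {
                (t.contig, t.position, t.strand): t for t in truth
            }
            called_keys = {(c.contig, c.position, c.strand) for c in calls}
            planted = {k: t for k, t in truth_keys.items() if t.decoy is None}
            report["planted_recovered"] = sum(
                1 for k in planted if k in called_keys
            )
            report["decoys_called"] = sum(
                1
                for k, t in truth_keys.items()
                if t.decoy is not None and k in called_keys
            )
            report["background_called"] = sum(
                1 for k in called_keys if k not in truth_keys
            )

        stage = "profile"
        if calls:
            pairs = [
                (
                    c,
                    extract_context(
                        reference, c.contig, c.position, c.strand,
                        config.profile_window,
                    ),
                )
                for c in calls
            ]
            unshifted, shifted = exclude_shifted(pairs, array, config.max_shift)
            report["unshifted_calls"] = len(unshifted)
            report["shifted_calls"] = len(shifted)
            if unshifted:
                profile = build_profile(
                    [ctx for _, ctx in unshifted],
                    [c.aggregate_efficiency for c, _ in unshifted],
                    config.profile_window,
                )
                export_profile(profile, out / "profile.tsv")

        stage = "scan"
        scan_rows = []
        for contig, seq in reference.items():
            for hit in scan_sequence(
                array, seq, min_matches=config.scan_min_matches
            ):
                scan_rows.append(
                    f"{contig}\t{hit.position}\t+\t{hit.center_base}"
                    f"\t{hit.report.n_match}\t{hit.report.n_mismatch}"
                    f"\t{hit.score}\t0"
                )
        with open(out / "scan.tsv", "w") as fh:
            fh.write(
                "contig\tposition\tstrand\tcenter_base\tn_match\tn_mismatch"
                "\tscore\toffset_used\n"
            )
            fh.write("\n".join(scan_rows) + ("\n" if scan_rows else ""))
        report["scan_hits"] = len(scan_rows)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
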