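"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: direct per-position table application and nested loops
with no shared code paths with the package internals beyond the public
data types.
"""

from __future__ import annotations

from ppredit.offtarget_caller import CallerParams, DatasetSet, SiteCounts
from ppredit.ppr_code import CodeTable, PPRArray, TargetWindow

_SCORED = {"P", "S", "P2", "S2"}


def brute_force_counts(
    array: PPRArray, window: TargetWindow, table: CodeTable
) -> tuple[int, int, int]:
    """(n_match, n_mismatch, n_scored) by direct table application."""
    n_match = n_mismatch = n_scored = 0
    for motif in array.motifs:
        if motif.index is None or motif.kind not in _SCORED:
            continue
        offset = motif.index - 3
        if offset not in window:
            continue
        n_scored += 1
        base = window[offset]
        if base == "N":
            continue
        pref = table.entries.get((motif.aa5, motif.aaL), frozenset())
        if not pref:
            continue
        if base in pref:
            n_match += 1
        else:
            n_mismatch += 1
    return n_match, n_mismatch, n_scored


def naive_call(
    sets: DatasetSet, counts: list[SiteCounts], params: CallerParams
) -> dict[tuple[str, int, str], float]:
    """Nested-loop re-derivation of the calling cascade.

    Returns {(contig, position, strand): aggregate efficiency} for every
    called site.
    """

    def evidence(site: SiteCounts):
        cov = sum(site.rna_counts)
        if cov == 0:
            return None
        a, c, g, t = site.rna_counts
        if site.dna_ref == "C":
            strand, edited, unedited = "+", t, c
        elif site.dna_ref == "G":
            strand, edited, unedited = "-", a, g
        else:
            return None
        return strand, edited, unedited, cov

    def passes(site: SiteCounts):
        ev = evidence(site)
        if ev is None:
            return None
        strand, edited, unedited, cov = ev
        if cov < params.min_coverage:
            return None
        if not (edited + unedited) / cov > params.min_transition_purity:
            return None
        if site.dna_counts is not None and sum(site.dna_counts) > 0:
            ref = "C" if strand == "+" else "G"
            idx = "ACGT".index(ref)
            if not site.dna_counts[idx] / sum(site.dna_counts) > params.min_dna_purity:
                return None
        frac = edited / (edited + unedited) if edited + unedited else 0.0
        if frac < params.min_edit_frac:
            return None
        return strand, edited, unedited

    keys = set()
    for site in counts:
        if site.dataset_id in sets.treatment:
            ev = evidence(site)
            if ev:
                keys.add((site.contig, site.position, ev[0]))
    called = {}
    for contig, position, strand in keys:
        datasets = set()
        edited_sum = unedited_sum = 0
        for site in counts:
            if (
                site.dataset_id in sets.treatment
                and site.contig == contig
                and site.position == position
            ):
                res = passes(site)
                if res and res[0] == strand:
                    datasets.add(site.dataset_id)
                    edited_sum += res[1]
                    unedited_sum += res[2]
        if len(datasets) < params.min_replicates:
            continue
        vetoed = False
        for site in counts:
            if (
                site.dataset_id in sets.control
                and site.contig == contig
                and site.position == position
            ):
                ev = evidence(site)
                if (
                    ev
                    and ev[0] == strand
                    and ev[3] >= params.min_control_coverage
                    and (ev[1] / (ev[1] + ev[2]) if ev[1] + ev[2] else 0.0)
                    >= params.min_control_frac
                ):
                    vetoed = True
        if vetoed:
            continue
        if edited_sum + unedited_sum:
            called[(contig, position, strand)] = edited_sum / (
                edited_sum + unedited_sum
            )
    return called
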