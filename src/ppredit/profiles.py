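"""Efficiency-weighted nucleotide profiles around called editing sites.

Each called site contributes its strand-oriented sequence context (edited
C at offset 0, upstream 5' to the left) weighted by its aggregate editing
efficiency, yielding a weighted position frequency matrix plus per-offset
Shannon information content (2 + sum f log2 f, in bits) ready for logo
rendering.  Sites whose best array alignment requires a nucleotide shift
can be partitioned out first, mirroring how consensus profiles are usually
restricted to canonically registered sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ppr_code import (
    PPRArray,
    TargetWindow,
    best_offset,
    reverse_complement,
)

RNA_ORDER = ("A", "C", "G", "U")


def extract_context(
    reference: Mapping[str, str],
    contig: str,
    position: int,
    strand: str,
    window: tuple[int, int] = (-20, 5),
) -> TargetWindow:
    """Strand-oriented context of an edited base (1-based position).

    The returned window reads C at offset 0 with upstream sequence at
    negative offsets; reverse-strand sites are reverse complemented.
    Out-of-contig offsets are padded with N.
    """
    if contig not in reference:
        raise KeyError(f"contig {contig!r} not in reference")
    seq = reference[contig].upper()
    lo, hi = window
    if strand == "+":
        start, end = position - 1 + lo, position - 1 + hi
        raw = _padded_slice(seq, start, end)
    else:
        # plus-strand slice covering the window, then reverse complement
        start, end = position - 1 - hi, position - 1 - lo
        raw = reverse_complement(_padded_slice(seq, start, end))
    return TargetWindow(raw, lo)


def _padded_slice(seq: str, start: int, end: int) -> str:
    """seq[start..end] inclusive with N padding outside the sequence."""
    left = max(0, -start)
    right = max(0, end - (len(seq) - 1))
    core = seq[max(0, start): min(len(seq), end + 1)]
    return "N" * left + core + "N" * right


@dataclass(frozen=True)
class WeightedProfile:
    """Weighted position frequency matrix over a window of offsets.

    ``freq`` has one row per offset and columns A, C, G, U; rows with any
    observed (non-N) base sum to 1.  ``ic`` is the per-offset information
    content in bits, in [0, 2].
    """

    offsets: tuple[int, ...]
    freq: np.ndarray
    ic: np.ndarray
    total_weight: float
    n_sequences: int

    def frequency(self, offset: int, base: str) -> float:
        i = self.offsets.index(offset)
        return float(self.freq[i, RNA_ORDER.index(base.upper().replace("T", "U"))])

    def argmax(self, offset: int) -> str:
        i = self.offsets.index(offset)
        return RNA_ORDER[int(np.argmax(self.freq[i]))]


def build_profile(
    contexts: Sequence[TargetWindow],
    weights: Sequence[float],
    window: tuple[int, int] = (-20, 5),
) -> WeightedProfile:
    """Build an efficiency-weighted frequency matrix from site contexts.

    freq(offset, b) = sum_i w_i [seq_i(offset) = b] / sum_i w_i, with N
    bases excluded from both sums at that offset.  Doubling all weights
    leaves the profile unchanged; equal weights give plain frequencies.
    """
    if not contexts:
        raise ValueError("at least one context required")
    if len(contexts) != len(weights):
        raise ValueError("one weight per context required")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    lo, hi = window
    offsets = tuple(range(lo, hi + 1))
    counts = np.zeros((len(offsets), 4))
    for ctx, wi in zip(contexts, w):
        for row, off in enumerate(offsets):
            base = ctx.get(off)
            if base is None or base == "N":
                continue
            counts[row, RNA_ORDER.index(base)] += wi
    totals = counts.sum(axis=1, keepdims=True)
    freq = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = np.where(totals[:, 0] > 0, 2.0 + plogp.sum(axis=1), 0.0)
    ic = np.clip(ic, 0.0, 2.0)
    return WeightedProfile(offsets, freq, ic, float(w.sum()), len(contexts))


def exclude_shifted(
    items: Iterable[tuple[object, TargetWindow]],
    array: PPRArray,
    max_shift: int = 2,
) -> tuple[list, list]:
    """Partition (call, context) pairs into unshifted and shifted sets.

    A site is *shifted* when sliding the repeat array by up to
    ``max_shift`` nucleotides yields strictly more code matches than the
    canonical register (``best_offset != 0``).
    """
    unshifted, shifted = [], []
    for call, ctx in items:
        if best_offset(array, ctx, max_shift) == 0:
            unshifted.append((call, ctx))
        else:
            shifted.append((call, ctx))
    return unshifted, shifted


def export_profile(profile: WeightedProfile, path) -> None:
    """Write the matrix as TSV (offset rows; A/C/G/U frequencies + ic)."""
    df = pd.DataFrame(profile.freq, columns=list(RNA_ORDER))
    df.insert(0, "offset", profile.offsets)
    df["ic"] = profile.ic
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def import_profile(path) -> WeightedProfile:
    """Re-import an exported matrix (weights/counts are not recoverable)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("empty profile table")
    freq = df[list(RNA_ORDER)].to_numpy(dtype=float)
    return WeightedProfile(
        tuple(int(o) for o in df["offset"]),
        freq,
        df["ic"].to_numpy(dtype=float),
        float("nan"),
        0,
    )
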