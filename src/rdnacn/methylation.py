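"""CpG strand merging, global methylation, and 200 bp bin aggregation.

A CpG dyad is the complementary pair (p, p+1); read counts from both
strands are summed into one record at the top-strand position before
binning.  Bins are the fixed partition [1-200], [201-400], ... of the
locus; a bin enters association only with >= 10 total reads and >= 4
covered CpGs (both thresholds configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np

from rdnacn.io import CpgRecord

DEFAULT_BIN_LEN = 200
DEFAULT_MIN_READS = 10
DEFAULT_MIN_CPGS = 4


@dataclass(frozen=True)
class MethylBin:
    """Aggregated methylation over one fixed-width bin."""

    start: int
    end: int
    n_cpgs_covered: int
    total_reads: int
    mean_meth: float        # nan when no covered CpG
    passes_filters: bool
    is_partial: bool = False

    def __post_init__(self) -> None:
        if self.mean_meth == self.mean_meth and not (0 <= self.mean_meth <= 100):
            raise ValueError("mean_meth must be within [0, 100]")


def infer_dyad_starts(records: Sequence[CpgRecord]) -> List[int]:
    """Greedy left-to-right pairing of adjacent positions into dyads.

    Useful when no CpG annotation is available: any two records 1 bp
    apart are treated as the two strands of one dyad.
    """
    positions = sorted({r.position for r in records})
    pos_set = set(positions)
    starts: List[int] = []
    taken = set()
    for p in positions:
        if p in taken:
            continue
        if p + 1 in pos_set:
            starts.append(p)
            taken.add(p + 1)
    return starts


def merge_strand_cpgs(
    records: Sequence[CpgRecord], cpg_positions: Iterable[int]
) -> List[CpgRecord]:
    """Merge complementary-strand counts of each CpG dyad.

    ``cpg_positions`` are the top-strand positions ``p`` of the dyads
    ``(p, p+1)``.  Counts observed at ``p`` and ``p+1`` are summed into a
    single record at ``p``; positions belonging to no dyad pass through
    unchanged.  Dyads may not overlap (no two starts 1 bp apart).
    """
    starts = sorted(set(cpg_positions))
    for a, b in zip(starts, starts[1:]):
        if b - a < 2:
            raise ValueError(f"overlapping dyads at positions {a} and {b}")
    start_set = set(starts)
    bottom_to_top = {p + 1: p for p in starts}

    merged: Dict[int, List[int]] = {}
    order: List[int] = []
    for rec in records:
        if rec.position in start_set:
            key = rec.position
        elif rec.position in bottom_to_top:
            key = bottom_to_top[rec.position]
        else:
            key = rec.position
        if key not in merged:
            merged[key] = [0, 0]
            order.append(key)
        merged[key][0] += rec.count_methylated
        merged[key][1] += rec.count_unmethylated
    return [
        CpgRecord(pos, merged[pos][0], merged[pos][1]) for pos in sorted(order)
    ]


def bin_methylation(
    records: Sequence[CpgRecord],
    locus_length: int,
    bin_len: int = DEFAULT_BIN_LEN,
    min_reads: int = DEFAULT_MIN_READS,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    coverage_weighted: bool = False,
    min_reads_per_cpg: bool = False,
) -> List[MethylBin]:
    """Aggregate merged CpG records into the fixed bin partition.

    Per bin, the per-CpG methylation percentages are computed from counts
    and averaged (unweighted by default; ``coverage_weighted`` pools the
    counts instead).  Bins failing either filter, and a trailing partial
    bin, are emitted flagged rather than dropped so callers can audit
    exclusions.  ``min_reads_per_cpg`` switches the read threshold from
    per-bin total to per-CpG.
    """
    if locus_length < 1:
        raise ValueError("locus_length must be >= 1")
    for rec in records:
        if not (1 <= rec.position <= locus_length):
            raise ValueError(
                f"CpG position {rec.position} outside [1, {locus_length}]"
            )

    n_bins = (locus_length + bin_len - 1) // bin_len
    per_bin: List[List[CpgRecord]] = [[] for _ in range(n_bins)]
    for rec in records:
        per_bin[(rec.position - 1) // bin_len].append(rec)

    bins: List[MethylBin] = []
    for b in range(n_bins):
        start = b * bin_len + 1
        end = min(start + bin_len - 1, locus_length)
        partial = end - start + 1 < bin_len
        covered = [r for r in per_bin[b] if r.coverage > 0]
        total_reads = sum(r.coverage for r in covered)
        if covered:
            if coverage_weighted:
                meth = 100.0 * sum(r.count_methylated for r in covered) / total_reads
            else:
                meth = float(np.mean([r.methylation_pct for r in covered]))
        else:
            meth = float("nan")
        if min_reads_per_cpg:
            reads_ok = bool(covered) and all(r.coverage >= min_reads for r in covered)
        else:
            reads_ok = total_reads >= min_reads
        passes = reads_ok and len(covered) >= min_cpgs and not partial
        bins.append(
            MethylBin(
                start=start,
                end=end,
                n_cpgs_covered=len(covered),
                total_reads=total_reads,
                mean_meth=meth,
                passes_filters=passes,
                is_partial=partial,
            )
        )
    return bins


def global_methylation(records: Sequence[CpgRecord]) -> float:
    """Coverage-weighted overall methylation % over all covered CpGs."""
    meth = sum(r.count_methylated for r in records)
    unmeth = sum(r.count_unmethylated for r in records)
    total = meth + unmeth
    if total == 0:
        raise ValueError("global_methylation: zero total coverage")
    return 100.0 * meth / total
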