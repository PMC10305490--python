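"""Window selection, background read depth, and relative copy-number
estimation.

The estimator is the depth ratio

    CN = ARD(150 bp rDNA window) / BRD

where BRD is the mean of the upper-tail-trimmed average read depths of
pooled single-copy exons and pooled single-copy introns.  The window is
either fixed from configuration or chosen by a 150 bp sliding-window scan
minimizing the mean per-group coefficient of variation of window means
across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from rdnacn.io import DepthTrack
from rdnacn.simulate import thin_depth

Interval = Tuple[int, int]

WINDOW_LEN = 150
DEFAULT_TRIM_FRACTION = 0.05


@dataclass(frozen=True)
class WindowStats:
    """CV statistics of one candidate quantification window."""

    segment: str
    start: int
    end: int
    group_cv: Dict[str, float]
    mean_cv: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != WINDOW_LEN:
            raise ValueError("window length must be exactly 150 bp")
        if self.mean_cv < 0:
            raise ValueError("CV must be non-negative")


@dataclass(frozen=True)
class CnEstimate:
    """Relative copy number for one sample and segment."""

    sample_id: str
    segment: str
    ard: float
    brd: float
    cn: float

    def __post_init__(self) -> None:
        if self.brd <= 0:
            raise ValueError("brd must be > 0")
        if self.cn < 0:
            raise ValueError("cn must be >= 0")


def _sliding_means(values: np.ndarray, window_len: int) -> np.ndarray:
    """Mean over every length-``window_len`` window (stride 1)."""
    c = np.concatenate(([0.0], np.cumsum(values, dtype=np.float64)))
    return (c[window_len:] - c[:-window_len]) / window_len


def window_scan(
    tracks: Mapping[str, DepthTrack],
    segment_interval: Interval,
    segment: str,
    groups: Optional[Mapping[str, str]] = None,
    window_len: int = WINDOW_LEN,
    step: int = 1,
    exclusion: Optional[Interval] = None,
) -> List[WindowStats]:
    """Slide a window over a segment and score depth stability per window.

    For each window the per-sample mean depth is computed; within each
    group the coefficient of variation (population SD / mean) of those
    means is taken, and ``mean_cv`` is the unweighted mean of the group
    CVs.  Windows overlapping ``exclusion`` or containing a zero-mean
    group are skipped.

    Parameters
    ----------
    tracks:
        sample_id -> DepthTrack covering at least the segment.
    segment_interval:
        1-based closed span of the segment within the reference.
    groups:
        sample_id -> group label; defaults to one group for all samples.
    """
    if len(tracks) < 2:
        raise ValueError("window_scan needs at least 2 samples")
    seg_start, seg_end = segment_interval
    if seg_end - seg_start + 1 < window_len:
        raise ValueError("segment shorter than the window")
    if groups is None:
        groups = {sid: "all" for sid in tracks}

    sample_ids = sorted(tracks)
    group_labels = sorted({groups[sid] for sid in sample_ids})
    # per-sample sliding means over the segment
    means = np.vstack(
        [
            _sliding_means(
                tracks[sid].slice(seg_start, seg_end).astype(np.float64), window_len
            )
            for sid in sample_ids
        ]
    )  # shape (n_samples, n_windows)
    n_windows = means.shape[1]
    starts = seg_start + np.arange(0, n_windows, step)
    means = means[:, ::step]

    group_rows = {
        g: [i for i, sid in enumerate(sample_ids) if groups[sid] == g]
        for g in group_labels
    }

    out: List[WindowStats] = []
    for j, w_start in enumerate(starts):
        w_end = int(w_start) + window_len - 1
        if exclusion is not None and not (w_end < exclusion[0] or w_start > exclusion[1]):
            continue
        cvs: Dict[str, float] = {}
        ok = True
        for g, rows in group_rows.items():
            m = means[rows, j]
            mu = m.mean()
            if mu == 0:
                ok = False
                break
            cvs[g] = float(m.std(ddof=0) / mu)
        if not ok:
            continue
        out.append(
            WindowStats(
                segment=segment,
                start=int(w_start),
                end=w_end,
                group_cv=cvs,
                mean_cv=float(np.mean(list(cvs.values()))),
            )
        )
    return out


def select_window(stats: Sequence[WindowStats]) -> WindowStats:
    """Window with minimal mean CV; ties broken by smallest start."""
    if not stats:
        raise ValueError("no candidate windows to select from")
    return min(stats, key=lambda w: (w.mean_cv, w.start))


def trimmed_mean_depth(depths, upper_fraction: float = DEFAULT_TRIM_FRACTION) -> float:
    """Mean depth after removing the top ``ceil(n * upper_fraction)`` values.

    Trimming guards the background estimate against alignment pile-ups.
    """
    values = np.asarray(depths, dtype=np.float64)
    if values.size == 0:
        raise ValueError("trimmed_mean_depth: empty input")
    if not (0 <= upper_fraction < 1):
        raise ValueError("upper_fraction must be in [0, 1)")
    n_drop = math.ceil(values.size * upper_fraction)
    if n_drop == 0:
        return float(values.mean())
    kept = np.sort(values)[: values.size - n_drop]
    if kept.size == 0:
        raise ValueError("trimming removed every value")
    return float(kept.mean())


def compute_brd(
    exon_tracks: Iterable[DepthTrack],
    intron_tracks: Iterable[DepthTrack],
    upper_fraction: float = DEFAULT_TRIM_FRACTION,
) -> float:
    """Background read depth: mean of trimmed exon and intron ARDs.

    Per-base depths are pooled across all regions of a class before the
    upper-tail trim; BRD = (ARD_exons + ARD_introns) / 2.
    """
    exon_pool = [t.depths for t in exon_tracks]
    intron_pool = [t.depths for t in intron_tracks]
    if not exon_pool:
        raise ValueError("compute_brd: exon pool is empty")
    if not intron_pool:
        raise ValueError("compute_brd: intron pool is empty")
    ard_exons = trimmed_mean_depth(np.concatenate(exon_pool), upper_fraction)
    ard_introns = trimmed_mean_depth(np.concatenate(intron_pool), upper_fraction)
    return (ard_exons + ard_introns) / 2.0


def estimate_cn(
    sample_id: str,
    segment: str,
    track: DepthTrack,
    window: Interval,
    brd: float,
) -> CnEstimate:
    """CN = untrimmed mean depth over the window / BRD."""
    if brd <= 0:
        raise ValueError("brd must be > 0")
    ard = float(track.slice(window[0], window[1]).mean())
    return CnEstimate(sample_id=sample_id, segment=segment, ard=ard, brd=brd, cn=ard / brd)


def _split_background(
    background_tracks: Mapping[str, DepthTrack]
) -> Tuple[List[DepthTrack], List[DepthTrack]]:
    """Partition background tracks into exons and introns by name prefix."""
    exons = [t for name, t in background_tracks.items() if name.startswith("exon")]
    introns = [t for name, t in background_tracks.items() if name.startswith("intron")]
    return exons, introns


def estimate_cohort_cn(
    rdna_tracks: Mapping[str, DepthTrack],
    background_tracks: Mapping[str, Mapping[str, DepthTrack]],
    windows: Mapping[str, Interval],
    upper_fraction: float = DEFAULT_TRIM_FRACTION,
) -> List[CnEstimate]:
    """Estimate CN for every sample and every configured segment window.

    ``background_tracks[sample_id]`` maps region name -> DepthTrack;
    region names starting with ``exon``/``intron`` assign the pool.
    """
    estimates: List[CnEstimate] = []
    for sample_id in sorted(rdna_tracks):
        exons, introns = _split_background(background_tracks[sample_id])
        brd = compute_brd(exons, introns, upper_fraction)
        for segment in sorted(windows):
            estimates.append(
                estimate_cn(sample_id, segment, rdna_tracks[sample_id], windows[segment], brd)
            )
    return estimates


def stability_profile(
    sample_id: str,
    rdna_track: DepthTrack,
    background_tracks: Mapping[str, DepthTrack],
    windows: Mapping[str, Interval],
    cpg_records=None,
    fractions: Sequence[float] = tuple(np.round(np.arange(1.0, 0.05, -0.1), 1)),
    seed: int = 0,
    upper_fraction: float = DEFAULT_TRIM_FRACTION,
) -> pd.DataFrame:
    """Re-estimate CN (and global methylation) under binomial depth thinning.

    Every track of the sample — rDNA and background — is thinned at each
    keep-fraction and CN recomputed; CpG counts are thinned the same way
    when ``cpg_records`` is given.  Fraction 1.0 reproduces the unthinned
    estimates exactly.
    """
    from rdnacn.methylation import global_methylation
    from rdnacn.io import CpgRecord

    rows = []
    rng = np.random.default_rng(seed)
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fraction {f} outside (0, 1]")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        thinned_rdna = thin_depth(rdna_track, f, seed=sub_seed)
        thinned_bg = {
            name: thin_depth(t, f, seed=sub_seed + 1 + i)
            for i, (name, t) in enumerate(sorted(background_tracks.items()))
        }
        exons, introns = _split_background(thinned_bg)
        brd = compute_brd(exons, introns, upper_fraction)
        row = {"sample_id": sample_id, "fraction": float(f)}
        for segment in sorted(windows):
            est = estimate_cn(sample_id, segment, thinned_rdna, windows[segment], brd)
            row[f"cn_{segment}"] = est.cn
        if cpg_records is not None:
            thin_rng = np.random.default_rng(sub_seed + 10_000)
            if f == 1.0:
                thinned = list(cpg_records)
            else:
                thinned = [
                    CpgRecord(
                        r.position,
                        int(thin_rng.binomial(r.count_methylated, f)),
                        int(thin_rng.binomial(r.count_unmethylated, f)),
                    )
                    for r in cpg_records
                ]
            covered = [r for r in thinned if r.coverage > 0]
            row["global_meth"] = global_methylation(covered) if covered else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
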