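"""Coordinate model of the modified 45S rDNA reference and filtering of
candidate single-copy background regions.

The modified reference is built by appending the first 14,000 bp of the
canonical ~43 kb repeat unit after its last 1,979 bp, so that the promoter
sits downstream of the upstream terminator region and the 18S / 5.8S / 28S
coding segments plus both external transcribed spacers are contained in a
single 15,979 bp contig.  Every interval here is 1-based and closed.

The 18S/28S segment spans, the 18S exclusion zone (a homology artifact
region near the start of 18S) and the default 150 bp quantification
windows are configuration, not constants: :func:`default_reference`
encodes the shipped defaults, and :func:`load_reference_config` reads the
same structure from YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import yaml

Interval = Tuple[int, int]

#: Length of the modified reference: last 1,979 bp + first 14,000 bp.
DEFAULT_TOTAL_LENGTH = 1_979 + 14_000

#: Segment spans in the modified-reference frame (canonical annotation
#: shifted by +1,979).
DEFAULT_SEGMENTS: Dict[str, Interval] = {
    "18S": (5_636, 7_506),
    "28S": (9_914, 14_948),
}

#: Fixed 150 bp quantification windows (modified-reference frame).
DEFAULT_WINDOWS: Dict[str, Interval] = {
    "18S": (6_986, 7_135),
    "28S": (11_564, 11_713),
}

#: Length of the homology artifact zone at the start of 18S.
EXCLUSION_ZONE_LEN = 900

WINDOW_LEN = 150


class ReferenceValidationError(ValueError):
    """Raised when an interval violates the reference coordinate model."""


def _check_interval(name: str, iv: Interval, lo: int, hi: int) -> None:
    start, end = iv
    if start > end:
        raise ReferenceValidationError(f"{name}: start {start} > end {end}")
    if start < lo or end > hi:
        raise ReferenceValidationError(
            f"{name}: interval ({start}, {end}) outside [{lo}, {hi}]"
        )


@dataclass(frozen=True)
class RdnaReference:
    """Validated coordinate model of the modified rDNA reference.

    Attributes
    ----------
    total_length:
        Reference length in bp.
    segments:
        Map of segment name (at least ``"18S"`` and ``"28S"``) to a
        1-based closed interval.
    exclusion_zone:
        Interval inside the 18S segment that the window scan must skip.
    default_windows:
        Map of segment name to a fixed 150 bp window inside that segment.
    """

    total_length: int = DEFAULT_TOTAL_LENGTH
    segments: Dict[str, Interval] = field(default_factory=lambda: dict(DEFAULT_SEGMENTS))
    exclusion_zone: Optional[Interval] = None
    default_windows: Dict[str, Interval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_length < 1:
            raise ReferenceValidationError("total_length must be >= 1")
        for name, iv in self.segments.items():
            _check_interval(f"segment {name!r}", iv, 1, self.total_length)
        s18 = self.segments.get("18S")
        s28 = self.segments.get("28S")
        if s18 is None or s28 is None:
            raise ReferenceValidationError("segments must include '18S' and '28S'")
        if not (s18[1] < s28[0] or s28[1] < s18[0]):
            raise ReferenceValidationError("18S and 28S segments overlap")
        if self.exclusion_zone is not None:
            _check_interval("exclusion_zone", self.exclusion_zone, s18[0], s18[1])
        for name, iv in self.default_windows.items():
            if name not in self.segments:
                raise ReferenceValidationError(
                    f"default window for unknown segment {name!r}"
                )
            seg = self.segments[name]
            _check_interval(f"default window {name!r}", iv, seg[0], seg[1])
            if iv[1] - iv[0] + 1 != WINDOW_LEN:
                raise ReferenceValidationError(
                    f"default window {name!r} has length {iv[1] - iv[0] + 1}, "
                    f"expected {WINDOW_LEN}"
                )

    def segment_interval(self, segment: str) -> Interval:
        try:
            return self.segments[segment]
        except KeyError:
            raise KeyError(f"unknown segment {segment!r}") from None


def build_reference(
    intervals: Dict[str, Interval],
    total_length: int = DEFAULT_TOTAL_LENGTH,
    exclusion_zone: Optional[Interval] = None,
    default_windows: Optional[Dict[str, Interval]] = None,
) -> RdnaReference:
    """Build and validate an :class:`RdnaReference` from named intervals.

    Parameters
    ----------
    intervals:
        Segment name -> 1-based closed interval; must contain 18S and 28S
        and they must be disjoint.
    total_length:
        Reference length in bp.
    exclusion_zone:
        Optional interval inside 18S to skip during window scanning.
        ``None`` installs the default: the first 900 bp of the 18S span.
    default_windows:
        Optional fixed 150 bp windows per segment.
    """
    if exclusion_zone is None and "18S" in intervals:
        s18 = intervals["18S"]
        exclusion_zone = (s18[0], min(s18[0] + EXCLUSION_ZONE_LEN - 1, s18[1]))
    return RdnaReference(
        total_length=total_length,
        segments=dict(intervals),
        exclusion_zone=exclusion_zone,
        default_windows=dict(default_windows or {}),
    )


def default_reference() -> RdnaReference:
    """The shipped default reference model (15,979 bp frame)."""
    return build_reference(
        DEFAULT_SEGMENTS,
        total_length=DEFAULT_TOTAL_LENGTH,
        default_windows=DEFAULT_WINDOWS,
    )


def load_reference_config(path) -> RdnaReference:
    """Read a reference model from a YAML file.

    Expected keys: ``total_length``, ``segments`` (name -> [start, end]),
    optional ``exclusion_zone`` ([start, end]) and ``windows``
    (name -> [start, end]).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    segments = {k: (int(v[0]), int(v[1])) for k, v in cfg["segments"].items()}
    excl = cfg.get("exclusion_zone")
    return build_reference(
        segments,
        total_length=int(cfg.get("total_length", DEFAULT_TOTAL_LENGTH)),
        exclusion_zone=(int(excl[0]), int(excl[1])) if excl is not None else None,
        default_windows={
            k: (int(v[0]), int(v[1])) for k, v in cfg.get("windows", {}).items()
        },
    )


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate single-copy exon or intron before/after filtering."""

    region_id: str
    gene_id: str
    kind: str  # "exon" | "intron"
    chrom: str
    start: int  # 1-based closed
    end: int
    has_ambiguous_hit: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"kind must be 'exon' or 'intron', got {self.kind!r}")
        if self.end < self.start:
            raise ValueError(
                f"region {self.region_id!r}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionSet:
    """Filtered single-copy regions of one kind, at most one per gene."""

    kind: str
    regions: Tuple[CandidateRegion, ...]

    def __post_init__(self) -> None:
        if any(r.kind != self.kind for r in self.regions):
            raise ValueError("all regions must share the RegionSet kind")
        genes = [r.gene_id for r in self.regions]
        if len(genes) != len(set(genes)):
            raise ValueError("more than one region for the same gene_id")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


# Single-copy region filter thresholds.
MIN_REGION_LEN = 300        # exons and introns must be strictly longer
MAX_INTRON_LEN = 10_000     # introns additionally capped at 10 kb (inclusive)


def filter_single_copy_regions(
    candidates: Iterable[CandidateRegion], kind: str
) -> RegionSet:
    """Apply the single-copy background filters to candidate regions.

    Steps, in order:

    1. drop candidates flagged ``has_ambiguous_hit`` (a significant
       cross-hit, E < 1e-6, to another region of the same kind);
    2. keep only the largest region per gene (ties broken by the smaller
       start coordinate);
    3. keep regions with length > 300 bp; introns must additionally be
       <= 10,000 bp.

    An empty result is returned with a warning, not an error.
    """
    if kind not in ("exon", "intron"):
        raise ValueError(f"kind must be 'exon' or 'intron', got {kind!r}")
    cands = list(candidates)
    if any(c.kind != kind for c in cands):
        raise ValueError(f"all candidates must have kind {kind!r}")

    unambiguous = [c for c in cands if not c.has_ambiguous_hit]

    best: Dict[str, CandidateRegion] = {}
    for c in unambiguous:
        cur = best.get(c.gene_id)
        if cur is None or (c.length, -c.start) > (cur.length, -cur.start):
            best[c.gene_id] = c

    kept: List[CandidateRegion] = []
    for c in best.values():
        if c.length <= MIN_REGION_LEN:
            continue
        if kind == "intron" and c.length > MAX_INTRON_LEN:
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start, c.region_id))

    if cands and not kept:
        warnings.warn(f"no {kind} regions survived filtering", stacklevel=2)
    return RegionSet(kind=kind, regions=tuple(kept))
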