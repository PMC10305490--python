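"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

* depth tables — three-column TSV ``(reference name, 1-based position,
  depth)`` as produced by ``samtools depth``;
* CpG coverage — the six-column Bismark ``.cov`` dialect ``(name, start,
  end, methylation %, methylated count, unmethylated count)``; counts are
  authoritative, the percentage column is recomputed on read;
* BED — 0-based half-open on disk, converted to 1-based closed in memory;
* sample sheets — CSV with one row per library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from rdnacn.refmodel import CandidateRegion


class ParseError(ValueError):
    """Malformed row in an input file; carries the path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass
class DepthTrack:
    """Per-base depth over a contiguous stretch of one reference.

    ``depths[i]`` is the depth at 1-based position ``start + i``.
    """

    ref_name: str
    start: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValueError("depths must be a non-empty 1-D array")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        if self.start < 1:
            raise ValueError("start must be >= 1")

    @property
    def end(self) -> int:
        """1-based position of the last element."""
        return self.start + self.depths.size - 1

    def slice(self, start: int, end: int) -> np.ndarray:
        """Depth values over the closed interval [start, end].

        Positions outside the track raise ``IndexError``.
        """
        if start < self.start or end > self.end or start > end:
            raise IndexError(
                f"[{start}, {end}] outside track [{self.start}, {self.end}]"
            )
        return self.depths[start - self.start : end - self.start + 1]


@dataclass(frozen=True)
class CpgRecord:
    """Methylated/unmethylated read counts for one CpG position."""

    position: int
    count_methylated: int
    count_unmethylated: int

    def __post_init__(self) -> None:
        if self.count_methylated < 0 or self.count_unmethylated < 0:
            raise ValueError("counts must be non-negative")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def methylation_pct(self) -> float:
        """Percent methylation; ``nan`` at zero coverage."""
        cov = self.coverage
        if cov == 0:
            return float("nan")
        return 100.0 * self.count_methylated / cov


@dataclass
class SampleLibrary:
    """One sequencing library with covariates and file pointers."""

    sample_id: str
    age: Optional[float] = None
    sex: Optional[int] = None       # 0/1
    group: Optional[int] = None     # 0 = control, 1 = case
    chemistry: str = "default"
    rdna_depth_path: Optional[str] = None
    background_depth_path: Optional[str] = None
    cov_path: Optional[str] = None
    extra: Dict[str, str] = field(default_factory=dict)


def read_depth_table(path, fill_missing_with_zero: bool = True) -> Dict[str, DepthTrack]:
    """Read a samtools-depth-style TSV into one track per reference name.

    With ``fill_missing_with_zero`` (the default), gaps between the first
    and last observed position of a reference are filled with depth 0 —
    the common dialect where zero-depth rows are omitted.  Positions must
    be strictly increasing within each reference.
    """
    names: List[str] = []
    per_ref: Dict[str, List[List[int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
            name, pos_s, depth_s = parts
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-integer position/depth: {pos_s!r}, {depth_s!r}"
                ) from None
            if depth < 0:
                raise ParseError(path, lineno, f"negative depth {depth}")
            rows = per_ref.setdefault(name, [])
            if name not in names:
                names.append(name)
            if rows and pos <= rows[-1][0]:
                raise ParseError(
                    path, lineno, f"unsorted position {pos} after {rows[-1][0]}"
                )
            rows.append([pos, depth])

    tracks: Dict[str, DepthTrack] = {}
    for name in names:
        rows = per_ref[name]
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        depths = np.array([r[1] for r in rows], dtype=np.int64)
        start = int(positions[0])
        if fill_missing_with_zero:
            full = np.zeros(int(positions[-1]) - start + 1, dtype=np.int64)
            full[positions - start] = depths
            tracks[name] = DepthTrack(name, start, full)
        else:
            if not (np.diff(positions) == 1).all():
                raise ParseError(
                    path, 0, f"reference {name!r} has gaps and gap-fill is off"
                )
            tracks[name] = DepthTrack(name, start, depths)
    return tracks


def write_depth_table(path, tracks: Iterable[DepthTrack]) -> None:
    """Write tracks as a three-column depth TSV (all positions emitted)."""
    with open(path, "w") as fh:
        for track in tracks:
            pos = track.start
            for d in track.depths:
                fh.write(f"{track.ref_name}\t{pos}\t{int(d)}\n")
                pos += 1


def read_bismark_cov(path) -> List[CpgRecord]:
    """Read a six-column Bismark coverage file.

    The file's methylation-% column is ignored; percentages are derived
    from the two count columns.  Rows must be sorted by position.
    """
    records: List[CpgRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(path, lineno, f"expected 6 columns, got {len(parts)}")
            _name, start_s, _end_s, _pct_s, meth_s, unmeth_s = parts
            try:
                pos = int(start_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer position or count") from None
            if records and pos <= records[-1].position:
                raise ParseError(
                    path, lineno, f"unsorted position {pos} after {records[-1].position}"
                )
            records.append(CpgRecord(pos, meth, unmeth))
    return records


def write_bismark_cov(path, records: Iterable[CpgRecord], ref_name: str = "rDNA") -> None:
    """Write CpG records in the six-column coverage dialect."""
    with open(path, "w") as fh:
        for rec in records:
            pct = rec.methylation_pct
            pct_s = f"{pct:.6g}" if pct == pct else "0"  # nan -> 0, Bismark-style
            fh.write(
                f"{ref_name}\t{rec.position}\t{rec.position}\t{pct_s}\t"
                f"{rec.count_methylated}\t{rec.count_unmethylated}\n"
            )


SEX_ENCODING = {"f": 0, "female": 0, "m": 1, "male": 1, "0": 0, "1": 1}
GROUP_ENCODING = {"control": 0, "ctrl": 0, "case": 1, "0": 0, "1": 1}

_REQUIRED_SHEET_COLUMNS = ("sample_id",)


def _encode(value, mapping: Dict[str, int], column: str, sample_id: str):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    key = str(value).strip().lower()
    if key not in mapping:
        raise ValueError(
            f"sample {sample_id!r}: cannot encode {column}={value!r}; "
            f"expected one of {sorted(mapping)}"
        )
    return mapping[key]


def read_sample_sheet(path) -> List[SampleLibrary]:
    """Read a cohort sample sheet (CSV with header).

    Required column: ``sample_id``.  Recognized optional columns: ``age``,
    ``sex`` (f/female/0 -> 0, m/male/1 -> 1), ``group`` (control/0 -> 0,
    case/1 -> 1), ``chemistry``, ``rdna_depth``, ``background_depth``,
    ``cov``.  Missing covariates are legal at load time; analysis stages
    that need them raise there.
    """
    df = pd.read_csv(path, dtype=str)
    for col in _REQUIRED_SHEET_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"sample sheet {path}: missing required column {col!r}")
    ids = df["sample_id"].tolist()
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValueError(f"sample sheet {path}: duplicate sample_id {dupes}")

    samples: List[SampleLibrary] = []
    known = {
        "sample_id", "age", "sex", "group", "chemistry",
        "rdna_depth", "background_depth", "cov",
    }
    for _, row in df.iterrows():
        sid = row["sample_id"]
        age = row.get("age")
        samples.append(
            SampleLibrary(
                sample_id=sid,
                age=float(age) if age not in (None, "") and age == age else None,
                sex=_encode(row.get("sex"), SEX_ENCODING, "sex", sid),
                group=_encode(row.get("group"), GROUP_ENCODING, "group", sid),
                chemistry=(row.get("chemistry") or "default"),
                rdna_depth_path=row.get("rdna_depth"),
                background_depth_path=row.get("background_depth"),
                cov_path=row.get("cov"),
                extra={
                    k: row[k] for k in df.columns if k not in known and row[k] == row[k]
                },
            )
        )
    return samples


def write_sample_sheet(path, samples: Iterable[SampleLibrary]) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "age": s.age,
                "sex": s.sex,
                "group": s.group,
                "chemistry": s.chemistry,
                "rdna_depth": s.rdna_depth_path,
                "background_depth": s.background_depth_path,
                "cov": s.cov_path,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bed(path, kind_from_name: bool = True) -> List[CandidateRegion]:
    """Read candidate regions from a BED file.

    BED is 0-based half-open on disk; regions are converted to 1-based
    closed.  The name column is expected to be
    ``region_id|gene_id|kind[|ambiguous]``; with ``kind_from_name`` off,
    every region is read as an exon with ``gene_id == region_id == name``.
    """
    regions: List[CandidateRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, lineno, "expected >= 4 BED columns")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start0 = int(start_s)
                end0 = int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer BED coordinates") from None
            if kind_from_name:
                fields = name.split("|")
                if len(fields) < 3:
                    raise ParseError(
                        path, lineno, f"BED name {name!r} not region|gene|kind[|ambiguous]"
                    )
                region_id, gene_id, kind = fields[:3]
                ambiguous = len(fields) > 3 and fields[3].lower() in ("1", "ambiguous", "true")
            else:
                region_id = gene_id = name
                kind, ambiguous = "exon", False
            regions.append(
                CandidateRegion(
                    region_id=region_id,
                    gene_id=gene_id,
                    kind=kind,
                    chrom=chrom,
                    start=start0 + 1,
                    end=end0,
                    has_ambiguous_hit=ambiguous,
                )
            )
    return regions


def write_bed(path, regions: Iterable[CandidateRegion]) -> None:
    """Write regions as BED (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            flag = "|ambiguous" if r.has_ambiguous_hit else ""
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                f"{r.region_id}|{r.gene_id}|{r.kind}{flag}\n"
            )


def write_table(path, df: pd.DataFrame, schema_version: str = "1") -> None:
    """Write a result table as TSV with a schema-version header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rdnacn table schema-version={schema_version}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
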