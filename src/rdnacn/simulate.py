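"""Synthetic cohort generator with known ground truth.

Emits, per sample, per-base depth tables over the rDNA reference and over
single-copy background regions, plus a Bismark-style CpG coverage file,
together with a sample sheet and a truth table.  The generative model
mirrors the structure the estimator assumes:

* true relative copy number ~ lognormal (high inter-individual spread);
* per-base rDNA depth ~ NegBin(mean = cn * bg_mean * profile(pos) * bias)
  where ``profile`` is a smooth seeded positional multiplier and ``bias``
  a per-chemistry multiplier applied to rDNA depth only;
* a homology artifact zone inside 18S receives an extra depth boost;
* background depth ~ NegBin(mean = bg_mean) per base;
* per-bin CpG methylation mean = clamp(intercept + slope * cn + covariate
  effects, 0, 100), realized as binomial counts per strand of each dyad.

Dispersion ``inf`` switches depth to its exact (deterministic) mean; true
CN values are then snapped so every mean is an integer and downstream
estimation recovers them to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from rdnacn.io import (
    CpgRecord,
    DepthTrack,
    SampleLibrary,
    write_bismark_cov,
    write_depth_table,
    write_sample_sheet,
)
from rdnacn.refmodel import RdnaReference, default_reference

Interval = Tuple[int, int]

#: Default background regions: (name, length). Names carry the exon/intron
#: class used by BRD pooling.
DEFAULT_BACKGROUND_REGIONS: Tuple[Tuple[str, int], ...] = tuple(
    [(f"exon_{i:02d}", 400 + 137 * i) for i in range(8)]
    + [(f"intron_{i:02d}", 900 + 611 * i) for i in range(8)]
)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort."""

    n_samples: int = 30
    cn_log_mean: float = math.log(200.0)
    cn_log_sd: float = 0.35
    background_depth_mean: float = 30.0
    background_depth_dispersion: float = 8.0  # NB size; inf => deterministic
    profile_smoothness: float = 0.25          # amplitude of smooth log-multiplier
    profile_waves: int = 6                    # low-frequency components
    artifact_boost: float = 3.0               # extra multiplier in exclusion zone
    chemistry_bias: Dict[str, float] = field(default_factory=lambda: {"default": 1.0})
    meth_intercept: float = 20.0              # %
    meth_slope_per_copy: float = 0.08         # % per copy
    meth_age_effect: float = 0.05             # % per year
    meth_sex_effect: float = 1.0              # %
    meth_group_effect: float = 1.5            # %
    null_bin_fraction: float = 0.2            # leading bins carry no CN slope
    n_cpg_per_bin_range: Tuple[int, int] = (6, 12)
    bin_len: int = 200
    age_range: Tuple[float, float] = (20.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.background_depth_mean <= 0:
            raise ValueError("background_depth_mean must be > 0")
        if not (self.background_depth_dispersion > 0):
            raise ValueError("background_depth_dispersion must be > 0 (inf allowed)")
        if any(b <= 0 for b in self.chemistry_bias.values()):
            raise ValueError("chemistry biases must be > 0")
        if not (0 <= self.null_bin_fraction <= 1):
            raise ValueError("null_bin_fraction must be in [0, 1]")
        lo, hi = self.n_cpg_per_bin_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid n_cpg_per_bin_range")

    @property
    def deterministic(self) -> bool:
        return math.isinf(self.background_depth_dispersion)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "n_cpg_per_bin_range" in raw:
            raw["n_cpg_per_bin_range"] = tuple(raw["n_cpg_per_bin_range"])
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["n_cpg_per_bin_range"] = list(self.n_cpg_per_bin_range)
        raw["age_range"] = list(self.age_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to the synthetic files."""

    samples: pd.DataFrame          # sample_id, true_cn, chemistry, age, sex, group
    meth_slope_per_copy: float
    bin_effects: pd.DataFrame      # bin_start, bin_end, has_effect

    def write(self, outdir: Path) -> None:
        self.samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
        self.bin_effects.to_csv(outdir / "truth_bins.tsv", sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; exact mean if inf."""
    mean = np.asarray(mean, dtype=np.float64)
    if math.isinf(dispersion):
        return np.rint(mean).astype(np.int64)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.int64)


def _smooth_profile(
    rng: np.random.Generator, length: int, amplitude: float, waves: int
) -> np.ndarray:
    """Smooth positive multiplier along the locus, mean-one on the log scale.

    A sum of a few random-phase low-frequency sinusoids guarantees a
    genuine depth-stability minimum somewhere along the locus.
    """
    if amplitude == 0:
        return np.ones(length)
    x = np.linspace(0, 2 * np.pi, length)
    y = np.zeros(length)
    for k in range(1, waves + 1):
        phase = rng.uniform(0, 2 * np.pi)
        y += rng.normal(0, 1) * np.sin(k * x + phase) / k
    y *= amplitude / max(np.abs(y).max(), 1e-12)
    return np.exp(y)


def thin_depth(track: DepthTrack, fraction: float, seed: int = 0) -> DepthTrack:
    """Binomially subsample a depth track with keep-probability ``fraction``.

    Stands in for read-level downsampling: each per-base depth ``d`` is
    replaced by a Binomial(d, fraction) draw, which matches read thinning
    in expectation.  ``fraction == 1`` returns an identical track.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return DepthTrack(track.ref_name, track.start, track.depths.copy())
    rng = np.random.default_rng(seed)
    return DepthTrack(
        track.ref_name, track.start, rng.binomial(track.depths, fraction)
    )


def _cpg_layout(
    rng: np.random.Generator, cfg: SimConfig, locus_length: int
) -> List[Tuple[int, int, np.ndarray]]:
    """Per bin: (bin_start, bin_end, top-strand dyad positions)."""
    layout = []
    n_bins = locus_length // cfg.bin_len
    lo, hi = cfg.n_cpg_per_bin_range
    for b in range(n_bins):
        start = b * cfg.bin_len + 1
        end = start + cfg.bin_len - 1
        n_cpg = int(rng.integers(lo, hi + 1))
        # dyads occupy (p, p+1); keep them >= 2 apart so dyads never overlap
        candidates = np.arange(start, end, 2)
        pos = np.sort(rng.choice(candidates, size=min(n_cpg, candidates.size), replace=False))
        layout.append((start, end, pos))
    return layout


def simulate_cohort(
    config: SimConfig,
    outdir,
    reference: Optional[RdnaReference] = None,
    background_regions: Sequence[Tuple[str, int]] = DEFAULT_BACKGROUND_REGIONS,
) -> Tuple[List[SampleLibrary], SyntheticTruth]:
    """Generate a full synthetic cohort on disk.

    Writes per sample ``<id>.rdna.depth.tsv``, ``<id>.bg.depth.tsv`` and
    ``<id>.cov``, plus ``samples.csv``, ``truth_samples.tsv`` and
    ``truth_bins.tsv`` in ``outdir``.  Identical configs (same seed)
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = reference or default_reference()
    root = np.random.default_rng(config.seed)
    # independent child streams so any one artefact is reproducible
    ss = root.spawn(4)
    rng_cohort, rng_profile, rng_depth, rng_meth = ss

    n = config.n_samples
    true_cn = np.exp(rng_cohort.normal(config.cn_log_mean, config.cn_log_sd, size=n))
    ages = np.round(rng_cohort.uniform(*config.age_range, size=n), 1)
    sexes = rng_cohort.integers(0, 2, size=n)
    groups = rng_cohort.integers(0, 2, size=n)
    chem_labels = sorted(config.chemistry_bias)
    chems = [chem_labels[i % len(chem_labels)] for i in range(n)]

    if config.deterministic:
        # snap CN so cn * bg_mean is an integer -> exact recovery downstream
        true_cn = np.rint(true_cn * config.background_depth_mean) / config.background_depth_mean

    profile = _smooth_profile(
        rng_profile, ref.total_length, config.profile_smoothness, config.profile_waves
    )
    if ref.exclusion_zone is not None and config.artifact_boost != 1.0:
        lo, hi = ref.exclusion_zone
        profile = profile.copy()
        profile[lo - 1 : hi] *= config.artifact_boost

    n_bins = ref.total_length // config.bin_len
    n_null = int(round(config.null_bin_fraction * n_bins))
    has_effect = np.ones(n_bins, dtype=bool)
    has_effect[:n_null] = False  # leading bins are null, mirroring a flat promoter edge
    layout = _cpg_layout(rng_meth, config, ref.total_length)

    samples: List[SampleLibrary] = []
    for i in range(n):
        sid = f"S{i:03d}"
        bias = config.chemistry_bias[chems[i]]
        rdna_mean = true_cn[i] * config.background_depth_mean * profile * bias
        rdna_depths = _nb_draw(rng_depth, rdna_mean, config.background_depth_dispersion)
        rdna_track = DepthTrack("rDNA", 1, rdna_depths)
        rdna_path = outdir / f"{sid}.rdna.depth.tsv"
        write_depth_table(rdna_path, [rdna_track])

        bg_tracks = []
        for name, length in background_regions:
            depths = _nb_draw(
                rng_depth,
                np.full(length, config.background_depth_mean),
                config.background_depth_dispersion,
            )
            bg_tracks.append(DepthTrack(name, 1, depths))
        bg_path = outdir / f"{sid}.bg.depth.tsv"
        write_depth_table(bg_path, bg_tracks)

        records: List[CpgRecord] = []
        for b, (_, _, dyads) in enumerate(layout):
            mean_pct = config.meth_intercept
            if has_effect[b]:
                mean_pct += config.meth_slope_per_copy * true_cn[i]
            mean_pct += (
                config.meth_age_effect * ages[i]
                + config.meth_sex_effect * sexes[i]
                + config.meth_group_effect * groups[i]
            )
            p = min(max(mean_pct, 0.0), 100.0) / 100.0
            cov_mean = true_cn[i] * config.background_depth_mean * bias / 2.0
            for pos in dyads:
                for strand_offset in (0, 1):  # top and bottom strand of the dyad
                    cov = int(
                        _nb_draw(
                            rng_meth,
                            np.array([cov_mean]),
                            config.background_depth_dispersion,
                        )[0]
                    )
                    meth = int(rng_meth.binomial(cov, p)) if not config.deterministic else int(round(cov * p))
                    records.append(CpgRecord(int(pos) + strand_offset, meth, cov - meth))
        cov_path = outdir / f"{sid}.cov"
        write_bismark_cov(cov_path, records)

        samples.append(
            SampleLibrary(
                sample_id=sid,
                age=float(ages[i]),
                sex=int(sexes[i]),
                group=int(groups[i]),
                chemistry=chems[i],
                # stored relative to the sample sheet's directory
                rdna_depth_path=rdna_path.name,
                background_depth_path=bg_path.name,
                cov_path=cov_path.name,
            )
        )

    write_sample_sheet(outdir / "samples.csv", samples)
    truth = SyntheticTruth(
        samples=pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in samples],
                "true_cn": true_cn,
                "chemistry": chems,
                "age": ages,
                "sex": sexes,
                "group": groups,
            }
        ),
        meth_slope_per_copy=config.meth_slope_per_copy,
        bin_effects=pd.DataFrame(
            {
                "bin_start": [layout[b][0] for b in range(n_bins)],
                "bin_end": [layout[b][1] for b in range(n_bins)],
                "has_effect": has_effect,
            }
        ),
    )
    truth.write(outdir)
    return samples, truth
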