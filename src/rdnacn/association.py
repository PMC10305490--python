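"""Per-bin copy-number/methylation regression, FDR control, case-control
testing, and cross-platform correlation.

The per-bin model follows the estimation pipeline's convention: relative
copy number is the response and bin methylation the predictor,

    CN ~ mean_meth + age + sex + group

with a two-sided Wald p-value for the methylation coefficient and
Benjamini-Hochberg adjustment across all tested bins of one segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from rdnacn.copynumber import CnEstimate
from rdnacn.methylation import MethylBin

SIGNIFICANCE_Q = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """Per-bin regression of CN on methylation with covariates."""

    bin_start: int
    bin_end: int
    n_samples: int
    beta: float
    se: float
    p_value: float
    q_value: float
    significant: bool
    skipped_reason: Optional[str] = None


@dataclass(frozen=True)
class GroupTestResult:
    """Logistic case-control test of CN adjusted for age and sex."""

    segment: str
    coefficient: float
    p_value: float
    n_samples: int
    covariates: Tuple[str, ...] = ("age", "sex")
    estimable: bool = True
    diagnostic: Optional[str] = None


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def per_bin_regression(
    cn: Sequence[CnEstimate],
    bins: Mapping[str, Sequence[MethylBin]],
    covariates: pd.DataFrame,
    min_samples: Optional[int] = None,
    meth_as_response: bool = False,
) -> List[AssociationResult]:
    """OLS of CN on bin methylation per 200 bp bin, BH-adjusted.

    Parameters
    ----------
    cn:
        One estimate per sample, all for the same segment.
    bins:
        sample_id -> MethylBin list over the same bin partition; only
        filter-passing bins enter the model.
    covariates:
        Indexed by sample_id with columns ``age``, ``sex``, ``group``
        (missing columns are simply omitted from the model).
    min_samples:
        Minimum complete-data samples per bin; defaults to number of
        predictors + 2.
    meth_as_response:
        Flip the model to ``mean_meth ~ CN + covariates``; association
        only, so both directions are offered.
    """
    segs = {e.segment for e in cn}
    if len(segs) > 1:
        raise ValueError(f"mixed segments in cn input: {sorted(segs)}")
    cn_by_sample = {e.sample_id: e.cn for e in cn}

    covar_cols = [c for c in ("age", "sex", "group") if c in covariates.columns]
    n_predictors = 1 + len(covar_cols)
    if min_samples is None:
        min_samples = n_predictors + 2

    sample_ids = [sid for sid in cn_by_sample if sid in bins]
    if not sample_ids:
        raise ValueError("no samples with both CN and methylation bins")
    bin_keys = [(b.start, b.end) for b in bins[sample_ids[0]]]

    rows: List[dict] = []
    for start, end in bin_keys:
        meths, cns, covs = [], [], []
        for sid in sample_ids:
            bin_ = next(
                (b for b in bins[sid] if b.start == start and b.end == end), None
            )
            if bin_ is None or not bin_.passes_filters:
                continue
            if bin_.mean_meth != bin_.mean_meth:
                continue
            cov_row = covariates.loc[sid, covar_cols] if covar_cols else pd.Series(dtype=float)
            if covar_cols and cov_row.isna().any():
                raise ValueError(f"sample {sid!r}: missing covariate for regression")
            meths.append(bin_.mean_meth)
            cns.append(cn_by_sample[sid])
            covs.append(cov_row.to_numpy(dtype=float))
        n_used = len(meths)
        if n_used < min_samples:
            rows.append(
                dict(start=start, end=end, n=n_used, skipped=f"only {n_used} samples")
            )
            continue
        y = np.asarray(cns if not meth_as_response else meths, dtype=float)
        x_main = np.asarray(meths if not meth_as_response else cns, dtype=float)
        X = np.column_stack([x_main] + ([np.vstack(covs)] if covar_cols else []))
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append(dict(start=start, end=end, n=n_used, skipped="collinear design"))
            continue
        fit = sm.OLS(y, X).fit()
        rows.append(
            dict(
                start=start,
                end=end,
                n=n_used,
                beta=float(fit.params[1]),
                se=float(fit.bse[1]),
                p=float(fit.pvalues[1]),
            )
        )

    tested = [r for r in rows if "p" in r]
    qs = bh_fdr([r["p"] for r in tested]) if tested else np.array([])
    for r, q in zip(tested, qs):
        r["q"] = float(q)

    results: List[AssociationResult] = []
    for r in rows:
        if "p" in r:
            results.append(
                AssociationResult(
                    bin_start=r["start"],
                    bin_end=r["end"],
                    n_samples=r["n"],
                    beta=r["beta"],
                    se=r["se"],
                    p_value=r["p"],
                    q_value=r["q"],
                    significant=r["q"] < SIGNIFICANCE_Q,
                )
            )
        else:
            results.append(
                AssociationResult(
                    bin_start=r["start"],
                    bin_end=r["end"],
                    n_samples=r["n"],
                    beta=float("nan"),
                    se=float("nan"),
                    p_value=float("nan"),
                    q_value=float("nan"),
                    significant=False,
                    skipped_reason=r["skipped"],
                )
            )
    return results


def group_comparison(
    cn: Sequence[CnEstimate], covariates: pd.DataFrame, min_samples: int = 8
) -> GroupTestResult:
    """Logistic regression ``group ~ CN + age + sex``; Wald p for CN.

    Perfect separation or a constant CN vector yields a flagged
    non-estimable result instead of an exception.
    """
    segs = {e.segment for e in cn}
    if len(segs) > 1:
        raise ValueError(f"mixed segments in cn input: {sorted(segs)}")
    segment = segs.pop()

    df = pd.DataFrame(
        {"cn": {e.sample_id: e.cn for e in cn}}
    ).join(covariates[["age", "sex", "group"]])
    df = df.dropna()
    if len(df) < min_samples:
        raise ValueError(f"group_comparison needs >= {min_samples} complete samples")
    if df["group"].nunique() != 2:
        raise ValueError("group must take exactly two values")

    if np.ptp(df["cn"].to_numpy()) == 0:
        return GroupTestResult(
            segment=segment,
            coefficient=float("nan"),
            p_value=float("nan"),
            n_samples=len(df),
            estimable=False,
            diagnostic="CN constant across samples",
        )

    X = sm.add_constant(df[["cn", "age", "sex"]].astype(float), has_constant="add")
    y = df["group"].astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        return GroupTestResult(
            segment=segment,
            coefficient=float("nan"),
            p_value=float("nan"),
            n_samples=len(df),
            estimable=False,
            diagnostic=f"model not estimable: {exc}",
        )
    return GroupTestResult(
        segment=segment,
        coefficient=float(fit.params["cn"]),
        p_value=float(fit.pvalues["cn"]),
        n_samples=len(df),
    )


def platform_correlation(
    cn_a: Sequence[CnEstimate], cn_b: Sequence[CnEstimate]
) -> Dict[str, float]:
    """Spearman r (with p) and Pearson r^2 between paired CN estimates.

    Estimates are matched by ``sample_id``; scipy's exact permutation
    p-value applies below n=10 ties permitting, the t-approximation above
    (scipy's default switch).  Ties receive average ranks.
    """
    a = {e.sample_id: e.cn for e in cn_a}
    b = {e.sample_id: e.cn for e in cn_b}
    unmatched = sorted(set(a) ^ set(b))
    if unmatched:
        raise ValueError(f"unmatched sample ids: {unmatched}")
    ids = sorted(a)
    if len(ids) < 4:
        raise ValueError("platform_correlation needs >= 4 pairs")
    va = np.array([a[i] for i in ids])
    vb = np.array([b[i] for i in ids])
    rho, p = stats.spearmanr(va, vb)
    pearson_r = stats.pearsonr(va, vb).statistic
    return {
        "n": len(ids),
        "spearman_r": float(rho),
        "spearman_p": float(p),
        "pearson_r2": float(pearson_r**2),
    }
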