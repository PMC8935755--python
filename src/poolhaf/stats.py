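"""Validation and QC statistics for pool allele-frequency tracks.

Covers pool-size design (Cochran's formula), agreement metrics between a
pool track and an individual-genotyping reference (RMSE, Pearson r,
zero-inflated negative-binomial group test), a bias regression on window
extension size and chromosomal position, and a neighbour-deviation QC scan
that flags haplotype windows whose frequency jumps away from both physical
neighbours — in a backcross population linkage blocks are large, so an
isolated jump would require a double crossover and is more plausibly a
calling error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

log = logging.getLogger(__name__)

__all__ = [
    "PoolDesign",
    "ComparisonResult",
    "BiasRegressionResult",
    "NeighborQCResult",
    "cochran_sample_size",
    "rmse",
    "pearson_r",
    "zinb_group_test",
    "bias_regression",
    "neighbor_deviation_qc",
    "compare_tracks",
]


@dataclass(frozen=True, slots=True)
class PoolDesign:
    """Minimum pool size for estimating a proportion at given precision."""

    confidence: float
    p: float
    e: float
    n0: int

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    rmse: float
    pearson_r: float
    p_count: float  # group p-value, negative-binomial component
    p_zero: float  # group p-value, zero-inflation component
    n_loci: int
    residual_width: float  # mean absolute deviation pool vs reference


@dataclass(frozen=True, slots=True)
class BiasRegressionResult:
    coef_extension: float
    p_extension: float
    coef_position: float
    p_position: float
    n: int
    collinear: bool = False


@dataclass(frozen=True, slots=True)
class NeighborQCResult:
    median_by_chrom: dict[str, float]
    flagged: tuple[str, ...]  # anchor_ids
    share_flagged: float


def cochran_sample_size(p: float, e: float, confidence: float) -> int:
    """Minimum sample size n0 = ceil(Z^2 p (1-p) / e^2).

    ``Z`` is the two-sided standard-normal quantile at the given confidence
    level. The ceiling makes n0 the smallest integer meeting the precision
    target (e.g. p=0.125, e=0.05, confidence=0.99 -> 291).
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if not 0 < e < 1:
        raise ValueError("e must lie in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    z = scipy.stats.norm.ppf(0.5 + confidence / 2.0)
    return int(np.ceil(z * z * p * (1.0 - p) / (e * e)))


def pool_design(p: float, e: float, confidence: float) -> PoolDesign:
    return PoolDesign(confidence, p, e, cochran_sample_size(p, e, confidence))


def rmse(estimated: Sequence[float], truth: Sequence[float]) -> float:
    """Root-mean-square deviation between paired frequency vectors."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("length mismatch between estimated and truth")
    if est.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN (flagged missing) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Zero-inflated negative binomial group test

def zinb_group_test(
    donor_reads: Sequence[int],
    total_reads: Sequence[int],
    group_labels: Sequence[int],
    maxiter: int = 500,
) -> tuple[float, float]:
    """Compare two frequency tracks as overdispersed, zero-inflated counts.

    Fits a zero-inflated NB2 regression of donor read counts on a group
    indicator, with log(total reads) as offset in the count component and
    the same indicator in the logit zero-inflation component. The structural
    zero component absorbs loci where a low-frequency allele produced no
    read at all; the NB component carries the loci with donor reads.

    Returns the Wald probabilities (p_count, p_zero) for the group
    coefficient in each component; p < 0.05 indicates a significant
    difference between the tracks. Non-convergence is retried from fallback
    optimisers and start values; a persistent failure returns (nan, nan),
    never fabricated probabilities.
    """
    y = np.asarray(donor_reads, dtype=float)
    offset = np.asarray(total_reads, dtype=float)
    group = np.asarray(group_labels, dtype=float)
    if not (y.shape == offset.shape == group.shape):
        raise ValueError("donor_reads, total_reads, group_labels must align")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("donor_reads must be non-negative integers")
    if np.any(offset < 1):
        raise ValueError("total_reads must be >= 1")
    groups = np.unique(group)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for g in groups:
        if np.sum(group == g) < 10:
            raise ValueError("need >= 10 loci per group")
    indicator = (group == groups[1]).astype(float)

    exog = pd.DataFrame({"const": 1.0, "group": indicator})
    model = ZeroInflatedNegativeBinomialP(
        y, exog, exog_infl=exog, offset=np.log(offset), inflation="logit", p=2
    )

    start_sets = [None]
    try:
        nb = sm.NegativeBinomialP(y, exog, offset=np.log(offset), p=2).fit(
            disp=0, maxiter=200)
        zero_share = np.clip(np.mean(y == 0), 0.05, 0.95)
        logit0 = np.log(zero_share / (1 - zero_share))
        start_sets.append(np.r_[logit0, 0.0, nb.params])
    except Exception:  # start-value helper only; silence and fall through
        pass

    for method in ("bfgs", "lbfgs", "nm"):
        for start in start_sets:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(start_params=start, method=method,
                                    maxiter=maxiter, disp=0)
                if not res.mle_retvals.get("converged", False):
                    continue
                p_zero = _param_pvalue(res, "inflate_group")
                p_count = _param_pvalue(res, "group")
                if np.isfinite(p_zero) and np.isfinite(p_count):
                    return float(p_count), float(p_zero)
            except Exception:
                continue
    log.warning("zinb_group_test: fit did not converge; returning NaN")
    return float("nan"), float("nan")


def _param_pvalue(res, name: str) -> float:
    names = list(res.model.exog_names)
    if name not in names:
        return float("nan")
    return float(np.asarray(res.pvalues)[names.index(name)])


def compare_tracks(
    pool_freqs: Sequence[float],
    ref_freqs: Sequence[float],
    pool_total_reads: Sequence[int],
    ref_total_reads: Sequence[int] | None = None,
) -> ComparisonResult:
    """Full agreement report between a pool track and a reference track.

    The reference is typically individual genotyping (frequencies without
    read depths); its frequencies are converted to pseudo-counts at the
    paired pool window's depth so both groups live on the same offset scale
    for the count model. If the reference has its own depths, those are used
    instead.
    """
    pool = np.asarray(pool_freqs, dtype=float)
    ref = np.asarray(ref_freqs, dtype=float)
    depth = np.asarray(pool_total_reads, dtype=int)
    if ref_total_reads is None:
        ref_depth = depth
    else:
        ref_depth = np.asarray(ref_total_reads, dtype=int)
    n = len(pool)
    donor = np.r_[np.round(pool * depth), np.round(ref * ref_depth)]
    offsets = np.r_[depth, ref_depth]
    labels = np.r_[np.zeros(n), np.ones(n)]
    p_count, p_zero = zinb_group_test(donor, offsets, labels)
    return ComparisonResult(
        rmse=rmse(pool, ref),
        pearson_r=pearson_r(pool, ref) if n >= 3 else float("nan"),
        p_count=p_count,
        p_zero=p_zero,
        n_loci=n,
        residual_width=float(np.mean(np.abs(pool - ref))),
    )


# ---------------------------------------------------------------------------
# Bias regression

def bias_regression(
    deviations: Sequence[float],
    extension_sizes: Sequence[float],
    positions: Sequence[float],
) -> BiasRegressionResult:
    """OLS of (estimated - true) frequency on extension size and position.

    Checks whether the window-extension step or the chromosomal location
    biases the HAF estimate. With an identically-zero response the standard
    errors degenerate; coefficients are reported as 0 with p = 1.
    """
    y = np.asarray(deviations, dtype=float)
    x1 = np.asarray(extension_sizes, dtype=float)
    x2 = np.asarray(positions, dtype=float)
    if not (y.shape == x1.shape == x2.shape):
        raise ValueError("inputs must have equal length")
    if y.size < 10:
        raise ValueError("need n >= 10")
    if np.all(y == 0):
        return BiasRegressionResult(0.0, 1.0, 0.0, 1.0, y.size)
    X = pd.DataFrame({"extension": x1, "position": x2})
    X = sm.add_constant(X)
    res = sm.OLS(y, X).fit()
    collinear = bool(np.linalg.matrix_rank(X.values) < X.shape[1])
    return BiasRegressionResult(
        coef_extension=float(res.params["extension"]),
        p_extension=float(res.pvalues["extension"]),
        coef_position=float(res.params["position"]),
        p_position=float(res.pvalues["position"]),
        n=int(y.size),
        collinear=collinear,
    )


# ---------------------------------------------------------------------------
# Neighbour-deviation QC

def neighbor_deviation_qc(haf_records: Sequence, multiplier: float = 5.0
                          ) -> NeighborQCResult:
    """Flag windows that deviate strongly from their physical neighbours.

    Per chromosome (windows sorted by position) the absolute HAF distance
    between consecutive windows is computed and its median taken. A window
    is flagged when its distance to BOTH neighbours exceeds
    ``multiplier * median`` (terminal windows use their single neighbour).
    Isolated frequency jumps in a large-linkage-block population are treated
    as suspect calls rather than double crossovers.
    """
    by_chrom: dict[str, list] = {}
    for r in haf_records:
        by_chrom.setdefault(r.chrom, []).append(r)
    medians: dict[str, float] = {}
    flagged: list[str] = []
    n_total = 0
    for chrom, group in by_chrom.items():
        group.sort(key=lambda r: (r.start, r.end))
        n = len(group)
        n_total += n
        if n < 3:
            raise ValueError(f"chromosome {chrom}: need >= 3 windows for QC")
        haf = np.array([r.haf for r in group])
        dist = np.abs(np.diff(haf))
        med = float(np.median(dist))
        medians[chrom] = med
        cut = multiplier * med
        for i, r in enumerate(group):
            if i == 0:
                bad = dist[0] > cut
            elif i == n - 1:
                bad = dist[-1] > cut
            else:
                bad = dist[i - 1] > cut and dist[i] > cut
            if bad:
                flagged.append(r.anchor_id)
    return NeighborQCResult(
        median_by_chrom=medians,
        flagged=tuple(flagged),
        share_flagged=len(flagged) / n_total if n_total else 0.0,
    )
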