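"""Allelic-imbalance testing, FDR control, and fold-change classification.

The skew test is a self-contained reimplementation: an exact two-sided
binomial test of the summed maternal count against the summed total at
p0 = 0.5 (default), or a beta-binomial variant with a single
overdispersion parameter estimated across peaks by the method of
moments.  Peaks with BH-adjusted q below the FDR threshold are
classified allele-specific.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SkewConfig",
    "SkewResult",
    "TestOutcome",
    "test_skew",
    "bh_fdr",
    "classify_fold",
    "estimate_overdispersion",
    "analyze_skew",
    "signal_match_subsample",
]


@dataclass
class SkewConfig:
    fdr_threshold: float = 0.1
    fold_thresholds: tuple[float, ...] = (2.0, 4.0)
    tf_halfwidth: int = 250
    histone_halfwidth: int = 500
    pseudocount: float = 1.0
    test: str = "binomial"  # {"binomial", "beta_binomial"}
    #: intraclass correlation for the beta-binomial test; estimated from
    #: the data by analyze_skew when None
    rho: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("SkewConfig.fdr_threshold must be in (0, 1)")
        if any(t <= 0 for t in self.fold_thresholds):
            raise ValueError("SkewConfig.fold_thresholds must be positive")
        if self.test not in ("binomial", "beta_binomial"):
            raise ValueError(f"unknown test {self.test!r}")


class TestOutcome(NamedTuple):
    p: float
    no_data: bool


@dataclass
class SkewResult:
    peak_id: str
    maternal_total: int
    paternal_total: int
    log2_fold: float
    p: float
    q: float = math.nan
    klass: str = "shared"  # {"allele_specific", "shared"}
    direction: str = "none"  # {"maternal", "paternal", "none"}
    magnitude: str = "lt2"  # {"lt2", "ge2", "ge4"}
    no_data: bool = False


def test_skew(
    maternal_counts: Sequence[int],
    paternal_counts: Sequence[int],
    config: SkewConfig | None = None,
) -> TestOutcome:
    """Two-sided allelic-imbalance p-value for one peak.

    Counts are summed across replicates.  A zero total yields p = 1 with
    the no-data flag set.
    """
    config = config or SkewConfig()
    m = int(np.sum(maternal_counts))
    p_ = int(np.sum(paternal_counts))
    if m < 0 or p_ < 0:
        raise ValueError("counts must be nonnegative")
    n = m + p_
    if n == 0:
        return TestOutcome(1.0, True)
    if config.test == "binomial":
        pval = stats.binomtest(m, n, 0.5).pvalue
    else:
        rho = config.rho or 0.0
        pval = _beta_binomial_pvalue(m, n, rho)
    return TestOutcome(float(min(1.0, pval)), False)


def _beta_binomial_pvalue(k: int, n: int, rho: float) -> float:
    """Two-sided symmetric beta-binomial test (doubled smaller tail)."""
    if rho <= 0:
        return stats.binomtest(k, n, 0.5).pvalue
    a = 0.5 * (1.0 / rho - 1.0)
    lower = stats.betabinom.cdf(k, n, a, a)
    upper = stats.betabinom.sf(k - 1, n, a, a)
    return min(1.0, 2.0 * min(lower, upper))


def estimate_overdispersion(
    maternal_totals: Sequence[int], paternal_totals: Sequence[int]
) -> float:
    """Method-of-moments intraclass correlation across peaks.

    Uses the standard weighted MoM estimator for the beta-binomial ICC
    under a common allelic proportion; clipped to [0, 0.99].  Returns 0
    when the data are binomially dispersed or there are too few peaks.
    """
    ks = np.asarray(maternal_totals, dtype=float)
    ns = ks + np.asarray(paternal_totals, dtype=float)
    keep = ns > 0
    ks, ns = ks[keep], ns[keep]
    m = len(ns)
    if m < 2:
        return 0.0
    w = ns
    phat = ks / ns
    pbar = ks.sum() / ns.sum()
    if pbar in (0.0, 1.0):
        return 0.0
    s = float(np.sum(w * (phat - pbar) ** 2))
    denom_binom = pbar * (1 - pbar)
    nw = ns.sum() - np.sum(ns**2) / ns.sum()
    # E[S] = p(1-p) * ((m-1) + rho * (sum(n) - sum(n^2)/sum(n) - (m-1)))
    extra = nw - (m - 1)
    if extra <= 0:
        return 0.0
    rho = (s / denom_binom - (m - 1)) / extra
    return float(np.clip(rho, 0.0, 0.99))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    Order-invariant: q-values are returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return np.maximum(q, p)


def classify_fold(
    maternal_total: float, paternal_total: float, config: SkewConfig | None = None
) -> tuple[float, str]:
    """Pseudocounted log2 fold change and its magnitude bin (strict >)."""
    config = config or SkewConfig()
    if maternal_total < 0 or paternal_total < 0:
        raise ValueError("totals must be nonnegative")
    pc = config.pseudocount
    log2_fold = math.log2((maternal_total + pc) / (paternal_total + pc))
    magnitude = "lt2"
    thresholds = sorted(config.fold_thresholds)
    if len(thresholds) >= 2 and abs(log2_fold) > math.log2(thresholds[1]):
        magnitude = "ge4"
    elif abs(log2_fold) > math.log2(thresholds[0]):
        magnitude = "ge2"
    return log2_fold, magnitude


def analyze_skew(
    records: Iterable[tuple[str, Sequence[int], Sequence[int]]],
    config: SkewConfig | None = None,
) -> list[SkewResult]:
    """Full skew analysis for (peak_id, maternal_counts, paternal_counts) records.

    For the beta-binomial test with ``config.rho`` unset, the
    overdispersion is first estimated across all peaks by the method of
    moments.
    """
    config = config or SkewConfig()
    items = [(pid, int(np.sum(mc)), int(np.sum(pc))) for pid, mc, pc in records]
    if config.test == "beta_binomial" and config.rho is None:
        rho = estimate_overdispersion([m for _, m, _ in items], [p for _, _, p in items])
        config = replace(config, rho=rho)
    results = []
    for pid, m, p_ in items:
        outcome = test_skew([m], [p_], config)
        log2_fold, magnitude = classify_fold(m, p_, config)
        results.append(
            SkewResult(
                peak_id=pid,
                maternal_total=m,
                paternal_total=p_,
                log2_fold=log2_fold,
                p=outcome.p,
                magnitude=magnitude,
                no_data=outcome.no_data,
            )
        )
    qvals = bh_fdr([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
        r.klass = "allele_specific" if q < config.fdr_threshold else "shared"
        if r.klass == "allele_specific" and r.log2_fold != 0:
            r.direction = "maternal" if r.log2_fold > 0 else "paternal"
    return results


def signal_match_subsample(
    shared_signals: Sequence[float],
    reference_signals: Sequence[float],
    n_bins: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Indices of a shared-peak subsample signal-matched to the reference.

    Reference signals are split into ``n_bins`` quantile bins; from each
    bin, shared peaks falling in the bin's signal range are drawn without
    replacement in proportion to the reference bin mass (capped at
    availability).  Deterministic given the seed.
    """
    shared = np.asarray(shared_signals, dtype=float)
    reference = np.asarray(reference_signals, dtype=float)
    if shared.size == 0 or reference.size == 0:
        raise ValueError("both peak sets must be nonempty")
    rng = np.random.default_rng(seed)
    edges = np.quantile(reference, np.linspace(0, 1, n_bins + 1))
    selected: list[int] = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        ref_mass = int(
            np.sum((reference >= lo) & ((reference < hi) | ((b == n_bins - 1) & (reference <= hi))))
        )
        if ref_mass == 0:
            continue
        if b == n_bins - 1:
            candidates = np.flatnonzero((shared >= lo) & (shared <= hi))
        else:
            candidates = np.flatnonzero((shared >= lo) & (shared < hi))
        if candidates.size == 0:
            warnings.warn(f"no shared candidates in signal bin {b}; skipped", stacklevel=2)
            continue
        take = min(ref_mass, candidates.size)
        selected.extend(rng.choice(candidates, size=take, replace=False).tolist())
    return np.sort(np.array(selected, dtype=int))
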