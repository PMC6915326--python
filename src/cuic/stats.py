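"""Bias and quantification statistics.

Covers the statistics used around the interface-index / abundance analysis:
two-sample Kolmogorov-Smirnov, Mann-Whitney rank-sum, Fisher's exact test on
the 2x2 high-index x abundance table, the fold-depletion of high-index RPs
from the abundant group, the stage-to-stage abundance-ratio comparison
between RP and non-RP transcripts, and the FRAP relative-recovery transform
Rx = (Ix - Ipost) / (Ipre - Ipost).

KS and rank-sum default to their large-sample approximations (asymptotic KS
distribution; tie-corrected normal approximation with continuity correction)
and offer exact label-permutation enumeration for small samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError, UndefinedResultError

logger = logging.getLogger(__name__)

#: Abundant / non-abundant FPKM split (strict >).
FPKM_CUT = 100.0
#: High / low interface-index split (strict >).
INDEX_CUT = 0.6
#: Largest n+m for which exact permutation enumeration is attempted.
EXACT_LIMIT = 16


def _check_samples(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    return x, y


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """D = sup |ECDF_x - ECDF_y|."""
    x, y = _check_samples(x, y)
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), grid, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], mode: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sided two-sample KS test.

    ``mode='asymptotic'`` uses the Kolmogorov limiting distribution;
    ``mode='exact'`` enumerates all label permutations (n+m <= 16).
    """
    x, y = _check_samples(x, y)
    d = ks_statistic(x, y)
    if mode == "asymptotic":
        res = sps.ks_2samp(x, y, method="asymp")
        return float(res.statistic), float(res.pvalue)
    if mode == "exact":
        p = _permutation_pvalue(x, y, ks_statistic, d)
        return d, p
    raise InputError(f"unknown mode {mode!r}")


def _permutation_pvalue(x, y, statistic, observed) -> float:
    n, m = len(x), len(y)
    if n + m > EXACT_LIMIT:
        raise InputError(
            f"exact enumeration limited to n+m <= {EXACT_LIMIT}, got {n + m}"
        )
    pooled = np.concatenate([x, y])
    idx = range(n + m)
    hits = total = 0
    for comb in combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(comb)] = True
        stat = statistic(pooled[mask], pooled[~mask])
        total += 1
        if stat >= observed - 1e-12:
            hits += 1
    return hits / total


def rank_sum_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U for the first sample, with midrank ties."""
    x, y = _check_samples(x, y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], mode: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    ``mode='asymptotic'`` is the tie-corrected normal approximation with
    continuity correction; ``mode='exact'`` enumerates label permutations
    (valid with ties; n+m <= 16).
    """
    x, y = _check_samples(x, y)
    u = rank_sum_statistic(x, y)
    if mode == "asymptotic":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if mode == "exact":
        centre = x.size * y.size / 2.0
        p = _permutation_pvalue(
            x, y, lambda a, b: abs(rank_sum_statistic(a, b) - centre),
            abs(u - centre),
        )
        return u, p
    raise InputError(f"unknown mode {mode!r}")


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums, over the conditional hypergeometric support, every
    table whose probability does not exceed the observed table's (with a
    small relative tolerance for float round-off).  The sample odds ratio is
    (a*d)/(b*c), with 0/inf/NaN for degenerate tables.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InputError("table must be 2x2 with non-negative integer counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise InputError("table total is zero")
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    r, col = a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r, col)
    p_obs = pmf[a - lo]
    p = float(np.sum(pmf[pmf <= p_obs * (1 + 1e-9)]))
    return odds, min(1.0, p)


# ---------------------------------------------------------------------------
# Interface-index vs abundance bias
# ---------------------------------------------------------------------------

@dataclass
class BiasResult:
    """Summary of the interface-index vs abundance comparison."""

    group_hi_mean: float          # mean index, abundant group
    group_lo_mean: float          # mean index, non-abundant group
    n_abundant: int
    n_non_abundant: int
    ks_D: float
    ks_p: float
    fisher_table: list[list[int]]  # [[hi&abundant, hi&non], [low&abundant, low&non]]
    fisher_odds: float
    fisher_p: float
    fold_depletion: float
    fpkm_cut: float
    index_cut: float

    def to_dict(self) -> dict:
        return {
            "group_hi_mean": self.group_hi_mean,
            "group_lo_mean": self.group_lo_mean,
            "n_abundant": self.n_abundant,
            "n_non_abundant": self.n_non_abundant,
            "ks_D": self.ks_D,
            "ks_p": self.ks_p,
            "fisher_table": self.fisher_table,
            "fisher_odds": self.fisher_odds,
            "fisher_p": self.fisher_p,
            "fold_depletion": self.fold_depletion,
            "fpkm_cut": self.fpkm_cut,
            "index_cut": self.index_cut,
        }


def depletion_fold(
    index_by_rp: Mapping[str, float],
    abundant: set[str],
    index_cut: float = INDEX_CUT,
    baseline: str = "non_abundant",
) -> float:
    """Fold-depletion of high-index RPs from the abundant group.

    fold = fraction(index > cut | baseline group) / fraction(index > cut |
    abundant).  ``baseline`` is the non-abundant group by default, or "all"
    RPs.  An abundant-group fraction of zero yields +inf with a warning.
    """
    ab = [v for k, v in index_by_rp.items() if k in abundant]
    non = [v for k, v in index_by_rp.items() if k not in abundant]
    if not ab or not non:
        raise InputError("both abundant and non-abundant groups must be non-empty")
    ref = non if baseline == "non_abundant" else list(index_by_rp.values())
    frac_ref = np.mean([v > index_cut for v in ref])
    frac_ab = np.mean([v > index_cut for v in ab])
    if frac_ref == 0 and frac_ab == 0:
        raise UndefinedResultError("no high-index RPs in either group")
    if frac_ab == 0:
        logger.warning("abundant group has no high-index RPs; fold is infinite")
        return math.inf
    return float(frac_ref / frac_ab)


def bias_report(
    index_by_rp: Mapping[str, float],
    fpkm_by_rp: Mapping[str, float],
    fpkm_cut: float = FPKM_CUT,
    index_cut: float = INDEX_CUT,
) -> BiasResult:
    """Full abundance-vs-structure comparison on the shared RP set."""
    shared = sorted(set(index_by_rp) & set(fpkm_by_rp))
    if len(shared) < 4:
        raise InputError("need at least 4 RPs shared between index and FPKM tables")
    idx = np.array([index_by_rp[k] for k in shared])
    abundant_mask = np.array([fpkm_by_rp[k] > fpkm_cut for k in shared])
    if abundant_mask.all() or not abundant_mask.any():
        raise InputError("abundance split produced an empty group")
    idx_ab, idx_non = idx[abundant_mask], idx[~abundant_mask]
    ks_d, ks_p = ks_two_sample(idx_ab, idx_non)
    hi = idx > index_cut
    table = [
        [int(np.sum(hi & abundant_mask)), int(np.sum(hi & ~abundant_mask))],
        [int(np.sum(~hi & abundant_mask)), int(np.sum(~hi & ~abundant_mask))],
    ]
    odds, fisher_p = fisher_exact_2x2(table)
    abundant_ids = {k for k, m in zip(shared, abundant_mask) if m}
    fold = depletion_fold(
        {k: index_by_rp[k] for k in shared}, abundant_ids, index_cut
    )
    return BiasResult(
        group_hi_mean=float(idx_ab.mean()),
        group_lo_mean=float(idx_non.mean()),
        n_abundant=int(abundant_mask.sum()),
        n_non_abundant=int((~abundant_mask).sum()),
        ks_D=ks_d,
        ks_p=ks_p,
        fisher_table=table,
        fisher_odds=odds,
        fisher_p=fisher_p,
        fold_depletion=fold,
        fpkm_cut=fpkm_cut,
        index_cut=index_cut,
    )


# ---------------------------------------------------------------------------
# Stage-ratio distributions and FRAP recovery
# ---------------------------------------------------------------------------

def stage_ratio_distribution(
    fpkm_a: Mapping[str, float],
    fpkm_b: Mapping[str, float],
    rp_ids: set[str],
    pseudocount: float = 1.0,
) -> tuple[dict[str, float], tuple[float, float]]:
    """Per-transcript log2 stage ratios and the RP vs non-RP KS comparison.

    ratio = (fpkm_b + pseudocount) / (fpkm_a + pseudocount), reported as
    log2; stage a is the earlier stage (e.g. branching P0.5) and b the later
    (refinement P7.5).  Returns (log2 ratios by transcript, (ks_D, ks_p)).
    """
    shared = sorted(set(fpkm_a) & set(fpkm_b))
    if not shared:
        raise InputError("no shared transcript ids between the two stages")
    ratios: dict[str, float] = {}
    for tid in shared:
        denom = fpkm_a[tid] + pseudocount
        if denom <= 0:
            raise InputError(
                f"non-positive denominator for {tid}: fpkm={fpkm_a[tid]}, "
                f"pseudocount={pseudocount}"
            )
        ratios[tid] = math.log2((fpkm_b[tid] + pseudocount) / denom)
    rp = [v for k, v in ratios.items() if k in rp_ids]
    non = [v for k, v in ratios.items() if k not in rp_ids]
    if len(rp) < 2 or len(non) < 2:
        raise InputError("need at least 2 RP and 2 non-RP shared transcripts")
    return ratios, ks_two_sample(rp, non)


def frap_relative_recovery(
    i_x: Sequence[float],
    i_pre: float,
    i_post: float,
    background: Optional[Sequence[float] | float] = None,
    background_pre: float = 0.0,
    background_post: float = 0.0,
) -> np.ndarray:
    """FRAP relative recovery Rx = (Ix - Ipost) / (Ipre - Ipost).

    Intensities are background-corrected first: ``background`` applies per
    timepoint (scalar or sequence) and ``background_pre``/``background_post``
    to the reference intensities.
    """
    ix = np.asarray(i_x, dtype=float)
    if background is not None:
        ix = ix - np.asarray(background, dtype=float)
    pre = i_pre - background_pre
    post = i_post - background_post
    if pre <= post:
        raise UndefinedResultError(
            f"recovery undefined: corrected Ipre ({pre}) <= Ipost ({post})"
        )
    return (ix - post) / (pre - post)
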