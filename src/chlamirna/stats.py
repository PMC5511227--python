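"""Expression quantification, differential flagging, and the
expression-level vs target-count comparison.

RPKM = 1e9*C/(N*L) and CPM = 1e6*C/N are the usual length/depth
normalisations.  Differential expression here is deliberately simple: an
exact two-sided binomial test on a pair of counts (or externally supplied
p-values), Benjamini-Hochberg adjustment across genes, and the
"q <= 0.05 and >= 2-fold change" rule.  The group comparison splits
miRNAs at 500 CPM mean expression and contrasts their per-class target
counts with a Wilcoxon rank-sum test and Cohen's d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def compute_rpkm(c: float, n: float, length: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if n <= 0:
        raise ValueError(f"library total must be positive, got {n}")
    if length <= 0:
        raise ValueError(f"transcript length must be positive, got {length}")
    if c < 0:
        raise ValueError(f"count must be non-negative, got {c}")
    return 1e9 * c / (n * length)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0)
    return np.minimum(sps.false_discovery_control(p, method="bh"), 1.0)


def de_flag(
    rpkm_a: Sequence[float],
    rpkm_b: Sequence[float],
    pvalues: Sequence[float],
    gene_ids: Sequence[str] | None = None,
    q_max: float = 0.05,
    min_fold: float = 2.0,
    pseudo_rpkm: float = 0.1,
) -> pd.DataFrame:
    """Per-gene log2 fold change, BH q-value and the differential flag.

    ``log2_fc = log2(rpkm_b / rpkm_a)``; when either RPKM is zero a
    pseudo-RPKM of ``pseudo_rpkm`` is added to both.  A gene is flagged
    differentially expressed iff q <= ``q_max`` and the fold change is at
    least ``min_fold`` in either direction.
    """
    a = np.asarray(rpkm_a, dtype=float)
    b = np.asarray(rpkm_b, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if not (a.size == b.size == p.size):
        raise ValueError("rpkm_a, rpkm_b and pvalues must have equal length")
    zero = (a == 0) | (b == 0)
    num = np.where(zero, b + pseudo_rpkm, b)
    den = np.where(zero, a + pseudo_rpkm, a)
    log2_fc = np.log2(num / den)
    q = benjamini_hochberg(p)
    is_de = (q <= q_max) & (np.abs(log2_fc) >= math.log2(min_fold))
    if gene_ids is None:
        gene_ids = [f"gene_{i}" for i in range(a.size)]
    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "is_de": is_de,
        }
    )


def count_test(c1: int, n1: int, c2: int, n2: int) -> float:
    """Exact two-sided binomial test for a pair of library counts.

    Tests c1 successes in c1+c2 trials against success probability
    N1/(N1+N2); two-sided by summing outcome probabilities no larger than
    that of the observed outcome.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    total = c1 + c2
    if total == 0:
        return 1.0
    return float(sps.binomtest(c1, total, n1 / (n1 + n2)).pvalue)


def bin_expression_histogram(
    mean_cpms: Sequence[float], bin_width: float = 500.0
) -> np.ndarray:
    """Histogram counts over half-open bins [0,w), [w,2w), ...

    A value exactly on a boundary goes into the right-hand bin; counts sum
    to the input size.  Empty input gives an empty histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(mean_cpms, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=int)
    if (values < 0).any():
        raise ValueError("CPM values must be non-negative")
    idx = np.floor(values / bin_width).astype(int)
    return np.bincount(idx)


def classify_expression(mean_cpm: float, cutoff: float = 500.0) -> str:
    """'high' iff mean CPM >= cutoff (inclusive), else 'low'."""
    if mean_cpm < 0:
        raise ValueError("mean CPM must be non-negative")
    return "high" if mean_cpm >= cutoff else "low"


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_max_nm: int = 400
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when n*m <= ``exact_max_nm`` and the
    pooled sample has no ties, and otherwise the normal approximation with
    midranks, tie correction and continuity correction (the reference
    semantics of R's wilcox.test).  Returns (U of the first sample,
    two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # degenerate: identical constant data carries no ordering information
        return float(a.size * b.size / 2), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= exact_max_nm and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with the classic pooled-SD denominator (n-1 variances).

    Sign convention: mean(a) - mean(b); callers report the magnitude where
    only effect size matters.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


@dataclass
class GroupComparison:
    """Low- vs high-expression miRNA target counts with test results."""

    site_class: str
    group_low: np.ndarray
    group_high: np.ndarray
    mean_low: float
    mean_high: float
    n_low: int
    n_high: int
    u_statistic: float
    p_two_sided: float
    cohens_d: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class": self.site_class,
                    "mean_low": self.mean_low,
                    "mean_high": self.mean_high,
                    "n_low": self.n_low,
                    "n_high": self.n_high,
                    "U": self.u_statistic,
                    "p": self.p_two_sided,
                    "cohens_d": self.cohens_d,
                }
            ]
        )


def compare_expression_vs_targets(
    expression: pd.DataFrame,
    target_counts: pd.DataFrame,
    site_class: str = "cleavage",
    cpm_cutoff: float = 500.0,
) -> GroupComparison:
    """Contrast per-miRNA target counts between expression classes.

    ``expression`` needs columns mirna_id and mean_cpm; ``target_counts``
    needs mirna, cleavage, translational, excluded.  MicroRNAs with no
    identifiable target at all (absent from the count table, zero counts
    in both classes, or flagged excluded, e.g. precursor-only targeting)
    are removed before splitting at ``cpm_cutoff`` mean CPM.
    """
    if site_class not in ("cleavage", "translational"):
        raise ValueError(f"unknown site class {site_class!r}")
    counts = target_counts.set_index("mirna")
    low, high = [], []
    for _, row in expression.iterrows():
        mirna = row["mirna_id"]
        if mirna not in counts.index:
            continue
        crow = counts.loc[mirna]
        if bool(crow["excluded"]) or (crow["cleavage"] + crow["translational"]) == 0:
            continue
        value = float(crow[site_class])
        if classify_expression(float(row["mean_cpm"]), cutoff=cpm_cutoff) == "high":
            high.append(value)
        else:
            low.append(value)
    if not low or not high:
        raise ValueError(
            "a comparison group is empty after exclusions "
            f"(n_low={len(low)}, n_high={len(high)}); "
            "check the CPM cutoff and the target-count table"
        )
    u, p = wilcoxon_rank_sum(low, high)
    return GroupComparison(
        site_class=site_class,
        group_low=np.asarray(low),
        group_high=np.asarray(high),
        mean_low=float(np.mean(low)),
        mean_high=float(np.mean(high)),
        n_low=len(low),
        n_high=len(high),
        u_statistic=u,
        p_two_sided=p,
        cohens_d=cohens_d(low, high),
    )
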