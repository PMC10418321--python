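"""Nonparametric cohort statistics and clinical formulas.

Implements the statistical readouts used to relate metagenomic species (MGS)
detection and abundance to ordered disease-severity groups: per-group
prevalence, Fisher's exact test, Pearson chi-squared, Mann-Whitney U with the
AUC effect size, Kruskal-Wallis, the two-sample Kolmogorov-Smirnov test, and
a combined Wilcoxon+KS screen for discriminating MGS with Benjamini-Hochberg
correction.  Statistics are computed from first principles (midranks,
hypergeometric enumeration, lattice-path KS recursion); scipy supplies only
reference distributions (normal, chi-squared, hypergeometric, Kolmogorov).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "prevalence_by_group",
    "fisher_exact",
    "chi_squared",
    "mann_whitney_auc",
    "kruskal_wallis",
    "ks_two_sample",
    "screen_discriminating_mgs",
    "homa_ir",
    "friedewald_ldl",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``effect`` carries the AUC for Mann-Whitney and the odds ratio for
    Fisher's exact test; ``extras`` holds method-specific diagnostics such as
    expected counts or low-count warnings.
    """

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    effect: float | None = None
    n: tuple = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------

def prevalence_by_group(
    detections: Mapping[str, bool] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
    group_order: Sequence[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Fraction of samples in which the species is detected, per group.

    Returns the per-group prevalence and the 2 x g contingency table
    (rows ``detected`` / ``undetected``) used by downstream count tests.
    """
    det = pd.Series(detections, dtype=bool)
    grp = pd.Series(groups)
    missing = det.index.difference(grp.index)
    if len(missing):
        raise ValueError(f"samples without a group: {list(missing)[:5]}")
    grp = grp.loc[det.index]
    order = list(group_order) if group_order is not None else list(pd.unique(grp))
    for g in order:
        if (grp == g).sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
    prev = pd.Series(
        [det[grp == g].mean() for g in order], index=order, name="prevalence"
    )
    table = pd.DataFrame(
        {
            g: [int(det[grp == g].sum()), int((~det[grp == g]).sum())]
            for g in order
        },
        index=["detected", "undetected"],
    )
    return prev, table


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2, two-sided by probability mass)
# ---------------------------------------------------------------------------

def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test for a 2x2 table.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, of tables whose probability does not exceed that of the
    observed table (with a 1 + 1e-7 relative slack against floating-point
    artefacts) -- the probability-mass convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    sel = pmf <= p_obs * (1 + 1e-7)
    p = 1.0 if sel.all() else float(min(1.0, pmf[sel].sum()))
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return TestResult(
        method="fisher_exact", statistic=p_obs, p_value=p, effect=odds, n=(n,)
    )


# ---------------------------------------------------------------------------
# Pearson chi-squared
# ---------------------------------------------------------------------------

def chi_squared(table) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("chi_squared requires an r x c table with r, c >= 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("degenerate table: a margin sums to zero")
    expected = np.outer(row, col) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(
        method="chi_squared",
        statistic=stat,
        p_value=p,
        df=df,
        n=(int(t.sum()),),
        extras={
            "expected": expected,
            "low_expected_counts": bool(np.any(expected < 5)),
        },
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U / AUC
# ---------------------------------------------------------------------------

def _u_null_counts(n: int, m: int) -> np.ndarray:
    """Number of label arrangements yielding each U value (0..n*m).

    Coefficients of the Gaussian binomial [n+m, n]_q, built by polynomial
    multiplication by (1 - q^(m+i)) and division by (1 - q^i).
    """
    size = n * m + 1
    dp = np.zeros(size)
    dp[0] = 1.0
    for i in range(1, n + 1):
        new = dp.copy()
        if m + i < size:
            new[m + i:] -= dp[: size - (m + i)]
        for u in range(i, size):
            new[u] += new[u - i]
        dp = new
    return dp


def mann_whitney_auc(x, y) -> TestResult:
    """Mann-Whitney U test with the AUC = U/(n_x n_y) effect size.

    The AUC equals the probability that a random ``x`` exceeds a random
    ``y``, counting ties as one half.  The p-value is exact (null-distribution
    enumeration) for untied samples with n_x + n_y <= 20, otherwise a
    tie-corrected, continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[:nx].sum()
    u = rx - nx * (nx + 1) / 2.0
    auc = u / (nx * ny)
    _, counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(counts > 1))
    nn = nx + ny
    if not has_ties and nn <= 20:
        null = _u_null_counts(nx, ny)
        cdf = np.cumsum(null) / null.sum()
        u_int = int(round(u))
        p = float(min(1.0, 2.0 * cdf[min(u_int, nx * ny - u_int)]))
    else:
        mu = nx * ny / 2.0
        tie_term = float(((counts ** 3 - counts)).sum()) / (nn * (nn - 1))
        sigma2 = nx * ny / 12.0 * ((nn + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
            z = max(z, 0.0)
            p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return TestResult(
        method="mann_whitney",
        statistic=float(u),
        p_value=p,
        effect=float(auc),
        n=(nx, ny),
        extras={"ties": has_ties},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups."""
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("need at least two groups")
    vectors = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(len(v) == 0 for v in vectors):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(vectors)
    nn = len(pooled)
    if np.unique(pooled).size < 2:
        raise ValueError("all values identical: H statistic undefined")
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for v in vectors:
        r = ranks[start : start + len(v)]
        h += r.sum() ** 2 / len(v)
        start += len(v)
    h = 12.0 / (nn * (nn + 1)) * h - 3 * (nn + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((counts ** 3 - counts).sum()) / (nn ** 3 - nn)
    h /= correction
    df = len(keys) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult(
        method="kruskal_wallis",
        statistic=float(h),
        p_value=p,
        df=df,
        n=tuple(len(v) for v in vectors),
    )


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def _ks_d_int(x: np.ndarray, y: np.ndarray) -> int:
    """sup |ECDF_x - ECDF_y| on the integer scale: D * n_x * n_y."""
    nx, ny = len(x), len(y)
    sx, sy = np.sort(x), np.sort(y)
    all_v = np.concatenate([sx, sy])
    cx = np.searchsorted(sx, all_v, side="right")
    cy = np.searchsorted(sy, all_v, side="right")
    return int(np.max(np.abs(cx * ny - cy * nx)))


def _ks_paths_below(n: int, m: int, c: int) -> float:
    """Number of monotone lattice paths (0,0)->(n,m) with |i*m - j*n| < c.

    Row-by-row recursion; each row is a cumulative sum over the contiguous
    band of allowed cells, so the whole count is O(n) vectorised steps.
    """
    j = np.arange(m + 1)
    row = np.zeros(m + 1)
    # row i=0: the allowed band starts at j=0, so reachable == allowed
    row[np.abs(j * n) < c] = 1.0
    for i in range(1, n + 1):
        allowed = np.abs(i * m - j * n) < c  # contiguous interval of j
        if not allowed.any():
            return 0.0
        seg = np.where(allowed, row, 0.0)
        lo = int(np.argmax(allowed))
        new = np.zeros(m + 1)
        new[lo:] = np.cumsum(seg[lo:])  # new[j] = new[j-1] + row[j] in band
        new[~allowed] = 0.0
        row = new
    return float(row[m])


def ks_exact_sf(n: int, m: int, d_int: int) -> float:
    """Exact P(D >= d) for the untied two-sample KS statistic.

    ``d_int`` is D on the integer scale (D * n * m).
    """
    if d_int <= 0:
        return 1.0
    below = _ks_paths_below(n, m, d_int)
    total = math.comb(n + m, n)
    return float(min(1.0, max(0.0, 1.0 - below / total)))


def ks_asymptotic_sf(n: int, m: int, d: float) -> float:
    """Kolmogorov asymptotic P(D >= d) with small-sample correction."""
    en = math.sqrt(n * m / (n + m))
    return float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))


def ks_two_sample(x, y, mode: str = "auto") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    ``mode='auto'`` uses the exact lattice-path null distribution when the
    samples are untied and n_x * n_y <= 10000, otherwise the Kolmogorov
    asymptotic approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    d_int = _ks_d_int(x, y)
    d = d_int / (nx * ny)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < nx + ny
    use_exact = mode == "exact" or (
        mode == "auto" and not has_ties and nx * ny <= 10_000
    )
    if use_exact:
        p = ks_exact_sf(nx, ny, d_int)
    else:
        p = ks_asymptotic_sf(nx, ny, d)
    return TestResult(
        method="ks_two_sample",
        statistic=float(d),
        p_value=p,
        n=(nx, ny),
        extras={"ties": bool(has_ties), "exact": use_exact},
    )


# ---------------------------------------------------------------------------
# vectorised per-column helpers (used by the MGS screen and calibration)
# ---------------------------------------------------------------------------

def rank_sum_p_columns(values: np.ndarray, is_x: np.ndarray) -> np.ndarray:
    """Tie-corrected normal-approximation Wilcoxon p per column.

    ``values`` is (n_samples, n_features); ``is_x`` flags the first group.
    Matches the large-sample branch of :func:`mann_whitney_auc`.
    """
    values = np.asarray(values, dtype=float)
    is_x = np.asarray(is_x, dtype=bool)
    nx = int(is_x.sum())
    ny = int((~is_x).sum())
    nn = nx + ny
    ranks = sps.rankdata(values, axis=0)
    rx = ranks[is_x].sum(axis=0)
    u = rx - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    # per-column tie correction
    sv = np.sort(values, axis=0)
    new_run = np.ones_like(sv, dtype=bool)
    new_run[1:] = sv[1:] != sv[:-1]
    tie_term = np.zeros(values.shape[1])
    tied_cols = np.nonzero(~new_run.all(axis=0))[0]
    for j in tied_cols:  # tie runs differ per column; untied columns stay 0
        counts = np.diff(np.append(np.where(new_run[:, j])[0], nn))
        tie_term[j] = float((counts ** 3 - counts).sum())
    sigma2 = nx * ny / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    z = np.where(sigma2 > 0, (np.abs(u - mu) - 0.5) / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)
    z = np.maximum(z, 0.0)
    return np.minimum(1.0, 2.0 * sps.norm.sf(z))


def ks_d_columns(values: np.ndarray, is_x: np.ndarray) -> np.ndarray:
    """KS D statistic per column of a (n_samples, n_features) matrix."""
    values = np.asarray(values, dtype=float)
    is_x = np.asarray(is_x, dtype=bool)
    nx = int(is_x.sum())
    ny = int((~is_x).sum())
    order = np.argsort(values, axis=0, kind="stable")
    steps = np.where(is_x[order], ny, -nx)  # |step| scaled by nx*ny
    walk = np.cumsum(steps, axis=0)
    return np.max(np.abs(walk), axis=0) / (nx * ny)


def screen_discriminating_mgs(
    profiles: pd.DataFrame,
    labels: Mapping[str, object] | pd.Series,
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
    combine: str = "both",
) -> pd.DataFrame:
    """Screen MGS abundance profiles for association with a binary condition.

    Runs a Wilcoxon rank-sum and a two-sample KS test per MGS (column of
    ``profiles``), adjusts each test family for multiple testing, and flags
    an MGS according to ``combine``: ``both`` (default) requires both
    adjusted p-values below ``alpha``; ``either`` requires one;
    ``fisher_combination`` combines the two raw p-values by Fisher's method
    before adjustment.  KS p-values are asymptotic here (vectorised screen).
    """
    labels = pd.Series(labels).loc[profiles.index]
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got {list(classes)}")
    is_x = (labels == classes[0]).to_numpy()
    if is_x.sum() < 3 or (~is_x).sum() < 3:
        raise ValueError("need at least 3 samples per class")
    values = profiles.to_numpy(dtype=float)
    nx, ny = int(is_x.sum()), int((~is_x).sum())
    wilcoxon_p = rank_sum_p_columns(values, is_x)
    d = ks_d_columns(values, is_x)
    en = math.sqrt(nx * ny / (nx + ny))
    ks_p = special.kolmogorov((en + 0.12 + 0.11 / en) * d)
    if adjust == "none":
        wilcoxon_adj, ks_adj = wilcoxon_p, ks_p
    else:
        wilcoxon_adj = multipletests(wilcoxon_p, method=adjust)[1]
        ks_adj = multipletests(ks_p, method=adjust)[1]
    if combine == "both":
        passed = (wilcoxon_adj < alpha) & (ks_adj < alpha)
    elif combine == "either":
        passed = (wilcoxon_adj < alpha) | (ks_adj < alpha)
    elif combine == "fisher_combination":
        stat = -2 * (np.log(np.maximum(wilcoxon_p, 1e-300)) + np.log(np.maximum(ks_p, 1e-300)))
        comb_p = sps.chi2.sf(stat, 4)
        comb_adj = comb_p if adjust == "none" else multipletests(comb_p, method=adjust)[1]
        passed = comb_adj < alpha
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return pd.DataFrame(
        {
            "wilcoxon_p": wilcoxon_p,
            "ks_p": ks_p,
            "wilcoxon_p_adj": wilcoxon_adj,
            "ks_p_adj": ks_adj,
            "passed": passed,
        },
        index=profiles.columns,
    )


# ---------------------------------------------------------------------------
# clinical formulas
# ---------------------------------------------------------------------------

def homa_ir(glucose_mmol_l: float, insulin_mu_l: float) -> float:
    """Homeostasis-model insulin-resistance index: glucose x insulin / 22.5."""
    if glucose_mmol_l <= 0 or insulin_mu_l <= 0:
        raise ValueError("glucose and insulin must be positive")
    return glucose_mmol_l * insulin_mu_l / 22.5


def friedewald_ldl(total_cholesterol: float, hdl: float, tg: float) -> float:
    """Friedewald LDL estimate (mmol/L): TC - HDL - TG/2.2, valid for TG < 4.6."""
    if tg >= 4.6:
        raise ValueError("Friedewald formula invalid for TG >= 4.6 mmol/L")
    if total_cholesterol < 0 or hdl < 0 or tg < 0:
        raise ValueError("inputs must be non-negative")
    return total_cholesterol - hdl - tg / 2.2
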