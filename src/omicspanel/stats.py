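"""Per-feature statistics: beta-binomial differential test, fold change,
Welch's t, single-feature AUC, and alpha/beta diversity.

The beta-binomial likelihood-ratio test targets spectral-count data, where
a protein's count in a sample is modeled as beta-binomially distributed
given the sample's total count.  The null model shares one underlying
proportion across both groups; the alternative gives each group its own
proportion; overdispersion is shared and profiled out.  Twice the
log-likelihood ratio is referred to chi-square with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform, pdist
from scipy.special import gammaln
from scipy.stats import rankdata

__all__ = [
    "DifferentialResult",
    "DiversityResult",
    "beta_binomial_test",
    "fold_change",
    "welch_t_test",
    "feature_auc",
    "compute_auc",
    "shannon_alpha",
    "bray_curtis_permanova",
]

_RHO_MAX = 0.995  # upper bound of the overdispersion search interval
_TOL = 1e-8


@dataclass
class DifferentialResult:
    """Outcome of one per-feature two-group test."""

    feature_id: str | None
    statistic: float
    p_value: float
    fold_change: float | None = None
    significant_fc: bool | None = None
    adjusted_p: float | None = None
    degenerate: bool = False


@dataclass
class DiversityResult:
    """Alpha diversity per sample plus a beta-diversity permutation test."""

    alpha: np.ndarray                 # per-sample Shannon entropy (nats)
    distance_matrix: np.ndarray       # pairwise Bray-Curtis, symmetric
    pseudo_f: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Beta-binomial likelihood machinery


def _betabin_loglik(k: np.ndarray, n: np.ndarray, pi: float, rho: float) -> float:
    """Log-likelihood of counts ``k`` of ``n`` under BetaBin(mean pi, overdisp rho).

    rho = 1/(a+b+1): rho -> 0 recovers the binomial.  Combinatorial terms are
    constant across the models compared and are omitted.
    """
    if rho <= 0.0:
        # binomial limit
        if pi <= 0.0:
            return 0.0 if np.all(k == 0) else -np.inf
        if pi >= 1.0:
            return 0.0 if np.all(k == n) else -np.inf
        return float(np.sum(k * np.log(pi) + (n - k) * np.log1p(-pi)))
    s = (1.0 - rho) / rho  # a + b
    a = pi * s
    b = (1.0 - pi) * s
    if a <= 0 or b <= 0:
        return -np.inf
    return float(
        np.sum(
            gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
        )
        + len(k) * (gammaln(a + b) - gammaln(a) - gammaln(b))
    )


def _mle_pi(k: np.ndarray, n: np.ndarray, rho: float) -> float:
    """Maximize the beta-binomial likelihood over the proportion at fixed rho."""
    tot_k, tot_n = k.sum(), n.sum()
    if tot_k == 0:
        return 0.0
    if tot_k == tot_n:
        return 1.0
    if rho <= 0.0:
        return tot_k / tot_n  # analytic binomial MLE
    res = minimize_scalar(
        lambda pi: -_betabin_loglik(k, n, pi, rho),
        bounds=(1e-9, 1 - 1e-9),
        method="bounded",
        options={"xatol": _TOL},
    )
    return float(res.x)


def _profile_loglik(groups: list[tuple[np.ndarray, np.ndarray]], rho: float) -> float:
    return sum(_betabin_loglik(k, n, _mle_pi(k, n, rho), rho) for k, n in groups)


def _maximize_over_rho(groups: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Profile likelihood over shared overdispersion, with the rho=0 boundary."""
    res = minimize_scalar(
        lambda r: -_profile_loglik(groups, r),
        bounds=(1e-9, _RHO_MAX),
        method="bounded",
        options={"xatol": _TOL},
    )
    best = -res.fun
    at_zero = _profile_loglik(groups, 0.0)
    return max(best, at_zero)


def beta_binomial_test(
    counts_a: Sequence[int],
    totals_a: Sequence[int],
    counts_b: Sequence[int],
    totals_b: Sequence[int],
    feature_id: str | None = None,
    overdispersion: float | None = None,
) -> DifferentialResult:
    """Likelihood-ratio test for a group difference in count proportions.

    Parameters
    ----------
    counts_a, totals_a, counts_b, totals_b:
        Per-sample feature counts and sample totals for the two groups.
    overdispersion:
        If given, the overdispersion is fixed at this value instead of being
        estimated (0 reduces the test to the binomial two-proportion LRT).

    Returns
    -------
    DifferentialResult with the LR statistic and its chi-square(1) p-value.
    All counts zero in both groups is reported as ``p = 1`` with the
    ``degenerate`` flag rather than raising.
    """
    ka, na = np.asarray(counts_a, float), np.asarray(totals_a, float)
    kb, nb = np.asarray(counts_b, float), np.asarray(totals_b, float)
    for k, n, tag in ((ka, na, "A"), (kb, nb, "B")):
        if k.shape != n.shape or k.ndim != 1:
            raise ValueError(f"group {tag}: counts and totals must be 1-D, same length")
        if len(k) < 2:
            raise ValueError(f"group {tag}: need at least 2 samples")
        if np.any(n <= 0):
            raise ValueError(f"group {tag}: totals must be positive")
        if np.any(k > n) or np.any(k < 0):
            raise ValueError(f"group {tag}: counts must lie in [0, total]")
    if ka.sum() == 0 and kb.sum() == 0:
        return DifferentialResult(feature_id, 0.0, 1.0, degenerate=True)

    pooled = [(np.concatenate([ka, kb]), np.concatenate([na, nb]))]
    split = [(ka, na), (kb, nb)]
    if overdispersion is None:
        ll_null = _maximize_over_rho(pooled)
        ll_alt = _maximize_over_rho(split)
    else:
        ll_null = _profile_loglik(pooled, overdispersion)
        ll_alt = _profile_loglik(split, overdispersion)
    lr = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(sps.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return DifferentialResult(feature_id, lr, p)


# ---------------------------------------------------------------------------
# Fold change and Welch's t


def fold_change(
    values_a: Sequence[float],
    values_b: Sequence[float],
    pseudocount: float = 0.0,
    threshold: float = 2.0,
) -> tuple[float, bool]:
    """Ratio of group means, (mean A + c) / (mean B + c), flagged at ``threshold``.

    The flag is raised for ratios >= threshold or <= 1/threshold.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("fold_change expects nonnegative values")
    fc = (a.mean() + pseudocount) / (b.mean() + pseudocount)
    flagged = bool(fc >= threshold or fc <= 1.0 / threshold)
    return float(fc), flagged


def welch_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    feature_id: str | None = None,
) -> DifferentialResult:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t_test needs at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return DifferentialResult(feature_id, 0.0, 1.0, degenerate=True)
        return DifferentialResult(feature_id, np.inf * np.sign(a.mean() - b.mean()), 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return DifferentialResult(feature_id, float(t), float(p))


# ---------------------------------------------------------------------------
# AUC


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve with ties given half credit (Mann-Whitney).

    ``labels`` must contain both classes (coded 0/1 or boolean).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("compute_auc requires both classes present")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class FeatureAuc:
    """Oriented single-feature AUC (>= 0.5) with the orientation recorded."""

    auc: float
    flipped: bool  # True when low values indicate the positive class


def feature_auc(values: Sequence[float], labels: Sequence[int]) -> FeatureAuc:
    """AUC of a single feature used directly as the classifier score.

    The direction is chosen so the reported AUC is >= 0.5; ``flipped``
    records whether the feature was negated.
    """
    raw = compute_auc(values, labels)
    if raw < 0.5:
        return FeatureAuc(1.0 - raw, True)
    return FeatureAuc(raw, False)


# ---------------------------------------------------------------------------
# Diversity


def shannon_alpha(count_row: Sequence[float]) -> float:
    """Shannon entropy (nats) of one sample's taxon counts."""
    x = np.asarray(count_row, float)
    total = x.sum()
    if total <= 0:
        raise ValueError("shannon_alpha requires a positive row total")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def _permanova_pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared distances: (SS_between/df_b) / (SS_within/df_w)."""
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    groups, counts = np.unique(labels, return_counts=True)
    for g, c in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * c)
    ss_between = ss_total - ss_within
    a = len(groups)
    if ss_within <= 1e-15:
        return np.inf if ss_between > 1e-15 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def bray_curtis_permanova(
    table,
    labels: Sequence[str],
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> DiversityResult:
    """Bray-Curtis beta diversity with a PERMANOVA group-label permutation test.

    Distances are computed on per-sample relative abundances; the permutation
    p-value uses +1 smoothing: ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    from .tables import relative_abundance

    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 3):
        raise ValueError("bray_curtis_permanova needs >= 3 samples per group")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse",
                      stacklevel=2)
    rng = np.random.default_rng() if rng is None else rng
    props = relative_abundance(table).matrix
    dm = squareform(pdist(props, metric="braycurtis"))
    # Shannon on the original counts
    alpha = np.array([shannon_alpha(row) for row in table.matrix])
    d2 = dm**2
    f_obs = _permanova_pseudo_f(d2, labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_pseudo_f(d2, perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return DiversityResult(alpha, dm, float(f_obs), float(p), n_perm)
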