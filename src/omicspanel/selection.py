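"""Combined LASSO / elastic-net stability selection.

The selection machinery repeatedly (default 100 times) draws a stratified
75/25 train/test split, tunes the penalty of a LASSO and of an elastic-net
logistic model by stratified 10-fold cross-validated AUC on the training
part, fits both at their tuned penalties, and records which features carry
nonzero coefficients.  Per-feature selection frequencies from the two
methods are summed into a combined frequency, features are ranked by it,
and the final marker set is the first (top) quartile of the ever-selected
features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._solver import fit_penalized_logistic, lambda_max, logistic_path

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyConfig",
    "StabilityRun",
    "StabilitySelection",
    "fit_penalized_logistic",
    "cv_optimize_lambda",
    "run_stability",
    "select_first_quartile",
]


@dataclass
class PenaltyConfig:
    """Settings of the penalized models and the resampling loop.

    ``lambda_grid`` holds descending fractions of the data-derived maximal
    penalty lambda_max (the smallest penalty with an empty L1 support), so
    the grid is scale-free; the default is 50 log-spaced points from 1 down
    to 0.001.
    """

    alpha_mix: float = 1.0            # 1 = LASSO; elastic net uses en_alpha
    en_alpha: float = 0.5             # elastic-net L1/L2 mixing
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1.0, 1e-3, 50)
    )
    cv_folds: int = 10
    train_fraction: float = 0.75
    n_iterations: int = 100
    seed: int = 0
    resample_mode: str = "split"      # "split" (re-split) or "bootstrap"
    cv_rule: str = "max"              # "max" or "one_se" (sparser models)
    tol: float = 1e-8

    def __post_init__(self) -> None:
        g = np.asarray(self.lambda_grid, float)
        if g.ndim != 1 or len(g) < 1 or np.any(np.diff(g) >= 0) and len(g) > 1:
            raise ValueError("lambda_grid must be 1-D and strictly descending")
        if np.any(g <= 0):
            raise ValueError("lambda_grid fractions must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.resample_mode not in ("split", "bootstrap"):
            raise ValueError("resample_mode must be 'split' or 'bootstrap'")
        if self.cv_rule not in ("max", "one_se"):
            raise ValueError("cv_rule must be 'max' or 'one_se'")
        self.lambda_grid = g


@dataclass
class StabilityRun:
    """Record of a single resampling iteration."""

    iteration: int
    train_sample_idx: np.ndarray
    lambda_lasso: float
    lambda_en: float
    support_lasso: np.ndarray  # boolean over features
    support_en: np.ndarray


@dataclass
class StabilitySelection:
    """Per-feature selection frequencies, ranks and the selected set.

    ``frequencies`` is indexed by feature ID with columns
    ``freq_lasso, freq_en, freq_combined, rank, selected``.
    """

    frequencies: pd.DataFrame
    n_iterations: int
    runs: list[StabilityRun] = field(default_factory=list, repr=False)

    @property
    def selected_features(self) -> list[str]:
        sel = self.frequencies[self.frequencies["selected"]]
        return list(sel.index)

    def to_tsv(self, path, layer: str = "") -> None:
        out = self.frequencies.copy()
        out.insert(0, "layer", layer)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def _fold_auc_matrix(scores: np.ndarray, y_val: np.ndarray) -> np.ndarray:
    """AUC per column of a (n_val, L) score matrix, ties half credit."""
    n1 = int(y_val.sum())
    n0 = len(y_val) - n1
    r = rankdata(scores, axis=0)
    return (r[y_val.astype(bool)].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def cv_optimize_lambda(
    X: np.ndarray,
    y: np.ndarray,
    config: PenaltyConfig,
    rng: np.random.Generator,
    alpha_mix: float | None = None,
) -> float:
    """Choose the penalty maximizing mean held-out AUC over the lambda grid.

    Folds are stratified by class; if the smaller class cannot populate
    every fold the fold count is reduced with a warning.  Ties are broken
    toward the larger lambda (the sparser model).  With
    ``config.cv_rule = "one_se"`` the largest lambda whose mean AUC lies
    within one standard error of the best is chosen instead (a sparser
    model at statistically indistinguishable performance).  The returned
    value is an absolute penalty (grid fraction times lambda_max of this
    data).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    alpha = config.alpha_mix if alpha_mix is None else alpha_mix
    if len(config.lambda_grid) == 1:
        return float(config.lambda_grid[0] * lambda_max(X, y, alpha))
    n_minority = int(min(np.bincount(y.astype(int), minlength=2)))
    folds = config.cv_folds
    if n_minority < folds:
        folds = max(2, n_minority)
        warnings.warn(
            f"reducing cv_folds to {folds}: minority class has {n_minority} samples",
            stacklevel=2,
        )
    lmax = lambda_max(X, y, alpha)
    grid = config.lambda_grid * lmax
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    aucs = np.zeros((folds, len(grid)))
    for fi, (tr, va) in enumerate(skf.split(X, y)):
        coefs, icpts = logistic_path(X[tr], y[tr], grid, alpha, tol=config.tol)
        scores = X[va] @ coefs.T + icpts
        aucs[fi] = _fold_auc_matrix(scores, y[va])
    mean_auc = aucs.mean(axis=0)
    # first index attaining the max = largest lambda (grid is descending)
    best = int(np.argmax(mean_auc > mean_auc.max() - 1e-12))
    if config.cv_rule == "one_se":
        se = aucs[:, best].std(ddof=1) / np.sqrt(folds)
        best = int(np.argmax(mean_auc >= mean_auc[best] - se))
    return float(grid[best])


def _stratified_train_idx(
    y: np.ndarray, train_fraction: float, seed: int
) -> np.ndarray:
    idx = np.arange(len(y))
    tr, _ = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    return np.sort(tr)


def run_stability(
    X: np.ndarray,
    y: np.ndarray,
    config: PenaltyConfig,
    feature_ids: list[str] | None = None,
) -> StabilitySelection:
    """Run the combined LASSO + elastic-net stability-selection loop.

    Each iteration draws a fresh stratified ``train_fraction`` subset
    (or a stratified bootstrap resample in ``bootstrap`` mode), tunes
    lambda for both methods by cross-validated AUC on it, refits, and
    accumulates the two nonzero-coefficient supports.  Combined frequency
    is the sum of the LASSO and elastic-net frequencies (0..2 x
    n_iterations); features are ranked by it, descending, ties broken by
    feature ID; ``selected`` marks the first quartile.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    if len(feature_ids) != p:
        raise ValueError("feature_ids length must match X columns")
    root = np.random.SeedSequence(config.seed)
    iter_seeds = root.spawn(config.n_iterations)
    freq_lasso = np.zeros(p, dtype=int)
    freq_en = np.zeros(p, dtype=int)
    runs: list[StabilityRun] = []
    for it in range(config.n_iterations):
        rng = np.random.default_rng(iter_seeds[it])
        for _attempt in range(100):
            if config.resample_mode == "bootstrap":
                tr = _stratified_bootstrap_idx(y, rng)
            else:
                tr = _stratified_train_idx(
                    y, config.train_fraction, int(rng.integers(2**31 - 1))
                )
            if len(np.unique(y[tr])) == 2:
                break
            logger.info("iteration %d: single-class draw, redrawing", it)
        Xt, yt = X[tr], y[tr]
        supports = {}
        lams = {}
        for method, alpha in (("lasso", 1.0), ("en", config.en_alpha)):
            lam = cv_optimize_lambda(Xt, yt, config, rng, alpha_mix=alpha)
            coef, _ = fit_penalized_logistic(Xt, yt, alpha, lam, tol=config.tol)
            supports[method] = coef != 0.0
            lams[method] = lam
        freq_lasso += supports["lasso"]
        freq_en += supports["en"]
        runs.append(
            StabilityRun(it, tr, lams["lasso"], lams["en"],
                         supports["lasso"], supports["en"])
        )
    combined = freq_lasso + freq_en
    order = np.lexsort((np.asarray(feature_ids, dtype=object), -combined))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    df = pd.DataFrame(
        {
            "freq_lasso": freq_lasso,
            "freq_en": freq_en,
            "freq_combined": combined,
            "rank": rank,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    sel = StabilitySelection(df, config.n_iterations, runs)
    chosen = select_first_quartile(sel)
    df["selected"] = df.index.isin(chosen)
    return sel


def _stratified_bootstrap_idx(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.sort(np.concatenate(idx))


def select_first_quartile(selection: StabilitySelection) -> list[str]:
    """First-quartile cut: top 25% of ever-selected features by combined frequency.

    The threshold is the 75th percentile of the positive combined
    frequencies; boundary ties are all included.  Features are returned
    ordered by frequency descending, then feature ID.
    """
    freq = selection.frequencies["freq_combined"]
    positive = freq[freq > 0]
    if positive.empty:
        warnings.warn("no feature was ever selected; returning empty panel",
                      stacklevel=2)
        return []
    cut = np.percentile(positive.to_numpy(), 75)
    chosen = positive[positive >= cut]
    chosen = chosen.sort_index().sort_values(ascending=False, kind="stable")
    return list(chosen.index)
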