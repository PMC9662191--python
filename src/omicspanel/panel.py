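"""Panel fitting and honest performance characterization.

A *panel* is a small set of selected features fit jointly with unpenalized
logistic regression.  Its discrimination is characterized by:

* a point AUC on a held-out stratified 25% test split (plus the apparent
  full-data AUC, labeled as such);
* a bootstrap AUC distribution — stratified resamples, refit, evaluated on
  the out-of-bag samples (avoiding resubstitution optimism);
* a permutation ("random AUC") null — labels shuffled, refit, evaluated on
  a held-out stratified 25% of the permuted data;
* sensitivity/specificity at the Youden-J-maximizing threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .stats import compute_auc
from .tables import FeatureTable

__all__ = [
    "PanelModel",
    "AucDistributions",
    "PanelReport",
    "fit_panel",
    "compute_auc",
    "bootstrap_auc",
    "permuted_auc_null",
    "sensitivity_specificity",
    "evaluate_panel",
    "reference_panel_auc",
    "DEFAULT_HEMOGLOBIN_IDS",
]

#: Hemoglobin subunits used as the stand-in for a fecal immunochemical test.
DEFAULT_HEMOGLOBIN_IDS = ("HBA1", "HBB", "HBD.HBE1", "HBG2.HBG1")

_RIDGE_FALLBACK_LAMBDA = 1e-6
_COEF_BLOWUP = 1e3


@dataclass
class PanelModel:
    """Unpenalized logistic fit over a fixed feature set."""

    feature_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    training_sample_ids: list[str] | None = None
    ridge_fallback: bool = False

    def scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients + self.intercept


@dataclass
class AucDistributions:
    point_auc: float
    bootstrap: np.ndarray
    permuted: np.ndarray


@dataclass
class PanelReport:
    model: PanelModel
    auc_test: float
    auc_apparent: float
    distributions: AucDistributions
    sensitivity: float
    specificity: float
    threshold: float

    def summary(self) -> dict:
        boot, null = self.distributions.bootstrap, self.distributions.permuted
        return {
            "features": list(self.model.feature_ids),
            "coefficients": [float(c) for c in self.model.coefficients],
            "intercept": float(self.model.intercept),
            "ridge_fallback": bool(self.model.ridge_fallback),
            "auc_test": float(self.auc_test),
            "auc_apparent": float(self.auc_apparent),
            "bootstrap_auc": {
                "mean": float(np.mean(boot)),
                "p2.5": float(np.percentile(boot, 2.5)),
                "p97.5": float(np.percentile(boot, 97.5)),
                "n": int(len(boot)),
            },
            "random_auc": {
                "mean": float(np.mean(null)),
                "p95": float(np.percentile(null, 95)),
                "n": int(len(null)),
            },
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "threshold": float(self.threshold),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")

    def distributions_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "bootstrap_auc": self.distributions.bootstrap,
                "random_auc": self.distributions.permuted,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y


def fit_panel(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> PanelModel:
    """Unpenalized logistic ML fit of the panel.

    Under (near-)perfect separation the ML solution diverges; the fit then
    falls back to a tiny ridge penalty (1e-6 on the per-sample scale) and is
    flagged via ``ridge_fallback``.
    """
    X, y = _check_xy(X, y)
    if X.shape[1] == 0:
        raise ValueError("empty panel")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000).fit(X, y)
        diverged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # if the fitted direction strictly separates the classes the ML solution
    # does not exist (coefficients diverge); fall back to a tiny ridge
    scores = X @ clf.coef_[0] + clf.intercept_[0]
    separated = scores[y == 1].min() > scores[y == 0].max()
    fallback = diverged or separated or np.abs(clf.coef_).max() > _COEF_BLOWUP
    if fallback:
        n = len(y)
        clf = LogisticRegression(
            penalty="l2", C=1.0 / (n * _RIDGE_FALLBACK_LAMBDA),
            solver="lbfgs", max_iter=5000,
        ).fit(X, y)
    return PanelModel(
        list(feature_ids),
        clf.coef_[0].copy(),
        float(clf.intercept_[0]),
        list(sample_ids) if sample_ids is not None else None,
        ridge_fallback=fallback,
    )


def bootstrap_auc(
    X_panel: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap AUC distribution, evaluated out-of-bag.

    Each iteration resamples within class (stratified, with replacement),
    refits the panel, and scores the samples never drawn; iterations whose
    out-of-bag set misses a class are redrawn.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    X, y = _check_xy(X_panel, y)
    rng = np.random.default_rng() if rng is None else rng
    idx_by_class = [np.flatnonzero(y == c) for c in np.unique(y)]
    out = np.empty(n_iterations)
    for it in range(n_iterations):
        while True:
            boot = np.concatenate(
                [rng.choice(m, size=len(m), replace=True) for m in idx_by_class]
            )
            oob = np.setdiff1d(np.arange(len(y)), boot)
            if oob.size and len(np.unique(y[oob])) == 2:
                break
        model = fit_panel(X[boot], y[boot])
        out[it] = compute_auc(model.scores(X[oob]), y[oob])
    return out


def permuted_auc_null(
    X_panel: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    test_fraction: float = 0.25,
) -> np.ndarray:
    """Random-label ("random AUC") null distribution.

    Per iteration the labels are permuted, the panel refit on a stratified
    75% of the permuted data, and the AUC taken on the held-out 25%.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    X, y = _check_xy(X_panel, y)
    rng = np.random.default_rng() if rng is None else rng
    out = np.empty(n_iterations)
    for it in range(n_iterations):
        yp = rng.permutation(y)
        tr, te = train_test_split(
            np.arange(len(y)),
            test_size=test_fraction,
            stratify=yp,
            random_state=int(rng.integers(2**31 - 1)),
        )
        model = fit_panel(X[tr], yp[tr])
        out[it] = compute_auc(model.scores(X[te]), yp[te])
    return out


def sensitivity_specificity(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Sensitivity and specificity at the Youden-J-maximizing threshold.

    A sample is called positive when its score is >= the threshold;
    candidate thresholds are midpoints between adjacent distinct scores
    plus the extremes.  Ties in J are broken toward higher specificity.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                            [uniq[-1] + 1.0]])
    best = (-np.inf, -np.inf, 0.0)  # (J, specificity, threshold)
    n_pos, n_neg = y.sum(), (~y).sum()
    for t in cands:
        called = s >= t
        sens = (called & y).sum() / n_pos
        spec = (~called & ~y).sum() / n_neg
        j = sens + spec - 1.0
        if (j, spec) > (best[0], best[1]):
            best = (j, spec, t)
    t = best[2]
    called = s >= t
    sens = float((called & y).sum() / n_pos)
    spec = float((~called & ~y).sum() / n_neg)
    return sens, spec, float(t)


def evaluate_panel(
    X_panel: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    test_fraction: float = 0.25,
    eval_split: tuple[np.ndarray, np.ndarray] | None = None,
) -> PanelReport:
    """Full panel characterization.

    The reported ``auc_test`` comes from one stratified train/test split
    (or from ``eval_split`` when the caller holds out an evaluation set
    before feature selection, keeping the test samples untouched by the
    whole selection procedure); ``auc_apparent`` is the resubstitution AUC
    of the full-data fit, which also supplies the sensitivity/specificity
    operating point.
    """
    X, y = _check_xy(X_panel, y)
    rng = np.random.default_rng() if rng is None else rng
    if eval_split is not None:
        tr, te = eval_split
    else:
        tr, te = train_test_split(
            np.arange(len(y)),
            test_size=test_fraction,
            stratify=y,
            random_state=int(rng.integers(2**31 - 1)),
        )
    split_model = fit_panel(X[tr], y[tr], feature_ids)
    auc_test = compute_auc(split_model.scores(X[te]), y[te])

    full_model = fit_panel(X, y, feature_ids)
    full_scores = full_model.scores(X)
    auc_apparent = compute_auc(full_scores, y)
    sens, spec, thr = sensitivity_specificity(full_scores, y)
    boot = bootstrap_auc(X, y, n_iterations, rng)
    null = permuted_auc_null(X, y, n_iterations, rng, test_fraction)
    return PanelReport(
        model=full_model,
        auc_test=float(auc_test),
        auc_apparent=float(auc_apparent),
        distributions=AucDistributions(float(auc_test), boot, null),
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
    )


def reference_panel_auc(
    table: FeatureTable,
    y: np.ndarray,
    reference_ids: Sequence[str] = DEFAULT_HEMOGLOBIN_IDS,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    eval_split: tuple[np.ndarray, np.ndarray] | None = None,
) -> PanelReport:
    """Evaluate a fixed reference panel (default: the hemoglobin subunits
    standing in for a fecal immunochemical test) through the same
    fit/evaluate path as any discovered panel.

    Reference IDs absent from the table are skipped with a warning; it is
    an error if none are present.
    """
    present = [f for f in reference_ids if f in table.values.columns]
    missing = [f for f in reference_ids if f not in table.values.columns]
    if missing:
        warnings.warn(f"reference features absent from table: {missing}",
                      stacklevel=2)
    if not present:
        raise ValueError("none of the reference feature IDs are present")
    X = table.values.loc[:, present].to_numpy(dtype=float)
    return evaluate_panel(X, y, present, n_iterations, rng, eval_split=eval_split)
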