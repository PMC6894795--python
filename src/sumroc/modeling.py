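"""Risk-model fitting: logistic regression with a multicollinearity rule,
stratified train/test split, and nested cross-validation.

The model choice follows a simple screen: variance inflation factors are
computed for every SNP column, and ridge (L2-penalized) logistic regression
is used only when at least two VIFs are infinite, i.e. under exact linear
dependence among predictors; otherwise the maximum-likelihood logistic fit
is used.  Single-SNP panels skip the screen and always use the standard
fit.  The ridge penalty is tuned by nested cross-validation: within each of
the outer folds, an inner CV picks the penalty maximizing held-out AUROC;
the outer held-out AUROCs average to an honest performance estimate, and
the final model is refit on all training data with the modal penalty.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .popsim import SimulatedPopulation
from .rocstats import pair_count_auroc

__all__ = [
    "FittedRiskModel",
    "compute_vif",
    "choose_model_kind",
    "split_population",
    "fit_risk_model",
    "predict_risk",
    "DEFAULT_PENALTY_GRID",
]

logger = logging.getLogger("sumroc")

#: default ridge penalty grid: 13 log-spaced values spanning 1e-4 .. 1e4
DEFAULT_PENALTY_GRID = tuple(np.logspace(-4, 4, 13))

# 1 - R^2 below this is treated as exact collinearity (VIF = infinity).
VIF_INFINITY_TOL = 1e-10

# |coefficient| above this in an unpenalized 0/1-feature fit signals
# (quasi-)separation: it corresponds to an odds ratio beyond e^30.
SEPARATION_COEF_LIMIT = 30.0


@dataclass
class FittedRiskModel:
    """A fitted logistic risk model and its evaluation bookkeeping."""

    intercept: float
    coefficients: np.ndarray
    model_kind: str  # "standard" | "ridge"
    ridge_penalty: float = 0.0
    vif_values: Optional[np.ndarray] = None
    cv_auroc: Optional[float] = None
    test_auroc: Optional[float] = None
    warnings: list = field(default_factory=list)


def compute_vif(features) -> np.ndarray:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R^2_j) from an
    OLS regression (with intercept) of column j on all other columns.

    Exact linear dependence (1 - R^2 < 1e-10) and constant columns are
    reported as +inf.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("compute_vif requires a matrix with >= 2 columns")
    if X.shape[0] < 3:
        raise ValueError("compute_vif requires >= 3 rows")
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        target = X[:, j]
        if np.ptp(target) == 0.0:  # constant column: degenerate predictor
            out[j] = np.inf
            continue
        design = sm.add_constant(np.delete(X, j, axis=1), has_constant="add")
        r2 = sm.OLS(target, design).fit().rsquared
        out[j] = np.inf if (1.0 - r2) < VIF_INFINITY_TOL else 1.0 / (1.0 - r2)
    return out


def choose_model_kind(vifs) -> str:
    """Return ``"ridge"`` iff at least two VIF entries are infinite."""
    vifs = np.asarray(vifs, dtype=float)
    return "ridge" if int(np.isinf(vifs).sum()) >= 2 else "standard"


def split_population(
    pop: SimulatedPopulation,
    train_fraction: float = 0.7,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SimulatedPopulation, SimulatedPopulation]:
    """Stratified train/test split preserving the case:control ratio in both
    parts to within one individual per class."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(pop.labels == cls)
        idx = rng.permutation(idx)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    for name, part in (("train", train_idx), ("test", test_idx)):
        y = pop.labels[part]
        if (y == 0).sum() < 2 or (y == 1).sum() < 2:
            raise ValueError(f"{name} part has < 2 individuals in a class")
    mk = lambda idx: SimulatedPopulation(
        features=pop.features[idx],
        labels=pop.labels[idx],
        coding=pop.coding,
        seed=pop.seed,
    )
    return mk(train_idx), mk(test_idx)


def _fit_logistic(X, y, penalty: Optional[float]):
    """One logistic fit; ``penalty`` None means unpenalized ML, else the L2
    penalty weight lambda (sklearn C = 1/lambda)."""
    # C is the inverse L2 penalty weight; C=inf is the unpenalized ML fit
    C = np.inf if penalty is None else 1.0 / penalty
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return float(clf.intercept_[0]), clf.coef_[0].astype(float)


def _separated(intercept: float, coefs: np.ndarray, X, y) -> bool:
    """Detect (quasi-)separation after an unpenalized fit: diverging
    coefficients, or a linear predictor that separates the classes
    completely (the ML estimate does not exist in either case)."""
    vals = np.append(coefs, intercept)
    if not np.all(np.isfinite(vals)) or np.abs(vals).max() > SEPARATION_COEF_LIMIT:
        return True
    z = X @ coefs
    return bool(z[y == 1].min() > z[y == 0].max() or z[y == 0].min() > z[y == 1].max())


def fit_risk_model(
    train: SimulatedPopulation,
    kind: str = "standard",
    penalty_grid: Optional[Sequence[float]] = None,
    cv: tuple[int, int] = (3, 2),
    rng: Optional[np.random.Generator] = None,
) -> FittedRiskModel:
    """Fit the risk model on the training population.

    For ``kind="standard"`` the final model is the unpenalized ML fit and
    ``cv_auroc`` is the mean held-out AUROC over the outer folds.  For
    ``kind="ridge"`` the penalty is selected per outer fold by inner-CV
    AUROC, ``cv_auroc`` averages the outer held-out AUROCs, and the final
    model is refit on all training data with the modal (tie -> smallest)
    selected penalty.  Perfect separation under the standard fit falls back
    to ridge at the smallest grid penalty, recorded in ``warnings``.
    """
    if kind not in ("standard", "ridge"):
        raise ValueError(f"unknown model kind {kind!r}")
    X = np.asarray(train.features, dtype=float)
    y = np.asarray(train.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    grid = sorted(DEFAULT_PENALTY_GRID if penalty_grid is None else penalty_grid)
    outer_folds, inner_folds = cv
    rng = np.random.default_rng() if rng is None else rng
    outer = StratifiedKFold(
        n_splits=outer_folds, shuffle=True,
        random_state=int(rng.integers(2**31)),
    )
    notes: list = []

    def fit_standard(Xt, yt):
        b0, b = _fit_logistic(Xt, yt, None)
        if _separated(b0, b, Xt, yt):
            b0, b = _fit_logistic(Xt, yt, grid[0])
            return b0, b, True
        return b0, b, False

    outer_aucs = []
    chosen_penalties = []
    for tr, te in outer.split(X, y):
        if kind == "standard":
            b0, b, fell_back = fit_standard(X[tr], y[tr])
            if fell_back:
                notes.append("separation_fallback_cv")
        else:
            lam = _select_penalty(
                X[tr], y[tr], grid, inner_folds, int(rng.integers(2**31))
            )
            chosen_penalties.append(lam)
            b0, b = _fit_logistic(X[tr], y[tr], lam)
        scores = _sigmoid(b0 + X[te] @ b)
        outer_aucs.append(pair_count_auroc(scores, y[te]))
    cv_auroc = float(np.mean(outer_aucs))

    if kind == "standard":
        b0, b, fell_back = fit_standard(X, y)
        final_kind, final_penalty = "standard", 0.0
        if fell_back:
            notes.append("separation_fallback")
            final_kind, final_penalty = "ridge", grid[0]
    else:
        # modal penalty across outer folds, ties resolved to the smallest
        counts = Counter(chosen_penalties)
        best_count = max(counts.values())
        final_penalty = min(p for p, c in counts.items() if c == best_count)
        b0, b = _fit_logistic(X, y, final_penalty)
        final_kind = "ridge"

    logger.info(
        "modeling: kind=%s penalty=%g cv_auroc=%.4f n_train=%d",
        final_kind, final_penalty, cv_auroc, len(y),
    )
    return FittedRiskModel(
        intercept=b0,
        coefficients=b,
        model_kind=final_kind,
        ridge_penalty=final_penalty,
        cv_auroc=cv_auroc,
        warnings=notes,
    )


def _select_penalty(X, y, grid, inner_folds: int, seed: int) -> float:
    """Inner-CV penalty selection: mean held-out AUROC per grid value,
    ties resolved to the smallest penalty."""
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(inner.split(X, y))
    best_lam, best_auc = None, -np.inf
    for lam in grid:  # grid is sorted ascending, so ties keep the smallest
        aucs = []
        for tr, te in splits:
            b0, b = _fit_logistic(X[tr], y[tr], lam)
            aucs.append(pair_count_auroc(_sigmoid(b0 + X[te] @ b), y[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_lam, best_auc = lam, mean_auc
    return best_lam


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def predict_risk(model: FittedRiskModel, features) -> np.ndarray:
    """Per-individual disease risk: inverse-logit of the linear predictor."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.coefficients):
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match model width {len(model.coefficients)}"
        )
    return _sigmoid(model.intercept + X @ model.coefficients)
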