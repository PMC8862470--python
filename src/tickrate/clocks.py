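"""Training and evaluation of the general and cell-type-specific clocks.

The general clock is an L1-penalised (lasso) linear regression of
chronological age on all CpG beta values, with the penalty chosen by
k-fold cross-validation minimising mean squared error; only CpGs with
non-zero weight are retained, and the prediction is
``sum_i w_i * beta_i + intercept``.

Cell-type clocks are L2-penalised (ridge) regressions restricted to one
aDMP category, with paired interaction features ``beta_i * ic`` so that
the readout can depend on the sample's immune fraction:
``sum_i w1_i*beta_i + w2_i*beta_i*ic + intercept``.

Features are standardised internally before penalisation and
coefficients are returned on the original beta scale (the convention of
penalised-regression packages); the penalty-selection rule is the
minimum mean CV error. Fold assignment is a seeded shuffle, so training
is deterministic given (data, seed, folds).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LassoCV, Ridge
from sklearn.model_selection import KFold

from .datamodel import BetaMatrix, ClockModel

__all__ = ["GeneralClock", "CellTypeClock", "train_general_clock",
           "train_celltype_clock", "predict_age", "clock_error"]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    return (X - mu) / scale, mu, scale


class GeneralClock(RegressorMixin, BaseEstimator):
    """Lasso-based age predictor over all CpGs.

    Parameters
    ----------
    n_folds : CV folds for penalty selection (default 10).
    random_state : seed for the CV fold shuffle.
    n_alphas, eps : geometric penalty path (length, ratio min/max).
    max_iter : coordinate-descent iteration cap.

    Fitted attributes: ``cpg_ids_`` (feature names), ``coef_`` /
    ``intercept_`` on the original beta scale, ``alpha_`` (chosen
    penalty), ``selected_`` (boolean mask of non-zero weights).
    """

    def __init__(self, n_folds: int = 10, random_state: int | None = None,
                 n_alphas: int = 100, eps: float = 1e-3, max_iter: int = 50_000):
        self.n_folds = n_folds
        self.random_state = random_state
        self.n_alphas = n_alphas
        self.eps = eps
        self.max_iter = max_iter

    def fit(self, X, y) -> "GeneralClock":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        if self.n_folds > n:
            raise ValueError(f"n_folds={self.n_folds} exceeds n_samples={n}")
        if n < 2 * self.n_folds:
            raise ValueError(
                f"need at least {2 * self.n_folds} samples for {self.n_folds}-fold CV"
            )
        values = X.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("beta matrix contains missing values; impute before training")
        self.cpg_ids_ = [str(c) for c in X.columns]
        Z, mu, scale = _standardize(values)
        if not Z.any():
            # no informative features: intercept-only model
            self.coef_ = np.zeros(values.shape[1])
            self.intercept_ = float(y.mean())
            self.alpha_ = np.inf
        else:
            cv = KFold(self.n_folds, shuffle=True, random_state=self.random_state)
            lasso = LassoCV(alphas=self.n_alphas, eps=self.eps, cv=cv,
                            max_iter=self.max_iter)
            lasso.fit(Z, y)
            self.coef_ = lasso.coef_ / scale
            self.intercept_ = float(lasso.intercept_ - np.dot(lasso.coef_ / scale, mu))
            self.alpha_ = float(lasso.alpha_)
        self.selected_ = self.coef_ != 0
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        values = X[self.cpg_ids_].to_numpy(dtype=float)
        return values @ self.coef_ + self.intercept_

    def to_clock_model(self) -> ClockModel:
        """Export retaining only CpGs with non-zero weight."""
        keep = np.flatnonzero(self.selected_)
        return ClockModel(
            kind="general",
            cpgs=[self.cpg_ids_[i] for i in keep],
            w=self.coef_[keep],
            w_ic=np.empty(0),
            intercept=self.intercept_,
            meta={"penalty": "lasso", "lambda": self.alpha_,
                  "cv_folds": self.n_folds, "seed": self.random_state},
        )


class CellTypeClock(RegressorMixin, BaseEstimator):
    """Ridge age predictor on one aDMP category with beta*ic interactions.

    ``fit(X, y, ic=...)`` builds the feature matrix ``[beta, beta*ic]``
    over the supplied CpGs, standardises it, and picks the ridge penalty
    from a log-spaced grid by k-fold CV (minimum mean squared error).
    ``predict(X, ic=...)`` needs the same per-sample immune fractions.
    """

    def __init__(self, kind: str = "epithelial", alphas=None, n_folds: int = 10,
                 random_state: int | None = None):
        self.kind = kind
        self.alphas = alphas
        self.n_folds = n_folds
        self.random_state = random_state

    def _grid(self, n: int) -> np.ndarray:
        if self.alphas is not None:
            return np.asarray(self.alphas, dtype=float)
        # log-spaced, scaled to sample size so the penalty-per-observation
        # range is stable across cohort sizes
        return np.logspace(-6, 2, 50) * n

    def fit(self, X, y, *, ic) -> "CellTypeClock":
        if self.kind not in ("epithelial", "immune"):
            raise ValueError(f"kind must be 'epithelial' or 'immune', got {self.kind!r}")
        X = pd.DataFrame(X)
        if X.shape[1] == 0:
            raise ValueError("empty CpG category: no features to train on")
        y = np.asarray(y, dtype=float)
        ic = np.asarray(ic, dtype=float)
        B = X.to_numpy(dtype=float)
        if np.isnan(B).any():
            raise ValueError("beta matrix contains missing values; impute before training")
        self.cpg_ids_ = [str(c) for c in X.columns]
        F = np.hstack([B, B * ic[:, None]])
        Z, mu, scale = _standardize(F)
        grid = self._grid(len(y))
        cv = KFold(self.n_folds, shuffle=True, random_state=self.random_state)
        mse = np.zeros(len(grid))
        for tr, te in cv.split(Z):
            for k, a in enumerate(grid):
                r = Ridge(alpha=a).fit(Z[tr], y[tr])
                mse[k] += np.mean((r.predict(Z[te]) - y[te]) ** 2)
        best = int(np.argmin(mse))
        self.alpha_ = float(grid[best])
        final = Ridge(alpha=self.alpha_).fit(Z, y)
        coef = final.coef_ / scale
        self.intercept_ = float(final.intercept_ - np.dot(final.coef_ / scale, mu))
        m = len(self.cpg_ids_)
        self.coef_ = coef[:m]
        self.coef_ic_ = coef[m:]
        return self

    def predict(self, X, *, ic) -> np.ndarray:
        X = pd.DataFrame(X)
        ic = np.asarray(ic, dtype=float)
        B = X[self.cpg_ids_].to_numpy(dtype=float)
        return B @ self.coef_ + (B * ic[:, None]) @ self.coef_ic_ + self.intercept_

    def to_clock_model(self) -> ClockModel:
        return ClockModel(
            kind=self.kind,
            cpgs=list(self.cpg_ids_),
            w=self.coef_.copy(),
            w_ic=self.coef_ic_.copy(),
            intercept=self.intercept_,
            meta={"penalty": "ridge", "lambda": self.alpha_,
                  "cv_folds": self.n_folds, "seed": self.random_state},
        )


# ---------------------------------------------------------------------------
# functional surface over the estimators
# ---------------------------------------------------------------------------

def train_general_clock(beta: BetaMatrix, ages, folds: int = 10,
                        seed: int | None = None) -> ClockModel:
    """Train the lasso general clock on a CpG x sample matrix."""
    est = GeneralClock(n_folds=folds, random_state=seed)
    est.fit(beta.samples_by_cpgs(), np.asarray(ages, dtype=float))
    model = est.to_clock_model()
    model.meta["n_train"] = len(beta.sample_ids)
    return model


def train_celltype_clock(beta: BetaMatrix, ic, ages, kind: str = "epithelial",
                         penalty_grid=None, folds: int = 10,
                         seed: int | None = None) -> ClockModel:
    """Train a ridge cell-type clock on a category-restricted matrix."""
    est = CellTypeClock(kind=kind, alphas=penalty_grid, n_folds=folds,
                        random_state=seed)
    est.fit(beta.samples_by_cpgs(), np.asarray(ages, dtype=float),
            ic=np.asarray(ic, dtype=float))
    model = est.to_clock_model()
    model.meta["n_train"] = len(beta.sample_ids)
    return model


def predict_age(model: ClockModel, beta: BetaMatrix, ic=None,
                allow_missing: str = "error") -> np.ndarray:
    """Evaluate a clock on a CpG x sample matrix.

    Raises if model CpGs are absent from the matrix (listing them).
    ``allow_missing='mean'`` is an explicit escape hatch that lets absent
    CpGs contribute at a neutral beta of 0.5; the default is a hard error
    because silent imputation shifts clock read-outs.
    """
    present = set(beta.cpg_ids)
    missing = [c for c in model.cpgs if c not in present]
    if missing and allow_missing != "mean":
        raise ValueError(
            f"{len(missing)} model CpGs absent from the matrix "
            f"(e.g. {missing[:5]}); pass allow_missing='mean' to proceed"
        )
    if model.has_interactions:
        if ic is None:
            raise ValueError(f"{model.kind} clock requires per-sample ic values")
        ic = np.asarray(ic, dtype=float)
        if ic.shape != (len(beta.sample_ids),):
            raise ValueError("ic must supply one value per sample")
    kept = [c for c in model.cpgs if c in present]
    idx = [i for i, c in enumerate(model.cpgs) if c in present]
    B = beta.select_cpgs(kept).values if kept else np.empty((0, len(beta.sample_ids)))
    pred = np.full(len(beta.sample_ids), model.intercept, dtype=float)
    if missing:
        # absent CpGs enter at beta = 0.5
        miss_idx = [i for i, c in enumerate(model.cpgs) if c not in present]
        pred = pred + 0.5 * model.w[miss_idx].sum()
        if model.has_interactions:
            pred = pred + 0.5 * model.w_ic[miss_idx].sum() * ic
    if kept:
        pred = pred + model.w[idx] @ B
        if model.has_interactions:
            pred = pred + (model.w_ic[idx] @ B) * ic
    return pred


def clock_error(pred, chrono) -> tuple[float, float]:
    """Median absolute error (years) and Pearson r of an age prediction.

    Returns ``r = nan`` when either vector has zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    chrono = np.asarray(chrono, dtype=float)
    if pred.shape != chrono.shape:
        raise ValueError("prediction and chronological-age vectors differ in length")
    mae = float(np.median(np.abs(pred - chrono)))
    if pred.size < 3 or np.std(pred) == 0 or np.std(chrono) == 0:
        return mae, float("nan")
    r = float(stats.pearsonr(pred, chrono).statistic)
    return mae, r
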