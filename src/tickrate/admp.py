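"""Per-CpG cell-type-aware aging regression and aDMP classification.

For every CpG, methylation beta is regressed by ordinary least squares on

    [1, ic, ec, age, ic*age, ec*age]

where ``ic``/``ec`` are the sample's immune and epithelial fractions. The
interaction coefficients measure how fast the CpG's methylation drifts
with age inside each compartment: ``b_ec_age`` is the epithelial-specific
and ``b_ic_age`` the immune-specific aging rate (beta/year). Age enters
in raw years (uncentred) — centring would rescale the interaction
coefficients relative to the classification thresholds below.

CpGs are then classified by coefficient magnitude against two thresholds
(defaults 1e-3 and 1e-5 beta/year, strict inequalities):

* ``epithelial_specific``: |b_ec_age| > thr_hi and |b_ic_age| < thr_lo
* ``immune_specific``:     |b_ic_age| > thr_hi and |b_ec_age| < thr_lo
* ``shared``: both interaction magnitudes > thr_hi (aging present in both
  compartments), or — for bulk signals not resolved into compartments —
  |b_age| > thr_hi with both interaction magnitudes < thr_lo
* ``other``: everything else

The shared rule is this package's definition (see docs): under a
three-compartment mixture in which a CpG ages identically in the
epithelial and immune compartments, the aging signal decomposes exactly
onto the two interaction columns and ``b_age`` stays 0, so shared aging
manifests as both interaction coefficients exceeding thr_hi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import BetaMatrix, SampleTable, check_aligned

__all__ = ["AdmpFit", "AdmpCatalog", "AdmpScreen", "fit_admp_model",
           "classify_admps", "CATEGORY_LABELS"]

COEF_NAMES = ("b0", "b_ic", "b_ec", "b_age", "b_ic_age", "b_ec_age")
CATEGORY_LABELS = ("epithelial_specific", "immune_specific", "shared", "other")

_RANK_MESSAGE = (
    "design matrix [1, ic, ec, age, ic*age, ec*age] is rank deficient: "
    "with ec = 1 - ic exactly (no third compartment varying) the "
    "cell-type-specific aging coefficients are unidentifiable"
)


@dataclass
class AdmpFit:
    """Per-CpG interaction-model coefficients (one row per tested CpG)."""

    coef: pd.DataFrame  # index: cpg_id; columns: COEF_NAMES + resid_var

    def __post_init__(self) -> None:
        needed = list(COEF_NAMES) + ["resid_var"]
        missing = [c for c in needed if c not in self.coef.columns]
        if missing:
            raise ValueError(f"AdmpFit missing columns: {missing}")
        if not np.isfinite(self.coef[list(COEF_NAMES)].to_numpy()).all():
            raise ValueError("non-finite coefficients in AdmpFit")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.coef.index)


@dataclass
class AdmpCatalog:
    """Per-CpG category calls with the thresholds that produced them."""

    category: pd.Series  # index: cpg_id, values in CATEGORY_LABELS
    thr_hi: float = 1e-3
    thr_lo: float = 1e-5

    def cpgs(self, label: str) -> list[str]:
        if label not in CATEGORY_LABELS:
            raise ValueError(f"unknown category {label!r}")
        return list(self.category.index[self.category == label])

    def counts(self) -> dict:
        return {k: int((self.category == k).sum()) for k in CATEGORY_LABELS}


def _design(age: np.ndarray, ic: np.ndarray, ec: np.ndarray) -> np.ndarray:
    return np.column_stack([
        np.ones_like(age), ic, ec, age, ic * age, ec * age,
    ])


def fit_admp_model(beta: BetaMatrix, samples: SampleTable) -> AdmpFit:
    """OLS fit of the six-term interaction model at every CpG.

    Vectorised: one least-squares factorisation of the shared design is
    reused across all CpGs. Missing beta values are refused — impute
    upstream rather than silently dropping samples per CpG.
    """
    check_aligned(beta, samples)
    Y = beta.values
    if np.isnan(Y).any():
        raise ValueError("beta matrix contains missing values; impute before fitting")
    D = _design(samples.age, samples.ic, samples.ec)
    n = D.shape[0]
    if n <= D.shape[1]:
        raise ValueError(f"need more than {D.shape[1]} samples, got {n}")
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError(_RANK_MESSAGE)
    coef, _, _, _ = np.linalg.lstsq(D, Y.T, rcond=None)
    resid = Y.T - D @ coef
    resid_var = (resid ** 2).sum(axis=0) / (n - D.shape[1])
    frame = pd.DataFrame(coef.T, index=beta.cpg_ids, columns=list(COEF_NAMES))
    frame["resid_var"] = resid_var
    return AdmpFit(frame)


def classify_admps(fits: AdmpFit, thr_hi: float = 1e-3,
                   thr_lo: float = 1e-5) -> AdmpCatalog:
    """Categorise CpGs by interaction-coefficient magnitude (strict tests)."""
    if thr_lo >= thr_hi:
        raise ValueError(f"thr_lo ({thr_lo}) must be < thr_hi ({thr_hi})")
    ec = fits.coef["b_ec_age"].abs()
    ic = fits.coef["b_ic_age"].abs()
    age = fits.coef["b_age"].abs()
    epi = (ec > thr_hi) & (ic < thr_lo)
    imm = (ic > thr_hi) & (ec < thr_lo)
    shared = ((ec > thr_hi) & (ic > thr_hi)) | (
        (age > thr_hi) & (ec < thr_lo) & (ic < thr_lo))
    category = pd.Series("other", index=fits.coef.index, name="category")
    category[shared] = "shared"
    category[epi] = "epithelial_specific"
    category[imm] = "immune_specific"
    return AdmpCatalog(category, thr_hi=thr_hi, thr_lo=thr_lo)


class AdmpScreen(BaseEstimator):
    """Estimator-style wrapper: fit the per-CpG model and classify.

    ``fit(X, y, ic=..., ec=...)`` takes a (sample x CpG) beta frame and
    chronological ages ``y``; fitted attributes are ``fit_`` (AdmpFit) and
    ``catalog_`` (AdmpCatalog).
    """

    def __init__(self, thr_hi: float = 1e-3, thr_lo: float = 1e-5):
        self.thr_hi = thr_hi
        self.thr_lo = thr_lo

    def fit(self, X: pd.DataFrame, y, *, ic, ec) -> "AdmpScreen":
        y = np.asarray(y, dtype=float)
        ic = np.asarray(ic, dtype=float)
        ec = np.asarray(ec, dtype=float)
        values = X.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("beta matrix contains missing values; impute before fitting")
        D = _design(y, ic, ec)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError(_RANK_MESSAGE)
        coef, _, _, _ = np.linalg.lstsq(D, values, rcond=None)
        resid = values - D @ coef
        dof = max(D.shape[0] - D.shape[1], 1)
        frame = pd.DataFrame(coef.T, index=list(X.columns), columns=list(COEF_NAMES))
        frame["resid_var"] = (resid ** 2).sum(axis=0) / dof
        self.fit_ = AdmpFit(frame)
        self.catalog_ = classify_admps(self.fit_, self.thr_hi, self.thr_lo)
        return self

    def cpgs(self, label: str) -> list[str]:
        return self.catalog_.cpgs(label)
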