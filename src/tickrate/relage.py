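"""Age-acceleration, relative epithelial/immune age, and reference adjustment.

Definitions (all in years):

* ``age_accel = general_clock_age - chronological_age``
* ``rea = epithelial_clock_age - general_clock_age`` (relative epithelial age)
* ``ria = immune_clock_age - general_clock_age`` (relative immune age)

Because clock read-outs depend on chronological age and on cell-type
composition, group comparisons use *adjusted* values: an ordinary least
squares fit of the raw value on covariates (default age and immune
fraction) over a designated reference subset (e.g. all controls, or
controls never on hormone therapy), with every sample's adjusted value
being its residual from that reference fit. Over the reference set the
residuals are exactly orthogonal to each covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import BetaMatrix, ClockModel, ClockScores, SampleTable, check_aligned
from .clocks import predict_age

__all__ = ["compute_scores", "adjust_by_reference", "ReferenceAdjuster",
           "score_cohort", "adjust_scores"]


def compute_scores(general, epithelial, immune, chrono,
                   sample_ids=None) -> ClockScores:
    """Assemble per-sample clock read-outs into a ClockScores table."""
    arrays = {
        "general_age": np.asarray(general, dtype=float),
        "epithelial_age": np.asarray(epithelial, dtype=float),
        "immune_age": np.asarray(immune, dtype=float),
        "age": np.asarray(chrono, dtype=float),
    }
    n = len(arrays["age"])
    if any(a.shape != (n,) for a in arrays.values()):
        raise ValueError("clock and chronological age vectors differ in length")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    sample_ids = [str(s) for s in sample_ids]
    if len(sample_ids) != n:
        raise ValueError("sample_ids length does not match score vectors")
    frame = pd.DataFrame({
        "sample_id": sample_ids,
        "age": arrays["age"],
        "general_age": arrays["general_age"],
        "epithelial_age": arrays["epithelial_age"],
        "immune_age": arrays["immune_age"],
        "age_accel": arrays["general_age"] - arrays["age"],
        "rea": arrays["epithelial_age"] - arrays["general_age"],
        "ria": arrays["immune_age"] - arrays["general_age"],
    })
    return ClockScores(frame)


class ReferenceAdjuster(TransformerMixin, BaseEstimator):
    """OLS residual adjustment against a reference subset.

    ``fit(X, y)`` regresses the values ``y`` on covariate columns ``X``
    (reference samples only); ``transform(X, y)`` returns
    ``y - predicted(X)`` for any samples. Linear (degree-1) adjustment
    only.
    """

    def __init__(self, covariates: tuple = ("age", "ic")):
        self.covariates = tuple(covariates)

    def _matrix(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise ValueError(f"covariate columns missing: {missing}")
        C = X[list(self.covariates)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(C)), C])

    def fit(self, X: pd.DataFrame, y) -> "ReferenceAdjuster":
        y = np.asarray(y, dtype=float)
        D = self._matrix(X)
        if len(y) < D.shape[1] + 1:
            raise ValueError(
                f"reference too small: need at least {D.shape[1] + 1} samples"
            )
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("collinear covariates within the reference set")
        self.coef_, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        return self

    def transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        if y is None:
            raise ValueError("transform requires the values to adjust")
        y = np.asarray(y, dtype=float)
        return y - self._matrix(X) @ self.coef_


def adjust_by_reference(values, samples: SampleTable, reference_mask,
                        covariates: tuple = ("age", "ic")) -> np.ndarray:
    """Residual-adjust ``values`` using an OLS fit on the reference subset.

    The fit uses ONLY reference samples; every sample (reference or not)
    is then adjusted by subtracting its fitted value at its own
    covariates.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(reference_mask, dtype=bool)
    if values.shape != (len(samples),) or mask.shape != (len(samples),):
        raise ValueError("values and reference_mask must match the sample table length")
    unknown = [c for c in covariates if c not in samples.frame.columns]
    if unknown:
        raise ValueError(f"covariates not in sample table: {unknown}")
    adj = ReferenceAdjuster(covariates)
    adj.fit(samples.frame.loc[mask], values[mask])
    return adj.transform(samples.frame, values)


def score_cohort(beta: BetaMatrix, samples: SampleTable, general: ClockModel,
                 epithelial: ClockModel, immune: ClockModel) -> ClockScores:
    """Apply all three clocks to an aligned cohort and assemble scores."""
    check_aligned(beta, samples)
    return compute_scores(
        general=predict_age(general, beta),
        epithelial=predict_age(epithelial, beta, ic=samples.ic),
        immune=predict_age(immune, beta, ic=samples.ic),
        chrono=samples.age,
        sample_ids=samples.sample_ids,
    )


def adjust_scores(scores: ClockScores, samples: SampleTable, reference_mask,
                  covariates: tuple = ("age", "ic")) -> ClockScores:
    """Fill the ``*_adj`` columns by reference adjustment of each statistic."""
    if scores.frame["sample_id"].tolist() != samples.sample_ids:
        raise ValueError("scores and sample table orderings differ")
    frame = scores.frame.copy()
    for col in ("age_accel", "rea", "ria"):
        frame[col + "_adj"] = adjust_by_reference(
            frame[col].to_numpy(), samples, reference_mask, covariates)
    return ClockScores(frame)
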