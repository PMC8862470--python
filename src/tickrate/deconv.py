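"""Reference-based cell-fraction estimation by constrained least squares.

Each sample's beta profile is modelled as a convex combination of pure
cell-type reference profiles. Fractions are obtained by non-negative
least squares with a sum-to-one constraint, solved by appending the
constraint as a heavily weighted row to the NNLS system and renormalising
the solution exactly. On mixtures generated from the reference profiles
the solution is exact; with measurement noise it is the non-negative
least-squares mixture re-projected onto the simplex.

This is a deliberately simple stand-in for published reference-based
deconvolution tools (robust-partial-correlation methods with curated
epithelial/fibroblast/immune references): downstream clock modelling
consumes only the fractions, which may equally be supplied externally
through the sample table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import BetaMatrix, _check_unique

__all__ = ["ReferenceProfiles", "CellDeconvolver", "estimate_fractions"]

_CONSTRAINT_WEIGHT = 1e6


@dataclass
class ReferenceProfiles:
    """Expected pure-compartment beta values (CpG x component)."""

    cpg_ids: list[str]
    components: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.components = [str(c) for c in self.components]
        self.values = np.asarray(self.values, dtype=float)
        if len(self.components) < 2:
            raise ValueError("reference needs at least two components")
        _check_unique(self.cpg_ids, "reference CpG ids")
        _check_unique(self.components, "component names")
        if self.values.shape != (len(self.cpg_ids), len(self.components)):
            raise ValueError("reference matrix shape does not match its IDs")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("reference beta values must lie in [0, 1]")


class CellDeconvolver(TransformerMixin, BaseEstimator):
    """Estimate cell-type fractions from beta profiles.

    Parameters
    ----------
    reference : ReferenceProfiles
        Pure-compartment profiles; the CpGs used are the intersection of
        the reference and the data.

    After :meth:`fit`, ``components_`` names the mixture components and
    ``cpgs_`` the CpGs actually used. :meth:`transform` maps a
    (sample x CpG) frame to a (sample x component) fraction frame whose
    rows are non-negative and sum to one.
    """

    def __init__(self, reference: ReferenceProfiles = None):
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None) -> "CellDeconvolver":
        if self.reference is None:
            raise ValueError("CellDeconvolver requires a reference")
        shared = [c for c in self.reference.cpg_ids if c in set(X.columns)]
        k = len(self.reference.components)
        if len(shared) < k:
            raise ValueError(
                f"only {len(shared)} CpGs shared with the reference; "
                f"need at least {k} (one per component)"
            )
        ref_pos = {c: i for i, c in enumerate(self.reference.cpg_ids)}
        self.cpgs_ = shared
        self.components_ = list(self.reference.components)
        self.ref_matrix_ = self.reference.values[[ref_pos[c] for c in shared], :]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "ref_matrix_"):
            raise ValueError("CellDeconvolver is not fitted")
        B = X[self.cpgs_].to_numpy(dtype=float)
        if np.isnan(B).any():
            raise ValueError("beta values must be complete for deconvolution")
        R = self.ref_matrix_
        A = np.vstack([R, _CONSTRAINT_WEIGHT * np.ones((1, R.shape[1]))])
        out = np.empty((B.shape[0], R.shape[1]))
        for j in range(B.shape[0]):
            b = np.concatenate([B[j], [_CONSTRAINT_WEIGHT]])
            f, _ = nnls(A, b)
            total = f.sum()
            if total <= 0:
                raise ValueError("degenerate deconvolution solution (all-zero fractions)")
            out[j] = f / total
        return pd.DataFrame(out, index=X.index, columns=self.components_)


def estimate_fractions(beta: BetaMatrix, ref: ReferenceProfiles) -> pd.DataFrame:
    """Per-sample cell fractions (rows sum to 1) for a CpG x sample matrix.

    When the reference carries several immune subtypes (component names
    starting with ``immune``), an aggregate ``ic`` column is added with
    their sum; ``ec`` and ``fib`` aliases are added for epithelial and
    fibroblast components when present.
    """
    est = CellDeconvolver(ref).fit(beta.samples_by_cpgs())
    frac = est.transform(beta.samples_by_cpgs())
    immune_cols = [c for c in frac.columns if c.startswith("immune")]
    if immune_cols and "ic" not in frac.columns:
        frac["ic"] = frac[immune_cols].sum(axis=1)
    if "epithelial" in frac.columns and "ec" not in frac.columns:
        frac["ec"] = frac["epithelial"]
    if "fibroblast" in frac.columns and "fib" not in frac.columns:
        frac["fib"] = frac["fibroblast"]
    return frac
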