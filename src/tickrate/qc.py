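"""Sample/probe quality filtering and KNN imputation for beta matrices.

The filter chain mirrors standard methylation-array processing: samples
with low median array intensity are dropped first, then samples with too
many failed probes (detection p above threshold), then probes failing in
too many of the remaining samples. All threshold comparisons are strict
(``>`` for failure fractions and detection p, ``<`` for intensity).

Remaining failed entries are imputed by the mean of the k nearest probe
rows (Euclidean distance over the samples where both probes are
observed), the convention of nearest-neighbour imputation in probe space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, CpGSet, _check_unique

__all__ = ["DetectionMatrix", "QcConfig", "QcReport", "flag_failed",
           "filter_cohort", "impute_failed", "apply_exclusions"]


@dataclass
class DetectionMatrix:
    """Per-entry detection p-values, same shape/IDs as a companion BetaMatrix."""

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValueError("detection matrix shape does not match its IDs")
        _check_unique(self.cpg_ids, "CpG ids")
        _check_unique(self.sample_ids, "sample ids")
        if np.any((self.values < 0) | (self.values > 1) | ~np.isfinite(self.values)):
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class QcConfig:
    """Thresholds for the filter chain.

    ``p_fail``: detection p above which a probe call is failed (strict >).
    ``sample_fail_frac``/``probe_fail_frac``: maximum tolerated failure
    fraction per sample / per probe (strict >). ``intensity_min``: minimum
    per-sample median log2 intensity (strict <). ``knn_k``: neighbours for
    imputation.
    """

    p_fail: float = 0.01
    sample_fail_frac: float = 0.10
    probe_fail_frac: float = 0.10
    intensity_min: float = 9.5
    knn_k: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.p_fail <= 1:
            raise ValueError("p_fail must be in [0, 1]")
        for name in ("sample_fail_frac", "probe_fail_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class QcReport:
    dropped_samples_intensity: list = field(default_factory=list)
    dropped_samples_failure: list = field(default_factory=list)
    dropped_probes: list = field(default_factory=list)
    n_failed_cells_remaining: int = 0

    def to_dict(self) -> dict:
        return {
            "dropped_samples_intensity": list(self.dropped_samples_intensity),
            "dropped_samples_failure": list(self.dropped_samples_failure),
            "dropped_probes": list(self.dropped_probes),
            "n_failed_cells_remaining": self.n_failed_cells_remaining,
        }


def flag_failed(detection: DetectionMatrix, cfg: QcConfig | None = None) -> np.ndarray:
    """Boolean mask, True exactly where detection p > cfg.p_fail (strict)."""
    cfg = cfg or QcConfig()
    return detection.values > cfg.p_fail


def filter_cohort(beta: BetaMatrix, detection: DetectionMatrix,
                  intensities: pd.DataFrame | None = None,
                  cfg: QcConfig | None = None,
                  ) -> tuple[BetaMatrix, DetectionMatrix, QcReport]:
    """Apply the sample/probe filter chain.

    Order: (1) drop samples with either median intensity < intensity_min;
    (2) drop samples whose failed-probe fraction > sample_fail_frac;
    (3) drop probes whose failure fraction over the remaining samples
    > probe_fail_frac. Returns the filtered beta and detection matrices and
    a report of dropped IDs.
    """
    cfg = cfg or QcConfig()
    if beta.cpg_ids != detection.cpg_ids or beta.sample_ids != detection.sample_ids:
        raise ValueError("beta and detection matrices must share IDs in order")
    report = QcReport()

    keep_samples = list(beta.sample_ids)
    if intensities is not None:
        missing = [s for s in keep_samples if s not in intensities.index]
        if missing:
            raise ValueError(f"intensities missing for samples: {missing[:10]}")
        low = []
        for s in keep_samples:
            row = intensities.loc[s]
            if (row["median_methylated"] < cfg.intensity_min
                    or row["median_unmethylated"] < cfg.intensity_min):
                low.append(s)
        report.dropped_samples_intensity = low
        keep_samples = [s for s in keep_samples if s not in set(low)]

    beta = beta.select_samples(keep_samples)
    det = DetectionMatrix(list(detection.cpg_ids), keep_samples,
                          detection.values[:, [detection.sample_ids.index(s)
                                               for s in keep_samples]])

    failed = flag_failed(det, cfg)
    frac_by_sample = failed.mean(axis=0)
    bad = frac_by_sample > cfg.sample_fail_frac
    report.dropped_samples_failure = [s for s, b in zip(keep_samples, bad) if b]
    keep_idx = np.flatnonzero(~bad)
    if keep_idx.size == 0:
        raise ValueError("all samples removed by QC filtering")
    keep_samples = [keep_samples[j] for j in keep_idx]
    beta = beta.select_samples(keep_samples)
    failed = failed[:, keep_idx]
    det = DetectionMatrix(list(det.cpg_ids), keep_samples, det.values[:, keep_idx])

    frac_by_probe = failed.mean(axis=1)
    bad_probe = frac_by_probe > cfg.probe_fail_frac
    report.dropped_probes = [c for c, b in zip(beta.cpg_ids, bad_probe) if b]
    keep_cpgs = np.flatnonzero(~bad_probe)
    if keep_cpgs.size == 0:
        raise ValueError("all probes removed by QC filtering")
    beta = BetaMatrix([beta.cpg_ids[i] for i in keep_cpgs], keep_samples,
                      beta.values[keep_cpgs, :])
    det = DetectionMatrix(list(beta.cpg_ids), keep_samples, det.values[keep_cpgs, :])
    report.n_failed_cells_remaining = int(flag_failed(det, cfg).sum())
    return beta, det, report


def impute_failed(beta: BetaMatrix, mask: np.ndarray,
                  cfg: QcConfig | None = None) -> BetaMatrix:
    """Replace masked entries by the mean of the k nearest probe rows.

    Distance between two probes is the Euclidean distance over samples
    where both are observed, rescaled to the full sample count (probes
    with no shared observed samples are infinitely far). Neighbours must
    be observed at the sample being imputed. Observed entries are
    returned bitwise untouched.
    """
    cfg = cfg or QcConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != beta.shape:
        raise ValueError("mask shape must match beta matrix")
    if not mask.any():
        return beta
    values = beta.values.copy()
    values[mask] = np.nan
    missing = np.isnan(values)
    if np.any(missing.all(axis=1)):
        bad = [beta.cpg_ids[i] for i in np.flatnonzero(missing.all(axis=1))]
        raise ValueError(f"probes with all samples missing cannot be imputed: {bad[:10]}")

    out = values.copy()
    n_probes, n_samples = values.shape
    rows_to_fix = np.flatnonzero(missing.any(axis=1))
    for i in rows_to_fix:
        obs_i = ~missing[i]
        # squared distance over shared observed samples, scaled to full length
        diff = values - values[i]
        shared = obs_i[None, :] & ~missing
        diff = np.where(shared, diff, 0.0)
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = (diff ** 2).sum(axis=1) / n_shared * n_samples
        d2[i] = np.inf
        d2[n_shared == 0] = np.inf
        for j in np.flatnonzero(missing[i]):
            candidates = np.flatnonzero(~missing[:, j] & np.isfinite(d2))
            if candidates.size == 0:
                raise ValueError(
                    f"no neighbour probes observed at sample "
                    f"{beta.sample_ids[j]!r} to impute {beta.cpg_ids[i]!r}"
                )
            order = candidates[np.argsort(d2[candidates], kind="stable")]
            nn = order[: cfg.knn_k]
            out[i, j] = float(np.mean(values[nn, j]))
    out = np.clip(out, 0.0, 1.0)
    return BetaMatrix(list(beta.cpg_ids), list(beta.sample_ids), out)


def apply_exclusions(beta: BetaMatrix, *lists: CpGSet) -> tuple[BetaMatrix, dict]:
    """Remove probes named in any exclusion list.

    Returns the reduced matrix and per-list counts of probes present in the
    matrix (overlapping lists count a probe in each list's tally, but it is
    removed once).
    """
    present = set(beta.cpg_ids)
    counts = {lst.name: len(lst.members & present) for lst in lists}
    union = set().union(*(lst.members for lst in lists)) if lists else set()
    keep = [c for c in beta.cpg_ids if c not in union]
    idx = [i for i, c in enumerate(beta.cpg_ids) if c not in union]
    return BetaMatrix(keep, list(beta.sample_ids), beta.values[idx, :]), counts
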