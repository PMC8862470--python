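"""Synthetic heterogeneous-tissue methylation cohorts with planted aging signal.

Emulates cervical-smear-like samples: each sample is a mixture of an
epithelial, a fibroblast and an immune compartment, with the immune
fraction roughly uniform across samples. Per CpG, each pure compartment
follows a linear methylation-vs-age trajectory:

    pure_epithelial = b0 + s_e * effective_epithelial_age
    pure_immune     = b0 + s_i * age
    pure_fibroblast = b0                       (fibroblasts do not age)

and the observed beta is the fraction-weighted mixture plus Gaussian
noise, clipped to [0, 1]. CpG categories plant the cell-type structure:
``shared`` CpGs age in both compartments (s_e = s_i), ``epithelial``/
``immune`` CpGs in one only, ``null`` CpGs in neither. A multiplicative
``case_effect`` < 1 slows the epithelial compartment's aging in case
samples — the planted analogue of a discordant epithelial tick rate.

Baselines of aging CpGs are drawn from the sub-interval of
``baseline_range`` for which the trajectory stays inside [0, 1] over the
whole age range, so the noiseless signal is exactly linear; clipping is
retained as a safeguard and clipped entries are counted in the truth
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix, SampleTable

__all__ = ["SynthConfig", "SyntheticTruth", "FailSpec", "generate_cohort",
           "generate_qc_artifacts", "DEFAULT_REFERENCE_SIZE", "reference_profiles_from_truth"]

CATEGORIES = ("shared", "epithelial_specific", "immune_specific", "null")


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a cervical-like training cohort: ages 20-75 years,
    immune fraction roughly uniform on [0, 0.95], a small fibroblast
    compartment (uniform on [0, 0.1] of the non-immune remainder), per-CpG
    baselines in [0.1, 0.9], aging slopes of magnitude 0.001-0.005
    beta/year with random sign.
    """

    n_samples: int = 800
    n_cpgs: int = 2000
    n_shared: int = 300
    n_epithelial: int = 100
    n_immune: int = 100
    n_null: int = 1500
    age_range: tuple[float, float] = (20.0, 75.0)
    slope_range: tuple[float, float] = (0.001, 0.005)
    baseline_range: tuple[float, float] = (0.1, 0.9)
    noise_sd: float = 0.0
    ic_range: tuple[float, float] = (0.0, 0.95)
    fib_frac_range: tuple[float, float] = (0.0, 0.1)
    case_effect: float = 1.0
    case_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_shared, self.n_epithelial, self.n_immune, self.n_null)
        if any(c < 0 for c in counts) or sum(counts) != self.n_cpgs:
            raise ValueError(
                f"category counts {counts} must be non-negative and sum to n_cpgs={self.n_cpgs}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ValueError("age_range must satisfy 0 < min < max")
        if not (0 <= self.case_fraction <= 1):
            raise ValueError("case_fraction must be in [0, 1]")
        if self.case_effect <= 0:
            raise ValueError("case_effect must be > 0")
        blo, bhi = self.baseline_range
        if not (0 <= blo < bhi <= 1):
            raise ValueError("baseline_range must be inside [0, 1]")
        slo, shi = self.slope_range
        if not (0 <= slo <= shi):
            raise ValueError("slope_range must satisfy 0 <= min <= max")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``cpgs``: per-CpG category, baseline and compartment slopes.
    ``samples``: per-sample true fractions, age, group and the effective
    epithelial age actually used. ``n_clipped``: entries clipped to [0, 1]
    after noise.
    """

    cpgs: pd.DataFrame
    samples: pd.DataFrame
    n_clipped: int = 0
    config: dict = field(default_factory=dict)


def _draw_baseline(rng: np.random.Generator, cfg: SynthConfig,
                   slopes: np.ndarray, max_age: float) -> np.ndarray:
    """Baselines keeping b0 + s*age inside [0, 1] for all ages <= max_age."""
    blo, bhi = cfg.baseline_range
    lo = np.maximum(blo, -slopes * max_age)
    hi = np.minimum(bhi, 1.0 - np.maximum(slopes, 0.0) * max_age)
    if np.any(lo >= hi):
        raise ValueError("baseline_range too narrow for the requested slopes/ages")
    return rng.uniform(lo, hi)


def generate_cohort(cfg: SynthConfig) -> tuple[BetaMatrix, SampleTable, SyntheticTruth]:
    """Generate a cohort; fully deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_cpgs

    age = rng.uniform(*cfg.age_range, n)
    ic = rng.uniform(*cfg.ic_range, n)
    fib = (1.0 - ic) * rng.uniform(*cfg.fib_frac_range, n)
    ec = 1.0 - ic - fib
    is_case = rng.random(n) < cfg.case_fraction
    group = np.where(is_case, "case", "control")
    eff_epi_age = np.where(is_case, age * cfg.case_effect, age)

    category = np.repeat(
        CATEGORIES,
        (cfg.n_shared, cfg.n_epithelial, cfg.n_immune, cfg.n_null),
    )
    slo, shi = cfg.slope_range
    mag = rng.uniform(slo, shi, m)
    sign = rng.choice([-1.0, 1.0], m)
    s = mag * sign
    s_epi = np.where(np.isin(category, ("shared", "epithelial_specific")), s, 0.0)
    s_imm = np.where(np.isin(category, ("shared", "immune_specific")), s, 0.0)

    max_age = cfg.age_range[1] * max(1.0, cfg.case_effect)
    # widest slope per CpG governs the feasible baseline interval
    s_extreme = np.where(np.abs(s_epi) >= np.abs(s_imm), s_epi, s_imm)
    b0 = _draw_baseline(rng, cfg, s_extreme, max_age)

    pure_epi = np.clip(b0[:, None] + s_epi[:, None] * eff_epi_age[None, :], 0.0, 1.0)
    pure_imm = np.clip(b0[:, None] + s_imm[:, None] * age[None, :], 0.0, 1.0)
    pure_fib = b0[:, None]
    mix = ec[None, :] * pure_epi + fib[None, :] * pure_fib + ic[None, :] * pure_imm
    if cfg.noise_sd > 0:
        mix = mix + rng.normal(0.0, cfg.noise_sd, mix.shape)
    clipped = int(np.sum((mix < 0) | (mix > 1)))
    values = np.clip(mix, 0.0, 1.0)

    cpg_ids = [f"cg{i:07d}" for i in range(m)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    beta = BetaMatrix(cpg_ids, sample_ids, values)
    samples = SampleTable(pd.DataFrame({
        "sample_id": sample_ids, "age": age, "ec": ec, "fib": fib, "ic": ic,
        "group": group,
    }))
    truth = SyntheticTruth(
        cpgs=pd.DataFrame({
            "cpg_id": cpg_ids, "category": category, "baseline": b0,
            "slope_epithelial": s_epi, "slope_immune": s_imm,
        }),
        samples=pd.DataFrame({
            "sample_id": sample_ids, "age": age, "ec": ec, "fib": fib,
            "ic": ic, "group": group, "effective_epithelial_age": eff_epi_age,
        }),
        n_clipped=clipped,
        config=asdict(cfg),
    )
    return beta, samples, truth


# ---------------------------------------------------------------------------
# QC fixtures
# ---------------------------------------------------------------------------

@dataclass
class FailSpec:
    """Cells to mark failed and samples to give low array intensity."""

    fail_cells: Sequence[tuple[str, str]] = ()        # (sample_id, cpg_id)
    low_intensity_samples: Sequence[str] = ()

    P_FAILED: float = 0.5
    P_OK: float = 0.0001
    INTENSITY_LOW: float = 9.3
    INTENSITY_OK: float = 10.5


def generate_qc_artifacts(beta: BetaMatrix, spec: FailSpec):
    """Detection p-values and per-sample median intensities for QC tests.

    Returns ``(DetectionMatrix, intensities)`` where intensities is a
    DataFrame indexed by sample with columns ``median_methylated`` and
    ``median_unmethylated`` (log2 scale).
    """
    from .qc import DetectionMatrix  # local import avoids a cycle

    cpg_pos = {c: i for i, c in enumerate(beta.cpg_ids)}
    smp_pos = {s: j for j, s in enumerate(beta.sample_ids)}
    p = np.full(beta.shape, spec.P_OK)
    for sample_id, cpg_id in spec.fail_cells:
        if sample_id not in smp_pos:
            raise KeyError(f"unknown sample id in fail spec: {sample_id!r}")
        if cpg_id not in cpg_pos:
            raise KeyError(f"unknown CpG id in fail spec: {cpg_id!r}")
        p[cpg_pos[cpg_id], smp_pos[sample_id]] = spec.P_FAILED
    unknown = [s for s in spec.low_intensity_samples if s not in smp_pos]
    if unknown:
        raise KeyError(f"unknown sample ids in fail spec: {unknown}")
    inten = np.full(len(beta.sample_ids), spec.INTENSITY_OK)
    for s in spec.low_intensity_samples:
        inten[smp_pos[s]] = spec.INTENSITY_LOW
    intensities = pd.DataFrame(
        {"median_methylated": inten, "median_unmethylated": inten},
        index=list(beta.sample_ids),
    )
    detection = DetectionMatrix(list(beta.cpg_ids), list(beta.sample_ids), p)
    return detection, intensities


# ---------------------------------------------------------------------------
# reference profiles for deconvolution round-trips
# ---------------------------------------------------------------------------

DEFAULT_REFERENCE_SIZE = 200


def reference_profiles_from_truth(truth: SyntheticTruth, at_age: float = 45.0):
    """Pure-compartment beta profiles implied by a cohort's ground truth.

    Evaluates each compartment's trajectory at ``at_age`` years. Cohort
    mixtures are exactly combinations of these profiles only for samples
    of age ``at_age``; for other ages the recovery is approximate in
    proportion to the aging slopes times the age offset.
    """
    from .deconv import ReferenceProfiles

    b0 = truth.cpgs["baseline"].to_numpy()
    s_epi = truth.cpgs["slope_epithelial"].to_numpy()
    s_imm = truth.cpgs["slope_immune"].to_numpy()
    profiles = np.column_stack([
        np.clip(b0 + s_epi * at_age, 0, 1),
        b0,
        np.clip(b0 + s_imm * at_age, 0, 1),
    ])
    return ReferenceProfiles(list(truth.cpgs["cpg_id"]),
                             ["epithelial", "fibroblast", "immune"], profiles)
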