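"""Core containers and delimited-text I/O.

All pipeline stages exchange four objects: a :class:`BetaMatrix` of
methylation beta values (CpG x sample, values in [0, 1], NaN = missing),
a :class:`SampleTable` of per-sample phenotypes and cell-type fractions,
a :class:`ClockModel` holding trained clock coefficients, and
:class:`ClockScores` holding per-sample clock read-outs.

Interchange is plain delimited text (TSV by default, CSV accepted).
Missing beta values are written as the literal ``NA``. Floats are written
with shortest round-tripping repr, so write-then-read is bitwise lossless.
Sample alignment between a BetaMatrix and a SampleTable is always by ID,
never positional; see :func:`align_samples`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleTable",
    "ClockModel",
    "ClockScores",
    "CpGSet",
    "align_samples",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_clock_model",
    "write_clock_model",
    "read_cpg_set",
    "write_cpg_set",
]

VALID_GROUPS = ("control", "case", "other")
FRACTION_TOL = 1e-6


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    return "," if str(path).endswith(".csv") else "\t"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen[x] = seen.get(x, 0) + 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation beta values.

    ``values[i, j]`` is the beta value of CpG ``cpg_ids[i]`` in sample
    ``sample_ids[j]``; NaN marks a missing (failed) measurement.
    """

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.cpg_ids)} CpGs, {len(self.sample_ids)} samples)"
            )
        _check_unique(self.cpg_ids, "CpG ids")
        _check_unique(self.sample_ids, "sample ids")
        bad = np.argwhere((self.values < 0) | (self.values > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0, 1] at CpG {self.cpg_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.values[i, j]!r} "
                f"({len(bad)} offending entries)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def select_cpgs(self, cpgs: Iterable[str]) -> "BetaMatrix":
        """Row-subset (and reorder) by CpG ID; unknown IDs raise KeyError."""
        wanted = list(cpgs)
        pos = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [c for c in wanted if c not in pos]
        if missing:
            raise KeyError(f"CpGs not in matrix: {missing[:10]}")
        idx = [pos[c] for c in wanted]
        return BetaMatrix(wanted, list(self.sample_ids), self.values[idx, :])

    def select_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        """Column-subset (and reorder) by sample ID; unknown IDs raise KeyError."""
        wanted = list(samples)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        idx = [pos[s] for s in wanted]
        return BetaMatrix(list(self.cpg_ids), wanted, self.values[:, idx])

    def samples_by_cpgs(self) -> pd.DataFrame:
        """Transposed view (sample x CpG) for estimator-style APIs."""
        return self.to_frame().T


@dataclass
class SampleTable:
    """Per-sample phenotype table.

    Required columns: ``sample_id``, ``age`` (years, > 0), ``ec``, ``fib``,
    ``ic`` (cell fractions in [0, 1], summing to at most 1), ``group``
    (control/case/other). Any further columns are treated as covariates
    (menopause status, HRT, OCP, tissue, ...).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = ["sample_id", "age", "ec", "fib", "ic", "group"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample ids")
        for c in ("age", "ec", "fib", "ic"):
            df[c] = df[c].astype(float)
        if (df["age"] <= 0).any():
            bad = df.loc[df["age"] <= 0, "sample_id"].tolist()
            raise ValueError(f"non-positive ages for samples: {bad}")
        for c in ("ec", "fib", "ic"):
            if ((df[c] < 0) | (df[c] > 1)).any():
                bad = df.loc[(df[c] < 0) | (df[c] > 1), "sample_id"].tolist()
                raise ValueError(f"fraction {c!r} outside [0, 1] for samples: {bad}")
        total = df[["ec", "fib", "ic"]].sum(axis=1)
        if (total > 1 + FRACTION_TOL).any():
            bad = df.loc[total > 1 + FRACTION_TOL, "sample_id"].tolist()
            raise ValueError(f"ec + fib + ic > 1 for samples: {bad}")
        unknown = set(df["group"].astype(str)) - set(VALID_GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def age(self) -> np.ndarray:
        return self.frame["age"].to_numpy()

    @property
    def ec(self) -> np.ndarray:
        return self.frame["ec"].to_numpy()

    @property
    def fib(self) -> np.ndarray:
        return self.frame["fib"].to_numpy()

    @property
    def ic(self) -> np.ndarray:
        return self.frame["ic"].to_numpy()

    @property
    def group(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, sample_ids: Iterable[str]) -> "SampleTable":
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing[:10]}")
        return SampleTable(self.frame.iloc[[pos[s] for s in wanted]].reset_index(drop=True))


def align_samples(beta: BetaMatrix, samples: SampleTable) -> tuple[BetaMatrix, SampleTable]:
    """Align a BetaMatrix and SampleTable to the table's sample order.

    Alignment is by ID. Raises if the sample sets differ.
    """
    bset, tset = set(beta.sample_ids), set(samples.sample_ids)
    if bset != tset:
        raise ValueError(
            f"sample sets differ: {sorted(bset - tset)[:5]} only in matrix, "
            f"{sorted(tset - bset)[:5]} only in table"
        )
    return beta.select_samples(samples.sample_ids), samples


def check_aligned(beta: BetaMatrix, samples: SampleTable) -> None:
    if beta.sample_ids != samples.sample_ids:
        raise ValueError(
            "BetaMatrix and SampleTable sample orderings differ; "
            "use align_samples() to reorder by ID"
        )


@dataclass
class ClockModel:
    """A trained epigenetic clock.

    ``kind='general'`` clocks predict ``sum_i w_i * beta_i + intercept``.
    Cell-type clocks (``kind='epithelial'|'immune'``) add per-CpG
    interaction weights applied to ``beta_i * ic`` where ``ic`` is the
    sample's immune fraction: ``sum_i w1_i*beta_i + w2_i*beta_i*ic + intercept``.
    """

    kind: str
    cpgs: list[str]
    w: np.ndarray
    w_ic: np.ndarray
    intercept: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("general", "epithelial", "immune"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        self.cpgs = [str(c) for c in self.cpgs]
        _check_unique(self.cpgs, "clock CpGs")
        self.w = np.asarray(self.w, dtype=float)
        self.w_ic = np.asarray(self.w_ic, dtype=float)
        self.intercept = float(self.intercept)
        if self.w.shape != (len(self.cpgs),):
            raise ValueError("main weight vector length must equal number of CpGs")
        if self.w_ic.size not in (0, len(self.cpgs)):
            raise ValueError("interaction weights must be empty or one per CpG")
        if self.kind == "general" and self.w_ic.size:
            raise ValueError("general clocks carry no interaction weights")

    @property
    def has_interactions(self) -> bool:
        return self.w_ic.size > 0


@dataclass
class ClockScores:
    """Per-sample clock read-outs and relative-age statistics.

    ``age_accel = general_age - age``; ``rea = epithelial_age - general_age``
    (relative epithelial age); ``ria = immune_age - general_age`` (relative
    immune age). ``*_adj`` columns hold reference-cohort-adjusted residuals
    and are NaN until an adjustment is applied.
    """

    frame: pd.DataFrame

    COLUMNS = (
        "sample_id", "age", "general_age", "epithelial_age", "immune_age",
        "age_accel", "rea", "ria", "age_accel_adj", "rea_adj", "ria_adj",
    )

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for c in self.COLUMNS:
            if c not in df.columns:
                if c.endswith("_adj"):
                    df[c] = np.nan
                else:
                    raise ValueError(f"scores missing column {c!r}")
        df = df[list(self.COLUMNS)]
        if not np.allclose(df["rea"], df["epithelial_age"] - df["general_age"],
                           atol=1e-9, equal_nan=True):
            raise ValueError("rea must equal epithelial_age - general_age")
        if not np.allclose(df["ria"], df["immune_age"] - df["general_age"],
                           atol=1e-9, equal_nan=True):
            raise ValueError("ria must equal immune_age - general_age")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CpGSet:
    """A named CpG list (e.g. mitotic-clock CpGs, exclusion lists)."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        members = [str(m) for m in self.members]
        if not members:
            raise ValueError(f"CpG set {self.name!r} is empty")
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"],
                     keep_default_na=False, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix.from_frame(df.astype(float))


def write_beta_matrix(beta: BetaMatrix, path: str | Path,
                      dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    df = beta.to_frame()
    with open(path, "w") as fh:
        fh.write("cpg_id" + sep + sep.join(df.columns) + "\n")
        for cpg, row in zip(df.index, df.to_numpy()):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(cpg + sep + sep.join(cells) + "\n")


def read_sample_table(path: str | Path, dialect: str | None = None) -> SampleTable:
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path,
                       dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    df = samples.frame.copy()
    for c in df.columns:
        if df[c].dtype == float:
            df[c] = df[c].map(lambda v: "NA" if np.isnan(v) else repr(float(v)))
    df.to_csv(path, sep=sep, index=False)


def read_clock_model(path: str | Path, dialect: str | None = None) -> ClockModel:
    """Read a clock coefficient table.

    Format: ``#kind=`` and ``#intercept=`` header lines (plus optional
    ``#meta=`` JSON), then a delimited table with columns
    ``cpg, weight[, interaction_weight]``.
    """
    sep = _sep_for(path, dialect)
    kind = None
    intercept = None
    meta: dict = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#kind="):
                kind = line.split("=", 1)[1].strip()
            elif line.startswith("#intercept="):
                intercept = float(line.split("=", 1)[1])
            elif line.startswith("#meta="):
                meta = json.loads(line.split("=", 1)[1])
            elif line.startswith("#") or not line.strip():
                continue
            else:
                body.append(line)
    if kind is None:
        raise ValueError(f"{path}: missing '#kind=' header")
    if intercept is None:
        raise ValueError(f"{path}: missing '#intercept=' header")
    if not body:
        return ClockModel(kind, [], np.empty(0), np.empty(0), intercept, meta)
    header = body[0].split(sep)
    if header[:2] != ["cpg", "weight"]:
        raise ValueError(f"{path}: expected columns 'cpg{sep}weight', got {body[0]!r}")
    has_inter = len(header) > 2 and header[2] == "interaction_weight"
    if has_inter and kind == "general":
        raise ValueError(f"{path}: interaction_weight column invalid for kind=general")
    cpgs, w, w_ic = [], [], []
    for line in body[1:]:
        cells = line.split(sep)
        cpgs.append(cells[0])
        w.append(float(cells[1]))
        if has_inter:
            w_ic.append(float(cells[2]))
    return ClockModel(kind, cpgs, np.array(w),
                      np.array(w_ic) if has_inter else np.empty(0), intercept, meta)


def write_clock_model(model: ClockModel, path: str | Path,
                      dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    with open(path, "w") as fh:
        fh.write(f"#kind={model.kind}\n")
        fh.write(f"#intercept={model.intercept!r}\n")
        if model.meta:
            fh.write(f"#meta={json.dumps(model.meta, sort_keys=True)}\n")
        cols = ["cpg", "weight"] + (["interaction_weight"] if model.has_interactions else [])
        fh.write(sep.join(cols) + "\n")
        for i, cpg in enumerate(model.cpgs):
            row = [cpg, repr(float(model.w[i]))]
            if model.has_interactions:
                row.append(repr(float(model.w_ic[i])))
            fh.write(sep.join(row) + "\n")


def read_cpg_set(path: str | Path) -> CpGSet:
    name = Path(path).stem
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#name="):
                name = line.split("=", 1)[1].strip()
            elif line and not line.startswith("#"):
                members.append(line)
    return CpGSet(name, frozenset(members))


def write_cpg_set(cpg_set: CpGSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={cpg_set.name}\n")
        for m in sorted(cpg_set.members):
            fh.write(m + "\n")
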