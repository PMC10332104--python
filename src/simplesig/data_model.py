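"""Core containers for DNA-methylation data.

A methylation matrix holds beta-values (fraction methylated, in [0, 1]) or
M-values (log2 ratio of methylated to unmethylated intensity) for p CpG
probes across n samples, oriented features x samples.  Labels, sample sheets
and signatures are thin, validated wrappers around pandas structures so the
rest of the package can stay free of file-format concerns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylMatrix",
    "LabelVector",
    "SampleSheet",
    "SignatureEntry",
    "Signature",
    "read_methyl_matrix",
    "write_methyl_matrix",
    "beta_to_mvalue",
    "mvalue_to_beta",
    "read_signature",
    "write_signature",
    "read_sample_sheet",
    "write_sample_sheet",
]

#: Strings treated as missing on read; "NA" is emitted on write.
NA_TOKENS = ("NA", "NaN", "")

#: Beta values are clamped to [EPS, 1-EPS] before the logit-type transform.
BETA_EPS = 1e-6


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class MethylMatrix:
    """Features x samples matrix of beta- or M-values.

    Parameters
    ----------
    values : ndarray, shape (p, n)
        Methylation values; NaN marks missing entries.
    feature_ids, sample_ids : sequences of unique strings.
    scale : {"beta", "mvalue"}
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    scale: str = "beta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        p, n = self.values.shape
        if p < 1 or n < 1:
            raise ValueError("matrix must have at least one feature and one sample")
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError(
                f"id lengths ({len(self.feature_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.scale not in ("beta", "mvalue"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "beta":
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            if bad.size:
                cells = [
                    f"{self.feature_ids[i]}/{self.sample_ids[j]}="
                    f"{self.values[i, j]:g}"
                    for i, j in bad[:5]
                ]
                raise ValueError(
                    f"{len(bad)} beta value(s) outside [0, 1]: {', '.join(cells)}"
                )

    # -- basic introspection -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "beta") -> "MethylMatrix":
        return cls(
            df.to_numpy(dtype=float),
            list(df.index.astype(str)),
            list(df.columns.astype(str)),
            scale=scale,
        )

    # -- subsetting ----------------------------------------------------------
    def select_features(self, ids: Iterable[str]) -> "MethylMatrix":
        ids = list(ids)
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        idx = [pos[f] for f in ids]
        return MethylMatrix(self.values[idx, :], ids, self.sample_ids, self.scale)

    def select_samples(self, ids: Iterable[str]) -> "MethylMatrix":
        ids = list(ids)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = [pos[s] for s in ids]
        return MethylMatrix(self.values[:, idx], self.feature_ids, ids, self.scale)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_methyl_matrix(
    path: str | Path, scale: str = "beta", transpose: bool = False
) -> MethylMatrix:
    """Read a delimited probes x samples table into a :class:`MethylMatrix`.

    The first column holds probe ids, the header row sample ids.  Separator
    is chosen from the extension (``.csv`` comma, otherwise tab).  ``NA``,
    ``NaN`` and empty cells are read as missing.  Beta-scale values outside
    [0, 1] raise with the offending probe/sample named.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=list(NA_TOKENS),
        keep_default_na=False,
        float_precision="round_trip",
    )
    if transpose:
        df = df.T
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    return MethylMatrix.from_frame(df, scale=scale)


def write_methyl_matrix(X: MethylMatrix, path: str | Path) -> None:
    path = Path(path)
    X.to_frame().to_csv(path, sep=_sep_for(path), na_rep="NA", float_format="%.12g")


def beta_to_mvalue(X: MethylMatrix) -> MethylMatrix:
    """M = log2(beta / (1 - beta)), with beta clamped to [1e-6, 1 - 1e-6].

    Clamping handles exact 0/1 values produced by rounding; stored data is
    never mutated.  Missing entries stay missing.
    """
    if X.scale != "beta":
        raise ValueError("input matrix is not on the beta scale")
    b = np.clip(X.values, BETA_EPS, 1.0 - BETA_EPS)
    with np.errstate(invalid="ignore"):
        m = np.log2(b / (1.0 - b))
    m[np.isnan(X.values)] = np.nan
    return MethylMatrix(m, X.feature_ids, X.sample_ids, scale="mvalue")


def mvalue_to_beta(X: MethylMatrix) -> MethylMatrix:
    """Inverse of :func:`beta_to_mvalue`: beta = 2^M / (2^M + 1)."""
    if X.scale != "mvalue":
        raise ValueError("input matrix is not on the M-value scale")
    e = np.exp2(X.values)
    return MethylMatrix(e / (e + 1.0), X.feature_ids, X.sample_ids, scale="beta")


@dataclass
class LabelVector:
    """Cell-type label per sample, with one-vs-rest binarization."""

    sample_ids: list[str]
    class_of: dict[str, str]
    target: str | None = None

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample ids")
        missing = [s for s in self.sample_ids if s not in self.class_of]
        if missing:
            raise ValueError(f"samples without a label: {missing[:5]}")

    @property
    def labels(self) -> list[str]:
        return [self.class_of[s] for s in self.sample_ids]

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return list(seen)

    def binarize(self, target: str | None = None) -> np.ndarray:
        """0/1 vector over samples: 1 where the label equals ``target``."""
        target = target if target is not None else self.target
        if target is None:
            raise ValueError("no target cell type given")
        return np.array(
            [1 if self.class_of[s] == target else 0 for s in self.sample_ids],
            dtype=int,
        )

    def for_samples(self, ids: Iterable[str]) -> "LabelVector":
        ids = list(ids)
        return LabelVector(ids, {s: self.class_of[s] for s in ids}, self.target)


SHEET_COLUMNS = ("sample_id", "cell_type", "split")


@dataclass
class SampleSheet:
    """Sample metadata: id, cell type, train/test split, free covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s): {missing}")
        _check_unique(self.table["sample_id"].astype(str).tolist(), "sample ids")
        bad = set(self.table["split"]) - {"train", "test"}
        if bad:
            raise ValueError(f"invalid split values: {sorted(bad)}")

    def ids(self, split: str | None = None) -> list[str]:
        t = self.table
        if split is not None:
            t = t[t["split"] == split]
        return t["sample_id"].astype(str).tolist()

    def labels(self, split: str | None = None) -> LabelVector:
        t = self.table
        if split is not None:
            t = t[t["split"] == split]
        ids = t["sample_id"].astype(str).tolist()
        return LabelVector(ids, dict(zip(ids, t["cell_type"].astype(str))))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


SIGNATURE_COLUMNS = (
    "target",
    "feature_id",
    "rank",
    "direction",
    "score_C",
    "aupr_train",
    "aupr_valid",
    "fold_activity",
    "selection_a",
    "ref_mean_target",
    "ref_mean_others",
)


@dataclass
class SignatureEntry:
    feature_id: str
    direction: str  # "hyper" (higher in target) or "hypo"
    score_c: float
    aupr_train: float
    aupr_valid: float
    fold_activity: int
    selection_a: float
    ref_mean_target: float
    ref_mean_others: float


@dataclass
class Signature:
    """Ranked CpG set for one target cell type (best entry first)."""

    target: str
    entries: list[SignatureEntry] = field(default_factory=list)
    n_sigs: int = 1

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.direction not in ("hyper", "hypo"):
                raise ValueError(f"bad direction {e.direction!r}")

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def top(self) -> SignatureEntry:
        return self.entries[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": self.target,
                "feature_id": e.feature_id,
                "rank": r + 1,
                "direction": e.direction,
                "score_C": e.score_c,
                "aupr_train": e.aupr_train,
                "aupr_valid": e.aupr_valid,
                "fold_activity": e.fold_activity,
                "selection_a": e.selection_a,
                "ref_mean_target": e.ref_mean_target,
                "ref_mean_others": e.ref_mean_others,
            }
            for r, e in enumerate(self.entries)
        ]
        return pd.DataFrame(rows, columns=list(SIGNATURE_COLUMNS))


def write_signature(sig: Signature, path: str | Path) -> None:
    if not sig.entries:
        raise ValueError("refusing to write an empty signature")
    sig.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_signature(path: str | Path) -> Signature:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signature file missing column(s): {missing}")
    if df.empty:
        raise ValueError("signature file has no entries")
    targets = df["target"].unique()
    if len(targets) != 1:
        raise ValueError(f"signature file mixes targets: {targets.tolist()}")
    df = df.sort_values("rank")
    entries = [
        SignatureEntry(
            feature_id=str(r.feature_id),
            direction=str(r.direction),
            score_c=float(r.score_C),
            aupr_train=float(r.aupr_train),
            aupr_valid=float(r.aupr_valid),
            fold_activity=int(r.fold_activity),
            selection_a=float(r.selection_a),
            ref_mean_target=float(r.ref_mean_target),
            ref_mean_others=float(r.ref_mean_others),
        )
        for r in df.itertuples()
    ]
    return Signature(target=str(targets[0]), entries=entries, n_sigs=len(entries))
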