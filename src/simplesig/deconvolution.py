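"""Reference-based cell-type deconvolution.

A mixture matrix V (signature CpGs x mixture samples) is modeled as
V = W . H where W holds the cell-type-specific mean methylation of the
signature CpGs and H the unknown non-negative cell-type proportions per
sample.  Each sample column is solved independently with non-negative least
squares; columns are renormalized to the unit simplex by default.  Missing
mixture entries are mean-imputed (with a warning count) before solving.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls

from .data_model import LabelVector, MethylMatrix, Signature

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceMatrix",
    "ProportionMatrix",
    "build_reference",
    "build_reference_from_scores",
    "impute_missing",
    "nnls_deconvolve",
    "deconvolve",
    "aggregate_proportions",
    "read_reference",
    "write_reference",
    "read_proportions",
    "write_proportions",
]


@dataclass
class ReferenceMatrix:
    """W: reference features x cell types (CpG means or classifier scores)."""

    values: np.ndarray
    feature_ids: list[str]
    cell_types: list[str]
    source: str = "cpg_means"  # or "classifier_scores"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.cell_types)):
            raise ValueError("reference shape does not match ids")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("duplicate cell types in reference")
        if self.source == "cpg_means":
            if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
                raise ValueError("CpG-mean reference values must lie in [0, 1]")
        if self.values.shape[0] < self.values.shape[1]:
            warnings.warn(
                "reference has fewer features than cell types; "
                "deconvolution may be under-determined",
                stacklevel=2,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.cell_types
        )


@dataclass
class ProportionMatrix:
    """H: cell types x mixture samples, entries >= 0."""

    values: np.ndarray
    cell_types: list[str]
    sample_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_types), len(self.sample_ids)):
            raise ValueError("proportion shape does not match ids")
        if (self.values < 0).any():
            raise ValueError("proportions must be non-negative")
        if self.normalized:
            sums = self.values.sum(axis=0)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1.0, atol=1e-9):
                raise ValueError("normalized columns must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_types, columns=self.sample_ids
        )


def build_reference(
    X: MethylMatrix, labels: LabelVector, signatures: list[Signature]
) -> ReferenceMatrix:
    """Average methylation of every signature CpG per cell type.

    Rows are the union of the signatures' CpGs (order preserved, duplicates
    collapsed), columns the signature targets; W[i, t] is the mean value of
    CpG i over the training samples labelled t.
    """
    if list(labels.sample_ids) != list(X.sample_ids):
        labels = labels.for_samples(X.sample_ids)
    feats: list[str] = []
    for sig in signatures:
        for f in sig.feature_ids:
            if f not in feats:
                feats.append(f)
    absent = [f for f in feats if f not in set(X.feature_ids)]
    if absent:
        raise KeyError(f"signature CpG(s) absent from the matrix: {absent[:5]}")
    cell_types = [sig.target for sig in signatures]
    if len(set(cell_types)) != len(cell_types):
        raise ValueError("duplicate signature targets")
    sub = X.select_features(feats)
    lab = np.array(labels.labels)
    W = np.empty((len(feats), len(cell_types)))
    for t_idx, t in enumerate(cell_types):
        mask = lab == t
        if not mask.any():
            raise ValueError(f"no samples labelled {t!r}")
        W[:, t_idx] = np.nanmean(sub.values[:, mask], axis=1)
    return ReferenceMatrix(W, feats, cell_types, source="cpg_means")


def build_reference_from_scores(
    scores: pd.DataFrame, labels: LabelVector
) -> ReferenceMatrix:
    """Reference from classifier scores: mean score per classifier, per type.

    ``scores`` has one row per sample and one column per classifier (one
    classifier per cell type); W[i, t] is the mean score of classifier i over
    samples of type t.  Mixture deconvolution then uses the classifier-score
    matrix as V.
    """
    ids = list(scores.index.astype(str))
    if set(ids) != set(labels.sample_ids):
        raise ValueError("score matrix samples do not match labels")
    lab = {s: labels.class_of[s] for s in ids}
    cell_types = list(scores.columns.astype(str))
    W = np.empty((len(cell_types), len(cell_types)))
    for t_idx, t in enumerate(cell_types):
        members = [s for s in ids if lab[s] == t]
        if not members:
            raise ValueError(f"no samples labelled {t!r}")
        W[:, t_idx] = scores.loc[members].mean(axis=0).to_numpy()
    return ReferenceMatrix(W, cell_types, cell_types, source="classifier_scores")


def impute_missing(
    V: MethylMatrix, W: ReferenceMatrix | None = None
) -> tuple[MethylMatrix, int]:
    """Mean-impute missing mixture entries so deconvolution can proceed.

    Each missing cell takes the mean of its feature's observed values across
    the mixture samples; a feature observed nowhere falls back to the mean of
    the corresponding reference row across cell types.  Returns the imputed
    matrix and the number of filled cells (0 leaves V untouched).
    """
    miss = np.isnan(V.values)
    n_miss = int(miss.sum())
    if n_miss == 0:
        return V, 0
    vals = V.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_mean = np.nanmean(vals, axis=1)
    if np.isnan(row_mean).any():
        if W is None:
            raise ValueError(
                "fully missing feature(s) and no reference to fall back on"
            )
        wpos = {f: i for i, f in enumerate(W.feature_ids)}
        for i in np.nonzero(np.isnan(row_mean))[0]:
            f = V.feature_ids[i]
            if f not in wpos:
                raise KeyError(f"fully missing feature {f!r} not in reference")
            row_mean[i] = W.values[wpos[f]].mean()
    fill = np.broadcast_to(row_mean[:, None], vals.shape)
    vals[miss] = fill[miss]
    warnings.warn(f"mean-imputed {n_miss} missing mixture value(s)", stacklevel=2)
    return MethylMatrix(vals, V.feature_ids, V.sample_ids, V.scale), n_miss


def nnls_deconvolve(
    V: MethylMatrix, W: ReferenceMatrix, normalize: bool = True
) -> ProportionMatrix:
    """Solve h = argmin ||W h - v||_2, h >= 0 for every mixture column.

    Features are aligned by inner join on probe id (in reference order);
    losing more than half of the reference features triggers a warning, an
    empty intersection is an error.  Negative entries (impossible with NNLS
    itself, possible with alternative back-ends) are capped at 0.  With
    ``normalize`` each column is rescaled to sum to 1; all-zero columns stay
    zero with a warning.
    """
    vpos = {f: i for i, f in enumerate(V.feature_ids)}
    shared = [f for f in W.feature_ids if f in vpos]
    if not shared:
        raise ValueError("no shared features between mixtures and reference")
    dropped = len(W.feature_ids) - len(shared)
    if dropped:
        logger.info("dropped %d reference features absent from mixtures", dropped)
    if dropped > len(W.feature_ids) / 2:
        warnings.warn(
            f"over half of the reference features ({dropped}/{len(W.feature_ids)}) "
            "are absent from the mixture matrix",
            stacklevel=2,
        )
    wpos = {f: i for i, f in enumerate(W.feature_ids)}
    Wm = W.values[[wpos[f] for f in shared], :]
    Vm = V.values[[vpos[f] for f in shared], :]
    if np.isnan(Vm).any():
        raise ValueError("mixture matrix has missing values; impute first")

    if np.linalg.matrix_rank(Wm) < Wm.shape[1]:
        warnings.warn(
            "reference matrix is rank-deficient; proportions may not be "
            "uniquely determined",
            stacklevel=2,
        )

    H = np.empty((Wm.shape[1], Vm.shape[1]))
    for j in range(Vm.shape[1]):
        H[:, j], _ = _nnls(Wm, Vm[:, j])
    H = np.maximum(H, 0.0)

    if normalize:
        sums = H.sum(axis=0)
        zero = sums == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} mixture column(s) deconvolved to all-zero "
                "proportions; left unnormalized",
                stacklevel=2,
            )
        H = np.where(zero, H, H / np.where(zero, 1.0, sums))
    return ProportionMatrix(H, list(W.cell_types), list(V.sample_ids), normalized=normalize)


def deconvolve(
    V: MethylMatrix, W: ReferenceMatrix, normalize: bool = True
) -> tuple[ProportionMatrix, int]:
    """Impute missing mixture values, then NNLS-deconvolve.

    Returns the proportion matrix and the number of imputed cells.
    """
    vpos = {f: i for i, f in enumerate(V.feature_ids)}
    shared = [f for f in W.feature_ids if f in vpos]
    if not shared:
        raise ValueError("no shared features between mixtures and reference")
    Vs = V.select_features(shared)
    Vi, n_imputed = impute_missing(Vs, W)
    return nnls_deconvolve(Vi, W, normalize=normalize), n_imputed


def aggregate_proportions(
    H: ProportionMatrix, group_map: dict[str, str]
) -> ProportionMatrix:
    """Sum granular cell-type rows into broader groups (column totals kept).

    Example: neutrophils + eosinophils + basophils -> granulocytes.  Every
    cell type must be mapped; groups appear in order of first member.
    """
    unmapped = [t for t in H.cell_types if t not in group_map]
    if unmapped:
        raise KeyError(f"cell type(s) without a group: {unmapped}")
    groups: list[str] = []
    for t in H.cell_types:
        g = group_map[t]
        if g not in groups:
            groups.append(g)
    G = np.zeros((len(groups), len(H.sample_ids)))
    gpos = {g: i for i, g in enumerate(groups)}
    for i, t in enumerate(H.cell_types):
        G[gpos[group_map[t]]] += H.values[i]
    return ProportionMatrix(G, groups, list(H.sample_ids), normalized=H.normalized)


# -- plumbing ----------------------------------------------------------------

def write_reference(W: ReferenceMatrix, path) -> None:
    W.to_frame().to_csv(path, float_format="%.12g")


def read_reference(path, source: str = "cpg_means") -> ReferenceMatrix:
    df = pd.read_csv(path, index_col=0)
    return ReferenceMatrix(
        df.to_numpy(float),
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        source=source,
    )


def write_proportions(H: ProportionMatrix, path) -> None:
    H.to_frame().to_csv(path, float_format="%.12g")


def read_proportions(path, normalized: bool = False) -> ProportionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ProportionMatrix(
        df.to_numpy(float),
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        normalized=normalized,
    )
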