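"""One-CpG signature selection.

The selector scores each CpG site for a target cell type by the difference of
group means Delta_i = mu_i^cell - mu_i^others and the sum of group variances
sigma_i = var_i^cell + var_i^others, combined into

    a_i = sigma_i / Delta_i^b        (b even, default 2; smaller is better)

Sites in the lowest quantile of a (default 0.5%) are "active".  A stratified
K-fold cross-validation then records, per site, in how many folds it was
active (f_i) and its single-feature AUPR on the fold-train and fold-validation
portions.  The final combined score

    C_i = (alpha1 * a~_i + alpha2 * AUPR_t,i + alpha2 * AUPR_v,i) * f_i / k

uses a~, the min-max-normalized and direction-flipped a (so larger is
uniformly better), and ranks sites descending; the top n_sigs sites form the
signature.  A brute-force baseline (rank every site by test AUPR) and an
unsupervised pre-filter for high-dimension-intolerant models are included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data_model import LabelVector, MethylMatrix, Signature, SignatureEntry

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureStats",
    "CVResult",
    "SelectionConfig",
    "group_stats",
    "selection_score",
    "preselect_active",
    "feature_aupr",
    "average_precision",
    "cross_validate",
    "combine_and_rank",
    "train_signature",
    "train_all_targets",
    "brute_force_select",
    "prefilter_features",
]


@dataclass
class SelectionConfig:
    """Tuning knobs of the selector.

    b : even non-negative exponent on Delta in the selection score (2).
    quantile_p : fraction of sites pre-selected as active per fold (0.005).
    k : number of CV folds (10; reduced to the target-class size when smaller).
    alpha1, alpha2 : weights of the normalized selection score and of each
        AUPR term in the combined score (0.8 / 0.2).
    n_sigs : signature size per target (1).
    """

    b: int = 2
    quantile_p: float = 0.005
    k: int = 10
    alpha1: float = 0.8
    alpha2: float = 0.2
    n_sigs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b < 0 or self.b % 2 != 0:
            raise ValueError(f"b must be an even non-negative integer, got {self.b}")
        if not 0 < self.quantile_p <= 1:
            raise ValueError("quantile_p must be in (0, 1]")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("alpha weights must be non-negative")
        if self.n_sigs < 1:
            raise ValueError("n_sigs must be at least 1")


@dataclass
class FeatureStats:
    """Per-feature two-group statistics for one target cell type."""

    feature_ids: list[str]
    delta: np.ndarray  # mu_target - mu_others
    sigma: np.ndarray  # var_target + var_others
    mu_target: np.ndarray
    mu_others: np.ndarray
    var_target: np.ndarray
    var_others: np.ndarray
    n_excluded_missing: int = 0


@dataclass
class FoldRecord:
    fold: int
    active_ids: list[str]
    aupr_train: dict[str, float]
    aupr_valid: dict[str, float]
    valid_skipped: bool = False
    valid_sample_ids: list[str] = field(default_factory=list)


@dataclass
class CVResult:
    """Aggregated cross-validation outcome for features active in >= 1 fold."""

    feature_ids: list[str]
    fold_activity: np.ndarray  # f_i, integer counts in [0, k]
    aupr_train_mean: np.ndarray
    aupr_valid_mean: np.ndarray
    k: int
    folds: list[FoldRecord] = field(default_factory=list)


def group_stats(X: MethylMatrix, y: np.ndarray) -> FeatureStats:
    """Two-group means/variances per feature for binary labels ``y``.

    Variances are unbiased (n-1 denominator).  Features with any missing
    value among the used samples are excluded (a count is logged): selection
    works on observed data only.
    """
    y = np.asarray(y, dtype=int)
    if y.shape != (X.n_samples,):
        raise ValueError("label vector length does not match sample count")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int((1 - y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"each group needs >= 2 samples (target={n_pos}, others={n_neg})"
        )
    complete = ~np.isnan(X.values).any(axis=1)
    n_excl = int((~complete).sum())
    if n_excl:
        logger.warning("excluding %d features with missing values", n_excl)
    V = X.values[complete]
    ids = [f for f, keep in zip(X.feature_ids, complete) if keep]
    if not ids:
        raise ValueError("no complete features available")
    pos = y == 1
    mu_t = V[:, pos].mean(axis=1)
    mu_o = V[:, ~pos].mean(axis=1)
    var_t = V[:, pos].var(axis=1, ddof=1)
    var_o = V[:, ~pos].var(axis=1, ddof=1)
    return FeatureStats(
        feature_ids=ids,
        delta=mu_t - mu_o,
        sigma=var_t + var_o,
        mu_target=mu_t,
        mu_others=mu_o,
        var_target=var_t,
        var_others=var_o,
        n_excluded_missing=n_excl,
    )


def selection_score(stats: FeatureStats, b: int = 2) -> np.ndarray:
    """a_i = sigma_i / Delta_i^b; Delta = 0 yields +inf (never selected)."""
    if b < 0 or b % 2 != 0:
        raise ValueError(f"b must be an even non-negative integer, got {b}")
    with np.errstate(divide="ignore", invalid="ignore"):
        a = stats.sigma / stats.delta**b
    a = np.where(stats.delta == 0, np.inf, a)
    # sigma = 0 with Delta != 0 is a perfect separator: best possible score
    return np.where(np.isnan(a), 0.0, a)


def preselect_active(
    scores: np.ndarray, feature_ids: list[str], quantile_p: float = 0.005
) -> list[str]:
    """Features whose score falls at or below the quantile_p threshold.

    The threshold Q(quantile_p) is computed over finite scores only; ties at
    the threshold are all kept, +inf scores never.  At least one feature is
    always returned.
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("no discriminative features: all selection scores infinite")
    thr = np.quantile(scores[finite], quantile_p)
    keep = finite & (scores <= thr)
    if not keep.any():  # degenerate tiny quantile
        keep[np.nanargmin(np.where(finite, scores, np.inf))] = True
    return [f for f, k in zip(feature_ids, keep) if k]


def average_precision(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the precision-recall curve as average precision.

    Higher score means more positive.  Ties are grouped into a single
    threshold step: every positive in a tie group contributes the precision
    evaluated at the end of the group.  For a constant score this reduces to
    the class prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = y[order]
    # group boundaries: last index of each distinct score value
    boundary = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    cum_pos = np.cumsum(t)[boundary]
    cum_n = boundary + 1
    pos_in_group = np.diff(np.concatenate(([0], cum_pos)))
    precision = cum_pos / cum_n
    return float((pos_in_group * precision).sum() / n_pos)


def feature_aupr(
    x: np.ndarray, y: np.ndarray, direction: str = "auto"
) -> float:
    """AUPR of a single feature used as a one-variable classifier.

    ``direction="hyper"`` ranks by x (target high), ``"hypo"`` by -x, and
    ``"auto"`` takes the better of the two orientations (which coincides with
    the sign of the mean difference on any feature worth selecting).
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature has missing values")
    if direction == "hyper":
        return average_precision(x, y)
    if direction == "hypo":
        return average_precision(-x, y)
    if direction == "auto":
        return max(average_precision(x, y), average_precision(-x, y))
    raise ValueError(f"unknown direction {direction!r}")


def _stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros_like(y), y)]


def cross_validate(
    X: MethylMatrix, y: np.ndarray, cfg: SelectionConfig
) -> CVResult:
    """Stratified K-fold CV recording per-feature activity and AUPRs.

    In each fold the pre-selection (group stats -> selection score -> active
    quantile) is recomputed on the fold-train portion; active features get
    their fold-train and fold-validation AUPR.  k drops to the target-class
    size when that is below cfg.k.  Folds whose validation part contains no
    positive sample contribute no validation AUPR (warned, not counted).
    """
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    if n_pos < 2:
        raise ValueError("need at least 2 target-class samples for CV")
    k = min(cfg.k, n_pos)
    folds = _stratified_folds(y, k, cfg.seed)

    activity: dict[str, int] = {}
    sum_t: dict[str, float] = {}
    sum_v: dict[str, float] = {}
    cnt_v: dict[str, int] = {}
    records: list[FoldRecord] = []

    for fold_no, (tr, va) in enumerate(folds):
        Xtr = MethylMatrix(
            X.values[:, tr],
            X.feature_ids,
            [X.sample_ids[j] for j in tr],
            X.scale,
        )
        stats = group_stats(Xtr, y[tr])
        a = selection_score(stats, cfg.b)
        active = preselect_active(a, stats.feature_ids, cfg.quantile_p)
        delta_of = dict(zip(stats.feature_ids, stats.delta))
        fpos = {f: i for i, f in enumerate(X.feature_ids)}

        valid_has_pos = bool(y[va].sum())
        if not valid_has_pos:
            warnings.warn(
                f"fold {fold_no}: no positive validation samples; "
                "validation AUPR skipped",
                stacklevel=2,
            )
        rec_t: dict[str, float] = {}
        rec_v: dict[str, float] = {}
        for f in active:
            row = X.values[fpos[f]]
            direction = "hyper" if delta_of[f] > 0 else "hypo"
            au_t = feature_aupr(row[tr], y[tr], direction)
            rec_t[f] = au_t
            activity[f] = activity.get(f, 0) + 1
            sum_t[f] = sum_t.get(f, 0.0) + au_t
            if valid_has_pos:
                au_v = feature_aupr(row[va], y[va], direction)
                rec_v[f] = au_v
                sum_v[f] = sum_v.get(f, 0.0) + au_v
                cnt_v[f] = cnt_v.get(f, 0) + 1
        records.append(
            FoldRecord(
                fold_no,
                active,
                rec_t,
                rec_v,
                valid_skipped=not valid_has_pos,
                valid_sample_ids=[X.sample_ids[j] for j in va],
            )
        )

    ids = sorted(activity)
    f_i = np.array([activity[f] for f in ids], dtype=int)
    au_t = np.array([sum_t[f] / activity[f] for f in ids])
    au_v = np.array(
        [sum_v.get(f, 0.0) / cnt_v[f] if cnt_v.get(f) else np.nan for f in ids]
    )
    return CVResult(ids, f_i, au_t, au_v, k=k, folds=records)


def combine_and_rank(
    cv: CVResult, stats: FeatureStats, cfg: SelectionConfig, target: str = ""
) -> Signature:
    """Combined score and final ranking over features active in >= 1 fold.

    The raw selection score a (smaller better, possibly infinite) is mapped
    to a~ = 1 - minmax(a) over the active set so a~ lies in [0, 1] with
    larger better; infinite a maps to 0.  The combined score is
    C = (alpha1*a~ + alpha2*AUPR_t + alpha2*AUPR_v) * f/k, ranked descending
    with ties broken by higher validation AUPR, then feature id.
    """
    if not cv.feature_ids:
        raise ValueError("cross-validation produced no active features")
    pos = {f: i for i, f in enumerate(stats.feature_ids)}
    missing = [f for f in cv.feature_ids if f not in pos]
    if missing:
        raise ValueError(f"active features absent from stats: {missing[:5]}")
    idx = np.array([pos[f] for f in cv.feature_ids])
    a = selection_score(stats, cfg.b)[idx]

    finite = np.isfinite(a)
    a_tilde = np.zeros_like(a)
    if finite.any():
        lo, hi = a[finite].min(), a[finite].max()
        if hi > lo:
            a_tilde[finite] = 1.0 - (a[finite] - lo) / (hi - lo)
        else:
            a_tilde[finite] = 1.0
    au_v = np.where(np.isnan(cv.aupr_valid_mean), 0.0, cv.aupr_valid_mean)
    C = (
        cfg.alpha1 * a_tilde
        + cfg.alpha2 * cv.aupr_train_mean
        + cfg.alpha2 * au_v
    ) * (cv.fold_activity / cv.k)

    tab = pd.DataFrame(
        {
            "feature_id": cv.feature_ids,
            "C": C,
            "aupr_train": cv.aupr_train_mean,
            "aupr_valid": au_v,
            "f": cv.fold_activity,
            "a": a,
        }
    ).sort_values(
        ["C", "aupr_valid", "feature_id"], ascending=[False, False, True]
    )

    entries = []
    for r in tab.head(cfg.n_sigs).itertuples():
        i = pos[r.feature_id]
        entries.append(
            SignatureEntry(
                feature_id=r.feature_id,
                direction="hyper" if stats.delta[i] > 0 else "hypo",
                score_c=float(r.C),
                aupr_train=float(r.aupr_train),
                aupr_valid=float(r.aupr_valid),
                fold_activity=int(r.f),
                selection_a=float(r.a),
                ref_mean_target=float(stats.mu_target[i]),
                ref_mean_others=float(stats.mu_others[i]),
            )
        )
    return Signature(target=target, entries=entries, n_sigs=cfg.n_sigs)


def train_signature(
    X: MethylMatrix,
    labels: LabelVector,
    target: str,
    cfg: SelectionConfig | None = None,
) -> Signature:
    """Full selection for one target: stats + CV + combined ranking."""
    cfg = cfg or SelectionConfig()
    if list(labels.sample_ids) != list(X.sample_ids):
        labels = labels.for_samples(X.sample_ids)
    y = labels.binarize(target)
    stats = group_stats(X, y)
    cv = cross_validate(X, y, cfg)
    return combine_and_rank(cv, stats, cfg, target=target)


def train_all_targets(
    X: MethylMatrix, labels: LabelVector, cfg: SelectionConfig | None = None
) -> dict[str, Signature]:
    """One signature per cell type present in the labels."""
    cfg = cfg or SelectionConfig()
    return {
        t: train_signature(X, labels, t, cfg) for t in sorted(set(labels.labels))
    }


def brute_force_select(
    X_train: MethylMatrix,
    y_train: np.ndarray,
    X_test: MethylMatrix,
    y_test: np.ndarray,
) -> pd.DataFrame:
    """Rank every feature by its test-set AUPR (direction auto).

    The exhaustive baseline: no pre-selection, no CV.  Returns a DataFrame
    with columns feature_id, aupr_train, aupr_test sorted by test AUPR
    descending (ties by train AUPR, then feature id).
    """
    if X_train.feature_ids != X_test.feature_ids:
        raise ValueError("train and test matrices must share features")
    for y, name in ((y_train, "train"), (y_test, "test")):
        if len(set(np.asarray(y, int))) < 2:
            raise ValueError(f"{name} labels contain a single class")
    rows = []
    for i, f in enumerate(X_train.feature_ids):
        rows.append(
            {
                "feature_id": f,
                "aupr_train": feature_aupr(X_train.values[i], y_train, "auto"),
                "aupr_test": feature_aupr(X_test.values[i], y_test, "auto"),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(
            ["aupr_test", "aupr_train", "feature_id"],
            ascending=[False, False, True],
        )
        .reset_index(drop=True)
    )


def prefilter_features(
    X: MethylMatrix,
    variance_thresh: float = 1e-8,
    corr_thresh: float = 0.9,
) -> list[str]:
    """Unsupervised filter for models that cannot cope with p >> n.

    Drops (1) near-constant features (variance below ``variance_thresh``),
    (2) one of each highly correlated pair (|Pearson r| > ``corr_thresh``,
    keeping the higher-variance member), and (3) exact linear combinations of
    surviving features, detected by sequential orthogonalization.  Returns
    surviving feature ids in original order.
    """
    if X.n_samples < 3:
        raise ValueError("pre-filter needs at least 3 samples")
    V = X.values
    var = np.nanvar(V, axis=1, ddof=1)
    alive = var > variance_thresh

    # correlation pass: scan in decreasing variance so the larger-variance
    # member of each offending pair is the one kept
    idx_by_var = np.argsort(-var, kind="stable")
    kept: list[int] = []
    for i in idx_by_var:
        if not alive[i]:
            continue
        xi = V[i]
        drop = False
        for j in kept:
            r = np.corrcoef(xi, V[j])[0, 1]
            if abs(r) > corr_thresh:
                drop = True
                break
        if drop:
            alive[i] = False
        else:
            kept.append(i)

    # linear-combination pass: sequential Gram-Schmidt in original order
    basis: list[np.ndarray] = []
    for i in range(X.n_features):
        if not alive[i]:
            continue
        v = V[i].astype(float)
        r = v.copy()
        for q in basis:
            r -= (q @ r) * q
        if np.linalg.norm(r) <= 1e-8 * max(np.linalg.norm(v), 1.0):
            alive[i] = False
        else:
            basis.append(r / np.linalg.norm(r))

    return [f for f, a in zip(X.feature_ids, alive) if a]
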