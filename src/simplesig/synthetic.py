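"""Synthetic purified-cell methylation data and artificial mixtures.

The generator emulates the structure of purified-cell-type reference panels
measured on Illumina-style arrays: for each cell type a few planted marker
CpGs are strongly methylated in that type and weakly elsewhere (hyper
markers) or the reverse (hypo markers), on top of thousands of background
CpGs whose mean methylation is shared across types.  Per-sample values are
drawn from Beta distributions parameterized by (mean, concentration):
alpha = mean * conc, beta = (1 - mean) * conc, so group means and spreads are
directly controllable.  Mixtures are convex combinations of the per-type mean
profiles with Dirichlet-distributed proportions plus additive Gaussian noise,
clipped back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .data_model import LabelVector, MethylMatrix, SampleSheet
from .deconvolution import ProportionMatrix, ReferenceMatrix

__all__ = [
    "SimulationConfig",
    "simulate_purified",
    "simulate_mixtures",
    "inject_missing",
    "type_profiles",
    "assign_split",
]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give 6 cell types with 3 markers each over 5000 background CpGs,
    20 purified samples per type, marker means 0.85/0.10, Beta concentration
    50 (sd ~ 0.05 at the marker means), and 20 mixtures with flat Dirichlet
    proportions and additive noise sd 0.01.
    """

    n_cell_types: int = 6
    n_markers_per_type: int = 3
    n_background: int = 5000
    samples_per_type: int = 20
    marker_high: float = 0.85
    marker_low: float = 0.10
    beta_concentration: float = 50.0
    n_mixtures: int = 20
    dirichlet_alpha: float = 1.0
    noise_sd: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cell_types",
            "n_markers_per_type",
            "n_background",
            "samples_per_type",
            "n_mixtures",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("marker_high", "marker_low"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def cell_types(self) -> list[str]:
        return [f"ct{t + 1}" for t in range(self.n_cell_types)]


def _beta_draw(rng: np.random.Generator, mean, conc: float, size) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def simulate_purified(
    cfg: SimulationConfig,
) -> tuple[MethylMatrix, LabelVector, dict[str, list[tuple[str, str]]]]:
    """Purified-cell beta matrix with planted markers.

    Returns the matrix (markers first, then background), the cell-type
    labels, and the ground-truth marker map ``{cell_type: [(feature_id,
    direction), ...]}`` where direction is "hyper" (high in its own type) or
    "hypo".  Half of each type's markers (odd indices) are hypo-methylated to
    exercise direction handling.  Deterministic for a given seed.
    """
    if abs(cfg.marker_high - cfg.marker_low) < 0.2:
        warnings.warn(
            "marker means are close (|high - low| < 0.2); "
            "recovery tests will be unreliable",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    types = cfg.cell_types
    n_marker = cfg.n_cell_types * cfg.n_markers_per_type
    p = n_marker + cfg.n_background
    n = cfg.n_cell_types * cfg.samples_per_type
    feature_ids = [f"cg{i + 1:08d}" for i in range(p)]
    sample_ids = [
        f"{t}_s{j + 1}" for t in types for j in range(cfg.samples_per_type)
    ]
    labels = np.repeat(types, cfg.samples_per_type)

    V = np.empty((p, n))
    marker_map: dict[str, list[tuple[str, str]]] = {t: [] for t in types}
    row = 0
    for t_idx, t in enumerate(types):
        in_type = labels == t
        for m in range(cfg.n_markers_per_type):
            direction = "hyper" if m % 2 == 0 else "hypo"
            hi, lo = (
                (cfg.marker_high, cfg.marker_low)
                if direction == "hyper"
                else (cfg.marker_low, cfg.marker_high)
            )
            vals = np.empty(n)
            vals[in_type] = _beta_draw(
                rng, hi, cfg.beta_concentration, int(in_type.sum())
            )
            vals[~in_type] = _beta_draw(
                rng, lo, cfg.beta_concentration, int((~in_type).sum())
            )
            V[row] = vals
            marker_map[t].append((feature_ids[row], direction))
            row += 1
    # background: one mean per feature, shared by every cell type
    bg_means = rng.uniform(0.2, 0.8, size=cfg.n_background)
    V[row:] = _beta_draw(
        rng, bg_means[:, None], cfg.beta_concentration, (cfg.n_background, n)
    )

    X = MethylMatrix(np.clip(V, 0.0, 1.0), feature_ids, sample_ids, scale="beta")
    lv = LabelVector(sample_ids, dict(zip(sample_ids, (str(t) for t in labels))))
    return X, lv, marker_map


def type_profiles(X: MethylMatrix, labels: LabelVector) -> ReferenceMatrix:
    """Per-cell-type mean profile over all features (the true W at full size)."""
    if list(labels.sample_ids) != list(X.sample_ids):
        labels = labels.for_samples(X.sample_ids)
    lab = np.array(labels.labels)
    types = labels.cell_types
    W = np.column_stack(
        [np.nanmean(X.values[:, lab == t], axis=1) for t in types]
    )
    return ReferenceMatrix(
        np.clip(W, 0.0, 1.0), list(X.feature_ids), types, source="cpg_means"
    )


def simulate_mixtures(
    profiles: ReferenceMatrix, cfg: SimulationConfig, seed: int | None = None
) -> tuple[MethylMatrix, ProportionMatrix]:
    """Mixtures V = profiles . H + noise with known Dirichlet proportions.

    H columns are drawn from Dirichlet(dirichlet_alpha) over the profile's
    cell types (each column sums to 1 exactly); i.i.d. Gaussian noise with sd
    ``noise_sd`` is added to V, which is then clipped to [0, 1].
    """
    if np.nanmin(profiles.values) < 0 or np.nanmax(profiles.values) > 1:
        raise ValueError("profiles must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    c = len(profiles.cell_types)
    alpha = np.full(c, cfg.dirichlet_alpha)
    H = rng.dirichlet(alpha, size=cfg.n_mixtures).T  # c x s
    V = profiles.values @ H
    if cfg.noise_sd > 0:
        V = V + rng.normal(0.0, cfg.noise_sd, size=V.shape)
    V = np.clip(V, 0.0, 1.0)
    sample_ids = [f"mix{j + 1}" for j in range(cfg.n_mixtures)]
    Vm = MethylMatrix(V, list(profiles.feature_ids), sample_ids, scale="beta")
    Hm = ProportionMatrix(H, list(profiles.cell_types), sample_ids, normalized=True)
    return Vm, Hm


def inject_missing(X: MethylMatrix, rate: float, seed: int = 0) -> MethylMatrix:
    """Set each cell missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return X
    rng = np.random.default_rng(seed)
    mask = rng.random(X.values.shape) < rate
    vals = X.values.copy()
    vals[mask] = np.nan
    return MethylMatrix(vals, X.feature_ids, X.sample_ids, X.scale)


def assign_split(
    labels: LabelVector, test_fraction: float = 0.25, seed: int = 0
) -> SampleSheet:
    """Random per-cell-type train/test assignment as a sample sheet.

    Each cell type contributes ceil(test_fraction * group size) test samples,
    so both splits retain every type whenever group sizes allow.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lab = np.array(labels.labels)
    split = np.full(len(lab), "train", dtype=object)
    for t in labels.cell_types:
        idx = np.nonzero(lab == t)[0]
        n_test = int(np.ceil(test_fraction * len(idx)))
        if n_test >= len(idx):
            n_test = len(idx) - 1
        test_idx = rng.choice(idx, size=n_test, replace=False)
        split[test_idx] = "test"
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": labels.sample_ids,
                "cell_type": lab,
                "split": split,
            }
        )
    )
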