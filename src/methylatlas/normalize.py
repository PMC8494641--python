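"""Beta-binomial posterior normalization, HVF selection and dimensionality reduction.

Each cell's raw per-feature methylation levels (mc/cov) in one context are
modelled as draws from a Beta(α, β) prior whose shape is estimated per cell
by the method of moments:

    α = m (m(1−m)/v − 1),   β = (1−m) (m(1−m)/v − 1)

with m and v the sample mean and variance of the raw levels.  The posterior
level of a feature is (α + mc)/(α + β + cov), which is then divided by the
cell's prior mean m = α/(α+β).  Features with zero coverage therefore get
exactly 1 — the matrix has no missing values and low-coverage features
shrink toward 1, removing the global-methylation confound between cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import MethylCountMatrix

__all__ = [
    "BetaPrior",
    "EmbeddingPCs",
    "HvfSelection",
    "NormalizedMethylMatrix",
    "estimate_beta_prior",
    "estimate_priors",
    "posterior_normalize",
    "reduce_dimensions",
    "select_hvf",
]

_MEAN_CLIP = 1e-4
_FALLBACK_STRENGTH = 100.0


@dataclass(frozen=True)
class BetaPrior:
    """Method-of-moments beta prior for one cell and context."""

    alpha: float
    beta: float
    sample_mean: float
    sample_var: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def strength(self) -> float:
        return self.alpha + self.beta


def estimate_beta_prior(
    raw_levels: np.ndarray, mean_cov: float | None = None
) -> BetaPrior:
    """Fit Beta(α, β) by method of moments to one cell's raw levels.

    ``raw_levels`` are per-feature mc/cov values; NaNs (cov = 0 features)
    are ignored.  By default the sample variance of the raw levels is used
    directly, which deliberately yields weaker priors for noisier cells.
    With ``mean_cov`` given, the binomial sampling component is subtracted
    first (v_p = (v − m(1−m)/c̄)/(1 − 1/c̄)), the classical beta-binomial
    moment estimator — use this to recover latent beta shapes from count
    data.  Degenerate cases — near-zero variance, or variance too large for
    a proper beta (m(1−m)/v ≤ 1) — fall back to a weak prior with the same
    mean and fixed strength α+β = 100.
    """
    levels = np.asarray(raw_levels, dtype=float)
    levels = levels[~np.isnan(levels)]
    if levels.size < 2:
        raise ValueError("need >= 2 covered features to estimate a beta prior")
    m = float(np.clip(levels.mean(), _MEAN_CLIP, 1 - _MEAN_CLIP))
    v = float(levels.var(ddof=0))
    if mean_cov is not None and mean_cov > 1:
        v = max((v - m * (1 - m) / mean_cov) / (1 - 1 / mean_cov), 0.0)
    if v <= 1e-12 or (m * (1 - m) / v - 1) <= 0:
        return BetaPrior(
            alpha=m * _FALLBACK_STRENGTH,
            beta=(1 - m) * _FALLBACK_STRENGTH,
            sample_mean=m,
            sample_var=v,
        )
    common = m * (1 - m) / v - 1
    return BetaPrior(alpha=m * common, beta=(1 - m) * common, sample_mean=m, sample_var=v)


def estimate_priors(counts: MethylCountMatrix, context: str) -> list[BetaPrior]:
    """Per-cell beta priors for one context class."""
    levels = counts.raw_levels(context)
    return [estimate_beta_prior(levels[i]) for i in range(counts.n_cells)]


@dataclass
class NormalizedMethylMatrix:
    """Cells × features normalized posterior methylation levels (no NaNs)."""

    values: np.ndarray
    context: str
    priors: list[BetaPrior]
    feature_names: list[str] | None = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def posterior_normalize(
    counts: MethylCountMatrix,
    priors: Sequence[BetaPrior] | None = None,
    context: str = "CH",
) -> NormalizedMethylMatrix:
    """Posterior methylation level divided by the cell's prior mean.

    Entries with cov = 0 are exactly 1 (the posterior equals the prior).
    """
    if priors is None:
        priors = estimate_priors(counts, context)
    if len(priors) != counts.n_cells:
        raise ValueError("one prior per cell required")
    mc = counts.mc[context].astype(float)
    cov = counts.cov[context].astype(float)
    alpha = np.array([p.alpha for p in priors])[:, None]
    beta = np.array([p.beta for p in priors])[:, None]
    post = (alpha + mc) / (alpha + beta + cov)
    norm = post / (alpha / (alpha + beta))
    norm[cov == 0] = 1.0
    return NormalizedMethylMatrix(
        values=norm,
        context=context,
        priors=list(priors),
        feature_names=list(counts.features["name"]) if "name" in counts.features else None,
    )


# ---------------------------------------------------------------------------
# highly variable features
# ---------------------------------------------------------------------------

@dataclass
class HvfSelection:
    table: pd.DataFrame  # mean, mean_cov, dispersion, dispersion_norm, selected
    n: int

    @property
    def mask(self) -> np.ndarray:
        return self.table["selected"].to_numpy()


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = pd.Series(x).rank(method="first")
    return pd.qcut(ranks, min(n_bins, len(x)), labels=False, duplicates="drop")


def select_hvf(
    norm: NormalizedMethylMatrix,
    counts: MethylCountMatrix,
    n: int = 3000,
    mean_bins: int = 20,
    cov_bins: int = 5,
) -> HvfSelection:
    """Select the top-``n`` features by mean/coverage-binned normalized dispersion.

    Both the mean methylation level and the mean coverage of a feature
    affect its dispersion, so features are grouped into a 2-D quantile grid
    of (mean normalized level, mean coverage) and the dispersion (variance
    of normalized levels) is z-scored within each group.  Groups with fewer
    than two members use the global dispersion scale instead.
    """
    values = norm.values
    mean = values.mean(axis=0)
    disp = values.var(axis=0)
    mean_cov = counts.cov[norm.context].mean(axis=0)
    mb = _quantile_bins(mean, mean_bins)
    cb = _quantile_bins(mean_cov, cov_bins)
    group = mb * (np.max(cb) + 1) + cb
    df = pd.DataFrame(
        {"mean": mean, "mean_cov": mean_cov, "dispersion": disp, "group": group}
    )
    global_std = disp.std() or 1.0
    global_mean = disp.mean()

    def _znorm(g: pd.Series) -> pd.Series:
        if len(g) < 2 or g.std() == 0:
            return (g - global_mean) / global_std
        return (g - g.mean()) / g.std()

    df["dispersion_norm"] = df.groupby("group")["dispersion"].transform(_znorm)
    n_sel = min(n, len(df))
    order = df.sort_values(
        ["dispersion_norm", "dispersion"], ascending=False, kind="mergesort"
    ).index[:n_sel]
    selected = np.zeros(len(df), dtype=bool)
    selected[order] = True
    df["selected"] = selected
    if norm.feature_names is not None:
        df.index = pd.Index(norm.feature_names, name="feature")
    return HvfSelection(table=df, n=n_sel)


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingPCs:
    """Concatenated per-context principal components (CH first, then CG)."""

    pcs: np.ndarray
    variance_ratio: dict[str, np.ndarray]
    n_pcs: dict[str, int]


def _scale(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def reduce_dimensions(
    norm_ch: NormalizedMethylMatrix | None,
    norm_cg: NormalizedMethylMatrix | None = None,
    hvf_ch: np.ndarray | None = None,
    hvf_cg: np.ndarray | None = None,
    n_pcs: int = 32,
    random_state: int = 0,
) -> EmbeddingPCs:
    """Scale HVF-masked matrices per context, run PCA, concatenate (CH, CG).

    The variance ratios are reported so the number of components can be
    chosen by elbow inspection; ``n_pcs`` is truncated to the matrix rank.
    """
    blocks, ratios, n_used = [], {}, {}
    for name, norm, mask in (("CH", norm_ch, hvf_ch), ("CG", norm_cg, hvf_cg)):
        if norm is None:
            continue
        x = norm.values if mask is None else norm.values[:, np.asarray(mask)]
        x = _scale(x)
        k = min(n_pcs, min(x.shape) - 1)
        if k < 1:
            raise ValueError(f"context {name}: not enough data for PCA")
        pca = PCA(n_components=k, svd_solver="full", random_state=random_state)
        blocks.append(pca.fit_transform(x))
        ratios[name] = pca.explained_variance_ratio_
        n_used[name] = k
    if not blocks:
        raise ValueError("at least one context matrix required")
    return EmbeddingPCs(pcs=np.hstack(blocks), variance_ratio=ratios, n_pcs=n_used)
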