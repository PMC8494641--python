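"""Chromatin-contact summaries: binning, balancing, insulation, saddle, embedding.

Implements the single-cell 3C statistics used alongside the methylome:
contact binning from pair tables, Knight–Ruiz-style matrix balancing,
per-distance observed/expected, the insulation score

    I_i = mean(A[i−w:i, i:i+w]) / max(mean(A[i−w:i, i−w:i]), mean(A[i:i+w, i:i+w]))

on observed/expected matrices, compartment saddle strength (corner ratio of
the 50×50 saddle ordered by the compartment score), distance–decay curves,
intra-domain contact fractions, and a smoothing + random-walk-with-restart
cell embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from sklearn.decomposition import PCA

__all__ = [
    "ContactMap",
    "InsulationProfile",
    "SaddleResult",
    "bin_contacts",
    "boundary_insulation",
    "compartment_strength",
    "contact_decay",
    "decay_slope",
    "insulation_profile",
    "intra_domain_fraction",
    "kr_balance",
    "loop_support",
    "observed_expected",
    "schicluster_embed",
]


@dataclass
class ContactMap:
    """Symmetric binned intra-chromosomal contact matrix."""

    chrom: str
    resolution: int
    matrix: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.matrix < 0):
            raise ValueError("contact matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def bin_contacts(
    pairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    resolution: int,
    min_separation: int | None = 1000,
) -> dict[str, ContactMap]:
    """Bin a (chrom1, pos1, chrom2, pos2) pair table into per-chromosome maps.

    Only intra-chromosomal pairs are kept; pairs closer than
    ``min_separation`` bp (self-ligation artefacts) are dropped when the
    filter is on.  Out-of-bounds coordinates are rejected with a count.
    """
    maps = {}
    n_rejected = 0
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / resolution))
        maps[chrom] = np.zeros((n_bins, n_bins))
    c1 = pairs.iloc[:, 0].to_numpy()
    p1 = pairs.iloc[:, 1].to_numpy(dtype=np.int64)
    c2 = pairs.iloc[:, 2].to_numpy()
    p2 = pairs.iloc[:, 3].to_numpy(dtype=np.int64)
    intra = c1 == c2
    if min_separation is not None:
        intra &= np.abs(p1 - p2) >= min_separation
    for chrom in maps:
        sel = intra & (c1 == chrom)
        size = chrom_sizes[chrom]
        ok = (p1[sel] >= 0) & (p1[sel] < size) & (p2[sel] >= 0) & (p2[sel] < size)
        n_rejected += int(np.sum(~ok))
        lo = np.minimum(p1[sel][ok], p2[sel][ok]) // resolution
        hi = np.maximum(p1[sel][ok], p2[sel][ok]) // resolution
        np.add.at(maps[chrom], (lo, hi), 1)  # upper triangle incl. diagonal
    out = {}
    for chrom, m in maps.items():
        full = np.triu(m, 1) + np.triu(m, 1).T + np.diag(np.diag(m))
        out[chrom] = ContactMap(chrom=chrom, resolution=resolution, matrix=full)
    if n_rejected:
        warnings.warn(f"{n_rejected} pairs beyond chromosome bounds rejected")
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def kr_balance(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 3000
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric matrix balancing to unit row sums (Knight–Ruiz style).

    Alternating row/column scaling on the non-empty submatrix; returns the
    balanced matrix and the scaling vector (NaN on empty bins).  Rows that
    are all-zero are masked out rather than failing.
    """
    a = np.asarray(matrix, dtype=float)
    mask = a.sum(axis=0) > 0
    sub = a[np.ix_(mask, mask)]
    x = np.ones(sub.shape[0])
    converged = False
    for _ in range(max_iter):
        rs = x * (sub @ x)  # row sums of diag(x) A diag(x)
        if np.max(np.abs(rs - 1)) < tol:
            converged = True
            break
        x = x / np.sqrt(rs)
    if not converged:
        warnings.warn("balancing did not reach tolerance; returning best iterate")
    balanced = sub * np.outer(x, x)
    out = np.full_like(a, np.nan)
    out[np.ix_(mask, mask)] = balanced
    scale = np.full(a.shape[0], np.nan)
    scale[mask] = x
    return out, scale


def observed_expected(matrix: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its (nan-aware) mean contact frequency."""
    n = matrix.shape[0]
    out = np.full_like(matrix, np.nan, dtype=float)
    for d in range(n):
        diag = np.diagonal(matrix, offset=d)
        mu = np.nanmean(diag) if np.any(~np.isnan(diag)) else np.nan
        if not np.isfinite(mu) or mu == 0:
            continue
        idx = np.arange(n - d)
        out[idx, idx + d] = diag / mu
        out[idx + d, idx] = diag / mu
    return out


# ---------------------------------------------------------------------------
# insulation
# ---------------------------------------------------------------------------

@dataclass
class InsulationProfile:
    scores: np.ndarray
    window: int


def insulation_profile(ove: np.ndarray, window: int = 10) -> InsulationProfile:
    """Insulation score per bin on an observed/expected matrix.

    I_i = mean of the cross square [i−w, i) × [i, i+w) divided by the max
    of the two within-side square means.  Undefined (NaN) within a window
    of the chromosome ends or where a flank is fully masked.
    """
    n = ove.shape[0]
    w = window
    scores = np.full(n, np.nan)
    for i in range(w, n - w):
        cross = ove[i - w : i, i : i + w]
        left = ove[i - w : i, i - w : i]
        right = ove[i : i + w, i : i + w]
        if np.all(np.isnan(cross)) or (np.all(np.isnan(left)) and np.all(np.isnan(right))):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            denom = np.nanmax([np.nanmean(left), np.nanmean(right)])
        if not np.isfinite(denom) or denom == 0:
            continue
        scores[i] = np.nanmean(cross) / denom
    return InsulationProfile(scores=scores, window=w)


def boundary_insulation(
    profile: InsulationProfile, boundaries: np.ndarray, flank_bins: int = 1
) -> float:
    """Average insulation over boundary bins ± ``flank_bins``."""
    vals = []
    for b in boundaries:
        lo = max(b - flank_bins, 0)
        hi = min(b + flank_bins + 1, profile.scores.size)
        vals.append(np.nanmean(profile.scores[lo:hi]))
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# compartment saddle
# ---------------------------------------------------------------------------

@dataclass
class SaddleResult:
    saddle: np.ndarray
    compartment_score: np.ndarray
    strength: float
    kept_bins: np.ndarray


def compartment_strength(
    matrix: np.ndarray,
    n_categories: int = 50,
    corner: int = 10,
    coverage_band: tuple[float, float] = (-1.0, 2.0),
    reference_track: np.ndarray | None = None,
) -> SaddleResult:
    """Saddle-plot compartment strength of a raw contact matrix.

    Bins whose z-scored coverage falls outside ``coverage_band`` are
    dropped; the matrix is balanced; PC1 of the balanced matrix is the
    compartment score (sign oriented by ``reference_track`` when given —
    the strength is invariant to the sign).  Score ranks are cut into
    ``n_categories`` equal-size categories and the saddle holds the mean
    observed/expected per category pair; strength = mean of the two
    like-with-like corner blocks over the mean of the two cross corners.
    """
    cov = matrix.sum(axis=0)
    z = (cov - cov.mean()) / (cov.std() or 1.0)
    keep = (z >= coverage_band[0]) & (z <= coverage_band[1])
    sub = matrix[np.ix_(keep, keep)]
    balanced, _ = kr_balance(sub)
    balanced = np.nan_to_num(balanced)
    ove_full = np.nan_to_num(observed_expected(balanced), nan=1.0)
    # PC1 of the balanced matrix with the distance decay divided out; the
    # decay otherwise dominates the leading component
    pca = PCA(n_components=1, svd_solver="full")
    score = pca.fit_transform(ove_full - ove_full.mean(axis=0)).ravel()
    if reference_track is not None:
        ref = np.asarray(reference_track, dtype=float)[keep]
        if np.corrcoef(score, ref)[0, 1] < 0:
            score = -score
    ove = ove_full
    order = np.argsort(score, kind="mergesort")
    n = order.size
    cats = np.minimum((np.arange(n) * n_categories) // n, n_categories - 1)
    cat_of = np.empty(n, dtype=int)
    cat_of[order] = cats
    saddle = np.full((n_categories, n_categories), np.nan)
    for i in range(n_categories):
        sel_i = cat_of == i
        for j in range(n_categories):
            block = ove[np.ix_(sel_i, cat_of == j)]
            if block.size:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    saddle[i, j] = np.nanmean(block)
    c = corner
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        like = np.nanmean(np.concatenate([saddle[:c, :c].ravel(), saddle[-c:, -c:].ravel()]))
        cross = np.nanmean(np.concatenate([saddle[:c, -c:].ravel(), saddle[-c:, :c].ravel()]))
    strength = float(like / cross)
    full_score = np.full(matrix.shape[0], np.nan)
    full_score[keep] = score
    return SaddleResult(
        saddle=saddle, compartment_score=full_score, strength=strength, kept_bins=keep
    )


# ---------------------------------------------------------------------------
# decay and domains
# ---------------------------------------------------------------------------

def contact_decay(maps, n_bins: int = 20) -> pd.DataFrame:
    """Normalized mean contact frequency per log-spaced genomic distance bin."""
    if isinstance(maps, ContactMap):
        maps = [maps]
    n = maps[0].n_bins
    res = maps[0].resolution
    dists = np.arange(1, n)
    edges = np.unique(
        np.geomspace(1, n - 1, num=min(n_bins + 1, n)).astype(int)
    )
    total = np.zeros(n - 1)
    for cm in maps:
        for d in dists:
            total[d - 1] += np.mean(np.diagonal(cm.matrix, offset=d))
    total /= len(maps)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = total[lo - 1 : hi - 1]
        if sel.size:
            rows.append(((lo + hi) / 2 * res, sel.mean()))
    df = pd.DataFrame(rows, columns=["distance", "frequency"])
    if df["frequency"].sum() > 0:
        df["frequency"] /= df["frequency"].iloc[0]
    return df


def decay_slope(decay: pd.DataFrame) -> float:
    """Log–log slope of the distance–frequency curve."""
    sel = decay[decay["frequency"] > 0]
    return float(np.polyfit(np.log10(sel["distance"]), np.log10(sel["frequency"]), 1)[0])


def intra_domain_fraction(cell_map: ContactMap, domains) -> float:
    """Fraction of a cell's contacts with both ends inside one domain (bin intervals)."""
    m = cell_map.matrix
    total = np.triu(m).sum()
    if total == 0:
        return 0.0
    intra = 0.0
    for start, end in domains:
        intra += np.triu(m[start:end, start:end]).sum()
    return float(intra / total)


def loop_support(cell_map: ContactMap, anchors: pd.DataFrame, pad_bins: int = 0) -> np.ndarray:
    """Contacts per loop (bin1, bin2 anchor pairs) supporting each loop in a cell."""
    out = np.zeros(len(anchors))
    m = cell_map.matrix
    for i, row in enumerate(anchors.itertuples(index=False)):
        b1, b2 = int(row[0]), int(row[1])
        lo1, hi1 = max(b1 - pad_bins, 0), min(b1 + pad_bins + 1, cell_map.n_bins)
        lo2, hi2 = max(b2 - pad_bins, 0), min(b2 + pad_bins + 1, cell_map.n_bins)
        out[i] = m[lo1:hi1, lo2:hi2].sum()
    return out


# ---------------------------------------------------------------------------
# smoothing-based embedding
# ---------------------------------------------------------------------------

def _smooth_rwr(matrix: np.ndarray, pad: int, restart_p: float, tol: float, max_iter: int):
    """Box convolution then random walk with restart to convergence."""
    size = 2 * pad + 1
    conv = uniform_filter(matrix, size=size, mode="constant") * size * size
    rs = conv.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    m = conv / rs
    # fixed point of Q = p·M + (1−p)·Q·M; at p = 1 this is the convolved map itself
    q = m.copy()
    for _ in range(max_iter):
        q_next = restart_p * m + (1 - restart_p) * q @ m
        if np.max(np.abs(q_next - q)) < tol:
            return q_next
        q = q_next
    return q


def schicluster_embed(
    cell_maps: list[ContactMap],
    pad: int = 1,
    restart_p: float = 0.5,
    top_quantile: float = 0.2,
    n_pcs: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    random_state: int = 0,
) -> np.ndarray:
    """Smoothed, binarized, PCA-reduced per-cell contact embedding.

    Each cell's map is box-convolved (window 2·pad+1), taken through a
    random walk with restart probability ``restart_p`` to a fixed point,
    its strongest ``top_quantile`` of entries binarized, and the stacked
    binary vectors reduced with PCA to ``n_pcs`` components.
    """
    if len(cell_maps) < 2:
        raise ValueError("need >= 2 cells to embed")
    feats = []
    for cm in cell_maps:
        if cm.matrix.sum() == 0:
            warnings.warn(f"empty contact map ({cm.chrom}); zero feature vector")
            feats.append(np.zeros(cm.n_bins * cm.n_bins))
            continue
        q = _smooth_rwr(cm.matrix, pad, restart_p, tol, max_iter)
        cut = np.quantile(q, 1 - top_quantile)
        feats.append((q > cut).astype(float).ravel())
    x = np.vstack(feats)
    k = min(n_pcs, min(x.shape) - 1)
    pca = PCA(n_components=k, svd_solver="full", random_state=random_state)
    return pca.fit_transform(x - x.mean(axis=0))
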