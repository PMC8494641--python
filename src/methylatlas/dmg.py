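"""Pairwise differential methylation genes, taxonomy, impact and overlap scores.

DMGs are called per ordered cluster pair with a one-sided Wilcoxon rank-sum
test for decreased normalized methylation (gene-body hypo-methylation marks
expression), Benjamini–Hochberg correction across genes within the
comparison, and three significance cuts: adjusted P < 1e−3, delta
(difference of mean normalized levels) < −0.5, AUROC > 0.8.  A subtype
taxonomy (average linkage, correlation distance over median levels of
top-50 pairwise markers) supports the impact score IS_A = (a−b)/(M·N) per
node per item and the node-height-weighted total impact Σ h_i·|IS_A|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import MethylCountMatrix

__all__ = [
    "TaxonomyTree",
    "build_taxonomy",
    "enforce_min_dmg",
    "impact_scores",
    "match_clusters",
    "overlap_score",
    "pairwise_dmg",
    "pseudo_cell_aggregate",
    "total_impact",
]

P_CUT = 1e-3
DELTA_CUT = -0.5
AUROC_CUT = 0.8


def _pair_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-sided rank-sum P(a < b) and AUROC of separating b above a."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0, 0.5
    res = mannwhitneyu(a, b, alternative="less", method="asymptotic")
    auroc = 1.0 - res.statistic / (len(a) * len(b))
    return float(res.pvalue), float(auroc)


def pairwise_dmg(
    norm_values: np.ndarray,
    labels: np.ndarray,
    gene_names=None,
    p_cut: float = P_CUT,
    delta_cut: float = DELTA_CUT,
    auroc_cut: float = AUROC_CUT,
) -> pd.DataFrame:
    """Hypo-methylation markers for every ordered cluster pair.

    A record (gene, A, B) tests whether the gene is hypo-methylated in A
    relative to B.  Returns the full table with ``significant`` flags; the
    delta and AUROC cuts are strict inequalities.
    """
    labels = np.asarray(labels)
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    for c in clusters:
        if np.sum(labels == c) < 2:
            raise ValueError(f"cluster {c!r} has < 2 cells")
    n_genes = norm_values.shape[1]
    if gene_names is None:
        gene_names = [f"gene_{i}" for i in range(n_genes)]
    rows = []
    for a, b in permutations(clusters, 2):
        xa = norm_values[labels == a]
        xb = norm_values[labels == b]
        pvals = np.empty(n_genes)
        aurocs = np.empty(n_genes)
        for g in range(n_genes):
            pvals[g], aurocs[g] = _pair_stats(xa[:, g], xb[:, g])
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        delta = xa.mean(axis=0) - xb.mean(axis=0)
        sig = (p_adj < p_cut) & (delta < delta_cut) & (aurocs > auroc_cut)
        for g in range(n_genes):
            rows.append(
                (gene_names[g], a, b, pvals[g], p_adj[g], delta[g], aurocs[g], sig[g])
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "cluster_a", "cluster_b", "p", "p_adj", "delta", "auroc",
                 "significant"],
    )


def enforce_min_dmg(
    labels: np.ndarray,
    norm_values: np.ndarray,
    pcs: np.ndarray,
    min_dmg: int = 5,
    gene_names=None,
    **dmg_kw,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Merge clusters until every pair is separated by ≥ ``min_dmg`` DMGs.

    A pair's marker count is the number of significant records in either
    direction; the smallest failing cluster is merged into the cluster with
    the nearest centroid in PC space, markers are recalled, and the loop
    repeats.  Returns the merged labels and the final DMG table.
    """
    labels = np.asarray(labels).copy()
    while True:
        clusters = sorted(set(labels))
        dmgs = pairwise_dmg(norm_values, labels, gene_names=gene_names, **dmg_kw)
        if len(clusters) < 2:
            warnings.warn("cluster merging collapsed to a single cluster")
            return labels, dmgs
        sig = dmgs[dmgs["significant"]]
        counts = sig.groupby(["cluster_a", "cluster_b"]).size()
        failing = []
        for c in clusters:
            worst = min(
                counts.get((c, d), 0) + counts.get((d, c), 0)
                for d in clusters
                if d != c
            )
            if worst < min_dmg:
                failing.append(c)
        if not failing:
            return labels, dmgs
        sizes = {c: np.sum(labels == c) for c in failing}
        src = min(failing, key=lambda c: (sizes[c], str(c)))
        centroids = {c: pcs[labels == c].mean(axis=0) for c in clusters}
        others = [c for c in clusters if c != src]
        dists = [np.linalg.norm(centroids[src] - centroids[c]) for c in others]
        dst = others[int(np.argmin(dists))]
        labels[labels == src] = dst
        if len(set(labels)) < 2:
            warnings.warn("cluster merging collapsed to a single cluster")
            return labels, pairwise_dmg(norm_values, labels, gene_names=gene_names, **dmg_kw)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTree:
    """Average-linkage, correlation-distance dendrogram over subtypes."""

    linkage_matrix: np.ndarray
    leaf_names: list
    profile: pd.DataFrame  # subtype × gene median normalized levels

    def nodes(self):
        """Yield (node_id, height, leaves_A, leaves_B) for non-singleton nodes."""
        root = to_tree(self.linkage_matrix)
        out = []

        def _leaves(node):
            return [self.leaf_names[i] for i in node.pre_order(lambda n: n.id)]

        def _walk(node):
            if node.is_leaf():
                return
            out.append((node.id, node.dist, _leaves(node.left), _leaves(node.right)))
            _walk(node.left)
            _walk(node.right)

        _walk(root)
        return out

    def to_newick(self) -> str:
        def _fmt(node, parent_dist):
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{parent_dist - node.dist:.6g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{parent_dist - node.dist:.6g}"

        root = to_tree(self.linkage_matrix)
        return f"({_fmt(root.left, root.dist)},{_fmt(root.right, root.dist)});"


def top_markers(dmgs: pd.DataFrame, top_n: int = 50) -> list:
    """Union over pairs of the top-``top_n`` most significant marker genes.

    Ranking within a pair: ascending adjusted P, then descending |delta|,
    then gene id (deterministic tie-break).
    """
    sig = dmgs[dmgs["significant"]].copy()
    sig["abs_delta"] = sig["delta"].abs()
    genes: set = set()
    for _, grp in sig.groupby(["cluster_a", "cluster_b"]):
        ranked = grp.sort_values(
            ["p_adj", "abs_delta", "gene"], ascending=[True, False, True],
            kind="mergesort",
        )
        genes.update(ranked["gene"].head(top_n))
    return sorted(genes)


def build_taxonomy(
    norm_values: np.ndarray,
    dmgs: pd.DataFrame,
    labels: np.ndarray,
    gene_names=None,
    top_n: int = 50,
) -> TaxonomyTree:
    """Dendrogram over subtypes from median levels of pairwise top markers."""
    labels = np.asarray(labels)
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValueError("need >= 2 subtypes to build a taxonomy")
    if gene_names is None:
        gene_names = [f"gene_{i}" for i in range(norm_values.shape[1])]
    gene_names = list(gene_names)
    marker_genes = top_markers(dmgs, top_n=top_n)
    if not marker_genes:
        raise ValueError("no significant markers to build the taxonomy from")
    col = {g: i for i, g in enumerate(gene_names)}
    idx = [col[g] for g in marker_genes]
    profile = pd.DataFrame(
        [np.median(norm_values[labels == c][:, idx], axis=0) for c in clusters],
        index=clusters,
        columns=marker_genes,
    )
    z = linkage(profile.to_numpy(), method="average", metric="correlation")
    return TaxonomyTree(linkage_matrix=z, leaf_names=clusters, profile=profile)


# ---------------------------------------------------------------------------
# impact scores
# ---------------------------------------------------------------------------

def impact_scores(tree: TaxonomyTree, significance: pd.DataFrame) -> pd.DataFrame:
    """Per-node per-item impact score IS_A = (a − b)/(M·N).

    ``significance`` rows are significant directed comparisons: columns
    ``cluster_a, cluster_b, item`` meaning the item shows the desired change
    (hypo-methylation for a gene, enrichment for a motif) on the
    ``cluster_a`` side of that pair.  At a node whose branches hold leaf
    sets A (M leaves) and B (N leaves), ``a`` counts significant pairs
    (x∈A, y∈B) and ``b`` pairs (y∈B, x∈A); IS_B = −IS_A.
    """
    sig = {
        (r.cluster_a, r.cluster_b, r.item)
        for r in significance.itertuples(index=False)
    }
    items = sorted(significance["item"].unique())
    rows = []
    for node_id, height, leaves_a, leaves_b in tree.nodes():
        m, n = len(leaves_a), len(leaves_b)
        if m == 0 or n == 0:
            continue
        for item in items:
            a = sum((x, y, item) in sig for x in leaves_a for y in leaves_b)
            b = sum((y, x, item) in sig for x in leaves_a for y in leaves_b)
            is_a = (a - b) / (m * n)
            rows.append((node_id, height, item, a, b, m, n, is_a, -is_a))
    return pd.DataFrame(
        rows,
        columns=["node", "height", "item", "a", "b", "M", "N", "IS_A", "IS_B"],
    )


def total_impact(impact_table: pd.DataFrame, nodes=None) -> pd.Series:
    """Node-height-weighted total impact Σ_i h_i·|IS_A| per item.

    ``nodes`` restricts the sum to a sub-tree or any node combination of
    interest.
    """
    tab = impact_table
    if nodes is not None:
        tab = tab[tab["node"].isin(set(nodes))]
    weighted = tab["height"] * tab["IS_A"].abs()
    return weighted.groupby(tab["item"]).sum().rename("IS_total")


# ---------------------------------------------------------------------------
# overlap score
# ---------------------------------------------------------------------------

def overlap_score(labels_a, labels_b, co_labels) -> pd.DataFrame:
    """OS(c_a, c_b) = Σ over co-clusters of min(frac of c_a, frac of c_b) in it.

    All three labelings must cover the same samples; scores lie in [0, 1]
    and reach 1 only when the two clusters distribute identically over the
    co-clusters.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    co_labels = np.asarray(co_labels)
    if not (len(labels_a) == len(labels_b) == len(co_labels)):
        raise ValueError("labelings must cover the same sample set")
    ca = sorted(set(labels_a))
    cb = sorted(set(labels_b))
    cos = sorted(set(co_labels))
    fa = np.zeros((len(ca), len(cos)))
    fb = np.zeros((len(cb), len(cos)))
    for i, c in enumerate(ca):
        mask = labels_a == c
        total = mask.sum()
        for j, co in enumerate(cos):
            fa[i, j] = np.sum(mask & (co_labels == co)) / total if total else 0.0
    for i, c in enumerate(cb):
        mask = labels_b == c
        total = mask.sum()
        for j, co in enumerate(cos):
            fb[i, j] = np.sum(mask & (co_labels == co)) / total if total else 0.0
    scores = np.minimum(fa[:, None, :], fb[None, :, :]).sum(axis=2)
    return pd.DataFrame(scores, index=ca, columns=cb)


def match_clusters(os_matrix: pd.DataFrame, threshold: float = 0.3) -> dict:
    """Partners above the OS threshold per row cluster; top-ranked if none."""
    out = {}
    for c, row in os_matrix.iterrows():
        above = list(row.index[row > threshold])
        out[c] = above if above else [row.idxmax()]
    return out


# ---------------------------------------------------------------------------
# pseudo-cell aggregation
# ---------------------------------------------------------------------------

def pseudo_cell_aggregate(
    counts: MethylCountMatrix,
    labels: np.ndarray,
    pcs: np.ndarray | None = None,
    cells_per_pseudo: int = 50,
    min_size: int = 10,
    seed: int = 0,
):
    """Sum cells into ~50-cell pseudo-cells by within-cluster k-means.

    ``k = n_cells_in_cluster // cells_per_pseudo`` (at least 1); k-means
    groups smaller than ``min_size`` cells are discarded.  Returns the
    aggregated :class:`MethylCountMatrix` and a cell → pseudo-cell mapping
    frame (-1 for discarded cells).  k-means runs on ``pcs`` when given,
    else on raw coverage-normalized levels.
    """
    labels = np.asarray(labels)
    if pcs is None:
        cov = sum(counts.cov[c] for c in counts.contexts).astype(float)
        mc = sum(counts.mc[c] for c in counts.contexts).astype(float)
        pcs = mc / np.maximum(cov, 1)
    mapping = np.full(counts.n_cells, -1, dtype=int)
    pseudo_ids: list[str] = []
    next_id = 0
    for c in sorted(set(labels)):
        idx = np.where(labels == c)[0]
        if idx.size < min_size:
            warnings.warn(f"cluster {c!r} has < {min_size} cells; no pseudo-cells")
            continue
        k = max(idx.size // cells_per_pseudo, 1)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pcs[idx])
        for g in range(k):
            members = idx[km.labels_ == g]
            if members.size < min_size:
                continue
            mapping[members] = next_id
            pseudo_ids.append(f"{c}:pseudo{g}")
            next_id += 1
    n_pseudo = next_id
    mc_out = {
        ctx: np.vstack(
            [counts.mc[ctx][mapping == p].sum(axis=0) for p in range(n_pseudo)]
        )
        for ctx in counts.contexts
    } if n_pseudo else {ctx: np.zeros((0, counts.n_features), dtype=int) for ctx in counts.contexts}
    cov_out = {
        ctx: np.vstack(
            [counts.cov[ctx][mapping == p].sum(axis=0) for p in range(n_pseudo)]
        )
        for ctx in counts.contexts
    } if n_pseudo else {ctx: np.zeros((0, counts.n_features), dtype=int) for ctx in counts.contexts}
    agg = MethylCountMatrix(
        mc=mc_out, cov=cov_out, features=counts.features.copy(), cell_ids=pseudo_ids
    )
    map_df = pd.DataFrame(
        {"cell": counts.cell_ids, "cluster": labels, "pseudo_cell": mapping}
    )
    return agg, map_df
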