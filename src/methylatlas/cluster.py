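"""Ensemble consensus clustering with supervised evaluation and outlier rescue.

The procedure: build a Euclidean KNN graph on concatenated principal
components, run Leiden community detection many times with different random
seeds at a fixed resolution, define a cell–cell distance as the fraction of
runs that assign the two cells to different communities (hamming distance
over the run-label matrix), and run DBSCAN over an epsilon grid to obtain
candidate consensus partitions spanning the per-run cluster-count range.
Each candidate is scored by a class-balanced random-forest classifier on a
held-out 10% of cells (balanced accuracy); the best candidate's model then
rescues DBSCAN outliers whose maximum predicted class probability exceeds
0.3.  Resolution selection keeps the largest resolution whose final
partition has <5% outliers, held-out accuracy >0.9 and ≥30 cells per
cluster on average.  The whole pipeline (normalize → HVF → PCA → consensus)
is re-run within each cluster for up to three nested levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from scipy.sparse import coo_matrix
from sklearn.cluster import DBSCAN
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .io import MethylCountMatrix
from .normalize import posterior_normalize, reduce_dimensions, select_hvf

OUTLIER = -1

__all__ = [
    "OUTLIER",
    "ClusterConfig",
    "ClusterHierarchy",
    "ConsensusPartition",
    "LeidenEnsemble",
    "build_knn_graph",
    "consensus_partition",
    "evaluate_partition",
    "iterative_cluster",
    "leiden_ensemble",
    "rescue_outliers",
    "select_resolution",
]


@dataclass
class LeidenEnsemble:
    labels: np.ndarray  # cells × runs
    resolution: float
    base_seed: int

    @property
    def n_runs(self) -> int:
        return self.labels.shape[1]

    def cluster_count_range(self) -> tuple[int, int]:
        counts = [len(np.unique(self.labels[:, r])) for r in range(self.n_runs)]
        return min(counts), max(counts)


@dataclass
class ConsensusPartition:
    labels: np.ndarray  # OUTLIER marks unassigned cells
    epsilon: float
    accuracy: float = np.nan
    rescue_prob: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels != OUTLIER]))

    @property
    def outlier_fraction(self) -> float:
        return float(np.mean(self.labels == OUTLIER))


def build_knn_graph(pcs: np.ndarray, k: int = 25) -> ig.Graph:
    """Undirected Euclidean KNN graph on the PC matrix (deterministic)."""
    n = pcs.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()  # drop self
    adj = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(np.int8)
    graph = ig.Graph.Adjacency((adj.toarray() > 0).tolist(), mode="undirected")
    return graph


def leiden_ensemble(
    graph: ig.Graph,
    resolution: float = 1.0,
    n_runs: int = 300,
    base_seed: int = 0,
) -> LeidenEnsemble:
    """Repeat Leiden with seeds base_seed..base_seed+n_runs−1 at one resolution."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    labels = np.empty((graph.vcount(), n_runs), dtype=np.int32)
    for r in range(n_runs):
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=base_seed + r,
            n_iterations=2,
        )
        labels[:, r] = part.membership
    return LeidenEnsemble(labels=labels, resolution=resolution, base_seed=base_seed)


def consensus_partition(
    ensemble: LeidenEnsemble,
    epsilon_grid: np.ndarray | None = None,
    min_samples: int = 5,
) -> list[ConsensusPartition]:
    """DBSCAN over hamming distances between run-label vectors.

    The distance between two cells is the fraction of ensemble runs that
    place them in different communities — permutation-safe because labels
    are only ever compared within a run.  Candidates whose cluster count
    falls within the [min, max] per-run count range are returned, one per
    distinct partition.
    """
    if epsilon_grid is None:
        epsilon_grid = np.arange(0.05, 0.61, 0.05)
    lo, hi = ensemble.cluster_count_range()
    feats = ensemble.labels.astype(float)
    candidates: list[ConsensusPartition] = []
    seen: set[bytes] = set()
    for eps in epsilon_grid:
        db = DBSCAN(eps=eps, min_samples=min_samples, metric="hamming").fit(feats)
        labels = db.labels_.copy()
        n_clusters = len(set(labels[labels != OUTLIER]))
        if n_clusters == 0:
            warnings.warn(f"epsilon {eps:.2f}: all cells outliers; candidate discarded")
            continue
        if not (lo <= n_clusters <= hi):
            continue
        key = labels.tobytes()
        if key in seen:
            continue
        seen.add(key)
        candidates.append(ConsensusPartition(labels=labels, epsilon=float(eps)))
    if not candidates:
        # fall back to the modal single run so callers always get a partition
        counts = [len(np.unique(ensemble.labels[:, r])) for r in range(ensemble.n_runs)]
        r = int(np.argmin(np.abs(np.array(counts) - lo)))
        candidates.append(
            ConsensusPartition(labels=ensemble.labels[:, r].astype(int), epsilon=np.nan)
        )
    return candidates


def hamming_distance_matrix(label_matrix: np.ndarray) -> np.ndarray:
    """Pairwise fraction-of-runs-disagreeing distance (pseudometric)."""
    n = label_matrix.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        out[i] = np.mean(label_matrix[i] != label_matrix, axis=1)
    return out


def _merge_tiny_clusters(pcs: np.ndarray, labels: np.ndarray, min_size: int = 2) -> np.ndarray:
    """Merge clusters below ``min_size`` into the Euclidean-nearest centroid."""
    labels = labels.copy()
    while True:
        ids, sizes = np.unique(labels[labels != OUTLIER], return_counts=True)
        small = ids[sizes < min_size]
        if small.size == 0 or ids.size <= 1:
            return labels
        warnings.warn(f"merging undersized cluster {small[0]} into nearest centroid")
        centroids = {c: pcs[labels == c].mean(axis=0) for c in ids}
        src = small[0]
        others = [c for c in ids if c != src]
        dists = [np.linalg.norm(centroids[src] - centroids[c]) for c in others]
        labels[labels == src] = others[int(np.argmin(dists))]


def evaluate_partition(
    pcs: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    test_size: float = 0.1,
    n_estimators: int = 100,
    use_rfe: bool = False,
    rfe_step: float = 0.1,
    rfe_cv: int = 10,
):
    """Held-out balanced accuracy of a class-balanced random forest.

    Outliers are excluded, clusters with fewer than two members merged into
    their nearest centroid, 10% of cells held out (stratified), and the
    model trained on the rest.  With ``use_rfe`` the features (PCs) go
    through recursive feature elimination with cross-validation first —
    an evaluation device for reproducibility, not part of the partition
    definition, so it is off by default for speed.
    """
    core = labels != OUTLIER
    if len(set(labels[core])) < 2:
        raise ValueError("need >= 2 non-outlier clusters to evaluate")
    y = _merge_tiny_clusters(pcs, labels)[core]
    x = pcs[core]
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_size, random_state=seed, stratify=y
    )
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )
    if use_rfe:
        selector = RFECV(clf, step=rfe_step, cv=rfe_cv, scoring="balanced_accuracy")
        selector.fit(x_tr, y_tr)
        support = selector.support_
        clf = selector.estimator_
        model = _SubspaceModel(clf, support)
        acc = balanced_accuracy_score(y_te, model.predict(x_te))
        return model, float(acc)
    clf.fit(x_tr, y_tr)
    acc = balanced_accuracy_score(y_te, clf.predict(x_te))
    return clf, float(acc)


class _SubspaceModel:
    """Classifier wrapper that applies an RFE feature mask before predicting."""

    def __init__(self, clf, support):
        self.clf = clf
        self.support = support

    @property
    def classes_(self):
        return self.clf.classes_

    def predict(self, x):
        return self.clf.predict(x[:, self.support])

    def predict_proba(self, x):
        return self.clf.predict_proba(x[:, self.support])


def rescue_outliers(
    model,
    pcs: np.ndarray,
    candidate: ConsensusPartition,
    prob_cut: float = 0.3,
) -> ConsensusPartition:
    """Assign each outlier its argmax class iff max probability > 0.3 (strict)."""
    labels = candidate.labels.copy()
    rescue_prob = np.full(labels.shape, np.nan)
    out_idx = np.where(labels == OUTLIER)[0]
    if out_idx.size:
        proba = model.predict_proba(pcs[out_idx])
        best = proba.max(axis=1)
        assign = model.classes_[proba.argmax(axis=1)]
        rescued = best > prob_cut
        labels[out_idx[rescued]] = assign[rescued]
        rescue_prob[out_idx] = best
    return ConsensusPartition(
        labels=labels,
        epsilon=candidate.epsilon,
        accuracy=candidate.accuracy,
        rescue_prob=rescue_prob,
    )


@dataclass
class SelectionCriteria:
    """Resolution acceptance rules (defaults as published)."""

    max_outlier_fraction: float = 0.05
    min_accuracy: float = 0.9
    min_cells_per_cluster: float = 30.0


def _finalize_candidates(pcs, candidates, seed, **eval_kw):
    """Evaluate each candidate, keep the best by accuracy, rescue its outliers."""
    best, best_model = None, None
    for cand in candidates:
        core = cand.labels != OUTLIER
        if len(set(cand.labels[core])) < 2:
            continue
        try:
            model, acc = evaluate_partition(pcs, cand.labels, seed=seed, **eval_kw)
        except ValueError:
            continue
        cand.accuracy = acc
        if best is None or acc > best.accuracy:
            best, best_model = cand, model
    if best is None:
        return None
    return rescue_outliers(best_model, pcs, best)


def select_resolution(
    pcs: np.ndarray,
    graph: ig.Graph,
    resolution_grid,
    n_runs: int = 100,
    base_seed: int = 0,
    criteria: SelectionCriteria | None = None,
    min_samples: int = 5,
    **eval_kw,
):
    """Largest resolution whose best consensus partition meets all criteria.

    Returns ``(resolution, partition, audit)``; if no resolution qualifies,
    the lowest-resolution partition is returned with ``resolution=None``
    and the audit log records each rejection.
    """
    crit = criteria or SelectionCriteria()
    audit = []
    fallback = None
    for res in sorted(resolution_grid, reverse=True):
        ens = leiden_ensemble(graph, resolution=res, n_runs=n_runs, base_seed=base_seed)
        cands = consensus_partition(ens, min_samples=min_samples)
        final = _finalize_candidates(pcs, cands, seed=base_seed, **eval_kw)
        if final is None:
            audit.append((res, "no evaluable candidate", None))
            continue
        fallback = (res, final)
        n_core = np.sum(final.labels != OUTLIER)
        mean_size = n_core / max(final.n_clusters, 1)
        ok = (
            final.outlier_fraction < crit.max_outlier_fraction
            and final.accuracy > crit.min_accuracy
            and mean_size >= crit.min_cells_per_cluster
        )
        audit.append(
            (res, "accepted" if ok else "rejected",
             dict(outliers=final.outlier_fraction, accuracy=final.accuracy,
                  mean_size=mean_size, n_clusters=final.n_clusters))
        )
        if ok:
            return res, final, audit
    if fallback is None:
        raise ValueError("no resolution produced an evaluable partition")
    warnings.warn("no resolution met the selection criteria; returning lowest-resolution partition")
    return None, fallback[1], audit


# ---------------------------------------------------------------------------
# iterative (multi-level) clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterConfig:
    """Per-round parameters of the preprocessing + consensus pipeline."""

    contexts: tuple[str, ...] = ("CH", "CG")
    n_hvf: int = 3000
    n_pcs: int = 16
    k: int = 25
    n_runs: int = 100
    resolution_grid: tuple[float, ...] = (0.5, 1.0)
    min_samples: int = 5
    min_cells: int = 60
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)


@dataclass
class ClusterHierarchy:
    """Nested labels per cell; level-k labels refine level-(k−1) labels."""

    levels: list[np.ndarray]  # each: object array of dotted-path labels
    outlier: np.ndarray

    def labels_at(self, level: int) -> np.ndarray:
        return self.levels[level]


def _cluster_round(counts: MethylCountMatrix, cfg: ClusterConfig, seed: int):
    """One preprocessing + consensus round; returns final labels or None."""
    norms, hvfs = {}, {}
    for ctx in cfg.contexts:
        if ctx not in counts.mc:
            continue
        norm = posterior_normalize(counts, context=ctx)
        hvfs[ctx] = select_hvf(norm, counts, n=min(cfg.n_hvf, norm.n_features)).mask
        norms[ctx] = norm
    pcs = reduce_dimensions(
        norm_ch=norms.get("CH"),
        norm_cg=norms.get("CG"),
        hvf_ch=hvfs.get("CH"),
        hvf_cg=hvfs.get("CG"),
        n_pcs=cfg.n_pcs,
    ).pcs
    k = min(cfg.k, counts.n_cells - 1)
    graph = build_knn_graph(pcs, k=k)
    try:
        res, final, audit = select_resolution(
            pcs, graph, cfg.resolution_grid, n_runs=cfg.n_runs,
            base_seed=seed, criteria=cfg.criteria, min_samples=cfg.min_samples,
        )
    except ValueError:
        return None  # branch has no splittable structure
    if res is None:
        return None
    return final


def iterative_cluster(
    counts: MethylCountMatrix,
    levels: int = 3,
    config: ClusterConfig | list[ClusterConfig] | None = None,
    seed: int = 0,
) -> ClusterHierarchy:
    """Nested consensus clustering: re-run the full pipeline inside each cluster.

    ``config`` may be a single :class:`ClusterConfig` or one per level
    (rounds of the iteration typically use different HVF/PC settings).
    A branch stops subdividing when it has fewer than ``min_cells`` cells or
    when no resolution meets the selection criteria there.  Labels are
    dotted paths ("0", "0.1", ...) so nesting is explicit.
    """
    if config is None:
        configs = [ClusterConfig()] * levels
    elif isinstance(config, ClusterConfig):
        configs = [config] * levels
    else:
        configs = list(config)
        if len(configs) < levels:
            configs = configs + [configs[-1]] * (levels - len(configs))
    n = counts.n_cells
    level_labels = [np.array([""] * n, dtype=object) for _ in range(levels)]
    outlier = np.zeros(n, dtype=bool)

    def _descend(cell_idx: np.ndarray, prefix: str, level: int, branch_seed: int):
        if level >= levels:
            return
        cfg = configs[level]
        if cell_idx.size < cfg.min_cells:
            for lv in range(level, levels):
                level_labels[lv][cell_idx] = prefix or "0"
            return
        sub = counts.subset(cells=cell_idx)
        final = _cluster_round(sub, cfg, seed=branch_seed)
        if final is None or final.n_clusters < 2:
            for lv in range(level, levels):
                level_labels[lv][cell_idx] = prefix or "0"
            return
        labels = final.labels
        outlier[cell_idx[labels == OUTLIER]] = True
        for c in sorted(set(labels[labels != OUTLIER])):
            name = f"{prefix}.{c}" if prefix else str(c)
            members = cell_idx[labels == c]
            for lv in range(level, levels):
                level_labels[lv][members] = name
            _descend(members, name, level + 1, branch_seed + 1000 * (c + 1))
        # outliers inherit the branch label at this and deeper levels
        stray = cell_idx[labels == OUTLIER]
        for lv in range(level, levels):
            level_labels[lv][stray] = prefix or "outlier"

    _descend(np.arange(n), "", 0, seed)
    return ClusterHierarchy(levels=level_labels, outlier=outlier)
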