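"""Synthetic single-cell methylome, annotation and chromatin-contact generators.

Every downstream stage of the pipeline is exercised on data from this
module, with the planted structure recorded in a :class:`SyntheticTruth` so
recovery can be scored.  The noise model mirrors the assumptions of the
normalization step: each cell draws a global methylation level per context,
each cluster has per-feature mean methylation fractions, per-feature levels
are beta-distributed around the (globally scaled) cluster mean, coverage is
negative-binomial, and methylated counts are binomial given coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MethylCountMatrix

__all__ = [
    "CohortSpec",
    "CoverageModel",
    "PlantedContacts",
    "PlantedDmr",
    "SyntheticTruth",
    "default_cohort_spec",
    "expected_contact_matrix",
    "extend_genes",
    "generate_annotations",
    "generate_contact_maps",
    "generate_gradient_population",
    "generate_methylome_cohort",
    "hierarchical_cluster_means",
    "planted_cluster_means",
    "region_neighbor_map",
]


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------

@dataclass
class CoverageModel:
    """Negative-binomial per-feature coverage: mean and dispersion (var = μ + μ²/θ)."""

    mean: float = 500.0
    dispersion: float = 10.0


@dataclass
class PlantedDmr:
    start: int
    end: int
    sign: int  # +1: mCG rises with global mCH; −1: falls
    cluster: int | None = None


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators (0-based half-open intervals)."""

    cell_cluster: np.ndarray | None = None
    cell_region: np.ndarray | None = None
    cell_global: dict = field(default_factory=dict)
    marker_features: dict = field(default_factory=dict)  # context -> {cluster: idx}
    planted_dmr: list = field(default_factory=list)
    planted_domains: dict = field(default_factory=dict)  # type -> [(start_bin, end_bin)]
    compartments: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class CohortSpec:
    """Parameters of a synthetic methylome cohort.

    ``cluster_means[ctx]`` is an (n_clusters, n_features) array of
    methylation fractions in [0, 1]; a cell's feature mean is the cluster
    mean scaled by the ratio of its global level to the midpoint of
    ``global_level_range[ctx]``.  ``beta_concentration`` controls
    within-cluster overdispersion (level ~ Beta(μs, (1−μ)s)).
    Region (spatial) labels are drawn from a per-cluster composition; an
    optional additive region effect on a random subset of features makes
    location predictable beyond cluster composition.
    """

    n_cells: int
    cluster_means: dict[str, np.ndarray]
    global_level_range: dict[str, tuple[float, float]]
    coverage: CoverageModel = field(default_factory=CoverageModel)
    beta_concentration: float = 50.0
    cluster_props: np.ndarray | None = None
    n_regions: int = 1
    region_composition: np.ndarray | None = None  # clusters × regions
    region_effect_features: int = 0
    region_effect_size: float = 0.0
    marker_features: dict | None = None
    bin_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("invalid spec field n_cells: must be >= 1")
        if not self.cluster_means:
            raise ValueError("invalid spec field cluster_means: empty")
        for ctx, means in self.cluster_means.items():
            means = np.asarray(means, dtype=float)
            if means.ndim != 2:
                raise ValueError(f"invalid spec field cluster_means[{ctx}]: need 2-D")
            if np.any(means < 0) or np.any(means > 1):
                raise ValueError(
                    f"invalid spec field cluster_means[{ctx}]: outside [0, 1]"
                )
            self.cluster_means[ctx] = means
            if ctx not in self.global_level_range:
                raise ValueError(f"invalid spec field global_level_range: missing {ctx}")
        if self.coverage.mean <= 0:
            raise ValueError("invalid spec field coverage.mean: must be > 0")
        shapes = {m.shape for m in self.cluster_means.values()}
        if len(shapes) != 1:
            raise ValueError("invalid spec field cluster_means: inconsistent shapes")

    @property
    def n_clusters(self) -> int:
        return next(iter(self.cluster_means.values())).shape[0]

    @property
    def n_features(self) -> int:
        return next(iter(self.cluster_means.values())).shape[1]


# ---------------------------------------------------------------------------
# cluster-mean builders
# ---------------------------------------------------------------------------

def planted_cluster_means(
    n_clusters: int,
    n_features: int,
    n_markers: int,
    base: float,
    marker_level: float,
    rng: np.random.Generator,
    base_jitter: float = 0.0,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Cluster × feature means with disjoint hypo-methylated marker blocks.

    Each cluster gets ``n_markers`` private features whose mean drops from
    ``base`` to ``marker_level`` (gene-body hypo-methylation marks cell
    identity in both CH and CG contexts).
    """
    if n_clusters * n_markers > n_features:
        raise ValueError("marker blocks exceed feature count")
    background = np.full(n_features, base)
    if base_jitter > 0:
        background = np.clip(background + rng.normal(0, base_jitter, n_features), 1e-3, 1 - 1e-3)
    means = np.tile(background, (n_clusters, 1))
    order = rng.permutation(n_features)
    markers: dict[int, np.ndarray] = {}
    for k in range(n_clusters):
        idx = order[k * n_markers : (k + 1) * n_markers]
        means[k, idx] = marker_level
        markers[k] = np.sort(idx)
    return means, markers


def hierarchical_cluster_means(
    n_classes: int,
    subtypes_per_class: int,
    n_features: int,
    n_class_markers: int,
    n_subtype_markers: int,
    base: float,
    class_marker_level: float,
    subtype_marker_level: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Two-level planted hierarchy: class-level and nested subtype-level markers.

    Returns means of shape (n_classes*subtypes_per_class, n_features) plus a
    truth dict with per-leaf class labels and marker indices.  Class markers
    carry a much larger effect than subtype markers, mimicking real atlases
    where cell classes differ globally and subtypes subtly.
    """
    n_leaves = n_classes * subtypes_per_class
    need = n_classes * n_class_markers + n_leaves * n_subtype_markers
    if need > n_features:
        raise ValueError("marker blocks exceed feature count")
    means = np.full((n_leaves, n_features), base)
    order = rng.permutation(n_features)
    pos = 0
    class_markers, subtype_markers, leaf_class = {}, {}, np.empty(n_leaves, dtype=int)
    for c in range(n_classes):
        idx = order[pos : pos + n_class_markers]
        pos += n_class_markers
        class_markers[c] = np.sort(idx)
        for s in range(subtypes_per_class):
            leaf = c * subtypes_per_class + s
            leaf_class[leaf] = c
            means[leaf, idx] = class_marker_level
            sidx = order[pos : pos + n_subtype_markers]
            pos += n_subtype_markers
            subtype_markers[leaf] = np.sort(sidx)
            means[leaf, sidx] = subtype_marker_level
    truth = {
        "leaf_class": leaf_class,
        "class_markers": class_markers,
        "subtype_markers": subtype_markers,
    }
    return means, truth


def default_cohort_spec(
    n_cells: int = 500,
    n_clusters: int = 3,
    n_features: int = 400,
    n_markers: int = 30,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """A ready-made two-context cohort with per-cluster hypo-marker blocks.

    Defaults emulate neuronal snmC data: global mCH of 1–4%, global mCG of
    65–85%, mean feature coverage 500 basecalls.
    """
    rng = np.random.default_rng(seed)
    n_markers = min(n_markers, n_features // n_clusters)
    ch_means, ch_markers = planted_cluster_means(
        n_clusters, n_features, n_markers, base=0.025, marker_level=0.008, rng=rng
    )
    cg_means, cg_markers = planted_cluster_means(
        n_clusters, n_features, n_markers, base=0.75, marker_level=0.35, rng=rng
    )
    spec = dict(
        n_cells=n_cells,
        cluster_means={"CH": ch_means, "CG": cg_means},
        global_level_range={"CH": (0.01, 0.04), "CG": (0.65, 0.85)},
        marker_features={"CH": ch_markers, "CG": cg_markers},
        seed=seed,
    )
    spec.update(overrides)
    return CohortSpec(**spec)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_methylome_cohort(spec: CohortSpec) -> tuple[MethylCountMatrix, SyntheticTruth]:
    """Draw a cohort of cells with planted cluster/region methylation structure.

    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, k, f = spec.n_cells, spec.n_clusters, spec.n_features
    props = spec.cluster_props
    if props is None:
        props = np.full(k, 1.0 / k)
    cluster = rng.choice(k, size=n, p=np.asarray(props) / np.sum(props))

    comp = spec.region_composition
    if comp is None:
        comp = np.full((k, spec.n_regions), 1.0 / spec.n_regions)
    comp = np.asarray(comp, dtype=float)
    comp = comp / comp.sum(axis=1, keepdims=True)
    region = np.array([rng.choice(spec.n_regions, p=comp[c]) for c in cluster])

    region_offsets = np.zeros((spec.n_regions, f))
    if spec.region_effect_features > 0 and spec.region_effect_size > 0:
        for r in range(spec.n_regions):
            idx = rng.choice(f, size=spec.region_effect_features, replace=False)
            sign = rng.choice([-1.0, 1.0], size=spec.region_effect_features)
            region_offsets[r, idx] = sign * spec.region_effect_size

    mc, cov, cell_global = {}, {}, {}
    s = spec.beta_concentration
    for ctx, means in spec.cluster_means.items():
        lo, hi = spec.global_level_range[ctx]
        g = rng.uniform(lo, hi, size=n)
        g_mid = 0.5 * (lo + hi)
        cell_global[ctx] = g
        mu = means[cluster] * (g / g_mid)[:, None]
        mu = mu * (1.0 + region_offsets[region])
        mu = np.clip(mu, 1e-3, 1 - 1e-3)
        c = _nb_draw(rng, spec.coverage.mean, spec.coverage.dispersion, (n, f))
        p = rng.beta(mu * s, (1 - mu) * s)
        mc[ctx] = rng.binomial(c, p)
        cov[ctx] = c

    bin_size = spec.bin_size
    features = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(f) * bin_size,
            "end": (np.arange(f) + 1) * bin_size,
            "name": [f"bin_{i}" for i in range(f)],
        }
    )
    counts = MethylCountMatrix(mc=mc, cov=cov, features=features)
    truth = SyntheticTruth(
        cell_cluster=cluster,
        cell_region=region,
        cell_global=cell_global,
        marker_features=dict(spec.marker_features or {}),
        extra={"region_offsets": region_offsets},
    )
    return counts, truth


# ---------------------------------------------------------------------------
# gradient population (CpG-site level)
# ---------------------------------------------------------------------------

def generate_gradient_population(
    n_cells: int,
    global_mch_range: tuple[float, float],
    dmr_spec: Sequence[PlantedDmr] = (),
    n_sites: int = 2000,
    site_spacing: int = 100,
    site_cov_mean: float = 2.0,
    background_frac: float = 0.9,
    gradient_span: float = 0.85,
    seed: int = 0,
) -> tuple[MethylCountMatrix, SyntheticTruth]:
    """Cells whose global mCH spans a range, with mCG gradient DMRs planted.

    CpG sites inside a +DMR rise in mCG fraction monotonically with the
    cell's global mCH (from ``background_frac − gradient_span`` up to
    ``background_frac``); −DMR sites fall symmetrically.  Background sites
    sit at ``background_frac``.  Per-site per-cell coverage is Poisson
    (single-cell CpG coverage is sparse); pooling cells into groups gives
    the depth the site-level test needs.
    """
    lo, hi = global_mch_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("global_mch_range must lie within [0, 1]")
    rng = np.random.default_rng(seed)
    g = rng.uniform(lo, hi, size=n_cells)
    t = np.zeros(n_cells) if hi == lo else (g - lo) / (hi - lo)

    positions = np.arange(n_sites) * site_spacing
    frac = np.full((n_cells, n_sites), background_frac)
    for dmr in dmr_spec:
        in_dmr = (positions >= dmr.start) & (positions < dmr.end)
        if dmr.sign > 0:
            frac[:, in_dmr] = background_frac - gradient_span * (1 - t)[:, None]
        else:
            frac[:, in_dmr] = background_frac - gradient_span * t[:, None]
    frac = np.clip(frac, 1e-3, 1 - 1e-3)
    cov = rng.poisson(site_cov_mean, size=(n_cells, n_sites))
    mc = rng.binomial(cov, frac)
    features = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": positions,
            "end": positions + 2,  # CpG dyad
            "name": [f"cpg_{p}" for p in positions],
        }
    )
    counts = MethylCountMatrix(mc={"CG": mc}, cov={"CG": cov}, features=features)
    truth = SyntheticTruth(
        cell_global={"CH": g},
        planted_dmr=list(dmr_spec),
        extra={"site_positions": positions},
    )
    return counts, truth


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclass
class PlantedContacts:
    """Planted 3D-genome structure for synthetic contact maps.

    Compartments are blocks of ``compartment_block`` bins carrying a
    balanced random A/B assignment (seeded, so deterministic): aperiodic
    like real compartments, which keeps the within/between contrast visible
    at every genomic distance.  Within-compartment expected contacts are
    multiplied by ``within_factor`` and between by ``between_factor``.
    ``domains`` maps cell type to half-open bin intervals whose
    intra-domain contacts are boosted by ``domain_factor``.
    """

    n_bins: int
    compartment_block: int = 0
    within_factor: float = 2.0
    between_factor: float = 0.5
    domains: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    domain_factor: float = 3.0
    decay_exponent: float = 1.0
    compartment_seed: int = 0


def _compartment_labels(planted: PlantedContacts) -> np.ndarray | None:
    if planted.compartment_block <= 0:
        return None
    rng = np.random.default_rng(planted.compartment_seed)
    n_blocks = int(np.ceil(planted.n_bins / planted.compartment_block))
    block_lab = np.zeros(n_blocks, dtype=int)
    block_lab[: n_blocks // 2] = 1
    block_lab = rng.permutation(block_lab)
    return np.repeat(block_lab, planted.compartment_block)[: planted.n_bins]


def expected_contact_matrix(planted: PlantedContacts, cell_type: str | None = None) -> np.ndarray:
    """Analytic expected contact matrix: power-law decay × planted structure."""
    n = planted.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    e = (dist + 1.0) ** (-planted.decay_exponent)
    lab = _compartment_labels(planted)
    if lab is not None:
        same = lab[:, None] == lab[None, :]
        e = e * np.where(same, planted.within_factor, planted.between_factor)
    if cell_type is not None and cell_type in planted.domains:
        for start, end in planted.domains[cell_type]:
            if start < 0 or end > n:
                raise ValueError(f"planted domain ({start}, {end}) outside chromosome")
            e[start:end, start:end] *= planted.domain_factor
    return e


def generate_contact_maps(
    n_cells_per_type: dict[str, int],
    planted: PlantedContacts,
    resolution: int = 1_000_000,
    depth: int = 50_000,
    chrom: str = "chrS",
    seed: int = 0,
):
    """Per-cell Poisson-sampled symmetric contact maps with planted structure.

    Returns ``(maps, cell_types, truth)`` where ``maps`` is a list of
    :class:`methylatlas.hic.ContactMap`.
    """
    from .hic import ContactMap  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    maps, types = [], []
    for cell_type, n_cells in n_cells_per_type.items():
        e = expected_contact_matrix(planted, cell_type)
        upper = np.triu(e)
        rate = upper / upper.sum() * depth
        for _ in range(n_cells):
            draw = rng.poisson(rate)
            mat = draw + np.triu(draw, 1).T
            maps.append(ContactMap(chrom=chrom, resolution=resolution, matrix=mat.astype(float)))
            types.append(cell_type)
    truth = SyntheticTruth(
        compartments=_compartment_labels(planted),
        planted_domains=dict(planted.domains),
        extra={"planted": planted},
    )
    return maps, np.array(types), truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    n_genes: int,
    chrom_sizes: dict[str, int],
    bin_size: int = 100_000,
    min_gene_len: int = 1_000,
    max_gene_len: int = 50_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping bins tiling each chromosome plus random gene intervals.

    Returns ``(bins, genes)`` BED-like frames; genes carry a ``strand``
    column and are at least ``min_gene_len`` long.
    """
    if any(size <= 0 for size in chrom_sizes.values()):
        raise ValueError("chrom_sizes must be positive")
    rng = np.random.default_rng(seed)
    bins = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size)
        ends = np.minimum(starts + bin_size, size)
        bins.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends,
                 "name": [f"{chrom}_bin{i}" for i in range(len(starts))]}
            )
        )
    bins_df = pd.concat(bins, ignore_index=True)

    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    gene_chrom_idx = rng.choice(len(chroms), size=n_genes, p=sizes / sizes.sum())
    lengths = rng.integers(min_gene_len, max_gene_len + 1, size=n_genes)
    rows = []
    for i in range(n_genes):
        chrom = chroms[gene_chrom_idx[i]]
        size = chrom_sizes[chrom]
        length = int(min(lengths[i], size))
        start = int(rng.integers(0, max(size - length, 1)))
        rows.append((chrom, start, start + length, f"gene_{i}", rng.choice(["+", "-"])))
    genes_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    genes_df = genes_df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return bins_df, genes_df


def extend_genes(genes: pd.DataFrame, flank: int = 2_000,
                 chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Gene body ±flank intervals (clipped to chromosome bounds when known)."""
    out = genes.copy()
    out["start"] = np.maximum(out["start"] - flank, 0)
    out["end"] = out["end"] + flank
    if chrom_sizes:
        out["end"] = [
            min(e, chrom_sizes.get(c, e)) for c, e in zip(out["chrom"], out["end"])
        ]
    return out


def region_neighbor_map(regions: Sequence[str], layout: str = "chain") -> dict[str, set[str]]:
    """Symmetric adjacency between dissection regions (chain layout by default)."""
    regions = list(regions)
    nbrs: dict[str, set[str]] = {r: set() for r in regions}
    if layout == "chain":
        for a, b in zip(regions[:-1], regions[1:]):
            nbrs[a].add(b)
            nbrs[b].add(a)
    elif layout != "none":
        raise ValueError(f"unknown layout {layout!r}")
    return nbrs
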