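"""Differential methylation at site and region level, with correlation stages.

Sites (CpG, strand pairs pre-summed) are tested across all samples at once
with a permutation root-mean-square goodness-of-fit test: the statistic is
the coverage-weighted RMS deviation of per-sample methylation fractions
from the pooled fraction, and the null is built by permuting methylated
basecalls among samples while preserving each sample's coverage.
Significant sites within 250 bp (inclusive) merge into regions; regions
keep only samples whose mCG fraction deviates by more than 0.3 from the
robust (interquartile) mean in a direction the site-level test supports.
Downstream: DMR–gene partial correlation with a shuffled-subtype null,
global-mCH gradient DMRs, and gene-body DMS enrichment by Fisher's test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr
from statsmodels.stats.multitest import multipletests

from .io import MethylCountMatrix

__all__ = [
    "DmrRecord",
    "GradientDmrSet",
    "assemble_dmrs",
    "call_dms",
    "dmr_gene_correlation",
    "dmr_sample_fractions",
    "gradient_dmr",
    "region_gene_enrichment",
    "robust_mean_filter",
]


# ---------------------------------------------------------------------------
# DMS calling
# ---------------------------------------------------------------------------

def _rms_stat(mc: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Coverage-weighted RMS deviation of sample fractions from the pooled fraction.

    ``mc``/``cov`` are (..., n_samples); samples with zero coverage carry
    zero weight.
    """
    cov = cov.astype(float)
    total_cov = cov.sum(axis=-1)
    pooled = mc.sum(axis=-1) / np.maximum(total_cov, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = mc / np.maximum(cov, 1)
    dev2 = (frac - pooled[..., None]) ** 2
    num = (cov * dev2).sum(axis=-1)
    return np.sqrt(num / np.maximum(total_cov, 1))


def _permute_counts(total_mc: int, covs: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Permute basecalls among samples preserving per-sample coverage.

    Sequential multivariate-hypergeometric sampling: returns an
    (n_perm, n_samples) matrix of methylated counts.
    """
    n_s = covs.size
    total = int(covs.sum())
    out = np.empty((n_perm, n_s), dtype=np.int64)
    remaining_mc = np.full(n_perm, total_mc, dtype=np.int64)
    remaining = total
    for s in range(n_s):
        c = int(covs[s])
        if s == n_s - 1:
            out[:, s] = remaining_mc
            break
        if c == 0:
            out[:, s] = 0
            continue
        draw = rng.hypergeometric(remaining_mc, remaining - remaining_mc, c)
        out[:, s] = draw
        remaining_mc -= draw
        remaining -= c
    return out


def call_dms(
    mc: np.ndarray,
    cov: np.ndarray,
    positions: np.ndarray,
    chrom: str = "chrS",
    n_perm: int = 999,
    seed: int = 0,
    sig_alpha: float = 0.01,
) -> pd.DataFrame:
    """Permutation RMS goodness-of-fit test per site across all samples.

    ``mc``/``cov`` are (n_samples, n_sites).  The empirical P value uses
    the add-one correction P = (1 + #{perm ≥ obs})/(n_perm + 1);
    ``significant`` flags BH-adjusted P < ``sig_alpha``.  Sites covered in
    fewer than two samples are skipped.
    """
    if mc.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(seed)
    n_sites = mc.shape[1]
    stat = np.full(n_sites, np.nan)
    pval = np.full(n_sites, np.nan)
    tested = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        covs = cov[:, j]
        if np.count_nonzero(covs) < 2:
            continue
        obs = _rms_stat(mc[:, j], covs)
        perm_mc = _permute_counts(int(mc[:, j].sum()), covs, n_perm, rng)
        perm_stat = _rms_stat(perm_mc, np.broadcast_to(covs, perm_mc.shape))
        stat[j] = obs
        pval[j] = (1 + np.sum(perm_stat >= obs)) / (n_perm + 1)
        tested[j] = True
    p_adj = np.full(n_sites, np.nan)
    if tested.any():
        p_adj[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = mc / np.maximum(cov, 1)
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions),
            "stat": stat,
            "p": pval,
            "p_adj": p_adj,
            "tested": tested,
        }
    )
    table["significant"] = (table["p_adj"] < sig_alpha).fillna(False)
    for s in range(mc.shape[0]):
        table[f"frac_{s}"] = frac[s]
        table[f"cov_{s}"] = cov[s]
    return table


# ---------------------------------------------------------------------------
# DMR assembly and filtering
# ---------------------------------------------------------------------------

@dataclass
class DmrRecord:
    chrom: str
    start: int
    end: int
    sites: np.ndarray
    sample_frac: np.ndarray | None = None
    robust_mean: float = np.nan
    hypo_samples: list = field(default_factory=list)
    hyper_samples: list = field(default_factory=list)


def assemble_dmrs(dms: pd.DataFrame, max_gap: int = 250) -> list[DmrRecord]:
    """Chain significant sites with inter-site distance ≤ 250 bp into regions.

    Intervals are 0-based half-open over member site positions; a singleton
    site yields a single-site region.
    """
    out: list[DmrRecord] = []
    if len(dms) == 0 or not dms["significant"].any():
        return out
    sig = dms[dms["significant"]].sort_values(["chrom", "pos"])
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if pos.size == 0:
            continue
        breaks = np.where(np.diff(pos) > max_gap)[0]
        start_idx = np.concatenate([[0], breaks + 1])
        end_idx = np.concatenate([breaks, [pos.size - 1]])
        for s, e in zip(start_idx, end_idx):
            members = pos[s : e + 1]
            out.append(
                DmrRecord(
                    chrom=chrom,
                    start=int(members[0]),
                    end=int(members[-1]) + 1,
                    sites=members,
                )
            )
    return out


def dmr_sample_fractions(
    dmrs: list[DmrRecord], dms: pd.DataFrame, n_samples: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-DMR per-sample pooled mCG fraction and directional evidence flags.

    A sample has hypo (hyper) evidence in a DMR if at least one member site
    has that sample's fraction below (above) the site's pooled fraction —
    the site-level analogue of a per-sample significant call.
    """
    frac_cols = [f"frac_{s}" for s in range(n_samples)]
    cov_cols = [f"cov_{s}" for s in range(n_samples)]
    fracs = np.zeros((len(dmrs), n_samples))
    hypo_flags = np.zeros((len(dmrs), n_samples), dtype=bool)
    hyper_flags = np.zeros((len(dmrs), n_samples), dtype=bool)
    by_key = dms.set_index(["chrom", "pos"])
    for i, dmr in enumerate(dmrs):
        sites = by_key.loc[[(dmr.chrom, p) for p in dmr.sites]]
        cov = sites[cov_cols].to_numpy(dtype=float)
        site_frac = sites[frac_cols].to_numpy(dtype=float)
        mc = site_frac * cov
        tot_cov = cov.sum(axis=0)
        fracs[i] = mc.sum(axis=0) / np.maximum(tot_cov, 1)
        pooled = mc.sum() / max(cov.sum(), 1)
        covered = cov > 0
        hypo_flags[i] = np.any(covered & (site_frac < pooled), axis=0)
        hyper_flags[i] = np.any(covered & (site_frac > pooled), axis=0)
    return fracs, hypo_flags, hyper_flags


def _robust_mean(fracs: np.ndarray) -> float:
    """Mean of the samples between the 25th and 75th percentile ranks."""
    s = np.sort(fracs)
    n = s.size
    if n < 4:
        warnings.warn("fewer than 4 samples; robust mean falls back to median")
        return float(np.median(s))
    ranks = np.arange(n) / (n - 1)
    mid = s[(ranks >= 0.25) & (ranks <= 0.75)]
    return float(mid.mean())


def robust_mean_filter(
    dmrs: list[DmrRecord],
    sample_frac: np.ndarray,
    hypo_flags: np.ndarray,
    hyper_flags: np.ndarray,
    delta: float = 0.3,
) -> list[DmrRecord]:
    """Assign hypo/hyper samples around the robust mean and drop empty DMRs.

    A sample is hypo when its fraction < m − 0.3 AND it has directional
    site-level evidence (strict inequalities); hyper symmetrically.  DMRs
    with neither assignment are excluded.
    """
    kept: list[DmrRecord] = []
    for i, dmr in enumerate(dmrs):
        fr = sample_frac[i]
        m = _robust_mean(fr)
        hypo = np.where((fr < m - delta) & hypo_flags[i])[0]
        hyper = np.where((fr > m + delta) & hyper_flags[i])[0]
        if hypo.size == 0 and hyper.size == 0:
            continue
        kept.append(
            DmrRecord(
                chrom=dmr.chrom,
                start=dmr.start,
                end=dmr.end,
                sites=dmr.sites,
                sample_frac=fr,
                robust_mean=m,
                hypo_samples=list(hypo),
                hyper_samples=list(hyper),
            )
        )
    return kept


def dmrs_to_bed(dmrs: list[DmrRecord]) -> pd.DataFrame:
    rows = []
    for i, d in enumerate(dmrs):
        rows.append(
            (d.chrom, d.start, d.end, f"dmr_{i}", len(d.sites), ".",
             d.robust_mean,
             ",".join(map(str, d.hypo_samples)),
             ",".join(map(str, d.hyper_samples)))
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "n_sites", "strand",
                 "robust_mean", "hypo_samples", "hyper_samples"],
    )


# ---------------------------------------------------------------------------
# DMR–gene partial correlation
# ---------------------------------------------------------------------------

def _regress_out(matrix: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column on [1, covariate]."""
    x = np.column_stack([np.ones_like(covariate, dtype=float), covariate])
    beta, *_ = np.linalg.lstsq(x, matrix, rcond=None)
    return matrix - x @ beta


def _pairwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between columns of a (n×p) and b (n×q) → (p, q)."""
    az = (a - a.mean(axis=0)) / np.where(a.std(axis=0) == 0, 1, a.std(axis=0))
    bz = (b - b.mean(axis=0)) / np.where(b.std(axis=0) == 0, 1, b.std(axis=0))
    return az.T @ bz / a.shape[0]


def dmr_gene_correlation(
    dmr_mcg: np.ndarray,
    gene_mch: np.ndarray,
    dmr_centers: np.ndarray,
    gene_tss: np.ndarray,
    dmr_chrom: np.ndarray | None = None,
    gene_chrom: np.ndarray | None = None,
    global_mcg: np.ndarray | None = None,
    global_mch: np.ndarray | None = None,
    window: float = 1_000_000,
    n_perm: int = 100,
    seed: int = 0,
    r_cut: float = 0.3,
    p_cut: float = 0.005,
) -> pd.DataFrame:
    """Residual Pearson correlation of DMR mCG vs gene mCH across subtypes.

    Global methylation (per-subtype mean mCG for DMRs, mean mCH for genes)
    is regressed out first; only pairs with |DMR centre − TSS| ≤ 1 Mb on
    the same chromosome are tested.  The two-sided empirical P comes from a
    pooled null built by shuffling the subtype order of both matrices
    ``n_perm`` times.  Reported pairs satisfy |r| > ``r_cut`` and
    P < ``p_cut``; the ``sign`` column separates positive and negative
    pairs.
    """
    n_subtypes = dmr_mcg.shape[0]
    if gene_mch.shape[0] != n_subtypes:
        raise ValueError("matrices must share the subtype axis")
    if n_subtypes < 10:
        warnings.warn("fewer than 10 subtypes: correlations are unstable")
    if global_mcg is None:
        global_mcg = dmr_mcg.mean(axis=1)
    if global_mch is None:
        global_mch = gene_mch.mean(axis=1)
    rd = _regress_out(dmr_mcg.astype(float), np.asarray(global_mcg, dtype=float))
    rg = _regress_out(gene_mch.astype(float), np.asarray(global_mch, dtype=float))

    dmr_centers = np.asarray(dmr_centers, dtype=float)
    gene_tss = np.asarray(gene_tss, dtype=float)
    close = np.abs(dmr_centers[:, None] - gene_tss[None, :]) <= window
    if dmr_chrom is not None and gene_chrom is not None:
        same = np.asarray(dmr_chrom)[:, None] == np.asarray(gene_chrom)[None, :]
        close &= same
    pair_idx = np.argwhere(close)
    if pair_idx.size == 0:
        return pd.DataFrame(
            columns=["dmr", "gene", "distance", "r", "p", "sign", "reported"]
        )

    r_full = _pairwise_r(rd, rg)
    r_obs = r_full[pair_idx[:, 0], pair_idx[:, 1]]

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, pair_idx.shape[0]))
    for t in range(n_perm):
        pd_ = rd[rng.permutation(n_subtypes)]
        pg_ = rg[rng.permutation(n_subtypes)]
        r_perm = _pairwise_r(pd_, pg_)
        null[t] = r_perm[pair_idx[:, 0], pair_idx[:, 1]]
    pooled = np.abs(null.ravel())
    pooled.sort()
    # two-sided empirical P from the pooled null, add-one corrected
    n_null = pooled.size
    ge = n_null - np.searchsorted(pooled, np.abs(r_obs), side="left")
    pvals = (1 + ge) / (n_null + 1)

    dist = dmr_centers[pair_idx[:, 0]] - gene_tss[pair_idx[:, 1]]
    out = pd.DataFrame(
        {
            "dmr": pair_idx[:, 0],
            "gene": pair_idx[:, 1],
            "distance": dist,
            "r": r_obs,
            "p": pvals,
            "sign": np.sign(r_obs).astype(int),
        }
    )
    out["reported"] = (np.abs(out["r"]) > r_cut) & (out["p"] < p_cut)
    return out


# ---------------------------------------------------------------------------
# gradient DMRs
# ---------------------------------------------------------------------------

@dataclass
class GradientDmrSet:
    gradient_dmrs: list[DmrRecord]
    control_dmrs: list[DmrRecord]
    rho: np.ndarray
    classification: np.ndarray  # +1, -1 or 0 (weak/excluded)
    group_thresholds: np.ndarray
    removed_by_control: int = 0


def _pool_groups(counts: MethylCountMatrix, groups: list[np.ndarray], context: str = "CG"):
    mc = np.vstack([counts.mc[context][g].sum(axis=0) for g in groups])
    cov = np.vstack([counts.cov[context][g].sum(axis=0) for g in groups])
    return mc, cov


def _intervals_overlap(a: DmrRecord, bs: list[DmrRecord]) -> bool:
    return any(
        a.chrom == b.chrom and a.start < b.end and b.start < a.end for b in bs
    )


def gradient_dmr(
    counts: MethylCountMatrix,
    global_mch: np.ndarray,
    n_groups: int = 4,
    cells_per_group: int = 400,
    n_control_groups: int = 15,
    rho_cut: float = 0.75,
    n_perm: int = 999,
    seed: int = 0,
) -> GradientDmrSet:
    """Classify DMRs whose mCG tracks the cells' global mCH level.

    Cells are split into ``n_groups`` evenly sized groups by global mCH;
    ``cells_per_group`` cells per group are pooled and DMRs called across
    the groups.  Control DMRs from ``n_control_groups`` random groups
    (ignoring global mCH) remove stochastic calls by interval overlap.
    Each surviving DMR's Pearson ρ of group mCG fractions against the group
    index (1..n) classifies it as +DMR (ρ > 0.75), −DMR (ρ < −0.75) or
    weakly correlated (excluded); both cutoffs are strict.
    """
    n_cells = counts.n_cells
    need = n_groups * cells_per_group
    if n_cells < need:
        raise ValueError(f"need at least {need} cells, got {n_cells}")
    rng = np.random.default_rng(seed)
    order = np.argsort(global_mch, kind="mergesort")
    group_size = n_cells // n_groups
    groups_all = [order[i * group_size : (i + 1) * group_size] for i in range(n_groups)]
    thresholds = np.array(
        [global_mch[order[(i + 1) * group_size - 1]] for i in range(n_groups - 1)]
    )
    groups = [rng.choice(g, size=cells_per_group, replace=False) for g in groups_all]

    positions = counts.features["start"].to_numpy()
    chrom = counts.features["chrom"].iloc[0]
    mc, cov = _pool_groups(counts, groups)
    dms = call_dms(mc, cov, positions, chrom=chrom, n_perm=n_perm, seed=seed)
    dmrs = assemble_dmrs(dms)
    fr, hypo_f, hyper_f = dmr_sample_fractions(dmrs, dms, n_groups)
    dmrs = robust_mean_filter(dmrs, fr, hypo_f, hyper_f)

    ctrl_groups = [
        rng.choice(n_cells, size=cells_per_group, replace=False)
        for _ in range(n_control_groups)
    ]
    cmc, ccov = _pool_groups(counts, ctrl_groups)
    cdms = call_dms(cmc, ccov, positions, chrom=chrom, n_perm=n_perm, seed=seed + 1)
    cdmrs = assemble_dmrs(cdms)
    cfr, chypo, chyper = dmr_sample_fractions(cdmrs, cdms, n_control_groups)
    cdmrs = robust_mean_filter(cdmrs, cfr, chypo, chyper)

    kept = [d for d in dmrs if not _intervals_overlap(d, cdmrs)]
    removed = len(dmrs) - len(kept)

    seq = np.arange(1, n_groups + 1, dtype=float)
    rho = np.full(len(kept), np.nan)
    cls = np.zeros(len(kept), dtype=int)
    for i, d in enumerate(kept):
        fr = d.sample_frac
        if fr is None or np.std(fr) == 0:
            continue
        rho[i] = pearsonr(fr, seq)[0]
        if rho[i] > rho_cut:
            cls[i] = 1
        elif rho[i] < -rho_cut:
            cls[i] = -1
    return GradientDmrSet(
        gradient_dmrs=kept,
        control_dmrs=cdmrs,
        rho=rho,
        classification=cls,
        group_thresholds=thresholds,
        removed_by_control=removed,
    )


# ---------------------------------------------------------------------------
# DMS/DMR gene enrichment
# ---------------------------------------------------------------------------

def region_gene_enrichment(
    dms_positions: np.ndarray,
    site_positions: np.ndarray,
    genes: pd.DataFrame,
    dms_chrom: np.ndarray | None = None,
    site_chrom: np.ndarray | None = None,
    flank: int = 1_000_000,
    min_dms: int = 20,
    min_gene_len: int = 5_000,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fisher's exact test of DMS density in gene bodies vs ±1 Mb flanks.

    Per gene: a 2×2 table of (DMS, non-DMS cytosines) × (body, flanks);
    enriched genes require BH-adjusted P < 0.01 and strictly more than 20
    DMSs in the body.  Genes shorter than 5 kb are excluded to prevent
    gene-length bias; genes with zero flank cytosines are skipped.
    """
    dms_positions = np.sort(np.asarray(dms_positions))
    site_positions = np.sort(np.asarray(site_positions))
    rows = []
    for g in genes.itertuples(index=False):
        if g.end - g.start <= min_gene_len:
            continue
        def _count(arr, lo, hi):
            return int(np.searchsorted(arr, hi) - np.searchsorted(arr, lo))
        dms_body = _count(dms_positions, g.start, g.end)
        sites_body = _count(site_positions, g.start, g.end)
        dms_flank = (
            _count(dms_positions, g.start - flank, g.start)
            + _count(dms_positions, g.end, g.end + flank)
        )
        sites_flank = (
            _count(site_positions, g.start - flank, g.start)
            + _count(site_positions, g.end, g.end + flank)
        )
        if sites_flank == 0:
            warnings.warn(f"gene {g.name}: zero flank cytosines; skipped")
            continue
        table = [[dms_body, sites_body - dms_body],
                 [dms_flank, sites_flank - dms_flank]]
        odds, p = fisher_exact(table, alternative="greater")
        rows.append((g.name, dms_body, sites_body, dms_flank, sites_flank, odds, p))
    out = pd.DataFrame(
        rows, columns=["gene", "dms_body", "sites_body", "dms_flank",
                       "sites_flank", "odds_ratio", "p"]
    )
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["enriched"] = (out["p_adj"] < alpha) & (out["dms_body"] > min_dms)
    else:
        out["p_adj"] = []
        out["enriched"] = []
    return out
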