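"""Reading, writing and quality control of single-cell methylation counts.

The base-level format is the ALLC table: one row per cytosine with
``chrom, pos (1-based), strand, trinucleotide context, mc, cov, indicator``.
Counts are aggregated over genomic features (100-kb bins, gene bodies) into
a :class:`MethylCountMatrix` holding paired ``(mc, cov)`` integer matrices
per context class.  All internal coordinates are BED-style 0-based
half-open; ALLC positions are converted on read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AllcRecord",
    "CellQCProfile",
    "CellQCThresholds",
    "MethylCountMatrix",
    "aggregate_counts",
    "compute_detection_ratio",
    "classify_context",
    "pair_cpg",
    "qc_filter_cells",
    "qc_filter_features",
    "read_allc",
    "write_allc",
]


class AllcRecord(NamedTuple):
    """One cytosine's methylation calls (ALLC row; ``pos`` is 1-based)."""

    chrom: str
    pos: int
    strand: str
    context: str
    mc: int
    cov: int
    indicator: int = 1


def classify_context(context: str) -> str:
    """Map a trinucleotide context to its class: ``CG``, ``CCC`` or ``CH``.

    CCC is a sub-context of CH tracked separately because the global mCCC
    fraction bounds the bisulfite non-conversion rate.
    """
    if len(context) < 2:
        raise ValueError(f"context too short: {context!r}")
    if context[1] == "G":
        return "CG"
    if context == "CCC":
        return "CCC"
    return "CH"


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_allc(path, pair_cpg_sites: bool = False) -> Iterator[AllcRecord]:
    """Stream :class:`AllcRecord` rows from a (optionally gzipped) ALLC file.

    With ``pair_cpg_sites=True``, base calls of the +/− strand cytosines of
    each CpG pair (positions p and p+1) are summed into a single record at
    the + strand position.
    """
    def _records():
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
                try:
                    rec = AllcRecord(
                        chrom=fields[0],
                        pos=int(fields[1]),
                        strand=fields[2],
                        context=fields[3],
                        mc=int(fields[4]),
                        cov=int(fields[5]),
                        indicator=int(fields[6]) if len(fields) > 6 else 1,
                    )
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: malformed line {lineno}: {line!r}"
                    ) from exc
                if rec.mc > rec.cov:
                    raise ValueError(
                        f"{path}: line {lineno}: mc ({rec.mc}) > cov ({rec.cov})"
                    )
                if rec.pos < 1:
                    raise ValueError(f"{path}: line {lineno}: pos must be >= 1")
                yield rec

    if pair_cpg_sites:
        return pair_cpg(_records())
    return _records()


def pair_cpg(records: Iterable[AllcRecord]) -> Iterator[AllcRecord]:
    """Sum base calls of adjacent +/− CpG records into one site.

    Records must be position-sorted within each chromosome.  A − strand CG
    at position p+1 is merged into a + strand CG at p; unpaired records pass
    through unchanged.
    """
    pending: AllcRecord | None = None
    for rec in records:
        cls = classify_context(rec.context)
        if pending is not None:
            if (
                cls == "CG"
                and rec.strand == "-"
                and rec.chrom == pending.chrom
                and rec.pos == pending.pos + 1
            ):
                yield pending._replace(mc=pending.mc + rec.mc, cov=pending.cov + rec.cov)
                pending = None
                continue
            yield pending
            pending = None
        if cls == "CG" and rec.strand == "+":
            pending = rec
        else:
            yield rec
    if pending is not None:
        yield pending


def write_allc(records: Iterable[AllcRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{rec.context}\t"
                f"{rec.mc}\t{rec.cov}\t{rec.indicator}\n"
            )


# ---------------------------------------------------------------------------
# count container
# ---------------------------------------------------------------------------

@dataclass
class MethylCountMatrix:
    """Paired (mc, cov) count matrices, cells × features, per context class.

    ``features`` is a BED-like frame with columns ``chrom, start, end, name``
    (0-based half-open).  ``mc[ctx]`` and ``cov[ctx]`` are non-negative
    integer arrays with ``mc <= cov`` elementwise.
    """

    mc: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]
    features: pd.DataFrame
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ctx in self.mc:
            if ctx not in self.cov:
                raise ValueError(f"context {ctx!r} missing cov matrix")
            if self.mc[ctx].shape != self.cov[ctx].shape:
                raise ValueError(f"context {ctx!r}: mc/cov shape mismatch")
            if np.any(self.mc[ctx] > self.cov[ctx]):
                raise ValueError(f"context {ctx!r}: mc > cov")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(self.n_cells)]

    @property
    def contexts(self) -> list[str]:
        return list(self.mc)

    @property
    def n_cells(self) -> int:
        return next(iter(self.mc.values())).shape[0]

    @property
    def n_features(self) -> int:
        return next(iter(self.mc.values())).shape[1]

    def global_level(self, context: str) -> np.ndarray:
        """Per-cell aggregate mc/cov fraction for one context class."""
        mc = self.mc[context].sum(axis=1).astype(float)
        cov = self.cov[context].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
        return frac

    def raw_levels(self, context: str) -> np.ndarray:
        """Raw per-feature mc/cov with NaN where cov == 0."""
        cov = self.cov[context].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.mc[context] / cov
        lv[cov == 0] = np.nan
        return lv

    def subset(self, cells=None, features=None) -> "MethylCountMatrix":
        cells = slice(None) if cells is None else np.asarray(cells)
        feats = slice(None) if features is None else np.asarray(features)
        cell_idx = np.arange(self.n_cells)[cells]
        return MethylCountMatrix(
            mc={c: m[cells][:, feats] for c, m in self.mc.items()},
            cov={c: m[cells][:, feats] for c, m in self.cov.items()},
            features=self.features.iloc[feats].reset_index(drop=True)
            if not isinstance(feats, slice)
            else self.features.copy(),
            cell_ids=[self.cell_ids[i] for i in cell_idx],
        )


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _feature_index(features: pd.DataFrame):
    """Per-chromosome sorted (starts, ends, row indices) for containment lookup."""
    index = {}
    for chrom, grp in features.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        index[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp.index.to_numpy(),
        )
    return index


def aggregate_counts(
    allc: Mapping[str, Iterable[AllcRecord]],
    features: pd.DataFrame,
    contexts: Sequence[str] = ("CG", "CH", "CCC"),
    ccc_in_ch: bool = False,
) -> MethylCountMatrix:
    """Sum base-level calls over features into a cells × features matrix.

    ``allc`` maps cell id to an iterable of records (e.g. from
    :func:`read_allc`).  Sites are assigned by 0-based half-open containment
    (a site exactly at a feature's ``end`` is excluded).  Records on
    chromosomes absent from ``features`` are counted in the returned
    matrix's ``features.attrs['n_skipped_records']`` rather than failing.
    CCC sites are excluded from the CH class unless ``ccc_in_ch``.
    """
    cell_ids = list(allc)
    n_feat = len(features)
    feats = features.reset_index(drop=True)
    index = _feature_index(feats)
    mc = {c: np.zeros((len(cell_ids), n_feat), dtype=np.int64) for c in contexts}
    cov = {c: np.zeros((len(cell_ids), n_feat), dtype=np.int64) for c in contexts}
    n_skipped = 0
    for ci, cell in enumerate(cell_ids):
        for rec in allc[cell]:
            if rec.chrom not in index:
                n_skipped += 1
                continue
            starts, ends, rows = index[rec.chrom]
            pos0 = rec.pos - 1  # ALLC is 1-based
            j = np.searchsorted(starts, pos0, side="right") - 1
            if j < 0 or pos0 >= ends[j]:
                continue
            row = rows[j]
            cls = classify_context(rec.context)
            targets = [cls]
            if cls == "CCC" and ccc_in_ch and "CH" in mc:
                targets.append("CH")
            for ctx in targets:
                if ctx in mc:
                    mc[ctx][ci, row] += rec.mc
                    cov[ctx][ci, row] += rec.cov
    out = MethylCountMatrix(mc=mc, cov=cov, features=feats, cell_ids=cell_ids)
    out.features.attrs["n_skipped_records"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellQCProfile:
    """Per-cell mapping metrics used for cell filtering."""

    cell_id: str
    mccc: float
    mcg: float
    mch: float
    final_reads: float
    mapping_rate: float


@dataclass(frozen=True)
class CellQCThresholds:
    """Cell-filter cutoffs; defaults are the atlas values.

    A cell is kept iff mCCC < 0.03, mCG > 0.5, mCH < 0.2,
    final reads > 500,000 and mapping rate > 0.5 (all strict).
    """

    max_mccc: float = 0.03
    min_mcg: float = 0.5
    max_mch: float = 0.2
    min_reads: float = 500_000
    min_mapping_rate: float = 0.5


def qc_filter_cells(
    profiles: Sequence[CellQCProfile],
    thresholds: CellQCThresholds | None = None,
) -> np.ndarray:
    """Boolean keep-mask over cells; all five metric cuts must pass."""
    th = thresholds or CellQCThresholds()
    keep = np.empty(len(profiles), dtype=bool)
    for i, p in enumerate(profiles):
        for name in ("mccc", "mcg", "mch", "final_reads", "mapping_rate"):
            value = getattr(p, name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError(f"cell {p.cell_id!r}: metric {name!r} missing")
        keep[i] = (
            p.mccc < th.max_mccc
            and p.mcg > th.min_mcg
            and p.mch < th.max_mch
            and p.final_reads > th.min_reads
            and p.mapping_rate > th.min_mapping_rate
        )
    return keep


def _overlaps_any(features: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Boolean per-feature mask: overlaps any interval in ``other``."""
    hit = np.zeros(len(features), dtype=bool)
    if other is None or len(other) == 0:
        return hit
    by_chrom = {c: g.sort_values("start") for c, g in other.groupby("chrom")}
    for i, row in enumerate(features.itertuples(index=False)):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        j = np.searchsorted(starts, row.end, side="left")
        if np.any(ends[:j] > row.start):
            hit[i] = True
    return hit


def qc_filter_features(
    counts: MethylCountMatrix,
    blacklist: pd.DataFrame | None = None,
    min_mean_cov: float = 250.0,
    max_mean_cov: float = 3000.0,
) -> np.ndarray:
    """Boolean keep-mask over features.

    Features are kept when their mean total cytosine base calls (summed
    over contexts, averaged over cells) lie in the closed interval
    [250, 3000] and they overlap no blacklist interval.  The published rule
    excludes bins with mean calls "<250 or >3,000", so both endpoints keep.
    """
    if counts.n_cells == 0:
        raise ValueError("empty count matrix")
    total = sum(counts.cov[c] for c in counts.contexts)
    mean_cov = total.mean(axis=0)
    keep = (mean_cov >= min_mean_cov) & (mean_cov <= max_mean_cov)
    keep &= ~_overlaps_any(counts.features, blacklist)
    return keep


def compute_detection_ratio(counts: MethylCountMatrix, min_cov: int = 20) -> np.ndarray:
    """Per-cell fraction of features with total coverage strictly above ``min_cov``."""
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    total = sum(counts.cov[c] for c in counts.contexts)
    return (total > min_cov).mean(axis=1)
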