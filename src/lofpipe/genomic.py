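"""Regulatory-genomics layer.

Partitions active-chromatin peaks into promoters (within 1 kb of a
transcription start site) and enhancers, assigns peaks to their closest
gene, tests enrichment of TF binding among differentially expressed genes
against an expressed-gene background, splits bound regions into functional
(assigned gene significantly downregulated) and non-functional sets, bins
coverage signal around peak centers, and provides a simplified exact-
binomial differential-binding test for replicate count matrices.

All coordinates follow the BED convention: 0-based, half-open. The
distance between an interval [s, e) and a TSS at position p is
max(0, s - p, p - e); distance 0 means the TSS lies in or immediately at
the edge of the peak. "Within 1 kb" means this gap is <= 1000 bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss

from . import stats

__all__ = [
    "interval_point_distance",
    "classify_regulatory_regions",
    "assign_regions_to_genes",
    "binding_enrichment",
    "functional_binding_partition",
    "CoverageTrack",
    "aggregate_signal",
    "region_signal_fold_change",
    "differential_binding",
    "PROMOTER_WINDOW",
]

PROMOTER_WINDOW = 1000


def _check_intervals(df: pd.DataFrame, what: str) -> pd.DataFrame:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{what}: missing column {col!r}")
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError(f"{what}: intervals must satisfy 0 <= start < end")
    return df


def interval_point_distance(start, end, pos):
    """Gap in bases between interval(s) [start, end) and point(s) pos."""
    return np.maximum(0, np.maximum(start - pos, pos - end))


def classify_regulatory_regions(
    active_peaks: pd.DataFrame, tss: pd.DataFrame, window: int = PROMOTER_WINDOW
) -> pd.DataFrame:
    """Label each active-chromatin peak promoter or enhancer.

    A peak is a promoter iff it lies within *window* bases of some TSS on
    the same chromosome (equivalently, intersects TSS +/- window); all
    remaining peaks are enhancers. Returns the peaks with ``klass``,
    ``assigned_gene`` (nearest TSS gene) and ``distance`` columns added.
    """
    peaks = _check_intervals(active_peaks.copy(), "active_peaks")
    assignment = assign_regions_to_genes(peaks, tss)
    klass = np.where(
        assignment["distance"].notna() & (assignment["distance"] <= window),
        "promoter", "enhancer",
    )
    out = peaks.reset_index(drop=True)
    out["klass"] = klass
    out["assigned_gene"] = assignment["gene_id"].values
    out["distance"] = assignment["distance"].values
    return out


def assign_regions_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Closest-gene assignment for every peak.

    *genes* is either a TSS table (gene_id, chrom, position[, strand]) or an
    interval table (chrom, start, end, gene_id). Each peak is assigned the
    gene at minimal distance (0 on overlap); exact ties are broken by the
    leftmost gene start, then by gene id. Peaks on chromosomes without any
    gene get gene_id None and NaN distance. Row order follows *peaks*.
    """
    if genes.empty:
        raise ValueError("empty gene annotation")
    peaks = _check_intervals(peaks, "peaks").reset_index(drop=True)
    if "position" in genes.columns:
        gstart = genes["position"].to_numpy(np.int64)
        gend = gstart  # a point: [p, p] under the gap formula
    else:
        _check_intervals(genes, "genes")
        gstart = genes["start"].to_numpy(np.int64)
        gend = genes["end"].to_numpy(np.int64)
    gid_col = "gene_id" if "gene_id" in genes.columns else "name"
    gids = genes[gid_col].astype(str).to_numpy()
    gchrom = genes["chrom"].astype(str).to_numpy()

    out_gene = np.full(len(peaks), None, dtype=object)
    out_dist = np.full(len(peaks), np.nan)
    for chrom, sub in peaks.groupby("chrom", sort=False):
        sel = gchrom == str(chrom)
        if not sel.any():
            continue
        gs, ge, gi = gstart[sel], gend[sel], gids[sel]
        ps = sub["start"].to_numpy(np.int64)[:, None]
        pe = sub["end"].to_numpy(np.int64)[:, None]
        # gap between [ps, pe) and [gs, ge): 0 on overlap
        dist = np.maximum(0, np.maximum(gs[None, :] - pe, ps - ge[None, :]))
        # lexicographic minimization: distance, then gene start, then gene id
        order = np.lexsort((gi, gs))
        dist_o = dist[:, order]
        best = np.argmin(dist_o, axis=1)  # argmin keeps the first = best tie-break
        out_gene[sub.index] = gi[order][best]
        out_dist[sub.index] = dist_o[np.arange(len(sub)), best]
    return pd.DataFrame({"peak_index": np.arange(len(peaks)),
                         "gene_id": out_gene, "distance": out_dist})


def binding_enrichment(bound_genes, class_genes, background_genes):
    """Fisher enrichment of TF binding in a gene class, within a background.

    The 2x2 table counts bound/unbound (rows) against in-class/out-of-class
    (columns) over the background universe. Returns ``(table, odds_ratio,
    p)``; the odds ratio carries the Haldane 0.5 correction when a cell is
    zero (flagged on the FisherResult available via stats.fisher_exact_2x2).
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    klass = set(class_genes) & background
    if klass == background:
        raise ValueError("gene class equals the background: degenerate column")
    bound = set(bound_genes) & background
    if not bound:
        raise ValueError("no bound gene lies in the background")
    a = len(bound & klass)
    b = len(bound - klass)
    c = len(klass - bound)
    d = len(background - bound - klass)
    table = np.array([[a, b], [c, d]])
    res = stats.fisher_exact_2x2(table)
    return table, res.odds_ratio, res.p_value


def functional_binding_partition(
    tf_peaks: pd.DataFrame,
    gene_assignment: pd.DataFrame,
    de: pd.DataFrame,
    q_threshold: float = 0.05,
):
    """Split TF-bound regions by whether their gene responds transcriptionally.

    A peak is functional iff its assigned gene is significantly
    downregulated (q < q_threshold and log2fc < 0) in the DE table.
    Returns ``(functional, non_functional)`` DataFrames that partition the
    peaks with an assigned gene present in the DE table.
    """
    de_idx = de.set_index(de["gene_id"].astype(str))
    genes = gene_assignment["gene_id"]
    known = genes.astype(str).isin(de_idx.index) & genes.notna()
    if not known.any():
        raise ValueError("no assigned gene has differential-expression information")
    peaks = tf_peaks.reset_index(drop=True).loc[known.values].copy()
    sub = de_idx.loc[genes.astype(str)[known.values]]
    functional_mask = (sub["q"].values < q_threshold) & (sub["log2fc"].values < 0)
    peaks["assigned_gene"] = genes[known.values].values
    return peaks[functional_mask], peaks[~functional_mask]


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping coverage intervals with bedGraph semantics.

    Positions not covered by any interval have value 0.
    """

    chroms: dict  # chrom -> (starts, ends, values, cumulative integral)

    @classmethod
    def from_bedgraph(cls, df: pd.DataFrame) -> "CoverageTrack":
        chroms = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            values = sub["value"].to_numpy(float)
            if np.any(values < 0):
                raise ValueError("coverage values must be non-negative")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            chroms[str(chrom)] = (starts, ends, values, cum)
        return cls(chroms=chroms)

    def total(self) -> float:
        return float(sum(c[3][-1] for c in self.chroms.values()))

    def integral(self, chrom: str, a, b) -> np.ndarray:
        """Vectorized integral of the track over [a, b) (array-friendly)."""
        a = np.asarray(a, dtype=np.int64)
        b = np.asarray(b, dtype=np.int64)
        if chrom not in self.chroms:
            return np.zeros(np.broadcast(a, b).shape)
        starts, ends, values, cum = self.chroms[chrom]

        def antiderivative(x):
            # F(x) = integral of the track over (-inf, x)
            i = np.searchsorted(ends, x, side="right")  # intervals fully left of x
            full = cum[i]
            inside = (i < len(starts)) & (x > starts[np.minimum(i, len(starts) - 1)])
            j = np.minimum(i, len(starts) - 1)
            partial = np.where(inside, (x - starts[j]) * values[j], 0.0)
            return full + partial

        return antiderivative(b) - antiderivative(a)


def aggregate_signal(
    regions: pd.DataFrame,
    track: CoverageTrack,
    flank: int,
    bin_size: int = 10,
    chrom_sizes: dict | None = None,
):
    """Mean coverage in fixed bins around each region's center.

    The window is [center - flank, center + flank) with
    center = floor((start + end) / 2), split into 2*flank/bin_size bins.
    Returns ``(matrix, column_means, oob_mask)``: a regions x bins array of
    per-bin mean signal, its column means, and a boolean mask marking bins
    that extend beyond chromosome bounds (those bins take value 0).
    Chromosome bounds default to [0, inf) when *chrom_sizes* is not given.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of the bin size")
    regions = _check_intervals(regions, "regions").reset_index(drop=True)
    n_bins = 2 * flank // bin_size
    mat = np.zeros((len(regions), n_bins))
    oob = np.zeros((len(regions), n_bins), dtype=bool)
    edges_rel = np.arange(n_bins + 1) * bin_size - flank
    for i, row in enumerate(regions.itertuples()):
        center = (row.start + row.end) // 2
        edges = center + edges_rel
        lo, hi = edges[:-1], edges[1:]
        limit = None if chrom_sizes is None else chrom_sizes.get(str(row.chrom))
        bad = lo < 0
        if limit is not None:
            bad |= hi > limit
        clo = np.clip(lo, 0, None)
        chi = np.clip(hi, 0, None) if limit is None else np.clip(hi, 0, limit)
        chi = np.maximum(chi, clo)
        vals = track.integral(str(row.chrom), clo, chi) / bin_size
        vals[bad] = 0.0
        mat[i] = vals
        oob[i] = bad
    return mat, mat.mean(axis=0), oob


def region_signal_fold_change(
    regions: pd.DataFrame,
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Per-region log2 fold change of track A over track B.

    Tracks are first scaled so their genome-wide sums are equal (each is
    multiplied by mean_total / own_total), which removes global depth
    differences; the per-region statistic is
    log2((mean_a * s_a + pc) / (mean_b * s_b + pc)).
    """
    ta, tb = track_a.total(), track_b.total()
    if ta <= 0 or tb <= 0:
        raise ValueError("a track has zero total signal")
    target = (ta + tb) / 2.0
    sa, sb = target / ta, target / tb
    regions = _check_intervals(regions, "regions").reset_index(drop=True)
    rows = []
    for row in regions.itertuples():
        length = row.end - row.start
        mean_a = track_a.integral(str(row.chrom), row.start, row.end) / length
        mean_b = track_b.integral(str(row.chrom), row.start, row.end) / length
        lfc = np.log2((mean_a * sa + pseudocount) / (mean_b * sb + pseudocount))
        rows.append({"chrom": row.chrom, "start": row.start, "end": row.end,
                     "mean_a": float(mean_a), "mean_b": float(mean_b),
                     "log2fc": float(lfc)})
    return pd.DataFrame(rows)


def compare_fold_changes(group_a: np.ndarray, group_b: np.ndarray):
    """Mann-Whitney comparison of two fold-change distributions."""
    return stats.rank_group_test([np.asarray(group_a), np.asarray(group_b)])


def differential_binding(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, fdr: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Simplified differential-binding test on region read-count matrices.

    Replicates are pooled per condition; each region's pooled count in
    condition A is tested against the library-size-expected A-fraction with
    a two-sided exact binomial test, and p values are BH-adjusted.
    log2fc is computed on library-size-normalized pooled counts with a
    pseudocount, so swapping the conditions negates it exactly. Regions
    with zero total count are excluded (flagged in the ``tested`` column).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if not (np.all(a == np.floor(a)) and np.all(b == np.floor(b))):
        raise ValueError("counts must be integers")
    pooled_a = a.sum(axis=1)
    pooled_b = b.sum(axis=1)
    la, lb = pooled_a.sum(), pooled_b.sum()
    if la + lb == 0:
        raise ValueError("no reads in either condition")
    frac_a = la / (la + lb)
    total = pooled_a + pooled_b
    tested = total > 0
    pvals = np.ones(len(total))
    for i in np.where(tested)[0]:
        pvals[i] = ss.binomtest(int(pooled_a[i]), int(total[i]), frac_a).pvalue
    qvals = np.ones(len(total))
    qvals[tested] = stats.bh_adjust(pvals[tested])
    target = (la + lb) / 2.0
    norm_a = pooled_a * (target / la) if la > 0 else pooled_a
    norm_b = pooled_b * (target / lb) if lb > 0 else pooled_b
    log2fc = np.log2((norm_a + pseudocount) / (norm_b + pseudocount))
    return pd.DataFrame({
        "count_a": pooled_a.astype(np.int64), "count_b": pooled_b.astype(np.int64),
        "log2fc": log2fc, "p": pvals, "q": qvals,
        "significant": tested & (qvals < fdr), "tested": tested,
    })
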