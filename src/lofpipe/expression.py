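"""Expression-matrix operations: probe collapsing, the expressed-gene
filter, per-sample ranking against the cohort median, and the
extreme-decile contrast analysis.

Matrices are pandas DataFrames on a linear (non-log) scale, genes in rows
and samples in columns. Per-tumor ranking scores each gene as

    log2((x[g, s] + pc) / (median_over_samples(x[g, .]) + pc))

so a sample that matches the cohort's per-gene median profile scores zero
everywhere. The extreme-decile contrast splits samples on one ranking
gene's expression (group size ceil(n / 10)) and compares query gene sets
between the low and high groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "GeneSet",
    "collapse_probes",
    "filter_expressed",
    "rank_sample_vs_cohort",
    "decile_partition",
    "decile_contrast",
    "make_de_table",
]


@dataclass(frozen=True)
class GeneSet:
    """Named, duplicate-free gene membership set."""

    name: str
    members: tuple

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen = []
        for m in self.members:
            if m not in seen:
                seen.append(m)
        object.__setattr__(self, "members", tuple(seen))

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def collapse_probes(probe_matrix: pd.DataFrame, probe_to_gene) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the probe with the highest variance across all samples is
    retained; exact variance ties are broken by the lexicographically
    smallest probe id. Probes without a gene assignment are dropped.
    """
    mapping = pd.Series(probe_to_gene).dropna()
    mapping.index = mapping.index.astype(str)
    keep = probe_matrix.index.intersection(mapping.index)
    if keep.empty:
        raise ValueError("no probe maps to any gene")
    sub = probe_matrix.loc[keep]
    variances = sub.var(axis=1, ddof=1)
    choice = (
        pd.DataFrame(
            {"gene": mapping.loc[keep].values, "var": variances.values,
             "probe": keep.values}
        )
        .sort_values(["gene", "var", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    out = sub.loc[choice["probe"].values]
    out.index = pd.Index(choice["gene"].values, name="gene_id")
    return out.sort_index()


def filter_expressed(table, threshold: float = 2.5) -> set[str]:
    """Expressed-gene filter: genes with log2(basemean) strictly > threshold.

    Accepts a differential-expression table with a ``basemean`` column or an
    expression matrix, in which case the per-gene row mean is the basemean
    proxy.
    """
    if isinstance(table, pd.DataFrame) and "basemean" in table.columns:
        base = pd.Series(table["basemean"].values,
                         index=table["gene_id"].values
                         if "gene_id" in table.columns else table.index)
    elif isinstance(table, pd.DataFrame):
        base = table.mean(axis=1)
    else:
        raise TypeError("expected a DataFrame")
    if (base < 0).any():
        raise ValueError("basemean must be non-negative")
    with np.errstate(divide="ignore"):
        log2base = np.log2(base.astype(float))
    return set(base.index[log2base > threshold].astype(str))


def rank_sample_vs_cohort(
    matrix: pd.DataFrame, sample_id: str, pseudocount: float = 1.0
) -> pd.Series:
    """Rank one sample's genes against the cohort's per-gene median.

    Returns a Series of scores sorted strictly descending; tied scores are
    ordered by gene id ascending so the ranking is deterministic.
    """
    if sample_id not in matrix.columns:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need at least three samples for a cohort ranking")
    med = matrix.median(axis=1)
    score = np.log2((matrix[sample_id] + pseudocount) / (med + pseudocount))
    frame = pd.DataFrame({"score": score, "gene": score.index.astype(str)})
    frame = frame.sort_values(["score", "gene"], ascending=[False, True])
    out = pd.Series(frame["score"].values, index=frame["gene"].values,
                    name=sample_id)
    return out


def decile_partition(values: pd.Series):
    """Split samples into the bottom and top deciles of *values*.

    Group size is ceil(n / 10); ties at a group boundary are resolved by
    sample id ascending. Returns ``(low_ids, high_ids)`` as lists.
    """
    values = pd.Series(values)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 samples for a decile split")
    k = math.ceil(n / 10)
    frame = pd.DataFrame({"v": values.values, "s": values.index.astype(str)})
    asc = frame.sort_values(["v", "s"], ascending=[True, True])
    low = asc["s"].iloc[:k].tolist()
    desc = frame.sort_values(["v", "s"], ascending=[False, True])
    high = desc["s"].iloc[:k].tolist()
    return low, high


def decile_contrast(
    matrix: pd.DataFrame,
    ranking_gene: str,
    query_sets: list[GeneSet],
    control_set: GeneSet,
    pseudocount: float = 1.0,
    expected_directions: list[str] | None = None,
    alpha: float = 0.05,
):
    """Contrast gene expression between extreme deciles of one gene's level.

    Samples are split into bottom/top deciles of *ranking_gene* expression;
    each gene's contrast is ``log2((mean_low + pc) / (mean_high + pc))``.
    Returns a dict with the per-gene contrast table, per-set median and IQR,
    a Kruskal-Wallis p across the query and control sets, and per-set
    concordance: the fraction of member genes individually different
    between the groups (two-sided Mann-Whitney, nominal p < *alpha*) in the
    expected direction. Directions default to the sign of each set's median
    contrast when not given explicitly as ``"down"`` / ``"up"``.
    """
    if ranking_gene not in matrix.index:
        raise KeyError(f"ranking gene {ranking_gene!r} not in matrix")
    low, high = decile_partition(matrix.loc[ranking_gene])
    all_sets = list(query_sets) + [control_set]
    for gs in all_sets:
        if not set(gs.members) & set(matrix.index):
            raise ValueError(f"gene set {gs.name!r} has no genes in the matrix")

    mean_low = matrix[low].mean(axis=1)
    mean_high = matrix[high].mean(axis=1)
    contrast = np.log2((mean_low + pseudocount) / (mean_high + pseudocount))
    table = pd.DataFrame({"contrast": contrast})

    groups, summaries = [], {}
    for gs in all_sets:
        members = [g for g in gs.members if g in matrix.index]
        vals = contrast.loc[members].values
        groups.append(vals)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summaries[gs.name] = {"median": float(med), "iqr": (float(q1), float(q3)),
                              "n_genes": len(members)}
    kw_stat, kw_p = stats.rank_group_test(groups)

    if expected_directions is None:
        expected_directions = [
            "down" if summaries[gs.name]["median"] < 0 else "up"
            for gs in query_sets
        ]
    concordance = {}
    for gs, direction in zip(query_sets, expected_directions):
        members = [g for g in gs.members if g in matrix.index]
        hits = 0
        too_small = len(low) + len(high) < 3  # no per-gene test possible
        for g in members:
            if too_small:
                p = 1.0
            else:
                _, p = stats.rank_group_test(
                    [matrix.loc[g, low].values, matrix.loc[g, high].values]
                )
            sign_ok = (
                contrast.loc[g] < 0 if direction == "down" else contrast.loc[g] > 0
            )
            if p < alpha and sign_ok:
                hits += 1
        concordance[gs.name] = hits / len(members)

    return {
        "contrast": table,
        "set_summaries": summaries,
        "kruskal_wallis": {"statistic": kw_stat, "p": kw_p},
        "concordance": concordance,
        "low_samples": low,
        "high_samples": high,
    }


def make_de_table(gene_ids, log2fc, basemean, q, q_threshold: float = 0.05):
    """Assemble a differential-expression table with a direction column.

    Direction is ``down``/``up`` for significant genes (q < threshold) by
    the sign of log2fc, ``ns`` otherwise.
    """
    df = pd.DataFrame(
        {"gene_id": np.asarray(gene_ids, dtype=str),
         "log2fc": np.asarray(log2fc, float),
         "basemean": np.asarray(basemean, float),
         "q": np.asarray(q, float)}
    )
    if (df["basemean"] < 0).any():
        raise ValueError("basemean must be non-negative")
    sig = df["q"] < q_threshold
    df["direction"] = np.where(
        sig & (df["log2fc"] < 0), "down", np.where(sig & (df["log2fc"] > 0), "up", "ns")
    )
    return df
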