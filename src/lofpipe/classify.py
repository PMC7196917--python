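"""Classify tumor samples into loss-of-function (LoF) phenotype groups.

Each sample's genes are ranked against the cohort median profile and the
LoF gene set is scored by preranked GSEA. The sample is labeled

    LoF       if NES < 0 and nominal p < alpha   (coordinated downregulation)
    Control1  if NES < 0 and p >= alpha
    Control2  if NES >= 0

NES exactly 0 (including the undefined-NES fallback) goes to Control2 and
p exactly alpha to Control1, so the three labels always partition the
cohort. The module also classifies mutation records into putative-LoF /
unknown / wildtype and tests the association between phenotype class and
mutation status with Fisher's exact test.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gsea, stats
from .expression import GeneSet, rank_sample_vs_cohort

__all__ = [
    "SampleClass",
    "classify_sample",
    "classify_cohort",
    "classify_mutation_record",
    "classify_mutation_table",
    "mutation_association",
    "group_expression_compare",
]

LABELS = ("LoF", "Control1", "Control2")
_MUT_TYPES = {"deletion", "substitution", "insertion", "structural_variant", "none"}
_IMPACTS = {"high", "loss_of_function", "unknown", "none"}


@dataclass(frozen=True)
class SampleClass:
    sample_id: str
    label: str
    nes: float
    p_nominal: float


def _label(nes: float, p: float, alpha: float) -> str:
    if nes < 0 and p < alpha:
        return "LoF"
    if nes < 0:
        return "Control1"
    return "Control2"


def classify_sample(
    ranked: pd.Series,
    lof_set: GeneSet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> SampleClass:
    """Three-way LoF / Control1 / Control2 call for one ranked sample."""
    res = gsea.gsea_preranked(ranked, [lof_set], n_perm=n_perm, seed=seed)
    nes = float(res["nes"].iloc[0])
    p = float(res["p_nominal"].iloc[0])
    return SampleClass(
        sample_id=str(ranked.name) if ranked.name is not None else "",
        label=_label(nes, p, alpha), nes=nes, p_nominal=p,
    )


def classify_cohort(
    matrix: pd.DataFrame,
    lof_set: GeneSet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify every sample of a cohort expression matrix.

    Each sample gets its own ranking (versus the per-gene cohort median)
    and its own permutation null; per-sample null seeds are derived from
    *seed* and the sample id, so the result does not depend on column
    order. Returns a DataFrame (sample_id, label, nes, p_nominal).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least three samples")
    rows = []
    for sample_id in matrix.columns:
        ranked = rank_sample_vs_cohort(matrix, sample_id, pseudocount=pseudocount)
        sub_seed = _sample_seed(seed, str(sample_id))
        sc = classify_sample(ranked, lof_set, n_perm=n_perm, alpha=alpha, seed=sub_seed)
        rows.append({"sample_id": str(sample_id), "label": sc.label,
                     "nes": sc.nes, "p_nominal": sc.p_nominal})
    return pd.DataFrame(rows)


def _sample_seed(seed, sample_id: str) -> int:
    base = 0 if seed is None else int(seed)
    return (base * 1_000_003 + zlib.crc32(sample_id.encode())) % (2**31 - 1)


def classify_mutation_record(mutation_type: str, impact: str) -> str:
    """Putative functional classification of one mutation record.

    Small deletions, insertions and single-base substitutions annotated
    with "high" functional impact, and structural variants annotated as
    loss-of-function, count as ``LoF_mutant``; any other mutation is of
    ``unknown`` consequence; absence of mutation is ``wildtype``.
    """
    if mutation_type not in _MUT_TYPES:
        raise ValueError(f"unrecognized mutation type: {mutation_type!r}")
    if impact not in _IMPACTS:
        raise ValueError(f"unrecognized impact label: {impact!r}")
    if mutation_type == "none":
        return "wildtype"
    if mutation_type in {"deletion", "substitution", "insertion"} and impact == "high":
        return "LoF_mutant"
    if mutation_type == "structural_variant" and impact == "loss_of_function":
        return "LoF_mutant"
    return "unknown"


def classify_mutation_table(mutations: pd.DataFrame) -> pd.Series:
    """Vector version over a (sample_id, mutation_type, impact) table."""
    out = {
        str(r.sample_id): classify_mutation_record(str(r.mutation_type), str(r.impact))
        for r in mutations.itertuples()
    }
    return pd.Series(out, name="mutation_class")


def mutation_association(
    classes: pd.DataFrame, mutations: pd.DataFrame, lof_vs: str = "all_others"
):
    """2x2 association between phenotype class and putative-LoF mutation.

    Rows are {LoF class, all other classes}, columns {LoF_mutant, not};
    mutations of unknown consequence count as "not" because the association
    concerns putative loss-of-function mutations only. Returns
    ``(table, odds_ratio, p)`` with a two-sided Fisher exact p.
    """
    if lof_vs != "all_others":
        raise ValueError("only the LoF-vs-all-others contrast is defined")
    mut_class = classify_mutation_table(mutations)
    ids = classes["sample_id"].astype(str)
    if not set(ids) & set(mut_class.index):
        raise ValueError("classification and mutation tables share no sample ids")
    is_lof_pheno = classes["label"].values == "LoF"
    is_mut = ids.map(mut_class).fillna("wildtype").values == "LoF_mutant"
    a = int(np.sum(is_lof_pheno & is_mut))
    b = int(np.sum(is_lof_pheno & ~is_mut))
    c = int(np.sum(~is_lof_pheno & is_mut))
    d = int(np.sum(~is_lof_pheno & ~is_mut))
    table = np.array([[a, b], [c, d]])
    res = stats.fisher_exact_2x2(table)
    return table, res.odds_ratio, res.p_value


def group_expression_compare(matrix: pd.DataFrame, gene_id: str, classes: pd.DataFrame):
    """Compare one gene's expression across the phenotype classes.

    Returns ``(group_values, summaries, statistic, p)`` with the omnibus
    rank test from the stats layer (Kruskal-Wallis; two-sided Mann-Whitney
    p when only two classes are populated).
    """
    if gene_id not in matrix.index:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    groups, summaries = {}, {}
    for label in LABELS:
        ids = classes.loc[classes["label"] == label, "sample_id"].astype(str)
        ids = [s for s in ids if s in matrix.columns]
        if ids:
            vals = matrix.loc[gene_id, ids].to_numpy(dtype=float)
            groups[label] = vals
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summaries[label] = {"n": len(vals), "median": float(med),
                                "iqr": (float(q1), float(q3))}
    if len(groups) < 2:
        raise ValueError("need at least two non-empty classes to compare")
    stat, p = stats.rank_group_test(list(groups.values()))
    return groups, summaries, stat, p
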