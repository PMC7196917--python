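"""Preranked gene-set enrichment analysis from first principles.

Implements the weighted Kolmogorov-Smirnov-like running-sum statistic: with
genes ranked by score, set members ("hits") advance the running sum by
|score|^w normalized by the summed weights of the set, and non-members
("misses") retreat it by 1/(N - N_hit). The enrichment score (ES) is the
running-sum value of maximal absolute deviation from zero, the leading edge
the set members at or before (after, for negative ES) the extremum.

Because the ranked list comes from a single sample there is no phenotype
label to permute; the null is built from random gene sets of the same size
("gene-tag" permutation). NES divides ES by the mean magnitude of same-sign
null values, and the nominal p is the same-sign permutation tail with
add-one smoothing: p = (b + 1) / (m + 1). FDR q values follow the
sign-stratified pooled-NES procedure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import GeneSet

__all__ = [
    "GseaResult",
    "NullDistribution",
    "enrichment_score",
    "permutation_null",
    "nes_and_pvalue",
    "gsea_preranked",
]

_PERM_BATCH = 2048  # permutations per vectorized batch, caps peak memory


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    q_fdr: float
    leading_edge: tuple
    n_perm_used: int
    set_size: int
    n_dropped: int = 0  # set members absent from the ranked list


@dataclass(frozen=True)
class NullDistribution:
    set_size: int
    values: np.ndarray
    seed: int | None = None

    def same_sign(self, es: float) -> np.ndarray:
        if es > 0:
            return self.values[self.values > 0]
        if es < 0:
            return self.values[self.values < 0]
        return self.values


def _as_arrays(ranked: pd.Series):
    genes = np.asarray(ranked.index, dtype=str)
    scores = np.asarray(ranked.values, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranked scores must be finite")
    if np.unique(genes).size != genes.size:
        raise ValueError("ranked list contains duplicate gene ids")
    return genes, scores


def _running_sum(hit_mask: np.ndarray, scores: np.ndarray, w: float) -> np.ndarray:
    n = scores.size
    n_hit = int(hit_mask.sum())
    weights = np.abs(scores) ** w
    denom = weights[hit_mask].sum()
    if denom == 0:
        # all hit scores are exactly zero: fall back to unweighted steps
        weights = np.ones(n)
        denom = float(n_hit)
    steps = np.where(hit_mask, weights / denom, -1.0 / (n - n_hit))
    return np.cumsum(steps)


def enrichment_score(ranked: pd.Series, gene_set: GeneSet, weight_exponent: float = 1.0):
    """Weighted running-sum enrichment score of a gene set in a ranked list.

    Returns ``(es, running_sum, leading_edge)``. The set must intersect the
    ranked list and must not cover it entirely (the miss decrement would be
    undefined). On an exact tie between the positive and negative extrema
    the positive one is taken.
    """
    genes, scores = _as_arrays(ranked)
    members = set(gene_set.members)
    hit_mask = np.fromiter((g in members for g in genes), bool, count=genes.size)
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the ranked list")
    if n_hit == genes.size:
        raise ValueError("gene set covers the entire ranked list")
    rs = _running_sum(hit_mask, scores, weight_exponent)
    i_max, i_min = int(np.argmax(rs)), int(np.argmin(rs))
    if rs[i_max] >= -rs[i_min]:
        es, extremum = float(rs[i_max]), i_max
        le_mask = hit_mask[: extremum + 1]
        leading = tuple(genes[: extremum + 1][le_mask])
    else:
        es, extremum = float(rs[i_min]), i_min
        le_mask = hit_mask[extremum:]
        leading = tuple(genes[extremum:][le_mask])
    return es, rs, leading


def _batch_es(scores: np.ndarray, subsets: np.ndarray, w: float) -> np.ndarray:
    """ES for many gene subsets at once; subsets is (n_perm, set_size) of indices."""
    n = scores.size
    n_perm, k = subsets.shape
    weights = np.abs(scores) ** w
    steps = np.full((n_perm, n), -1.0 / (n - k))
    rows = np.repeat(np.arange(n_perm), k)
    cols = subsets.ravel()
    denom = weights[subsets].sum(axis=1)
    zero = denom == 0
    if np.any(zero):
        denom = np.where(zero, k, denom)
        hit_w = np.where(zero[:, None], 1.0, weights[subsets])
    else:
        hit_w = weights[subsets]
    steps[rows, cols] = (hit_w / denom[:, None]).ravel()
    rs = np.cumsum(steps, axis=1)
    hi = rs.max(axis=1)
    lo = rs.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def permutation_null(
    ranked: pd.Series, set_size: int, n_perm: int, seed=None, weight_exponent: float = 1.0
) -> NullDistribution:
    """Null ES distribution from uniformly random gene sets of a given size."""
    _, scores = _as_arrays(ranked)
    n = scores.size
    if not (1 <= set_size < n):
        raise ValueError("set_size must satisfy 1 <= set_size < N")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    values = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(_PERM_BATCH, n_perm - done)
        # random k-subsets via partial argsort of uniform keys
        keys = rng.random((b, n))
        subsets = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        values[done : done + b] = _batch_es(scores, subsets, weight_exponent)
        done += b
    return NullDistribution(set_size=set_size, values=values,
                            seed=seed if isinstance(seed, int) else None)


def nes_and_pvalue(es: float, null: NullDistribution):
    """Normalize an ES against its permutation null.

    NES = ES / mean(|same-sign null values|); nominal p = (b + 1) / (m + 1)
    with m the number of same-sign null values and b how many of those are
    at least as extreme as |ES|. With ES = 0, or no same-sign null values,
    NES is reported as 0 with p = 1.
    """
    if not (-1.0 - 1e-12 <= es <= 1.0 + 1e-12):
        raise ValueError("ES must lie in [-1, 1]")
    if null.values.size == 0:
        raise ValueError("empty null distribution")
    if es == 0:
        return 0.0, 1.0
    same = null.same_sign(es)
    m = same.size
    if m == 0:
        return 0.0, 1.0
    nes = es / float(np.mean(np.abs(same)))
    b = int(np.sum(np.abs(same) >= abs(es)))
    p = (b + 1) / (m + 1)
    return float(nes), float(p)


def _fdr_pooled(obs_nes: np.ndarray, perm_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified pooled-NES FDR.

    For each observed NES, q = (fraction of pooled permuted NES at least as
    extreme, same sign) / (fraction of observed NES at least as extreme,
    same sign), clipped to [0, 1] and monotonized within each sign stratum
    so q never decreases as |NES| decreases.
    """
    q = np.ones(obs_nes.size)
    for sign in (1, -1):
        idx = np.where(np.sign(obs_nes) == sign)[0]
        if idx.size == 0:
            continue
        perm = perm_nes[np.sign(perm_nes) == sign]
        obs = obs_nes[idx]
        for j, i in enumerate(idx):
            mag = abs(obs_nes[i])
            num = np.mean(np.abs(perm) >= mag) if perm.size else 0.0
            den = np.mean(np.abs(obs) >= mag)
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        # monotonize: traverse from most to least extreme, carry the running max
        order = idx[np.argsort(-np.abs(obs_nes[idx]))]
        running = 0.0
        for i in order:
            running = max(running, q[i])
            q[i] = running
    return q


def gsea_preranked(
    ranked: pd.Series,
    gene_sets,
    n_perm: int = 10_000,
    weight_exponent: float = 1.0,
    seed=None,
) -> pd.DataFrame:
    """Preranked GSEA over one or more gene sets.

    Each set is scored, normalized and assigned a nominal p against its own
    size-matched random-set null; q values pool observed and permuted NES
    per sign stratum. Gene-set input order does not affect any reported
    number. Returns a DataFrame with one row per set.
    """
    if isinstance(gene_sets, GeneSet):
        gene_sets = [gene_sets]
    gene_sets = list(gene_sets)
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    genes, _ = _as_arrays(ranked)
    universe = set(genes)

    rows = []
    perm_nes_pool = []
    rng = np.random.default_rng(seed)
    # draw per-set null seeds from the set name so results are order-invariant
    base = rng.integers(0, 2**31 - 1)
    for gs in sorted(gene_sets, key=lambda g: g.name):
        present = [g for g in gs.members if g in universe]
        dropped = len(gs.members) - len(present)
        if not present:
            raise ValueError(f"gene set {gs.name!r} does not intersect the ranked list")
        es, _, leading = enrichment_score(
            ranked, GeneSet(gs.name, tuple(present)), weight_exponent
        )
        set_seed = (base + zlib.crc32(gs.name.encode())) % (2**31 - 1)
        null = permutation_null(ranked, len(present), n_perm, seed=int(set_seed),
                                weight_exponent=weight_exponent)
        nes, p = nes_and_pvalue(es, null)
        mean_pos = np.mean(null.values[null.values > 0]) if np.any(null.values > 0) else np.nan
        mean_neg = np.mean(np.abs(null.values[null.values < 0])) if np.any(null.values < 0) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            pn = np.where(null.values > 0, null.values / mean_pos,
                          null.values / mean_neg)
        perm_nes_pool.append(pn[np.isfinite(pn)])
        rows.append(
            {"set_name": gs.name, "size": len(present), "es": es, "nes": nes,
             "p_nominal": p, "leading_edge": leading, "n_dropped": dropped}
        )
    obs_nes = np.array([r["nes"] for r in rows])
    q = _fdr_pooled(obs_nes, np.concatenate(perm_nes_pool))
    for r, qv in zip(rows, q):
        r["q_fdr"] = float(qv)
        r["n_perm_used"] = n_perm
    df = pd.DataFrame(rows)
    return df[["set_name", "size", "es", "nes", "p_nominal", "q_fdr",
               "leading_edge", "n_perm_used", "n_dropped"]]


def result_from_row(row) -> GseaResult:
    """Convenience: a typed record from one ``gsea_preranked`` output row."""
    return GseaResult(
        set_name=row["set_name"], es=float(row["es"]), nes=float(row["nes"]),
        p_nominal=float(row["p_nominal"]), q_fdr=float(row["q_fdr"]),
        leading_edge=tuple(row["leading_edge"]), n_perm_used=int(row["n_perm_used"]),
        set_size=int(row["size"]), n_dropped=int(row["n_dropped"]),
    )
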