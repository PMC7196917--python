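"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data the analysis consumes:

* ``gen_cohort`` — a tumor expression cohort in which a chosen fraction of
  samples carries a coordinated log2 downshift of a designated gene set
  (the loss-of-function phenotype), plus mutation labels drawn with a
  stated penetrance in phenotype samples and a background rate elsewhere.
  Per-gene baseline log2 means are uniform over a configurable range and
  sample values are Gaussian in log2 space, then exponentiated, so the
  matrix is strictly positive on a linear scale.
* ``gen_regulatory_landscape`` — TSSs, active-chromatin peaks, TF-binding
  peaks, a differential-expression table in which TF-bound genes are
  downregulated with a configured odds ratio, and a pair of fixed-step
  coverage tracks that differ at functional regions.
* ``gen_motif_sequences`` — background sequences drawn i.i.d. from a PWM's
  background distribution with motif instances (sampled position-wise from
  the PWM) planted at random offsets and strands.
* ``gen_tma_cases`` — tissue-microarray core records (intensity,
  percent-positive, grade) with a configurable intensity shift in
  high-grade cases.

All generators are deterministic for a fixed config and seed, and return a
``GroundTruth`` record whose identifier sets refer only to generated
entities. Everything lives on a single synthetic chromosome ``chrS``
unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .motifs import PWM

__all__ = [
    "CohortSimConfig",
    "LandscapeSimConfig",
    "GroundTruth",
    "gen_cohort",
    "gen_regulatory_landscape",
    "gen_motif_sequences",
    "gen_tma_cases",
]

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class GroundTruth:
    lof_sample_ids: frozenset = frozenset()
    mutated_sample_ids: frozenset = frozenset()
    set_gene_ids: frozenset = frozenset()
    bound_gene_ids: frozenset = frozenset()
    down_gene_ids: frozenset = frozenset()
    motif_region_ids: frozenset = frozenset()


@dataclass(frozen=True)
class CohortSimConfig:
    n_samples: int = 120
    n_genes: int = 1000
    lof_fraction: float = 0.2
    set_size: int = 100
    effect_log2: float = 1.0
    noise_sd: float = 0.5
    baseline_mean_range: tuple = (3.0, 10.0)
    mutation_penetrance: float = 0.19
    background_mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.set_size >= self.n_genes:
            raise ValueError("set_size must be smaller than n_genes")
        for name in ("lof_fraction", "mutation_penetrance", "background_mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def gen_cohort(config: CohortSimConfig):
    """Simulate an expression cohort with a planted LoF phenotype.

    Returns ``(matrix, truth, mutations)``: a strictly positive linear-scale
    gene-by-sample DataFrame, the GroundTruth record, and a mutation table
    (sample_id, mutation_type, impact) in which mutated samples carry a
    small deletion of "high" functional impact.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"g{i:04d}" for i in range(config.n_genes)])
    samples = np.array([f"s{i:03d}" for i in range(config.n_samples)])
    n_lof = round(config.lof_fraction * config.n_samples)
    lof_idx = rng.choice(config.n_samples, size=n_lof, replace=False)
    set_idx = rng.choice(config.n_genes, size=config.set_size, replace=False)

    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    log2vals = rng.normal(baseline[:, None], config.noise_sd,
                          size=(config.n_genes, config.n_samples))
    shift = np.zeros((config.n_genes, config.n_samples))
    shift[np.ix_(set_idx, lof_idx)] = config.effect_log2
    log2vals -= shift
    matrix = pd.DataFrame(np.exp2(log2vals), index=genes, columns=samples)
    matrix.index.name = "gene_id"

    is_lof = np.zeros(config.n_samples, dtype=bool)
    is_lof[lof_idx] = True
    p_mut = np.where(is_lof, config.mutation_penetrance,
                     config.background_mutation_rate)
    mutated = rng.random(config.n_samples) < p_mut
    mutations = pd.DataFrame({
        "sample_id": samples,
        "mutation_type": np.where(mutated, "deletion", "none"),
        "impact": np.where(mutated, "high", "none"),
    })
    truth = GroundTruth(
        lof_sample_ids=frozenset(samples[is_lof]),
        mutated_sample_ids=frozenset(samples[mutated]),
        set_gene_ids=frozenset(genes[set_idx]),
    )
    return matrix, truth, mutations


@dataclass(frozen=True)
class LandscapeSimConfig:
    n_genes: int = 1000
    genome_length: int = 10_000_000
    n_active_peaks: int = 400
    n_tf_peaks: int = 200
    frac_peaks_promoter: float = 0.5
    binding_down_odds_ratio: float = 5.0
    de_down_fraction: float = 0.2
    chrom: str = "chrS"
    peak_width: int = 400
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.frac_peaks_promoter <= 1.0):
            raise ValueError("frac_peaks_promoter must lie in [0, 1]")
        if self.binding_down_odds_ratio < 0:
            raise ValueError("odds ratio must be non-negative")
        if not (0.0 < self.de_down_fraction < 1.0):
            raise ValueError("de_down_fraction must lie in (0, 1)")
        # genes sit on a regular grid; enhancer peaks reach up to 4 kb from
        # their TSS and must stay closer to it than to any neighbor
        spacing = self.genome_length // (self.n_genes + 1)
        if spacing < 2 * (4000 + self.peak_width):
            raise ValueError("genome too small for the requested genes and peaks")
        if self.n_tf_peaks > self.n_genes or self.n_active_peaks > 2 * self.n_genes:
            raise ValueError("genome too small for the requested peaks")


def _down_probs(or_target: float, bound_frac: float, overall: float):
    """Per-group downregulation probabilities hitting the target odds ratio.

    Solves bound_frac * p1 + (1 - bound_frac) * p0 = overall with
    odds(p1) / odds(p0) = or_target.
    """
    if or_target == 1.0:
        return overall, overall

    def p1_of(p0):
        o = or_target * p0 / (1 - p0)
        return o / (1 + o)

    f = lambda p0: bound_frac * p1_of(p0) + (1 - bound_frac) * p0 - overall
    p0 = brentq(f, 1e-9, 1 - 1e-9)
    return p1_of(p0), p0


def gen_regulatory_landscape(config: LandscapeSimConfig):
    """Simulate a regulatory landscape with a planted binding-DE association.

    Returns a dict with keys ``tss`` (gene_id, chrom, position, strand),
    ``active_peaks`` and ``tf_peaks`` (BED-like DataFrames), ``de`` (the
    differential-expression table), ``track_a``/``track_b`` (fixed 10-bp
    step bedGraph DataFrames covering the peak neighborhoods; track_a is
    doubled at functional TF peaks) and ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    n, w = config.n_genes, config.peak_width
    spacing = config.genome_length // (n + 1)
    genes = np.array([f"g{i:04d}" for i in range(n)])
    tss_pos = (np.arange(1, n + 1) * spacing).astype(np.int64)
    strands = rng.choice(["+", "-"], size=n)
    tss = pd.DataFrame({"gene_id": genes, "chrom": config.chrom,
                        "position": tss_pos, "strand": strands})

    # TF peaks: bound genes chosen at random; promoter peaks sit on the TSS,
    # enhancer peaks at a 2-5 kb offset (still closest to their gene).
    bound_idx = np.sort(rng.choice(n, size=config.n_tf_peaks, replace=False))
    is_prom = rng.random(config.n_tf_peaks) < config.frac_peaks_promoter
    offset = np.where(
        is_prom,
        rng.integers(-500, 501, size=config.n_tf_peaks),
        rng.integers(2000, 4001, size=config.n_tf_peaks)
        * rng.choice([-1, 1], size=config.n_tf_peaks),
    )
    centers = tss_pos[bound_idx] + offset
    tf_peaks = pd.DataFrame({
        "chrom": config.chrom,
        "start": np.maximum(0, centers - w // 2),
        "end": centers + w // 2,
        "name": [f"tf_peak_{i:04d}" for i in range(config.n_tf_peaks)],
        "score": np.round(rng.uniform(10, 1000, config.n_tf_peaks), 2),
        "strand": ".",
    }).sort_values("start", ignore_index=True)

    # active-chromatin peaks: cover every TF peak, plus extra promoter and
    # distal peaks at unbound genes up to n_active_peaks
    extra = max(0, config.n_active_peaks - config.n_tf_peaks)
    unbound = np.setdiff1d(np.arange(n), bound_idx)
    extra_idx = rng.choice(unbound, size=min(extra, unbound.size), replace=False)
    extra_prom = rng.random(extra_idx.size) < config.frac_peaks_promoter
    extra_off = np.where(
        extra_prom,
        rng.integers(-500, 501, size=extra_idx.size),
        rng.integers(2000, 4001, size=extra_idx.size)
        * rng.choice([-1, 1], size=extra_idx.size),
    )
    extra_centers = tss_pos[extra_idx] + extra_off
    active_centers = np.concatenate([centers, extra_centers])
    active = pd.DataFrame({
        "chrom": config.chrom,
        "start": np.maximum(0, active_centers - w // 2),
        "end": active_centers + w // 2,
        "name": [f"active_peak_{i:04d}" for i in range(active_centers.size)],
        "score": 0,
        "strand": ".",
    }).sort_values("start", ignore_index=True)

    # DE outcomes with the planted binding -> downregulation odds ratio
    bound_mask = np.zeros(n, dtype=bool)
    bound_mask[bound_idx] = True
    p_bound, p_unbound = _down_probs(
        config.binding_down_odds_ratio, bound_mask.mean(), config.de_down_fraction
    )
    down = rng.random(n) < np.where(bound_mask, p_bound, p_unbound)
    q = np.where(down, rng.uniform(1e-6, 0.049, n), rng.uniform(0.05, 1.0, n))
    log2fc = np.where(down, rng.uniform(-3.0, -0.5, n), rng.normal(0.0, 0.3, n))
    basemean = np.exp2(rng.uniform(2.6, 12.0, n))
    de = pd.DataFrame({
        "gene_id": genes, "log2fc": log2fc, "basemean": basemean, "q": q,
        "direction": np.where(down, "down", "ns"),
    })

    # coverage: 10-bp step tracks over each TF peak's +/- 2 kb neighborhood;
    # track_a doubled at functional peaks (bound gene truly downregulated)
    functional = down[bound_idx]
    step = 10
    rows_a, rows_b = [], []
    for center, fn in zip(centers, functional):
        start = max(0, (center - 2000) // step * step)
        stops = np.arange(start, center + 2000, step)
        base = np.round(rng.uniform(0.5, 2.0, stops.size), 3)
        in_peak = (stops + step > center - w // 2) & (stops < center + w // 2)
        a = np.where(in_peak & fn, base * 2.0, base)
        for s, va, vb in zip(stops, a, base):
            rows_a.append((config.chrom, int(s), int(s + step), float(va)))
            rows_b.append((config.chrom, int(s), int(s + step), float(vb)))
    cols = ["chrom", "start", "end", "value"]
    track_a = pd.DataFrame(rows_a, columns=cols).drop_duplicates(["chrom", "start"])
    track_b = pd.DataFrame(rows_b, columns=cols).drop_duplicates(["chrom", "start"])

    truth = GroundTruth(
        bound_gene_ids=frozenset(genes[bound_mask]),
        down_gene_ids=frozenset(genes[down]),
    )
    return {"tss": tss, "active_peaks": active, "tf_peaks": tf_peaks, "de": de,
            "track_a": track_a, "track_b": track_b, "truth": truth}


def gen_motif_sequences(
    n_regions: int,
    region_length: int,
    pwm: PWM,
    insertion_prob: float,
    seed: int = 0,
):
    """Sequences with motif instances planted at random offsets and strands.

    Background bases are i.i.d. draws from the PWM's background
    distribution; with probability *insertion_prob* a region receives one
    instance sampled position-wise from the PWM. Returns
    ``(sequences, truth)`` with sequences as an ordered dict of id -> str.
    """
    if region_length < pwm.width:
        raise ValueError("regions must be at least as long as the motif")
    if not (0.0 <= insertion_prob <= 1.0):
        raise ValueError("insertion_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bg = np.asarray(pwm.background)
    seqs: dict[str, str] = {}
    planted = []
    for i in range(n_regions):
        region_id = f"region_{i:04d}"
        chars = rng.choice(list(_ALPHABET), size=region_length, p=bg)
        if rng.random() < insertion_prob:
            inst = [
                _ALPHABET[rng.choice(4, p=pwm.probs[j])] for j in range(pwm.width)
            ]
            if rng.random() < 0.5:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                inst = [comp[b] for b in reversed(inst)]
            off = int(rng.integers(0, region_length - pwm.width + 1))
            chars[off : off + pwm.width] = inst
            planted.append(region_id)
        seqs[region_id] = "".join(chars)
    truth = GroundTruth(motif_region_ids=frozenset(planted))
    return seqs, truth


def gen_tma_cases(
    n_cases: int,
    cores_per_case: int,
    grade_effect: float,
    seed: int = 0,
    grade_probs: tuple = (0.5, 0.45, 0.05),
) -> pd.DataFrame:
    """Simulate tissue-microarray core scores with a grade-linked shift.

    Grades are drawn as G2/G3/Gx with *grade_probs*; each core's intensity
    is a latent Gaussian (case-level mean 1.5, raised by *grade_effect* for
    G3 cases, core noise sd 0.8) rounded and clipped to 0-3, and the
    percent-positive value increases with intensity. Returns the core table
    (case_id, core_id, intensity, percent_positive, grade).
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    if cores_per_case < 1:
        raise ValueError("need at least one core per case")
    rng = np.random.default_rng(seed)
    rows = []
    grades = rng.choice(["G2", "G3", "Gx"], size=n_cases, p=grade_probs)
    for i in range(n_cases):
        mu = 1.5 + (grade_effect if grades[i] == "G3" else 0.0)
        for j in range(cores_per_case):
            intensity = int(np.clip(round(rng.normal(mu, 0.8)), 0, 3))
            pct = float(np.clip(rng.normal(25.0 + 20.0 * intensity, 15.0), 0, 100))
            rows.append({"case_id": f"case_{i:04d}", "core_id": f"core_{j}",
                         "intensity": intensity, "percent_positive": round(pct, 1),
                         "grade": grades[i]})
    return pd.DataFrame(rows)
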