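"""Known-motif scanning and binomial enrichment.

Regions are scanned on both strands with a log-odds scorer built from a
position weight matrix (probabilities over A/C/G/T per position, floored at
1e-4 before the log, against the matrix's own background distribution). A
position is a hit when its log-odds score reaches a configurable fraction
of the maximal attainable score; positions containing N never score.
Scanning is restricted to the central +/- window of each region, matching
the convention of scoring the sequence around a binding-peak summit.

Region-level enrichment is the one-tailed binomial test of the number of
regions with at least one hit against a background hit probability; the
"union" coverage of several motifs is the fraction of regions hit by any
of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats

__all__ = [
    "PWM",
    "MotifHit",
    "scan_regions",
    "motif_region_enrichment",
    "motif_union_coverage",
    "estimate_background_prob",
]

_ALPHABET = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_PROB_FLOOR = 1e-4


@dataclass(frozen=True)
class PWM:
    """Probability matrix over A/C/G/T with a background distribution."""

    motif_id: str
    probs: np.ndarray  # (width, 4), rows sum to 1
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("PWM needs a (width, 4) probability matrix")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        object.__setattr__(self, "probs", arr)
        object.__setattr__(self, "background", tuple(bg))

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        p = np.maximum(self.probs, _PROB_FLOOR)
        bg = np.maximum(np.asarray(self.background), _PROB_FLOOR)
        return np.log2(p / bg[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_biomotif(cls, motif, background=None) -> "PWM":
        """Build from a ``Bio.motifs`` motif (e.g. parsed from JASPAR)."""
        counts = np.array([list(motif.counts[b]) for b in _ALPHABET], float).T
        pseudo = counts + 0.5  # avoids zero columns in sparse JASPAR matrices
        probs = pseudo / pseudo.sum(axis=1, keepdims=True)
        if background is None:
            bg = getattr(motif, "background", None)
            background = (
                tuple(bg[b] for b in _ALPHABET) if bg else (0.25,) * 4
            )
        return cls(motif_id=motif.matrix_id or motif.name or "motif",
                   probs=probs, background=background)


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int  # 0-based within the full region sequence
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), -1, dtype=np.int8)
    for i, base in enumerate(_ALPHABET):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return idx


def _revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def _scan_one(encoded: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; -inf where an N falls in the window."""
    w = lom.shape[0]
    n = encoded.size
    if n < w:
        return np.empty(0)
    scores = np.zeros(n - w + 1)
    valid = np.ones(n - w + 1, dtype=bool)
    for j in range(w):
        col = encoded[j : j + n - w + 1]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, lom[j][np.maximum(col, 0)], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan_regions(
    sequences: dict[str, str],
    pwm: PWM,
    threshold_fraction: float = 0.8,
    window: int = 250,
):
    """Scan the central +/- *window* of each region on both strands.

    Returns ``(hits, has_motif, skipped)``: the list of MotifHit records, a
    dict region_id -> bool (at least one hit), and the ids of regions
    shorter than the motif (skipped). Offsets are 0-based positions of the
    match start within the full (uncropped) region sequence, on the given
    strand's coordinates of the forward sequence.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1]")
    cutoff = threshold_fraction * pwm.max_score
    lom = pwm.log_odds
    hits: list[MotifHit] = []
    has_motif: dict[str, bool] = {}
    skipped: list[str] = []
    for region_id, seq in sequences.items():
        seq = seq.upper()
        if len(seq) < pwm.width:
            skipped.append(region_id)
            continue
        center = len(seq) // 2
        lo = max(0, center - window)
        hi = min(len(seq), center + window)
        sub = seq[lo:hi]
        found = False
        fwd = _scan_one(_encode(sub), lom)
        for off in np.where(fwd >= cutoff)[0]:
            hits.append(MotifHit(region_id, lo + int(off), "+", float(fwd[off])))
            found = True
        rev = _scan_one(_encode(_revcomp(sub)), lom)
        for off in np.where(rev >= cutoff)[0]:
            # map a reverse-strand match back to forward coordinates
            fwd_off = lo + len(sub) - int(off) - pwm.width
            hits.append(MotifHit(region_id, fwd_off, "-", float(rev[off])))
            found = True
        has_motif[region_id] = found
    return hits, has_motif, skipped


def motif_region_enrichment(n_with_motif: int, n_regions: int, background_prob: float):
    """Fraction of motif-positive regions and its one-tailed binomial p.

    p is the upper tail P(X >= n_with_motif) for X ~ Binomial(n_regions,
    background_prob). A zero background with observed hits is degenerate
    and reported as p = 0 with a flag.
    """
    if not (0 <= n_with_motif <= n_regions):
        raise ValueError("need 0 <= n_with_motif <= n_regions")
    fraction = n_with_motif / n_regions if n_regions else 0.0
    if background_prob == 0:
        return fraction, (0.0 if n_with_motif > 0 else 1.0), True
    p = stats.binomial_upper_tail(n_with_motif, n_regions, background_prob)
    return fraction, p, False


def motif_union_coverage(per_motif_flags: list[dict[str, bool]]) -> float:
    """Fraction of regions with at least one hit for at least one motif."""
    if not per_motif_flags:
        raise ValueError("no motif results supplied")
    keys = set(per_motif_flags[0])
    for flags in per_motif_flags[1:]:
        if set(flags) != keys:
            raise ValueError("motifs were scored on different region lists")
    if not keys:
        raise ValueError("empty region list")
    covered = sum(any(flags[k] for flags in per_motif_flags) for k in keys)
    return covered / len(keys)


def estimate_background_prob(
    background_sequences: dict[str, str],
    pwm: PWM,
    threshold_fraction: float = 0.8,
    window: int = 250,
) -> float:
    """Per-region hit probability estimated by scanning background regions."""
    _, flags, _ = scan_regions(background_sequences, pwm, threshold_fraction, window)
    if not flags:
        raise ValueError("no scorable background region")
    return sum(flags.values()) / len(flags)
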