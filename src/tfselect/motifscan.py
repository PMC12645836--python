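"""PWM representation, binding-site scanning with exact score p-values, and the
ratio-score statistic for variant impact on binding affinity.

Columns of a PWM are normalized to counts summing to 1,000, so entries read as
per-position allele frequencies out of 1,000. Window scores are log-odds against a
background base composition; the p-value of a score is computed from the exact
null score distribution obtained by dynamic-programming convolution over motif
positions on a discretized score grid. A window is a hit when its p-value is at or
below the threshold (default 0.05), on either strand.

The ratio score of a variant inside a motif compares the PWM counts of the
ancestral and the variant allele at that position:

    ratio_score = |count_ancestral - count_variant| / max(count_ancestral, count_variant)

0 means the two alleles are equally frequent in the motif model; 1 means the
variant allele is absent from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COLUMN_TOTAL = 1000
DEFAULT_GRID = 0.01


@dataclass
class PWM:
    name: str
    counts: np.ndarray  # (4, L) integer counts, each column sums to ~1000
    background: np.ndarray  # (4,) probabilities
    log_odds: np.ndarray  # (4, L)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def count(self, base: str, position: int) -> int:
        """Normalized count (out of 1,000) of a base at a 0-based motif position."""
        return int(self.counts[_BASE_INDEX[base.upper()], position])

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            counts=self.counts[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            log_odds=self.log_odds[::-1, ::-1].copy(),
        )


@dataclass
class MotifHit:
    contig: str
    start: int
    end: int
    strand: str
    motif_id: str
    score: float
    pvalue: float


def pwm_from_counts(raw_counts, pseudocount: float = 1.0, background=None, name: str = "motif") -> PWM:
    """Build a PWM from a (4, L) count matrix.

    Adds ``pseudocount`` to every cell, rescales each column to total 1,000
    (largest-remainder rounding keeps the sum at 999-1000), and computes log-odds
    against the background (uniform by default). With pseudocount 0 and a zero
    cell, the corresponding log-odds is -inf (flagged degenerate, still usable).
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != 4 or raw.shape[1] < 1:
        raise ValueError(f"counts must be (4, L>=1), got {raw.shape}")
    if (raw < 0).any():
        raise ValueError("negative counts")
    if (raw.sum(axis=0) == 0).any():
        raise ValueError("all-zero PWM column")
    padded = raw + pseudocount
    colsum = padded.sum(axis=0)
    scaled = padded / colsum * COLUMN_TOTAL
    counts = np.floor(scaled).astype(int)
    # largest-remainder top-up so each column sums to 1000
    remainder = scaled - np.floor(scaled)
    deficit = COLUMN_TOTAL - counts.sum(axis=0)
    for j in range(counts.shape[1]):
        order = np.argsort(-remainder[:, j])
        for i in order[: max(0, deficit[j])]:
            counts[i, j] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    probs = padded / colsum
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / bg[:, None])
    return PWM(name=name, counts=counts, background=bg, log_odds=log_odds)


def _seq_to_indices(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def score_distribution(pwm: PWM, grid: float = DEFAULT_GRID):
    """Exact null distribution of the discretized log-odds score.

    Scores are rounded to multiples of ``grid``; the distribution of the window
    score under i.i.d. background bases is built by convolving per-position score
    distributions. Returns (offset, probs) where probs[i] is the probability of
    integer score offset + i.
    """
    q = discretized_log_odds(pwm, grid)
    cur_lo = 0
    cur = np.array([1.0])
    for j in range(pwm.length):
        jmin = int(q[:, j].min())
        col = np.zeros(int(q[:, j].max()) - jmin + 1)
        for b in range(4):
            col[q[b, j] - jmin] += pwm.background[b]
        cur = np.convolve(cur, col)
        cur_lo += jmin
    return cur_lo, cur


def discretized_log_odds(pwm: PWM, grid: float = DEFAULT_GRID) -> np.ndarray:
    """Integer score matrix on the grid; -inf cells map to a large negative value.

    Window scores and the DP null distribution both use this matrix, so the
    p-value of a window score is exactly its tail probability under the DP.
    """
    finite = np.where(np.isfinite(pwm.log_odds), pwm.log_odds, -1e4)
    return np.round(finite / grid).astype(np.int64)


def pvalue_lookup(pwm: PWM, grid: float = DEFAULT_GRID):
    """Callable mapping a discretized integer window score to its exact p-value."""
    lo, probs = score_distribution(pwm, grid)
    sf = np.minimum(1.0, np.cumsum(probs[::-1])[::-1])  # P(S >= lo + i)

    def pvalue(int_score: int) -> float:
        idx = int(int_score) - lo
        if idx < 0:
            return 1.0
        if idx >= len(sf):
            return 0.0
        return float(sf[idx])

    return pvalue


def _window_scores(idx: np.ndarray, int_log_odds: np.ndarray) -> np.ndarray:
    """Integer window scores on the grid; NaN marks windows with ambiguous bases."""
    m = int_log_odds.shape[1]
    n_win = len(idx) - m + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe_lo = np.vstack([int_log_odds, np.zeros((1, m), dtype=np.int64)])  # row 4: ambiguous
    clipped = idx.copy()
    clipped[clipped < 0] = 4
    for j in range(m):
        scores += safe_lo[clipped[j : j + n_win], j]
        valid &= idx[j : j + n_win] >= 0
    scores[~valid] = np.nan
    return scores


def scan(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 0.05,
    contig: str = "chr1",
    offset: int = 0,
    grid: float = DEFAULT_GRID,
) -> list[MotifHit]:
    """Scan both strands of a sequence for windows scoring at p <= p_threshold.

    Windows containing ambiguous bases are skipped. Coordinates in the returned
    hits are 0-based half-open on the forward strand, shifted by ``offset``.
    """
    idx = _seq_to_indices(sequence)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        pv = pvalue_lookup(mat, grid)
        scores = _window_scores(idx, discretized_log_odds(mat, grid))
        for i, s in enumerate(scores):
            if np.isnan(s):
                continue
            p = pv(int(s))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        contig, offset + i, offset + i + pwm.length, strand,
                        pwm.name, float(s) * grid, p,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def ratio_score(count_ancestral: float, count_variant: float) -> float:
    """Binding-disruption score in [0, 1] from two PWM allele counts."""
    a, v = float(count_ancestral), float(count_variant)
    if a < 0 or v < 0:
        raise ValueError("counts must be non-negative")
    if a == 0 and v == 0:
        raise ValueError("ratio score undefined for two zero counts")
    return abs(a - v) / max(a, v)


def stratify_by_ratio_score(variants, thresholds=(0.0, 0.25, 0.5, 0.75), min_count: int = 400):
    """Group variants into ratio-score regimes.

    ``variants`` is an iterable of objects (or dicts) with ``count_ancestral`` and
    ``count_variant`` attributes/keys. Regime 0.0 pools all variants with no count
    gate; every other regime keeps variants whose ratio score reaches the
    threshold and whose two allele counts are both >= ``min_count``.
    """

    def get(v, key):
        return v[key] if isinstance(v, dict) else getattr(v, key)

    strata: dict[float, list] = {}
    for t in thresholds:
        if t == 0.0:
            strata[t] = list(variants)
            continue
        kept = []
        for v in variants:
            a, c = get(v, "count_ancestral"), get(v, "count_variant")
            if a >= min_count and c >= min_count and ratio_score(a, c) >= t:
                kept.append(v)
        strata[t] = kept
    return strata
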