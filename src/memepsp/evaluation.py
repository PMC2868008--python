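"""Motif-quality metrics: inter-motif distance, AMA, rank correlation.

The headline metric is the scaled Euclidean distance between two motif
probability matrices,

    D(f, g) = (1/w) * sum_i ||f_.,i - g_.,i||_2 / sqrt(2),

which is 0 for identical motifs and 1 for disjoint point-mass motifs.
Because a reported motif may differ in width or strand from the reference,
the practical distance minimizes D over every alignment offset (with the
overlap at least the shorter motif's width) and over the reverse
complement, and — for benchmarking success — reports the maximal distance
1.0 when the reported motif lacks any 6-column window of mean information
content >= 1 bit.  A discovery counts as a success when this aligned
distance is below 0.25.

Motif accuracy without a gold-standard motif is measured by the Spearman
correlation between sequences' average-motif-affinity (AMA) scores and an
external binding score, and algorithms are compared by an exact two-sided
sign test over paired samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .background import BackgroundModel
from .motifs import PSPM, information_content

__all__ = [
    "MotifDistanceResult",
    "scaled_distance",
    "aligned_distance",
    "ama_score",
    "spearman_cc",
    "sign_test",
    "success",
    "SUCCESS_DISTANCE",
]

SUCCESS_DISTANCE = 0.25
IC_FILTER_WIDTH = 6
IC_FILTER_BITS = 1.0
SQRT2 = math.sqrt(2.0)


@dataclass
class MotifDistanceResult:
    distance: float
    offset: int
    strand: str
    n_columns: int


def scaled_distance(f: PSPM, g: PSPM) -> float:
    """Scaled Euclidean distance between two width-matched motifs.

    Mean over columns of the column-wise Euclidean distance divided by
    sqrt(2); lies in [0, 1].
    """
    if f.width != g.width:
        raise ValueError("widths differ; use aligned_distance")
    col = np.sqrt(((f.matrix - g.matrix) ** 2).sum(axis=1))
    return float(col.sum() / (f.width * SQRT2))


def _overlap_distance(fm: np.ndarray, gm: np.ndarray, off: int) -> tuple[float, int]:
    """Distance over the overlap when f is shifted by `off` against g."""
    lo_f = max(0, -off)
    lo_g = max(0, off)
    n = min(len(fm) - lo_f, len(gm) - lo_g)
    fa = fm[lo_f:lo_f + n]
    ga = gm[lo_g:lo_g + n]
    col = np.sqrt(((fa - ga) ** 2).sum(axis=1))
    return float(col.sum() / (n * SQRT2)), n


def aligned_distance(f: PSPM, g: PSPM,
                     ic_filter: bool = False) -> MotifDistanceResult:
    """Minimum scaled distance over all alignments and both orientations.

    Offsets slide ``f`` (or its reverse complement) along ``g`` such that
    the overlap is at least the shorter motif's width; the per-alignment
    distance averages over the overlapping columns only.  With
    ``ic_filter``, a reported motif ``f`` lacking a 6-wide window of mean
    information content >= 1 bit (against a uniform background) is assigned
    the maximal distance 1.0 outright.
    """
    if ic_filter:
        uni = BackgroundModel.uniform(f.alphabet)
        window = min(IC_FILTER_WIDTH, f.width)
        if information_content(f, uni, window) < IC_FILTER_BITS:
            return MotifDistanceResult(1.0, 0, "+", 0)
    minov = min(f.width, g.width)
    variants = [("+", f.matrix)]
    if f.alphabet.complement is not None:
        variants.append(("-", f.reverse_complement().matrix))
    best: MotifDistanceResult | None = None
    for strand, fm in variants:
        for off in range(-(f.width - minov), g.width - minov + 1):
            d, n = _overlap_distance(fm, g.matrix, off)
            if best is None or d < best.distance:
                best = MotifDistanceResult(d, off, strand, n)
    return best


def ama_score(theta: PSPM, seq: str, bg: BackgroundModel,
              strand_mode: str = "double") -> float:
    """Average motif affinity of a sequence.

    Mean over every legal (position, strand) of the odds ratio
    ``Pr(window | theta) / Pr(window | bg)``, the denominator computed
    under the full order-k background chain.  A proxy for the average
    binding affinity of the whole region; windows containing ambiguous
    residues are excluded from the average.
    """
    alph = theta.alphabet
    codes = alph.encode(seq)
    w = theta.width
    if len(codes) < w:
        raise ValueError(f"sequence of length {len(codes)} is shorter than "
                         f"the motif (w={w})")
    bg_l2 = bg.window_log2probs(codes, w)
    ok = np.isfinite(bg_l2)
    if not ok.any():
        raise ValueError("every window contains ambiguous residues")
    win = np.lib.stride_tricks.sliding_window_view(codes, w)[ok]
    logt = np.log2(np.clip(theta.matrix, 1e-300, None))
    vals = []
    motif_l2 = logt[np.arange(w), win].sum(axis=1)
    vals.append(np.exp2(motif_l2 - bg_l2[ok]))
    if strand_mode == "double":
        rc = theta.reverse_complement()
        logrc = np.log2(np.clip(rc.matrix, 1e-300, None))
        motif_l2 = logrc[np.arange(w), win].sum(axis=1)
        vals.append(np.exp2(motif_l2 - bg_l2[ok]))
    allv = np.concatenate(vals)
    return float(allv.mean())


def spearman_cc(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns NaN (with a warning) when either vector is constant, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def sign_test(wins: int, losses: int) -> float:
    """Exact two-sided binomial sign test at success probability 1/2.

    Ties are excluded before calling; returns the p-value (capped at 1).
    """
    n = wins + losses
    if n < 1:
        raise ValueError("need at least one non-tied pair")
    return float(min(stats.binomtest(wins, n, 0.5,
                                     alternative="two-sided").pvalue, 1.0))


def success(reported: PSPM, known: PSPM) -> bool:
    """The benchmark success criterion: IC-filtered aligned distance < 0.25."""
    res = aligned_distance(reported, known, ic_filter=True)
    return bool(res.distance < SUCCESS_DISTANCE)
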