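"""The probabilistic motif core: PSPM representation and likelihood ratios.

A motif is a position-specific probability matrix (PSPM) theta: a
column-stochastic ``w x A`` matrix whose entry ``f[k, a]`` is the probability
of letter ``a`` at motif position ``k``.  Sites are scored by the product of
the matching entries; significance and information measures compare those
frequencies against the zero-order background marginals ``p_a`` in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import Alphabet, DNA
from .background import BackgroundModel

__all__ = [
    "PSPM",
    "site_likelihood",
    "weighted_llr",
    "information_content",
]


@dataclass
class PSPM:
    """Position-specific probability matrix (the motif model theta).

    ``matrix`` has shape ``(w, A)``: rows are motif positions, columns are
    letters in alphabet order.  Every row sums to 1.
    """

    matrix: np.ndarray
    alphabet: Alphabet = DNA
    nsites: int | None = None
    evalue: float | None = None
    name: str | None = None
    _logm: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.alphabet.size:
            raise ValueError(f"matrix shape {self.matrix.shape} does not "
                             f"match alphabet size {self.alphabet.size}")
        if (self.matrix < 0).any():
            raise ValueError("PSPM entries must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PSPM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_matrix(self) -> np.ndarray:
        if self._logm is None:
            with np.errstate(divide="ignore"):
                self._logm = np.log(self.matrix)
        return self._logm

    def reverse_complement(self) -> "PSPM":
        comp = self.alphabet.comp_codes
        return PSPM(self.matrix[::-1][:, comp], self.alphabet,
                    self.nsites, self.evalue, self.name)

    @classmethod
    def from_counts(cls, counts: np.ndarray, alphabet: Alphabet = DNA,
                    pseudo: float | np.ndarray = 0.0, **kw) -> "PSPM":
        counts = np.asarray(counts, dtype=float) + pseudo
        return cls(counts / counts.sum(axis=1, keepdims=True), alphabet, **kw)

    @classmethod
    def uniform(cls, width: int, alphabet: Alphabet = DNA) -> "PSPM":
        A = alphabet.size
        return cls(np.full((width, A), 1.0 / A), alphabet)


def site_likelihood(theta: PSPM, seq: str | np.ndarray, j: int,
                    strand: str = "+") -> float:
    """Probability of the width-w window starting at ``j`` under the motif.

    The window is reverse-complemented first when ``strand`` is ``"-"`` (so
    a minus-strand site is read off the opposite strand).  Windows containing
    an ambiguous residue have likelihood 0.
    """
    codes = theta.alphabet.encode(seq) if isinstance(seq, str) else seq
    w = theta.width
    if j < 0 or j + w > len(codes):
        raise ValueError(f"window [{j}, {j + w}) outside sequence of length "
                         f"{len(codes)}")
    win = codes[j:j + w]
    if strand == "-":
        win = theta.alphabet.revcomp(win)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    if (win < 0).any():
        return 0.0
    return float(np.prod(theta.matrix[np.arange(w), win]))


def _accumulate_counts(site_words: list[str | np.ndarray], weights: np.ndarray,
                       alphabet: Alphabet) -> np.ndarray:
    widths = set()
    counts = None
    for word, b in zip(site_words, weights):
        codes = alphabet.encode(word) if isinstance(word, str) else word
        widths.add(len(codes))
        if len(widths) > 1:
            raise ValueError("sites have unequal widths")
        if counts is None:
            counts = np.zeros((len(codes), alphabet.size))
        if (codes < 0).any():
            raise ValueError("site window contains an ambiguous residue")
        counts[np.arange(len(codes)), codes] += b
    if counts is None:
        raise ValueError("no sites given")
    return counts


def weighted_llr(site_words: list[str | np.ndarray], weights: np.ndarray,
                 bg: BackgroundModel) -> float:
    """Weighted log-likelihood ratio (bits) of an aligned set of sites.

    Each site's letter counts are scaled by its weight ``b`` in ``(0, 1]``
    (the site's prior divided by the largest prior in its sequence); the
    weighted counts ``c[a,k]`` are normalized to frequencies
    ``f = c / N_wt`` and scored as
    ``sum_k sum_a c[a,k] * log2(f[a,k] / p_a)`` with ``0*log(0/p) = 0``.
    With unit weights this is the ordinary LLR of the site alignment.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(site_words):
        raise ValueError("one weight per site required")
    if (weights <= 0).any() or (weights > 1).any():
        raise ValueError("weights must lie in (0, 1]")
    counts = _accumulate_counts(site_words, weights, bg.alphabet)
    n_wt = weights.sum()
    if n_wt == 0:
        raise ValueError("total site weight is zero")
    f = counts / n_wt
    p = bg.marginals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log2(f / p)
    return float(np.where(counts > 0, terms, 0.0).sum())


def information_content(theta: PSPM, bg: BackgroundModel,
                        window: int | None = None) -> float:
    """Largest mean per-column information content (bits) over any
    ``window`` consecutive motif columns.

    Column IC is the relative entropy ``sum_a f[a] log2(f[a]/p_a)`` against
    the background marginals.  ``window=None`` (or wider than the motif,
    with a warning) means the whole motif.
    """
    w = theta.width
    if window is None:
        window = w
    elif window > w:
        warnings.warn("IC window wider than motif; using the whole motif",
                      stacklevel=2)
        window = w
    if window < 1:
        raise ValueError("window must be >= 1")
    f = theta.matrix
    p = bg.marginals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * np.log2(f / p)
    col_ic = np.where(f > 0, terms, 0.0).sum(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(col_ic)])
    means = (csum[window:] - csum[:-window]) / window
    return float(means.max())
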