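"""Order-k Markov background models of residue composition.

The background model plays two roles. Its zero-order marginals ``p_a`` enter
every motif log-likelihood-ratio (the null letter distribution inside the
LLR), while the full order-k chain provides sequence- and window-level null
likelihoods for average-motif-affinity (AMA) scoring.
"""

from __future__ import annotations

import warnings

import numpy as np

from .alphabet import Alphabet, DNA, SequenceSet

__all__ = ["BackgroundModel", "estimate_background"]


class BackgroundModel:
    """Markov chain over an alphabet.

    Parameters
    ----------
    conditionals
        One array per order ``o`` in ``0..order``; array ``o`` has shape
        ``(A**o, A)`` and row ``ctx`` holds ``P(a | ctx)`` for the length-o
        context with code ``sum(c_i * A**(o-1-i))``.  Every row sums to 1.
    """

    def __init__(self, conditionals: list[np.ndarray],
                 alphabet: Alphabet = DNA) -> None:
        self.alphabet = alphabet
        A = alphabet.size
        self.conditionals = [np.asarray(c, dtype=float) for c in conditionals]
        for o, cond in enumerate(self.conditionals):
            if cond.shape != (A ** o, A):
                raise ValueError(f"order-{o} table has shape {cond.shape}")
            sums = cond.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"order-{o} conditionals do not sum to 1")
        if (self.conditionals[0] <= 0).any():
            raise ValueError("zero-order marginals must be strictly positive")

    @property
    def order(self) -> int:
        return len(self.conditionals) - 1

    @property
    def marginals(self) -> np.ndarray:
        """Zero-order letter probabilities p_a."""
        return self.conditionals[0][0]

    @property
    def log2_marginals(self) -> np.ndarray:
        return np.log2(self.marginals)

    @classmethod
    def uniform(cls, alphabet: Alphabet = DNA) -> "BackgroundModel":
        A = alphabet.size
        return cls([np.full((1, A), 1.0 / A)], alphabet)

    @classmethod
    def zero_order(cls, p: np.ndarray,
                   alphabet: Alphabet = DNA) -> "BackgroundModel":
        return cls([np.asarray(p, dtype=float).reshape(1, -1)], alphabet)

    # -- likelihoods --------------------------------------------------------

    def seq_log2prob(self, codes: np.ndarray) -> float:
        """log2 probability of a standalone sequence under the chain.

        The first ``min(order, j)`` letters of any position use the highest
        conditional order available for their context ("ramp-in").
        Ambiguous letters (code -1) contribute probability 1 and break the
        Markov context.
        """
        A = self.alphabet.size
        total = 0.0
        ctx = 0
        ctx_len = 0
        for c in codes:
            if c < 0:
                ctx, ctx_len = 0, 0
                continue
            o = min(ctx_len, self.order)
            total += float(np.log2(self.conditionals[o][ctx % (A ** o), c]))
            ctx_len = min(ctx_len + 1, self.order)
            ctx = (ctx * A + int(c)) % (A ** self.order) if self.order else 0
        return total

    def window_log2probs(self, codes: np.ndarray, w: int) -> np.ndarray:
        """log2 probability of every width-w window, each as a standalone
        sequence under the chain; windows containing an ambiguous residue
        get -inf."""
        m = len(codes) - w + 1
        if m < 1:
            raise ValueError("sequence shorter than window")
        out = np.empty(m)
        for j in range(m):
            win = codes[j:j + w]
            out[j] = -np.inf if (win < 0).any() else self.seq_log2prob(win)
        return out


def estimate_background(seqs: SequenceSet, order: int = 0, *,
                        double_strand: bool = True,
                        pseudo_frac: float = 0.01) -> BackgroundModel:
    """Estimate an order-k Markov background from the sequence data.

    In double-strand mode the k-mer counts of both strands are pooled, which
    makes the null strand-symmetric.  A pseudocount of
    ``pseudo_frac * total_count / n_cells`` is added to every cell of every
    order's count table so no probability is exactly zero.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if len(seqs) == 0 or int(seqs.lengths.sum()) == 0:
        raise ValueError("cannot estimate a background from empty input")
    alph = seqs.alphabet
    A = alph.size
    strands = [seqs.encoded()]
    if double_strand:
        strands.append([alph.revcomp(x) for x in seqs.encoded()])
    conditionals = []
    for o in range(order + 1):
        k = o + 1
        counts = np.zeros((A ** o, A))
        total = 0
        for strand in strands:
            for codes in strand:
                for j in range(len(codes) - k + 1):
                    kmer = codes[j:j + k]
                    if (kmer < 0).any():
                        continue
                    ctx = 0
                    for c in kmer[:-1]:
                        ctx = ctx * A + int(c)
                    counts[ctx, int(kmer[-1])] += 1
                    total += 1
        pseudo = pseudo_frac * max(total, 1) / counts.size
        counts += pseudo
        seen = total and (counts - pseudo > 0).sum()
        if o > 0 and seen and seen < counts.size / 2:
            warnings.warn(
                f"order-{o} contexts are mostly unseen; pseudocounts dominate",
                stacklevel=2)
        conditionals.append(counts / counts.sum(axis=1, keepdims=True))
    return BackgroundModel(conditionals, alph)
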