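"""Planted-motif fixtures: sequence sets with known sites plus matched PSPs.

Emulates a ChIP-derived positive set: background DNA with one motif site
sampled from a known PSPM planted in a stated fraction of sequences at a
uniformly random legal position (optionally on either strand).  A matched
position-specific prior can be generated whose mass is concentrated on the
true sites (an idealized stand-in for an externally built informative
prior) or, at concentration 0, is exactly the uniform prior.

The defaults mirror a deliberately *weak* motif regime — 50 sequences of
200 bp, a width-8 motif of ~1.2 bits mean information content planted in
half the sequences — where an informative prior has measurable value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import DNA, Alphabet, SequenceSet
from .background import BackgroundModel
from .motifs import PSPM
from .priors import PositionSpecificPrior, make_uniform_psp

__all__ = ["PlantSpec", "weak_motif", "generate_dataset", "generate_psp"]

DEFAULT_N = 50
DEFAULT_LENGTH = 200
DEFAULT_WIDTH = 8
DEFAULT_SITE_FRACTION = 0.5
DEFAULT_DOMINANT_PROB = 0.87   # per-column IC ~= 1.22 bits vs uniform bg


@dataclass
class PlantSpec:
    """Everything that determines one synthetic dataset (seed included)."""

    motif: PSPM
    n: int = DEFAULT_N
    length: int = DEFAULT_LENGTH
    site_fraction: float = DEFAULT_SITE_FRACTION
    mutation_rate: float = 0.0
    background: BackgroundModel | None = None
    strand_policy: str = "both"  # "forward" | "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.site_fraction <= 1.0:
            raise ValueError("site_fraction outside [0, 1]")
        if self.length < self.motif.width:
            raise ValueError("sequences shorter than the motif")
        if self.strand_policy not in ("forward", "both"):
            raise ValueError(f"bad strand_policy {self.strand_policy!r}")


def weak_motif(width: int = DEFAULT_WIDTH, seed: int = 0,
               dominant: float = DEFAULT_DOMINANT_PROB,
               alphabet: Alphabet = DNA) -> PSPM:
    """A random motif with one dominant letter per column.

    The default dominant probability of 0.87 gives ~1.2 bits of mean
    information content against a uniform background — strong enough to be
    discoverable, weak enough that a good prior still helps.
    """
    rng = np.random.default_rng(seed)
    A = alphabet.size
    mat = np.full((width, A), (1.0 - dominant) / (A - 1))
    mat[np.arange(width), rng.integers(0, A, size=width)] = dominant
    return PSPM(mat, alphabet)


def generate_dataset(spec: PlantSpec) -> tuple[SequenceSet,
                                               list[tuple[int, int, str]],
                                               PSPM]:
    """Sample a sequence set with planted sites.

    Returns ``(sequences, truth, planted_motif)`` where ``truth`` lists
    ``(sequence_index, forward_start, strand)`` for every planted site.
    Fully determined by ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    alph = spec.motif.alphabet
    A = alph.size
    bg = spec.background or BackgroundModel.uniform(alph)
    w = spec.motif.width
    n_sites = int(np.floor(spec.site_fraction * spec.n))
    sited = np.sort(rng.choice(spec.n, size=n_sites, replace=False))
    residues: list[str] = []
    truth: list[tuple[int, int, str]] = []
    sited_set = set(int(i) for i in sited)
    for i in range(spec.n):
        codes = _sample_background(rng, bg, spec.length)
        if i in sited_set:
            j = int(rng.integers(0, spec.length - w + 1))
            site = np.array([rng.choice(A, p=spec.motif.matrix[k])
                             for k in range(w)], dtype=np.int8)
            if spec.mutation_rate > 0:
                hit = rng.random(w) < spec.mutation_rate
                site[hit] = rng.integers(0, A, size=int(hit.sum()))
            strand = "+"
            if spec.strand_policy == "both" and rng.random() < 0.5:
                site = alph.revcomp(site)
                strand = "-"
            codes[j:j + w] = site
            truth.append((i, j, strand))
        residues.append(alph.decode(codes))
    seqs = SequenceSet.from_strings(residues, alph)
    return seqs, truth, spec.motif


def _sample_background(rng: np.random.Generator, bg: BackgroundModel,
                       length: int) -> np.ndarray:
    A = bg.alphabet.size
    if bg.order == 0:
        return rng.choice(A, size=length, p=bg.marginals).astype(np.int8)
    out = np.empty(length, dtype=np.int8)
    ctx = 0
    ctx_len = 0
    for pos in range(length):
        o = min(ctx_len, bg.order)
        p = bg.conditionals[o][ctx % (A ** o)]
        c = int(rng.choice(A, p=p))
        out[pos] = c
        ctx_len = min(ctx_len + 1, bg.order)
        ctx = (ctx * A + c) % (A ** bg.order)
    return out


def generate_psp(truth: list[tuple[int, int, str]], seqs: SequenceSet,
                 w0: int, concentration: float,
                 model: str = "zoops",
                 strand_mode: str = "double") -> PositionSpecificPrior:
    """An informative PSP anchored on the true sites.

    Sequences with a planted site put prior mass ``concentration`` on the
    true start, spread over its +-1 neighbours by a triangular kernel
    (1/4, 1/2, 1/4; out-of-range lobes fold back to the center), with the
    remaining mass uniform over legal positions.  Sequences without a site
    get the uniform positional prior, scaled under ZOOPS so that their
    no-site mass is ``concentration``.  ``concentration = 0`` reproduces
    the uniform PSP exactly.
    """
    if not 0.0 <= concentration <= 1.0:
        raise ValueError("concentration outside [0, 1]")
    psp = make_uniform_psp(seqs, w0, model, strand_mode)
    if concentration == 0.0:
        return psp
    by_seq = {i: j for i, j, _ in truth}
    for i, v in enumerate(psp.positional):
        m = len(v) - w0 + 1
        if i in by_seq:
            j = by_seq[i]
            kern = np.zeros(m)
            for dj, wt in ((-1, 0.25), (0, 0.5), (1, 0.25)):
                jj = j + dj
                if 0 <= jj < m:
                    kern[jj] += wt
                else:
                    kern[j] += wt
            v[:m] = (1.0 - concentration) / m + concentration * kern
        elif model == "zoops":
            v[:m] = (1.0 - concentration) / m
            psp.p0[i] = concentration
        # under OOPS siteless sequences keep the uniform prior (P0 must be 0)
    return psp
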