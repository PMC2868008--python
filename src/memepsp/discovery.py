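"""Three-phase EM motif discovery with position-specific priors.

Phase I screens candidate starting matrices built from subsequences of the
data, ranking potential sites by likelihood x prior and scoring site sets
with the prior-weighted log-likelihood ratio.  Phase II runs EM under the
OOPS (one site per sequence) or ZOOPS (zero or one site) model; the E-step
combines the site-frequency parameter gamma with the positional shape of
the prior, Pr(site at j) = gamma * P[i,j] / (1 - P[i,0]), halved per strand
when both DNA strands are searched.  Phase III selects the sites with the
largest posterior Z, scores the alignment by the product of Hertz-Stormo
column-LLR p-values, and converts that to an E-value by multiplying by the
number of ways the sites could have been placed.  Reported motifs are
probabilistically erased before the next motif is sought.

The public entry points are :class:`MotifDiscovery` (a scikit-learn style
estimator) and the functional wrappers (`discover_motifs`, `phase1_search`,
`e_step`, `m_step`, `run_em`, `select_sites`, `erase`, `column_pvalue`,
`product_pvalue`, `motif_evalue`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import SequenceSet
from .background import BackgroundModel, estimate_background
from .motifs import PSPM
from .priors import (PositionSpecificPrior, make_uniform_psp, renormalize_psp,
                     validate_psp)

__all__ = [
    "ModelParams", "ZMatrix", "CandidateStart", "ErasureWeights",
    "MotifResult", "SiteSelection", "MotifDiscovery",
    "subsequence_to_pspm", "phase1_search", "e_step", "m_step", "run_em",
    "column_pvalue", "product_pvalue", "motif_evalue", "select_sites",
    "erase", "discover_motifs",
]

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Sequence-model parameters phi = (theta, gamma, P)."""

    theta: PSPM
    gamma: float
    psp: PositionSpecificPrior | None
    model: str  # "oops" | "zoops"
    strand_mode: str = "double"

    def __post_init__(self) -> None:
        if self.model not in ("oops", "zoops"):
            raise ValueError(f"bad model {self.model!r}")
        if self.model == "oops" and self.gamma != 1.0:
            raise ValueError("OOPS requires gamma = 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma outside [0, 1]")


@dataclass
class ZMatrix:
    """Posterior site-start probabilities.

    ``z[i]`` has shape ``(n_strands, m_i)``; entry ``[s, j]`` is the
    posterior probability of a site on strand ``s`` (0 = forward,
    1 = reverse) whose *leftmost forward* coordinate is ``j``.  ``z0[i]`` is
    the posterior no-site probability (0 under OOPS).  Per sequence,
    ``z0[i] + z[i].sum() = 1``.
    """

    z0: np.ndarray
    z: list[np.ndarray]
    iteration: int = 0


@dataclass
class CandidateStart:
    """A Phase I starting point for EM."""

    word: str
    width: int
    nsites: int
    score: float
    theta0: PSPM


@dataclass
class ErasureWeights:
    """Per-position retention weights u[i][pos] in [0,1], initially 1.

    Multiplied into the positional prior mass before each later discovery
    pass, so positions covered by already-reported motifs are
    probabilistically excluded.
    """

    u: list[np.ndarray]

    @classmethod
    def ones(cls, seqs: SequenceSet) -> "ErasureWeights":
        return cls([np.ones(len(r)) for _, r in seqs])

    def copy(self) -> "ErasureWeights":
        return ErasureWeights([v.copy() for v in self.u])


@dataclass
class SiteSelection:
    """Ranked candidate sites chosen from a ZMatrix.

    ``ranked`` holds at most one ``(seq_index, start, strand)`` per sequence
    in decreasing posterior order.  Under ZOOPS every prefix of length
    2..len(ranked) is a candidate site set; under OOPS the whole list is
    the single candidate.
    """

    ranked: list[tuple[int, int, str]]
    z_values: np.ndarray
    model: str

    def prefixes(self) -> list[list[tuple[int, int, str]]]:
        if self.model == "oops":
            return [self.ranked]
        return [self.ranked[:t] for t in range(2, len(self.ranked) + 1)]


@dataclass
class MotifResult:
    """A reported motif: sites, matrices, significance and the EM trace."""

    pspm: PSPM                      # empirical frequencies of the sites
    theta: PSPM                     # EM's converged motif matrix
    sites: list[tuple[str, int, int, str]]  # (seq id, start, end, strand)
    width: int
    nsites: int
    gamma: float
    llr: float
    log10_evalue: float
    objective_trace: list[float]
    converged: bool
    model: str
    t_start: int
    zmatrix: ZMatrix = field(repr=False, default=None)

    @property
    def evalue(self) -> float:
        return 10.0 ** self.log10_evalue


# ---------------------------------------------------------------------------
# column p-values (Hertz & Stormo) and the p-value product
# ---------------------------------------------------------------------------

class ColumnPvalueCalculator:
    """Null distribution of the column LLR for t i.i.d. background draws.

    For ``t <= exact_max`` (DNA) the full multinomial composition lattice is
    enumerated exactly; above that a discretized dynamic program over
    letters accumulates the distribution on a score lattice.
    Tables are cached per number of sites.
    """

    EXACT_MAX = 200
    LATTICE_BINS = 1 << 14

    def __init__(self, bg: BackgroundModel) -> None:
        self.p = bg.marginals
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _llr_of_counts(self, counts: np.ndarray, t: int) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts * np.log2(counts / (t * self.p))
        return np.where(counts > 0, terms, 0.0).sum(axis=-1)

    def _exact_table(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        A = len(self.p)
        grids = np.meshgrid(*[np.arange(t + 1, dtype=np.int32)] * (A - 1),
                            indexing="ij")
        free = np.stack([g.ravel() for g in grids], axis=1)
        keep = free.sum(axis=1) <= t
        free = free[keep]
        counts = np.column_stack([free, t - free.sum(axis=1)])
        logpmf = (gammaln(t + 1) - gammaln(counts + 1).sum(axis=1)
                  + (counts * np.log(self.p)).sum(axis=1))
        llr = self._llr_of_counts(counts, t)
        order = np.argsort(-llr, kind="stable")
        return llr[order], np.cumsum(np.exp(logpmf[order]))

    def _lattice_table(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        A = len(self.p)
        c = np.arange(t + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(c[None, :] > 0,
                         c[None, :] * np.log2(c[None, :]
                                              / (t * self.p[:, None])), 0.0)
        # per-letter terms can be negative; anchor the lattice at the most
        # negative achievable partial sum
        lo = float(np.minimum(g, 0.0).min(axis=1).sum())
        hi = float(max(g.max(), 0.0))
        nbins = self.LATTICE_BINS
        scale = (hi - lo) / (nbins - 1) if hi > lo else 1.0
        zero_bin = int(round(-lo / scale))
        log_fact = gammaln(c + 1)
        dp = np.zeros((t + 1, nbins))
        dp[0, zero_bin] = 1.0
        for a in range(A):
            # floor-binning shifts (relative to the zero anchor) never
            # over-state a score, so tail p-values are not under-counted
            sbin = np.floor(g[a] / scale + 1e-12).astype(int)
            wgt = np.exp(c * math.log(self.p[a]) - log_fact)
            new = np.zeros_like(dp)
            for ca in range(t + 1):
                shifted = dp[: t + 1 - ca]
                s = sbin[ca]
                if s > 0:
                    new[ca:, s:] += shifted[:, : nbins - s] * wgt[ca]
                elif s < 0:
                    new[ca:, : nbins + s] += shifted[:, -s:] * wgt[ca]
                else:
                    new[ca:] += shifted * wgt[ca]
            dp = new
        pmf = dp[t] * math.exp(gammaln(t + 1))
        scores = (np.arange(nbins) - zero_bin) * scale
        order = np.argsort(-scores, kind="stable")
        return scores[order], np.cumsum(pmf[order])

    def table(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        if t not in self._tables:
            if len(self.p) == 4 and t <= self.EXACT_MAX:
                self._tables[t] = self._exact_table(t)
            else:
                self._tables[t] = self._lattice_table(t)
        return self._tables[t]

    def pvalue(self, counts: np.ndarray, t: int) -> float:
        """Pr(column LLR >= observed) for one column of t sites."""
        if t == 0:
            return 1.0
        obs = float(self._llr_of_counts(np.asarray(counts, dtype=float), t))
        llr_desc, cum = self.table(t)
        idx = np.searchsorted(-llr_desc, -(obs - 1e-9), side="right")
        if idx == 0:
            return float(cum[0]) if llr_desc[0] >= obs - 1e-9 else 0.0
        return float(min(cum[idx - 1], 1.0))


def column_pvalue(counts, nsites: int, bg: BackgroundModel) -> float:
    """p-value of one motif column's LLR under the background null.

    ``counts`` are the per-letter counts of the column (summing to
    ``nsites``).  The null draws ``nsites`` letters i.i.d. from the
    background marginals.
    """
    counts = np.asarray(counts, dtype=float)
    if nsites == 0:
        return 1.0
    if counts.sum() != nsites:
        raise ValueError("counts must sum to nsites")
    return ColumnPvalueCalculator(bg).pvalue(counts, nsites)


def _log_product_pvalue(sum_ln_p: float, k: int) -> float:
    """ln of the p-value of a product of k independent uniform p-values.

    With p = prod p_i, the tail probability is
    p * sum_{i=0..k-1} (ln(1/p))^i / i!.
    """
    if k == 0:
        return 0.0
    if sum_ln_p >= 0.0:
        return 0.0
    neg = -sum_ln_p
    i = np.arange(k)
    with np.errstate(divide="ignore"):
        terms = sum_ln_p + i * np.log(neg) - gammaln(i + 1)
    return float(min(logsumexp(terms), 0.0))


def product_pvalue(column_pvalues) -> float:
    """p-value of the product of independent column p-values."""
    ps = np.asarray(list(column_pvalues), dtype=float)
    if ps.size == 0:
        return 1.0
    if ((ps <= 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return math.exp(_log_product_pvalue(float(np.log(ps).sum()), ps.size))


# ---------------------------------------------------------------------------
# starting-point matrices
# ---------------------------------------------------------------------------

def subsequence_to_pspm(word: str | np.ndarray, beta: float = 0.55,
                        alphabet=None) -> PSPM:
    """Convert a subsequence into a starting PSPM.

    Column k puts probability ``beta`` on the word's letter and spreads the
    remainder evenly over the other letters.
    """
    from .alphabet import DNA
    alphabet = alphabet or DNA
    codes = alphabet.encode(word) if isinstance(word, str) else np.asarray(word)
    if (codes < 0).any():
        raise ValueError("starting word may not contain ambiguous residues")
    A = alphabet.size
    mat = np.full((len(codes), A), (1.0 - beta) / (A - 1))
    mat[np.arange(len(codes)), codes] = beta
    return PSPM(mat, alphabet)


# ---------------------------------------------------------------------------
# the flat-table engine
# ---------------------------------------------------------------------------

class _Engine:
    """Precomputed flat site tables for one (dataset, prior, width) combo.

    Every legal site ``(sequence, strand, start)`` is one row.  Reverse
    strand sites are represented by windows of the cached reverse-complement
    sequence; their prior is the forward prior at the site's leftmost
    forward coordinate (the strand-symmetry convention).  Rows whose window
    contains an ambiguous residue keep a sanitized window but get prior
    mass 0, so they can never be selected.
    """

    def __init__(self, seqs: SequenceSet, psp: PositionSpecificPrior,
                 bg: BackgroundModel, w: int, strand_mode: str,
                 erasure: ErasureWeights | None = None) -> None:
        self.seqs = seqs
        self.bg = bg
        self.w = w
        self.strand_mode = strand_mode
        self.n_strands = 2 if strand_mode == "double" else 1
        alph = seqs.alphabet
        self.A = alph.size
        enc = seqs.encoded()
        n = len(seqs)
        if erasure is None:
            erasure = ErasureWeights.ones(seqs)

        seq_idx, strand, jfwd, wins, rho, valid = [], [], [], [], [], []
        seg_starts = [0]
        self.m = np.zeros(n, dtype=int)
        for i, x in enumerate(enc):
            L = len(x)
            m = L - w + 1
            if m < 1:
                raise ValueError(
                    f"sequence {seqs.ids[i]!r} (length {L}) is shorter than "
                    f"motif width {w}")
            self.m[i] = m
            pv = psp.positional[i][:m] * erasure.u[i][:m]
            fw = np.lib.stride_tricks.sliding_window_view(x, w)
            bad = (fw < 0).any(axis=1)
            for s in range(self.n_strands):
                if s == 0:
                    win = fw
                    j = np.arange(m)
                    r = np.where(bad, 0.0, pv)
                else:
                    xrc = alph.revcomp(x)
                    win = np.lib.stride_tricks.sliding_window_view(xrc, w)
                    j = (L - w) - np.arange(m)          # forward leftmost
                    r = np.where(bad[::-1], 0.0, pv[::-1])
                seq_idx.append(np.full(m, i))
                strand.append(np.full(m, s, dtype=np.int8))
                jfwd.append(j)
                wins.append(np.clip(win, 0, None))
                rho.append(r)
                valid.append(~bad if s == 0 else ~bad[::-1])
            seg_starts.append(seg_starts[-1] + self.n_strands * m)

        self.seq_idx = np.concatenate(seq_idx)
        self.strand = np.concatenate(strand)
        self.jfwd = np.concatenate(jfwd)
        self.rho = np.concatenate(rho)
        self.valid = np.concatenate(valid)
        win = np.concatenate(wins).astype(np.intp)
        self.win = win
        # offsets into a row-major (w, A) matrix raveled flat
        self.win_off = win + (np.arange(w) * self.A)[None, :]
        self.seg_starts = np.asarray(seg_starts[:-1])
        self.n = n
        self.P = len(self.rho)
        with np.errstate(divide="ignore"):
            self.log_rho = np.log(self.rho)
        self.seg_sum_rho = np.add.reduceat(self.rho, self.seg_starts)
        self.seg_max_rho = np.maximum.reduceat(self.rho, self.seg_starts)
        # per-sequence positional prior shape q (sums to 1 per sequence)
        with np.errstate(invalid="ignore"):
            self.q = np.where(self.seg_sum_rho[self.seq_idx] > 0,
                              self.rho / self.seg_sum_rho[self.seq_idx], 0.0)
        # zero-order background log-likelihood of all sequences (constant)
        lp = np.log(bg.marginals)
        self.bg_loglik = float(sum(lp[x[x >= 0]].sum() for x in enc))

    # -- helpers ------------------------------------------------------------

    def _gather_sum(self, mat_flat: np.ndarray) -> np.ndarray:
        return mat_flat[self.win_off].sum(axis=1)

    def _gather_prod(self, mat_flat: np.ndarray) -> np.ndarray:
        return mat_flat[self.win_off].prod(axis=1)

    def _counts(self, rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
        C = np.zeros(self.w * self.A)
        np.add.at(C, self.win_off[rows],
                  np.broadcast_to(np.asarray(weights)[:, None],
                                  (len(rows), self.w)))
        return C.reshape(self.w, self.A)

    def candidate_rows(self, max_starts: int) -> np.ndarray:
        idx = np.flatnonzero((self.strand == 0) & self.valid)
        if len(idx) > max_starts:
            pick = np.unique(np.linspace(0, len(idx) - 1,
                                         max_starts).round().astype(int))
            idx = idx[pick]
        return idx

    def _weighted_llr_from_counts(self, C: np.ndarray, n_wt: float) -> float:
        f = C / n_wt
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = C * np.log2(f / self.bg.marginals)
        return float(np.where(C > 0, terms, 0.0).sum())

    # -- Phase I ------------------------------------------------------------

    def t_schedule(self, model: str, n_avail: int) -> list[int]:
        if model == "oops":
            return [n_avail]
        ts = []
        t = 2
        while t < n_avail:
            ts.append(t)
            t *= 2
        if n_avail >= 2:
            ts.append(n_avail)
        elif n_avail == 1:
            ts.append(1)
        return ts

    def phase1(self, model: str, beta: float = 0.55,
               max_starts: int = 500) -> dict[int, CandidateStart]:
        if self.seg_max_rho.max() <= 0:
            raise ValueError("no legal sites: all prior mass is zero")
        cand_rows = self.candidate_rows(max_starts)
        if len(cand_rows) == 0:
            raise ValueError("no candidate starting subsequences "
                             "(every window contains an ambiguous residue)")
        alive = self.seg_max_rho > 0
        n_avail = int(alive.sum())
        schedule = self.t_schedule(model, n_avail)
        best: dict[int, CandidateStart] = {}
        seg = self.seg_starts
        with np.errstate(invalid="ignore", divide="ignore"):
            b_row = np.where(self.seg_max_rho[self.seq_idx] > 0,
                             self.rho / self.seg_max_rho[self.seq_idx], 0.0)

        for row in cand_rows:
            word_codes = self.win[row].astype(np.int8)
            theta0 = subsequence_to_pspm(word_codes, beta, self.seqs.alphabet)
            val = self._gather_sum(theta0.log_matrix().ravel()) + self.log_rho

            if model == "oops":
                seg_max = np.maximum.reduceat(val, seg)
                finite = np.isfinite(val)
                hit = finite & (val == seg_max[self.seq_idx])
                cand = np.flatnonzero(hit)
                _, first = np.unique(self.seq_idx[cand], return_index=True)
                rows = cand[first]
                wts = b_row[rows]
                C = self._counts(rows, wts)
                score = self._weighted_llr_from_counts(C, wts.sum())
                t = n_avail
                if t not in best or score > best[t].score:
                    best[t] = CandidateStart(
                        self.seqs.alphabet.decode(word_codes), self.w, t,
                        score, theta0)
            else:
                order = np.argsort(-val, kind="stable")
                finite = np.isfinite(val[order])
                order = order[finite]
                _, first = np.unique(self.seq_idx[order], return_index=True)
                ranked = order[np.sort(first)]
                T = len(ranked)
                if T == 0:
                    continue
                wts = b_row[ranked]
                onehot = np.zeros((T, self.w * self.A))
                rws = np.arange(T)[:, None]
                onehot[rws, self.win_off[ranked]] = wts[:, None]
                cumC = np.cumsum(onehot, axis=0)
                cumW = np.cumsum(wts)
                for t in schedule:
                    if t > T:
                        continue
                    C = cumC[t - 1].reshape(self.w, self.A)
                    score = self._weighted_llr_from_counts(C, cumW[t - 1])
                    if t not in best or score > best[t].score:
                        best[t] = CandidateStart(
                            self.seqs.alphabet.decode(word_codes), self.w, t,
                            score, theta0)
        return best

    # -- Phase II -----------------------------------------------------------

    def e_step_flat(self, theta: np.ndarray, gamma: float,
                    model: str) -> tuple[np.ndarray, np.ndarray, float]:
        """One E-step; returns (Z rows, Z0, observed-data log likelihood)."""
        ratio = (theta / self.bg.marginals).ravel()
        lr = self._gather_prod(ratio)
        site_mass = gamma * self.q * lr
        s = np.add.reduceat(site_mass, self.seg_starts)
        z0_mass = np.full(self.n, 1.0 - gamma)
        if model == "oops":
            z0_mass[:] = 0.0
        denom = s + z0_mass
        if (denom <= 0).any():
            i = int(np.argmax(denom <= 0))
            raise ValueError(
                f"sequence {self.seqs.ids[i]!r}: total posterior mass is "
                "zero (all site priors vanish)")
        z = site_mass / denom[self.seq_idx]
        z0 = z0_mass / denom
        loglik = float(np.log(denom).sum()) + self.bg_loglik
        return z, z0, loglik

    def m_step_flat(self, z: np.ndarray, z0: np.ndarray, model: str,
                    pseudo_frac: float) -> tuple[np.ndarray, float]:
        delta = pseudo_frac * self.bg.marginals
        C = self._counts(np.arange(self.P), z)
        theta = (C + delta) / (z.sum() + delta.sum())
        if model == "oops":
            gamma = 1.0
        else:
            gamma = float(np.clip(np.mean(1.0 - z0), 1.0 / self.n, 1.0))
        return theta, gamma

    def run_em(self, theta0: PSPM, gamma0: float, model: str,
               max_iter: int = 50, tol: float = 1e-3,
               pseudo_frac: float = 0.01):
        theta = theta0.matrix.copy()
        gamma = 1.0 if model == "oops" else float(gamma0)
        trace: list[float] = []
        delta_pc = pseudo_frac * self.bg.marginals
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            z, z0, loglik = self.e_step_flat(theta, gamma, model)
            with np.errstate(divide="ignore"):
                prior_term = float((delta_pc * np.log(theta)).sum())
            trace.append(loglik + prior_term)
            theta_new, gamma = self.m_step_flat(z, z0, model, pseudo_frac)
            change = float(np.abs(theta_new - theta).max())
            theta = theta_new
            if change < tol:
                converged = True
                break
        z, z0, _ = self.e_step_flat(theta, gamma, model)
        return theta, gamma, z, z0, trace, converged, it

    def zmatrix(self, z: np.ndarray, z0: np.ndarray,
                iteration: int = 0) -> ZMatrix:
        out = []
        for i in range(self.n):
            a = self.seg_starts[i]
            m = self.m[i]
            zi = np.zeros((self.n_strands, m))
            zi[0] = z[a:a + m]
            if self.n_strands == 2:
                zi[1] = z[a + m:a + 2 * m][::-1]   # re-index to forward start
            out.append(zi)
        return ZMatrix(z0.copy(), out, iteration)

    # -- Phase III ----------------------------------------------------------

    def rank_sites(self, z: np.ndarray, model: str) -> np.ndarray:
        """Row indices of the best site per sequence, in decreasing
        posterior order (at most one per sequence)."""
        order = np.argsort(-z, kind="stable")
        keep = z[order] > 0
        order = order[keep]
        _, first = np.unique(self.seq_idx[order], return_index=True)
        return order[np.sort(first)]

    def score_sites(self, ranked: np.ndarray, model: str,
                    calc: ColumnPvalueCalculator):
        """Best prefix of the ranked sites by E-value.

        Returns (rows, nsites, llr, log10_evalue, counts).
        """
        T = len(ranked)
        if T == 0:
            raise ValueError("no sites to score")
        strands = self.n_strands
        log_m = np.log(strands * self.m.astype(float))
        if model == "oops":
            t_values = [T]
        else:
            t_values = list(range(2, T + 1)) if T >= 2 else [T]
        onehot = np.zeros((T, self.w * self.A))
        onehot[np.arange(T)[:, None], self.win_off[ranked]] = 1.0
        cumC = np.cumsum(onehot, axis=0)
        cum_logm = np.cumsum(log_m[self.seq_idx[ranked]])
        best = None
        for t in t_values:
            C = cumC[t - 1].reshape(self.w, self.A)
            sum_ln_p = 0.0
            for k in range(self.w):
                pv = calc.pvalue(C[k], t)
                sum_ln_p += math.log(pv)
            log_p = _log_product_pvalue(sum_ln_p, self.w)
            if model == "oops":
                ln_ways = float(cum_logm[t - 1])
            else:
                ln_ways = float(cum_logm[t - 1]) + float(
                    gammaln(self.n + 1) - gammaln(t + 1)
                    - gammaln(self.n - t + 1))
            log10_e = (log_p + ln_ways) / LN10
            if best is None or log10_e < best[3]:
                llr = self._weighted_llr_from_counts(C, float(t))
                best = (ranked[:t], t, llr, log10_e, C)
        return best

    def sites_output(self, rows: np.ndarray) -> list[tuple[str, int, int, str]]:
        out = []
        for r in rows:
            i = int(self.seq_idx[r])
            j = int(self.jfwd[r])
            s = "+" if self.strand[r] == 0 else "-"
            out.append((self.seqs.ids[i], j, j + self.w, s))
        return out


# ---------------------------------------------------------------------------
# functional wrappers over the engine
# ---------------------------------------------------------------------------

def _resolve(seqs: SequenceSet, psp: PositionSpecificPrior | None,
             bg: BackgroundModel | None, w: int, model: str,
             strand_mode: str, erasure: ErasureWeights | None,
             renormalize: bool = True):
    if bg is None:
        bg = estimate_background(seqs, 0,
                                 double_strand=(strand_mode == "double"))
    if psp is None:
        psp = make_uniform_psp(seqs, w, model, strand_mode)
    if renormalize and psp.w0 != w:
        psp = renormalize_psp(psp, w)
    return _Engine(seqs, psp, bg, w, strand_mode, erasure), bg


def phase1_search(seqs: SequenceSet, psp: PositionSpecificPrior | None,
                  bg: BackgroundModel | None, w: int, model: str = "zoops",
                  erasure: ErasureWeights | None = None,
                  strand_mode: str = "double", beta: float = 0.55,
                  max_starts: int = 500) -> dict[int, CandidateStart]:
    """Best EM starting point for each number-of-sites t at width w."""
    eng, _ = _resolve(seqs, psp, bg, w, model, strand_mode, erasure)
    return eng.phase1(model, beta, max_starts)


def e_step(seqs: SequenceSet, params: ModelParams,
           bg: BackgroundModel | None = None,
           erasure: ErasureWeights | None = None) -> ZMatrix:
    """Posterior site-start probabilities Z given current parameters."""
    eng, _ = _resolve(seqs, params.psp, bg, params.theta.width, params.model,
                      params.strand_mode, erasure)
    z, z0, _ = eng.e_step_flat(params.theta.matrix, params.gamma,
                               params.model)
    return eng.zmatrix(z, z0)


def m_step(seqs: SequenceSet, Z: ZMatrix, model: str,
           bg: BackgroundModel | None = None, width: int | None = None,
           pseudo_frac: float = 0.01,
           strand_mode: str | None = None) -> ModelParams:
    """Re-estimate theta (with background-proportional pseudocounts) and
    gamma from a normalized ZMatrix; the PSP is held fixed (not returned)."""
    if width is None:
        some = Z.z[0]
        width = len(seqs.residues[0]) - some.shape[1] + 1
    if strand_mode is None:
        strand_mode = "double" if Z.z[0].shape[0] == 2 else "single"
    if bg is None:
        bg = estimate_background(seqs, 0,
                                 double_strand=(strand_mode == "double"))
    eng = _Engine(seqs, make_uniform_psp(seqs, width, model, strand_mode),
                  bg, width, strand_mode)
    z = np.empty(eng.P)
    for i in range(eng.n):
        a = eng.seg_starts[i]
        m = eng.m[i]
        z[a:a + m] = Z.z[i][0]
        if eng.n_strands == 2:
            z[a + m:a + 2 * m] = Z.z[i][1][::-1]
    theta, gamma = eng.m_step_flat(z, Z.z0, model, pseudo_frac)
    return ModelParams(PSPM(theta, seqs.alphabet), gamma, None, model,
                       strand_mode)


@dataclass
class EMResult:
    params: ModelParams
    zmatrix: ZMatrix
    objective_trace: list[float]
    converged: bool
    n_iter: int


def run_em(start: CandidateStart, seqs: SequenceSet,
           psp: PositionSpecificPrior | None, bg: BackgroundModel | None,
           model: str = "zoops", max_iter: int = 50, tol: float = 1e-3,
           strand_mode: str = "double", erasure: ErasureWeights | None = None,
           pseudo_frac: float = 0.01) -> EMResult:
    """EM from a Phase I starting point until theta stabilizes.

    Records the observed-data log posterior (sequence log likelihood plus
    the Dirichlet pseudocount term) at the start of every iteration; the
    trace is non-decreasing.
    """
    eng, bg = _resolve(seqs, psp, bg, start.width, model, strand_mode,
                       erasure)
    gamma0 = 1.0 if model == "oops" else min(max(start.nsites / eng.n,
                                                 1.0 / eng.n), 1.0)
    theta, gamma, z, z0, trace, conv, it = eng.run_em(
        start.theta0, gamma0, model, max_iter, tol, pseudo_frac)
    params = ModelParams(PSPM(theta, seqs.alphabet), gamma, psp, model,
                         strand_mode)
    return EMResult(params, eng.zmatrix(z, z0, it), trace, conv, it)


def select_sites(Z: ZMatrix, model: str = "zoops") -> SiteSelection:
    """Rank site candidates by posterior: at most one site per sequence,
    in decreasing Z order, ties broken by (sequence, strand, position)."""
    entries = []
    for i, zi in enumerate(Z.z):
        if zi.max() <= 0:
            continue
        flat = int(np.argmax(zi))
        s, j = divmod(flat, zi.shape[1])
        entries.append((i, j, "+" if s == 0 else "-", float(zi[s, j])))
    entries.sort(key=lambda e: (-e[3], e[0], e[1], e[2]))
    ranked = [(i, j, s) for i, j, s, _ in entries]
    zv = np.array([v for *_, v in entries])
    return SiteSelection(ranked, zv, model)


def motif_evalue(sites: list[tuple[int, int, str]], theta: PSPM,
                 seqs: SequenceSet, bg: BackgroundModel,
                 model: str = "zoops",
                 strand_mode: str = "double") -> float:
    """log10 E-value of a motif defined by an explicit site list.

    The motif p-value is the product-of-column-p-values statistic of the
    site alignment; the E-value multiplies it by the number of distinct
    ways the same number of sites could have been placed.
    """
    w = theta.width
    t = len(sites)
    if t == 0:
        raise ValueError("no sites")
    alph = seqs.alphabet
    counts = np.zeros((w, alph.size))
    strands = 2 if strand_mode == "double" else 1
    ln_ways = 0.0
    chosen = []
    for i, j, s in sites:
        codes = seqs.encoded()[i][j:j + w]
        if s == "-":
            codes = alph.revcomp(codes)
        counts[np.arange(w), codes] += 1
        chosen.append(i)
        ln_ways += math.log(strands * (len(seqs.residues[i]) - w + 1))
    if model == "zoops":
        n = len(seqs)
        ln_ways += float(gammaln(n + 1) - gammaln(t + 1) - gammaln(n - t + 1))
    calc = ColumnPvalueCalculator(bg)
    sum_ln_p = sum(math.log(calc.pvalue(counts[k], t)) for k in range(w))
    return (_log_product_pvalue(sum_ln_p, w) + ln_ways) / LN10


def erase(erasure: ErasureWeights, Z: ZMatrix, w: int) -> ErasureWeights:
    """Probabilistically erase a reported motif's sites.

    Every position covered by a potential site start j is down-weighted by
    ``1 - Pr(site starts at j)`` (summed over strands), so a certain site
    zeroes out its footprint while a weak one barely dents it.
    """
    out = erasure.copy()
    for i, zi in enumerate(Z.z):
        start_p = np.clip(zi.sum(axis=0), 0.0, 1.0)
        g = 1.0 - start_p
        m = len(g)
        for d in range(w):
            out.u[i][d:d + m] *= g
    return out


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

def discover_motifs(seqs: SequenceSet,
                    psp: PositionSpecificPrior | None = None,
                    bg: BackgroundModel | None = None,
                    model: str = "zoops", minw: int = 7, maxw: int = 12,
                    nmotifs: int = 1, strand_mode: str = "double",
                    seed: int = 0, max_starts: int = 500, beta: float = 0.55,
                    pseudo_frac: float = 0.01, max_iter: int = 50,
                    tol: float = 1e-3) -> list[MotifResult]:
    """Discover up to ``nmotifs`` motifs, each the best E-value over every
    width in ``[minw, maxw]`` and every number-of-sites in the schedule.

    With ``psp=None`` the uniform prior at design width ``minw`` is used —
    the identical code path, so a uniform PSP and no PSP give bitwise equal
    results.  The procedure is deterministic given its inputs.
    """
    del seed  # deterministic throughout; accepted for interface stability
    if minw > maxw or minw < 1:
        raise ValueError(f"empty width range [{minw}, {maxw}]")
    if model not in ("oops", "zoops"):
        raise ValueError(f"bad model {model!r}")
    if bg is None:
        bg = estimate_background(seqs, 0,
                                 double_strand=(strand_mode == "double"))
    if psp is None:
        psp = make_uniform_psp(seqs, minw, model, strand_mode)
    else:
        diag = validate_psp(psp, model)
        if not diag:
            raise ValueError(f"invalid PSP: {diag.violations[:3]}")
    calc = ColumnPvalueCalculator(bg)
    erasure = ErasureWeights.ones(seqs)
    results: list[MotifResult] = []
    for _ in range(nmotifs):
        best: MotifResult | None = None
        for w in range(minw, maxw + 1):
            pspw = renormalize_psp(psp, w) if psp.w0 != w else psp
            eng = _Engine(seqs, pspw, bg, w, strand_mode, erasure)
            starts = eng.phase1(model, beta, max_starts)
            for t in sorted(starts):
                cand = starts[t]
                gamma0 = 1.0 if model == "oops" else min(
                    max(t / eng.n, 1.0 / eng.n), 1.0)
                theta, gamma, z, z0, trace, conv, it = eng.run_em(
                    cand.theta0, gamma0, model, max_iter, tol, pseudo_frac)
                ranked = eng.rank_sites(z, model)
                if len(ranked) == 0:
                    continue
                rows, nsites, llr, log10_e, C = eng.score_sites(
                    ranked, model, calc)
                if best is None or log10_e < best.log10_evalue:
                    pspm = PSPM(C / nsites, seqs.alphabet, nsites=nsites)
                    best = MotifResult(
                        pspm=pspm,
                        theta=PSPM(theta, seqs.alphabet),
                        sites=eng.sites_output(rows),
                        width=w, nsites=nsites, gamma=gamma, llr=llr,
                        log10_evalue=log10_e, objective_trace=trace,
                        converged=conv, model=model, t_start=t,
                        zmatrix=eng.zmatrix(z, z0, it))
        if best is None:
            break
        results.append(best)
        erasure = erase(erasure, best.zmatrix, best.width)
    return results


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

class MotifDiscovery(TransformerMixin, BaseEstimator):
    """Unsupervised motif discovery as a scikit-learn estimator.

    ``fit(X)`` discovers motifs in a :class:`SequenceSet` (or list of
    sequence strings); ``transform(X)`` returns the average-motif-affinity
    (AMA) score of every sequence under every fitted motif, a
    ``(n_sequences, n_motifs)`` array usable downstream in sklearn
    pipelines and model selection.

    Parameters mirror :func:`discover_motifs`; fitted attributes carry the
    customary trailing underscore.
    """

    def __init__(self, model: str = "zoops", min_width: int = 7,
                 max_width: int = 12, n_motifs: int = 1,
                 both_strands: bool = True, bg_order: int = 0,
                 max_starts: int = 500, beta: float = 0.55,
                 pseudocount: float = 0.01, max_iter: int = 50,
                 tol: float = 1e-3, seed: int = 0) -> None:
        self.model = model
        self.min_width = min_width
        self.max_width = max_width
        self.n_motifs = n_motifs
        self.both_strands = both_strands
        self.bg_order = bg_order
        self.max_starts = max_starts
        self.beta = beta
        self.pseudocount = pseudocount
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    @staticmethod
    def _as_seqs(X) -> SequenceSet:
        if isinstance(X, SequenceSet):
            return X
        return SequenceSet.from_strings(list(X))

    def fit(self, X, y=None, psp: PositionSpecificPrior | None = None,
            background: BackgroundModel | None = None) -> "MotifDiscovery":
        seqs = self._as_seqs(X)
        strand_mode = "double" if self.both_strands else "single"
        bg = background
        if bg is None:
            bg = estimate_background(seqs, self.bg_order,
                                     double_strand=self.both_strands)
        self.background_ = bg
        self.motifs_ = discover_motifs(
            seqs, psp=psp, bg=bg, model=self.model, minw=self.min_width,
            maxw=self.max_width, nmotifs=self.n_motifs,
            strand_mode=strand_mode, seed=self.seed,
            max_starts=self.max_starts, beta=self.beta,
            pseudo_frac=self.pseudocount, max_iter=self.max_iter,
            tol=self.tol)
        self.best_motif_ = self.motifs_[0] if self.motifs_ else None
        self.n_sequences_ = len(seqs)
        return self

    def transform(self, X) -> np.ndarray:
        from .evaluation import ama_score
        if not hasattr(self, "motifs_"):
            raise AttributeError("MotifDiscovery instance is not fitted yet")
        seqs = self._as_seqs(X)
        strand_mode = "double" if self.both_strands else "single"
        out = np.zeros((len(seqs), len(self.motifs_)))
        for k, res in enumerate(self.motifs_):
            # the EM matrix is pseudocount-smoothed, so no window scores an
            # exact zero the way the raw site-frequency matrix would
            for i, (_, residues) in enumerate(seqs):
                out[i, k] = ama_score(res.theta, residues, self.background_,
                                      strand_mode)
        return out
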