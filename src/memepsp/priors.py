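"""Position-specific priors (PSPs) over motif site locations.

A PSP assigns, for every start position j in every sequence i, the prior
probability ``P[i,j]`` that a motif site of a stated design width ``w0``
begins there, plus a per-sequence "no site anywhere" mass ``P[i,0]``.
Constraints: values lie in [0,1], the last ``w0-1`` positions are 0 (a site
must fit inside the sequence), and per sequence
``P[i,0] + sum_j P[i,j] = 1``.  The OOPS sequence model (exactly one site
per sequence) forces ``P[i,0] = 0``.

When motifs of a width ``w != w0`` are searched, the prior is renormalized:
for ``w > w0`` the prior of a wide site is the geometric mean of the priors
of every width-``w0`` site it completely contains (capped at ``w0`` factors),
rescaled per sequence so the distribution still sums to one; for ``w < w0``
the prior is used as-is, which leaves the trailing positions at zero.

On double-stranded DNA the prior is required to be strand-symmetric: the
prior of a site on the reverse strand equals the forward value at the site's
leftmost forward coordinate.  Only the forward array is stored, which makes
the symmetry automatic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import SequenceSet

__all__ = [
    "PositionSpecificPrior",
    "PSPDiagnostics",
    "make_uniform_psp",
    "validate_psp",
    "renormalize_psp",
    "reverse_strand_prior",
    "mirror_psp",
]

SUM_TOL = 1e-6


@dataclass
class PositionSpecificPrior:
    """Per-sequence positional prior arrays tied to a design width.

    ``positional[i]`` has length ``L_i`` and holds ``P[i,j]`` for 0-based
    start positions; entries beyond ``L_i - w0`` are zero.  ``p0[i]`` is the
    no-site mass ``P[i,0]``.
    """

    positional: list[np.ndarray]
    p0: np.ndarray
    w0: int
    strand_mode: str = "double"  # "single" | "double"
    seq_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.positional = [np.asarray(v, dtype=float) for v in self.positional]
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.strand_mode not in ("single", "double"):
            raise ValueError(f"bad strand_mode {self.strand_mode!r}")
        if self.w0 < 1:
            raise ValueError("w0 must be >= 1")
        if len(self.positional) != len(self.p0):
            raise ValueError("positional and p0 differ in length")

    def __len__(self) -> int:
        return len(self.positional)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(v) for v in self.positional])

    def copy(self) -> "PositionSpecificPrior":
        return PositionSpecificPrior(
            [v.copy() for v in self.positional], self.p0.copy(), self.w0,
            self.strand_mode, None if self.seq_ids is None else list(self.seq_ids))


@dataclass
class PSPDiagnostics:
    ok: bool
    violations: list[tuple[int, str]]

    def __bool__(self) -> bool:
        return self.ok


def make_uniform_psp(seqs: SequenceSet, w0: int, model: str = "zoops",
                     strand_mode: str = "double") -> PositionSpecificPrior:
    """The default prior: uniform over the legal start positions.

    ``P[i,j] = 1/m_i`` on the ``m_i = L_i - w0 + 1`` legal positions, zero on
    the trailing ``w0 - 1``, and ``P[i,0] = 0`` (site/no-site balance is
    carried by the sequence model's gamma, not the PSP).
    """
    if w0 < 1:
        raise ValueError("w0 must be >= 1")
    positional = []
    for sid, res in seqs:
        L = len(res)
        m = L - w0 + 1
        if m < 1:
            raise ValueError(f"sequence {sid!r} (length {L}) is shorter than "
                             f"w0={w0}")
        v = np.zeros(L)
        v[:m] = 1.0 / m
        positional.append(v)
    return PositionSpecificPrior(positional, np.zeros(len(seqs)), w0,
                                 strand_mode, list(seqs.ids))


def validate_psp(psp: PositionSpecificPrior,
                 model: str = "zoops") -> PSPDiagnostics:
    """Check every PSP constraint; returns diagnostics, never raises."""
    violations: list[tuple[int, str]] = []
    for i, v in enumerate(psp.positional):
        if ((v < 0) | (v > 1)).any():
            violations.append((i, "value outside [0, 1]"))
        tail = v[max(len(v) - psp.w0 + 1, 0):]
        if (tail != 0).any():
            violations.append((i, f"last {psp.w0 - 1} positions not all zero"))
        total = psp.p0[i] + v.sum()
        if abs(total - 1.0) > SUM_TOL:
            violations.append((i, f"mass sums to {total:.8f}, not 1"))
        if not 0 <= psp.p0[i] <= 1:
            violations.append((i, "no-site mass outside [0, 1]"))
        if model == "oops" and psp.p0[i] != 0:
            violations.append((i, "nonzero no-site mass"))
    return PSPDiagnostics(not violations, violations)


def renormalize_psp(psp: PositionSpecificPrior,
                    w: int) -> PositionSpecificPrior:
    """Adapt a width-``w0`` prior to motif width ``w``.

    ``w == w0``: returned unchanged.  ``w < w0``: values used as-is (the
    design-width prior carries no information about the extra trailing start
    positions, which therefore stay at zero).  ``w > w0``: the raw prior of a
    wide site is the geometric mean of the ``c = min(w - w0 + 1, w0)``
    contained design-width sites starting at its left edge, and the positional
    mass is then rescaled per sequence to ``1 - P[i,0]`` (the no-site mass the
    user encoded is preserved).

    Deterministic and idempotent at fixed ``w``; log-addends of each
    geometric mean are sorted before summation so the operation commutes
    exactly with mirroring the prior.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    if w <= psp.w0:
        return psp.copy()
    c = min(w - psp.w0 + 1, psp.w0)
    out = []
    for i, v in enumerate(psp.positional):
        L = len(v)
        m = L - w + 1
        new = np.zeros(L)
        if m >= 1:
            with np.errstate(divide="ignore"):
                logs = np.log(v[:L - psp.w0 + 1])
            if m > 0:
                win = np.lib.stride_tricks.sliding_window_view(logs[:m + c - 1], c)
                raw = np.exp(np.sort(win, axis=1).sum(axis=1) / c)
                new[:m] = raw
        total = math.fsum(new[:max(m, 0)])
        target = 1.0 - psp.p0[i]
        if total == 0.0:
            if m >= 1 and target > 0:
                warnings.warn(
                    f"sequence index {i}: renormalized prior vanished; "
                    "falling back to uniform over legal positions",
                    stacklevel=2)
                new[:m] = target / m
        else:
            new[:m] *= target / total
        out.append(new)
    return PositionSpecificPrior(out, psp.p0.copy(), w, psp.strand_mode,
                                 None if psp.seq_ids is None
                                 else list(psp.seq_ids))


def reverse_strand_prior(psp: PositionSpecificPrior, w: int, i: int,
                         j: int) -> float:
    """Prior for a reverse-strand site occupying forward interval
    ``[j, j + w - 1]`` of sequence ``i``.

    By the strand-symmetry requirement this equals the forward prior at the
    site's leftmost forward coordinate; positions outside the legal range
    return 0.
    """
    if psp.strand_mode != "double":
        raise ValueError("reverse-strand prior requires double-strand mode")
    v = psp.positional[i]
    if j < 0 or j > len(v) - w:
        return 0.0
    return float(v[j])


def mirror_psp(psp: PositionSpecificPrior) -> PositionSpecificPrior:
    """The PSP that corresponds to reverse-complementing every sequence.

    A forward site at start j of the original maps to a forward site at
    start ``L - w0 - j`` of the reverse-complemented sequence, so the legal
    range of each positional array is reversed in place.
    """
    out = []
    for v in psp.positional:
        m = len(v) - psp.w0 + 1
        new = np.zeros_like(v)
        new[:m] = v[:m][::-1]
        out.append(new)
    return PositionSpecificPrior(out, psp.p0.copy(), psp.w0, psp.strand_mode,
                                 None if psp.seq_ids is None
                                 else list(psp.seq_ids))
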