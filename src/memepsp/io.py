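"""File formats: FASTA, Markov background files, PSP files, motif blocks.

The PSP dialect (this package's own, documented specification):
each record starts with a header line ``>seqID w0``; the following
whitespace-separated decimal values give the positional prior, exactly
``L_i`` values for sequence ``i`` (one per start position, 1-based; the
last ``w0 - 1`` must be 0).  An optional leading token ``p0=VALUE`` gives
the no-site mass ``P_{i,0}`` (default: 1 minus the positional sum, clamped
at 0 when within 1e-6).  All records must declare the same ``w0``;
sequences absent from the file receive the uniform prior.

Background files follow the MEME-style convention: one k-mer and one
probability per line, covering every k-mer of every order 0..K.
"""

from __future__ import annotations

import itertools
import math
import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DNA, Alphabet, SequenceSet
from .background import BackgroundModel, estimate_background  # noqa: F401
from .motifs import PSPM
from .priors import PositionSpecificPrior, make_uniform_psp

__all__ = [
    "read_fasta", "write_fasta",
    "read_background", "write_background", "estimate_background",
    "read_psp", "write_psp",
    "write_motif", "read_motif", "write_sites_bed",
]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path, alphabet: Alphabet = DNA) -> SequenceSet:
    """Read a FASTA file into a SequenceSet (uppercased, validated).

    Residues outside the alphabet (plus its ambiguity letter) raise an
    error naming the record and 1-based offset; an empty file yields an
    empty set with a warning.
    """
    ids, residues = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        residues.append(str(rec.seq).upper())
    if not ids:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    seqs = SequenceSet(ids, residues, alphabet)
    seqs.encoded()  # validate residues eagerly
    return seqs


def write_fasta(seqs: SequenceSet, path) -> None:
    records = [SeqRecord(Seq(res), id=sid, description="")
               for sid, res in seqs]
    SeqIO.write(records, str(path), "fasta")


# -- background files -------------------------------------------------------

def read_background(path, alphabet: Alphabet = DNA) -> BackgroundModel:
    """Read a MEME-style background file (lines of "k-mer probability")."""
    probs: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'kmer probability'")
        kmer, val = parts[0].upper(), float(parts[1])
        if val < 0:
            raise ValueError(f"{path}:{lineno}: negative probability")
        probs[kmer] = val
    if not probs:
        raise ValueError(f"{path}: empty background file")
    A = alphabet.size
    max_k = max(len(k) for k in probs)
    conditionals = []
    for k in range(1, max_k + 1):
        table = np.zeros((A ** (k - 1), A))
        joint = {}
        for kmer in itertools.product(alphabet.letters, repeat=k):
            word = "".join(kmer)
            if word not in probs:
                raise ValueError(
                    f"{path}: order {k - 1} is incomplete: missing {word!r}")
            joint[word] = probs[word]
        total = sum(joint.values())
        if abs(total - 1.0) > 1e-3:
            warnings.warn(
                f"{path}: order-{k - 1} probabilities sum to {total:.6f}; "
                "renormalizing", stacklevel=2)
        for word, val in joint.items():
            ctx = 0
            for c in word[:-1]:
                ctx = ctx * A + alphabet.index(c)
            table[ctx, alphabet.index(word[-1])] = val
        row_sums = table.sum(axis=1, keepdims=True)
        if (row_sums == 0).any():
            raise ValueError(f"{path}: order {k - 1} has an all-zero context")
        conditionals.append(table / row_sums)
    return BackgroundModel(conditionals, alphabet)


def write_background(bg: BackgroundModel, path) -> None:
    """Write joint k-mer probabilities for all orders 0..K."""
    alph = bg.alphabet
    A = alph.size
    lines = []
    for o, cond in enumerate(bg.conditionals):
        # joint probability of a k-mer = marginal chain product
        for ctx_codes in itertools.product(range(A), repeat=o):
            pref = 1.0
            c = 0
            for d, code in enumerate(ctx_codes):
                pref *= bg.conditionals[min(d, len(bg.conditionals) - 1)][
                    c % (A ** min(d, bg.order)), code]
                c = c * A + code
            for a in range(A):
                word = "".join(alph.letters[x] for x in ctx_codes) + \
                    alph.letters[a]
                lines.append(f"{word} {pref * cond[c % (A ** o), a]:.8e}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- PSP files --------------------------------------------------------------

def read_psp(path, seqs: SequenceSet,
             strand_mode: str = "double") -> PositionSpecificPrior:
    """Read a PSP file against a sequence set.

    Sequences missing from the file get the uniform prior at the declared
    ``w0``.  Raises on unknown ids, out-of-range values, positional sums
    above 1 + 1e-6, nonzero trailing values, or inconsistent ``w0``.
    """
    text = Path(path).read_text()
    records: list[tuple[str, int, list[str]]] = []
    cur = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            if len(parts) != 2:
                raise ValueError(f"{path}: bad PSP header {line!r}")
            cur = (parts[0], int(parts[1]), [])
            records.append(cur)
        else:
            if cur is None:
                raise ValueError(f"{path}: values before any header")
            cur[2].extend(line.split())
    if not records:
        raise ValueError(f"{path}: empty PSP file")
    w0s = {w for _, w, _ in records}
    if len(w0s) != 1:
        raise ValueError(f"{path}: records declare different w0: {sorted(w0s)}")
    w0 = w0s.pop()
    by_id = {}
    for sid, _, toks in records:
        if sid not in seqs.ids:
            raise ValueError(f"{path}: unknown sequence id {sid!r}")
        p0 = None
        if toks and toks[0].startswith("p0="):
            p0 = float(toks[0][3:])
            toks = toks[1:]
        vals = np.array([float(t) for t in toks])
        by_id[sid] = (p0, vals)
    positional, p0s = [], []
    for i, (sid, res) in enumerate(seqs):
        L = len(res)
        if sid not in by_id:
            uni = make_uniform_psp(
                SequenceSet([sid], [res], seqs.alphabet), w0,
                strand_mode=strand_mode)
            positional.append(uni.positional[0])
            p0s.append(0.0)
            continue
        p0, vals = by_id[sid]
        if len(vals) != L:
            raise ValueError(
                f"{path}: sequence {sid!r}: expected {L} values, "
                f"got {len(vals)}")
        bad = np.flatnonzero((vals < 0) | (vals > 1))
        if bad.size:
            j = int(bad[0])
            raise ValueError(
                f"{path}: sequence {sid!r}, position {j + 1}: value "
                f"{vals[j]} outside [0, 1]")
        tail = vals[L - w0 + 1:] if w0 > 1 else vals[L:]
        if (tail != 0).any():
            raise ValueError(
                f"{path}: sequence {sid!r}: the last {w0 - 1} values must "
                "be 0 (a width-w0 site cannot start there)")
        s = float(vals.sum())
        if s > 1.0 + 1e-6:
            raise ValueError(
                f"{path}: sequence {sid!r}: positional sum {s:.8f} exceeds 1")
        if p0 is None:
            p0 = 1.0 - s
            if abs(p0) <= 1e-6:
                p0 = 0.0
        if not 0.0 <= p0 <= 1.0 + 1e-6:
            raise ValueError(f"{path}: sequence {sid!r}: p0 {p0} outside "
                             "[0, 1]")
        positional.append(vals)
        p0s.append(min(p0, 1.0))
    return PositionSpecificPrior(positional, np.array(p0s), w0, strand_mode,
                                 list(seqs.ids))


def write_psp(psp: PositionSpecificPrior, path) -> None:
    ids = psp.seq_ids or [f"seq{i + 1}" for i in range(len(psp))]
    lines = []
    for sid, v, p0 in zip(ids, psp.positional, psp.p0):
        lines.append(f">{sid} {psp.w0}")
        toks = []
        if p0 != 0.0:
            toks.append(f"p0={float(p0)!r}")
        toks.extend(repr(float(x)) for x in v)
        for a in range(0, len(toks), 8):
            lines.append(" ".join(toks[a:a + 8]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- motif blocks -----------------------------------------------------------

def write_motif(motif: PSPM, sites, evalue: float, path) -> None:
    """Write a minimal text motif block plus BED-like site lines.

    ``sites`` is a list of ``(sequence id, start, end, strand)`` with
    0-based half-open coordinates.
    """
    w = motif.width
    lines = [
        f"MOTIF {motif.name or 'motif'}",
        f"alphabet= {motif.alphabet.letters} width= {w} "
        f"nsites= {len(sites)} evalue= {evalue:.6e}",
    ]
    for k in range(w):
        lines.append(" ".join(f"{x:.10f}" for x in motif.matrix[k]))
    lines.append("SITES")
    for sid, start, end, strand in sites:
        lines.append(f"{sid}\t{start}\t{end}\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_motif(path, alphabet: Alphabet = DNA):
    """Read back a motif block; returns (PSPM, sites, evalue)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("MOTIF"):
        raise ValueError(f"{path}: not a motif block")
    name = lines[0].split(maxsplit=1)[1] if len(lines[0].split()) > 1 else None
    meta = dict(zip(lines[1].split()[::2], lines[1].split()[1::2]))
    w = int(meta["width="])
    nsites = int(meta["nsites="])
    evalue = float(meta["evalue="])
    mat = np.array([[float(x) for x in lines[2 + k].split()]
                    for k in range(w)])
    mat = mat / mat.sum(axis=1, keepdims=True)
    sites = []
    idx = 2 + w
    if idx < len(lines) and lines[idx] == "SITES":
        for ln in lines[idx + 1:]:
            sid, start, end, strand = ln.split("\t")
            sites.append((sid, int(start), int(end), strand))
    pspm = PSPM(mat, alphabet, nsites=nsites, evalue=evalue, name=name)
    return pspm, sites, evalue


def write_sites_bed(sites, path) -> None:
    """BED-like site list: sequence id, 0-based half-open interval, strand."""
    lines = [f"{sid}\t{start}\t{end}\tsite\t0\t{strand}"
             for sid, start, end, strand in sites]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
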