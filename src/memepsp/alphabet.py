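"""Residue alphabets and integer sequence encoding.

Motif discovery treats sequences as arrays of small integer letter codes.
Ambiguous residues (``N`` for DNA, ``X`` for protein) are encoded as -1 and
are masked out of every likelihood computation downstream: a candidate site
window containing an ambiguous residue gets prior and likelihood zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Alphabet", "DNA", "PROTEIN", "SequenceSet"]


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with an optional complement mapping."""

    letters: str
    ambiguous: str = "N"
    complement: str | None = None

    @property
    def size(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        return self.letters.index(letter)

    def _table(self) -> np.ndarray:
        tbl = np.full(128, -2, dtype=np.int8)
        for i, c in enumerate(self.letters):
            tbl[ord(c)] = i
            tbl[ord(c.lower())] = i
        for c in self.ambiguous:
            tbl[ord(c)] = -1
            tbl[ord(c.lower())] = -1
        return tbl

    def encode(self, residues: str) -> np.ndarray:
        """Encode to int8 codes; ambiguous -> -1. Raises on a foreign letter."""
        raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
        codes = self._table()[raw]
        if (codes == -2).any():
            off = int(np.argmax(codes == -2))
            raise ValueError(
                f"residue {residues[off]!r} at offset {off + 1} is not in "
                f"alphabet {self.letters!r}"
            )
        return codes

    def decode(self, codes: np.ndarray) -> str:
        out = []
        for c in codes:
            out.append(self.ambiguous[0] if c < 0 else self.letters[int(c)])
        return "".join(out)

    @property
    def comp_codes(self) -> np.ndarray:
        if self.complement is None:
            raise ValueError("alphabet has no complement mapping")
        return np.array([self.letters.index(c) for c in self.complement],
                        dtype=np.int8)

    def revcomp(self, codes: np.ndarray) -> np.ndarray:
        """Reverse complement an encoded sequence (ambiguous stays -1)."""
        comp = self.comp_codes
        out = np.where(codes < 0, np.int8(-1), comp[np.clip(codes, 0, None)])
        return out[::-1].copy()

    def revcomp_str(self, residues: str) -> str:
        return self.decode(self.revcomp(self.encode(residues)))


DNA = Alphabet("ACGT", ambiguous="N", complement="TGCA")
PROTEIN = Alphabet("ACDEFGHIKLMNPQRSTVWY", ambiguous="X")


@dataclass
class SequenceSet:
    """An ordered, indexed collection of named sequences over one alphabet."""

    ids: list[str]
    residues: list[str]
    alphabet: Alphabet = DNA
    _encoded: list[np.ndarray] | None = field(default=None, repr=False,
                                              compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.residues):
            raise ValueError("ids and residues differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i in self.ids if self.ids.count(i) > 1][0]
            raise ValueError(f"duplicate sequence id {dup!r}")
        self.residues = [r.upper() for r in self.residues]

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.residues))

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.residues], dtype=np.int64)

    def encoded(self) -> list[np.ndarray]:
        """Integer-encoded sequences (validated against the alphabet, cached)."""
        if self._encoded is None:
            enc = []
            for sid, res in self:
                try:
                    enc.append(self.alphabet.encode(res))
                except ValueError as exc:
                    raise ValueError(f"record {sid!r}: {exc}") from None
            self._encoded = enc
        return self._encoded

    def index_of(self, sid: str) -> int:
        return self.ids.index(sid)

    @classmethod
    def from_strings(cls, residues: list[str], alphabet: Alphabet = DNA,
                     prefix: str = "seq") -> "SequenceSet":
        ids = [f"{prefix}{i + 1}" for i in range(len(residues))]
        return cls(ids=ids, residues=list(residues), alphabet=alphabet)
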