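"""Core alignment containers: alphabet, integer-encoded MSA, batch planning.

An MSA (multiple sequence alignment) is stored as an M x L integer matrix
over a q-symbol alphabet. The default alphabet is the 20 canonical amino
acids followed by the alignment gap ``-`` (so q = 21 and the gap has the
last index), which gives Potts parameter files a stable column order.
Tiny alphabets (q = 2..4) are supported so that exact-enumeration checks
remain feasible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical amino-acid order, gap last (index 20).
PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY-"

#: Characters silently mapped to the gap symbol unless strict mode is on.
_NON_CANONICAL = set("BZJXOU.*")


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set with a bijective symbol <-> index map.

    Parameters
    ----------
    symbols : str
        Ordered, duplicate-free characters. If ``-`` is present it is the
        gap; otherwise the last symbol plays the gap role (relevant only
        for toy alphabets used in exact enumeration tests).
    """

    symbols: str = PROTEIN_SYMBOLS
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.symbols)})

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return self._index.get("-", self.q - 1)

    @property
    def mask_index(self) -> int:
        """Reserved internal mask token; never a legal output symbol."""
        return self.q

    def encode(self, seq: str, strict: bool = False) -> np.ndarray:
        """Map a character sequence to symbol indices.

        Non-canonical residues (B, Z, X, '.', lowercase, ...) map to the
        gap with a warning; ``strict=True`` raises instead.
        """
        out = np.empty(len(seq), dtype=np.int16)
        bad = []
        for k, c in enumerate(seq):
            i = self._index.get(c)
            if i is None:
                cu = c.upper() if c.islower() else c
                i = self._index.get(cu)
                if i is None:
                    if cu in _NON_CANONICAL or c == "." or c.islower():
                        bad.append(c)
                        i = self.gap_index
                    else:
                        raise ValueError(f"unknown symbol {c!r} for alphabet {self.symbols!r}")
            out[k] = i
        if bad:
            if strict:
                raise ValueError(f"non-canonical symbols in strict mode: {sorted(set(bad))}")
            logger.warning("mapped %d non-canonical symbols to gap: %s", len(bad), sorted(set(bad)))
        return out

    def decode(self, indices: np.ndarray) -> str:
        return "".join(self.symbols[int(i)] for i in indices)


@dataclass
class Msa:
    """Integer-encoded alignment: M sequences (rows) x L sites (columns)."""

    ids: list[str]
    data: np.ndarray
    alphabet: Alphabet = field(default_factory=Alphabet)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("MSA data must be a non-empty 2D matrix")
        if len(self.ids) != self.data.shape[0]:
            raise ValueError("number of ids must match number of rows")
        # mask token (== q) is allowed transiently during generation
        if self.data.min() < 0 or self.data.max() > self.alphabet.q:
            raise ValueError("symbol indices out of range for alphabet")

    @property
    def depth(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def q(self) -> int:
        return self.alphabet.q

    def sequences(self) -> list[str]:
        return [self.alphabet.decode(row) for row in self.data]

    def subset(self, rows: np.ndarray) -> "Msa":
        rows = np.asarray(rows)
        return Msa([self.ids[i] for i in rows], self.data[rows].copy(), self.alphabet)

    def copy(self) -> "Msa":
        return Msa(list(self.ids), self.data.copy(), self.alphabet)

    @classmethod
    def from_sequences(
        cls, seqs: list[str], ids: list[str] | None = None,
        alphabet: Alphabet | None = None, strict: bool = False,
    ) -> "Msa":
        alphabet = alphabet or Alphabet()
        if not seqs:
            raise ValueError("empty sequence list")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        if ids is None:
            ids = [f"seq{k}" for k in range(len(seqs))]
        data = np.stack([alphabet.encode(s, strict=strict) for s in seqs])
        return cls(ids, data, alphabet)


def one_hot_encode(msa: Msa) -> np.ndarray:
    """One-hot encode an MSA as an M x (L*q) matrix.

    Block k (width q) encodes column k; each row sums to L exactly.
    """
    M, L = msa.data.shape
    q = msa.q
    if msa.data.max() >= q:
        raise ValueError("cannot one-hot encode an MSA containing mask tokens")
    out = np.zeros((M, L * q), dtype=np.float64)
    cols = np.arange(L) * q + msa.data
    out[np.arange(M)[:, None], cols] = 1.0
    return out


@dataclass
class BatchPlan:
    """Disjoint row-index batches covering an MSA, drawn without replacement."""

    batches: list[np.ndarray]
    batch_depth: int
    seed: int

    def __post_init__(self) -> None:
        sizes = [len(b) for b in self.batches]
        if any(s > self.batch_depth for s in sizes):
            raise ValueError("batch exceeds batch_depth")


def plan_batches(msa: Msa, batch_depth: int, seed: int) -> BatchPlan:
    """Partition MSA rows uniformly at random into batches of ``batch_depth``.

    The last batch may be smaller. Deterministic given ``seed``.
    """
    if batch_depth < 1:
        raise ValueError("batch_depth must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(msa.depth)
    batches = [perm[k:k + batch_depth] for k in range(0, msa.depth, batch_depth)]
    return BatchPlan(batches=batches, batch_depth=batch_depth, seed=seed)
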