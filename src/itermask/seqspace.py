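"""Sequence-space distribution analyses.

Distances are normalised Hamming distances (fraction of differing sites;
the gap is an ordinary symbol). The module locates, for each generated
sequence, its closest natural sequence — excluding itself when comparing
natural sequences with one another — counts neighbors within a radius
delta, projects one-hot encoded MSAs onto the principal components of the
natural MSA, transfers per-sequence scores (e.g. experimental relative
enrichments) from nearest natural neighbors, and computes additive scores
against single-mutation effect tables from deep mutational scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .msa import Alphabet, Msa, one_hot_encode
from .msastats import pairwise_hamming


def hamming(x: np.ndarray, y: np.ndarray, normalized: bool = True) -> float:
    """Hamming distance between two equal-length index vectors."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    diff = int((x != y).sum())
    return diff / len(x) if normalized else float(diff)


def closest_natural(query: Msa, natural: Msa,
                    exclude_self: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per query row, the (index, distance) of the nearest natural row.

    Exact brute-force search; ties go to the lowest natural index.
    ``exclude_self=True`` skips the same row index (for a natural MSA
    compared against itself, a sequence is never its own neighbor).
    """
    if natural.depth < 1:
        raise ValueError("natural MSA is empty")
    if query.length != natural.length:
        raise ValueError("MSAs must have equal length")
    if exclude_self and natural.depth == 1 and query.depth >= 1:
        raise ValueError("cannot exclude self with a single natural sequence")
    d = pairwise_hamming(query.data, natural.data)
    if exclude_self:
        n = min(query.depth, natural.depth)
        d[np.arange(n), np.arange(n)] = np.inf
    idx = np.argmin(d, axis=1)
    return idx, d[np.arange(query.depth), idx]


def neighbor_counts(msa: Msa, delta: float = 0.2) -> np.ndarray:
    """Number of rows within normalised Hamming distance delta (self included).

    The reciprocal of this count is exactly the sequence weight w_i used
    by the effective depth M_eff.
    """
    d = pairwise_hamming(msa.data)
    return (d < delta).sum(axis=1)


@dataclass
class PcaBasis:
    """Principal components of a one-hot encoded natural MSA."""

    mean: np.ndarray
    components: np.ndarray            # k x (L*q), orthonormal rows
    explained_variance: np.ndarray    # eigenvalues
    explained_variance_ratio: np.ndarray


def pca_fit(natural: Msa, k: int = 2) -> PcaBasis:
    """Fit the top-k principal components of the mean-centered one-hot MSA.

    If k exceeds the data rank, k is reduced with a warning-free clamp
    (the returned basis simply has fewer components).
    """
    if natural.depth < 2:
        raise ValueError("PCA requires at least 2 sequences")
    X = one_hot_encode(natural)
    k_eff = min(k, min(X.shape) - 1) or 1
    p = PCA(n_components=k_eff, svd_solver="full")
    p.fit(X)
    return PcaBasis(mean=p.mean_, components=p.components_,
                    explained_variance=p.explained_variance_,
                    explained_variance_ratio=p.explained_variance_ratio_)


def pca_project(msa: Msa, basis: PcaBasis) -> np.ndarray:
    """Project an MSA onto a fitted basis (subtracting the *natural* mean)."""
    X = one_hot_encode(msa) - basis.mean
    return X @ basis.components.T


def transfer_score_nn(generated: Msa, natural: Msa,
                      scores: np.ndarray) -> np.ndarray:
    """Per generated row, the score of its closest natural sequence."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (natural.depth,):
        raise ValueError("need exactly one score per natural sequence")
    idx, _ = closest_natural(generated, natural, exclude_self=False)
    return scores[idx]


@dataclass
class DmsTable:
    """Single-mutation effect table from a deep mutational scan.

    ``effects`` maps (0-based position, symbol index) -> measured effect;
    reference symbols carry an implicit effect of 0.
    """

    reference: np.ndarray
    effects: dict
    alphabet: Alphabet

    def __post_init__(self) -> None:
        L = len(self.reference)
        for (pos, sym) in self.effects:
            if not 0 <= pos < L:
                raise ValueError(f"effect position {pos} outside reference")
            if not 0 <= sym < self.alphabet.q:
                raise ValueError(f"effect symbol index {sym} outside alphabet")

    @classmethod
    def read_tsv(cls, path: str | Path, alphabet: Alphabet | None = None) -> "DmsTable":
        """Read a TSV with columns position (1-based), wt, mut, effect."""
        alphabet = alphabet or Alphabet()
        df = pd.read_csv(path, sep="\t")
        L = int(df["position"].max())
        ref = np.zeros(L, dtype=np.int16)
        for _, row in df.iterrows():
            ref[int(row["position"]) - 1] = alphabet.encode(str(row["wt"]))[0]
        effects = {(int(r["position"]) - 1, int(alphabet.encode(str(r["mut"]))[0])):
                   float(r["effect"]) for _, r in df.iterrows()}
        return cls(reference=ref, effects=effects, alphabet=alphabet)

    def write_tsv(self, path: str | Path) -> None:
        rows = [{"position": pos + 1,
                 "wt": self.alphabet.symbols[self.reference[pos]],
                 "mut": self.alphabet.symbols[sym], "effect": eff}
                for (pos, sym), eff in sorted(self.effects.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def dms_score(seq: np.ndarray, table: DmsTable) -> tuple[float, int]:
    """Additive mutational score of a sequence against a reference.

    Sums the tabulated effects of every position where ``seq`` differs
    from the reference. Mutations absent from the table (including gaps
    at differing positions) contribute 0 and are counted in
    ``n_missing``.
    """
    seq = np.asarray(seq)
    if seq.shape != table.reference.shape:
        raise ValueError("sequence length does not match DMS reference")
    score, n_missing = 0.0, 0
    for pos in np.nonzero(seq != table.reference)[0]:
        key = (int(pos), int(seq[pos]))
        if key in table.effects:
            score += table.effects[key]
        else:
            n_missing += 1
    return score, n_missing
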