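"""Alignment statistics at increasing order.

Plug-in (unsmoothed, no pseudocount) empirical frequencies f_i, f_ij,
f_ijk feed connected correlations

    C_ij(x,y)   = f_ij(x,y) - f_i(x) f_j(y)
    C_ijk(x,y,z)= f_ijk(x,y,z) - f_ij(x,y) f_k(z) - f_ik(x,z) f_j(y)
                  - f_jk(y,z) f_i(x) + 2 f_i(x) f_j(y) f_k(z)

and plug-in Shannon entropies (base 2, bits), mutual information
I_ij = H_i + H_j - H_ij and the co-information

    I_ijk = H_i + H_j + H_k - H_ij - H_ik - H_jk + H_ijk,

which vanishes for independent columns and is negative for synergy (the
parity triple scores exactly -1 bit). Plug-in entropies carry a
systematic finite-size bias; no correction is applied — comparisons should
be made between MSAs of equal length and depth so both sides carry the
same bias.

The r20 score compares two MSAs at orders 2..10: for each of ``n_sets``
random column subsets of a given size, the frequencies of the 20 most
frequent "words" (subsequences restricted to those columns) in the
reference MSA are correlated (Pearson) with the same words' frequencies in
the target MSA, and correlations are averaged over subsets.

The effective depth M_eff(delta) = sum_i w_i weighs each sequence by the
reciprocal of its number of neighbors within normalised Hamming distance
delta (self included), with delta = 0.2 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .msa import Msa

logger = logging.getLogger(__name__)


@dataclass
class FreqTables:
    """Plug-in frequency tables for requested sites, pairs and triplets."""

    f1: np.ndarray                      # L x q
    f2: dict = field(default_factory=dict)   # (i, j) -> q x q
    f3: dict = field(default_factory=dict)   # (i, j, k) -> q x q x q

    def pair(self, i: int, j: int) -> np.ndarray:
        if (i, j) in self.f2:
            return self.f2[(i, j)]
        if (j, i) in self.f2:
            return self.f2[(j, i)].T
        raise KeyError(f"pair {(i, j)} not in frequency tables")

    def triplet(self, i: int, j: int, k: int) -> np.ndarray:
        for perm in [(i, j, k), (i, k, j), (j, i, k), (j, k, i), (k, i, j), (k, j, i)]:
            if perm in self.f3:
                src = self.f3[perm]
                axes = [perm.index(s) for s in (i, j, k)]
                return np.transpose(src, axes)
        raise KeyError(f"triplet {(i, j, k)} not in frequency tables")


def frequencies(msa: Msa, pairs=None, triplets=None) -> FreqTables:
    """Empirical f_i for all sites plus f_ij / f_ijk for requested tuples.

    ``pairs="all"`` computes every i<j pair; likewise ``triplets="all"``
    (use with care: the number of triplets grows as L choose 3).
    """
    data, q, M, L = msa.data, msa.q, msa.depth, msa.length
    onehot = np.zeros((M, L, q))
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], data] = 1.0
    f1 = onehot.mean(axis=0)
    if pairs == "all":
        pairs = list(combinations(range(L), 2))
    if triplets == "all":
        triplets = list(combinations(range(L), 3))
    f2 = {}
    for (i, j) in (pairs or []):
        f2[(i, j)] = onehot[:, i, :].T @ onehot[:, j, :] / M
    f3 = {}
    for (i, j, k) in (triplets or []):
        f3[(i, j, k)] = np.einsum("ma,mb,mc->abc", onehot[:, i, :],
                                  onehot[:, j, :], onehot[:, k, :]) / M
    return FreqTables(f1=f1, f2=f2, f3=f3)


def connected_corr2(f: FreqTables, i: int, j: int) -> np.ndarray:
    """Second-order connected correlation C_ij(x,y)."""
    return f.pair(i, j) - np.outer(f.f1[i], f.f1[j])


def connected_corr3(f: FreqTables, i: int, j: int, k: int) -> np.ndarray:
    """Third-order connected correlation C_ijk(x,y,z)."""
    fij, fik, fjk = f.pair(i, j), f.pair(i, k), f.pair(j, k)
    fi, fj, fk = f.f1[i], f.f1[j], f.f1[k]
    return (f.triplet(i, j, k)
            - fij[:, :, None] * fk[None, None, :]
            - fik[:, None, :] * fj[None, :, None]
            - fjk[None, :, :] * fi[:, None, None]
            + 2.0 * fi[:, None, None] * fj[None, :, None] * fk[None, None, :])


def _entropy(p: np.ndarray) -> float:
    """Plug-in Shannon entropy in bits; 0 log 0 = 0."""
    p = np.asarray(p).ravel()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropies_and_information(f: FreqTables, i: int, j: int,
                              k: int | None = None) -> dict:
    """Plug-in entropies (bits), mutual information and co-information.

    Returns H_i, H_j, H_ij, I_ij, and with ``k`` also H_k, the remaining
    joint entropies, and the co-information I_ijk (negative = synergy).
    """
    out = {
        "H_i": _entropy(f.f1[i]), "H_j": _entropy(f.f1[j]),
        "H_ij": _entropy(f.pair(i, j)),
    }
    out["I_ij"] = out["H_i"] + out["H_j"] - out["H_ij"]
    if k is not None:
        out["H_k"] = _entropy(f.f1[k])
        out["H_ik"] = _entropy(f.pair(i, k))
        out["H_jk"] = _entropy(f.pair(j, k))
        out["H_ijk"] = _entropy(f.triplet(i, j, k))
        out["I_ijk"] = (out["H_i"] + out["H_j"] + out["H_k"]
                        - out["H_ij"] - out["H_ik"] - out["H_jk"] + out["H_ijk"])
    return out


@dataclass
class R20Curve:
    """Mean top-word frequency correlation per subsequence order."""

    orders: list[int]
    scores: list[float]
    n_sets: int
    top_k: int
    seed: int
    n_skipped: dict = field(default_factory=dict)


def _word_frequencies(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct words (rows) of a column-restricted MSA and their frequencies."""
    words, counts = np.unique(sub, axis=0, return_counts=True)
    return words, counts / sub.shape[0]


def r20_curve(target: Msa, reference: Msa, orders=range(2, 11),
              n_sets: int = 1000, top_k: int = 20, seed: int = 0,
              word_selection: str = "reference") -> R20Curve:
    """Statistical similarity of two MSAs at word orders 2..10.

    For each order s and each of ``n_sets`` uniformly drawn column subsets
    of size s, the ``top_k`` most frequent words are identified (in the
    reference MSA by default; ``word_selection="per_msa"`` ranks words in
    each MSA separately and correlates the union's frequencies). Ties at
    rank ``top_k`` break by lexicographic word order. The Pearson
    correlation between the words' frequencies in the two MSAs is averaged
    over subsets; degenerate subsets (fewer than 2 distinct reference
    words, or zero variance on either side) are skipped and logged.
    """
    if target.length != reference.length:
        raise ValueError("MSAs must have equal length")
    orders = list(orders)
    L = reference.length
    if L < max(orders):
        raise ValueError(f"L={L} smaller than maximum order {max(orders)}")
    if word_selection not in ("reference", "per_msa"):
        raise ValueError("word_selection must be 'reference' or 'per_msa'")
    rng = np.random.default_rng(seed)
    scores, n_skipped = [], {}
    for s in orders:
        vals, skipped = [], 0
        for _ in range(n_sets):
            cols = rng.choice(L, size=s, replace=False)
            ref_sub = reference.data[:, cols]
            tgt_sub = target.data[:, cols]
            ref_words, ref_freqs = _word_frequencies(ref_sub)
            if len(ref_words) < 2:
                skipped += 1
                continue
            tgt_words, tgt_freqs = _word_frequencies(tgt_sub)
            tgt_lookup = {w.tobytes(): f for w, f in zip(tgt_words, tgt_freqs)}
            if word_selection == "reference":
                top = _top_k_indices(ref_words, ref_freqs, top_k)
                x = ref_freqs[top]
                y = np.array([tgt_lookup.get(ref_words[t].tobytes(), 0.0) for t in top])
            else:
                ref_lookup = {w.tobytes(): f for w, f in zip(ref_words, ref_freqs)}
                top_ref = {ref_words[t].tobytes() for t in
                           _top_k_indices(ref_words, ref_freqs, top_k)}
                top_tgt = {tgt_words[t].tobytes() for t in
                           _top_k_indices(tgt_words, tgt_freqs, top_k)}
                keys = sorted(top_ref | top_tgt)
                x = np.array([ref_lookup.get(kk, 0.0) for kk in keys])
                y = np.array([tgt_lookup.get(kk, 0.0) for kk in keys])
            if x.std() == 0 or y.std() == 0:
                skipped += 1
                continue
            vals.append(float(np.corrcoef(x, y)[0, 1]))
        if skipped:
            logger.info("r20 order %d: skipped %d degenerate subsets", s, skipped)
        n_skipped[s] = skipped
        scores.append(float(np.mean(vals)) if vals else float("nan"))
    return R20Curve(orders=orders, scores=scores, n_sets=n_sets, top_k=top_k,
                    seed=seed, n_skipped=n_skipped)


def _top_k_indices(words: np.ndarray, freqs: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most frequent words; rank ties break lexicographically.

    np.unique returns words already in lexicographic order, so a stable
    sort on descending frequency realises the tie-break.
    """
    order = np.argsort(-freqs, kind="stable")
    return order[:k]


@dataclass
class WeightVector:
    """Reciprocal-neighbor sequence weights and the effective depth M_eff."""

    weights: np.ndarray
    delta: float
    m_eff: float


def pairwise_hamming(a: np.ndarray, b: np.ndarray | None = None,
                     chunk: int = 512) -> np.ndarray:
    """Normalised Hamming distances between rows of a (and b), chunked."""
    b = a if b is None else b
    L = a.shape[1]
    out = np.empty((a.shape[0], b.shape[0]))
    for lo in range(0, a.shape[0], chunk):
        hi = min(lo + chunk, a.shape[0])
        out[lo:hi] = (a[lo:hi, None, :] != b[None, :, :]).mean(axis=2)
    return out


def sequence_weights(msa: Msa, delta: float = 0.2) -> WeightVector:
    """w_i = 1 / |{i' : d_H(x(i), x(i')) < delta}| and M_eff = sum_i w_i.

    The neighbor count includes the sequence itself (distance 0 < delta),
    so 1 <= M_eff <= M always.
    """
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    d = pairwise_hamming(msa.data)
    counts = (d < delta).sum(axis=1)
    w = 1.0 / counts
    return WeightVector(weights=w, delta=delta, m_eff=float(w.sum()))


def effective_depth(msa: Msa, delta: float = 0.2) -> float:
    return sequence_weights(msa, delta).m_eff
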