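"""Synthetic data generators used as test fixtures and demo inputs.

Everything here is deterministic given an integer seed and deliberately
minimal: profile MSAs have statistically independent columns, random
Potts models have sparse Gaussian couplings, and tree evolution uses the
simplest symmetric substitution process (Poisson-many events per site
along each branch, each drawing a uniformly random symbol). The goal is
controllable statistical structure — column conservation, pairwise
couplings, phylogenetic correlation — not biological realism.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from .msa import Alphabet, Msa
from .potts import PottsModel
from .seqspace import DmsTable


def _toy_alphabet(q: int) -> Alphabet:
    if q == 21:
        return Alphabet()
    if q == 2:
        return Alphabet("A-")
    return Alphabet("ACDEFGHIKLMNPQRSTVWY"[:q - 1] + "-")


def random_profile_msa(L: int, M: int, concentration: float = 1.0,
                       seed: int = 0, alphabet: Alphabet | None = None
                       ) -> tuple[np.ndarray, Msa]:
    """Independent-column MSA from Dirichlet-drawn per-column profiles.

    Column probability vectors are drawn from a symmetric
    Dirichlet(concentration); small concentrations give conserved
    columns, large ones near-uniform columns. Rows are sampled
    independently per column, so all connected correlations vanish at the
    distribution level.
    """
    if L < 1 or M < 1:
        raise ValueError("L and M must be >= 1")
    alphabet = alphabet or Alphabet()
    q = alphabet.q
    rng = np.random.default_rng(seed)
    profile = rng.dirichlet([concentration] * q, size=L)
    u = rng.random((M, L))
    data = (profile.cumsum(axis=1)[None, :, :] < u[:, :, None]).sum(axis=2)
    ids = [f"profile{k}" for k in range(M)]
    return profile, Msa(ids, data.astype(np.int16), alphabet)


def sample_from_profile(profile: np.ndarray, M: int, seed: int = 0,
                        alphabet: Alphabet | None = None) -> Msa:
    """Draw M independent rows from an L x q column-profile matrix."""
    alphabet = alphabet or _toy_alphabet(profile.shape[1])
    rng = np.random.default_rng(seed)
    u = rng.random((M, profile.shape[0]))
    data = (profile.cumsum(axis=1)[None, :, :] < u[:, :, None]).sum(axis=2)
    ids = [f"profile{k}" for k in range(M)]
    return Msa(ids, data.astype(np.int16), alphabet)


def random_potts_model(L: int, q: int, coupling_density: float = 0.5,
                       coupling_scale: float = 0.5, field_scale: float = 0.5,
                       seed: int = 0) -> PottsModel:
    """Random Potts model: Gaussian fields, sparse Gaussian couplings.

    Each site pair receives a coupling block with probability
    ``coupling_density``; entries are N(0, coupling_scale^2). Scale 0
    gives the zero model; density 0 gives an independent-site model whose
    Boltzmann distribution factorises over sites.
    """
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, field_scale, size=(L, q)) if field_scale > 0 else np.zeros((L, q))
    pairs = {}
    for i in range(L):
        for j in range(i + 1, L):
            if coupling_density > 0 and rng.random() < coupling_density:
                mat = (rng.normal(0.0, coupling_scale, size=(q, q))
                       if coupling_scale > 0 else np.zeros((q, q)))
                pairs[(i, j)] = mat
    return PottsModel(L, q, h, pairs)


def star_tree(n_leaves: int, branch: float = 0.1) -> TreeNode:
    """Star topology: every leaf hangs directly off the root."""
    newick = "(" + ",".join(f"t{k}:{branch}" for k in range(n_leaves)) + ");"
    return TreeNode.read([newick])


def two_clade_tree(n_per_clade: int, within: float = 0.02,
                   between: float = 0.5) -> TreeNode:
    """Two clades separated by long stems, shallow within — a "stemmy" shape."""
    a = "(" + ",".join(f"a{k}:{within}" for k in range(n_per_clade)) + f"):{between}"
    b = "(" + ",".join(f"b{k}:{within}" for k in range(n_per_clade)) + f"):{between}"
    return TreeNode.read([f"({a},{b});"])


def evolve_on_tree(tree: TreeNode, root_seq: np.ndarray, rate: float,
                   seed: int = 0, alphabet: Alphabet | None = None) -> Msa:
    """Evolve a root sequence down a tree; returns leaf sequences.

    Along each branch of length t, every site receives Poisson(rate * t)
    substitution events, each replacing the symbol by a uniformly random
    one. Leaves are returned sorted by label.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    root_seq = np.asarray(root_seq, dtype=np.int16)
    alphabet = alphabet or _toy_alphabet(int(root_seq.max()) + 2)
    q = alphabet.q
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {id(tree): root_seq.copy()}
    leaves: list[tuple[str, np.ndarray]] = []
    for node in tree.preorder(include_self=True):
        if node.parent is not None:
            seq = seqs[id(node.parent)].copy()
            t = float(node.length or 0.0)
            n_events = rng.poisson(rate * t, size=len(seq))
            hit = n_events > 0
            # only the last event matters: uniform symbol
            seq[hit] = rng.integers(0, q, size=int(hit.sum()))
            seqs[id(node)] = seq
        if node.is_tip():
            leaves.append((str(node.name), seqs[id(node)]))
    leaves.sort(key=lambda kv: kv[0])
    ids = [name for name, _ in leaves]
    data = np.stack([s for _, s in leaves])
    return Msa(ids, data, alphabet)


def toy_dms_table(reference: np.ndarray, seed: int = 0,
                  coverage: float = 0.6, effect_scale: float = 1.0,
                  alphabet: Alphabet | None = None) -> DmsTable:
    """Random single-mutation effect table over a reference sequence.

    A fraction ``coverage`` of the (position, non-reference symbol) pairs
    receives a Gaussian effect; the rest are left unmeasured. Reference
    symbols carry an implicit effect of 0.
    """
    reference = np.asarray(reference, dtype=np.int16)
    alphabet = alphabet or _toy_alphabet(int(reference.max()) + 2)
    rng = np.random.default_rng(seed)
    effects = {}
    for pos in range(len(reference)):
        for sym in range(alphabet.q):
            if sym != reference[pos] and rng.random() < coverage:
                effects[(pos, sym)] = float(rng.normal(0.0, effect_scale))
    return DmsTable(reference=reference, effects=effects, alphabet=alphabet)
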