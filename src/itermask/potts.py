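"""Potts models over aligned sequences: scoring, sampling, fitting, oracle.

A Potts model assigns to a sequence x = (x_1, ..., x_L), x_i in {0..q-1},
the Hamiltonian

    H(x) = - sum_i h_i(x_i) - sum_{i<j} e_ij(x_i, x_j)

and the Boltzmann distribution P(x) = exp(-H(x)/T) / Z, with sampling
temperature T defaulting to 1. The statistical energy score of a sequence
is -H(x): higher means more family-like under the model. Probabilities are
gauge invariant — adding a constant to all h_i(.) at a fixed site leaves
P unchanged — so parameters are only comparable after fixing a gauge
(the fitter reports in the zero-sum gauge).

The module provides exact enumeration for tiny state spaces (the test
oracle), a vectorised single-site Metropolis–Hastings sampler, a
moment-matching Boltzmann-machine fitter with L2 regularisation, and an
exact-conditional masked-sequence model that lets the iterative masking
procedure run against a known ground-truth distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa import Alphabet, Msa

logger = logging.getLogger(__name__)

_ENUM_GUARD = 10 ** 6


@dataclass
class PottsModel:
    """Fields h (L x q) and pair couplings e_ij (q x q per unordered pair).

    Couplings are provided once per pair i < j; internally a dense
    symmetric tensor with e[j, i] = e[i, j].T and zero diagonal blocks is
    kept so that energies and conditionals vectorise.
    """

    L: int
    q: int
    h: np.ndarray
    couplings: dict = field(default_factory=dict)
    _e: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.h.shape != (self.L, self.q):
            raise ValueError(f"fields must have shape {(self.L, self.q)}")
        e = np.zeros((self.L, self.L, self.q, self.q))
        for (i, j), mat in self.couplings.items():
            if not 0 <= i < j < self.L:
                raise ValueError(f"coupling pair {(i, j)} must satisfy 0 <= i < j < L")
            mat = np.asarray(mat, dtype=np.float64)
            if mat.shape != (self.q, self.q):
                raise ValueError(f"coupling {(i, j)} must be {(self.q, self.q)}")
            e[i, j] = mat
            e[j, i] = mat.T
        if not np.all(np.isfinite(self.h)) or not np.all(np.isfinite(e)):
            raise ValueError("Potts parameters must be finite")
        self._e = e

    def coupling(self, i: int, j: int) -> np.ndarray:
        """e_ij as a q x q matrix for any i != j (e_ji(b,a) = e_ij(a,b))."""
        return self._e[i, j]

    @property
    def dense_couplings(self) -> np.ndarray:
        return self._e

    def to_zero_sum_gauge(self) -> "PottsModel":
        """Re-express parameters in the zero-sum gauge (same distribution)."""
        e = self._e
        h = self.h.copy()
        new_pairs = {}
        for (i, j) in self.couplings:
            m = e[i, j]
            row = m.mean(axis=1, keepdims=True)
            col = m.mean(axis=0, keepdims=True)
            tot = m.mean()
            new_pairs[(i, j)] = m - row - col + tot
            h[i] += (row[:, 0] - tot)
            h[j] += (col[0, :] - tot)
        h -= h.mean(axis=1, keepdims=True)
        return PottsModel(self.L, self.q, h, new_pairs)

    # --- serialisation (no standard format exists; documented JSON schema) ---

    def to_json(self, path: str | Path, alphabet: Alphabet | None = None) -> None:
        alphabet = alphabet or _toy_alphabet(self.q)
        pairs = [{"i": int(i), "j": int(j), "e": self._e[i, j].tolist()}
                 for (i, j) in sorted(self.couplings)]
        doc = {"L": self.L, "q": self.q, "alphabet": alphabet.symbols,
               "h": self.h.tolist(), "couplings": pairs}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "PottsModel":
        return cls.load(path)[0]

    @classmethod
    def load(cls, path: str | Path) -> tuple["PottsModel", Alphabet]:
        """Read a model file; returns the model and its alphabet."""
        doc = json.loads(Path(path).read_text())
        pairs = {(p["i"], p["j"]): np.array(p["e"]) for p in doc["couplings"]}
        model = cls(doc["L"], doc["q"], np.array(doc["h"]), pairs)
        alphabet = (Alphabet(doc["alphabet"]) if doc.get("alphabet")
                    else _toy_alphabet(doc["q"]))
        return model, alphabet


@dataclass(frozen=True)
class SamplingConfig:
    """Metropolis–Hastings settings: N steps per chain at temperature T."""

    n_steps: int
    temperature: float = 1.0
    n_chains: int = 1
    init: str = "random"  # or "from_msa"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")


def default_n_steps(model: PottsModel) -> int:
    """Heuristic chain length when none is given: 10 * L * q steps."""
    return 10 * model.L * model.q


def hamiltonian(model: PottsModel, seq: np.ndarray) -> float:
    """H(x) = -sum_i h_i(x_i) - sum_{i<j} e_ij(x_i, x_j)."""
    return float(hamiltonians(model, np.asarray(seq)[None, :])[0])


def hamiltonians(model: PottsModel, data: np.ndarray) -> np.ndarray:
    """Vectorised Hamiltonian for an M x L matrix of sequences."""
    data = np.asarray(data)
    if data.ndim != 2 or data.shape[1] != model.L:
        raise ValueError(f"sequences must have length L={model.L}")
    if data.min() < 0 or data.max() >= model.q:
        raise ValueError("symbol indices out of range")
    M, L = data.shape
    rows = np.arange(L)
    field_term = model.h[rows, data].sum(axis=1)
    coupling_term = np.zeros(M)
    for (i, j) in model.couplings:
        coupling_term += model._e[i, j][data[:, i], data[:, j]]
    return -(field_term + coupling_term)


def statistical_energy_score(model: PottsModel, seq: np.ndarray) -> float:
    """-H(x): higher is better (more probable at T=1)."""
    return -hamiltonian(model, seq)


def statistical_energy_scores(model: PottsModel, msa: Msa | np.ndarray) -> np.ndarray:
    data = msa.data if isinstance(msa, Msa) else np.asarray(msa)
    return -hamiltonians(model, data)


def enumerate_states(L: int, q: int) -> np.ndarray:
    """All q**L sequences in lexicographic order, as a (q**L, L) matrix."""
    if q ** L > _ENUM_GUARD:
        raise ValueError(f"state space q**L = {q ** L} exceeds enumeration guard")
    grids = np.meshgrid(*[np.arange(q)] * L, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def exact_distribution(model: PottsModel, temperature: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Exact Boltzmann probabilities over all q**L states.

    Returns (states, probs) with states in lexicographic order. The
    normaliser Z is computed by full enumeration; guarded to q**L <= 1e6.
    """
    states = enumerate_states(model.L, model.q)
    energies = hamiltonians(model, states)
    logw = -energies / temperature
    logw -= logw.max()
    w = np.exp(logw)
    return states, w / w.sum()


def conditional_distribution(model: PottsModel, seq: np.ndarray, site: int,
                             temperature: float = 1.0) -> np.ndarray:
    """Exact single-site conditional p(x_site = a | rest of seq).

    p(a) is proportional to exp((h_site(a) + sum_{j != site} e_site,j(a, x_j)) / T).
    """
    seq = np.asarray(seq)
    if not 0 <= site < model.L:
        raise IndexError(f"site {site} out of range for L={model.L}")
    local = model.h[site] + model._e[site, :, :, :][np.arange(model.L) != site,
                                                    :, seq[np.arange(model.L) != site]].sum(axis=0)
    z = local / temperature
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def metropolis_sample(model: PottsModel, config: SamplingConfig,
                      init_msa: Msa | None = None,
                      alphabet: Alphabet | None = None,
                      trace: dict | None = None) -> Msa:
    """Single-site Metropolis–Hastings sampling, vectorised over chains.

    Each step proposes, independently per chain, a uniformly random site
    and a uniformly random different symbol, and accepts with probability
    min(1, exp(-dH / T)). Chains are independent; the run is deterministic
    given the seed. If ``trace`` is a dict, per-step arrays ``dH`` and
    ``accepted`` for chain 0 are stored in it.
    """
    rng = np.random.default_rng(config.seed)
    L, q = model.L, model.q
    n = config.n_chains
    if config.init == "from_msa":
        if init_msa is None:
            raise ValueError("init='from_msa' requires init_msa")
        idx = rng.choice(init_msa.depth, size=n, replace=init_msa.depth < n)
        X = init_msa.data[idx].astype(np.int64)
    else:
        X = rng.integers(0, q, size=(n, L))
    e = model._e
    chains = np.arange(n)
    if trace is not None:
        trace["dH"], trace["accepted"] = [], []
    for _ in range(config.n_steps):
        sites = rng.integers(0, L, size=n)
        old = X[chains, sites]
        # uniform over the q-1 other symbols
        prop = rng.integers(0, q - 1, size=n)
        prop += (prop >= old)
        # dH = -(h_new - h_old) - sum_j (e[s,j,new,x_j] - e[s,j,old,x_j])
        dh_field = model.h[sites, prop] - model.h[sites, old]
        cur = e[sites, :, prop, :][np.arange(n)[:, None], np.arange(L)[None, :], X] \
            - e[sites, :, old, :][np.arange(n)[:, None], np.arange(L)[None, :], X]
        dH = -(dh_field + cur.sum(axis=1))
        accept = rng.random(n) < np.exp(np.minimum(0.0, -dH / config.temperature))
        X[chains[accept], sites[accept]] = prop[accept]
        if trace is not None:
            trace["dH"].append(dH[0])
            trace["accepted"].append(bool(accept[0]))
    alphabet = alphabet or (init_msa.alphabet if init_msa is not None else _toy_alphabet(q))
    ids = [f"chain{k}" for k in range(n)]
    return Msa(ids, X.astype(np.int16), alphabet)


def _toy_alphabet(q: int) -> Alphabet:
    if q == 21:
        return Alphabet()
    return Alphabet("ACDEFGHIKLMNPQRSTVWY-"[:q - 1] + "-") if q > 2 else Alphabet("A-")


class PottsOracleModel:
    """Exact-conditional masked-sequence model backed by a Potts model.

    At each masked cell (m, i) the emitted logits are the log of the exact
    single-site conditional of the Potts model given row m's unmasked
    context; masked cells within a row are treated as independent given
    that context (the masked-language-model pseudolikelihood structure).
    Other masked context symbols are handled per ``masked_context``:
    ``"gap"`` (default) treats them as the gap symbol, ``"drop"`` removes
    their coupling terms entirely. The true joint conditional over a mask
    is exponential in the mask size, so neither policy is exact for
    simultaneous masks — at low mask density they agree closely.
    """

    def __init__(self, model: PottsModel, masked_context: str = "gap"):
        if masked_context not in ("gap", "drop"):
            raise ValueError("masked_context must be 'gap' or 'drop'")
        self.model = model
        self.masked_context = masked_context
        L, q = model.L, model.q
        # flat coupling matrix: (L*q, L*q); row block i, col block j = e_ij
        self._flat_e = model._e.transpose(0, 2, 1, 3).reshape(L * q, L * q)

    def __call__(self, masked: Msa) -> np.ndarray:
        model = self.model
        L, q = model.L, model.q
        if masked.length != L or masked.q != q:
            raise ValueError("MSA shape/alphabet does not match the Potts model")
        data = masked.data
        is_masked = data == masked.alphabet.mask_index
        ctx = np.where(is_masked, masked.alphabet.gap_index, data)
        onehot = np.zeros((masked.depth, L * q))
        cols = np.arange(L) * q + ctx
        onehot[np.arange(masked.depth)[:, None], cols] = 1.0
        logits = (onehot @ self._flat_e.T).reshape(masked.depth, L, q) + model.h[None]
        if self.masked_context == "drop":
            mask_flat = np.repeat(is_masked, q, axis=1)
            oh_masked = np.where(mask_flat, onehot, 0.0)
            logits -= (oh_masked @ self._flat_e.T).reshape(masked.depth, L, q)
        return logits


def potts_oracle_mlm(model: PottsModel, masked_context: str = "gap") -> PottsOracleModel:
    """Build the exact-conditional oracle as a pluggable masked-sequence model."""
    return PottsOracleModel(model, masked_context=masked_context)


# ---------------------------------------------------------------------------
# Boltzmann-machine fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Moment-matching fit settings.

    regularization : L2 penalty strength lambda on all parameters
        (default 1e-2, the usual scale for this class of fits).
    learning_rate : gradient step size.
    max_sweeps : gradient iterations before giving up.
    n_chains / steps_per_sweep : persistent MCMC chains used to estimate
        model moments, and Metropolis steps run between gradient updates.
    tolerance : max absolute one-/two-body moment error at which the fit
        is declared converged.
    exact_moments : compute model moments by exact enumeration instead of
        MCMC. Default (None) enumerates automatically when q**L <= 2048,
        which removes the Monte-Carlo noise floor on desk-scale models;
        set False to force the sampling estimator.
    """

    regularization: float = 1e-2
    learning_rate: float = 0.05
    max_sweeps: int = 500
    n_chains: int = 1000
    steps_per_sweep: int | None = None
    tolerance: float = 5e-3
    exact_moments: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")


@dataclass
class BoltzmannFit:
    """Result of :func:`fit_boltzmann_machine`.

    model : the fitted Potts parameters, reported in the zero-sum gauge.
    history : max absolute moment error per sweep.
    converged : whether the tolerance was reached within max_sweeps.
    """

    model: PottsModel
    history: list[float]
    converged: bool

    @property
    def final_error(self) -> float:
        return self.history[-1] if self.history else float("nan")


def empirical_moments(data: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """One- and two-body symbol frequencies f_i(a), f_ij(a,b) of a matrix."""
    M, L = data.shape
    onehot = np.zeros((M, L, q))
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], data] = 1.0
    f1 = onehot.mean(axis=0)
    flat = onehot.reshape(M, L * q)
    f2 = (flat.T @ flat / M).reshape(L, q, L, q).transpose(0, 2, 1, 3)
    return f1, f2


def fit_boltzmann_machine(msa: Msa, config: FitConfig = FitConfig()) -> BoltzmannFit:
    """Fit a Potts model by persistent-chain moment matching.

    Iteratively nudges (h, e) along the difference between the data's
    one-/two-body frequencies and the model's — estimated from persistent
    Metropolis–Hastings chains, or by exact enumeration on tiny state
    spaces (see :class:`FitConfig.exact_moments`) — with an L2 penalty
    ``lambda`` on every parameter. This is a minimal Boltzmann machine in the spirit of the
    standard direct-coupling inference tools, not a port of any of them;
    parity with their exact training schedules is out of scope.

    Returns the fit in the zero-sum gauge with the per-sweep maximum
    moment error as the convergence diagnostic. Non-convergence returns
    the best parameters seen, flagged via ``converged=False``.
    """
    if msa.depth < 2:
        raise ValueError("need at least 2 sequences to fit")
    L, q = msa.length, msa.q
    lam = config.regularization
    f1_data, f2_data = empirical_moments(msa.data, q)
    rng = np.random.default_rng(config.seed)
    h = np.zeros((L, q))
    e = np.zeros((L, L, q, q))
    steps = config.steps_per_sweep or max(10, 2 * L * q)
    exact = (q ** L <= 2048 if config.exact_moments is None
             else config.exact_moments)
    states = enumerate_states(L, q) if exact else None
    X = rng.integers(0, q, size=(config.n_chains, L))
    pair_list = [(i, j) for i in range(L) for j in range(i + 1, L)]
    history: list[float] = []
    best_err, best_params = np.inf, (h.copy(), e.copy())
    offdiag = ~np.eye(L, dtype=bool)
    converged = False
    for _ in range(config.max_sweeps):
        if exact:
            f1_model, f2_model = _exact_moments(h, e, states, q)
        else:
            X = _mh_steps(h, e, X, steps, rng)
            f1_model, f2_model = empirical_moments(X, q)
        g1 = f1_data - f1_model
        g2 = f2_data - f2_model
        err = float(np.abs(g1).max())
        if L > 1:
            err = max(err, float(np.abs(g2[offdiag]).max()))
        history.append(float(err))
        if err < best_err:
            best_err, best_params = err, (h.copy(), e.copy())
        if err < config.tolerance:
            converged = True
            break
        h += config.learning_rate * (g1 - 2 * lam * h)
        de = config.learning_rate * (g2 - 2 * lam * e)
        de[np.eye(L, dtype=bool)] = 0.0
        e += (de + de.transpose(1, 0, 3, 2)) / 2.0
    if not converged:
        logger.warning("Boltzmann-machine fit did not reach tolerance %.2g "
                       "(best moment error %.3g); returning best-so-far",
                       config.tolerance, best_err)
        h, e = best_params
    model = PottsModel(L, q, h, {(i, j): e[i, j] for (i, j) in pair_list})
    return BoltzmannFit(model=model.to_zero_sum_gauge(), history=history,
                        converged=converged)


def _exact_moments(h: np.ndarray, e: np.ndarray, states: np.ndarray,
                   q: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact model moments by enumeration of all states of raw (h, e)."""
    L = h.shape[0]
    rows = np.arange(L)
    energy = -h[rows, states].sum(axis=1)
    for i in range(L):
        for j in range(i + 1, L):
            energy -= e[i, j][states[:, i], states[:, j]]
    logw = -energy - (-energy).max()
    w = np.exp(logw)
    p = w / w.sum()
    n = states.shape[0]
    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], rows[None, :], states] = 1.0
    f1 = np.einsum("s,sia->ia", p, onehot)
    flat = onehot.reshape(n, L * q)
    f2 = ((flat * p[:, None]).T @ flat).reshape(L, q, L, q).transpose(0, 2, 1, 3)
    return f1, f2


def _mh_steps(h: np.ndarray, e: np.ndarray, X: np.ndarray, n_steps: int,
              rng: np.random.Generator) -> np.ndarray:
    """In-place Metropolis steps on chain matrix X for raw (h, e) arrays."""
    n, L = X.shape
    q = h.shape[1]
    chains = np.arange(n)
    cols = np.arange(L)[None, :]
    rows = np.arange(n)[:, None]
    for _ in range(n_steps):
        sites = rng.integers(0, L, size=n)
        old = X[chains, sites]
        prop = rng.integers(0, q - 1, size=n)
        prop += (prop >= old)
        dh_field = h[sites, prop] - h[sites, old]
        cur = e[sites, :, prop, :][rows, cols, X] - e[sites, :, old, :][rows, cols, X]
        dH = -(dh_field + cur.sum(axis=1))
        accept = rng.random(n) < np.exp(np.minimum(0.0, -dH))
        X[chains[accept], sites[accept]] = prop[accept]
    return X
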