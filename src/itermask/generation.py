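"""Iterative masking generation of synthetic alignments.

The procedure repeatedly (i) masks each eligible cell of an input MSA
independently with probability ``p`` and (ii) asks a masked-sequence model
for per-cell symbol logits and writes back a symbol at every masked cell —
greedily (argmax) by default, or by sampling softmax(logits / T). With the
defaults p = 0.1 and I = 200 iterations, each cell is masked p*I = 20 times
on average over a run. Columns are never inserted or deleted, so the output
stays aligned with the input.

Masked cells within one iteration are filled simultaneously and
independently from a single model evaluation, mirroring the
masked-language-model pseudolikelihood structure that ignores dependencies
between masked entries.

Two restricted variants mask only the first row, treating the remaining
rows as context — either fixed, or resampled from a pool at each iteration.
Fewer iterations are needed there (I = 20 suffices in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .msa import Msa, plan_batches

SCOPES = ("whole_msa", "first_row_fixed_context", "first_row_variable_context")


@runtime_checkable
class MaskedSequenceModel(Protocol):
    """Contract: masked MSA in, per-cell symbol logits out.

    The callable receives an :class:`Msa` whose masked cells carry the
    reserved mask token (index q) and must return a finite float array of
    shape (M, L, q). Values at unmasked cells are unused.
    """

    def __call__(self, masked: Msa) -> np.ndarray: ...


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the iterative masking procedure.

    p : masking probability per cell per iteration (default 0.1).
    iterations : number of mask/fill rounds I (default 200 for whole-MSA
        scope; 20 is typically enough for first-row scopes).
    batch_depth : rows per model call when splitting a deep MSA (default 600).
    selection : "greedy" (argmax, ties to lowest index) or "softmax"
        (sample from softmax(logits / temperature)).
    temperature : softmax selection temperature T > 0; greedy is the T -> 0
        limit.
    scope : which cells are eligible for masking.
    """

    p: float = 0.1
    iterations: int = 200
    batch_depth: int = 600
    selection: str = "greedy"
    temperature: float = 1.0
    scope: str = "whole_msa"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("masking probability p must be in [0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.selection not in ("greedy", "softmax"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if self.selection == "softmax" and not self.temperature > 0:
            raise ValueError("softmax selection requires temperature > 0")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")


def mask_msa(msa: Msa, p: float, rng: np.random.Generator | int,
             scope: str = "whole_msa") -> tuple[Msa, np.ndarray]:
    """Mask each eligible cell independently with probability ``p``.

    Returns the masked copy (masked cells carry the mask token, index q)
    and the boolean M x L mask matrix.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("masking probability p must be in [0, 1]")
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mask = np.zeros(msa.data.shape, dtype=bool)
    if scope == "whole_msa":
        mask[:] = rng.random(msa.data.shape) < p
    else:
        mask[0] = rng.random(msa.length) < p
    masked = msa.copy()
    masked.data[mask] = msa.alphabet.mask_index
    return masked, mask


def fill_masked(masked: Msa, mask: np.ndarray, logits: np.ndarray,
                selection: str = "greedy", temperature: float = 1.0,
                rng: np.random.Generator | int = 0) -> Msa:
    """Write a symbol into every masked cell from the model's logits.

    Greedy mode picks the argmax symbol (ties broken toward the lowest
    index); softmax mode samples from softmax(logits / temperature).
    Unmasked cells are untouched and the mask token never survives.
    """
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape != (*masked.data.shape, masked.q):
        raise ValueError(f"logits shape {logits.shape} does not match MSA "
                         f"shape {(*masked.data.shape, masked.q)}")
    cell_logits = logits[mask]
    if not np.all(np.isfinite(cell_logits)):
        raise ValueError("non-finite logits at masked cells violate the model contract")
    if selection == "greedy":
        filled = np.argmax(cell_logits, axis=-1)
    elif selection == "softmax":
        rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
        z = cell_logits / temperature
        z -= z.max(axis=-1, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(axis=-1, keepdims=True)
        u = rng.random(probs.shape[0])
        filled = (probs.cumsum(axis=-1) < u[:, None]).sum(axis=-1)
    else:
        raise ValueError(f"unknown selection mode {selection!r}")
    out = masked.copy()
    out.data[mask] = filled
    return out


def iterative_masking(msa: Msa, model: MaskedSequenceModel,
                      config: GenerationConfig,
                      context_pool: Msa | None = None,
                      mask_counts: np.ndarray | None = None) -> Msa:
    """Run ``config.iterations`` mask/fill rounds on a single batch.

    For ``first_row_variable_context`` scope, rows 1..M-1 are resampled
    from ``context_pool`` at each iteration. If ``mask_counts`` (an M x L
    integer array) is given, it accumulates how often each cell was masked.
    ``visit`` hooks are not provided; callers wanting the trajectory can
    run one iteration at a time with ``iterations=1`` and chained seeds.
    """
    if config.scope == "first_row_variable_context" and context_pool is None:
        raise ValueError("variable-context scope requires a context_pool")
    rng = np.random.default_rng(config.seed)
    current = msa.copy()
    for _ in range(config.iterations):
        if config.scope == "first_row_variable_context":
            idx = rng.choice(context_pool.depth, size=current.depth - 1,
                             replace=context_pool.depth < current.depth - 1)
            current.data[1:] = context_pool.data[idx]
        masked, mask = mask_msa(current, config.p, rng, scope=config.scope)
        if mask_counts is not None:
            mask_counts += mask
        logits = np.asarray(model(masked), dtype=np.float64)
        if logits.shape != (*masked.data.shape, masked.q):
            raise ValueError("model returned logits of wrong shape "
                             f"{logits.shape}, expected {(*masked.data.shape, masked.q)}")
        current = fill_masked(masked, mask, logits, selection=config.selection,
                              temperature=config.temperature, rng=rng)
    return current


def generate_synthetic_msa(natural: Msa, model: MaskedSequenceModel,
                           config: GenerationConfig,
                           mask_counts: np.ndarray | None = None) -> Msa:
    """Generate a synthetic MSA with the same depth as ``natural``.

    The natural MSA is partitioned uniformly at random into batches of at
    most ``config.batch_depth`` rows; each batch is run through the
    iterative masking procedure independently and the outputs are
    concatenated in plan order.
    """
    plan = plan_batches(natural, config.batch_depth, config.seed)
    pieces = []
    for k, rows in enumerate(plan.batches):
        batch = natural.subset(rows)
        sub_counts = None
        if mask_counts is not None:
            sub_counts = np.zeros(batch.data.shape, dtype=np.int64)
        out = iterative_masking(
            batch, model, replace(config, seed=config.seed + 1 + k),
            mask_counts=sub_counts)
        if mask_counts is not None:
            mask_counts[rows] += sub_counts
        pieces.append(out)
    ids = [i for p in pieces for i in p.ids]
    data = np.concatenate([p.data for p in pieces], axis=0)
    return Msa(ids, data, natural.alphabet)


def pseudolikelihood_loss(model: MaskedSequenceModel, msa: Msa,
                          mask: np.ndarray) -> float:
    """Masked-language-model loss: -sum over masked cells of log p(true symbol).

    Probabilities are the softmax-normalised model logits computed on the
    masked MSA. Always >= 0; a model assigning probability one to every
    true symbol scores exactly 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    masked = msa.copy()
    masked.data[mask] = msa.alphabet.mask_index
    logits = np.asarray(model(masked), dtype=np.float64)
    cell_logits = logits[mask]
    z = cell_logits - cell_logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    true_symbols = msa.data[mask]
    return float(-logp[np.arange(len(true_symbols)), true_symbols].sum())


class ConstantLogitModel:
    """Stub model emitting the same logit vector at every cell."""

    def __init__(self, logits: np.ndarray):
        self.logits = np.asarray(logits, dtype=np.float64)

    def __call__(self, masked: Msa) -> np.ndarray:
        M, L = masked.data.shape
        return np.broadcast_to(self.logits, (M, L, len(self.logits))).copy()


class UniformModel:
    """Stub model with zero logits: uniform over the alphabet."""

    def __call__(self, masked: Msa) -> np.ndarray:
        M, L = masked.data.shape
        return np.zeros((M, L, masked.q))
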