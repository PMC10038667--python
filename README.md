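# itermask

Generative protein-sequence modelling tools built around **iterative
masking**: start from a natural multiple sequence alignment (MSA), repeatedly
mask a random fraction of its cells and let a masked-sequence model refill
them, and read off the result as a synthetic MSA of the same shape. The
package also implements Potts-model (direct coupling analysis) sampling and
scoring, and the complete statistical battery needed to judge how well a
synthetic MSA reproduces a natural one — low- and high-order covariation
statistics, sequence-space distributions, and phylogeny spectra.

It is aimed at researchers studying generative models of protein families:
people who want to generate candidate sequences from alignment-conditioned
language models or Potts models, and — just as importantly — to *measure*
what those generators get right and wrong.

## The core procedure and models

**Iterative masking.** Given an MSA batch `M'` (up to 600 rows), repeat `I`
times: (1) mask each cell independently with probability `p`; (2) obtain
per-cell symbol logits from a masked-sequence model and write back, at every
masked cell, either the argmax symbol (greedy) or a draw from
`softmax(logits / T)`. Defaults `p = 0.1`, `I = 200`, so each cell is
remasked `p·I = 20` times on average over a run; columns are never inserted
or deleted, so the output stays aligned. Restricted variants mask only the
first row, with the remaining rows acting as fixed or resampled context
(`I = 20` suffices there). Any model satisfying the one-call contract
(masked MSA in, `M × L × q` logits out) plugs in: the built-in exact
Potts-conditional oracle, fixed-logit stubs, or a pretrained MSA-conditioned
language model through the thin `esm_adapter` hook.

**Potts models.** Sequences `x = (x_1..x_L)` over `q = 21` symbols (20 amino
acids + gap) are scored by the Hamiltonian

    H(x) = − Σ_i h_i(x_i) − Σ_{i<j} e_ij(x_i, x_j)

with Boltzmann distribution `P(x) ∝ exp(−H(x)/T)`. The package provides the
statistical energy score `−H(x)`, exact enumeration on tiny state spaces, a
vectorised single-site Metropolis–Hastings sampler at temperature `T`, and a
minimal Boltzmann-machine fitter (moment matching with L2 regularisation λ,
default `10⁻²`).

**Comparison statistics.** Connected correlations `C_ij`, `C_ijk`, mutual
information and co-information (bits), the `r20` word-frequency correlation
at orders 2–10, effective depth `M_eff(δ) = Σ_i w_i` with reciprocal
neighbor-count weights at Hamming radius `δ = 0.2`, closest-natural
distances, one-hot PCA projections, additive mutational-scan scores, and
bootstrap-aggregated modified-graph-Laplacian (MGL) spectra of
neighbor-joining trees.

## Worked example

Generate a synthetic MSA from a known ground-truth Potts model via the
exact-conditional oracle, then compare it to the natural (MCMC-sampled) MSA:

```python
import numpy as np
from itermask import (GenerationConfig, SamplingConfig, generate_synthetic_msa,
                      metropolis_sample, potts_oracle_mlm, r20_curve,
                      effective_depth, closest_natural, statistical_energy_scores)
from itermask.synthetic import random_potts_model
from itermask.msa import Alphabet

model = random_potts_model(L=8, q=4, coupling_density=0.6,
                           coupling_scale=0.4, field_scale=0.4, seed=0)
alphabet = Alphabet("ACD-")
natural = metropolis_sample(model, SamplingConfig(n_steps=2000, n_chains=300,
                                                  seed=1), alphabet=alphabet)

config = GenerationConfig(p=0.1, iterations=200, seed=2)
synthetic = generate_synthetic_msa(natural, potts_oracle_mlm(model), config)

curve = r20_curve(synthetic, natural, orders=range(2, 7), n_sets=200, seed=3)
_, dists = closest_natural(synthetic, natural)
print("r20 scores :", [round(s, 3) for s in curve.scores])
print("mean closest-natural distance:", round(float(dists.mean()), 3))
print("M_eff natural  :", round(effective_depth(natural), 1))
print("M_eff synthetic:", round(effective_depth(synthetic), 1))
print("mean energy score natural  :",
      round(float(statistical_energy_scores(model, natural).mean()), 2))
print("mean energy score synthetic:",
      round(float(statistical_energy_scores(model, synthetic).mean()), 2))
```

Output:

```
r20 scores : [0.544, 0.388, 0.355, 0.482, 0.584]
mean closest-natural distance: 0.09
M_eff natural  : 236.8
M_eff synthetic: 11.2
mean energy score natural  : 2.2
mean energy score synthetic: 4.63
```

The numbers show the characteristic behavior of greedy iterative masking:
generated sequences move away from their starting points (mean distance
0.09 to the closest natural sequence) and reach *better* statistical energy
scores than the equilibrium natural sample (4.63 vs 2.2), at the price of a
collapse in diversity (`M_eff` drops from 237 to 11) — greedy filling pulls
sequences toward local high-probability configurations. Softmax selection at
`T > 0` trades score back for diversity. The `r20` values quantify how well
2- to 6-column word statistics of the natural MSA are reproduced.

The same pipeline is scriptable from the shell:

```bash
itermask synth potts -L 8 --q 4 --seed 0 --out model.json
itermask potts sample --model model.json --steps 2000 --chains 300 --seed 1 --out nat.fasta
itermask generate --in nat.fasta --model oracle:model.json --p 0.1 --iters 200 --seed 2 --out synth.fasta
itermask compare --natural nat.fasta --synthetic synth.fasta --potts-file model.json --out report/
```

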