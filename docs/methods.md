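# Methods

This note documents the models and procedures implemented in `itermask`,
the parameter choices that matter, the numerical decisions, and what the
synthetic fixtures do and do not establish about real protein data.

## Iterative masking generation

The generator operates on an integer-encoded MSA (M rows × L columns over
q symbols; default alphabet the 20 canonical amino acids plus gap, q = 21,
gap at index 20). One iteration masks each eligible cell independently
with probability `p` (masked cells carry a reserved internal token, index
q, which is never a legal output symbol) and refills all masked cells
simultaneously from a single model evaluation. Refilling is greedy
(argmax of the logits; ties resolve to the lowest symbol index, for
determinism) or stochastic (a draw from `softmax(logits / T)`; greedy is
the `T → 0` limit, which the tests verify at `T = 10⁻⁶` on non-tied
logits). Gaps are maskable and the gap is a legal fill, so alignment
columns are preserved exactly — generation never changes (M, L).

Defaults: `p = 0.1` and `I = 200` iterations for whole-MSA masking, so
each cell is remasked `p·I = 20` times in expectation over a run; the
first-row variants (fixed or per-iteration-resampled context) default to
`I = 20`. Deep MSAs are split into uniform-random batches of at most 600
rows, each batch is generated independently, and outputs are concatenated
in plan order, giving a synthetic MSA of the natural depth. Each
iteration draws fresh Bernoulli masks, independent of previous
iterations.

Because all masked cells in an iteration are filled independently given
the unmasked context, the procedure inherits the masked-language-model
pseudolikelihood structure: dependencies *between* simultaneously masked
cells are ignored. This is a property of the procedure, not an
implementation shortcut; its visible consequence is quantified below
under "Oracle-driven generation".

The model is any callable taking a masked MSA and returning finite
`M × L × q` logits. Three implementations ship: fixed-logit stubs, the
exact Potts-conditional oracle, and a lazy adapter to a pretrained
MSA-conditioned transformer (`esm_adapter`; requires the optional
`fair-esm` and `torch` packages plus downloaded weights, and is therefore
not exercised by the default suite).

## Potts models

`H(x) = −Σ_i h_i(x_i) − Σ_{i<j} e_ij(x_i,x_j)`, with `P(x) ∝
exp(−H(x)/T)` and `T = 1` by default. Couplings are supplied once per
unordered pair `i < j`; internally a dense symmetric tensor with
`e[j,i] = e[i,j]ᵀ` and zero diagonal blocks vectorises energies and
conditionals. Probabilities are gauge invariant (adding a site-wise
constant to `h_i(·)` changes nothing), asserted by enumeration; fitted
parameters are reported in the zero-sum gauge for comparability, while
sampling and scoring are gauge-agnostic.

*Exact enumeration* is guarded to `q^L ≤ 10⁶` states and is the oracle
for every distributional test at desk scale.

*Metropolis–Hastings sampling*: each step proposes a uniformly random
site and a uniformly random different symbol, accepted with probability
`min(1, exp(−ΔH/T))`; `ΔH` is computed from local fields only. Chains are
independent and vectorised (one NumPy step advances all chains). The
default chain length, when none is given, is the `10·L·q` heuristic; the
equilibrium tests use explicit, longer runs (N = 2000 on L = 3, q = 2,
where total variation against enumeration measures ≈ 0.005–0.01 with
20,000 chains).

*Temperature* divides the Hamiltonian in the acceptance rule. On a fixed
tiny model the mean statistical energy score of samples is non-increasing
in T over {0.33, 1, 3} and mean pairwise Hamming distance is
non-decreasing — the score/diversity trade-off of low-temperature
sampling.

*Boltzmann-machine fitting* matches one- and two-body frequencies by
gradient steps `h += η(f₁ᵈᵃᵗᵃ − f₁ᵐᵒᵈᵉˡ − 2λh)` (couplings analogously,
kept pair-symmetric), with L2 strength λ (default 10⁻²; λ here is this
fitter's penalty scale and maps onto external DCA tools'
regularisation only to order of magnitude). Model moments come from
persistent Metropolis chains, or — automatically when `q^L ≤ 2048` — from
exact enumeration, which removes the Monte-Carlo noise floor and lets the
independent-site closed form (`softmax(h) = f_i` at λ = 0) hold to 10⁻³.
Convergence is declared when the maximum absolute moment error falls
below the tolerance; otherwise the best-so-far parameters are returned
with a warning flag. Replicating any external DCA package's training
schedule or its automatic chain-length estimation is a non-goal.

*The exact-conditional oracle* turns a Potts model into a
masked-sequence model: at each masked cell the logits are the log of the
exact single-site conditional given the row's unmasked cells. Masked
context cells are treated as gaps by default; a `drop` policy removes
their coupling terms instead. Both policies coincide on rows with a
single masked cell and agree closely at low mask density; neither is the
(exponentially expensive) exact joint conditional over a multi-cell mask.

### Oracle-driven generation as a sampler

With softmax selection at `T = 1` and first-row masking, the procedure is
a random-scan Gibbs-style sampler for the focal row: at `p = 0.1` most
iterations mask zero or one cell, and a single masked cell is refilled
from its exact conditional. Long-run visited-state frequencies on an
L = 3, q = 2 benchmark match the exact Boltzmann distribution within
total variation ≈ 0.013–0.027 over 40,000 iterations. The residual above
pure Monte-Carlo error is the simultaneous-fill bias: when two or more
cells are masked in one iteration they are filled independently, which
perturbs the stationary distribution by an amount that grows with
coupling strength and with `p`.

## MSA statistics

Frequencies are plug-in (no pseudocount). Connected correlations follow
the standard cumulant forms at orders 2 and 3; their marginalisation
identities (`Σ_x C_ij(x,y) = 0`, `Σ_x C_ijk(x,y,z) = 0`) hold to 10⁻¹²
on arbitrary data and are asserted as such. Entropies, mutual information
and co-information use log base 2, which makes the parity triple
(z = x XOR y on uniform bits) score exactly −1 bit of co-information and
duplicated uniform binary columns exactly 1 bit of mutual information.
Plug-in entropy estimates carry a systematic finite-size bias that is
deliberately *not* corrected; meaningful comparisons are between MSAs of
equal length and depth, which share the bias.

The r20 score averages, over random column subsets of each order
(2–10; "non-contiguous" is read as *not necessarily contiguous*, with no
adjacency exclusion), the Pearson correlation between the frequencies of
the 20 most frequent words. Words are ranked in the *reference* MSA
(a per-MSA union variant is available behind `word_selection`); ties at
rank 20 break lexicographically, which is well defined because distinct
words are enumerated in lexicographic order. Subsets where the
correlation is undefined (fewer than two distinct reference words, or
zero variance on either side) are skipped, counted, and excluded from
the average; an order where every subset is degenerate reports NaN
rather than a fabricated score. Gap-containing words are legal words.

Effective depth: `M_eff(δ) = Σ_i w_i` with `w_i` the reciprocal number of
rows within normalised Hamming distance δ (self included; δ = 0.2
default). `1 ≤ M_eff ≤ M` always, `M_eff` is non-increasing in δ, and
`1/w_i` equals the neighbor counts computed in the sequence-space module
exactly (a cross-module identity under test).

## Sequence space

Distances are normalised Hamming distances with the gap as an ordinary
symbol. Closest-natural search is exact brute force (chunked; M ~ 10⁵ ×
L ~ 10² is desk-feasible), ties to the lowest natural index, with an
`exclude_self` flag so natural sequences are never their own neighbors.
PCA is always fitted on the one-hot encoded *natural* MSA only; synthetic
data are projected by subtracting the natural mean — never refitted.
Nearest-neighbor score transfer assigns each generated sequence the score
of its closest natural sequence. Additive mutational-scan scores sum
tabulated single-mutation effects over positions where a sequence
differs from the reference; unmeasured mutations (including gaps at
differing positions) contribute zero and are counted as missing, a
policy this package defines explicitly. Positions are 0-based in code
and 1-based in the TSV table format and CLI, following mutational-scan
convention.

## Phylogeny spectra

Trees are inferred by neighbor joining on normalised Hamming distance
matrices (scikit-bio's implementation; negative branch-length estimates
are clamped to zero). On additive matrices NJ reproduces the generating
patristic distances to 10⁻¹⁰, which the tests assert. Externally built
trees can be imported as Newick for users wanting an approximate-ML
topology instead.

The modified graph Laplacian of a tree is `D − Δ`, where `Δ` holds
patristic distances between nodes and `D = diag(Δ·1)`. Row sums vanish by
construction, so 0 is always an eigenvalue (asserted to 10⁻⁸ relative
tolerance); the matrix is symmetric, so the spectrum is real. The node
set defaults to *all* nodes (internal + leaves), with a leaves-only flag.
Deep MSAs are summarised by a bootstrap-aggregated density: by default
200 trees, each from a random 500-sequence sub-MSA, eigenvalues pooled
raw (a log-scale option exists), Gaussian KDE with Scott's-rule
bandwidth, and adjusted Fisher–Pearson sample skewness. Right-shifted or
negatively skewed densities indicate "tippy" trees; the opposite,
"stemmy" trees. On constructed fixtures, a star-like MSA yields higher
pooled-spectrum skewness than a two-clade long-stem MSA, and only this
ordering — not the absolute skewness values — is asserted.

## Synthetic fixtures

The generators exist to induce *controllable* statistical structure, not
realism:

- **Profile MSAs** — columns drawn from symmetric Dirichlet
  (concentration parameter controls conservation), rows i.i.d. per
  column. All connected correlations vanish at the distribution level.
- **Random Potts models** — Gaussian fields, sparse Gaussian couplings
  (Bernoulli density × scale). Density 0 factorises exactly.
- **Tree-evolved MSAs** — Poisson(rate × branch length) substitution
  events per site, each drawing a uniformly random symbol (the simplest
  symmetric model); induces phylogenetic correlation with tunable depth
  structure. No indels, no realistic amino-acid exchangeabilities.
- **Toy mutational-effect tables** — Gaussian effects on a random subset
  of single mutations.

Consequently, passing tests establish correctness of the *machinery*
(the procedure, the sampler, the estimators, the identities) on data
whose ground truth is known exactly. They do not establish that any
particular pretrained language model generates good protein sequences:
that question requires real weights and real families, reachable through
the adapter hook but outside this package's test scope.

## Problem sizes and determinism

Distributional checks run on enumerable models (L = 3, q = 2; 8 states)
with 20,000 Metropolis chains of 2,000 steps, oracle-generation runs of
40,000 iterations, and fits to 20,000 sampled sequences — sizes chosen so
exact enumeration is the reference and the whole suite completes in well
under a minute per check. Every stochastic operation takes an explicit
integer seed; the CLI and the comparison report derive per-stage seeds
from one global seed by hashing it with a stable stage tag, so identical
inputs and configuration produce byte-identical outputs.

## Known limitations

- The Boltzmann-machine fitter is minimal; its λ is not numerically
  interchangeable with external DCA implementations' regularisation.
- The oracle's treatment of multi-cell masks (gap or drop policy) is an
  approximation to the exact joint conditional; generation quality
  degrades as `p` grows, mirroring the pseudolikelihood structure.
- Neighbor joining on Hamming distances is a coarse substitute for
  maximum-likelihood tree inference; MGL spectra are compared only at
  the level of density shape and skewness.
- r20 at high orders on small or highly diverse MSAs can be undefined
  (all words unique); the implementation reports NaN with a skip count
  instead of extrapolating.
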