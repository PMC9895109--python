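# Methods

## Model

`pgagp` scores candidate genes for a query disease by network propagation on
a two-layer heterogeneous network: a disease–disease layer `A_D` (binary or
real-valued similarity weights), a gene–gene layer `A_G` (binary protein
interactions), and a binary bipartite association matrix `R` joining them.
Everything downstream assumes the combined node order diseases-first; the
combined adjacency is the symmetric block matrix `[[A_D, R], [Rᵀ, A_G]]`.

The method rests on one modelling premise: genes associated with the same or
similar diseases are functionally related and therefore near each other in
the interaction network.  The embedding exists to pool that cross-layer
evidence into node features; the improved network exists to feed it back as
within-layer edges the measured networks may be missing.

## Embedding

Raw features are a Gaussian sketch `X = B·S` of the proximity polynomial
`B = Σ_r α_r Ã^r`, where `Ã` is the symmetrically normalized combined
adjacency (isolated nodes keep all-zero rows rather than being rejected) and
`S` has i.i.d. `N(0, 1/d′)` entries.  `E[S·Sᵀ] = I`, so the sketch preserves
the proximity Gram in expectation; the test suite verifies the Monte-Carlo
convergence of `mean(X·Xᵀ)` to `B·Bᵀ`.  The sketch is computed by `q`
propagations of an n×d′ matrix, so no n×n power is ever formed, and the
refinement eigendecomposes only the d′×d′ Gram — the scalability property of
the approach survives in the implementation even though the shipped fixture
is small.

Refinement: the features are column-centered (subtracting the column mean;
the centering step is standard even though a plain sum also appears in
related write-ups — subtracting an unnormalized column sum would neither
center nor preserve scale), the centered Gram `YᵀY` is eigendecomposed with
eigenvalues sorted descending and values below `1e−12·λ₁` clamped to zero,
and the selected dimension is the smallest `k` whose cumulative contribution
`c_k` reaches the threshold (with a `1e−12` slack so cumsum round-off cannot
overshoot the spectrum's rank at threshold 1).  The projection is applied to
the *uncentered* features, `Z = X·V_d`.  Consequence, verified in the tests:
at full retention `Z·Zᵀ` reproduces `X·Xᵀ` only up to the rank-one component
along the direction the centering removed; the identity is exact when `X` is
centered beforehand.

Parameters and defaults: `p = 0.1` (initial dimension `d′ = ⌈p·n⌉`; the
ceiling keeps at least the requested fraction on small networks, so a sweep
over the contribution threshold remains meaningful even at `p = 0.01`),
`threshold = 0.5` (both values the sweep experiments recommend), `q = 3`
with uniform weights `α = (1,1,1,1)` as the least-informative default, and
an explicit integer seed for the subspace — the entire pipeline is
bit-reproducible for a fixed seed.

## Network improvement

Cosine similarity of the disease and gene feature blocks (the diagonal
normalization of the feature Gram reduces exactly to pairwise cosine;
zero-norm rows — possible for isolated nodes — yield all-zero similarity
rows) gives dense layers that are sparsified per row to the `k` largest
strictly positive entries (ties toward the lower index) and symmetrized by
elementwise maximum — the standard kNN-graph construction; `k = 10` by
default.  Negative cosines are discarded: they would be meaningless as
random-walk weights.  Note that max-symmetrization bounds each row's own
selection at `k` but not its in-degree — a hub can be the nearest neighbor
of arbitrarily many nodes.

Variants: **HNim** max-merges the sparsified similarity with the original
layer (original support is provably never lost), **HNrc** uses the
sparsified similarity alone, **original** passes the input layers through —
the plain heterogeneous-walk baseline.  The association matrix `R` is
carried unchanged in all variants.  The merge uses the *sparsified*
similarity (a dense merge would destroy the sparsity the sparsification
exists to provide and make HNim's degree unbounded).

## Propagation

`M_D`, `M_G`, `R`, `Rᵀ` are column-normalized (all-zero columns stay zero),
assembled into the 2×2 block transition matrix with off-diagonal blocks
scaled by the jump probability λ and diagonal blocks by 1−λ, then
column-normalized once more so nodes missing from one layer still have
stochastic columns.  The walk iterates `P_{t+1} = (1−r)·T_H·P_t + r·P_0`
until the L1 change drops below `tol` (the convergence norm is a choice; L1
is the natural norm for probability vectors).  Dangling (all-zero) columns
are left absorbing-free: mass leaks uniformly within a query, which cannot
change a ranking, so no teleportation is added.  The iterative solution is
tested against the closed form `r·(I−(1−r)T)⁻¹·P_0`.

The restart vector places mass `1−η` on the query disease and `η` split
uniformly over its known training genes (all mass on the disease if it has
none).  The split-restart construction follows the established
heterogeneous-walk convention; η is exposed because the upstream description
of `P_0` is ambiguous.  Defaults `λ = 0.5`, `r = 0.7`, `η = 0.5`,
`tol = 1e−6`, `max_iter = 1000` follow common practice for this family of
methods; none is tuned to any dataset.

Ranked lists exclude the query's known training genes (they are seeds, not
candidates) and break score ties by gene index so reruns and
cross-implementation comparisons are stable.

## Evaluation

Folds split association *pairs*, not diseases, matching the seed-based
prioritization setting.  Per test disease, AUROC and AUPRC are computed over
its full candidate ranking (held-out genes positive, every other ranked
candidate negative) and macro-averaged; precision/recall/F1 are reported at
k ∈ {1, 5, 10}.  "Association Precision" has no published formula, so it is
implemented, clearly labeled, as the micro-averaged precision of the pooled
top-10 predictions across test diseases.  All metrics are verified against
brute-force threshold-sweep oracles; AUROC/AUPRC are delegated to
scikit-learn behind this module's interface.

## Synthetic data

The generator is a planted partition over two node universes: `m` matched
modules of diseases and genes, within-layer edges with probability `p_in`
inside modules and `p_out` across, associations with probability `assoc_in`
between matched modules and `assoc_out` otherwise, and a fraction of the
matched-module associations withheld as ground truth (only signal
associations are withheld, so the truth is recoverable in principle).  The
default fixture — 4 modules × (5 diseases + 30 genes), `p_in = 0.3`,
`p_out = 0.02`, `assoc_in = 0.2`, `assoc_out = 0.005`, holdout 0.3, seed 7 —
is 140 nodes and runs through the full pipeline in well under a second,
which also sets the problem sizes used by the test suite and the
reproduction script (ten embedding seeds there; twenty in the recovery
study).

What the fixture does show: the full pipeline recovers planted cross-layer
structure (held-out same-module genes outrank ~82% of other-module genes
under HNim, averaged over twenty seeds), propagation and embedding behave
per their oracles, and the threshold sweep reproduces the expected
information-starved-regime direction at `p = 0.01`.

What it does not show — two known limitations worth stating plainly:

1. **Sketch noise at desk scale.**  At `n = 140`, `p = 0.1` gives `d′ = 14`,
   i.e. ~27% relative Johnson–Lindenstrauss error on inner products, while
   the within/cross-module cosine gap of the exact polynomial features is
   only ~0.14.  The kNN graphs built from the sketch are therefore mostly
   noise (purity ~0.45 vs ~0.9 with exact features).  The regime the method
   targets — tens of thousands of nodes, where `d′ ≈ 2000` brings the sketch
   error to ~2% — cannot be reproduced at fixture scale.
2. **No incompleteness to repair.**  The generator's layers are complete
   draws of the planted truth, so even a noise-free embedding has nothing to
   add: with exact features, HNim performs on par with the original-network
   baseline here (0.798 vs 0.789 macro AUROC).  The improvement the
   embedding-merged network delivers on real data comes from measured
   networks being incomplete and noisy relative to the underlying functional
   structure — a property this generator deliberately does not emulate.
   Consequently the fixture-scale recovery study shows HNim *working*, not
   HNim *winning*: its mean macro AUROC over twenty seeds (0.72) sits below
   the 0.8 bar and below the baseline (0.79), and the corresponding
   end-to-end acceptance check is expected to fail at this scale.

## Numerical choices

- Eigenvalue clamp `1e−12·λ₁`; degenerate (all-zero) spectra raise a
  dedicated error rather than silently selecting nothing.
- Duplicate input edges keep the maximum weight (order-independent);
  self-loops are dropped with a warning but their nodes are kept.
- All matrices are dense numpy arrays: the supported problem sizes are set
  by the d′×d′ eigendecomposition, not by adjacency storage, and dense
  arithmetic keeps every oracle comparison exact.
- Ties everywhere (kNN selection, ranking) resolve toward the lower index,
  making every output deterministic for a fixed seed.
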