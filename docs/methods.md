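# Methods

## Problem and model

`mdalp` predicts unobserved microbe–disease associations from a binary
incidence matrix Y (n microbes × m diseases) under the smoothness
assumption that similar microbes associate with similar diseases. The
known 1-entries are positives; 0-entries are unlabeled, not confirmed
negatives — which motivates both the positive–unlabeled negative
selection and the rank-based (AUC) evaluation.

The pipeline composes five pieces, each implemented as its own module
behind the `MDAModel.fit()` entry point:

**Gaussian association-profile (GAP) kernels.** The profile of microbe i
is row i of Y; similarity is `exp(−γ‖A(i)−A(j)‖²)` with
`γ = γ′ / mean_k ‖A(k)‖²`. The normalization makes the kernel invariant
to a global rescaling of the profiles and adapts the bandwidth to the
data's density. An all-zero profile set leaves γ undefined and is
rejected ("degenerate bandwidth"); individual all-zero profiles (new
entities under CV1/CV2 masking) are allowed and get self-similarity 1.

**Symptom similarity.** Disease–symptom weight vectors are compared by
cosine after TF-IDF weighting with the smoothed inverse document
frequency `1 + log(N/df)`. The smoothing matters: with dense symptom
tables (every symptom observed in every disease at some weight) the
unsmoothed `log(N/df)` degenerates to the zero matrix, whereas the
smoothed form reduces exactly to the raw cosine when document frequencies
are uniform. Diseases absent from the symptom table get zero similarity
with a logged warning, not an error, so association data and symptom data
need not cover identical disease sets. A precomputed symptom-similarity
matrix can be supplied instead, and is then authoritative. The combined
disease similarity `S_D = S_G + γ·S_s` is left unnormalized (entries may
exceed 1); the neighborhood step below re-derives weights from it, so its
scale is immaterial.

**Linear neighborhood similarity (LNS).** Entity i's feature vector is
its row of the base similarity matrix; its K nearest neighbors are the
positions with the largest base-similarity values (ties broken by
ascending index). The reconstruction weights solve

    min_w  wᵀ (G + αI) w    s.t.  Σw = 1,  w ≥ 0,

with `G[j,k] = (X_i − X_{i_j})·(X_i − X_{i_k})`. The ridge α makes the
objective strictly convex, hence the solution unique and reproducible.
The QP is solved exactly by a small active-set method: solve the
equality-constrained KKT system on the free variables, drop the most
negative variable when the iterate leaves the simplex, and re-admit a
bound variable whose dual multiplier is infeasible; SLSQP is the fallback
for singular Gram matrices at α = 0. Weights below `qp_tolerance`
(default 1e-8) are clipped to zero and the row renormalized. The diagonal
of W is zero — self-reconstruction is degenerate — and W is row-stochastic
but generally asymmetric, which is intended: it is a directed graph, and
its spectral radius ≤ 1 guarantees convergence of the diffusion below for
β < 1.

K is not fixed by the method's description; the default is
`K = round(0.3·N)` (at least 1, at most N−1), a common choice in the
linear-neighborhood literature, and both an absolute `k_neighbors` and
the fraction are exposed to grid search.

**Negative selection.** The heterogeneous network stacks
`[[S_M, Y],[Yᵀ, S_D]]` with zero diagonals on the similarity blocks and
column normalization (isolated nodes keep all-zero columns with a
warning). For each disease, a walk restarts with probability r = 0.5 at
the disease node plus its known microbes; pair (i, j) is scored by the
stationary mass on microbe node i, computed by power iteration to an L1
tolerance of 1e-10. The lowest-scoring unlabeled pairs — as many as there
are positives, by default — become the reliable negatives. The symmetric
pre-LNS similarities are used here because a random walk needs a
symmetric affinity; the directed LNS graphs would bias the stationary
distribution. The seeding rule, restart probability, scoring rule and
selection size are this package's own concrete choices for a scheme the
method family describes only as "PU learning + random walk with restart";
all are configurable. Downstream, the selected negatives are clamped to
label 0 during propagation (explicitly, though this is a no-op on
already-unlabeled entries) and serve as the negative class when
integration weights are fitted.

**Label propagation and integration.** Diffusion
`Y(t+1) = βWY(t) + (1−β)Y⁰` has closed form `(1−β)(I−βW)⁻¹Y⁰`, which is
the production path (the graphs are small, a direct solve is exact and
fast); the iterative mode exists as a verification oracle and the two
agree within 1e-8 in tests. Three models are propagated: microbe-side on
LNS(S_M), disease-side on LNS(S_G), disease-side on LNS(S_s) — the three
computed similarity sources. When no symptom data is available the third
model falls back to LNS(S_D), which then equals LNS(S_G), effectively a
two-source model (logged). Scores combine convexly `Z = Σ ω_k Y^k`.
No ω values are prescribed by the method family; the default is uniform
(1/3 each), with an optional grid fit (step 0.1) maximizing the AUC
separating known positives from selected negatives. Ties in the grid fit
prefer the candidate closest to uniform, then lexicographic order, so a
globally tied fit returns the canonical uninformed choice. Scores are
relative propensities, not calibrated probabilities.

## Cross-validation

CV1/CV2/CV3 mask whole rows / whole columns / individual positive
entries; training zeroes the masked units and the pipeline is refit from
scratch per fold, so similarities never see test information (a leakage
assert enforces this). Test negatives follow the all-unlabeled
convention: every unlabeled pair under CV3, the unlabeled pairs within
the masked rows/columns under CV1/CV2 (a `negatives="global"` switch
evaluates against all unlabeled pairs instead). Because negatives vastly
outnumber positives, specificity and accuracy nearly coincide — the test
suite asserts this property explicitly.

AUC is the tied-rank Mann–Whitney statistic. The contingency metrics need
a threshold the method family does not specify; the package uses
prevalence matching (declare positive the top-q test pairs, q = number of
test positives), a parameter-free deterministic rule, with ties broken by
pair index. Trial t of a repeated run uses seed + t, making the averaged
report reproducible; the grid search evaluates candidate configurations
by mean AUC, first-in-iteration-order on ties.

## Synthetic benchmark

The generator plants cluster structure: microbes and diseases are
assigned round-robin to `n_clusters` clusters (round-robin rather than
random for exact size control), same-cluster pairs associate with
probability `p_in`, others with `p_out`, and each disease's symptom
vector is its cluster's one-hot block prototype mixed with uniform noise
at rate `symptom_noise`. The default study condition — 100 microbes × 30
diseases, 3 clusters, p_in = 0.5, p_out = 0.02, symptom_dim = 30, noise
0.2 — yields a sparse matrix (≈18% density) in the size range of curated
microbe–disease data while keeping a full 10-trial × 5-fold CV run in
tens of seconds on one CPU; those sizes are also what the acceptance
script uses.

What the generator does *not* emulate: the heavy-tailed degree
distribution of curated databases (many taxa with a single known
disease), taxonomic nesting between microbe entries, correlated curation
biases, or real symptom text mining. Passing the benchmark therefore
demonstrates that the pipeline recovers block-structured signal and is
correctly calibrated under a shuffled null — not that it attains any
particular performance on real curated data.

## Numerical choices

- QP: active-set KKT solves, drop tolerance 1e-10, dual-feasibility
  tolerance 1e-9, SLSQP fallback (ftol 1e-14); outputs clipped at
  `qp_tolerance = 1e-8` and renormalized.
- RWR: power iteration, L1 tolerance 1e-10, max 1000 iterations,
  convergence failure is an error carrying diagnostics.
- Propagation: direct linear solve; `β < 1` enforced at config level so
  `I − βW` is invertible for row-stochastic W.
- Determinism: the pipeline itself contains no randomness; all stochastic
  steps (generation, fold shuffling, trial repetition) derive from
  explicit integer seeds, and repeated runs are byte-identical.
- Degenerate inputs: all-zero profile sets, empty association matrices,
  overlapping positive/negative test sets, and non-binary entries are
  rejected with named errors; all-zero rows, isolated network nodes and
  missing symptom diseases degrade gracefully with logged warnings.

## Known limitations

- CV1 (new microbes) performs near chance: a masked microbe has an empty
  profile, so both its kernel similarity and its propagation labels carry
  no information, and no microbe-side feature (the analogue of symptoms)
  is available to bridge the gap. This mirrors the method family's own
  reported weakness on new-microbe prediction.
- Similarity and neighborhood computation are dense O(N²)–O(N³); the
  implementation targets hundreds-to-thousands of entities, not genome-
  scale catalogs.
- The curated HMDAD benchmark is not bundled and its preprocessing (483 →
  450 associations) is not reproducible from public descriptions; the
  loader performs duplicate-collapse only. Reported literature numbers on
  that benchmark are therefore not recomputed here.
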