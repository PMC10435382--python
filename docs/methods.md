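# Methods

## Model

The package factorises a binary diagnosis matrix W (D individuals × S
disease codes) as `P(W_ds = 1) = (θ_d · φ)_s`: each individual's Bernoulli
probability for a code is a mixture over K topics, with per-individual
mixing weights θ_d ~ Dirichlet(α) and per-topic Bernoulli probabilities
φ_k ∈ [0,1]^S. A latent assignment Z_ds ~ Categorical(θ_d) selects which
topic generates each disease variable, and W_ds ~ Bernoulli(φ[Z_ds, s]).
Repeated diagnoses are collapsed to a single 1 before modelling.

Topics receive a structured spike-and-slab prior driven by a rooted disease
ontology supplied as a two-column child/parent table (reserved parent token
`root`). Per topic, a Markov process sweeps the tree from the root (whose
latent state is fixed to 0) assigning each node a binary indicator with
transitions ρ01 = P(active | parent inactive), ρ11 = P(active | parent
active); the transition probabilities are global (shared across topics and
edges, one Beta prior each). Code nodes then draw φ from Beta(a₁, b₁) when
active and Beta(a₀, b₀) when inactive. Non-root internal nodes that are not
observed codes (e.g. chapter headers) carry indicators but no emission
parameters; this keeps the Markov chain connected through them. The flat
variant (flatLFA) is the identical model on the star tree where every code
hangs from the root, so ρ11 never touches data and only ρ01 is informed.

Assumptions worth keeping in mind: one pair of (ρ01, ρ11) for the whole
tree; indicators conditionally Markov on the tree; no age structure,
coding error, or longitudinal information.

## Default hyperparameters

| parameter | simulation preset | top-100 preset | top-436 preset |
|---|---|---|---|
| φ active prior | Beta(2, 4) | Beta(2, 4) | Beta(1.2, 3) |
| φ inactive prior | Beta(0.3, 80) | Beta(0.3, 80) | Beta(0.1, 3000) |
| ρ01 prior | Beta(4.8, 20) | Beta(3, 20) | Beta(3, 20) |
| ρ11 prior | Beta(20, 4.8) | Beta(3, 3) | Beta(3, 3) |
| flat-tree ρ01 | Beta(7, 20) | — | — |
| LDA η | 0.01 | 0.01 | 0.01 |

The simulation ρ priors encode sparse topics (E[ρ01] ≈ 0.19) whose active
codes cluster on branches (E[ρ11] ≈ 0.81); the flat ρ01 ~ Beta(7, 20)
matches the expected number of active codes per topic between the two tree
shapes. The sparser inactive prior of the top-436 preset accounts for rare
codes. α defaults to (1, 0.1, …, 0.1) on real data — the large first entry
anticipates the empty topic that absorbs healthy individuals — and is
optimised by Gibbs-EM; on simulated data the true α is supplied and held
fixed, so the comparison isolates the effect of the tree prior.

## Inference

θ is integrated out analytically, giving the collapsed conditional
`P(Z_ds = k | ·) ∝ (N_dk^{-ds} + α_k) φ_ks^W (1-φ_ks)^{1-W}`. One
systematic scan updates all Z (numba-compiled, counts maintained
incrementally), then every indicator by single-site Gibbs in topological
order (weights = Beta density of the node's φ under each state, times the
parent transition, times the child transitions; computed in log space), then
φ by conjugate Beta draws, then ρ from pooled edge-transition counts. The
update order Z → I → φ → ρ is a fixed systematic scan; single-site indicator
updates were chosen over tree-wide forward-filter/backward-sampling for
simplicity and are validated against exact enumeration on a tiny instance
(tests). φ is clamped to [1e-12, 1 − 1e-12] wherever Bernoulli or Beta
densities are evaluated, so no conditional can degenerate to all-zero
weights.

All randomness flows through numpy PCG64 generators; the compiled kernels
consume pre-generated uniforms, so runs are bit-reproducible given a seed
and independent of thread count. Per-chain generators are spawned from the
master `SeedSequence`.

Initialisation: simulation mode — I = 0, φ from the inactive prior, Z
uniform; real mode — φ ~ Beta(1, 5·10⁶) (near zero), I = 0, topic 1
assigned to every variable of individuals with no diagnoses, the rest
random.

The Dirichlet concentration is optimised by Gibbs-EM: E-steps advance the
chain and collect assignment count tables; the M-step maximises the joint
Dirichlet-multinomial likelihood of all collected tables by Minka's
fixed-point iteration, with entries floored at 1e-4 to keep the prior
proper. All collected Z samples enter one joint likelihood (rather than
averaging per-sample optima). ρ is sampled throughout EM, not only in the
final run.

Chain schedules: the full simulation schedule is 10 chains × 20 samples at
interval 100 after 15,000 burn-in; the desk-scale `reduced_schedule` is 2
chains × 10 samples after 3,000 burn-in with interval 20 (the shorter
interval keeps the sampling phase proportionate to the shorter burn-in).
Real-data presets use the two-stage EM schedules (2,000 × (20 sweeps, 1
sample) then 200 × (200 sweeps, 10 samples) for ~100 codes; 1,500/350
iterations for ~436 codes) followed by 5,000 burn-in sampling runs.

## Post-processing

θ is recovered from counts as θ_dt = (N_dt + α_t)/(N_d + Σα). Topic labels
are arbitrary, so topics are combined across samples and chains by building
a shared-nearest-neighbour graph over all posterior topic vectors
(Euclidean k-NN; scran-style rank weights by default, Jaccard optional) and
partitioning it with Louvain. The neighbourhood size defaults to
k = (n_chains · n_samples_per_chain)/2 — half the number of samples each
true topic contributes, small enough that distinct topics rarely merge.
Cluster support counts the distinct chains represented in a cluster;
per-cluster α follows each sample's topic label and is averaged.

Near-empty topics from over-provisioned models land in separate clusters,
so cluster averages are then merged agglomeratively (average linkage) while
any pair has cosine distance ≤ 0.1 **or** Manhattan distance ≤ 1; the
procedure stops when every remaining pair clears both thresholds. The
disjunctive merge rule is deliberate: near-empty topics can point in
arbitrary directions (large cosine distance) while being numerically tiny
(small Manhattan distance), and it is the Manhattan criterion that
collapses them into a single empty topic. The number of retained topics can
also be forced manually. Merged topics' α entries are summed (the collapsed
topic absorbs the weight of its members).

## Evaluation

**Δφ** — mean absolute per-entry difference between aligned true and
inferred topic matrices, Σ|φ^true − φ^infer|/(K·S). Inferred topics are
matched to true ones greedily by cosine similarity (best remaining pair
first; matched references are removed; ties break to the lower reference
index). The per-dataset statistic aligns *every posterior sample* to the
truth and averages the per-sample Δφ over samples and chains: this is
robust to label switching anywhere in the run and reflects the full
posterior (bias plus spread) instead of only a point estimate. For the LDA
baseline, whose topics are simplex vectors, the true Bernoulli topics are
row-normalised before comparison. When a model infers a topic the truth
lacks, the reference is padded with zero topics.

**Predictive likelihood** — per held-out individual,
log[(1/M) Σ_m Π_s Bern(W_ds | (θ^(m)·φ)_s)] with θ^(m) ~ Dirichlet(α) and
M = 200, averaged over posterior φ samples on the likelihood scale,
log-sum-exp stabilised. **R_pl** is the ratio of averaged per-individual
predictive likelihoods of two models; the geometric mean
(exp of the difference of mean logs) is the default for numerical
stability, with the arithmetic variant also available. In the benchmark
harness the same θ draws (common random numbers) are used for both models
on a dataset: the Monte-Carlo noise of M = 200 otherwise exceeds the
few-tenths-of-a-percent model difference being measured.

**Topic coherence** — NPMI f(ci,cj) = log[P(ci,cj)/(P(ci)P(cj))] /
(−log P(ci,cj)) averaged over all pairs of each topic's top codes
(n_top = 10 by default, matching topic diversity), with probabilities from
training co-occurrence; zero joint counts are smoothed by ε = 1/(2D).
**Topic diversity** — unique codes among all topics' top-10 divided by
10·K. **Ontology concordance** — Pearson correlation of (sum-normalised)
topics with binary chapter/category vectors, top 5 per topic.

Model differences in Δφ across paired datasets are tested with the
two-sided paired Wilcoxon signed-rank test.

## Simulator and what the tests show

The simulator reproduces the benchmark conditions exactly: the fixed
three-layer tree (root, 5 branch nodes, 15 leaves; all 20 non-root nodes
are codes) and four hand-constructed topics — three activating one full
branch (4 codes) each, the fourth activating two full branches (8 codes).
The misspecified setting keeps the same per-topic active-code counts but
scatters the active codes so that no parent–child pair is jointly active.
Active codes get a single probability `active_prob`; the published heatmap
does not print its value, so it is an explicit parameter with a documented
default of 0.5. Datasets are drawn from the generative process itself with
symmetric Dirichlet α ∈ {1, 0.1} and D ∈ {2500, 5000, 300, 1000}, 20
paired train/test sets per cell.

Because the data are drawn from the model being fitted, passing benchmarks
demonstrates correct inference and the value of the structural prior under
matched conditions — not robustness to coding error, age structure,
non-stationary prevalence, or any other real-EHR complication the
simulator deliberately omits.

Problem sizes: the test suite runs the replicated benchmark at 12 paired
datasets per group with 2 chains, 1,000 burn-in and 6 thinned samples —
enough for the paired signed-rank comparisons to resolve the model
difference. `scripts/acceptance.py` uses 20 datasets per group with the
full desk-scale schedule (2 chains, 3,000 burn-in, 10 samples at interval
20). The exactness oracle runs 24 independent chains on a 3-individual,
2-code instance whose posterior is enumerable in closed form (θ, φ and ρ
integrated analytically via Dirichlet-multinomial and Beta identities).

## Downstream utilities

Topic weights are exported for association testing after a logit transform
y = log(θ'/(1−θ')), θ' = clamp(θ, ε, 1−ε) with ε = 10⁻⁶ (the transform's
behaviour at exact 0/1 is undefined, so clamping is applied and reported);
output follows the PLINK phenotype dialect (FID, IID, one column per
topic, NA for missing), with completely healthy individuals optionally set
missing for disease-topic traits. Code-level polygenic scores are the
topic-level scores mixed by φ: PRS_ds = Σ_t PRS_dt · φ_ts.

The power simulation illustrates why merging diseases dilutes single-SNP
signals: five independent binary genotypes g ~ Bernoulli(0.1); per
genotype a disease y ~ Bernoulli(logit⁻¹(b0 + b1·g)) with
b0 = log(0.1/0.9) and b1 = 0.1, re-drawn until its own logistic regression
(Wald test) is significant at 0.05; the union of the five diseases is then
regressed on all five genotypes jointly, and the retained significant
fraction is averaged over 1,000 replicates. Logistic fits use a capped
Newton-Raphson maximum-likelihood routine; replicates with separation are
re-drawn and counted. The source description of this simulation prints the
inverse-logit and b0 formulas in a typographically garbled form; they are
interpreted as the standard inverse-logit and b0 = log(0.1/(1−0.1)).

## Known limitations

- Single global (ρ01, ρ11): heterogeneous branch densities are absorbed by
  the indicators, not the transitions.
- Single-site indicator updates can mix slowly on deep trees; a
  forward-filter/backward-sample pass over the tree would be the natural
  optimisation.
- The SNN weighting scheme and Louvain resolution of the original
  post-processing pipeline are not published; the defaults here (rank
  weights, resolution 1) are configurable and sensitivity-tested, but not
  guaranteed identical.
- LDA's Δφ is computed against row-normalised true topics and is not on
  the same scale as the Bernoulli models' Δφ.
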