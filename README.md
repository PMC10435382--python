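# treelfa

Bayesian topic modelling of binary diagnosis matrices with an
ontology-tree prior, for finding multimorbidity clusters in
electronic-health-record data.

## The model

Given a binary matrix *W* (D individuals × S disease codes), the model
factorises the Bernoulli probability matrix into K *topics* and per-individual
*topic weights*:

    θ_d  ~ Dirichlet(α)                 topic weights of individual d
    Z_ds ~ Categorical(θ_d)             topic assignment of each disease variable
    W_ds ~ Bernoulli(φ[Z_ds, s])        presence/absence of code s

Each topic φ_k is a vector of S Bernoulli probabilities — a cluster of
diseases that tend to co-occur. Unlike LDA, absences are modelled, so the
number of diagnoses is informative and an "empty" (healthy) topic emerges
naturally.

The distinguishing piece is a structured spike-and-slab prior on topics: a
Markov process runs from the root of a disease ontology (e.g. ICD-10),
assigning each node a binary indicator I with transition probabilities
ρ01 = P(active | parent inactive) and ρ11 = P(active | parent active).
Active codes draw φ from Beta(a₁, b₁), inactive codes from a much sparser
Beta(a₀, b₀). Small ρ01 and large ρ11 produce sparse topics whose active
codes cluster on ontology branches. Attaching every code directly to the
root gives the non-informative twin model, **flatLFA**; a collapsed-Gibbs
**LDA** baseline is also included.

Inference is by partially collapsed Gibbs sampling (θ integrated out
analytically), with conjugate updates for φ, I and ρ, a Gibbs-EM fixed-point
optimisation of α, and held-out topic-weight inference. Post-processing
recovers θ from assignment counts, clusters posterior topic samples across
chains (shared-nearest-neighbour graph + Louvain), and collapses near-empty
topics. Evaluation utilities cover topic-recovery error (Δφ), Monte-Carlo
held-out predictive likelihood and the between-model ratio R_pl, topic
coherence (NPMI), topic diversity, and concordance with expert-defined code
groups. Downstream helpers export logit-transformed topic weights as PLINK
phenotypes and mix topic-level polygenic risk scores into code-level scores.

## Worked example

```python
import numpy as np
import treelfa as t

tree = t.build_sim_tree()                      # root, 5 branches, 20 codes
topics = t.make_sim_topics(tree, "correct_prior")   # 4 known topics
data, theta, Z = t.simulate_dataset(topics, alpha=1.0, D=2500, seed=1,
                                    code_ids=tree.code_order)

hyper = t.sim_hyperparams(K=4, alpha=1.0)
sched = t.reduced_schedule()                   # 2 chains, 3,000 burn-in
post = t.fit(data, tree, "treelfa", hyper, sched, seed=1)

err = np.mean([t.aligned_delta_phi(topics.phi, phi)
               for c in post.chains for phi in c.phi])
print(f"delta-phi = {err:.4f}")
```

This prints `delta-phi = 0.0104`: on average each of the 4×20 topic entries
is recovered to about 0.01 of its true probability (active entries are 0.5,
so ~2% relative error). Running the flat-prior twin on the same data
(`t.fit(data, tree, "flatlfa", ...)`) gives a slightly larger error — the
ontology prior is what pulls uncertain codes toward their branch.

The same workflow is available from a shell:

```bash
treelfa fixtures make healthy-mix --out fx/
treelfa train --data fx/W.tsv --tree fx/tree.tsv --model treelfa \
        --topics 4 --preset sim --seed 1 --out run.h5
treelfa postprocess run.h5 --out topics.h5
treelfa evaluate --run run.h5 --test fx/W.tsv --metrics pl,td --out report.json
```

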