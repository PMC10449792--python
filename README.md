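# synspan

Cross-species comparison of single presynapses from SynTOF
(synaptometry-by-time-of-flight) mass-cytometry data.

## The problem

SynTOF profiles individual synaptosomes — one acquired *event* per
presynaptic particle — across a panel of 20 antibody channels.  Comparing
presynaptic molecular composition *across species* (human, macaque, mouse)
requires pooling millions of single events from heterogeneous acquisitions
into one analysis while guarding against species, subject, and antibody
confounders.  `synspan` implements that comparative pipeline for
neuroscientists and cytometrists:

1. **Joint embedding + clustering.**  Two parallel fully-connected
   autoencoders are pretrained on the pooled, arcsinh-transformed,
   species-balanced event matrix under MSE reconstruction loss; their
   bottleneck codes are concatenated into a shared latent representation
   `z`.  A clustering layer of K centres `μ_j` assigns Student-t soft
   memberships

       q_ij = (1 + ‖z_i − μ_j‖²/α)^(−(α+1)/2) / Σ_k (…)

   and fine-tuning minimises `L = MSE + γ·KL(P‖Q)` where
   `p_ij ∝ q_ij²/f_j`, `f_j = Σ_i q_ij` is the sharpened target
   distribution (the DEC/IDEC recipe).  Training uses Adagrad (initial
   learning rate 0.1, batch size 1024), Glorot initialisation, K-means
   centre initialisation, elbow K-selection, and early stopping.
2. **Consensus.**  The training is repeated over 10 seeds; the run
   labelings are merged by greedy cluster matching onto a reference run
   and per-event majority vote, scored by pairwise F-score and NMI.
3. **Confounder validation.**  Silhouette scores of the latent space under
   cluster vs species vs subject partitions; within- vs between-cluster
   cross-species earth mover's distances per marker; coefficient-of-
   variation comparison of mono- vs multi-species pooling; antibody
   reactivity tests.
4. **Differential statistics.**  Per-subject cluster frequencies with a
   0.01 mean-frequency noise floor, exact Wilcoxon rank-sum tests on
   subject-level replicates with Benjamini–Hochberg correction, pseudo-bulk
   differential expression with a |log2FC| > 0.5 rule, and Pearson
   correlation / nearest-neighbour graphs with Bonferroni-corrected edges
   and Fruchterman–Reingold layouts.

A synthetic-data module generates SynTOF-like three-species event tables
with planted subpopulations (11 primate-shared, 4 mouse-exclusive, one
low-expression cluster shared by all species) so the whole pipeline is
testable end-to-end with known ground truth.

## Worked example

```python
from synspan import (default_cortex_scenario, generate_events, arcsinh_transform,
                     balanced_downsample, SynTofDEC, TrainConfig, validation_report)

config = default_cortex_scenario(events_per_subject=500)   # 15 subjects, 3 species
events = generate_events(config, seed=1)
table = balanced_downsample(arcsinh_transform(events, cofactor=5.0),
                            per_species=2000, seed=0)

model = SynTofDEC(table, TrainConfig(n_runs=3, max_epochs_pretrain=40,
                                     max_epochs_finetune=20))
res = model.fit(k="auto", k_range=range(10, 23), seed=0)
print(res.summary())
```

prints

```
Deep embedded clustering results
================================
events: 6000   latent dim: 16   K: 16
consensus clusters: 16   mean F-score: 1.000   mean NMI: 1.000
elbow: k=16 strength=0.669 (elbow)
per-run agreement with consensus:
  run  0 seed=0          epochs= 20 KL 0.3866->0.3546 F=1.000 NMI=1.000
  run  1 seed=1000       epochs= 20 KL 0.2051->0.1679 F=1.000 NMI=1.000
  run  2 seed=2000       epochs= 20 KL 0.2070->0.1784 F=1.000 NMI=1.000
consensus cluster sizes: 0:326, 1:469, 2:437, ...
```

The elbow found the 16 planted subpopulations and all three seeded runs
agree perfectly with the consensus partition.  The confounder battery on
the same fit:

```python
report = validation_report(table, res.latent, res.labels, seed=0)
# s_cluster=0.884  s_species=0.048  s_subject=-0.058
# EMD within=0.062  between=1.347  p=3.02e-40
```

The latent space is organised by cluster (silhouette 0.88), not by
species (0.05) or subject (−0.06), and a marker's distribution for two
different species inside the same cluster is far closer (mean EMD 0.06)
than across clusters (1.35) — the signature of a clustering driven by
presynaptic phenotype rather than species origin.

The same analysis is scriptable end-to-end (`synspan run --config
config.yaml`), one model per brain region, writing labelled events,
validation reports, frequency/differential tables, graphs, and a JSON
summary.

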