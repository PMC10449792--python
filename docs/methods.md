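# Methods

## Model

`synspan` clusters pooled multi-species single-presynapse (SynTOF) event
data in a learned low-dimensional space.  The observation model is simple:
each event is a vector of 20 antibody intensities; intensities are
nonnegative and right-skewed, so they are variance-stabilised with
`asinh(x/c)` before any modelling.  The clustering model is deep embedded
clustering with a retained reconstruction term (IDEC):

- **Embedding.**  Two parallel fully-connected autoencoders with the same
  architecture (20 → 64 → 32 → 8 → 32 → 64 → 20; ReLU hidden layers,
  linear bottleneck and output) are trained on the same input.  The shared
  representation is the concatenation of the two bottleneck codes
  (16 dimensions).  Using two parallel encoders rather than one widens the
  effective code while keeping each encoder small; their independent
  initialisations also decorrelate the two halves of the code.
- **Clustering layer.**  K centres μ_j live in the shared code space.
  Soft assignments use the Student-t kernel
  `q_ij ∝ (1 + ‖z_i − μ_j‖²/α)^−(α+1)/2` with α = 1.  The target
  distribution `p_ij ∝ q_ij²/f_j` (f_j the soft cluster frequency)
  sharpens confident assignments while normalising away cluster-size
  imbalance.
- **Losses.**  Pretraining minimises reconstruction MSE only.  Fine-tuning
  minimises `MSE + γ·KL(P‖Q)` with γ = 0.1; P is recomputed every 140
  mini-batches.  Setting γ = 0 with no fine-tuning epochs reduces the
  model exactly to autoencoder + K-means, which the tests exploit as an
  equivalence oracle.

## Training protocol

Adagrad with initial learning rate 0.1 and batch size 1024; Glorot-uniform
weight initialisation; seeded shuffling, so a run is bit-reproducible given
its seed.  Early stopping monitors the epoch training loss with patience 10
and minimum improvement 1e-4, capped at 60 pretraining and 40 fine-tuning
epochs.  Cluster centres are initialised by K-means on the pretrained codes
(empty-cluster fits are retried with a shifted seed, bounded).  K-means,
silhouette, NMI and the pair-confusion counts come from scikit-learn; the
autoencoder, its backpropagation and the clustering-layer gradients are
implemented directly in NumPy (the KL gradient was verified against
central finite differences during development).

Two numerical choices deserve note:

- **Optimizer continuation.**  Fine-tuning *continues* the pretraining
  Adagrad state (the per-parameter accumulated squared gradients are
  carried over).  With fresh accumulators, the first Adagrad steps have
  magnitude ≈ lr for every weight, which scrambles the pretrained encoder
  before the clustering loss can act and can collapse clusters; with the
  carried state the fine-tune is a smooth continuation.
- **Elbow criterion.**  K is chosen from the K-means SSE curve on the
  pretrained codes by the maximal *normalised* second difference
  `(SSE[k−1] − 2·SSE[k] + SSE[k+1]) / SSE[k]` — the drop in marginal SSE
  relative to the SSE still unexplained.  A raw second difference cannot
  distinguish a genuine elbow from the smooth decay of structureless data;
  the normalised form is large (≫ 0.1) at a planted elbow and small
  (≈ 0.02) on a single Gaussian.  Below 0.1 the curve is declared
  elbow-free: the smallest k in the range is returned with a warning.
  Ties break toward smaller k.

## Ensemble and consensus

The whole training is repeated 10 times with distinct seeds.  The
consensus picks the run with the highest mean NMI to all others as the
reference, greedily relabels each other run's clusters onto the reference
clusters in order of decreasing event overlap (leftover clusters go to
their best-overlap reference cluster), and takes a per-event majority
vote with ties resolved in favour of the reference.  This is O(R·K²),
deterministic, and avoids the O(n²) co-association matrix that is
infeasible at millions of events.  Agreement is reported per run as
pairwise F-score (F1 over co-clustered event pairs, with the convention
that two all-singleton partitions score 1) and NMI with arithmetic-mean
normalisation; a cluster-level best-match F-measure is available as an
alternative.  One caution: adding a duplicate of an arbitrary run can
*switch* the reference and is not guaranteed to raise mean NMI;
duplicating the reference run is monotone, and that is the form the
property test asserts.

## Confounder validation

- **Silhouettes** are computed in the latent space on a seeded subsample
  of 20,000 events (the full-data silhouette is O(n²)), under three
  partitions: fitted clusters, species, subjects.  A clustering driven by
  phenotype shows s_cluster ≫ s_species ≈ s_subject ≈ 0.
- **EMD.**  For every marker, the exact 1-D Wasserstein distance is taken
  between the expression of two different species within the same cluster
  (the "within" set) and across different clusters (the "between" set),
  on the arcsinh scale with no binning; cells are capped at 1,000 events
  for tractability.  A one-sided rank-sum per marker (and pooled overall)
  tests within < between.
- **CV and reactivity.**  Coefficients of variation compare mono- vs
  multi-species pooling per marker (paired t-test across markers;
  identical inputs give p = 1 by convention).  Antibody reactivity is a
  one-sided one-sample t-test (mean > 0) on subject-level pseudo-bulk;
  cross-species mean levels use one-way ANOVA (pairwise t for two
  species) with Benjamini–Hochberg correction across the 20 markers.

## Differential statistics

Subjects — never events — are the replication unit everywhere, guarding
against pseudo-replication.  Cluster abundances are per-subject event
proportions; a (species, cluster) cell whose mean frequency falls below
0.01 is filtered as noise before testing.  Rank-sum tests use the exact
null distribution up to 12 subjects per group (the designs here have
4–6) and the tie-corrected normal approximation beyond.  "Fold change"
is `|log2(mean_A/mean_B)| > 0.5` (volcano-plot convention); when a group
mean is nonpositive the effect is reported as a signed difference with a
flag.  BH families are per analysis: across clusters for abundance tests,
across markers for pseudo-bulk, and jointly across all (cluster, marker)
pairs for per-cluster differential expression.  The pseudo-bulk
differential can additionally require consistency within a pair of groups
(e.g. a Mu-vs-primate hit must show no Hu-vs-NHP difference).

## Graphs

Correlation graphs take labelled mean-expression vectors as nodes
(cluster × species profiles or per-subject means), all-pairs Pearson r
with the two-sided non-correlation t-test (n − 2 df), Bonferroni over all
node pairs, and retain edges with adjusted p < α **and** |r| above the
global mean |r| computed over all pairs *before* significance filtering.
Zero-variance nodes are left isolated with a warning.  The
nearest-neighbour graph weights edges by 1 − d/d_max (z-scaled
coordinates behind a flag) and keeps weights above the mean; all-identical
nodes degenerate to a complete graph of weight 1.  Layouts are
Fruchterman–Reingold (networkx spring layout), weight-aware and seeded.

## Synthetic data

The generator emulates a three-species cerebral-cortex experiment:
Hu 6 subjects (2 F), NHP 4 (4 F), Mu 5 (3 F); 20-marker panel; 16 latent
subpopulations — 11 shared by the two primates only, 4 mouse-exclusive,
and one all-species cluster with near-zero means on every marker
(events the panel cannot distinguish) that absorbs 30% of mouse events
but only 3% of primate events.  One cluster per lineage co-expresses
VGLUT and GAD65, and one primate cluster is "high-expressed" on most
markers.  Raw intensities are log-normal around each cluster's mean
(location log μ, scale 0.25), giving the right-skewed nonnegative signal
characteristic of mass cytometry; per-subject batch shifts (SD 0.05) and
event noise (SD 0.05) act additively on the arcsinh scale, mimicking
acquisition-batch effects.  Cluster signatures are six elevated markers
(raw means 25–75 against a 0.5 background) rejection-sampled so any two
clusters differ in at least four signature markers.  Effect sizes are a
design choice — no per-cluster effect sizes exist to copy — set once so
that the subpopulations are separable by the pipeline; recovery of
planted structure, not any real-data cluster count, is what the tests
assert.  Mixing weights per species are fixed, uneven, and sum to one;
truth labels travel in a reserved metadata column.

What the generator does *not* emulate: raw mass-channel spectra,
barcoding/debarcoding, bead normalisation, spillover, gating debris,
marker-marker correlation structure within a subpopulation, or heavy-tail
acquisition artifacts.  Passing tests therefore demonstrate that the
pipeline recovers well-separated planted structure under realistic
skew/batch noise at this scale — not that real SynTOF data contain any
particular number of clusters.

## Problem sizes and defaults

The default scenario generates 3,333 events per subject (49,995 events);
species balancing to the smallest species leaves ~40k for training.  At
that size a 10-run ensemble plus validation completes in ≈ 5 minutes on
one CPU core.  All randomness flows from one base seed, expanded
deterministically per stage; artifact files round floats to 6 significant
digits so reruns are byte-identical.  FCS import supports 3.0/3.1
list-mode float data (CyTOF-style); CSV/Parquet are the canonical on-disk
forms, with species/subject/region/sex/truth/cluster as reserved columns.
The arcsinh cofactor defaults to 5, the mass-cytometry convention.

## Known limitations

- The two-autoencoder architecture, γ = 0.1, target-refresh interval 140
  and layer sizes are package defaults, configurable but not tuned; no
  hyperparameter search is performed.
- The consensus is anchored to a single reference run; pathological
  ensembles (no majority structure) inherit the reference's biases.
- Silhouettes are subsampled estimates; EMD cells are capped at 1,000
  events.
- Per-cluster differential tests assume ≥ 2 subjects of each species per
  tested cluster and skip the rest.
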