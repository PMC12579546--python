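# Methods

This note documents the models, parameters and design choices behind
`phoszsl`, and what the synthetic benchmarks do and do not establish.

## Task formulation

Let `X` be the space of phosphosite sequence windows and `Y` a set of
kinases. Training data are pairs `(x_i, y_i)` with `y_i` drawn from a set
of training ("light") kinases; at test time the model ranks a disjoint set
of held-out ("dark") kinases for each site. Because one site can be
phosphorylated by several kinases, the task is multilabel: a predicted
kinase is correct if it matches any annotated kinase of the site. Sites
are represented by 15-residue windows (seven flanking residues on each
side of the phosphorylated S/T/Y, pad character `_` at protein termini);
kinases by their domain sequences plus categorical annotations (group,
family, EC numbers, with sentinels `Other2` / `otherFamily` for
unassignable kinases).

## Split construction

Splits are made over kinases, never over sites, and satisfy three rules:

1. **Per-kinase minimums.** A kinase enters the test set only with ≥ 15
   association pairs, validation only with ≥ 10, so per-class AP is
   estimated from enough sites. Kinases below the test threshold are
   pinned to training.
2. **Group stratification.** Test kinases are drawn per kinase group;
   every group with at least three eligible kinases contributes at least
   one test kinase.
3. **Identity clustering.** Kinases whose domains align at ≥ 90 %
   identity are merged by single linkage and assigned wholesale, so no
   cross-split pair reaches the threshold.

Sequence identity is computed from end-to-end global alignment
(Needleman–Wunsch via Biopython's `PairwiseAligner`) with BLOSUM62 and gap
open 10 / extend 0.5 (EMBOSS-needle defaults; configurable). The identity
denominator is the full alignment length **including gap columns** — the
strictest convention, chosen because a smaller denominator could only
inflate identity and mask leakage. Single linkage is likewise the
conservative choice: it merges any chain of near-duplicates.

The 80/10/10 targets are measured over association pairs (not kinases).
Procedure: clusters containing an ineligible kinase are forced to train;
remaining multi-member clusters are pre-assigned wholesale to the held-out
side with probability equal to the target fraction; then a stratified draw
per group tops the held-out pair count up to the target, stopping when the
running total first reaches it. Two refinements keep the achieved
fractions tight on heavy-tailed kinomes, where single clusters can carry
several percent of all pairs: a cluster is pre-assigned or drawn only if
its pair count fits the remaining deficit to target (uniformly among the
fitting clusters of the group), and when none fits, the group's smallest
cluster is taken so stratification never stalls. Oversized clusters
therefore stay in training, which is also the leakage-safe side. With
plain uniform draws the achieved fractions wandered 10–20 points from
target on synthetic kinomes; with deficit-aware draws they stay within
±5 points whenever the kinome has ≥ 40 eligible kinases. The validation
stage repeats the same procedure over the remaining training kinases with
the ≥ 10-pair threshold. All randomness flows through one seeded
generator, so a (dataset, config, seed) triple reproduces the split
bit for bit. `validate_split` re-checks every rule on any split, generated
or external.

## Classifiers

**Zero-shot k-NN (training-free).** For a test site, rank all training
*(site, kinase)* pairs by similarity of their site embeddings to the query
(cosine by default; Euclidean available). A multilabel training site
contributes one neighbour per kinase label. Among the k nearest, the most
common light kinase wins; if no label strictly exceeds all others
(plurality tie), the nearest neighbour's label is used. The score of each
dark kinase is the cosine similarity between its embedding and the voted
light kinase's embedding. Distance ties at the k-th neighbour resolve by
pair index, making runs reproducible. k is the only hyperparameter and is
chosen by validation macro AP (ties to the smallest k), conventionally
from {3, 5, 7}.

**Bilinear compatibility model.** Representations are bias-augmented and
scored by `F(x, y) = [θ(x), 1] W [φ(y), 1]ᵀ`, whose expansion separates a
pairwise term `θᵀW₁₁φ`, linear priors in `θ` and in `φ`, and a trainable
scalar. `W ∈ R^{(d+1)×(m+1)}` is the only parameter; embeddings stay
fixed. Training minimises mini-batch softmax cross-entropy of each pair
against the light-kinase set, with the L2 penalty applied as decoupled
weight decay (`W ← W − lr·λ·W` after the optimiser step; the bias row and
column are decayed like every other entry). At test time the softmax runs
over the dark kinases. The implementation is NumPy with explicit
gradients; single-threaded runs are bitwise reproducible from the seed.

Defaults and ranges: learning rate 1e-3 in [1e-6, 0.1]; weight decay 1e-4
in [1e-5, 0.01]; optimisers Adam, SGD with momentum, RMSprop; schedules
exponential (γ = 0.99 per epoch), step (halve every 50), cosine annealing;
momentum in [0.95, 0.9999] (used as the SGD/RMSprop momentum and as
Adam's second-moment coefficient); 200 epochs, batch size 64. Epochs and
batch size are package defaults — they are not prescribed by the
formulation and tests use smaller values. `W` is initialised
N(0, 1/√(d+1)); with a validation split, the checkpoint with the best
validation macro AP is returned. Random hyperparameter search samples
learning rate and weight decay log-uniformly and the categorical choices
uniformly, scoring by validation macro AP; `run_restarts` trains n = 3
models differing only in seed and reports macro AP as mean ± sample
standard deviation.

## Evaluation

Average precision is the non-interpolated information-retrieval
definition: sort descending with stable tie order (input order breaks
ties) and average precision at each positive's rank. Macro AP ranks all
test sites per kinase column and averages per-kinase APs with equal
weight; classes (or sites) without positives are excluded from the mean
with a logged warning rather than scored zero. Phosphosite AP ranks
kinases per site. Family/group-aggregated AP pools member-kinase scores by
**max** (sum available) — max was chosen because a class should score as
well as its best member; the alternative is exposed for sensitivity
checks. Masked-group AP sets scores of kinases outside the union of a
site's true kinases' groups to −∞ (ranked strictly last, still counted as
negatives), isolating within-group ranking; it can never fall below plain
macro AP because masking only demotes negatives. hit@k is the fraction of
sites with a true kinase in the top k. The random baseline draws an
independent uniform score for every (site, kinase) cell — equivalently, a
uniformly random kinase ranking per site — and reports the mean and
standard deviation of macro AP over 1000 runs by default.

## Encodings

Windows are fixed-length, so baseline encodings concatenate one block per
position (alphabet: 20 residues + X + pad, 22 symbols); variable-length
domains are position-averaged (21 symbols, no pad). One-hot blocks are
indicators (pooled vectors lie on the probability simplex); BLOSUM62
blocks are the residue's 20-entry substitution row (pads contribute
zeros); trigram encoding averages the vectors of all overlapping 3-grams
from a user-supplied table, out-of-vocabulary 3-grams contributing zeros.
The packaged `nlf_synthetic.tsv` is a **synthetic stand-in** for the
published non-linear-Fisher-transform descriptor table (which is
distributed inside an epitope-prediction tool, not as a plain file): 18
descriptors per residue from a double-centred spectral embedding of the
BLOSUM62 similarity matrix. It preserves the shape and substitution-
similarity structure of the real table but not its exact values;
`nlf_encode`/`load_nlf_table` accept the genuine coefficients as TSV.
Precomputed language-model embeddings are consumed as files: TSV vector
stores, or HDF5 token stores pooled by non-pad column average or by the
CLS row (index 0; the store records whether a CLS row is present).
Kinase vectors can be augmented with one-hot family and group blocks and
a multi-hot EC block; augmentation never alters the leading coordinates.

## Synthetic benchmarks

The generator emulates the *statistical* structure of curated
kinase–phosphosite data, not its biochemistry: group ancestor sequences
(length 250) are mutated into family ancestors (30 % per-residue
substitution) and then kinase domains (8 %, keeping sibling identities
safely below the 90 % threshold); a clone fraction (10 %) receives
near-duplicate partners with exactly 5 % of residues substituted (~95 %
identity, must co-cluster at 90 %); sites-per-kinase counts are log-normal
(median 18, σ = 0.9, clipped to [1, 200]) so kinases fall on both sides of
the 15-pair eligibility threshold; 10 % of sites get a second same-group
kinase label. Kinase embeddings scatter around group centres
(σ_within = 1, centre scale 4 in 16 dimensions) and site embeddings around
their kinase's embedding with noise σ_site — the recovery dial. A variant
maps sites through a fixed random linear map of the kinase embedding,
stressing the bilinear model beyond what cosine k-NN can express. Site
windows are random 15-mers; their content is deliberately uninformative,
so synthetic tests exercise the embedding pathway, not sequence biology.

The `noise_free_spec` preset (orthogonal group centres, zero within-group
spread, zero site noise) with a one-kinase-per-group holdout is a provable
oracle: every site embedding equals its group centre, the held-out kinase
of that group is the unique dark kinase at cosine 1, so both classifiers
must reach macro AP exactly 1.0, and performance must decay monotonically
toward the random baseline as σ_site grows. Passing these tests shows the
pipeline is wired correctly and recovers known structure; it says nothing
about absolute performance on real phosphoproteomes, where windows carry
motif signal, embeddings are not isotropic Gaussians, and annotation
incompleteness deflates measured AP.

## Numerical and engineering choices

* Pad character `_`; 1-based site positions; window index 8 of 15 holds
  the phosphorylated residue.
* Softmax is max-subtracted; AP rejects NaN scores; −∞ scores are legal
  and rank strictly last.
* Cross-entropy clamps probabilities at 1e-300 before the log; training
  aborts with diagnostics on non-finite loss.
* Identity is 1.0 for byte-identical sequences without running the
  aligner; the all-vs-all matrix is symmetric with unit diagonal and can
  be precomputed once and reused across split seeds.
* Problem sizes in the test suite (kinomes of ~50–70 kinases, 1–3 k
  pairs, 16-dimensional embeddings; 50 datasets × 3 seeds for the split
  audit) were chosen as the smallest scales at which every invariant is
  non-trivially exercised.

## Known limitations

* No isoform/fusion-kinase canonicalisation, no retrieval from external
  resources; inputs arrive as tables, and upstream curation is assumed.
* Exact nearest-neighbour search only; fine at benchmark scale
  (~10⁴–10⁵ training pairs) on one CPU.
* The packaged NLF stand-in is not the published descriptor table;
  absolute numbers obtained with it are not comparable to results using
  the genuine coefficients.
* Baseline kinase-domain vectors use position-averaged pooling; other
  conventions for encoding variable-length domains exist and would change
  baseline numbers.
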