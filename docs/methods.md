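# Methods

## Problem setting

`dlselex` models the two computational halves of a structure-guided SELEX
campaign for a family of related small molecules (the built-in synthetic
family emulates steroid-like targets: a shared fused four-ring carbon
scaffold with small substituent differences per class):

1. **Guided initial-library design (AptaVAE).** From a modest collection of
   published aptamer–target pairs — sequence, secondary structure, target
   chemistry, class, and a relative binding score in [0, 1] — learn a latent
   representation good enough to *generate* high-scoring sequences per
   target class, and collapse those generations into a library template of
   confined bases (fixed A/C/G/T) and free positions (N) flanked by primers.
2. **Pool summarization (AptaClux).** From the NGS read pools of early,
   middle, and late selection rounds, train a sequence+structure VAE and
   summarize the pool two ways: the consensus of the densest region of the
   latent space (high-density route, HD) and the consensus of decoded
   k-means cluster centers (cluster-consensus route, CC).

## Encodings

Sequences are one-hot encoded over A,C,G,T; secondary structures over
'(' , ')' , '.'. Structures come from a built-in Nussinov base-pair
maximizer (non-crossing pairs, hairpin loops ≥ 3, Watson–Crick by default
with an optional GT-wobble flag, deterministic 5'-preferring traceback);
externally predicted dot-brackets can be supplied through the sidecar
format wherever structures are consumed, so a thermodynamic folder remains
pluggable. Targets are parsed from organic-subset SMILES into heavy-atom
graphs; the target is represented by its topological distance matrix
(bond-count shortest paths — deterministic and conformer-free; a 3D backend
can be adapted in), its adjacency matrix, and a hashed circular (Morgan
style, radius 2, 2048 bits, fixed hashing seed) fingerprint. The "sandwich"
tensor stacks [distance | structure one-hot | adjacency] into a 3×S×S array
with S = max(atom count, sequence length) over the dataset.

Token embeddings for the co-attention are produced by a pluggable provider;
the built-in provider hashes 6-mer DNA tokens and SMILES characters to
seeded unit vectors, so the pipeline is deterministic and needs no
downloaded weights. The co-attention uses the modified attention

    modified_attention(Q, K, V) = softmax(Q K^T / sqrt(d_K)) V + Q / sqrt(d_Q)

with the target as query and the sequence as key and value; masked key
positions receive −∞ logits. The pooled (query-mean) context vector enters
the encoder, and the decoder reconstructs it (that reconstruction is the
attention loss — the self-reconstruction target is a declared choice, and
the term can be disabled).

## AptaVAE: loss and training

The composite loss is

    total  = sequence + target + class + 2·score + attention + matrix + KL
    matrix = α·distance + β·structure + (1−α−β)·adjacency,  α = 0.3, β = 0.4

with binary cross-entropy (predictions clipped to [1e−7, 1−1e−7]) for
sequence, target (fingerprint), class, structure, and adjacency; mean
squared error for score, attention, and distance; and the closed-form
diagonal-Gaussian KL −½·Σ(1 + log σ² − μ² − σ²). Per sample, each term is
summed over its tensor's elements and KL over latent dimensions, then
averaged over the batch: each data modality therefore contributes in
proportion to its size, which is what makes the information-theoretic
trade-off against the KL term meaningful at this data scale.

Distances are min–max normalized by the dataset-wide maximum before both
encoding and reconstruction, so the distance MSE lives on the same [0, 1]
scale as the other heads.

Architecture: two encoder branches — a 1D stream (sequence one-hot ⊕
fingerprint ⊕ class one-hot ⊕ score block) and the flattened sandwich
tensor — are mixed with the attention context into a 256-unit hidden layer
feeding 256-d μ and log σ² heads. The decoder mirrors this with one hidden
layer and per-modality heads (sigmoid everywhere except the attention
head). Skip connections carry the *3D-branch* features across the
bottleneck: their stated purpose is to counter the dilution of the sparse
sandwich tensor, and restricting them to that branch prevents the decoder
from bypassing the latent for the 1D stream entirely (an unrestricted skip
measurably collapses the latent). During training the skip is dropped with
probability 0.5 per sample so the decoder also functions in the generation
regime, where no encoder side exists and the skip is zero.

Training-stability choices, each of which proved necessary on 195-pair
data (all defaults in `ModelConfig`):

* **Score block (width 48).** The relative score enters and leaves the
  model as a repeated block rather than a lone scalar. A single element
  among ~6000 features is both swamped in the encoder input and too cheap
  to ignore in the reconstruction; the block gives the deliberately
  emphasized score term enough mass for the latent to encode score at all.
  The decoded score is the block mean.
* **KL warm-up (30 epochs) and tight log-variance initialization (−1).**
  Standard collapse guards: the decoder must see μ, not noise, before the
  KL term has anything to regularize. The logged loss components and
  totals always use the full weighting, so the loss identity is auditable
  at every epoch; only the optimized objective ramps.
* **Latent-mixup score regularization.** The score head is additionally
  trained on interpolants of two training codes: toward the λ-weighted
  score mean within a class and toward 0 across classes. Without it the
  score surface stays high along inter-class latent corridors that no data
  constrains, and sampling retains chimeric sequences.
* **Isotonic score recalibration.** After best-checkpoint restoration the
  raw decoded scores of the training pairs are monotonically recalibrated
  against the true scores. A VAE score head regresses toward the local
  mean, compressing the score range; the monotone map restores the scale
  without changing the learned ranking, which thresholded retention
  requires.
* **Anchor-preserving stratified validation split (20%).** Each class's
  top-score pair (the per-source reference aptamer, relative score 1 after
  normalization) always stays in the training partition: the generative
  pipeline depends on those anchors being fit, and at ~24 pairs per class
  losing one to the holdout is fatal for that class.
* Adam (1e−3), batch 16, up to 400 epochs with early stopping at patience
  120 on the validation total (validation is evaluated in the generation
  regime: z = μ, skip = 0), checkpoint = lowest validation loss after
  warm-up. The longer patience reflects the jagged validation trajectory
  at this data scale.

## Batch-generated analysis and library templating

BGA draws latent codes in batches, decodes them, and tracks per-batch and
cumulative mean score, score SD, and the proportion above the 0.9
threshold; the stream is declared steady once the relative change of all
three cumulative statistics stays below 1% over a 5-batch window. Retained
(score > 0.9) sequences are grouped by decoded class and sorted by score.

Sampling draws from the **aggregate posterior** — pick a training pair's
posterior uniformly and sample its diagonal Gaussian — rather than the
N(0, I) prior (available via `sample_prior=True`). In a 256-d latent space
the trained region carries essentially no standard-normal mass: prior
draws land far from every posterior, decode to uninformative blends, and
nothing passes the 0.9 threshold. "Sampling the trained latent space" is
implemented literally.

Per class, the retained sequences (top 60 by score) are aligned with the
built-in progressive aligner (UPGMA guide tree on edit distances,
profile–profile Needleman–Wunsch with match +1 / mismatch −1 / gap −2,
terminal gaps free, deterministic tie-breaks) and collapsed: columns with
gap fraction ≥ 0.5 are dropped; a kept column is confined to its modal
base when that base reaches 80% of non-gap entries, else N. The rendered
library is lowercase-forward-primer + template + lowercase-reverse-primer,
with confined positions listed in the FASTA header. MAFFT (or any external
aligner) can replace the built-in aligner through the FASTA interfaces.

## AptaClux

The pool VAE encodes each unique sequence as concatenated sequence +
structure one-hots, with a 32-d latent (a single-modality model needs far
less capacity than AptaVAE; the dimension is a config key), 128 hidden
units, and loss sequence + structure + KL with the same element-level
forms and reductions as AptaVAE. Unique sequences are deduplicated for
training; read counts re-enter downstream:

* **HD route.** Gaussian KDE (bandwidth 0.5) over the latent means,
  evaluated after PCA reduction to 8 dimensions (in raw 256-d-scale spaces
  a 0.5 bandwidth makes every kernel term vanish; `pca_dims=0` restores
  the raw space). The KDE is weighted by read counts — the density of the
  pool's *reads*, which is what encoding the raw read stream would give.
  The top 1% of sequences by density are aligned and collapsed to a
  consensus candidate by per-column plurality (gap-majority columns
  dropped; the collapse falls back to an all-column plurality rather than
  ever returning an empty candidate).
* **CC route.** k-means (k = 10, k-means++ with a fixed seed, Lloyd to
  tol 1e−6 / 300 iterations) over the same latent matrix, weighted by read
  counts so singleton background reads cannot claim clusters of their own.
  Cluster centers are decoded to sequences and aligned with each center
  replicated in proportion to its cluster's read mass — the consensus is
  then carried by where the pool's mass sits, not by however many sparse
  background clusters happen to exist — and collapsed to the
  cluster-consensus candidate. Per-cluster position×4 logo count matrices
  are emitted for plotting.

Both routes consume the identical latent matrix; its hash is recorded in
the output for provenance.

## Evaluation machinery and baselines

Candidates are scored by Levenshtein distance (edlib-backed) to a ground
truth and by feature-space centroid distance: flattened sequence+structure
one-hots, a single 2-component PCA fit on the union of all compared sets
(sign convention: each component's largest-magnitude loading is positive),
Euclidean distance between set centroids and the truth centroid. Matched
top-N views are compared (same N on both sides). The ranking harness
reports tie-corrected AUROC, step-interpolated AUPRC, and Top-1.
Conventional baselines: frequency ranking (count-descending, ties
lexicographic), depth-normalized round-over-round enrichment with
pseudocount 1, and greedy single-linkage clustering at edit radius 3
(declared, tunable) with largest-cluster and whole-library consensus.

## Synthetic data: what it does and does not emulate

`gen_pairs` emulates a literature-collected family dataset: 195 pairs over
8 classes, 40-nt sequences, one distinct 8–12-nt motif per class implanted
at a class-fixed position with probability equal to the pair's score.
Scores are Beta(2,2) plus N(0, 0.05) noise, clipped to [0,1] and then
min–max normalized per class — one synthetic "source table" per target,
mirroring how relative scores from heterogeneous publications are
normalized per source, which pins each class's best aptamer at exactly 1.
`simulate_selex` evolves a 2000-read pool by multinomial resampling with
selection weight count·exp(2.5·fitness), fitness = −(edit distance to a
planted binder)/length, followed by per-base mutation at 0.002 (a
PCR-error analogue, applied after resampling); the initial pool is random
background plus a 2% planted family of slightly diverged binder copies, so
an enrichable lineage exists from round zero. These choices reproduce the
qualitative phenomena the pipeline must handle — motif-linked scores,
round-wise enrichment, selection bias — with sharpness 2.5 chosen so that
the binder family holds roughly half the pool at round 3 and nearly all of
it by round 7.

What passing tests on this generator do **not** show: real aptamer scores
are noisy across assay types rather than cleanly motif-linked; real pools
carry sequencing artifacts, length variation, and primer remnants; real
binding involves structure in ways a planted-motif fitness cannot capture.
The synthetic results validate the machinery and its directional claims,
not wet-lab performance.

## Numerical choices and degenerate inputs

Probabilities are clipped at 1e−7 before any logarithm; logits in softmax
are max-shifted; log-variances are clipped to [−10, 10]. Argmax decoding
breaks ties toward the lexicographically first symbol. Decoded structure
strings that fail the balance check fall back to all-dots. Zero-variance
latent sets yield uniform KDE densities with a warning; rank-deficient PCA
inputs yield a zero second component with a warning. All stochastic stages
take explicit seeds; the CLI fans a single global seed out to per-stage
seeds through a recorded hash so every stage is independently
reproducible. Problem sizes used throughout the test suite and the
acceptance script — 195 training pairs, 2000-read pools, 150×64 BGA
samples — are the study-condition defaults stated above.

## Known limitations

* The two VAEs train on a small in-repo reverse-mode autodiff engine;
  training is single-threaded CPU numpy and scales to the hundreds-of-
  sequences regime this package targets, not to millions of reads.
* The built-in folder maximizes base pairs; it is not thermodynamic and
  ignores pseudoknots. Supply external structures for realistic folding.
* The built-in SMILES parser covers the organic subset without
  stereochemistry, charges, or isotopes; fingerprints are not
  bit-compatible with any external toolkit (by design — the backend is
  adaptable, the built-in is the reference).
* Decoded sequences have the model's trained length; variable-length
  generation is not attempted.
* The progressive aligner is accurate for the similar-sequence sets this
  pipeline produces; highly divergent random inputs align poorly (as they
  do under any aligner) and are handled by the mass-weighted consensus
  rather than by alignment quality.
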