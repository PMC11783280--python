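# Methods

This note documents the models, conventions and numerical choices behind
the toolkit, what the synthetic data generator does and does not emulate,
and the design decisions taken where more than one reasonable option
existed.

## RBP cataloguing

RBP candidacy is decided by case-insensitive regular expressions over gene
product annotations. The shipped rule file (`phistruct/data/rules.yaml`) is
a curated approximation of the RBP annotation vocabulary (tail fiber/fibre,
tailspike, receptor-binding protein, spike protein, …) with exclusions for
RBP-adjacent structural parts (adaptors, chaperones, assembly proteins,
hinges, …); it is fully user-overridable and the tests pin behavior to the
shipped file. Exclusion vetoes inclusion; records matching only a
"hypothetical"-style pattern are routed to a side channel for an external
RBP detector — this toolkit never guesses their status.

Length outliers are removed by Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
with quartiles computed by linear interpolation between order statistics
(the "type 7" convention); the fence endpoints are inclusive (a record
exactly on a fence is kept). Deduplication is exact-sequence identity with
first-occurrence survival; near-duplicate collapsing is left to identity
clustering at s = 1.

## Structure-aware tokens and masking

Tokens are pairs (r_i, f_i) of the amino-acid residue and a letter of an
opaque 20-letter lowercase structure alphabet (3Di-style; deriving it from
coordinates is a structure-search tool's job and out of scope). Per-residue
pLDDT lives on the 0–100 scale; inputs on 0–1 are auto-rescaled with a
logged notice. Masking replaces a channel with the sentinel `#`:
all residues, all structure letters, or structure letters at positions with
pLDDT strictly below the threshold (default 70 — "below 70" is read as
strict inequality; a residue at exactly 70 keeps its structure letter).
pLDDT is read from the B-factor column of the CA atom of each residue of a
predicted-structure PDB file; altloc duplicates keep the parser-selected
conformer with a warning, unknown residue names map to `X`.

## Sequence identity and leakage control

Identity between two sequences is

    identity(a, b) = max(0, S(a, b)) / min(|a|, |b|)

where S is the optimal global alignment score with match = 1, mismatch = 0
and a linear gap penalty of −0.5 per gap symbol. This convention is
uniquely defined (it is a score, not a count over one arbitrarily chosen
co-optimal alignment), symmetric, equals 1 exactly iff the sequences are
identical, and divides by the shorter length in the CD-HIT tradition. The
gap penalty matters: with free gaps the score degenerates to the longest
common subsequence, whose background ratio between *unrelated* random
protein sequences is ≈ 0.34 — dangerously close to the 0.4 threshold at
which splits are audited. With the −0.5 linear penalty the background is
≈ 0.13 (maximum ≈ 0.17 over 40 random length-200 pairs), leaving a wide
margin. An independent dynamic-programming oracle with the same scoring
backs the implementation in the tests.

Clustering is greedy-incremental: records in descending length order (ties
by id) join the first existing cluster whose representative they match at
identity ≥ s, else found a new cluster. Greedy clustering does not
transitively bound identity between members of *different* clusters, so
every split is auditable by `verify_no_leakage`, a brute-force scan of all
train × test pairs.

The split itself is representative-stratified: per genus, representatives
are shuffled (seeded) and ⌊0.7·n⌋ go to training; members inherit their
representative's side, so final member proportions can deviate from 70/30
(logged). A genus with fewer than two representatives goes entirely to
training with a warning. The outgroup sample is drawn uniformly without
replacement, sized to the smallest in-scope test class.

## SMOTE–Tomek

SMOTE draws a minority member x and one of its k = 5 (capped at class
size − 1) nearest same-class neighbors x_nn and emits x + u·(x_nn − x),
u ~ U[0, 1), until every class reaches the majority count. Tomek links are
mutual single nearest neighbors with different labels (Euclidean, distance
ties broken by lower index); one cleaning pass removes both members of each
link by default (`REMOVE_MAJORITY_ONLY` removes only the larger class's
member; after equalization class counts tie, and ties remove both).
Balancing is applied to the training set only, after splitting. A class
with a single training sample cannot be interpolated; `smote` treats it as
an error, and the pipeline leaves such a class unaugmented with a warning.

## Classifier

Architecture and training constants are fixed by the recipe: hidden layers
⌊L/8⌋ and ⌊L/16⌋ (minimum 1; L < 16 is rejected), ReLU, dropout 0.2 after
the first hidden layer only, softmax output; cross-entropy plus an L2
penalty λ·Σ‖W‖² (λ = 10⁻⁴, biases exempt); Adam with lr 10⁻³,
β = (0.9, 0.999), ε = 10⁻⁸ (the conventional constant; unstated in the
recipe), batch 128 with the last partial batch kept, 200 epochs, no early
stopping. Weights are He-uniform initialized (standard for ReLU; the
recipe does not specify initialization). All randomness — initialization,
epoch shuffles, dropout masks — derives from a single seeded generator, so
training is bit-reproducible. Inference disables dropout.

The implementation is plain numpy with hand-derived backpropagation;
analytic gradients agree with central finite differences to ~10⁻⁶ relative
error (asserted at 10⁻⁴ in the tests). A NaN/inf loss aborts with a
diagnostic pointing at the learning rate and input scale.

Grid search (`tune`) holds out a stratified 10% validation split, scores
each candidate by macro-F1 at k = 0, breaks ties toward the earlier grid
entry, and refits the winner on the full training set (validation
included) — the standard refit convention.

## Abstention and metrics

The decision rule emits the argmax genus iff p₁ − p₂ ≥ k (with 10⁻¹²
slack so exact margins survive floating point); argmax ties take the
earlier class in declared order. The accounting rules are listed in the
`evalkit` module docstring; the two that are genuinely a choice:

- **Abstention on an in-scope sample is an FN for its true class and an FP
  for nothing.** This is the only accounting under which lowering k
  prioritizes recall and raising k prioritizes precision, which is the
  point of the parameterization.
- **N and n_c count in-scope samples only** by default; outgroup records
  contribute solely through FPs. `count_outgroup_in_n=True` restores the
  alternative reading. TN is recorded (non-abstained samples touching the
  class neither as truth nor as decision) but used by no reported metric.

Per-class terms with zero denominators contribute 0 (the scikit-learn
convention). Confusion matrices carry an OUTGROUP truth rim and an ABSTAIN
decision rim; row normalization makes the in-scope diagonal the per-class
recall, column normalization the per-class precision.

## Paired-distance analysis

For a genus g, within pairs (both RBPs target g) and cross pairs (exactly
one does) are sampled uniformly without replacement from the sets of pairs
whose sequence identity is below the cap (default 0.40), by walking a
seeded random permutation of the candidate pairs — equivalent to uniform
sampling of the eligible set without materializing it. An RBP may appear
in several pairs (`forbid_reuse=True` disallows it). Distances are cosine
(1 − u·v/‖u‖‖v‖) between embeddings or externally supplied per-pair values
(e.g. structural RMSDs from a TSV), making the test machinery
distance-agnostic.

The Mann–Whitney U test uses midranks, the standard tie-corrected variance,
and a two-sided normal approximation with 0.5 continuity correction —
accurate at the group sizes used here (hundreds); exact small-sample
p-values are out of scope. U_A is the conventional #{a > b} + ½·ties, so
U_A + U_B = n_A·n_B identically. Degenerate pooled samples (all values
tied) return p = 1.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure each stage relies on:

- **Sequences** grow from random ancestors in two-level families: subfamily
  founders diverge from the family founder at rate 0.3 (held by seeded
  rejection sampling in a mid identity band ≈ 0.45–0.56), members scatter
  tightly around their founder (rates ≤ 0.02), and families are independent.
  This yields three well-separated identity bands — ≈ 0.95 within
  subfamilies, ≈ 0.5 across subfamilies, ≈ 0.13 across families — that
  straddle the audited thresholds {0.4, 0.6, 0.8} without sitting on them,
  the regime in which greedy clustering resolves coherent groups. Members
  are kept sequence-unique, emulating a deduplicated catalog. Lengths are
  normal around a median of 550 aa (clipped to [150, 2000]), echoing
  typical RBP length distributions.
- **Confidence profiles**: per-protein mean pLDDT from a clipped normal
  (default 80 ± 5, the range typical of predicted RBP structures),
  per-residue values scattered around it (± 8) and rounded to the PDB
  B-factor precision so toy CA-only PDB files round-trip exactly.
- **Embeddings**: genus centers are random directions scaled so pairwise
  center distance ≈ `center_separation` (default 10) with isotropic
  within-genus noise σ = 1 at L = 1280. At this separation the genus
  clusters are cleanly separable (nearest-centroid Bayes error ≈ Φ(−5)) —
  the synthetic analogue of embeddings that form visible per-genus
  clusters — while `center_separation = 0` gives an exact null. Per-record
  noise is seeded from (global seed, CRC32 of the protein id), so
  embeddings are independent of processing order. A shift proportional to
  the masked-token fraction makes masking strategies measurably move
  embeddings.

What passing tests on these data show: the pipeline's machinery —
filtering, clustering, splitting, balancing, optimization, metrics, the
statistical test — behaves exactly as specified under controlled, favorable
geometry. What they do not show: performance on real RBPs, whose embedding
geometry, class overlap and family structure are far messier; absolute
scores on synthetic data are not comparable to scores on real data.

## Problem sizes

Defaults in the test-suite and acceptance script are desk-scale, chosen so
the full loop runs in seconds to minutes on one CPU core: leakage audits on
~39-protein catalogs (length ≈ 150) over four thresholds and many seeds;
classifier recovery at the full L = 1280 with 100 training / 30 test
proteins per genus; Mann-Whitney calibration at 500 per group over 1000
null replicates; the end-to-end determinism check at L = 256 with 8
proteins per genus. Every size is a parameter, and all of them scale up
unchanged.

## Known limitations

- The embedder contract ships with only the synthetic backend; adapters
  for real structure-aware language models are user-supplied.
- Greedy clustering approximates, but does not reproduce, CD-HIT's exact
  cluster boundaries (word-size heuristics and banded alignment differ);
  the leakage audit, not the clustering, is the guarantee.
- The annotation rule file is a documented approximation of the published
  RBP annotation vocabulary, not a claim of equivalence to any specific
  prior rule set.
- Exact Mann-Whitney p-values for small groups are not implemented.
- The structure channel's 3Di-style strings are random; they exercise
  formats and masking, not structural signal.
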