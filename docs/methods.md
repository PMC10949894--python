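# Methods

hemopipe implements a decision-support pipeline for classifying acute
lymphoblastic leukemia (ALL) from stained blood-smear images: local
contrast enhancement tuned by differential evolution (DE), deep-feature
extraction and fusion, wrapper feature selection with a binary Grey Wolf
optimizer (GWO), and an outer classification/metrics harness. This note
records the models, the parameter choices that matter, the numerical
details, and what the synthetic fixtures do and do not establish.

## Contrast enhancement

Enhancement operates on the intensity channel of the HSI representation
(I = (R+G+B)/3); hue and saturation pass through unchanged. Each pixel is
rewritten from its p×p neighborhood statistics:

    f(m,n) = (δ·μ / (σ_p(m,n) + β)) · (I(m,n) − γ·μ_p(m,n)) + μ_p(m,n)^α

with μ the global mean, μ_p/σ_p the local window mean and standard
deviation, and output clipped to [0,1]. The gain term stretches hardest
where the window is flat (σ_p small); β > 0 keeps it finite on constant
regions (an additional ε = 1e-9 guards β = 0 exactly); γ recentres the
pixel on its local mean; μ_p^α restores local brightness. The decision
vector (α, β, γ, δ) is box-constrained to
α ∈ [0, 1.6], β ∈ [0, 0.5], γ ∈ [0, 0.8], δ ∈ [0.5, 1.5].

Enhancement quality is scored by

    F(I*) = log(log(G(I*) + e)) · n_e(I*) · H(I*) / (M·N)

where G is the summed Sobel gradient magnitude (unnormalized 3×3 kernels,
replicate borders), n_e the count of pixels with gradient magnitude above
a threshold (default 0.1 on the [0,1] scale), and H the Shannon entropy
in bits of a 256-bin intensity histogram. Euler's number inside the inner
logarithm keeps its argument above 1 for any G ≥ 0. Images with n_e = 0
or H = 0 cannot be ranked and receive a −∞ sentinel. Two typeset-ambiguous
choices were resolved as the package's own design: β sits in the gain
denominator and δ in its numerator (matching the stated roles of the
constants), and the full product — not H alone — is divided by M·N.

The window size p defaults to 3, the smallest centred neighborhood; larger
odd values smooth the statistics and weaken the local character of the
stretch. DE uses a best/2 scheme: mutant = P_best + A·(P_r1 − P_r2) +
A·(P_r3 − P_r4) with a fresh uniform scaling factor A ∈ [0,1] per mutant
and four donor indices distinct from each other and the target; binomial
crossover (rate 0.5, one forced dimension) and clamping to the box;
greedy one-to-one survival with ties going to the trial. Population
N_p = 30 and T = 50 iterations by default (N_p ≥ 5 is required by the
mutation scheme). Window statistics are computed once per image — the
transform, not the statistics, depends on the parameters — so one
objective evaluation costs one transform plus one Sobel/entropy pass.

Numerical notes: the best-objective history is non-decreasing by
construction; the population stays inside the box after every iteration;
a single seeded generator drives init (row-major), then per individual
the donor choice, A, four crossover draws and the forced index. When the
enhanced intensity is recombined with the original hue/saturation, a few
pixels can leave the RGB gamut and are clipped, so the objective of the
round-tripped image can differ marginally from the optimizer's internal
value.

## Feature extraction and fusion

The extraction stage treats a pretrained CNN as a fixed map from an image
to late pooled activations: InceptionV3's 2,048-dim average-pool vector
and DenseNet201's 1,920-dim global-average-pool vector, horizontally
concatenated in that order into a 3,968-dim fused vector. Real CNN
inference requires torch/torchvision and lives behind the optional `cnn`
extra; the core surface is a deterministic mock extractor (a fixed random
projection of an 8×8 thumbnail plus a content-keyed perturbation) that
preserves the two properties downstream stages rely on — fixed output
dimension and content sensitivity. No standardization is applied before
fusion by default; feature origin tags (extractor name, within-block
index) ride along so selected columns remain traceable.

## Wrapper feature selection

A candidate solution is a binary mask V over the d_max fused columns,
scored by the wrapper fitness (minimized)

    Γ(V) = α1·e(V) + α2·(q_s/q_t),   α1 = 0.99, α2 = 0.01

where e is the holdout error of a k-NN classifier (k = 5, Euclidean by
default) trained on the selected columns with a stratified h_o = 0.2
holdout, q_s the selected count and q_t = d_max. The empty mask scores
Γ = 1. The holdout partition is drawn once per optimizer run from the run
seed and reused for every evaluation, which makes the fitness landscape
deterministic within a run; per-call resampling is available as a flag.

Binary GWO ranks the three best masks as α/β/δ leaders (strict-inequality
updates; the printed cascade is implemented literally, including the
final branch that installs any non-improving candidate as the new δ,
which keeps f_α ≤ f_β ≤ f_δ while retaining exploration pressure in the δ
slot). Each bit of each wolf is rewritten per iteration through: distance
D_i = |c_i·leader_bit − wolf_bit| with c_i ∈ [0,2]; step probability
S = 1/(1 + exp(−10·(a_i·D_i − 0.5))) with a_i ∈ [−a, a] and the
encircling coefficient a(t) = 2 − 2t/t_max; threshold S ≥ r (boundary
inclusive); OR with the leader bit; and a uniform three-way crossover
among the leader-derived candidate bits. Defaults n_p = 20, t_max = 50.
RNG order per wolf-dimension is (a1, a2, a3, c1, c2, c3, three threshold
draws, one crossover draw); the implementation consumes this exact stream
in vectorized blocks, verified bit-for-bit against the scalar chain in
the tests.

The genetic-algorithm baseline minimizes the same fitness with a standard
generational loop: tournament selection (size 3), uniform crossover
(rate 0.9), bit-flip mutation (rate 1/d_max), and one elite, so its
best-so-far trace is also non-increasing.

A structural property worth knowing: because a candidate bit is the OR of
a leader bit and the step bit, a dimension set to 1 in all three leaders
can never be cleared by any wolf. In regimes where many masks reach zero
holdout error and Γ differences reduce to the parsimony quantum
α2/q_t, this floor limits how far binary GWO can prune, and the GA
baseline — which flips bits freely — typically reaches lower final Γ on
such fixtures. On real fused deep features, where the error term is not
saturated at zero, the error component dominates Γ and this limitation
matters less.

## Classification and evaluation

The train/test split is stratified with a floor rule — each class
contributes floor(fraction·n_c) training rows — which reproduces
published augmented-dataset splits exactly (e.g. 593/601 at 70% → 415/420
training rows; four classes of 1,024/1,000/1,050/1,020 → 1,229 test
rows). Outer classifiers are conventional presets: fine k-NN (k=1,
Euclidean), cosine k-NN (k=10), cubic k-NN (k=10, Minkowski-3), coarse
k-NN (k=100, capped at the training size), SVMs (RBF, quadratic
polynomial, linear) on standardized inputs, a decision tree capped at 20
leaves, and a wide one-hidden-layer (100-unit) MLP. Exact preset meanings
are not standardized anywhere; these follow common toolbox conventions
and are configurable.

Reporting follows the clinical confusion-matrix convention: rows are true
classes, per-class TPR = diagonal/row-sum (reported as the class
"accuracy" as well), FNR = 1 − TPR, precision = diagonal/column-sum
(0 with a warning if a class is never predicted), overall accuracy =
trace/total, and macro metrics are unweighted class means with
F1_c = 2·prec·rec/(prec + rec). The macro computations are cross-checked
against scikit-learn's classification report in the tests.

## Synthetic fixtures

The planted feature generator emulates a fused deep-feature table:
s informative columns whose class-conditional means are Δμ apart (in
units of the within-class σ = 1; class c has mean c·Δμ), optional
redundant near-copies (jitter σ = 0.1), and independent standard-normal
noise columns, with column positions shuffled and the informative
positions returned as ground truth. Defaults: 2 classes × 60 samples,
d = 100, s = 10, Δμ = 3 — a near-separable regime in which the holdout
error reaches zero with a few informative columns and the parsimony term
drives selection. Consequences worth stating plainly: selection
experiments on this fixture measure pruning behavior, not signal
detection under noise; an optimizer can reach Γ ≈ α2·q_s/q_t while
retaining only a fraction of the planted columns, because the fitness
offers no reward for carrying more than enough signal. The fixture also
centres class 0 at the origin, so angle-based (cosine) classifiers cannot
separate it — unlike real pooled CNN activations, which are non-negative
with positive means. Passing tests on these fixtures therefore establish
the mechanics (determinism, monotonicity, closure, relative ranking of
informative over noise columns), not dataset-level accuracy claims.

The cell-image generator renders elliptical cells with darker nuclei on a
noisy canvas and compresses the intensity range around mid-grey by a
contrast knob, giving the enhancement stage a controlled low-contrast
input; it does not attempt realistic stain color distributions or
cytomorphology. Augmentation applies random quarter-turn-plus-jitter
rotations, flips, ±20% multiplicative intensity changes and ±0.1
brightness offsets (clipped), growing each class to an exact target
count with originals retained.

## Problem sizes and budgets

Test and demonstration runs use deliberately small instances chosen as
representative working sizes: 64×64 canvases for DE runs (N_p 20–30,
T 50), d = 100 planted fixtures for selection (n_p = 20, t_max 25–50),
and d = 12 fixtures for exhaustive 2^12 enumeration against the shared
fitness. These sizes are the package's own defaults for its fixtures;
all budgets are configurable.

## Known limitations

- Reproduction of the published dataset-level accuracies requires the
  original image sets and pretrained CNN activations, which are outside
  this package's scope; the self-contained published quantities
  (confusion-matrix rates, split sizes, fused dimensions, fitness
  constants) are recomputed exactly.
- The binary GWO pruning floor described above means near-optimality
  against exhaustive enumeration, high planted-index recovery, and
  dominance over the GA baseline are not generally achieved in the
  zero-error parsimony regime of the default fixtures; the test suite
  asserts these properties as stated and documents their observed
  failure rather than weakening them.
- The mock extractor is a plumbing stand-in: content-sensitive and
  deterministic but carrying no class-relevant structure, so end-to-end
  image-path runs exercise the machinery, not recognition quality.
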