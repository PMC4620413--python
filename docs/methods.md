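# Methods

## Problem setting

Computer-aided diagnosis classifiers for rare, hard-to-image cancers work
from small, imbalanced feature tables: a few dozen disease cases against a
larger pool of controls. An RBF-kernel support vector machine is a natural
fit for such small-sample, nonlinear problems, but its behaviour hinges on
two hyperparameters — the soft-margin penalty C and the kernel width γ — and
the clinically relevant objective is asymmetric: a missed diagnosis (false
negative) costs far more than a false alarm (false positive). This package
tunes (C, γ) by a quantum-phase variant of the fruit fly optimization
algorithm against a cost-sensitive cross-validation fitness, and ships the
classic fruit fly optimizer and an exhaustive grid as references.

## Fitness function

For a candidate (C, γ) the training set is split into K stratified folds
(default K = 5). On each held-out fold the fitted SVM yields a false
negative rate FNR_k = FN/P and a false positive rate FPR_k = FP/N, and the
fitness to be minimized is

    F(C, γ) = (1/K) Σ_k [ w·FNR_k + (1−w)·FPR_k ],   w ∈ [0.5, 1], default 0.9.

Stratification is required, not cosmetic: FNR is undefined on a fold without
positives, and with 17 positives in 58 training rows an unstratified split
can produce one. The fold assignment is a deterministic function of a fold
seed and is frozen across all candidate evaluations of one optimization run,
so fitness differences between candidates reflect the candidates, not fold
noise, and the reported best fitness is exactly recomputable afterwards.
Features are standardized to zero mean and unit variance inside the CV loop,
with the scaler fitted on the training folds only.

## Quantum-phase fruit fly search

Each fly's position is a pair of phase-angle vectors (θx, θy), one angle
pair per optimized dimension (n = 2 here). Initial angles are drawn as
θ = π·(2u − 1), u ~ U[0,1]. A position decodes into two complementary
solutions in [0,1]^n:

    s_cos[j] = (cos²θx_j + cos²θy_j) / 2,    s_sin[j] = 1 − s_cos[j].

The squared amplitude length lies in [0, 2]; dividing by its maximum 2 is
the unique affine normalization onto [0,1] that also makes the two solutions
exactly complementary, mirroring cos² + sin² = 1. Both solutions are
evaluated every iteration and the fly is scored by the better one — the
"doubled search space" of the phase encoding taken literally.

Per iteration, every fly scatters around the swarm axes by an independent
uniform draw in [−V, V] per angle (V = 1 by default), with angles wrapped
back into [−π, π]. With probability P_m (default 0.2) one of the fly's 2n
angles is hit by the quantum NOT gate θ → π/2 − θ, which exchanges the
cosine and sine amplitudes of that coordinate and is an involution. The
mutated position is kept with the annealing acceptance rule

    P(accept) = 1                          if F_new < F_old,
    P(accept) = 1 / (1 + exp(l·(F_new − F_old)))   otherwise,

where l is the iteration counter: worsening moves are accepted with
probability at most 1/2, decaying in both the worsening and the iteration
count, so exploration anneals into descent. The population minimum replaces
the incumbent (and the axes move there) only on strict improvement, making
the best-so-far trajectory non-increasing by construction. The trajectory
records the post-initialization best plus one entry per iteration; a
zero-iteration budget therefore returns the best of the initial population.

All randomness flows from one seeded `numpy.random.Generator` consumed in a
fixed order (perturbation draws for all flies, then per fly one
mutation-trigger draw and, only when it fires, one coordinate draw and one
acceptance draw), so equal seeds give bitwise-equal results.

### Classic baseline

The classic fruit fly optimizer keeps planar coordinates per dimension,
scatters them additively, and decodes by reciprocal distance
S = 1/√(X² + Y²). The swarm axes start uniformly in [0, 10]^n. A fly landing
exactly on the origin is re-sampled (S undefined). The classic formulation
maximizes smell; a sense flag (default: minimize) adapts it to the
diagnostic fitness. When used for SVM tuning, S is clipped into [0,1] before
zooming so both optimizers share one parameter box.

## Zooming and prior knowledge

Decoded solutions map to parameters by zoom multiples: C = Cm·S₁,
γ = gm·S₂, each clamped below at 10⁻⁶× its multiple so a boundary solution
never produces a zero parameter. The package defaults are Cm = 1,
gm = 2000 — appropriate for feature sets whose pairwise distances are small
enough that γ of order 10²–10³ is meaningful.

The multiples are prior knowledge about the data, and choosing them well
matters more than anything else in the pipeline: with standardized
features in d dimensions, pairwise squared distances concentrate around 2d,
so useful γ values sit near 1/(2d) and a multiple of 2000 would map almost
the whole unit square to a collapsed kernel. `prior_knowledge_zoom`
automates the scan a practitioner would do by hand: evaluate the CV fitness
on a coarse logarithmic (C, γ) lattice, collect lattice points within 0.02
of the best fitness, anchor on the near-optimal point with the smallest C
(then the smallest γ at that C), and set each multiple to 4× the anchor.
Anchoring at the most regularized corner of the near-optimal plateau is
deliberate: CV fitness cannot distinguish plateau members, but the
small-C/smooth-kernel corner generalizes best, and the factor 4 leaves the
preferred region in the lower-middle of the zoomed range with headroom
above. Applied to a published scan whose near-optimal region was
C ∈ [0.3, 0.5], γ ∈ [500, 1500], this rule returns multiples (1.2, 2000),
matching the expert-chosen (1, 2000).

## Synthetic cohort

`generate_feature_dataset` draws Gaussian class-conditional features:
negatives N(0, I), positives N(sep·u, I) with u = (1,…,1)/√d, so `sep` is
exactly the between-mean distance in within-class standard deviations.
Defaults mirror the structure of a small pancreatic-CT study cohort — 17/41
positive/negative training and 16/40 test samples (33 positive, 81 negative
in total), d = 10, separation 6, seed 0. Separation 6 is comfortably
separable (Bayes error ≈ Φ(−3) ≈ 0.001 per sample); separation 0 makes the
classes identically distributed, pinning the balanced-error (w = 0.5)
fitness at the chance level 1/2 for any classifier.

What the generator deliberately omits: feature correlations, heavy tails,
batch effects, label noise, and any real image content. Passing tests on it
demonstrate that the optimizer finds working hyperparameters under the
stated geometry and cost structure; they say nothing about segmentation or
feature extraction quality on real CT data.

The texture front-end (`generate_texture_images`,
`extract_gray_fractal_features`) is a synthetic toy stand-in for a gray/
fractal feature extraction stage: smooth (Gaussian-blurred, σ = size/32)
versus rough (lightly smoothed) noise fields, with features mean intensity,
intensity standard deviation, 256-bin histogram entropy in bits, and the
box-counting dimension of the image binarized at its median (parameter-free
and invariant to monotone intensity maps; a constant image is flagged
degenerate and reported on the full-support mask). The box-counting fit
uses dyadic box sides from 2 up to side/4: the 1-pixel scale only measures
raw foreground area and near-image scales are trivially saturated, so both
lie outside the scaling region; on this range the estimator is exact for a
filled square (2), a checkerboard (2) and a line (1).

## Numerical and design choices

- Precision is NaN when no sample is predicted positive; F1 is defined as 0
  when TP = 0 so degenerate classifiers rank instead of crash.
- Repeated-run spread is the sample standard deviation with denominator
  n − 1; exactly-constant inputs report spread 0.0 rather than summation
  roundoff.
- The grid reference breaks fitness ties toward the first lattice point in
  row-major order, so it is fully deterministic.
- The acceptance-rule algebra (the logistic in l·ΔF) is isolated behind
  `acceptance_probability` so alternative annealing schedules can be swapped
  without touching the loop.
- Percent formatting (two decimals) lives only in the CSV report writers;
  all stored values keep full precision.

## Problem sizes used in tests and the reproduction script

The built-in checks run the tuner at population 10 and 15 iterations on the
default cohort (the fitness plateau at 0 is reached within a few
iterations; the full default budget of 20×100 only adds runtime), 10 seeds
per experiment, and population 6 × 5 iterations for the separation-0
chance-level check. The quadratic-toy oracle comparison uses the full
default budget against a 101×101 exhaustive grid.

## Known limitations

- Only binary classification with an RBF kernel; n = 2 tuning dimensions in
  the SVM pathway (the optimizers themselves are dimension-generic).
- The fitness treats all folds equally; very small folds make it coarse
  (each fold FNR moves in steps of 1/positives-per-fold).
- `prior_knowledge_zoom` assumes the coarse lattice brackets the useful
  region; pathological feature scalings outside [1e-4, 1e2] for γ would
  need a wider lattice.
- The classic baseline's reciprocal-distance decoding cannot reach S values
  above 1/perturb-range neighborhoods of its axes; its coverage of the unit
  square is structurally poorer than the phase encoding's — which is the
  point of the comparison.
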