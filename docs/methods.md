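# Methods

This note records the modelling assumptions, default parameters and known
limitations of the package, in the order the pipeline runs.

## Synthetic ground truth

**Clinical cohort.** The default truth is a seven-node discrete Bayesian
network: six binary prognostic indicators — histological grade, tumor
stage, diagnosis age, tumor size, examined lymph-node count, positive
lymph-node count, each coded low/high risk — all pointing into a binary
survival status, plus one predictor–predictor edge
tumor stage → positive lymph nodes (P(high | late stage) = 0.8 vs 0.2),
so skeleton discovery faces at least one non-trivial conditioning case.
The outcome follows a risk-burden response: P(death | k adverse factors) =
(0.02, 0.05, 0.15, 0.85, 0.95, 0.98, 0.98) for k = 0…6, i.e. mortality
rises steeply once about three adverse factors accumulate. This shape was
chosen deliberately: a near-additive response makes each parent's
*conditional* information barely exceed its *marginal* information, in
which case a penalized greedy search will prefer the cheap outward
orientation of outcome edges and the collider structure is unrecoverable
in expectation, regardless of sample size noise. A thresholded response
gives each parent far more conditional than marginal information — the
signal structure learning actually exploits — while remaining a plausible
stylization of multi-factor clinical risk.

An extended sixteen-variable catalog adds ten independent nuisance
variables (gender, marital status, location, affected side, pathological
type, transfer, diffusion, lymph-node accumulation, operation type,
radiotherapy; two or three levels each) so the screening stage has
something to reject.

**Continuous variables.** Diagnosis age, tumor size and the two
lymph-node counts are emitted continuously by sampling the discrete level
first and then drawing uniformly *strictly inside* that level's interval
(age 35–85 years, size 0.5–8.5 cm, examined nodes 0–40, positive nodes
0–20; two levels each in the truth). The equidistant discretization is
therefore exactly invertible, which turns "discretization recovers the
generating level for every row" into a crisp test. Where no generator
interval spec exists, the catalog default is r = 4 equal intervals.

**Phantoms.** Lesions are ellipsoids on a constant background (lesion
190, background 70 on the 8-bit scale) with optional additive Gaussian
noise, voxel centers at (index + 0.5)·spacing. The analytic truth is the
longest in-plane diameter 2·max(a_row, a_col) and volume (4/3)πabc. No
anatomical realism is attempted: passing tests show that the measurement
chain is geometrically correct, not that it would segment real CT.

**Follow-up.** Event times are exponential per arm (default medians
ln 2/λ of 7.1 months for the model-guided arm and 4.8 for control, the
magnitudes a two-arm NSCLC maintenance comparison would show) with
administrative censoring at 18 months. Real PFS is not exponential; the
generator only supports parameter-recovery and direction-of-effect tests.

## Feature selection

Chi-square screening uses Pearson's test without continuity correction
(tables are generally larger than 2×2; Yates is a flag), continuous
variables pre-binned with their equidistant spec. The logistic filter is
a joint maximum-likelihood fit (Newton/IRLS, tolerance 1e-8, ≤ 100
iterations); single-degree-of-freedom variables report B, SE, Wald p,
exp(B) and the Wald 95% interval exp(B ± 1.96·SE); categorical variables
with more than two levels are dummy-coded against the first level and
tested by a likelihood-ratio test. Retention threshold p < 0.05 at both
stages. Perfect single-column separation raises an error naming the
column; non-convergence flags the result rather than silently retaining
variables. Rows with missing entries are dropped with a logged count.

The equidistant rule maps x to level j when
X_min + j·d < x ≤ X_min + (j+1)·d (d = (X_max − X_min)/r), with the
minimum assigned level 0; a 1e-9·d guard absorbs floating-point boundary
error.

## Structure learning

Defaults: significance level α = 0.05, maximum conditioning-set size
maxk = 3, BIC score (BDeu with equivalent sample size 10 as option),
Laplace pseudocount 1 for CPTs. Zero-count cells contribute 0 to the G²
sum and empty strata do not reduce degrees of freedom (documented
simplification). A test whose sample-per-degree-of-freedom ratio falls
below 5 is treated as uninformative during MMPC (standard small-sample
guard). Ties everywhere break lexicographically by variable name, making
every stage order-invariant up to the documented tie-break. Hill-climbing
caches node scores per parent set, forbids cycles, restricts additions to
the skeleton, and accepts only strictly improving moves; the move log is
exposed so the strict-increase property is testable.

Two caveats, both verified in tests and worth knowing:

- *Faithfulness.* MMPC admits a variable only if it is marginally (or
  low-order conditionally) dependent on the target. A parity-like
  collider (T = A xor B) is marginally independent of each parent and is
  invisible to any constraint- or score-based learner; recovery fixtures
  therefore use noisy-OR effects.
- *Type-I behaviour.* Each pairwise test has exactly level α, so with
  five candidate variables a null dataset still has a ≈ 23% chance that
  some CPC is non-empty. The null test asserts the per-candidate
  false-admission rate, not familywise emptiness.

Orientation of score-equivalent edges is reported as learned; equivalence
classes (CPDAG via v-structures plus the Meek rules) are used only for
comparison, with the structural Hamming distance counting per-pair
mismatches of edge presence/direction/reversibility. Greedy search can
rarely (about one seed in ten at n = 5000) lock into a local optimum in
which the outcome is oriented as a root; this is an inherent property of
single-restart hill-climbing, not of the scoring.

Exact inference enumerates the unobserved configurations of the
factorization — tractable for the ≤ 16-node networks in scope — with
posterior ties broken toward the lowest level and flagged.

## Image pipeline

- **Wiener filter:** adaptive local-statistics form; noise variance
  estimated as the mean local variance; window 5 default.
- **Fuzzy enhancement:** the intensification operator around a crossover
  membership (default mid-gray). Note it *compresses* values near the
  extremes, so the global standard deviation can decrease for images
  concentrated near 0 or 255; what it reliably increases is the
  separation of classes straddling the crossover, and that is what is
  tested.
- **GLCM texture:** re-quantization to `levels` bins (default 8),
  symmetrized and normalized. Two algebraic forms of the features are
  provided: the `standard` contrast ΣΣ(i−j)²p, marginal mean ΣΣ i·p and
  entropy −ΣΣ p·log₂p (bits), and a `printed` variant (ΣΣ(i−j)p²,
  ΣΣp/(M·N), ΣΣ(i−j)p·log₁₀p) kept for fidelity; the printed inertia and
  entropy cancel identically on symmetric matrices, which is why
  `standard` is the default.
- **Fractal dimension:** differential box counting with non-overlapping
  s×s blocks (2 < s < N/2), gray-box height h = s·G/N with G = 256,
  n_r = l − k + 1 per block, scale ratio r = s/N, FD fitted as the
  log N_r vs log(1/r) slope over the scale set {4, 8, 16} by default.
  A constant image gives FD = 2 exactly; fractional Brownian fixtures
  check the FD ≈ 3 − H ordering (direction only).
- **Pixel classifier:** one sigmoid hidden layer, one sigmoid output
  unit thresholded at 0.5, squared-error objective E = ½Σ(V−T)²,
  per-sample (online) gradient descent in a seeded shuffled order,
  learning rate 0.5 default. The update equations carry no bias terms in
  their plainest reading; a constant-one augmented input per layer
  supplies the biases without changing the update rule's form. The hidden
  width must lie between the rounded mean of the input/output widths and
  the overfitting bound N_s/(α(N_i+N_o)), α = 5 (middle of the accepted
  2–10 range). Features per pixel: normalized intensity, local mean,
  local standard deviation, a local two-bin entropy texture channel and a
  local gray-span roughness channel (radius 2). Whether a clinical
  implementation would feed raw pixels or such derived channels is an
  open reading; the feature-based default is flagged here.
- **Measurement:** largest connected component (8-connectivity in 2-D,
  26 in 3-D); longest in-plane diameter as the maximum pairwise distance
  between boundary-pixel centers within the best slice; volume as voxel
  count × voxel volume. Volume changes are reported to 0.1 cm³; the
  aerated-lung surrogate reports post − pre of normal-lung volume as the
  tumor-reduction equivalent.

## Efficacy

CR requires all target lesions undetectable and sustained ≥ 4 weeks;
PD is any new lesion or a follow-up sum ≥ 1.20× baseline (inclusive);
PR is a reduction of strictly more than 30% under the default dialect
(`recist11` switches to the standard inclusive ≥ 30%); SD otherwise;
precedence CR → PD → PR → SD. ORR and DCR are reported to 0.1%.
Kaplan–Meier estimation is delegated to lifelines, with the median at the
earliest time the curve reaches 0.5 and flagged undefined when it never
does. Group DCRs are compared by Pearson chi-square (Yates optional).
A plain chi-square on 18/20 vs 15/20 disease control gives p ≈ 0.21 —
the package reports its computed p-value and makes no significance claim
at that sample size.

## Pipeline

One seed drives all stages through spawned seed sequences; rerunning a
config reproduces byte-identical tabular artifacts. Validation patients
are assigned to the model-guided arm when the predicted survival
posterior favors survival (P ≥ 0.5) — the assignment rule is a package
choice, as is the training-cohort default of n = 2000 (a plausible
five-year single-centre lung-cancer database) and the validation default
of n = 40 split into two arms. Arm-level effect sizes (response-category
probabilities and PFS medians) live in the config; setting both arms
equal yields a null run, used by the no-systematic-advantage test.
Phantom segmentation in the pipeline trains on 1 200 balanced pixels for
30 epochs, sizes chosen to keep a full run around a second on one CPU
while leaving the separable problem easily solvable. Directional
single-seed checks use a 400-patient validation cohort so the per-arm
rates are stable; distributional checks (type-I, null-effect) run 20–30
seeds at reduced cohort sizes.

## Known limitations

- The generator's dependence structures are small and binary-dominant;
  nothing here speaks to high-dimensional or continuous-Gaussian
  networks, which are out of scope.
- Exhaustive MinAssoc subsets are exponential in maxk; maxk = 3 keeps the
  search exact and fast at this scale but is not suitable for large
  conditioning neighborhoods.
- Single-restart hill-climbing can return a score-local optimum (see
  above); multi-restart or tabu search is deliberately not implemented.
- The phantom pipeline measures geometry on synthetic ellipsoids; Dice
  and diameter results do not transfer to real CT without registration,
  intensity calibration and anatomical variability, none of which are
  modelled.
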