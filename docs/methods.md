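# Methods

## The task and its simulator

The Wisconsin Card Sorting Test (WCST) asks a participant to sort stimulus
cards, varying in color, form, and number, onto four fixed key piles (one
red triangle, two green stars, three yellow crosses, four blue circles).
The examiner holds a hidden sorting rule, answers "right"/"wrong" after
each sort, silently advances the rule after 10 consecutive correct sorts,
and discontinues the test after 6 completed categories or when the deck
(two identical 64-card full-factorial decks, 128 cards) runs out.

The simulator reproduces this protocol exactly. Because the four key cards
pairwise differ on every dimension, each attribute value of any card
matches exactly one pile; this property makes the model's choice rule
normalize automatically and is asserted by a property test. Decisions the
protocol leaves open, and how they are resolved here:

- **Card order.** The commercial deck's fixed card order is proprietary and
  not public. The default deck is a seeded shuffle of the 64-card factorial
  per copy; a fixed order can be loaded from CSV. Results that depend on the
  deck (every simulation study) are therefore averages over deck seeds.
- **First rule and cycle.** Color first, then Form, then Number, cycled —
  the conventional administration.
- **Cards identical to key cards** are kept in the deck by default
  (configurable), since the factorial contains them and the protocol does
  not forbid them.
- **Deck exhaustion mid-category** simply ends the administration with a
  `deck_exhausted` termination flag.

## WCST scores

Five standard scores are computed from the trial log: perseverative errors
(PSV), non-perseverative errors (NPSV), categories achieved (NCAT),
failures to maintain set (FSET, runs of ≥ 5 consecutive correct within a
category that end in an error before completion), and trials to complete
the first set (TRSET1; if the first category is never completed the total
trial count is reported with a `completed = False` flag so downstream
statistics can censor).

Full manual perseveration scoring involves an intricate
"perseverated-to principle" algorithm with three-response establishment and
sandwich clauses whose exact published operationalizations vary. This
package deliberately uses a simple, fully specified rule: the
perseverated-to dimension is the previously correct rule, set at each rule
change; an error counts as perseverative when the chosen pile matches the
card on that dimension (no principle exists before the first rule change,
so early errors are non-perseverative). A stricter variant
(`previous-rule-unambiguous`) counts only errors matching *solely* on the
perseverated-to dimension. The strategy is a keyword argument, so
alternative scoring rules can be added without touching the scorer. The
invariant PSV + NPSV = total errors holds under every strategy.

## The attention-learning model

The model (four free parameters) maintains attention weights
`a = (a_color, a_form, a_number)` on the 3-simplex, the belief about the
prevailing rule.

- Choice: `P(pile k) = Σ_i m_ik a_i^d / Σ_i a_i^d`, with `m_ik` the
  card-vs-pile match indicator and `d ∈ [0, 5]` the decision consistency
  (0 = random among matching piles, large = deterministic).
- Feedback signal: after "right", `s ∝ m ∘ a^f`; after "wrong",
  `s ∝ (1 − m) ∘ a^f`, normalized; `f ∈ [0, 5]` is attentional focusing
  (0 = equal weight on all eligible dimensions).
- Update: `a' = (1 − r) a + r s` after "right", `a' = (1 − p) a + p s`
  after "wrong", with reward/punishment sensitivities `r, p ∈ [0, 1]`.

Numerical choices, all configurable on `ModelConfig`:

- **Initial state** `(1/3, 1/3, 1/3)` — the only symmetric choice.
- **Choice floor** `ε_c = 10⁻³`: choices are mixed with a uniform lapse,
  `P' = (1 − ε_c) P + ε_c/4`. The raw rule assigns probability zero to the
  pile sharing no attribute with the card, which real participants do
  choose occasionally; without the floor one such choice makes the
  likelihood −∞. The floor bounds every trial's log-probability below by
  `log(ε_c/4)`.
- **Attention clamp** `ε_a = 10⁻⁶` with renormalization, so `a^f` weighting
  never divides by zero.
- **Convention `0^0 = 1`** so `f = 0` (and `d = 0`) weight dimensions
  equally.
- **Bounds `d, f ∈ [0, 5]`**: wide enough that the score landscape is flat
  in both exponents well before the bound, without numerical overflow.

The likelihood of a recorded session propagates the state with the
participant's *actual* choices and feedback (standard practice for fitting)
and needs only the match vector of the chosen pile per trial. The
sequential recursion cannot be vectorized across trials, so the trace is
compiled with numba (~17 µs per 128-trial evaluation); a plain-Python
reimplementation of the same equations serves as the independent oracle in
the test suite (agreement to 1e-10 on random logs).

A notable consequence of the model structure: the *best-performing*
parameter region has **low** reward sensitivity. After a correct sort the
feedback signal is spread over all dimensions matching the chosen pile
(often more than one), so a large `r` step corrupts a belief that is
already correct; high `p`, high `d`, and low `f` complete the
near-ceiling profile. The simulation studies below confirm this direction.

## Bayesian estimation

Each participant is fit independently (no pooling). Priors default to flat
over the bounded supports; `PriorSpec` accepts per-parameter overrides so
informative priors (e.g. from a published fit) can be dropped in. Sampling uses emcee's
affine-invariant ensemble (default 24 walkers, 750 warm-up + 750 retained
iterations); walkers are grouped into 4 pseudo-chains for split-R̂ and ESS
(arviz). Fits with any R̂ > 1.05 are flagged `non-convergence`, never
silently dropped. The MAP is the highest-posterior retained sample refined
by bounded L-BFGS-B — a joint posterior mode, stable at the per-participant
data scale.

Model variants: RPDF (full), RRDF (`r = p`), RP1F (`d = 1`), RPD0
(`f = 0`), each with 3 free parameters except the full model's 4.

**DIC.** `DIC = D̄ + pD`, `pD = D̄ − D(θ̄)` with `θ̄` the posterior mean —
the classic plug-in form. The reference is a uniformly random 4-option
chooser, `DIC_random = −2 log(1/4)` per trial, and `ΔDIC = DIC_random −
DIC` (larger = better). Two caveats discovered and documented while
validating:

- `pD` can come out negative when chains are short or the posterior is a
  boundary-hugging ridge (near-ceiling performers); with the default chain
  lengths `pD` is positive for informative data.
- On data from a *uniform* chooser the model cannot approach the baseline:
  the model family (any `d ≥ 0`) never assigns more than `ε_c/4` to the
  no-match pile, which a uniform agent picks a quarter of the time, so
  ΔDIC is strongly negative rather than ≈ 0. The test suite asserts the
  substantive claim (no gain over baseline on chance data).

## Simulation studies

All studies derive every deck/behavior/fit seed from a master seed via
`SeedSequence`, making each study a pure function of (config, seed).

- **Parameter recovery**: simulate virtual participants per grid point of
  generating parameters, fit each, tabulate MAP vs truth (pooled Spearman
  and Pearson correlations, bias). Desk-scale default is a 2-level grid
  per parameter × 10 virtual participants (160 fits, ≈3 minutes); the
  full-scale 3-level grid × 60 virtual participants is a CLI option.
- **Posterior predictive check**: simulate `n_rep` fresh administrations at
  each participant's MAP, score them with the same scorer as the observed
  data, and compare observed vs mean-predicted scores across participants.
- **Score landscape**: mean scores over seeded simulations on a parameter
  grid. On 5-point sweeps (50 runs/cell), mean PSV falls steeply and
  monotonically in P; it rises with F, but the F effect saturates above
  f ≈ 2, so the F direction is a monotone *trend* (rank correlation of
  cell means), not a strict cell-to-cell ordering at this replication.
  Perseveration is maximal at low P with high D and high F. PSV is low
  both at ceiling-performing settings and at near-random ones (random
  errors are largely non-perseverative), so "low PSV" alone does not
  locate good performance — NCAT disambiguates.

## Synthetic cohort

The cohort generator plants the statistical structure of a frontal-lesion
study so every
downstream stage is testable without patient data: four 50-participant
groups with ellipsoidal lesion territories (jittered centers/radii) on a
40×48×40 voxel grid at 4 mm; the right-prefrontal group's punishment
sensitivity mean is lowered by 0.30. Baseline parameter means
(r 0.25 ± 0.12, p 0.70 ± 0.15, d 2.0 ± 0.6, f 0.75 ± 0.5) describe a
mostly-competent patient population with broad individual variation; draws
are truncated normals inside the model bounds, which biases group means
slightly toward the interior (accepted and visible in the tests'
tolerances). Age is weakly coupled to P (−0.002 per year) so that
residualization has something real, but negligible, to remove. Covariates:
age (truncated normal 55 ± 12 on [20, 89]), education (14 ± 3 on [8, 20]),
lesion volume (true voxel volume × 5% noise).

What the generator does **not** emulate: realistic lesion morphology
(vascular territories, white-matter geometry), registration error,
demographic score norms, and any correlation between lesion size and
parameter shifts beyond group membership. Passing the planted-effect tests
therefore demonstrates that the pipeline recovers a clean territorial
signal at realistic sample sizes — not that it would survive the
anatomical confounds of real lesion data.

## Lesion-symptom mapping

Per voxel with lesion overlap ≥ 12 (and at least two spared participants),
lesioned vs spared participants are compared with the Brunner-Munzel test
(midranks; relative effect `P(X>Y) + ½P(X=Y)`; positive z = lesioned group
stochastically larger). Voxels sharing an identical lesioned set are tested
once. FDR control is Benjamini-Hochberg over analyzed voxels at q = 0.01,
so the critical z is data-derived (on the default synthetic cohort it comes
out ≈ 3.2).

- **Reference distribution.** The default is Brunner and Munzel's
  small-sample t approximation (Welch-type df). This matters: at the
  overlap threshold the lesioned group has only 12 members, and the
  large-sample normal reference is anticonservative exactly in the deep
  tail that FDR thresholds probe — with the normal reference ~20% of label
  permutations of the synthetic cohort produced spurious discoveries,
  versus 0/40 with the t reference and identical recovery of the planted
  effect. A permutation reference (exhaustive when feasible, else seeded
  Monte-Carlo over the relative effect) is provided for very small groups,
  where any asymptotic p can be off by several percentage points.
- **Sidedness** is configurable (`two-sided`, `less`, `greater`). Deficit
  maps use `less`. This is not cosmetic: in a cohort where one group
  carries a deficit, the spared pool at *other* groups' voxels contains the
  deficit participants, so a two-sided test legitimately flags the
  complementary direction there.
- **Power flag.** A voxel is flagged as insufficiently powered when even
  complete separation (the most extreme assignment of the observed values
  to its lesioned group) could not reach the current significance cutoff —
  an explicit, testable analogue of the power shading in lesion-mapping
  GUIs, whose exact algorithm is not published.
- **Residualization** regresses a behavioral variable on covariates +
  intercept (rows with missing covariates dropped and reported;
  rank-deficient designs fail naming the collinear columns) and reports the
  residual-vs-original Pearson correlation, the diagnostic used to decide
  whether confounds matter.
- Conjunction overlays of two thresholded maps are three-valued labels
  (only-A / only-B / both) — descriptive overlap, not an interaction test.

## Cluster profiling

Two-step k-means on the four parameters: k = 2..7 under euclidean,
cityblock, and correlation distances with 20 seeded greedy restarts; the
(k, metric) maximizing mean silhouette (computed under the same metric)
wins; the largest cluster is then re-clustered by the same procedure,
giving labels like 1, 2a, 2b, 2c, 3. Centroid updates follow the metric
(mean / coordinate-wise median / row-standardized mean). Parameters are
z-standardized by default — r, p live on [0, 1] and d, f on [0, 5], so raw
Euclidean distances would be dominated by the exponents; a raw-scale mode
is retained for analyses that prefer the native parameter units.

Practical notes from validation: correlation distance over only four
dimensions happily assigns high silhouettes to "shape patterns" in pure
noise, and a cluster near the zero profile has no defined shape at all —
real parameter profiles are never the zero vector, but synthetic test data
must avoid that degenerate placement. Solutions with best mean silhouette
below 0.5 (the Kaufman-Rousseeuw band for weak/no substantial structure)
carry a warning. Stability is assessed by resampling 50% of participants
with replacement (default 1000 resamples), re-running the full two-step
procedure, and greedily matching resampled to original clusters by Pearson
correlation of mean-parameter profiles.

## Problem sizes used in the test suite

The automated tests run the full pipeline at deliberately reduced scale,
chosen as the smallest sizes at which each claim is expressed clearly:
recovery on a 2⁴ grid × 10 virtual participants; model comparison on 30
participants × 4 variants; PPC on 40 participants × 20 replicates; VLSM on
the full 200-participant default cohort with 20 permutation nulls;
bootstrap cluster validation with 100 resamples. Short MCMC settings
(16 walkers, 500 + 500 iterations) are used inside these studies; they
trade some per-fit convergence (flags are expected and tolerated) for
breadth, and every aggregate claim was verified stable under the default
longer chains.

## Known limitations

- The commercial card order, the full manual perseveration algorithm, and
  any particular published prior specification are not bundled; the
  documented, configurable stand-ins above take their place.
- DIC is the only model-comparison score implemented (no WAIC/LOO), and
  only the four listed variants are compared; no alternative model family
  is considered.
- The VLSM is mass-univariate; spatially correlated lesion anatomy is
  neither modeled nor corrected beyond FDR.
- MAP point estimates at hard parameter bounds (p → 1 in near-ceiling
  performers) are attracted to the boundary under flat priors; interval
  summaries from the posterior draws are the better report for such
  participants.
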