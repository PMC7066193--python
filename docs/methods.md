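# Methods

## The measurement problem

Behavioral lateralization comes in two distinct forms. *Population-level*
lateralization (directional asymmetry) means side biases aligned the same
way across most individuals; *individual-level* lateralization
(antisymmetry) means strong per-individual side preferences whose directions
are not aligned across the population. Distinguishing the two requires a
signed index per animal: the population question is whether the **mean of
the signed index** departs from zero, the individual question is whether the
**mean of its absolute value** exceeds what index-estimation noise alone
would produce. This package implements that analysis for fruit flies
recorded alone or in pairs in circular arenas, together with a simulator in
which both levels of asymmetry are injected explicitly, so that the whole
inferential chain can be validated by parameter recovery.

## Indices

**Circling asymmetry C.** For each frame triple the turn angle is the signed
angle between the displacement vector arriving at the middle frame and the
one leaving it, wrapped to (−180°, 180°), anticlockwise positive. Then

    C = Σ turn / Σ |turn|,   |C| = abs(C).

C = +1 means every deviation was anticlockwise, −1 every deviation
clockwise. A triple is discarded when either displacement is below
`min_step` (default 0.1 mm — roughly the tracking noise floor at 10 frames/s
in a 25.4 mm arena; the original processing did not state a threshold, so it
is exposed as a knob), when a step spans a tracking gap, or when the turn is
an exact 180° reversal, whose sign is undefined.

**Wing-use asymmetry W.** With per-frame wing opening angles relative to the
body midline,

    W = (Σ right − Σ left) / (Σ right + Σ left),

summed over frames whose opening exceeds `min_open` (default 0°: every
positive opening counts). Positive W = predominantly right-wing use. A fly
that never opens a wing has no W; undefined indices propagate as missing
values, never as zeros, because a zero would fake perfect symmetry.

**Dyad geometry.** Per frame: Distance (centroid separation, mm, symmetric);
Position (signed angle from the focal fly's heading to the focal→partner
bearing, in (−180°, 180°], positive = partner on the focal fly's left, 0 =
dead ahead, ±180° = focal fly in front of the partner; focal-specific, so a
dyad contributes two Position series); Orientation (unsigned circular
heading difference in [0°, 180°], symmetric). The heading defaults to the
tracker's body axis (`heading_source="body"`), since the defining vector is
anatomical; a displacement-based heading is available for sensitivity
checks. Position exactly at −180° is mapped to +180°; frames at exactly 0°
or 180° carry no side information and are excluded from the side-bias count
(n_left − n_right)/(n_left + n_right).

All angles live in a mathematical frame: y axis up, degrees,
counter-clockwise positive. Image-origin tables (y down) must be read with
the `y-down` flag, which negates y and reflects headings; without it every
signed quantity in the analysis flips sign. The package's tests pin this
down as an exact antisymmetry: mirroring the world and swapping wing labels
negates C, W and Position and preserves |C|, |W|, Distance and Orientation.

## Statistics

* **One-sample t-tests** of each index against 0, two-sided, α = 0.05, with
  Cohen's d = mean/SD and a 95% t-interval.
* **Factorial ANOVA** of each index on Context (FF, MM, FM, SINGLE), Sex and
  Strain with interactions. The design is structurally incomplete (an FF
  dyad contains no males), so interactions with empty cells are inestimable;
  they are detected by an explicit cell-count check and dropped with a
  report entry rather than silently absorbed into a rank-deficient fit.
  Sums of squares default to Type II for the unbalanced design (Type I is
  available; the two coincide on balanced data, which the tests assert).
  Effects are screened by omega-squared,
  ω² = (SS_eff − df_eff·MS_err)/(SS_tot + MS_err), floored at 0, with a
  meaningfulness threshold of 0.06 ("medium"); the threshold is a config
  value, not hard-coded into conclusions.
* **Dyad contrast**: a one-factor ANOVA on a derived dyad-vs-single
  indicator, the cleanest test of whether company changes individual
  asymmetry.
* **Bootstrap density bands.** Position distributions are multimodal, so
  conditions are compared via kernel densities with a bootstrap standard
  error: flies (trials) are resampled with replacement 100 times, each fly
  carrying equal weight regardless of its frame count, and the density is
  recomputed per replicate on a fixed grid. The resampling unit is the fly,
  never the frame — frames within a trial are strongly autocorrelated and
  frame-level resampling would understate the SE. The Gaussian bandwidth is
  fixed once from the full pooled sample (Silverman's rule) and reused in
  every replicate, so the band reflects sampling variation only. Angular
  data are replicated at ±360° so the density is continuous across the wrap.
  For large pooled samples on a uniform grid the kernel sum is evaluated by
  binning at the grid resolution and convolving with the kernel; the tests
  bound the approximation error against direct summation.
* **Null overlays.** The no-asymmetry reference for a signed index is a
  normal density centred at 0 with σ estimated from the observed signed
  sample; for the absolute index it is the corresponding folded
  (half-normal) density with the same σ. How "adjusted on the observed
  variance" should map onto the absolute index is ambiguous; matching the
  parent normal's σ is the default, and matching the variance of the
  absolute values instead (σ = sd(|x|)/√(1−2/π)) is available as a flag.

## The synthetic experiment

Each fly is a correlated random walk on a 25.4 mm disk at 10 frames/s: per
moving frame the heading increments by Normal(b_i, turn_noise²) degrees,
step lengths are truncated-normal ≥ 0, pauses occur with probability
`pause_prob`, and headings reflect specularly off the wall (the simplest
rule that reproduces the ring-shaped wall-following occupancy of real
arenas without dedicated wall logic). The per-fly turning bias b_i ~
Normal(μ_pop, σ_ind²) cleanly separates the two levels of lateralization:
μ_pop injects population asymmetry, σ_ind injects individual asymmetry.
Modeling the bias as a per-step heading increment (rather than a turn-
direction probability) maps directly onto C's signed-sum structure. Wing
bouts start as a memoryless per-frame process (geometric bout duration,
mean 5 frames — no bout statistics are published, so memoryless is the
minimal assumption) and choose the right wing with a per-fly logit-normal
probability p_i. Dyads add a weak heading attraction toward the partner
when the pair is more than a body length apart and, in female–male dyads, a
stronger steering of the male toward the female's bearing offset by λ
(`position_side_bias_lambda`); λ = 0 produces the courtship geometry
(male's Position mode near 0°, female's near ±180°) and a non-zero λ
injects a recoverable left/right bias. All randomness descends from one
root seed: Track-emitting APIs spawn one `SeedSequence` child per fly in
emission order so any fly is re-simulable alone; the positions-only batch
path uses a single stream for speed and is equally deterministic.

### Default parameters and calibration

| parameter | default | meaning |
|---|---|---|
| `turn_noise` | 15 °/step | within-fly SD of heading increments |
| `mu_pop` | 0.02 °/step | population-mean turning bias |
| `sigma_ind` | 4.9 °/step | between-fly SD of turning bias (singles) |
| `dyad_sigma_boost` | 1.65 | σ_ind multiplier for flies tested in dyads |
| `speed_mean`, `speed_sd` | 4, 2 mm/s | step-length distribution |
| `pause_prob` | 0.3 | per-frame probability of zero displacement |
| `wing_event_rate` | 0.05 | per-frame bout-start probability |
| `wing_side_mu`, `wing_side_sigma` | 0, 0.1 (logit) | right-wing preference across flies |
| `dyad_attraction` | 0.05 | heading pull toward the partner |
| `follow_gain` | 0.3 | male-toward-female pull in FM dyads |

The defaults were calibrated once, by a single oracle simulation run at
full trial length (36,000 frames), to the study conditions the package
emulates: grand mean |C| ≈ 0.34 with dyad flies above singles, grand mean C
within a few thousandths of zero, and wing indices nearly symmetric (SD(W)
of a few hundredths) with only mild per-fly wing preference. They were
pinned thereafter. The packaged design table (3,519 individuals across five
inbred strains, five social contexts) ships with a companion set of
per-strain dyad multipliers expressing that two strains show strong
courtship-like dyadic modulation and two show weak modulation.

### What the emulation does and does not capture

The generator reproduces the *statistical structure* the analysis consumes:
two separable levels of turning asymmetry, per-fly wing-side preference,
chasing geometry and its injectable side bias, arena-bounded kinematics,
and the design's group sizes. It does not attempt fly biomechanics,
behavioral states (fighting/chasing/courtship song), identity swaps or
tracking dropouts, and its Gaussian bias population makes the between-fly
spread of |C| (≈0.2) broader than observed in real flies (≈0.1). Passing
the recovery tests therefore shows the *pipeline* is correct and
well-calibrated — not that real flies satisfy the generator's assumptions.

## Numerical choices and degenerate inputs

* Turn triples: zero-length displacements are directionless even at
  `min_step = 0`; exact ±180° turns are dropped.
* Undefined indices (no valid turns, no wing opening, no sided frames) are
  NaN and excluded from tests, with exclusion counts in the report.
* One-sample tests refuse n < 2 (insufficient data) and zero-variance
  samples (degenerate) with typed errors.
* ANOVA estimability is checked on the full level product of each
  interaction's factors; the first empty cell is named in the error.
* KDE bandwidth uses min(SD, IQR/1.34); a zero-spread sample is a typed
  error rather than a zero bandwidth.
* CSV round-trips are bit-exact: floats are written with shortest-repr
  formatting and parsed with `float_precision="round_trip"`.
* Reports are JSON with sorted keys; reruns with the same inputs and seed
  are byte-identical.

## Problem sizes used in the shipped checks

The packaged calibration and recovery studies run at reduced problem sizes
chosen so the quantity under test is insensitive to the reduction: the
type-I-error study uses 1,000 replicate experiments of 50 flies at 2-minute
trials (the null distribution of C is centred at zero at any trial length);
the σ_ind recovery ladder uses 10-minute trials, long enough that the
1/√n_turns noise floor of |C| sits below the signal of the smallest
non-zero spread (0.5 °/step); the synthetic replica of the full study runs
all 3,519 flies at 10-minute trials, which shifts mean |C| by well under
0.01 relative to full-length trials. `scripts/acceptance.py` records the
problem size next to every number it reports.

## Known limitations

* The ANOVA's aliasing handling drops inestimable interactions rather than
  re-parameterizing the design (e.g. nesting Sex within Context); the
  dropped terms are listed in the report.
* The bootstrap band is a pointwise SE, not a simultaneous confidence band.
* The simulator's wall reflection is specular; real flies follow walls
  actively, so near-wall occupancy is only qualitatively reproduced.
* Time-of-day effects, tracking dropouts and identity swaps are out of
  scope; dropouts in real data are handled (as analysis breaks) but never
  simulated.
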