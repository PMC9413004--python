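# Methods

## Design representation

The experiment is a Taguchi L18 layout over five three-level factors:
chitosan type (A: ch1/ch2/ch3), pH (B: 5/6/7), dosage (C: 45/55/65 mg/L),
rapid mixing (D: 250/350/450 rpm) and slow mixing (E: 50/100/150 rpm).
The array is stored as the explicit list of 18 run labels rather than
generated from a generic L18(3⁶) catalogue: the study fixes one particular
column selection, and reproducing its row order and level assignment
exactly is part of the contract. `check_balance` verifies the defining
orthogonality properties — each level appears 6 times per factor and each
of the 9 level pairs exactly twice for every one of the 10 factor pairs.
Level indices are 1-based everywhere; physical settings are metadata only.

Flocculation efficiency is EF = 100·(OD₀ − OD)/OD₀ from optical densities
at 600 nm. EF may be negative when the suspension gets denser after
treatment; it is reported as-is (a signal of failed flocculation), not
clamped, since the formula imposes no floor.

## Signal-to-noise convention

The larger-the-better form S/N = −10·log₁₀((1/n)·Σ 1/yᵢ²) is used with a
single replicate per run (n = 1), where it reduces to 20·log₁₀(y). This
convention reproduces all 18 published EF S/N values to 4 decimals, which
fixes it as the definition; smaller-the-better and nominal-is-best
variants are out of scope. The S/N is undefined for non-positive
responses and the code raises rather than silently dropping runs.

## Balanced ANOVA

With the orthogonal design, sequential and adjusted sums of squares
coincide, so factor SS = 6·Σ_levels (level mean − grand mean)². Error SS
is total SS minus the five factor SS (df: 2 per factor, 17 total, 7
error); F = factor MS / error MS with the exact F(2, 7) upper tail for
p-values. "p = 0.000" in rendered tables is display rounding of a small
float, never a stored zero. A zero error mean square (exact additive
data) yields F = ∞ with p = 0. Numerical guard: error SS is floored at 0
to absorb float cancellation on exact fits.

## Grey relational analysis

All five responses are larger-the-better, normalized per column over the
18 design runs by min–max. Deviations are Δ = 1 − X. In the coefficient
GRC = (Δmin + ψΔmax)/(Δ + ψΔmax), Δmin/Δmax are taken globally over the
deviation matrix; after min–max normalization every column attains 0 and
1, so the global and per-column conventions coincide on in-design data —
the global choice is the documented one and the pipeline pins them to
(0, 1) explicitly. ψ defaults to 0.5 (the conventional midpoint between
maximal discrimination and maximal smoothing) and is configurable in
(0, 1]. Grades are weighted means with equal weights by default; weights
must be non-negative and sum to 1 within 1e-8. Ranking is competition
style (ties share a rank, next rank skipped); the study data contain no
ties.

### The repeating-thirds convention

Zone diameters are triplicate means, and printed values ending .33/.67
are 2-decimal renderings of exact thirds (x + 1/3, x + 2/3). The fixture
loader expands them back to thirds by default, which reproduces the
published normalized/coefficient tables to 4 decimals; with literal
2-decimal inputs agreement degrades to about 5e-4. Downstream tolerances
of ±1e-3 on 4-dp table values absorb both this and the rounding of
printed inputs. Published EF S/N values are matched at the table's own
precision (half a unit in the 4th decimal) because two printed EF inputs
are themselves roundings of values the published S/N implies.

### Validation scoring

Out-of-design runs are normalized against the stored design context. The
validation run's *Aspergillus* zone (44.85 mm) exceeds the design maximum
(44.33 mm); normalized values are therefore clipped to [0, 1] by default,
treating better-than-design responses as ideal (Δ = 0) — this convention
is what reproduces the published validation grade. `clamp=False` keeps
the out-of-range values (coefficients may then exceed 1) and flags every
offending cell. The context is *not* refit including the validation run;
refitting would change every in-design grade.

## Additive prediction

The predicted grade at a combination is the grand mean plus the sum of
chosen factors' level-mean deviations. The method supports both the raw
GRG value scale and the S/N decibel scale (with 10^(pred/20) back
transform) and arbitrary term subsets, because no single variant is
canonical in the field. The default — value scale, all terms — predicts
0.8712 at the multi-response optimum from the 18 design grades. This does
not equal the study's published prediction of 0.8673, and no additive
variant implemented here (S/N scale, significant-terms-only) reproduces
that number; its provenance is unstated, so the package documents the
divergence and treats the measured validation grade as the meaningful
comparison. Degenerate case: with zero terms the prediction is the
overall mean; on exactly additive data the all-terms prediction at any
design run returns that run's value identically.

## Synthetic data generator

The generator emulates what the analysis assumes about the real data and
nothing more: responses are baseline + additive per-factor level effects
(zero-sum per factor for identifiability) + Gaussian noise. EF is a
single measurement clipped into (0.01, 100] — the epsilon floor keeps the
S/N finite and every clipped cell is reported as a generator artifact —
and each zone response is the mean of 3 independent draws rounded to 2
decimals, mimicking the triplicate assay format (and exercising the
thirds-tolerance path). With σ = 0 the output equals the noise-free
surface exactly (no rounding applied), so exact-recovery properties are
testable.

Default calibration (chosen for realism, not fitted): baselines
(84 %, 36/35/35/37 mm), noise 1.5 % EF and 1 mm zones — comparable to the
run-to-run scatter the design leaves unexplained — and effect profiles
with argmax (3, 1, 2, 3, 1) whose direction is shared across responses
via positive loadings. The shared direction matters: it makes every
response individually maximal at the planted combination, so the
nonlinear GRC transform cannot reorder level means and noise-free
recovery is exact. The noise-free surface at the planted optimum sits
near the best observed runs (EF ≈ 97 %, zones ≈ 40 mm). Interactions are
deliberately absent — the analysis itself assumes none, so recovery is
well-defined.

The planted optimum is the per-factor argmax of equal-weight-summed
effects, with exact ties broken toward the lowest level index so the
truth is always a single combination; under all-zero effects this makes
the per-factor chance level exactly 1/3. `recovery_experiment` spawns
child seeds from the config seed, so rates are reproducible; a factor
counts as recovered only when its argmax is unique and correct.

What passing synthetic tests does **not** show about real data:
mechanistic flocculation kinetics, dose–response curvature, factor
interactions, and non-Gaussian measurement error are all outside the
generator; it validates the statistical machinery, not the chemistry.

## Problem sizes and determinism

Everything runs at the study's own scale (18 runs × 5 responses), so the
full pipeline completes in milliseconds. Recovery experiments use 1000
repetitions for the chance-level check (the 3-standard-error band at
1000 repetitions is ±0.045) and 200 for the noise sweep in the analysis
driver. All file outputs are deterministically ordered with fixed float
formatting (4 dp for GRA tables, 5 dp for GRG S/N and ANOVA SS/MS,
matching the published rendering); internal computation is always double
precision, and rounding happens only at the display/export boundary.

## Known limitations

- Only larger-the-better responses and three-level balanced designs are
  supported; no interaction terms, factor pooling, or prediction
  confidence intervals.
- The published prediction 0.8673 is unexplained (see above).
- The thirds convention is a reconstruction of the data-recording format;
  it is the convention that reproduces the published tables, but original
  raw triplicates are not available to confirm it directly.
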