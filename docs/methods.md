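# Methods

## The simulated system

`ploidyflux` models an asexual *S. cerevisiae* population propagated by
daily serial transfer: 1/101 of a saturated 10 mL YPD culture is moved
into fresh medium every 24 h, imposing log₂(101) ≈ 6.658 population
doublings per day and a bottleneck of ~10⁷ cells. Within a cycle each
strain

1. **lags** for `lag` hours (default 1.5 h; growth during lag sits below
   the OD detection limit, which is why the lag assay is glucose-based),
2. **grows exponentially** at the effective per-hour rate
   `h_i = r_i · (1 + b_i (1 − f_i) / ln 2)`,
3. **stops** when the shared glucose pool is exhausted.

`r_i` is the maximal growth rate (default 0.5 h⁻¹, typical for YPD at
30 °C). `b_i` is a per-generation Malthusian frequency-dependence
coefficient: `b > 0` grants an advantage when rare that declines linearly
with the strain's own frequency `f_i`, the minimal functional form for
negative frequency-dependent selection. Because `b` is per generation and
the ODE runs in hours, it is converted with the strain's instantaneous
doubling rate `r_i / ln 2` (generations per hour). With two strains of
equal `r` and coefficients `b₁`, `b₂` the deterministic dynamics have a
stable interior equilibrium at frequency `b₂/(b₁+b₂)`.

**Resource accounting.** Fresh medium carries 2 % w/v glucose (the
standard YPD recipe; 200 mg in 10 mL). Every new cell of strain *i*
consumes `yield_per_cell_i` mg (haploid default 2×10⁻⁷ mg, giving ~10⁹
cells at saturation). Diploid volume and per-cell glucose demand scale
together (110/60 ≈ 1.8× the haploid), so a diploid culture consumes
glucose at the same population rate with fewer, larger cells — the
configuration observed experimentally, and the reason the glucose-based
lag assay and the biomass assay are both ploidy-blind in the default
scenarios. Glucose conservation is exact by construction:
`R₀ − R(t) = Σᵢ yieldᵢ · (new cells of strain i)`.

**No diauxic phase.** Growth halts at glucose exhaustion; ethanol
respiration is deliberately not modelled (selection on post-diauxic growth
is weak under a 24 h cycle, and the hard stop keeps every assayed quantity
analytically checkable). Consequence: simulated OD curves have a sharp
saturation kink that real curves round off.

**Integration.** Cycles are integrated piecewise (segments delimited by
strain lags) with RK45 at rtol 1e-10 on log counts, with a terminal event
at glucose exhaustion. With `b = 0` the dynamics are exactly a two-strain
exponential race, and the per-cycle logit change equals `Δr · t_exp` to
~1e-10 — used as an oracle test.

**Bottleneck.** Per-strain binomial sampling with success probability
1/101 (independent across strains; at 10⁹ cells indistinguishable from
hypergeometric sampling), or exact division for noise-free runs.
Spontaneous diploidization converts haploid cells to a derived `_2N`
lineage with binomial probability `1 − (1 − rate)^{6.658}` per cycle.

**OD model.** OD is proportional to biovolume density
(Σ countᵢ·volumeᵢ / mL), calibrated so the reference haploid saturates at
OD ≈ 1.3 (Bioscreen-typical for YPD); the instrument floor is OD 0.04.
Read noise is i.i.d. Gaussian (default sd 0.002).

**Flow cytometry.** DNA-content peaks are Gaussian with CV 8 % at
positions c/2c (haploid G1/G2) and 2c/4c (diploid), so an unarrested
haploid G2 peak coincides with a diploid G1 peak. Hydroxyurea arrest
collapses each ploidy to its G1 peak except for an escape fraction
(default 0.10) left at G2.

**Cell geometry.** Major axes are log-normal; minor axes follow the
strain's target eccentricity with independent log-normal noise (spread
cv/2). The log-location is chosen so the expected recomputed prolate-
spheroid volume equals the strain's target exactly. Defaults: haploid
60 µm³ / e = 0.47, diploid 110 µm³ / e = 0.57.

## Estimators

**Geometry.** Full-axis prolate-spheroid forms: V = πLW²/6,
SA = 2πb²(1 + (a/be)·asin e) with a = L/2, b = W/2, e = √(1−(W/L)²). For
e < 10⁻⁶ the asin(e)/e factor is replaced by its Maclaurin series so the
sphere limit πW² is exact. W > L inputs are swapped with a warning
(manually drawn ellipses can transpose axes). Both formulas are verified
against quadrature (cross-section and surface-of-revolution integrals) to
1e-9 / 1e-6 relative over L ∈ [2, 12], W ∈ [1, L], and satisfy the
isoperimetric bound SA ≥ (36π)^{1/3} V^{2/3} with equality only at e = 0.

**Growth rate.** Natural-log OD is smoothed by local polynomial
regression with tricube weights on a 0.05 h grid; the maximal first
derivative is the growth rate. Readings at or below the 0.04 floor are
excluded, not imputed. The local fit is **cubic with span 0.2**: for
derivative estimation a local quadratic carries a large one-sided boundary
bias — on a logistic benchmark whose steepest log-slope sits at t = 0 it
overshoots by ~15 % (R's `loess`, degree 2 span 0.3, gives the identical
0.553 vs true 0.481) — while the cubic's extra term absorbs the curvature
change, recovering log-linear input exactly and the logistic benchmark to
~1 %. Estimates are invariant to OD rescaling. Biomass is the nearest
reading to 24 h minus the nearest to 0 h (±0.25 h, no interpolation). Lag
is *not* estimated from OD; it is exercised only through the glucose
series.

**Competition.** The two-type Malthusian model
`NonFluor(T) = p₀e^{mT} / (p₀e^{mT} + 1 − p₀)` is fitted by least squares
on the fraction scale (what a nonlinear LS fit of the model as written
does) via Gauss–Newton with the analytic Jacobian and step halving;
initialisation comes from the exact logit linearity
(`logit NonFluor = logit p₀ + mT`), which also serves as an independent
oracle. Observed fractions are clipped to [1/(n+1), n/(n+1)] only for the
logit initialisation. Assays whose fractions are all 0 or all 1 are
rejected as saturated. Generations are exact: T = day · log₂(101) =
0, 6.658, 13.316, 19.974 for days 0–3 (printed roundings 6.7 / 20.0 are
reproduced at one decimal; a printed 13.2 for day 2 is treated as a
rounding discrepancy and never used internally).

**Ploidy.** Colony G1 peaks are the lowest mode (≥ 10 % of the density
maximum) of a Silverman-bandwidth Gaussian KDE. k-means with k = 2 in one
dimension is solved *exactly* by enumerating the n−1 sorted splits
(optimal 1-D clusters are contiguous), eliminating initialisation
sensitivity; the lower-centroid cluster is haploid, or control anchors fix
the orientation. Arrested-sample diploid fractions gate at 1.5× the
haploid G1 peak (the c/2c midpoint; the original gates were manual) and
correct for arrest escape: raw = d + (1−d)·esc ⇒ d = (raw − esc)/(1 − esc),
clipped to [0, 1] (escaped diploids move 2c→4c and stay above the gate).
A literal "gate outside the data range" error would reject legitimate
pure-haploid samples (all events below the gate), so the gate check is a
sanity bound only. Coverage ratios are each chromosome's share of mapped
sites over its share of reference sites; flags at ≥ 1.4 or ≤ 0.6 sit
midway between euploid (1.0) and single-chromosome-gain expectations
(2× haploid, 1.5× diploid).

**Statistics.** All tests are computed from their defining formulas with
scipy supplying only reference distributions: Welch t with
Welch–Satterthwaite df (df ≤ 1 designs run with a low-power note; zero
variance with equal means returns t = 0, p = 1, with unequal means it is
an error); partial correlation as residual-on-residual Pearson r with
t = r√((n−2−k)/(1−r²)); Fisher's exact 2×2 by hypergeometric enumeration
with the probability-ordering two-sided rule (R's convention); simple
regression F with an "exact fit" flag instead of a zero division;
two-way ANOVA restricted to balanced layouts, where sequential and
marginal sums of squares coincide (unbalanced input is redirected to a
regression formulation). No multiple-testing correction is applied
anywhere. Test oracles are independent routes: exact rational enumeration
(`math.comb`/`Fraction`) for Fisher, explicit projection matrices for
ANOVA, scipy's implementations for Welch/Pearson.

## Scenarios and problem sizes

- `neutral`: identical kinetics, 50:50 start — every assay null.
- `diploid_fds`: b = 0.08/generation for **both** ploidies (the symmetric
  minimal choice with a stable interior equilibrium at 0.5; with b on the
  diploid alone the rates equalise only at fixation), diploids seeded at
  1 %. They pass 20 % by day 8 and reach ≈ 0.43 by day 14 while
  monoculture growth/biomass assays stay null — the package's central
  demonstration. "No detectable advantage" is scored as the
  diploid-minus-haploid estimate staying below 2 SE in the advantage
  direction.
- `late_sweeper`: one diploid lineage with the same maximal rate but a
  1 h shorter lag (≈ 0.5 logit/day) seeded at 5 % — it fixes while the
  growth-rate assay sees nothing, mimicking takeover by a subset lineage.

Replicate-tube replays estimate start/end diploid fractions through the
full closed loop (arrested flow samples → KDE peak of a haploid control →
gated, escape-corrected fraction), never from simulator truth.

Default problem sizes: 5 colonies per ploidy × 7 Bioscreen wells (3 in
the replicated paradox runs), 15 cells per colony for geometry, 4
competition replicates at 10,000 events/day over days 0–3, 30,000 flow
events per sample, 14-day evolution runs. These match the scale of the
experiments being emulated while keeping a 50-replicate scenario sweep
inside a couple of minutes.

## What the generator does and does not emulate

It reproduces the statistical structure the estimators rely on: binomial
drift at bottlenecks and flow counters, Gaussian OD read noise and flow
peak CVs, G1/G2 peak coincidence across ploidies, arrest escape,
frequency-dependent growth, and volume-coupled glucose yields. It does
**not** model diauxic/ethanol growth, mating or sexual recombination,
inter-colony genetic variation within a ploidy (colonies of a ploidy are
i.i.d. replicates of one parameter set), instrument drift between runs, or
debris/doublet events. Passing closed-loop tests therefore certify the
estimators against the modelled noise processes, not against every
artefact of real plate readers and cytometers.

## Known limitations

- The hard stop at glucose exhaustion puts a kink in simulated OD curves;
  the loess rate estimator overshoots the true rate by ~5 % on such
  curves (identically for both ploidies, so comparisons are unaffected).
- The escape-fraction correction assumes the escape rate is known and
  equal across ploidies; a miscalibrated escape shifts absolute fractions
  but largely cancels in day-14 − day-0 changes.
- The linear b(1−f) form is the minimal frequency-dependence model; real
  interactions need not be linear, and b is not identifiable from
  monoculture data at all (that blindness is the point).
- 1-D k-means with k = 2 assumes exactly two genome-size classes;
  aneuploid intermediates would need k selection, which is reported only
  descriptively via the WSS ratio.
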