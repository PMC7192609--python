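# Methods

## The measurement being modelled

The assay quantifies a single dNTP species (dATP, dCTP, dGTP, dTTP) in a
biological extract by making it the limiting substrate of a one-cycle,
non-amplifying primer-elongation reaction.  A TaqMan-style probe releases a
quenched fluorophore when degraded by the polymerase's 5'-3' exonuclease
activity, which happens through two competing routes:

* a **fast phase** coupled to incorporation of the limiting dNTP — its
  amplitude `A1` is proportional to the amount of that dNTP present;
* a **slow phase** from polymerization-independent background hydrolysis of
  the probe — present even in blank reactions with zero specific dNTP.

Because there is no template amplification, Cq-based qPCR mathematics does
not apply.  Instead each well's fluorescence-vs-time record is treated as an
enzyme-kinetics progress curve and decomposed into exponential phases.

## Progress-curve models

With positive amplitudes and a plateau `F0` (all in arbitrary fluorescence
units, time in seconds):

```
single:  F(t) = F0 − A  · exp(−k_obs · t)                      (blank-like)
double:  F(t) = F0 − A1 · exp(−k1_obs · t) − A2 · exp(−k2_obs · t)
```

The fast phase is identified by convention as the one with the larger rate
constant; fits are re-ordered after optimization so `k1_obs > k2_obs`
always holds in reported results.  The time origin is taken at the first
recorded cycle; any constant instrument offset is absorbed by the
amplitudes and plateau and cannot affect `A1`.

Both models are fitted to every well by bounded nonlinear least squares
(SciPy's trust-region reflective algorithm) and compared with the
small-sample-corrected Akaike information criterion computed from the
residual sum of squares of `N` points and `k` parameters (3 or 5):

```
AICc = 2k + N·ln(RSS)                          N/k ≥ 40
AICc = 2k + N·ln(RSS) + 2k(k+1)/(N−k−1)        N/k < 40
```

The model with the lower AICc wins.  Two special cases:

* **Perfect fits.**  When RSS is at numerical zero (below
  `(1e-6 · data range)² · N`), AICc is meaningless; the comparison then
  prefers the model with fewer parameters.
* **Degenerate double fits.**  A double fit whose rates agree within 1% or
  whose amplitudes sit at their bound has not actually resolved two phases;
  it is treated as single-model evidence.  This mirrors the
  "inseparable phases" failure mode that the QC checkpoints also police.

### Fitting numerics

Deterministic initialization: `F0 ← max(F)`, total amplitude `← max−min`;
the single-model rate comes from a log-linear regression of
`ln(F0 + ε − F)` on `t`; the double model starts from the typical fitted
magnitudes `(k1, k2) = (2×10⁻³, 1×10⁻⁴) s⁻¹` with a 30/70 amplitude split.
Randomized restarts (log-uniform rates, random amplitude splits; up to 5,
driven by the configured seed) are spent only when the optimizer fails
outright or lands at a suspect local minimum, defined as residual RMS above
1% of the data range; restarts stop after two consecutive non-improving
attempts.  Rates are bounded to `[1e-7, 1] s⁻¹` and amplitudes to `≥ 0` by
default (the lower bound is configurable; releasing it lets inverse runs
fit with negative raw `A1` so QC can flag them).  Standard errors are the
local-linearization values, `sqrt(diag((JᵀJ)⁻¹ · RSS/(N−k)))`.  Fits are
unweighted.  An evaluation budget (`max_nfev = 2000`) stops the
pathological case of the double model wandering a degenerate valley on
single-exponential data; the result is kept but marked non-converged,
which downstream treats as single-model evidence.

### Lag-phase trimming

Raw curves can show an initial flat lag (observed around 100–200 s).  The
trim search drops the first `m` points for every `m` whose removed duration
is ≤ `max_lag_s` (default 240 s, leaving at least 7 points), re-runs model
selection on the remainder, and keeps the smallest trim minimizing a
per-point information criterion.  For this comparison — and only this one —
the criterion uses `ln(RSS/N)` rather than `ln(RSS)`: the two differ by a
constant at fixed `N`, but across different trim lengths only the
normalized form is consistent (with plain `ln(RSS)` per point, pure noise
would always reward maximal trimming).  A patience rule (stop after two
candidates without improvement) keeps the search cheap; setting
`trim_patience = None` forces the exhaustive scan, and both paths are
tested to agree.  Trimmed curves are re-zeroed in time and the offset
reported per well.

## Quality-control checkpoints

Six checks invalidate wells whose fitted parameters cannot support
quantification; any flag excludes the well and its explanation appears in
the report:

1. `INSEPARABLE_PHASES` — model selection preferred the single model for a
   well expected to contain specific dNTP.  Blanks are exempt (they are
   expected single-exponential).
2. `A1_ERROR_EXCEEDS_VALUE` — `se(A1) > A1`.
3. `K1_WITHIN_K2_RANGE` — `|k1_obs − mean(k2_obs)| ≤ m · sd(k2_obs)`,
   where the mean and SD are over all converged double fits on the plate.
   The "error range of the average" is formalized as `m = 1` sample SD
   (configurable); SEM or min–max would be defensible alternatives.
4. `K2_TOO_SLOW` — `k2_obs < 1e-5 s⁻¹`, strict inequality: exactly
   `1e-5` passes.
5. `A1_NEGATIVE` — raw fitted fast amplitude below zero (an inverse run).
6. `SIGNAL_TOO_SMALL` — fitted total amplitude `A1 + A2` below 50% of the
   lowest calibration point's.  The fitted total is used rather than the
   raw max−min to be robust to noise.

Checkpoints 3 and 6 need plate context (≥ 2 contributing wells; ≥ 1 valid
lowest-calibration well); when missing they are skipped and recorded as
not evaluated rather than silently passed.

## Calibration, LOD/LOQ, quantification

Calibration is an ordinary least-squares line through `(amount, A1)` over
QC-passing calibration wells.  Blanks are excluded by construction (and a
"calibration" well declared at 0 pmol is reclassified as a blank).  Wells
where the double fit failed at low amounts are recorded as under the
detection limit.  The fitted range defaults to all usable points; a
narrower `[lo, hi]` and per-well exclusions support the refinement loop in
which a user drops outlier points and refits.

Detection limits come from two estimators:

* **Method A** — the lowest calibration amount that still produced usable
  double fits.
* **Method B** — `3·SD/slope` (LOD) and `5·SD/slope` (LOQ), with SD taken
  over replicate `A1` values at the lowest included amount.  This expresses
  the `intercept + 3·SD` signal-axis criterion on the amount axis, where
  subtracting the intercept is implicit in the inversion.

The reported LOD/LOQ is the larger of the two, so a mathematically tiny
method-B value never undercuts the lowest resolvable point; `LOD ≤ LOQ`
holds by construction since `3·SD ≤ 5·SD`.

Unknown wells are quantified by inverting the line,
`pmol = (A1 − intercept)/slope`, flagged `BELOW_LOD`, `BELOW_LOQ` or
`ABOVE_RANGE` as appropriate, and normalized to the whole extract and a
fixed cell count:

```
pmol_extract = pmol_reaction · dilution · (V_extract / V_assayed)
normalized   = pmol_extract · basis / cells_extracted
```

with basis `1e6` cells (human) or `1e8` CFU (bacterial).

Assay statistics follow standard plate-assay definitions: CV = 100·SD/mean
with the sample SD (n−1); intra-assay over technical replicates within a
plate and inter-assay over plate means, averaged across concentration
levels; accuracy = 100·mean(measured/nominal) at the lowest and highest
calibration amounts (the mean-ratio convention; inverse-prediction-based
accuracy would be an alternative reading); standard-addition recovery =
100·(spiked − unspiked)/added.

## Quadratic tight-binding characterization

The fraction of signal in the fast phase, `relA1 = A1/(A1+A2)`, rises with
added dNTP and saturates once the dNTP exceeds the
polymerase:template:primer:probe complex.  Because the dNTP is
substoichiometric to the complex over most of the range, the hyperbolic
isotherm is invalid and the ligand-depletion (quadratic, "tight-binding")
form is fitted:

```
F(L_T) = F0 + A_quad · [(E_T + L_T + K_app) − sqrt((E_T + L_T + K_app)² − 4·E_T·L_T)] / (2·E_T)
```

Only the minus root is implemented: it gives a bound fraction of 0 at
`L_T = 0` and 1 at saturation, while the plus root starts above 1 and
diverges, so it cannot describe a binding curve.  `E_T` is fitted free by
default (it carries a standard error in the reference fits, implying it was
free there too) with an option to fix it.  The intercept parameter and the
complex amount correspond to what binding-plot legends often label `S` and
`c`; the mapping is confirmed by the internal consistency of complementary
fits — `relA1` and `relA2 = 1 − relA1` data yield `A_quad` of equal
magnitude and opposite sign with identical `E_T` and `K_app`, and the two
model curves sum to one at every ligand amount.

With the published dTTP parameters (`A_quad = 0.660`, `F0 = 0.054`,
`E_T = 8.345` pmol, `K_app = 0.741` pmol) the model saturates at
`F0 + A_quad = 0.714`: at superstoichiometric dNTP the fast phase carries
0.7 of the signal, i.e. ~30% of the complex never produces specific-phase
fluorescence.  `scripts/acceptance.py` recomputes this value.

## The synthetic-data generator

`synthgen` forward-evaluates the exponential models on an acquisition
schedule and adds independent Gaussian read noise.  Defaults are chosen to
match the observed assay magnitudes: blanks with
`A ≈ 2.9e4, k ≈ 2e-4 s⁻¹`; specific wells with
`k1 ≈ 2.5e-3, k2 ≈ 1.1e-4 s⁻¹` (±10% per-well jitter), plateau
`≈ 3.5e4`, constant total amplitude `≈ 3e4`; a split-time schedule of 100
cycles × 13 s then 200 × 80 s (short cycles resolve the fast phase, long
cycles reach the slow plateau); calibration at 0.5–12 pmol in duplicate
with `A1 = 2100 · amount` (the slope implied by the published 3 pmol
example fit); noise SD of 1% of total amplitude.  Amplitude competition is
modelled by fixing the total: `A2 = A_total − A1`, with `A1` from either
the linear law or, optionally, the quadratic binding law.  A lag is a flat
hold at `F(0)` followed by the time-shifted model — the simplest shape
consistent with flat starts on raw curves.  The matrix-inhibition factor
multiplies both rate constants of sample wells only, reproducing the key
robustness property of the readout: matrix effects slow the kinetics but
leave `A1`, and therefore the recovered amount, unchanged.

What the generator deliberately does not emulate: mechanistic reaction
chemistry (it samples the fitted-model family directly, so model
misspecification is not exercised), photobleaching or baseline drift,
non-Gaussian or heteroscedastic instrument noise, and pipetting error
correlated across replicates.  Passing tests therefore demonstrate the
correctness and robustness of the analysis given the two-exponential signal
model, not the chemical validity of that model for any particular
polymerase or buffer.

## Problem sizes and determinism

The test suite and examples use 96-curve parameter grids, a 96-well
model-selection plate, and ~20–30-well end-to-end plates — sizes chosen to
match a real single-plate experiment while keeping a full run in a few
minutes on one core.  All stochastic tests fix their generator seeds, and
Hypothesis runs derandomized, so results are reproducible run to run.

## Known limitations

* Standard errors are linearization-based; near-degenerate double fits can
  have badly conditioned Jacobians, in which case the affected SE is
  reported as NaN and checkpoint 2 flags the well.
* Whether the reference analysis bounds its fits or how it derives errors
  is not documented; bounded fits with linearization errors are this
  package's choice.
* The lag-trim criterion is this package's construction; only the fact
  that lag points are removed, and the 100–200 s scale of observed lags,
  constrain it.
* Vendor export dialects are best-effort adapters onto the canonical long
  table; the vendors' column layouts are not standardized and may need a
  custom mapping step.
* dUTP is accepted as a species label for layout bookkeeping, but
  amplitude-based quantification of dUTP is known to be unreliable and is
  out of scope.
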