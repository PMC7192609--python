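# dntpkin

Kinetic analysis for polymerase-based fluorescent dNTP quantification.

Cellular dNTP pools are measured by making the dNTP of interest the
limiting substrate of a single-cycle primer-elongation reaction read out
with a TaqMan-style probe on a real-time PCR instrument.  The probe's
fluorophore is released both by specific dNTP incorporation and by the
polymerase's background 5'-3' exonuclease activity, so every well — even a
blank — produces a rising signal.  `dntpkin` separates the two processes
kinetically instead of subtracting blanks: each progress curve is fitted
with both

```
F(t) = F0 − A·e^(−k_obs·t)                       (single exponential)
F(t) = F0 − A1·e^(−k1_obs·t) − A2·e^(−k2_obs·t)  (double exponential)
```

and the small-sample-corrected Akaike information criterion,

```
AICc = 2k + N·ln(RSS)  [+ 2k(k+1)/(N−k−1) when N/k < 40],
```

selects between them.  The fast-phase amplitude `A1` (the phase with the
larger rate constant) is proportional to the amount of the limiting dNTP
and — unlike the observed rates — is insensitive to matrix effects of
biological extracts, so quantification is a linear calibration of `A1`
against known amounts, inverted for unknown wells and normalized to
10⁶ cells or 10⁸ CFU.  Six quality checkpoints (inseparable phases,
`se(A1) > A1`, fast rate within the plate's background-rate band,
`k2_obs < 10⁻⁵ s⁻¹`, negative raw `A1`, total signal under half the lowest
calibration point) exclude unreliable wells with per-well explanations in
the report.  A quadratic tight-binding module characterizes the
competition between incorporation and background hydrolysis from relative
amplitudes, and a synthetic-plate generator provides ground-truth data for
every pipeline stage.

Intended users: labs running plate-based enzymatic dNTP assays who want a
scriptable, auditable replacement for manual curve fitting, and method
developers who need a simulator with known truth.

## Worked example

Simulate a plate (2 blanks, six calibration amounts 0.5–12 pmol in
duplicate, three samples in duplicate, 1% read noise), then analyze it:

```bash
$ dntpkin simulate --seed 3 --out curves.csv --layout layout.yaml --truth truth.csv
20 wells written to curves.csv

$ dntpkin analyze curves.csv --layout layout.yaml --out report.csv
calibration [dGTP]: slope=1930/pmol intercept=245.1 R2=0.9798 LOD=0.5 pmol LOQ=0.5 pmol
report written to report.csv (20 wells, 0 flagged)
```

The slope of 1930 fluorescence units per pmol estimates the generator's
true 2100 within the noise; LOD/LOQ fall back to the lowest calibration
point (0.5 pmol) because the 3·SD/slope criterion gives a smaller value.
The report's sample rows (true amounts 1.5, 1.5, 3, 3, 6, 6 pmol):

```
well  role    model            A1    k1obs  pmol_in_reaction quant_flag  normalized_amount
 B3   sample  double  2836.135006 0.002521          1.342527         OK          13.425267
 B4   sample  double  2926.851145 0.002343          1.389531         OK          13.895306
 B5   sample  double  4643.505521 0.002874          2.279004         OK          22.790041
 B6   sample  double  6201.600959 0.002582          3.086321         OK          30.863212
 B7   sample  double 11435.751357 0.002459          5.798363         OK          57.983626
 B8   sample  double 12652.218680 0.002449          6.428667         OK          64.286673
```

`pmol_in_reaction` is `(A1 − intercept)/slope`; `normalized_amount` scales
it to pmol per 10⁶ cells using the layout's extract/assay volumes and cell
count (here a factor of 10).  Individual wells scatter with the noise
(B5 reads 2.28 for a true 3.0); replicate medians are the intended
readout.

The same steps are available as library calls:

```python
from dntpkin import PlateSpec, synth_plate, analyze_plate, AnalysisConfig

curves, layout, truth = synth_plate(PlateSpec(seed=3))
result = analyze_plate(curves, layout, AnalysisConfig())
print(result.calibration.slope, result.calibration.lod_pmol)
```

`dntpkin characterize` fits the quadratic binding model to
`relA1 = A1/(A1+A2)` versus added dNTP, reporting the apparent complex
amount `E_T`, the apparent dissociation constant `K_app` and the
saturating fast-phase fraction.

See `docs/methods.md` for the model details, numerical choices and the
generator's scope.

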