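# phloempet

Compartmental kinetic analysis of ¹¹C-PET time-activity curves (TACs)
from plant shoots.

Dynamic PET of a pulse-labelled plant yields, for each cylindrical stem
region of interest (ROI), the decay-corrected tracer concentration per
5-min frame over two hours.  This package turns such curves into
physiology: it fits a four-compartment transport model over four
consecutive ROIs (input + 3 downstream) and estimates, per ROI set, the
phloem front speed `s_Ph` (µm s⁻¹) and the exchange rates for unloading
(`a₁₂`), retrieval (`a₂₁ = h·a₁₂`, `h = 0.68759`), irreversible storage
(`b`) and respiratory efflux (`c`).  With `k = s_Ph/l` for ROI length
`l`:

    dC¹ᵢ/dt = k·C¹ᵢ₋₁ − k·C¹ᵢ − a₁₂·C¹ᵢ + a₂₁·C²ᵢ
    dC²ᵢ/dt = a₁₂·C¹ᵢ − (a₂₁ + b + c)·C²ᵢ
    dC³ᵢ/dt = b·C²ᵢ

The input ROI is forced by its measured total (`C¹ = total − C² − C³`).
Calibration minimizes the RMSE between simulated and measured frame
totals of ROIs 1–3 with a shuffled-complex-evolution (SCE-UA) global
search; identifiability is certified per fit with the collinearity
index (threshold 15).  A positron-range Monte Carlo answers whether
sub-2-mm stems retain the annihilations they produce, and a synthetic
TAC/phantom generator stands in for the scanner so the whole pipeline
is testable from nothing.

Intended users: plant physiologists and imaging scientists doing
radiotracer transport studies, and modellers who need a tested
reference implementation of frame-averaged compartmental fitting with
identifiability diagnostics.

## Worked example

```python
import phloempet as pp
from phloempet.model import PRIMARY_SHOOT_PARAMS

# 1. synthesize one primary-shoot ROI set at the reported class means
cfg = pp.SyntheticConfig(params=PRIMARY_SHOOT_PARAMS, seed=0)
noiseless, noisy, truth = pp.generate_roi_set(cfg)

# 2. calibrate the four-parameter model on the clean table
fit = pp.calibrate(noiseless, cfg.geom, pp.CalibrationConfig(seed=1))
print(f"s_Ph = {fit.params.s_ph:.1f} um/s   a12 = {fit.params.a12*60:.3f} /min")
print(f"rmse = {fit.rmse:.2e} MBq/mL, converged = {fit.converged}")

# 3. is the fitted parameter set identifiable?
S = pp.relative_sensitivities(fit.params, cfg.geom, noiseless)
print(f"gamma(s_Ph,a12,b,c) = {pp.collinearity_index(S):.1f}  (threshold 15)")

# 4. do positrons from a 1.5-mm stem annihilate inside it?
est = pp.annihilation_probability(pp.StemCylinder(diameter_mm=1.5),
                                  n_samples=1_000_000, seed=7)
print(f"P_annihilation = {est.p_percent:.1f}%")
```

prints

```
s_Ph = 128.0 um/s   a12 = 0.270 /min
rmse = 2.56e-07 MBq/mL, converged = True
gamma(s_Ph,a12,b,c) = 11.7  (threshold 15)
P_annihilation = 71.8%
```

The fit recovers the generating truth (s_Ph 128 µm/s, unloading
0.27 min⁻¹) to within 0.002%, the RMSE is at the solver floor, the
collinearity index of the full parameter set sits below the
identifiability threshold, and roughly seven of ten positrons born in
the near-surface phloem of a 1.5-mm stem annihilate within it — the
PET signal genuinely reflects in-stem transport.

A command-line interface mirrors the library
(`phloempet simulate | phantom | fit | identify | pannihilation |
summarize | run`), e.g.

```bash
phloempet fit --tac set.csv --geom set.yaml --seed 1 --identifiability --out fit.json
phloempet pannihilation --diameter 1.3 --n 1000000 --seed 7
```

## Analysis scripts

`analysis/01...05` rebuild the study's desk-scale results end to end:
synthetic cohort (4 plants × 2 ROI sets × primary/secondary),
per-set SCE-UA fits with identifiability reports, the
diameter-vs-annihilation sweep, and group summaries (mean ± SE per
shoot class, position correlations).  Each script prints what it found
and writes tables under `results/`.

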