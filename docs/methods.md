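# Methods

## The model

Phloem transport of recently fixed ¹¹C photoassimilate along a shoot is
described over a set of four consecutive cylindrical regions of interest
(ROIs): the proximal *input* ROI plus three downstream ROIs, each of
axial length `l` (4 mm on primary shoots, 10 mm on secondary shoots).
Each ROI is split into four pools:

1. the transport pathway (sieve element / companion cell complexes), `C¹`;
2. a transient storage pool (phloem parenchyma), `C²`;
3. an irreversible storage pool (phloem cap), `C³`;
4. the atmosphere, reached by respiratory efflux.

With `k = s_Ph / l` the advective rate constant, concentrations
(MBq mL⁻¹, all TACs decay-corrected so no decay term appears) obey

    dC¹ᵢ/dt = k·C¹ᵢ₋₁ − k·C¹ᵢ − a₁₂·C¹ᵢ + a₂₁·C²ᵢ
    dC²ᵢ/dt = a₁₂·C¹ᵢ − (a₂₁ + b + c)·C²ᵢ
    dC³ᵢ/dt = b·C²ᵢ

where `s_Ph` (µm s⁻¹) is the phloem front speed under an idealized
plug-flow assumption, `a₁₂` is continuous unloading from the pathway,
`a₂₁ = h·a₁₂` is retrieval (with `h = 0.68759` a fixed dimensionless
coupling, the mean of the calibrations in which `h` itself was
identifiable), `b` immobilizes tracer in storage, and `c` is
respiratory efflux.  The input ROI is forced by measurement: its
transport-pool concentration is the measured total minus the two
simulated storage pools (floored at zero under noise), and its storage
pools evolve by the same equations.  Initial condition: all first-frame
activity in the transport pool of the input ROI; a distributed
alternative is exposed (`SolverConfig.init_mode`) and changes frame
totals by < 0.1% of signal, confirming the insensitivity of the fits to
this choice.

### Units of the exchange rates

`s_Ph` is carried in µm s⁻¹ and `l` in mm (`k = s_ph/(1000·l)` s⁻¹);
TAC files use minutes; all integration is in seconds.  The exchange
rates `a₁₂`, `b`, `c` are stored in s⁻¹, and the class-mean defaults
(`PRIMARY_SHOOT_PARAMS`, `SECONDARY_SHOOT_PARAMS`) interpret the
commonly quoted magnitudes 0.27/0.08/0.38 (primary) and 0.07/0.25/0.30
(secondary) as **per-minute** rates, i.e. 0.0045/0.0013/0.0063 s⁻¹ and
so on.  Three independent observations force this reading: (i) taken
per second, the exchange time constants (~3 s) are quasi-static at
5-min frames and the four-parameter set becomes structurally
unidentifiable (collinearity indices 10³–10⁵, and an SCE fit can land
87% away from a synthetic truth while changing the RMSE by 0.03% of
signal); (ii) per-second magnitudes attenuate the TAC several-fold per
ROI, where observed TACs decrease only mildly from ROI to ROI; and
(iii) emptying a parenchyma pool to the atmosphere in ~3 s is not
physiologically plausible, while 0.38 min⁻¹ is.  Under the per-minute
reading all three inconsistencies disappear.

## Numerics

The chain is a linear ODE system forced by the piecewise-linear
interpolant of the measured input total (nodes at frame midpoints,
constant extrapolation outside).  It is integrated by an adaptive
embedded Cash–Karp Runge–Kutta 4(5) stepper compiled with numba, with
relative tolerance 10⁻⁵ and a 0.01-min step cap by default.  The state
is augmented with running integrals of each ROI total, so per-frame
averages (the quantity a PET frame measures) are exact divided
differences at frame edges rather than quadrature over a sampled grid;
midpoint sampling is available as an option.  Additional running
integrals of the advective inflow, the atmospheric efflux and the
distal outflow make the conservation audit

    |stored + efflux + outflow − inflow| / inflow

an exact by-product; it sits at ~10⁻¹⁵ for all tested configurations
(tolerance 10⁻⁴).  The stepper is cross-checked in the test suite
against an independent fixed-step explicit-Euler integration
(dt = 0.001 min, agreement < 10⁻³ relative) and against the closed-form
step response of the advection cascade obtained at `a₁₂ = 0`
(< 10⁻⁴ relative).  Inside the calibration objective the step cap is
relaxed to 0.5 min: the error control alone reproduces the capped
solution to ~10⁻⁹ relative and is an order of magnitude faster, which
matters at thousands of objective evaluations per fit.  Tiny negative
concentrations from Runge–Kutta undershoot are clipped to zero.

## Calibration

Each ROI set is fitted independently by minimizing the RMSE between
simulated and measured frame totals of the three downstream ROIs (the
input ROI is forcing, not data; equal pooling over frames and ROIs)
with a shuffled-complex-evolution (SCE-UA) global search: nine
complexes for the four-parameter problem (2n+1), 2n+1 points per
complex, subcomplexes of n+1 points chosen by triangular probability,
reflection/contraction/random-within-hypercube moves, 2n+1 evolution
steps per complex per shuffling loop.  Convergence is declared when the
best objective improves by less than 10⁻⁵ (relative) over the last five
shuffling loops.  The default evaluation budget is 12 000: with nine
complexes, convergence on clean data takes ~10 000 objective calls in
this implementation, and the accuracy criterion — not the budget —
should be the operative stop.  A solver failure inside the objective
returns 10⁶ × the data scale so the search continues.  Fits are
deterministic given the seed, and fitted parameters are invariant to
rescaling all TAC columns (verified to ~10⁻⁷ relative).

Default bounds: `s_Ph ∈ [1, 500]` µm s⁻¹ (bracketing the observed
32–216 with margin) and `a₁₂, b, c ∈ [0, 0.05]` s⁻¹ (~10× the observed
0.0012–0.0075 s⁻¹).  The theoretically admissible `[0, 1]` s⁻¹ box is
deliberately not the default: it contains a spurious quasi-static basin
at ~60-fold faster rates, indistinguishable from the true basin to
~0.02% of signal, into which a uniformly initialized population
collapses.  Widen the bounds explicitly if second-scale exchange is
plausible for your system.

The five-parameter variant frees `h` as well (eleven complexes, budget
30 000 — the `h` direction is weakly identified and slow to converge).
The intended workflow mirrors the study design: calibrate five
parameters per ROI set, keep the fits in which `h` is identifiable by
the collinearity criterion, fix `h` to their average (`average_h`,
reported to four decimals), and recalibrate the four-parameter model.

## Identifiability

Relative sensitivities `θ·∂y/∂θ` are computed by central finite
differences (relative step 10⁻⁴, absolute floor 10⁻⁸, one-sided at a
bound, solver tightened to rtol 10⁻⁹) and scaled row-wise by the
measurement-error model `sd = 0.05·y + 0.001` MBq mL⁻¹ — the canonical
scale-factor choice for collinearity analysis.  The collinearity index
of a subset is `γ = 1/√λ_min` of the Gram matrix of its unit-normalized
columns (γ = 1 for orthonormal columns and for singletons by
convention; ∞ for exactly collinear or zero columns); subsets with
γ > 15 are deemed unidentifiable.  γ is invariant to column scaling and
row permutation, monotone under subset inclusion, and is verified
against an SVD oracle to 10⁻⁸.

Two output surfaces are exposed.  The default, `"trajectories"`, takes
the simulated compartment concentrations of the downstream ROIs on a
dense grid — the model-output surface a kinetic-modelling tool
certifies; at the primary-shoot means it gives γ ≈ 12 for the full
{s_Ph, a₁₂, b, c} set (threshold 15; pairwise values 1–3, triplets
3–14).  The `"frames"` surface restricts the rows to the frame-averaged
ROI totals the objective can actually see and is substantially stricter
(γ ≈ 70 at the same point): at 5-min frames one mixed combination of
the four parameters is only weakly expressed in the data.  The
practical consequence is quantified below.

### What noise does to the fits

Clean-data calibration is essentially exact (median relative error
0.01% over cohorts spanning the observed parameter ranges, ≤ 0.002% at
the class means).  At 5% multiplicative frame noise, however, the
weakly expressed frame-surface direction dominates the error budget:
Cramér–Rao bounds computed from the measurement-scaled frame-surface
sensitivities give median relative standard errors of ~190% for the
exchange rates (50% for s_Ph) under the default acquisition (24 × 5-min
frames, three downstream ROIs).  Observed SCE fits scatter with median
relative errors of roughly 20% (s_Ph) to 60–170% (exchange rates), the
bounded search box truncating the theoretical wander.  No fitting
procedure can do fundamentally better under these conditions; the
per-ROI-set *front speed* is the robustly estimated quantity, while
individual exchange rates should be interpreted through their
identifiable combinations or averaged over many ROI sets.

## Positron physics

A ¹¹C positron's range in tissue is modelled as an exponential with the
nuclide's mean range, 1.2 mm, hard-truncated at the 4.2 mm maximum (the
truncated sample mean is analytically 1.073 mm; a two-component
exponential mixture with a heavier tail is config-exposed).  Positron
origins are placed uniformly on the phloem ring at depth 0.09·d below
the surface of a cylinder of diameter d, treated as axially infinite
(ROI length ≫ diameter).  Emission is isotropic and the exit chord is
the closed-form ray/cylinder intersection (axis-parallel rays are
capped by the maximum range).

The default estimator follows the published construction: the *mean*
in-stem path available toward the stem interior (inward hemisphere;
outward emissions cross only the ~0.09·d cortical shell), capped at the
maximum range, is converted to a probability through the truncated
range CDF.  For the study stems this gives P ≈ 67% (d = 1.3 mm) and
78% (d = 1.8 mm), and P → 100% exactly once the phloem depth exceeds
the range cap.  A per-positron estimator (`method="direct"`: fraction
of sampled ranges shorter than the individual chord, full isotropic
sphere) is also provided; because it counts every near-surface escape
individually it yields substantially lower values (~37% at 1.3 mm) and
is the stricter physical reading.  The mean-distance construction is
our operationalization of the distance-to-probability conversion used
for the published 67–76% figures; the choice between the two matters
whenever the source sits within one mean range of a surface.

## Synthetic data

The generator replaces the scanner.  The input-ROI TAC is a
gamma-variate bolus `A·(t/t_p)^α·exp(α(1−t/t_p))` with peak time
t_p = 65 min (activity peaks 65–70 min post labelling), shape α = 3 and
amplitude 2.0 MBq mL⁻¹, evaluated as 5-min frame averages (24 frames);
downstream ROIs are produced by the forward model at known true
parameters.  Noise is mean-zero multiplicative Gaussian,
`sd = cv·value + floor` with cv = 5% and floor = 0.001 MBq mL⁻¹,
clipped at zero — an approximation to count-limited PET at the
small-ROI scale.  It does **not** emulate frame-duration/activity
dependence of true PET noise, reconstruction correlations between
neighbouring ROIs, partial-volume cross-talk, or input-function bias;
passing tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not scanner-grade realism.
The optional 4D phantom paints the per-frame ROI concentrations into a
voxelized stem cylinder (default 400 µm voxels, stem along z, optional
0.8 mm FWHM Gaussian blur to mimic scanner resolution and
partial-volume signal loss); cylindrical-ROI extraction uses a
voxel-center-inside rule and recovers painted TACs exactly when blur is
off and ROI matches stem.

## Reported-scale choices

Desk-scale defaults used by the analysis scripts and acceptance
machinery: recovery cohorts of 20 ROI sets with truths drawn uniformly
from s_Ph ∈ [32, 216] µm s⁻¹ and the per-minute-read exchange ranges
(a₁₂ ∈ [0.05, 0.35]/60, b ∈ [0.04, 0.30]/60, c ∈ [0.10, 0.45]/60 s⁻¹);
the synthetic cohort in `analysis/` uses 4 plants × 2 ROI sets per
shoot class (half the study's 4 × 4) to keep a full run in tens of
seconds; positron Monte Carlo uses 10⁶ samples (standard error on P
well below 0.1 percentage points).

## Known limitations

- One effective front speed per ROI set (plug flow): no dispersion, no
  xylem counter-flow, no bidirectional transport.
- The input-closure relation makes the input ROI's transport pool track
  the measurement algebraically; input-noise propagates into downstream
  predictions as forcing error.
- Exchange rates are practically non-identifiable from single noisy ROI
  sets (see above); this is a property of the acquisition, not of the
  optimizer.
- The positron module is pure geometry + range statistics: no scatter,
  no tissue heterogeneity, no detector response.
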