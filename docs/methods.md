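# Methods

## Regression core

PLS1 is fitted by NIPALS on mean-centered data: per component, weights
**w** ∝ Xᶜᵀyᶜ (normalised), scores **t** = Xᶜ**w**, x-loadings
**p** = Xᶜᵀ**t**/(**t**ᵀ**t**), y-loading q = yᶜᵀ**t**/(**t**ᵀ**t**),
followed by deflation of both X and y. The regression vector for l
components is **b** = W(PᵀW)⁻¹q, so prediction is a single affine map;
this identity is asserted in the tests. NIPALS was preferred over SIMPLS
because OSC and the update diagnostics consume the componentwise
quantities, and it is deterministic (no random initialisation).

Cross-validation draws k = 5 random folds from an explicit seed
(optionally grouping a fruit's three replicate spectra into one fold,
since replicate leakage inflates CV optimism; the default treats each
spectrum as an independent sample, matching how the reference values are
measured at the spectral position). RMSECV is computed over concatenated
held-out predictions for every LV count in one pass per fold; the chosen
count is the first minimum, i.e. ties break toward parsimony.

Metric conventions: RMSE = √mean(ŷ−y)², bias = mean(ŷ−y),
R² = 1 − SSE/SST (negative values possible and meaningful),
RPD = SD(y)/RMSE with the *population* SD (divisor n) on both numerator
and denominator, which makes the constant-mean predictor score exactly
RPD = 1 — a useful anchor that a sample-SD convention would break.
Calibration-column RPD is reported as SD(calibration y)/RMSECV; the
field uses several conventions for that column, so cross-package
comparisons should rely on the unambiguous prediction columns.

## Pretreatments

* **2D** — Savitzky–Golay second derivative, window 13 points, fit order
  2, with respect to variable *index* (unit step, not nm): the constant
  spacing² factor is absorbed by the regression, matching common
  instrument software. Edge windows use asymmetric polynomial fits
  (`scipy.signal.savgol_filter(mode="interp")`), so all 151 variables are
  kept and the derivative is exact for polynomials of degree ≤ 2
  everywhere, including the edges.
* **SNV** — per-spectrum standardisation (population SD).
* **MSC** — each spectrum regressed on the calibration-mean reference by
  OLS over wavelengths; corrected = (x − b₀)/b₁. The reference is frozen
  at fit and reused for every later set; prediction sets never refit
  scatter references.
* **VSN** — weighted SNV whose per-wavelength weights are estimated by
  iterative reweighting: normalise with current weights, take the
  pointwise median spectrum as reference, compute the across-spectra
  median absolute residual m_j per wavelength, and set
  w_j = 1/(1 + (m_j/s)²) with s the median of m_j; iterate to max-change
  < 1e-6 or 50 iterations (non-convergence warns and returns the last
  iterate). Wavelengths that vary for chemical rather than scatter
  reasons get low weight, so the normalisation parameters come from the
  scatter-dominated region. With uniform weights the transform *is* SNV,
  which pins down the implementation against an exact limit. Weights are
  fitted on calibration only.
* **NSR** — corrected_j = (x_j − x(λ2))/(x(λ1) − x(λ2)), anchoring every
  spectrum to 1 at λ1 and 0 at λ2. The anchor pair is chosen purely by
  downstream PLSR RMSECV: a coarse search over every 4th wavelength pair,
  then a ±3-step refinement around the optimum. Anchors are selected on
  the chain's declared input (derivative spectra in a `2D+NSR` chain).

Chains are parsed from strings (`"2D+VSN"`), fitted left-to-right on
calibration data (each step on the output of the previous), and applied
frozen.

## Wavelength selection

All selectors report the RMSECV of a final cross-validated refit on the
selected variables, and stochastic ones record their seed.

* **Window search** — every contiguous window on a (start, width) grid
  (defaults: widths from 20 variables step 10, starts step 2, full span
  always included — about 900 windows at p = 151), each with its own
  CV-chosen LV count; the full RMSECV surface is kept for plotting.
* **MC-UVE** — coefficients collected over random 80% subsample fits;
  stability = mean/SD per variable; keep the largest |stability|.
* **SPA** — chains grown by maximal residual column norm after projecting
  out the chosen span; every (start, length) prefix scored by RMSECV at
  fixed folds.
* **VCPA** — binary-matrix subset sampling with an exponential retention
  schedule from p down to `final_max` (endpoints exact), variable
  frequency among the best 10% of subsets deciding survival; the ≤
  `final_max` survivors are searched exhaustively (refused above 20
  variables as a combinatorial guard). Subset scoring uses a fixed LV
  count (the full-spectrum CV choice) and shared folds per round, since
  per-subset LV optimisation is quadratically expensive.
* **IRIV** — per round, subsets from a binary inclusion matrix are scored;
  a variable whose inclusion raises the ensemble's mean RMSECV
  (uninformative or interfering — a Mann–Whitney test at α = 0.05 only
  distinguishes the labels) is dropped; rounds repeat until stable, then
  backward elimination polishes the survivors.

## Model maintenance

* **MU** refits preprocessing and PLSR on calibration ∪ standards at the
  fixed LV count.
* **SBC** fits reference = a + b·prediction on the standards and corrects
  predictions only; calibration metrics are untouched by construction.
* **OSC** extracts components of centered X whose scores are
  orthogonalised against centered y (seeded from the first principal
  direction not aligned with y; the least-squares preimage iteration is
  run with score-norm stabilisation; removed calibration scores are
  exactly y-orthogonal). The refit re-selects its LV count by CV —
  removing y-orthogonal variance characteristically lowers the needed
  count. OSC uses calibration data only, never the standards.
* **DOP** builds a difference matrix by pairing each standard with the
  mean calibration spectrum of nearest reference value (ties averaged) —
  the simplest faithful matching when no sample correspondence exists —
  takes the top-K eigenvectors V of DᵀD, projects P = I − VVᵀ onto
  calibration and all future spectra, and refits. K is the smallest value
  within 2% of the minimum standards-RMSEP over K = 1…20: a strict argmin
  drifts to the largest K by overfitting the standards, while the
  parsimonious rule recovers the true interference dimension on planted
  low-dimensional shifts.
* **Coverage** — mean-centered PCA scores (shared rotation fitted on the
  pooled spectra); the coverage index is the fraction of prediction
  points inside the 2-D convex hull of the update points. Reported as a
  diagnostic; no threshold is applied.

## Synthetic data generator

The generator emulates the two-variety study design: 12 populations with
the study's per-population fruit counts, SSC means/SDs (0.77–1.84 °Brix)
and TA statistics (populations 1–6 only, 16–101 g/L taken verbatim per
population), 3 replicate spectra per fruit.

A clean spectrum is a sum of Gaussian bands at the instrument's
characteristic peaks: chlorophyll at 680 nm (scaled by a per-population
chlorophyll level), water O-H at 740/840 nm (fixed loading), an N-H band
at 815 nm, and sugar C-H bands at 840/880/920 nm whose loadings are
proportional to SSC — so the SSC signal is linear in absorbance and an
oracle PLSR on clean spectra succeeds (RPD > 2, asserted). Band widths
are 12–25 nm (centers are known; widths are a modelling choice). A TA
band at 770 nm defaults to an amplitude near the noise floor
(2e-5 absorbance per g/L), reflecting that acidity is spectroscopically
weak in this range; `ta_signal_scale` raises it for power studies.

An observed spectrum is gainᵢ·clean + polynomial baseline + sᵢ·**d** +
white noise, with per-spectrum gain ~ N(gain, 0.05), interferent loading
sᵢ ~ N(mean, sd) on a unit-norm direction **d**, optional wavelength
shift by linear resampling, replicate-level SSC jitter of 0.15 °Brix
(each replicate's reference is its own SSC, as juice is measured at the
spectral position), and noise SD 0.002 absorbance. All draws come from
substreams keyed by (population, fruit), so any subset of populations is
reproducible from the one seed. Setting `gain_sd = 0` with zero batch
effects and noise makes the output exactly the closed-form band sum,
which the tests exploit.

**Variety-shift design.** Populations 7–12 carry a gain drift
(1.04–1.08) and a structured interferent that is a population-specific
combination of two unit-norm bands at 710 nm (chlorophyll shoulder) and
880 nm (inside the sugar-information region), so the shift spans a
2-dimensional subspace overlapping the calibration's active
coefficients. Loadings (~0.1–0.25) were set once from the measured
coefficient response (~+7.5 and ~+4.5 °Brix per unit loading) so that
the design realises the study's qualitative regime: direct cross-variety
prediction fails (RPD < 1); the two covering update splits have mean
effects matched to their prediction sets, so MU/SBC/DOP recover;
populations 9–10 load only on the 710 nm direction, in a tight cluster
whose mean effect differs from the rest — an update set drawn from them
leaves the 880 nm direction unseen and mis-centers its corrections (the
"negative group"). OSC is excluded from the strict negative-vs-covering
ordering: it never consumes the update set, so its split differences
ride only on prediction-set composition, and the negative prediction
set's larger reference SD inflates its RPD, so no coverage-driven
ordering can be attributed to it.

**What the generator does not emulate:** radiative transfer or tissue
optics, temperature effects, detector nonlinearity, wavelength-dependent
noise, and the real covariance between SSC and maturity-linked pigment
changes. Passing tests therefore demonstrate the *mechanisms* (scatter
corrections invert the distortions they model; maintenance methods
remove the batch structures they target; coverage governs update
success), not instrument-grade error levels — the synthetic task is
easier than real fruit, and absolute RMSEPs here are optimistic.

## Problem sizes and numerical choices

The end-to-end update suite runs 20 fruit per population over 10 seeds,
and selector tests use reduced run counts (e.g. 200 binary-matrix
samples) — sizes chosen to make the qualitative claims testable at desk
scale; the `analysis/` drivers run the full 12-population design. Other
choices: grid uniformity is checked to 1e-9 nm; NIPALS stops a component
when the residual covariance norm falls below 1e-14 (the model truncates
rather than fabricating components); VSN's kernel scale guard returns
uniform weights if the median residual is zero (identical spectra);
CSV round trips write 17 significant digits; serialized artifacts carry
a format-version field and refuse to load on mismatch.

## Known limitations

TA modelling is retained only through the pretreatment comparison (it
fails, as expected for low-acid intact fruit in this wavelength range,
and the default pipeline carries only SSC forward). DOP fits one basis
per update set (no per-batch re-estimation). No Kennard–Stone standard
selection: update sets are random fruit from designated populations.
Single-instrument batch drift only — no cross-instrument transfer.
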