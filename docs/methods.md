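# Methods

This note documents the models, defaults and design choices behind
`nircal`, in enough detail to re-derive every number the package computes.

## Calibration model

Spectra are absorbance rows `x ∈ R^n` on a common nm grid; the response is
lignin content `y` in mg/g.  The calibration is PLS1 fitted by NIPALS on
column-centred `X` and centred `y`:

    X = T P' + E,    y = U q' + F,    U = T B  (B diagonal).

For a single response the weight step is closed-form (`w ∝ E'f`), so no
inner iteration is needed.  Coefficients are folded back to the raw scale,
`ŷ = b0 + X b`, with `b = W (P'W)^{-1} q`.  The latent-variable count is
chosen by leave-one-out cross-validation (LOO RMSECV), argmin with ties
broken toward fewer components; requested counts beyond `min(m−2, n)` are
capped with a logged warning.  The default ceiling is 20 components.

Model quality is reported as RMSECV/RMSEP plus two flavours of "R": the
coefficient-of-determination-style `1 − SSres/SStot` (with SStot centred on
the evaluated set's own mean) and the Pearson correlation between observed
and predicted values.  The two differ, both appear in the chemometric
literature under the same symbol, and neither is silently substituted for
the other — pipeline tables carry both (`rp` and `rp_pearson`).

Internal model search (GA fitness, CARS/SiPLS scoring) uses a cheaper
venetian-blind k-fold CV (sample `i` → fold `i mod k`; deterministic, no
RNG); every `SelectionResult.score_rmsecv` is then recomputed by LOO on the
final subset so the reported score is reproducible from the indices alone.

## Preprocessing

* **SNV** — per-row centring and scaling by the sample SD (divisor m−1, the
  dominant chemometric convention).  Constant rows raise an error naming the
  sample.
* **MSC** — per-row OLS against a reference spectrum; the reference is the
  calibration-set mean, stored with the master model and reused on new data
  so no information flows from test to train.  (When the split itself is
  computed on MSC-preprocessed spectra the whole-batch mean is used for the
  split distances only; the model's reference is refitted on the
  calibration rows.)
* **Savitzky–Golay derivatives** — `scipy.signal.savgol_filter` with
  polynomial edge handling (`mode="interp"`), scaled to per-nm units so
  results are grid-independent.  Requires an evenly spaced grid (relative
  tolerance 1e-9).  Paper-style settings: order 1 / poly 1 / window 11 and
  order 2 / poly 2 / window 11.

The pipeline order is trim → replicate averaging → preprocessing.

## Kennard–Stone splitting

Greedy max–min Euclidean selection: seed with the most distant pair, then
repeatedly add the sample maximising the minimum distance to the selected
set.  Ties break toward the lowest index, making the split fully
deterministic.  The calibration count is round-half-up(fraction·m), floor 2;
a split leaving no prediction samples is rejected.  For the study's batch
sizes this yields 160→96/64 (fraction 0.60) and 120→48/72, 104→42/62,
128→51/77 (fraction 0.40).  Distances are computed on the preprocessed
spectra that feed the model (configurable to raw via `split_on`).

## Wavelength selection

* **GA** — binary masks; tournament selection (size 3), uniform crossover
  (p=0.8), bit-flip mutation (p=0.01), elitism 2; fitness is −RMSECV of a
  PLS fit on the masked columns (LV by inner CV, capped).  Defaults:
  population 100, generations 100, 5-fold fitness CV.  An optional
  `max_selected` cardinality cap (off by default) implements the standard
  GA-PLS practice of bounding the subset size; the band-recovery experiments
  use cap 12 because an uncapped CV-fitness GA is near-indifferent to
  harmless columns and exploits spurious in-sample correlations, so it
  retains a diffuse mask even when the informative region is known.
* **CARS** — N Monte Carlo runs (default 100); each run fits PLS on a random
  80 % sample subset, keeps the top fraction `r_i = a·exp(−k·i)` of
  wavelengths by |coefficient| (a, k fixed by `r_1 = 1`, `r_N = 2/n`; floor
  2), then resamples survivors with probability ∝ |coefficient|; the run
  minimising 10-fold RMSECV wins.  Max 10 LVs.
* **SPA** — chains of minimally collinear columns grown by orthogonal
  projection (ties to the lowest index; exactly collinear columns are never
  added), each `(start, k)` chain scored by MLR validation RMSE on an
  internal 70/30 Kennard–Stone split; default k range 5–30.
* **SiPLS** — contiguous partition into `n_intervals` (remainder spread over
  the leading intervals: 387 over 20 → 7×20 + 13×19), exhaustive scoring of
  every combination of 2–4 intervals by CV RMSECV.

All stochastic selectors are deterministic given their seed.

## SS-FPME updating

Given supervising coefficients `bm` and an update set `(Xs, y)` from a new
batch, the update solves

    min_{b0s, bs} ‖y − b0s − Xs bs‖²   s.t.   corr(bs, bm) ≥ r_th,

Pearson correlation on the coefficient vectors, intercept unconstrained.
Solver route, in order:

1. If the unconstrained least-squares solution is feasible it is the global
   optimum and is returned (iterations = 0).
2. Otherwise SLSQP starts from `bs = bm` (always feasible) with analytic
   gradients.  The constraint is implemented in the degree-1 homogeneous
   form `u·v̂ − r_th‖u‖ ≥ 0` (`u` the centred coefficients, `v̂` the unit
   centred supervisor direction), which is far better scaled for SQP than
   the normalised ratio.  On under-determined update sets (more wavelengths
   than update samples) this warm start matters: SQP descends to a
   zero-residual solution *near the supervisor*, the implicit regularisation
   that makes the update generalise.
3. For `r_th ≥ 0` the feasible set is a convex cone, and an exact solver
   arbitrates: writing `b = c·1 + u1·v̂ + W w`, the constraint is the
   second-order cone `‖w‖ ≤ tan(θ)·u1`, the inner problem at fixed `u1` is a
   trust-region subproblem solved via the SVD secular equation, and the
   outer value function is convex in `u1` (golden-section search).  The
   better feasible solution wins; if SQP already matches the arbiter's
   objective its iterate is kept and marked converged.  Solutions are held
   strictly off the cone apex (a constant coefficient vector, where the
   correlation is undefined).

Enforced guarantees: the returned objective never exceeds the objective at
the feasible initialiser, and `corr(bs, bm) ≥ r_th − 1e-8`; otherwise the
initialiser is returned with `converged=False` and a warning.  Intercepts
are warm-started from the supervisor's intercept.

`r_th` defaults to **0.95**.  At 0.80 the constraint almost never binds for
realistic batch drift — every update then reaches (near) its unconstrained
optimum regardless of the supervisor, and the independent and sequential
schemes become indistinguishable.  At 0.95 the supervision is active: a
heavily drifted batch cannot be reached in one constrained step from the
master, while the sequential chain approaches it through intermediate
batches — which is exactly the regime in which sequential updating earns its
keep.  The threshold is a config parameter and is logged with every
experiment.

Scheme semantics: *independent* supervises every batch with the master's
coefficients; *sequential* supervises batch i with the coefficients produced
for batch i−1.  The *direct* baseline always applies the unmodified master
model to the new batch (at the master's wavelengths and preprocessing).

## Synthetic study generator

The generator emulates a four-batch fruit-lignin NIR study with full ground
truth.  Optics are linear in absorbance: each constituent is a sum of
Gaussian bands; a sample's clean spectrum is `Σ_k c_k s_k(λ)` plus a fixed
quadratic baseline.  Defaults:

* **Grid** — 387 evenly spaced points on [1033, 2300] nm.  (The source
  instrument's native grid is non-uniform and unrecoverable from the
  published point counts, so an even grid with the stated endpoint and count
  is used.)
* **Lignin** — bands near 1160, 1198, 1420, 1680 and 2270 nm (C–H/O–H/C=O
  overtone and combination regions), response 0.0015 AU per mg/g at unit
  band amplitude.  Reference values are drawn from truncated normals
  matching each batch's printed mean ± SD and range, and carry 0.1 mg/g
  measurement noise (the order of a wet-chemistry lab error); zero-noise
  configurations reproduce the lignin content exactly.
* **Other constituents** — water (1450/1940 nm), sugars (1580/1730/2100 nm)
  and a cell-wall-like confounder whose bands overlap the lignin bands
  (1180/1440/1700/2280 nm), all with per-sample random concentrations.
* **Scatter** — per-sample multiplicative gain (SD 0.15) and offset
  (SD 0.03), the path-length/surface variation of intact fruit that SNV/MSC
  remove exactly; smaller replicate-level gain/offset; per-sample wavelength
  registration jitter (SD 0.3 nm), an irreducible error no row-wise
  pretreatment removes; per-scan noise SD 0.0015 AU.
* **Replicates** — 9 positions × 3 scans simulated and averaged through
  `core_io.average_replicates`.
* **Batch drift** — batch A clean (master); B/C/D drift progressively in a
  consistent direction: wavelength shift 0.5/2.5/4.5 nm, gain
  1.010/1.025/1.045, baseline offset 0.005/0.012/0.020 AU, plus a growing
  interferent band placed *on top of* the 1680 nm lignin band
  (amplitudes 0.004/0.020/0.040) so the drift demands a genuine coefficient
  rotation rather than a bias shift.  Batch D additionally has the
  compressed lignin spread of the printed study (SD 0.55).  These values
  were set so that the master model degrades mildly on B and severely on
  C/D, the qualitative pattern the transfer experiment studies.
* **Seeding** — per-batch seeds derive from one master seed via
  `numpy.random.SeedSequence(seed).generate_state(n_batches)` (31-bit
  masked), so batches are independent and the whole study is reproducible
  bit-for-bit.

What the generator does *not* emulate: nonlinear detector response,
temperature-dependent band shapes, fruit-geometry stray light, or any
radiative-transfer physics.  Passing tests therefore demonstrate the
machinery and its qualitative behaviour under linear-mixing assumptions, not
performance on real fruit spectra.

A second fixture, `single_band_config`, generates one batch (120 samples,
120 grid points) whose analyte signal is confined to a single 12-column
band, with two nuisance constituents away from the band and per-column noise
strong enough that uninformative columns genuinely dilute a full-spectrum
model.  It is the ground-truth target for the wavelength-selection recovery
experiments; those evaluate 10 optimizer seeds on one fixed dataset drawn
with seed 3, since the stochastic component under test is the selector.

## Experiment pipeline

`run_master_experiment` KS-splits the master batch 60/40, compares the five
pretreatments on the full spectrum, then runs the configured
wavelength-selection methods on the winning pretreatment.  The persisted
master model is the best *selection-based* model by prediction RMSEP — a
parsimonious subset model, as is standard for deployment — with the
full-spectrum model kept as the baseline row (and used only if every
selector fails).  The default selector is SPA: it is deterministic, fast,
and returns subsets of ≤30 wavelengths, which keeps the update problems on
new batches overdetermined (update sets have 42–51 samples).  Failed
candidates appear in the report flagged rather than aborting the
experiment.

`run_transfer_experiment` KS-splits each new batch 40/60 into update and
prediction sets on the master's preprocessing, checks grid alignment, and
tabulates direct / independent / sequential Rp and RMSEP per batch.

The robustness experiment (and `scripts/acceptance.py`) repeats the whole
study over 20 seeds and reports means; 20 gives stable orderings of the
scheme comparison at a few minutes of runtime on one CPU.  The
wavelength-recovery experiment uses GA population 40 / 100 generations /
cardinality cap 12 and CARS at its defaults.

## Known limitations

* The linear-mixing generator makes scatter exactly SNV-correctable, so
  preprocessing comparisons are cleaner than on real instruments.
* The exact cone solver covers `r_th ≥ 0`; for negative thresholds (rarely
  meaningful) only the SQP route runs and the usual local-optimum caveats of
  SQP apply.
* Uncapped CV-fitness GA selection inherits the selection-bias pathologies
  of GA-PLS: it will happily keep columns whose in-sample CV contribution is
  spurious.  The cardinality cap mitigates but does not remove this.
* PLS1 only; multiple simultaneous responses are out of scope.
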