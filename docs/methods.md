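# Methods

## The assay being modeled

Surface-tethered, fluorescently labeled centromeric DNA molecules are
incubated with cell extract containing one GFP-tagged kinetochore protein,
washed at a chosen time, and imaged by two-channel TIRF microscopy.  Each
DNA appears as a diffraction-limited spot in the 647-nm channel; the protein
has been acquired when a 488-nm spot colocalizes with it.  The observable is
the fraction of DNAs carrying GFP as a function of incubation time, sampled
at 0, 5, 10, 30, 60, 90, 120, 150 and 180 min, with at least 3000 DNA
molecules pooled per timepoint and three biological replicates.  A
centromere point mutant that abolishes assembly provides the specificity
control; chance colocalization on such fields stays below 1%.

## Kinetic model

Assembly through `n` sequential irreversible transitions with a shared rate
constant `k` (min⁻¹) gives

    f(t) = Cmax · P(n, k·t),   n ∈ {1, 2, 3, 4}

with `P` the regularized lower incomplete gamma function — the Erlang(n, k)
CDF scaled by the plateau `Cmax ∈ (0, 1]`.  The model does not resolve the
molecular identity of the steps; it is a two-parameter family whose shape
(lag followed by rise) approximates more complex irreversible pathways.
`eval_assembly_curve` evaluates the explicit closed forms
(polynomial × exponential); the gamma-CDF identity serves as an independent
numerical cross-check in the test suite rather than as the implementation,
so agreement between the two routes is a real test.  For k·t ≳ 700 the
exponential underflows and the curve returns exactly `Cmax`, which is the
correct limit to far below the 1e-9 tolerance we check.

### Fitting

`fit_fixed_steps` minimizes

    chi² = Σ_t ((f̄_obs(t) − f(t)) / σ_t)²

over the timepoint means, with `σ_t` the replicate SD floored at the pooled
binomial SE `sqrt(p̂(1−p̂)/N_t)` and at an absolute 1e-3.  The floor matters:
the SD of three replicates is occasionally zero by coincidence, and a
timepoint with p̂ = 0 (t = 0) has zero binomial SE; neither should carry
infinite weight.  Exactly two parameters are free.  `k` is optimized on a
log scale from a deterministic grid of 16 starts log-spaced over
1e-4…1 min⁻¹ (local searches may leave that range, bounded at 1e-6…1e3);
`Cmax` is profiled out at each `k` by weighted linear least squares and
clipped to (0, 1].  The best start is polished by a bounded scalar
minimization to ~1e-12 in log k, which is what lets noise-free data be
recovered to 1e-6 relative with chi² below 1e-12.  The t = 0 observation
participates in the fit; f(0) = 0 holds by the model form, not by
constraint.  An all-zero series returns a converged but non-informative fit
with `Cmax` at the lower bound.

`select_model` fits all four step counts and keeps the minimum-chi² fit, raw
chi² with no small-sample correction; ties below 1e-9 break toward fewer
steps (parsimony — the model family is nested in shape, not in parameters,
so exact ties essentially only occur on degenerate data).  All four
candidate fits are retained in the fit payload.

### T30 and censoring

`time_to_threshold` inverts f(t) = 0.30 numerically by bracketed root
finding on [0, 10·t_max] (Brent, xtol 1e-10, so the curve evaluated at the
root returns the threshold to well under 1e-6); one code path serves all
step counts, anchored in tests against the one-step closed form
−ln(1 − thr/Cmax)/k.  The timing is censored — rendered "> t_max min" —
when the plateau does not exceed the threshold or the crossing falls beyond
the last observed timepoint.  The 30% threshold is a comparative convention;
it carries no mechanistic meaning, and `k` itself is not interpreted.

### Uncertainties

`estimate_uncertainties` runs a parametric bootstrap: resample
`n_colocalized ~ Binomial(n_dna, f̂(t))` per replicate and timepoint from
the fitted curve, refit with the selected step count, and report the SD of
`Cmax` and `T30` over (default 200) bootstrap replicates.  Censored
bootstrap T30 values are excluded; if more than half are censored, `se_t30`
is reported absent.  This is the package's convention for uncertainties —
chosen because it needs only the fitted curve and the counting design — not
a reproduction of any particular published error analysis.  On
design-sized data (3000 × 3 replicates) it yields `se_cmax` ≈ 0.003–0.005
and `se_t30` below a minute for a well-constrained curve, the same order as
error bars quoted for comparable experiments (±1%, ±4 min).

### Identifiability limits

Two regimes of the 9-point schedule are intrinsically uninformative, and no
estimator can repair them:

* If the rise completes before the second sampled timepoint (T30 ≈ 4 min
  with a low plateau), the data contain almost no information about the step
  count: n = 2 vs 3 vs 4 differ only inside the unsampled first 5 minutes.
  Parameter recovery tests therefore assess step-count recovery pooled
  across the condition grid, and n = 3 vs 4 are near-degenerate everywhere.
* If the plateau is not approached within 180 min (slow one-step curves),
  `Cmax` is weakly constrained and its error can exceed the few-per-mil
  typical of well-sampled conditions.

## Imaging

`detect_spots` band-passes the field with a difference of Gaussians (σ and
3σ, with σ the PSF width in px), finds local maxima at minimum distance 2σ,
and keeps those whose filtered amplitude exceeds `threshold_k` (default 5)
times a robust noise scale, 1.4826 × MAD of the filtered image — MAD rather
than SD because bright spots inflate the SD.  Maxima within ⌈3σ⌉ px of the
border are discarded.  Subpixel positions come from a Gaussian-masked
iterative center of mass in a (2⌈3σ⌉+1)² window on the background-subtracted
image: the Gaussian mask (width σ) is recentered on the running estimate
until convergence.  A plain windowed centroid is biased toward the window
center (shrinkage) and measurably less precise; the masked iteration removes
the bias and empirically reaches the Cramér–Rao bound for this noise model,
(noise SD / peak amplitude)·√(2/π) px per coordinate for a Gaussian PSF
sampled at ~1 px — ≈ 0.16 px at SNR 5 and 0.08 px at SNR 10.  Localization
accuracy is quoted per coordinate axis (the standard localization-precision
convention); the radial error is √2 larger.

`match_spots` performs greedy one-to-one closest-pair matching within a
radius, ties broken toward the lower reference index.  At sparse density
this equals the optimal assignment, and every decision is auditable.  The
default colocalization radius is 1.5 px (≈165 nm at 0.11 µm/px, ≈240 nm at
0.16 µm/px): below half the minimum simulated spot separation, and small
enough that chance colocalization at 200 spots per 512×512 field stays well
under 1% (expected λπr² ≈ 0.6% at that density).  The radius is a
convention of this package (centroid distance, not segmented-object
overlap) and is the main knob trading sensitivity against the chance floor.

Fractions are computed per replicate by pooling counts across fields (sum
numerators and denominators, then divide), matching the ≥3000-molecule
pooled denominator of the assay design; a warning fires when the pooled
count falls short.  A timepoint with zero detected DNAs is recorded as
missing, not as zero.  `estimate_chance_colocalization` transposes the GFP
coordinates (x↔y; scaled remap for non-square fields) and re-scores,
destroying true spatial correlation while preserving density — an in-assay
estimate of the chance floor, complementary to the simulated zero-binding
control.

## Photobleaching

Steps are changepoints of a piecewise-constant fit minimizing within-segment
RSS plus `penalty × σ² × log(n)` per changepoint, with σ estimated from
first differences (MAD-based, ÷√2) so the steps themselves do not inflate
it.  The default multiplier 3 is a BIC-flavored choice.  Segments must
persist at least two frames: a one-frame excursion is noise, not bleaching.
The optimum is computed exactly by O(n²) optimal-partitioning dynamic
programming, so the segmentation provably equals exhaustive enumeration of
changepoint placements under the same objective — a property the test suite
checks directly on short traces.  Exact DP was chosen over greedy binary
segmentation precisely because greedy search cannot guarantee that
equivalence.  Counting is sign-agnostic, with a downward-only count carried
alongside; `single_molecule_fraction` reports the fraction of traces with
exactly one downward step.  Doubling the penalty never increases the step
count (standard monotonicity of penalized segmentation).

## Synthetic data

The generator's defaults are the assay's design conditions: 512×512 px
fields at 0.11 µm/px, PSF σ = 1.3 px (diffraction-limited spot at ~600 nm
emission and 0.11 µm sampling), the 9-point schedule, 3 replicates, and
200 DNAs per field × 16 fields so ≥3000 DNAs pool per timepoint.  Surface
density is not specified by the assay description, so 200/field was fixed
once as a realistic sparse density (mean nearest-neighbor spacing ≈ 19 px ≈
2 µm); spots are placed uniformly with a minimum separation of 4σ by
rejection sampling, consistent with the sparse tethering that makes
single-molecule scoring valid, and with an edge margin of ⌈3σ⌉+2 px so that
every generated molecule lies in the detector's analyzable (non-border)
region.  Default SNRs are 10 (DNA channel) and 8 (GFP): typical for
washed-field TIRF with organic dyes vs GFP.

Each DNA is independently bound with probability f(t) from the generating
curve (Bernoulli per DNA per timepoint; zero in `mutant_mode`), and GFP
spots are rendered only at bound DNA positions — no orphan GFP signal unless
a false-colocalization rate is enabled.  Camera noise is additive Gaussian
on a constant background; amplitude = SNR × noise SD.  Channel
mis-registration is a configurable constant offset.  `simulate_series`
skips rendering entirely and draws binomial counts from f(t) — the
appropriate tool for kinetics-level questions, since detection at design
SNR is essentially lossless.  `simulate_specificity_field` places equal
numbers of DNA and GFP spots independently, the zero-binding control.

What the generator does **not** emulate: lysate autofluorescence, uneven
illumination or flat-field structure, stage drift, fluorophore blinking,
EMCCD gain statistics (shot noise), or chromatic aberration beyond a
constant offset.  Passing tests therefore demonstrate correctness of the
measurement and inference chain under idealized optics, not robustness to
every real-microscope artifact; the detection thresholds and radius were
chosen to have headroom rather than to sit at the edge of the idealized
regime.

Photobleach traces are piecewise-constant with the configured number of
equal downward steps at uniformly drawn interior frames (excluding the
first/last 5%), plus Gaussian noise of SD step_height/SNR.

## Problem sizes in the shipped tests

The test suite runs the assay at its design scale where the check is about
statistics (3000 × 3 replicates, 100-seed recovery ensembles) and at reduced
field counts where the check is about imaging mechanics (2 fields per
timepoint suffice to verify fraction accuracy against per-field ground
truth, since the comparison is to the realized bound state rather than to
the noiseless curve).  The acceptance script simulates the specificity
series at full per-timepoint scale (16 fields × 200 DNAs × 9 timepoints ×
10 seeds).
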