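# Methods

This note documents the models implemented in `nucleoflux`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions. Every empirical number mentioned
here is computed by the test suite or the example scripts.

## Two-compartment transport model

Nuclear and cytoplasmic concentrations of a light-gated probe are assumed
to exchange by first-order kinetics. During the recovery phase (light
off, import signal exposed) both relax with a single rate `k = k_I + k_E`:

    [N](t) = [N]_e − ([N]_e − [N]_0) e^{−kt}
    [C](t) = [C]_e + ([C]_0 − [C]_e) e^{−kt}

Mass conservation couples the amplitudes through the relative
nucleus-to-cytoplasm volume factor `v = ([C]_0 − [C]_e)/([N]_e − [N]_0)`,
and for a nucleus that starts empty the ratio collapses to

    [N]/[C](t) = K_e (1 − e^{−kt}) / (1 + v K_e e^{−kt})

with `K_e = [N]_e/[C]_e = k_I/k_E`. Export experiments track `[C]/[N]`
and obey the same functional form with the compartment roles swapped
(`K_e = k_E/k_I`). Three conventions are worth stating because the
surrounding literature is typeset inconsistently:

* `K_e` is the steady-state compartment ratio `k_I/k_E`, not
  `k_I/(k_I + k_E)`; fitted accumulations above 1 (e.g. 1.87) are only
  possible under the ratio reading.
* the volume-factor denominator is `[N]_e − [N]_0` — the unique choice
  under which the closed ratio form follows from the two exponentials.
* both exponentials decay with the same total rate `k`; giving `[N]` and
  `[C]` distinct rates (`k_I`, `k_E`) is inconsistent with a single-rate
  ratio expression and with mass conservation.

The rate decomposition is `k_I = k·K_e/(1 + K_e)`, `k_E = k − k_I`
(import mode; swapped for export), so `k_I/k_E = K_e` holds exactly.

### Fitting

`fit_recovery` performs bounded least squares (`scipy.optimize`,
trust-region reflective) on the recovery-phase ratio series with weights
`1/max(y, 0.05·max(y))` — the natural weighting when intensity noise is
multiplicative — and bounds `K_e ∈ (0, 50]`, `k ∈ (0, 1 s⁻¹]`,
`v ∈ [0.1, 10]`. Initial guesses: `K_e⁰` = final ratio, `k⁰ = ln 2 /
t_half`, `v⁰ = 1`. Standard errors come from the weighted-Jacobian
curvature at the optimum.

`k` and `v` are only weakly identified jointly: the plateau pins `K_e`,
while the early-time curvature constrains the product `v·K_e` and `k`
together. Parameter-recovery benchmarks therefore fix `v` at its known
simulated value (policy `("fixed", v)`); on 100 simulated cells at
`K_e = 1.87`, `k = 4.94 ks⁻¹`, `v = 1`, 10% multiplicative noise and 45
one-minute frames this yields median relative errors of ~2% on `K_e` and
~4% on `k_I`. With `v` free (the default for real data, where `v` is
unknown) `K_e` is equally accurate but `k_I` degrades to ~16% median
error — a property of the model, not of the optimizer.

### Quality control

`qc_filter` tags cells, deterministically given thresholds, as:

* `POOR_ACTIVATION` — end-of-activation ratio above 0.5× the cell's
  fitted plateau (the nucleus never emptied);
* `UNPHYSICAL` — non-convergent fit or a parameter within 1% *relative*
  proximity of a bound (absolute-span proximity would misflag every
  slow-exchange fit, since typical `k ≈ 5×10⁻³ s⁻¹` sits near the bottom
  of a (0, 1] range);
* `OUTLIER` — `K_e` or `k_I` beyond median ± 3.5 scaled-MAD within the
  construct group, computed over cells surviving the first two checks.

The MAD rule is a concrete stand-in for the semi-automatic outlier
screening such experiments use; 3.5 scaled-MAD is a conventional robust
cutoff.

### Split statistic and group comparison

`split_percent = 100(mean_N/mean_C − 1)` on accumulations or rates;
reported splits are rounded to the nearest percent. Group comparisons use
the two-tailed Mann–Whitney U (exact where scipy deems it feasible,
tie-corrected normal approximation otherwise). When every observation is
tied the P value is reported as 1 (no evidence either way).

## Image quantification

Frames are background-corrected by subtracting the median of a cell-free
region (clipped at zero) and quantified as integrated-intensity fractions
`N_norm = ΣI_nucleus/ΣI_cell`, `C_norm = 1 − N_norm`; cytoplasm = cell −
nucleus. Ratios of summed intensities differ from concentration ratios by
the compartment area/volume factor, which the fit's `v` absorbs — this is
the documented convention, matching how such data are normalized in
practice. Quantification is exactly invariant under global gain and,
after correction, under a uniform background plane. The recovery clock is
re-zeroed at the first frame after illumination off.

The frame generator uses elliptical compartments with uniform intensity
per compartment, a flat background plane and optional Poisson shot noise
(`gain` photons per intensity unit) and Gaussian blur. It does not model
a PSF by default, photobleaching, or camera-specific noise. At gain 200
the roundtrip error of quantification against the noiseless truth is
≤ 2% RMS over recovery frames with ratio > 0.1; when the nucleus is nearly
empty the relative error of a near-zero ratio is dominated by the
zero-clipping of the background correction and is not a meaningful
accuracy measure.

## Force-ramp unfolding

### FJC elasticity

`x(F) = ΔL_c [coth(β) − 1/β]`, `β = F l_K/kT`, with Kuhn length
`l_K = 1.1 nm` and `kT = 4.11 pN·nm` fixed (experimental temperature;
not recomputed). For `β < 10⁻³` the bracket is evaluated by its series
`β/3 − β³/45` for numerical stability. `contour_from_step` is the exact
inverse at the same force (roundtrip identity to 1e−9 relative).

### Bell-model ramp simulator

Under a linear ramp `F = rt` each state unfolds with rate
`k(F) = k₀ e^{FΔx/kT}`, giving the survival function
`S(F) = exp(−(k₀kT)/(rΔx)(e^{FΔx/kT} − 1))`, sampled by inverse
transform. The most probable rupture force is
`F* = (kT/Δx) ln(rΔx/(k₀kT))`. Simulated extension is the FJC extension
at the current force of all contour released so far, plus linear drift
and Gaussian noise. Bell parameters are free inputs; the defaults used in
tests and examples (`k₀ = 6.3×10⁻³ s⁻¹, Δx = 1.0 nm` and
`k₀ = 2.8×10⁻⁴ s⁻¹, Δx = 0.5 nm`) put the rupture-force modes near 15 and
50 pN at 1 pN/s, the regime of a weak intermediate followed by a stronger
unfolding event with ΔL_c of 22 and 65 nm.

### Step detection

Each sample is scored by the contrast between the medians of the leading
and trailing windows (default 0.5 s). Because force changes by only
~0.5 pN across a window, the elastic baseline is locally flat and no
explicit detrending is needed at these scales. The threshold is the
larger of `min_step` (default 5 nm) and a noise floor
`z·σ̂·sqrt(π/w)`, where `σ̂` is the robust (MAD) noise scale from first
differences and `z` the Bonferroni-corrected normal quantile over the
~n/w independent window positions, calibrated so a pure-noise trace fires
with probability ≤ `fp_rate` (default 0.05). Events are score maxima
above threshold separated by at least one window; the step is the
difference of flanking window medians, `F_U = r·t_U` (force is
deterministic under the ramp), and ΔL_c follows from the FJC inverse at
`F_U`. Measured on 1,000 simulated two-event traces at 1 nm noise:
sensitivity > 95%, ΔL_c bias ≈ +0.3 nm, noise-only false-event rate ≈ 0.
Window-median step measurement slightly overestimates the instantaneous
jump when the baseline drifts; the bias stays well under 1 nm at default
settings.

Marginal modes in `event_summary` are estimated by the argmax of a
Gaussian KDE on a fine grid; for the skewed Bell rupture-force
distribution the KDE smoothing bias is ≈ h²/(2b) ≪ 1 pN at n = 10⁴.

## Backbone hydrogen bonds

Donors are backbone amide N atoms, acceptors carbonyl O atoms, of
residues ≥ 2 apart in sequence. A bond requires donor–acceptor distance
≤ 4 Å and, when the amide hydrogen is present in the coordinates, a
D–H···A deviation from linearity ≤ 30° (N–H···O angle ≥ 150°). Without
hydrogens the bond is accepted on distance alone and flagged `fallback` —
counts from hydrogen-free crystal structures are therefore upper bounds.
Parsing keeps model 1 of an ensemble and the highest-occupancy altloc.
β-strand spans come from CA-geometry secondary-structure annotation
(P-SEA via biotite) of the same coordinates, in sequence order, so for an
Ig-like β-sandwich the first two spans are the A/A′ strands and the last
is G; resolved spans are echoed in CLI output for auditability.
`interstrand_count` is symmetric in its two residue ranges and monotone
in both cutoffs.

## TF disorder survey

Per-TF: one NLS (highest predictor score; ties to the smallest start), one
isoform (longest; ties lexicographic by id). The NLS position is its
interval midpoint; if it falls in the first half of the sequence
(inclusive) the region runs from residue 1 to the NLS end, otherwise from
the NLS start to the last residue — NLS residues are included in the
region, a convention recorded in the output. The survey compares
`{region mean}` against `{full-sequence mean}` across TFs with the
two-tailed Mann–Whitney U, and reports box-plot summaries plus the NLS
relative-position distribution. A paired Wilcoxon on the per-TF
differences is available via `compare_groups` on `region − full` as a
sensitivity analysis; the headline statistic stays unpaired to match
standard practice for these box-plot comparisons.

An operating characteristic worth knowing: the region mean is computed
over a subset of the residues that enter the full mean, so the two groups
are positively correlated within a TF and the unpaired comparison is
*conservative* under the null — simulated type-I error ≈ 0.02 at
α = 0.05 with 300 TFs, not the nominal 0.05. Power against a planted
region-wide elevation of 0.15 at n = 300 is ≈ 100%. A test asserting
nominal type-I behaviour for this design will therefore fail; the
conservatism is a property of applying an unpaired test to nested means,
not an implementation defect.

### Synthetic TF datasets

Lengths uniform on 200–800 residues, NLS lengths 8–16, NLS start uniform,
baseline disorder 0.45, per-residue Gaussian noise (sd 0.15), scores
clipped to [0, 1], region elevation `delta` added before clipping. The
generator does not emulate between-TF baseline heterogeneity, sequence-
dependent disorder structure, or correlated predictor errors; passing
survey benchmarks on it demonstrates the pipeline's selection rules,
averaging and statistics, not the biology of real disorder predictors.

## Cell-simulation conditions

Defaults follow the standard imaging schedule of such optogenetic
experiments: 10 min activation and 45 min recovery at one frame per
minute. Intensity noise is multiplicative lognormal (CV default 0.1,
applied independently per compartment and frame), reflecting that
fluorescence noise scales with signal; the activation phase reuses the
first-order machinery with the export signal exposed (steady-state ratio
0.05, rate 4× the recovery `k`, both free parameters), starting from the
nuclear-accumulated steady state. With `activation_duration = 0` the
recovery starts from an exactly emptied nucleus, which is the regime the
closed-form fit assumes; after a finite activation phase the residual
nuclear fraction (< 10% of `N_e` at defaults) introduces a small model
mismatch of the same kind real cells show. Noiseless simulations conserve
`v·[N] + [C]` to 1e−9 at every frame, and identical specs and seeds give
bit-identical outputs (`numpy.random.default_rng`).

## Problem sizes

Benchmarks use 100 cells per construct, 1,000 ramp traces per detection
benchmark, 10,000 rupture-force draws, and 1,000 replicate surveys of 300
TFs — sizes at which the Monte-Carlo error of each reported rate or bias
is comfortably below the asserted tolerance while the whole suite runs in
about a minute on one core.

## Known limitations

* The kinetic model is two-pool and first-order; it does not represent
  photoswitching kinetics of the LOV2 domain, importin binding, or
  multi-compartment trafficking.
* Step detection assumes a monotone force ramp and upward steps; it is
  not a force-clamp dwell analyzer.
* Hydrogen-bond counts on static native structures need not equal the
  number of bonds disrupted along a mechanical unfolding trajectory;
  terminal-anchoring comparisons should be read qualitatively.
* The survey consumes external disorder/NLS predictions as given; nothing
  is inferred from sequence here.
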