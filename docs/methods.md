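# Methods

## Forward signal model

Each voxel's hyperpolarized magnetization follows the forward-only two-pool
exchange

    dP/dt = u(t) − P/T1_pyr − k_PL·P
    dL/dt = k_PL·P − L/T1_lac

where `u(t)` is the pyruvate delivery rate. The reverse rate k_LP, and the
bicarbonate and alanine pools, are deliberately absent. Delivery is a
normalized gamma-variate, `u(t) = A·((t−t₀)/(αβ))^α·exp(α − (t−t₀)/β)` for
t > t₀, which peaks at exactly `A` at `t₀ + αβ`. Defaults: t₀ = 4 s (imaging
starts before bolus arrival), α = 2, β = 3.5 s (peak at 11 s, bolus washed
out within ~40 s), A = 1 (arbitrary magnetization units; every downstream
metric is scale-invariant or reported relative to noise).

At every frame time (Δt = 3 s, 20 frames = 57 s by default — the frame count
is a configuration choice, chosen to cover the full bolus passage) each
metabolite is excited once with its protocol flip angle: the recorded signal
is `M_z·sin θ·exp(−TE/T2*)` and the remaining magnetization is `M_z·cos θ`.
Per-slice excitation multiplicity is not modeled; one effective excitation
per metabolite per frame matches the effective-TR convention of the
inputless fit. The ODEs are integrated with classical RK4 at a fixed 0.1 s
substep (≥30× finer than the frame spacing); halving the step changes the
signals by <1e−6 relative, so discretization error is negligible against the
fitting tolerance.

Vessel voxels receive a 10× pyruvate input and convert nothing (k_PL = 0),
emulating the large intravascular pyruvate pool that dominates ratio maps.
Noise is zero-mean Gaussian per voxel-frame; a Rician magnitude option
exists but is off by default because the analysis operates at summed SNR
≈ 10–14, where the Gaussian approximation holds.

### Study generator

A study draws each exam's true rate as
`k_PL = mean + b_subject + c_site + e_exam` with independent Gaussian
components, truncated below at 1e−4 s⁻¹ (a negative rate constant is
unphysical). The implied site-level ICC(A,1) is
σ_b²/(σ_b² + σ_c² + σ_e²). Defaults: mean 0.024 s⁻¹, σ_b = 0.0018,
σ_c = 0.0004, σ_e = 0.0007 s⁻¹ — magnitudes consistent with healthy-brain
repeatability data and an implied ICC of ≈0.83. The default layout is the
traveling-volunteer design: 3 subjects, 2 sites, eight single-resolution
(protocol 1) exams split 3/3/2 across subjects at both sites plus four
variable-resolution (protocol 2) exams at site 1 (3/4/5 exams per subject,
12 total).

Acquisition noise defaults are calibrated so a default tissue voxel's
time-summed pyruvate SNR is ≈11 under each protocol: SD 0.068 for
protocol 1 and 0.012 for protocol 2 (the variable-resolution protocol's
heavy T2* loss at TE 30.7 ms is compensated in vivo by its much more
sensitive 24-channel receive array; a single noise level would render one of
the protocols unusable, which is not what the instrument pairing produces).

What the generator does *not* emulate: EPI k-space artifacts, B0
inhomogeneity and off-resonance, coil sensitivity profiles, partial-volume
effects at ROI boundaries, physiological variation of T1 and bolus shape
within a study, and spatial heterogeneity of k_PL within tissue (all tissue
voxels of an exam share one rate). Passing tests therefore demonstrate the
correctness and internal consistency of the estimators under the stated
statistical model, not robustness to every artifact of real acquisitions.

## Kinetic fitting

The fit is inputless: measured pyruvate signal is converted to magnetization
by dividing by sin θ_P and treated as the known driver, so no bolus model is
assumed. Lactate propagates by the trapezoid rule between frames with
relaxation weighting (see README for the recursion); the discretization was
validated against the continuous simulator — noise-free recovery error is
≤0.2% across k_PL ∈ [0.01, 0.05] s⁻¹, well inside the 5% acceptance band.

Choices that are fixed rather than fitted:

* **T1_lac = 25 s** (configurable). Joint (k_PL, T1) estimation from
  single-bolus data is ill-conditioned; fixing the lactate T1 is standard
  practice. The value used by any given human study is rarely stated, so it
  is exposed as configuration and recorded in outputs.
* **lac0 from the first lactate frame.** Imaging begins before bolus
  arrival, so the initial lactate magnetization is essentially noise;
  fitting it would add a degenerate degree of freedom.
* **Bounds [0, 0.3] s⁻¹, initial estimate 0.02 s⁻¹.** Forward-only
  physicality with a ceiling an order of magnitude above healthy-brain
  means.
* **Per-voxel SNR gate (default 3)** on time-summed pyruvate
  (`AUC/(σ·√n_frames)`). Voxels failing the gate are flagged unfitted, never
  zero-filled. A 3-SD gate admits pure-noise voxels at the expected far-tail
  rate (~0.1%); this is accepted rather than hidden.

The single free parameter is solved with bounded least squares (trust-region
reflective, tolerances 1e−14), giving recovery of discrete-model data to
better than 1e−6 relative.

## Model-free metrics

The lactate/pyruvate ratio is defined on time-summed signals as the ratio of
ROI means (not the ROI mean of voxelwise ratios, which is noise-unstable;
the convention is recorded here because either reading is defensible). When
the pyruvate grid is finer than the lactate grid (variable-resolution
protocol), pyruvate is block-averaged onto the lactate grid first — block
averaging preserves ROI means. The Z-score uses the population SD over
brain voxels, making it exactly invariant to any global lactate scaling —
which is why the echo-time correction is never applied to it. ROI summary
statistics use the sample SD; a single-voxel ROI reports SD 0 by convention.

## Echo-time harmonization

T2* is taken from the non-localized post-imaging spectrum linewidth under
the Lorentzian convention T2* = 1/(π·FWHM); a Gaussian option is omitted to
keep a single convention. The correction multiplies each metabolite channel
by exp(+TE/T2*): the corrected quantity is the TE = 0 signal, which can only
exceed the observed, decayed signal, so factors are ≥1 by construction (the
sign is a documented constant, not configuration). Correction is applied to
the signals before fitting, so it propagates consistently to every metric;
the fitted k_PL changes exactly by factor_lac/factor_pyr and the Z-score not
at all. An exam without a spectrum receives the arithmetic mean of the
measured *factors* (not of the T2* values) of the other exams under the same
protocol, with provenance recorded.

## Repeatability statistics

ICC(A,1) — single-measurement, absolute agreement, two-way random effects —
is computed from the ANOVA mean squares. Single-measurement (not
average-measures) is used because the study compares single site-level
measurements per subject; the average-measures form is a documented switch
away. Significance of H₀: ICC = 0 uses F = MS_R/MS_E on (n−1, (n−1)(k−1))
degrees of freedom. Interpretation bands are left-closed:
[0.5, 0.75) moderate, [0.75, 0.9) good, ≥0.9 excellent.

Aggregation: in site mode, all of a subject's exams at one site are averaged
into the cell; a subject missing a site is an error, not an imputation. In
examination mode, columns are chronological exam indices truncated to the
minimum count across subjects — truncation keeps the two-way ANOVA balanced;
REML-based unbalanced estimation is a noted extension, not the default. A
table whose total variance is at floating-point round-off scale is treated
as exact agreement (ICC 1, warning logged) in the reporting path, while the
low-level estimator raises, keeping silent degeneracy impossible.

The sample-size planner inverts the asymptotic half-width of the ICC
estimator: n = ⌈1 + 2·z²_{1−α/2}·(1−ρ)²(1+(k−1)ρ)²/(k(k−1)w²)⌉, floored at
2. The companion confidence interval is computed on the variance-stabilized
scale z = ½·ln((1+(k−1)ρ)/(1−ρ)), whose asymptotic SE,
√(k/(2(k−1)(n−1))), is the delta-method image of the planner's variance
term — so planner and interval are mutually consistent — while holding
finite-sample coverage near nominal (≈94% at n = 14) where the plain Wald
interval undercovers (≈90%).

## Pipeline

`RunConfig` (pydantic-validated, YAML-loadable) fixes every tunable and one
master seed; a run is deterministic end to end, byte-identical in its CSV
outputs. The acquisition constants of the two protocols (flip angles 10°/40°
and 20°/30°, TE 21.7/30.7 ms, 3 s frames) are part of the protocol table,
not free configuration. The multi-site analysis uses protocol-1 exams only
and reports per-ROI summaries plus ICC tables under both aggregation modes;
the protocol comparison quantifies all exams twice (uncorrected, corrected)
and reports the relative between-protocol difference of whole-brain k_PL and
ratio. Test and example runs use a 16×16×6 phantom (~200 converting voxels);
the phantom default is 24×24×8. Simulated ground-truth T2* defaults are
(18.0, 16.7) ms for protocol 1 and (8.9, 7.5) ms for protocol 2 —
volume-coil versus multichannel-coil magnitudes.

## Known limitations

* The discrete trapezoid fit carries a small systematic bias (≤0.2% under
  default conditions) relative to continuous dynamics; it grows with Δt and
  k_PL.
* Global (spectrum-derived) T2* ignores spatial T2* variation; local
  multi-echo or B0-derived estimates are out of scope.
* The ICC of a 3-subject study is extremely noisy; the package reports it
  faithfully (wide variation across seeds is expected and is the motivation
  for the sample-size planner).
* Ratio metrics are not flip-angle-corrected by construction; cross-protocol
  ratio comparisons remain confounded when flip schemes differ even after
  T2* correction.
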