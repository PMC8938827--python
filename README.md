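# hp13c

Quantification and multi-site repeatability analysis of hyperpolarized
[1-¹³C]pyruvate brain MRI.

Hyperpolarized [1-¹³C]pyruvate MRI watches, in real time, the enzymatic
conversion of an injected pyruvate bolus to lactate. Before the technique can
support multicenter trials, its primary readout — the apparent conversion
rate constant k_PL — must be shown to be repeatable across imaging sites and
acquisition protocols. This package implements the full analysis chain of a
two-site, two-protocol traveling-volunteer repeatability study, together with
a synthetic study generator so that every stage is testable without access to
clinical data. It is intended for imaging scientists developing or validating
hyperpolarized-MRI quantification pipelines and for statisticians planning
multi-site repeatability studies.

## What it computes

**Kinetics.** k_PL is estimated voxel-wise with a forward-only, inputless
two-site exchange model: the measured pyruvate signal drives the lactate pool
(no arterial input function, no reverse rate), with T1 decay and per-excitation
RF depletion. With flip angles θ_P, θ_L, frame interval Δt and
E₁ = exp(−Δt/T1_lac), lactate magnetization propagates as

    L⁻(n+1) = L⁺(n)·E₁ + k_PL·Δt·(P⁺(n)·E₁ + P⁻(n+1))/2,

where ⁻/⁺ denote magnetization before/after each excitation (signal
= M_z·sin θ, depletion = ×cos θ). A bounded least-squares fit over
k_PL ∈ [0, 0.3] s⁻¹ (initial estimate 0.02 s⁻¹) inverts this per voxel, gated
by a time-summed pyruvate SNR threshold.

**Model-free metrics.** Lactate-to-pyruvate ratio of time-summed (AUC)
signals, the lactate Z-score (ROI lactate in whole-brain voxel SDs from the
whole-brain mean), and summed-signal SNR against a noise region outside the
head; plus phantom QA (double-angle B1⁺ mapping, phantom SNR).

**Harmonization.** The two protocols differ in echo time (21.7 vs 30.7 ms)
while metabolite T2* is short (≈8–18 ms), so quantification differs by tens of
percent between protocols. A global per-metabolite T2* from the post-imaging
spectrum linewidth (T2* = 1/(π·FWHM), Lorentzian) rescales each channel to its
TE = 0 amplitude via S₀ = S·exp(TE/T2*).

**Repeatability statistics.** ICC(A,1) — the single-measurement intraclass
correlation for absolute agreement under a two-way random-effects model —
from the ANOVA mean squares

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)),

with F-test, interpretation bands (poor/moderate/good/excellent), Welch
t-tests, a variance-stabilized confidence interval, and the matching
precision-based sample-size planner
n = ⌈1 + 2·z²·(1−ρ)²(1+(k−1)ρ)² / (k(k−1)w²)⌉.

**Synthetic studies.** A labeled head phantom (whole brain, cortex, deep white
matter, vessel, outside-head noise region), gamma-variate bolus input,
fine-grid RK4 integration of the exchange ODEs, per-metabolite T2*
attenuation, Gaussian (optionally Rician) noise, and
between-subject/between-site/residual variance components on k_PL so that the
generating ICC of a study is known exactly.

## Worked example

Plan a confirmatory study (how many volunteers to confirm a site-to-site ICC
of 0.8 within ±0.2 at 95% confidence, two sites?):

```sh
$ hp13c plan-samplesize --rho 0.8 --w 0.2 --k 2
{"rho": 0.8, "w": 0.2, "alpha": 0.05, "k": 2, "n_required": 14}
```

Fourteen volunteers at two sites (ten if each travels to three sites).

Echo-time correction factor for the variable-resolution protocol
(TE = 30.7 ms) given a 35.76 Hz pyruvate linewidth:

```sh
$ hp13c harmonize --te 30.7 --fwhm 35.76
T2* = 8.90 ms; correction factor exp(TE/T2*) = 31.467
```

A short T2* at a long echo time implies a ~31× signal loss — exactly why
cross-protocol comparison fails without correction.

Run the full cross-protocol comparison on a simulated study:

```python
from hp13c.pipeline import RunConfig, run_protocol_comparison

cfg = RunConfig(seed=1, phantom={"shape": (16, 16, 6)})
bundle = run_protocol_comparison(cfg)
print(bundle["discrepancy"].to_string(index=False))
```

```
  metric_name  correction  protocol1_mean  protocol2_mean  rel_difference
         k_pl uncorrected          0.0207          0.0118          0.4335
         k_pl   corrected          0.0228          0.0224          0.0180
lac_pyr_ratio uncorrected          0.3143          0.0942          0.7002
lac_pyr_ratio   corrected          0.3452          0.1794          0.4803
```

Uncorrected, the two protocols disagree on whole-brain k_PL by ~43%; after
T2* correction they agree within 2% (the generating k_PL was 0.024 s⁻¹; the
whole-brain mean sits slightly lower because intravascular voxels convert no
pyruvate). The lactate/pyruvate ratio remains discrepant even after
correction because, unlike the kinetic fit, it does not account for the
different flip-angle schemes — the argument for model-based metrics in
multi-protocol settings.

Other CLI verbs: `simulate` (write a synthetic study as NIfTI + manifest),
`quantify` (metrics from a written study), `report` (same-protocol multi-site
ICC analysis), `compare` (as above).

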