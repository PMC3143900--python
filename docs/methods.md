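# Methods

## The measurement

A Tm-shifted melting-curve SNP assay amplifies the two alleles of a SNP
into PCR products with deliberately different melting temperatures,
Tm(A) < Tm(B) (typically 3–5 °C apart). During the post-PCR dissociation
ramp the instrument records fluorescence F(T) of a double-strand-binding
dye; each duplex's melting transition is a sigmoidal drop in F, hence a
peak on the melting curve M(T) = −dF/dT near its Tm. A homozygote shows
one peak, a heterozygote two. The caller's job is to turn one well's
F(T) trace plus the assay definition (Tm(A), Tm(B), allele labels, offset
δ) into an ordinal genotype call 1 (AA), 2 (AB), 3 (BB) or a "no call".

## Differentiation (`curves`)

M is computed with central differences on interior points and one-sided
differences at the two ends (`numpy.gradient`), keeping the original
temperature grid so Tm-anchored region lookups stay aligned. Non-uniform
grids are supported by dividing by the local step. Optional Gaussian
smoothing (`scipy.ndimage.gaussian_filter1d`, reflective padding) is
applied after differentiation, with sigma given in °C and converted to
samples by the median grid step. Smoothing is **off by default**: on the
0.2 °C instrument gradient the raw derivative is clean enough, and
differentiation and Gaussian filtering commute, so the order of the two
operations is immaterial away from the edges.

## Peak detection and the signal ratio (`peaks`)

Search regions extend each theoretical Tm by half the Tm gap on each side:

    R_A = (2·Tm(A) − Tm(B), (Tm(A)+Tm(B))/2]
    R_B = ((Tm(A)+Tm(B))/2, 2·Tm(B) − Tm(A)]

both half-open on the left. Within a region, zero crossings of the
discrete first difference of M classify extrema: a +→− crossing is a peak,
−→+ a valley. Valleys are logged but never reported as allele signal.
Peak height is read at the crossing sample with no sub-grid interpolation
(discretisation error on a 0.2 °C grid is far below the calling margin);
on an exact-zero plateau the last plateau index is taken, and ties between
equally tall peaks go to the lower temperature — both rules purely for
determinism.

Signal strengths deduct the arithmetic mean of M over the **whole**
recorded grid from the tallest peak height in each region; a missing peak,
or one whose deducted height is negative, contributes zero (the clamp
keeps x in [0, 1]). If both D_A and D_B are zero the well is undetectable
(a peak-level no-call); otherwise x = D_B/(D_A + D_B).

Two consequences of the mean-deduction rule are worth knowing:

- The deduction cancels any constant additive offset of M exactly (e.g. a
  linear baseline drift of F), but it biases x away from the underlying
  amplitude share when the two peaks are *unequal*: for peak amplitudes
  with B-share r and curve-mean-to-total-amplitude ratio c, the readout
  gives (r − c)/(1 − 2c) rather than r. On the default synthetic geometry
  c ≈ 0.07, so balanced heterozygotes are read essentially exactly while
  strongly imbalanced ones drift outward — precisely the behaviour the
  SNP-specific offsets δ exist to absorb on real data.
- Additive noise never produces a no-call: noise injects spurious zero
  crossings, and some in-region local maximum always clears the curve
  mean, so a noisy well stays "detectable" with a corrupted ratio. Loss of
  detectability is the signature of absent amplification — a flat or
  monotone M in both regions. The test suite asserts this actual
  behaviour.

## The calling model (`model`, `estimators`)

Genotype classes are ordered (the heterozygote's signal sits between the
homozygotes'), so a proportional-odds (cumulative logit) model with the
single covariate X = x − δ is used:

    logit P(Z ≤ 1) = α₁ − βX,   logit P(Z ≤ 2) = α₂ − βX

with p₁ = logistic(α₁ − βX), p₂ by differencing, p₃ the complement,
evaluated with the numerically stable logistic so p₁+p₂+p₃ = 1 to machine
precision for any real X. α₁ < α₂ guarantees the cumulative ordering;
β > 0 orients increasing X toward class 3. X is deliberately not clamped
to [0, 1].

Calls use a probability margin ρ, branches evaluated in a fixed order
(allele 2, then 3, then 1): a class is called iff its probability exceeds
**both** others by strictly more than ρ, else "no call" with reason
`margin_too_small`. A gap exactly equal to ρ, or an exact tie, is a
no-call. Defaults: ρ = 0.05; the shipped preset `paper-2011` carries
α₁ = 15.3, α₂ = 35.8, β = 51, the published demonstration fit. With ρ = 0
every detectable well receives the argmax class.

`OrdinalGenotypeCaller` exposes this as a scikit-learn classifier
(fit / predict / predict_proba; predict returns 0 for a no-call since the
reject option is intrinsic to the method), and `SnpOffsetCalibrator` as a
transformer, so the two stages compose in a `sklearn.pipeline.Pipeline`.

## Training (`train`)

Offsets: for each genotype class, per-SNP means of x are averaged across
SNPs (unweighted mean of means) to give grand means ⟨x⟩; each SNP's
deviations from ⟨x⟩ over the classes it actually has are averaged into a
single per-SNP scalar (the per-class deviations are retained in the
training report), then rounded half-away-from-zero to one decimal. The
low resolution is deliberate: most SNPs keep δ = 0 and share one model.
The mean-over-available-classes reduction is this package's choice; so is
the rounding rule.

Coefficients: Newton–Raphson on the cumulative-logit log-likelihood with
an analytic gradient, finite-difference Hessian, and step-halving (the
accepted log-likelihood path is monotone). Initialisation: α's at the
logits of the empirical cumulative class frequencies, β = 0. Convergence:
max-norm of the gradient below 1e−8, at most 100 iterations. All three
classes must be present; wells without detectable peaks carry no x and are
excluded.

Separation: steep fitted slopes (like the preset's β = 51) indicate
nearly separated classes, where the likelihood is unbounded. Divergence is
detected two ways and reported (warning + `separated_` flag) rather than
raised: any coefficient exceeding a cap (default 500), or the
log-likelihood plateauing above −1e−3 — the separated-data supremum is 0
and is reached numerically, at moderate coefficient values, before any
reasonable cap. No regularisation is applied by default; near separation
the *point estimates* have large sampling variance even when the optimiser
is exact (the package's fits agree with an independent ordered-logit
implementation to ~1e−6 on the same data), which is why calling uses
pre-trained, frozen coefficients.

## Synthetic curves (`synth`)

The generator builds a target melting curve as one or two Gaussian peaks
(amplitudes amp_a, amp_b forced by genotype; a single shared Tm jitter
draw per well emulating plate-level temperature offset), integrates −M*
cumulatively into F (trapezoid rule, F₀ = 100), then adds linear baseline
drift and i.i.d. Gaussian noise to F — noise enters before
differentiation, so the derivative amplifies it as on a real instrument.
Defaults: grid 60–95 °C in 0.2 °C steps (the instrument ramp), peak sigma
1.0 °C (bell widths of typical derivative melt peaks), Tm jitter SD
0.3 °C, baseline slope −0.05 /°C, noise SD 0.01 fluorescence units,
amplitude 2.0.

`generate_panel` labels every well and includes a weak-first-allele
heterozygote subpopulation: a fixed share of het wells (default 2%,
shrink factor 0.2) has its A-peak amplitude shrunk, pushing x toward 1 so
those hets are miscalled as BB — the discordance mode seen on real
Tm-shifted panels, at roughly its observed prevalence. The share is a
deterministic count (round(fraction × n_hets), positions random), making
the panel composition a controlled condition rather than a binomial draw.

What the generator does **not** emulate: thermodynamic melt shapes
(two-state duplex melting gives slightly asymmetric peaks), primer-dimer
and multi-product artifacts, plate-position effects, or SNP-specific
signal bias (demo assays all have δ = 0). Passing the synthetic
end-to-end checks therefore demonstrates the pipeline's correctness and
its qualitative failure modes, not instrument-level accuracy on real
exports.

## Problem sizes and determinism

The end-to-end panel check uses 12 assays × 3 genotypes × 15 wells
(540 curves, 176 samples each) at the default noise; parameter-recovery
checks use 2 000 wells in the well-conditioned regime and 500 in the
steep regime, matching the scale of the demonstration dataset. All
randomness flows through seeded `numpy.random.default_rng` generators;
identical seeds give bit-identical curves and fits.

## Known limitations

- Peak "height" is the absolute M value minus the curve mean, not
  prominence relative to neighbouring valleys; a tall shoulder inside a
  region can therefore out-compete the true allele peak.
- A real Tm drifting outside its search region entirely makes the allele
  invisible (assay failure); such wells become no-calls or one-sided
  calls.
- Single-covariate model: no per-SNP slopes, no covariates beyond X, no
  posterior calibration beyond the three probabilities.
- VCF is deliberately not emitted: these are single-SNP, non-positional
  assay calls that do not map cleanly onto VCF records.
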