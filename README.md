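# meltcall

Supervised genotype calling for Tm-shifted melting-curve SNP assays.

Tm-shifted assays genotype a SNP with two allele-specific forward primers
(plus a common reverse primer) designed so the two allele PCR products melt
at distinct temperatures, Tm(A) < Tm(B). After amplification the instrument
records a dissociation curve — fluorescence F of a double-strand dye while
the temperature T ramps up — and each allele present in the sample shows up
as a peak on the melting curve M = −dF/dT near its theoretical Tm.
Unsupervised callers cluster a whole plate of the same SNP at once and need
all three genotypes present; a clinical lab that receives samples one at a
time needs a *supervised* caller with pre-trained, SNP-portable
coefficients. That is what this package implements.

## Method

For each well:

1. **Melting curve** — M = −dF/dT (central differences; optional Gaussian
   smoothing).
2. **Region-anchored peak detection** — allele signals are searched inside

       R_A = (2·Tm(A) − Tm(B), (Tm(A)+Tm(B))/2]
       R_B = ((Tm(A)+Tm(B))/2, 2·Tm(B) − Tm(A)]

   Zero crossings of dM identify peaks; the tallest peak height in each
   region, minus the mean of M over the whole curve, gives the signal
   strengths D_A and D_B (zero if no peak). If both are zero the well is a
   **no call**. Otherwise the signal-strength ratio is x = D_B/(D_A + D_B):
   near 0 for homozygous AA, near 0.5 for heterozygous AB, near 1 for BB.
3. **Offset adjustment** — X = x − δ, where δ is a SNP-specific offset
   (one-decimal resolution) aligning each SNP's ratio distribution with the
   cross-SNP grand means, so one shared model covers many SNPs.
4. **Ordinal regression call** — genotypes are ordered classes
   Z ∈ {1 (AA), 2 (AB), 3 (BB)} and a proportional-odds model scores them:

       logit P(Z ≤ 1) = α₁ − βX
       logit P(Z ≤ 2) = α₂ − βX

   with P(Z=2) and P(Z=3) by differencing. A class is called only when its
   probability exceeds **both** others by more than a margin ρ; otherwise
   the well is flagged "no call" for human review.

Training (`meltcall train` or `meltcall.train` / the scikit-learn style
estimators `SnpOffsetCalibrator` and `OrdinalGenotypeCaller`) estimates the
δ's from per-SNP class means and fits (α₁, α₂, β) by Newton–Raphson maximum
likelihood. The published demonstration coefficients α₁ = 15.3, α₂ = 35.8,
β = 51, ρ = 0.05 ship as the preset `paper-2011`.

## Worked example

Simulate a small labelled panel for the 12-SNP demo configuration, then
call it with the preset model:

```sh
meltcall simulate --config examples/demo_config.yaml \
    --out-curves curves.csv --out-truth truth.csv --seed 42 --n-per-genotype 2
meltcall call --curves curves.csv --config examples/demo_config.yaml --out calls.csv
```

which prints

```
simulated 72 wells -> curves.csv, truth -> truth.csv
called 72 wells -> calls.csv (calls: 72, no-calls: 0)
```

and `calls.csv` begins

```
well_id,snp_id,call,genotype,x,X,p1,p2,p3,reason
SNP1-g1-w000,SNP1,allele1,TT,0.0,0.0,1.0,0.0,0.0,ok
SNP1-g1-w001,SNP1,allele1,TT,0.0,0.0,1.0,0.0,0.0,ok
SNP1-g2-w000,SNP1,allele2,TC,0.4976,0.4976,0.0,0.9999,0.0,ok
SNP1-g2-w001,SNP1,allele2,TC,0.4991,0.4991,0.0,0.9999,0.0,ok
```

Each row is one well: the ordinal call and its base-pair rendering, the raw
and offset-adjusted signal ratios, the three class probabilities, and why
the decision was (or was not) made. A heterozygote's ratio sits near 0.5,
so P(Z=2) ≈ 1 and the call is `allele2` (`TC` for a T/C SNP).

The same pipeline is available as a library:

```python
import meltcall as mc

model = mc.get_preset("paper-2011")
assay = mc.SnpAssayDef(snp_id="SNP5", tm_a=78.0, tm_b=82.5,
                       allele_a="C", allele_b="G", delta=-0.1)
curve, _ = mc.generate_well(mc.SynthParams(assay=assay, genotype=2, seed=1))
result = mc.call_well(mc.melting_curve(curve), assay, model)
print(result.call.value, result.x_adjusted, result.probabilities)
```

## Input formats

- **Curves**: long-format delimited text (comma or tab), header
  `well_id,snp_id,temperature,fluorescence`. Instrument exports are
  converted to this dialect by the user.
- **Config**: YAML with a `snps` list (snp_id, tm_a, tm_b, allele_a,
  allele_b, delta) and a `model` block (either `preset: paper-2011` or
  explicit alpha1/alpha2/beta, plus rho and smoothing_sigma); see
  `examples/demo_config.yaml`.
- **Truth table** (training): `well_id,genotype` with genotype ∈ {1,2,3}.

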