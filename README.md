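# gwasmix

Causal Gaussian-mixture modelling of GWAS summary statistics.

`gwasmix` estimates three quantities that jointly describe the genetic
architecture of a complex trait, using nothing but GWAS z-scores and the
LD/heterozygosity structure of a reference panel:

- **polygenicity** π₁ — the fraction of reference-panel SNPs with a non-null
  causal effect;
- **discoverability** σβ² — the variance of causal effect sizes (in units of
  phenotypic variance), i.e. the typical strength of a causal association;
- **residual inflation** σ₀² — a uniform variance distortion of the z-scores,
  e.g. from cryptic relatedness, distinct from stratification-induced bias.

From these it derives SNP heritability h² = π₁·n_snp·H̄·σβ² (with a
liability-scale conversion for case-control traits), the number of causal
SNPs, the genomic-control factor λ, posterior effect sizes E(δ|z), and the
proportion A(N) of SNP heritability captured by genome-wide-significant SNPs
as a function of sample size — a power forecast for future GWAS.

## Model

Each SNP's causal effect follows the point-normal mixture
β ~ π₁·N(0, σβ²) + (1−π₁)·N(0, 0).  Through LD, a typed SNP's z-score picks
up the effects of its neighbours:

    z_i = √N · Σ_j √H_j · r_ij · β_j + ε,   ε ~ N(0, σ₀²),

where H_j = 2p_j(1−p_j) is heterozygosity and r_ij the genotype correlation.
The marginal z-score density is therefore a convolution of two-point
mixtures, one per neighbour in the SNP's LD block.  It is computed *exactly*
on a uniform grid (2¹⁰ points on [−38, 38), Δz = 0.0742) by multiplying
characteristic functions and inverting with an FFT:

    pdf(z) = F⁻¹[ G(k) · E(k) ],
    G(k) = Π_w ( π₁ e^{A_w k²} + 1 − π₁ )^{n_w},   A_w = −2π² N H_w r²_w σ₀²σβ²,
    E(k) = e^{−2π² σ₀² k²},

where {n_w, H_w, r²_w} is the SNP's LD histogram over 20 equally spaced r²
bins on [0.05, 1].  An explicit expansion over causal-count configurations
(the small-block oracle) is also provided and agrees with the FFT to
≤ 1e-6.  Parameters are fit by Nelder-Mead maximum likelihood on multinomial
z-score bin counts, accumulated over a 10×10 heterozygosity × total-LD grid
and averaged over 10 random pruning iterations (r² > 0.8); confidence
intervals come from the inverse observed Fisher information.

## Worked example

Simulate a synthetic study (20,000-SNP block-LD panel, N = 100,000,
π₁ = 2.5×10⁻³, h² = 0.3) and fit it:

```bash
gwasmix simulate --n-snp 20000 --panel-samples 500 --gwas-n 100000 \
    --pi1 2.5e-3 --h2 0.3 --seed 1 --out demo
gwasmix fit --sumstats demo/sumstats.tsv --panel-cache demo/panel.h5 \
    --out demo/fit --seed 2
```

which prints the fitted parameters:

```json
{
  "pi1": 0.0024638468066847763,
  "sigma_beta2": 0.03153923620620293,
  "sigma0_2": 0.9994795365308127
}
```

The generator's ground truth for this seed was π₁ = 2.5×10⁻³,
σβ² = 0.0292, σ₀² = 1: polygenicity is recovered to 1.5%, discoverability
to 8%, and no spurious inflation is reported.  `demo/fit/result.json`
additionally contains λ (empirical 1.119 vs model 1.127), h², causal-SNP
count, confidence intervals, and A(N) at the current sample size; QQ and
power curves are written as TSV.  Chaining into the derived statistics:

```bash
gwasmix derive --params demo/fit/result.json --n-snp 20000 --h-bar 0.22
```

```json
{
  "h2_observed": 0.34191452421249185,
  "h2_liability": null,
  "n_causal": 49.27693613369553
}
```

i.e. ĥ² = 0.34 (true 0.30) from ~49 estimated causal SNPs (true 50).  For a
case-control trait, add `--prevalence`, `--cases` and `--controls` to get
the liability-scale heritability.

Other subcommands: `gwasmix panel` (build an LD cache from a genotype
matrix), `gwasmix power` (A(N) curve), `gwasmix qq` (model vs empirical QQ
curves with a Clopper-Pearson band).

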