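# Methods

## Generative model

We assume a standardized phenotype produced by an additive model over a
reference panel of n_snp common SNPs (MAF ≥ 0.002).  Causal effects follow
the point-normal mixture β ~ π₁·N(0, σβ²) + (1−π₁)·δ₀.  For a typed SNP i
the GWAS z-score aggregates neighbouring causal effects through LD,

z_i = √N Σ_j √H_j r_ij β_j + ε_i,

with H_j = 2p_j(1−p_j) and r_ij the genotype correlation between SNPs i and
j.  The residuals ε_i are taken independent N(0, σ₀²); σ₀² > 1 models
uniform variance distortion (e.g. cryptic relatedness).  Correlations among
residuals induced by LD (a multivariate ε with the r² matrix as covariance)
are deliberately not modelled — this is the main approximation, and it can
produce mild misfit at very high polygenicity.  Bias shifts from population
stratification are likewise outside the model; we assume they were removed
upstream.

The three inflation-aware parameters are (π₁, σβ², σ₀²).  Internally the
genetic variance always appears through the product σ̃β² = σ₀²σβ², so the
reported σβ² is automatically "corrected for inflation", and heritability
estimates use the uninflated σβ².

## LD structure

Everything the likelihood needs about a SNP is its LD histogram:
w_max = 20 equally spaced r² bins on [r2_min, 1] with r2_min = 0.05
(roughly the estimation noise floor of a few-hundred-sample panel), holding
the neighbour count n_w (self included at r² = 1), the mean neighbour
heterozygosity H_w, and the bin-midpoint representative r²_w.  Bin edges
are half-open [lo, hi) with the final bin closed at 1.  The total LD
L = Σ_j r²_ij over stored entries (an LD score truncated at the noise
floor, self included) and the block size n = Σ_w n_w are both available as
data-reduction axes; L is the default, block size sits behind
`use_block_size=True`.  r² is computed from genotype dosages without
phasing, and a configurable index window (default ±1,500 SNPs) bounds the
sparse scan.

For fitting, typed SNPs are coarse-grained onto a 10×10 grid of equally
spaced heterozygosity × total-LD bins.  Per occupied bin the member
histograms are averaged: counts as unweighted real means, H_w as
count-weighted means (so pooled neighbour heterozygosity is conserved).
Empty bins simply never enter the cost.  The averaged real-valued counts
are used directly as exponents of the characteristic function, which is
well defined for real n_w; the expansion oracle instead rounds to integers.

## The z-score pdf

Because the z-score is a sum of independent mixture contributions, its
density is computed spectrally on a uniform grid of n = 2¹⁰ points from
z₁ = −38 (Δz = 0.0742), which accommodates two-sided p-values down to
5.8×10⁻³¹⁶.  With the e^{−2πikz} kernel, each neighbour in window w
contributes the factor π₁e^{A_w k²} + 1 − π₁ with
A_w = −2π²·N·H_w·r²_w·σ̃β², the environment contributes e^{−2π²σ₀²k²}, and
the pdf is the inverse FFT of the product, evaluated in the log domain for
numerical safety, clipped at −10⁻¹² and renormalized.  The alternative
route enumerates configurations (k_1…k_w) of causal neighbours per window,
weighting φ(z; 0, Σ k_w H_w r²_w σ̃β²N + σ₀²) by per-window binomial
probabilities Π_w C(n_w,k_w)π₁^{k_w}(1−π₁)^{n_w−k_w}.  These weights are
the exact term-by-term expansion of the characteristic-function product
(a single multinomial over w+1 SNP categories with window-membership
priors is its small-π₁ approximation and differs at the 10⁻⁴ level); the
two routes agree to ~10⁻¹⁰ sup-norm on small blocks and the expansion is
kept as an oracle, truncated at K_max = min(20, n) with total configuration
count capped.

## Fitting

Within each occupied H-L bin, z-scores of randomly pruned SNPs (threshold
r² > 0.8, 10 iterations, one uniformly random representative per synonymous
set per iteration, implemented as a seeded random sweep) are counted into
Δz-wide bins, and the model pdf supplies per-bin probabilities (floored at
10⁻³⁰⁰).  The cost is the multinomial negative log-likelihood with the
parameter-free log-coefficient omitted — absolute cost values are therefore
convention-dependent — averaged across pruning iterations and summed over
bins; since the probabilities do not depend on the pruning, the average is
evaluated on pruning-averaged counts.  Minimisation is Nelder-Mead in
unconstrained coordinates (logit π₁, log σβ², log σ₀²), x-tolerance 10⁻⁴,
f-tolerance 10⁻⁶, ≤2,000 evaluations, with one restart from the first
optimum.  Before the simplex starts, a cheap ladder of method-of-moments
candidate starts (π₁ ∈ 10⁻⁵…10⁻², σβ² matched to the excess z variance
through var(z) = σ₀² + Nσ̃β²π₁·S̄) is scored and the best seeds the search;
without it a single fixed start can strand the simplex in a null basin when
discoverability is orders of magnitude away.  Per-SNP sample sizes are
summarised by their median for pdf construction.

Confidence intervals use the observed Fisher information: a central-
difference Hessian of the cost in the transformed coordinates, inverted
(nearest-PSD repair with a flag if needed), with 95% intervals formed in
transformed space and mapped back so they respect parameter domains, and
delta-method propagation (including covariances) for h².

## Posterior effects and power

The latent effect δ (z = δ + ε) has prior density F⁻¹[G] — the z pdf with
the environmental factor dropped — on the same grid as z.  Posterior
moments E(δ|z), E(δ²|z) follow by quadrature with likelihood
φ(z; δ, σ₀²).  The proportion of SNP heritability captured by SNPs
reaching |z| > z_t (z_t = Φ⁻¹(1 − p/2), 5.45 at p = 5×10⁻⁸) is

A(N) = Σ_{H,L} Σ_{|z|>z_t} C(z) / Σ_{H,L} Σ_z C(z),  C(z) = E(δ²|z)P(z).

C is evaluated spectrally: the Fourier transform of δ²·pdf_δ is
−G″(k)/4π² with G″ computed analytically, and multiplying by E(k) restores
spectral decay — this keeps A(N) accurate even when the δ prior is far
narrower than the grid spacing (small N), where a naive grid convolution
shows aliasing ripple.  H-L bins are weighted by their SNP membership so
the ratio represents the panel rather than the uneven grid occupancy.  The
known caveat that genome-wide-significant SNPs may have atypical LD
structure is not corrected; A(N) is exact only insofar as those effects
cancel in the ratio (they do as A → 1).

## Derived statistics

h² = π₁·n_snp·H̄·σβ² on the observed scale; for ascertained case-control
studies the liability-scale value multiplies by K(1−K)/(P(1−P)) (ratio of
phenotypic variances) and rescales by K(1−K)/a², where a = φ(z_K) at the
truncation point with upper-tail mass K (z_K by inverse normal cdf, no
approximation tables).  Panel constants for an 11M-SNP common-variant
panel (n_snp = 11,015,833, H̄ = 0.2165) are defaults so published parameter
sets can be chained without the underlying genotypes.  Headline values are
conventionally reported at 2 significant figures; JSON artifacts keep full
precision.  N_eff = 4/(1/N_cases + 1/N_controls).  λ is median z²/0.455,
reported both empirically (on the pruned selection by default — full-set
values run higher) and from the model's weighted mixture median.  QQ
curves evaluate the H-L-weighted model tail on a 10,000-point nominal |z|
vector (refinement beyond that changes the curve by <10⁻³), with an exact
Clopper-Pearson 95% band using n_tot/f effective trials (f = 10
approximates LD between scores).

## Synthetic data

The generator produces what the estimator consumes, at desk scale:

- **Panels.** LD blocks (geometric sizes, mean 25, capped at 100) built
  from pools of 32 founder haplotypes; founder alleles follow a Markov
  copying process along the block (switch probability 0.1), and cohort
  haplotypes resample the pool mutation-free, so realised r² spans the
  noise floor to 1 with the sampling noise of a 500-sample panel.  Base
  MAF follows 0.002 + 0.498·u^3.1, calibrated once so the realised panel
  mean heterozygosity is ≈0.22, typical of a common-variant panel; the
  floor MAF ≥ 0.002 is enforced by resampling.
- **Effects.** Causal SNPs drawn uniformly (count = round(π₁·n_snp)),
  β ~ N(0,1), rescaled so Σβ²H equals the target h² exactly on the
  standardized-phenotype scale; the realised σβ² is recorded as ground
  truth.  Misspecification variants: heterozygosity-coupled variance
  (β ∝ H^{−1/2}, rarer SNPs get larger effects), a two-component mixture
  (10% of causal SNPs with 10× variance), and an LD-dependent causal prior
  (probability decreasing linearly in total LD).  These are generic forms
  for robustness exercises, not calibrated to any particular selection
  model.
- **z-scores.** Either directly from the generative equation (signed
  correlations, independent unit-normal residuals, overall σ₀ scaling) or
  at genotype level: fresh cohorts from the same founder pools, phenotype
  Y = Gβ + ε with ε orthogonalised and scaled so var(Gβ)/var(Y) is the
  target h² exactly, then correlation → t → two-sided p → signed z.

Default study conditions (n_snp = 10⁵, panel 500 samples, N = 10⁵)
deliberately keep full LD-structure realism while shrinking the genome ~100×,
so a replicate simulates and fits in well under a minute.  What passing
tests at this scale do *not* probe: genome-scale LD (blocks up to ~1,500
SNPs), per-SNP effects as tiny as real traits' (desk-scale σβ² is ~100×
larger at matched h², so |z| can saturate the grid for very concentrated
architectures), imputation noise, and stratification — conclusions about
those require the full-scale setting.

## Numerical choices and limitations

- Grid: n = 2¹⁰, z₁ = −38 (configurable power of 2); out-of-range data
  z-scores are clamped to the extreme bins with a warning.
- Negative FFT lobes below 10⁻¹² are clipped and the pdf renormalized;
  larger lobes raise an error.
- Probability floor 10⁻³⁰⁰ per z bin avoids log(0) without perturbing the
  likelihood.
- Optimizer determinism: all randomness flows through seeded generators;
  identical seeds and data give byte-identical results.
- Degenerate inputs: σβ² → 0 makes A(N) undefined (raised as an error);
  empty H-L bins are dropped; zero-variance genotype columns are excluded
  from LD with a warning (diagonal kept at 1).
- Polygenicity scales inversely with reference-panel density (halving the
  panel doubles π̂₁); n_causal and h² are the panel-stable quantities.
- Phased-haplotype LD, imputation-quality modelling, covariate-adjusted
  prevalences, winner's-curse corrections and residual-correlation
  matrices are out of scope.
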