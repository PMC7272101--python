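"""Synthetic reference panels, causal effects and GWAS z-scores.

The generator emulates what the estimator sees in real data: a panel
with block-structured LD (realised r2 spanning the noise floor up to
1), a common-variant MAF spectrum with floor 0.002, mixture-distributed
causal effects, and z-scores produced either directly from the
LD-weighted generative equation or from a genotype-level GWAS on
simulated cohorts.

LD blocks are built from small founder haplotype pools: founder
haplotypes follow a Markov copying process along the block (allele
copied from the previous SNP with high probability), and cohort
haplotypes are drawn by mutation-free resampling of the pool, so
realised r2 carries the sampling noise of a few-hundred-sample panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ldstruct import (
    MAF_FLOOR,
    ReferencePanel,
    compute_heterozygosity,
    compute_sparse_r2,
)
from .fit import ZScoreSet

__all__ = [
    "SimConfig",
    "TruthRecord",
    "generate_panel",
    "draw_betas",
    "simulate_zscores_direct",
    "simulate_genotype_level",
    "inflate_zscores",
]

EFFECT_MODELS = ("constant", "het-weighted", "two-component", "ld-dependent-prior")


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the desk-scale conditions used throughout the test
    suite: a 1e5-SNP panel typed on 500 reference samples and a GWAS of
    N = 1e5, with polygenicity 1e-3 and SNP heritability 0.4.
    """

    n_snp: int = 100_000
    n_samples: int = 500  # reference panel samples
    N: int = 100_000  # GWAS sample size
    pi1: float = 1e-3
    h2: float = 0.4
    sigma0: float = 1.0
    mean_block_size: float = 25.0
    max_block_size: int = 100
    n_founders: int = 32
    switch_prob: float = 0.1  # founder Markov copying; sets r2 decay
    maf_exponent: float = 3.1  # maf = floor + (0.5-floor)*u**exponent
    effect_model: str = "constant"
    seed: int | None = None

    def __post_init__(self):
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(f"effect_model must be one of {EFFECT_MODELS}")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if self.pi1 * self.n_snp < 1 and self.h2 > 0:
            raise ValueError("pi1 * n_snp must be >= 1 for a non-null trait")


@dataclass
class TruthRecord:
    """Ground truth for one instantiation of causal effects."""

    causal_index: np.ndarray
    beta: np.ndarray  # full-length; nonzero exactly at causal_index
    sigma_beta2: float  # realised variance of causal betas
    h2: float  # realised heritability sum(beta^2 * H)
    sigma0: float = 1.0


def _draw_block_sizes(n_snp: int, cfg: SimConfig, rng) -> np.ndarray:
    sizes = []
    total = 0
    while total < n_snp:
        s = int(rng.geometric(1.0 / cfg.mean_block_size))
        s = min(max(s, 1), cfg.max_block_size, n_snp - total)
        sizes.append(s)
        total += s
    return np.array(sizes)


def _founder_pool(size: int, cfg: SimConfig, rng) -> np.ndarray:
    """Founder haplotypes (n_founders x size) with Markov LD along the
    block; every SNP is forced polymorphic within the pool."""
    K = cfg.n_founders
    base = MAF_FLOOR + (0.5 - MAF_FLOOR) * rng.random(size) ** cfg.maf_exponent
    pool = np.empty((K, size), dtype=np.int8)
    pool[:, 0] = rng.random(K) < base[0]
    for j in range(1, size):
        redraw = rng.random(K) < cfg.switch_prob
        pool[:, j] = np.where(redraw, rng.random(K) < base[j], pool[:, j - 1])
    # resample monomorphic founder columns (pool freq 0 or 1)
    for j in range(size):
        for _ in range(100):
            s = int(pool[:, j].sum())
            if 0 < s < K:
                break
            pool[:, j] = rng.random(K) < max(base[j], 2.0 / K)
    return pool


def _sample_genotypes(pool: np.ndarray, n_samples: int, rng) -> np.ndarray:
    K = pool.shape[0]
    h1 = pool[rng.integers(0, K, size=n_samples)]
    h2 = pool[rng.integers(0, K, size=n_samples)]
    return (h1 + h2).astype(np.int8)


def generate_panel(config: SimConfig, return_pools: bool = False):
    """Generate a reference panel with block LD and its genotype matrix.

    Returns ``(panel, genotypes)``; with ``return_pools=True`` also the
    per-block founder pools so GWAS cohorts can be drawn from the same
    haplotype distribution.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _draw_block_sizes(config.n_snp, config, rng)
    pools = [_founder_pool(s, config, rng) for s in sizes]
    geno = np.empty((config.n_samples, config.n_snp), dtype=np.int8)
    start = 0
    for pool, s in zip(pools, sizes):
        geno[:, start : start + s] = _sample_genotypes(pool, config.n_samples, rng)
        start += s

    # enforce the MAF floor on realised panel frequencies by resampling
    for _ in range(50):
        freq = geno.mean(axis=0) / 2.0
        bad = np.minimum(freq, 1 - freq) < MAF_FLOOR
        if not np.any(bad):
            break
        start = 0
        for b, (pool, s) in enumerate(zip(pools, sizes)):
            idx = np.nonzero(bad[start : start + s])[0]
            for j in idx:
                pool[:, j] = rng.random(pool.shape[0]) < max(
                    0.1, 2.0 / pool.shape[0]
                )
                col = _sample_genotypes(pool[:, [j]], config.n_samples, rng)
                geno[:, start + j] = col[:, 0]
            start += s

    freq = geno.mean(axis=0) / 2.0
    r2, r_signed = compute_sparse_r2(
        geno.astype(np.float64),
        r2_min=0.05,
        window_cap=config.max_block_size,
        return_signed=True,
    )
    panel = ReferencePanel(
        snp_ids=np.array([f"snp{i}" for i in range(config.n_snp)]),
        allele_freq=freq,
        het=compute_heterozygosity(freq),
        r2=r2,
        n_ref_samples=config.n_samples,
        r_signed=r_signed,
    )
    if return_pools:
        return panel, geno, (pools, sizes)
    return panel, geno


def draw_betas(panel: ReferencePanel, config: SimConfig, rng=None) -> TruthRecord:
    """Draw causal SNPs and effect sizes.

    Causal SNPs are chosen uniformly without replacement (except under
    the LD-dependent-prior misspecification variant); betas start as
    standard normal draws, optionally reweighted by the effect-model
    variant, then are rescaled so the realised heritability
    sum(beta_j^2 H_j) equals the target h2 on the standardized
    phenotype scale.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_causal = int(round(config.pi1 * panel.n_snp))
    beta = np.zeros(panel.n_snp)
    if config.h2 == 0.0 or n_causal == 0:
        return TruthRecord(
            causal_index=np.empty(0, dtype=int),
            beta=beta,
            sigma_beta2=0.0,
            h2=0.0,
            sigma0=config.sigma0,
        )
    if config.effect_model == "ld-dependent-prior":
        # prior probability of being causal decreases linearly in total LD
        L = np.asarray(panel.r2.sum(axis=1)).ravel()
        w = np.maximum(1.0 - L / (L.max() + 1e-12), 1e-3)
        p = w / w.sum()
        causal = rng.choice(panel.n_snp, size=n_causal, replace=False, p=p)
    else:
        causal = rng.choice(panel.n_snp, size=n_causal, replace=False)
    b = rng.standard_normal(n_causal)
    if config.effect_model == "het-weighted":
        # rarer causal SNPs get larger effects (selection-like coupling)
        b = b * (panel.het[causal] / panel.het.mean()) ** -0.5
    elif config.effect_model == "two-component":
        # a small fraction of causal SNPs with 10x effect-size variance
        big = rng.random(n_causal) < 0.1
        b = b * np.where(big, math.sqrt(10.0), 1.0)
    scale = math.sqrt(config.h2 / float(np.sum(b**2 * panel.het[causal])))
    beta[causal] = b * scale
    return TruthRecord(
        causal_index=np.sort(causal),
        beta=beta,
        sigma_beta2=float(np.mean((b * scale) ** 2)),
        h2=config.h2,
        sigma0=config.sigma0,
    )


def simulate_zscores_direct(
    panel: ReferencePanel,
    truth: TruthRecord,
    N: float,
    sigma0: float = 1.0,
    seed=None,
) -> ZScoreSet:
    """z-scores straight from the generative equation: the LD-weighted
    sum of causal effects plus independent unit-normal noise, scaled by
    the inflation sigma0.  Requires the panel's signed correlations."""
    if panel.r_signed is None:
        raise ValueError("panel must carry signed correlations for direct simulation")
    rng = np.random.default_rng(seed)
    delta = math.sqrt(N) * (panel.r_signed @ (np.sqrt(panel.het) * truth.beta))
    eps = rng.standard_normal(panel.n_snp)
    z = sigma0 * (delta + eps)
    return ZScoreSet(
        snp_ids=panel.snp_ids,
        z=z,
        n_eff=np.full(panel.n_snp, float(N)),
        panel_index=np.arange(panel.n_snp),
    )


def simulate_genotype_level(
    cohort_genotypes: np.ndarray,
    truth: TruthRecord,
    seed=None,
) -> tuple[ZScoreSet, dict]:
    """Genotype-level GWAS: build Y = G beta + eps with the residual
    scaled to the target heritability, then per-SNP correlation -> t ->
    two-sided p -> signed z.

    Returns the z-score set and a dict with the realised var(Y_G)/var(Y).
    """
    rng = np.random.default_rng(seed)
    G = np.asarray(cohort_genotypes, dtype=float)
    N = G.shape[0]
    yg = G @ truth.beta
    var_g = yg.var()
    if truth.h2 > 0:
        eps = rng.standard_normal(N)
        # orthogonalise against the genetic component so the realised
        # variance ratio hits the target exactly
        ygc = yg - yg.mean()
        eps -= eps.mean() + ygc * (eps @ ygc) / (ygc @ ygc)
        eps *= math.sqrt(var_g * (1 - truth.h2) / truth.h2) / eps.std()
        y = yg + eps
    else:
        y = rng.standard_normal(N)
    realized_h2 = var_g / y.var() if y.var() > 0 else 0.0

    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    dead = sd == 0.0
    num = Gc.T @ yc / N
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (sd * yc.std())
    r = np.clip(np.where(dead, np.nan, r), -0.999999, 0.999999)
    t = r * np.sqrt((N - 2) / (1 - r**2))
    # z with the same two-sided p as t (log-space for extreme tails)
    logp_half = stats.t.logsf(np.abs(t), N - 2)
    z = stats.norm.isf(np.exp(logp_half)) * np.sign(r)
    z = np.where(np.isfinite(z), z, np.nan)
    keep = ~np.isnan(z)
    return (
        ZScoreSet(
            snp_ids=np.array([f"snp{i}" for i in np.nonzero(keep)[0]]),
            z=z[keep],
            n_eff=np.full(int(keep.sum()), float(N)),
            panel_index=np.nonzero(keep)[0],
        ),
        {
            "realized_h2": float(realized_h2),
            "n_dropped": int((~keep).sum()),
            "phenotype": y,
        },
    )


def inflate_zscores(z: np.ndarray, sigma0: float) -> np.ndarray:
    """Variance-distortion inflation: z -> sigma0 * z."""
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    return np.asarray(z, dtype=float) * sigma0
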