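"""Scalar quantities derived from the fitted mixture parameters.

Causal-SNP count, observed- and liability-scale SNP heritability,
effective sample size for case-control designs, genomic-control lambda,
and QQ curves with exact binomial confidence bands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ldstruct import HLGrid
from .modelpdf import ModelParams, ZGrid, pdf_convolution_batch

__all__ = [
    "HeritabilityResult",
    "QQCurve",
    "n_causal",
    "h2_observed",
    "liability_scale",
    "effective_sample_size",
    "lambda_gc",
    "lambda_gc_model",
    "two_sided_p",
    "qq_curves",
    "PANEL_N_SNP",
    "PANEL_MEAN_HET",
]

# Reference-panel constants for an ~11M-SNP common-variant panel
# (MAF > 0.002), so derived statistics are reproducible without the
# underlying genotypes.
PANEL_N_SNP = 11_015_833
PANEL_MEAN_HET = 0.2165

NULL_MEDIAN_CHI2 = 0.455  # median of a 1-df chi-square


def two_sided_p(z) -> np.ndarray:
    """Two-sided normal p-value, evaluated in log space so extreme
    scores (|z| up to 38, p ~ 5.8e-316) stay representable."""
    z = np.abs(np.asarray(z, dtype=float))
    return 2.0 * np.exp(stats.norm.logsf(z))


def n_causal(pi1: float, n_snp: int = PANEL_N_SNP) -> float:
    """Estimated number of causal SNPs, pi1 * n_snp."""
    if pi1 < 0 or n_snp <= 0:
        raise ValueError("pi1 and n_snp must be non-negative / positive")
    return pi1 * n_snp


def h2_observed(
    pi1: float,
    sigma_beta2: float,
    n_snp: int = PANEL_N_SNP,
    mean_het: float = PANEL_MEAN_HET,
) -> float:
    """Observed-scale SNP heritability pi1 * n_snp * H_bar * sigma_beta2."""
    h2 = pi1 * n_snp * mean_het * sigma_beta2
    if h2 > 1.0:
        warnings.warn(f"h2 estimate {h2:.3f} exceeds 1", stacklevel=2)
    return h2


def liability_scale(
    h2_obs: float, K: float, n_cases: float, n_controls: float
) -> float:
    """Liability-scale heritability for an ascertained case-control
    study: multiply by K(1-K)/(P(1-P)) (ratio of phenotypic variances)
    and rescale by K(1-K)/a^2, where a is the standard normal density
    at the liability truncation point z_K with upper tail mass K."""
    if not (0.0 < K < 1.0):
        raise ValueError("prevalence K must be strictly inside (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case/control counts must be positive")
    P = n_cases / (n_cases + n_controls)
    z_K = stats.norm.isf(K)
    a = stats.norm.pdf(z_K)
    return h2_obs * (K * (1 - K)) ** 2 / (P * (1 - P) * a**2)


@dataclass
class HeritabilityResult:
    h2_observed: float
    n_causal: float
    h2_liability: float | None = None
    K: float | None = None
    P: float | None = None
    a: float | None = None
    mean_het: float = PANEL_MEAN_HET


def heritability_chain(
    params: ModelParams,
    n_snp: int = PANEL_N_SNP,
    mean_het: float = PANEL_MEAN_HET,
    K: float | None = None,
    n_cases: float | None = None,
    n_controls: float | None = None,
) -> HeritabilityResult:
    """Full chain from fitted parameters to heritability, with the
    liability conversion when prevalence and study counts are given."""
    h2 = h2_observed(params.pi1, params.sigma_beta2, n_snp, mean_het)
    res = HeritabilityResult(
        h2_observed=h2, n_causal=n_causal(params.pi1, n_snp), mean_het=mean_het
    )
    if K is not None:
        if n_cases is None or n_controls is None:
            raise ValueError("liability conversion needs case/control counts")
        res.h2_liability = liability_scale(h2, K, n_cases, n_controls)
        res.K = K
        res.P = n_cases / (n_cases + n_controls)
        res.a = float(stats.norm.pdf(stats.norm.isf(K)))
    return res


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """N_eff = 4 / (1/N_cases + 1/N_controls); equals the total N for
    balanced designs."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def lambda_gc(z: np.ndarray) -> float:
    """Empirical genomic-control factor: median z^2 over the null
    median 0.455."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one z-score")
    return float(np.median(z**2) / NULL_MEDIAN_CHI2)


def lambda_gc_model(
    hlgrid: HLGrid,
    params: ModelParams,
    N: float,
    zgrid: ZGrid | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Model genomic-control factor from the median of the mixture
    |z| distribution accumulated over H-L bins."""
    zgrid = zgrid or ZGrid()
    tail, _ = _model_tail_function(hlgrid, params, N, zgrid, weights)
    znom = np.linspace(0.0, -zgrid.z1, 20_000)
    q = tail(znom)
    z_med = float(np.interp(-0.5, -q, znom))  # q decreasing in z
    return z_med**2 / NULL_MEDIAN_CHI2


def _model_tail_function(hlgrid, params, N, zgrid, weights=None):
    """Weighted model two-sided tail probability q(z) = P(|Z| >= z)."""
    pdfs = pdf_convolution_batch(
        hlgrid.counts, hlgrid.mean_het, hlgrid.mean_r2, N, params, zgrid
    )
    w = hlgrid.bin_counts if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    mix = w @ pdfs  # (n_z,)
    # two-sided tail on |z| via the symmetric upper tail
    upper = mix[zgrid.z_values >= 0]
    zpos = zgrid.z_values[zgrid.z_values >= 0]
    # survival from each grid point: cumulative sum from the top with a
    # half-bin midpoint correction so S(0) = 1/2 exactly
    rev = (np.cumsum(upper[::-1])[::-1] - 0.5 * upper) * zgrid.dz

    def tail(znom):
        t = 2.0 * np.interp(znom, zpos, rev)
        return np.clip(t, 0.0, 1.0)

    return tail, mix


@dataclass
class QQCurve:
    """Model and empirical QQ curves on the (-log10 q, -log10 p) scale
    with a Clopper-Pearson band around the empirical curve."""

    z_nominal: np.ndarray
    neglog_p: np.ndarray
    neglog_q_model: np.ndarray
    neglog_q_empirical: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    lambda_empirical: float
    lambda_model: float
    f_independence: float
    n_tot: int


def qq_curves(
    z: np.ndarray,
    hlgrid: HLGrid,
    params: ModelParams,
    N: float,
    zgrid: ZGrid | None = None,
    f: float = 10.0,
    n_nominal: int = 10_000,
    weights: np.ndarray | None = None,
) -> QQCurve:
    """QQ summary: proportion q of SNPs whose z-scores exceed each
    two-tailed threshold p, for data and model.

    The model curve is the H-L-weighted mixture tail on an
    equally-spaced nominal |z| vector; the empirical band is the exact
    Clopper-Pearson 95% interval with n_tot/f effective trials
    (f approximates LD between the scores).
    """
    zgrid = zgrid or ZGrid()
    z = np.asarray(z, dtype=float)
    znom = np.linspace(0.0, -zgrid.z1, n_nominal)
    with np.errstate(divide="ignore"):
        neglog_p = -np.log10(two_sided_p(znom))

    tail, _ = _model_tail_function(hlgrid, params, N, zgrid, weights)
    q_model = tail(znom)

    az = np.sort(np.abs(z))
    n_tot = len(az)
    q_emp = 1.0 - np.searchsorted(az, znom, side="left") / n_tot

    n_eff = max(n_tot / f, 1.0)
    k = q_emp * n_eff
    lo = stats.beta.ppf(0.025, k, n_eff - k + 1)
    hi = stats.beta.ppf(0.975, k + 1, n_eff - k)
    lo = np.where(k <= 0, 0.0, lo)
    hi = np.where(k >= n_eff, 1.0, hi)

    with np.errstate(divide="ignore"):
        return QQCurve(
            z_nominal=znom,
            neglog_p=neglog_p,
            neglog_q_model=-np.log10(np.maximum(q_model, 1e-320)),
            neglog_q_empirical=-np.log10(np.maximum(q_emp, 1e-320)),
            band_lo=-np.log10(np.maximum(hi, 1e-320)),
            band_hi=-np.log10(np.maximum(lo, 1e-320)),
            lambda_empirical=lambda_gc(z),
            lambda_model=lambda_gc_model(hlgrid, params, N, zgrid, weights),
            f_independence=f,
            n_tot=n_tot,
        )
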