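"""Model z-score densities for the causal Gaussian mixture.

A SNP's z-score is the sum of LD- and heterozygosity-weighted causal
effects of its neighbours plus an environmental residual.  Each
neighbour contributes a two-component mixture (null spike + Gaussian),
so the marginal z-score density is a convolution of mixtures.  It is
computed exactly on a uniform z grid by multiplying characteristic
functions and inverting with an FFT; a multinomial-expansion form over
explicit causal-count configurations serves as a small-instance oracle.

Fourier conventions use the exp(-2*pi*i*k*z) kernel, under which a
Gaussian with variance v transforms to exp(-2*pi^2*v*k^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .ldstruct import LdHistogram

__all__ = [
    "ModelParams",
    "ZGrid",
    "PdfVector",
    "idealized_mixture_pdf",
    "fourier_kernel_Aw",
    "genetic_characteristic_function",
    "environment_characteristic_function",
    "pdf_convolution",
    "pdf_convolution_batch",
    "pdf_multinomial",
    "count_compositions",
]

_TWO_PI2 = 2.0 * np.pi**2
NEGATIVITY_TOL = 1e-12
NORMALIZATION_TOL = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Mixture parameters: polygenicity pi1, discoverability
    sigma_beta2 (causal effect-size variance, phenotype-variance units)
    and residual inflation sigma0_2 (z-score variance distortion)."""

    pi1: float
    sigma_beta2: float
    sigma0_2: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.pi1 <= 1.0):
            raise ValueError("pi1 must be in [0, 1]")
        if self.sigma_beta2 < 0.0 or self.sigma0_2 <= 0.0:
            raise ValueError("sigma_beta2 must be >= 0 and sigma0_2 > 0")

    @property
    def sigma_tilde_beta2(self) -> float:
        """Inflated effect-size variance sigma0_2 * sigma_beta2; this is
        the variance that enters the z-score pdf."""
        return self.sigma0_2 * self.sigma_beta2

    def to_array(self) -> np.ndarray:
        return np.array([self.pi1, self.sigma_beta2, self.sigma0_2])

    # -- unconstrained coordinates for the optimizer -------------------
    def to_transformed(self) -> np.ndarray:
        p = min(max(self.pi1, 1e-15), 1 - 1e-15)
        return np.array(
            [math.log(p / (1 - p)), math.log(self.sigma_beta2), math.log(self.sigma0_2)]
        )

    @staticmethod
    def from_transformed(theta: np.ndarray) -> "ModelParams":
        t0 = float(np.clip(theta[0], -700, 700))
        return ModelParams(
            pi1=1.0 / (1.0 + math.exp(-t0)),
            sigma_beta2=math.exp(float(theta[1])),
            sigma0_2=math.exp(float(theta[2])),
        )


class ZGrid:
    """Uniform z discretisation on [z1, -z1) with its Fourier dual.

    Defaults (n = 2**10 points from -38) give dz = 0.0742 and admit
    two-sided p-values down to 5.8e-316.  z[n/2] = 0 and dz*dk = 1/n.
    """

    def __init__(self, n_points: int = 1024, z1: float = -38.0):
        if n_points < 2 or (n_points & (n_points - 1)) != 0:
            raise ValueError("n_points must be a power of 2")
        if z1 >= 0:
            raise ValueError("z1 must be negative")
        self.n_points = int(n_points)
        self.z1 = float(z1)
        self.dz = -2.0 * z1 / n_points
        self.z_values = z1 + self.dz * np.arange(n_points)
        self.dk = 1.0 / (n_points * self.dz)
        self.f_c = 1.0 / (2.0 * self.dz)
        self.k_values = (np.arange(n_points) - n_points // 2) * self.dk

    def bin_edges(self) -> np.ndarray:
        """Edges of z bins centred on the grid points."""
        return np.concatenate(
            [self.z_values - 0.5 * self.dz, [self.z_values[-1] + 0.5 * self.dz]]
        )

    def __repr__(self):
        return f"ZGrid(n_points={self.n_points}, z1={self.z1}, dz={self.dz:.6g})"


@dataclass
class PdfVector:
    """Density values aligned to a ZGrid, with provenance metadata."""

    values: np.ndarray
    zgrid: ZGrid
    metadata: dict = field(default_factory=dict)

    def integral(self) -> float:
        return float(self.values.sum() * self.zgrid.dz)

    def variance(self) -> float:
        z = self.zgrid.z_values
        return float((self.values * z**2).sum() * self.zgrid.dz)


def idealized_mixture_pdf(
    z, k_causal: float, r2: float, H: float, N: float, params: ModelParams, alpha: float = 1.0
):
    """Closed-form density for the idealised case of a SNP in LD with
    exactly ``k_causal`` causal SNPs, all at the same r2 and H: a
    Gaussian with variance k*r2*sigma_tilde_beta2*N*H + sigma0_2, mixed
    with the pure-null Gaussian with weight ``alpha``."""
    if k_causal < 0:
        raise ValueError("k_causal must be >= 0")
    z = np.asarray(z, dtype=float)
    var1 = k_causal * r2 * params.sigma_tilde_beta2 * N * H + params.sigma0_2
    f1 = stats.norm.pdf(z, 0.0, math.sqrt(var1))
    if alpha == 1.0:
        return f1
    f0 = stats.norm.pdf(z, 0.0, math.sqrt(params.sigma0_2))
    return (1.0 - alpha) * f0 + alpha * f1


def fourier_kernel_Aw(N: float, H_w, r2_w, sigma_tilde_beta2: float):
    """Gaussian-in-k exponent coefficient A_w = -2*pi^2*N*H_w*r2_w*
    sigma_tilde_beta2 for one LD window's characteristic function."""
    return -_TWO_PI2 * N * np.asarray(H_w, float) * np.asarray(r2_w, float) * sigma_tilde_beta2


def genetic_characteristic_function(
    k_values: np.ndarray, histogram: LdHistogram, N: float, params: ModelParams
) -> np.ndarray:
    """Characteristic function of the genetic (LD-mediated) component:
    prod_w (pi1*exp(A_w k^2) + 1 - pi1)**n_w, accumulated in log domain
    so real (bin-averaged) counts are valid exponents."""
    k2 = np.asarray(k_values, float) ** 2
    A = fourier_kernel_Aw(N, histogram.mean_het, histogram.mean_r2, params.sigma_tilde_beta2)
    with np.errstate(under="ignore", divide="ignore"):
        comp = params.pi1 * np.exp(np.outer(A, k2)) + (1.0 - params.pi1)
        logG = histogram.counts @ np.log(comp)
        return np.exp(logG)


def environment_characteristic_function(k_values: np.ndarray, sigma0_2: float) -> np.ndarray:
    """Characteristic function of the environmental residual,
    exp(-2*pi^2*sigma0_2*k^2)."""
    if sigma0_2 <= 0:
        raise ValueError("sigma0_2 must be > 0")
    with np.errstate(under="ignore"):
        return np.exp(-_TWO_PI2 * sigma0_2 * np.asarray(k_values, float) ** 2)


def invert_characteristic(F: np.ndarray, zgrid: ZGrid) -> np.ndarray:
    """Inverse Fourier transform from the natural-order k grid to the
    natural-order z grid (continuous convention, Riemann-sum scaled)."""
    F = np.atleast_2d(F)
    shifted = np.fft.ifftshift(F, axes=-1)
    vals = np.fft.fftshift(np.fft.ifft(shifted, axis=-1), axes=-1).real / zgrid.dz
    return vals[0] if vals.shape[0] == 1 else vals


def _finalize_pdf(vals: np.ndarray, zgrid: ZGrid) -> np.ndarray:
    if vals.min() < -NEGATIVITY_TOL:
        raise FloatingPointError(
            f"pdf has negative lobes ({vals.min():.3e}) beyond tolerance"
        )
    vals = np.clip(vals, 0.0, None)
    total = vals.sum() * zgrid.dz
    if abs(total - 1.0) > 1e-3:
        raise FloatingPointError(f"pdf mass {total:.6f} too far from 1")
    return vals / total


def pdf_convolution(
    histogram: LdHistogram, N: float, params: ModelParams, zgrid: ZGrid | None = None
) -> PdfVector:
    """Exact model z-score pdf by Fourier convolution (genetic times
    environmental characteristic function, inverted on the z grid)."""
    zgrid = zgrid or ZGrid()
    G = genetic_characteristic_function(zgrid.k_values, histogram, N, params)
    E = environment_characteristic_function(zgrid.k_values, params.sigma0_2)
    vals = _finalize_pdf(invert_characteristic(G * E, zgrid), zgrid)
    return PdfVector(values=vals, zgrid=zgrid, metadata={"N": N, "params": params})


def pdf_convolution_batch(
    counts: np.ndarray,
    mean_het: np.ndarray,
    mean_r2: np.ndarray,
    N: float,
    params: ModelParams,
    zgrid: ZGrid,
    genetic_only: bool = False,
) -> np.ndarray:
    """Model pdf rows for many LD histograms at once.

    ``counts``/``mean_het`` are (n_bins, w_max); returns (n_bins, n_z).
    Exploits evenness of the characteristic function in k: values are
    computed on the non-negative half-grid and mirrored.
    """
    n = zgrid.n_points
    half = n // 2
    k2 = (zgrid.dk * np.arange(half + 1)) ** 2  # |k| = 0 .. f_c
    A = -_TWO_PI2 * N * params.sigma_tilde_beta2 * mean_het * mean_r2[None, :]
    with np.errstate(under="ignore"):
        comp = params.pi1 * np.exp(A[:, :, None] * k2[None, None, :]) + (1.0 - params.pi1)
        logF = np.einsum("bw,bwk->bk", counts, np.log(comp))
        if not genetic_only:
            logF -= _TWO_PI2 * params.sigma0_2 * k2[None, :]
        Fh = np.exp(logF)
    # natural order: k_j = (j - n/2) dk, j = 0..n-1 -> |j - n/2| indexes Fh
    idx = np.abs(np.arange(n) - half)
    F = Fh[:, idx]
    vals = np.atleast_2d(invert_characteristic(F, zgrid))
    vals = np.clip(vals, 0.0, None)
    vals /= vals.sum(axis=1, keepdims=True) * zgrid.dz
    return vals


def count_compositions(K: int, w: int) -> int:
    """Number of ways to distribute K causal SNPs among w LD windows."""
    return math.comb(K + w - 1, w - 1)


def _compositions(K: int, caps: list):
    """Yield tuples (k_1..k_w), 0 <= k_i <= caps[i], summing to K."""
    w = len(caps)

    def rec(prefix, remaining, pos):
        if pos == w - 1:
            if remaining <= caps[pos]:
                yield prefix + (remaining,)
            return
        for k in range(min(remaining, caps[pos]) + 1):
            yield from rec(prefix + (k,), remaining - k, pos + 1)

    yield from rec((), K, 0)


def pdf_multinomial(
    histogram: LdHistogram,
    N: float,
    params: ModelParams,
    zgrid: ZGrid | None = None,
    K_max: int | None = None,
    max_terms: int = 500_000,
) -> PdfVector:
    """Model z-score pdf by explicit expansion over causal counts.

    Enumerates every configuration (k_1..k_w) of K causal SNPs among
    the w LD windows (K = 0..K_max), weighting the component Gaussian
    phi(z; 0, (sum_w k_w H_w r2_w) sigma_tilde_beta2 N + sigma0_2) by
    the probability of that configuration.  Weights are products of
    per-window binomials prod_w C(n_w, k_w) pi1^k_w (1-pi1)^(n_w-k_w) -
    each of the n_w neighbours in a window is independently causal with
    probability pi1 - which is the exact expansion of the convolution's
    characteristic-function product (a single multinomial over w+1 SNP
    categories with window-membership priors is the small-pi1
    approximation of this).  Counts are rounded to integers; meant as
    an exact oracle for small LD blocks, not for production fits.
    """
    zgrid = zgrid or ZGrid()
    nw = np.round(histogram.counts).astype(int)
    if np.any(nw < 0):
        raise ValueError("negative window counts")
    n = int(nw.sum())
    if n < 1:
        raise ValueError("LD block must contain at least the SNP itself")
    if K_max is None:
        K_max = min(20, n)
    K_max = min(K_max, n)
    w = len(nw)
    total_terms = sum(count_compositions(K, w) for K in range(K_max + 1))
    if total_terms > max_terms:
        raise ValueError(
            f"{total_terms} expansion terms exceed cap {max_terms}; "
            "the multinomial form is a small-instance oracle"
        )

    pi1 = params.pi1
    log_p1 = math.log(pi1) if pi1 > 0.0 else -math.inf
    log_q1 = math.log1p(-pi1) if pi1 < 1.0 else -math.inf
    log_binom = [
        np.array([gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1) for k in range(m + 1)])
        for m in nw
    ]
    var_w = histogram.mean_het * histogram.mean_r2 * params.sigma_tilde_beta2 * N

    z = zgrid.z_values
    dens = np.zeros_like(z)
    weight_sum = 0.0
    caps = nw.tolist()
    for K in range(K_max + 1):
        for ks in _compositions(K, caps):
            ks_arr = np.array(ks)
            logM = K * log_p1 + (n - K) * log_q1 + sum(
                log_binom[i][k] for i, k in enumerate(ks)
            )
            weight = math.exp(logM)
            var = float(np.dot(ks_arr, var_w)) + params.sigma0_2
            dens += weight * np.exp(-0.5 * z**2 / var) / math.sqrt(2 * math.pi * var)
            weight_sum += weight
    return PdfVector(
        values=dens,
        zgrid=zgrid,
        metadata={"N": N, "params": params, "weight_sum": weight_sum, "K_max": K_max},
    )
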