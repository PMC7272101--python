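"""Posterior genetic effects and discovery-power curves.

The latent genetic component delta of a z-score (z = delta + eps,
eps ~ N(0, sigma0_2)) has a prior density obtained like the z-score pdf
but without the environmental factor.  Posterior moments E(delta|z) and
E(delta^2|z) follow by quadrature on the shared z/delta grid, and the
proportion A(N) of SNP heritability captured by genome-wide-significant
SNPs is a tail-to-total ratio of E(delta^2|z)P(z) accumulated over the
H-L grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ldstruct import HLGrid, LdHistogram
from .modelpdf import (
    ModelParams,
    PdfVector,
    ZGrid,
    environment_characteristic_function,
    genetic_characteristic_function,
    invert_characteristic,
)

__all__ = [
    "PowerCurve",
    "genetic_effect_pdf",
    "posterior_delta_moments",
    "significance_threshold",
    "power_A_of_N",
    "power_curve",
]

GENOME_WIDE_P = 5e-8


class DegenerateModelError(ValueError):
    """Raised when the model carries no genetic variance and a
    genetic-variance ratio is requested."""


def genetic_effect_pdf(
    histogram: LdHistogram, N: float, params: ModelParams, zgrid: ZGrid | None = None
) -> PdfVector:
    """Prior density of the latent genetic effect delta on the z grid
    (the z-score pdf with the environmental factor dropped)."""
    zgrid = zgrid or ZGrid()
    G = genetic_characteristic_function(zgrid.k_values, histogram, N, params)
    vals = invert_characteristic(G, zgrid)
    vals = np.clip(vals, 0.0, None)
    vals /= vals.sum() * zgrid.dz
    return PdfVector(values=vals, zgrid=zgrid, metadata={"N": N, "params": params})


def circular_convolve(values: np.ndarray, kernel: np.ndarray, zgrid: ZGrid) -> np.ndarray:
    """Riemann-sum convolution on the periodic z grid with a kernel
    centred at z = 0; exactly consistent with the spectral pdfs (the
    z-score pdf is this convolution of the genetic pdf with the
    environmental Gaussian)."""
    n = zgrid.n_points
    K = np.fft.rfft(np.fft.ifftshift(kernel))
    V = np.fft.rfft(np.asarray(values, float), n=n, axis=-1)
    return np.fft.irfft(V * K, n=n, axis=-1) * zgrid.dz


def posterior_delta_moments(
    z: float,
    histogram: LdHistogram,
    N: float,
    params: ModelParams,
    zgrid: ZGrid | None = None,
) -> tuple[float, float]:
    """E(delta | z) and E(delta^2 | z) by quadrature over the delta
    grid, with likelihood P(z|delta) = phi(z; delta, sigma0_2)."""
    zgrid = zgrid or ZGrid()
    zmax = -zgrid.z1
    if abs(z) > zmax:
        import warnings

        warnings.warn("z outside the grid; clamped", stacklevel=2)
        z = math.copysign(zmax, z)
    prior = genetic_effect_pdf(histogram, N, params, zgrid).values
    return moments_given_prior(z, prior, zgrid.z_values, params.sigma0_2)


def moments_given_prior(
    z: float, prior: np.ndarray, delta_grid: np.ndarray, sigma0_2: float
) -> tuple[float, float]:
    """Bayes-rule posterior moments of delta for an arbitrary discrete
    prior on ``delta_grid``, with likelihood phi(z; delta, sigma0_2)."""
    lik = stats.norm.pdf(z, delta_grid, math.sqrt(sigma0_2))
    w = lik * np.asarray(prior, dtype=float)
    norm = w.sum()
    if norm <= 0:
        raise FloatingPointError("P(z) vanished; posterior undefined")
    m1 = float((w * delta_grid).sum() / norm)
    m2 = float((w * delta_grid**2).sum() / norm)
    return m1, m2


def significance_threshold(p_threshold: float = GENOME_WIDE_P) -> float:
    """Two-sided z threshold for a p-value threshold; 5e-8 -> 5.45."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    return float(stats.norm.isf(p_threshold / 2.0))


def _heritability_flux(
    hlgrid: HLGrid, N: float, params: ModelParams, zgrid: ZGrid
) -> np.ndarray:
    """C(z | N, H, L) = E(delta^2 | z) P(z) for every H-L bin: the
    density of delta^2 'heritability flux' over observed z.

    Computed spectrally: the Fourier transform of delta^2 * pdf_delta
    is -G''(k)/(4 pi^2) with G the genetic characteristic function, so
    C = invFT[-G'' E / (4 pi^2)].  G'' is evaluated analytically; the
    environmental factor E restores spectral decay, which keeps the
    result clean even when the delta prior is far narrower than the
    grid spacing (small N).
    """
    n = zgrid.n_points
    half = n // 2
    k = zgrid.dk * np.arange(half + 1)
    k2 = k**2
    pi1 = params.pi1
    A = -2.0 * np.pi**2 * N * params.sigma_tilde_beta2 * (
        hlgrid.mean_het * hlgrid.mean_r2[None, :]
    )  # (B, w)
    cnt = hlgrid.counts
    with np.errstate(under="ignore"):
        ew = np.exp(A[:, :, None] * k2[None, None, :])  # (B, w, K)
        cw = pi1 * ew + (1.0 - pi1)
        logG = np.einsum("bw,bwk->bk", cnt, np.log(cw))
        base = 2.0 * pi1 * A[:, :, None] * ew / cw
        uw = base * k[None, None, :]  # per-window d/dk log c_w
        vw = base * (1.0 + 2.0 * A[:, :, None] * k2[None, None, :])
        lp = np.einsum("bw,bwk->bk", cnt, uw)
        lpp = np.einsum("bw,bwk->bk", cnt, vw - uw**2)
        G2 = np.exp(logG) * (lp**2 + lpp)  # G''(k) on the half grid
        E = np.exp(-2.0 * np.pi**2 * params.sigma0_2 * k2)
    Fh = -(G2 / (4.0 * np.pi**2)) * E
    idx = np.abs(np.arange(n) - half)
    C = np.atleast_2d(invert_characteristic(Fh[:, idx], zgrid))
    return np.clip(C * zgrid.dz, 0.0, None)


def power_A_of_N(
    N: float,
    hlgrid: HLGrid,
    params: ModelParams,
    z_t: float | None = None,
    zgrid: ZGrid | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Proportion of SNP heritability captured by SNPs with |z| > z_t
    at sample size N: the ratio of tail-restricted to total
    sum of E(delta^2|z)P(z) over the z grid and H-L bins.

    Bins are weighted by their SNP membership so the ratio represents
    the panel rather than the (uneven) grid occupancy.
    """
    zgrid = zgrid or ZGrid()
    if z_t is None:
        z_t = significance_threshold()
    if params.pi1 * params.sigma_beta2 <= 0:
        raise DegenerateModelError("no genetic variance; A(N) undefined")
    C = _heritability_flux(hlgrid, N, params, zgrid)
    if weights is None:
        weights = hlgrid.bin_counts
    weights = np.asarray(weights, dtype=float)
    tail = np.abs(zgrid.z_values) > z_t
    num = float(weights @ C[:, tail].sum(axis=1))
    den = float(weights @ C.sum(axis=1))
    if den <= 0:
        raise DegenerateModelError("zero total genetic variance flux")
    return num / den


@dataclass
class PowerCurve:
    """A(N) on a log-spaced ladder of sample sizes."""

    N: np.ndarray
    A: np.ndarray
    z_t: float
    current_N: float | None = None
    current_A: float | None = None

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"N": self.N, "A": self.A})


def power_curve(
    hlgrid: HLGrid,
    params: ModelParams,
    n_min: float,
    n_max: float,
    n_grid: int = 30,
    p_threshold: float = GENOME_WIDE_P,
    zgrid: ZGrid | None = None,
    current_N: float | None = None,
    weights: np.ndarray | None = None,
) -> PowerCurve:
    """A(N) over a log-spaced N range, annotated at the current N."""
    zgrid = zgrid or ZGrid()
    z_t = significance_threshold(p_threshold)
    Ns = np.geomspace(n_min, n_max, n_grid)
    A = np.array(
        [power_A_of_N(N, hlgrid, params, z_t, zgrid, weights) for N in Ns]
    )
    cur = (
        power_A_of_N(current_N, hlgrid, params, z_t, zgrid, weights)
        if current_N is not None
        else None
    )
    return PowerCurve(N=Ns, A=A, z_t=z_t, current_N=current_N, current_A=cur)
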