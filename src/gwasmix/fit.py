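"""Maximum-likelihood fitting of the causal-mixture parameters.

The data are binned: within each heterozygosity x total-LD (H-L) grid
element, pruned z-scores are counted in bins of width dz, and the model
pdf for that element supplies the per-bin success probabilities.  The
cost is the multinomial negative log-likelihood (the parameter-free
log-multinomial coefficient is omitted), averaged over pruning
iterations and accumulated over H-L bins, minimised by Nelder-Mead in
unconstrained coordinates (logit pi1, log sigma_beta2, log sigma0_2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .ldstruct import HLGrid, PruneMask
from .modelpdf import ModelParams, PdfVector, ZGrid, pdf_convolution_batch

__all__ = [
    "ZScoreSet",
    "FitResult",
    "FitData",
    "bin_zscores",
    "bin_probabilities",
    "multinomial_negloglike",
    "prepare_fit_data",
    "total_cost",
    "fit_model",
    "fisher_confidence",
]

PROB_FLOOR = 1e-300
Z_LIMIT = 38.0


@dataclass
class ZScoreSet:
    """GWAS z-scores mapped onto reference-panel indices.

    ``n_eff`` is the (per-SNP or global) effective sample size; |z|
    beyond the grid limit is clamped with a warning.
    """

    snp_ids: np.ndarray
    z: np.ndarray
    n_eff: np.ndarray
    panel_index: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.n_eff = np.broadcast_to(
            np.asarray(self.n_eff, dtype=float), self.z.shape
        ).copy()
        over = np.abs(self.z) > Z_LIMIT
        if np.any(over):
            warnings.warn(
                f"{int(over.sum())} z-score(s) beyond |z|={Z_LIMIT} clamped",
                stacklevel=2,
            )
            self.z = np.clip(self.z, -Z_LIMIT, Z_LIMIT)

    def __len__(self):
        return len(self.z)

    @property
    def median_n(self) -> float:
        return float(np.median(self.n_eff))


@dataclass
class FitResult:
    """Fitted parameters with uncertainty and derived quantities."""

    params: ModelParams
    cost: float
    cov: np.ndarray  # 3x3 covariance, natural scale
    cov_transformed: np.ndarray  # 3x3 covariance in optimizer coordinates
    ci95: dict  # per-parameter (lo, hi), natural scale
    derived: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True


def bin_zscores(z: np.ndarray, zgrid: ZGrid) -> np.ndarray:
    """Histogram z-scores into the grid's dz-wide bins (bins centred on
    the grid points; out-of-range values counted in the extreme bins)."""
    z = np.asarray(z, dtype=float)
    if np.any(np.abs(z) > -zgrid.z1):
        warnings.warn("out-of-range z-scores clamped to extreme bins", stacklevel=2)
    idx = _zbin_index(z, zgrid)
    return np.bincount(idx, minlength=zgrid.n_points).astype(float)


def _zbin_index(z: np.ndarray, zgrid: ZGrid) -> np.ndarray:
    idx = np.floor((z - (zgrid.z1 - 0.5 * zgrid.dz)) / zgrid.dz).astype(np.int64)
    return np.clip(idx, 0, zgrid.n_points - 1)


def bin_probabilities(pdf, zgrid: ZGrid | None = None, floor: float = PROB_FLOOR) -> np.ndarray:
    """Per-z-bin success probabilities from a normalized model pdf."""
    if isinstance(pdf, PdfVector):
        values, zgrid = pdf.values, pdf.zgrid
    else:
        values = np.asarray(pdf, dtype=float)
        if zgrid is None:
            raise ValueError("zgrid required when pdf is a bare array")
    probs = values * zgrid.dz
    return np.maximum(probs, floor)


def multinomial_negloglike(counts: np.ndarray, probabilities: np.ndarray) -> float:
    """-sum counts*log(prob); the log multinomial coefficient, constant
    in the model parameters, is omitted."""
    counts = np.asarray(counts, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    if counts.shape != probabilities.shape:
        raise ValueError("counts and probabilities must align")
    p = np.maximum(probabilities, PROB_FLOOR)
    return float(-(counts * np.log(p)).sum())


@dataclass
class FitData:
    """Per-H-L-bin binned z-score counts, pre-averaged over prunings.

    Because the model probabilities do not depend on the pruning
    iteration, averaging -ln(p_m) over prunings equals evaluating the
    cost on pruning-averaged counts (up to the omitted constant).
    """

    mean_counts: np.ndarray  # (n_bins, n_z)
    n_prunings: int
    n_selected: np.ndarray  # per-pruning totals
    zgrid: ZGrid


def prepare_fit_data(
    zscores: ZScoreSet,
    hlgrid: HLGrid,
    prune_masks: PruneMask | None,
    zgrid: ZGrid | None = None,
) -> FitData:
    """Accumulate per-pruning, per-H-L-bin z-score counts."""
    zgrid = zgrid or ZGrid()
    n_bins = hlgrid.n_bins
    nz = zgrid.n_points
    zbin = _zbin_index(zscores.z, zgrid)
    bin_of_snp = hlgrid.bin_index  # aligned to typed SNPs = zscores order
    if len(bin_of_snp) != len(zscores):
        raise ValueError("H-L grid assignment does not match the z-score set")
    flat = bin_of_snp * nz + zbin
    if prune_masks is None:
        masks = [np.ones(len(zscores), dtype=bool)]
    else:
        masks = [m[zscores.panel_index] for m in prune_masks.iteration_masks]
    total = np.zeros(n_bins * nz)
    n_selected = []
    for m in masks:
        total += np.bincount(flat[m], minlength=n_bins * nz)
        n_selected.append(int(m.sum()))
    mean_counts = (total / len(masks)).reshape(n_bins, nz)
    return FitData(
        mean_counts=mean_counts,
        n_prunings=len(masks),
        n_selected=np.array(n_selected),
        zgrid=zgrid,
    )


def total_cost(
    params: ModelParams,
    data: FitData,
    hlgrid: HLGrid,
    N: float,
) -> float:
    """Pruning-averaged multinomial negative log-likelihood over all
    occupied H-L bins."""
    pdfs = pdf_convolution_batch(
        hlgrid.counts, hlgrid.mean_het, hlgrid.mean_r2, N, params, data.zgrid
    )
    probs = np.maximum(pdfs * data.zgrid.dz, PROB_FLOOR)
    cost = float(-(data.mean_counts * np.log(probs)).sum())
    if not np.isfinite(cost):
        bad = np.nonzero(~np.isfinite((data.mean_counts * np.log(probs)).sum(axis=1)))[0]
        raise FloatingPointError(f"non-finite cost in H-L bin(s) {bad.tolist()}")
    return cost


DEFAULT_INIT = ModelParams(pi1=1e-4, sigma_beta2=1e-4, sigma0_2=1.0)


def _prescan_starts(data: FitData, hlgrid: HLGrid, N: float) -> list:
    """Method-of-moments candidate starts for the simplex search.

    Under the mixture, var(z) = sigma0_2 + N*sigma_tilde_beta2*pi1*S
    with S the mean per-SNP sum of n_w H_w r2_w; for a ladder of pi1
    values this pins a matching sigma_beta2 scale, which spans the
    orders of magnitude the data could support far more reliably than
    any single fixed starting point.
    """
    w = data.mean_counts.sum(axis=1)
    z = data.zgrid.z_values
    tot = data.mean_counts.sum()
    var_z = float((data.mean_counts * z**2).sum() / max(tot, 1.0))
    S = float((w @ (hlgrid.counts * hlgrid.mean_het * hlgrid.mean_r2).sum(axis=1)) / max(w.sum(), 1.0))
    excess = max(var_z - 1.0, 1e-3)
    starts = []
    for pi1 in (1e-5, 1e-4, 1e-3, 1e-2):
        sb2 = excess / (N * pi1 * S)
        for fac in (0.3, 1.0, 3.0):
            sb2f = min(sb2 * fac, 1.0)
            if sb2f > 0:
                starts.append(ModelParams(pi1=pi1, sigma_beta2=sb2f, sigma0_2=1.0))
    return starts


def fit_model(
    data: FitData,
    hlgrid: HLGrid,
    N: float,
    init: ModelParams = DEFAULT_INIT,
    xatol: float = 1e-4,
    fatol: float = 1e-6,
    maxfev: int = 2000,
    n_restarts: int = 1,
    compute_ci: bool = True,
    n_snp: int | None = None,
    mean_het: float | None = None,
    prescan: bool = True,
) -> FitResult:
    """Nelder-Mead maximum-likelihood fit of (pi1, sigma_beta2,
    sigma0_2), with one default restart from the first optimum and
    Fisher-information confidence intervals.

    With ``prescan`` (default) a cheap ladder of method-of-moments
    candidate starts is evaluated and the best one seeds the simplex;
    otherwise the search starts from ``init`` alone.  If ``n_snp`` and
    ``mean_het`` are given, heritability and the causal-SNP count are
    attached to ``derived``.
    """

    def cost_fn(theta):
        try:
            return total_cost(ModelParams.from_transformed(theta), data, hlgrid, N)
        except FloatingPointError:
            return 1e30

    start = init
    if prescan:
        candidates = [init] + _prescan_starts(data, hlgrid, N)
        costs = [cost_fn(c.to_transformed()) for c in candidates]
        start = candidates[int(np.argmin(costs))]
    theta0 = start.to_transformed()
    trace = []
    best = None
    for attempt in range(1 + n_restarts):
        res = optimize.minimize(
            cost_fn,
            theta0,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
        )
        trace.append(
            {"start": theta0.tolist(), "cost": float(res.fun), "nfev": int(res.nfev),
             "success": bool(res.success)}
        )
        if best is None or res.fun < best.fun:
            best = res
        theta0 = res.x.copy()

    converged = bool(best.success)
    if not converged:
        warnings.warn("optimizer did not converge; best-seen returned", stacklevel=2)
    params = ModelParams.from_transformed(best.x)

    cov_t = np.full((3, 3), np.nan)
    cov = np.full((3, 3), np.nan)
    ci95: dict = {}
    if compute_ci:
        cov_t, cov, ci95 = fisher_confidence(best.x, cost_fn)

    result = FitResult(
        params=params,
        cost=float(best.fun),
        cov=cov,
        cov_transformed=cov_t,
        ci95=ci95,
        diagnostics={"trace": trace, "n_prunings": data.n_prunings, "N": N},
        converged=converged,
    )
    if n_snp is not None and mean_het is not None:
        from .derived import h2_observed, n_causal

        h2 = h2_observed(params.pi1, params.sigma_beta2, n_snp, mean_het)
        result.derived["h2"] = h2
        result.derived["n_causal"] = n_causal(params.pi1, n_snp)
        if compute_ci and np.all(np.isfinite(cov_t)):
            # delta method on log h2: grad wrt (logit pi1, log sb2, log s02)
            g = np.array([1.0 - params.pi1, 1.0, 0.0])
            var_log = float(g @ cov_t @ g)
            se = np.sqrt(max(var_log, 0.0))
            result.derived["h2_ci95"] = (
                h2 * np.exp(-1.96 * se),
                h2 * np.exp(1.96 * se),
            )
    return result


def fit_gwas(
    panel,
    zscores: ZScoreSet,
    w_max: int = 20,
    r2_min: float = 0.05,
    n_h: int = 10,
    n_l: int = 10,
    prune_r2: float = 0.8,
    prune_iters: int = 10,
    seed: int | None = None,
    zgrid: ZGrid | None = None,
    init: ModelParams = DEFAULT_INIT,
    compute_ci: bool = True,
    structures: tuple | None = None,
):
    """End-to-end fit from a reference panel and a z-score set.

    Builds per-SNP LD histograms, the H-L grid over the typed SNPs,
    random pruning masks, the binned counts, and runs the
    maximum-likelihood fit at the median effective sample size.
    Returns ``(FitResult, (histograms, hlgrid, prune_masks))``; pass
    ``structures`` back in to reuse them across refits of the same
    panel/typing (for example when only the z-scores change).
    """
    from .ldstruct import build_hl_grid, build_ld_histograms, random_prune

    zgrid = zgrid or ZGrid()
    if structures is None:
        hists = build_ld_histograms(panel.r2, panel.het, w_max=w_max, r2_min=r2_min)
        hlgrid = build_hl_grid(
            hists, panel.het, n_h=n_h, n_l=n_l, typed=zscores.panel_index
        )
        masks = random_prune(
            panel.r2, threshold=prune_r2, n_iter=prune_iters, seed=seed,
            candidates=zscores.panel_index,
        )
    else:
        hists, hlgrid, masks = structures
    data = prepare_fit_data(zscores, hlgrid, masks, zgrid)
    result = fit_model(
        data,
        hlgrid,
        zscores.median_n,
        init=init,
        compute_ci=compute_ci,
        n_snp=panel.n_snp,
        mean_het=float(panel.het.mean()),
    )
    return result, (hists, hlgrid, masks)


def _nearest_psd(A: np.ndarray) -> np.ndarray:
    S = 0.5 * (A + A.T)
    vals, vecs = np.linalg.eigh(S)
    return (vecs * np.maximum(vals, 1e-12)) @ vecs.T


def fisher_confidence(theta_opt: np.ndarray, cost_fn, step: float = 1e-3):
    """Observed-information covariance at the optimum.

    The Hessian of the cost in transformed coordinates is estimated by
    central differences; its inverse is the covariance there, mapped to
    the natural scale by the delta method.  95% intervals are formed in
    transformed coordinates and mapped back, so they respect the
    parameter domains.
    """
    theta_opt = np.asarray(theta_opt, dtype=float)
    p = len(theta_opt)
    h = step * (1.0 + np.abs(theta_opt))
    H = np.empty((p, p))
    f0 = cost_fn(theta_opt)

    def f(dx):
        return cost_fn(theta_opt + dx)

    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(ei) - 2 * f0 + f(-ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(ei + ej) - f(ei - ej) - f(-ei + ej) + f(-ei - ej)
            ) / (4 * h[i] * h[j])

    repaired = False
    try:
        cov_t = np.linalg.inv(H)
        if np.any(np.linalg.eigvalsh(0.5 * (cov_t + cov_t.T)) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_t = np.linalg.pinv(_nearest_psd(H))
        repaired = True
    cov_t = 0.5 * (cov_t + cov_t.T)

    params = ModelParams.from_transformed(theta_opt)
    # d(natural)/d(transformed) at the optimum
    jac = np.diag(
        [params.pi1 * (1 - params.pi1), params.sigma_beta2, params.sigma0_2]
    )
    cov = jac @ cov_t @ jac

    se_t = np.sqrt(np.maximum(np.diag(cov_t), 0.0))
    lo = ModelParams.from_transformed(theta_opt - 1.96 * se_t)
    hi = ModelParams.from_transformed(theta_opt + 1.96 * se_t)
    ci95 = {
        "pi1": (lo.pi1, hi.pi1),
        "sigma_beta2": (lo.sigma_beta2, hi.sigma_beta2),
        "sigma0_2": (lo.sigma0_2, hi.sigma0_2),
    }
    if repaired:
        ci95["hessian_repaired"] = True
    return cov_t, cov, ci95
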