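"""Reference-panel LD and heterozygosity structure.

Everything the mixture model knows about a SNP is condensed into its LD
"histogram": for each of ``w_max`` equally spaced r-squared bins on
[r2_min, 1], the number of reference SNPs in that LD range with the focal
SNP (self included, at r2 = 1) and their mean heterozygosity.  SNPs are
then coarse-grained onto a two-dimensional heterozygosity x total-LD
("H-L") grid whose per-bin averaged histograms drive the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ReferencePanel",
    "LdHistogram",
    "LdHistogramSet",
    "HLGrid",
    "PruneMask",
    "compute_heterozygosity",
    "compute_sparse_r2",
    "build_ld_histogram",
    "build_ld_histograms",
    "build_hl_grid",
    "random_prune",
]

MAF_FLOOR = 0.002


def compute_heterozygosity(allele_freq: np.ndarray) -> np.ndarray:
    """Heterozygosity H = 2p(1-p) for allele frequencies p in (0, 1)."""
    p = np.asarray(allele_freq, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return 2.0 * p * (1.0 - p)


@dataclass
class ReferencePanel:
    """Per-SNP allele frequency/heterozygosity plus sparse pairwise LD.

    ``r2`` stores squared genotype correlations at or above the noise
    floor ``r2_min`` (unit diagonal always present).  ``r_signed``
    optionally keeps the signed correlations for the same entries; the
    estimator itself only ever uses r2, but the direct z-score simulator
    needs signs.
    """

    snp_ids: np.ndarray
    allele_freq: np.ndarray
    het: np.ndarray
    r2: sp.csr_matrix
    n_ref_samples: int
    r2_min: float = 0.05
    r_signed: sp.csr_matrix | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    @property
    def n_snp(self) -> int:
        return len(self.allele_freq)

    def validate(self) -> None:
        maf = np.minimum(self.allele_freq, 1.0 - self.allele_freq)
        if np.any(maf < MAF_FLOOR - 1e-12):
            raise ValueError(f"panel contains SNPs with MAF < {MAF_FLOOR}")
        if np.any(self.het <= 0.0) or np.any(self.het > 0.5 + 1e-12):
            raise ValueError("heterozygosity outside (0, 0.5]")
        d = self.r2.diagonal()
        if not np.allclose(d, 1.0):
            raise ValueError("r2 diagonal must be 1 (LD with self)")


def compute_sparse_r2(
    genotypes: np.ndarray,
    r2_min: float = 0.05,
    window_cap: int = 1500,
    return_signed: bool = False,
    chunk: int = 1024,
):
    """Sparse pairwise squared correlation between genotype columns.

    Parameters
    ----------
    genotypes : (n_samples, n_snp) array of dosages (columns are SNPs).
    r2_min : entries with r2 below this noise floor are dropped.
    window_cap : only SNP pairs within this index distance are scanned;
        LD blocks in practice span at most O(1000) panel SNPs.
    return_signed : also return the signed correlation matrix on the
        same sparsity pattern.

    Zero-variance columns are flagged with a warning and excluded from
    off-diagonal LD (their diagonal stays 1).
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("genotypes must be a (samples >= 2) x SNPs matrix")
    n_samples, n_snp = X.shape
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0.0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-variance SNP column(s) excluded from LD",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        Xs = np.where(dead, 0.0, X / np.where(dead, 1.0, sd))

    rows, cols, vals = [], [], []
    for a in range(0, n_snp, chunk):
        b = min(a + chunk, n_snp)
        hi = min(b + window_cap, n_snp)
        # upper-triangle band of the correlation matrix
        C = Xs[:, a:b].T @ Xs[:, a:hi] / n_samples
        r, c = np.nonzero(C * C >= r2_min)
        keep = (c + a) > (r + a)  # strictly upper triangle, no self
        keep &= (c + a) - (r + a) <= window_cap
        r, c = r[keep], c[keep]
        rows.append(r + a)
        cols.append(c + a)
        vals.append(C[r, c])

    i = np.concatenate(rows) if rows else np.empty(0, int)
    j = np.concatenate(cols) if cols else np.empty(0, int)
    v = np.concatenate(vals) if vals else np.empty(0, float)
    diag = np.arange(n_snp)
    i_all = np.concatenate([i, j, diag])
    j_all = np.concatenate([j, i, diag])
    v_all = np.concatenate([v, v, np.ones(n_snp)])
    r_signed = sp.coo_matrix((v_all, (i_all, j_all)), shape=(n_snp, n_snp)).tocsr()
    r2 = r_signed.copy()
    r2.data = r2.data**2
    if return_signed:
        return r2, r_signed
    return r2


@dataclass
class LdHistogram:
    """Single-SNP LD histogram: neighbour counts per r2 bin, mean
    neighbour heterozygosity per bin, bin-midpoint r2, total LD."""

    counts: np.ndarray
    mean_het: np.ndarray
    mean_r2: np.ndarray
    total_ld: float
    block_size: float


@dataclass
class LdHistogramSet:
    """Vectorised LD histograms for a whole panel (one row per SNP)."""

    counts: np.ndarray  # (n_snp, w_max)
    mean_het: np.ndarray  # (n_snp, w_max); 0 where counts == 0
    mean_r2: np.ndarray  # (w_max,) bin midpoints
    total_ld: np.ndarray  # (n_snp,)
    block_size: np.ndarray  # (n_snp,)
    w_max: int = 20
    r2_min: float = 0.05

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __getitem__(self, i: int) -> LdHistogram:
        return LdHistogram(
            counts=self.counts[i].copy(),
            mean_het=self.mean_het[i].copy(),
            mean_r2=self.mean_r2.copy(),
            total_ld=float(self.total_ld[i]),
            block_size=float(self.block_size[i]),
        )


def r2_bin_edges(w_max: int = 20, r2_min: float = 0.05) -> np.ndarray:
    """w_max equally spaced r2 bins on [r2_min, 1]; half-open except the
    last, which is closed at 1."""
    return np.linspace(r2_min, 1.0, w_max + 1)


def _r2_bin_index(r2vals: np.ndarray, w_max: int, r2_min: float) -> np.ndarray:
    w = np.floor((r2vals - r2_min) / (1.0 - r2_min) * w_max).astype(np.int64)
    return np.clip(w, 0, w_max - 1)


def build_ld_histograms(
    r2: sp.csr_matrix,
    het: np.ndarray,
    w_max: int = 20,
    r2_min: float = 0.05,
) -> LdHistogramSet:
    """LD histograms for every SNP from the stored sparse r2 rows."""
    r2 = r2.tocsr()
    n_snp = r2.shape[0]
    het = np.asarray(het, dtype=float)
    indptr, indices, data = r2.indptr, r2.indices, r2.data
    nnz_per_row = np.diff(indptr)
    row = np.repeat(np.arange(n_snp), nnz_per_row)
    w = _r2_bin_index(data, w_max, r2_min)
    flat = row * w_max + w
    counts = np.bincount(flat, minlength=n_snp * w_max).reshape(n_snp, w_max)
    het_sum = np.bincount(flat, weights=het[indices], minlength=n_snp * w_max)
    het_sum = het_sum.reshape(n_snp, w_max)
    with np.errstate(invalid="ignore"):
        mean_het = np.where(counts > 0, het_sum / np.maximum(counts, 1), 0.0)
    total_ld = np.asarray(r2.sum(axis=1)).ravel()
    edges = r2_bin_edges(w_max, r2_min)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return LdHistogramSet(
        counts=counts.astype(float),
        mean_het=mean_het,
        mean_r2=mids,
        total_ld=total_ld,
        block_size=nnz_per_row.astype(float),
        w_max=w_max,
        r2_min=r2_min,
    )


def build_ld_histogram(
    snp_index: int,
    r2: sp.csr_matrix,
    het: np.ndarray,
    w_max: int = 20,
    r2_min: float = 0.05,
) -> LdHistogram:
    """LD histogram for one SNP (self included at r2 = 1)."""
    r2 = r2.tocsr()
    lo, hi = r2.indptr[snp_index], r2.indptr[snp_index + 1]
    nbr, vals = r2.indices[lo:hi], r2.data[lo:hi]
    w = _r2_bin_index(vals, w_max, r2_min)
    counts = np.bincount(w, minlength=w_max).astype(float)
    het_sum = np.bincount(w, weights=np.asarray(het, float)[nbr], minlength=w_max)
    mean_het = np.where(counts > 0, het_sum / np.maximum(counts, 1.0), 0.0)
    edges = r2_bin_edges(w_max, r2_min)
    return LdHistogram(
        counts=counts,
        mean_het=mean_het,
        mean_r2=0.5 * (edges[:-1] + edges[1:]),
        total_ld=float(vals.sum()),
        block_size=float(len(vals)),
    )


@dataclass
class HLGrid:
    """Heterozygosity x total-LD grid with per-bin averaged histograms.

    Only occupied bins are materialised; ``bin_index`` maps each typed
    SNP to its position in the occupied-bin arrays.
    """

    h_edges: np.ndarray
    l_edges: np.ndarray
    bin_index: np.ndarray  # (n_typed,) -> [0, n_bins)
    counts: np.ndarray  # (n_bins, w_max) bin-averaged real counts
    mean_het: np.ndarray  # (n_bins, w_max)
    mean_r2: np.ndarray  # (w_max,)
    bin_counts: np.ndarray  # (n_bins,) member SNPs
    bin_mean_H: np.ndarray
    bin_mean_L: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_counts)


def _grid_digitize(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    nb = len(edges) - 1
    span = edges[-1] - edges[0]
    if span <= 0:
        return np.zeros(len(x), dtype=np.int64)
    idx = np.floor((x - edges[0]) / span * nb).astype(np.int64)
    return np.clip(idx, 0, nb - 1)  # max edge inclusive


def build_hl_grid(
    histograms: LdHistogramSet,
    het: np.ndarray,
    total_ld: np.ndarray | None = None,
    n_h: int = 10,
    n_l: int = 10,
    typed: np.ndarray | None = None,
    use_block_size: bool = False,
) -> HLGrid:
    """Bin typed SNPs on a (heterozygosity, total LD) grid and average
    the member LD histograms per occupied bin.

    Counts are averaged as reals across members; per-bin heterozygosity
    is the count-weighted mean.  ``use_block_size=True`` swaps total LD
    for LD block size as the second binning axis.
    """
    het = np.asarray(het, dtype=float)
    if total_ld is None:
        total_ld = histograms.block_size if use_block_size else histograms.total_ld
    total_ld = np.asarray(total_ld, dtype=float)
    n_all = len(het)
    if typed is None:
        typed = np.arange(n_all)
    typed = np.asarray(typed)
    if typed.dtype == bool:
        typed = np.nonzero(typed)[0]

    h, L = het[typed], total_ld[typed]
    h_edges = np.linspace(h.min(), h.max(), n_h + 1)
    l_edges = np.linspace(L.min(), L.max(), n_l + 1)
    hi = _grid_digitize(h, h_edges)
    li = _grid_digitize(L, l_edges)
    raw = hi * n_l + li
    occupied, bin_index = np.unique(raw, return_inverse=True)
    n_bins = len(occupied)

    w_max = histograms.w_max
    c = histograms.counts[typed]
    hs = histograms.counts[typed] * histograms.mean_het[typed]
    flat = bin_index[:, None] * w_max + np.arange(w_max)[None, :]
    sum_c = np.bincount(flat.ravel(), weights=c.ravel(), minlength=n_bins * w_max)
    sum_h = np.bincount(flat.ravel(), weights=hs.ravel(), minlength=n_bins * w_max)
    sum_c = sum_c.reshape(n_bins, w_max)
    sum_h = sum_h.reshape(n_bins, w_max)
    members = np.bincount(bin_index, minlength=n_bins).astype(float)
    avg_counts = sum_c / members[:, None]
    mean_het = np.where(sum_c > 0, sum_h / np.maximum(sum_c, 1e-300), 0.0)
    return HLGrid(
        h_edges=h_edges,
        l_edges=l_edges,
        bin_index=bin_index,
        counts=avg_counts,
        mean_het=mean_het,
        mean_r2=histograms.mean_r2.copy(),
        bin_counts=members,
        bin_mean_H=np.bincount(bin_index, weights=h, minlength=n_bins) / members,
        bin_mean_L=np.bincount(bin_index, weights=L, minlength=n_bins) / members,
    )


@dataclass
class PruneMask:
    """Random-pruning selections: one boolean mask per iteration, each a
    maximal set of mutually sub-threshold SNPs."""

    iteration_masks: list
    r2_threshold: float
    n_iterations: int
    seed: int | None

    def __iter__(self):
        return iter(self.iteration_masks)


def random_prune(
    r2: sp.csr_matrix,
    threshold: float = 0.8,
    n_iter: int = 10,
    seed: int | None = None,
    candidates: np.ndarray | None = None,
) -> PruneMask:
    """Random pruning at ``r2 > threshold``.

    Each iteration sweeps SNPs in a fresh random order; a SNP is
    selected if no already-selected SNP tags it above the threshold, so
    each subset of "synonymous" SNPs contributes one random
    representative and selected SNPs are mutually below-threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    r2 = r2.tocsr()
    n = r2.shape[0]
    indptr, indices, data = r2.indptr, r2.indices, r2.data
    rng = np.random.default_rng(seed)
    if candidates is None:
        candidates = np.arange(n)
    candidates = np.asarray(candidates)
    eligible = np.zeros(n, dtype=bool)
    eligible[candidates] = True

    masks = []
    for _ in range(n_iter):
        order = rng.permutation(candidates)
        selected = np.zeros(n, dtype=bool)
        tagged = np.zeros(n, dtype=bool)
        for i in order:
            if tagged[i]:
                continue
            selected[i] = True
            lo, hi = indptr[i], indptr[i + 1]
            strong = indices[lo:hi][data[lo:hi] > threshold]
            tagged[strong] = True
            tagged[i] = True
        masks.append(selected & eligible)
    return PruneMask(
        iteration_masks=masks,
        r2_threshold=threshold,
        n_iterations=n_iter,
        seed=seed,
    )
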