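"""Readers, writers and the end-to-end pipeline.

Summary statistics are delimited text with a header; required columns
are a SNP identifier plus either Z or (P and a signed effect) and a
sample size (column or global value).  Panel LD structure can be cached
in an HDF5 container so repeated fits skip the genotype scan.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .fit import ZScoreSet
from .ldstruct import ReferencePanel, compute_heterozygosity

log = logging.getLogger("gwasmix")

__all__ = [
    "read_sumstats",
    "read_genotype_matrix",
    "save_panel_cache",
    "load_panel_cache",
    "run_pipeline",
]

_ALIASES = {
    "snp": {"snp", "rsid", "id", "snpid", "markername", "marker"},
    "z": {"z", "zscore", "z_score", "stat"},
    "p": {"p", "pval", "pvalue", "p_value", "p_bolt_lmm"},
    "beta": {"beta", "b", "effect", "log_odds", "logor", "or"},
    "n": {"n", "neff", "n_eff", "nchrobs", "n_total"},
    "chr": {"chr", "chrom", "chromosome"},
    "pos": {"pos", "bp", "position", "base_pair_location"},
}


def _resolve(columns, key):
    lower = {c.lower(): c for c in columns}
    for alias in _ALIASES[key]:
        if alias in lower:
            return lower[alias]
    return None


def read_sumstats(
    path,
    panel: ReferencePanel | None = None,
    n_global: float | None = None,
    sep: str | None = None,
) -> ZScoreSet:
    """Read GWAS summary statistics and map them onto a panel.

    Z is taken directly when present; otherwise z = -Phi^-1(p/2) *
    sign(effect) from a P column and a signed effect (BETA, or an odds
    ratio, whose log supplies the sign).  Duplicate SNP ids keep the
    first occurrence; non-numeric rows are dropped with a count.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    snp_col = _resolve(df.columns, "snp")
    if snp_col is None:
        raise ValueError("sumstats must contain a SNP identifier column")
    z_col = _resolve(df.columns, "z")
    if z_col is not None:
        z = pd.to_numeric(df[z_col], errors="coerce")
    else:
        p_col = _resolve(df.columns, "p")
        b_col = _resolve(df.columns, "beta")
        if p_col is None or b_col is None:
            raise ValueError("sumstats need Z, or P plus a signed effect column")
        p = pd.to_numeric(df[p_col], errors="coerce")
        eff = pd.to_numeric(df[b_col], errors="coerce")
        if b_col.lower() == "or":
            eff = np.log(eff)
        z = pd.Series(stats.norm.isf(p / 2), index=df.index) * np.sign(eff)

    n_col = _resolve(df.columns, "n")
    if n_col is not None:
        n_eff = pd.to_numeric(df[n_col], errors="coerce")
    elif n_global is not None:
        n_eff = pd.Series(float(n_global), index=df.index)
    else:
        raise ValueError("sample size column missing and no global N supplied")

    ok = z.notna() & n_eff.notna() & (n_eff > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropped %d non-numeric/invalid sumstats rows", n_bad)
    df = df.loc[ok]
    z = z.loc[ok].to_numpy(dtype=float)
    n_eff = n_eff.loc[ok].to_numpy(dtype=float)
    ids = df[snp_col].astype(str).to_numpy()

    uniq, first = np.unique(ids, return_index=True)
    if len(uniq) < len(ids):
        warnings.warn(
            f"{len(ids) - len(uniq)} duplicate SNP id(s); first kept", stacklevel=2
        )
        first = np.sort(first)
        ids, z, n_eff = ids[first], z[first], n_eff[first]

    if panel is None:
        panel_index = np.arange(len(ids))
    else:
        lookup = {s: i for i, s in enumerate(panel.snp_ids.astype(str))}
        hit = np.array([lookup.get(s, -1) for s in ids])
        n_miss = int((hit < 0).sum())
        if n_miss:
            log.warning("%d sumstats SNP(s) absent from the panel; dropped", n_miss)
        keep = hit >= 0
        ids, z, n_eff, panel_index = ids[keep], z[keep], n_eff[keep], hit[keep]

    return ZScoreSet(snp_ids=ids, z=z, n_eff=n_eff, panel_index=panel_index)


def read_genotype_matrix(path, sep: str | None = None) -> np.ndarray:
    """Delimited samples x SNPs dosage matrix (header optional)."""
    df = pd.read_csv(path, sep=sep, engine="python", header=None)
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = pd.read_csv(path, sep=sep, engine="python")
    return df.to_numpy(dtype=float)


def save_panel_cache(panel: ReferencePanel, path) -> None:
    """Persist the panel (frequencies plus sparse LD) in HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["n_ref_samples"] = panel.n_ref_samples
        f.attrs["r2_min"] = panel.r2_min
        f.create_dataset("snp_ids", data=panel.snp_ids.astype("S"))
        f.create_dataset("allele_freq", data=panel.allele_freq)
        for name, mat in (("r2", panel.r2), ("r_signed", panel.r_signed)):
            if mat is None:
                continue
            grp = f.create_group(name)
            grp.create_dataset("data", data=mat.data)
            grp.create_dataset("indices", data=mat.indices)
            grp.create_dataset("indptr", data=mat.indptr)


def load_panel_cache(path) -> ReferencePanel:
    import h5py

    with h5py.File(path, "r") as f:
        freq = f["allele_freq"][:]
        n = len(freq)

        def csr(name):
            if name not in f:
                return None
            g = f[name]
            return sp.csr_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]), shape=(n, n)
            )

        return ReferencePanel(
            snp_ids=f["snp_ids"][:].astype(str),
            allele_freq=freq,
            het=compute_heterozygosity(freq),
            r2=csr("r2"),
            n_ref_samples=int(f.attrs["n_ref_samples"]),
            r2_min=float(f.attrs["r2_min"]),
            r_signed=csr("r_signed"),
        )


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def run_pipeline(config: dict) -> dict:
    """Orchestrate LD structure -> pruning -> fit -> derived -> power
    -> QQ from a config mapping, writing all artifacts under
    ``config['out']``.

    Required keys: ``sumstats`` (path) and one of ``panel_cache`` or
    ``genotypes`` (+ ``snp_meta``).  Optional: seed, n_global,
    prevalence/cases/controls, grid and pruning settings, power range.
    Returns the result bundle that was written to JSON.
    """
    from . import __version__
    from .derived import heritability_chain, qq_curves
    from .fit import fit_gwas
    from .ldstruct import compute_sparse_r2
    from .modelpdf import ZGrid
    from .posterior import power_curve

    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "panel_cache" in config:
        cache = Path(config["panel_cache"])
        if not cache.exists():
            raise FileNotFoundError(
                f"panel cache {cache} not found; build one with the "
                "`gwasmix panel` subcommand or point `genotypes` at a matrix"
            )
        panel = load_panel_cache(cache)
    elif "genotypes" in config:
        geno = read_genotype_matrix(config["genotypes"])
        meta = pd.read_csv(config["snp_meta"], sep=None, engine="python")
        freq = geno.mean(axis=0) / 2.0
        panel = ReferencePanel(
            snp_ids=meta[_resolve(meta.columns, "snp")].astype(str).to_numpy(),
            allele_freq=freq,
            het=compute_heterozygosity(freq),
            r2=compute_sparse_r2(geno, r2_min=config.get("r2_min", 0.05)),
            n_ref_samples=geno.shape[0],
        )
    else:
        raise ValueError("config needs `panel_cache` or `genotypes`")

    zs = read_sumstats(
        config["sumstats"], panel=panel, n_global=config.get("n_global")
    )
    zgrid = ZGrid(
        n_points=int(config.get("n_points", 1024)), z1=float(config.get("z1", -38.0))
    )
    result, (hists, hlgrid, masks) = fit_gwas(
        panel,
        zs,
        w_max=int(config.get("w_max", 20)),
        r2_min=float(config.get("r2_min", 0.05)),
        n_h=int(config.get("n_h", 10)),
        n_l=int(config.get("n_l", 10)),
        prune_r2=float(config.get("prune_r2", 0.8)),
        prune_iters=int(config.get("prune_iters", 10)),
        seed=seed,
        zgrid=zgrid,
    )

    her = heritability_chain(
        result.params,
        n_snp=int(config.get("n_snp", panel.n_snp)),
        mean_het=float(config.get("h_bar", panel.het.mean())),
        K=config.get("prevalence"),
        n_cases=config.get("cases"),
        n_controls=config.get("controls"),
    )
    N = zs.median_n
    qq = qq_curves(zs.z[masks.iteration_masks[0][zs.panel_index]], hlgrid,
                   result.params, N, zgrid)
    pd.DataFrame(
        {
            "z_nominal": qq.z_nominal,
            "neglog_p": qq.neglog_p,
            "neglog_q_model": qq.neglog_q_model,
            "neglog_q_empirical": qq.neglog_q_empirical,
            "band_lo": qq.band_lo,
            "band_hi": qq.band_hi,
        }
    ).to_csv(out / "qq.tsv", sep="\t", index=False)

    try:
        pc = power_curve(
            hlgrid,
            result.params,
            n_min=float(config.get("n_min", N / 10)),
            n_max=float(config.get("n_max", N * 100)),
            n_grid=int(config.get("n_grid", 30)),
            zgrid=zgrid,
            current_N=N,
        )
        pc.as_table().to_csv(out / "power.tsv", sep="\t", index=False)
        power_now = pc.current_A
    except ValueError:
        power_now = None

    bundle = {
        "version": __version__,
        "seed": seed,
        "N_median": N,
        "params": {
            "pi1": result.params.pi1,
            "sigma_beta2": result.params.sigma_beta2,
            "sigma0_2": result.params.sigma0_2,
        },
        "ci95": _jsonify(result.ci95),
        "cost": result.cost,
        "converged": result.converged,
        "derived": _jsonify(result.derived),
        "h2_observed": her.h2_observed,
        "h2_liability": her.h2_liability,
        "n_causal": her.n_causal,
        "lambda_empirical": qq.lambda_empirical,
        "lambda_model": qq.lambda_model,
        "power_at_current_N": power_now,
    }
    (out / "result.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
    log.info("pipeline complete; results under %s", out)
    return bundle
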