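"""Pooling-error-corrected association testing and inverse-variance meta-analysis.

Per pool, the case-minus-control difference d in mean pooled allele
frequency is tested with a chi-square statistic d^2/var(d), where

    var(d) = pbar (1-pbar) (1/(2 n_case) + 1/(2 n_control))
             + sigma2_pool (1/k_case + 1/k_control)

the first term being the binomial sampling variance of the allele
frequencies at the pool's sample sizes and the second the bead-array
measurement variance averaged over the replicate arrays — the "pooling
error" correction.  Per-pool results are combined across pools by
fixed-effect inverse-variance meta-analysis, ranked, and tiered at the
conventional genome-wide (5e-8) and suggestive (1e-6) thresholds.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import PoolDesign

log = logging.getLogger(__name__)

GW_ALPHA = 5e-8
SUGGESTIVE_ALPHA = 1e-6


def pool_test(
    mean_paf_case,
    mean_paf_control,
    n_case: int,
    n_control: int,
    k_case: int,
    k_control: int,
    sigma2_pool: float,
) -> pd.DataFrame:
    """Pooling-error-corrected allelic test for one pool comparison.

    Accepts scalars or aligned arrays of case/control mean PAF (across
    replicate arrays).  Returns a frame with columns d, var_d, chi2, p;
    SNPs whose pooled mean frequency is 0 or 1 are monomorphic and get
    NaN statistics.
    """
    if k_case < 1 or k_control < 1:
        raise ValueError("need at least one array per group")
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one sample per group")
    if sigma2_pool < 0:
        raise ValueError("sigma2_pool must be >= 0")
    pc = np.atleast_1d(np.asarray(mean_paf_case, dtype=float))
    pu = np.atleast_1d(np.asarray(mean_paf_control, dtype=float))
    d = pc - pu
    pbar = (n_case * pc + n_control * pu) / (n_case + n_control)
    var_d = pbar * (1 - pbar) * (0.5 / n_case + 0.5 / n_control) + sigma2_pool * (
        1.0 / k_case + 1.0 / k_control
    )
    mono = (pbar <= 0) | (pbar >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(mono, np.nan, d * d / var_d)
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame(
        {"d": d, "var_d": np.where(mono, np.nan, var_d), "chi2": chi2, "p": p}
    )


def estimate_sigma2_pool(
    paf_table: pd.DataFrame,
    floor: float = 6.8e-5,
) -> float:
    """Estimate the per-array PAF measurement variance from replicate arrays.

    Median across SNP x pool x group cells of the replicate-array PAF
    variance, floored at ``floor``.  Without any replicated group the
    floor is returned with a warning.
    """
    g = paf_table.groupby(["snp_id", "pool_id", "group"], sort=False)["paf"]
    var = g.var()
    var = var.dropna()
    if var.empty:
        log.warning("no replicate arrays; using sigma2_pool floor %.3g", floor)
        return floor
    return float(max(np.median(var), floor))


def test_pools(
    paf_summary: pd.DataFrame,
    design: PoolDesign,
    sigma2_pool: float | str = "auto",
    paf_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-pool association tests for every SNP in a PAF summary.

    ``paf_summary`` is the output of :func:`poolgwas.qc.summarize_paf`.
    ``sigma2_pool="auto"`` estimates the array variance from the
    replicate arrays in ``paf_table`` (falling back to the design value).
    """
    if sigma2_pool == "auto":
        if paf_table is not None:
            sigma2_pool = estimate_sigma2_pool(paf_table)
        else:
            sigma2_pool = design.sigma2_pool
    sigma2_pool = float(sigma2_pool)

    wide = paf_summary.pivot_table(
        index=["snp_id", "pool_id"], columns="group", values="mean_paf", aggfunc="first"
    )
    out = []
    for spec in design.pools:
        try:
            sub = wide.xs(spec.pool_id, level="pool_id")
        except KeyError:
            continue
        sub = sub.dropna(subset=["case", "control"])
        res = pool_test(
            sub["case"].to_numpy(),
            sub["control"].to_numpy(),
            n_case=spec.n_cases,
            n_control=spec.n_controls,
            k_case=spec.k_case_arrays,
            k_control=spec.k_control_arrays,
            sigma2_pool=sigma2_pool,
        )
        res.insert(0, "snp_id", sub.index.to_numpy())
        res.insert(1, "pool_id", spec.pool_id)
        out.append(res)
    if not out:
        raise ValueError("no pool has PAF data for both groups")
    return pd.concat(out, ignore_index=True)


def meta_analyze(pool_results: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect inverse-variance combination of per-pool results.

    Per SNP: weights w_i = 1/var_d_i, combined_d = sum(w d)/sum(w),
    combined_var = 1/sum(w), chi2_meta = combined_d^2/combined_var.
    Pools with non-finite var_d (monomorphic) are dropped per SNP.
    """
    res = pool_results.dropna(subset=["var_d"])
    if res.empty:
        raise ValueError("no testable pool results")
    w = 1.0 / res["var_d"]
    g = res.assign(w=w, wd=w * res["d"]).groupby("snp_id", sort=False)
    sw = g["w"].sum()
    combined_d = g["wd"].sum() / sw
    combined_var = 1.0 / sw
    chi2 = combined_d**2 / combined_var
    meta = pd.DataFrame(
        {
            "combined_d": combined_d,
            "combined_var": combined_var,
            "chi2_meta": chi2,
            "p_meta": stats.chi2.sf(chi2, df=1),
            "n_pools_used": g.size(),
        }
    )
    return meta.rename_axis("snp_id").reset_index()


def rank_and_threshold(
    meta: pd.DataFrame,
    gw_alpha: float = GW_ALPHA,
    suggestive_alpha: float = SUGGESTIVE_ALPHA,
) -> pd.DataFrame:
    """Rank SNPs by meta p-value and assign significance tiers.

    Ascending p, ties broken by |combined_d| descending then snp_id.
    Tier: "genome_wide" if p <= gw_alpha, "suggestive" if p < suggestive
    threshold, else "none".
    """
    out = meta.copy()
    out["_absd"] = -out["combined_d"].abs()
    out = out.sort_values(["p_meta", "_absd", "snp_id"], kind="mergesort").drop(columns="_absd")
    out["rank"] = np.arange(1, len(out) + 1)
    out["tier"] = np.select(
        [out["p_meta"] <= gw_alpha, out["p_meta"] < suggestive_alpha],
        ["genome_wide", "suggestive"],
        default="none",
    )
    return out.reset_index(drop=True)


def proxy_support(
    index_snp: str,
    ld_r2: Mapping[str, float] | pd.Series,
    meta: pd.DataFrame,
    r2_min: float = 0.5,
    support_alpha: float = 1e-3,
) -> str:
    """Corroborate an index SNP's signal with SNPs in LD with it.

    A proxy is any other SNP with r2 > ``r2_min`` against the index.
    Returns "no_proxy" if none exists, "supported" if at least one proxy
    has meta p < ``support_alpha``, else "unsupported".
    """
    m = meta.set_index("snp_id")
    if index_snp not in m.index:
        raise ValueError(f"index SNP {index_snp!r} not in meta results")
    r2 = pd.Series(ld_r2, dtype=float)
    proxies = r2[(r2 > r2_min) & (r2.index != index_snp)].index
    proxies = proxies.intersection(m.index)
    if len(proxies) == 0:
        return "no_proxy"
    if (m.loc[proxies, "p_meta"] < support_alpha).any():
        return "supported"
    return "unsupported"
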