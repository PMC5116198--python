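"""Beadscore cleaning, correction factor, PAF computation and SNP filters.

The pooling allele frequency (PAF) of a SNP on a two-channel bead array
is estimated as red/(red + green/corr), where corr is a per-array,
per-strand correction factor rescaling the green channel so that the
mean PAF over SNPs is 0.5 — compensating systematic channel imbalance.

After PAF estimation, SNPs pass a filter cascade before association
testing: reference-panel MAF > 1%, at most 10% negative beadscores,
mean red+green intensity sum >= 1200 on every array, autosomal location,
no significant case-control replicate-variance difference, sufficient
probe counts, and |PAF - reference frequency| <= 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import AUTOSOMES, BeadArrayMeasurement

log = logging.getLogger(__name__)

#: long-format PAF table schema: one row per SNP x array
PAF_COLUMNS = ("snp_id", "pool_id", "group", "array_id", "strand", "paf", "n_probes_used")

FILTER_RULES = (
    "maf_panel",
    "negative_probes",
    "intensity_sum",
    "autosome",
    "variance_diff",
    "probe_count",
    "ref_af_concordance",
    "matched",
)


class EstimationError(RuntimeError):
    """Raised when the correction factor cannot be estimated."""


@dataclass
class QCThresholds:
    """Filter-cascade thresholds; defaults are the published analysis values."""

    maf_min: float = 0.01            # panel MAF must exceed this
    neg_max: float = 0.10            # max tolerated fraction of negative beadscores
    intensity_min: float = 1200.0    # min mean red + mean green per SNP per array
    var_alpha: float = 0.001         # two-sided F-test level for case/control variance
    probe_frac_low: float = 0.5      # required probe fraction for MAF in (maf_min, 0.05]
    probe_frac_high: float = 1.0 / 3.0  # required probe fraction for MAF > 0.05
    conc_max: float = 0.3            # max |PAF - reference frequency|


def _usable(probes: pd.DataFrame) -> pd.DataFrame:
    """Probes usable for PAF: both channels non-negative, not both zero."""
    m = (probes["red"] >= 0) & (probes["green"] >= 0) & (probes["red"] + probes["green"] > 0)
    return probes[m]


def _mean_paf_over_snps(probes: pd.DataFrame, corr: float) -> float:
    paf = probes["red"] / (probes["red"] + probes["green"] / corr)
    return paf.groupby(probes["snp_id"], sort=False).mean().mean()


def compute_correction_factor(
    array: BeadArrayMeasurement,
    snp_ids: Iterable[str] | None = None,
    tol: float = 1e-6,
    bracket: tuple[float, float] = (1e-3, 1e3),
) -> float:
    """Solve the green-channel correction factor for one array (one strand).

    Finds corr > 0 such that the mean over SNPs of the mean-probe PAF
    equals 0.5 within ``tol``.  PAF is strictly increasing in corr, so the
    root is found by bisection on ``bracket``.

    ``snp_ids`` optionally restricts the calibration SNP set (e.g. to SNPs
    passing the pre-PAF filters).
    """
    probes = array.probes
    if snp_ids is not None:
        probes = probes[probes["snp_id"].isin(set(snp_ids))]
    probes = _usable(probes)
    if probes.empty:
        raise EstimationError(f"array {array.array_id}: no usable probes for calibration")

    lo, hi = bracket
    f_lo = _mean_paf_over_snps(probes, lo) - 0.5
    f_hi = _mean_paf_over_snps(probes, hi) - 0.5
    if f_lo > 0 or f_hi < 0:
        raise EstimationError(
            f"array {array.array_id}: no correction factor in [{lo}, {hi}]"
        )
    while True:
        mid = np.sqrt(lo * hi)  # bisect on log scale: bracket spans 6 decades
        f_mid = _mean_paf_over_snps(probes, mid) - 0.5
        if abs(f_mid) < tol:
            return float(mid)
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-14:  # bracket exhausted at float precision
            return float(mid)


def compute_paf(array: BeadArrayMeasurement, corr: float) -> pd.DataFrame:
    """Per-SNP pooled allele frequency on one array.

    Probe-level PAF = red/(red + green/corr) over usable probes
    (red >= 0, green >= 0, positive denominator); the SNP's PAF is the
    mean over its usable probes, NaN when no probe is usable.
    Returns a frame with columns snp_id, paf, n_probes_used.
    """
    if corr <= 0:
        raise ValueError("corr must be > 0")
    probes = _usable(array.probes)
    paf = probes["red"] / (probes["red"] + probes["green"] / corr)
    by_snp = paf.groupby(probes["snp_id"], sort=False)
    out = pd.DataFrame({"paf": by_snp.mean(), "n_probes_used": by_snp.size()})
    all_snps = array.probes["snp_id"].unique()
    out = out.reindex(all_snps)
    out["n_probes_used"] = out["n_probes_used"].fillna(0).astype(int)
    return out.rename_axis("snp_id").reset_index()


def estimate_paf_table(
    arrays: Sequence[BeadArrayMeasurement],
    calibration_snps: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Correction-factor calibration + PAF for a set of arrays.

    corr is solved per array (per strand) on ``calibration_snps`` when
    given, then PAF is computed for all SNPs on the array.  Returns the
    long-format PAF table (one row per SNP x array).
    """
    frames = []
    for arr in arrays:
        corr = compute_correction_factor(arr, snp_ids=calibration_snps)
        paf = compute_paf(arr, corr)
        paf.insert(1, "pool_id", arr.pool_id)
        paf.insert(2, "group", arr.group)
        paf.insert(3, "array_id", arr.array_id)
        paf.insert(4, "strand", arr.strand)
        frames.append(paf)
    table = pd.concat(frames, ignore_index=True)
    return table[list(PAF_COLUMNS)]


def summarize_paf(paf_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate arrays: mean and variance of PAF per SNP x pool x group."""
    g = paf_table.groupby(["snp_id", "pool_id", "group"], sort=False)["paf"]
    out = g.agg(mean_paf="mean", var_paf="var", n_arrays="count").reset_index()
    return out


def _variance_diff_fail(
    summary: pd.DataFrame, alpha: float
) -> pd.Series:
    """Two-sided F-test of case vs control replicate-array PAF variance.

    A SNP fails when any pool shows a case/control variance ratio with
    two-sided p < alpha.  Pools with fewer than 2 arrays in either group
    contribute no evidence.
    """
    wide = summary.pivot_table(
        index=["snp_id", "pool_id"],
        columns="group",
        values=["var_paf", "n_arrays"],
        aggfunc="first",
    )
    fail = pd.Series(False, index=summary["snp_id"].unique())
    if ("var_paf", "case") not in wide.columns or ("var_paf", "control") not in wide.columns:
        return fail
    v1 = wide[("var_paf", "case")]
    v0 = wide[("var_paf", "control")]
    k1 = wide[("n_arrays", "case")]
    k0 = wide[("n_arrays", "control")]
    ok = (k1 >= 2) & (k0 >= 2) & (v0 > 0) & v1.notna() & v0.notna()
    f = (v1 / v0)[ok]
    d1 = (k1 - 1)[ok]
    d0 = (k0 - 1)[ok]
    cdf = stats.f.cdf(f, d1, d0)
    p = 2 * np.minimum(cdf, 1 - cdf)
    bad_snps = f.index.get_level_values("snp_id")[p < alpha].unique()
    fail.loc[fail.index.intersection(bad_snps)] = True
    return fail


def apply_snp_filters(
    paf_table: pd.DataFrame,
    arrays: Sequence[BeadArrayMeasurement],
    panel: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Apply the SNP filter cascade; returns the per-SNP FilterReport frame.

    Columns: snp_id, one boolean per rule (True = pass), and ``retained``
    = logical AND of all rules.  SNPs present in the beadscores but absent
    from the panel fail the ``matched`` rule.
    """
    th = thresholds or QCThresholds()
    pan = panel.set_index("snp_id")
    snp_ids = pd.Index(pd.unique(pd.concat([a.probes["snp_id"] for a in arrays])))
    rep = pd.DataFrame(index=snp_ids.rename("snp_id"))

    rep["matched"] = rep.index.isin(pan.index)
    maf = np.minimum(pan["ref_af"], 1 - pan["ref_af"]).reindex(rep.index)
    rep["maf_panel"] = (maf > th.maf_min).fillna(False)

    # negative-probe fraction pooled over all probes on all arrays
    all_probes = pd.concat([a.probes for a in arrays], ignore_index=True)
    neg = (all_probes["red"] < 0) | (all_probes["green"] < 0)
    neg_frac = neg.groupby(all_probes["snp_id"]).mean().reindex(rep.index).fillna(1.0)
    rep["negative_probes"] = neg_frac <= th.neg_max

    # intensity sum: mean red + mean green >= threshold on every array
    ok_int = pd.Series(True, index=rep.index)
    for a in arrays:
        means = a.probes.groupby("snp_id", sort=False)[["red", "green"]].mean()
        s = (means["red"] + means["green"]).reindex(rep.index)
        ok_int &= (s >= th.intensity_min) | s.isna()
    rep["intensity_sum"] = ok_int

    rep["autosome"] = pan["chrom"].reindex(rep.index).isin(AUTOSOMES).fillna(False)

    summary = summarize_paf(paf_table)
    fail_var = _variance_diff_fail(summary, th.var_alpha)
    rep["variance_diff"] = ~fail_var.reindex(rep.index).fillna(False)

    # probe count: mean probes-present per array must exceed the MAF-dependent
    # fraction of the design's expected count (strict inequality)
    counts = all_probes.groupby("snp_id").size() / len(arrays)
    expected = pan["expected_probes"].reindex(rep.index)
    frac_needed = pd.Series(np.where(maf > 0.05, th.probe_frac_high, th.probe_frac_low),
                            index=rep.index)
    rep["probe_count"] = (counts.reindex(rep.index).fillna(0) > frac_needed * expected).fillna(False)

    # concordance: overall mean PAF across all arrays vs reference frequency
    overall = paf_table.groupby("snp_id", sort=False)["paf"].mean()
    diff = (overall.reindex(rep.index) - pan["ref_af"].reindex(rep.index)).abs()
    rep["ref_af_concordance"] = (diff <= th.conc_max).fillna(False)

    rule_cols = list(FILTER_RULES)
    rep["retained"] = rep[rule_cols].all(axis=1)
    return rep.reset_index()


def run_qc(
    arrays: Sequence[BeadArrayMeasurement],
    panel: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full QC stage: calibrate, compute PAF, filter.

    The correction factor is calibrated on SNPs passing the pre-PAF rules
    (panel MAF, negative-beadscore and intensity-sum), then PAF is
    recomputed for every SNP and the full cascade applied.
    Returns (paf_table restricted to retained SNPs, filter report).
    """
    th = thresholds or QCThresholds()
    # first pass: uncalibrated PAF only to drive the PAF-free rules
    prelim = estimate_paf_table(arrays)
    report0 = apply_snp_filters(prelim, arrays, panel, th)
    pre_ok = report0.loc[
        report0[["matched", "maf_panel", "negative_probes", "intensity_sum"]].all(axis=1),
        "snp_id",
    ]
    paf_table = estimate_paf_table(arrays, calibration_snps=pre_ok)
    report = apply_snp_filters(paf_table, arrays, panel, th)
    retained = set(report.loc[report["retained"], "snp_id"])
    kept = paf_table[paf_table["snp_id"].isin(retained)].reset_index(drop=True)
    log.info("QC retained %d / %d SNPs", len(retained), report.shape[0])
    return kept, report
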