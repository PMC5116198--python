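"""End-to-end driver: simulate -> QC -> pooled association -> validation -> LD.

A single seed fans out deterministically to per-stage child seeds (via
numpy SeedSequence spawn keys), so the whole run is reproducible while
stages stay decoupled.  Every stage writes a schema-stable TSV and the
run ends with a JSON summary of filter survival, significance tiers and
recovery against the simulation truth.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, io, ld, qc, synthetic, validation
from .config import RunConfig

log = logging.getLogger(__name__)

_STAGE_KEYS = {"panel": 0, "genotypes": 1, "pools": 2, "arrays": 3, "replication": 4}


def stage_seed(seed: int, stage: str, extra: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(_STAGE_KEYS[stage], extra))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pooled-GWAS chain on synthetic data; returns the summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"seed": config.seed}

    # --- simulate ---------------------------------------------------------
    panel = synthetic.simulate_panel(
        config.panel.n_snps, config.panel.maf_low, config.panel.maf_high,
        seed=stage_seed(config.seed, "panel"),
    )
    snp_ids = panel["snp_id"].to_numpy()
    or_map = {snp_ids[i]: v for i, v in config.effects.items()}
    discovery = synthetic.simulate_genotypes(
        panel, config.cohort.discovery_cases, config.cohort.discovery_controls,
        or_map=or_map, seed=stage_seed(config.seed, "genotypes"), id_prefix="D",
    )
    io.write_panel(panel, out / "panel.tsv")
    io.write_ped_map(discovery, out / "discovery", panel)

    sizes = [tuple(s) for s in config.pools.sizes]
    case_ids, control_ids = discovery.case_ids, discovery.control_ids
    pools, ci, ui = [], 0, 0
    for i, (nc, nu, k) in enumerate(sizes, start=1):
        pools.append(synthetic.PoolSpec(
            pool_id=f"pool{i}",
            case_ids=tuple(case_ids[ci:ci + nc]),
            control_ids=tuple(control_ids[ui:ui + nu]),
            k_case_arrays=k, k_control_arrays=k,
        ))
        ci += nc
        ui += nu
    design = synthetic.PoolDesign(pools=pools, sigma2_pool=config.pools.sigma2_pool)
    summary["pool_cases_total"] = design.total_cases
    summary["pool_controls_total"] = design.total_controls

    arrays, truth = [], {}
    for pi, spec in enumerate(design.pools):
        for gi, (group, ids, k) in enumerate(
            [("case", spec.case_ids, spec.k_case_arrays),
             ("control", spec.control_ids, spec.k_control_arrays)]
        ):
            frac = synthetic.construct_pool(
                discovery, ids, config.pools.contribution_cv,
                seed=stage_seed(config.seed, "pools", 2 * pi + gi),
            )
            truth[(spec.pool_id, group)] = frac
            arrays.extend(synthetic.simulate_arrays(
                frac, panel.set_index("snp_id")["expected_probes"], k,
                pool_id=spec.pool_id, group=group,
                channel_imbalance=config.arrays.channel_imbalance,
                intensity_scale=config.arrays.intensity_scale,
                noise_cv=config.arrays.noise_cv,
                negative_rate=config.arrays.negative_rate,
                probe_count_jitter=config.arrays.probe_count_jitter,
                seed=stage_seed(config.seed, "arrays", 2 * pi + gi),
            ))
    io.write_beadscores(arrays, out / "beadscores.tsv")
    log.info("simulation done in %.1fs", time.time() - t0)

    # --- QC ---------------------------------------------------------------
    t1 = time.time()
    paf_table, report = qc.run_qc(arrays, panel, config.qc)
    io.write_tsv(paf_table, out / "paf.tsv")
    io.write_tsv(report, out / "filter_report.tsv")
    summary["n_snps_input"] = int(report.shape[0])
    summary["n_snps_retained"] = int(report["retained"].sum())
    summary["filter_fail_counts"] = {
        rule: int((~report[rule]).sum()) for rule in qc.FILTER_RULES
    }
    log.info("QC done in %.1fs", time.time() - t1)

    # --- pooled association ----------------------------------------------
    t2 = time.time()
    paf_summary = qc.summarize_paf(paf_table)
    pool_results = association.test_pools(
        paf_summary, design, sigma2_pool=config.assoc.sigma2_pool, paf_table=paf_table
    )
    meta = association.meta_analyze(pool_results)
    ranked = association.rank_and_threshold(
        meta, config.assoc.gw_alpha, config.assoc.suggestive_alpha
    )
    results = ranked.merge(panel[["snp_id", "chrom", "pos"]], on="snp_id")
    io.write_tsv(pool_results, out / "pool_results.tsv")

    candidates = results.loc[results["tier"] != "none", "snp_id"].tolist()
    summary["tier_counts"] = results["tier"].value_counts().to_dict()
    summary["candidates"] = candidates

    # proxy check for candidates against the rest of the candidate set,
    # r^2 from the discovery control genotypes
    proxy = {}
    ctrl_dose = discovery.dosages.loc[discovery.control_ids]
    for snp in candidates:
        r2_map = {
            other: ld.r2_between(
                ctrl_dose[snp].to_numpy(float), ctrl_dose[other].to_numpy(float)
            )
            for other in candidates if other != snp
        }
        proxy[snp] = association.proxy_support(
            snp, r2_map, meta, config.assoc.r2_min, config.assoc.support_alpha
        )
    results["proxy_support"] = results["snp_id"].map(proxy).fillna("")
    io.write_tsv(results, out / "meta_results.tsv")
    log.info("association done in %.1fs", time.time() - t2)

    # --- two-stage validation --------------------------------------------
    t3 = time.time()
    staged = pd.DataFrame()
    if candidates:
        disc_val = validation.validate_snps(discovery, candidates)
        replication = synthetic.simulate_genotypes(
            panel, config.cohort.replication_cases, config.cohort.replication_controls,
            or_map=or_map, seed=stage_seed(config.seed, "replication"), id_prefix="R",
        )
        rep_val = validation.validate_snps(replication, candidates)
        merged = disc_val.merge(rep_val, on="snp_id", suffixes=("_discovery", "_replication"))
        merged = merged.rename(columns={
            "p_allelic_discovery": "p_discovery", "or_crude_discovery": "or_discovery",
            "p_allelic_replication": "p_replication", "or_crude_replication": "or_replication",
        })
        staged = validation.two_stage_filter(
            merged, config.validation.validation_alpha, config.validation.replication_alpha
        )
        io.write_tsv(staged, out / "validation_results.tsv")
    summary["validated"] = (
        staged.loc[staged["stage"].isin(["validated", "replicated"]), "snp_id"].tolist()
        if len(staged) else []
    )
    summary["replicated"] = (
        staged.loc[staged["stage"] == "replicated", "snp_id"].tolist() if len(staged) else []
    )

    # --- LD among candidates ---------------------------------------------
    ld_rows = []
    for i, s1 in enumerate(candidates):
        for s2 in candidates[i + 1:]:
            counts = np.zeros((3, 3))
            d1 = ctrl_dose[s1].to_numpy(int)
            d2 = ctrl_dose[s2].to_numpy(int)
            for a, b in zip(d1, d2):
                counts[a, b] += 1
            res = ld.ld_from_genotypes(counts)
            ld_rows.append({
                "locus1": s1, "locus2": s2, "d_prime": res.d_prime, "lod": res.lod,
                "r2": res.r2, "ci_low": res.ci_low, "ci_high": res.ci_high,
            })
    if ld_rows:
        io.write_tsv(pd.DataFrame(ld_rows), out / "ld_results.tsv")
    log.info("validation + LD done in %.1fs", time.time() - t3)

    # --- recovery vs truth ------------------------------------------------
    retained = set(report.loc[report["retained"], "snp_id"])
    errs = []
    agg = paf_summary.set_index(["snp_id", "pool_id", "group"])["mean_paf"]
    for (pool_id, group), frac in truth.items():
        keep = frac.index.intersection(
            [s for s in frac.index if s in retained]
        )
        est = agg.loc[[(s, pool_id, group) for s in keep]].to_numpy()
        errs.append(np.abs(est - frac.loc[keep].to_numpy()))
    if errs:
        allerr = np.concatenate(errs)
        summary["paf_mean_abs_error"] = float(allerr.mean())
        summary["paf_frac_within_0.01"] = float((allerr <= 0.01).mean())
    planted = [snp_ids[i] for i in config.effects]
    summary["planted_snps"] = planted
    summary["planted_detected_suggestive"] = [s for s in planted if s in candidates]
    log.info("pipeline finished in %.1fs", time.time() - t0)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
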