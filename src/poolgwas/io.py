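"""Readers and writers for the pipeline's plain-text formats.

All tabular outputs are tab-separated with a header row; genotypes go
through PLINK PED/MAP (alleles coded 1 = minor/effect, 2 = major,
0 = missing; sex 1 = M / 2 = F; phenotype 2 = case / 1 = control) with
covariates in a separate sample_id/sex/age TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import BeadArrayMeasurement, GenotypeDataset


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str}, keep_default_na=True)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    write_tsv(panel[["snp_id", "chrom", "pos", "ref_af", "expected_probes"]], path)


def read_panel(path: str | Path) -> pd.DataFrame:
    return read_tsv(path)


def write_beadscores(arrays: Sequence[BeadArrayMeasurement], path: str | Path) -> None:
    frames = []
    for a in arrays:
        f = a.probes.copy()
        f.insert(0, "array_id", a.array_id)
        f.insert(1, "pool_id", a.pool_id)
        f.insert(2, "group", a.group)
        f.insert(3, "strand", a.strand)
        frames.append(f)
    write_tsv(pd.concat(frames, ignore_index=True), path)


def read_beadscores(path: str | Path) -> list[BeadArrayMeasurement]:
    df = read_tsv(path)
    arrays = []
    for (array_id, pool_id, group, strand), sub in df.groupby(
        ["array_id", "pool_id", "group", "strand"], sort=False
    ):
        arrays.append(
            BeadArrayMeasurement(
                array_id=str(array_id),
                pool_id=str(pool_id),
                group=str(group),
                strand=str(strand),
                probes=sub[["snp_id", "probe_index", "red", "green"]].reset_index(drop=True),
            )
        )
    return arrays


def write_ped_map(
    dataset: GenotypeDataset, prefix: str | Path, panel: pd.DataFrame | None = None
) -> None:
    """Write genotypes as PED/MAP plus a covariate TSV at ``prefix``.{ped,map,covar.tsv}."""
    prefix = Path(prefix)
    snps = dataset.dosages.columns
    if panel is not None:
        pan = panel.set_index("snp_id").reindex(snps)
        chrom, pos = pan["chrom"].fillna("0"), pan["pos"].fillna(0).astype(int)
    else:
        chrom, pos = pd.Series("0", index=snps), pd.Series(0, index=snps)
    pd.DataFrame(
        {"chrom": chrom.values, "snp_id": snps, "cm": 0, "pos": pos.values}
    ).to_csv(prefix.with_suffix(".map"), sep="\t", index=False, header=False)

    allele_strings = {0: "2 2", 1: "1 2", 2: "1 1"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for _, row in dataset.samples.iterrows():
            dose = dataset.dosages.loc[row.sample_id]
            geno = " ".join(
                allele_strings.get(int(d), "0 0") if not pd.isna(d) else "0 0" for d in dose
            )
            sex = "1" if row.sex == "M" else "2"
            pheno = "2" if row.phenotype == "case" else "1"
            fh.write(f"{row.sample_id} {row.sample_id} 0 0 {sex} {pheno} {geno}\n")
    dataset.samples[["sample_id", "sex", "age"]].to_csv(
        str(prefix) + ".covar.tsv", sep="\t", index=False
    )


def read_ped_map(prefix: str | Path) -> GenotypeDataset:
    """Read PED/MAP (+ covariate TSV if present) back into a GenotypeDataset."""
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"), sep="\t", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str},
    )
    snps = mp["snp_id"].tolist()
    ids, phenos, sexes, doses = [], [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            sexes.append("M" if parts[4] == "1" else "F")
            phenos.append("case" if parts[5] == "2" else "control")
            alleles = parts[6:]
            row = []
            for i in range(len(snps)):
                a1, a2 = alleles[2 * i], alleles[2 * i + 1]
                if a1 == "0" or a2 == "0":
                    row.append(np.nan)
                else:
                    row.append((a1 == "1") + (a2 == "1"))
            doses.append(row)
    samples = pd.DataFrame(
        {"sample_id": ids, "phenotype": phenos, "sex": sexes, "age": np.nan}
    )
    covar_path = Path(str(prefix) + ".covar.tsv")
    if covar_path.exists():
        covar = pd.read_csv(covar_path, sep="\t")
        samples = samples.drop(columns=["sex", "age"]).merge(covar, on="sample_id", how="left")
        samples = samples[["sample_id", "phenotype", "sex", "age"]]
    return GenotypeDataset(
        samples=samples,
        dosages=pd.DataFrame(doses, index=ids, columns=snps, dtype=float),
    )
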