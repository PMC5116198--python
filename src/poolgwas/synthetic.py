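"""Synthetic pooled-GWAS data with known ground truth.

Generates the three layers of a pooled case-control study: individual
genotypes under Hardy-Weinberg equilibrium with per-SNP allelic odds
ratios, DNA pools built from those individuals with optional per-sample
contribution error, and replicate two-channel bead-array measurements
of each pool with channel imbalance, multiplicative intensity noise,
failed (negative) probes and variable probe counts.

Every generator is deterministic given its seed, so downstream QC and
association stages can be tested against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))

#: column schema of a SNP panel frame
PANEL_COLUMNS = ("snp_id", "chrom", "pos", "ref_af", "expected_probes")


@dataclass(frozen=True)
class PoolSpec:
    """One case-control pool comparison: member ids and replicate-array counts."""

    pool_id: str
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    k_case_arrays: int = 2
    k_control_arrays: int = 2

    def __post_init__(self) -> None:
        if self.k_case_arrays < 1 or self.k_control_arrays < 1:
            raise ValueError("each group needs at least one replicate array")
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError("case and control id sets must be disjoint")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


# replicate-array variance of a single pooled allele-frequency measurement
# on a 1M-class Illumina bead array (frequency^2 units)
DEFAULT_SIGMA2_POOL = 6.8e-5

# default pool sizes of the discovery design: (cases, controls, k arrays)
DEFAULT_POOL_SIZES = ((154, 198, 4), (218, 213, 3), (40, 87, 2))


@dataclass
class PoolDesign:
    """Pool membership plus the per-array measurement variance sigma2_pool."""

    pools: list[PoolSpec]
    sigma2_pool: float = DEFAULT_SIGMA2_POOL

    def __post_init__(self) -> None:
        if self.sigma2_pool < 0:
            raise ValueError("sigma2_pool must be >= 0")

    @property
    def total_cases(self) -> int:
        return sum(p.n_cases for p in self.pools)

    @property
    def total_controls(self) -> int:
        return sum(p.n_controls for p in self.pools)


def default_pool_design(
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    sigma2_pool: float = DEFAULT_SIGMA2_POOL,
) -> PoolDesign:
    """Partition a discovery cohort into the default three-pool design.

    Pools take 154/198, 218/213 and 40/87 cases/controls in id order,
    measured on 4, 3 and 2 replicate arrays per group respectively.
    """
    need_cases = sum(s[0] for s in DEFAULT_POOL_SIZES)
    need_controls = sum(s[1] for s in DEFAULT_POOL_SIZES)
    if len(case_ids) < need_cases or len(control_ids) < need_controls:
        raise ValueError(
            f"default design needs >= {need_cases} cases and {need_controls} controls"
        )
    pools = []
    ci = 0
    ui = 0
    for i, (nc, nu, k) in enumerate(DEFAULT_POOL_SIZES, start=1):
        pools.append(
            PoolSpec(
                pool_id=f"pool{i}",
                case_ids=tuple(case_ids[ci : ci + nc]),
                control_ids=tuple(control_ids[ui : ui + nu]),
                k_case_arrays=k,
                k_control_arrays=k,
            )
        )
        ci += nc
        ui += nu
    return PoolDesign(pools=pools, sigma2_pool=sigma2_pool)


@dataclass
class GenotypeDataset:
    """Individual-level genotypes with phenotype and covariates.

    ``samples`` has columns sample_id, phenotype ("case"/"control"),
    sex ("M"/"F"), age; ``dosages`` is a samples x SNPs frame of
    minor-allele dosages in {0, 1, 2} (NaN = missing).
    """

    samples: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples["phenotype"].isin(["case", "control"]).all():
            raise ValueError("phenotype must be 'case' or 'control' for every sample")
        if not self.samples["sample_id"].is_unique:
            raise ValueError("sample ids must be unique")

    @property
    def case_ids(self) -> list[str]:
        s = self.samples
        return s.loc[s.phenotype == "case", "sample_id"].tolist()

    @property
    def control_ids(self) -> list[str]:
        s = self.samples
        return s.loc[s.phenotype == "control", "sample_id"].tolist()

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeDataset":
        ids = list(sample_ids)
        samples = self.samples.set_index("sample_id").loc[ids].reset_index()
        return GenotypeDataset(samples=samples, dosages=self.dosages.loc[ids])


@dataclass
class BeadArrayMeasurement:
    """One bead array of one pool: probe-level red/green intensities.

    ``probes`` has columns snp_id, probe_index, red, green; negative
    intensities mark failed probes.
    """

    array_id: str
    pool_id: str
    group: str  # "case" | "control"
    strand: str = "top"
    probes: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_panel(
    n_snps: int,
    maf_low: float = 0.01,
    maf_high: float = 0.5,
    seed: int | None = 0,
    chromosomes: Sequence[str] = AUTOSOMES,
    expected_probes_range: tuple[int, int] = (10, 25),
) -> pd.DataFrame:
    """Simulate a reference SNP panel.

    Reference-population allele frequencies are drawn with minor-allele
    frequency uniform in [maf_low, maf_high] and randomly assigned to
    either allele, emulating a European reference frequency panel.
    Positions are strictly increasing within each chromosome.
    """
    if not (0 <= maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, n_snps)
    flip = rng.random(n_snps) < 0.5
    ref_af = np.where(flip, 1.0 - maf, maf)
    chrom = rng.choice(np.asarray(chromosomes, dtype=object), n_snps)
    expected = rng.integers(expected_probes_range[0], expected_probes_range[1] + 1, n_snps)
    panel = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": 0,
            "ref_af": ref_af,
            "expected_probes": expected,
        }
    )
    # strictly increasing positions within chromosome
    steps = rng.integers(500, 50_000, n_snps)
    panel["pos"] = panel.groupby("chrom", sort=False)["pos"].transform(
        lambda s: np.cumsum(steps[s.index])
    )
    return panel


def case_frequency(p_control: np.ndarray, odds_ratio: np.ndarray) -> np.ndarray:
    """Case allele frequency implied by a control frequency and allelic OR.

    Solves p_a/(1-p_a) = OR * p_u/(1-p_u); the monomorphic endpoints 0
    and 1 are fixed points for every OR.
    """
    p = np.asarray(p_control, dtype=float)
    orr = np.asarray(odds_ratio, dtype=float)
    if np.any(orr <= 0):
        raise ValueError("odds ratios must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = orr * p / (1.0 - p)
        out = np.where(p >= 1.0, 1.0, odds / (1.0 + odds))
    return out


def simulate_genotypes(
    panel: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    or_map: Mapping[str, float] | None = None,
    seed: int | None = 0,
    female_frac_case: float = 0.8,
    female_frac_control: float = 0.5,
    age_case: tuple[float, float] = (45.3, 14.5),
    age_control: tuple[float, float] = (56.3, 24.4),
    id_prefix: str = "S",
) -> GenotypeDataset:
    """Simulate case/control genotypes under HWE with per-SNP allelic ORs.

    Dosages count the panel's reference (red-channel) allele, so pool
    fractions line up with the bead-array intensity model and the
    PAF-vs-reference concordance filter.  Controls are drawn at the
    panel's reference allele frequency; cases at the frequency implied
    by the allelic odds ratio (default 1 for every SNP).  The OR in
    ``or_map`` is for carrying the *minor* allele, so it is inverted on
    SNPs where the reference allele is the major one.  Sex and age
    defaults approximate a thyroid-autoimmunity cohort (~80% female
    cases, ~50% female controls).
    """
    rng = np.random.default_rng(seed)
    snp_ids = panel["snp_id"].to_numpy()
    ref_af = panel["ref_af"].to_numpy(dtype=float)
    p_u = ref_af
    orr = np.ones(len(snp_ids))
    if or_map:
        idx = {s: i for i, s in enumerate(snp_ids)}
        for snp, v in or_map.items():
            if v <= 0:
                raise ValueError(f"odds ratio for {snp} must be > 0")
            if snp not in idx:
                raise ValueError(f"unknown SNP in or_map: {snp}")
            orr[idx[snp]] = v
    # minor-allele OR -> reference-allele OR
    orr = np.where(ref_af <= 0.5, orr, 1.0 / orr)
    p_a = case_frequency(p_u, orr)

    n = n_cases + n_controls
    dos_case = rng.binomial(2, p_a, size=(n_cases, len(snp_ids)))
    dos_ctrl = rng.binomial(2, p_u, size=(n_controls, len(snp_ids)))
    dosages = np.vstack([dos_case, dos_ctrl]).astype(np.int8)

    ids = [f"{id_prefix}{i:05d}" for i in range(n)]
    phenotype = ["case"] * n_cases + ["control"] * n_controls
    female = np.concatenate(
        [
            rng.random(n_cases) < female_frac_case,
            rng.random(n_controls) < female_frac_control,
        ]
    )
    age = np.concatenate(
        [
            rng.normal(age_case[0], age_case[1], n_cases),
            rng.normal(age_control[0], age_control[1], n_controls),
        ]
    ).clip(9, 95)
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "phenotype": phenotype,
            "sex": np.where(female, "F", "M"),
            "age": np.round(age, 1),
        }
    )
    return GenotypeDataset(
        samples=samples,
        dosages=pd.DataFrame(dosages, index=ids, columns=snp_ids),
    )


def construct_pool(
    dataset: GenotypeDataset,
    member_ids: Sequence[str],
    contribution_cv: float = 0.0,
    seed: int | None = 0,
) -> pd.Series:
    """True per-SNP allele fraction of a DNA pool built from given samples.

    Each sample contributes weight w_i = max(0, 1 + cv * z_i) with z_i
    standard normal, modelling unequal DNA amounts at pool construction;
    the pool fraction is sum(w_i * dosage_i) / (2 * sum(w_i)).  With
    contribution_cv = 0 this is the exact equimolar mean.
    """
    ids = list(member_ids)
    if not ids:
        raise ValueError("member set must be non-empty")
    if contribution_cv < 0:
        raise ValueError("contribution_cv must be >= 0")
    missing = set(ids) - set(dataset.dosages.index)
    if missing:
        raise ValueError(f"ids not in dataset: {sorted(missing)[:5]}")
    dose = dataset.dosages.loc[ids].to_numpy(dtype=float)
    if contribution_cv == 0:
        w = np.ones(len(ids))
    else:
        rng = np.random.default_rng(seed)
        w = np.maximum(0.0, 1.0 + contribution_cv * rng.standard_normal(len(ids)))
        if w.sum() == 0:
            raise ValueError("all contribution weights truncated to zero")
    frac = (w @ dose) / (2.0 * w.sum())
    return pd.Series(frac, index=dataset.dosages.columns, name="true_af")


def simulate_arrays(
    true_af: pd.Series,
    expected_probes: pd.Series,
    k_arrays: int,
    pool_id: str,
    group: str,
    channel_imbalance: float = 1.0,
    intensity_scale: float = 2000.0,
    noise_cv: float = 0.05,
    negative_rate: float = 0.01,
    probe_count_jitter: float = 0.1,
    strand: str = "top",
    seed: int | None = 0,
) -> list[BeadArrayMeasurement]:
    """Simulate replicate bead arrays measuring one pool.

    Probe intensity model (linear in allele fraction p, multiplicative
    Gaussian channel noise):

        red   = intensity_scale * p * (1 + noise_cv * z_r)
        green = intensity_scale * channel_imbalance * (1 - p) * (1 + noise_cv * z_g)

    so with no noise and balanced channels red/(red+green) = p exactly,
    and an imbalance factor c is undone by green/corr with corr = c.
    A fraction ``negative_rate`` of probes fails and is recorded with
    sign-flipped (negative) intensities; per-SNP probe counts are the
    panel's expected counts perturbed multiplicatively by
    ``probe_count_jitter``.
    """
    if k_arrays < 1:
        raise ValueError("k_arrays must be >= 1")
    if not (0 <= negative_rate <= 1):
        raise ValueError("negative_rate must be in [0, 1]")
    if channel_imbalance <= 0:
        raise ValueError("channel_imbalance must be > 0")
    rng = np.random.default_rng(seed)
    snp_ids = true_af.index.to_numpy()
    p = true_af.to_numpy(dtype=float)
    expected = expected_probes.reindex(true_af.index).to_numpy(dtype=float)

    arrays = []
    for k in range(k_arrays):
        if probe_count_jitter > 0:
            counts = np.rint(
                expected * (1.0 + probe_count_jitter * rng.standard_normal(len(p)))
            ).astype(int)
            counts = np.clip(counts, 0, None)
        else:
            counts = expected.astype(int)
        total = int(counts.sum())
        snp_col = np.repeat(snp_ids, counts)
        p_col = np.repeat(p, counts)
        probe_index = np.concatenate([np.arange(c) for c in counts]) if total else np.array([], int)
        red = intensity_scale * p_col
        green = intensity_scale * channel_imbalance * (1.0 - p_col)
        if noise_cv > 0:
            red = red * (1.0 + noise_cv * rng.standard_normal(total))
            green = green * (1.0 + noise_cv * rng.standard_normal(total))
        if negative_rate > 0:
            bad = rng.random(total) < negative_rate
            red = np.where(bad, -np.abs(red) - 1.0, red)
            green = np.where(bad, -np.abs(green) - 1.0, green)
        probes = pd.DataFrame(
            {
                "snp_id": snp_col,
                "probe_index": probe_index,
                "red": red,
                "green": green,
            }
        )
        arrays.append(
            BeadArrayMeasurement(
                array_id=f"{pool_id}_{group}_a{k}",
                pool_id=pool_id,
                group=group,
                strand=strand,
                probes=probes,
            )
        )
    return arrays


def simulate_paf_measurements(
    true_af: pd.Series | np.ndarray,
    k_arrays: int,
    sigma_pool: float,
    seed: int | None = 0,
) -> np.ndarray:
    """Per-array pooled-allele-frequency measurements with Gaussian array error.

    Direct frequency-scale counterpart of :func:`simulate_arrays`: each of
    ``k_arrays`` replicate arrays observes the true pool fraction plus
    N(0, sigma_pool^2) noise, clipped to [0, 1].  Returns an array of
    shape (n_snps, k_arrays).  ``sigma_pool`` is the pooling standard
    deviation (sigma2_pool = sigma_pool**2).
    """
    if k_arrays < 1:
        raise ValueError("k_arrays must be >= 1")
    if sigma_pool < 0:
        raise ValueError("sigma_pool must be >= 0")
    rng = np.random.default_rng(seed)
    p = np.asarray(true_af, dtype=float)[:, None]
    noise = rng.normal(0.0, sigma_pool, size=(p.shape[0], k_arrays)) if sigma_pool else 0.0
    return np.clip(p + noise, 0.0, 1.0)
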