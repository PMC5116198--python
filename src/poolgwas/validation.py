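"""Individual-genotyping association: allelic chi-square, Woolf CI,
covariate-adjusted logistic regression and the two-stage gates.

The crude analysis treats each chromosome as an observation (2 per
genotyped individual): Pearson chi-square on the 2x2 allele-count table,
cross-product odds ratio, and the Woolf confidence interval
exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  The adjusted analysis
is a per-individual logistic regression of phenotype on minor-allele
dosage with sex and age as covariates, giving a Wald p-value and
exp(beta) odds ratio.  A SNP is "validated" when the discovery-cohort
p-value is <= 1e-4 and "replicated" when the replication cohort adds
p < 0.05 with the same effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table; ``a`` is the minor/effect allele."""

    a_case: int
    b_case: int
    a_control: int
    b_control: int

    def __post_init__(self) -> None:
        if min(self.a_case, self.b_case, self.a_control, self.b_control) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a_case + self.b_case + self.a_control + self.b_control


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


def allele_table_from(
    f_case: float, f_control: float, n_case: int, n_control: int
) -> AlleleTable:
    """Reconstruct a 2x2 allele table from published frequencies and sample sizes.

    Counts are rounded to the nearest whole allele out of 2n chromosomes
    per group, the way printed frequency columns are back-converted.
    """
    for f in (f_case, f_control):
        if not 0 <= f <= 1:
            raise ValueError("frequencies must be in [0, 1]")
    if n_case < 1 or n_control < 1:
        raise ValueError("sample sizes must be >= 1")
    a_case = round(2 * n_case * f_case)
    a_control = round(2 * n_control * f_control)
    return AlleleTable(a_case, 2 * n_case - a_case, a_control, 2 * n_control - a_control)


def allele_table_from_dosages(
    dosage: np.ndarray, is_case: np.ndarray
) -> AlleleTable:
    """Tabulate minor-allele counts from per-individual dosages (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    ok = ~np.isnan(dosage)
    a_case = int(dosage[ok & is_case].sum())
    a_control = int(dosage[ok & ~is_case].sum())
    n_case = int((ok & is_case).sum())
    n_control = int((ok & ~is_case).sum())
    return AlleleTable(a_case, 2 * n_case - a_case, a_control, 2 * n_control - a_control)


def _or_cells(t: AlleleTable) -> tuple[float, float, float, float]:
    """Cells for OR/CI with Haldane-Anscombe +0.5 when any cell is zero."""
    cells = (t.a_case, t.b_case, t.a_control, t.b_control)
    if min(cells) == 0:
        return tuple(c + 0.5 for c in cells)  # type: ignore[return-value]
    return tuple(float(c) for c in cells)  # type: ignore[return-value]


def allelic_test(table: AlleleTable) -> tuple[float, float, float]:
    """Pearson chi-square (df=1, no continuity correction) and crude OR.

    Returns (chi2, p, or_crude).  The odds ratio uses the cross-product
    with the +0.5 zero-cell correction; the chi-square does not.  A table
    with an empty margin is untestable.
    """
    a, b, c, d = table.a_case, table.b_case, table.a_control, table.b_control
    n = table.total
    if n == 0 or (a + b) == 0 or (c + d) == 0:
        raise ValueError("untestable table: empty row")
    if (a + c) == 0 or (b + d) == 0:
        # monomorphic: no association information
        chi2, p = 0.0, 1.0
    else:
        num = n * (a * d - b * c) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = num / den
        p = float(stats.chi2.sf(chi2, df=1))
    ca, cb, cc, cd = _or_cells(table)
    or_crude = (ca * cd) / (cb * cc)
    return float(chi2), p, float(or_crude)


def woolf_ci(table: AlleleTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf confidence interval for the allelic odds ratio.

    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); zero cells get the
    +0.5 correction.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a, b, c, d = _or_cells(table)
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def logistic_fit(
    genotype: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    tol: float = 1e-10,
    maxiter: int = 50,
) -> tuple[float, float]:
    """Covariate-adjusted odds ratio by maximum-likelihood logistic regression.

    ``genotype`` is the per-observation allele indicator or dosage,
    ``phenotype`` a 0/1 (or case/control boolean) outcome, ``covariates``
    an optional matrix (e.g. sex indicator and age) entered untransformed.
    The fit is Newton-Raphson (IRLS); returns (or_adjusted, p_wald) for
    the genotype coefficient.

    Raises :class:`SeparationError` when the data are perfectly separated
    and ValueError on a rank-deficient design.
    """
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(genotype, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # constant covariates are absorbed by the intercept
        for j in range(cov.shape[1]):
            if np.nanstd(cov[:, j]) > 0:
                cols.append(cov[:, j])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    mask = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    X, y = X[mask], y[mask]
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation surfaces as SeparationError
            fit = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
    except (np.linalg.LinAlgError, PerfectSeparationError) as e:
        raise SeparationError(
            "perfect separation: logistic maximum-likelihood estimate does not exist"
        ) from e
    eta = X @ fit.params
    if not np.all(np.isfinite(fit.bse)) or np.abs(eta).max() > 30:
        raise SeparationError(
            "perfect separation: logistic maximum-likelihood estimate does not exist"
        )
    beta = fit.params[1]
    p_wald = float(fit.pvalues[1])
    return float(np.exp(beta)), p_wald


def two_stage_filter(
    results: pd.DataFrame,
    validation_alpha: float = 1e-4,
    replication_alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign validation/replication stages to per-SNP two-cohort results.

    ``results`` needs columns snp_id, p_discovery, or_discovery and
    (optionally NaN) p_replication, or_replication.  Stage is
    "validated" when p_discovery <= validation_alpha, upgraded to
    "replicated" when additionally p_replication < replication_alpha and
    both odds ratios are on the same side of 1; otherwise "failed".
    """
    out = results.copy()
    validated = out["p_discovery"] <= validation_alpha
    same_dir = (
        np.sign(np.log(out["or_discovery"].astype(float)))
        == np.sign(np.log(out["or_replication"].astype(float)))
    )
    replicated = (
        validated
        & (out["p_replication"] < replication_alpha)
        & same_dir.fillna(False)
    )
    out["stage"] = np.select([replicated, validated], ["replicated", "validated"], "failed")
    return out


def or_concordance(pooled_or, individual_or) -> tuple[float, float]:
    """Pearson correlation between pooled and individual log odds ratios.

    Returns (r, p).  Requires equal-length vectors of at least 3 positive
    odds ratios with non-zero variance on the log scale.
    """
    x = np.log(np.asarray(pooled_or, dtype=float))
    y = np.log(np.asarray(individual_or, dtype=float))
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length OR vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("odds ratios must be positive and finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def validate_snps(
    dataset,
    snp_ids,
    adjust: bool = True,
) -> pd.DataFrame:
    """Crude + adjusted association for a list of SNPs in one cohort.

    ``dataset`` is a :class:`poolgwas.synthetic.GenotypeDataset`.  Returns
    one row per SNP: chi2, p_allelic, or_crude, ci_low, ci_high and —
    when ``adjust`` — or_adjusted, p_adjusted from a dosage logistic
    model with sex and age covariates.
    """
    is_case = (dataset.samples["phenotype"] == "case").to_numpy()
    sex = (dataset.samples["sex"] == "F").to_numpy(dtype=float)
    age = dataset.samples["age"].to_numpy(dtype=float)
    rows = []
    for snp in snp_ids:
        dose = dataset.dosages[snp].to_numpy(dtype=float)
        t = allele_table_from_dosages(dose, is_case)
        chi2, p, orc = allelic_test(t)
        lo, hi = woolf_ci(t)
        row = {
            "snp_id": snp, "chi2": chi2, "p_allelic": p,
            "or_crude": orc, "ci_low": lo, "ci_high": hi,
        }
        if adjust:
            try:
                ora, pa = logistic_fit(dose, is_case.astype(float),
                                       np.column_stack([sex, age]))
            except (SeparationError, ValueError):
                ora, pa = np.nan, np.nan
            row["or_adjusted"] = ora
            row["p_adjusted"] = pa
        rows.append(row)
    return pd.DataFrame(rows)
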