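"""Two-locus haplotype frequencies by EM and linkage-disequilibrium summaries.

From unphased genotypes at two biallelic loci only the double
heterozygote is phase-ambiguous; the EM algorithm splits it between the
coupling (AB/ab) and repulsion (Ab/aB) phases in proportion to the
current haplotype-frequency products, which monotonically increases the
observed-data likelihood.  From the fitted haplotype frequencies the
usual summaries follow: D = p_AB - p_A p_B, D' = |D|/D_max, r^2 =
D^2/(p_A p_a p_B p_b), a base-10 LOD comparing the fit to linkage
equilibrium, and likelihood-based confidence bounds on |D'|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# haplotype order used throughout: AB, Ab, aB, ab
# (A, B are the dosage-counted alleles at locus 1 and 2)


@dataclass
class LDResult:
    """Haplotype frequencies and LD summaries for one locus pair."""

    hap_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    d_prime: float
    r2: float
    lod: float
    ci_low: float
    ci_high: float
    defined: bool = True  # False when either locus is monomorphic


def genotype_class_probs(h: np.ndarray) -> np.ndarray:
    """3x3 joint genotype probabilities implied by haplotype frequencies.

    Index [i, j] is the probability of dosage i at locus 1 and j at
    locus 2 under random union of gametes.
    """
    pAB, pAb, paB, pab = h
    return np.array(
        [
            [pab**2, 2 * paB * pab, paB**2],
            [2 * pAb * pab, 2 * pAB * pab + 2 * pAb * paB, 2 * pAB * paB],
            [pAb**2, 2 * pAB * pAb, pAB**2],
        ]
    )


def loglik(counts: np.ndarray, h: np.ndarray) -> float:
    """Observed-data log-likelihood of a 3x3 genotype table under ``h``."""
    probs = genotype_class_probs(h)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(probs), 0.0)
    if np.any(counts[probs == 0] > 0):
        return -np.inf
    return float(terms.sum())


def _margins(counts: np.ndarray) -> tuple[float, float]:
    """Allele frequencies (p_A, p_B) of the dosage-counted alleles."""
    n = counts.sum()
    dos = np.arange(3, dtype=float)
    p_a = (counts.sum(axis=1) @ dos) / (2 * n)
    p_b = (counts.sum(axis=0) @ dos) / (2 * n)
    return float(p_a), float(p_b)


def em_haplotypes(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """EM estimate of (p_AB, p_Ab, p_aB, p_ab) from a 3x3 genotype table.

    ``counts[i, j]`` is the number of individuals with dosage i at locus 1
    and j at locus 2.  Starts from linkage equilibrium; converges when the
    largest frequency change is below ``tol``.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3, 3) or np.any(c < 0):
        raise ValueError("counts must be a non-negative 3x3 table")
    n = c.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    # unambiguous haplotype contributions
    base = np.array(
        [
            2 * c[2, 2] + c[2, 1] + c[1, 2],  # AB
            2 * c[2, 0] + c[2, 1] + c[1, 0],  # Ab
            2 * c[0, 2] + c[0, 1] + c[1, 2],  # aB
            2 * c[0, 0] + c[0, 1] + c[1, 0],  # ab
        ]
    )
    n_dh = c[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    p_a, p_b = _margins(c)
    h = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    for _ in range(max_iter):
        coupling = h[0] * h[3]
        repulsion = h[1] * h[2]
        tot = coupling + repulsion
        q = 0.5 if tot == 0 else coupling / tot
        new = base + n_dh * np.array([q, 1 - q, 1 - q, q])
        new /= 2 * n
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    return h


def ld_measures(
    hap_freqs: np.ndarray,
    n: int,
    genotype_counts: np.ndarray | None = None,
    ci_level: float = 0.95,
    ci_grid: int = 101,
) -> LDResult:
    """LD summaries from haplotype frequencies.

    D' normalizes D by its maximum attainable magnitude given the allele
    frequencies; the LOD is the base-10 likelihood ratio of the fitted
    haplotype frequencies against linkage equilibrium; the |D'| confidence
    bounds come from the likelihood normalized over a uniform D' grid with
    the allele frequencies held at their estimates.

    The likelihood uses the unphased ``genotype_counts`` when provided;
    otherwise the expected haplotype counts 2n * hap_freqs stand in (exact
    when phase is unambiguous).
    """
    h = np.asarray(hap_freqs, dtype=float)
    if h.shape != (4,) or np.any(h < 0) or abs(h.sum() - 1) > 1e-6:
        raise ValueError("hap_freqs must be 4 non-negative frequencies summing to 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    p_a = h[0] + h[1]
    p_b = h[0] + h[2]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDResult(h, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, defined=False)

    D = h[0] - p_a * p_b
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))

    if genotype_counts is not None:
        counts = np.asarray(genotype_counts, dtype=float)
        ll = lambda hh: loglik(counts, hh)  # noqa: E731
    else:
        hap_counts = 2 * n * h

        def ll(hh: np.ndarray) -> float:
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(hap_counts > 0, hap_counts * np.log(hh), 0.0)
            if np.any(hap_counts[hh == 0] > 0):
                return -np.inf
            return float(terms.sum())

    h0 = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    lod = (ll(h) - ll(h0)) / np.log(10)
    lod = max(lod, 0.0)

    # likelihood-based CI on |D'|: margins fixed, D' scanned on a grid
    sign = 1.0 if D >= 0 else -1.0
    grid = np.linspace(0.0, 1.0, ci_grid)
    lls = np.array([ll(_freqs_at(p_a, p_b, sign * dp * d_max)) for dp in grid])
    lls -= lls.max()
    lik = np.exp(lls)
    lik /= lik.sum()
    cum = np.cumsum(lik)
    alpha = 1 - ci_level
    ci_low = float(grid[np.searchsorted(cum, alpha / 2)])
    ci_high = float(grid[np.searchsorted(cum, 1 - alpha / 2)])
    return LDResult(h, float(D), float(d_prime), float(r2), float(lod), ci_low, ci_high)


def _freqs_at(p_a: float, p_b: float, D: float) -> np.ndarray:
    h = np.array(
        [
            p_a * p_b + D,
            p_a * (1 - p_b) - D,
            (1 - p_a) * p_b - D,
            (1 - p_a) * (1 - p_b) + D,
        ]
    )
    return np.clip(h, 0.0, 1.0)


def ld_from_genotypes(counts: np.ndarray, ci_level: float = 0.95) -> LDResult:
    """EM haplotype estimation + LD summaries straight from a 3x3 table."""
    c = np.asarray(counts, dtype=float)
    h = em_haplotypes(c)
    return ld_measures(h, int(c.sum()), genotype_counts=c, ci_level=ci_level)


def r2_between(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """r^2 between two SNPs from per-individual dosages via the EM fit."""
    counts = np.zeros((3, 3))
    ok = ~(np.isnan(dosages_a) | np.isnan(dosages_b))
    for i, j in zip(np.asarray(dosages_a)[ok].astype(int), np.asarray(dosages_b)[ok].astype(int)):
        counts[i, j] += 1
    res = ld_from_genotypes(counts)
    return res.r2 if res.defined else np.nan
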