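"""Per-site inbreeding coefficient (F_IS), clonality calibration, and
triallelic-site statistics.

F_IS is computed as 1 - Ho/He, where Ho is the observed heterozygote count
and He the Hardy-Weinberg expected heterozygote count 2*p*(1-p)*n rounded to
the nearest integer (round-half-to-even by default; half-up available).
F_IS is 0 at Hardy-Weinberg equilibrium, -1 when every individual is
heterozygous (the strict-clonality limit), and +1 when heterozygotes are
absent despite both alleles segregating.

Triallelic sites carry three of the four nucleotides and admit three
heterozygote classes (A/B, A/C, B/C).  Without genetic exchange, a
triallelic site showing all three heterozygote classes requires yet another
independent mutation, so the expected number of such sites is P3 * N3 with
P3 = N3 / (N2 + N3); an excess of observed three-heterozygote sites over
this expectation is evidence of genotype mixing between individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenotypeMatrix

__all__ = [
    "FisResult",
    "TriallelicSummary",
    "site_fis",
    "minor_allele_count",
    "filter_mac",
    "site_fis_matrix",
    "het_count_components",
    "aggregate_fis",
    "subsample_mean_fis",
    "clonality_pvalue",
    "classify_allelic_state",
    "triallelic_enrichment",
    "private_het_uniformity",
]


@dataclass(frozen=True)
class FisResult:
    fis: float  # 1 - Ho/He with rounded He; nan if undefined
    fis_unrounded: float  # same with fractional He
    ho: int
    he: int  # rounded expected heterozygote count
    he_raw: float
    p: float  # frequency of the first allele
    undefined: bool  # He rounded to zero


@dataclass(frozen=True)
class TriallelicSummary:
    n2: int  # biallelic site count
    n3: int  # triallelic site count
    p3: float  # N3 / (N2 + N3)
    expected_three_het: float  # P3 * N3
    observed_three_het: int
    fold_enrichment: float
    z: float
    pvalue: float
    undefined: bool = False


def _round_counts(x: float, mode: str) -> int:
    if mode == "half_even":
        return int(np.round(x))
    if mode == "half_up":
        return int(np.floor(x + 0.5))
    raise ValueError("rounding must be 'half_even' or 'half_up'")


def _rounded_he(c_a: int, c_b: int, n: int, mode: str) -> int:
    """He = round(2*p*(1-p)*n) = round(c_a*c_b/(2*n)) in exact integer
    arithmetic (c_a, c_b allele copy counts), so exact .5 ties obey the tie
    rule instead of float representation noise."""
    num = c_a * c_b
    den = 2 * n
    q, r = divmod(num, den)
    if 2 * r > den:
        return q + 1
    if 2 * r == den:
        if mode == "half_up":
            return q + 1
        if mode == "half_even":
            return q + (q & 1)
        raise ValueError("rounding must be 'half_even' or 'half_up'")
    return q


def site_fis(genotype_counts, rounding: str = "half_even") -> FisResult:
    """F_IS = 1 - Ho/He for one biallelic site.

    Parameters
    ----------
    genotype_counts : (n_AA, n_AB, n_BB) observed genotype counts.
    rounding : tie rule used when rounding the fractional expected
        heterozygote count to an integer.

    Raises
    ------
    ValueError for monomorphic input (no minor allele).
    """
    n_aa, n_ab, n_bb = (int(x) for x in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("empty site")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p == 0.0 or p == 1.0:
        raise ValueError("no minor allele: site is monomorphic")
    he_raw = 2.0 * p * (1.0 - p) * n
    he = _rounded_he(2 * n_aa + n_ab, 2 * n_bb + n_ab, n, rounding)
    ho = n_ab
    fis_unrounded = 1.0 - ho / he_raw
    if he == 0:
        return FisResult(float("nan"), fis_unrounded, ho, he, he_raw, p, True)
    return FisResult(1.0 - ho / he, fis_unrounded, ho, he, he_raw, p, False)


def _biallelic_counts(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mask of clean biallelic sites, Ho, minor-allele copy count)."""
    g = matrix.genotypes
    n_ind = matrix.n_individuals
    ok = ~matrix.has_missing() & matrix.is_biallelic()
    ho = (g[:, :, 0] != g[:, :, 1]).sum(axis=1)
    # per-site copy count of each observed allele
    mac = np.zeros(matrix.n_sites, dtype=np.int64)
    for i in np.nonzero(ok)[0]:
        alleles = matrix.site_alleles(i)
        c0 = int((g[i] == alleles[0]).sum())
        mac[i] = min(c0, 2 * n_ind - c0)
    return ok, ho, mac


def minor_allele_count(site_genotypes: np.ndarray) -> int:
    """Copy count of the rarer allele among the 2n chromosomes of one
    biallelic site (site_genotypes: (n_individuals, 2) allele codes)."""
    g = np.asarray(site_genotypes)
    if (g < 0).any():
        raise ValueError("missing genotypes not allowed")
    alleles = np.unique(g)
    if len(alleles) != 2:
        raise ValueError("site is not biallelic")
    c0 = int((g == alleles[0]).sum())
    return min(c0, g.size - c0)


def filter_mac(matrix: GenotypeMatrix, mac_min: int = 4) -> GenotypeMatrix:
    """Keep clean biallelic sites with minor allele count >= ``mac_min``."""
    ok, _ho, mac = _biallelic_counts(matrix)
    return matrix.take_sites(np.nonzero(ok & (mac >= mac_min))[0])


def site_fis_matrix(matrix: GenotypeMatrix, rounding: str = "half_even") -> np.ndarray:
    """Per-site F_IS over the clean biallelic sites of ``matrix``.

    Returns an array aligned with the matrix's sites; non-biallelic sites
    and sites with He rounding to zero carry nan.
    """
    g = matrix.genotypes
    n = matrix.n_individuals
    out = np.full(matrix.n_sites, np.nan)
    ok, ho, _ = _biallelic_counts(matrix)
    for i in np.nonzero(ok)[0]:
        alleles = matrix.site_alleles(i)
        c0 = int((g[i] == alleles[0]).sum())
        he = _rounded_he(c0, 2 * n - c0, n, rounding)
        if he > 0:
            out[i] = 1.0 - ho[i] / he
    return out


def het_count_components(matrix: GenotypeMatrix, mac_min: int = 4) -> tuple[float, float]:
    """(sum of observed het counts, sum of unrounded expected het counts)
    over the clean biallelic sites with MAC >= ``mac_min``.

    Summing components before taking the F_IS ratio (as multi-locus
    F-statistic estimators do) avoids the Jensen bias of averaging
    per-dataset ratios when the denominators fluctuate strongly."""
    kept = filter_mac(matrix, mac_min)
    if kept.n_sites == 0:
        raise ValueError("no qualifying sites")
    g = kept.genotypes
    n = kept.n_individuals
    ho = float((g[:, :, 0] != g[:, :, 1]).sum())
    he = 0.0
    for i in range(kept.n_sites):
        alleles = kept.site_alleles(i)
        c0 = int((g[i] == alleles[0]).sum())
        p = c0 / (2 * n)
        he += 2.0 * p * (1.0 - p) * n
    return ho, he


def aggregate_fis(matrix: GenotypeMatrix, mac_min: int = 4) -> float:
    """Aggregate inbreeding coefficient 1 - sum(Ho)/sum(He) over the clean
    biallelic sites with MAC >= ``mac_min`` (He unrounded).

    Unlike the per-site mean of 1 - Ho/He, this directly estimates the
    genome-wide departure of heterozygote counts from the Hardy-Weinberg
    expectation, so it is the natural readout for testing whether a
    population's genotype proportions sit at HWE."""
    ho, he = het_count_components(matrix, mac_min)
    return 1.0 - ho / he


def subsample_mean_fis(
    matrix: GenotypeMatrix,
    n_individuals: int = 8,
    mac_min: int = 4,
    n_snps: int = 200,
    n_sets: int = 100,
    rng: np.random.Generator | int | None = None,
    rounding: str = "half_even",
) -> np.ndarray:
    """Mean F_IS over random SNP sets, following the standard subsampling
    scheme: per set, draw ``n_individuals`` without replacement, keep
    biallelic SNPs with MAC >= ``mac_min`` within the subsample, draw
    ``n_snps`` SNPs without replacement (all qualifying SNPs if fewer),
    and average their F_IS values.
    """
    rng = np.random.default_rng(rng)
    if matrix.n_individuals < n_individuals:
        raise ValueError("matrix has fewer individuals than requested")
    means = np.empty(n_sets)
    for k in range(n_sets):
        inds = rng.choice(matrix.n_individuals, size=n_individuals, replace=False)
        sub = matrix.take_individuals(np.sort(inds))
        sub = filter_mac(sub, mac_min)
        fis = site_fis_matrix(sub, rounding=rounding)
        fis = fis[~np.isnan(fis)]
        if fis.size == 0:
            raise ValueError("no qualifying SNPs in subsample")
        if fis.size > n_snps:
            fis = rng.choice(fis, size=n_snps, replace=False)
        means[k] = fis.mean()
    return means


def clonality_pvalue(observed_set_means, simulated_set_means) -> float:
    """One-sided p: fraction of simulated set means >= the minimum observed
    set mean (no add-one correction, no
    multiple-comparison adjustment)."""
    obs = np.asarray(observed_set_means, dtype=float)
    sim = np.asarray(simulated_set_means, dtype=float)
    if obs.size == 0 or sim.size == 0:
        raise ValueError("both mean lists must be non-empty")
    return float((sim >= obs.min()).sum() / sim.size)


def classify_allelic_state(site_genotypes: np.ndarray):
    """Allelic state of one site: (n_alleles, het classes present,
    private-het carrier index or None).

    The carrier is reported when the least frequent heterozygote class is
    carried by exactly one individual (candidate cross-contamination
    signature if concentrated in few individuals).
    """
    g = np.asarray(site_genotypes)
    if (g < 0).any():
        raise ValueError("missing genotypes not allowed")
    alleles = np.unique(g)
    het_rows = np.nonzero(g[:, 0] != g[:, 1])[0]
    classes: dict[tuple[int, int], list[int]] = {}
    for i in het_rows:
        key = (int(min(g[i])), int(max(g[i])))
        classes.setdefault(key, []).append(int(i))
    private_carrier = None
    if classes:
        least = min(classes.values(), key=len)
        if len(least) == 1:
            private_carrier = least[0]
    return len(alleles), sorted(classes.keys()), private_carrier


def triallelic_enrichment(n2: int, n3: int, observed_threehet: int) -> TriallelicSummary:
    """Three-heterozygote enrichment at triallelic sites.

    Expected count is P3 * N3 with P3 = N3/(N2+N3); the departure of
    observed/N3 from P3 is tested with a two-sided one-sample Z-test for
    proportions without continuity correction.
    """
    if n2 + n3 <= 0:
        raise ValueError("N2 + N3 must be positive")
    if observed_threehet > n3:
        raise ValueError("observed three-het count cannot exceed N3")
    p3 = n3 / (n2 + n3)
    expected = p3 * n3
    if n3 == 0:
        return TriallelicSummary(n2, n3, p3, 0.0, observed_threehet, float("nan"),
                                 float("nan"), float("nan"), undefined=True)
    phat = observed_threehet / n3
    se = np.sqrt(p3 * (1.0 - p3) / n3)
    z = (phat - p3) / se if se > 0 else float("inf") * np.sign(phat - p3)
    pvalue = 2.0 * stats.norm.sf(abs(z))
    fold = observed_threehet / expected if expected > 0 else float("nan")
    return TriallelicSummary(n2, n3, p3, expected, observed_threehet, fold, float(z),
                             float(pvalue))


def private_het_uniformity(carriers, n_individuals: int):
    """Chi-square goodness of fit of private-heterozygote carriers against
    a uniform distribution over individuals.

    Parameters
    ----------
    carriers : iterable of carrier individual indices (one per site).

    Returns
    -------
    (counts per individual, chi-square statistic, p-value)
    """
    carriers = np.asarray(list(carriers), dtype=int)
    counts = np.bincount(carriers, minlength=n_individuals)
    if len(counts) > n_individuals:
        raise ValueError("carrier index out of range")
    chi2, p = stats.chisquare(counts)
    return counts, float(chi2), float(p)


def triallelic_summary_from_matrix(matrix: GenotypeMatrix) -> TriallelicSummary:
    """Convenience: N2/N3 classification and three-het test over a matrix."""
    n_all = matrix.n_alleles()
    clean = ~matrix.has_missing()
    n2 = int(((n_all == 2) & clean).sum())
    tri = np.nonzero((n_all == 3) & clean)[0]
    observed = 0
    for i in tri:
        _, het_classes, _ = classify_allelic_state(matrix.genotypes[i])
        if len(het_classes) == 3:
            observed += 1
    return triallelic_enrichment(n2, len(tri), observed)
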