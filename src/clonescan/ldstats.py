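"""Linkage disequilibrium statistics and per-segment recombination tests.

Implements r-squared between phased haplotypes, squared Pearson correlation
between unphased genotype dosages, pseudo-haplotypes from all-homozygous
sites, distance binning with percentile-bootstrap confidence intervals, and
three per-segment tests for recombination:

* correlation of r-squared with physical distance (recombination makes LD
  decay with distance, so the correlation is negative);
* sum of distances between site pairs displaying all four gametes
  (recombination concentrates four-gamete pairs at large distances);
* the pairwise homoplasy index (PHI): mean incompatibility over nearby
  informative-site pairs.

All three tests draw their null from permutations of SNP positions along the
segment (haplotype columns fixed), with add-one permutation p-values
(b + 1)/(m + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BinSummary",
    "haplotype_r2",
    "r2_matrix",
    "genotype_corr2",
    "homozygote_haplotypes",
    "pair_table",
    "bin_and_bootstrap",
    "segment_r2_distance_test",
    "sum_of_distances_test",
    "phi_test",
    "decay_curve",
    "loess2",
]


# ---------------------------------------------------------------------------
# pairwise statistics


def haplotype_r2(alleles_i: np.ndarray, alleles_j: np.ndarray) -> float:
    """r^2 = D^2 / (pA(1-pA) pB(1-pB)) between two biallelic sites observed
    on the same haplotypes.  Symmetric, in [0, 1], invariant to allele
    relabeling."""
    x = np.asarray(alleles_i)
    y = np.asarray(alleles_j)
    if x.shape != y.shape:
        raise ValueError("haplotype vectors must align")
    ax, ay = np.unique(x), np.unique(y)
    if len(ax) != 2 or len(ay) != 2:
        raise ValueError("both sites must be biallelic and polymorphic")
    xa = (x == ax[0]).astype(float)
    ya = (y == ay[0]).astype(float)
    pa, pb = xa.mean(), ya.mean()
    d = (xa * ya).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def r2_matrix(haplotypes: np.ndarray) -> np.ndarray:
    """All-pairs r^2 for a (n_haplotypes, n_sites) 0/1-codable matrix.

    Equals the squared Pearson correlation between allele-indicator columns.
    Columns must each carry exactly two alleles.
    """
    h = np.asarray(haplotypes)
    ind = np.empty(h.shape, dtype=float)
    for j in range(h.shape[1]):
        a = np.unique(h[:, j])
        if len(a) != 2:
            raise ValueError("all sites must be biallelic and polymorphic")
        ind[:, j] = h[:, j] == a[0]
    c = np.corrcoef(ind, rowvar=False)
    return c * c


def genotype_corr2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation between two genotype dosage vectors."""
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("dosage vectors must be non-constant")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def homozygote_haplotypes(matrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo-haplotypes from sites homozygous in every individual.

    Returns (pseudo_haplotypes (n_individuals, n_kept), contigs, positions).
    Each individual contributes its single allele per kept site, so LD can be
    assessed from unphased data without a heterozygote phase.
    """
    import warnings

    g = matrix.genotypes
    hom = (g[:, :, 0] == g[:, :, 1]).all(axis=1) & ~matrix.has_missing()
    keep = np.nonzero(hom)[0]
    if keep.size == 0:
        warnings.warn("no all-homozygous sites; returning empty pseudo-haplotypes")
    pseudo = g[keep, :, 0].T.astype(np.int8)
    return pseudo, matrix.contigs[keep], matrix.positions[keep]


# ---------------------------------------------------------------------------
# pair tables and binning


def pair_table(
    haplotypes: np.ndarray,
    contigs: np.ndarray,
    positions: np.ndarray,
    statistic: str = "r2",
    mac_min: int = 4,
) -> pd.DataFrame:
    """Two-locus records (contig pair, distance, statistic) over all site
    pairs.  ``statistic``: "r2" on haplotype rows, or "geno_corr2" where
    ``haplotypes`` is interpreted as a dosage matrix (individuals x sites).

    Distance is |pos_i - pos_j| within a contig and NaN across contigs;
    sites failing the MAC filter (counted on the rows given) are dropped.
    """
    h = np.asarray(haplotypes)
    contigs = np.asarray(contigs).astype(str)
    positions = np.asarray(positions)
    keep = []
    for j in range(h.shape[1]):
        vals, counts = np.unique(h[:, j], return_counts=True)
        if len(vals) != 2:
            continue
        if counts.min() >= mac_min:
            keep.append(j)
    keep = np.array(keep, dtype=int)
    h = h[:, keep]
    contigs, positions = contigs[keep], positions[keep]
    if statistic == "r2":
        stat = r2_matrix(h)
    elif statistic == "geno_corr2":
        c = np.corrcoef(h.astype(float), rowvar=False)
        stat = c * c
    else:
        raise ValueError("unknown statistic kind")
    i_idx, j_idx = np.triu_indices(len(keep), k=1)
    same = contigs[i_idx] == contigs[j_idx]
    dist = np.where(same, np.abs(positions[i_idx] - positions[j_idx]), np.nan)
    return pd.DataFrame(
        {
            "contig_i": contigs[i_idx],
            "pos_i": positions[i_idx],
            "contig_j": contigs[j_idx],
            "pos_j": positions[j_idx],
            "same_contig": same,
            "distance": dist,
            "value": stat[i_idx, j_idx],
            "kind": statistic,
        }
    )


@dataclass
class BinSummary:
    """Distance-binned means with bootstrap CIs and a cross-contig baseline."""

    edges: np.ndarray  # bin edges (left-closed)
    mean: np.ndarray
    n: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    baseline: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "mean": self.mean,
                "n": self.n,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _bootstrap_ci(
    values: np.ndarray, rng: np.random.Generator, n_boot: int, level: float = 0.95
) -> tuple[float, float]:
    if values.size == 0:
        return np.nan, np.nan
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    reps = values[idx].mean(axis=1)
    lo, hi = np.percentile(reps, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


def bin_and_bootstrap(
    pairs: pd.DataFrame,
    scheme: str = "fixed",
    bin_width: float = 200.0,
    max_distance: float = 4000.0,
    n_bins: int = 4,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> BinSummary:
    """Bin within-contig pairs by distance and summarise each bin.

    ``scheme`` "fixed": left-closed bins of ``bin_width`` bp up to
    ``max_distance``; "equal_count": ``n_bins`` quantile bins with
    approximately equal numbers of pairs (boundary ties go to the lower
    bin).  Cross-contig pairs feed the baseline summary.
    """
    rng = np.random.default_rng(rng)
    within = pairs[pairs["same_contig"]]
    cross = pairs[~pairs["same_contig"]]["value"].to_numpy()
    d = within["distance"].to_numpy(float)
    v = within["value"].to_numpy(float)
    if scheme == "fixed":
        edges = np.arange(0.0, max_distance + bin_width, bin_width)
        sel = d < edges[-1]
        d, v = d[sel], v[sel]
        which = np.digitize(d, edges) - 1
    elif scheme == "equal_count":
        if len(d) < n_bins:
            raise ValueError("fewer pairs than bins")
        qs = np.quantile(d, np.linspace(0, 1, n_bins + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        # ties at a boundary fall in the lower bin: right-closed intervals
        which = np.searchsorted(qs[1:-1], d, side="left")
        edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    else:
        raise ValueError("scheme must be 'fixed' or 'equal_count'")
    k = len(edges) - 1
    mean = np.full(k, np.nan)
    n = np.zeros(k, dtype=int)
    lo = np.full(k, np.nan)
    hi = np.full(k, np.nan)
    for b in range(k):
        vals = v[which == b]
        n[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            lo[b], hi[b] = _bootstrap_ci(vals, rng, n_boot)
    baseline = {}
    if cross.size:
        baseline = {
            "mean": float(cross.mean()),
            "median": float(np.median(cross)),
            "p10": float(np.percentile(cross, 10)),
            "p90": float(np.percentile(cross, 90)),
            "se": float(cross.std(ddof=1) / np.sqrt(cross.size)) if cross.size > 1 else np.nan,
            "n": int(cross.size),
        }
    return BinSummary(np.asarray(edges, float), mean, n, lo, hi, baseline)


# ---------------------------------------------------------------------------
# per-segment recombination tests


def _biallelic_site_mask(haplotypes: np.ndarray) -> np.ndarray:
    h = np.asarray(haplotypes)
    out = np.zeros(h.shape[1], dtype=bool)
    for j in range(h.shape[1]):
        out[j] = len(np.unique(h[:, j])) == 2
    return out


def _four_gamete_matrix(h01: np.ndarray) -> np.ndarray:
    """Boolean matrix: True where a site pair displays all four gametes
    among the rows of a 0/1 haplotype matrix."""
    a = h01.astype(bool)
    # presence of each of the four gametes for every pair via matrix products
    n11 = (a.T.astype(np.int32) @ a.astype(np.int32)) > 0
    n00 = ((~a).T.astype(np.int32) @ (~a).astype(np.int32)) > 0
    n10 = (a.T.astype(np.int32) @ (~a).astype(np.int32)) > 0
    n01 = ((~a).T.astype(np.int32) @ a.astype(np.int32)) > 0
    return n11 & n00 & n10 & n01


def _to_binary(haplotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(0/1 recode of the biallelic polymorphic columns, their indices)."""
    h = np.asarray(haplotypes)
    mask = _biallelic_site_mask(h)
    idx = np.nonzero(mask)[0]
    out = np.empty((h.shape[0], idx.size), dtype=np.int8)
    for k, j in enumerate(idx):
        out[:, k] = h[:, j] == np.unique(h[:, j])[1]
    return out, idx


def segment_r2_distance_test(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
):
    """Pearson correlation of pairwise r^2 with distance, with a one-sided
    permutation p (fraction of position permutations with correlation <=
    observed; recombination pushes the correlation negative).

    Returns (correlation, p, skipped_flag); segments with < 4 biallelic SNPs
    are skipped.
    """
    rng = np.random.default_rng(rng)
    h01, idx = _to_binary(haplotypes)
    pos = np.asarray(positions, dtype=float)[idx]
    if h01.shape[1] < 4:
        return np.nan, np.nan, True
    r2 = r2_matrix(h01)
    iu = np.triu_indices(h01.shape[1], k=1)
    vals = r2[iu]
    if np.std(vals) == 0:
        return np.nan, np.nan, True
    def corr_with(p_vec):
        d = np.abs(p_vec[iu[0]] - p_vec[iu[1]])
        dc = d - d.mean()
        vc = vals - vals.mean()
        return float((dc * vc).sum() / np.sqrt((dc * dc).sum() * (vc * vc).sum()))
    obs = corr_with(pos)
    b = 0
    for _ in range(n_perm):
        if corr_with(rng.permutation(pos)) <= obs:
            b += 1
    return obs, (b + 1) / (n_perm + 1), False


def sum_of_distances_test(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
):
    """Sum of distances between four-gamete site pairs (D4) with a one-sided
    permutation p (fraction of position permutations with D4 >= observed).

    Returns (D4, p, skipped_flag).  No four-gamete pair gives D4 = 0, p = 1.
    """
    rng = np.random.default_rng(rng)
    h01, idx = _to_binary(haplotypes)
    pos = np.asarray(positions, dtype=float)[idx]
    if h01.shape[1] < 4:
        return np.nan, np.nan, True
    fg = _four_gamete_matrix(h01)
    iu = np.triu_indices(h01.shape[1], k=1)
    viol = fg[iu]
    if not viol.any():
        return 0.0, 1.0, False
    def d4(p_vec):
        return float(np.abs(p_vec[iu[0]] - p_vec[iu[1]])[viol].sum())
    obs = d4(pos)
    b = 0
    for _ in range(n_perm):
        if d4(rng.permutation(pos)) >= obs:
            b += 1
    return obs, (b + 1) / (n_perm + 1), False


def _mantel_moments(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact mean and variance of Q = sum_{i!=j} a_ij b_{s(i)s(j)} over
    uniformly random permutations s (both matrices symmetric, zero diag)."""
    n = a.shape[0]
    def parts(m):
        s1 = m.sum()
        s2 = (m * m).sum()
        rows = m.sum(axis=1)
        s3 = (rows * rows).sum() - s2  # paths through a shared index
        return s1, s2, s3
    a1, a2, a3 = parts(a)
    b1, b2, b3 = parts(b)
    f2 = n * (n - 1)
    f3 = f2 * (n - 2)
    f4 = f3 * (n - 3)
    mean = a1 * b1 / f2
    e2 = (
        2.0 * a2 * b2 / f2
        + 4.0 * a3 * b3 / f3
        + (a1 * a1 - 2 * a2 - 4 * a3) * (b1 * b1 - 2 * b2 - 4 * b3) / f4
    )
    return mean, e2 - mean * mean


def phi_test(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    window: float = 100.0,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    method: str = "permutation",
):
    """Pairwise homoplasy index over informative-site pairs within
    ``window`` bp of each other.

    The incompatibility score of a pair of binary sites is 1 when all four
    gametes are present, else 0; PHI is the mean score over in-window pairs.
    Under recombination nearby sites are *more* compatible than distant
    ones, so the observed PHI falls in the lower tail of the site-order
    permutation distribution; without recombination incompatibility (from
    recurrent mutation) carries no distance signal and the site order is
    exchangeable.  ``method`` "permutation" permutes site order; "normal"
    uses the exact permutation moments of the statistic (lower tail).

    Returns (PHI, p, skipped_flag).
    """
    from scipy import stats

    rng = np.random.default_rng(rng)
    h01, idx = _to_binary(haplotypes)
    pos = np.asarray(positions, dtype=float)[idx]
    m = h01.shape[1]
    if m < 2:
        return np.nan, np.nan, True
    inc = _four_gamete_matrix(h01).astype(float)
    np.fill_diagonal(inc, 0.0)
    win = (np.abs(pos[:, None] - pos[None, :]) <= window).astype(float)
    np.fill_diagonal(win, 0.0)
    n_pairs = win.sum()
    if n_pairs == 0:
        return np.nan, np.nan, True
    obs = float((win * inc).sum() / n_pairs)
    if method == "normal":
        mean_q, var_q = _mantel_moments(win, inc)
        if var_q <= 0:
            return obs, 1.0, False
        z = (obs * n_pairs - mean_q) / np.sqrt(var_q)
        return obs, float(stats.norm.cdf(z)), False
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        q = float((win * inc[np.ix_(perm, perm)]).sum() / n_pairs)
        if q <= obs:
            b += 1
    return obs, (b + 1) / (n_perm + 1), False


# ---------------------------------------------------------------------------
# LOESS decay curve


def loess2(
    x: np.ndarray, y: np.ndarray, span: float = 0.4, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Second-degree LOESS with tricube weights.

    Local quadratic weighted least squares over the ``span`` fraction of
    nearest points, evaluated on ``grid`` (default: 100 points spanning x).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need >= 10 points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    k = max(int(np.ceil(span * x.size)), 5)
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sel = w > 0
        xs, ys, ws = x[sel] - g, y[sel], w[sel]
        basis = np.column_stack([np.ones_like(xs), xs, xs * xs])
        wb = basis * ws[:, None]
        coef, *_ = np.linalg.lstsq(wb.T @ basis, wb.T @ ys, rcond=None)
        out[i] = coef[0]
    return np.asarray(grid, float), out


def decay_curve(
    pairs: pd.DataFrame,
    span: float = 0.4,
    grid: np.ndarray | None = None,
):
    """Smoothed mean statistic versus distance plus the baseline-entry
    distance: the smallest grid distance at which the curve first enters the
    cross-contig baseline mean +/- 1 SE band (NaN if it never does).

    Returns (grid, smoothed values, baseline dict, entry distance).
    """
    within = pairs[pairs["same_contig"]]
    d = within["distance"].to_numpy(float)
    v = within["value"].to_numpy(float)
    gx, gy = loess2(d, v, span=span, grid=grid)
    cross = pairs[~pairs["same_contig"]]["value"].to_numpy(float)
    baseline = {}
    entry = np.nan
    if cross.size > 1:
        mean = cross.mean()
        se = cross.std(ddof=1) / np.sqrt(cross.size)
        baseline = {"mean": float(mean), "se": float(se), "n": int(cross.size)}
        inside = np.abs(gy - mean) <= se
        if inside.any():
            entry = float(gx[np.argmax(inside)])
    return gx, gy, baseline, entry
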