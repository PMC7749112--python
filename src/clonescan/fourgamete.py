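"""The modified four-gamete test for reciprocal recombination.

Within-locus gene conversion can turn a heterozygous genotype into a
homozygous one but never the reverse, so conversion alone cannot produce a
pair of individuals that are BOTH heterozygous at two sites while jointly
displaying all four two-locus gametes.  Scanning phased segments for such
"recombinant" SNP pairs therefore detects reciprocal recombination in a way
that is immune to gene conversion (recurrent mutation can create recombinant
pairs, but their frequency carries no increasing trend with physical
distance, unlike recombination).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .core import SegmentHaplotypes
from .ldstats import BinSummary, _bootstrap_ci

__all__ = [
    "gamete_set",
    "scan_recombinant_pairs",
    "recombinant_fraction_by_bin",
    "distance_shift_test",
]


def gamete_set(ind1_haplotypes, ind2_haplotypes) -> set[tuple]:
    """Distinct two-locus gametes among the 4 phased haplotypes of two
    individuals, each given as a (2, 2) array (haplotype x site).

    Both individuals must be heterozygous at both sites (the configuration
    the test conditions on; conversion destroys it rather than creating it).
    """
    g1 = np.asarray(ind1_haplotypes)
    g2 = np.asarray(ind2_haplotypes)
    if g1.shape != (2, 2) or g2.shape != (2, 2):
        raise ValueError("each individual contributes 2 haplotypes x 2 sites")
    for g in (g1, g2):
        if g[0, 0] == g[1, 0] or g[0, 1] == g[1, 1]:
            raise ValueError("both individuals must be heterozygous at both sites")
    return {tuple(g1[0]), tuple(g1[1]), tuple(g2[0]), tuple(g2[1])}


def scan_recombinant_pairs(
    segments: list[SegmentHaplotypes],
    individuals: list[str] | None = None,
    deduplicate_site_pairs: bool = False,
) -> pd.DataFrame:
    """Enumerate doubly-heterozygous SNP pairs for every unordered pair of
    individuals across phased segments and classify each by its gamete count.

    Returns a table with one row per (individual pair, site pair):
    contig, positions, distance, individuals, n_gametes, recombinant flag
    (n_gametes == 4).  With ``deduplicate_site_pairs`` a site pair is kept
    only once (its first individual-pair occurrence).
    """
    rows = []
    for seg in segments:
        inds = individuals or seg.individuals
        idx = [seg.individuals.index(i) for i in inds]
        h = seg.haplotypes
        pos = seg.positions
        m = len(pos)
        if m < 2:
            continue
        het = np.array([h[2 * i] != h[2 * i + 1] for i in idx])  # (k, m)
        seen_pairs = set()
        for a_k, b_k in itertools.combinations(range(len(idx)), 2):
            a, b = idx[a_k], idx[b_k]
            both = np.nonzero(het[a_k] & het[b_k])[0]
            if both.size < 2:
                continue
            ha = h[2 * a : 2 * a + 2][:, both]
            hb = h[2 * b : 2 * b + 2][:, both]
            # distinct gametes among the 4 haplotypes for every site pair
            stack = np.stack([ha[0], ha[1], hb[0], hb[1]])  # (4, mm)
            mm = both.size
            codes = stack.astype(np.int16)
            g = codes[:, :, None] * 8 + codes[:, None, :]  # (4, mm, mm)
            gs = np.sort(g, axis=0)
            n_gam = 1 + (np.diff(gs, axis=0) != 0).sum(axis=0)
            iu = np.triu_indices(mm, k=1)
            for x, y in zip(*iu):
                si, sj = int(both[x]), int(both[y])
                if deduplicate_site_pairs:
                    key = (seg.contig, si, sj)
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                ng = int(n_gam[x, y])
                rows.append(
                    {
                        "contig": seg.contig,
                        "pos_i": int(pos[si]),
                        "pos_j": int(pos[sj]),
                        "distance": int(abs(pos[sj] - pos[si])),
                        "ind_a": inds[a_k],
                        "ind_b": inds[b_k],
                        "n_gametes": ng,
                        "recombinant": ng == 4,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos_i", "pos_j", "distance",
            "ind_a", "ind_b", "n_gametes", "recombinant",
        ],
    )


def recombinant_fraction_by_bin(
    records: pd.DataFrame,
    n_bins: int = 4,
    n_boot: int = 1000,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
):
    """Equal-count distance bins with the recombinant fraction per bin,
    bootstrap CIs, and all pairwise bin comparisons by permutation.

    Bin comparisons shuffle records between the two compared bins; two-sided
    add-one p-values with Bonferroni correction over the bin pairs.

    Returns (BinSummary, DataFrame of pairwise comparisons).
    """
    rng = np.random.default_rng(rng)
    if len(records) < n_bins:
        raise ValueError("fewer records than bins")
    d = records["distance"].to_numpy(float)
    rec = records["recombinant"].to_numpy(bool).astype(float)
    qs = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    which = np.searchsorted(qs[1:-1], d, side="left")  # boundary ties -> lower bin
    mean = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    members = []
    for b in range(n_bins):
        vals = rec[which == b]
        members.append(vals)
        n[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
            lo[b], hi[b] = _bootstrap_ci(vals, rng, n_boot)
    summary = BinSummary(qs, mean, n, lo, hi, {})
    comps = []
    pairs = list(itertools.combinations(range(n_bins), 2))
    for a, b in pairs:
        va, vb = members[a], members[b]
        if va.size == 0 or vb.size == 0:
            comps.append({"bin_a": a, "bin_b": b, "diff": np.nan,
                          "p": np.nan, "p_bonferroni": np.nan})
            continue
        obs = abs(va.mean() - vb.mean())
        pooled = np.concatenate([va, vb])
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[: va.size].mean() - pooled[va.size :].mean()) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        comps.append(
            {"bin_a": a, "bin_b": b, "diff": obs, "p": p,
             "p_bonferroni": min(1.0, p * len(pairs))}
        )
    return summary, pd.DataFrame(comps)


def distance_shift_test(
    records: pd.DataFrame,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test for the difference in mean distance
    between recombinant and non-recombinant SNP pairs (random relabeling,
    add-one convention).

    Returns (observed |mean difference|, p).
    """
    rng = np.random.default_rng(rng)
    d = records["distance"].to_numpy(float)
    rec = records["recombinant"].to_numpy(bool)
    n_rec = int(rec.sum())
    if n_rec == 0 or n_rec == len(rec):
        raise ValueError("both classes must be non-empty")
    obs = abs(d[rec].mean() - d[~rec].mean())
    hits = 0
    lab = rec.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if abs(d[lab].mean() - d[~lab].mean()) >= obs - 1e-12:
            hits += 1
    return float(obs), (hits + 1) / (n_perm + 1)
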