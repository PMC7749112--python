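"""Simulation experiments that calibrate the statistics against known
reproductive regimes.

These drivers run the package's desk-scale calibration designs: the
cloning-rate sweep read out through subsampled mean F_IS, the clonal
Hardy-Weinberg equilibrium under gene conversion at alpha = 1/(2*Ne), the
conversion-proofness of the modified four-gamete test, the type-I/power
calibration of the per-segment recombination tests, and the hybrid-origin
recovery experiment.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import fourgamete, genostats, haplophylo, ldstats
from .simpop import SCALED_PRESET, SimConfig, run_simulation, simulate_hybrid_scenario

__all__ = [
    "CLONING_RATES",
    "cloning_rate_sweep",
    "sexual_rate_threshold",
    "clonal_hwe_experiment",
    "pooled_fis",
    "CLONAL_HWE_PRESET",
    "conversion_proof_experiment",
    "segment_test_calibration",
    "hybrid_recovery",
    "HYBRID_PRESET",
]

CLONING_RATES = (0.0, 0.5, 0.9, 0.99, 0.999, 1.0)


def _derive_seed(master: int, *fields: int) -> int:
    x = int(master)
    for f in fields:
        x = (x * 1_000_003 + int(f) + 17) % (2**31 - 1)
    return x


def cloning_rate_sweep(
    seed: int,
    rates=CLONING_RATES,
    n_replicates: int = 20,
    base_config: SimConfig = SCALED_PRESET,
    n_individuals: int = 8,
    mac_min: int = 4,
    n_snps: int = 200,
) -> pd.DataFrame:
    """Mean F_IS per replicate for each cloning rate.

    Per replicate: run the forward model, sample ``n_individuals``, keep
    biallelic SNPs with MAC >= ``mac_min``, draw ``n_snps`` SNPs and average
    their F_IS (one SNP set per replicate)."""
    rows = []
    for rate in rates:
        for rep in range(n_replicates):
            s = _derive_seed(seed, int(rate * 1000), rep)
            cfg = replace(base_config, cloning_rate=rate, seed=s)
            sample = run_simulation(cfg)
            means = genostats.subsample_mean_fis(
                sample.genotypes,
                n_individuals=n_individuals,
                mac_min=mac_min,
                n_snps=n_snps,
                n_sets=1,
                rng=np.random.default_rng(s + 1),
            )
            rows.append({"cloning_rate": rate, "replicate": rep,
                         "mean_fis": float(means[0])})
    return pd.DataFrame(rows)


def sexual_rate_threshold(sweep: pd.DataFrame) -> float:
    """Smallest simulated rate of sexual reproduction (in percent) whose
    replicate mean-F_IS distribution is indistinguishable from the fully
    sexual one, requiring that all higher sexual rates are also
    indistinguishable and that near-clonal regimes (sexual rate < the
    threshold) fall below the fully sexual central 95% interval.

    Clonality depresses F_IS, never raises it, so the comparison is
    one-sided (matching the one-sided clonality p-value): a rate is
    indistinguishable when the median of its replicate means does not fall
    below the lower bound of the central 95% interval of the
    cloning-rate-0 replicate means.
    """
    base = sweep.loc[sweep["cloning_rate"] == 0.0, "mean_fis"].to_numpy()
    lo = np.percentile(base, 2.5)
    med = sweep.groupby("cloning_rate")["mean_fis"].median()
    rates = sorted(med.index)  # ascending cloning rate = descending sexual rate
    status = {r: (med[r] >= lo) for r in rates}
    threshold = None
    for r in rates:  # scan from most sexual to least
        if status[r]:
            threshold = round(100.0 * (1.0 - r), 6)
        else:
            break
    if threshold is None:
        return float("nan")
    return threshold


# Strictly clonal populations with per-site gene conversion.  The
# mutation-conversion-drift equilibrium alpha* = 1/(2*Ne) concerns the
# neutral balance between within-individual divergence (timescale 1/alpha)
# and the clonal coalescent (timescale ~2*Ne), so this experiment runs
# without the deleterious class (clonal background selection would shrink
# the effective between-individual timescale and shift the equilibrium).
# Ne is small because the sampled-genealogy shape - hence the F_IS
# distribution - is scale-free, and the run must cover ~10/alpha
# generations to reach the conversion-mutation equilibrium.
CLONAL_HWE_PRESET = SimConfig(
    pop_size=150,
    genome_length=3000,
    mutation_rate=2e-5,
    crossover_rate=0.0,
    cloning_rate=1.0,
    deleterious_fraction=0.0,
    n_generations=3000,
    sample_size=8,
    init="equilibrium",
)


def clonal_hwe_experiment(
    seed: int,
    alpha_factors=(0.1, 1.0, 10.0),
    n_replicates: int = 60,
    base_config: SimConfig = CLONAL_HWE_PRESET,
) -> pd.DataFrame:
    """F_IS of strictly clonal populations at conversion rates
    alpha = factor / (2*Ne); factor 1 is the predicted Hardy-Weinberg
    equilibrium point.

    Per replicate the observed and Hardy-Weinberg-expected heterozygote
    counts over the 8-individual sample's MAC >= 4 sites are recorded;
    :func:`pooled_fis` sums them across replicates before taking the ratio
    1 - sum(Ho)/sum(He).  Pooling components is essential here: the
    per-replicate ratio fluctuates so strongly under clonal genealogies
    (sd ~ 0.4) that averaging ratios carries a Jensen bias of -0.1 to -0.2
    even when the population sits exactly at the Hardy-Weinberg point; see
    docs/methods.md."""
    rows = []
    for factor in alpha_factors:
        alpha = factor / (2 * base_config.pop_size)
        for rep in range(n_replicates):
            s = _derive_seed(seed, int(factor * 100), rep)
            cfg = replace(base_config, conversion_rate=alpha, seed=s)
            sample = run_simulation(cfg)
            ho, he = genostats.het_count_components(sample.genotypes, mac_min=4)
            rows.append({"alpha_factor": factor, "alpha": alpha,
                         "replicate": rep, "ho": ho, "he": he,
                         "fis_replicate": 1.0 - ho / he})
    return pd.DataFrame(rows)


def pooled_fis(experiment: pd.DataFrame) -> pd.Series:
    """F_IS = 1 - sum(Ho)/sum(He) per alpha factor, pooling heterozygote
    count components across replicates (ratio-of-sums estimator)."""
    grouped = experiment.groupby("alpha_factor")[["ho", "he"]].sum()
    return 1.0 - grouped["ho"] / grouped["he"]


CONVERSION_PROOF_PRESET = SimConfig(
    pop_size=50,
    genome_length=3000,
    mutation_rate=3e-5,
    crossover_rate=0.0,
    cloning_rate=1.0,
    conversion_rate=0.005,
    n_generations=400,
    sample_size=6,
    n_contigs=3,
)


def conversion_proof_experiment(
    seed: int,
    n_clonal: int = 50,
    n_sexual: int = 15,
    base_config: SimConfig = CONVERSION_PROOF_PRESET,
):
    """Modified four-gamete scan on clonal-with-conversion samples versus
    matched sexual samples.

    Returns (total recombinant count over the clonal samples, total eligible
    clonal pairs, pooled sexual record table)."""
    clonal_recomb = 0
    clonal_pairs = 0
    for rep in range(n_clonal):
        cfg = replace(base_config, seed=_derive_seed(seed, 1, rep))
        sample = run_simulation(cfg)
        rec = fourgamete.scan_recombinant_pairs(sample.to_segments())
        clonal_pairs += len(rec)
        if len(rec):
            clonal_recomb += int(rec["recombinant"].sum())
    sexual_cfg = replace(
        base_config,
        cloning_rate=0.0,
        conversion_rate=0.0,
        crossover_rate=base_config.mutation_rate,
    )
    frames = []
    for rep in range(n_sexual):
        cfg = replace(sexual_cfg, seed=_derive_seed(seed, 2, rep))
        sample = run_simulation(cfg)
        rec = fourgamete.scan_recombinant_pairs(sample.to_segments())
        if len(rec):
            frames.append(rec)
    sexual_records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return clonal_recomb, clonal_pairs, sexual_records


CALIBRATION_PRESET = SimConfig(
    pop_size=100,
    genome_length=5000,
    mutation_rate=2.5e-5,
    crossover_rate=2.5e-5,
    n_generations=800,
    sample_size=8,
    n_contigs=5,
)


def segment_test_calibration(
    seed: int,
    n_segments: int = 200,
    n_perm: int = 199,
    min_snps: int = 8,
    base_config: SimConfig = CALIBRATION_PRESET,
) -> pd.DataFrame:
    """p-values of the three per-segment tests on recombination-free
    (strictly clonal) and on sexual (4*Ne*r = 0.01 per bp) segments."""
    rows = []
    for regime in ("clonal", "sexual"):
        if regime == "clonal":
            cfg0 = replace(base_config, cloning_rate=1.0, crossover_rate=0.0)
        else:
            cfg0 = base_config
        collected = 0
        rep = 0
        while collected < n_segments and rep < 20 * n_segments:
            cfg = replace(cfg0, seed=_derive_seed(seed, 3 if regime == "clonal" else 4, rep))
            sample = run_simulation(cfg)
            rng = np.random.default_rng(_derive_seed(seed, 5, rep))
            for seg in sample.to_segments():
                if collected >= n_segments:
                    break
                h = seg.haplotypes
                if seg.n_snps < min_snps:
                    continue
                _, p_r2, sk1 = ldstats.segment_r2_distance_test(
                    h, seg.positions, n_perm=n_perm, rng=rng
                )
                _, p_d4, sk2 = ldstats.sum_of_distances_test(
                    h, seg.positions, n_perm=n_perm, rng=rng
                )
                _, p_phi, sk3 = ldstats.phi_test(
                    h, seg.positions, n_perm=n_perm, rng=rng
                )
                if sk1 or sk2 or sk3:
                    continue
                rows.append({"regime": regime, "p_r2dist": p_r2,
                             "p_sumdist": p_d4, "p_phi": p_phi})
                collected += 1
            rep += 1
    return pd.DataFrame(rows)


# Mutation rate is high so that within-population nearest-neighbour
# haplotype distances exceed the 3-SNP counterpart-unambiguity margin on
# 1 kb segments; the source populations stay separated by ~20*Ne
# generations of isolation.
HYBRID_PRESET = SimConfig(
    pop_size=80,
    genome_length=5000,
    mutation_rate=1e-4,
    crossover_rate=2.5e-5,
    n_generations=300,
    sample_size=8,
    init="equilibrium",
    n_contigs=5,
)
HYBRID_SPLIT_GENERATIONS = 1600
HYBRID_N = 3


def hybrid_recovery(
    seed: int,
    n_boot: int = 200,
    support_min: float = 70.0,
    margin: int = 3,
    n_scenarios: int = 4,
):
    """F1-hybrid recovery: counterpart origins and monophyly scanning.

    Simulates the two-population hybrid scenario (3 F1 individuals plus 8
    individuals sampled from population A only, mirroring a study design in
    which the second parental population is unsampled), then per segment:

    * classifies each hybrid's haplotype grouping; a segment is informative
      for a hybrid when the classification is determined;
    * checks whether the reciprocal counterparts of its two haplotypes come
      from different source populations (truth origin labels);
    * scans the midpoint-rooted bootstrap NJ tree for clades made only of
      hybrid haplotypes.

    Returns a dict of summary counts pooled over ``n_scenarios``
    independent scenario replicates.
    """
    informative = 0
    split_origin = 0
    one_per_ind_clades = 0
    all_hybrid_clades = 0
    scanned = 0
    rng = np.random.default_rng(_derive_seed(seed, 9))
    for rep in range(n_scenarios):
        cfg_a = replace(HYBRID_PRESET, seed=_derive_seed(seed, 7, rep))
        cfg_b = replace(HYBRID_PRESET, seed=_derive_seed(seed, 8, rep))
        sample = simulate_hybrid_scenario(
            cfg_a, cfg_b, split_generations=HYBRID_SPLIT_GENERATIONS,
            n_hybrids=HYBRID_N, burnin_generations=300, n_sample_a=8, n_sample_b=0,
        )
        segments = sample.to_segments()
        hybrids = [ind for ind in sample.individuals if ind.startswith("H")]
        targets = {f"{h}.{k}" for h in hybrids for k in (1, 2)}
        for seg in segments:
            if seg.n_snps < 10:
                continue
            dist = haplophylo.hap_distance_matrix(seg)
            labels = seg.labels()
            origin_of = dict(zip(labels, sample.origins))
            for h in hybrids:
                status, _ = haplophylo.classify_grouping(seg, h, margin=margin)
                if status == "undetermined":
                    continue
                informative += 1
                c1 = haplophylo.closest_counterpart(dist, f"{h}.1", margin)
                c2 = haplophylo.closest_counterpart(dist, f"{h}.2", margin)
                origins = {origin_of[c1.best], origin_of[c2.best]}
                if origins == {"A", "B"}:
                    split_origin += 1
            tree = haplophylo.bootstrap_support(seg, n_boot=n_boot, rng=rng)
            rooted = haplophylo.midpoint_root(tree)
            report = haplophylo.monophyly_scan(rooted, targets, support_min=support_min)
            scanned += 1
            for size, opi in zip(report.sizes, report.one_per_individual):
                if size == 2 * HYBRID_N:
                    all_hybrid_clades += 1
                if opi and size == HYBRID_N:
                    one_per_ind_clades += 1
    return {
        "informative": informative,
        "split_origin": split_origin,
        "segments_scanned": scanned,
        "one_per_individual_clades": one_per_ind_clades,
        "all_hybrid_clades": all_hybrid_clades,
    }
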