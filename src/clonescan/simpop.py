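"""Forward-in-time Wright-Fisher simulation of facultatively clonal diploids.

The model: a constant-size population of ``Ne`` diploids.  Each offspring is,
independently, produced clonally with probability ``cloning_rate`` (a mitotic
copy of one fitness-weighted parent) or sexually otherwise (two
fitness-weighted parents, each transmitting one recombinant gamete with
crossovers at ``crossover_rate`` per bp).  New mutations arise at
``mutation_rate`` per bp per transmitted genome copy; a fraction
``deleterious_fraction`` of them draw a negative-gamma selection coefficient
(additive within locus: heterozygote effect s/2, homozygote s; multiplicative
across loci).  Within-locus gene conversion acts per segregating site per
individual per generation at rate ``conversion_rate``: a heterozygous site is
overwritten by the allele of one haplotype (donor chosen with probability
1/2), which conserves expected allele frequencies while eroding
heterozygosity.

Two mutation models are supported: ``infinite`` sites (every mutation creates
a new biallelic site at a fresh continuous coordinate) and ``finite4``
(Jukes-Cantor-equal mutation among 4 alleles at integer coordinates, which
generates recurrent mutation and triallelic sites).

Coordinates live on [0, genome_length) and are striped over ``n_contigs``
equal-length contigs at export; physical distance is defined within a contig
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
import numpy as np

from . import _kernels
from .core import GenotypeMatrix, SegmentHaplotypes, genotypes_from_haplotypes

__all__ = [
    "SimConfig",
    "Population",
    "SampleSet",
    "PAPER_PRESET",
    "SCALED_PRESET",
    "draw_dfe_effect",
    "equilibrium_population",
    "advance_generation",
    "apply_conversion",
    "run_simulation",
    "simulate_hybrid_scenario",
    "write_sample",
]

# Neutral:deleterious mutation rate ratio 1:0.4
DEFAULT_DELETERIOUS_FRACTION = 0.4 / 1.4


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the facultatively clonal Wright-Fisher model."""

    pop_size: int = 1000  # Ne, diploid individuals
    genome_length: int = 10_000  # L, base pairs
    mutation_rate: float = 2.5e-6  # mu, per bp per generation per genome copy
    crossover_rate: float = 2.5e-6  # r, per bp per sexual generation
    cloning_rate: float = 0.0  # probability an offspring is clonal
    conversion_rate: float = 0.0  # alpha, per segregating site per generation
    deleterious_fraction: float = DEFAULT_DELETERIOUS_FRACTION
    dfe_mean: float = -0.01  # mean selection coefficient (negative gamma)
    dfe_shape: float = 0.1  # gamma shape parameter
    n_generations: int = 5000
    sample_size: int = 8
    seed: int = 0
    sites_model: str = "infinite"  # "infinite" | "finite4"
    n_contigs: int = 10
    init: str = "monomorphic"  # "monomorphic" | "equilibrium"

    def __post_init__(self) -> None:
        if not (0.0 <= self.cloning_rate <= 1.0):
            raise ValueError("cloning_rate must be in [0, 1]")
        if self.mutation_rate < 0 or self.crossover_rate < 0 or self.conversion_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.dfe_shape <= 0:
            raise ValueError("dfe_shape must be positive")
        if self.dfe_mean > 0:
            raise ValueError("dfe_mean must be <= 0 (deleterious effects)")
        if not (0.0 <= self.deleterious_fraction <= 1.0):
            raise ValueError("deleterious_fraction must be in [0, 1]")
        if self.sample_size > self.pop_size:
            raise ValueError("sample_size must not exceed pop_size")
        if self.sites_model not in ("infinite", "finite4"):
            raise ValueError("sites_model must be 'infinite' or 'finite4'")
        if self.init not in ("monomorphic", "equilibrium"):
            raise ValueError("init must be 'monomorphic' or 'equilibrium'")
        if self.init == "equilibrium" and self.sites_model != "infinite":
            raise ValueError("equilibrium init is defined for infinite sites only")

    @property
    def theta_bp(self) -> float:
        """Population-scaled mutation rate 4*Ne*mu per bp."""
        return 4.0 * self.pop_size * self.mutation_rate

    @property
    def rho_bp(self) -> float:
        """Population-scaled crossover rate 4*Ne*r per bp."""
        return 4.0 * self.pop_size * self.crossover_rate


# The study's simulation parameterisation: Ne = 2500, mu = r = 1e-6 per bp,
# 1 Mb genome, 200,000 generations (4*Ne*mu = 0.01 per bp).
PAPER_PRESET = SimConfig(
    pop_size=2500,
    genome_length=1_000_000,
    mutation_rate=1e-6,
    crossover_rate=1e-6,
    n_generations=200_000,
)

# Desk-scale preset.  The population-scaled rates 4*Ne*mu = 4*Ne*r = 0.01
# per bp match the full-scale design, and Ne stays large (1500) because the
# cloning-rate sweep's discriminating quantity is the population-scaled rate
# of sex Ne*(1 - c): this preset keeps cloning rate 0.99 deep inside the
# sexual-like regime (Ne*(1-c) = 15) while 0.999 sits on the clonal side
# (Ne*(1-c) = 1.5).  The run starts from neutral mutation-drift equilibrium
# (built-in coalescent initialisation) and evolves 2*Ne generations under
# the focal reproductive regime.  See docs/methods.md for the equilibration
# argument.
SCALED_PRESET = SimConfig(
    pop_size=1500,
    genome_length=10_000,
    mutation_rate=0.01 / 6000,
    crossover_rate=0.01 / 6000,
    n_generations=3000,
    init="equilibrium",
)


@dataclass
class Population:
    """Evolving haplotype state over the currently segregating sites.

    ``haplotypes`` has one row per genome copy (rows 2i, 2i+1 belong to
    individual i) and one column per segregating site.  ``background`` maps a
    position to the allele carried by every column-less genome copy there
    (fixed derived states); absent positions carry allele 0.
    """

    config: SimConfig
    haplotypes: np.ndarray  # (2*Ne, S) int8
    positions: np.ndarray  # (S,) float64, coordinates on [0, L)
    eff_allele: np.ndarray  # (S,) int8 allele carrying the fitness effect
    eff_s: np.ndarray  # (S,) float64 selection coefficient (0 = neutral)
    background: dict = field(default_factory=dict)
    generation: int = 0

    @classmethod
    def initial(cls, config: SimConfig) -> "Population":
        n = 2 * config.pop_size
        return cls(
            config=config,
            haplotypes=np.zeros((n, 0), dtype=np.int8),
            positions=np.empty(0, dtype=np.float64),
            eff_allele=np.zeros(0, dtype=np.int8),
            eff_s=np.zeros(0, dtype=np.float64),
        )

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def copy(self) -> "Population":
        return Population(
            config=self.config,
            haplotypes=self.haplotypes.copy(),
            positions=self.positions.copy(),
            eff_allele=self.eff_allele.copy(),
            eff_s=self.eff_s.copy(),
            background=dict(self.background),
            generation=self.generation,
        )

    def fitness(self) -> np.ndarray:
        """Multiplicative fitness per individual; heterozygote effect s/2."""
        sel = np.nonzero(self.eff_s != 0.0)[0]
        return _kernels.fitness_multiplicative(
            self.haplotypes, sel, self.eff_allele[sel], self.eff_s[sel]
        )

    def prune(self) -> None:
        """Drop monomorphic columns (folding fixed alleles into the
        background) and keep columns sorted by position."""
        if self.n_sites == 0:
            return
        lo = self.haplotypes.min(axis=0)
        hi = self.haplotypes.max(axis=0)
        seg = lo != hi
        fixed = np.nonzero(~seg)[0]
        for j in fixed:
            pos = self.positions[j]
            allele = int(lo[j])
            if allele == 0:
                self.background.pop(pos, None)
            else:
                self.background[pos] = allele
        keep = np.nonzero(seg)[0]
        order = keep[np.argsort(self.positions[keep], kind="stable")]
        self.haplotypes = np.ascontiguousarray(self.haplotypes[:, order])
        self.positions = self.positions[order]
        self.eff_allele = self.eff_allele[order]
        self.eff_s = self.eff_s[order]


@dataclass
class SampleSet:
    """Sampled diploid genotypes with their truth haplotypes and provenance."""

    genotypes: GenotypeMatrix
    haplotypes: np.ndarray  # (2*n_sampled, n_sites) int8, truth phase
    global_positions: np.ndarray  # coordinates on [0, L)
    config: SimConfig
    seed: int
    generation: int
    origins: list[str] | None = None  # per-haplotype provenance labels

    @property
    def individuals(self) -> list[str]:
        return self.genotypes.individuals

    @property
    def n_sites(self) -> int:
        return self.genotypes.n_sites

    def is_empty(self) -> bool:
        return self.n_sites == 0

    def to_segments(self) -> list[SegmentHaplotypes]:
        """One truth-phased segment per contig (the no-phasing-noise path)."""
        segments = []
        contig_len = self.config.genome_length / self.config.n_contigs
        contigs = self.genotypes.contigs.astype(str)
        for contig in sorted(set(contigs), key=lambda c: int(c.split("_")[-1])):
            mask = contigs == contig
            if not mask.any():
                continue
            segments.append(
                SegmentHaplotypes(
                    contig=contig,
                    start=1,
                    end=int(contig_len),
                    positions=self.genotypes.positions[mask],
                    individuals=list(self.individuals),
                    haplotypes=self.haplotypes[:, mask],
                    origins=self.origins,
                )
            )
        return segments


def _kingman_columns(
    n_tips: int, mut_rate_locus: float, pop_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Neutral infinite-sites columns for one non-recombining locus, from a
    Kingman coalescent of ``n_tips`` genome copies (pairwise coalescence
    rate 1/(2*Ne) per generation).

    Returns, for each segregating site, the array of carrier tip indices.
    """
    # build the tree: children pointers + branch lengths
    n_nodes = 2 * n_tips - 1
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = list(range(n_tips))
    t = 0.0
    nxt = n_tips
    # pre-drawn randomness for the merge loop
    exps = rng.exponential(size=n_tips - 1)
    pair_u = rng.random((n_tips - 1, 2))
    for step in range(n_tips - 1):
        m = len(active)
        t += exps[step] * 2.0 * pop_size / (m * (m - 1) / 2.0)
        i = int(pair_u[step, 0] * m)
        j = int(pair_u[step, 1] * (m - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        # swap-remove both (order-safe)
        for k in sorted((i, j), reverse=True):
            active[k] = active[-1]
            active.pop()
        left[nxt], right[nxt] = a, b
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    root = n_nodes - 1
    parent_time = np.empty(n_nodes)
    parent_time[root] = node_time[root]
    for v in range(root, n_tips - 1, -1):
        parent_time[left[v]] = node_time[v]
        parent_time[right[v]] = node_time[v]
    edge_len = parent_time - node_time
    edge_len[root] = 0.0
    total = edge_len.sum()
    n_mut = rng.poisson(mut_rate_locus * total)
    if n_mut == 0:
        return []
    edges = rng.choice(n_nodes, size=n_mut, p=edge_len / total)
    cols = []
    for v in edges:
        # descendant tips of v
        stack = [int(v)]
        tips = []
        while stack:
            u = stack.pop()
            if u < n_tips:
                tips.append(u)
            else:
                stack.append(int(left[u]))
                stack.append(int(right[u]))
        cols.append(np.asarray(tips, dtype=np.int64))
    return cols


def equilibrium_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Population drawn from neutral mutation-drift equilibrium.

    Independent coalescent genealogies are drawn per linkage window of width
    ~1/(4*Ne*r) - the scale beyond which equilibrium linkage disequilibrium
    has decayed - capped at one window per contig when crossover is absent.
    Within-window associations relax further during the forward phase.
    Sites start selectively neutral; the deleterious class is built up by
    forward-time mutation.
    """
    n = 2 * config.pop_size
    contig_len = config.genome_length / config.n_contigs
    rho_bp = 4.0 * config.pop_size * config.crossover_rate
    if rho_bp > 0:
        window = min(max(1.0 / rho_bp, 1.0), contig_len)
    else:
        window = contig_len
    per_contig = max(int(round(contig_len / window)), 1)
    window = contig_len / per_contig
    positions = []
    columns = []
    for c in range(config.n_contigs):
        for w in range(per_contig):
            start = c * contig_len + w * window
            cols = _kingman_columns(
                n, config.mutation_rate * window, config.pop_size, rng
            )
            for carriers in cols:
                positions.append(rng.uniform(start, start + window))
                columns.append(carriers)
    s = len(columns)
    haps = np.zeros((n, s), dtype=np.int8)
    for j, carriers in enumerate(columns):
        haps[carriers, j] = 1
    pop = Population(
        config=config,
        haplotypes=haps,
        positions=np.asarray(positions),
        eff_allele=np.ones(s, dtype=np.int8),
        eff_s=np.zeros(s),
    )
    pop.prune()
    return pop


def draw_dfe_effect(config: SimConfig, rng: np.random.Generator) -> float:
    """Draw one selection coefficient from the mutation-effect distribution.

    With probability ``1 - deleterious_fraction`` the mutation is neutral
    (s = 0); otherwise s is a negative-gamma draw with mean ``dfe_mean`` and
    shape ``dfe_shape``.
    """
    if rng.random() >= config.deleterious_fraction:
        return 0.0
    scale = -config.dfe_mean / config.dfe_shape
    return -float(rng.gamma(config.dfe_shape, scale))


def _draw_dfe_effects(config: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    s = np.zeros(n)
    if n == 0:
        return s
    deleterious = rng.random(n) < config.deleterious_fraction
    k = int(deleterious.sum())
    if k and config.dfe_mean < 0:
        scale = -config.dfe_mean / config.dfe_shape
        s[deleterious] = -rng.gamma(config.dfe_shape, scale, size=k)
    return s


def apply_conversion(
    haplotype_pair: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply within-locus gene conversion to one individual's haplotype pair.

    Each site independently converts with probability ``alpha``; at a
    converted heterozygous site one haplotype's allele overwrites the
    other's, the donor chosen with probability 1/2.  Homozygous sites are
    unaffected, so the expected population allele frequency is conserved.
    """
    pair = np.array(haplotype_pair, dtype=np.int8, copy=True)
    if pair.ndim != 2 or pair.shape[0] != 2:
        raise ValueError("haplotype_pair must have shape (2, n_sites)")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n = pair.shape[1]
    if n == 0 or alpha == 0.0:
        return pair
    hit = rng.random(n) < alpha
    het = pair[0] != pair[1]
    conv = np.nonzero(hit & het)[0]
    if conv.size:
        donor_is_first = rng.random(conv.size) < 0.5
        pair[1, conv[donor_is_first]] = pair[0, conv[donor_is_first]]
        pair[0, conv[~donor_is_first]] = pair[1, conv[~donor_is_first]]
    return pair


def _population_conversion(pop: Population, rng: np.random.Generator) -> None:
    """Per-(individual, site) Bernoulli(alpha) conversion, by thinning."""
    alpha = pop.config.conversion_rate
    ne = pop.config.pop_size
    s = pop.n_sites
    if alpha <= 0.0 or s == 0:
        return
    n_events = rng.binomial(ne * s, alpha)
    if n_events == 0:
        return
    flat = np.unique(rng.integers(0, ne * s, size=n_events))
    ind = flat // s
    site = flat % s
    a = pop.haplotypes[2 * ind, site]
    b = pop.haplotypes[2 * ind + 1, site]
    het = a != b
    ind, site, a, b = ind[het], site[het], a[het], b[het]
    if ind.size == 0:
        return
    donor_first = rng.random(ind.size) < 0.5
    pop.haplotypes[2 * ind[donor_first] + 1, site[donor_first]] = a[donor_first]
    pop.haplotypes[2 * ind[~donor_first], site[~donor_first]] = b[~donor_first]


def _gamete_rows(
    pop: Population,
    parents: np.ndarray,
    sexual: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int, int, np.ndarray]]]:
    """Source row per offspring genome copy plus crossover fix-ups.

    Returns (src_rows, fixups) where src_rows[2i], src_rows[2i+1] are the
    parental haplotype rows copied into offspring i, and each fix-up is
    (child_row, row_a, row_b, breakpoints) for gametes with >= 1 crossover.
    """
    ne = pop.config.pop_size
    src = np.empty(2 * ne, dtype=np.int64)
    # clones copy the parent's two rows verbatim
    clone = ~sexual
    src[0::2][clone] = 2 * parents[clone, 0]
    src[1::2][clone] = 2 * parents[clone, 0] + 1
    # sexual offspring: one gamete per parent, random starting haplotype
    n_sex = int(sexual.sum())
    fixups: list[tuple[int, int, int, np.ndarray]] = []
    if n_sex:
        start = rng.integers(0, 2, size=(n_sex, 2))
        sex_idx = np.nonzero(sexual)[0]
        for k in (0, 1):
            src[2 * sex_idx + k] = 2 * parents[sex_idx, k] + start[:, k]
        lam = pop.config.crossover_rate * pop.config.genome_length
        if lam > 0:
            n_x = rng.poisson(lam, size=(n_sex, 2))
            total = int(n_x.sum())
            if total:
                xs = rng.uniform(0.0, pop.config.genome_length, size=total)
                flat = n_x.ravel()
                ends = np.cumsum(flat)
                for f in np.nonzero(flat)[0]:
                    j, k = divmod(int(f), 2)
                    bp = xs[ends[f] - flat[f] : ends[f]]
                    parent = parents[sex_idx[j], k]
                    row_a = 2 * parent + start[j, k]
                    row_b = 2 * parent + 1 - start[j, k]
                    fixups.append((2 * sex_idx[j] + k, int(row_a), int(row_b), bp))
    return src, fixups


def advance_generation(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> Population:
    """Produce the next Wright-Fisher generation (in a new Population).

    Parent sampling is multinomial with replacement, proportional to
    multiplicative fitness (selfing allowed).  Mutation, crossover and gene
    conversion act as described in the module docstring.
    """
    ne = config.pop_size
    w = pop.fitness()
    tot = w.sum()
    if tot <= 0 or np.all(w == w[0]):
        parents = rng.integers(0, ne, size=(ne, 2))
    else:
        # fitness-proportional sampling by rejection (fast when fitness is
        # near-uniform), falling back to inverse-CDF for stragglers
        wmax = w.max()
        flat = np.empty(2 * ne, dtype=np.int64)
        pending = np.arange(2 * ne)
        for _ in range(8):
            cand = rng.integers(0, ne, size=pending.size)
            ok = rng.random(pending.size) * wmax < w[cand]
            flat[pending[ok]] = cand[ok]
            pending = pending[~ok]
            if pending.size == 0:
                break
        if pending.size:
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            rest = np.searchsorted(cdf, rng.random(pending.size), side="right")
            flat[pending] = np.minimum(rest, ne - 1)
        parents = flat.reshape(ne, 2)
    sexual = rng.random(ne) >= config.cloning_rate

    src, fixups = _gamete_rows(pop, parents, sexual, rng)

    # new mutations (one per transmitted genome copy per bp at rate mu)
    n_mut = rng.poisson(2 * ne * config.genome_length * config.mutation_rate)
    mut_rows = rng.integers(0, 2 * ne, size=n_mut)
    if config.sites_model == "infinite":
        mut_pos = rng.uniform(0.0, config.genome_length, size=n_mut)
    else:
        mut_pos = rng.integers(0, config.genome_length, size=n_mut).astype(np.float64)
    mut_s = _draw_dfe_effects(config, rng, n_mut)

    s_old = pop.n_sites
    allele_u = rng.random(n_mut)
    if config.sites_model == "infinite":
        # every mutation opens a fresh biallelic column (continuous
        # coordinates never collide); ancestral allele is 0, derived 1
        n_new = n_mut
        child = np.empty((2 * ne, s_old + n_new), dtype=np.int8)
        _kernels.offspring_copy(pop.haplotypes, src, child)
        _kernels.apply_crossovers(pop.haplotypes, pop.positions, child, fixups)
        child[:, s_old:] = 0
        child[mut_rows, s_old + np.arange(n_mut)] = 1
        eff_allele = np.concatenate([pop.eff_allele, np.ones(n_new, dtype=np.int8)])
        eff_s = np.concatenate([pop.eff_s, mut_s])
        positions = np.concatenate([pop.positions, mut_pos])
    else:
        # finite sites: recurrent Jukes-Cantor mutation among 4 alleles
        pos_to_col = {p_: j for j, p_ in enumerate(pop.positions)}
        new_positions: list[float] = []
        plan: list[tuple[int, int, float, float]] = []  # row, col, u, s
        for i in range(n_mut):
            pos = float(mut_pos[i])
            col = pos_to_col.get(pos, -1)
            if col == -1:
                col = s_old + len(new_positions)
                pos_to_col[pos] = col
                new_positions.append(pos)
            plan.append((int(mut_rows[i]), col, float(allele_u[i]), float(mut_s[i])))
        n_new = len(new_positions)
        child = np.empty((2 * ne, s_old + n_new), dtype=np.int8)
        _kernels.offspring_copy(pop.haplotypes, src, child)
        _kernels.apply_crossovers(pop.haplotypes, pop.positions, child, fixups)
        for j, pos in enumerate(new_positions):
            child[:, s_old + j] = pop.background.get(pos, 0)
        eff_allele = np.concatenate([pop.eff_allele, np.zeros(n_new, dtype=np.int8)])
        eff_s = np.concatenate([pop.eff_s, np.zeros(n_new)])
        positions = np.concatenate([pop.positions, np.asarray(new_positions)])
        for row, col, u, s in plan:
            cur = int(child[row, col])
            new_allele = (cur + 1 + int(u * 3)) % 4
            child[row, col] = new_allele
            if s != 0.0:
                eff_allele[col] = new_allele
                eff_s[col] = s

    out = Population(
        config=config,
        haplotypes=child,
        positions=positions,
        eff_allele=eff_allele,
        eff_s=eff_s,
        background=dict(pop.background),
        generation=pop.generation + 1,
    )
    _population_conversion(out, rng)
    return out


_PRUNE_INTERVAL = 10


def _evolve(pop: Population, config: SimConfig, n_generations: int, rng: np.random.Generator) -> Population:
    for _ in range(n_generations):
        pop = advance_generation(pop, config, rng)
        if pop.generation % _PRUNE_INTERVAL == 0:
            pop.prune()
    pop.prune()
    return pop


def _export_coordinates(
    global_positions: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Map [0, L) coordinates to (contig label, 1-based local position),
    keeping local positions unique and strictly increasing per contig."""
    contig_len = config.genome_length / config.n_contigs
    idx = np.minimum((global_positions / contig_len).astype(int), config.n_contigs - 1)
    local = np.floor(global_positions - idx * contig_len).astype(np.int64) + 1
    contigs = np.array([f"contig_{i + 1}" for i in idx], dtype=object)
    # de-collide after rounding
    for c in np.unique(idx):
        m = np.nonzero(idx == c)[0]
        p = local[m]
        for k in range(1, len(p)):
            if p[k] <= p[k - 1]:
                p[k] = p[k - 1] + 1
        local[m] = p
    return contigs, local


def _sample_population(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    individuals: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> SampleSet:
    if individuals is None:
        individuals = rng.choice(config.pop_size, size=config.sample_size, replace=False)
        individuals.sort()
    rows = np.empty(2 * len(individuals), dtype=np.int64)
    rows[0::2] = 2 * np.asarray(individuals)
    rows[1::2] = 2 * np.asarray(individuals) + 1
    haps = pop.haplotypes[rows]
    # keep sites segregating within the sample
    seg = haps.min(axis=0) != haps.max(axis=0)
    haps = np.ascontiguousarray(haps[:, seg])
    gpos = pop.positions[seg]
    order = np.argsort(gpos, kind="stable")
    haps, gpos = haps[:, order], gpos[order]
    if labels is None:
        labels = [f"S{i + 1}" for i in range(len(individuals))]
    if haps.shape[1] == 0:
        warnings.warn("no segregating sites in sample; returning empty SampleSet")
    contigs, local = _export_coordinates(gpos, config)
    gm = GenotypeMatrix(contigs, local, genotypes_from_haplotypes(haps), labels)
    return SampleSet(
        genotypes=gm,
        haplotypes=haps,
        global_positions=gpos,
        config=config,
        seed=config.seed,
        generation=pop.generation,
    )


def run_simulation(config: SimConfig) -> SampleSet:
    """Run the model for ``config.n_generations`` and sample
    ``config.sample_size`` individuals without replacement.

    Deterministic given ``config`` (including its ``seed``)."""
    rng = np.random.default_rng(config.seed)
    if config.init == "equilibrium":
        pop = equilibrium_population(config, rng)
    else:
        pop = Population.initial(config)
    pop = _evolve(pop, config, config.n_generations, rng)
    return _sample_population(pop, config, rng)


def _make_gamete(
    pop: Population, parent: int, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from ``parent`` (meiosis with crossovers)."""
    start = int(rng.integers(0, 2))
    row_a, row_b = 2 * parent + start, 2 * parent + 1 - start
    gamete = pop.haplotypes[row_a].copy()
    lam = pop.config.crossover_rate * pop.config.genome_length
    k = rng.poisson(lam) if lam > 0 else 0
    if k:
        bp = rng.uniform(0.0, pop.config.genome_length, size=k)
        parity = (bp[:, None] <= pop.positions[None, :]).sum(axis=0) % 2
        take_b = parity.astype(bool)
        gamete[take_b] = pop.haplotypes[row_b][take_b]
    return gamete


def simulate_hybrid_scenario(
    config_a: SimConfig,
    config_b: SimConfig,
    split_generations: int,
    n_hybrids: int,
    burnin_generations: int | None = None,
    n_sample_a: int | None = None,
    n_sample_b: int = 0,
) -> SampleSet:
    """Two populations isolated for ``split_generations`` after a common
    ancestral burn-in, then ``n_hybrids`` F1 individuals formed with one
    gamete from each population.

    The returned sample holds the F1s first, then ``n_sample_a`` individuals
    from population A and ``n_sample_b`` from population B, with per-
    haplotype origin labels ("A", "B").  Both configs must share genome
    coordinates (length, contig count and sites model).
    """
    if (
        config_a.genome_length != config_b.genome_length
        or config_a.n_contigs != config_b.n_contigs
        or config_a.sites_model != config_b.sites_model
    ):
        raise ValueError("source configs must share genome coordinates")
    if burnin_generations is None:
        burnin_generations = config_a.n_generations
    if n_sample_a is None:
        n_sample_a = config_a.sample_size

    rng = np.random.default_rng(config_a.seed)
    if config_a.init == "equilibrium":
        start = equilibrium_population(config_a, rng)
    else:
        start = Population.initial(config_a)
    ancestor = _evolve(start, config_a, burnin_generations, rng)
    pop_a = ancestor.copy()
    pop_a.config = config_a
    pop_b = ancestor.copy()
    pop_b.config = config_b
    rng_a = np.random.default_rng(rng.integers(0, 2**31 - 1))
    rng_b = np.random.default_rng(rng.integers(0, 2**31 - 1))
    pop_a = _evolve(pop_a, config_a, split_generations, rng_a)
    pop_b = _evolve(pop_b, config_b, split_generations, rng_b)

    # union of segregating sites and fixed differences between backgrounds
    pos_a = {p: j for j, p in enumerate(pop_a.positions)}
    pos_b = {p: j for j, p in enumerate(pop_b.positions)}
    all_pos = set(pos_a) | set(pos_b)
    all_pos |= {
        p
        for p in set(pop_a.background) | set(pop_b.background)
        if pop_a.background.get(p, 0) != pop_b.background.get(p, 0)
    }
    union = np.array(sorted(all_pos))

    def expand(pop: Population, pos_map: dict) -> np.ndarray:
        out = np.empty((pop.haplotypes.shape[0], len(union)), dtype=np.int8)
        for j, p in enumerate(union):
            col = pos_map.get(p)
            if col is None:
                out[:, j] = pop.background.get(p, 0)
            else:
                out[:, j] = pop.haplotypes[:, col]
        return out

    full_a = expand(pop_a, pos_a)
    full_b = expand(pop_b, pos_b)

    hap_rows: list[np.ndarray] = []
    labels: list[str] = []
    origins: list[str] = []

    exp_a = Population(
        config=config_a, haplotypes=full_a, positions=union,
        eff_allele=np.zeros(len(union), np.int8), eff_s=np.zeros(len(union)),
        background={}, generation=pop_a.generation,
    )
    exp_b = Population(
        config=config_b, haplotypes=full_b, positions=union,
        eff_allele=np.zeros(len(union), np.int8), eff_s=np.zeros(len(union)),
        background={}, generation=pop_b.generation,
    )
    parents_a = rng.choice(config_a.pop_size, size=n_hybrids, replace=False)
    parents_b = rng.choice(config_b.pop_size, size=n_hybrids, replace=False)
    for h in range(n_hybrids):
        hap_rows.append(_make_gamete(exp_a, int(parents_a[h]), rng))
        hap_rows.append(_make_gamete(exp_b, int(parents_b[h]), rng))
        labels.append(f"H{h + 1}")
        origins.extend(["A", "B"])
    pick_a = rng.choice(
        np.setdiff1d(np.arange(config_a.pop_size), parents_a), size=n_sample_a, replace=False
    )
    for i in sorted(pick_a):
        hap_rows.append(full_a[2 * i])
        hap_rows.append(full_a[2 * i + 1])
        labels.append(f"A{i + 1}")
        origins.extend(["A", "A"])
    if n_sample_b:
        pick_b = rng.choice(
            np.setdiff1d(np.arange(config_b.pop_size), parents_b), size=n_sample_b, replace=False
        )
        for i in sorted(pick_b):
            hap_rows.append(full_b[2 * i])
            hap_rows.append(full_b[2 * i + 1])
            labels.append(f"B{i + 1}")
            origins.extend(["B", "B"])

    haps = np.array(hap_rows, dtype=np.int8)
    seg = haps.min(axis=0) != haps.max(axis=0)
    haps = np.ascontiguousarray(haps[:, seg])
    gpos = union[seg]
    origins_arr = list(origins)
    if haps.shape[1] == 0:
        warnings.warn("no segregating sites in hybrid sample")
    contigs, local = _export_coordinates(gpos, config_a)
    gm = GenotypeMatrix(contigs, local, genotypes_from_haplotypes(haps), labels)
    return SampleSet(
        genotypes=gm,
        haplotypes=haps,
        global_positions=gpos,
        config=config_a,
        seed=config_a.seed,
        generation=max(pop_a.generation, pop_b.generation),
        origins=origins_arr,
    )


def write_sample(sample: SampleSet, out_dir, phased: bool = True) -> dict:
    """Write a SampleSet to VCF + truth-haplotype FASTA + sites TSV.

    Thin wrapper over :mod:`clonescan.io`; see there for formats."""
    from . import io as _io

    return _io.write_sample(sample, out_dir, phased=phased)
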