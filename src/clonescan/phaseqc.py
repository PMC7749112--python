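"""Quality control of read-based phasing output.

Read-based phasers (e.g. HapCUT2) emit per-individual blocks of jointly
phased heterozygous SNPs with per-SNP switch/mismatch confidence scores.
Because each diploid individual carries at most two haplotypes over any pair
of sites, read fragments supporting a third two-site combination indicate
PCR template switching, paralogous alignment or phasing error; such blocks
are discarded.  The surviving blocks can be split at single low-confidence
SNPs, complemented with embedded homozygous SNPs, intersected across
individuals into commonly phased segments, and compared between independent
phasings of the same individual for switch inconsistencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PhasedBlock, SegmentHaplotypes

__all__ = [
    "conflicting_evidence_filter",
    "quality_split",
    "complement_homozygous",
    "common_phased_segments",
    "switch_inconsistency",
    "fragment_evidence_from_frame",
]


def fragment_evidence_from_frame(frame: pd.DataFrame) -> dict:
    """Index fragment evidence by (individual, contig, pos_i, pos_j).

    Expected columns: individual, contig, pos_i, pos_j, combo (two-character
    allele-code string like "01"), count.
    """
    out: dict = {}
    for row in frame.itertuples(index=False):
        lo, hi = sorted((int(row.pos_i), int(row.pos_j)))
        key = (row.individual, row.contig, lo, hi)
        out.setdefault(key, {})[str(row.combo)] = int(row.count)
    return out


def conflicting_evidence_filter(
    block: PhasedBlock, evidence: dict, min_reads: int = 1
) -> bool:
    """True (keep) unless any within-block site pair is covered by reads
    supporting more than two distinct two-site combinations, each seen in at
    least ``min_reads`` fragments.  Pairs without evidence are treated as
    non-conflicting."""
    pos = block.positions
    for i, j in itertools.combinations(range(block.n_snps), 2):
        lo, hi = sorted((int(pos[i]), int(pos[j])))
        combos = evidence.get((block.individual, block.contig, lo, hi))
        if not combos:
            continue
        supported = sum(1 for c in combos.values() if c >= min_reads)
        if supported > 2:
            return False
    return True


def quality_split(block: PhasedBlock, q_threshold: float = 100.0) -> list[PhasedBlock]:
    """Split or drop a block based on low-confidence SNPs.

    A SNP is "low" when its switch or mismatch quality is below
    ``q_threshold``.  More than one low SNP: the block is dropped (empty
    list).  Exactly one: the block is split at that SNP, which is excluded
    from both halves.  None: the block is returned unchanged.
    """
    if block.switch_qual is None or block.mismatch_qual is None:
        raise ValueError("block lacks quality scores")
    low = (block.switch_qual < q_threshold) | (block.mismatch_qual < q_threshold)
    n_low = int(low.sum())
    if n_low == 0:
        return [block]
    if n_low > 1:
        return []
    k = int(np.nonzero(low)[0][0])
    out = []
    for sl in (slice(0, k), slice(k + 1, block.n_snps)):
        idx = np.arange(block.n_snps)[sl]
        if idx.size:
            out.append(block.subset(idx))
    return out


def complement_homozygous(block: PhasedBlock, genotypes: GenotypeMatrix) -> PhasedBlock:
    """Add homozygous SNPs lying strictly inside the block's span to both
    haplotypes (their phase is trivially known)."""
    het_pos = block.positions[block.het_mask()]
    if het_pos.size == 0:
        return block
    lo, hi = het_pos[0], het_pos[-1]
    ind = genotypes.individuals.index(block.individual)
    contigs = genotypes.contigs.astype(str)
    inside = (
        (contigs == block.contig)
        & (genotypes.positions > lo)
        & (genotypes.positions < hi)
    )
    g = genotypes.genotypes[:, ind, :]
    hom = inside & (g[:, 0] == g[:, 1]) & (g[:, 0] >= 0)
    add_pos = genotypes.positions[hom]
    new = ~np.isin(add_pos, block.positions)
    add_pos, add_allele = add_pos[new], g[hom, 0][new]
    if add_pos.size == 0:
        return block
    positions = np.concatenate([block.positions, add_pos])
    order = np.argsort(positions, kind="stable")
    hap1 = np.concatenate([block.hap1, add_allele])[order]
    hap2 = np.concatenate([block.hap2, add_allele])[order]
    hom_mask = np.concatenate([block.homozygous, np.ones(add_pos.size, bool)])[order]
    def _pad(q):
        if q is None:
            return None
        return np.concatenate([q, np.full(add_pos.size, np.inf)])[order]
    return PhasedBlock(
        block.individual,
        block.contig,
        positions[order],
        hap1,
        hap2,
        _pad(block.switch_qual),
        _pad(block.mismatch_qual),
        hom_mask,
    )


def _non_singleton_mask(haps: np.ndarray) -> np.ndarray:
    """SNP columns whose minor allele occurs in >= 2 of the given haplotypes."""
    out = np.zeros(haps.shape[1], dtype=bool)
    for j in range(haps.shape[1]):
        vals, counts = np.unique(haps[:, j], return_counts=True)
        if len(vals) < 2:
            continue
        # polymorphic and the second-most-common allele seen at least twice
        out[j] = np.sort(counts)[-2] >= 2
    return out


def common_phased_segments(
    blocks: list[PhasedBlock],
    individuals: list[str],
    min_nonsingleton: int = 15,
) -> list[SegmentHaplotypes]:
    """Maximal contig intervals where every requested individual is covered
    by exactly one phased block, keeping segments with at least
    ``min_nonsingleton`` non-singleton SNPs phased in all individuals.

    A non-singleton SNP is one whose minor allele occurs in at least two of
    the phased haplotypes.  Returns per-segment haplotype matrices.
    """
    by_ind_contig: dict = {}
    for b in blocks:
        by_ind_contig.setdefault((b.individual, b.contig), []).append(b)
    contigs = sorted({b.contig for b in blocks})
    segments = []
    for contig in contigs:
        per_ind = []
        ok = True
        for ind in individuals:
            bl = by_ind_contig.get((ind, contig), [])
            if not bl:
                ok = False
                break
            per_ind.append(sorted(bl, key=lambda b: b.span[0]))
        if not ok:
            continue
        # sweep maximal intervals where each individual has one covering block
        bounds = sorted(
            {b.span[0] for bl in per_ind for b in bl}
            | {b.span[1] for bl in per_ind for b in bl}
        )
        events = []
        for lo, hi in zip(bounds, bounds[1:]):
            covers = []
            for bl in per_ind:
                c = [b for b in bl if b.span[0] <= lo and b.span[1] >= hi]
                covers.append(c[0] if len(c) == 1 else None)
            events.append(all(c is not None for c in covers))
        # merge consecutive covered windows with identical block tuples
        i = 0
        while i < len(events):
            if not events[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(events) and events[j + 1]:
                j += 1
            lo, hi = bounds[i], bounds[j + 1]
            seg = _build_segment(per_ind, individuals, contig, lo, hi, min_nonsingleton)
            if seg is not None:
                segments.append(seg)
            i = j + 1
    return segments


def _build_segment(per_ind, individuals, contig, lo, hi, min_nonsingleton):
    block_of = []
    for bl in per_ind:
        c = [b for b in bl if b.span[0] <= lo and b.span[1] >= hi]
        if len(c) != 1:
            return None
        block_of.append(c[0])
    shared = None
    for b in block_of:
        inside = set(b.positions[(b.positions >= lo) & (b.positions <= hi)])
        shared = inside if shared is None else shared & inside
    shared = np.array(sorted(shared), dtype=np.int64)
    if shared.size == 0:
        return None
    haps = np.empty((2 * len(individuals), shared.size), dtype=np.int8)
    for k, b in enumerate(block_of):
        sel = np.searchsorted(b.positions, shared)
        haps[2 * k] = b.hap1[sel]
        haps[2 * k + 1] = b.hap2[sel]
    if _non_singleton_mask(haps).sum() < min_nonsingleton:
        return None
    return SegmentHaplotypes(
        contig=contig,
        start=int(lo),
        end=int(hi),
        positions=shared,
        individuals=list(individuals),
        haplotypes=haps,
    )


def switch_inconsistency(
    phasing_a: list[PhasedBlock], phasing_b: list[PhasedBlock]
) -> tuple[float, dict]:
    """Fraction of adjacent co-phased heterozygous SNP pairs whose relative
    phase orientation differs between two phasings of one individual.

    Invariant under a global haplotype flip of either phasing within a
    block; returns (fraction, per-contig any-inconsistency flags).  With no
    shared pairs the fraction is nan.
    """
    def pair_orientations(blocks):
        out = {}
        for b in blocks:
            het = b.het_mask()
            pos = b.positions[het]
            h1 = b.hap1[het]
            h2 = b.hap2[het]
            for i in range(len(pos) - 1):
                # orientation of the adjacent pair: does hap1 carry the
                # (lexicographically) lower allele at both sites?
                key = (b.contig, int(pos[i]), int(pos[i + 1]))
                ori = (h1[i] < h2[i]) == (h1[i + 1] < h2[i + 1])
                out[key] = ori
        return out

    ind = {b.individual for b in phasing_a} | {b.individual for b in phasing_b}
    if len(ind) > 1:
        raise ValueError("phasings must belong to a single individual")
    oa = pair_orientations(phasing_a)
    ob = pair_orientations(phasing_b)
    shared = sorted(set(oa) & set(ob))
    if not shared:
        return float("nan"), {}
    flags: dict = {}
    bad = 0
    for key in shared:
        mismatch = oa[key] != ob[key]
        bad += mismatch
        flags[key[0]] = flags.get(key[0], False) or mismatch
    return bad / len(shared), flags
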