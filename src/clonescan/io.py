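"""Reading and writing of VCF, FASTA and TSV artefacts.

VCF output is VCFv4.2 text with diploid GT fields; phased samples use '|'
separators plus a PS (phase set) tag holding the position of the first SNP
of the phased block (one block per contig for simulator truth output).
Haplotypes travel as FASTA with two records per individual per contig over
the contig's SNP columns.  VCF input is parsed with cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import NUCLEOTIDES, GenotypeMatrix, PhasedBlock, genotypes_from_haplotypes

__all__ = [
    "write_sample",
    "write_vcf",
    "read_vcf",
    "write_haplotype_fasta",
    "read_haplotype_fasta",
    "read_phased_blocks_vcf",
]


def write_vcf(
    path,
    matrix: GenotypeMatrix,
    haplotypes: np.ndarray | None = None,
    phased: bool = True,
    contig_length: int | None = None,
) -> None:
    """Write genotypes (and optionally phased haplotypes) as VCFv4.2 text.

    With ``phased`` and ``haplotypes`` given, GT uses the haplotype order
    with '|' and a PS tag (first SNP position of the contig); otherwise GT
    is unphased and sorted.
    """
    path = Path(path)
    contigs = matrix.contigs.astype(str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonescan\n")
        for c in dict.fromkeys(contigs):  # stable order
            ln = f",length={contig_length}" if contig_length else ""
            fh.write(f"##contig=<ID={c}{ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if phased and haplotypes is not None:
            fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        ps_of_contig = {}
        for c in dict.fromkeys(contigs):
            first = matrix.positions[contigs == c]
            ps_of_contig[c] = int(first[0]) if len(first) else 1
        for i in range(matrix.n_sites):
            alleles = matrix.site_alleles(i)
            ref = int(alleles[0])
            alts = [int(a) for a in alleles[1:]]
            index_of = {a: k for k, a in enumerate([ref] + alts)}
            alt_str = ",".join(NUCLEOTIDES[a] for a in alts) if alts else "."
            if phased and haplotypes is not None:
                fmt = "GT:PS"
                ps = ps_of_contig[contigs[i]]
                cells = []
                for j in range(matrix.n_individuals):
                    a, b = haplotypes[2 * j, i], haplotypes[2 * j + 1, i]
                    cells.append(f"{index_of[int(a)]}|{index_of[int(b)]}:{ps}")
            else:
                fmt = "GT"
                cells = []
                for j in range(matrix.n_individuals):
                    a, b = matrix.genotypes[i, j]
                    if a < 0:
                        cells.append("./.")
                    else:
                        x, y = sorted((index_of[int(a)], index_of[int(b)]))
                        cells.append(f"{x}/{y}")
            fh.write(
                f"{contigs[i]}\t{matrix.positions[i]}\t.\t{NUCLEOTIDES[ref]}\t"
                f"{alt_str}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path):
    """Read a VCF into (GenotypeMatrix, haplotypes or None, phase sets).

    Haplotypes are returned when every genotype is phased; phase sets is an
    (n_sites, n_individuals) int array of PS tags (-1 where absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    contigs, positions, geno_rows, hap_rows, ps_rows = [], [], [], [], []
    code_of = {n: k for k, n in enumerate(NUCLEOTIDES)}
    all_phased = True
    for var in vcf:
        codes = [code_of[a] for a in [var.REF] + [a for a in var.ALT if a != "."]]
        contigs.append(var.CHROM)
        positions.append(var.POS)
        g = np.asarray(var.genotypes, dtype=object)
        row = np.empty((len(individuals), 2), dtype=np.int8)
        for j, entry in enumerate(g):
            a, b, phased = int(entry[0]), int(entry[1]), bool(entry[2])
            row[j, 0] = codes[a] if a >= 0 else -1
            row[j, 1] = codes[b] if b >= 0 else -1
            if not phased:
                all_phased = False
        geno_rows.append(row)
        hap_rows.append(row.copy())
        try:
            ps = var.format("PS")
            ps_rows.append(
                ps[:, 0].astype(np.int64) if ps is not None else np.full(len(individuals), -1)
            )
        except Exception:
            ps_rows.append(np.full(len(individuals), -1, dtype=np.int64))
    vcf.close()
    if not positions:
        empty = GenotypeMatrix(
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty((0, len(individuals), 2), dtype=np.int8),
            individuals,
        )
        return empty, None, np.empty((0, len(individuals)), dtype=np.int64)
    geno = np.stack(geno_rows)
    matrix = GenotypeMatrix(np.array(contigs, dtype=object), np.array(positions), geno, individuals)
    haplotypes = None
    if all_phased:
        h = np.stack(hap_rows)  # (S, n, 2) phased order
        haplotypes = np.empty((2 * len(individuals), len(positions)), dtype=np.int8)
        haplotypes[0::2] = h[:, :, 0].T
        haplotypes[1::2] = h[:, :, 1].T
    return matrix, haplotypes, np.stack(ps_rows)


def write_haplotype_fasta(path, matrix: GenotypeMatrix, haplotypes: np.ndarray) -> None:
    """Two FASTA records per individual per contig over its SNP columns."""
    contigs = matrix.contigs.astype(str)
    with open(path, "w") as fh:
        for c in dict.fromkeys(contigs):
            mask = contigs == c
            for j, ind in enumerate(matrix.individuals):
                for k in (0, 1):
                    seq = "".join(NUCLEOTIDES[haplotypes[2 * j + k, mask]])
                    fh.write(f">{ind}.{k + 1}|{c}\n{seq}\n")


def read_haplotype_fasta(path, matrix: GenotypeMatrix) -> np.ndarray:
    """Rebuild the (2n, n_sites) haplotype matrix written by
    :func:`write_haplotype_fasta` (site order from ``matrix``)."""
    from Bio import SeqIO

    code_of = {n: k for k, n in enumerate(NUCLEOTIDES)}
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    contigs = matrix.contigs.astype(str)
    out = np.empty((2 * matrix.n_individuals, matrix.n_sites), dtype=np.int8)
    for c in dict.fromkeys(contigs):
        cols = np.nonzero(contigs == c)[0]
        for j, ind in enumerate(matrix.individuals):
            for k in (0, 1):
                seq = records[f"{ind}.{k + 1}|{c}"]
                out[2 * j + k, cols] = [code_of[ch] for ch in seq]
    return out


def write_sample(sample, out_dir, phased: bool = True) -> dict:
    """Write a simulator SampleSet as VCF + truth FASTA + sites TSV.

    Returns the written paths; the trio round-trips through
    :func:`read_vcf` / :func:`read_haplotype_fasta`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contig_length = int(sample.config.genome_length / sample.config.n_contigs)
    paths = {
        "vcf": out / "sample.vcf",
        "fasta": out / "haplotypes.fasta",
        "sites": out / "sites.tsv",
    }
    write_vcf(
        paths["vcf"],
        sample.genotypes,
        haplotypes=sample.haplotypes if phased else None,
        phased=phased,
        contig_length=contig_length,
    )
    write_haplotype_fasta(paths["fasta"], sample.genotypes, sample.haplotypes)
    sites = pd.DataFrame(
        {
            "contig": sample.genotypes.contigs.astype(str),
            "position": sample.genotypes.positions,
            "global_position": sample.global_positions,
        }
    )
    sites.to_csv(paths["sites"], sep="\t", index=False)
    return paths


def read_phased_blocks_vcf(path) -> list[PhasedBlock]:
    """Extract per-individual phased blocks from a PS-tagged VCF.

    Heterozygous SNPs sharing a PS tag on one contig form a block; switch
    and mismatch qualities are not stored in VCF and are set to +inf.
    """
    matrix, haplotypes, ps = read_vcf(path)
    if haplotypes is None:
        raise ValueError("VCF is not fully phased")
    contigs = matrix.contigs.astype(str)
    blocks = []
    for j, ind in enumerate(matrix.individuals):
        het = haplotypes[2 * j] != haplotypes[2 * j + 1]
        for c in dict.fromkeys(contigs):
            on_contig = (contigs == c) & het
            for tag in np.unique(ps[on_contig, j]):
                sel = on_contig & (ps[:, j] == tag)
                if not sel.any():
                    continue
                q = np.full(int(sel.sum()), np.inf)
                blocks.append(
                    PhasedBlock(
                        ind,
                        c,
                        matrix.positions[sel],
                        haplotypes[2 * j, sel],
                        haplotypes[2 * j + 1, sel],
                        q,
                        q.copy(),
                    )
                )
    return blocks
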