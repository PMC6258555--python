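"""Readers and writers: minimal VCF v4.2 (GT only), FASTA haplotypes, TSV.

The VCF dialect is biallelic SNP records with a GT subfield; positions are
1-based in the file and 0-based in memory.  Multi-allelic or non-SNP
records are skipped and counted.  FASTA haplotype headers follow the
grammar ``>sampleid|pop|ecotype|locus[|outgroup]``; alleles are written as
nucleotides using each column's REF/ALT mapping (A = ancestral/0,
G = derived/1 for simulated data).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .datatypes import GenotypeTable, HaplotypeSet, LocusHaplotypes

log = logging.getLogger("divflow")

__all__ = ["read_vcf", "write_vcf", "read_sample_metadata",
           "write_haplotypes_fasta", "read_haplotypes_fasta",
           "read_outlier_table"]


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as minimal VCF v4.2 (GT field only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for locus in pd.unique(table.sites["locus"]):
            fh.write(f"##contig=<ID={locus}>\n")
        cols = "\t".join(table.samples["id"])
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 "FORMAT\t" + cols + "\n")
        gt_codes = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for s in range(table.n_sites):
            row = table.sites.iloc[s]
            gts = "\t".join(gt_codes[int(g)] for g in
                            table.genotypes[:, s])
            fh.write(f"{row['locus']}\t{row['pos'] + 1}\t{row['id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t"
                     f"{gts}\n")


def read_vcf(path, metadata: pd.DataFrame | None = None) -> GenotypeTable:
    """Read biallelic SNP records from a VCF into a GenotypeTable.

    ``metadata`` is a sample table with columns id, population, ecotype,
    habitat; samples missing from it get empty labels.  Unsupported
    records (multi-allelic, non-SNP) are skipped with a logged count.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    geno_cols, rows = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        gt = np.asarray(var.genotype.array())
        if gt.shape[1] < 3:
            raise ValueError("non-diploid genotypes in VCF")
        alleles = gt[:, :2]
        g = alleles.sum(axis=1).astype(np.int8)
        g[(alleles < 0).any(axis=1)] = -1
        geno_cols.append(g)
        rows.append({"locus": var.CHROM, "pos": var.POS - 1,
                     "ref": var.REF, "alt": var.ALT[0],
                     "id": var.ID if var.ID not in (None, ".")
                     else f"{var.CHROM}:{var.POS - 1}"})
    if skipped:
        log.info("read_vcf: skipped %d unsupported records", skipped)
    geno = np.column_stack(geno_cols) if geno_cols else \
        np.zeros((len(sample_ids), 0), np.int8)
    sites = pd.DataFrame(rows, columns=["locus", "pos", "ref", "alt", "id"])
    samples = pd.DataFrame({"id": sample_ids})
    if metadata is not None:
        samples = samples.merge(metadata, on="id", how="left")
    for col, default in (("population", ""), ("ecotype", ""),
                         ("habitat", np.nan)):
        if col not in samples.columns:
            samples[col] = default
    return GenotypeTable(geno, samples, sites)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (columns id, population, ecotype,
    habitat)."""
    meta = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "population", "ecotype"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    return meta


def read_outlier_table(path) -> pd.DataFrame:
    """Read a per-SNP outlier-support TSV (snp_id, locus, support[, pos])."""
    tab = pd.read_csv(path, sep="\t")
    missing = {"snp_id", "locus", "support"} - set(tab.columns)
    if missing:
        raise ValueError(f"outlier table lacks columns: {sorted(missing)}")
    return tab


def _sequences(loc: LocusHaplotypes) -> np.ndarray:
    """Expand 0/1 haplotypes to nucleotide strings (A = 0, G = 1)."""
    letters = np.where(loc.haplotypes == 1, "G", "A")
    return np.array(["".join(row) for row in letters])


def write_haplotypes_fasta(hapset: HaplotypeSet, path,
                           samples: pd.DataFrame | None = None) -> None:
    """Write per-locus haplotypes to one multi-locus FASTA.

    Headers are ``sampleid|pop|ecotype|locus`` with haploid copies of one
    deme named ``<deme>_h<k>`` when no sample table is given; an attached
    outgroup is written with the ``outgroup`` tag.
    """
    records = []
    for loc in hapset:
        seqs = _sequences(loc)
        for k, seq in enumerate(seqs):
            deme = int(loc.deme[k])
            name = f"d{deme}_h{k:03d}"
            pop = f"pop{deme + 1}"
            eco = "S" if deme == 0 else "L"
            records.append(SeqRecord(
                Seq(seq), id=f"{name}|{pop}|{eco}|{loc.locus}",
                description=""))
        if loc.outgroup is not None:
            og = "".join(np.where(loc.outgroup == 1, "G", "A"))
            records.append(SeqRecord(
                Seq(og), id=f"outgroup|-|-|{loc.locus}|outgroup",
                description=""))
    SeqIO.write(records, str(path), "fasta")


def read_haplotypes_fasta(path) -> HaplotypeSet:
    """Read a multi-locus haplotype FASTA written by this package.

    Columns are re-coded to 0/1 by majority-vs-outgroup-free convention:
    at each column the allele carried by the outgroup (when present) or
    the alphabetically first allele is coded 0.  Raises on ragged
    alignments or duplicate sample-locus pairs.
    """
    per_locus: dict[str, list] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 4:
            raise ValueError(f"malformed haplotype header: {rec.id}")
        sample, pop, eco, locus = fields[:4]
        is_outgroup = len(fields) > 4 and fields[4] == "outgroup"
        per_locus.setdefault(locus, []).append(
            (sample, pop, eco, str(rec.seq), is_outgroup))
    loci = []
    for locus, entries in per_locus.items():
        lengths = {len(e[3]) for e in entries}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment at locus {locus}")
        names = [e[0] for e in entries]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate sample-locus pair at {locus}")
        ingroup = [e for e in entries if not e[4]]
        outg = [e for e in entries if e[4]]
        if len(outg) > 1:
            raise ValueError(f"multiple outgroup sequences at {locus}")
        mat = np.array([list(e[3]) for e in ingroup])
        og_seq = np.array(list(outg[0][3])) if outg else None
        seg, og_bits = [], []
        positions = []
        length = len(entries[0][3])
        for col in range(mat.shape[1]):
            column = mat[:, col]
            pool = column if og_seq is None else np.append(column,
                                                           og_seq[col])
            alleles = sorted(set(pool))
            if len(alleles) == 1:
                continue
            if len(alleles) > 2:
                raise ValueError(f"more than two alleles at {locus} "
                                 f"column {col}")
            anc = og_seq[col] if og_seq is not None else alleles[0]
            seg.append((column != anc).astype(np.uint8))
            if og_seq is not None:
                og_bits.append(np.uint8(0))
            positions.append(col)
        haps = np.array(seg).T if seg else \
            np.zeros((len(ingroup), 0), np.uint8)
        ecotypes = [e[2] for e in ingroup]
        if set(ecotypes) <= {"S", "L"}:
            deme = np.array([0 if e == "S" else 1 for e in ecotypes])
        else:
            first = ecotypes[0]
            deme = np.array([0 if e == first else 1 for e in ecotypes])
        loci.append(LocusHaplotypes(
            locus=locus, haplotypes=haps, deme=deme,
            positions=np.array(positions, int), length=length,
            outgroup=np.array(og_bits, np.uint8) if og_seq is not None
            else None))
    return HaplotypeSet(loci)
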