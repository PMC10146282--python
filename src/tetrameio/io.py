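"""File interchange: VCF readers (cyvcf2), a VCF writer for synthetic read
counts (pysam), and TSV conventions for matrices.

All pipeline intermediates are plain-text TSV/CSV so that every stage is
inspectable and diffable; VCF is supported at the boundaries (reference
genotypes in, synthetic allele-depth VCF out).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_vcf_genotypes(path: str | Path) -> pd.DataFrame:
    """Diallelic-site genotype matrix from a VCF: alt-allele counts
    (0/1/2, NaN for missing), indexed by (chrom, pos)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        rows.append(gt.sum(axis=1))
        idx.append((var.CHROM, var.POS))
    vcf.close()
    return pd.DataFrame(rows, columns=samples,
                        index=pd.MultiIndex.from_tuples(idx,
                                                        names=["chrom", "pos"]))


def read_vcf_allele_depths(path: str | Path) -> pd.DataFrame:
    """Long read-count table (chrom, pos, sample, diag_reads, total_reads)
    from a VCF with AD fields; the alternate allele is taken as the
    diagnostic allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    frames = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ad = var.format("AD")
        ad = np.maximum(ad, 0)
        frames.append(pd.DataFrame({
            "chrom": var.CHROM, "pos": var.POS, "sample": samples,
            "diag_reads": ad[:, 1], "total_reads": ad.sum(axis=1),
        }))
    vcf.close()
    return pd.concat(frames, ignore_index=True)


def write_counts_vcf(counts: pd.DataFrame, chrom_lengths: dict[str, int],
                     path: str | Path) -> None:
    """Emit a diallelic-sites VCF with AD fields from a long read-count
    table (synthetic alleles A/T; genotypes left uncalled)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths (ref, diagnostic alt)">')
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    samples = sorted(counts["sample"].unique())
    for s in samples:
        header.add_sample(s)
    wide_d = counts.pivot_table(index=["chrom", "pos"], columns="sample",
                                values="diag_reads").astype(int)
    wide_t = counts.pivot_table(index=["chrom", "pos"], columns="sample",
                                values="total_reads").astype(int)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos) in wide_d.index:
            rec = out.new_record(contig=chrom, start=int(pos) - 1,
                                 stop=int(pos), alleles=("A", "T"))
            for s in samples:
                d = int(wide_d.loc[(chrom, pos), s])
                t = int(wide_t.loc[(chrom, pos), s])
                rec.samples[s]["AD"] = (t - d, d)
            out.write(rec)


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def read_matrix(path: str | Path, index_col: str = "id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values="NA")
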