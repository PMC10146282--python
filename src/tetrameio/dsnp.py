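"""Taxon-diagnostic SNP mining via the inter-population differentiation
parameter GST.

A diallelic site is diagnostic for a taxon when GST between that taxon and
the equal-weight pool of the remaining taxa equals 1, i.e. the two
subpopulations are fixed for different alleles.  GST is computed from
Nei-style expected heterozygosities:

    GST = (HeTot - (He_Ti + He_T-i) / 2) / HeTot

with He = 1 - sum p_i^2 and the total-population allele frequency taken as
the unweighted mean of the two subpopulation frequencies (every taxon is
given the same population size).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: tolerance for testing GST == 1 (absorbs float rounding)
GST_ONE_TOL = 1e-9


def expected_het(freqs) -> float:
    """Expected heterozygosity He = 1 - sum p_i^2 of an allele-frequency
    vector (must sum to 1)."""
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    return float(1.0 - np.sum(p ** 2))


def gst(p_focal: float, p_rest: float) -> float:
    """GST between a focal taxon and the pooled rest, from their
    alternate-allele frequencies.  Returns NaN when the total population is
    monomorphic (HeTot = 0), where GST is undefined."""
    out = gst_vector(np.asarray([p_focal]), np.asarray([p_rest]))
    return float(out[0])


def gst_vector(p_focal: np.ndarray, p_rest: np.ndarray) -> np.ndarray:
    p_focal = np.asarray(p_focal, dtype=float)
    p_rest = np.asarray(p_rest, dtype=float)
    if np.any((p_focal < 0) | (p_focal > 1) | (p_rest < 0) | (p_rest > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    p_tot = (p_focal + p_rest) / 2.0
    he_tot = 2.0 * p_tot * (1.0 - p_tot)
    he_sub = (2.0 * p_focal * (1.0 - p_focal)
              + 2.0 * p_rest * (1.0 - p_rest)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (he_tot - he_sub) / he_tot
    out = np.where(he_tot == 0.0, np.nan, out)
    return out


def taxon_allele_freqs(genotypes: pd.DataFrame,
                       taxon_map: pd.Series) -> pd.DataFrame:
    """Per-taxon alternate-allele frequency at every site.

    ``genotypes`` is sites x accessions with diploid alt-allele counts
    (0/1/2, NaN missing): heterozygous accessions contribute half an allele
    (standard allele counting).  Sites where a taxon has no called
    accession get NaN for that taxon.
    """
    missing = set(genotypes.columns) - set(taxon_map.index)
    if missing:
        raise KeyError(f"accessions without taxon assignment: {sorted(missing)}")
    freqs = {}
    for taxon, accs in taxon_map.groupby(taxon_map).groups.items():
        cols = [a for a in accs if a in genotypes.columns]
        if not cols:
            raise ValueError(f"taxon {taxon!r} has no accessions in the matrix")
        freqs[taxon] = genotypes[cols].mean(axis=1, skipna=True) / 2.0
    return pd.DataFrame(freqs)


def mine_dsnps(genotypes: pd.DataFrame, taxon_map: pd.Series,
               max_missing: float = 0.20,
               tol: float = GST_ONE_TOL) -> pd.DataFrame:
    """Identify diagnostic SNPs (GST = 1, one-vs-rest per taxon).

    ``genotypes`` is indexed by (chrom, pos).  Sites with more than
    ``max_missing`` missing calls, or where any taxon is entirely missing,
    are excluded before GST.  The rest-pool frequency is the unweighted
    mean of the other taxa's frequencies.  Returns the panel (chrom, pos,
    taxon, diag_allele, gst) sorted by position.
    """
    miss_frac = genotypes.isna().mean(axis=1)
    keep = miss_frac <= max_missing
    geno = genotypes.loc[keep]
    freqs = taxon_allele_freqs(geno, taxon_map)
    complete = freqs.notna().all(axis=1)
    freqs = freqs.loc[complete]
    taxa = list(freqs.columns)

    records = []
    for taxon in taxa:
        p_f = freqs[taxon].to_numpy()
        p_r = freqs[[t for t in taxa if t != taxon]].mean(axis=1).to_numpy()
        g = gst_vector(p_f, p_r)
        hit = np.abs(g - 1.0) <= tol
        if not np.any(hit):
            continue
        idx = freqs.index[hit]
        diag = np.where(p_f[hit] > 0.5, "alt", "ref")
        for (chrom, pos), allele, gval in zip(idx, diag, g[hit]):
            records.append((chrom, pos, taxon, allele, float(gval)))
    panel = pd.DataFrame(records,
                         columns=["chrom", "pos", "taxon", "diag_allele", "gst"])
    return panel.sort_values(["chrom", "pos"], ignore_index=True)


def panel_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome x per-taxon DSNP counts with totals and percentages
    (report shape of the DSNP distribution table)."""
    tab = (panel.pivot_table(index="chrom", columns="taxon", values="pos",
                             aggfunc="count", fill_value=0)
           .astype(int))
    tab["total"] = tab.sum(axis=1)
    tab.loc["total"] = tab.sum(axis=0)
    pct = 100.0 * tab.loc["total"] / tab.loc["total", "total"]
    tab.loc["pct"] = pct.round(2)
    return tab
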