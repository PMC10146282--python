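"""Windowed ancestral-dose estimation from diagnostic-allele read counts.

Doses are called per genomic window of 20 diagnostic SNPs by a pooled
binomial likelihood: diagnostic reads summed across the window's sites are
compared with the expected diagnostic-allele fraction d / P for each dose
d in {0..P} (P = ploidy), with the sequencing error rate pushing the
boundary fractions off 0 and 1.  A call is set to missing when pooled
coverage is below ``min_reads`` or the best dose does not beat the
second-best by ``lr_threshold`` in log10 likelihood ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

WINDOW_SIZE = 20
MIN_READS = 10
LR_THRESHOLD = 1.0
DEFAULT_EPS = 0.01


def window_partition(panel: pd.DataFrame, size: int = WINDOW_SIZE,
                     min_size: int | None = None) -> pd.DataFrame:
    """Group consecutive same-taxon DSNPs into windows of ``size`` per
    chromosome.

    The terminal remainder is kept as its own window when it has at least
    ``min_size`` (default size / 2) sites, otherwise it is merged into the
    previous window.  Returns the panel with a ``window_id`` column plus,
    as attrs-free second use, call :func:`window_table` for the window
    definitions (id, chrom, taxon, index, start, end, representative
    position = mean of member positions, n_snps).
    """
    if panel.empty:
        raise ValueError("empty DSNP panel")
    if min_size is None:
        min_size = size // 2
    panel = panel.sort_values(["chrom", "pos"], kind="stable").copy()
    ids = np.empty(len(panel), dtype=object)
    for (taxon, chrom), grp in panel.groupby(["taxon", "chrom"], sort=False):
        n = len(grp)
        widx = np.arange(n) // size
        n_windows = int(widx.max()) + 1
        remainder = n - (n_windows - 1) * size
        if n_windows > 1 and remainder < min_size:
            widx[widx == n_windows - 1] = n_windows - 2
        rows = panel.index.get_indexer(grp.index)
        for r, w in zip(rows, widx):
            ids[r] = f"{taxon[:3]}_{chrom}_w{w:03d}"
    panel["window_id"] = ids
    return panel.reset_index(drop=True)


def window_table(panel_with_windows: pd.DataFrame) -> pd.DataFrame:
    """Window definitions from a partitioned panel."""
    agg = (panel_with_windows.groupby("window_id", sort=False)
           .agg(chrom=("chrom", "first"), taxon=("taxon", "first"),
                start=("pos", "min"), end=("pos", "max"),
                rep_pos=("pos", "mean"), n_snps=("pos", "count")))
    agg = agg.sort_values(["taxon", "chrom", "start"])
    agg["widx"] = agg.groupby(["taxon", "chrom"], sort=False).cumcount()
    return agg.reset_index()


def window_dose_likelihood(diag_reads: int, total_reads: int, ploidy: int = 4,
                           eps: float = DEFAULT_EPS,
                           min_reads: int = MIN_READS,
                           lr_threshold: float = LR_THRESHOLD,
                           ) -> tuple[float, np.ndarray]:
    """Dose call and per-dose log-likelihoods for pooled window reads.

    Returns ``(call, loglik)`` where ``call`` is NaN if coverage or the
    log10 likelihood-ratio criterion fails.
    """
    if diag_reads > total_reads:
        raise ValueError("diagnostic reads exceed total reads")
    calls, logliks = _call_vectorized(
        np.asarray([diag_reads]), np.asarray([total_reads]),
        ploidy, eps, min_reads, lr_threshold)
    return float(calls[0]), logliks[0]


def _call_vectorized(a: np.ndarray, t: np.ndarray, ploidy: int, eps: float,
                     min_reads: int, lr_threshold: float,
                     ) -> tuple[np.ndarray, np.ndarray]:
    doses = np.arange(ploidy + 1)
    f = np.clip(doses / ploidy, eps, 1.0 - eps)
    # loglik[i, d] = log Binom(a_i | t_i, f_d)
    loglik = stats.binom.logpmf(a[:, None], t[:, None], f[None, :])
    order = np.argsort(loglik, axis=1)
    best = order[:, -1]
    second = order[:, -2]
    rows = np.arange(len(a))
    lr10 = (loglik[rows, best] - loglik[rows, second]) / np.log(10.0)
    calls = best.astype(float)
    calls[(t < min_reads) | (lr10 < lr_threshold)] = np.nan
    return calls, loglik


def call_hybrid_doses(counts: pd.DataFrame, panel_with_windows: pd.DataFrame,
                      taxon: str, ploidy: int = 4, eps: float = DEFAULT_EPS,
                      min_reads: int = MIN_READS,
                      lr_threshold: float = LR_THRESHOLD) -> pd.DataFrame:
    """Dose matrix (samples x windows) for one tracked ancestor.

    ``counts`` is the long read-count table (chrom, pos, sample,
    diag_reads, total_reads); reads are pooled across each window's member
    DSNPs before the likelihood call.  Windows with zero covered sites for
    a sample give a missing cell.
    """
    key = panel_with_windows.loc[panel_with_windows["taxon"] == taxon,
                                 ["chrom", "pos", "window_id"]]
    if key.empty:
        raise ValueError(f"no windows for taxon {taxon!r}")
    merged = counts.merge(key, on=["chrom", "pos"], how="inner")
    pooled = (merged.groupby(["sample", "window_id"], sort=False)
              .agg(a=("diag_reads", "sum"), t=("total_reads", "sum"))
              .reset_index())
    calls, _ = _call_vectorized(pooled["a"].to_numpy(), pooled["t"].to_numpy(),
                                ploidy, eps, min_reads, lr_threshold)
    pooled["dose"] = calls
    mat = pooled.pivot(index="sample", columns="window_id", values="dose")
    # physical column order (chromosome, then start position)
    order = (key.groupby("window_id")
             .agg(chrom=("chrom", "first"), start=("pos", "min"))
             .sort_values(["chrom", "start"]).index)
    cols = [w for w in order if w in mat.columns]
    return mat[cols]
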