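"""Gamete inference from hybrid dose matrices and matrix cleaning.

Because each tracked ancestor (C. medica for the ovule parent,
P. trifoliata for the pollen parent) is carried by exactly one parent, the
hybrid's dose of that ancestor *is* the gamete's dose: inference is a
verbatim copy with doses above 2 flagged as inconsistent.  Cleaning then
replaces singleton calls with missing data, applies the missing-data
filters (windows first, then individuals), and removes individuals with an
aberrant number of apparent recombinations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_WINDOW_MISSING = 0.15
MAX_INDIVIDUAL_MISSING = 0.20


def infer_gametes(hybrid_doses: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Gamete dose matrix (0/1/2 or missing) from a hybrid dose matrix.

    Hybrid doses of 3 or 4 are impossible under the cross design (the other
    parent contributes zero of the tracked ancestor); they are set missing
    and counted.  Returns ``(matrix, n_inconsistent)``.
    """
    vals = hybrid_doses.to_numpy(dtype=float)
    bad = vals > 2
    n_inconsistent = int(np.nansum(bad))
    out = vals.copy()
    out[bad] = np.nan
    return pd.DataFrame(out, index=hybrid_doses.index,
                        columns=hybrid_doses.columns), n_inconsistent


def _chrom_blocks(columns, windows: pd.DataFrame) -> list[np.ndarray]:
    """Column indices grouped by chromosome, in physical order."""
    info = windows.set_index("window_id").loc[list(columns)]
    blocks = []
    for chrom in info["chrom"].unique():
        mask = (info["chrom"] == chrom).to_numpy()
        idx = np.where(mask)[0]
        order = np.argsort(info.loc[mask, "rep_pos"].to_numpy(), kind="stable")
        blocks.append(idx[order])
    return blocks


def remove_singletons(matrix: pd.DataFrame,
                      windows: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace singleton calls with missing data.

    A singleton is an interior call that differs from both of its nearest
    non-missing neighbours on the same chromosome while those neighbours
    agree with each other (an isolated apparent double recombinant, most
    likely a dosing error).  Chromosome ends are left untouched.
    """
    vals = matrix.to_numpy(dtype=float).copy()
    n_removed = 0
    for cols in _chrom_blocks(matrix.columns, windows):
        block = vals[:, cols]
        for i in range(block.shape[0]):
            row = block[i]
            obs = np.where(~np.isnan(row))[0]
            if len(obs) < 3:
                continue
            v = row[obs]
            single = (v[1:-1] != v[:-2]) & (v[:-2] == v[2:])
            hits = obs[1:-1][single]
            row[hits] = np.nan
            n_removed += len(hits)
        vals[:, cols] = block
    return pd.DataFrame(vals, index=matrix.index,
                        columns=matrix.columns), n_removed


def filter_matrix(matrix: pd.DataFrame,
                  max_window_missing: float = MAX_WINDOW_MISSING,
                  max_individual_missing: float = MAX_INDIVIDUAL_MISSING,
                  ) -> tuple[pd.DataFrame, dict]:
    """Drop windows then individuals exceeding their missing-data thresholds
    (windows with > 15% missing calls, individuals with > 20%)."""
    win_missing = matrix.isna().mean(axis=0)
    keep_w = win_missing <= max_window_missing
    out = matrix.loc[:, keep_w]
    ind_missing = out.isna().mean(axis=1)
    keep_i = ind_missing <= max_individual_missing
    out = out.loc[keep_i]
    if out.empty:
        raise ValueError("missing-data filters removed every window/individual")
    report = {
        "windows_dropped": [str(c) for c in matrix.columns[~keep_w]],
        "individuals_dropped": [str(i) for i in matrix.index[~keep_i]],
    }
    return out, report


def transition_counts(matrix: pd.DataFrame,
                      windows: pd.DataFrame) -> pd.Series:
    """Per-individual apparent-recombination load: sum of |dose change|
    between consecutive non-missing windows within each chromosome."""
    vals = matrix.to_numpy(dtype=float)
    total = np.zeros(len(matrix))
    for cols in _chrom_blocks(matrix.columns, windows):
        block = vals[:, cols]
        for i in range(block.shape[0]):
            v = block[i][~np.isnan(block[i])]
            if len(v) > 1:
                total[i] += np.abs(np.diff(v)).sum()
    return pd.Series(total, index=matrix.index, name="transitions")


def drop_aberrant_individuals(matrix: pd.DataFrame, windows: pd.DataFrame,
                              k_iqr: float = 3.0,
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove individuals whose recombination load exceeds
    median + ``k_iqr`` x IQR of the cohort (robust automatic version of
    inspecting the global recombination distribution).

    Requires at least 10 individuals.  Returns the filtered matrix and a
    per-individual report (transitions, cutoff, dropped flag).
    """
    if len(matrix) < 10:
        raise ValueError("need >= 10 individuals to calibrate the cutoff")
    t = transition_counts(matrix, windows)
    q1, med, q3 = np.percentile(t, [25, 50, 75])
    cutoff = med + k_iqr * (q3 - q1)
    dropped = t > cutoff
    report = pd.DataFrame({"transitions": t, "cutoff": cutoff,
                           "dropped": dropped})
    return matrix.loc[~dropped], report
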