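"""Recombination fractions, Kosambi genetic maps, Marey-map recombination
rates, and dissimilarity-based factorial coordinates.

The recombination-fraction estimator for diploid-gamete dose data is

    r_hat = min(0.5, sum_g |d_i(g) - d_j(g)| / (2 N))

each unit of dose change between two loci evidencing one crossover among
the gamete's two chromatids.  It is exact for single-crossover intervals
and undercounts double crossovers, which is acceptable at the 20-DSNP
window resolution.  Marker order is taken from the physical assembly; the
Kosambi function (incomplete interference) converts adjacent recombination
fractions into map distances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

RF_THRESHOLD = 0.15
LOESS_SPAN = 0.15
MIN_RF_OVERLAP = 20


# ---------------------------------------------------------------------------
# recombination fractions
# ---------------------------------------------------------------------------

def rf_matrix(matrix: pd.DataFrame,
              min_overlap: int = MIN_RF_OVERLAP) -> pd.DataFrame:
    """All-pairs recombination fractions between window columns.

    Entries with fewer than ``min_overlap`` jointly non-missing gametes are
    NaN.  Computed from dose-class indicator products, so it stays fast for
    thousands of windows.
    """
    vals = matrix.to_numpy(dtype=float)
    ind = {d: np.nan_to_num((vals == d).astype(float)) for d in (0, 1, 2)}
    m = (~np.isnan(vals)).astype(float)
    n_shared = m.T @ m
    # sum_g |d_i - d_j| expanded over dose-class indicator cross-products
    absdiff = 2.0 * (ind[0].T @ ind[2] + ind[2].T @ ind[0]) \
        + (ind[0].T @ ind[1] + ind[1].T @ ind[0]
           + ind[1].T @ ind[2] + ind[2].T @ ind[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = np.minimum(0.5, absdiff / (2.0 * n_shared))
    rf[n_shared < min_overlap] = np.nan
    np.fill_diagonal(rf, 0.0)
    return pd.DataFrame(rf, index=matrix.columns, columns=matrix.columns)


def pairwise_rf(matrix: pd.DataFrame, window_i: str, window_j: str,
                min_overlap: int = MIN_RF_OVERLAP) -> float:
    """Recombination fraction between two windows (NaN if the jointly
    non-missing overlap is below ``min_overlap``)."""
    a = matrix[window_i].to_numpy(dtype=float)
    b = matrix[window_j].to_numpy(dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < min_overlap:
        return float("nan")
    return float(min(0.5, np.abs(a[ok] - b[ok]).sum() / (2.0 * ok.sum())))


def linkage_groups(rf: pd.DataFrame,
                   threshold: float = RF_THRESHOLD) -> pd.Series:
    """Single-linkage grouping: windows joined whenever rf < threshold.

    Returns a window -> group-label series; labels are ordered by first
    appearance along the input columns.
    """
    vals = rf.to_numpy(dtype=float)
    adj = csr_matrix(np.nan_to_num(vals, nan=1.0) < threshold)
    _, labels = connected_components(adj, directed=False)
    # relabel in order of first appearance
    seen: dict[int, int] = {}
    out = []
    for lab in labels:
        seen.setdefault(lab, len(seen) + 1)
        out.append(f"LG{seen[lab]}")
    return pd.Series(out, index=rf.index, name="linkage_group")


# ---------------------------------------------------------------------------
# Kosambi map
# ---------------------------------------------------------------------------

def kosambi_cm(r: float) -> float:
    """Kosambi map distance in cM: 25 ln((1 + 2r) / (1 - 2r)), 0 <= r < 0.5."""
    r = float(r)
    if not 0.0 <= r < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def build_map(matrix: pd.DataFrame, windows: pd.DataFrame,
              min_overlap: int = MIN_RF_OVERLAP,
              max_interval_cm: float | None = None) -> pd.DataFrame:
    """Genetic map on fixed physical order: per chromosome, adjacent-window
    recombination fractions accumulated through the Kosambi function.

    Intervals with missing rf are skipped (zero length, with a warning);
    an adjacent rf at the 0.5 cap is likewise skipped unless
    ``max_interval_cm`` supplies a finite interval to assign.  Returns one
    row per mapped window: chrom, window_id, bp (representative position),
    cm (cumulative).
    """
    info = windows.set_index("window_id")
    rows = []
    for chrom in info.loc[[c for c in matrix.columns if c in info.index],
                          "chrom"].unique():
        wins = [w for w in matrix.columns
                if w in info.index and info.loc[w, "chrom"] == chrom]
        wins.sort(key=lambda w: info.loc[w, "rep_pos"])
        cm = 0.0
        rows.append((chrom, wins[0], float(info.loc[wins[0], "rep_pos"]), 0.0))
        for prev, cur in zip(wins[:-1], wins[1:]):
            r = pairwise_rf(matrix, prev, cur, min_overlap)
            if np.isnan(r):
                warnings.warn(f"missing rf for {prev}..{cur}; "
                              "zero-length interval assigned")
                d = 0.0
            elif r >= 0.5:
                if max_interval_cm is None:
                    warnings.warn(f"rf at cap for {prev}..{cur}; "
                                  "zero-length interval assigned")
                    d = 0.0
                else:
                    d = float(max_interval_cm)
            else:
                d = kosambi_cm(r)
            cm += d
            rows.append((chrom, cur, float(info.loc[cur, "rep_pos"]), cm))
    return pd.DataFrame(rows, columns=["chrom", "window_id", "bp", "cm"])


def map_summary(genetic_map: pd.DataFrame) -> pd.DataFrame:
    """Per-linkage-group marker counts and map lengths, with a total row."""
    grp = genetic_map.groupby("chrom")
    out = pd.DataFrame({"n_markers": grp.size(), "length_cm": grp["cm"].max()})
    out.loc["total"] = [out["n_markers"].sum(), out["length_cm"].sum()]
    out["n_markers"] = out["n_markers"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Marey map
# ---------------------------------------------------------------------------

def marey_rate(genetic_map: pd.DataFrame, span: float = LOESS_SPAN,
               min_markers: int = 10, min_points: int = 4) -> pd.DataFrame:
    """Local recombination rate (cM/Mb) along each chromosome.

    The Marey curve (cM against bp) is smoothed by local linear regression
    with tricube weights over a ``span`` fraction of the chromosome's
    markers (at least ``min_points``); the local slope at each marker is
    the rate, negative slopes clipped to 0.
    """
    frames = []
    for chrom, grp in genetic_map.groupby("chrom"):
        grp = grp.sort_values("bp")
        x = grp["bp"].to_numpy(dtype=float)
        y = grp["cm"].to_numpy(dtype=float)
        n = len(grp)
        if n < min_markers:
            raise ValueError(f"{chrom}: {n} markers; need >= {min_markers}")
        if np.ptp(x) == 0:
            raise ValueError(f"{chrom}: degenerate physical positions")
        k = max(min_points, int(np.ceil(span * n)))
        rates = np.empty(n)
        for i in range(n):
            d = np.abs(x - x[i])
            near = np.argsort(d, kind="stable")[:k]
            dmax = d[near].max()
            w = (1.0 - (d[near] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(k)
            xw, yw = x[near], y[near]
            wsum = w.sum()
            xm = np.sum(w * xw) / wsum
            ym = np.sum(w * yw) / wsum
            sxx = np.sum(w * (xw - xm) ** 2)
            slope = np.sum(w * (xw - xm) * (yw - ym)) / sxx if sxx > 0 else 0.0
            rates[i] = max(0.0, slope) * 1e6  # cM/bp -> cM/Mb
        frames.append(pd.DataFrame({"chrom": chrom,
                                    "window_id": grp["window_id"],
                                    "bp": x, "cm": y, "rate_cm_per_mb": rates}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# dissimilarity and factorial coordinates
# ---------------------------------------------------------------------------

def manhattan_dissimilarity(xi, xj) -> float:
    """Mean absolute difference over jointly non-missing loci (NaN if no
    locus is shared)."""
    a = np.asarray(xi, dtype=float)
    b = np.asarray(xj, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not ok.any():
        return float("nan")
    return float(np.abs(a[ok] - b[ok]).mean())


def dissimilarity_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Manhattan dissimilarity between individuals (rows)."""
    vals = matrix.to_numpy(dtype=float)
    n = len(vals)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(vals[i] - vals[i + 1:])
        d[i, i + 1:] = np.nanmean(diff, axis=1)
    d = d + d.T
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def factorial_coordinates(d: pd.DataFrame,
                          k: int = 3) -> tuple[pd.DataFrame, pd.Series]:
    """Principal coordinates (classical MDS) of a symmetric dissimilarity
    matrix: returns the first ``k`` axes and the proportion of variance of
    each axis (relative to the positive eigenvalues)."""
    vals = d.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T,
                                                         atol=1e-8):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    dm = DistanceMatrix(vals, ids=[str(i) for i in d.index])
    res = _skbio_pcoa(dm, number_of_dimensions=min(k, len(d) - 1))
    coords = res.samples.iloc[:, :k].copy()
    coords.index = d.index
    coords.columns = [f"axis{i + 1}" for i in range(coords.shape[1])]
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 0].sum()
    pct = pd.Series(100.0 * np.maximum(eig[:coords.shape[1]], 0.0)
                    / (pos if pos > 0 else 1.0),
                    index=coords.columns, name="pct_variance")
    return coords, pct
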