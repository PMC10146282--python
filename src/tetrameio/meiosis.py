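"""Meiotic-behavior statistics of a diploid gamete population.

For a duplex locus A1A1A2A2 of a doubled diploid, without double reduction,
the diploid gametes fall in three classes with probabilities governed by
the tetrasomic parameter tau (= 1 - PP, the proportion of gametes from
random pairing):

    P(A1A1) = tau / 6,   P(A2A2) = tau / 6,   P(A1A2) = 1 - tau / 3

In dose terms for the tracked ancestor: dose 2, dose 0 and dose 1.  tau is
estimated per centromeric marker by maximizing the multinomial likelihood
L(tau) = C (tau/6)^(x1+x2) (1 - tau/3)^x3 over a grid from 0 to 1 (step
0.005), and PP = 1 - tau_hat.  Parental heterozygosity restitution (PHR)
is the fraction of gametes with the heterozygous configuration (dose 1).
Deviation from the fully tetrasomic expectation (1/6, 1/6, 4/6) is tested
per window by a chi-square test with FDR-adjusted q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TAU_GRID_STEP = 0.005
Q_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# PHR
# ---------------------------------------------------------------------------

def phr(column: pd.Series | np.ndarray) -> float:
    """Parental heterozygosity restitution of one window: fraction of
    non-missing gametes with dose 1.  NaN when every call is missing."""
    v = np.asarray(column, dtype=float)
    n = np.sum(~np.isnan(v))
    if n == 0:
        return float("nan")
    return float(np.nansum(v == 1) / n)


def phr_by_window(matrix: pd.DataFrame) -> pd.Series:
    vals = matrix.to_numpy(dtype=float)
    n = np.sum(~np.isnan(vals), axis=0)
    het = np.nansum(vals == 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, het / n, np.nan)
    return pd.Series(out, index=matrix.columns, name="phr")


def phr_by_chromosome(matrix: pd.DataFrame,
                      windows: pd.DataFrame) -> pd.Series:
    """Chromosome PHR = unweighted mean over its windows."""
    w = phr_by_window(matrix)
    chrom = windows.set_index("window_id")["chrom"].reindex(w.index)
    return w.groupby(chrom).mean().rename("phr")


# ---------------------------------------------------------------------------
# preferential pairing
# ---------------------------------------------------------------------------

def tetrasomic_probs(tau: float) -> tuple[float, float, float]:
    """Gamete class probabilities (P(A1A1), P(A2A2), P(A1A2)) for a duplex
    centromeric marker at tetrasomic parameter tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    # (6 - 2 tau) / 6 == 1 - tau/3, but exact at the tau = 1 endpoint (4/6)
    return (tau / 6.0, tau / 6.0, (6.0 - 2.0 * tau) / 6.0)


def class_counts(column: pd.Series | np.ndarray) -> tuple[int, int, int]:
    """Observed gamete class counts (x1 = dose 2, x2 = dose 0, x3 = dose 1)
    at one window."""
    v = np.asarray(column, dtype=float)
    return (int(np.nansum(v == 2)), int(np.nansum(v == 0)),
            int(np.nansum(v == 1)))


def _grid_loglik(s: np.ndarray, x3: np.ndarray,
                 step: float) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood over the tau grid for homozygote counts ``s`` =
    x1 + x2 and heterozygote counts ``x3`` (combinatory constant dropped).
    Returns (grid, loglik[case, grid])."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    grid[-1] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_hom = np.log(grid / 6.0)        # -inf at tau = 0
        log_het = np.log(1.0 - grid / 3.0)
    s = np.asarray(s, dtype=float)[:, None]
    x3 = np.asarray(x3, dtype=float)[:, None]
    with np.errstate(invalid="ignore"):  # 0 * -inf at the tau = 0 endpoint
        ll = np.where(s > 0, s * log_hom[None, :], 0.0) \
            + x3 * log_het[None, :]
    return grid, ll


def estimate_tau(x1: int, x2: int, x3: int,
                 step: float = TAU_GRID_STEP) -> tuple[float, float]:
    """Maximum-likelihood tau over the grid [0, 1] (ties broken toward the
    smaller tau); returns (tau_hat, PP = 1 - tau_hat)."""
    if x1 < 0 or x2 < 0 or x3 < 0 or x1 + x2 + x3 == 0:
        raise ValueError("class counts must be non-negative with N > 0")
    tau = estimate_tau_vector(np.asarray([x1 + x2]), np.asarray([x3]), step)[0]
    return float(tau), float(1.0 - tau)


def estimate_tau_vector(s: np.ndarray, x3: np.ndarray,
                        step: float = TAU_GRID_STEP) -> np.ndarray:
    """Vectorized grid-search tau for homozygote totals ``s`` and
    heterozygote counts ``x3``."""
    grid, ll = _grid_loglik(s, x3, step)
    return grid[np.argmax(ll, axis=1)]  # argmax takes the first (smallest) tie


def pp_per_chromosome(matrix: pd.DataFrame, windows: pd.DataFrame,
                      centromeres: dict[str, float] | pd.DataFrame,
                      n_markers: int = 3,
                      step: float = TAU_GRID_STEP) -> pd.DataFrame:
    """Preferential pairing per chromosome from centromeric markers.

    For each chromosome the window nearest the centromere midpoint and its
    two nearest flanking windows are used (``n_markers`` total); tau is
    estimated per marker and the chromosome PP is the mean of the marker
    PPs.  Returns one row per marker with the chromosome mean attached.
    """
    if isinstance(centromeres, pd.DataFrame):
        centromeres = dict(zip(centromeres["chrom"], centromeres["centromere"]))
    info = windows.set_index("window_id")
    present = [w for w in matrix.columns if w in info.index]
    rows = []
    for chrom, cen in centromeres.items():
        wins = [w for w in present if info.loc[w, "chrom"] == chrom]
        if len(wins) < n_markers:
            raise ValueError(
                f"chromosome {chrom} has {len(wins)} windows; "
                f"need >= {n_markers} for the centromeric PP estimate")
        pos = np.array([info.loc[w, "rep_pos"] for w in wins], dtype=float)
        order = np.argsort(pos, kind="stable")
        pos, wins = pos[order], [wins[i] for i in order]
        nearest = int(np.argmin(np.abs(pos - cen)))
        chosen = {nearest}
        lo, hi = nearest - 1, nearest + 1
        while len(chosen) < n_markers:
            if lo >= 0 and (hi >= len(wins)
                            or abs(pos[lo] - cen) <= abs(pos[hi] - cen)):
                chosen.add(lo)
                lo -= 1
            else:
                chosen.add(hi)
                hi += 1
        for i in sorted(chosen):
            x1, x2, x3 = class_counts(matrix[wins[i]])
            tau_hat, pp = estimate_tau(x1, x2, x3, step)
            rows.append((chrom, wins[i], float(pos[i]), x1, x2, x3,
                         tau_hat, pp))
    out = pd.DataFrame(rows, columns=["chrom", "window_id", "rep_pos",
                                      "x1", "x2", "x3", "tau_hat", "pp"])
    out["chrom_pp"] = out.groupby("chrom")["pp"].transform("mean")
    return out


# ---------------------------------------------------------------------------
# deviation from tetrasomic segregation
# ---------------------------------------------------------------------------

def storey_qvalues(pvals: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam)) if m else 1.0
    pi0 = max(pi0, 1.0 / m) if m else 1.0
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, pi0 * p[i] * m / (rank + 1))
        q[i] = prev
    return q


def tetrasomic_deviation_scan(matrix: pd.DataFrame,
                              q_threshold: float = Q_THRESHOLD,
                              min_n: int = 20,
                              fdr_method: str = "bh") -> pd.DataFrame:
    """Chi-square test of each window against the fully tetrasomic
    expectation (N/6, N/6, 4N/6), df = 2, with FDR q-values over all
    tested windows (``fdr_method`` 'bh' or 'storey').

    Windows with N < ``min_n`` are still tested but flagged ``low_n``.
    Returns per-window statistics sorted as the input columns.
    """
    rows = []
    for w in matrix.columns:
        x1, x2, x3 = class_counts(matrix[w])
        n = x1 + x2 + x3
        if n == 0:
            continue
        expected = np.array([n / 6.0, n / 6.0, 4.0 * n / 6.0])
        chi2 = float(np.sum((np.array([x1, x2, x3]) - expected) ** 2
                            / expected))
        p = float(stats.chi2.sf(chi2, df=2))
        rows.append((w, n, x1, x2, x3, chi2, p, n < min_n))
    out = pd.DataFrame(rows, columns=["window_id", "n", "x1", "x2", "x3",
                                      "chi2", "p", "low_n"])
    if out.empty:
        return out.assign(q=[], neglog10_q=[], significant=[])
    if fdr_method == "bh":
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    elif fdr_method == "storey":
        out["q"] = storey_qvalues(out["p"].to_numpy())
    else:
        raise ValueError(f"unknown FDR method {fdr_method!r}")
    with np.errstate(divide="ignore"):
        out["neglog10_q"] = -np.log10(out["q"])
    out["significant"] = out["q"] < q_threshold
    return out


def deviation_summary(scan: pd.DataFrame,
                      windows: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome summary of the segregation scan: window count, mean
    -log10(q), number and percentage significant."""
    chrom = windows.set_index("window_id")["chrom"]
    s = scan.assign(chrom=scan["window_id"].map(chrom))
    grp = s.groupby("chrom")
    out = pd.DataFrame({
        "n_windows": grp.size(),
        "mean_neglog10_q": grp["neglog10_q"].mean(),
        "n_significant": grp["significant"].sum(),
    })
    out["pct_significant"] = 100.0 * out["n_significant"] / out["n_windows"]
    total = pd.DataFrame({
        "n_windows": [len(s)],
        "mean_neglog10_q": [s["neglog10_q"].mean()],
        "n_significant": [s["significant"].sum()],
        "pct_significant": [100.0 * s["significant"].mean()],
    }, index=["total"])
    return pd.concat([out, total])
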