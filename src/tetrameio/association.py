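"""Dose-phenotype association and candidate-gene inheritance tabulation.

The association scan fits, per window and trait, the general linear model
phenotype ~ intercept + dose with additive 0/1/2 dose coding and reports
the F-test p-value (for a single regressor, F = t^2 and the p-values
coincide).  Candidate-gene inheritance maps gene intervals onto the
windows that cover them and tabulates the percentage of hybrids carrying
zero, one, or two doses of the donor ancestor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

P_THRESHOLD = 0.01


def glm_scan(doses: pd.DataFrame, phenotypes: pd.DataFrame,
             windows: pd.DataFrame | None = None,
             p_threshold: float = P_THRESHOLD) -> pd.DataFrame:
    """Per-window, per-trait linear-model association scan.

    ``doses`` is individuals x windows (0/1/2 or missing), ``phenotypes``
    individuals x traits; rows are aligned on their shared ids (mismatched
    ids are an error).  Windows with fewer than two distinct dose classes
    among phenotyped individuals are skipped.  Returns a tidy table with
    effect (slope), F, p, -log10(p), per-class counts, and a significance
    flag at ``p_threshold``.
    """
    shared = doses.index.intersection(phenotypes.index)
    if len(shared) == 0:
        raise ValueError("no shared individuals between doses and phenotypes")
    d = doses.loc[shared]
    ph = phenotypes.loc[shared]
    rep = None
    if windows is not None:
        rep = windows.set_index("window_id")["rep_pos"]
    rows = []
    for trait in ph.columns:
        y_all = ph[trait].to_numpy(dtype=float)
        for w in d.columns:
            x = d[w].to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~np.isnan(y_all)
            x_ok, y_ok = x[ok], y_all[ok]
            classes = np.unique(x_ok)
            if len(classes) < 2 or len(x_ok) < 3:
                continue
            res = stats.linregress(x_ok, y_ok)
            f_stat = res.rvalue ** 2 * (len(x_ok) - 2) \
                / max(1e-300, 1.0 - res.rvalue ** 2)
            counts = {c: int(np.sum(x_ok == c)) for c in (0.0, 1.0, 2.0)}
            rows.append((trait, w,
                         float(rep[w]) if rep is not None and w in rep.index
                         else np.nan,
                         float(res.slope), float(f_stat), float(res.pvalue),
                         float(-np.log10(max(res.pvalue, 1e-300))),
                         counts[0.0], counts[1.0], counts[2.0],
                         bool(res.pvalue < p_threshold)))
    return pd.DataFrame(rows, columns=["trait", "window_id", "rep_pos",
                                       "effect", "F", "p", "neglog10_p",
                                       "n0", "n1", "n2", "significant"])


def gene_inheritance(doses: pd.DataFrame, genes: pd.DataFrame,
                     windows: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Donor-ancestor dose inheritance at candidate-gene intervals.

    ``genes`` columns: gene, trait, chrom, start, end.  Each gene is
    assigned the windows whose [start, end] span overlaps it; a hybrid's
    dose at the gene is the majority dose across those windows (missing or
    tied -> undetermined).  Returns per-gene percentage rows (dose 0 / 1 /
    2 / undetermined) and the overall fraction of hybrids carrying at
    least one dose at *all* supplied genes.
    """
    info = windows.set_index("window_id")
    rows = []
    per_gene_dose = {}
    for _, g in genes.iterrows():
        overlap = [w for w in doses.columns if w in info.index
                   and info.loc[w, "chrom"] == g["chrom"]
                   and info.loc[w, "start"] <= g["end"]
                   and info.loc[w, "end"] >= g["start"]]
        if not overlap:
            warnings.warn(f"gene {g['gene']} overlaps no covered window; "
                          "undetermined for all hybrids")
            calls = pd.Series(np.nan, index=doses.index)
        else:
            sub = doses[overlap]

            def majority(row: pd.Series) -> float:
                v = row.dropna()
                if v.empty:
                    return np.nan
                counts = v.value_counts()
                top = counts[counts == counts.max()]
                return float(top.index[0]) if len(top) == 1 else np.nan

            calls = sub.apply(majority, axis=1)
        per_gene_dose[g["gene"]] = calls
        n = len(calls)
        pct = {d: 100.0 * float((calls == d).sum()) / n for d in (0, 1, 2)}
        undet = 100.0 * float(calls.isna().sum()) / n
        rows.append((g["gene"], g.get("trait", ""), g["chrom"],
                     int(g["start"]), int(g["end"]),
                     pct[0], pct[1], pct[2], undet))
    table = pd.DataFrame(rows, columns=["gene", "trait", "chrom", "start",
                                        "end", "pct_dose0", "pct_dose1",
                                        "pct_dose2", "pct_undetermined"])
    dose_df = pd.DataFrame(per_gene_dose)
    at_least_one_everywhere = float((dose_df >= 1).all(axis=1).mean()) \
        if not dose_df.empty else float("nan")
    return table, at_least_one_everywhere
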