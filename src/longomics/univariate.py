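"""Univariate screening and over-representation analysis.

Per-timepoint two-tailed t-tests of genotype, per-animal log2 fold changes
against the wild-type mean (input to the network stage), and Fisher-exact
term enrichment with Benjamini-Hochberg FDR against the all-detected
background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DIFFERENTIAL_COLUMNS = [
    "analyte_id", "block", "timepoint", "mean_wt", "mean_mut",
    "t", "df", "p", "direction", "associated", "tested",
]


def t_test_by_genotype(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    timepoint: str,
    alpha: float = 0.05,
    block: str = "",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test of MUT vs WT per analyte at one timepoint.

    The classical pooled equal-variance (Student) test by default; set
    ``equal_var=False`` for Welch. Missing values are dropped per analyte;
    analytes with fewer than 2 observed values in either group are reported
    with ``tested=False`` rather than a fabricated p-value. ``direction``
    follows the sign of (MUT mean - WT mean) and ``associated`` flags
    uncorrected p < ``alpha``.
    """
    if timepoint not in set(metadata["timepoint"]):
        raise ValueError(f"timepoint {timepoint!r} absent from metadata")
    meta = metadata[metadata["timepoint"] == timepoint]
    wt = matrix.loc[meta.index[meta["genotype"] == "WT"]]
    mut = matrix.loc[meta.index[meta["genotype"] == "MUT"]]
    rows = []
    for analyte in matrix.columns:
        a = wt[analyte].dropna().to_numpy()
        b = mut[analyte].dropna().to_numpy()
        mean_wt = a.mean() if a.size else np.nan
        mean_mut = b.mean() if b.size else np.nan
        if a.size < 2 or b.size < 2:
            rows.append((analyte, block, timepoint, mean_wt, mean_mut,
                         np.nan, np.nan, np.nan, "", False, False))
            continue
        t, p = stats.ttest_ind(b, a, equal_var=equal_var)
        df = a.size + b.size - 2 if equal_var else np.nan
        direction = "up" if mean_mut - mean_wt > 0 else "down"
        rows.append((analyte, block, timepoint, mean_wt, mean_mut,
                     float(t), df, float(p), direction, bool(p < alpha), True))
    return pd.DataFrame(rows, columns=DIFFERENTIAL_COLUMNS)


def differential_all_timepoints(
    dataset, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """Run :func:`t_test_by_genotype` for every block and timepoint."""
    tables = []
    for tp in dataset.samples["timepoint"].unique():
        for name, X in dataset.blocks.items():
            tables.append(
                t_test_by_genotype(X, dataset.samples, tp, alpha=alpha,
                                   block=name, equal_var=equal_var)
            )
    return pd.concat(tables, ignore_index=True)


def log2fc_vs_wt_mean(
    matrix: pd.DataFrame, metadata: pd.DataFrame, timepoint: str
) -> pd.DataFrame:
    """Per-MUT-animal log2 fold change against the WT mean at one timepoint.

    On log2-scale input, subtracting the WT mean is the fold change relative
    to the WT geometric mean: a MUT abundance double that mean maps to +1.
    """
    if timepoint not in set(metadata["timepoint"]):
        raise ValueError(f"timepoint {timepoint!r} absent from metadata")
    meta = metadata[metadata["timepoint"] == timepoint]
    wt_idx = meta.index[meta["genotype"] == "WT"]
    mut_idx = meta.index[meta["genotype"] == "MUT"]
    if len(wt_idx) == 0:
        raise ValueError(f"no WT samples at timepoint {timepoint!r}")
    n_wt_obs = matrix.loc[wt_idx].notna().sum(axis=0)
    if (n_wt_obs == 0).any():
        bad = list(matrix.columns[n_wt_obs == 0])
        raise ValueError(f"analytes with no observed WT values at {timepoint!r}: {bad}")
    if len(mut_idx) == 0:
        log.warning("no MUT samples at timepoint %s; empty fold-change matrix", timepoint)
        return matrix.iloc[0:0]
    wt_mean = matrix.loc[wt_idx].mean(axis=0, skipna=True)
    return matrix.loc[mut_idx] - wt_mean


def fisher_enrichment(
    foreground, annotation_map: pd.DataFrame, background
) -> pd.DataFrame:
    """One-sided Fisher-exact term over-representation.

    For each term the 2x2 table is (foreground-in-term, foreground-not-in-term)
    vs (background-only-in-term, background-only-not-in-term), tested for
    over-representation (alternative 'greater'). The enrichment ratio is
    (k/n)/(K/N) with k, n counted in the foreground and K, N in the full
    background. Benjamini-Hochberg q-values are computed across terms.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    ann = annotation_map[annotation_map["analyte_id"].isin(background)]
    if ann.empty:
        raise ValueError("annotation map covers no background analyte")
    n = len(foreground)
    N = len(background)
    rows = []
    for term, members in ann.groupby("term")["analyte_id"]:
        in_term = set(members)
        K = len(in_term)
        k = len(in_term & foreground)
        if K == 0:
            log.warning("term %s has no carriers in the background; skipped", term)
            continue
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        ratio = (k / n) / (K / N) if n else np.nan
        rows.append((term, k, n, K, N, ratio, odds, p))
    out = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "enrichment_ratio", "odds_ratio", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.sort_values("p", ignore_index=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
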