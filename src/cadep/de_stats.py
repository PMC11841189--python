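"""DEG calling, multiple-testing adjustment, and a surrogate two-group DE test.

A gene is a DEG for a contrast when FDR < 0.01 and |log2FC| >= 0.5 (strict
FDR gate, inclusive fold-change gate); everything else is UC — unchanged.
The surrogate test exists so fully synthetic count matrices can be pushed
end-to-end through the pipeline: it uses median-of-ratios size factors and a
Welch t-test on log2-transformed normalized counts.  It is intentionally
simple (no dispersion shrinkage) and is not a negative-binomial GLM.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

UP = "UP"
DOWN = "DOWN"
UC = "UC"
STATUSES = (UP, DOWN, UC)

#: Pseudo-count added to mean normalized counts before the log-ratio, so a
#: zero-mean group does not produce an infinite fold change.
PSEUDOCOUNT = 0.5


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Output is >= the input p, <= 1, and monotone nondecreasing when sorted by
    the input p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deg(log2fc: float, fdr: float, fdr_cutoff: float = 0.01,
             lfc_cutoff: float = 0.5) -> str:
    """Classify one gene/contrast as UP, DOWN or UC.

    UP requires fdr < fdr_cutoff and log2fc >= lfc_cutoff; DOWN requires
    fdr < fdr_cutoff and log2fc <= -lfc_cutoff; anything else — including
    significant genes with |log2fc| below the fold-change gate — is UC.
    A NaN fdr yields UC with a warning.
    """
    if fdr_cutoff <= 0 or lfc_cutoff <= 0:
        raise ValueError("cutoffs must be > 0")
    if np.isnan(fdr):
        logger.warning("NaN fdr encountered; calling UC")
        return UC
    if fdr < fdr_cutoff:
        if log2fc >= lfc_cutoff:
            return UP
        if log2fc <= -lfc_cutoff:
            return DOWN
    return UC


def call_deg_table(de: pd.DataFrame, fdr_cutoff: float = 0.01,
                   lfc_cutoff: float = 0.5) -> pd.DataFrame:
    """Vectorized :func:`call_deg` over a DE table; adds a ``status`` column."""
    if fdr_cutoff <= 0 or lfc_cutoff <= 0:
        raise ValueError("cutoffs must be > 0")
    out = de.copy()
    fdr = out["fdr"].to_numpy(dtype=float)
    lfc = out["log2fc"].to_numpy(dtype=float)
    n_nan = int(np.isnan(fdr).sum())
    if n_nan:
        logger.warning("%d NaN fdr values called UC", n_nan)
    sig = ~np.isnan(fdr) & (fdr < fdr_cutoff)
    status = np.full(len(out), UC, dtype=object)
    status[sig & (lfc >= lfc_cutoff)] = UP
    status[sig & (lfc <= -lfc_cutoff)] = DOWN
    out["status"] = status
    out.attrs = dict(de.attrs)
    return out


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes with all-positive counts."""
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        logger.warning(
            "no gene has all-positive counts; falling back to total-count "
            "size factors"
        )
        totals = counts.sum(axis=0).astype(float)
        return totals / np.exp(np.mean(np.log(totals)))
    logc = np.log(counts[positive].astype(float))
    log_geomean = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - log_geomean, axis=0))


def surrogate_de(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    contrast_id: str = "",
) -> pd.DataFrame:
    """Two-group differential-expression surrogate on a genes x samples matrix.

    Size factors are median-of-ratios over both groups jointly; the reported
    log2 fold change is log2((mean_norm_b + 0.5) / (mean_norm_a + 0.5));
    p-values come from a Welch t-test on log2(normalized + 1) and are BH
    adjusted.  Genes with zero variance in both groups get p = 1 when means
    agree (p = 0 otherwise, which cannot occur with equal means).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    samples = list(group_a) + list(group_b)
    mat = counts.loc[:, samples].to_numpy(dtype=float)
    sf = _size_factors(mat)
    norm = mat / sf
    a = norm[:, : len(group_a)]
    b = norm[:, len(group_a):]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))

    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    out = pd.DataFrame(
        {
            "gene_id": counts.index.astype(str),
            "log2fc": log2fc,
            "pvalue": p,
            "fdr": bh_adjust(p),
        }
    ).reset_index(drop=True)
    out.attrs["contrast_id"] = contrast_id
    return out
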