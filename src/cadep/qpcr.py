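"""RT-qPCR relative quantification (2^-ddCt), RNA-seq concordance, and
baseline-subtracted peak extraction for Ca2+ reporter traces.

The 2^-ddCt method assumes amplification efficiency 2 (one cycle = one
doubling).  Target Ct values are normalized per sample against the
arithmetic mean Ct of the reference genes — equivalent to the geometric mean
of their linear quantities — then treated and control conditions are
compared.  Technical repeats should be averaged at the Ct level before this
module sees them; rows sharing (gene, sample) are averaged here for
convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RelativeExpression:
    gene_id: str
    treated: str
    control: str
    ddct: float
    ratio: float
    #: 2^-(dCt_treated_rep - mean dCt_control), one per treated replicate;
    #: carries biological variability into SE or ANOVA downstream.
    replicate_ratios: np.ndarray


def _delta_ct(
    ct: pd.DataFrame, gene: str, condition: str, reference_genes: tuple[str, ...]
) -> np.ndarray:
    """Per-replicate dCt = Ct_gene - mean(Ct references) for one condition."""
    sub = ct[ct["condition"] == condition]
    gene_ct = (
        sub[sub["gene_id"] == gene]
        .groupby("sample_id")["ct"].mean()  # technical repeats -> one Ct
        .sort_index()
    )
    if gene_ct.empty:
        raise ValueError(f"gene {gene!r} has no Ct values in condition {condition!r}")
    ref = sub[sub["gene_id"].isin(reference_genes)]
    ref_ct = ref.groupby(["sample_id", "gene_id"])["ct"].mean().unstack()
    for sample in gene_ct.index:
        if sample not in ref_ct.index or ref_ct.loc[sample].isna().any():
            missing = (
                [g for g in reference_genes if sample not in ref_ct.index
                 or pd.isna(ref_ct.loc[sample].get(g))]
                if sample in ref_ct.index else list(reference_genes)
            )
            raise ValueError(
                f"missing reference measurement for gene(s) {missing} "
                f"in sample {sample!r} (target {gene!r})"
            )
    ref_mean = ref_ct.loc[gene_ct.index].mean(axis=1)
    return (gene_ct - ref_mean).to_numpy()


def delta_delta_ct(
    ct: pd.DataFrame,
    gene: str,
    treated: str,
    control: str,
    reference_genes: tuple[str, ...] = ("REF_ACTIN", "REF_GAPDH"),
) -> RelativeExpression:
    """Relative expression of ``gene`` in ``treated`` vs ``control``.

    ddCt = mean dCt_treated - mean dCt_control; ratio = 2^-ddCt.  Invariant
    to any additive shift common to all Ct values.
    """
    dct_t = _delta_ct(ct, gene, treated, reference_genes)
    dct_c = _delta_ct(ct, gene, control, reference_genes)
    ddct = float(dct_t.mean() - dct_c.mean())
    return RelativeExpression(
        gene_id=gene,
        treated=treated,
        control=control,
        ddct=ddct,
        ratio=float(2.0 ** -ddct),
        replicate_ratios=2.0 ** -(dct_t - dct_c.mean()),
    )


def concordance(qpcr_log2_ratios, rnaseq_log2fc) -> dict[str, float]:
    """OLS of qPCR log2 ratios on RNA-seq log2FC plus Pearson correlation."""
    y = np.asarray(qpcr_log2_ratios, dtype=float)
    x = np.asarray(rnaseq_log2fc, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    fit = stats.linregress(x, y)
    return {
        "pearson_r": float(fit.rvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p": float(fit.pvalue),
    }


def delta_peak(
    time, value, injection_time: float, baseline_window: float = 10.0
) -> float:
    """Baseline-subtracted peak response of a reporter trace.

    Returns max(value after injection) minus the mean value over the
    ``baseline_window`` seconds immediately preceding the injection.  A trace
    peaking only before injection yields a non-positive delta, not an error.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(value, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if baseline_window > injection_time - t[0]:
        raise ValueError("baseline window extends before the trace start")
    base = v[(t >= injection_time - baseline_window) & (t < injection_time)]
    post = v[t > injection_time]
    if base.size == 0:
        raise ValueError("no samples in baseline window")
    if post.size == 0:
        raise ValueError("no samples after injection")
    return float(post.max() - base.mean())


def ratio_anova(replicate_ratios: dict[str, np.ndarray]) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD over per-condition replicate ratios.

    Thin convenience over statsmodels for annotating bar charts of relative
    expression; returns the pairwise Tukey table.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(v, float) for v in replicate_ratios.values()])
    groups = np.concatenate(
        [np.repeat(k, len(v)) for k, v in replicate_ratios.items()]
    )
    res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return frame
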