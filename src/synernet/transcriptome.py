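"""Two-group differential expression filter and heat-map preparation.

Genes pass when the linear-scale fold change of group means meets the
cutoff (default 1.3-fold, inclusive, in either direction) and the Welch
two-sample t-test on log2 values is significant at the raw p threshold
(default 0.05, no multiplicity correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as sps

from .datatypes import ExpressionMatrix, ValidationError


def differential_genes(
    matrix: ExpressionMatrix, fc_cut: float = 1.3, p_cut: float = 0.05
) -> pd.DataFrame:
    """Per-gene fold change + Welch t filter, sorted by ascending p.

    Fold change is the ratio of arithmetic group means on the linear scale,
    second sorted group label over the first (treatment/placebo under the
    generator's labelling). The t-test runs on log2-transformed values with
    Welch's unequal-variance correction. A gene with zero variance in both
    groups and equal means gets p = 1 rather than an error.

    Returns a DataFrame with columns ``gene, fc, log2fc, p, passes``.
    """
    if fc_cut < 1:
        raise ValidationError("fc_cut must be >= 1")
    g1, g2 = matrix.split()
    m1 = g1.mean(axis=1).to_numpy()
    m2 = g2.mean(axis=1).to_numpy()
    fc = m2 / m1
    log2fc = np.log2(fc)
    l1 = np.log2(g1.to_numpy())
    l2 = np.log2(g2.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        t = sps.ttest_ind(l2, l1, axis=1, equal_var=False)
    p = np.asarray(t.pvalue, dtype=float)
    degenerate = (l1.var(axis=1) == 0) & (l2.var(axis=1) == 0)
    p = np.where(degenerate & (np.abs(l2.mean(axis=1) - l1.mean(axis=1)) == 0), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    passes = (np.abs(log2fc) >= np.log2(fc_cut) - 1e-12) & (p < p_cut)
    out = pd.DataFrame(
        {"gene": matrix.values.index, "fc": fc, "log2fc": log2fc, "p": p, "passes": passes}
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def zscore_matrix(matrix: ExpressionMatrix, genes: list[str] | pd.Index) -> pd.DataFrame:
    """Per-gene standardization (mean 0, sd 1 across samples) for heat maps.

    Uses the population (ddof=0) standard deviation. Zero-variance genes
    cannot be standardized and raise, naming the offender.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("gene subset must be non-empty")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    sub = matrix.values.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    flat = sd[sd == 0]
    if len(flat):
        raise ValidationError(f"zero-variance gene cannot be standardized: {flat.index[0]!r}")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
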