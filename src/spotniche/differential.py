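"""Spot-level differential expression between annotation groups.

Produces the two axes of the marker-group volcano variants: per gene, the
difference in expressing-spot proportion (delta_pct) and the log2 fold
change of back-transformed normalized means, with a Wilcoxon rank-sum
p-value and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix
from .preprocess import NormMatrix


def rank_sum_de(
    norm: NormMatrix,
    counts: CountMatrix,
    group_a_spots,
    group_b_spots,
    pseudocount: float = 1e-9,
    positivity_threshold: int = 1,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two disjoint spot groups (each >= 3 spots).

    log2fc is computed on expm1-backtransformed normalized means with a small
    pseudocount; delta_pct = pct_a - pct_b uses raw counts at the shared
    positivity threshold. The rank-sum test is exact for small tie-free
    groups and otherwise uses the tie-corrected normal approximation
    (scipy's method="auto"). FDR is Benjamini-Hochberg over all tested genes;
    rows are sorted by p-value then symbol.
    """
    a, b = list(group_a_spots), list(group_b_spots)
    if set(a) & set(b):
        raise ValueError("groups overlap")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 spots")

    ia, ib = norm.spot_indices(a), norm.spot_indices(b)
    cpos = {s: i for i, s in enumerate(counts.spot_ids)}
    ca = np.array([cpos[s] for s in a])
    cb = np.array([cpos[s] for s in b])
    raw = counts.dense()

    back = np.expm1(norm.values)
    mean_a = back[:, ia].mean(axis=1)
    mean_b = back[:, ib].mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    pct_a = (raw[:, ca] >= positivity_threshold).mean(axis=1)
    pct_b = (raw[:, cb] >= positivity_threshold).mean(axis=1)

    pvals = np.empty(len(norm.gene_ids))
    for gi in range(len(norm.gene_ids)):
        xa, xb = norm.values[gi, ia], norm.values[gi, ib]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            pvals[gi] = 1.0  # all values identical: no evidence either way
        else:
            pvals[gi] = mannwhitneyu(xa, xb, alternative="two-sided", method="auto").pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "log2fc": log2fc,
            "delta_pct": pct_a - pct_b,
            "p_value": pvals,
            "fdr": fdr,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
        }
    )
    return out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)
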