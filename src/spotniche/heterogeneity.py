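"""Tumor transcriptional diversity.

The statistic is a robust scale of the pairwise co-expression structure in
the tumor region: all upper-triangle Pearson correlations among highly
variable genes across tumor spots, summarized by the median absolute
deviation times 1.4826 (the consistency constant that makes the MAD estimate
the standard deviation under normality). Its inverse is the conventional
plotting axis against the marker expression rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CountMatrix
from .preprocess import HVGSet, NormMatrix

MAD_CONSISTENCY = 1.4826


@dataclass
class DiversityResult:
    sample_id: str
    D: float
    inverse_D: float | None
    n_hvg: int
    n_pairs: int
    n_dropped_genes: int

    def to_record(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "D": self.D,
            "inverse_D": self.inverse_D if self.inverse_D is not None else float("nan"),
            "n_hvg": self.n_hvg,
            "n_pairs": self.n_pairs,
            "n_dropped_genes": self.n_dropped_genes,
        }


def scaled_mad(values) -> float:
    """1.4826 x median(|v - median(v)|): the core robust-scale statistic."""
    v = np.asarray(values, dtype=float)
    return float(MAD_CONSISTENCY * np.median(np.abs(v - np.median(v))))


def transcriptional_diversity(
    norm: NormMatrix,
    hvgs: HVGSet,
    tumor_spots,
    sample_id: str = "sample",
) -> DiversityResult:
    """Diversity D over the tumor spots of one sample.

    Genes with zero variance across the tumor spots are dropped (their
    correlations are undefined) and counted. Requires >= 3 tumor spots and
    >= 2 usable genes.
    """
    tumor_spots = list(tumor_spots)
    if len(tumor_spots) < 3:
        raise ValueError("need at least 3 tumor spots")
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    gene_idx = [gene_pos[g] for g in hvgs.genes if g in gene_pos]
    if len(gene_idx) < 2:
        raise ValueError("need at least 2 HVGs present in the matrix")
    sub = norm.values[np.ix_(gene_idx, norm.spot_indices(tumor_spots))]

    variances = sub.var(axis=1)
    usable = variances > 0
    n_dropped = int((~usable).sum())
    sub = sub[usable]
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 genes with nonzero variance in the tumor region")

    corr = np.corrcoef(sub)
    iu = np.triu_indices(corr.shape[0], k=1)
    rho = corr[iu]
    d = scaled_mad(rho)
    return DiversityResult(
        sample_id=sample_id,
        D=d,
        inverse_D=(1.0 / d) if d > 0 else None,
        n_hvg=len(gene_idx),
        n_pairs=len(rho),
        n_dropped_genes=n_dropped,
    )


def marker_expression_rate(
    counts: CountMatrix, marker_gene: str, tumor_spots, min_count: int = 1
) -> float:
    """Fraction of tumor spots where the marker reaches the positivity
    threshold shared with spot annotation."""
    tumor_spots = list(tumor_spots)
    if not tumor_spots:
        raise ValueError("empty tumor spot list")
    pos = {s: i for i, s in enumerate(counts.spot_ids)}
    unknown = [s for s in tumor_spots if s not in pos]
    if unknown:
        raise KeyError(f"unknown spot(s): {unknown[:5]}")
    vec = counts.gene_counts(marker_gene)
    idx = [pos[s] for s in tumor_spots]
    return float((vec[idx] >= min_count).mean())
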