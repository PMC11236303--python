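"""Normalization and highly-variable-gene selection.

Counts are depth-normalized per spot to a fixed scale factor and
log-transformed (natural log of 1 + CPx), the LogNormalize convention.
HVGs are genes whose normalized mean lies in a band and whose variance
strictly exceeds a quantile of the candidate variance distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import CountMatrix, FormatError

logger = logging.getLogger(__name__)


@dataclass
class NormMatrix:
    """Gene x spot (or gene x cell) log-normalized expression, dense."""

    gene_ids: list[str]
    spot_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise FormatError("NormMatrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise FormatError("NormMatrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def spot_indices(self, spot_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.spot_ids)}
        return np.array([pos[s] for s in spot_ids], dtype=int)


@dataclass
class HVGSet:
    """Highly variable genes, ordered by variance descending."""

    genes: list[str]
    mean_bounds: tuple[float, float]
    variance_quantile: float
    variances: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormMatrix:
    """value(g, s) = ln(1 + count(g, s) * scale_factor / total(s)).

    Spots with zero total count are dropped (logged), since their depth
    normalization is undefined.
    """
    dense = counts.dense().astype(float)
    if (dense < 0).any():
        raise FormatError("negative counts cannot be normalized")
    totals = dense.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [s for s, k in zip(counts.spot_ids, keep) if not k]
        logger.warning("dropping %d zero-total spot(s): %s", len(dropped), dropped[:5])
    dense = dense[:, keep]
    totals = totals[keep]
    values = np.log1p(dense * (scale_factor / totals))
    spot_ids = [s for s, k in zip(counts.spot_ids, keep) if k]
    return NormMatrix(list(counts.gene_ids), spot_ids, values)


def select_hvgs(
    norm: NormMatrix,
    mean_low: float = 0.125,
    mean_high: float = 3.0,
    var_quantile: float = 0.5,
) -> HVGSet:
    """Select genes with normalized mean in [mean_low, mean_high] whose
    variance strictly exceeds the ``var_quantile`` quantile (type-7, linear
    interpolation) of the candidate variances.

    Result is ordered by variance descending, ties broken by gene symbol.
    Variances use the unbiased (n-1) denominator.
    """
    if norm.shape[1] < 2:
        raise ValueError("HVG selection needs at least 2 spots")
    means = norm.values.mean(axis=1)
    variances = norm.values.var(axis=1, ddof=1)
    candidate = (means >= mean_low) & (means <= mean_high)
    if not candidate.any():
        warnings.warn("no genes fall in the HVG mean band; returning an empty set")
        return HVGSet([], (mean_low, mean_high), var_quantile)
    cand_vars = variances[candidate]
    cutoff = float(np.quantile(cand_vars, var_quantile))
    selected = candidate & (variances > cutoff)
    idx = np.flatnonzero(selected)
    order = sorted(idx, key=lambda i: (-variances[i], norm.gene_ids[i]))
    genes = [norm.gene_ids[i] for i in order]
    return HVGSet(
        genes,
        (mean_low, mean_high),
        var_quantile,
        {norm.gene_ids[i]: float(variances[i]) for i in order},
    )


def expressing_fraction(counts: CountMatrix, gene: str, spot_subset) -> float:
    """Fraction of the given spots with at least one count of ``gene``."""
    spot_subset = list(spot_subset)
    if not spot_subset:
        raise ValueError("empty spot subset")
    pos = {s: i for i, s in enumerate(counts.spot_ids)}
    unknown = [s for s in spot_subset if s not in pos]
    if unknown:
        raise KeyError(f"unknown spot(s): {unknown[:5]}")
    vec = counts.gene_counts(gene)
    idx = [pos[s] for s in spot_subset]
    return float((vec[idx] >= 1).mean())
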