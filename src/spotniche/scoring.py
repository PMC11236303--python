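"""Gene-set scoring: per-spot ssGSEA, binned-control module scores,
pseudotime trajectory curves, and the ratio-of-medians differential
enrichment statistic.

ssGSEA follows the single-sample weighted-ECDF running sum: per spot, genes
are ranked by expression (descending; average ranks on ties), the in-set
ECDF steps by |r_i|^alpha normalized over the set, the out-of-set ECDF steps
uniformly, and the enrichment score is the sum of the difference along the
whole ranked list. With normalize=True all raw scores are divided by
(max - min) over the matrix, the usual cross-sample normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import GeneSetCollection
from .preprocess import NormMatrix


@dataclass
class EnrichmentMatrix:
    """Signature x spot enrichment scores plus the parameters that made them."""

    signatures: list[str]
    spot_ids: list[str]
    scores: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.signatures), len(self.spot_ids)):
            raise ValueError("EnrichmentMatrix shape mismatch")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite enrichment score")

    def row(self, signature: str) -> pd.Series:
        i = self.signatures.index(signature)
        return pd.Series(self.scores[i], index=self.spot_ids, name=signature)

    def to_long_records(self):
        return [
            {"signature": sig, "spot_id": sid, "score": self.scores[i, j]}
            for i, sig in enumerate(self.signatures)
            for j, sid in enumerate(self.spot_ids)
        ]


def ssgsea_scores(
    norm: NormMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.75,
    normalize: bool = True,
) -> EnrichmentMatrix:
    """Per-spot single-sample GSEA scores for every signature.

    Each signature must share at least one gene with the matrix and leave at
    least one gene outside it (the out-of-set ECDF is undefined otherwise).
    Ranks are computed per spot with average ties; ordering among tied
    expression values is fixed by gene symbol for determinism.
    """
    genes = norm.gene_ids
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    memberships = {}
    for name in sets.names():
        idx = np.array([gene_pos[g] for g in sets[name] if g in gene_pos], dtype=int)
        if idx.size == 0:
            raise ValueError(f"gene set {name!r} shares no genes with the matrix")
        if idx.size == n_genes:
            raise ValueError(f"gene set {name!r} covers every gene in the matrix")
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        memberships[name] = mask

    symbol_order = np.argsort(np.array(genes))  # tie-break key
    symbol_rank = np.empty(n_genes)
    symbol_rank[symbol_order] = np.arange(n_genes)

    names = list(sets.names())
    raw = np.empty((len(names), len(norm.spot_ids)))
    for j in range(len(norm.spot_ids)):
        expr = norm.values[:, j]
        ranks = rankdata(expr, method="average")  # top expression -> rank n_genes
        order = np.lexsort((symbol_rank, -expr))  # descending expression
        weights = np.abs(ranks[order]) ** alpha
        for si, name in enumerate(names):
            in_set = memberships[name][order]
            w_in = np.where(in_set, weights, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_set) / (n_genes - in_set.sum())
            raw[si, j] = float(np.sum(p_in - p_out))

    params = {"alpha": alpha, "normalize": normalize}
    if normalize:
        span = raw.max() - raw.min()
        scores = raw / span if span > 0 else raw.copy()
    else:
        scores = raw
    return EnrichmentMatrix(names, list(norm.spot_ids), scores, "ssgsea", params)


def module_score(
    norm: NormMatrix,
    gene_set,
    n_bins: int = 24,
    n_control: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per spot.

    Genes are cut into ``n_bins`` bins by average expression; the score is the
    mean expression of the set genes minus the mean of ``n_control`` control
    genes sampled (seeded, with replacement) from each set gene's bin. Set
    genes missing from the matrix are dropped.
    """
    genes = norm.gene_ids
    if len(genes) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes, have {len(genes)}")
    present = [g for g in gene_set if g in set(genes)]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    gene_pos = {g: i for i, g in enumerate(genes)}

    avg = norm.values.mean(axis=1)
    order = sorted(range(len(genes)), key=lambda i: (avg[i], genes[i]))
    bins = np.array_split(np.array(order), n_bins)
    bin_of = np.empty(len(genes), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    rng = np.random.default_rng(seed)
    set_idx = np.array([gene_pos[g] for g in present])
    control_idx = []
    for gi in set_idx:
        pool = bins[bin_of[gi]]
        control_idx.append(rng.choice(pool, size=n_control, replace=True))
    control_idx = np.concatenate(control_idx)

    score = norm.values[set_idx].mean(axis=0) - norm.values[control_idx].mean(axis=0)
    return pd.Series(score, index=norm.spot_ids)


@dataclass
class TrajectoryScore:
    """Per-cell scores along pseudotime; difference = resistance - sensitivity."""

    cells: pd.DataFrame   # cell_id, pseudotime, resistance, sensitivity, difference
    curves: pd.DataFrame  # center, res/sens/diff mean and 2.5/97.5 bootstrap bands


def cuproptosis_curves(
    traj_matrix: NormMatrix,
    pseudotime,
    resistance_set,
    sensitivity_set,
    window_fraction: float = 0.1,
    n_boot: int = 200,
    seed: int = 0,
) -> TrajectoryScore:
    """Resistance / sensitivity module scores along pseudotime with sliding
    window means and bootstrap percentile bands.

    Cells are sorted by pseudotime; the window is ``window_fraction`` of the
    cells, centered per cell; bands are 2.5/97.5 percentiles of the window
    mean over ``n_boot`` resamples of the window's cells. The difference
    series is smoothed identically.
    """
    resistance_set, sensitivity_set = list(resistance_set), list(sensitivity_set)
    if set(resistance_set) & set(sensitivity_set):
        raise ValueError("resistance and sensitivity sets overlap")
    t = np.asarray(pseudotime, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("pseudotime must be finite")
    n = len(traj_matrix.spot_ids)
    if t.shape != (n,):
        raise ValueError("pseudotime length does not match the matrix")
    window = int(round(window_fraction * n))
    if window < 3:
        raise ValueError(f"window of {window} cells is too small (< 3)")

    res = module_score(traj_matrix, resistance_set, seed=seed).to_numpy()
    sens = module_score(traj_matrix, sensitivity_set, seed=seed + 1).to_numpy()
    diff = res - sens

    order = np.lexsort((np.array(traj_matrix.spot_ids), t))
    t_sorted = t[order]
    series = {"res": res[order], "sens": sens[order], "diff": diff[order]}

    half = window // 2
    rng = np.random.default_rng(seed + 2)
    rows = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        row = {"center_pseudotime": t_sorted[i]}
        idx = np.arange(lo, hi)
        boot = rng.integers(0, idx.size, size=(n_boot, idx.size))
        for key, vals in series.items():
            w = vals[idx]
            row[f"{key}_mean"] = float(w.mean())
            means = w[boot].mean(axis=1)
            row[f"{key}_lo"] = float(np.percentile(means, 2.5))
            row[f"{key}_hi"] = float(np.percentile(means, 97.5))
        rows.append(row)

    cells = pd.DataFrame(
        {
            "cell_id": np.array(traj_matrix.spot_ids)[order],
            "pseudotime": t_sorted,
            "resistance": series["res"],
            "sensitivity": series["sens"],
            "difference": series["diff"],
        }
    )
    return TrajectoryScore(cells, pd.DataFrame(rows))


def differential_enrichment(
    enr: EnrichmentMatrix, group_a_spots, group_b_spots
) -> pd.DataFrame:
    """Per-signature ratio of median enrichment scores between two spot groups.

    The ratio is median_a / median_b when both medians are positive; otherwise
    the row is flagged and the difference of medians stands in. Both medians
    are always reported.
    """
    group_a_spots, group_b_spots = list(group_a_spots), list(group_b_spots)
    if not group_a_spots or not group_b_spots:
        raise ValueError("both groups must be non-empty")
    pos = {s: i for i, s in enumerate(enr.spot_ids)}
    ia = [pos[s] for s in group_a_spots]
    ib = [pos[s] for s in group_b_spots]
    rows = []
    for i, sig in enumerate(enr.signatures):
        ma = float(np.median(enr.scores[i, ia]))
        mb = float(np.median(enr.scores[i, ib]))
        if ma > 0 and mb > 0:
            rows.append(
                {
                    "signature": sig,
                    "median_a": ma,
                    "median_b": mb,
                    "ratio": ma / mb,
                    "difference": ma - mb,
                    "flag": "",
                }
            )
        else:
            why = "median_b<=0" if mb <= 0 else "median_a<=0"
            rows.append(
                {
                    "signature": sig,
                    "median_a": ma,
                    "median_b": mb,
                    "ratio": float("nan"),
                    "difference": ma - mb,
                    "flag": f"ratio undefined ({why}); difference reported",
                }
            )
    return pd.DataFrame(rows)
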