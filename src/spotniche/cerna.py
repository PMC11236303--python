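"""Competing-endogenous-RNA (lncRNA - miRNA - mRNA) network construction.

Candidate triplets are the join of lncRNA-miRNA and miRNA-mRNA interaction
edges. A triplet survives when the lncRNA is upregulated (log2FC above the
cut, adjusted p below the cut), the miRNA downregulated, the target mRNA
passes its own screen (when a DE entry exists), and the lncRNA-mRNA Pearson
correlation across paired samples is positive and significant — the ceRNA
sponge logic implies positive co-expression of the lncRNA and the
de-repressed target. Every dropped triplet carries its first failing filter
as a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

DE_CLASSES = {"lncRNA", "miRNA", "mRNA"}


@dataclass
class CeRNANetwork:
    triplets: pd.DataFrame       # lncRNA, miRNA, mRNA, pearson_r, pearson_p
    nodes: pd.DataFrame          # symbol, class, log2fc, direction
    rejections: list = field(default_factory=list)  # {"triplet": (l,m,t), "reason": str}

    def __len__(self) -> int:
        return len(self.triplets)


def _validate_de(de: pd.DataFrame) -> pd.DataFrame:
    required = {"symbol", "class", "log2fc", "adj_p"}
    missing = required - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    bad = set(de["class"]) - DE_CLASSES
    if bad:
        raise ValueError(f"unknown DE class(es) {sorted(bad)}")
    if de.duplicated(["symbol", "class"]).any():
        raise ValueError("duplicate symbol within a DE class")
    return de


def _check_edges(edges, name: str) -> list[tuple[str, str]]:
    out = []
    for lineno, row in enumerate(edges, start=1):
        row = tuple(row)
        if len(row) != 2 or not all(isinstance(x, str) and x for x in row):
            raise ValueError(f"{name}: malformed edge at row {lineno}: {row!r}")
        out.append(row)
    return out


def build_cerna_network(
    de: pd.DataFrame,
    lnc_mir_edges,
    mir_mrna_edges,
    expr_for_correlation: pd.DataFrame,
    targets=None,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
    corr_p_cut: float = 0.05,
) -> CeRNANetwork:
    """Apply the ceRNA filters and correlation screen to all candidate triplets.

    ``expr_for_correlation`` is a symbol x sample frame; ``targets`` optionally
    restricts the admissible mRNAs (e.g. a fixed cuproptosis gene list). The
    mRNA DE screen applies whenever the mRNA has a DE entry. Retained triplets
    are ranked by correlation, descending.
    """
    de = _validate_de(de)
    lnc_mir = _check_edges(lnc_mir_edges, "lncRNA-miRNA edges")
    mir_mrna = _check_edges(mir_mrna_edges, "miRNA-mRNA edges")
    target_set = set(targets) if targets is not None else None

    de_of = {(r["class"], r["symbol"]): r for _, r in de.iterrows()}
    mrna_of_mir: dict[str, list[str]] = {}
    for mir, mrna in mir_mrna:
        mrna_of_mir.setdefault(mir, []).append(mrna)

    candidates = []
    seen = set()
    for lnc, mir in lnc_mir:
        for mrna in mrna_of_mir.get(mir, ()):
            trip = (lnc, mir, mrna)
            if trip not in seen:
                seen.add(trip)
                candidates.append(trip)

    kept_rows, rejections = [], []
    for lnc, mir, mrna in candidates:
        reason = _first_failure(
            lnc, mir, mrna, de_of, target_set, expr_for_correlation,
            fc_cut, p_cut, corr_p_cut,
        )
        if reason is None:
            x = expr_for_correlation.loc[lnc].to_numpy(float)
            y = expr_for_correlation.loc[mrna].to_numpy(float)
            r, p = pearsonr(x, y)
            kept_rows.append(
                {"lncRNA": lnc, "miRNA": mir, "mRNA": mrna,
                 "pearson_r": float(r), "pearson_p": float(p)}
            )
        else:
            rejections.append({"triplet": (lnc, mir, mrna), "reason": reason})

    triplets = pd.DataFrame(kept_rows, columns=["lncRNA", "miRNA", "mRNA", "pearson_r", "pearson_p"])
    triplets = triplets.sort_values(
        ["pearson_r", "lncRNA", "miRNA"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)

    node_rows = []
    for _, row in triplets.iterrows():
        for cls, col in (("lncRNA", "lncRNA"), ("miRNA", "miRNA"), ("mRNA", "mRNA")):
            sym = row[col]
            entry = de_of.get((cls, sym))
            fc = float(entry["log2fc"]) if entry is not None else float("nan")
            node_rows.append(
                {"symbol": sym, "class": cls, "log2fc": fc,
                 "direction": "up" if fc > 0 else ("down" if fc < 0 else "n/a")}
            )
    nodes = pd.DataFrame(node_rows, columns=["symbol", "class", "log2fc", "direction"])
    if len(nodes):
        nodes = nodes.drop_duplicates(["symbol", "class"]).reset_index(drop=True)
    return CeRNANetwork(triplets, nodes, rejections)


def _first_failure(
    lnc, mir, mrna, de_of, target_set, expr, fc_cut, p_cut, corr_p_cut
):
    """The first filter a candidate triplet fails, or None if it passes all."""
    lrow = de_of.get(("lncRNA", lnc))
    if lrow is None:
        return "lncRNA not in DE table"
    if not lrow["log2fc"] > fc_cut:
        return "lncRNA fold-change"
    if not lrow["adj_p"] < p_cut:
        return "lncRNA adjusted p"
    mrow = de_of.get(("miRNA", mir))
    if mrow is None:
        return "miRNA not in DE table"
    if not mrow["log2fc"] < -fc_cut:
        return "miRNA direction"
    if not mrow["adj_p"] < p_cut:
        return "miRNA adjusted p"
    if target_set is not None and mrna not in target_set:
        return "mRNA not in targets"
    trow = de_of.get(("mRNA", mrna))
    if trow is not None:
        if not trow["log2fc"] > fc_cut:
            return "mRNA fold-change"
        if not trow["adj_p"] < p_cut:
            return "mRNA adjusted p"
    if lnc not in expr.index or mrna not in expr.index:
        return "expression missing"
    x = expr.loc[lnc].to_numpy(float)
    y = expr.loc[mrna].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return "expression missing"  # degenerate vector, correlation undefined
    r, p = pearsonr(x, y)
    if not r > 0:
        return "correlation sign"
    if not p < corr_p_cut:
        return "correlation p"
    return None


def validate_network(
    network: CeRNANetwork,
    de: pd.DataFrame,
    expr: pd.DataFrame,
    targets=None,
    fc_cut: float = 1.0,
    p_cut: float = 0.05,
    corr_p_cut: float = 0.05,
) -> bool:
    """Independent re-check that every retained triplet satisfies all filters."""
    de = _validate_de(de)
    de_of = {(r["class"], r["symbol"]): r for _, r in de.iterrows()}
    target_set = set(targets) if targets is not None else None
    for _, row in network.triplets.iterrows():
        reason = _first_failure(
            row["lncRNA"], row["miRNA"], row["mRNA"], de_of, target_set, expr,
            fc_cut, p_cut, corr_p_cut,
        )
        if reason is not None:
            raise AssertionError(
                f"retained triplet {tuple(row[:3])} fails filter: {reason}"
            )
    return True


def rank_axes(network: CeRNANetwork) -> pd.DataFrame:
    """Ordered triplet table: pearson_r descending, ties by (lncRNA, miRNA),
    with a 1-based rank column. Empty networks yield an empty table with the
    full header."""
    cols = ["rank", "lncRNA", "miRNA", "mRNA", "pearson_r", "pearson_p"]
    if len(network) == 0:
        return pd.DataFrame(columns=cols)
    t = network.triplets.sort_values(
        ["pearson_r", "lncRNA", "miRNA"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    t.insert(0, "rank", np.arange(1, len(t) + 1))
    return t[cols]
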