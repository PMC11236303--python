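"""Seeded synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates a hex-lattice tissue with contiguous tumor / normal /
necrotic regions, a marker gene (CDKN2A-like) expressed with dropout in a
connected tumor subregion, immune gene programs elevated near that subregion,
a pseudotime matrix with planted monotone resistance/sensitivity trends, and
toy lncRNA/miRNA/mRNA tables with planted correlations. Every generator is a
pure function of (config, seed).

Counts follow a negative binomial (mean m, shape theta; var = m + m^2/theta),
the standard overdispersion model for UMI data. The marker gene draws
1 + NB(m-1) on planted-positive spots (so a positive spot always has at least
one molecule before dropout thinning) and exactly zero elsewhere, which makes
planted positivity recoverable at dropout 0 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, GeneSetCollection, SpotTable
from .neighborhood import build_adjacency
from .preprocess import NormMatrix

ROW_PITCH = math.sqrt(3.0) / 2.0  # vertical spacing between hex rows

# Small published-style immune signatures used as default planted programs.
SPP1_TAM_GENES = [
    "SPP1", "MMP7", "MMP9", "CD68", "CD163", "APOE", "C1QA", "C1QB",
    "TREM2", "MARCO", "MRC1", "CTSB", "CTSD", "FN1", "VEGFA",
]
TCELL_GENES = [
    "CD3D", "CD3E", "CD2", "CD8A", "GZMB", "PRF1", "IL7R", "CCL5", "NKG7", "CD7",
]

REGION_CLASSES = (
    "tumor", "normal", "necrotic", "marker_pos", "near_marker_pos", "near_marker_neg",
)


@dataclass
class TrajectoryConfig:
    n_cells: int = 500
    n_genes: int = 100
    resistance_genes: tuple = tuple(f"RES{i}" for i in range(1, 11))
    sensitivity_genes: tuple = tuple(f"SEN{i}" for i in range(1, 11))
    resistance_slope: float = 2.0
    sensitivity_slope: float = -2.0
    baseline: float = 1.0
    noise_sd: float = 0.5


@dataclass
class SimulationConfig:
    """Study conditions for the spatial fixture.

    Defaults give a 10 x 20 = 200-spot tissue where the planted niche and
    marker structure are detectable by the downstream statistics.
    """

    seed: int
    n_rows: int = 10
    n_cols: int = 20  # spots per row; array columns span 0 .. 2*n_cols-1
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    n_background_genes: int = 200
    marker_gene: str = "CDKN2A"
    marker_mean_pos: float = 20.0
    dropout_pos: float = 0.1
    tumor_fraction: float = 0.35
    necrotic_fraction: float = 0.05
    marker_fraction: float = 0.4
    program_genes: dict = field(
        default_factory=lambda: {"SPP1_TAM": list(SPP1_TAM_GENES), "TCELL": list(TCELL_GENES)}
    )
    program_region: dict = field(
        default_factory=lambda: {"SPP1_TAM": "near_marker_pos", "TCELL": "normal"}
    )
    program_effect: dict = field(
        default_factory=lambda: {"SPP1_TAM": 4.0, "TCELL": 4.0}
    )
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.baseline_mean <= 0 or self.dispersion <= 0 or self.marker_mean_pos <= 0:
            raise ValueError("means and dispersion must be positive")
        if not 0.0 <= self.dropout_pos <= 1.0:
            raise ValueError("dropout_pos must be in [0, 1]")
        for prog in self.program_genes:
            region = self.program_region.get(prog)
            if region not in REGION_CLASSES:
                raise ValueError(f"program {prog!r} has invalid region class {region!r}")
            if self.program_effect.get(prog, 1.0) <= 0:
                raise ValueError(f"program {prog!r} effect must be positive")


@dataclass
class TissueLayout:
    """Ground-truth regions and planted marker-positive subregion."""

    spot_table: SpotTable
    region_of: dict
    marker_truth: dict

    def __post_init__(self) -> None:
        ids = set(self.spot_table.spot_ids)
        if set(self.region_of) != ids:
            raise ValueError("region_of must cover exactly the spot table")
        for sid, truth in self.marker_truth.items():
            if truth and self.region_of[sid] != "tumor":
                raise ValueError(f"marker_truth true on non-tumor spot {sid!r}")

    def spots_in(self, region: str) -> list[str]:
        return [s for s in self.spot_table.spot_ids if self.region_of[s] == region]


def make_hex_grid(n_rows: int, n_cols: int) -> SpotTable:
    """Regular hex grid: spots at all (r, c) with 0<=r<n_rows, 0<=c<2*n_cols
    and even (r+c) parity; unit horizontal pitch per array-col step of 2 and
    sqrt(3)/2 vertical pitch, so all six ring-1 neighbors sit at distance 1.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid extents must be >= 1")
    rows = []
    for r in range(n_rows):
        for c in range(2 * n_cols):
            if (r + c) % 2 == 0:
                rows.append(
                    {
                        "spot_id": f"S{r:03d}x{c:03d}",
                        "array_row": r,
                        "array_col": c,
                        "pixel_x": c / 2.0,
                        "pixel_y": r * ROW_PITCH,
                        "in_tissue": True,
                    }
                )
    return SpotTable(pd.DataFrame(rows))


def _grow_blob(start, size, neighbors, allowed, rng) -> set:
    """Seeded breadth-first accretion of a connected blob of ``size`` spots."""
    blob = {start}
    frontier = [n for n in neighbors[start] if n in allowed]
    while len(blob) < size and frontier:
        frontier.sort()  # determinism before the seeded draw
        pick = frontier.pop(rng.integers(len(frontier)))
        if pick in blob:
            continue
        blob.add(pick)
        frontier.extend(n for n in neighbors[pick] if n in allowed and n not in blob)
    return blob


def paint_layout(
    spot_table: SpotTable,
    seed: int,
    tumor_fraction: float = 0.35,
    necrotic_fraction: float = 0.05,
    marker_fraction: float = 0.4,
) -> TissueLayout:
    """Grow a connected tumor blob, carve a necrotic blob strictly inside it,
    and plant a connected marker-positive tumor sub-blob touching the tumor
    boundary (so that nearby-marker niches exist)."""
    n = len(spot_table)
    if not (0 < tumor_fraction < 1) or not (0 <= necrotic_fraction < 1):
        raise ValueError("fractions must lie in (0,1)")
    if not 0 <= marker_fraction < 1:
        raise ValueError("marker_fraction must lie in [0,1)")
    if tumor_fraction + necrotic_fraction >= 1:
        raise ValueError("tumor + necrotic fractions must sum below 1")
    n_tumor_total = int(round((tumor_fraction + necrotic_fraction) * n))
    n_necrotic = int(round(necrotic_fraction * n))
    if n_tumor_total < max(1, n_necrotic + 1):
        raise ValueError("fractions infeasible for this grid size")

    rng = np.random.default_rng(seed)
    graph = build_adjacency(spot_table, mode="array_hex", ring=1)
    nbrs = graph.neighbors
    ids = sorted(spot_table.spot_ids)
    all_spots = set(ids)

    start = ids[rng.integers(len(ids))]
    tumor_all = _grow_blob(start, n_tumor_total, nbrs, all_spots, rng)
    if len(tumor_all) < n_tumor_total:
        raise ValueError("could not grow a connected tumor blob of the requested size")

    necrotic: set = set()
    if n_necrotic:
        # most interior tumor spot: maximal hex-graph distance from non-tumor
        depth = _distance_from_outside(tumor_all, nbrs)
        core = max(sorted(tumor_all), key=lambda s: depth[s])
        necrotic = _grow_blob(core, n_necrotic, nbrs, tumor_all, rng)
    tumor = tumor_all - necrotic
    # carving may in principle split the tumor; keep the largest component and
    # fold stray components into necrotic so the connectivity invariant holds
    components = _components(tumor, nbrs)
    components.sort(key=lambda c: (-len(c), min(c)))
    for extra in components[1:]:
        necrotic |= extra
        tumor -= extra

    marker: set = set()
    n_marker = int(round(marker_fraction * len(tumor)))
    if n_marker:
        boundary = sorted(
            s for s in tumor if any(nb not in tumor_all for nb in nbrs[s])
        ) or sorted(tumor)
        mstart = boundary[rng.integers(len(boundary))]
        marker = _grow_blob(mstart, n_marker, nbrs, tumor, rng)

    region_of = {}
    for s in spot_table.spot_ids:
        if s in tumor:
            region_of[s] = "tumor"
        elif s in necrotic:
            region_of[s] = "necrotic"
        else:
            region_of[s] = "normal"
    marker_truth = {s: (s in marker) for s in spot_table.spot_ids}
    return TissueLayout(spot_table, region_of, marker_truth)


def _distance_from_outside(blob: set, nbrs: dict) -> dict:
    from collections import deque

    depth = {}
    queue = deque()
    for s in sorted(blob):
        if any(nb not in blob for nb in nbrs[s]):
            depth[s] = 0
            queue.append(s)
    if not queue:  # blob covers everything
        return {s: 0 for s in blob}
    while queue:
        s = queue.popleft()
        for nb in nbrs[s]:
            if nb in blob and nb not in depth:
                depth[nb] = depth[s] + 1
                queue.append(nb)
    return depth


def _components(spots: set, nbrs: dict) -> list[set]:
    from collections import deque

    remaining = set(spots)
    out = []
    while remaining:
        start = min(remaining)
        comp = {start}
        queue = deque([start])
        while queue:
            s = queue.popleft()
            for nb in nbrs[s]:
                if nb in remaining and nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        out.append(comp)
        remaining -= comp
    return out


def region_class_spots(layout: TissueLayout) -> dict[str, set]:
    """Spot sets for each program-assignable region class.

    near_marker_pos / near_marker_neg are non-tumor spots ring-1 adjacent to
    planted marker-positive / marker-negative tumor spots (positives win when
    a spot touches both, keeping the planted niche contrast clean).
    """
    graph = build_adjacency(layout.spot_table, mode="array_hex", ring=1)
    tumor = set(layout.spots_in("tumor"))
    classes: dict[str, set] = {
        "tumor": tumor,
        "normal": set(layout.spots_in("normal")),
        "necrotic": set(layout.spots_in("necrotic")),
        "marker_pos": {s for s in tumor if layout.marker_truth[s]},
    }
    near_pos, near_neg = set(), set()
    for s in layout.spot_table.spot_ids:
        if s in tumor or layout.region_of[s] == "necrotic":
            continue
        touches_pos = any(
            nb in tumor and layout.marker_truth[nb] for nb in graph.neighbors[s]
        )
        touches_neg = any(
            nb in tumor and not layout.marker_truth[nb] for nb in graph.neighbors[s]
        )
        if touches_pos:
            near_pos.add(s)
        elif touches_neg:
            near_neg.add(s)
    classes["near_marker_pos"] = near_pos
    classes["near_marker_neg"] = near_neg
    return classes


def _nb_draw(rng, mean, theta, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p, size=size)


def simulate_counts(layout: TissueLayout, config: SimulationConfig) -> CountMatrix:
    """Draw the gene x spot count matrix for a painted layout.

    Background genes get a per-gene lognormal mean factor (constant across
    spots); program genes are additionally elevated by their multiplicative
    effect in their assigned region class.
    """
    rng = np.random.default_rng(config.seed)
    spots = layout.spot_table.spot_ids
    n_spots = len(spots)
    classes = region_class_spots(layout)

    program_gene_list: list[str] = []
    for prog in sorted(config.program_genes):
        for g in config.program_genes[prog]:
            if g not in program_gene_list:
                program_gene_list.append(g)
    if config.marker_gene in program_gene_list:
        raise ValueError("marker gene cannot belong to a program")
    genes = [config.marker_gene] + program_gene_list + [
        f"BG{i:04d}" for i in range(config.n_background_genes)
    ]

    spot_pos = {s: j for j, s in enumerate(spots)}
    mat = np.zeros((len(genes), n_spots), dtype=np.int64)

    # marker gene: shifted NB on planted positives, zero elsewhere, then dropout
    pos_idx = np.array(
        [spot_pos[s] for s in spots if layout.marker_truth[s]], dtype=int
    )
    if pos_idx.size:
        draws = 1 + _nb_draw(
            rng, max(config.marker_mean_pos - 1.0, 0.0), config.dispersion, pos_idx.size
        )
        kept = rng.random(pos_idx.size) >= config.dropout_pos
        mat[0, pos_idx] = draws * kept

    # per-gene baseline heterogeneity
    gene_factor = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))

    effect_of_gene: dict[str, list[tuple[set, float]]] = {}
    for prog in sorted(config.program_genes):
        target = classes[config.program_region[prog]]
        eff = float(config.program_effect.get(prog, 1.0))
        for g in config.program_genes[prog]:
            effect_of_gene.setdefault(g, []).append((target, eff))

    for gi, gene in enumerate(genes):
        if gi == 0:
            continue
        mean = np.full(n_spots, config.baseline_mean * gene_factor[gi])
        for target, eff in effect_of_gene.get(gene, ()):
            idx = [spot_pos[s] for s in target]
            mean[idx] *= eff
        mat[gi] = _nb_draw(rng, mean, config.dispersion, n_spots)

    return CountMatrix(genes, list(spots), sp.csr_matrix(mat))


def simulate_trajectory(config: SimulationConfig) -> tuple[NormMatrix, np.ndarray]:
    """Pseudotime-ordered expression with planted monotone set trends.

    Pseudotime is uniform on [0,1]; resistance genes rise linearly at the
    planted slope, sensitivity genes fall, background genes are flat.
    Gaussian noise on the log scale, clipped at zero.
    """
    tc = config.trajectory
    res = list(tc.resistance_genes)
    sen = list(tc.sensitivity_genes)
    if set(res) & set(sen):
        raise ValueError("resistance and sensitivity sets overlap")
    rng = np.random.default_rng(config.seed + 1)
    n = tc.n_cells
    t = rng.uniform(0.0, 1.0, n)
    n_bg = max(tc.n_genes - len(res) - len(sen), 0)
    genes = res + sen + [f"TBG{i:04d}" for i in range(n_bg)]
    values = np.empty((len(genes), n))
    for gi, g in enumerate(genes):
        if g in res:
            intercept = tc.baseline + max(0.0, -tc.resistance_slope)
            mean = intercept + tc.resistance_slope * t
        elif g in sen:
            intercept = tc.baseline + max(0.0, -tc.sensitivity_slope)
            mean = intercept + tc.sensitivity_slope * t
        else:
            mean = np.full(n, tc.baseline + 0.5)
        values[gi] = np.clip(mean + rng.normal(0.0, tc.noise_sd, n), 0.0, None)
    cells = [f"C{i:04d}" for i in range(n)]
    return NormMatrix(genes, cells, values), t


def default_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """The planted programs as a GMT-ready collection."""
    return GeneSetCollection(
        {p: list(g) for p, g in sorted(config.program_genes.items())},
        {p: f"planted program ({config.program_region[p]})" for p in config.program_genes},
    )


# ----------------------------------------------------------------- ceRNA ----


@dataclass
class CeRNAFixture:
    de_table: pd.DataFrame            # symbol, class, log2fc, adj_p
    lnc_mir_edges: list               # (lncRNA, miRNA)
    mir_mrna_edges: list              # (miRNA, mRNA)
    expression: pd.DataFrame          # symbol x sample
    targets: list                     # candidate mRNA symbols
    truth_triplets: list              # [(lncRNA, miRNA, mRNA), ...] planted passers
    decoys: list                      # [{"triplet": (...), "reason": str}, ...]


def _vector_with_exact_correlation(rng, x: np.ndarray, r: float) -> np.ndarray:
    """A vector whose empirical Pearson correlation with x is exactly r."""
    xs = (x - x.mean()) / x.std()
    e = rng.normal(size=x.size)
    e = e - e.mean()
    e = e - xs * (e @ xs) / (xs @ xs)  # orthogonalize against x
    e = e / e.std()
    y = r * xs + math.sqrt(max(1.0 - r * r, 0.0)) * e
    return 5.0 + y  # shift into a positive expression range


def simulate_cerna_tables(seed: int, n_samples: int = 30) -> CeRNAFixture:
    """DE tables, interaction edges and paired expression with one planted
    passing lncRNA-miRNA-mRNA triplet and decoys each failing exactly one
    filter. Decoy correlations are forced to their planted value exactly, so
    the failing filter is deterministic for every seed.
    """
    rng = np.random.default_rng(seed)

    de_rows = []

    def de(symbol, cls, log2fc, adj_p):
        de_rows.append({"symbol": symbol, "class": cls, "log2fc": log2fc, "adj_p": adj_p})

    chains = {
        # name -> (lnc_fc, lnc_p, mir_fc, mir_p, mrna_fc, mrna_p, corr, reason or None)
        "A": (2.5, 1e-4, -2.0, 1e-3, 1.8, 1e-3, 0.8, None),
        "B": (0.5, 1e-3, -2.0, 1e-3, 1.8, 1e-3, 0.8, "lncRNA fold-change"),
        "C": (2.2, 1e-3, 1.5, 1e-3, 1.8, 1e-3, 0.8, "miRNA direction"),
        "D": (2.2, 0.2, -2.0, 1e-3, 1.8, 1e-3, 0.8, "lncRNA adjusted p"),
        "E": (2.2, 1e-3, -2.0, 1e-3, 1.8, 1e-3, -0.6, "correlation sign"),
        "F": (2.2, 1e-3, -2.0, 1e-3, 1.8, 1e-3, 0.1, "correlation p"),
        "G": (2.2, 1e-3, -2.0, 1e-3, 0.2, 1e-3, 0.8, "mRNA fold-change"),
        "H": (2.2, 1e-3, -2.0, 1e-3, 1.8, 1e-3, None, "expression missing"),
    }

    lnc_mir, mir_mrna = [], []
    expression: dict[str, np.ndarray] = {}
    truth, decoys = [], []
    for name, (lfc, lp, mfc, mp, tfc, tp, corr, reason) in chains.items():
        lnc, mir, mrna = f"LINC-{name}", f"MIR-{name}", f"TRG-{name}"
        de(lnc, "lncRNA", lfc, lp)
        de(mir, "miRNA", mfc, mp)
        de(mrna, "mRNA", tfc, tp)
        lnc_mir.append((lnc, mir))
        mir_mrna.append((mir, mrna))
        x = rng.normal(5.0, 1.0, n_samples)
        if reason != "expression missing":
            expression[lnc] = x
            expression[mrna] = _vector_with_exact_correlation(rng, x, corr)
        else:
            expression[mrna] = rng.normal(5.0, 1.0, n_samples)
        triplet = (lnc, mir, mrna)
        if reason is None:
            truth.append(triplet)
        else:
            decoys.append({"triplet": triplet, "reason": reason})

    samples = [f"SAMPLE{i:02d}" for i in range(n_samples)]
    expr = pd.DataFrame(expression, index=samples).T
    expr.index.name = "symbol"
    targets = [f"TRG-{n}" for n in chains]
    return CeRNAFixture(
        pd.DataFrame(de_rows), lnc_mir, mir_mrna, expr, targets, truth, decoys
    )


def config_as_dict(config: SimulationConfig) -> dict:
    return asdict(config)
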