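# spotniche

Spatial-transcriptomics niche analysis around a marker-defined tumor
subregion, on the 10x Visium-style hexagonal spot lattice.

The motivating question is how the microenvironment differs next to tumor
regions that express a marker gene (CDKN2A in colorectal cancer, where its
expression tracks resistance to cuproptosis, the copper-dependent cell
death) versus tumor regions that do not. `spotniche` provides the full
chain as a tested, reusable library and CLI:

- **Spot annotation** — tumor spots are split into marker-positive
  (raw count ≥ threshold, default 1 UMI), marker-negative, and "other"
  (e.g. necrotic, excluded from statistics); a manual-override channel with
  an audit trail mirrors pathology curation.
- **Nearby-niche classification** — non-tumor spots are classed by the
  tumor spots they touch on the hex lattice: `nearby_pos`, `nearby_neg`,
  `nearby_both`, or `nearby_none`. Adjacency is ring-1 hex by default, with
  ring-k and pixel-distance modes.
- **Per-spot ssGSEA** — the single-sample weighted-ECDF running sum: genes
  ranked per spot, in-set steps weighted by |rank|^α (α = 0.75), out-of-set
  steps uniform; ES is the summed difference. Group contrasts use the
  *ratio of median enrichment scores*.
- **Transcriptional diversity** — D = 1.4826 × MAD of all pairwise Pearson
  correlations among highly variable genes across tumor spots; 1/D is the
  conventional plotting axis against the marker expression rate.
- **Spot differential expression** — Wilcoxon rank-sum per gene with BH
  FDR, reporting log2 fold change of back-transformed normalized means and
  Δpct, the difference in expressing-spot proportion.
- **Pseudotime trajectory scores** — binned-control module scores for
  resistance and sensitivity gene sets along pseudotime, sliding-window
  smoothed with bootstrap bands, plus their difference.
- **ceRNA network** — lncRNA–miRNA–mRNA triplets filtered by the DE screen
  (lncRNA up: log2FC > 1, adj. p < 0.05; miRNA down; mRNA up) and a
  positive, significant lncRNA–mRNA Pearson correlation; every rejected
  triplet logs the filter it failed.
- **Synthetic data** — a seeded generator plants all of this structure
  (connected tumor/necrotic/marker blobs, negative-binomial counts with
  dropout, niche-elevated immune programs, monotone trajectory trends,
  ceRNA tables with decoys) so the entire pipeline runs and is tested
  without any download.

Normalization follows the LogNormalize convention,
`ln(1 + count · 10⁴ / spot_total)`, and HVGs are genes with normalized mean
in [0.125, 3] whose variance exceeds the median candidate variance.

## Worked example

```python
import spotniche as sn
from spotniche.synthetic_data import default_gene_sets

cfg = sn.SimulationConfig(seed=1)
grid = sn.make_hex_grid(cfg.n_rows, cfg.n_cols)
layout = sn.paint_layout(grid, cfg.seed, cfg.tumor_fraction,
                         cfg.necrotic_fraction, cfg.marker_fraction)
counts = sn.simulate_counts(layout, cfg)

ann = sn.call_marker_positivity(counts, layout.region_of, "CDKN2A")
classified = sn.classify_nearby(ann, sn.build_adjacency(grid))
print(sn.nearby_census(classified))

norm = sn.log_normalize(counts)
enr = sn.ssgsea_scores(norm, default_gene_sets(cfg))
diff = sn.differential_enrichment(
    enr,
    classified.spots_where(nearby_group="nearby_pos"),
    classified.spots_where(nearby_group="nearby_neg"),
)
print(diff[["signature", "median_a", "median_b", "ratio"]].round(4).to_string(index=False))

hvgs = sn.select_hvgs(norm)
div = sn.transcriptional_diversity(norm, hvgs, ann.spots_where(region="tumor"))
print(f"diversity D = {div.D:.4f} over {div.n_pairs} HVG pairs; 1/D = {div.inverse_D:.2f}")
```

prints

```
{'nearby_pos': 5, 'nearby_neg': 18, 'nearby_both': 5, 'nearby_none': 112, 'not_applicable': 60}
signature  median_a  median_b   ratio
 SPP1_TAM    0.4176    0.0276 15.1569
    TCELL    0.3380    0.2796  1.2091
diversity D = 0.1335 over 4560 HVG pairs; 1/D = 7.49
```

On this 200-spot tissue the planted SPP1⁺-TAM program is ~15× enriched
(ratio of median ssGSEA scores) in spots bordering marker-positive tumor
relative to spots bordering marker-negative tumor, while the control T-cell
program is near parity — the niche contrast the pipeline is built to
detect. D summarizes how dispersed the pairwise HVG correlations are in the
tumor region; its inverse is the axis plotted against the marker
expression rate (here `sn.marker_expression_rate(...)`).

The same chain runs from the shell over on-disk artifacts
(MatrixMarket counts, `tissue_positions.csv`, GMT signatures, TSV outputs):

```sh
spotniche run-all --outdir out --seed 1
spotniche cerna --outdir out --seed 1
```

Each stage writes a key-sorted JSON manifest (parameters, derived stage
seed, input checksums) and identical config + seed give byte-identical
outputs.

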