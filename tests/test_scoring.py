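import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

import spotniche as sn
from spotniche.synthetic_data import default_gene_sets, region_class_spots


def ssgsea_oracle(expr, genes, set_genes, alpha):
    """Independent brute-force running-sum ssGSEA for one sample.

    Walks the descending-expression gene list position by position,
    accumulating the weighted in-set ECDF and the uniform out-of-set ECDF
    explicitly; returns the sum of their differences.
    """
    n = len(genes)
    ranks = rankdata(expr, method="average")
    order = sorted(range(n), key=lambda i: (-expr[i], genes[i]))
    in_set = [genes[i] in set_genes for i in order]
    n_in = sum(in_set)
    denom = sum(abs(ranks[order[i]]) ** alpha for i in range(n) if in_set[i])
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in range(n):
        if in_set[i]:
            p_in += abs(ranks[order[i]]) ** alpha / denom
        else:
            p_out += 1.0 / (n - n_in)
        es += p_in - p_out
    return es


def random_norm(rng, n_genes=50, n_spots=10):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    spots = [f"S{j:02d}" for j in range(n_spots)]
    values = rng.gamma(1.5, 1.0, size=(n_genes, n_spots))
    values[rng.random(values.shape) < 0.3] = 0.0  # UMI-like tie-heavy zeros
    return sn.NormMatrix(genes, spots, values)


class TestSsgsea:
    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.75, 1.0])
    def test_matches_brute_force_oracle(self, rng, alpha):
        for _ in range(5):
            norm = random_norm(rng)
            set_genes = list(rng.choice(norm.gene_ids, size=8, replace=False))
            sets = sn.GeneSetCollection({"S": set_genes})
            enr = sn.ssgsea_scores(norm, sets, alpha=alpha, normalize=False)
            for j in range(len(norm.spot_ids)):
                expected = ssgsea_oracle(
                    norm.values[:, j], norm.gene_ids, set(set_genes), alpha
                )
                assert enr.scores[0, j] == pytest.approx(expected, abs=1e-9)

    def test_alpha_zero_reduces_to_unweighted_ks_form(self, rng):
        # with alpha=0 every in-set increment is 1/n_set
        norm = random_norm(rng, n_genes=30, n_spots=4)
        set_genes = list(rng.choice(norm.gene_ids, size=6, replace=False))
        enr = sn.ssgsea_scores(
            norm, sn.GeneSetCollection({"S": set_genes}), alpha=0.0, normalize=False
        )
        n = len(norm.gene_ids)
        for j in range(4):
            order = sorted(
                range(n), key=lambda i: (-norm.values[i, j], norm.gene_ids[i])
            )
            es = p_in = p_out = 0.0
            for i in order:
                if norm.gene_ids[i] in set_genes:
                    p_in += 1.0 / len(set_genes)
                else:
                    p_out += 1.0 / (n - len(set_genes))
                es += p_in - p_out
            assert enr.scores[0, j] == pytest.approx(es, abs=1e-9)

    def test_top_gene_set_scores_positive(self):
        genes = ["A", "B", "C", "D", "E"]
        values = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        norm = sn.NormMatrix(genes, ["S0"], values)
        enr = sn.ssgsea_scores(norm, sn.GeneSetCollection({"TOP": ["A"]}), normalize=False)
        assert enr.scores[0, 0] > 0

    def test_bottom_two_genes_score_negative(self):
        genes = ["A", "B", "C", "D", "E"]
        values = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        norm = sn.NormMatrix(genes, ["S0"], values)
        enr = sn.ssgsea_scores(
            norm, sn.GeneSetCollection({"BOT": ["D", "E"]}), normalize=False
        )
        assert enr.scores[0, 0] < 0

    def test_identical_spots_identical_scores(self, rng):
        col = rng.gamma(2.0, 1.0, size=20)
        norm = sn.NormMatrix(
            [f"G{i}" for i in range(20)], ["S0", "S1"], np.column_stack([col, col])
        )
        enr = sn.ssgsea_scores(
            norm, sn.GeneSetCollection({"S": ["G0", "G5", "G7"]})
        )
        assert enr.scores[0, 0] == enr.scores[0, 1]

    def test_invariant_under_monotone_transform(self, rng):
        norm = random_norm(rng, n_genes=25, n_spots=3)
        transformed = sn.NormMatrix(
            norm.gene_ids, norm.spot_ids, np.sqrt(norm.values) + 0.5
        )
        sets = sn.GeneSetCollection({"S": list(norm.gene_ids[:5])})
        a = sn.ssgsea_scores(norm, sets, normalize=False)
        b = sn.ssgsea_scores(transformed, sets, normalize=False)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_degenerate_sets_rejected(self, rng):
        norm = random_norm(rng, n_genes=10, n_spots=2)
        with pytest.raises(ValueError, match="shares no genes"):
            sn.ssgsea_scores(norm, sn.GeneSetCollection({"S": ["NOPE"]}))
        with pytest.raises(ValueError, match="covers every gene"):
            sn.ssgsea_scores(norm, sn.GeneSetCollection({"S": list(norm.gene_ids)}))


class TestModuleScore:
    def test_all_zero_matrix_scores_zero(self):
        norm = sn.NormMatrix(
            [f"G{i}" for i in range(30)], ["S0", "S1"], np.zeros((30, 2))
        )
        score = sn.module_score(norm, ["G0", "G1"], n_bins=5, seed=0)
        assert (score == 0).all()

    def test_planted_program_elevated_on_its_spots(self, sim_config, tissue):
        grid, layout, counts = tissue
        norm = sn.log_normalize(counts)
        classes = region_class_spots(layout)
        score = sn.module_score(norm, sim_config.program_genes["SPP1_TAM"], seed=0)
        target = sorted(classes["near_marker_pos"])
        other = sorted(classes["normal"] - classes["near_marker_pos"])
        assert score[target].mean() > score[other].mean()

    def test_seed_determinism(self, rng):
        norm = random_norm(rng, n_genes=60, n_spots=5)
        a = sn.module_score(norm, norm.gene_ids[:4], n_bins=10, seed=7)
        b = sn.module_score(norm, norm.gene_ids[:4], n_bins=10, seed=7)
        assert a.equals(b)


class TestCuproptosisCurves:
    def _toy(self, n=60, seed=0):
        cfg = sn.SimulationConfig(seed=seed)
        cfg.trajectory.n_cells = n
        return sn.simulate_trajectory(cfg), cfg

    def test_difference_column_exact(self):
        (nm, t), cfg = self._toy()
        ts = sn.cuproptosis_curves(
            nm, t, cfg.trajectory.resistance_genes, cfg.trajectory.sensitivity_genes,
            window_fraction=0.2, n_boot=50, seed=0,
        )
        np.testing.assert_array_equal(
            ts.cells["difference"], ts.cells["resistance"] - ts.cells["sensitivity"]
        )

    def test_reversed_pseudotime_mirrors_mean_curves(self):
        (nm, t), cfg = self._toy()
        kw = dict(window_fraction=0.2, n_boot=10, seed=0)
        fwd = sn.cuproptosis_curves(
            nm, t, cfg.trajectory.resistance_genes, cfg.trajectory.sensitivity_genes, **kw
        )
        rev = sn.cuproptosis_curves(
            nm, 1.0 - t, cfg.trajectory.resistance_genes, cfg.trajectory.sensitivity_genes, **kw
        )
        np.testing.assert_allclose(
            fwd.curves["res_mean"].to_numpy(),
            rev.curves["res_mean"].to_numpy()[::-1],
            atol=1e-12,
        )

    def test_window_too_small_rejected(self):
        (nm, t), cfg = self._toy(n=20)
        with pytest.raises(ValueError, match="window"):
            sn.cuproptosis_curves(
                nm, t, cfg.trajectory.resistance_genes,
                cfg.trajectory.sensitivity_genes, window_fraction=0.05,
            )

    def test_overlapping_sets_rejected(self):
        (nm, t), cfg = self._toy(n=30)
        with pytest.raises(ValueError, match="overlap"):
            sn.cuproptosis_curves(nm, t, ["RES1"], ["RES1", "SEN1"])


class TestDifferentialEnrichment:
    def _enr(self, a_scores, b_scores):
        scores = np.array([a_scores + b_scores])
        spots = [f"A{i}" for i in range(len(a_scores))] + [
            f"B{i}" for i in range(len(b_scores))
        ]
        enr = sn.EnrichmentMatrix(["SIG"], spots, scores, "ssgsea")
        return enr, [s for s in spots if s.startswith("A")], [
            s for s in spots if s.startswith("B")
        ]

    def test_ratio_of_medians(self):
        enr, a, b = self._enr([0.4, 0.4, 0.4], [0.2, 0.2, 0.2])
        out = sn.differential_enrichment(enr, a, b)
        assert out.loc[0, "ratio"] == pytest.approx(2.0)

    def test_identical_groups_ratio_one(self):
        enr, a, b = self._enr([0.3, 0.5, 0.4], [0.4, 0.3, 0.5])
        out = sn.differential_enrichment(enr, a, b)
        assert out.loc[0, "ratio"] == pytest.approx(1.0)

    def test_zero_median_flagged_with_difference(self):
        enr, a, b = self._enr([0.4, 0.4, 0.4], [0.0, 0.0, 0.0])
        out = sn.differential_enrichment(enr, a, b)
        assert "undefined" in out.loc[0, "flag"]
        assert np.isnan(out.loc[0, "ratio"])
        assert out.loc[0, "difference"] == pytest.approx(0.4)

    def test_empty_group_rejected(self):
        enr, a, b = self._enr([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            sn.differential_enrichment(enr, a, [])


def test_planted_tam_signature_higher_near_marker_positive(sim_config, tissue, annotated):
    """The planted niche contrast: SPP1-TAM ssGSEA scores are stochastically
    larger in nearby_pos spots than nearby_neg spots."""
    grid, layout, counts = tissue
    classified, _ = annotated
    norm = sn.log_normalize(counts)
    enr = sn.ssgsea_scores(norm, default_gene_sets(sim_config))
    tam = enr.row("SPP1_TAM")
    a = tam[classified.spots_where(nearby_group="nearby_pos")]
    b = tam[classified.spots_where(nearby_group="nearby_neg")]
    assert len(a) >= 3 and len(b) >= 3
    p = mannwhitneyu(a, b, alternative="greater").pvalue
    assert p < 0.01
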