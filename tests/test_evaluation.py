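import numpy as np
import pytest

from netimpute import (
    assign_quartiles,
    common_imputed_entries,
    evaluate,
    mask_uniform_per_gene,
    per_gene_correlation,
    per_gene_mse,
    top_performers,
)
from netimpute.masking import MaskedDataset

from .conftest import make_matrix, random_sparse_matrix


def _masked_fixture(rng, n_genes=6, n_cells=30, fraction=0.4):
    matrix = make_matrix(rng.uniform(1.0, 6.0, size=(n_genes, n_cells)))
    return mask_uniform_per_gene(matrix, fraction, seed=0)


def _shifted(masked, a=1.0, b=0.0):
    """An 'imputation' equal to a*original + b at every entry."""
    out = masked.original.copy()
    out.values = a * out.values + b
    return out


class TestCommonImputedEntries:
    def test_everything_imputed_returns_all_coords(self, rng):
        masked = _masked_fixture(rng)
        imp = _shifted(masked)
        assert common_imputed_entries(masked, {"A": imp}) == masked.coords

    def test_method_imputing_nothing_empties_the_set(self, rng):
        masked = _masked_fixture(rng)
        assert common_imputed_entries(
            masked, {"A": _shifted(masked), "B": masked.masked}
        ) == []

    def test_hand_intersection_on_small_fixture(self):
        matrix = make_matrix(np.full((2, 12), 3.0))
        masked = mask_uniform_per_gene(matrix, 0.5, seed=1)
        imp_a = _shifted(masked)
        imp_b = _shifted(masked)
        # B fails to impute the first masked coordinate of gene g0
        g, c, _ = next(co for co in masked.coords if co[0] == "g0")
        imp_b.values[imp_b.gene_index()[g], imp_b.cell_ids.index(c)] = 0.0
        got = common_imputed_entries(masked, {"A": imp_a, "B": imp_b})
        assert got == [co for co in masked.coords if not (co[0] == g and co[1] == c)]

    def test_shape_mismatch_rejected(self, rng):
        masked = _masked_fixture(rng)
        with pytest.raises(ValueError, match="shape"):
            common_imputed_entries(masked, {"A": make_matrix(np.ones((2, 2)))})


class TestPerGeneCorrelation:
    def test_perfect_imputation_gives_r_one(self, rng):
        masked = _masked_fixture(rng)
        corr = per_gene_correlation(masked, _shifted(masked), masked.coords)
        assert corr and all(r == pytest.approx(1.0) for r in corr.values())

    def test_affine_invariance(self, rng):
        masked = _masked_fixture(rng)
        corr = per_gene_correlation(masked, _shifted(masked, 2.0, 3.0), masked.coords)
        assert corr and all(r == pytest.approx(1.0) for r in corr.values())

    def test_matches_textbook_formula_on_12_points(self, rng):
        matrix = make_matrix(rng.uniform(1.0, 6.0, size=(1, 24)))
        masked = mask_uniform_per_gene(matrix, 0.5, seed=2)  # 12 masked entries
        imp = masked.original.copy()
        noise = rng.normal(0, 0.5, imp.values.shape)
        imp.values = np.abs(imp.values + noise)
        corr = per_gene_correlation(masked, imp, masked.coords)
        # independent evaluation of the product-moment formula
        orig = np.array([v for _, _, v in masked.coords])
        pred = np.array(
            [imp.values[0, imp.cell_ids.index(c)] for _, c, _ in masked.coords]
        )
        sx, sy = orig - orig.mean(), pred - pred.mean()
        expected = float((sx @ sy) / np.sqrt((sx @ sx) * (sy @ sy)))
        assert corr["g0"] == pytest.approx(expected, abs=1e-12)

    def test_min_entries_and_constant_sides_are_absent(self, rng):
        masked = _masked_fixture(rng, n_cells=30)
        imp = _shifted(masked)
        assert per_gene_correlation(masked, imp, masked.coords, min_entries=13) == {}
        constant = masked.original.copy()
        constant.values = np.full_like(constant.values, 2.0)
        assert per_gene_correlation(masked, constant, masked.coords) == {}


class TestPerGeneMse:
    def test_perfect_imputation_zero_error(self, rng):
        masked = _masked_fixture(rng)
        mse = per_gene_mse(masked, _shifted(masked), masked.coords)
        assert all(v == 0.0 for v in mse.values())

    def test_constant_error_squares(self, rng):
        masked = _masked_fixture(rng)
        mse = per_gene_mse(masked, _shifted(masked, 1.0, 2.0), masked.coords)
        assert all(v == pytest.approx(4.0) for v in mse.values())

    def test_mixed_errors_average(self):
        matrix = make_matrix(np.array([[5.0, 5.0, 5.0, 9.9]]))
        masked = mask_uniform_per_gene(matrix, 0.75, seed=0)  # 3 masked entries
        imp = masked.original.copy()
        errors = {co: e for co, e in zip(masked.coords, (1.0, -1.0, 2.0))}
        for (g, c, v), e in errors.items():
            imp.values[0, imp.cell_ids.index(c)] = v - e
        mse = per_gene_mse(masked, imp, masked.coords)
        assert mse["g0"] == pytest.approx(2.0)  # (1 + 1 + 4) / 3

    def test_affine_closed_form(self, rng):
        masked = _masked_fixture(rng)
        a, b = 1.5, -0.25
        mse = per_gene_mse(masked, _shifted(masked, a, b), masked.coords)
        by_gene = {}
        for g, _, v in masked.coords:
            by_gene.setdefault(g, []).append(((a - 1.0) * v + b) ** 2)
        for g, vals in by_gene.items():
            assert mse[g] == pytest.approx(np.mean(vals))


class TestAssignQuartiles:
    def test_eight_increasing_means_split_evenly(self):
        matrix = make_matrix(np.arange(1, 9, dtype=float)[:, None] * np.ones((8, 4)))
        quarts = list(assign_quartiles(matrix).values())
        assert quarts == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_ties_broken_by_gene_order(self):
        matrix = make_matrix(np.ones((4, 3)))
        assert assign_quartiles(matrix) == {
            "g0": "Q1", "g1": "Q2", "g2": "Q3", "g3": "Q4"
        }

    def test_invariant_to_cell_permutation(self, rng):
        matrix = random_sparse_matrix(rng)
        perm = rng.permutation(matrix.n_cells)
        shuffled = make_matrix(matrix.values[:, perm])
        shuffled.cell_ids = [matrix.cell_ids[j] for j in perm]
        assert assign_quartiles(matrix) == assign_quartiles(shuffled)


class TestTopPerformers:
    def test_correlation_band_example(self):
        rs = {"A": {"g": 0.9}, "B": {"g": 0.85}, "C": {"g": 0.5}}
        top, foreground = top_performers(rs, "correlation")["g"]
        assert top == {"A", "B"} and foreground

    def test_all_within_band_is_background_only(self):
        rs = {"A": {"g": 0.9}, "B": {"g": 0.85}, "C": {"g": 0.82}}
        top, foreground = top_performers(rs, "correlation")["g"]
        assert top == {"A", "B", "C"} and not foreground

    def test_mse_range_band_example(self):
        mses = {"A": {"g": 1.0}, "B": {"g": 1.02}, "C": {"g": 2.0}}
        top, foreground = top_performers(mses, "mse")["g"]
        assert top == {"A", "B"} and foreground

    def test_needs_two_methods(self):
        with pytest.raises(ValueError, match="2 methods"):
            top_performers({"A": {"g": 1.0}}, "mse")


class TestEvaluateReport:
    def test_report_table_is_method_order_independent(self, rng):
        masked = _masked_fixture(rng, n_genes=5, n_cells=40)
        noisy = masked.original.copy()
        noisy.values = np.abs(noisy.values + rng.normal(0, 1.0, noisy.values.shape))
        imps = {"A": _shifted(masked), "B": noisy}
        r1 = evaluate(masked, imps)
        r2 = evaluate(masked, dict(reversed(list(imps.items()))))
        t1 = r1.table.sort_values(["gene", "method"]).reset_index(drop=True)
        t2 = r2.table.sort_values(["gene", "method"]).reset_index(drop=True)
        assert t1.equals(t2)
        assert set(r1.table.columns) >= {
            "gene", "method", "n", "pearson_r", "mse", "quartile", "top_corr", "top_mse"
        }

    def test_report_round_trips_to_tsv(self, rng, tmp_path):
        masked = _masked_fixture(rng)
        report = evaluate(masked, {"A": _shifted(masked), "B": _shifted(masked, 2.0)})
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        assert out.read_text().startswith("gene\tmethod\tn\t")
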