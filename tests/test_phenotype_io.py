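import numpy as np
import pytest

from phenocomplete import (
    PhenotypeSchema,
    apply_normalization,
    fit_normalization,
    read_phenotype_table,
    split_individuals,
    write_phenotype_table,
)

from conftest import make_matrix


class TestReadWrite:
    def test_roundtrip_is_identity_on_values_mask_ids(self, tmp_path, small_matrix):
        path = tmp_path / "pheno.tsv"
        write_phenotype_table(small_matrix, path)
        back = read_phenotype_table(path, small_matrix.schema)
        assert back.ids == small_matrix.ids
        np.testing.assert_array_equal(back.mask, small_matrix.mask)
        np.testing.assert_allclose(
            back.values[back.mask], small_matrix.values[small_matrix.mask]
        )

    def test_csv_roundtrip(self, tmp_path, small_matrix):
        path = tmp_path / "pheno.csv"
        write_phenotype_table(small_matrix, path)
        back = read_phenotype_table(path, small_matrix.schema)
        np.testing.assert_array_equal(back.mask, small_matrix.mask)

    def test_header_only_file_gives_empty_matrix(self, tmp_path):
        schema = PhenotypeSchema(("x", "y"), ("continuous", "binary"))
        path = tmp_path / "empty.tsv"
        path.write_text("IID\tx\ty\n")
        data = read_phenotype_table(path, schema)
        assert data.n_samples == 0
        assert data.n_phenotypes == 2

    def test_na_cell_sets_single_mask_zero(self, tmp_path):
        schema = PhenotypeSchema(("x", "y"), ("continuous", "continuous"))
        path = tmp_path / "t.tsv"
        path.write_text("IID\tx\ty\nA\t1\t2\nB\tNA\t4\nC\t5\t6\n")
        data = read_phenotype_table(path, schema)
        assert data.mask.sum() == 5
        assert not data.mask[1, 0]

    @pytest.mark.parametrize("token", ["na", "NaN", "NAN", ""])
    def test_missing_tokens_case_insensitive(self, tmp_path, token):
        schema = PhenotypeSchema(("x",), ("continuous",))
        path = tmp_path / "t.tsv"
        path.write_text(f"IID\tx\nA\t{token}\nB\t3\n")
        data = read_phenotype_table(path, schema)
        assert not data.mask[0, 0] and data.mask[1, 0]

    def test_columns_reordered_continuous_first(self, tmp_path):
        schema = PhenotypeSchema(("b", "x"), ("binary", "continuous"))
        path = tmp_path / "t.tsv"
        path.write_text("IID\tb\tx\nA\t1\t2.5\n")
        data = read_phenotype_table(path, schema)
        assert data.schema.names == ("x", "b")
        assert data.original_columns == ("b", "x")
        out = tmp_path / "o.tsv"
        write_phenotype_table(data, out)
        assert out.read_text().splitlines()[0] == "IID\tb\tx"

    def test_read_errors(self, tmp_path):
        schema = PhenotypeSchema(("x", "b"), ("continuous", "binary"))
        bad_col = tmp_path / "a.tsv"
        bad_col.write_text("IID\tx\tb\tz\nA\t1\t0\t2\n")
        with pytest.raises(ValueError, match="not in schema"):
            read_phenotype_table(bad_col, schema)
        non_num = tmp_path / "b.tsv"
        non_num.write_text("IID\tx\tb\nA\thello\t0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_phenotype_table(non_num, schema)
        bad_bin = tmp_path / "c.tsv"
        bad_bin.write_text("IID\tx\tb\nA\t1\t2\n")
        with pytest.raises(ValueError, match="outside"):
            read_phenotype_table(bad_bin, schema)
        dup = tmp_path / "d.tsv"
        dup.write_text("IID\tx\tb\nA\t1\t0\nA\t2\t1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_phenotype_table(dup, schema)

    def test_schema_json_roundtrip(self, tmp_path):
        schema = PhenotypeSchema(("x", "o", "b"), ("continuous", "ordinal", "binary"))
        schema.to_json(tmp_path / "s.json")
        assert PhenotypeSchema.from_json(tmp_path / "s.json") == schema
        assert schema.n_continuous == 2  # ordinal counts toward C


class TestSplit:
    def test_partition_is_disjoint_and_complete(self, small_matrix):
        train, val, test = split_individuals(small_matrix, 0.5, 0.2, seed=3)
        ids = [*train.ids, *val.ids, *test.ids]
        assert sorted(ids) == sorted(small_matrix.ids)
        assert len(set(ids)) == len(ids)

    def test_fifty_fifty_then_eighty_twenty_proportions(self):
        data = make_matrix(n=1000, seed=5)
        train, val, test = split_individuals(data, 0.5, 0.2, seed=1)
        assert test.n_samples == 500
        assert val.n_samples == 100  # 20% of the remaining half
        assert train.n_samples == 400

    def test_zero_test_fraction(self, small_matrix):
        train, val, test = split_individuals(small_matrix, 0.0, 0.2, seed=1)
        assert test.n_samples == 0
        assert train.n_samples + val.n_samples == small_matrix.n_samples

    def test_same_seed_identical_split(self):
        data = make_matrix(n=100, seed=2)
        a = split_individuals(data, 0.3, 0.1, seed=9)
        b = split_individuals(data, 0.3, 0.1, seed=9)
        for x, y in zip(a, b):
            assert x.ids == y.ids

    def test_errors(self, small_matrix):
        with pytest.raises(ValueError):
            split_individuals(small_matrix, 1.0, 0.2, seed=0)
        with pytest.raises(ValueError):
            split_individuals(small_matrix, -0.1, 0.2, seed=0)
        tiny = make_matrix(n=3, seed=0)
        with pytest.raises(ValueError, match="too small"):
            split_individuals(tiny, 0.01, 0.0, seed=0)


class TestNormalization:
    def test_mean_and_population_sd(self, tmp_path):
        schema = PhenotypeSchema(("x",), ("continuous",))
        path = tmp_path / "t.tsv"
        path.write_text("IID\tx\nA\t1\nB\t2\nC\t3\n")
        stats = fit_normalization(read_phenotype_table(path, schema))
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.sd[0] == pytest.approx(np.sqrt(2.0 / 3.0))  # divide-by-N
        assert stats.binary_recode

    def test_constant_column_error_names_column(self, tmp_path):
        schema = PhenotypeSchema(("x",), ("continuous",))
        path = tmp_path / "t.tsv"
        path.write_text("IID\tx\nA\t5\nB\t5\nC\t5\n")
        with pytest.raises(ValueError, match="'x'"):
            fit_normalization(read_phenotype_table(path, schema))

    def test_forward_inverse_identity(self, small_matrix):
        stats = fit_normalization(small_matrix)
        fwd = apply_normalization(small_matrix, stats, "forward")
        back = apply_normalization(fwd, stats, "inverse")
        np.testing.assert_allclose(
            back.values[back.mask], small_matrix.values[small_matrix.mask], atol=1e-10
        )
        np.testing.assert_array_equal(back.mask, small_matrix.mask)

    def test_no_leakage_train_stats_on_shifted_test(self):
        train = make_matrix(n=200, seed=1)
        test = make_matrix(n=200, seed=2)
        test.values[test.mask[:, 0], 0] += 10.0  # shift must survive
        stats = fit_normalization(train)
        normed = apply_normalization(test, stats, "forward")
        col = normed.values[normed.mask[:, 0], 0]
        assert abs(col.mean()) > 1.0

    def test_missing_cells_stay_sentinel(self, small_matrix):
        stats = fit_normalization(small_matrix)
        fwd = apply_normalization(small_matrix, stats, "forward")
        assert np.isnan(fwd.values[~fwd.mask]).all()

    def test_stats_json_roundtrip(self, tmp_path, small_matrix):
        from phenocomplete import NormalizationStats

        stats = fit_normalization(small_matrix)
        stats.to_json(tmp_path / "stats.json")
        back = NormalizationStats.from_json(tmp_path / "stats.json")
        np.testing.assert_allclose(back.mean[:6], stats.mean[:6])
        assert np.isnan(back.sd[6:]).all()
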