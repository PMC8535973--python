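import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_clinical, make_expr
from pyropattern.data_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    correct_batch,
    filter_samples,
    fpkm_to_tpm,
    merge_cohorts,
    read_clinical,
    read_expression,
    read_gene_sets,
    write_clinical,
    write_expression,
    write_gene_sets,
)
from pyropattern.synthetic_data import SimulationConfig, simulate_study


class TestExpressionMatrix:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene_ids"):
            make_expr(np.ones((2, 2)), genes=["A", "A"])

    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample_ids"):
            make_expr(np.ones((2, 2)), samples=["S", "S"])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            make_expr([[1.0, np.nan]], scale="log2")

    def test_negative_linear_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_expr([[1.0, -1.0]], scale="linear")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ExpressionMatrix(["A"], ["S1", "S2"], np.ones((2, 2)))

    def test_to_log2_round_values(self):
        m = make_expr([[1.0, 3.0]], scale="linear")
        out = m.to_log2()
        assert out.scale == "log2"
        np.testing.assert_allclose(out.values, [[1.0, 2.0]])


class TestFpkmToTpm:
    def test_simple_column(self):
        m = make_expr(np.array([[5.0], [10.0], [5.0]]), scale="linear")
        out = fpkm_to_tpm(m)
        np.testing.assert_allclose(out.values[:, 0], [250000, 500000, 250000])

    def test_scale_invariance(self, rng):
        col = rng.uniform(0.1, 50, size=(30, 1))
        a = fpkm_to_tpm(make_expr(col, scale="linear"))
        b = fpkm_to_tpm(make_expr(2 * col, scale="linear"))
        np.testing.assert_allclose(a.values, b.values)

    def test_matches_direct_formula(self, rng):
        col = rng.uniform(0.01, 100, size=50)
        m = make_expr(col[:, None], scale="linear")
        out = fpkm_to_tpm(m)
        expected = col / col.sum() * 1e6  # the formula, evaluated element-wise
        np.testing.assert_allclose(out.values[:, 0], expected)

    @given(
        arrays(
            np.float64,
            (7, 4),
            elements=st.floats(0, 1e4, allow_nan=False, allow_infinity=False),
        ).filter(lambda a: (a.sum(axis=0) > 1e-6).all())
    )
    @settings(max_examples=50, deadline=None)
    def test_column_sums_property(self, values):
        out = fpkm_to_tpm(make_expr(values, scale="linear"))
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_column_names_sample(self):
        m = make_expr(np.array([[0.0, 1.0], [0.0, 2.0]]), samples=["BAD", "OK"])
        m.scale = "linear"
        with pytest.raises(ValueError, match="BAD"):
            fpkm_to_tpm(m)

    def test_log2_scale_rejected(self, small_expr):
        with pytest.raises(ValueError, match="linear"):
            fpkm_to_tpm(small_expr)


class TestFilterSamples:
    def test_min_days_threshold(self):
        c = make_clinical([10, 29, 30, 400], [1, 1, 0, 1])
        kept, removed = filter_samples(c, min_days=30)
        assert list(kept.time) == [30, 400]
        assert removed == ["S0", "S1"]

    def test_missing_event_removed(self):
        df = pd.DataFrame(
            {"time": [100.0, 200.0], "event": [1.0, np.nan]},
            index=pd.Index(["A", "B"], name="sample_id"),
        )
        kept, removed = filter_samples(type("T", (), {"data": df})(), min_days=30)
        assert removed == ["B"]

    def test_min_days_zero_is_identity(self):
        c = make_clinical([5, 10, 400], [1, 0, 1])
        kept, removed = filter_samples(c, min_days=0)
        assert removed == []
        assert kept.data.equals(c.data)

    def test_empty_result_warns(self):
        c = make_clinical([5, 10], [1, 0])
        with pytest.warns(UserWarning, match="every sample"):
            kept, removed = filter_samples(c, min_days=1000)
        assert len(removed) == 2
        assert len(kept.sample_ids) == 0


class TestMergeCohorts:
    def test_gene_intersection(self):
        a = make_expr(np.ones((2, 2)), genes=["A", "B"], samples=["s1", "s2"])
        b = make_expr(np.ones((3, 2)), genes=["A", "B", "C"], samples=["s3", "s4"])
        merged = merge_cohorts([a, b])
        assert merged.gene_ids == ["A", "B"]
        assert merged.sample_ids == ["s1", "s2", "s3", "s4"]

    def test_single_cohort_identity(self, small_expr):
        merged = merge_cohorts([small_expr])
        np.testing.assert_array_equal(merged.values, small_expr.values)
        assert merged.gene_ids == small_expr.gene_ids

    def test_matches_set_intersection_oracle(self, rng):
        universe = [f"G{i}" for i in range(30)]
        mats = []
        for c in range(3):
            genes = sorted(rng.choice(30, size=20, replace=False))
            names = [universe[i] for i in genes]
            mats.append(
                make_expr(
                    rng.normal(size=(20, 3)),
                    genes=names,
                    samples=[f"c{c}s{j}" for j in range(3)],
                )
            )
        merged = merge_cohorts(mats)
        oracle = set(mats[0].gene_ids) & set(mats[1].gene_ids) & set(mats[2].gene_ids)
        assert set(merged.gene_ids) == oracle

    def test_row_content_associative(self, rng):
        mats = [
            make_expr(
                rng.normal(size=(6, 2)),
                genes=[f"G{i}" for i in sorted(rng.choice(9, 6, replace=False))],
                samples=[f"c{c}s{j}" for j in range(2)],
            )
            for c in range(3)
        ]
        ab_c = merge_cohorts([merge_cohorts(mats[:2]), mats[2]])
        abc = merge_cohorts(mats)
        assert set(ab_c.gene_ids) == set(abc.gene_ids)
        pd.testing.assert_frame_equal(
            ab_c.to_frame().loc[sorted(ab_c.gene_ids)],
            abc.to_frame().loc[sorted(abc.gene_ids)],
        )

    def test_duplicate_sample_rejected(self):
        a = make_expr(np.ones((2, 1)), genes=["A", "B"], samples=["s1"])
        b = make_expr(np.ones((2, 1)), genes=["A", "B"], samples=["s1"])
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_cohorts([a, b])

    def test_empty_intersection_rejected(self):
        a = make_expr(np.ones((1, 1)), genes=["A"], samples=["s1"])
        b = make_expr(np.ones((1, 1)), genes=["B"], samples=["s2"])
        with pytest.raises(ValueError, match="no genes shared"):
            merge_cohorts([a, b])

    def test_mixed_scales_rejected(self):
        a = make_expr(np.ones((1, 1)), genes=["A"], samples=["s1"], scale="linear")
        b = make_expr(np.ones((1, 1)), genes=["A"], samples=["s2"], scale="log2")
        with pytest.raises(ValueError, match="different scales"):
            merge_cohorts([a, b])


class TestCorrectBatch:
    def _two_cohorts(self, rng, shift=3.0):
        x = rng.normal(5, 1, size=(10, 20))
        x[:, 10:] += shift
        cohort = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        return make_expr(x, cohort=cohort)

    def test_single_cohort_rejected(self, small_expr):
        with pytest.raises(ValueError, match="two cohorts"):
            correct_batch(small_expr)

    def test_one_sample_cohort_rejected(self, rng):
        m = make_expr(rng.normal(size=(3, 3)), cohort=np.array(["a", "a", "b"]))
        with pytest.raises(ValueError, match="fewer than 2"):
            correct_batch(m)

    def test_linear_scale_rejected(self, rng):
        m = make_expr(
            rng.uniform(1, 5, size=(3, 4)),
            scale="linear",
            cohort=np.array(["a", "a", "b", "b"]),
        )
        with pytest.raises(ValueError, match="log2"):
            correct_batch(m)

    def test_constant_shift_removed(self, rng):
        m = self._two_cohorts(rng)
        out = correct_batch(m)
        for g in range(out.n_genes):
            mean_a = out.values[g, :10].mean()
            mean_b = out.values[g, 10:].mean()
            assert abs(mean_a - mean_b) < 1e-9

    def test_idempotent(self, rng):
        m = self._two_cohorts(rng)
        once = correct_batch(m)
        twice = correct_batch(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_within_cohort_order_preserved(self, rng):
        m = self._two_cohorts(rng)
        out = correct_batch(m)
        for mask in (slice(0, 10), slice(10, 20)):
            before = np.argsort(m.values[:, mask], axis=1)
            after = np.argsort(out.values[:, mask], axis=1)
            np.testing.assert_array_equal(before, after)

    def test_zero_variance_cell_centers_only(self):
        x = np.array([[1.0, 1.0, 2.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        m = make_expr(x, cohort=np.array(["a", "a", "b", "b"]))
        with pytest.warns(UserWarning, match="zero variance"):
            out = correct_batch(m)
        # cohort means still equalized for the degenerate gene
        assert abs(out.values[0, :2].mean() - out.values[0, 2:].mean()) < 1e-9

    def test_simulated_batch_variance_fraction(self):
        cfg = SimulationConfig(
            seed=7,
            samples_per_pattern=40,
            n_regulators=10,
            n_signature_genes=10,
            n_noise_genes=30,
            n_cohorts=3,
            batch_shift_sd=2.0,
            batch_scale_range=(0.5, 2.0),
        )
        expr, *_ = simulate_study(cfg)
        out = correct_batch(expr)
        # between-cohort fraction of per-gene variance < 1% after correction
        labels = np.asarray(out.cohort)
        fracs = []
        for g in range(out.n_genes):
            x = out.values[g]
            total = x.var()
            if total == 0:
                continue
            grand = x.mean()
            between = sum(
                (labels == c).sum() * (x[labels == c].mean() - grand) ** 2
                for c in np.unique(labels)
            ) / len(x)
            fracs.append(between / total)
        assert max(fracs) < 0.01


class TestGeneSets:
    def test_gmt_duplicate_member_warns(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tA\tB\tA\n")
        with pytest.warns(UserWarning, match="duplicate members"):
            sets = read_gene_sets(p)
        assert sets["S1"] == ["A", "B"]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_gene_sets(p)

    def test_short_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("S1\tdesc\tA\nS2\tonlydesc\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gene_sets(p)

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("S1\td\tA\tB\nS1\td\tC\tD\n")
        with pytest.raises(ValueError, match="duplicate set name"):
            read_gene_sets(p)

    def test_round_trip(self, tmp_path, rng):
        sets = GeneSetCollection(
            {
                f"SET{i}": [f"G{j}" for j in rng.choice(50, size=5 + i, replace=False)]
                for i in range(4)
            }
        )
        p = tmp_path / "rt.gmt"
        write_gene_sets(sets, p)
        assert read_gene_sets(p) == sets

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection({"S": []})


class TestTableIO:
    def test_expression_round_trip(self, tmp_path, small_expr):
        p = tmp_path / "expr.tsv"
        write_expression(small_expr, p)
        back = read_expression(p, scale="log2")
        np.testing.assert_allclose(back.values, small_expr.values)
        assert back.gene_ids == small_expr.gene_ids

    def test_clinical_round_trip(self, tmp_path):
        c = make_clinical([100, 200, 50], [1, 0, 1], age=[60, 70, 55])
        p = tmp_path / "clin.tsv"
        write_clinical(c, p)
        back = read_clinical(p)
        pd.testing.assert_frame_equal(back.data, c.data, check_dtype=False)

    def test_clinical_validation(self):
        with pytest.raises(ValueError, match="positive"):
            make_clinical([0, 100], [1, 1])
        with pytest.raises(ValueError, match="binary"):
            make_clinical([10, 100], [1, 2])
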