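"""Preprocessing filters, aggregation, miRNA mapping, z-score, alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panprog.datatypes import ClinicalTable, InteractionTable, OmicsLayer
from panprog.harmonize import (
    aggregate_duplicates,
    align_dataset,
    filter_expression,
    filter_missing,
    filter_sample_type,
    harmonize_dataset,
    map_mirna_to_genes,
    zscore_normalize,
)


def _layer(values, kind="GE", genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return OmicsLayer(kind, pd.DataFrame(values, index=genes, columns=samples))


def _clinical(sample_ids, codes=None):
    n = len(sample_ids)
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "time_days": np.linspace(10, 100, n),
                "event": [1] * n,
                "sample_type_code": codes or ["01"] * n,
            }
        )
    )


class TestSampleTypeFilter:
    def test_keeps_primary_tumor_code(self):
        clin = _clinical(["a", "b", "c"], codes=["01", "01", "11"])
        assert filter_sample_type(clin).data.shape[0] == 2

    def test_all_matching_is_identity(self):
        clin = _clinical(["a", "b"])
        pd.testing.assert_frame_equal(filter_sample_type(clin).data, clin.data)

    def test_no_matching_empty_result(self):
        clin = _clinical(["a", "b"], codes=["11", "11"])
        assert filter_sample_type(clin).data.empty


class TestMissingFilter:
    @pytest.mark.parametrize(
        "n_missing,kept", [(6, False), (5, True), (0, True)],
        ids=["6-of-100-removed", "exactly-5pct-kept", "complete-kept"],
    )
    def test_five_percent_rule_is_strict(self, n_missing, kept):
        vals = np.ones((1, 100))
        vals[0, :n_missing] = np.nan
        out = filter_missing(_layer(np.vstack([vals, np.full((1, 100), 2.0)])))
        assert ("g0" in out.gene_ids) == kept

    def test_survivors_are_row_mean_imputed(self):
        vals = np.array([[1.0, 3.0, np.nan, np.nan, 2.0] + [2.0] * 95])
        out = filter_missing(_layer(vals))
        assert not out.values.isna().any().any()
        row = out.values.iloc[0]
        assert row.iloc[2] == pytest.approx(np.nanmean(vals))

    def test_idempotent(self):
        vals = np.random.default_rng(0).normal(size=(5, 40))
        vals[0, :5] = np.nan
        once = filter_missing(_layer(vals))
        twice = filter_missing(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestExpressionFilter:
    def test_ge_majority_positive_rule_strict(self):
        vals = np.zeros((2, 100))
        vals[0, :51] = 5.0  # positive in 51% -> kept
        vals[1, :50] = 5.0  # positive in exactly 50% -> removed
        out = filter_expression(_layer(vals, "GE"))
        assert out.gene_ids == ["g0"]

    def test_me_ten_percent_rule(self):
        vals = np.zeros((2, 100))
        vals[0, :11] = 2.0  # >1 in 11% -> kept
        vals[1, :10] = 2.0  # >1 in exactly 10% -> removed
        out = filter_expression(_layer(vals, "ME"))
        assert out.gene_ids == ["g0"]

    def test_non_expression_layers_pass_through(self):
        lay = _layer(np.zeros((3, 10)), "SCNA")
        assert filter_expression(lay) is lay


class TestAggregateDuplicates:
    def test_two_probes_average(self):
        lay = _layer([[1.0, 5.0], [3.0, 7.0]], genes=["gX", "gX"])
        out = aggregate_duplicates(lay)
        np.testing.assert_allclose(out.values.loc["gX"], [2.0, 6.0])

    def test_unique_rows_identity(self):
        lay = _layer([[1.0, 2.0], [3.0, 4.0]])
        assert aggregate_duplicates(lay) is lay

    def test_three_probes_match_direct_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(3, 4))
        lay = _layer(vals, genes=["gX"] * 3)
        out = aggregate_duplicates(lay)
        np.testing.assert_allclose(out.values.loc["gX"], vals.sum(axis=0) / 3.0)

    def test_conserves_group_mean_property(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 5))
        genes = ["a", "a", "b", "b", "b", "c"]
        out = aggregate_duplicates(_layer(vals, genes=genes))
        for g in "abc":
            rows = [i for i, x in enumerate(genes) if x == g]
            np.testing.assert_allclose(out.values.loc[g], vals[rows].mean(axis=0))


class TestMirnaMapping:
    def _interactions(self, rows):
        return InteractionTable(
            pd.DataFrame(
                rows, columns=["mirna_id", "gene_id", "n_experiments",
                               "n_anticorrelated_cancers"]
            )
        )

    def test_bound_mirnas_averaged_per_gene(self):
        me = _layer([[2.0, 8.0], [4.0, 2.0]], "ME", genes=["mir1", "mir2"])
        inter = self._interactions(
            [("mir1", "TP53", 6, 2), ("mir2", "TP53", 9, 1)]
        )
        out = map_mirna_to_genes(me, inter)
        np.testing.assert_allclose(out.values.loc["TP53"], [3.0, 5.0])

    def test_weak_interactions_excluded(self):
        me = _layer([[2.0, 8.0], [4.0, 2.0]], "ME", genes=["mir1", "mir2"])
        inter = self._interactions(
            [("mir1", "TP53", 4, 2), ("mir2", "TP53", 9, 1)]  # mir1: 4 expts
        )
        out = map_mirna_to_genes(me, inter)
        np.testing.assert_allclose(out.values.loc["TP53"], [4.0, 2.0])

    def test_single_interaction_copies_row(self):
        me = _layer([[2.0, 8.0]], "ME", genes=["mir1"])
        inter = self._interactions([("mir1", "KRAS", 5, 1)])
        out = map_mirna_to_genes(me, inter)
        np.testing.assert_allclose(out.values.loc["KRAS"], [2.0, 8.0])

    def test_nothing_survives_raises_with_thresholds(self):
        me = _layer([[1.0, 1.0]], "ME", genes=["mir1"])
        inter = self._interactions([("mir1", "KRAS", 2, 0)])
        with pytest.raises(ValueError, match="min_experiments=5"):
            map_mirna_to_genes(me, inter)


class TestZScore:
    def test_global_mean_zero_sd_one(self):
        lay = _layer([[1.0, 2.0], [3.0, 4.0]])
        out = zscore_normalize(lay)
        arr = out.values.to_numpy()
        assert abs(arr.mean()) < 1e-3
        assert arr.std() == pytest.approx(1.0, abs=1e-3)

    def test_four_decimal_rounding(self):
        rng = np.random.default_rng(4)
        out = zscore_normalize(_layer(rng.normal(size=(10, 10))))
        arr = out.values.to_numpy()
        np.testing.assert_array_equal(arr, np.round(arr, 4))

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="standard deviation"):
            zscore_normalize(_layer(np.full((3, 3), 7.0)))

    def test_per_gene_mode_rows_standardized(self):
        rng = np.random.default_rng(5)
        out = zscore_normalize(_layer(rng.normal(5, 3, size=(4, 50))), mode="per-gene")
        means = out.values.mean(axis=1)
        assert np.all(np.abs(means) < 1e-3)


class TestAlign:
    def test_sample_and_gene_intersection(self):
        layers = {
            "GE": _layer(np.ones((3, 3)), "GE", ["g1", "g2", "g3"], ["a", "b", "c"]),
            "SCNA": _layer(np.ones((2, 2)), "SCNA", ["g1", "g2"], ["a", "b"]),
            "DM": _layer(np.ones((3, 3)), "DM", ["g1", "g2", "g3"], ["a", "b", "c"]),
            "ME": _layer(np.ones((2, 2)), "ME", ["g2", "g1"], ["b", "a"]),
        }
        ds = align_dataset(layers, _clinical(["a", "b"]))
        assert ds.sample_ids == ["a", "b"]
        assert sorted(ds.gene_ids) == ["g1", "g2"]
        assert ds.clinical.sample_ids == ["a", "b"]

    def test_disjoint_genes_raise(self):
        layers = {
            "GE": _layer(np.ones((1, 2)), "GE", ["g1"], ["a", "b"]),
            "SCNA": _layer(np.ones((1, 2)), "SCNA", ["g2"], ["a", "b"]),
            "DM": _layer(np.ones((1, 2)), "DM", ["g1"], ["a", "b"]),
            "ME": _layer(np.ones((1, 2)), "ME", ["g1"], ["a", "b"]),
        }
        with pytest.raises(ValueError, match="gene intersection"):
            align_dataset(layers, _clinical(["a", "b"]))

    def test_identical_sets_identity_order(self):
        rng = np.random.default_rng(6)
        layers = {
            k: _layer(rng.normal(size=(2, 3)), k, ["g1", "g2"], ["a", "b", "c"])
            for k in ("GE", "SCNA", "DM", "ME")
        }
        ds = align_dataset(layers, _clinical(["a", "b", "c"]))
        assert ds.sample_ids == ["a", "b", "c"]


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_filters_idempotent_on_random_layers(seed):
    """Applying any filter twice equals applying it once."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(8, 30))
    vals[rng.random(vals.shape) < 0.04] = np.nan
    for kind in ("GE", "ME"):
        lay = _layer(np.abs(vals), kind)
        once = filter_expression(filter_missing(lay))
        twice = filter_expression(filter_missing(once))
        pd.testing.assert_frame_equal(once.values, twice.values)


def test_full_harmonization_chain():
    """End-to-end: dirty layers with duplicates, missing cells and a
    miRNA matrix come out aligned, z-scored and 4-decimal rounded."""
    rng = np.random.default_rng(9)
    samples = [f"s{i}" for i in range(40)]
    genes = [f"g{i}" for i in range(12)]
    ge = _layer(np.abs(rng.normal(2, 1, size=(13, 40))), "GE",
                genes + ["g0"], samples)        # duplicate probe for g0
    scna = _layer(rng.normal(size=(12, 40)), "SCNA", genes, samples)
    dm_vals = rng.normal(size=(12, 40))
    dm_vals[0, :1] = np.nan                      # 2.5% missing: kept, imputed
    dm = _layer(dm_vals, "DM", genes, samples)
    me = _layer(np.abs(rng.normal(3, 1, size=(5, 40))), "ME",
                [f"mir{i}" for i in range(5)], samples)
    inter = InteractionTable(
        pd.DataFrame(
            [(f"mir{i}", g, 6, 1) for i, g in enumerate(
                ["g0", "g1", "g2", "g3", "g4"] )]
            + [(f"mir{i}", g, 7, 2) for i, g in enumerate(
                genes[5:10], start=0)],
            columns=["mirna_id", "gene_id", "n_experiments", "n_anticorrelated_cancers"],
        )
    )
    clinical = _clinical(samples)
    ds = harmonize_dataset(
        {"GE": ge, "SCNA": scna, "DM": dm, "ME": me}, clinical, interactions=inter
    )
    # gene set limited by mapped ME targets; all layers share it
    for kind in ("GE", "SCNA", "DM", "ME"):
        assert ds.layers[kind].gene_ids == ds.layers["GE"].gene_ids
        arr = ds.layers[kind].values.to_numpy()
        np.testing.assert_array_equal(arr, np.round(arr, 4))
        assert abs(arr.mean()) < 1e-3
    assert ds.clinical.sample_ids == ds.sample_ids
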