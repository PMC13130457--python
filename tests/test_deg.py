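"""DE flagging, gene classification against a brute-force oracle, z-scores."""

import math

import numpy as np
import pandas as pd
import pytest

from fiberquant import classify_gene, classify_table, flag_de, make_deg_table, zscore_matrix
from fiberquant.errors import ValidationError
from fiberquant.synthetic import DEG_CLASSES


def oracle_classify(row, fc_thresh=1.5, p_thresh=0.05):
    """Independent truth-table implementation of the class definitions."""
    cut = math.log2(fc_thresh)
    d = abs(row["log2fc_DEN"]) >= cut and row["p_DEN"] < p_thresh
    i = abs(row["log2fc_SH_IN"]) >= cut and row["p_SH_IN"] < p_thresh
    e = abs(row["log2fc_SH_DE"]) >= cut and row["p_SH_DE"] < p_thresh
    s = lambda x: x > 0  # noqa: E731 (sign as boolean; zero handled by caller)
    table = {
        (False, False, False): "none",
        (False, True, False): "AIN_In",
        (False, False, True): "AIN_De",
        (False, True, True): "AIN_InDe",
        (True, False, False): "AD_untouched",
    }
    if (d, i, e) in table:
        return table[(d, i, e)]
    if d and i and not e:
        return "AD_In_pos" if s(row["log2fc_SH_IN"]) == s(row["log2fc_DEN"]) else "AD_In_neg"
    if d and not i and e:
        return "AD_De_pos" if s(row["log2fc_SH_DE"]) == s(row["log2fc_DEN"]) else "AD_De_neg"
    return "AD_InDe" if s(row["log2fc_SH_IN"]) == s(row["log2fc_SH_DE"]) else "AD_InDe_inverse"


def random_table(rng, n=20):
    """Random (log2fc, p) triples spanning all flag/sign combinations."""
    df = pd.DataFrame({"gene": [f"r{j}" for j in range(n)]})
    for c in ("DEN", "SH_IN", "SH_DE"):
        fc = rng.normal(0, 1.2, n)
        fc[np.abs(fc) < 1e-6] = 0.5  # avoid exact zeros (signs undefined)
        df[f"log2fc_{c}"] = fc
        df[f"p_{c}"] = rng.uniform(0, 0.15, n)
    return df


class TestFlagDe:
    def test_boundary_behavior(self):
        # fold-change boundary is inclusive, p boundary strict
        assert flag_de(math.log2(1.5), 0.049) is True
        assert flag_de(0.50, 0.01) is False    # |FC| = 1.41 < 1.5
        assert flag_de(1.0, 0.05) is False     # p not strictly below
        assert flag_de(-math.log2(1.5), 0.01) is True  # down-regulation counts

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            flag_de(1.0, 1.5)

    def test_monotone_in_p_threshold(self):
        """Raising p_thresh never un-flags a gene."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            fc, p = rng.normal(0, 1.5), rng.uniform(0, 1)
            if flag_de(fc, p, p_thresh=0.05):
                assert flag_de(fc, p, p_thresh=0.10)


class TestClassifyGene:
    def test_documented_example_ad_in_pos(self):
        rec = {
            "gene": "x",
            "log2fc_DEN": 1.0, "p_DEN": 0.001,
            "log2fc_SH_IN": 0.8, "p_SH_IN": 0.01,
            "log2fc_SH_DE": 0.1, "p_SH_DE": 0.9,
        }
        assert classify_gene(rec).gene_class == "AD_In_pos"

    def test_knockdown_only_innervated(self):
        rec = {
            "gene": "x",
            "log2fc_DEN": 0.0, "p_DEN": 0.9,
            "log2fc_SH_IN": 1.0, "p_SH_IN": 0.001,
            "log2fc_SH_DE": 0.0, "p_SH_DE": 0.9,
        }
        assert classify_gene(rec).gene_class == "AIN_In"

    def test_opposite_knockdown_signs_inverse(self):
        rec = {
            "gene": "x",
            "log2fc_DEN": -1.0, "p_DEN": 0.001,
            "log2fc_SH_IN": 1.0, "p_SH_IN": 0.001,
            "log2fc_SH_DE": -1.0, "p_SH_DE": 0.001,
        }
        assert classify_gene(rec).gene_class == "AD_InDe_inverse"

    def test_agrees_with_oracle_on_random_tables(self):
        """Gene-for-gene agreement with the brute-force truth table over
        1000 seeded random tables."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            df = random_table(rng, n=12)
            assignments, _, _ = classify_table(df)
            for (_, row), got in zip(df.iterrows(), assignments["gene_class"]):
                assert got == oracle_classify(row)


class TestClassifyTable:
    def test_round_trip_recovers_requested_counts(self):
        requested = {"AIN_InDe": 5, "AD_De_pos": 7, "AD_untouched": 11}
        table, _ = make_deg_table(requested, seed=17)
        _, counts, _ = classify_table(table)
        for cls in DEG_CLASSES:
            assert counts[cls] == requested.get(cls, 0)

    def test_round_trip_all_classes(self):
        requested = {cls: 3 for cls in DEG_CLASSES}
        table, truth = make_deg_table(requested, seed=23)
        assignments, counts, _ = classify_table(table)
        assert counts == requested
        merged = assignments.merge(truth.objects, on="gene")
        assert (merged["gene_class"] == merged["true_class"]).all()

    def test_partition_property(self):
        table, _ = make_deg_table({cls: 4 for cls in DEG_CLASSES}, seed=31)
        assignments, counts, _ = classify_table(table)
        assert sum(counts.values()) == len(table)
        assert assignments["gene_class"].isin(DEG_CLASSES).all()

    def test_venn_regions_consistent_with_flags(self):
        table, _ = make_deg_table(
            {"AD_untouched": 4, "AIN_In": 3, "AD_InDe": 2, "none": 5}, seed=37
        )
        _, _, summary = classify_table(table)
        venn = summary["venn"]
        assert venn["DEN_only"] == 4
        assert venn["SH_IN_only"] == 3
        assert venn["DEN_SH_IN_SH_DE"] == 2
        assert sum(venn.values()) == 9  # "none" genes sit outside all circles

    def test_empty_table_all_zero(self):
        table, _ = make_deg_table({}, seed=0)
        _, counts, summary = classify_table(table)
        assert all(v == 0 for v in counts.values())
        assert all(v == 0 for v in summary["venn"].values())

    def test_duplicate_gene_rejected(self):
        table, _ = make_deg_table({"AIN_In": 2}, seed=0)
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError):
            classify_table(dup)

    def test_raising_p_threshold_never_shrinks_de_sets(self):
        rng = np.random.default_rng(41)
        df = random_table(rng, n=200)
        loose_counts = {}
        for p_thresh, store in ((0.05, False), (0.10, True)):
            a, _, _ = classify_table(df, p_thresh=p_thresh)
            for c in ("DEN", "SH_IN", "SH_DE"):
                if store:
                    assert a[f"de_{c}"].sum() >= loose_counts[c]
                else:
                    loose_counts[c] = a[f"de_{c}"].sum()


class TestZscoreMatrix:
    def test_closed_form_row(self):
        df = pd.DataFrame(
            {
                "gene": ["a"],
                "log2fc_DEN": [1.0], "p_DEN": [0.5],
                "log2fc_SH_IN": [2.0], "p_SH_IN": [0.5],
                "log2fc_SH_DE": [3.0], "p_SH_DE": [0.5],
            }
        )
        z, flagged = zscore_matrix(df, ["a"])
        np.testing.assert_allclose(z.loc["a"], [-1.225, 0.0, 1.225], atol=1e-3)
        assert flagged == []

    def test_constant_row_flagged_zero(self):
        df = pd.DataFrame(
            {
                "gene": ["a"],
                "log2fc_DEN": [2.0], "p_DEN": [0.5],
                "log2fc_SH_IN": [2.0], "p_SH_IN": [0.5],
                "log2fc_SH_DE": [2.0], "p_SH_DE": [0.5],
            }
        )
        z, flagged = zscore_matrix(df, ["a"])
        assert (z.loc["a"] == 0).all()
        assert flagged == ["a"]

    def test_rows_normalized(self):
        table, _ = make_deg_table({"AD_InDe": 10}, seed=3)
        z, _ = zscore_matrix(table, table["gene"])
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_missing_gene_rejected(self):
        table, _ = make_deg_table({"AIN_In": 2}, seed=0)
        with pytest.raises(KeyError):
            zscore_matrix(table, ["not_a_gene"])
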