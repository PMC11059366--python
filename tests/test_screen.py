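"""Reporter-screen statistics: normalization, Welch test, validation,
gene aggregation, and the model/results workflow."""

import numpy as np
import pandas as pd
import pytest

from utrscreen import (
    MTIRecord,
    ReporterScreen,
    aggregate_gene_level,
    normalize_rlu,
    validate_mti,
    validation_rate,
    welch_t_test,
)

from oracles import welch_closed_form


def plate_rows(cid, mirna, ratios_by_rep, renilla=10.0, gene=None):
    """One condition's tidy rows; both duplicates carry the replicate ratio."""
    rows = []
    for rep, ratio in enumerate(ratios_by_rep, start=1):
        for dup in (1, 2):
            row = {"construct_id": cid, "mirna": mirna, "replicate": rep,
                   "duplicate": dup, "firefly": ratio * renilla,
                   "renilla": renilla}
            if gene:
                row["gene"] = gene
            rows.append(row)
    return rows


class TestNormalizeRlu:
    def test_ratio_of_ratios(self):
        test = pd.DataFrame(plate_rows("c", "m", [0.8, 0.8, 0.8, 0.8]))
        ctrl = pd.DataFrame(plate_rows("c", "empty", [1, 1, 1, 1]))
        assert np.allclose(normalize_rlu(test, ctrl), 0.8)

    def test_identity(self):
        test = pd.DataFrame(plate_rows("c", "m", [1.1, 0.9, 1.0, 1.2]))
        assert np.allclose(normalize_rlu(test, test), 1.0)

    def test_duplicate_averaging_arithmetic(self):
        # duplicates (100,110)/renilla 10 vs control (125,125)/10 -> 10.5/12.5
        test = pd.DataFrame([
            {"construct_id": "c", "mirna": "m", "replicate": 1, "duplicate": 1,
             "firefly": 100.0, "renilla": 10.0},
            {"construct_id": "c", "mirna": "m", "replicate": 1, "duplicate": 2,
             "firefly": 110.0, "renilla": 10.0},
        ])
        ctrl = pd.DataFrame([
            {"construct_id": "c", "mirna": "empty", "replicate": 1,
             "duplicate": d, "firefly": 125.0, "renilla": 10.0}
            for d in (1, 2)
        ])
        assert normalize_rlu(test, ctrl) == pytest.approx([0.84])

    def test_replicate_mismatch(self):
        test = pd.DataFrame(plate_rows("c", "m", [0.8, 0.8]))
        ctrl = pd.DataFrame(plate_rows("c", "empty", [1, 1, 1]))
        with pytest.raises(ValueError):
            normalize_rlu(test, ctrl)

    def test_nonpositive_renilla(self):
        test = pd.DataFrame(plate_rows("c", "m", [0.8], renilla=-1.0))
        with pytest.raises(ValueError):
            normalize_rlu(test, test)


class TestWelch:
    def test_hand_example(self):
        a = (0.78, 0.80, 0.80, 0.82)
        b = (0.98, 1.00, 1.00, 1.02)
        res = welch_t_test(a, b)
        t, df, p = welch_closed_form(a, b)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_antisymmetry(self, rng):
        a = rng.normal(0.8, 0.05, 4)
        b = rng.normal(1.0, 0.05, 4)
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_identical_samples(self):
        a = (0.9, 1.0, 1.1, 1.0)
        res = welch_t_test(a, a)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            welch_t_test((1, 1, 1), (2, 2, 2))

    def test_matches_closed_form_on_random_pairs(self, rng):
        for _ in range(200):
            a = rng.normal(rng.uniform(0.4, 1.2), rng.uniform(0.01, 0.2),
                           int(rng.integers(3, 9)))
            b = rng.normal(1.0, rng.uniform(0.01, 0.2), int(rng.integers(3, 9)))
            res = welch_t_test(a, b)
            t, df, p = welch_closed_form(list(a), list(b))
            assert abs(res.t - t) < 1e-10
            assert abs(res.df - df) < 1e-10
            assert abs(res.p - p) < 1e-10


class TestValidateMti:
    @pytest.mark.parametrize(
        "mean_rlu, p, validated, category",
        [
            (0.85, 0.01, True, "moderate"),
            (0.95, 0.001, False, "none"),
            (0.85, 0.20, False, "moderate"),
            (0.60, 0.001, True, "strong"),
            (1.30, 0.008, False, "upregulated"),
            (1.30, 0.50, False, "none"),
            (0.90, 0.001, False, "none"),  # cutoff is strict
        ],
    )
    def test_rule(self, mean_rlu, p, validated, category):
        assert validate_mti(mean_rlu, p) == (validated, category)


def record(mean, p, gene="g", mirna="m"):
    validated, category = validate_mti(mean, p)
    return MTIRecord("c", gene, mirna, (mean,) * 4, mean, p, validated, category)


class TestGeneAggregation:
    def test_minima_reported_independently(self):
        res = aggregate_gene_level([record(0.80, 0.04), record(0.88, 0.001)])
        assert (res.best_rlu, res.best_p) == (0.80, 0.001)
        assert res.validated

    def test_single_fragment(self):
        res = aggregate_gene_level([record(0.85, 0.01)])
        assert (res.best_rlu, res.best_p, res.validated) == (0.85, 0.01, True)

    def test_any_fragment_validates(self):
        res = aggregate_gene_level([record(0.85, 0.01), record(0.95, 0.30)])
        assert res.validated

    def test_adding_fragments_never_unvalidates(self, rng):
        base = [record(0.7, 0.01)]
        for _ in range(20):
            base.append(record(float(rng.uniform(0.4, 1.3)),
                               float(rng.uniform(0, 1))))
            assert aggregate_gene_level(base).validated

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_gene_level([])

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gene_level([record(0.8, 0.1, gene="a"),
                                  record(0.8, 0.1, gene="b")])


class TestValidationRate:
    def test_values(self):
        assert validation_rate(76, 95) == 80.0
        assert validation_rate(96, 190) == 50.5
        assert validation_rate(0, 10) == 0.0

    def test_zero_tested(self):
        with pytest.raises(ValueError):
            validation_rate(0, 0)


class TestReporterScreenWorkflow:
    @pytest.fixture
    def fitted(self):
        rows = (
            plate_rows("c1", "empty", [1.00, 1.02, 0.98, 1.00], gene="GENE1")
            + plate_rows("c1", "miR-x", [0.78, 0.80, 0.80, 0.82], gene="GENE1")
            + plate_rows("c2", "empty", [1.00, 1.01, 0.99, 1.00], gene="GENE1")
            + plate_rows("c2", "miR-x", [0.99, 1.01, 1.02, 0.98], gene="GENE1")
        )
        return ReporterScreen.from_plate_table(pd.DataFrame(rows)).fit()

    def test_mti_table(self, fitted):
        df = fitted.mti_table.set_index("construct_id")
        assert df.loc["c1", "validated"]
        assert not df.loc["c2", "validated"]
        expected = np.mean([0.78 / 1.00, 0.80 / 1.02, 0.80 / 0.98, 0.82 / 1.00])
        assert df.loc["c1", "mean_rlu"] == pytest.approx(expected)
        assert "p_adj_bh" in df.columns

    def test_gene_table_pools_fragments(self, fitted):
        gt = fitted.gene_table
        assert len(gt) == 1
        row = gt.iloc[0]
        assert row["validated"] and row["n_constructs"] == 2
        assert row["best_rlu"] == fitted.mti_table["mean_rlu"].min()
        assert row["best_p"] == fitted.mti_table["p_value"].min()

    def test_summary_mentions_rates(self, fitted):
        text = fitted.summary()
        assert "validation rule" in text
        assert "miR-x" in text

    def test_normalized_mode_agrees_with_plate_mode(self, fitted):
        norm_rows = []
        for rec in fitted.records:
            for rep, v in enumerate(rec.normalized_rlu, start=1):
                norm_rows.append({
                    "construct_id": rec.construct_id, "gene": rec.gene,
                    "mirna": rec.mirna, "replicate": rep, "normalized_rlu": v,
                })
        res2 = ReporterScreen.from_normalized(pd.DataFrame(norm_rows)).fit()
        left = fitted.mti_table.set_index("construct_id")["mean_rlu"]
        right = res2.mti_table.set_index("construct_id")["mean_rlu"]
        assert np.allclose(left.sort_index(), right.sort_index())

    def test_missing_control_errors(self):
        rows = plate_rows("c1", "miR-x", [0.8, 0.8, 0.8, 0.8])
        with pytest.raises(ValueError):
            ReporterScreen.from_plate_table(pd.DataFrame(rows)).fit()
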