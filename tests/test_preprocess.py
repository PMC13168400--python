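"""Normalization, filtering, batch adjustment and PCA QC."""

import numpy as np
import pandas as pd
import pytest

from netdriver import io as nio
from netdriver.preprocess import (ConfoundingError, DegenerateDepthError,
                                  batch_adjust, filter_low_expression,
                                  normalize_log2, pca_scores)
from netdriver.synthetic import SimConfig, generate_network, simulate_counts


def _meta(n_per_group=4, batches=("A", "B")):
    rows = []
    for b in batches:
        for cond in ("control", "knockdown"):
            for r in range(n_per_group):
                rows.append({"cell_line": b, "condition": cond})
    meta = pd.DataFrame(rows)
    meta.index = pd.Index([f"s{i}" for i in range(len(meta))])
    return meta


class TestNormalizeLog2:
    def test_scaling_factor_formula(self):
        # depths 100 and 300 (mean 200): count 9 -> (9+1)*200/100 = 20
        counts = pd.DataFrame(
            {"s1": [9, 91], "s2": [30, 270]},
            index=pd.Index(["A", "B"], name="feature_id"),
        )
        expr, norm = normalize_log2(counts)
        assert norm["depth"].tolist() == [100.0, 300.0]
        assert expr.loc["A", "s1"] == pytest.approx(np.log2(20.0), abs=1e-12)
        assert expr.loc["A", "s1"] == pytest.approx(4.321928094887363)

    def test_mean_depth_sample_is_plain_log2(self):
        # both depths equal the mean -> factor 1 -> log2(count+1)
        counts = pd.DataFrame({"s1": [3, 97], "s2": [7, 93]},
                              index=["A", "B"])
        expr, _ = normalize_log2(counts)
        assert expr.loc["A", "s1"] == pytest.approx(np.log2(4))
        # and a zero count maps to log2(1) = 0
        counts.loc["A", "s1"] = 0
        counts.loc["B", "s1"] = 100
        expr, _ = normalize_log2(counts)
        assert expr.loc["A", "s1"] == 0.0

    def test_zero_depth_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]}, index=["A", "B"])
        with pytest.raises(DegenerateDepthError):
            normalize_log2(counts)

    def test_monotone_within_sample(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)),
                              index=[f"G{i}" for i in range(50)],
                              columns=list("abcd"))
        expr, _ = normalize_log2(counts)
        for col in counts:
            order = counts[col].argsort(kind="stable")
            assert (np.diff(expr[col].to_numpy()[order]) >= 0).all()

    def test_factor_invariant(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 5)))
        _, norm = normalize_log2(counts)
        assert (norm["depth"] * norm["factor"]).mean() == pytest.approx(
            norm["depth"].mean())


class TestFilterLowExpression:
    def test_column_minimum_removed_high_retained(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(5, 1, size=(40, 6)),
                            index=[f"G{i}" for i in range(40)])
        expr.loc["LOW"] = expr.min().min() - 10.0   # minimum everywhere
        expr.loc["HIGH"] = expr.max().max() + 10.0  # above every median
        kept, _ = filter_low_expression(expr)
        assert "LOW" not in kept.index
        assert "HIGH" in kept.index

    def test_low_in_three_of_four_samples_retained(self):
        # 75% of samples below threshold < the 90% requirement
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(5, 1, size=(40, 4)),
                            index=[f"G{i}" for i in range(40)])
        low = expr.min().min() - 10.0
        row = expr.iloc[0].copy()
        row.iloc[:3] = low
        row.iloc[3] = expr.iloc[:, 3].max() + 1
        expr.loc["PARTIAL"] = row
        kept, _ = filter_low_expression(expr, frac=0.90)
        assert "PARTIAL" in kept.index

    def test_invalid_percentile_rejected(self):
        expr = pd.DataFrame([[1.0]])
        for pct in (0, 100, -3):
            with pytest.raises(ValueError):
                filter_low_expression(expr, pct=pct)

    def test_idempotent_with_frozen_thresholds(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(60, 8)))
        once, thr = filter_low_expression(expr)
        twice, _ = filter_low_expression(once, thresholds=thr)
        pd.testing.assert_frame_equal(once, twice)

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(30, 5)))
        kept, _ = filter_low_expression(expr)
        assert set(kept.index) <= set(expr.index)


class TestBatchAdjust:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(10, 8)),
                            columns=[f"s{i}" for i in range(8)])
        meta = _meta(batches=("A",))
        out = batch_adjust(expr, meta)
        pd.testing.assert_frame_equal(out, expr)

    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(10, 8)),
                            columns=[f"s{i}" for i in range(8)])
        meta = pd.DataFrame({
            "cell_line": ["A"] * 4 + ["B"] * 4,
            "condition": ["control"] * 4 + ["knockdown"] * 4,
        }, index=expr.columns)
        with pytest.raises(ConfoundingError):
            batch_adjust(expr, meta)

    def test_center_mode_preserves_feature_means_in_balanced_null(self):
        rng = np.random.default_rng(8)
        meta = _meta()
        expr = pd.DataFrame(rng.normal(5, 1, size=(30, len(meta))),
                            columns=meta.index)
        expr.loc[:, meta["cell_line"] == "B"] += 2.0
        out = batch_adjust(expr, meta, method="center")
        np.testing.assert_allclose(out.mean(axis=1), expr.mean(axis=1),
                                   atol=1e-6)
        # and batch means now coincide exactly
        a = out.loc[:, meta["cell_line"] == "A"].mean(axis=1)
        b = out.loc[:, meta["cell_line"] == "B"].mean(axis=1)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_eb_mode_removes_planted_offsets_and_keeps_effect(self):
        """Simulation check against the generator's known batch offsets."""
        diffs, errs = [], []
        for seed in range(3):
            cfg = SimConfig(seed=seed, n_tf=5, n_mirna=10, n_target_genes=300,
                            targets_per_driver=(3, 8),
                            hub_kd_log2_shift=0.0, hidden_driver_fraction=0.0,
                            de_gene_fraction=0.05, de_gene_log2_shift=2.0,
                            depth_range=(100_000, 150_000))
            net = generate_network(cfg)
            mrna, mirna, samples, truth = simulate_counts(net, cfg)
            expr, _ = normalize_log2(mrna)
            meta = samples[samples["assay"] == "mRNA"].set_index("sample_id")
            adj = batch_adjust(expr, meta)
            cl = meta["cell_line"]
            gap = (adj.loc[:, (cl == "CL1").values].mean(axis=1)
                   - adj.loc[:, (cl == "CL2").values].mean(axis=1))
            diffs.append(gap.abs().mean())
            kd = (meta["condition"] == "knockdown").values
            shifted = [f for f, s in truth.expression_shifted_features.items()
                       if f in adj.index and s == 2.0]
            est = (adj.loc[shifted, kd].mean(axis=1)
                   - adj.loc[shifted, ~kd].mean(axis=1)).mean()
            errs.append(abs(est - 2.0) / 2.0)
        assert np.mean(diffs) < 0.1
        assert np.mean(errs) < 0.2


class TestPcaScores:
    def test_duplicate_samples_identical_scores(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(20, 5)),
                            columns=[f"s{i}" for i in range(5)])
        expr["s_dup"] = expr["s0"]
        scores = pca_scores(expr, n_components=3)
        np.testing.assert_allclose(scores.loc["s0"], scores.loc["s_dup"],
                                   atol=1e-9)

    def test_variances_non_increasing(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.normal(size=(30, 10)))
        scores = pca_scores(expr, n_components=5)
        ev = scores.attrs["explained_variance"]
        assert all(a >= b - 1e-12 for a, b in zip(ev, ev[1:]))

    def test_two_feature_toy_matches_eigendecomposition(self):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.normal(size=(2, 40)))
        scores = pca_scores(expr, n_components=2)
        cov = np.cov(expr.to_numpy())          # independent 2x2 oracle
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(scores.attrs["explained_variance"], eig,
                                   rtol=1e-10)

    def test_component_bound_enforced(self):
        expr = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            pca_scores(expr, n_components=4)
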