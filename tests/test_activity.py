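"""Mutual information estimation and activity scoring."""

import numpy as np
import pandas as pd
import pytest

from netdriver.activity import activity_scores, mi_weights, mutual_information
from netdriver.network import RegulatoryNetwork


def _net(rows):
    return RegulatoryNetwork(pd.DataFrame(
        rows, columns=["source", "target", "source_class", "sign", "rho", "mi"]))


def brute_force_activity(expr, edges, standardize=True):
    """Independent double-loop reimplementation of the score definition."""
    values = expr.copy().astype(float)
    if standardize:
        values = values.sub(values.mean(axis=1), axis=0)
        sd = expr.std(axis=1, ddof=1).replace(0, 1.0)
        values = values.div(sd, axis=0)
    out = {}
    for driver in dict.fromkeys(edges["source"]):
        sub = edges[edges["source"] == driver]
        sub = sub[sub["target"].isin(values.index)]
        if sub.empty:
            continue
        scores = []
        for sample in values.columns:
            total = 0.0
            for _, e in sub.iterrows():
                total += e["sign"] * e["mi"] * values.loc[e["target"], sample]
            scores.append(total / len(sub))
        out[driver] = scores
    return pd.DataFrame(out, index=values.columns).T


class TestMutualInformation:
    def test_zero_rank_correlation_gives_zero(self):
        # construct rho_s = 0 exactly: symmetric pattern
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 4.0, 4.0, 1.0]  # wait: need exact zero; checked below
        rho = np.corrcoef(
            pd.Series(x).rank(), pd.Series(y).rank())[0, 1]
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_pair_hits_clamp(self):
        x = np.arange(10.0)
        assert mutual_information(x, x**3) == pytest.approx(
            -0.5 * np.log(1e-6), rel=1e-9)  # ~6.9078

    def test_bivariate_gaussian_closed_form(self):
        rng = np.random.default_rng(0)
        rho = 0.6
        n = 5000
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        est = mutual_information(xy[:, 0], xy[:, 1])
        assert est == pytest.approx(-0.5 * np.log(1 - rho**2), abs=0.05)

    def test_constant_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0

    def test_binned_estimator_orders_dependence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        indep = mutual_information(x, rng.normal(size=2000), estimator="binned")
        dep = mutual_information(x, x + 0.3 * rng.normal(size=2000),
                                 estimator="binned")
        assert dep > indep

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2, 3], [3, 2, 1])


class TestMiWeights:
    def test_weights_match_scalar_estimator(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(6, 12)),
                            index=[f"F{i}" for i in range(6)])
        net = _net([("F0", "F1", "miRNA", -1, -0.5, np.nan),
                    ("F0", "F2", "miRNA", -1, -0.5, np.nan),
                    ("F3", "F4", "TF", 1, 0.5, np.nan)])
        weighted = mi_weights(expr, net)
        for _, e in weighted.edges.iterrows():
            expected = mutual_information(expr.loc[e["source"]],
                                          expr.loc[e["target"]])
            assert e["mi"] == pytest.approx(expected, abs=1e-12)

    def test_missing_endpoint_dropped(self):
        expr = pd.DataFrame(np.random.default_rng(3).normal(size=(2, 8)),
                            index=["A", "B"])
        net = _net([("A", "B", "TF", 1, 0.1, np.nan),
                    ("A", "GONE", "TF", 1, 0.1, np.nan)])
        assert mi_weights(expr, net).n_edges == 1


class TestActivityScores:
    def test_single_target_repressor(self):
        expr = pd.DataFrame([[1.0, -1.0, 0.5, -0.5]], index=["G1"],
                            columns=list("abcd"))
        net = _net([("M1", "G1", "miRNA", -1, -0.5, 0.7)])
        act = activity_scores(expr, net, standardize=False)
        np.testing.assert_allclose(act.loc["M1"],
                                   -0.7 * expr.loc["G1"].to_numpy())

    def test_two_equal_weights_average(self):
        expr = pd.DataFrame([[2.0, 4.0], [6.0, 8.0]], index=["G1", "G2"],
                            columns=["a", "b"])
        net = _net([("M1", "G1", "miRNA", -1, -0.5, 0.3),
                    ("M1", "G2", "miRNA", -1, -0.5, 0.3)])
        act = activity_scores(expr, net, standardize=False)
        expected = -0.3 * expr.mean(axis=0)
        np.testing.assert_allclose(act.loc["M1"], expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        targets = [f"G{i}" for i in range(30)]
        expr = pd.DataFrame(rng.normal(size=(30, 8)), index=targets,
                            columns=[f"s{i}" for i in range(8)])
        rows = []
        for d in range(6):
            for t in rng.choice(targets, size=5, replace=False):
                rows.append((f"D{d}", t, "miRNA", -1, -0.5,
                             abs(rng.normal())))
        net = _net(rows)
        act = activity_scores(expr, net)
        oracle = brute_force_activity(expr, net.edges)
        np.testing.assert_allclose(act.to_numpy(),
                                   oracle.loc[act.index, act.columns].to_numpy(),
                                   atol=1e-10)

    def test_linear_in_expression(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(5, 6)),
                            index=[f"G{i}" for i in range(5)])
        net = _net([("M1", f"G{i}", "miRNA", -1, -0.5, 0.4) for i in range(5)])
        a1 = activity_scores(expr, net, standardize=False)
        a3 = activity_scores(3.0 * expr, net, standardize=False)
        np.testing.assert_allclose(a3.to_numpy(), 3.0 * a1.to_numpy(),
                                   atol=1e-12)

    def test_decreasing_targets_raise_repressor_activity(self):
        """Lower target expression must read as higher miRNA activity."""
        expr = pd.DataFrame(np.random.default_rng(6).normal(5, 1, size=(4, 6)),
                            index=[f"G{i}" for i in range(4)])
        net = _net([("M1", f"G{i}", "miRNA", -1, -0.5, 0.5) for i in range(4)])
        base = activity_scores(expr, net, standardize=False)
        lower = activity_scores(expr - 1.0, net, standardize=False)
        assert (lower.loc["M1"] > base.loc["M1"]).all()

    def test_duplicating_regulon_leaves_score_unchanged(self):
        rng = np.random.default_rng(7)
        row = rng.normal(size=6)
        expr = pd.DataFrame([row, row, rng.normal(size=6), rng.normal(size=6)],
                            index=["G1", "G1b", "G2", "G2b"])
        expr.loc["G2b"] = expr.loc["G2"]
        single = _net([("M1", "G1", "miRNA", -1, -0.5, 0.4),
                       ("M1", "G2", "miRNA", -1, -0.5, 0.8)])
        doubled = _net([("M1", "G1", "miRNA", -1, -0.5, 0.4),
                        ("M1", "G1b", "miRNA", -1, -0.5, 0.4),
                        ("M1", "G2", "miRNA", -1, -0.5, 0.8),
                        ("M1", "G2b", "miRNA", -1, -0.5, 0.8)])
        a1 = activity_scores(expr, single, standardize=False)
        a2 = activity_scores(expr, doubled, standardize=False)
        np.testing.assert_allclose(a1.loc["M1"], a2.loc["M1"], atol=1e-12)

    def test_driver_without_enough_targets_dropped(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["a", "b"])
        net = _net([("M1", "G1", "miRNA", -1, -0.5, 0.5),
                    ("M2", "GONE", "miRNA", -1, -0.5, 0.5)])
        act = activity_scores(expr, net, min_targets=1)
        assert list(act.index) == ["M1"]

    def test_missing_mi_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["a", "b"])
        net = _net([("M1", "G1", "miRNA", -1, -0.5, np.nan)])
        with pytest.raises(ValueError, match="MI"):
            activity_scores(expr, net)
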