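"""Marginal factor effects and the significance-gated regression tree."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from prebreedsim.decision import (
    build_tree,
    marginal_effects,
    parse_tree,
    render_tree,
)


def _noise_records(rng, n=200, factors=6):
    df = pd.DataFrame(
        {f"f{i}": rng.choice(["a", "b"], size=n) for i in range(factors)}
    )
    df["h2"] = rng.choice([0.25, 0.5], size=n)
    df["merit"] = rng.normal(size=n)
    return df


class TestMarginalEffects:
    def test_identical_levels_share_a_letter(self, rng):
        base = pd.DataFrame({"x": ["a"] * 40 + ["b"] * 40})
        base["merit"] = np.tile(rng.normal(size=40), 2)  # same records duplicated
        out = marginal_effects(base, "merit", ["x"])
        letters = dict(zip(out["level"], out["letters"]))
        assert set(letters["a"]) & set(letters["b"])

    def test_planted_one_sd_effect_detected(self, rng):
        df = pd.DataFrame({"x": rng.choice(["lo", "hi"], size=200)})
        y = rng.normal(size=200)
        y[df["x"] == "hi"] += 1.0  # one SD
        df["merit"] = y
        out = marginal_effects(df, "merit", ["x"], alpha=0.01)
        letters = dict(zip(out["level"], out["letters"]))
        assert not (set(letters["lo"]) & set(letters["hi"]))

    def test_monotone_factor_fully_separated(self, rng):
        levels = [0, 20, 40, 60]
        df = pd.DataFrame({"n_syn": np.repeat(levels, 120)})
        df["merit"] = df["n_syn"] / 60.0 * 0.5 + rng.normal(0, 0.1, len(df))
        out = marginal_effects(df, "merit", ["n_syn"], alpha=0.01)
        out = out.sort_values("level")
        assert out["mean"].is_monotonic_increasing
        assert len(set(out["letters"])) == 4  # all four levels separated

    def test_pairwise_p_values_match_statsmodels_oracle(self, rng):
        """The one-way model's pairwise comparisons must agree with an
        independent OLS fit and pairwise t-tests."""
        import statsmodels.formula.api as smf
        from prebreedsim.decision import _pairwise_p

        df = pd.DataFrame({"x": rng.choice(["a", "b", "c"], size=90)})
        df["merit"] = rng.normal(size=90) + (df["x"] == "c") * 0.8
        ours = _pairwise_p(df["merit"], ["a", "b", "c"], df["x"])
        fit = smf.ols("merit ~ C(x)", data=df).fit()
        oracle = fit.t_test_pairwise("C(x)").result_frame["P>|t|"]
        assert ours[("a", "b")] == pytest.approx(oracle["b-a"], abs=1e-8)
        assert ours[("a", "c")] == pytest.approx(oracle["c-a"], abs=1e-8)
        assert ours[("b", "c")] == pytest.approx(oracle["c-b"], abs=1e-8)

    def test_empty_filter_fails(self):
        with pytest.raises(ValueError, match="empty"):
            marginal_effects(pd.DataFrame(columns=["x", "merit"]), "merit", ["x"])


class TestTree:
    def test_pure_noise_gives_single_leaf(self, rng):
        df = _noise_records(rng)
        tree = build_tree(df, "merit", ["f0", "f1", "f2", "h2"], seed=1)
        assert tree.root.is_leaf

    def test_dominant_binary_factor_splits_root(self, rng):
        df = _noise_records(rng, n=300)
        df.loc[df["f2"] == "b", "merit"] += 2.0
        tree = build_tree(df, "merit", ["f0", "f1", "f2", "h2"], seed=1)
        assert tree.root.factor == "f2"

    def test_ordinal_factor_splits_on_order(self, rng):
        df = pd.DataFrame({"n_syn": rng.choice([0, 20, 40, 60], size=400)})
        df["merit"] = (df["n_syn"] >= 40).astype(float) + rng.normal(0, 0.3, 400)
        tree = build_tree(df, "merit", ["n_syn"], seed=2)
        assert not tree.root.is_leaf
        assert sorted(tree.root.left_levels + tree.root.right_levels) == [0, 20, 40, 60]
        assert max(tree.root.left_levels) < min(tree.root.right_levels)

    def test_leaf_weighted_mean_equals_overall_mean(self, rng):
        df = _noise_records(rng, n=400)
        df.loc[df["f0"] == "b", "merit"] += 1.5
        df.loc[df["f1"] == "b", "merit"] += 0.8
        tree = build_tree(df, "merit", ["f0", "f1", "f2"], seed=3)
        leaves = tree.leaves()
        weighted = sum(lf.mean * lf.n for lf in leaves) / sum(lf.n for lf in leaves)
        assert weighted == pytest.approx(df["merit"].mean())

    def test_monotone_in_alpha(self, rng):
        df = _noise_records(rng, n=300)
        df.loc[df["f0"] == "b", "merit"] += 1.0
        closed = build_tree(df, "merit", ["f0", "f1"], alpha=1e-12, seed=4)
        assert closed.root.is_leaf
        open_ = build_tree(
            df, "merit", ["f0", "f1"], alpha=0.9999, min_leaf=2,
            n_permutations=200, seed=4,
        )
        assert not open_.root.is_leaf

    def test_too_many_levels_rejected(self, rng):
        df = pd.DataFrame({"x": np.arange(60) % 20, "merit": rng.normal(size=60)})
        with pytest.raises(ValueError, match="levels"):
            build_tree(df, "merit", ["x"], seed=0)

    def test_false_split_rate_controlled_on_noise(self, rng):
        """The alpha = 0.01 gate, Bonferroni-adjusted over 6 factors, must
        split a pure-noise response in at most 5% of datasets."""
        false_splits = 0
        n_runs = 200
        for i in range(n_runs):
            df = _noise_records(np.random.default_rng(1000 + i), n=64)
            tree = build_tree(
                df, "merit", [f"f{j}" for j in range(6)],
                alpha=0.01, n_permutations=999, seed=i,
            )
            false_splits += not tree.root.is_leaf
        assert false_splits / n_runs <= 0.05


class TestRendering:
    def test_round_trip_is_stable(self, rng):
        df = _noise_records(rng, n=300)
        df.loc[df["f0"] == "b", "merit"] += 1.2
        tree = build_tree(df, "merit", ["f0", "f1"], seed=5)
        text, payload = render_tree(tree)
        again_text, again_payload = render_tree(parse_tree(payload))
        assert again_text == text
        assert again_payload == payload

    def test_single_leaf_renders_mean_and_quantiles(self, rng):
        df = _noise_records(rng)
        tree = build_tree(df, "merit", ["f0"], alpha=1e-12, seed=6)
        text, _ = render_tree(tree)
        assert "leaf: mean=" in text and "n=200" in text

    def test_node_count_matches_json_structure(self, rng):
        import json

        df = _noise_records(rng, n=400)
        df.loc[df["f0"] == "b", "merit"] += 2.0
        df.loc[df["f1"] == "b", "merit"] += 1.0
        tree = build_tree(df, "merit", ["f0", "f1", "f2"], seed=7)
        _, payload = render_tree(tree)

        def count(d):
            if "factor" in d:
                return 1 + count(d["left"]) + count(d["right"])
            return 1

        assert count(json.loads(payload)["root"]) == tree.n_nodes()
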