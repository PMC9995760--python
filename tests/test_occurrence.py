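"""Normality transform selection, normal-CDF scoring, key-module call."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cnmod.network import ModulePartition
from cnmod.occurrence import (
    call_key_module,
    normcdf,
    score_occurrence,
    select_transform,
)
from cnmod.qpcr import delta_delta_ct
from cnmod.simulate import SimConfig, generate_catalog, generate_ct_table


def adjusted_skewness(x):
    """One-line oracle: adjusted Fisher-Pearson sample skewness."""
    x = np.asarray(x, float)
    n = len(x)
    m2 = np.mean((x - x.mean()) ** 2)
    m3 = np.mean((x - x.mean()) ** 3)
    return (m3 / m2 ** 1.5) * math.sqrt(n * (n - 1)) / (n - 2)


class TestSelectTransform:
    def test_zero_value_forces_sqrt(self):
        spec = select_transform([0.0, 1.0, 4.0, 9.0])
        assert spec.name == "sqrt" and spec.skew_ln is None

    def test_lognormal_data_selects_ln(self):
        rng = np.random.default_rng(3)
        values = np.exp(rng.normal(0, 1, size=500))
        spec = select_transform(values)
        assert spec.name == "ln"
        assert spec.skew_ln == pytest.approx(adjusted_skewness(np.log(values)), rel=1e-9)
        assert spec.skew_sqrt == pytest.approx(adjusted_skewness(np.sqrt(values)), rel=1e-9)
        assert abs(spec.skew_ln) < abs(spec.skew_sqrt)

    def test_exact_tie_goes_to_sqrt(self):
        # symmetric values: both transforms of {1} are degenerate; build a
        # set whose sqrt and ln skewness are both exactly 0 by symmetry
        vals = [1.0, 1.0, 1.0, 1.0]
        spec = select_transform(vals)
        assert spec.name == "sqrt"

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            select_transform([1.0, -0.5, 2.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            select_transform([1.0, 2.0])


class TestNormcdf:
    def test_center_is_half(self):
        assert normcdf(3.0, 3.0, 2.0) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("z, expected", [(1.959964, 0.975), (-1.959964, 0.025)])
    def test_reference_quantiles(self, z, expected):
        assert normcdf(z) == pytest.approx(expected, abs=1e-6)

    def test_agrees_with_reference_on_grid(self):
        z = np.linspace(-8, 8, 1601)
        assert np.max(np.abs(normcdf(z) - stats.norm.cdf(z))) <= 1e-12

    def test_symmetry(self):
        z = np.linspace(0, 8, 100)
        np.testing.assert_allclose(normcdf(-z), 1 - normcdf(z), atol=1e-12)

    def test_monotone_and_open_interval(self):
        z = np.linspace(-8, 8, 500)
        p = normcdf(z)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            normcdf(0.0, 0.0, 0.0)


def expr_frame(gene_values, tissue="shoot", cond="scn24"):
    return pd.DataFrame({
        "gene_id": list(gene_values),
        "tissue": tissue,
        "condition_id": cond,
        "mean_rel_expr": list(gene_values.values()),
    })


class TestScoreOccurrence:
    def test_probability_order_matches_value_order(self):
        values = {f"g{i}": v for i, v in enumerate([0.5, 1.0, 1.5, 2.0, 8.0])}
        probs = score_occurrence(expr_frame(values), list(values), "shoot", ["scn24"])
        ordered = probs.sort_values("p")["gene_id"].tolist()
        assert ordered == sorted(values, key=values.get)
        assert probs.loc[probs["gene_id"] == "g4", "p"].item() > 0.5

    def test_permutation_invariance(self):
        values = {f"g{i}": v for i, v in enumerate([0.2, 1.1, 2.5, 0.7])}
        frame = expr_frame(values)
        a = score_occurrence(frame, list(values), "shoot", ["scn24"])
        shuffled = frame.sample(frac=1, random_state=1)
        b = score_occurrence(shuffled, list(values), "shoot", ["scn24"])
        merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], atol=0)

    def test_degenerate_stratum_is_error(self):
        values = {f"g{i}": 1.0 for i in range(5)}
        with pytest.raises(ValueError, match="scn24"):
            score_occurrence(expr_frame(values), list(values), "shoot", ["scn24"])

    def test_missing_gene_is_error(self):
        values = {"g0": 1.0, "g1": 2.0, "g2": 3.0}
        with pytest.raises(ValueError, match="g9"):
            score_occurrence(expr_frame(values), ["g0", "g1", "g2", "g9"], "shoot", ["scn24"])

    def test_ln_scores_invariant_under_scaling(self):
        rng = np.random.default_rng(5)
        base = np.exp(rng.normal(0, 1, size=30))
        for c in (1.0, 10.0):
            values = {f"g{i}": c * v for i, v in enumerate(base)}
            probs = score_occurrence(expr_frame(values), list(values), "shoot", ["scn24"])
            assert (probs["transform"] == "ln").all()
            if c == 1.0:
                ref = probs["p"].to_numpy()
        np.testing.assert_allclose(probs["p"].to_numpy(), ref, atol=1e-12)

    def test_planted_key_genes_dominate_noise_free(self):
        cfg = SimConfig(seed=7, ct_noise_sd=0.0, key_effect_log2fc=3.0, tissues=("shoot",))
        cat = generate_catalog(cfg)
        expr = delta_delta_ct(generate_ct_table(cfg, cat), "GAPDH", "scn0")
        key = set(cat.loc[cat["planted_module"] == cfg.key_module_index, "gene_id"])
        og_conditions = [c for c in cfg.condition_ids if c.endswith("_og")]
        probs = score_occurrence(expr.aggregated, cat["gene_id"].tolist(), "shoot", og_conditions)
        for cond, block in probs.groupby("condition_id"):
            key_p = block.loc[block["gene_id"].isin(key), "p"]
            other_p = block.loc[~block["gene_id"].isin(key), "p"]
            assert key_p.min() > other_p.max()


def probs_frame(records):
    return pd.DataFrame(records, columns=["gene_id", "tissue", "condition_id", "p"])


def partition_from(membership):
    return ModulePartition(membership=membership, modularity=0.0, resolution=0.8)


class TestCallKeyModule:
    def test_clear_winner(self):
        membership = {"a1": 1, "a2": 1, "b1": 2, "b2": 2}
        probs = probs_frame([
            ("a1", "shoot", "c", 0.9), ("a2", "shoot", "c", 0.9),
            ("b1", "shoot", "c", 0.1), ("b2", "shoot", "c", 0.1),
        ])
        rep = call_key_module(probs, partition_from(membership))
        assert rep.key_module == 1
        mod = rep.modules.set_index("module_id")
        assert mod.loc[1, "frac_exceed"] == 1.0
        assert mod.loc[2, "frac_exceed"] == 0.0
        assert rep.tiebreak == "frac_exceed"

    def test_all_below_threshold_falls_back_to_mean_p(self):
        membership = {"a": 1, "b": 2}
        probs = probs_frame([("a", "shoot", "c", 0.4), ("b", "shoot", "c", 0.6)])
        rep = call_key_module(probs, partition_from(membership))
        assert rep.key_module == 2 and rep.tiebreak == "mean_p"

    def test_full_tie_prefers_smaller_module_id(self):
        membership = {"a": 1, "b": 2}
        probs = probs_frame([("a", "shoot", "c", 0.5), ("b", "shoot", "c", 0.5)])
        rep = call_key_module(probs, partition_from(membership))
        assert rep.key_module == 1 and rep.tiebreak == "module_id"

    def test_exact_threshold_is_not_exceedance(self):
        membership = {"a": 1, "b": 2}
        probs = probs_frame([("a", "shoot", "c", 0.75), ("b", "shoot", "c", 0.2)])
        rep = call_key_module(probs, partition_from(membership), threshold=0.75)
        assert rep.modules["n_exceed"].sum() == 0

    @settings(deadline=None, max_examples=50)
    @given(ps=st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=2, max_size=12
    ))
    def test_exceedance_count_is_strict_threshold(self, ps):
        membership = {f"g{i}": 1 for i in range(len(ps))}
        probs = probs_frame([(f"g{i}", "shoot", "c", p) for i, p in enumerate(ps)])
        rep = call_key_module(probs, partition_from(membership), threshold=0.75)
        assert rep.modules.loc[0, "n_exceed"] == sum(p > 0.75 for p in ps)

    def test_empty_probabilities_rejected(self):
        with pytest.raises(ValueError):
            call_key_module(probs_frame([]), partition_from({"a": 1}))
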