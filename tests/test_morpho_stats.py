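"""Trait summaries, Fisher's LSD with letter display, trait distances."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markerdiv import (
    MarkerdivError,
    TraitEntry,
    MorphoSpec,
    TraitTable,
    ValidationError,
    generate_trait_table,
    lsd_test,
    morpho_distance,
    summarize,
)
from markerdiv.morpho_stats import _letters_from_nonsig, pairwise_t_test


def table_from_groups(groups, trait="plant_height_cm"):
    rows = [
        {"genotype": g, "trait": trait, "replicate": r, "value": v}
        for g, vals in groups.items()
        for r, v in enumerate(vals, start=1)
    ]
    return TraitTable(pd.DataFrame(rows))


class TestSummarize:
    def test_constant_replicates(self):
        t = table_from_groups({"a": (10, 10, 10), "b": (1, 1, 1)})
        s = summarize(t).set_index("genotype")
        assert s.loc["a", "mean"] == 10
        assert s.loc["a", "se"] == 0

    def test_closed_form_se(self):
        t = table_from_groups({"a": (1, 2, 3), "b": (0, 0)})
        s = summarize(t).set_index("genotype")
        assert s.loc["a", "mean"] == 2
        assert s.loc["a", "se"] == pytest.approx(1 / np.sqrt(3))

    def test_invariant_to_record_order(self):
        t = table_from_groups({"a": (1, 2, 3), "b": (4, 5, 6)})
        shuffled = TraitTable(t.records.sample(frac=1, random_state=0))
        lhs = summarize(t).sort_values("genotype").reset_index(drop=True)
        rhs = summarize(shuffled).sort_values("genotype").reset_index(drop=True)
        pd.testing.assert_frame_equal(lhs, rhs)

    def test_single_replicate_flagged(self):
        t = table_from_groups({"a": (1.0,), "b": (1, 2)})
        s = summarize(t).set_index("genotype")
        assert not s.loc["a", "se_defined"]
        assert np.isnan(s.loc["a", "se"])


class TestLsd:
    def test_worked_three_group_example(self, worked_lsd_table):
        # MSE = 1, df_within = 6, t = 2.447, LSD = 2.447 * sqrt(2/3) = 1.998
        res = lsd_test(worked_lsd_table, "plant_height_cm", alpha=0.05)
        assert res.mse == pytest.approx(1.0)
        assert res.df_within == 6
        assert res.lsd_value == pytest.approx(1.998, abs=1e-3)
        assert res.significant.loc["A", "B"] and res.significant.loc["A", "C"]
        assert not res.significant.loc["B", "C"]
        assert res.letters == {"A": "a", "B": "b", "C": "b"}

    def test_identical_groups_share_letter(self):
        t = table_from_groups({"a": (1, 2, 3), "b": (1, 2, 3)})
        res = lsd_test(t, "plant_height_cm")
        assert res.letters["a"] == res.letters["b"]

    def test_zero_variance_equal_means_is_one_letter(self):
        t = table_from_groups({"a": (5, 5, 5), "b": (5, 5, 5)})
        res = lsd_test(t, "plant_height_cm")
        assert set(res.letters.values()) == {"a"}
        assert np.isnan(res.f_stat)

    def test_zero_variance_distinct_means_fully_separated(self):
        t = table_from_groups({"a": (5, 5), "b": (6, 6)})
        res = lsd_test(t, "plant_height_cm")
        assert res.f_stat == np.inf and res.p_value == 0.0
        assert res.letters["a"] != res.letters["b"]

    def test_anova_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(13)
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, 8) for i in range(4)}
        res = lsd_test(table_from_groups(groups), "plant_height_cm")
        ref = stats.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_alpha_warns_and_separates_everything(self):
        t = table_from_groups({"a": (1, 2), "b": (1.1, 2.1), "c": (5, 6)})
        with pytest.warns(UserWarning, match="degenerate"):
            res = lsd_test(t, "plant_height_cm", alpha=1.0)
        assert res.significant.loc["a", "b"]  # any mean gap counts at alpha=1

    def test_input_contracts(self):
        t = table_from_groups({"a": (1, 2, 3)})
        with pytest.raises(MarkerdivError):
            lsd_test(t, "plant_height_cm")
        t2 = table_from_groups({"a": (1, 2), "b": (3.0,)})
        with pytest.raises(ValidationError, match="b"):
            lsd_test(t2, "plant_height_cm")

    def test_distinct_genotype_gets_private_letter(self):
        """A genotype whose mean sits far above all others (>= 10 pooled
        sd) must end up with a letter shared by no other genotype."""
        entries = [
            TraitEntry(genotype=g, trait="n_petals", mean=8.0, sd=1.0, n=10)
            for g in ("red", "yellow", "purple", "orange")
        ] + [TraitEntry(genotype="violet", trait="n_petals", mean=40.0, sd=1.0, n=10)]
        hits = 0
        for seed in range(20):
            t = generate_trait_table(MorphoSpec(entries=tuple(entries), seed=seed))
            res = lsd_test(t, "n_petals")
            violet = set(res.letters["violet"])
            others = set("".join(res.letters[g] for g in res.letters if g != "violet"))
            hits += violet.isdisjoint(others)
        assert hits == 20

    def test_unprotected_lsd_familywise_error_under_null(self):
        """With 5 equal-mean groups the chance of >= 1 false positive lies
        between the per-test alpha and the Sidak bound 1-(1-a)^10."""
        rng = np.random.default_rng(17)
        alpha, reps, hits = 0.05, 400, 0
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(0.0, 1.0, 10) for i in range(5)}
            res = lsd_test(table_from_groups(groups), "plant_height_cm", alpha=alpha)
            hits += res.significant.to_numpy().any()
        frac = hits / reps
        assert alpha < frac < 1 - (1 - alpha) ** 10 + 0.05

    def test_pairwise_t_option_roughly_tracks_lsd(self, worked_lsd_table):
        df = pairwise_t_test(worked_lsd_table, "plant_height_cm")
        sig = {(r.genotype_a, r.genotype_b): r.significant for r in df.itertuples()}
        assert sig[("A", "B")] and sig[("A", "C")] and not sig[("B", "C")]


class TestCompactLetterDisplay:
    def test_reconstruction_on_random_significance_graphs(self):
        """Letter sharing must exactly encode pairwise non-significance."""
        rng = np.random.default_rng(19)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            genotypes = [f"g{i}" for i in range(n)]
            nonsig = nx.Graph()
            nonsig.add_nodes_from(genotypes)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        nonsig.add_edge(genotypes[i], genotypes[j])
            letters = _letters_from_nonsig(genotypes, nonsig)
            for i in range(n):
                for j in range(i + 1, n):
                    share = bool(set(letters[genotypes[i]]) & set(letters[genotypes[j]]))
                    assert share == nonsig.has_edge(genotypes[i], genotypes[j])


class TestMorphoDistance:
    def test_two_genotypes_one_trait_unstandardized(self):
        s = summarize(table_from_groups({"a": (0, 0), "b": (2, 2)}))
        d = morpho_distance(s, standardize=False)
        assert d.pair("a", "b") == pytest.approx(2.0)

    def test_identical_profiles_distance_zero(self):
        t = table_from_groups({"a": (3, 3), "b": (3, 3)})
        d = morpho_distance(summarize(t), standardize=False)
        assert d.pair("a", "b") == 0.0

    def test_hand_computed_three_by_two(self):
        rows = []
        means = {"a": {"t1": 0.0, "t2": 10.0}, "b": {"t1": 1.0, "t2": 20.0},
                 "c": {"t1": 2.0, "t2": 30.0}}
        for g, traits in means.items():
            for trait, mu in traits.items():
                for r in (1, 2):
                    rows.append({"genotype": g, "trait": trait, "replicate": r, "value": mu})
        s = summarize(TraitTable(pd.DataFrame(rows)))
        d = morpho_distance(s, standardize=True)
        # both traits z-score to (-1, 0, 1): d(a,b) = sqrt(2), d(a,c) = 2*sqrt(2)
        assert d.pair("a", "b") == pytest.approx(np.sqrt(2))
        assert d.pair("a", "c") == pytest.approx(2 * np.sqrt(2))

    def test_invariant_to_affine_rescaling_of_one_trait(self):
        rng = np.random.default_rng(23)
        rows = []
        for g in "abcd":
            for trait in ("t1", "t2", "t3"):
                mu = rng.normal(0, 5)
                for r in (1, 2, 3):
                    rows.append(
                        {"genotype": g, "trait": trait, "replicate": r, "value": mu}
                    )
        t = TraitTable(pd.DataFrame(rows))
        base = morpho_distance(summarize(t), standardize=True)
        scaled = t.records.copy()
        mask = scaled["trait"] == "t2"
        scaled.loc[mask, "value"] = scaled.loc[mask, "value"] * 25.4 + 7.0
        rescaled = morpho_distance(summarize(TraitTable(scaled)), standardize=True)
        np.testing.assert_allclose(base.values, rescaled.values, atol=1e-9)

    def test_constant_trait_dropped_with_warning(self):
        rows = []
        for g, v in (("a", 1.0), ("b", 2.0)):
            for trait, val in (("varies", v), ("flat", 5.0)):
                for r in (1, 2):
                    rows.append(
                        {"genotype": g, "trait": trait, "replicate": r, "value": val}
                    )
        s = summarize(TraitTable(pd.DataFrame(rows)))
        with pytest.warns(UserWarning, match="flat"):
            d = morpho_distance(s, standardize=True)
        assert d.pair("a", "b") > 0
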